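"""Shared fixtures: study-condition force fields, grids and a cached
synthetic experiment used by the ensemble-level tests."""

import numpy as np
import pytest

from dmxan.broadening import BroadeningParams
from dmxan.pipeline import PipelineConfig
from dmxan.spectra import default_grid
from dmxan.synthetic import SamplerConfig, make_synthetic_experiment, optimized_ff


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    # 2 eV step keeps the ensemble-fit tests fast; the oscillation structure
    # of the toy model is fully resolved at this spacing
    return default_grid(0.0, 200.0, 2.0)


@pytest.fixture(scope="session")
def truth_ff():
    return optimized_ff()


@pytest.fixture(scope="session")
def truth_broadening():
    return BroadeningParams(gamma_exp=1.5, gamma_core=1.2, e_onset=30.0, amp=3.0)


@pytest.fixture(scope="session")
def coarse_pipeline(coarse_grid, truth_broadening):
    return PipelineConfig(grid=coarse_grid, broadening_init=truth_broadening,
                          fit_maxiter=250, fit_restarts=0)


@pytest.fixture(scope="session")
def synthetic_experiment(truth_ff, truth_broadening, coarse_grid, coarse_pipeline):
    """400-frame, low-noise ground-truth experiment on the coarse grid."""
    exp, gt = make_synthetic_experiment(
        truth_ff, truth_broadening, noise=0.002, n_frames=400, seed=42,
        sampler=SamplerConfig(seed=0, burn_in=3000, stride=50),
        epsilon=0.01, grid=coarse_grid, pipeline_config=coarse_pipeline,
    )
    return exp, gt
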