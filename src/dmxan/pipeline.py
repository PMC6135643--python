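"""Shared ensemble-evaluation path: snapshots -> clusters -> per-frame
spectra -> running average -> inelastic-loss fit.

Used by the windowed R_sq analysis, the refinement loop and the CLI so
every stage evaluates an ensemble in exactly the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from dmxan.broadening import BroadeningParams, STEP_DELTA, fit_nonstructural
from dmxan.forward import ToyModelConfig, get_calculator
from dmxan.spectra import ExperimentalSpectrum, default_grid
from dmxan.stats import EnsembleAverage, FitResult, ensemble_average
from dmxan.structure import Snapshot, select_cluster

__all__ = ["PipelineConfig", "evaluate_average", "evaluate_ensemble"]


@dataclass
class PipelineConfig:
    """Everything between a snapshot list and a fitted R_sq."""

    grid: np.ndarray = field(default_factory=default_grid)
    calculator: str = "toy"
    toy: ToyModelConfig = field(default_factory=ToyModelConfig)
    cluster_size: int = 100
    broadening_init: BroadeningParams = field(default_factory=BroadeningParams)
    n_free: int = 4
    delta: float = STEP_DELTA
    fit_maxiter: int = 400
    fit_restarts: int = 1


def _calculator(cfg: PipelineConfig):
    fn = get_calculator(cfg.calculator)
    if cfg.calculator == "toy":
        return lambda cluster, grid: fn(cluster, grid, cfg.toy)
    return fn


def evaluate_average(frames: Sequence[Snapshot], cfg: PipelineConfig | None = None) -> EnsembleAverage:
    """Configurational average of the per-snapshot raw spectra."""
    cfg = cfg or PipelineConfig()
    calc = _calculator(cfg)
    return ensemble_average(
        calc(select_cluster(f, cfg.cluster_size), cfg.grid) for f in frames
    )


def evaluate_ensemble(
    frames: Sequence[Snapshot],
    exp: ExperimentalSpectrum,
    cfg: PipelineConfig | None = None,
) -> FitResult:
    """Average an ensemble and fit the inelastic losses against experiment."""
    cfg = cfg or PipelineConfig()
    avg = evaluate_average(frames, cfg)
    return fit_nonstructural(
        avg.sigma, exp, cfg.broadening_init, n_free=cfg.n_free,
        delta=cfg.delta, maxiter=cfg.fit_maxiter, restarts=cfg.fit_restarts,
    )
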