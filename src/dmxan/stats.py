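"""Residual statistics of the dynamic-ensemble analysis.

Three statistics quantify the comparison between the ensemble-averaged
theoretical spectrum and experiment:

* ``r_sq`` — the square residual function
  R_sq = n * sum_i w_i [(y_i_th - y_i_exp)/eps_i]^2 / sum_i w_i,
  with n the number of independent fit parameters, the goodness-of-fit
  figure that drives both the inelastic-loss fit and the force-field
  refinement;
* ``f_error`` — the pointwise squared misfit f(E) = (y_th(E) - y_exp(E))^2
  and its cumulative integral, which localises the misfit in energy;
* ``ensemble_average`` / R_f(N) — the L2 distance between successive
  running averages sigma^N and sigma^(N-1), the convergence statistic for
  the number of snapshots entering the average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any, Iterable, Sequence

import numpy as np

from dmxan.spectra import Spectrum, ExperimentalSpectrum

if TYPE_CHECKING:
    from dmxan.broadening import BroadeningParams
    from dmxan.structure import Snapshot

__all__ = [
    "FitResult",
    "EnsembleAverage",
    "ConvergenceReport",
    "WindowedRsqResult",
    "r_sq",
    "f_error",
    "ensemble_average",
    "check_convergence",
    "windowed_rsq",
]


@dataclass
class FitResult:
    """Outcome of a non-structural (inelastic-loss) fit."""

    r_sq: float
    broadening: "BroadeningParams"
    f_curve: np.ndarray
    f_integral: np.ndarray
    n_used: int
    m_used: int
    energies: np.ndarray | None = None
    n_iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.r_sq < 0:
            raise ValueError("R_sq must be >= 0")
        if np.any(self.f_curve < 0):
            raise ValueError("f(E) must be pointwise >= 0")
        if np.any(np.diff(self.f_integral) < -1e-15):
            raise ValueError("cumulative f(E) integral must be non-decreasing")

    def to_dict(self) -> dict[str, Any]:
        b = self.broadening
        return {
            "r_sq": self.r_sq,
            "gamma_exp": b.gamma_exp,
            "gamma_core": b.gamma_core,
            "e_onset": b.e_onset,
            "amp": b.amp,
            "n_used": self.n_used,
            "m_used": self.m_used,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


@dataclass
class EnsembleAverage:
    """Running configurational average sigma^N with its R_f(N) history.

    ``rf_history[j]`` holds R_f(N = j + 2): the first entry compares the
    two-frame average with the single first frame.
    """

    sigma: Spectrum
    n_frames: int
    rf_history: np.ndarray


def r_sq(y_th, exp: ExperimentalSpectrum, n: int = 1) -> float:
    """Square residual R_sq = n * sum w_i [(y_th - y_exp)/eps_i]^2 / sum w_i."""
    y_th = np.asarray(y_th, dtype=float)
    if y_th.size == 0:
        raise ValueError("empty spectra: m must be >= 1")
    if y_th.shape != exp.values.shape:
        raise ValueError(f"length mismatch: theory {y_th.size}, experiment {len(exp)}")
    if n < 1:
        raise ValueError("n (number of independent parameters) must be >= 1")
    z = (y_th - exp.values) / exp.epsilon
    return float(n * np.sum(exp.weights * z**2) / np.sum(exp.weights))


def f_error(y_th, y_exp, energies=None) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise squared misfit f(E) and its cumulative trapezoidal integral.

    With ``energies`` omitted a unit grid spacing is assumed.  The integral
    is in (normalized absorption)^2 * eV area units and starts at 0.
    """
    y_th = np.asarray(y_th, dtype=float)
    y_exp = np.asarray(y_exp, dtype=float)
    if y_th.shape != y_exp.shape:
        raise ValueError("f_error requires equal-length curves")
    curve = (y_th - y_exp) ** 2
    x = np.arange(curve.size, dtype=float) if energies is None else np.asarray(energies, float)
    integral = np.concatenate([[0.0], np.cumsum(0.5 * (curve[1:] + curve[:-1]) * np.diff(x))])
    return curve, integral


def ensemble_average(spectra: Iterable[Spectrum]) -> EnsembleAverage:
    """Streaming mean of per-snapshot spectra with the R_f(N) convergence trace.

    R_f(N) = [sum_i (sigma^N(E_i) - sigma^(N-1)(E_i))^2]^(1/2), recorded for
    every N >= 2.  All spectra must share one energy grid.
    """
    sigma = None
    grid = None
    n = 0
    rf: list[float] = []
    for spec in spectra:
        n += 1
        if sigma is None:
            grid = spec.energies
            sigma = spec.values.astype(float).copy()
            continue
        if spec.energies.shape != grid.shape or not np.allclose(spec.energies, grid):
            raise ValueError(f"frame {n} is on a different energy grid")
        new = sigma + (spec.values - sigma) / n
        rf.append(float(np.sqrt(np.sum((new - sigma) ** 2))))
        sigma = new
    if sigma is None:
        raise ValueError("ensemble_average requires at least one spectrum")
    return EnsembleAverage(Spectrum(grid.copy(), sigma, {"n_frames": n}),
                           n, np.asarray(rf))


@dataclass
class ConvergenceReport:
    converged: bool
    first_pass: int | None
    threshold: float
    after: int


def check_convergence(avg: EnsembleAverage, threshold: float, after: int = 2) -> ConvergenceReport:
    """True iff R_f(N) < threshold for every N >= ``after``.

    ``first_pass`` is the smallest N from which R_f stays below the
    threshold for good (None if it never does).
    """
    if avg.n_frames < after:
        raise ValueError(f"rf history covers N <= {avg.n_frames} < after={after}")
    rf = avg.rf_history  # entry j is R_f(j + 2)
    below = rf < threshold
    first = None
    for j in range(below.size - 1, -1, -1):
        if not below[j]:
            break
        first = j + 2
    converged = first is not None and first <= after
    return ConvergenceReport(converged, first, threshold, after)


@dataclass
class WindowedRsqResult:
    """Per-window R_sq series from contiguous non-overlapping time windows."""

    starts: np.ndarray  # ps
    ends: np.ndarray  # ps
    r_sq: np.ndarray
    fits: list[FitResult] = field(default_factory=list)
    n_frames: np.ndarray | None = None

    @property
    def best(self) -> int:
        return int(np.argmin(self.r_sq))

    @property
    def worst(self) -> int:
        return int(np.argmax(self.r_sq))

    def to_frame(self):
        import pandas as pd

        rows = {"t_start_ps": self.starts, "t_end_ps": self.ends, "r_sq": self.r_sq}
        if self.n_frames is not None:
            rows["n_frames"] = self.n_frames
        for name in ("gamma_exp", "gamma_core", "e_onset", "amp"):
            rows[name + "_eV"] = [getattr(f.broadening, name) for f in self.fits]
        return pd.DataFrame(rows)


def windowed_rsq(
    frames: Sequence["Snapshot"],
    window: float,
    exp: ExperimentalSpectrum,
    config=None,
    discard_first: bool = False,
) -> WindowedRsqResult:
    """R_sq of the full averaging + inelastic-loss fit in time windows.

    Frames are partitioned into contiguous, non-overlapping, left-aligned
    windows of ``window`` ps starting at the first frame time; each window
    is averaged and fitted independently.  ``discard_first`` drops the
    first window (equilibration).
    """
    from dmxan.pipeline import PipelineConfig, evaluate_ensemble

    config = config or PipelineConfig()
    times = np.array([f.time for f in frames])
    if times.size < 2:
        raise ValueError("windowed analysis needs at least two frames")
    spacing = np.min(np.diff(np.unique(times)))
    if window < spacing:
        raise ValueError(f"window {window} ps smaller than frame spacing {spacing} ps")
    # span counts one frame spacing so that N frames at spacing dt fill
    # exactly N*dt; a window equal to the full span yields one window
    duration = times[-1] - times[0] + spacing
    if duration < window - 1e-9:
        raise ValueError(f"total duration {duration} ps shorter than window {window} ps")
    idx = np.floor((times - times[0]) / window + 1e-9).astype(int)
    groups = sorted(set(idx))
    if discard_first and len(groups) > 1:
        groups = groups[1:]
    starts, ends, vals, fits, counts = [], [], [], [], []
    for g in groups:
        sub = [f for f, j in zip(frames, idx) if j == g]
        fit = evaluate_ensemble(sub, exp, config)
        starts.append(times[0] + g * window)
        ends.append(times[0] + (g + 1) * window)
        vals.append(fit.r_sq)
        fits.append(fit)
        counts.append(len(sub))
    return WindowedRsqResult(np.array(starts), np.array(ends), np.array(vals),
                             fits, np.array(counts))
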