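"""Inelastic-loss broadening and the fit of its non-structural parameters.

The ensemble-averaged raw spectrum is compared to experiment after applying
the losses a measured near-edge spectrum contains: the finite 1s core-hole
lifetime, plasmon excitation switching on above an energy onset, and the
instrumental resolution.  The first two are Lorentzian in character with an
energy-dependent width

    Gamma_L(E) = gamma_core + amp * [1/2 + (1/pi) arctan((E - e_onset)/delta)],

a smooth step of fixed width ``delta`` (default 5 eV); the instrumental
term is a Gaussian of FWHM ``gamma_exp``.  Splitting the constant width
into a Lorentzian lifetime part and a Gaussian experimental part keeps the
two separately identifiable in the fit — a pure-Lorentzian sum would leave
only gamma_core + gamma_exp determined.  ``gamma_of_E`` reports the total
effective width including both constants.

These four parameters are the only quantities fitted in the
dynamic-ensemble analysis; structural information enters solely through the
ensemble itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import erf

from dmxan.spectra import Spectrum, ExperimentalSpectrum, resample
from dmxan.stats import FitResult, r_sq, f_error

__all__ = [
    "BroadeningParams",
    "gamma_of_E",
    "lorentzian_width",
    "convolve",
    "fit_nonstructural",
]

STEP_DELTA = 5.0  # eV, fixed width of the plasmon smooth step
PAD_EV = 50.0  # default zero-padding on each side before convolution


@dataclass(frozen=True)
class BroadeningParams:
    """Non-structural (inelastic-loss) parameters, all in eV, all >= 0.

    gamma_exp : instrumental (experimental) broadening, Gaussian FWHM.
    gamma_core : core-hole lifetime width, Lorentzian FWHM.
    e_onset : plasmon energy onset E_s.
    amp : plasmon amplitude A_s, extra Lorentzian width far above onset.
    """

    gamma_exp: float = 1.0
    gamma_core: float = 1.25
    e_onset: float = 30.0
    amp: float = 2.0

    def __post_init__(self) -> None:
        for name in ("gamma_exp", "gamma_core", "e_onset", "amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma_exp, self.gamma_core, self.e_onset, self.amp])

    @classmethod
    def from_array(cls, x) -> "BroadeningParams":
        return cls(*(float(v) for v in x))


def _step(E, e_onset: float, delta: float) -> np.ndarray:
    return 0.5 + np.arctan((np.asarray(E, dtype=float) - e_onset) / delta) / np.pi


def lorentzian_width(E, p: BroadeningParams, delta: float = STEP_DELTA) -> np.ndarray:
    """Energy-dependent Lorentzian FWHM: lifetime plus plasmon step (eV)."""
    return p.gamma_core + p.amp * _step(E, p.e_onset, delta)


def gamma_of_E(E, p: BroadeningParams, delta: float = STEP_DELTA) -> np.ndarray:
    """Total effective broadening width (eV) at energy E.

    Tends to gamma_core + gamma_exp far below the plasmon onset and to
    gamma_core + gamma_exp + amp far above; equals the midpoint
    gamma_core + gamma_exp + amp/2 at E = e_onset.
    """
    return p.gamma_exp + lorentzian_width(E, p, delta)


def _lorentz_bin_kernel(e_out: np.ndarray, e_src: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """K[i, s]: mass of a unit Lorentzian centred at e_src[s] (FWHM widths[s])
    integrated over the output bin around e_out[i]; columns renormalised so
    each source bin spreads exactly unit mass over the padded grid."""
    h = e_out[1] - e_out[0]
    x = e_out[:, None] - e_src[None, :]
    hw = np.maximum(widths[None, :], 1e-12) / 2.0
    cdf_hi = np.arctan((x + h / 2) / hw) / np.pi
    cdf_lo = np.arctan((x - h / 2) / hw) / np.pi
    K = cdf_hi - cdf_lo
    return K / K.sum(axis=0, keepdims=True)


def _gauss_bin_kernel(e_out: np.ndarray, fwhm: float) -> np.ndarray:
    h = e_out[1] - e_out[0]
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    x = e_out[:, None] - e_out[None, :]
    z = 1.0 / (sigma * np.sqrt(2.0))
    K = 0.5 * (erf((x + h / 2) * z) - erf((x - h / 2) * z))
    return K / K.sum(axis=0, keepdims=True)


def convolve(
    raw: Spectrum,
    p: BroadeningParams,
    delta: float = STEP_DELTA,
    pad: float = PAD_EV,
) -> Spectrum:
    """Apply the inelastic-loss broadening to a uniform-grid spectrum.

    The spectrum is zero-padded by ``pad`` eV on both sides, convolved with
    the unit-area energy-dependent Lorentzian (width evaluated at the
    source energy) and, if gamma_exp > 0, with the instrumental Gaussian,
    then trimmed back to the input grid.  Kernels are bin-integrated so
    that each source bin spreads exactly its own mass.
    """
    if not raw.is_uniform():
        raise ValueError("convolve requires a uniform energy grid; resample first")
    h = raw.energies[1] - raw.energies[0]
    n_pad = int(np.ceil(pad / h))
    e = np.concatenate([
        raw.energies[0] + h * np.arange(-n_pad, 0),
        raw.energies,
        raw.energies[-1] + h * np.arange(1, n_pad + 1),
    ])
    y = np.concatenate([np.zeros(n_pad), raw.values, np.zeros(n_pad)])

    widths = np.asarray(lorentzian_width(e, p, delta), dtype=float)
    if np.any(widths > 1e-9):
        y = _lorentz_bin_kernel(e, e, widths) @ y
    if p.gamma_exp > 1e-9:
        y = _gauss_bin_kernel(e, p.gamma_exp) @ y
    out = y[n_pad:n_pad + len(raw)]
    meta = dict(raw.meta)
    meta["broadening"] = p
    return Spectrum(raw.energies.copy(), out, meta)


def fit_nonstructural(
    avg: Spectrum,
    exp: ExperimentalSpectrum,
    init: BroadeningParams | None = None,
    n_free: int = 4,
    delta: float = STEP_DELTA,
    maxiter: int = 800,
    restarts: int = 1,
) -> FitResult:
    """Fit the four inelastic-loss parameters by simplex minimisation of R_sq.

    The averaged raw spectrum is broadened, interpolated onto the
    experimental grid over the overlap range, and compared through R_sq
    with ``n_free`` independent parameters (4 when all of gamma_exp,
    gamma_core, e_onset and amp are free).  Non-negativity is enforced by
    reflection (the objective sees |x|).  Deterministic given ``init``.
    """
    init = init or BroadeningParams()
    mask = (exp.energies >= avg.energies[0]) & (exp.energies <= avg.energies[-1])
    if not np.any(mask):
        raise ValueError("experimental and theoretical grids do not overlap")
    e_exp = exp.energies[mask]
    y_exp = exp.values[mask]
    w = exp.weights[mask]
    eps = exp.epsilon if np.ndim(exp.epsilon) == 0 else exp.epsilon[mask]
    sub = ExperimentalSpectrum(e_exp, y_exp, eps, w)

    def predict(p: BroadeningParams) -> np.ndarray:
        conv = convolve(avg, p, delta=delta)
        return np.interp(e_exp, conv.energies, conv.values)

    def objective(x: np.ndarray) -> float:
        p = BroadeningParams.from_array(np.abs(x))
        val = r_sq(predict(p), sub, n_free)
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite R_sq at parameter vector {x!r}")
        return val

    x = init.as_array()
    nit = 0
    for _ in range(restarts + 1):
        res = minimize(objective, x, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-10})
        x = res.x
        nit += res.nit
    best = BroadeningParams.from_array(np.abs(x))
    y_th = predict(best)
    curve, integral = f_error(y_th, y_exp, e_exp)
    return FitResult(
        r_sq=float(objective(x)),
        broadening=best,
        f_curve=curve,
        f_integral=integral,
        n_used=n_free,
        m_used=int(e_exp.size),
        energies=e_exp.copy(),
        n_iterations=nit,
        converged=bool(res.success),
    )
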