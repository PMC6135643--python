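"""Spectrum containers, plain-text I/O and grid resampling.

Energies are in eV relative to the absorption edge (edge = 0); absorption
values are normalized and dimensionless.  The default analysis grid spans
0–200 eV in 1 eV steps, the energy range over which near-edge fits are
typically carried out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "Spectrum",
    "ExperimentalSpectrum",
    "default_grid",
    "read_spectrum",
    "write_spectrum",
    "resample",
]


def default_grid(e_min: float = 0.0, e_max: float = 200.0, step: float = 1.0) -> np.ndarray:
    """Uniform analysis grid in eV relative to the edge."""
    n = int(round((e_max - e_min) / step)) + 1
    return e_min + step * np.arange(n)


def _validate_energies(energies: np.ndarray) -> None:
    if energies.ndim != 1 or energies.size == 0:
        raise ValueError("energies must be a non-empty 1-D array")
    if not np.all(np.isfinite(energies)):
        raise ValueError("energies must be finite")
    if np.any(np.diff(energies) <= 0):
        bad = int(np.argmax(np.diff(energies) <= 0))
        raise ValueError(
            f"energies must be strictly increasing (violation after index {bad}: "
            f"{energies[bad]} -> {energies[bad + 1]})"
        )


@dataclass
class Spectrum:
    """A theoretical absorption curve on an energy grid.

    Parameters
    ----------
    energies : array of eV relative to the edge, strictly increasing.
    values : normalized absorption, same length, all finite.
    meta : free-form provenance tags (calculator name, seeds, ...).
    """

    energies: np.ndarray
    values: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _validate_energies(self.energies)
        if self.values.shape != self.energies.shape:
            raise ValueError(
                f"values length {self.values.size} != energies length {self.energies.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.energies.size

    def is_uniform(self, rtol: float = 1e-9) -> bool:
        d = np.diff(self.energies)
        return bool(np.all(np.abs(d - d[0]) <= rtol * abs(d[0])))


@dataclass
class ExperimentalSpectrum:
    """An experimental absorption curve with a constant per-point error.

    The per-point error ``epsilon`` is a single positive scalar applied to
    every point (the convention for normalized near-edge data); the
    statistical weights default to 1.
    """

    energies: np.ndarray
    values: np.ndarray
    epsilon: float | np.ndarray
    weights: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _validate_energies(self.energies)
        if self.values.shape != self.energies.shape:
            raise ValueError("values and energies must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if np.ndim(self.epsilon) == 0:
            if not float(self.epsilon) > 0:
                raise ValueError(f"epsilon must be positive, got {self.epsilon!r}")
            self.epsilon = float(self.epsilon)
        else:
            self.epsilon = np.asarray(self.epsilon, dtype=float)
            if self.epsilon.shape != self.values.shape:
                raise ValueError("per-point epsilon must match values in length")
            if not np.all(self.epsilon > 0):
                raise ValueError("all per-point errors must be positive")
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights must match values in length")
            if np.any(self.weights < 0) or not np.any(self.weights > 0):
                raise ValueError("weights must be >= 0 with at least one positive entry")

    def __len__(self) -> int:
        return self.energies.size

    def as_spectrum(self) -> Spectrum:
        return Spectrum(self.energies.copy(), self.values.copy(), dict(self.meta))


_SPLIT = re.compile(r"[,\s]+")


def read_spectrum(
    path,
    epsilon_default: float = 0.01,
    constant_epsilon: bool = True,
) -> ExperimentalSpectrum:
    """Read a 2- or 3-column plain-text spectrum (energy, value[, error]).

    Columns may be separated by whitespace or commas; lines starting with
    '#' are comments.  A third column carries per-point errors; by default
    these are collapsed to their arithmetic mean so that a single constant
    error applies to the whole data set, which is the usual convention for
    normalized near-edge data.  ``constant_epsilon=False`` keeps the column
    as per-point errors instead.  Without a third column ``epsilon_default``
    is used.

    Raises
    ------
    ValueError
        on non-numeric rows (with the offending line number) or on a
        non-monotone energy column.
    """
    energies: list[float] = []
    values: list[float] = []
    errors: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = [p for p in _SPLIT.split(text) if p]
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value in {parts!r}") from exc
            energies.append(row[0])
            values.append(row[1])
            if len(row) == 3:
                errors.append(row[2])
    if not energies:
        raise ValueError(f"{path}: no data rows found")
    if errors and len(errors) != len(energies):
        raise ValueError(f"{path}: error column present on only some rows")

    if errors:
        eps = float(np.mean(errors)) if constant_epsilon else np.array(errors)
    else:
        eps = float(epsilon_default)
    return ExperimentalSpectrum(np.array(energies), np.array(values), eps, meta={"source": str(path)})


def write_spectrum(spec: Spectrum | ExperimentalSpectrum, path, header: str | None = None) -> None:
    """Write a spectrum as whitespace-separated columns with a '#' header."""
    with open(path, "w") as fh:
        fh.write(f"# {header or 'energy_eV  normalized_absorption'}\n")
        if isinstance(spec, ExperimentalSpectrum):
            eps = np.broadcast_to(spec.epsilon, spec.values.shape)
            for e, v, s in zip(spec.energies, spec.values, eps):
                fh.write(f"{float(e)!r} {float(v)!r} {float(s)!r}\n")
        else:
            for e, v in zip(spec.energies, spec.values):
                fh.write(f"{float(e)!r} {float(v)!r}\n")


def resample(spec: Spectrum, grid) -> Spectrum:
    """Linearly interpolate ``spec`` onto a target energy grid.

    The target grid must lie within the source range; extrapolation is an
    error naming the offending energy.  Endpoints are reproduced exactly.
    """
    grid = np.asarray(grid, dtype=float)
    _validate_energies(grid)
    lo, hi = spec.energies[0], spec.energies[-1]
    if grid[0] < lo or grid[-1] > hi:
        bad = grid[0] if grid[0] < lo else grid[-1]
        raise ValueError(
            f"resample target energy {bad} eV outside source range [{lo}, {hi}] eV"
        )
    vals = np.interp(grid, spec.energies, spec.values)
    return Spectrum(grid, vals, dict(spec.meta))
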