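"""Residual-driven force-field refinement and ensemble comparison.

The refinement emulates the iterative procedure used to optimise bonded
parameters against a measured near-edge spectrum: propose a change to one
parameter, regenerate the ensemble, average, fit the inelastic losses, and
keep the change only if the square residual R_sq strictly decreases.  Here
the procedure is automated as greedy coordinate descent with step halving;
the refinable set is bond equilibrium lengths r0 and angle force constants
and equilibrium values (partial charges are deliberately excluded — they
come from electronic-structure calculations, not from residual descent).

Parameters are addressed by name strings:

    ``bond:FE-C_CO:r0``        Fe-C equilibrium length (Å)
    ``angle:FE-C_CO-O_CO:k``   Fe-C-O bending constant (kcal/mol/rad^2)
    ``angle:N_HIS-FE-C_CO:theta0``  equilibrium angle (degrees)
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from dmxan.pipeline import PipelineConfig, evaluate_ensemble
from dmxan.spectra import ExperimentalSpectrum
from dmxan.stats import FitResult
from dmxan.synthetic import Angle, Bond, ForceFieldParams, SamplerConfig, build_site_model, sample_ensemble

log = logging.getLogger(__name__)

__all__ = [
    "RefineConfig",
    "RefineStep",
    "RefinementTrace",
    "get_param",
    "set_param",
    "propose_moves",
    "refine_loop",
    "compare_ensembles",
    "write_topology_fragment",
]


# ---------------------------------------------------------------------------
# parameter addressing

def _parse(name: str):
    kind, labels, attr = name.split(":")
    labs = tuple(labels.split("-"))
    if kind == "bond":
        if len(labs) != 2 or attr != "r0":
            raise KeyError(f"refinable bond parameters are 'bond:A-B:r0'; got {name!r}")
    elif kind == "angle":
        if len(labs) != 3 or attr not in ("k", "theta0"):
            raise KeyError(
                f"refinable angle parameters are 'angle:A-B-C:k' or ':theta0'; got {name!r}")
    else:
        raise KeyError(f"unknown parameter kind in {name!r}")
    return kind, labs, attr


def get_param(ff: ForceFieldParams, name: str) -> float:
    kind, labs, attr = _parse(name)
    if kind == "bond":
        return ff.bond(*labs).r0
    a = ff.angle(*labs)
    return a.k_theta if attr == "k" else a.theta0


def set_param(ff: ForceFieldParams, name: str, value: float) -> ForceFieldParams:
    """Return a new parameter set with one named parameter replaced."""
    kind, labs, attr = _parse(name)
    if kind == "bond":
        target = ff.bond(*labs)
        bonds = [replace(b, r0=float(value)) if b is target else b for b in ff.bonds]
        return replace(ff, bonds=bonds)
    target = ff.angle(*labs)
    kw = {"k_theta": float(value)} if attr == "k" else {"theta0": float(value)}
    angles = [replace(a, **kw) if a is target else a for a in ff.angles]
    return replace(ff, angles=angles)


def _is_physical(name: str, value: float) -> bool:
    kind, _, attr = _parse(name)
    if attr == "theta0":
        return 0.0 < value <= 180.0
    return value > 0.0


def propose_moves(ff: ForceFieldParams, step_table: dict[str, float]):
    """Two candidates (+step, -step) per listed parameter, others fixed.

    Candidates that would leave the physical range (r0 <= 0, k <= 0,
    theta0 outside (0, 180]) are skipped with a log entry.  Order is
    deterministic: table order, +step before -step.
    """
    candidates = []
    for name, step in step_table.items():
        base = get_param(ff, name)
        for sign in (+1.0, -1.0):
            value = base + sign * step
            if not _is_physical(name, value):
                log.info("skipping unphysical candidate %s = %g", name, value)
                continue
            candidates.append((name, value, set_param(ff, name, value)))
    return candidates


# ---------------------------------------------------------------------------
# refinement loop

@dataclass
class RefineConfig:
    step_table: dict[str, float] = field(
        default_factory=lambda: {"bond:FE-C_CO:r0": 0.05, "bond:FE-N_HIS:r0": 0.05})
    step_floor: dict[str, float] = field(default_factory=dict)
    default_floor_r0: float = 0.005  # Å
    default_floor_k: float = 0.2  # kcal/mol/rad^2 (also used for theta0, degrees)
    shrink: float = 0.5
    max_rounds: int = 50
    seed: int = 0
    common_random_numbers: bool = True
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(n_steps=1200, burn_in=1500, stride=10))
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def floor(self, name: str) -> float:
        if name in self.step_floor:
            return self.step_floor[name]
        kind, _, attr = _parse(name)
        return self.default_floor_r0 if (kind, attr) == ("bond", "r0") else self.default_floor_k


@dataclass
class RefineStep:
    parameter: str
    proposed: float
    r_sq_before: float
    r_sq_after: float
    accepted: bool
    seed: int


@dataclass
class RefinementTrace:
    steps: list[RefineStep]
    final: ForceFieldParams
    final_r_sq: float
    initial_r_sq: float
    n_evaluations: int

    def __post_init__(self) -> None:
        for s in self.steps:
            if s.accepted and not s.r_sq_after < s.r_sq_before:
                raise ValueError("accepted step must strictly lower R_sq")


def _eval_seed(master: int, round_idx: int, cand_idx: int, crn: bool) -> int:
    tag = f"{master}:{round_idx}" if crn else f"{master}:{round_idx}:{cand_idx}"
    return int.from_bytes(hashlib.sha256(tag.encode()).digest()[:4], "big") % (2**31)


def _evaluate(ff: ForceFieldParams, exp: ExperimentalSpectrum, cfg: RefineConfig,
              seed: int) -> FitResult:
    sampler = replace(cfg.sampler, seed=seed)
    frames = sample_ensemble(build_site_model(ff), ff, sampler)
    return evaluate_ensemble(frames, exp, cfg.pipeline)


def refine_loop(start: ForceFieldParams, exp: ExperimentalSpectrum,
                cfg: RefineConfig | None = None) -> RefinementTrace:
    """Greedy coordinate descent on the force-field parameters.

    Each round evaluates every +/-step candidate with a freshly sampled
    (seeded) ensemble and accepts the best strictly improving one; when no
    candidate improves, all steps are halved; the loop stops when every
    step is below its floor or ``max_rounds`` is reached.  With
    ``common_random_numbers`` the baseline and all candidates of a round
    share one sampler seed, so candidates differ only through the
    parameters — the R_sq comparison is then deterministic given the
    master seed.
    """
    cfg = cfg or RefineConfig()
    steps = dict(cfg.step_table)
    current = start
    trace: list[RefineStep] = []
    n_eval = 0
    crn = cfg.common_random_numbers

    seed0 = _eval_seed(cfg.seed, 0, 0, True)
    initial_r_sq = _evaluate(current, exp, cfg, seed0).r_sq
    n_eval += 1
    current_r_sq = initial_r_sq

    for rnd in range(1, cfg.max_rounds + 1):
        if all(steps[name] < cfg.floor(name) for name in steps):
            break
        if crn:
            # one seed for the whole run: the baseline is the current value
            # and every acceptance strictly lowers R_sq at that seed
            round_seed, baseline = seed0, current_r_sq
        else:
            round_seed = _eval_seed(cfg.seed, rnd, 0, False)
            baseline = _evaluate(current, exp, cfg, round_seed).r_sq
            n_eval += 1
        best = None
        for ci, (name, value, cand_ff) in enumerate(propose_moves(current, steps)):
            seed = round_seed if crn else _eval_seed(cfg.seed, rnd, ci + 1, False)
            try:
                r = _evaluate(cand_ff, exp, cfg, seed).r_sq
            except (FloatingPointError, ValueError) as exc:
                log.warning("candidate %s=%g failed evaluation: %s", name, value, exc)
                trace.append(RefineStep(name, value, baseline, float("inf"), False, seed))
                n_eval += 1
                continue
            n_eval += 1
            trace.append(RefineStep(name, value, baseline, r, False, seed))
            if r < baseline and (best is None or r < best[0]):
                best = (r, name, value, cand_ff, len(trace) - 1)
        if best is None:
            steps = {k: v * cfg.shrink for k, v in steps.items()}
            log.info("round %d: no improvement; steps halved to %s", rnd, steps)
            continue
        r, name, value, cand_ff, ti = best
        trace[ti] = replace(trace[ti], accepted=True)
        current, current_r_sq = cand_ff, r
        log.info("round %d: accepted %s = %g (R_sq %.4g -> %.4g)",
                 rnd, name, value, baseline, r)

    return RefinementTrace(trace, current, current_r_sq, initial_r_sq, n_eval)


def compare_ensembles(ff_a: ForceFieldParams, ff_b: ForceFieldParams,
                      exp: ExperimentalSpectrum, cfg: RefineConfig | None = None,
                      seed: int | None = None) -> tuple[FitResult, FitResult]:
    """Evaluate two parameter sets against one experiment with identical
    seeds and grids; returns the paired fits (R_sq plus integrated f(E))."""
    cfg = cfg or RefineConfig()
    s = cfg.seed if seed is None else seed
    fit_a = _evaluate(ff_a, exp, cfg, s)
    fit_b = _evaluate(ff_b, exp, cfg, s)
    return fit_a, fit_b


# ---------------------------------------------------------------------------
# topology export

_ATOM_TYPES = {"FE": "FE", "N_HIS": "NR2", "C_CO": "CM", "O_CO": "OM",
               "N_PYR1": "NPH", "N_PYR2": "NPH", "N_PYR3": "NPH", "N_PYR4": "NPH"}
KCAL_TO_KJ = 4.184


def write_topology_fragment(ff: ForceFieldParams, path) -> None:
    """Emit a GROMACS-topology-style fragment of the site model.

    Units follow the GROMACS convention: nm for lengths (Å / 10), kJ/mol
    for energies (kcal x 4.184), bond constants in kJ/mol/nm^2 (x 418.4),
    angle constants in kJ/mol/rad^2.  GROMACS harmonic terms carry the 1/2
    factor, so half-k constants convert by the energy factor alone;
    no-half-k (CHARMM-style) constants are doubled first.
    """
    conv = 2.0 if not ff.half_k else 1.0
    lines = [
        "; harmonic heme-site fragment (synthetic model)",
        f"; total charge = {ff.total_charge:+.4f} e "
        f"(sum of [atoms] charges = {sum(ff.charges.values()):+.4f} e)",
        "; lengths nm, energies kJ/mol; V_bond = 1/2 kb (b - b0)^2, "
        "V_angle = 1/2 kth (th - th0)^2",
        "",
        "[ atoms ]",
        ";  nr  type  resnr  residue  atom  cgnr     charge",
    ]
    order = list(ff.charges) or list(_ATOM_TYPES)
    for i, lab in enumerate(order, start=1):
        if lab not in _ATOM_TYPES:
            raise ValueError(f"cannot map site label {lab!r} to an atom type")
        q = ff.charges.get(lab, 0.0)
        lines.append(f"{i:5d}  {_ATOM_TYPES[lab]:<4s}  1      HEM      "
                     f"{lab:<7s}{i:4d}  {q:9.4f}")
    idx = {lab: i + 1 for i, lab in enumerate(order)}
    lines += ["", "[ bonds ]", ";  ai  aj  func      b0_nm        kb"]
    for b in ff.bonds:
        ai, aj = (idx.get(l, 0) for l in b.labels)
        kb = conv * b.k_b * KCAL_TO_KJ * 100.0
        lines.append(f"{ai:5d}{aj:5d}  1    {b.r0 / 10.0:9.4f}  {kb:11.2f}")
    lines += ["", "[ angles ]", ";  ai  aj  ak  func   th0_deg       cth"]
    for a in ff.angles:
        ai, aj, ak = (idx.get(l, 0) for l in a.labels)
        cth = conv * a.k_theta * KCAL_TO_KJ
        lines.append(f"{ai:5d}{aj:5d}{ak:5d}  1   {a.theta0:8.2f}  {cth:9.2f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
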