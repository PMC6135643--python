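# Methods

## Overview

`dmxan` implements the dynamic-ensemble variant of quantitative near-edge
X-ray absorption (XANES) analysis: instead of fitting structural parameters
of a single static geometry to an experimental spectrum, a whole snapshot
ensemble — here produced by a Monte-Carlo surrogate of molecular dynamics —
is converted frame by frame into theoretical spectra, averaged, broadened
by inelastic losses, and compared to experiment through a square-residual
statistic.  The residual then drives refinement of the bonded force-field
parameters that generated the ensemble.  The target system is the heme
Fe site of carboxy-myoglobin (Fe coordinated by four pyrrole nitrogens,
the proximal-histidine nitrogen, and a bound CO), but every component is
generic over the absorber-centred cluster it receives.

The pipeline is

    force field -> Metropolis ensemble -> per-frame cluster (<= 100 nearest
    atoms around Fe) -> per-frame raw spectrum -> running average sigma^N
    -> inelastic-loss convolution -> R_sq against experiment

with only the four inelastic-loss parameters fitted; all structural
content enters through the ensemble.

## Residual statistics

* `R_sq = n * sum_i w_i [(y_i_th - y_i_exp)/eps_i]^2 / sum_i w_i`, with `n`
  the number of independent fit parameters (4 in ensemble fits, where only
  the losses are free), `w_i = 1` by default and a constant per-point error
  `eps`.  The constant-error convention is enforced at file read (a
  three-column input's error column is collapsed to its mean) but per-point
  errors can be kept by flag.
* `f(E) = (y_th(E) - y_exp(E))^2` with its cumulative trapezoidal
  integral, used to localise misfit in energy and to compare two fits
  whose R_sq differ by little.
* `R_f(N) = ||sigma^N - sigma^(N-1)||_2`, the distance between successive
  running averages, as the ensemble-size convergence statistic.  For iid
  frames it decays as C/N (the suite verifies log-log slope -1 +/- 0.1);
  the convergence threshold is a configuration value because its absolute
  scale depends on the cross-section units in use.

## Forward model

The full multiple-scattering engines used in production XANES work are out
of scope here; the package ships a pluggable calculator registry with the
contract `(Cluster, energy grid) -> Spectrum` and one registered `toy`
calculator.  The toy model is an arctan edge step `mu0(E) = 1/2 +
arctan(E/Gamma0)/pi` dressed with EXAFS-like single-scattering
oscillations per neighbour,

    chi_j(E) = A (Z_j/Z_Fe) F_j sin(2 k r_j + a + b k) e^(-2 r_j/lambda) / (k r_j^2),

with free-electron dispersion `k = 0.5123 sqrt(E)` 1/Å, plus a
forward-focusing factor `F_j = 1 + g exp(-(pi - beta_j)^2 / 2 w^2)` applied
to atoms sitting behind a first-shell neighbour (the Fe–C–O collinear
geometry), where `beta_j` is the absorber–bridge–atom angle.  Defaults:
`Gamma0 = 2 eV`, `lambda = 8 Å`, `A = 0.4`, `a = 0`, `b = -0.35 rad·Å`,
`g = 2`, `w = 0.3 rad`, first shell within 2.6 Å.

This is a structural stand-in, not a near-edge theory: it exists so that
the four geometric quantities the refinement targets (Fe–C, Fe–N_His, C–O
lengths and the Fe–C–O angle) all imprint on the curve, preserving the
structure of the inference problem.  It depends only on distances and
internal angles (hence is rigid-motion invariant), and a 0.01 Å bond
change produces a detectable spectral change (verified as a nonzero L2
difference) — the non-degeneracy the refinement needs.  Conclusions about
real spectra require a real scattering engine plugged into the registry.

## Inelastic losses

The measured spectrum contains the 1s core-hole lifetime, plasmon losses
switching on above an onset, and instrumental resolution.  These are
modelled as an energy-dependent Lorentzian FWHM

    Gamma_L(E) = gamma_core + amp * [1/2 + arctan((E - e_onset)/delta)/pi]

with a fixed smooth-step width `delta = 5 eV`, followed by a Gaussian of
FWHM `gamma_exp` for the instrument.  The total effective width reported
by `gamma_of_E` is `gamma_exp + Gamma_L(E)`: it tends to
`gamma_core + gamma_exp` far below the onset and gains `amp` far above.

The Lorentzian/Gaussian split is a deliberate design choice: if the
instrumental width were also Lorentzian, only the sum
`gamma_core + gamma_exp` would be identifiable and a four-parameter fit
would sit on a flat ridge.  The Voigt-style decomposition is the
physically standard one and makes all four parameters separately
recoverable (the suite demonstrates recovery within 2% from a noise-free
synthetic experiment).  Note that `gamma_exp` around 1.5 eV needs a grid
no coarser than ~1 eV to be resolvable against the Lorentzian shape.

Numerics: spectra are zero-padded by 50 eV on both sides, convolved, and
trimmed.  Kernels are bin-integrated (arctan CDF for the Lorentzian, erf
for the Gaussian) and column-renormalised so each source bin spreads
exactly unit mass over the padded grid; without renormalisation the fat
Lorentzian tails would lose ~2% of the area at 50 eV padding.  The width
is evaluated at the source energy, which makes the operator linear in the
input spectrum.  The fit is Nelder–Mead on |x| (non-negativity by
reflection), relative tolerance 1e-10 on the objective, optional restart
from the first optimum; it is deterministic given the initial point.

## Synthetic generator and study conditions

The generator stands in for the unavailable inputs of the original
analyses (a measured Fe K-edge spectrum and 100 ns of solvated-protein
MD).  The site model holds Fe at the origin, four pyrrole N fixed at
2.00 Å in the xy-plane (scenery for the forward model, never refined),
N_His below and C, O above on the z-axis.  The energy is purely bonded:

    U = sum 1/2 k_b (r - r0)^2 + sum 1/2 k_th (theta - theta0)^2

over the Fe–N_His, Fe–C, C–O bonds and N_His–Fe–C, Fe–C–O angles.  The
half-k convention is the internal one; CHARMM-style `K (x - x0)^2`
constants are accepted via a flag (`k -> 2K`), and the topology exporter
documents the conversion.  The half-k reading of the published
67.4 kcal/mol/rad^2 bending constant reproduces the observed ~173 +/- 3.5
degree bending spread, which is why it is the default.

Two canonical parameter sets ship as fixtures: the "optimized" set
(Fe–C 1.80 Å, Fe–N_His 2.04 Å, C–O 1.25 Å, bending 67.4) and a
CHARMM36-like starting set (1.90, 2.20, 1.128 Å, 70.0).  Bond force
constants (270/258/1115 kcal/mol/Å²) and the N_His–Fe–C constant
(50 kcal/mol/rad²) are typical heme-chemistry values chosen once; the
seven-atom charge set is synthetic, summing to the declared -2 e of the
heme+His+CO unit.

Sampling is Metropolis Monte Carlo in the Cartesian coordinates of the
three movable atoms (N_His, C, O) at 300 K (`kT = 0.5962 kcal/mol`);
single-atom uniform-cube proposals, step auto-tuned toward ~40% acceptance
during burn-in and then frozen; frames are emitted every `stride` steps
after burn-in and the stream is bit-reproducible given the seed.  The
inner loop is plain Python floats by design — 10^6 steps run in a few
seconds, which the million-sample angle statistics rely on.

Because sampling is Cartesian, marginals carry their geometric Jacobians:
bond lengths follow `r^2 exp(-(r-r0)^2 / 2 s_b^2)` with `s_b^2 = kT/k_b`,
and the deviation `phi = pi - theta` of a linear angle is Rayleigh with
scale `s = sqrt(kT/k_th)` — mean `s sqrt(pi/2)`, sd `s sqrt(2 - pi/2)`.
For the Fe–C–O unit this gives 173.25 +/- 3.53 degrees at 300 K; the
sampler reproduces both (KS tests against the closed forms pass at
p > 0.01 with 10^4 thinned samples).

What the generator does *not* emulate: solvent and protein environment,
electrostatics, anharmonicity, coupled protein conformational states
(e.g. distal-histidine tautomers or side-chain flips), and real MD
integrator dynamics.  Passing tests therefore demonstrate the statistical
machinery and the inference loop, not force-field accuracy for
myoglobin; regime differences enter the tests only as geometric ensemble
differences, which is exactly the quantity the windowed and paired
comparisons are designed to detect.

Synthetic experiments are built by running the full pipeline under a
ground-truth parameter set and adding iid Gaussian noise of constant sd;
the stated per-point error of the product defaults to that sd (0.01 for
noise-free curves), and the generating record (parameters, broadening,
seeds) is kept alongside.

## Refinement

Greedy coordinate descent: for each refinable parameter (bond r0, angle
force constant, equilibrium angle — charges are excluded, they come from
electronic-structure calculations) two candidates `+/-step` are proposed;
each candidate is evaluated by sampling a fresh seeded ensemble,
averaging, and fitting the losses; the best strictly-improving candidate
is accepted; when none improves all steps are halved; the loop stops when
every step is below its floor (defaults 0.005 Å / 0.2) or after
`max_rounds` (default 50).  With common random numbers (default) one
sampler seed serves the entire run, so candidate comparisons are free of
resampling noise, the run is deterministic given the master seed, and the
final R_sq is guaranteed `<=` the initial one.  Without CRN the guarantee
is only statistical.

Evaluation problem sizes are configuration values; the shipped defaults
for desk-scale studies are 120–200 frames per evaluation at a thinning
stride of 50 MC steps, a 0–200 eV grid at 1 eV (2 eV in the fast paths),
and ~30 ensemble evaluations per one-parameter refinement.  Under these
conditions the suite demonstrates the two bond-length corrections the
method is built for — Fe–C from 1.90 to within 0.02 Å of 1.80, and
Fe–N_His from 2.20 to within 0.03 Å of 2.04 — as well as replicate-level
discrimination of a +0.10 Å perturbed ensemble and clean windowed
separation of a concatenated two-regime trajectory.

## Degenerate inputs and tie-breaking

Empty clusters return the bare edge with a warning; cluster selection
breaks distance ties by input order (stable sort); snapshots with fewer
atoms than requested return all of them with a single logged warning;
radial distributions are raw per-frame count histograms (no 4 pi r^2 rho
normalisation) so that peak positions read directly as modes, with the
running coordination number as the cumulative mean count; windows in the
time-resolved residual are left-aligned, non-overlapping, and a window
equal to the full span reproduces the global fit.

## Known limitations

* The toy calculator has no multiple-scattering paths beyond the single
  collinear focusing correction and no muffin-tin physics; absolute R_sq
  values are not comparable to published fits against real engines.
* Error bars on fitted loss parameters are not computed (no correlation
  matrix); the fit returns point estimates and an iteration audit.
* The refinement explores one parameter at a time; strongly correlated
  parameters (e.g. Fe–C and C–O under a fixed Fe–O constraint) may
  require the step table to be staged manually.
* Binary trajectory formats and periodic-boundary imaging are out of
  scope; clusters are assumed pre-imaged.
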