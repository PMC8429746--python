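# Methods

## The measurement model

PET-FCS converts conformational exchange into intensity blinking: a
fluorophore on one lobe of a bi-lobate domain is quenched by contact with
a tryptophan on the other lobe, so opening/closing of the clamshell gates
the emission between a bright and a dim state.  The observable is the
baseline-free correlation function of the detected photon stream,

    G(τ) = (1/N) · (1 + τ/τ_D)⁻¹ · (1 + Σₙ aₙ e^(−τ/τₙ)),

the product of a planar-diffusion factor and independent multiplicative
kinetic relaxations.  The planar (2D) diffusion form is the exact model
when the axial extent of the focus greatly exceeds its lateral waist,
which is the regime the synthetic generator reproduces by default; no
triplet, flow or anomalous-diffusion terms are modelled, and no +1
baseline is carried (instrument files with a g(2) = 1 + G convention are
baseline-subtracted on read, with a log message).

For one two-state mode with microscopic rates k₁₂ (bright→dim), k₂₁ and
dim/bright brightness ratio q,

    τ_rel = 1/(k₁₂ + k₂₁),
    a = p_B·p_D·(1 − q)² / (p_B + p_D·q)²,   p_B = k₂₁/(k₁₂+k₂₁),

the standard two-state reaction-FCS amplitude.  Only the brightness
*ratio* enters.  The inverse mapping solves a quadratic in p_B; when both
roots are feasible the dim-majority branch is returned by convention, and
an infeasible amplitude raises an error naming the maximum
(1−q)²/(4q) achievable at that q.  The brightness ratio of a
tryptophan-quenched oxazine is not established quantitatively, so q = 0
(full quenching) is the simulation default and q is exposed as a free
parameter.

## Synthetic data

Two generators produce the study conditions.

**Direct curve synthesis** (`synth_acf`) draws
g_k = G(τ_k) + Normal(0, σ_k) on a multi-tau grid with

    σ_k = noise_scale · (1 + g_k) · √(τ_k / T),

a simplified standard-error scaling in the measurement duration T:
longer lags average fewer independent segments.  This is a stand-in shape
for full correlator-noise theory; its purpose is heteroscedasticity with
the right qualitative lag- and duration-dependence, and the Monte-Carlo
noise test pins the realized per-lag s.d. to σ_k within 10%.  The default
study conditions are noise_scale = 0.01 and T = 600 s (a 10-minute
acquisition), with curves normalized to N = 1 and an LBD-scale diffusion
time of 0.5 ms; condition parameter sets live in `datasets.py`, printed
values where they exist and representative bar-graph-scale values where
only figures were published (marked as such).

**Photon-trace Monte Carlo** (`simulate_trace`) places M molecules in a
periodic box, takes Gaussian Brownian steps of per-axis variance 2·D·Δt
per bin, evaluates the detection profile exp(−2r²/w²) (with a Gaussian
axial factor in the optional 3D mode), gates each molecule by an
exact-waiting-time telegraph state integrated over the bin (no per-step
switching-probability bias; a warning fires when Δt ≥ 0.1/(k₁₂+k₂₁)), and
draws Poisson counts.  The box is sized so the mean focal occupancy
equals the requested N, with occupancy N = c·πw² for the squared-Gaussian
planar profile.  Defaults — waist 250 nm, brightness 50 kHz at focus
centre, background 1 kHz, box_factor 14 — are plausible conventions for
the described class of confocal setup, not published values.

A closed box holds a *fixed* M, so focal-occupancy fluctuations lack the
Poisson number-fluctuation term of an open reservoir.  For independent
molecules this is exact and additive:

    G_box(τ) = G_open(τ) − 1/M.

`correct_finite_box` adds 1/M back using the molecule count recorded on
the trace; the default box keeps the raw offset below ~2% of G(0)
(relative size π/box_factor²).  Periodic-image effects appear only at
lags where √(4Dτ) approaches the box size, beyond the fitted range in all
shipped scenarios.

`split_channels` thins photons binomially (p = 1/2) onto two detector
channels, reproducing the two-detector cross-correlation trick that
removes afterpulsing and dead-time artefacts — which are therefore not
simulated.  `multi_tau_correlate` implements the hardware-style scheme:
a first block of 2m lags at native width, then m lags per block with
pairwise re-binning doubling the width (m = 16 by default), symmetric
normalization with lag-dependent monitor means, and a per-lag standard
error estimated from 16 contiguous batch means of the product series
(approximate at the deepest levels, where batches are short).  The
automatic depth stops while the deepest level still averages ≥ 32·m
re-binned points.  Each level is bit-identical to a direct correlation of
the externally re-binned trace, which is the brute-force oracle used in
the tests.

What passing these tests does *not* show about real data: detector
afterpulsing residuals, optical saturation and aberrations, triplet
blinking, sample drift and photobleaching over 10-minute runs are all
outside the generator, so pipeline accuracy on real instrument files is
bounded by those effects, not by the numerics validated here.

## Fitting and model selection

Curves are fitted by weighted least squares (weights 1/σ² when per-lag
uncertainties are present, unweighted otherwise — the original weighting
convention is not documented, so both paths exist).  Time constants are
fitted in log-space for conditioning across five decades of lag.
Multistart initialization: τₙ starts on a 5-point log grid over the lag
window explored combinatorially with τ descending (≤ C(5,n) ≤ 10 starts
per n, plus warm starts), amplitudes start at 0.2, N at 1/g(first lag),
τ_D at the half-decay lag.  Bounds: N > 0, τ_D ∈ [min lag, 100·max lag],
aₙ ∈ [0, 10], τₙ ∈ [min lag/2, max lag].  Kinetic phases are deliberately
not constrained to be faster than τ_D; the selection filters handle
degeneracy.  Standard errors come from the Jacobian covariance scaled by
reduced χ², transformed back from log-space by the delta method.  Fits
are deterministic; the seed argument is recorded for provenance only.

Model complexity is chosen by a nested ladder n = 0, 1, …, n_max: n+1
replaces n only if the nested F-test on the weighted residual sums has
p < α (default 0.01) *and* the larger fit passes four plausibility
filters — every amplitude ≥ 0.01, every parameter's relative standard
error < 100%, consecutive time constants separated by ≥ 3×, and all τₙ
strictly inside the lag window.  The first failure stops the ladder; ties
favour fewer exponentials.  AIC/BIC are available behind a flag.  Each
fit is warm-started from the previous solution with a zero-amplitude
extra phase, which makes χ²(n) non-increasing and the F-statistic
well-defined.  A fit already at machine precision short-circuits the test
(noise-free curves would otherwise produce unstable F ratios).  Because
the accept rule is a hypothesis test at α = 0.01, a small design
false-accept rate is inherent; reliability checks therefore ask for ≥ 95%
correct selections over seeds rather than unanimity.

Phases with amplitude below 0.10 are considered too small to assign a
motion (the published assignment convention); `compare_conditions`
greedily matches assigned phases across conditions by smallest log-τ
distance subject to a τ ratio ≤ 3 — chosen because observed modes are
spaced roughly a decade apart — and reports unmatched reference phases as
*stalled*, unmatched probe phases as *emergent*.  The stall-scan pipeline
applies this per condition against a reference (QC: ≥ 50 lags spanning
≥ 4 decades), flags a "residual fast phase" when an assigned τ ≤ 1 µs
survives, and serializes fits so verdicts can be reproduced
bit-identically from the JSON (verdicts are a pure function of fitted
parameters).  Replicate handling follows the convention of fitting each
curve and averaging parameters rather than fitting averaged curves.

## Hydrodynamics

A reference dye of known diffusion coefficient calibrates the focus,
w = √(4·D_ref·τ_D,ref); measured diffusion times then give
D = w²/(4τ_D) and R_h = k_B·T/(6πηD).  Defaults: Atto655 with
D = 4.26×10⁻¹⁰ m²/s, T = 298.15 K, η = 8.9×10⁻⁴ Pa·s (water, 25 °C),
all configurable; buffer-viscosity corrections are out of scope.
Calibration cancels exactly in ratios of radii, which is why the
dimerization comparison is robust: doubling the mass of a compact globule
predicts a 2^(1/3) − 1 = 26% radius increase.

Structure-based radii use the mass-weighted radius of gyration over
polymer atoms only — waters, ions and bound ligands excluded, alternate
locations beyond the first dropped, hydrogens included only if present
(the published protocol names only the viewer used, so this selection is
this package's documented convention) — converted by the uniform-sphere
law R_h = R_g/√(3/5).  Chain selection is explicit: one chain for a
monomer, two for a dimer.  When crystal coordinates are not available
locally, `synthetic_globule` builds a labelled synthetic stand-in: a
uniform-ball pseudo-structure sized by the empirical folded-protein
scaling R_g ≈ 2.2·N_res^0.38 Å.  It exercises the structural code path
and the size scale of a ~290-residue domain; it is not a model of any
particular protein, and structure-specific radii should not be quoted
from it.

## Binding titrations

The summed assigned sub-ms amplitude (the default observable; a single
phase's amplitude works equally) decays with ligand concentration as a
1:1 isotherm, a([L]) = a_u + (a_b − a_u)·[L]/([L] + K_d), fitted by
weighted least squares with K_d multistarted on a log grid spanning
[min positive conc/10, max conc·10].  K_d is scale-invariant in the
amplitudes.  The default design uses 8 concentrations spanning
0.1–100×K_d with multiplicative amplitude noise.  Free ligand is taken
equal to total — exact to < 0.1% at nanomolar labelled protein — and the
quadratic mass-balance correction is provided for scenario testing.
Unidentifiable series (amplitudes without concentration dependence) are
flagged non-converged rather than returned silently.

## Degree of labeling

DOL = (A_max·ε_prot)/((A_280 − A_max·CF_280)·ε_max) from the conjugate's
absorbance spectrum.  A conjugate whose dye-corrected 280-nm absorbance
is non-positive raises an error.  The 0.3 classification threshold
separating specific (engineered-Cys, ~60%) from background (~10%)
labeling is this package's convention, motivated by that contrast.

## Problem sizes and numerical choices

The shipped analyses and checks use: 352-lag multi-tau grids (25 ns –
0.84 s); 20–50 seeds for selection-reliability studies; 100 seeds for
parameter-recovery statistics; a 5×10⁶-bin (2 s, 0.4 µs bins) trace at
τ_D = 20 µs and τ_rel = 5 µs for the end-to-end recovery, sized so
duration = 10⁵·τ_D with scenario brightness 500 kHz chosen to give
photons-per-transit comparable to a real ms-scale measurement at the
compressed τ_D; and a 2¹⁴-bin trace for the correlator oracle.  The
analysis drivers use a scaled-down 0.5 s trace for the same recovery
demonstration.  Optimizer tolerances are xtol = ftol = gtol = 1e−14
(least-squares, trf with bounds); noise-free round-trips recover
parameters to ~1e−15 relative.

## Known limitations

- The correlator's batch-mean error bars under-count correlations at the
  deepest lag levels; weighted fits there lean on approximate weights.
- The telegraph gate is evaluated as time-in-state per bin, which is
  exact for the expected intensity but smooths kinetics at
  τ_rel ≲ 10·Δt (hence the under-resolution warning).
- The finite-box correction is exact for independent point emitters;
  interacting or very dense systems are outside the model.
- The 3D-Gaussian focus mode exists for realism studies only; its ACF is
  not the planar fitting model and no 3D fitting model is provided.
- Representative (bar-graph-scale) condition parameters in `datasets.py`
  reproduce qualitative patterns — stalling, slowing on dimerization,
  allosteric uncoupling — not quantitative per-condition values.
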