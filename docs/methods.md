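# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Equilibrium binding models

Saturation binding is the hyperbola `bmax·L/(L + K_D) + ns·L`; Bmax is
fitted internally on a log10 scale so that receptor densities from ~10³ to
~10⁶ sites/cell are equally well conditioned.

The allosteric ternary complex model (ATCM) describes a receptor engaging a
radioligand L\*, an orthosteric agonist I and an allosteric modulator B at
equilibrium. Its parameters are the ligand affinities (pK_D ≡ −log10 K_A\*,
pK_i, pK_B), the agonist–modulator binding cooperativity α and the
radioligand–modulator cooperativity α′. All affinities and cooperativities
are carried in log10 units throughout the package: that is how they are
reported in the field, it keeps the optimization well scaled, and it makes
root-sum-of-squares SEM propagation meaningful. Concentrations, by
contrast, are never log-transformed inside model functions, so vehicle
(zero) rows are handled exactly.

The interaction-binding observable is fractional specific binding —
radioligand occupancy with nonspecific binding already subtracted — rather
than raw counts. This matches how interaction data are normalized in
practice and decouples the cooperativity analysis from the saturation
(Bmax) analysis.

## Operational models

Functional data use the Black–Leff operational model and its allosteric
extension in the Leach–Sexton–Christopoulos form (see README for the
equations). Defaults, each a deliberate choice:

- `em = 100`, fixed: responses are normalized to the maximal agonist
  response, so the system maximum is the normalization itself. A
  `fit_em` flag exists for plates where that assumption is doubtful; when
  several agonist datasets are fit globally, Em is shared within the fit.
- `basal = 0`, fixed by default: normalized curves start near zero.
  Fittable via `fit_basal`.
- transducer slope `n = 1`, fittable only via `fit_slope`: interaction
  datasets rarely constrain n and letting it float degrades the
  identifiability of log αβ.
- Binding parameters (pK_a per agonist, pK_B, log α) enter the functional
  fit as fixed constants determined from equilibrium binding; only
  log τ_A (per agonist), log τ_B (shared across agonist datasets by
  default) and log αβ (per agonist–modulator pair) are free.

`log_tau_B = −inf` is a valid parameter value encoding a modulator with no
intrinsic efficacy; the modulator-alone curve is then exactly flat while
log αβ remains identifiable from the potency shifts of the agonist curves.

Expression-corrected efficacy uses log τ_C = log τ − log10(Bmax/Bmax_ref):
in the operational model τ = R_T/K_E is proportional to receptor number, so
an expression difference moves log τ by exactly the log of the Bmax ratio.
The reference is the wild-type Bmax.

Derived parameters: occupied-state affinities pK + log α, fold
cooperativity 10^logα, and log β = log αβ − log α. SEMs of sums and
differences of log-scale quantities are propagated as the square root of
the sum of squares; the SEM of a fold value (10^x) is mapped to the linear
scale by the delta method (ln10 · 10^x · s), since a root-sum-square of a
single log-scale SEM has no linear-scale meaning.

## Fitting pipeline

Fits are bounded nonlinear least squares (trust-region reflective, via
lmfit) with multi-start: 5 starts by default, jittered ±1 log unit around
the initial values with a seeded generator; the lowest residual sum of
squares wins, ties broken by the smaller parameter norm. Sharing is
expressed through parameter names — shared parameters appear once and
constrain every dataset in the group; per-agonist parameters carry a
`__<label>` suffix.

Two replicate-handling modes exist. The default fits each independent
experiment separately and summarizes every parameter as mean ± SEM
(sd/√n) over experiments, matching how assay parameters are conventionally
reported. `fit(per_replicate=False)` instead pools all points into one
global fit and reports asymptotic SEs from the Jacobian. The per-replicate
SEM with n = 3 experiments is itself noisy; recovery tests that compare an
error against "k SEMs" therefore use the pooled asymptotic SEs.

Degenerate inputs are flagged rather than raised: all-zero saturation data
yield `converged=False` with a `[degenerate: bmax ~ 0]` message; an
all-flat functional response likewise. Fewer than three nonzero modulator
levels triggers a weak-identifiability warning.

## Synthetic assay designs and noise

The interaction design places the radioligand at its K_D, the agonist on a
half-log dilution series spanning pK_i ± 3 and the modulator on a half-log
series from pK_B − 1 downward (9 levels by default) plus vehicle; 3
replicate experiments by default. Noise defaults are additive Gaussian, SD
0.03 on fractional specific binding and SD 3 response units on Em = 100
(saturation curves use 2% multiplicative noise); these produce recovered
SEMs of the same order as those reported for the real assays.

What the generator does **not** emulate: counting statistics, plate and
edge effects, heteroscedasticity, radioligand depletion, or any kinetic
(pre-equilibrium) artifact. Parameter-recovery results therefore
demonstrate the correctness and calibration of the estimation machinery
under the declared noise model, not robustness to real-assay pathologies.

Replicate streams are spawned from a `SeedSequence`, so replicates differ
only through noise and every pipeline is exactly reproducible from its
seed.

## GaMD engine

The dynamics engine is a BAOAB Langevin integrator in reduced units: unit
mass, energies in kcal/mol, k_B = 0.0019872041 kcal/mol/K, default
T = 300 K, friction 1/ps-like units, default dt 10⁻³. Only the boost and
reweighting mathematics are claimed faithful to production GaMD codes —
there is no force field, thermostat chain, or constraint algorithm.

A run has three stages: (1) conventional dynamics collecting running
potential statistics (Welford, sample SD); (2) boosted equilibration in
which the boost parameters are recomputed from the updated statistics every
`update_interval` steps (default 10⁴ — production codes update on a
comparable fraction of their equilibration length); (3) production with
frozen boost parameters, recording coordinates, unboosted potential and
boost per frame. Forces on the boosted surface scale the gradient by
1 − k(E − V) for V < E, a factor guaranteed in [0, 1] by the
Vmax ≤ E ≤ Vmin + 1/k invariant, which is enforced on every
`BoostParameters` construction.

Threshold modes: lower bound (E = Vmax,
k0 = min(1, (σ0/σ_V)·(Vmax−Vmin)/(Vmax−Vavg))) and upper bound
(k0″ = (1 − σ0/σ_V)·(Vmax−Vmin)/(Vavg−Vmin), E = Vmin + 1/k), the upper
bound being accepted only when 0 < k0″ ≤ 1 and falling back to the
lower-bound formula otherwise. Degenerate statistics (Vmax = Vmin) disable
the boost with a flag; σ_V = 0 gives k0 = 1 in lower mode. Dual-boost
applies an independent boost to the first term of a two-term surface
decomposition (the fast, dihedral-like term) and to the total potential;
it requires a surface that exposes the decomposition.

Reweighting histograms the reaction coordinate (bins below a frame-count
cutoff, default 500, are discarded) and multiplies each retained bin's
boosted weight by the ensemble-averaged Boltzmann factor of the boost:
`exp(β·C1 + β²·C2/2)` with C1 the in-bin mean and C2 the in-bin population
variance of ΔV (second-order cumulant, the default), or the exact
exponential average evaluated through log-sum-exp. The PMF is
−k_B T ln p, shifted so its minimum is zero over retained bins. A
gaussianity report (per-bin skew and excess kurtosis, flag at |skew| > 0.5)
indicates where the cumulant approximation is trustworthy.

Problem sizes: the double-well demonstrations (a = 7, b = 1 kcal/mol,
barrier a·b⁴ = 7 kcal/mol ≈ 11.7 k_BT at 300 K) use 2×10⁴ statistics
steps, 3×10⁵ boosted-equilibration steps and 10⁶ production steps at
dt = 0.015 — well inside the BAOAB stability limit (dt·ω ≈ 0.11 at the
well curvature) while giving enough barrier recrossings for converged well
populations. The acceptance script combines three independent production
runs for its PMF, mirroring how production GaMD studies pool replicate
trajectories. With these sizes the cumulant-reweighted PMF tracks the
analytic Boltzmann profile (per-bin integral of e^{−βV}) to well under
0.5 kcal/mol at every retained bin.

## Trajectory geometry

Superposition is the Kabsch algorithm implemented directly via SVD of the
covariance matrix with the reflection branch corrected by a sign flip on
the smallest singular direction. (The quaternion-based aligner in the
scientific stack resolves residuals only to ~10⁻⁸; the direct SVD keeps
rigid-motion residuals at ~10⁻¹⁵, which the tests rely on.) Collinear or
under-determined selections raise a degeneracy error.

RMSD series superpose each frame on a fitting selection and report the
RMSD over a separate measuring selection, which covers ligand-RMSD-after-
receptor-fit. RMSF aligns all frames to the running mean structure,
iterated twice, over an optional fitting selection; fitting on a static
scaffold makes the oscillating-atom oracle exact, whereas fitting on all
atoms absorbs 1/N of any single-atom motion into the centroid. Dihedrals
use the standard signed atan2 torsion; the tryptophan χ2 convention is
CA–CB–CG–CD1 (the common analysis-toolkit choice). Ring-to-group distances
default to centroid–centroid, the usual convention when the definition is
not otherwise specified. Coordinates are angstroms throughout; the XYZ
reader assumes angstroms.

## Known limitations

- The ATCM and operational models are equilibrium descriptions; no
  kinetic, two-state or biased-agonism machinery is included.
- SEMs from three replicates are themselves uncertain by ~50%; treat
  "within k SEMs" statements accordingly.
- The toy engine is 1D/2D only — no periodic boundaries, constraints or
  pressure coupling — so GaMD conclusions transfer only at the level of
  the boost/reweighting mathematics.
- Exponential-average reweighting is variance-prone when per-bin boost is
  broad; the gaussianity report flags, but does not fix, such bins.
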