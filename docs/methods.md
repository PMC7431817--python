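# Methods

## The equilibrium model

Each EGFR molecule carries two switches: the extracellular domain is closed
(tethered) or extended, and the kinase domain is inactive or active.  The
model's assumptions, in the package's terms:

1. only extended monomers dimerize and only extended domains bind EGF;
2. the two switches are uncoupled in monomers (K₁ and K₂ are independent);
3. inactive-kinase monomers (EI) dimerize into symmetric-kinase dimers
   (DES…), active-kinase monomers (EA) into asymmetric, activating dimers
   (DEA…) — two separate pathways with distinct ligand affinities;
4. free ligand equals added ligand (no depletion — `depletion_check`
   quantifies the error, a few percent at worst under assay-like
   conditions);
5. no oligomers beyond dimers, no intermediate kinase conformations.

Units: receptor species in copies/cell (dimers as dimer copies), ligand in
nM; dissociation constants inherit those units and no volume conversion is
attempted, exactly as the data (receptors/cell from calibrated flow
cytometry, nM dilution series) are reported.

### Closed-form solution

All twelve species are mass-action multiples of [EI] (see
`egfrbind.equilibrium`), so receptor conservation becomes

    a(L)·[EI]² + b(L)·[EI] − R_tot = 0,   a, b > 0,

with exactly one positive root.  We evaluate it as
2·R_tot/(b + √(b² + 4aR_tot)), which is free of subtractive cancellation
when a·R_tot ≪ b² (low expression or weak dimerization).  L = 0 and
R_tot = 0 are handled analytically.  Bound EGF counts one ligand per singly
and two per doubly liganded dimer.  The solver is verified against (i) a
simultaneous 13-unknown numeric root solve of the raw equation system and
(ii) a bracketing scalar root solve of the conservation relation, over
1,000 random parameter draws spanning ±3 decades.

## Structural identifiability of the global fit

This is the package's most consequential numerical finding.  The observable
— bound EGF as a function of (R_tot, L) — is **exactly invariant** under the
one-parameter family

    K₂+1 → γ(K₂+1),  K₃ → K₃/γ,  K₄ → K₄/γ²,  K₇ → K₇/γ²   (γ > 0),

because the monomer pool only enters through the combinations (K₂+1)·[EI]
and [EI]/K₃ (the family relabels [EI]; `gauge_transform` implements it, and
a property test verifies bit-level invariance).  Binding data therefore
cannot determine K₂, K₃, K₄, K₇ individually — only gauge combinations such
as K₃(K₂+1), K₄/K₃² and the linkage constants K₄K₅K₆/K₃², K₇K₈K₉/K₃².

A second, independent flat direction exists because each condition's dimer
load enters only through one quadratic in L,
P₀ + P₁L + P₂L², which is a *sum* of the two pathway contributions: the
split between the symmetric (K₄, K₅, K₆) and asymmetric (K₇, K₈, K₉)
pathways can be re-apportioned — with compensating shifts of the K₁s —
almost freely.  The compensation is not algebraically exact, but we
measured it (50-digit arithmetic) to reproduce every data point of the
12-dataset design to better than 10⁻¹⁵ relative over more than a decade of
K₅.  No optimizer operating on any realistically precise data can resolve
it: an unconstrained 11-parameter fit of noiseless data returns an
arbitrary point on a two-dimensional flat manifold (observed spreads: K₅
25–11,000 nM, K₆ 0.0045–1.19 nM, K₈ ±35% across numerically tied optima,
while K₃(K₂+1), K₄·((K₂+1)/3.9)² and K₉ stayed within 1%).

**Resolution.**  `GlobalFitConfig.fixed` pins parameters during fitting; by
default K₂ (gauge choice) and K₅ (mixture valley) are fixed at the
reference estimates, leaving nine identifiable free parameters, which cold
multi-start fits then recover from noiseless synthetic data to ~10⁻¹³
relative.  `fixed={}` restores the literal all-free fit for users who want
the flat-manifold behaviour.  Reported constants that depend on a pinned
convention are exactly those the convention names: K₂ and K₅ themselves are
input, not inference; K₃, K₄, K₇ are estimates *given* the K₂ gauge; K₆,
K₈ and the K₁s are estimates given the K₅ pin; K₉ is robustly identified
regardless.  Bootstrap intervals are conditional on the same conventions.

## Global fitting procedure

* Objective: sum of squared deviations between measured intensity and
  scale·bound over all datasets; optional 1/SEM² weighting.
* Intensity scales are nuisance parameters, profiled in closed form
  (scale_g = Σ wIp / Σ wp² over group g).  Default: one scale per
  pharmacological condition, shared across expression gates (common
  staining and instrument settings); per-dataset scales are a config
  switch.
* Optimisation in log₁₀ parameter space with box bounds (default: two
  decades below to four above each constant's reference magnitude),
  multi-start from a Latin hypercube (default 40 starts), local refinement
  by trust-region least squares (`scipy.optimize.least_squares`,
  tolerances 10⁻¹³).  Deterministic given the seed.
* Tie-break: solutions whose norms agree within 10⁻⁹ relative — or sit at
  the floating-point floor of the objective — are treated as tied, and the
  one with the smallest K₇ (the least identifiable axis) wins, making the
  result well-defined even on flat landscapes.
* Confidence intervals: parametric bootstrap.  Each repeat perturbs every
  intensity by Normal(0, SEM) and reruns the multi-start optimisation
  (warm-started at the point estimate); the 2.5/97.5 percentiles over
  repeats form the 95% CI.  The procedure "repeat the optimisation many
  times" admits a pure-restart reading as well; we chose data resampling
  because restart scatter of a deterministic optimizer measures landscape
  flatness, not data uncertainty.  Fewer than 50% converged repeats raises
  an error rather than returning a misleading interval.

## Hill and Scatchard analysis

The Hill equation is fitted in log₁₀-concentration space by multi-start
least squares (n ∈ {0.5, 1, 2} × K_d at the concentration quartiles; best
norm wins, ties to the smallest n), with I_min bounded below by zero and
standard errors taken from the Jacobian at the optimum (asymptotic).  Very
small published errors on such fits may instead be SEMs over replicate
fits; asymptotic errors are what we report.  Preconditions (≥5 points over
≥2 decades) reject curves that cannot constrain four parameters.  The
Scatchard transform uses the nominal concentration as free ligand,
consistent with the no-depletion assumption.

## Homo-FRET cluster analysis

Anisotropy r = (I∥ − G·I⊥)/(I∥ + 2G·I⊥).  For a mixture of monomers
(fraction `mon`) and N-mers bleached to residual fraction s, the surviving
occupancy of a cluster is binomial, each survivor contributes intensity
weight k, and a k-cluster's anisotropy is r₁(1+d⁶)/(1+kd⁶) +
r_FRET(k−1)d⁶/(1+kd⁶).  The prefactor of the clustered term is
(1−mon)/(N·s) — the unique normalisation for which r → r₁ as s → 0, at
N = 1, and at mon = 1 (the intensity weights satisfy
Σ k·C(N,k)sᵏ(1−s)^(N−k) = N·s, a tested identity).  Fixed constants:
r₁ = 0.34 (GFP), r_FRET = 0, d = 1 (fluorophore spacing equal to the
GFP–GFP Förster distance of 4.8 nm); all exposed as arguments.

Fitting: N is scanned on the integer grid 1..30 (the binomial sum is
defined for integers; a linear-interpolation relaxation to fractional N is
available for sensitivity analysis), and for each N the monomer fraction is
profiled in closed form — the model is linear in `mon` — then clipped to
[0, 1].  Ties prefer the smallest N.  A flat series (all-monomer solution)
is flagged degenerate and returned as N = 1, mon = 1 with a warning, since
cluster size carries no information there.  Monte-Carlo CIs: 500 synthetic
series drawn pointwise from Normal(r, SD), each refitted; 2.5/97.5
percentiles.

## Synthetic-data generators

The binding generator emulates the study design: 3 conditions (K₁ = 104 /
25 / 162 for untreated / erlotinib / lapatinib) × 4 expression gates
(R_tot = 390,000 / 630,000 / 1,070,000 / 560,000 receptors per cell), a
2-fold dilution series of 14 points descending from 260 nM (the stock and
dilution factor are known; the exact range is an assumption matched to the
published axis span), 3 replicates, multiplicative Gaussian noise with 5%
CV (flow-cytometric mean intensities are high-count, so CV-type noise;
the level matches the published error-bar scale), per-condition intensity
scales, negative draws truncated at zero (logged; rare at 5%).  Reported
intensity is the replicate mean, SEM the replicate standard error.  The
bleach generator draws r(s) from the mixture model plus Normal(0, SD) noise
on a geometric bleaching schedule (12 steps, ratio 0.77, reaching
s ≈ 0.06).

What the generators do **not** emulate: per-cell heterogeneity within a
gate, instrument background and its correction residuals, spectral
crosstalk, ligand depletion, pre-equilibrium sampling, or (for homo-FRET)
segmentation errors and high-NA depolarisation.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
statistical model, not robustness to those systematic effects.

## Problem sizes and numerical choices

Defaults used in the shipped tests and the acceptance script: 12 datasets ×
14 concentrations (168 points), 40 multi-starts for cold global fits
(seconds on one core), reduced start/repeat counts for bootstrap tests
(the CI machinery scales linearly in both), 1,000 random draws for
solver-vs-oracle properties, 500 Monte-Carlo repeats for homo-FRET CIs.
Equilibrium conservation is validated to 10⁻⁸ relative; the solver itself
is closed-form and exact to rounding.

## Known limitations

* Estimates of K₂, K₃, K₄, K₇ (and, through the mixture valley, K₅, K₆,
  K₈, the K₁s) are convention-dependent as described above; cross-study
  comparison should use gauge-invariant combinations (linkage constants,
  K₃(K₂+1), K₉).
* The bootstrap treats the per-condition scale-sharing choice as true;
  misspecified sharing would bias CIs.
* The homo-FRET model assumes one cluster size N rather than a
  distribution, and d = 1 for all pairs in a cluster.
* Kinetics (association/dissociation rates, internalisation) are outside
  the model; the equilibrium assumption is the user's responsibility.
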