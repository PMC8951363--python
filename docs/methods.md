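# Methods

This note documents the model, the numerical conventions, and the
design choices behind `venomscale`, in the spirit of the methods pages
of statistical simulation packages: what is computed, under what
assumptions, and what the tests do and do not demonstrate.

## Curation model

One row of the analysis table is one published LD50 measurement; a
species typically contributes several. Curation applies three rules
before any modelling:

1. **Units.** All doses are converted exactly to mg of dried venom per
   kg of test subject. Six unit tokens are recognized (`mg/kg`, `ug/g`,
   `mg/g`, `ug/kg`, `ug/animal`, `mg/animal`); per-animal doses divide
   by the subject's body mass and are rejected without it. Unknown
   tokens raise an error: literature units are chaotic, and a silent
   misparse is strictly worse than a failure.
2. **Inclusion.** Only dried-venom records with mass information
   sufficient for the conversion and the configured test organism
   (default *Mus musculus*) survive. The filter is idempotent and logs
   one reason per excluded record so curation is auditable.
3. **Shape indices.** Chela and telson length/width ratios are
   mass-independent morphology indices. When a species has several
   morphology records, raw measurements are averaged arithmetically
   *before* the ratio is formed (mean length / mean width) — the
   conventional choice; the alternative (mean of ratios) differs and is
   deliberately not offered. Species names are matched after trimming,
   whitespace collapsing, case-folding and underscore→space
   replacement; anything beyond that is treated as a real mismatch and
   aborts with a named list rather than fuzzy-matching.

LD50 and total body length are log10-transformed; on that scale the
body-length coefficient is the exponent `a` of the power law
LD50 ∝ (body length)^a.

## Phylogenetic covariance

The "animal" random effect has covariance `σ²_a A`, where `A[i, j]` is
the branch length shared between the root-to-i and root-to-j paths
(equivalently the depth of the pair's most recent common ancestor).
The implementation accumulates each branch's length over all tip pairs
descending from it; tests check it against an independent
path-intersection oracle. Conventions:

- **Branch lengths.** Trees without lengths get Grafen's assignment
  (internal node height = descendant tips − 1, tips at 0, heights
  scaled to unit depth). A config switch substitutes all-branches-1.
  The choice is declared, not estimated: topology-only trees carry no
  length information to recover.
- **Scaling.** `A` is divided by its maximum diagonal, so variance
  components — and hence h² — are comparable regardless of tree units.
  An ultrametric tree then has unit diagonal.
- **Polytomies** are accepted as-is; the covariance is well defined on
  multifurcations, and random resolution would silently randomize
  results.

## The sampler

All full conditionals are conjugate, so the model is fitted by a
systematic-scan Gibbs sampler over four blocks: β (Gaussian), animal
effects u (Gaussian, precision `A⁻¹/σ²_a + Z'Z/σ²_e`), species effects
s (Gaussian, diagonal precision), and the three variances
(inverse-gamma, shape ν/2 + count/2, scale (νV + SS)/2, where the sum
of squares for u is weighted by `A⁻¹`). Numerical conventions:

- Priors: `V = 1, ν = 0.002` per variance component, `N(0, 1e10)` fixed
  effects — the conventional weakly informative defaults for this model
  family; configurable for sensitivity analysis.
- `A⁻¹` is computed once per fit via Cholesky; 1e−10 jitter is added
  (and logged) if factorization fails. Variance draws are floored at
  1e−12 to keep conditionals invertible on degenerate data.
- Default schedule: 130 000 iterations, 30 000 burn-in, thinning 100 →
  1000 stored draws per chain, three chains. If any stored parameter's
  effective sample size falls below 1000, the chain's total length is
  doubled, up to two doublings (4×); a chain still short of the target
  is flagged, not hidden.
- Chains differ in seed (derived deterministically from one master
  seed via `SeedSequence`) and in starting variances, rotated through
  {0.1, 1, 10} so the Gelman–Rubin diagnostic starts from genuinely
  dispersed states. β starts at 0 in every chain; it is redrawn from
  its full conditional in the first sweep, so its start value cannot
  influence the chain.
- With `A = I` the animal/species split is unidentifiable; only the
  sum σ²_a + σ²_s is (documented, and tested on the sum).

## Posterior reporting

- **Mode**: argmax of a Gaussian KDE (Silverman bandwidth) on a
  512-point grid over the draw range; constant samples short-circuit.
  Modes are bandwidth-sensitive, so the convention is fixed.
- **95% HPD**: shortest window containing ⌈0.95 N⌉ sorted draws,
  leftmost window on ties. A fixed term is *significant* iff zero lies
  outside this interval.
- **pMCMC**: twice the smaller sign fraction, zeros counted as neither
  sign, floored at 1/N (finite Monte Carlo cannot certify zero).
- **h² and companions** are computed per draw —
  σ²_a/(σ²_a + σ²_s + σ²_e) and the species/residual analogues, which
  sum to 1 within each draw — then summarized, so each proportion
  carries its own HPD interval. Summarized-variance ratios would not.
- **PSRF** is `sqrt(1 + B_n/W)` (between-chain variance of means over
  mean within-chain variance). The textbook (n−1)/n deflation is
  omitted deliberately: it makes identical chains report values below
  1, while this form reports exactly 1 and converges to the same limit.
  Threshold for the converged flag: 1.1. One chain → diagnostics
  "unavailable", not "passed".
- **ESS**: N/(1 + 2Στ) with the autocorrelation sum truncated by
  Geyer's initial-positive-sequence rule; capped at N; constant chains
  report 0 with a warning.
- **Collinearity screen**: pairwise OLS among log10 length, chela and
  telson ratios at the *species* level — morphology is constant within
  species, so measure-level rows would fabricate sample size. Flag at
  p < 0.05.
- **Predictions**: `predict_ld50` evaluates 10^(linear predictor) at
  the posterior modes; `delta_ld50` exposes the difference between two
  covariate settings (the basis for "change in LD50 across the observed
  range" statements). Full-posterior prediction intervals are out of
  scope.

## Synthetic data

The generator emulates the comparative dataset the pipeline targets:

| quantity | default | rationale |
|---|---|---|
| species / measures | 36 / 62 | published dataset shape |
| body length | log-uniform 40.5–200 mm | published range; log-uniform makes log10 length uniform, the model's scale |
| chela ratio | uniform 0.7–6.2 | published range |
| telson ratio | uniform 1.0–4.0 | declared choice — no published range exists |
| routes | SC .5, IV .3, IP .15, IM .05 | SC-heavy mix as in literature LD50 data |
| fixed effects | −4.82, 3.24, −0.26, 0.04, routes 0 | published posterior modes as ground truth |
| variances (animal, species, residual) | 0.60, 0.01, 0.26 | published variance-proportion modes used as raw components; true h² = 0.60/0.87 ≈ 0.69 |
| tree | Yule, depth 1 | neutral standard for species trees |
| subject mass | 0.02 kg | house-mouse body mass |

Trees come from a pure-birth simulator; since it stops exactly at the
n-th speciation (zero-length youngest tips), every tip branch is
extended by the Exp(nλ) waiting time to the next event — the correct
continuation of the process — keeping `A` nonsingular. Measures are
allocated one per species plus a uniform multinomial remainder. Each
species' measures are contiguous, morphology files are back-computed
from the drawn ratios, and all floats are written at round-trip
precision, so disk round-trips reproduce the in-memory table exactly.
The truth record stores every latent draw (u, s, e, linear predictor),
so the response is exactly reconstructible.

What the generator does *not* emulate: measurement error in
morphology, phylogenetic signal in the covariates (available as
independent draws only), non-Gaussian residuals, and any correlation
between route and species identity. Passing recovery tests therefore
show that the sampler and summaries are correct under the model's own
assumptions — not that real literature data satisfy those assumptions.

## Problem sizes used in the checks

Stochastic validation uses reduced-but-adequate problem sizes chosen
from the sampler's mixing behavior: the replicate recovery experiment
runs 20 datasets at the full published shape with 3 chains × 6000
iterations (burn-in 2000, thinning 4 → 1000 draws/chain); the
GLS cross-check holds variances fixed and uses 12 000 iterations,
unthinned; scale-invariance uses two seed-matched 2-chain fits, which
couple almost exactly and make the test sharp. The acceptance script's
headline fit uses 3 × 20 000 iterations (thin 15), giving pooled ESS
near or above 1000 for every parameter at the default dataset shape.

## Known limitations

- Gaussian response only; no non-mouse test-model mixing, no
  fixed-effect interactions, no Pagel's-λ or OU transformations of `A`.
- The posterior mode depends on the KDE convention; values within a few
  percent of another package's modes are expected, identity is not.
- The HPD of strongly bounded proportions (h² near 0 or 1) inherits the
  usual slight under-coverage of density-free interval estimates.
- Open Tree topologies carry no branch lengths; Grafen scaling is a
  modelling convention, and results should be read conditional on it.
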