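# Methods

## The assay and its analysis windows

A scotopic VMR experiment tracks one larva per well and bins displacement
(cm) per second through a protocol of 30 min darkness, 60 min dim light
(0.01 lx) and 5 min darkness. The analyzed event is the light offset; the
two analysis windows are the first post-offset second (immediate startle)
and seconds 1–30 inclusive (the whole burst, dimension p = 30). Offsets
are 1-based and inclusive, so "1 to 30 s" is exactly 30 columns; `t_sec`
is the 0-based bin start, so all recorded times are strictly below the
protocol duration.

The stimulus irradiance is derived photometrically: each neutral-density
filter multiplies intensity by its transmittance, so seven ~40 % filters
attenuate a 3.2 µW cm⁻² source to 3.2 × 0.40⁷ ≈ 0.005 µW cm⁻². Only this
broadband figure is treated as arithmetic; printed narrow-band and lux
values reflect measured filters and are not reproduced by the formula.

## Generative model

Per-second displacement of larva *w* in batch *b*:

    d(w, t) = max(0, b_w + u_b + v_w + A_w · exp(−(k−1)/τ_w) · 1[k ≥ 1] + ε_wt)

with `k = t − t_off` the post-offset second; `b_w ~ N(baseline_rate,
baseline_dispersion²)` the larva's dark baseline; `u_b ~ N(0,
batch_scale²)` an additive batch effect; `v_w` an additive per-well
intensity effect proportional to plate column (a linear lamp-inhomogeneity
proxy); `A_w` the startle amplitude of responding larvae; `ε ~ N(0,
noise_scale²)` measurement noise. Dead larvae (toxic wells) emit only
sub-millimetre tracking jitter. Drug effects multiply amplitude and decay
constant; a "sustained response" hit uses amplitude ×1.5 and τ ×4.

Defaults (units cm and s): baseline_rate 0.08, baseline_dispersion 0.02,
noise_scale 0.05, τ 3, response probability 1. Startle amplitudes are
calibrated so baseline + amplitude equals the published first-second group
means: wild type 0.08 + 0.201 = 0.281, Q344X 0.08 + 0.047 = 0.127. With
these dispersions the zero-clipping bias is < 0.001 cm at both operating
points (clipped-normal mean E[max(0, N(µ, σ))] = µΦ(µ/σ) + σφ(µ/σ)), so
the simulated grand means land on the targets without correction.

Batch effects default to SD 0.03 cm. An additive batch term large enough
to reproduce the published between-replicate s.e.m. (0.036 cm over 18
replicates implies batch-mean SD ≈ 0.15 cm) would exceed the dark baseline
itself; under the max(0, ·) clipping such shifts become non-additive,
cannot be recovered by any linear normalization, and would bias the group
means. We therefore model moderate additive batch variability (recoverable
by design) and accept that the simulated between-replicate s.e.m. is
smaller than the published one. What the generator does **not** emulate:
habituation, circadian drift, sub-second kinematics, non-Gaussian burst
shapes, or correlated noise between neighbouring wells — so passing tests
demonstrate correctness of the analysis chain, not realism of zebrafish
behaviour.

## Normalization

Fitted on the dark-acclimation window only (default: the full first dark
segment), jointly on control and treated wells, so post-offset treatment
effects cannot be absorbed:

1. OLS of per-second baseline displacement on additive batch and
   well-position factors (treatment coding, first level as reference;
   rank-deficient designs warn and fall back to the minimum-norm
   solution).
2. Each larva's residual baseline mean is kept as its idiosyncratic
   activity term; the predicted baseline of a larva (intercept + batch +
   well + residual) equals its own baseline-window mean.
3. Normalized activity = raw − predicted baseline + offset, with a single
   global offset `max(0, −min(adjusted))` so all normalized values are
   non-negative and the minimum is exactly zero when the offset binds.

Because the subtracted terms are treatment-independent in expectation,
post-offset group contrasts are preserved (verified to < 5 % relative
change on effect-free plates), while between-batch baseline variance drops
by > 90 % on plates with planted batch shifts.

## Hypothesis tests

**Hotelling's T²** (used when n₁ + n₂ − 2 ≥ p): pooled-covariance
Mahalanobis distance of the mean vectors, converted to
`F = (n₁+n₂−p−1)/(p(n₁+n₂−2))·T²` with `F_{p, n₁+n₂−p−1}` reference. The
pooled covariance is solved by Cholesky factorization; singularity raises
an explicit error, with an optional ridge `εI` that is reported in the
result when used. At p = 1 the statistic equals the squared pooled
two-sample t, and it is invariant under common invertible affine
transforms — both used as test oracles, alongside an independent
cross-check against `pingouin.multivariate_ttest`.

**High-dimensional two-sample mean test** (for p > n): statistic
`T_HD = max_j |x̄₁ⱼ − x̄₂ⱼ| / √(s₁ⱼ²/n₁ + s₂ⱼ²/n₂)`. The default
calibration permutes group labels and recomputes the fully studentized
statistic; permutation p-values are exactly uniform under exchangeability,
which is the relevant null both for mean comparison and for the
replicate-similarity criterion. A Gaussian multiplier bootstrap of the
centered data (fixed denominators) is retained as `method="multiplier"`,
but at the screen's operating point (n = 24/24, p = 30) it is measurably
anticonservative (type-I ≈ 0.10 at α = 0.05 versus ≈ 0.04 for
permutation), so it is not the default. P-values use the add-one
convention `(1 + #{T* ≥ T})/(B + 1)`, B = 1000 by default, and are
bit-reproducible given the seed.

Supporting tests: Welch's t with Satterthwaite df; Pearson χ² on 2×2
tables **without** continuity correction (the uncorrected statistic is
what reproduces the published 4.09 and 5.33 on the rod-distribution
tables, which collapse to Intermediate-vs-Weak because the Strong column
is empty in both drug groups, giving df = 1); one-way ANOVA with pooled
pairwise t-tests adjusted by Benjamini–Hochberg step-up.

## Hit calling

Per drug, with strict inequalities throughout: (1) *toxicity* — a larva is
dead when its total recorded displacement is below 5 % of the
healthy-vehicle median, and the drug is toxic when more than 50 % of its
larvae are dead (the dead/alive totals separate by two orders of
magnitude, so the rule is insensitive to the exact fraction); (2)
*consistency* — high-dimensional test between the two replicate window
matrices of normalized displacement, pass iff p > 0.9; (3) *significance*
— Hotelling against the pooled DMSO vehicle, by default required of each
replicate separately (pooled mode available), pass iff p < 0.05. A hit
must clear all three. Funnel counts are monotone by construction.

Consistency is evaluated on **normalized** windows: with replicates in
different batches, raw-trace comparisons would mostly measure the batch
shift. Per-drug seeds are spawned deterministically from the master seed
in sorted drug order.

### Sensitivity of the two-stage criterion

A point that matters for interpreting any screen scored this way: if a
drug's two replicates are genuine independent draws from the same
distribution, a calibrated similarity test yields a *uniform* p-value, so
the p > 0.9 gate passes only ~10 % of truly reproducible drugs. In our
end-to-end simulations the planted sustained-response hit is significant
against vehicle in 10/10 screens but clears consistency in only ~1/10 —
and the published screen itself passed only 4–5 of 68 non-toxic drugs
(≈ the 10 % null rate). The consistency cutoff therefore acts less as a
quality filter than as a heavy random subsample; the package implements
the criterion as defined and documents rather than hides this property.

## Dose-response analysis

Readings are normalized per experiment to the maximum per-dose mean
(strongest dose level maps to mean 1; idempotent). The fit is least
squares on log₁₀ molar dose of

    y = bottom + (top − bottom) / (1 + 10^(∓(pXC50 + log₁₀ d)·h))

(− for agonist, + for antagonist), by default the three-parameter model
(bottom, top, pXC50; hill h fixed at 1) with an opt-in variable-slope
four-parameter mode. Starting values are fixed heuristics (asymptotes from
the extreme per-dose means, pXC50 from the dose nearest half-max), the
returned RSS never exceeds the initialization RSS, and standard errors are
asymptotic (from the curvature); across-experiment mean ± SD of pXC50 is
reported separately because the two uncertainties answer different
questions. Vehicle (dose 0) wells inform normalization only. Constant
responses raise a fit error; a per-dose-mean trend contradicting the
declared orientation warns. On the half-log grid 10⁻⁹–10⁻⁵ M with 4
wells/dose and noise SD 0.05, recovery bias of a planted pXC50 is < 0.01
log units over 200 simulations.

## Problem sizes and numerical choices

Full-protocol simulations (5700 s, 864 larvae per arm) are used for the
calibration checks; screen-scale simulations in the test suite and the
worked examples use a compressed 180/120/40-s protocol that preserves the
structure the analysis depends on — a dark baseline window for the
normalization fit and ≥ 31 s of post-offset recording — chosen as a
realistic desk-scale size for repeated end-to-end runs. Trace CSVs write
floats as `%.17g` and parse with round-trip precision, so file I/O is
lossless and byte-deterministic. All randomness flows from explicit seeds
through `numpy.random.default_rng`; per-stage streams are spawned from the
master seed.

## Known limitations

- The normalization design is one concrete realization of "correct for
  baseline, per-well intensity and batch effect by linear regression";
  exact numeric parity with any particular lab's scripts is out of scope.
- The toxicity rule (5 % movement threshold, 50 % dead fraction) is a
  configurable convention; the underlying assays report only the toxic
  count, not the rule.
- Real-data headline statistics (e.g. Hotelling T = 378/456 for the
  screen's hit) require the original recordings and are not asserted;
  property-based checks on synthetic data stand in for them.
- The high-dimensional test is one member of the max-type family; other
  implementations will differ numerically while agreeing in calibration.
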