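# Methods

`metaface` implements the behavioural-analysis arm of a within-subjects TMS
psychophysics design: two-choice face discrimination (orientation or
emotion) under the method of constant stimuli, with a 4-point Perceptual
Awareness Scale (PAS) rating after every decision, performed once after
inhibitory stimulation of lateral prefrontal cortex (LPFC) and once after
stimulation of a somatosensory control site (S1). This note documents the
models, the estimation choices, and what the synthetic data generator does
and does not emulate.

## Generative model of the synthetic observers

Raw data of this kind are typically not shareable, so the package ships a
first-class simulator whose output has the exact statistical structure the
analysis assumes. Each observer is a two-stage Gaussian signal-detection
(SDT) process:

- **First stage (decision).** Stimulus class S ∈ {−1, +1}, equiprobable and
  exactly balanced within each contrast cell. Evidence
  x ~ N(S·d′(c)/2, 1); the response is sign(x − c₁) for criterion c₁.
  Sensitivity follows a Naka–Rushton contrast-response function
  d′(c) = d′_max · c^γ / (c^γ + c₅₀^γ), chosen because it is smooth,
  monotone, and spans sub- to supra-threshold performance across the six
  tested RMS contrasts (0.009–0.035). Only the tested contrasts matter
  downstream (no interpolation is ever performed), so the particular link
  is a modelling convenience, not a commitment.
- **Second stage (confidence).** The confidence report sees a corrupted
  copy of the evidence, y = x + η with η ~ N(0, σ_m). PAS is
  1 + #{k : |y − c₁| > θ_k} for three ordered thresholds, i.e. shared
  response-symmetric confidence criteria at increasing distance from the
  decision criterion.
- **Site effect.** The stimulation manipulation is modelled as an additive
  per-contrast increase of σ_m at LPFC only. Second-stage noise leaves the
  type-1 response untouched by construction, reproducing the target
  dissociation: intact d′ and overall PAS, degraded confidence–accuracy
  coupling. The default profile (0, 0.1, 0.4, 0.4, 0.1, 0) peaks at
  intermediate contrasts, where a site × contrast interaction on
  metacognition should appear.

Default design: 24 trials per contrast × 6 contrasts = 144 trials per task
per site; 28 subjects. Population parameters (means ± SD) put threshold
performance (75% correct, d′ ≈ 1.35) inside the contrast range:
d′_max 3.0 ± 0.5, c₅₀ 0.015 ± 0.003 (clipped inside the contrast range),
γ 4.0 ± 0.8, c₁ 0.0 ± 0.15, θ = (0.5, 1.0, 1.6) ± (0.1, 0.15, 0.2)
(sorted after drawing), baseline σ_m 0.3 ± 0.1 (clipped at 0). One RNG
stream per cohort; subject streams are spawned deterministically from
(cohort seed, subject index).

What the simulator does **not** emulate: sequential effects, lapses and
finger errors, learning or fatigue across the session, criterion drift,
response-specific confidence usage (exposed as a config option but not
defaulted), unequal-variance SDT, and any task difference beyond labels.
Passing recovery tests therefore show that the estimators are correct under
the model's assumptions — not that real data satisfy those assumptions.

## Type-1 summaries

d′ = z(HR) − z(FAR), c = −(z(HR) + z(FAR))/2. Extreme proportions are
handled by a configurable policy; the default replaces 0 with 1/(2N) and 1
with 1 − 1/(2N) and touches nothing else (a log-linear policy and "none"
are available). Counts live in a 2 × 2 × 4 stimulus × response × confidence
tensor with a documented nR_S1/nR_S2 serialization (per stimulus class:
response "−1" with confidence 4…1, then response "+1" with confidence 1…4),
so fixtures from the wider meta-d′ ecosystem can be replayed bit-exactly.

## Type 2 AUC

For each confidence criterion k ∈ {2, 3, 4}: type-2 hit rate
P(PAS ≥ k | correct) and false-alarm rate P(PAS ≥ k | incorrect). The AUC is
the trapezoidal area over these points plus (0,0) and (1,1), sorted by
false-alarm rate — the standard nonparametric estimator, with no smoothing
and no convex-hull correction. A cell with no correct or no incorrect
trials has no Type 2 ROC; the value propagates as NaN and the pipeline
drops such subjects from grid analyses with a log entry rather than
imputing. (At 24 trials per cell, error-free cells at high contrast are
common; the reported n per test makes the attrition visible.)

## Meta-d′

Meta-d′ is the type-1 sensitivity a metacognitively *ideal* observer would
need to produce the observed confidence data. The model: unit-variance
Gaussians at ±meta-d′/2; decision criterion fixed by the ratio-preserving
convention meta-c = c₁ · meta-d′/d′ (the standard convention of this model
family); 2(K−1) response-conditional type-2 criteria fanning outward from
meta-c. The likelihood is multinomial over confidence cells *conditional on
stimulus and response* — the observed type-1 performance enters only
through the c/d′ ratio.

- **MLE path.** Criteria are parameterized as strictly positive gaps
  (softplus transform, floor 1e-4) so the optimization is unconstrained;
  three deterministic starts at meta-d′ ∈ {0.5, 1, 1.5} × d′, L-BFGS-B
  followed by a Nelder–Mead polish, best log-likelihood wins, ties broken
  toward |meta-d′ − d′| smallest. The anchor d′/c uses the 1/(2N) policy.
- **Bayesian path.** Single-subject posterior sampled with an
  affine-invariant ensemble sampler (emcee): 24 walkers, 500 warm-up and
  500 retained steps, walkers split into 4 pseudo-chains for the
  rank-normalized split-R̂ diagnostic (threshold 1.05) and effective sample
  size. Priors: meta-d′ ~ N(d′_anchor, 2²); criterion-gap parameters
  ~ N(0, 2²) on the softplus scale — weakly informative, documented as this
  package's choice. No zero-cell-count correction is applied to the
  confidence counts, which is what makes this path usable at low trial
  numbers; the type-1 anchor still uses the extremes-only 1/(2N) adjustment
  because an anchor at HR or FAR of exactly 0/1 is infinite. Unconverged
  fits are returned flagged (with a warning and full diagnostics), never
  silently.
- **Efficiency.** meta-d′ − d′, a pure subtraction with a provenance check;
  0 for an ideal observer, negative under second-stage noise, > 0 in the
  hyper-sensitivity regime. The ratio M = meta-d′/d′ is deliberately not a
  primary metric here.

## Psychometric summaries and inclusion

Per-contrast accuracy is the exact trial proportion with a two-sided 95%
binomial CI (Clopper–Pearson by default, Wilson optional). The
near-threshold contrast is the *tested* contrast with accuracy closest to
75%, computed per task from counts pooled across sites (pooling doubles the
trial count behind the estimate; the site factor is validated separately to
not shift thresholds). Ties break toward the lower contrast, keeping the
analysis on the rising limb of the psychometric function. A subject enters
the threshold analysis iff the CI covers 75% at one or more contrasts;
exclusions are labelled ceiling, floor, or "threshold not captured".

## Group inference

- **Paired t-tests** with dz = mean(diff)/SD(diff) = t/√n; two-tailed,
  uncorrected (the report labels them as such).
- **Power** for the paired design via the noncentral t:
  power(n) = 1 − F_nct(t_crit; n−1, d√n) + F_nct(−t_crit; n−1, d√n); the
  sample-size inversion returns the exact smallest integer n meeting the
  target (bracket + binary search on the monotone power curve).
- **Wald-type statistic** W = n (Hȳ)ᵀ (H Σ̂ Hᵀ)⁺ (Hȳ) with empirical
  covariance Σ̂ and Kronecker contrasts H (P_k = I − J/k for factors in the
  effect, averaging rows otherwise); valid without sphericity or normality
  assumptions. The pseudoinverse truncates singular values below
  1e-12 × the largest covariance diagonal so exactly degenerate directions
  give W = 0 instead of amplified rounding noise. The generic Kronecker
  builder also covers the 2(task) × 2(site) × 6(contrast) extension used to
  compare the two tasks.
- **Permutation p-value.** The null distribution pools all n × 12
  observations and reassigns them at random across cells and subjects,
  recomputing W each time; p = (1 + #{W* ≥ W_obs})/(n_perm + 1) (the +1
  avoids p = 0). Default 10,000 permutations. A subject-level sign-flip
  scheme is a documented alternative but pooled reshuffling is the default.
  The asymptotic χ²(rank H) p-value is reported as a cross-check only.
- **η_p².** A Wald-type statistic has no canonical partial eta squared; the
  reported value comes from the companion classical balanced
  repeated-measures ANOVA, computed via centering projections
  (SS_eff = n‖C ȳ‖², SS_err = Σ_i ‖C(y_i − ȳ)‖²). It is a descriptive
  companion, not part of the test.
- **Within-subject SEs** (for error bars): subject-center, add back the
  grand mean, per-cell SD/√n, times the √(k/(k−1)) bias correction.
- **Contingency checks** (zero-cell-count comparisons between sites):
  Fisher's exact test for 2 × 2, a full-enumeration Freeman–Halton
  extension for 2 × M (cross-validated against R's `fisher.test`), and
  Pearson χ² without continuity correction on the same table.

## Pipeline and reproducibility

`run_threshold_analysis` and `run_contrast_analysis` (and the combined
`run_full_analysis`) consume the tidy trial table and a declarative
`AnalysisConfig`. One seed propagates to every stochastic stage; stage
seeds are derived deterministically from (seed, stage label) and kept below
2³¹. Bundles serialize to plain CSV plus a provenance block (canonical
config hash, seed, package version) and are byte-identical across runs of
the same config and seed. Filters log counts in/out at every stage.

Degenerate-input behaviour is uniform: malformed configuration raises
`ConfigError` (CLI exit 2), out-of-contract data `DataError` (exit 3),
failed estimation `EstimationError` (exit 4); undefined per-cell metrics
propagate as NaN and are dropped-with-log at the analysis stage.

## Numerical and test-scale choices

Recovery and calibration tests run at sizes chosen to make the checks
sharp while keeping the suite quick: ideal-observer and noise-ordering
checks use 10,000 trials per condition; the type-I-error calibration of the
permutation interaction test uses 500 null cohorts of 27 subjects × 1,000
permutations, with the empirical rejection rate required to fall in
[.03, .07] at the .05 level; oracle-equivalence checks use 100 (Type 2 AUC)
and 50 (meta-d′ grid search) random count tensors.

## Known limitations

- The meta-d′ model inherits the equal-variance Gaussian assumption; no
  unequal-variance or response-specific (meta-d′ per response) variant.
- No hierarchical (group-level) Bayesian meta-d′; the Bayesian fit is
  single-subject by design.
- The ensemble sampler explores a 7-parameter posterior well in practice
  (R̂ < 1.02 on the shipped examples) but is not a gradient-based sampler;
  very sparse tensors can need more draws.
- The permutation scheme destroys the subject covariance structure under
  the alternative; it is a null-calibrated test, not a bootstrap.
- Power calculations assume normally distributed paired differences.
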