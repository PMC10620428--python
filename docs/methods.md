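# Methods

## Model

Two-sample Mendelian randomisation treats each selected variant j as an
instrument for the exposure (here a drug-response biomarker on the
natural-log scale). With summary statistics
(β_Xj, σ_Xj) from the exposure GWAS and (β_Yj, σ_Yj) from an
independent outcome GWAS, the structural model is

    β_Yj = θ · β_Xj + α_j + ε_j,     ε_j ~ N(0, σ_Yj²),

where θ is the causal log-odds effect per unit of biomarker and α_j is
a possible direct (pleiotropic) effect of variant j on the outcome.
Valid instruments have α_j = 0; each estimator in the battery relaxes
this in a different direction (see below). Because the proxies are
built for biomarker-*lowering* drugs, point estimates are reported as
odds ratios per unit *decrease*: OR = exp(−θ), with 95% CI
(exp(−θ−1.96·SE), exp(−θ+1.96·SE)).

## Instrument selection

The selection flow mirrors standard cis drug-proxy practice and is
implemented exactly as staged counts so the whole funnel is auditable:

1. **Region extraction** — variants inside the union of the target's
   gene/promoter/enhancer intervals (deduplicated). The count n of this
   set is the Bonferroni denominator.
2. **Significance** — keep variants with exposure p < α/n (α = 0.05 by
   default, strict inequality).
3. **LD clumping** — greedy: repeatedly take the smallest-p unclaimed
   variant as an index (p ties broken by rsid for determinism) and
   discard unclaimed variants with r² ≥ 0.1 to the index *and* within
   1 Mb of it. The AND combination matches standard clumping semantics.
   Pairs absent from the LD matrix count as unlinked with a logged
   warning (reference panels never cover every variant); a strict mode
   errors instead.
4. **Palindrome exclusion** — A/T and C/G variants are removed
   unconditionally. Because of this, harmonisation never needs
   frequency-based strand inference and EAF is never consulted.

All in-memory coordinates are 1-based inclusive; BED input is converted
on read. The genome build is carried as config metadata and never
converted.

## Harmonisation

Outcome records are aligned to the exposure's effect allele: identical
pairs copy, swapped pairs negate β_Y, incompatible pairs are dropped
with a logged reason (as are variants missing from the outcome GWAS —
no proxy-variant substitution is attempted). Before estimation every
instrument is re-expressed with β_X ≥ 0 (joint negation), which leaves
every Wald ratio unchanged but fixes the orientation that MR-Egger
requires.

## Estimators

* **Wald ratio** (k = 1): θ = β_Y/β_X with first-order SE σ_Y/|β_X|.
  Exposure-side uncertainty is ignored, appropriate for the very large
  biomarker GWAS this design assumes.
* **IVW, multiplicative random effects** (k ≥ 2): weighted
  through-origin regression with weights 1/σ_Y². The fixed-effect SE is
  multiplied by max(1, √(Q/(k−1))) — heterogeneity inflates the SE but
  can never deflate it below the fixed-effect value.
* **Weighted median** (k ≥ 3): ratio estimates sorted, weights
  1/se(θ_j)² (first-order delta method; a second-order weight is
  available via the estimator class), point estimate by
  weighted-percentile interpolation at 50%. SE by parametric bootstrap:
  β_Xj and β_Yj resampled from normals at their stated SEs, 1,000
  replicates by default, seeded.
* **Weighted mode** (k ≥ 3): Gaussian kernel density over ratio
  estimates with the same weights; bandwidth = φ × 0.9·s·k^(−1/5) with
  s the MAD-based robust spread (φ = 1 default); the mode is the argmax
  on a 512-point grid spanning the ratio range ± 3 bandwidths. If all
  ratios coincide the common value is returned directly. SE by the same
  parametric bootstrap.
* **MR-Egger** (k ≥ 3): weighted regression *with* intercept; under
  InSIDE the intercept estimates the average direct effect and its
  two-sided normal p is the pleiotropy test. Both SEs are inflated by
  the residual scale √(RSS_w/(k−2)) floored at 1.
* **MR-RAPS** (k ≥ 3): solves the adjusted profile estimating equations
  in (θ, τ²) for standardized residuals
  t_j = (β_Yj − θβ_Xj)/√(σ_Yj² + θ²σ_Xj² + τ²), with influence function
  ψ either the identity (l2) or the Huber clip at c = 1.345 (default —
  95% efficiency at the normal). The overdispersion moment equation
  uses E[ψ(Z)Z] = 2Φ(c)−1 for the Huber loss. Solved by alternating
  bracketed root-finds in θ and τ² (τ² floored at 0), with seeded
  multi-start; the fit is deterministic given inputs and seed. SE by
  the sandwich formula with an HC1-style small-sample factor k/(k−p);
  when τ̂² sits on the boundary the one-parameter sandwich is used.
* **MR-PRESSO** (k ≥ 4): the observed statistic is the leave-one-out
  weighted residual sum of squares
  RSS = Σ_j (β_Yj − θ̂₋ⱼβ_Xj)²/σ_Yj². Its null distribution is built by
  parametric simulation (β*_Xj ~ N(β_Xj, σ_Xj), β*_Yj ~ N(θ̂₋ⱼβ_Xj,
  σ_Yj); 1,000 replicates by default) and all empirical p-values use
  the (1 + exceedances)/(n_sim + 1) correction, so they are never zero.
  Per-variant outlier p-values rank each observed weighted squared
  residual in its own simulated distribution and are Bonferroni
  multiplied by k (note the attainable floor k/(n_sim+1): detecting
  outliers among 20 variants at 0.05 requires n_sim ≳ 1,000). The
  outlier-corrected estimate is IVW on the unflagged set. The
  distortion test compares (θ_corrected − θ_full)/|θ_full| against the
  same quantity after removing random same-size subsets of the
  *non-flagged* variants — sampling from all variants would put a floor
  of about 1/k on the p-value because the flagged subset itself can be
  redrawn.

## Diagnostics

Cochran's Q uses the fixed-effect IVW slope and k−1 degrees of freedom
(one fitted parameter). Leave-one-out re-fits IVW k times. Cook's
distances come from the weighted through-origin regression
(D_j = r_j²·h_j/(1−h_j) with p = 1 parameter, leverage
h_j = w_jβ_Xj²/Σw β_X²); the default threshold is the common 4/k rule
and is configurable, and the full battery is re-run on the surviving
set. Scatter and funnel tables (ratio vs precision with per-method
reference slopes) are emitted as data; figure rendering is left to the
user.

## Synthetic data generator

The generator emulates exactly the statistical structure the estimators
assume, on the summary-statistic scale — no individual-level genotypes
are simulated, and outcome effects are drawn directly on the log-odds
scale. Defaults are pitched at the scale of the motivating application,
an 18-variant cis proxy for a log-biomarker analysed against a large
case-control GWAS:

| parameter | default | meaning |
|---|---|---|
| k | 18 | instrument count |
| theta_true | 0.58 | log-odds per unit log-biomarker (OR/decrease 0.56) |
| beta_x_scale | 0.08 | exposure effects: \|β_X\| ~ U(0.5, 1.5)·scale, random sign |
| se_x | 0.005 | exposure SE (a ~10⁵–10⁶-participant biomarker GWAS) |
| se_y | 0.04 | outcome SE (log-odds; gives IVW SE ≈ 0.11 at k = 18) |
| pleiotropy | none | α_j regime: none / balanced / directional / inside_violating |
| pleiotropy_scale | 0.0 | α_j magnitude (log-odds) |
| pleiotropy_frac | 1.0 | fraction of instruments receiving α_j |
| palindrome_frac | 0.0 | fraction of A/T–C/G variants |
| outcome_flip_frac | 0.25 | outcome rows stored on the swapped allele orientation |

Directional direct effects are defined on the biomarker-increasing
orientation (α_j is attached with the sign of the true β_Xj), so that
after estimation-time orientation they have mean +magnitude — this is
what makes the regime directional for MR-Egger rather than collapsing
to balanced under joint sign flips. `pleiotropy_frac < 1` produces the
contaminated design (some instruments invalid, the rest clean) used to
study robust-estimator breakdown. The region-scenario generator plants
a selection funnel whose outcome is known by construction: significant
variants inside gene/promoter intervals, LD blocks whose lowest-p
member must survive clumping, palindromic singletons that must be
dropped last, and non-significant decoys both inside the regions
(inflating the Bonferroni denominator) and outside.

What the generator does *not* emulate: realistic human LD maps, allele
frequency spectra, winner's-curse selection of instruments, sample
overlap between the two GWAS, and case-control ascertainment effects.
Passing tests therefore demonstrate correctness of the estimators and
pipeline under the stated generative model, not robustness to every
artefact of real GWAS data.

## Numerical choices and problem sizes

* CIs use the normal 1.96 multiplier throughout (bootstrap SEs feed the
  same formula); p-values are two-sided normal except Q (upper-tail χ²).
* Clumping ties in p are broken lexicographically by rsid; output is
  position-sorted. LD matrices must be symmetric to 1e-8 and are then
  symmetrised exactly.
* Summary-statistic files are parsed with round-trip float precision,
  so write→read reproduces every field bit-identically.
* RAPS root-finding uses Brent brackets expanded from the IVW start,
  tolerance 1e-13 in θ, 200 alternations maximum, 6 seeded starts.
* Monte-Carlo test sizes: null calibration uses 2,000 replicates
  (type-I error and coverage), robustness ordering 500 paired
  replicates, outlier-detection power 40 runs with n_sim = 1,000 —
  sizes chosen so binomial noise is well inside the asserted bands
  while the whole suite stays interactive.

## Validation strategy

The per-variant instrument tables of published drug-target analyses are
not redistributed with the package, so validation is synthetic and
property-based end to end: closed-form oracle equivalence for
IVW/Egger/Q (against statsmodels WLS) and for clumping (against an
independent step-by-step simulation of the greedy rule), exact
accounting on planted selection scenarios, null calibration and CI
coverage at the study scale, directional-pleiotropy robustness ordering
(weighted median vs IVW), PRESSO power and distortion behaviour, and
byte-identical determinism of pipeline reports. `scripts/acceptance.py`
recomputes all of these from scratch with a single seed.

## Known limitations

* No multivariable or bidirectional MR, no Steiger filtering, no
  contamination-mixture/CAUSE estimators.
* No proxy-variant substitution for instruments missing from the
  outcome GWAS; they are dropped and logged.
* Weighted-median/mode weights ignore exposure-side uncertainty
  (first-order); RAPS is the estimator that models σ_X.
* The MR-PRESSO implementation is simulation-based only and inherits
  Monte-Carlo floors on its p-values.
* LD handling assumes a single ancestry's r² matrix supplied by the
  user; no multi-ancestry weighting.
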