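# Methods

## Data model and conventions

All summary statistics are per-variant records (`VariantAssoc`) with
effect/other allele, effect-allele frequency, effect size, SE, p-value and
sample size.  Effects are log odds ratios for binary traits and SD units
for quantitative traits.  Positions are 1-based inclusive everywhere;
BED-like locus files are converted on read.  Records with SE ≤ 0,
non-ACGT or identical alleles, EAF outside [0,1] or p outside (0,1] are
dropped at ingest and counted in an audit; a p-value inconsistent with
|β/SE| is only flagged, since published tables round.

The 95% normal quantile is fixed at 1.959964 (the value implicit in
published confidence intervals) so that SEs reconstructed from printed
`OR (lower, upper)` cells — `se = (ln U − ln L)/(2z)` — are stable.
Reconstruction from rounded CIs reproduces most published fixed-effect
pooled ORs to ±0.003 and I² to ±1 point; two rows (ERBB3 and MMP12 in the
atopic-dermatitis panel) deviate slightly more, which bounds what CI-level
reconstruction can recover.

## Instrument selection and harmonization

Filters run in a fixed order — cis window, significance, MHC — with
per-filter removal counts.  The cis window is measured from the gene-body
ends (start − 1 Mb, end + 1 Mb, closed interval), since "upstream or
downstream of the gene" does not distinguish TSS from gene body; the MHC
interval is chr6:26–34 Mb, closed, any overlap excluded.  LD pruning is
greedy in ascending p (ties broken lexicographically by variant id, for
determinism): a variant is kept iff r² < 0.001 against every variant
already kept.  Pruning is done per protein.

Harmonization aligns outcome records to the exposure effect allele,
resolving swapped and strand-complemented alleles by sign/EAF flips.
Palindromic variants (A/T, C/G) are dropped when EAF ∈ (0.42, 0.58) — the
common two-sample-MR default, as no threshold is stated in the source
analyses — or when EAF is missing; surviving palindromes are aligned by
EAF concordance.

## Estimators

* **Wald ratio** β̂ᵧ/β̂ₓ with first-order SE σᵧ/|β̂ₓ| (second-order
  delta-method SE available).
* **IVW**: weighted regression of outcome on exposure effects through the
  origin, weights 1/σ²ᵧ.  The SE uses multiplicative overdispersion
  scaling max(1, √(Q/(J−1))) by default — the common two-sample default;
  a fixed-effect switch exists.  Under the null with 50 strong
  instruments this is mildly conservative (empirical size ≈ 0.042,
  coverage ≈ 95.8% over 2,000 replicates).
* **MR-Egger**: instruments oriented to β̂ₓ ≥ 0, weighted least squares
  with free intercept; the intercept estimates average directional
  pleiotropy, and its SE carries the same overdispersion scaling.
* **Weighted median**: ratio estimates ordered, weights β̂ₓ²/σ²ᵧ,
  midpoint-cumulative weights linearly interpolated at 0.5.  The SE is a
  seeded parametric bootstrap (default 1,000 draws).  With interpolation,
  splitting an instrument into two half-weight copies can move the
  estimate within one adjacent-ratio gap; exact invariance holds only for
  the non-interpolated definition.
* **MR-PRESSO**: observed RSS from leave-one-out IVW predictions; the
  null distribution re-computes the same statistic on each of 1,000
  seeded parametric draws of both effect vectors.  Per-instrument
  empirical p-values are Bonferroni-corrected; outliers (corrected
  p < 0.05) are removed and IVW re-run.  Both p-values use the
  add-one permutation convention (1 + #{≥ obs})/(n + 1).
* **RAPS**: the profile-likelihood score
  Σ (β̂ᵧ − θβ̂ₓ)(β̂ₓσ²ᵧ + θβ̂ᵧσ²ₓ)/(σ²ᵧ + θ²σ²ₓ)² = 0, solved by bracketed
  root search expanding around the IVW solution (the score decays at
  large |θ|, so a fixed wide bracket can straddle no sign change).  This
  score is unbiased under exposure-side measurement error — the source of
  weak-instrument dilution in IVW — and reduces to the IVW normal
  equation when σₓ → 0.  A simpler score of the form
  Σ (β̂ᵧ − θβ̂ₓ)β̂ₓ/(σ²ᵧ + θ²σ²ₓ) is *not* used: it is biased under
  exposure noise and, whenever exposure and outcome SEs share the
  2f(1−f)n allele-frequency scaling, collapses to IVW exactly.  The SE is
  the observed-information value 1/√(−ψ′(θ̂)).  An optional multiplicative
  overdispersion inflates it by the mean squared standardized residual.
* **Policy**: PRESSO-corrected if the global test is significant with
  outliers found; else Egger if the intercept p < 0.05; else IVW (Wald
  for single-instrument proteins).  The selection reason is recorded.

FDR control is Benjamini–Hochberg within each outcome across proteins.

## Directionality

Per-variant explained variance uses r² = z²/(z² + n − 2), which needs no
allele frequencies and works for binary traits; instrument r² values are
summed on each side (independence after pruning).  The Steiger statistic
is the Fisher-z difference with independent-samples SE (non-overlapping
cohorts); "direction ok" requires both r²_exposure > r²_outcome and
p < 0.05.  Reverse MR runs the full suite with the disease's genome-wide
significant variants as instruments at a corrected threshold p < 0.01.
A protein is excluded only when the Steiger test fails AND reverse MR is
significant; with forward-causal synthetic data the false-removal rate is
0 over 500 seeds.

## Meta-analysis

Fixed-effect inverse-variance pooling with Cochran's Q and
I² = max(0, (Q − df)/Q)·100.  I² > 50 (strict) switches to
DerSimonian–Laird random effects, τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) —
the standard moment estimator the I²-switch convention implies; REML is
not implemented.  The implementation matches `metafor`'s DL and FE fits
to 10⁻⁹ on a reference dataset.  Replication passes when the pooled
p < 0.05 and the pooled sign matches discovery — a criterion inferred
from the published verdicts (a pooled p = 0.186 row is marked failed) and
recorded here as a package decision.  Cohorts with missing estimates are
pooled over whatever is available.

## Colocalization

Wakefield log-ABF per SNP: ½ln(V/(V+W)) + z²W/(2(V+W)), with prior effect
SD W^½ = 0.15 for quantitative and 0.2 for binary traits (the cited
method's conventional defaults; only the configuration priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ are stated by the source analysis).  Hypothesis
sums follow the single-causal-variant identities, with the H3 cross term
ΣB₁ΣB₂ − ΣB₁B₂ evaluated via log-sum-exp and log1p so z ≈ 40 inputs do
not overflow.  Only variants present in both datasets enter; one shared
SNP makes H3 exactly impossible.  The implementation agrees with
brute-force enumeration over all (M+1)² causal configurations to 10⁻¹⁰
on small regions.

## External validation, PPI and tiers

TWAS/PWAS association is the weighted score z = wᵀz/√(wᵀRw); under the
null with identity LD this is exactly standard normal (empirical size
0.046 at 500 seeds).  External validation passes when either study is
FDR-significant below 0.05; requiring direction concordance is a
configurable flag, OFF by default, because the published flags apply it
inconsistently.  PPI linkage demands a direct edge with interaction score
≥ 0.4 to a known drug target; path-based linkage is a non-default option.

Tier rules are evaluated in order (excluded → 1 → 2 → 3 → 4), first match
wins, every clause outcome recorded in a rationale.  Tier 3 is read
conjunctively — PPH4 > 0.8 AND (replication ∨ external ∨ PPI) — which
reproduces the internally consistent atopic-dermatitis section of the
published decision table exactly; the disjunctive "or solely PPI-linked"
reading is available via a flag.  One published asthma row (IL6R) is
labelled a tier lower than any consistent rule produces and is not used
as an anchor.

## Synthetic data

Generators are pure functions of (config, seed).  For instruments:
EAF ~ U(0.1, 0.9); exposure SE 1/√(2f(1−f)N_exp); outcome (binary) SE
1/√(2f(1−f)N_out·v) with case-balance factor v = 0.25 — the logistic-GWAS
scaling for a balanced design; true effects |γⱼ| ~ N(μ, γ_sd²) with μ set
so the expected exposure z reaches 8 (> the genome-wide threshold of
5.45) for every instrument, i.e. instruments arrive pre-selected, with a
decoy switch emitting sub-threshold variants for filter tests.  Effect
signs are random by default; recovery studies of directional pleiotropy
set them positive, because pleiotropy is sign-coupled to the variant
coding and mixed signs cancel the Egger intercept after orientation.  An
invalid fraction receives αⱼ ~ N(α_mean, α_sd²) added to the outcome
effect.  Cohort series share γⱼ and draw θₖ ~ N(θ, τ²) with independent
noise.  Colocalization regions use AR(1) LD, marginal z-means Σλ and
z ~ MVN(Σλ, Σ).  Defaults (N_exp = 7,000; N_out = 450,000; 4 cohorts)
mirror a plasma-proteomics discovery cohort feeding a biobank-scale
binary GWAS.

What the generators do **not** emulate: realistic MAF spectra and LD
beyond AR(1), sample overlap between exposure and outcome, winner's
curse in instrument selection, and individual-level genotypes.  Passing
recovery tests therefore demonstrates correctness of the estimators and
decision logic under the stated model, not robustness to those
real-data features.

## Problem sizes and numerics

Simulation suites use 2,000 replicates for null calibration, 500 seeds
for bias/recovery comparisons, and 200 seeds for MR-PRESSO detection and
colocalization power — sizes at which the Monte-Carlo error is well
inside each acceptance band.  Root finding uses Brent's method at
xtol = 10⁻¹²; bootstrap and simulation draws use `numpy` Generator
streams seeded per call; p-values are floored at 10⁻³⁰⁰ to avoid
underflow to zero at extreme z.  Output TSVs print floats at 10
significant digits, making repeated runs byte-identical.

## Known limitations

CI-reconstructed random-effects rows of the published replication table
do not reproduce under DL pooling (the source's exact random-effects
variant is unknown); multivariable MR, SuSiE-style multi-causal
colocalization, proxy-SNP lookup and winner's-curse correction are out of
scope; the Steiger r² sum assumes post-pruning independence.
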