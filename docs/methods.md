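# Methods

This note documents the statistical model behind `targetmr`, the choices made
where the design was genuinely open, what the synthetic data generator does
and does not emulate, and the numerical conventions. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Two-sample MR with correlated instruments

The units of analysis are summary statistics: for each variant *j* of a gene
region, an estimated SNP-exposure effect β̂ₓⱼ (per SD of expression or
protein level) with standard error sₓⱼ, an estimated SNP-outcome effect β̂ᵧⱼ
(log-odds for binary outcomes, SD units for quantitative ones) with sᵧⱼ, and
the LD correlation matrix ρ of the instruments from a reference panel. The
structural assumption is the instrumental-variable triad: instruments are
associated with the exposure (enforced by the FDR < 0.05 QTL inclusion
filter), share no confounder with the outcome (plausible by Mendelian
inheritance), and affect the outcome only through the exposure (the
exclusion restriction — probed, not assumed, by the Egger intercept,
heterogeneity statistics, colocalization and specificity re-analysis).

Because clumping uses r² < 0.2 rather than full independence — trading a
little redundancy for power and testability of bias — the estimators model
the correlation explicitly. The exposure and outcome samples are disjoint
("two-sample"), so cross-covariance between β̂ₓ and β̂ᵧ is zero. The
within-study sampling covariance of β̂ᵧ is approximated by Σ = D ρ D with
D = diag(sᵧ); this is the standard first-order approximation for marginal
association estimates from a single cohort.

### Estimators

* **Wald ratio** (J = 1): θ̂ = β̂ᵧ/β̂ₓ. Default SE is the second-order delta
  method √(sᵧ²/βₓ² + βᵧ²sₓ²/βₓ⁴); the first-order form sᵧ/|βₓ| is a switch
  (`second_order=False`), since single-SNP toolchains commonly default to
  first order. β̂ₓ = 0 is a hard error ("weak/degenerate instrument").
* **IVW (GLS)**: θ̂ = (βₓᵀΣ⁻¹βₓ)⁻¹βₓᵀΣ⁻¹βᵧ. With identity ρ this is exactly
  the classical inverse-variance-weighted mean of Wald ratios with weights
  βₓⱼ²/sᵧⱼ². J = 1 delegates to the Wald ratio, exactly.
* **MR-Egger**: instruments are first oriented so every β̂ₓⱼ ≥ 0 (joint sign
  flip of (βₓⱼ, βᵧⱼ) and conjugation of ρ — all estimators are invariant
  under such flips, which are pure relabelings of the effect allele). GLS of
  βᵧ on [1, βₓ]; the slope is the causal estimate, consistent under the
  InSIDE assumption even with directional pleiotropy, and the intercept θ₀
  estimates the mean direct effect.
* **Maximum likelihood**: maximize the joint normal likelihood of (β̂ₓ, β̂ᵧ)
  with means (γ, θγ) over the nuisance true effects γ ∈ ℝᴶ and θ, with
  covariance blocks DₓρDₓ and DᵧρDᵧ. BFGS from γ = β̂ₓ, θ = θ̂_IVW, gradient
  tolerance 1e-8, at most 500 iterations; non-convergence raises with the
  final gradient norm. SE from the inverse observed information (analytic
  Hessian). For J = 1 the profile likelihood collapses analytically to the
  Wald ratio, and the implementation delegates so the identity is exact.
* **Weighted median**: linear interpolation of the weighted empirical
  quantile function of the per-SNP ratios at 0.5 (breakpoints
  pⱼ = (Sⱼ − wⱼ/2)/S_J, first-order inverse-variance weights wⱼ = βₓⱼ²/sᵧⱼ²);
  consistent when ≥ 50% of weight is valid.
* **Weighted mode**: mode of the inverse-variance-weighted Gaussian-kernel
  density of the ratios, bandwidth φ·0.9·min(sd, IQR/1.349)·J^(−1/5) with
  φ = 1 by default; consistent when the largest group of agreeing
  instruments is valid.

Median and mode SEs come from a parametric bootstrap (default 1000
replicates) that resamples (β̂ₓⱼ, β̂ᵧⱼ) from their sampling normals with an
explicit seed; repeated calls with the same seed are bit-identical.

### Random-effects inflation and test calibration

Whether the IVW/Egger SEs should be inflated for heterogeneity is a genuine
design choice; common MR packages use a *floored* multiplicative factor
φ = max(1, √(Q/df)) with normal p-values. That rule is conservative by
construction: because Q ~ χ²(df) independently of θ̂ under the model, its
exact null rejection rate at α = 0.05 is

E[2Φ̄(1.96·max(1, √(Q/df)))] ≈ 0.039 at J = 10 (0.037 at J = 4),

not 0.05. `targetmr` instead defaults to the exact multiplicative
random-effects model: φ = √(Q/(J−1)) without the floor and t(J−1) p-values
for IVW at J ≥ 4 (fixed-effect, normal p for J < 4, where a scale estimate
from 1–2 residual degrees of freedom would be useless), and φ = √(Q_E/(J−2))
with t(J−2) for Egger slope and intercept. Since φ²·df is χ²(df) and
independent of the GLS coefficients, (θ̂−θ)/se is exactly t-distributed and
the nominal test size is exact — the property the calibration tests verify
by simulation. The floored convention remains available as
`inflation="floored"` (and `"fixed"` disables inflation); the φ actually
applied is recorded on every estimate together with the reference
distribution of its p-value.

### Diagnostics

Generalized Cochran's Q = (βᵧ − θ̂βₓ)ᵀΣ⁻¹(βᵧ − θ̂βₓ) is evaluated at the IVW
θ̂ (not re-estimated per method) with df = J−1 and an upper-tail χ² p-value;
I² = max(0, (Q−df)/Q). Egger residual Q uses df = J−2. Pass conventions,
with boundary values passing: Q passes iff p ≥ 0.05, I² passes iff
I² ≤ 0.50, the Egger intercept passes iff its two-sided t(J−2) p ≥ 0.05.
Direction consistency between phases/methods is strict sign agreement;
θ̂ = 0 carries no direction and counts as inconsistent.

## Harmonization

The outcome study is aligned to the exposure study's effect alleles:
swapped alleles negate βᵧ and reflect eaf → 1−eaf; strand flips (A↔T, C↔G)
are relabelled; combinations resolve to a flip. Palindromic variants (A/T,
G/C) cannot be disambiguated by labels, so they are kept only when both
allele frequencies exist and both fall outside [0.42, 0.58] — a common
harmonization default — and are then oriented by frequency; otherwise they
are excluded as `palindromic_ambiguous`, and a missing frequency on a
palindromic variant is conservatively excluded too. Irreconcilable allele
pairs are excluded as `allele_mismatch`, never silently kept. Multi-allelic
records are rejected at parse time. Harmonization is idempotent, and
swapping+negating every outcome record leaves the harmonized result
invariant (both property-tested). Coordinates are 1-based GRCh37.

## Instrument selection

Per gene: variants within gene ± 5 kb (inclusive bounds) on the gene's
chromosome; QTLs significant at study-wide Benjamini–Hochberg FDR < 0.05;
greedy LD clumping — repeatedly take the remaining variant with the smallest
exposure p-value (ties broken by lexicographic variant id, making the result
input-order invariant) and discard everything at ρ² ≥ threshold against any
selected index. Variants missing from the LD panel are dropped with a log
entry by default (a hard-error policy is available).

Steiger filtering is gene-level: the gene is kept iff Σⱼ r²ₓⱼ > Σⱼ r²ᵧⱼ with
r² = t²/(t²+n−2) and, for binary traits, effective n = 4/(1/n_cases +
1/n_controls). Ties drop the gene — the filter exists to remove genes that
do *not* explain more exposure variance. The specificity re-analysis keeps
only variants mapped to exactly the target gene in the QTL source's
SNP-gene map; an unmapped variant is treated as non-specific.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor,
log ABF = ½(log(1−r) + r·z²) with r = W/(W+se²). Prior effect variances,
not stated by the upstream convention's users and configurable here:
W = 0.15² for quantitative traits and 0.2² (log-odds) for binary traits.
Region priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. With S1 = Σⱼ ABF1ⱼ, S2 = Σⱼ ABF2ⱼ
and S12 = Σⱼ ABF1ⱼ·ABF2ⱼ, the unnormalized hypothesis masses are L0 = 1,
L1 = p1·S1, L2 = p2·S2, L3 = p1·p2·(S1·S2 − S12), L4 = p12·S12. Everything
runs in log space; the H3 subtraction uses log1p(−exp(·)), which is safe
because S1·S2 ≥ S12 always (all cross terms positive) with equality exactly
for a single-SNP region, where PPH3 = 0 by construction. Colocalization is
attempted on the full (unclumped) cis-window statistics — the configuration
sums need the whole region, not an LD-thinned subset — and interpreted only
when powered (PPH3+PPH4 ≥ 0.8); strong evidence is PPH4 ≥ 0.75. An
unpowered region yields a blank evidence cell, never a failure.

## Meta-analysis and inflation

The replication outcome is combined METAL-style: zᵢ = sign(βᵢ)·Φ⁻¹(1−pᵢ/2),
z_meta = Σ wᵢzᵢ/√(Σ wᵢ²) with wᵢ = √Nᵢ (effective N for case-control
studies). p-to-z conversion uses `scipy`'s inverse survival function, which
is accurate into the far tail; p = 0 or 1 is a hard error to be clamped
upstream by explicit policy. Betas/SEs for downstream MR are reconstructed
from z on the per-allele scale using the pooled effective sample size and
the emission convention below. λ = median(z²)/0.4549364 and
λ₁₀₀₀ = 1 + (λ−1)(1/n_cases + 1/n_controls)/(2/1000) are reported in the
run manifest; inflation is never applied as a correction.

## Study design and multiplicity

Discovery significance is BH FDR < 0.05 *within each exposure-tissue ×
outcome scope* (blood-risk genes corrected together, brain-risk genes
corrected together); this grouping is configurable because coarser and finer
readings are defensible. Replication, age-at-onset follow-up and pQTL
validation use nominal p < 0.05; replication additionally requires sign
agreement with discovery. Each progression outcome gets its own independent
FDR screen. The sensitivity re-analysis re-clumps at r² < 0.001 and
computes IVW for J ≥ 2 plus Egger/median/mode for J ≥ 3 ("more than 1–2
SNPs" is read exactly this way). pQTL instruments are p < 5×10⁻⁶ in their
source with no cis restriction (trans pQTLs are legitimate instruments for
protein levels); multiple sources must agree in sign for support. Evidence
flags requiring J > 2 are "not testable" at J ≤ 2, mirroring blank cells in
a printed evidence table, and rows are ordered by descending pass count.
Discovery significance is decided by the Wald/IVW primary estimate only;
ML and Egger act as confirmatory flags.

## The synthetic data generator

Simulation happens directly at the summary-statistic level. For a region
with AR(1) LD (ρⱼₖ = decay^|j−k|, positive definite by construction) and
true per-SNP standardized effects γ, marginal effects are ρ·γ and estimates
are drawn as ρ·γ + L·ε·se with L the Cholesky factor of ρ, so sampling
noise carries the same LD correlation a single real cohort would produce.
On the standardized scale se = 1/√n (quantitative) or 2/√n_eff (log-odds);
emission divides by √(2f(1−f)) to the conventional per-allele scale, so the
serialized se matches 1/√(2f(1−f)n). Exposure effects are emitted for
standardized expression by construction — the "per SD of expression" unit
is an assumption about the real resources but a property of the simulator.

Defaults are the emulated study conditions: blood QTL n = 31,684; brain
QTL n = 1,387; discovery outcome 13,708 cases / 95,282 controls;
replication 8,036 / 5,803 built as a sample-size-weighted meta-analysis of
3 independent sub-studies; age-at-onset n = 17,996 (quantitative);
progression n = 4,093; pQTL n = 3,301. Causal QTL effects are 0.15–0.35 SD
per allele (top cis-eQTL scale, ~2–10% of expression variance), 3 causal
QTLs per gene, LD decay 0.9 within regions of 60 SNPs spanning gene ± 5 kb,
MAF uniform on (0.05, 0.5), ~1/6 palindromic variants, and outcome tables
emitted with random allele swaps (30%) and strand flips (15%) so
harmonization is genuinely exercised. θ = 0.3 for causal genes.

Scenario semantics: `causal` (θ ≠ 0), `null` (real cis-QTLs, θ = 0 — the
genes on which FDR control is meaningful; a no-QTL exposure is available
via `n_causal_qtls=0`), `pleiotropic_artifact` (θ = 0, the strongest QTL
has a direct outcome effect of 0.10, and its SNP is mapped to a second gene
so the specificity filter bites), `linkage_distinct_variants` (θ = 0, the
outcome variant sits > 25 SNPs from the QTLs, pairwise ρ² < 0.01 at the
default decay — the H3 truth), and `reverse_causation` (a primary outcome
association of 0.12 with an induced QTL signal at ratio 0.3, making
r²-outcome ≈ 3× r²-exposure so Steiger removes it; the induced exposure z
still passes the QTL inclusion filter, as a real reverse signal would).
The default suite bundles, per tissue: 100 null + 5 causal + 2 pleiotropic
+ 2 linkage + 2 reverse genes; two causal genes also shift age at onset
(θ = −0.3) and two shift the first progression marker (θ = 0.5).

One master seed fans out through CRC32-tagged `SeedSequence` children, so
any single table regenerates byte-identically without the rest, and a full
study rerun under the same seed writes byte-identical artifacts (fixed
`%.10g` float formatting, sorted orderings, no timestamps).

What the generator does **not** emulate: realistic human LD (block
structure, long-range LD), allele-frequency spectra of the real panels,
sample overlap between studies, population stratification, winner's-curse
selection in the QTL sources, or genotype-level data. Passing tests
therefore demonstrate the correctness and calibration of the machinery
under the stated model, not robustness to those real-data pathologies.

## Numerical conventions

- ρ gets a 1e-8 diagonal ridge before every inversion/Cholesky; residual
  non-PSD failures are hard `ld_singular` errors.
- p-values are floored at ~1e-320 to stay inside (0, 1].
- Q is floored at 0; I² at 0.
- Tables are tab-delimited text with "NA" missing values; LD matrices are
  square tab-delimited with variant-id header row and column.
- Problem sizes in the validation suite — 2000-replicate calibrations,
  1000-replicate recovery, 500-replicate Steiger, 200-replicate coloc
  ensembles on 200-SNP regions, and 10–20 seeded full-study runs of the
  111-gene × 2-tissue suite — were chosen to give Monte-Carlo standard
  errors comfortably inside the asserted bands while keeping a full run in
  the low minutes on one CPU.

## Known limitations

- The Σ = DρD approximation ignores the (small) contribution of effect-size
  variance to the covariance of marginal estimates.
- Weak-instrument bias is not corrected, only made negligible by the QTL
  inclusion filter; no conditional/joint (COJO-style) selection or
  fine-mapping-based instrument choice.
- No MR-PRESSO outlier removal, multivariable MR, Rucker model selection,
  or SuSiE-style multi-causal colocalization — deliberately out of scope.
- The bootstrap for median/mode ignores instrument correlation (standard
  practice, slightly anticonservative at r² close to the clumping bound).
- Binary-outcome effective-n conventions (4/(1/n₁+1/n₀)) are approximations
  that degrade for extreme case-control imbalance.
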