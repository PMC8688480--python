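# targetmr

Drug-target Mendelian randomization (MR) on GWAS/QTL summary statistics:
a library and pipeline for asking, gene by gene across the druggable genome,
whether genetically determined expression (or protein level) of a target
causally shifts a disease outcome — the *in silico* analogue of a
pharmacological trial of that target.

It is written for statistical geneticists and drug-discovery informaticians
who work with cis-eQTL/pQTL resources (eQTLGen- or PsychENCODE-style tables)
and disease GWAS summary statistics, and who need the full evidence-triage
design rather than a single estimator: discovery screen, independent
replication, sensitivity and specificity re-analyses, heterogeneity and
pleiotropy diagnostics, Bayesian colocalization, and a tri-state evidence
matrix per gene × outcome × tissue.

## The method

For gene *g* with harmonized instruments *j = 1..J* (cis-QTLs clumped at
r² < 0.2), SNP-exposure effects **β**ₓ (per SD of expression), SNP-outcome
effects **β**ᵧ (log-odds for case-control outcomes) and LD correlation
matrix **ρ**, the causal effect θ per 1-SD increase in expression is
estimated by:

- **Wald ratio** (J = 1): θ̂ = βᵧ/βₓ, SE by the second-order delta method;
- **IVW, generalized to correlated instruments**: with Σ = D**ρ**D,
  D = diag(seᵧ),

  θ̂ = (**β**ₓᵀΣ⁻¹**β**ₓ)⁻¹ **β**ₓᵀΣ⁻¹**β**ᵧ

  with multiplicative random-effects SE scaling φ = √(Q/(J−1)) and t(J−1)
  p-values for J ≥ 4 (exactly calibrated; see `docs/methods.md`);
- **MR-Egger**: GLS of **β**ᵧ on [1, **β**ₓ] after orienting βₓⱼ ≥ 0; the
  intercept θ₀ estimates directional pleiotropy;
- **maximum likelihood**: joint normal likelihood over (θ, γ) with exposure
  and outcome covariance blocks Dₓ**ρ**Dₓ and Dᵧ**ρ**Dᵧ;
- **weighted median / weighted mode** sensitivity estimators (bootstrap SEs)
  at the stricter r² < 0.001 clumping.

Supporting machinery: generalized Cochran's Q = (**β**ᵧ − θ̂**β**ₓ)ᵀΣ⁻¹(**β**ᵧ −
θ̂**β**ₓ) with I² = max(0, (Q−df)/Q); Steiger filtering (a gene is dropped
when its instruments explain more outcome than exposure variance,
r² = t²/(t²+n−2) with effective n for binary traits); Wakefield
approximate-Bayes-factor colocalization with priors p1 = p2 = 10⁻⁴,
p12 = 10⁻⁵, a power gate PPH3+PPH4 ≥ 0.8 and strong evidence at
PPH4 ≥ 0.75; sample-size-weighted (METAL-style) meta-analysis with genomic
inflation λ and its λ₁₀₀₀ rescaling; and Benjamini–Hochberg FDR applied
within each exposure-tissue × outcome scope.

Because the real consortium datasets are access-controlled, the package
ships a first-class synthetic-data generator (`targetmr.synthetic_data`)
that emulates their statistical structure at the summary-statistic level
with known ground truth — causal, null, pleiotropic-artifact,
linkage-of-distinct-variants and reverse-causation genes — so every stage of
the pipeline is testable end to end.

## Worked example

```python
import targetmr as mr
from targetmr.pipeline import StudyConfig, StudyData, run_full_study

suite = mr.generate_scenario_suite(7)          # 111 genes x 2 tissues, known truth
data = StudyData.from_suite(suite)
config = StudyConfig(seed=7, tissues=("blood", "brain"),
                     progression_outcomes=("prog_motor",))
result = run_full_study(data, config)

m = result.manifest
print(f"discovery hits: {m['n_discovery_hits']}")
print(f"replication lambda: {m['replication_inflation']['lambda']:.3f} "
      f"(lambda_1000 = {m['replication_inflation']['lambda_1000']:.3f})")
top = result.evidence.iloc[0]
print(f"top gene: {top.gene_id} ({top.tissue}, {top.outcome_id}), "
      f"J={top.n_snps}, theta={top.theta_hat:+.3f}, flags passed {top.n_pass}/11")
```

prints

```
discovery hits: 11
replication lambda: 1.140 (lambda_1000 = 1.021)
top gene: GENE0101 (blood, risk_discovery), J=6, theta=+0.285, flags passed 11/11
```

Reading: 11 gene × tissue pairs passed the BH-corrected discovery screen
(FDR < 0.05). The meta-analysed replication cohort shows mild genomic
inflation (λ = 1.140) that becomes negligible when rescaled to a
1000-case/1000-control study (λ₁₀₀₀ = 1.021). The best-supported gene is
estimated to raise disease risk by θ̂ = +0.285 log-odds per SD of expression
(OR ≈ 1.33) from 6 correlated instruments, and passes all 11 evidence flags
(replication, ML/Egger confirmation, intercept/Q/I² diagnostics, pQTL
support, strong colocalization, r² = 0.001 robustness, SNP specificity,
direction consistency). Its generator ground truth is a causal gene with
θ = 0.3 — the pipeline recovered it and its effect size. The same study runs
from the shell:

```sh
targetmr simulate --seed 7 --out-dir study_data
targetmr run-all --data-dir study_data --out-dir results --seed 7
```

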