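"""Orchestration of the full drug-target MR study design.

Stages, mirroring the discovery-replication triage the package implements:

1. **Discovery screen** per exposure tissue against the discovery outcome:
   cis-window filter -> FDR-significant QTLs -> harmonization -> LD clumping
   at r^2 < 0.2 -> Steiger filter -> Wald/IVW estimate -> BH correction
   across genes within the (tissue x outcome) scope, significant at q < 0.05.
2. **Replication** of discovery hits against an independent cohort at nominal
   p < 0.05 with direction consistency.
3. **Follow-up** of risk hits against an age-at-onset analogue (nominal
   p < 0.05) and independent FDR screens per progression analogue.
4. **Sensitivity**: re-clumping at r^2 < 0.001 with IVW / MR-Egger /
   weighted-median / weighted-mode where enough SNPs survive.
5. **Specificity**: re-analysis after removing SNPs associated with any
   other gene's expression.
6. **Colocalization** of the full (unclumped) region statistics.
7. **pQTL validation** (p < 5e-6 instruments, trans permitted).
8. **Evidence matrix**: one row per gene x outcome x tissue of tri-state
   pass/fail/not-testable flags, ordered by descending pass count.

Every computation is deterministic given the config seed; rerunning a study
writes byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .colocalization import ColocPriors, ColocResult, coloc_posteriors
from .diagnostics import (HeterogeneityResult, direction_consistency,
                          egger_intercept_test, generalized_q)
from .estimators import (EstimationError, MrEstimate, egger_correlated,
                         ivw_correlated, max_likelihood, weighted_median,
                         weighted_mode)
from .instruments import (SteigerResult, bh_fdr, cis_window_filter,
                          greedy_clump, specificity_filter, steiger_filter)
from .meta import genomic_lambda, lambda_1000
from .summary_data import (BINARY, GeneAnnotation, InstrumentSet, LdMatrix,
                           VariantAssociation, build_instrument_set)

PASS, FAIL, NT = "pass", "fail", "not_testable"

FLOAT_FMT = "%.10g"  # fixed table float formatting => byte-identical reruns


@dataclass(frozen=True)
class StudyConfig:
    """Resolved thresholds and naming of the study's inputs."""

    seed: int = 0
    tissues: tuple[str, ...] = ("blood", "brain")
    discovery_outcome: str = "risk_discovery"
    replication_outcome: str = "risk_replication"
    age_at_onset_outcome: str | None = "age_at_onset"
    progression_outcomes: tuple[str, ...] = ()
    pqtl_sources: tuple[str, ...] = ()
    r2_clump: float = 0.2
    r2_sensitivity: float = 0.001
    fdr: float = 0.05                 # discovery / progression significance
    alpha_nominal: float = 0.05       # replication / follow-up / pQTL
    exposure_fdr: float = 0.05        # QTL inclusion threshold
    cis_window: int = 5_000
    pqtl_p_threshold: float = 5e-6
    coloc_priors: ColocPriors = ColocPriors()
    boot_reps: int = 1000
    inflation: str = "multiplicative"

    def validate(self, study: "StudyData") -> None:
        """Fail fast, before any computation, if the config names missing data."""
        for t in self.tissues:
            if t not in study.exposures:
                raise ValueError(f"exposure tissue {t!r} not in study data")
        if not self.tissues:
            raise ValueError("config must name at least one exposure tissue")
        for name in (self.discovery_outcome, self.replication_outcome):
            if not name or name not in study.outcomes:
                raise ValueError(f"required outcome {name!r} not in study data")
        if self.age_at_onset_outcome and self.age_at_onset_outcome not in study.outcomes:
            raise ValueError(f"outcome {self.age_at_onset_outcome!r} not in study data")
        for name in self.progression_outcomes:
            if name not in study.outcomes:
                raise ValueError(f"outcome {name!r} not in study data")
        for name in self.pqtl_sources:
            if name not in study.pqtl:
                raise ValueError(f"pQTL source {name!r} not in study data")


@dataclass
class StudyData:
    """All inputs of one study: exposures, outcomes, LD, annotations, maps."""

    genes: list[GeneAnnotation]
    exposures: dict[str, pd.DataFrame]
    outcomes: dict[str, pd.DataFrame]
    ld: dict[str, LdMatrix]
    snp_gene_map: dict[str, set[str]]
    pqtl: dict[str, pd.DataFrame] = field(default_factory=dict)

    @classmethod
    def from_suite(cls, suite) -> "StudyData":
        return cls(genes=list(suite.genes), exposures=dict(suite.exposures),
                   outcomes=dict(suite.outcomes), ld=dict(suite.ld),
                   snp_gene_map=dict(suite.snp_gene_map), pqtl=dict(suite.pqtl))

    @classmethod
    def from_directory(cls, path) -> "StudyData":
        """Load a bundle written by :meth:`ScenarioSuite.write`."""
        from .instruments import read_snp_gene_map
        from .summary_data import read_ld_matrix
        path = Path(path)
        genes_df = pd.read_csv(path / "genes.tsv", sep="\t", dtype={"chrom": str,
                               "druggability_tier": str})
        genes = [GeneAnnotation(r.gene_id, r.symbol, r.chrom, int(r.start),
                                int(r.end), r.druggability_tier)
                 for r in genes_df.itertuples()]
        exposures = {p.stem.removeprefix("exposure_"): _read_table(p)
                     for p in sorted(path.glob("exposure_*.tsv"))}
        outcomes = {p.stem.removeprefix("outcome_"): _read_table(p)
                    for p in sorted(path.glob("outcome_*.tsv"))}
        pqtl = {p.stem.removeprefix("pqtl_"): _read_table(p)
                for p in sorted(path.glob("pqtl_*.tsv"))}
        ld = {p.stem: read_ld_matrix(p) for p in sorted((path / "ld").glob("*.tsv"))}
        return cls(genes=genes, exposures=exposures, outcomes=outcomes, ld=ld,
                   snp_gene_map=read_snp_gene_map(path / "snp_gene_map.tsv"),
                   pqtl=pqtl)


def _read_table(p) -> pd.DataFrame:
    return pd.read_csv(p, sep="\t", dtype={"chrom": str}, na_values=["NA"],
                       keep_default_na=False)


# ---------------------------------------------------------------------------
# Row <-> record conversion
# ---------------------------------------------------------------------------

def _rows_to_assocs(df: pd.DataFrame) -> list[VariantAssociation]:
    out = []
    for r in df.itertuples(index=False):
        d = r._asdict()
        def _num(key):
            v = d.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return float(v)
        out.append(VariantAssociation(
            variant_id=d["variant_id"], chrom=str(d["chrom"]), pos=int(d["pos"]),
            effect_allele=d["effect_allele"], other_allele=d["other_allele"],
            beta=float(d["beta"]), se=float(d["se"]), pvalue=float(d["pvalue"]),
            trait_id=d["trait_id"], eaf=_num("eaf"), n=_num("n"),
            n_cases=_num("n_cases"), n_controls=_num("n_controls"),
            trait_type=d.get("trait_type") or "quantitative"))
    return out


# ---------------------------------------------------------------------------
# Per-gene MR recipe
# ---------------------------------------------------------------------------

STATUS_SIGNIFICANT = "significant"
STATUS_NOT_SIGNIFICANT = "not_significant"
STATUS_NO_INSTRUMENTS = "skipped_no_instruments"
STATUS_STEIGER = "skipped_steiger"


@dataclass
class GeneAnalysis:
    """Outcome of the per-gene MR recipe against one outcome."""

    gene_id: str
    outcome_id: str
    tissue: str
    status: str
    estimate: MrEstimate | None = None
    instruments: InstrumentSet | None = None
    steiger: "SteigerResult | None" = None
    heterogeneity: HeterogeneityResult | None = None

    @property
    def n_snps(self) -> int:
        return len(self.instruments) if self.instruments else 0


def analyze_gene(
    gene: GeneAnnotation,
    exposure_rows: pd.DataFrame,
    outcome_indexed: pd.DataFrame,
    ld: LdMatrix,
    tissue: str,
    outcome_id: str,
    config: StudyConfig,
    r2: float | None = None,
    apply_steiger: bool = True,
    apply_cis_window: bool = True,
) -> GeneAnalysis:
    """cis filter -> harmonize -> clump -> Steiger -> Wald/IVW estimate."""
    r2 = config.r2_clump if r2 is None else r2
    qtls = _rows_to_assocs(exposure_rows)
    if apply_cis_window:
        qtls = cis_window_filter(qtls, gene, config.cis_window)
    if not qtls:
        return GeneAnalysis(gene.gene_id, outcome_id, tissue, STATUS_NO_INSTRUMENTS)
    ids = [v.variant_id for v in qtls]
    out_rows = outcome_indexed.loc[outcome_indexed.index.intersection(ids)]
    out_assocs = _rows_to_assocs(out_rows.reset_index(drop=True))
    inst, _harm = build_instrument_set(gene, qtls, out_assocs, ld, tissue)
    if inst is None:
        return GeneAnalysis(gene.gene_id, outcome_id, tissue, STATUS_NO_INSTRUMENTS)
    inst = greedy_clump(inst, r2)
    if len(inst) == 0:
        return GeneAnalysis(gene.gene_id, outcome_id, tissue, STATUS_NO_INSTRUMENTS)
    steiger = None
    if apply_steiger:
        steiger = steiger_filter(inst)
        if not steiger.keep:
            return GeneAnalysis(gene.gene_id, outcome_id, tissue, STATUS_STEIGER,
                                instruments=inst, steiger=steiger)
    try:
        est = ivw_correlated(inst, inflation=config.inflation)
    except EstimationError:
        return GeneAnalysis(gene.gene_id, outcome_id, tissue, STATUS_NO_INSTRUMENTS,
                            instruments=inst, steiger=steiger)
    het = generalized_q(inst, est.theta_hat) if len(inst) >= 2 else None
    ga = GeneAnalysis(gene.gene_id, outcome_id, tissue, STATUS_NOT_SIGNIFICANT,
                      estimate=est, instruments=inst, steiger=steiger,
                      heterogeneity=het)
    return ga


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Per gene x outcome x tissue screen outcome with its BH q-value."""

    gene_id: str
    outcome_id: str
    tissue: str
    status: str
    estimate: MrEstimate | None = None
    q_value: float | None = None
    instruments: InstrumentSet | None = None
    steiger: "SteigerResult | None" = None
    heterogeneity: HeterogeneityResult | None = None

    @property
    def significant(self) -> bool:
        return self.status == STATUS_SIGNIFICANT


def _significant_exposure(df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Study-wide BH over all QTL p-values; keep q < threshold rows."""
    q = bh_fdr(df["pvalue"].to_numpy())
    return df.loc[q < threshold]


def run_screen(
    study: StudyData,
    tissue: str,
    outcome_name: str,
    config: StudyConfig,
    significance: str = "fdr",
) -> list[ScreenResult]:
    """Screen every gene of one tissue against one outcome.

    BH correction runs across all genes within this (tissue x outcome) scope;
    ``significance="nominal"`` skips BH and uses p < alpha (replication /
    follow-up convention).  Every excluded gene carries an explicit status.
    """
    exposure = study.exposures[tissue]
    sig_rows = _significant_exposure(exposure, config.exposure_fdr)
    by_gene = dict(tuple(sig_rows.groupby("trait_id", sort=False)))
    out_indexed = study.outcomes[outcome_name].set_index("variant_id", drop=False)

    analyses: list[GeneAnalysis] = []
    for gene in study.genes:
        rows = by_gene.get(gene.gene_id)
        if rows is None or rows.empty:
            analyses.append(GeneAnalysis(gene.gene_id, outcome_name, tissue,
                                         STATUS_NO_INSTRUMENTS))
            continue
        analyses.append(analyze_gene(gene, rows, out_indexed,
                                     study.ld[gene.gene_id], tissue,
                                     outcome_name, config))

    results: list[ScreenResult] = []
    tested = [a for a in analyses if a.estimate is not None]
    if tested:
        qvals = bh_fdr([a.estimate.pvalue for a in tested])
    qmap = {id(a): q for a, q in zip(tested, qvals)} if tested else {}
    for a in analyses:
        q = qmap.get(id(a))
        status = a.status
        if a.estimate is not None:
            if significance == "fdr":
                hit = q < config.fdr
            else:
                hit = a.estimate.pvalue < config.alpha_nominal
            status = STATUS_SIGNIFICANT if hit else STATUS_NOT_SIGNIFICANT
        results.append(ScreenResult(a.gene_id, a.outcome_id, a.tissue, status,
                                    a.estimate, q, a.instruments, a.steiger,
                                    a.heterogeneity))
    return results


def run_replication(
    hits: Sequence[ScreenResult],
    study: StudyData,
    config: StudyConfig,
    outcome_name: str | None = None,
) -> dict[tuple[str, str], dict]:
    """Replicate discovery hits against an independent outcome cohort.

    Replicated iff nominal p < alpha AND the effect direction matches the
    discovery estimate.  Hits without usable instruments in the replication
    outcome are flagged not_testable.  The two outcome cohorts must not share
    individuals; that disjointness is the caller's responsibility.
    """
    outcome_name = outcome_name or config.replication_outcome
    out_indexed = study.outcomes[outcome_name].set_index("variant_id", drop=False)
    gene_by_id = {g.gene_id: g for g in study.genes}
    flags: dict[tuple[str, str], dict] = {}
    for hit in hits:
        key = (hit.gene_id, hit.tissue)
        exposure = study.exposures[hit.tissue]
        sig = _significant_exposure(exposure, config.exposure_fdr)
        rows = sig.loc[sig["trait_id"] == hit.gene_id]
        ga = analyze_gene(gene_by_id[hit.gene_id], rows, out_indexed,
                          study.ld[hit.gene_id], hit.tissue, outcome_name, config)
        if ga.estimate is None:
            flags[key] = {"flag": NT, "estimate": None, "status": ga.status}
            continue
        consistent = direction_consistency([hit.estimate, ga.estimate])
        ok = ga.estimate.pvalue < config.alpha_nominal and consistent
        flags[key] = {"flag": PASS if ok else FAIL, "estimate": ga.estimate,
                      "direction_consistent": consistent, "status": ga.status}
    return flags


def run_sensitivity_r2_001(
    hits: Sequence[ScreenResult],
    study: StudyData,
    config: StudyConfig,
    outcome_name: str | None = None,
) -> dict[tuple[str, str], dict]:
    """Re-clump discovery hits at r^2 < 0.001 and re-estimate.

    Robust iff the primary (Wald/IVW) estimate stays nominally significant
    with the discovery sign.  With >= 3 surviving SNPs the IVW, MR-Egger,
    weighted-median and weighted-mode estimates are all recorded; with 2,
    median/mode are not testable and IVW is still computed.
    """
    outcome_name = outcome_name or config.discovery_outcome
    out_indexed = study.outcomes[outcome_name].set_index("variant_id", drop=False)
    gene_by_id = {g.gene_id: g for g in study.genes}
    results: dict[tuple[str, str], dict] = {}
    for hit in hits:
        key = (hit.gene_id, hit.tissue)
        exposure = study.exposures[hit.tissue]
        sig = _significant_exposure(exposure, config.exposure_fdr)
        rows = sig.loc[sig["trait_id"] == hit.gene_id]
        ga = analyze_gene(gene_by_id[hit.gene_id], rows, out_indexed,
                          study.ld[hit.gene_id], hit.tissue, outcome_name,
                          config, r2=config.r2_sensitivity)
        entry: dict = {"estimates": {}, "n_snps": ga.n_snps}
        if ga.estimate is None:
            entry["flag"] = NT
            results[key] = entry
            continue
        entry["estimates"]["primary"] = ga.estimate
        if ga.n_snps >= 3 and ga.instruments is not None:
            seed = _derive_seed(config.seed, "sensitivity", hit.gene_id, hit.tissue)
            for name, fn in (
                ("egger", lambda i: egger_correlated(i, inflation=config.inflation)),
                ("weighted_median", lambda i: weighted_median(i, config.boot_reps, seed)),
                ("weighted_mode", lambda i: weighted_mode(i, 1.0, config.boot_reps, seed)),
            ):
                try:
                    entry["estimates"][name] = fn(ga.instruments)
                except EstimationError:
                    pass
        ok = (ga.estimate.pvalue < config.alpha_nominal
              and direction_consistency([hit.estimate, ga.estimate]))
        entry["flag"] = PASS if ok else FAIL
        results[key] = entry
    return results


def run_specificity(
    hits: Sequence[ScreenResult],
    study: StudyData,
    config: StudyConfig,
    outcome_name: str | None = None,
) -> dict[tuple[str, str], dict]:
    """Re-analysis keeping only SNPs associated with no other gene's expression."""
    outcome_name = outcome_name or config.discovery_outcome
    results: dict[tuple[str, str], dict] = {}
    for hit in hits:
        key = (hit.gene_id, hit.tissue)
        if hit.instruments is None:
            results[key] = {"flag": NT, "status": "no_specific_instruments"}
            continue
        specific = specificity_filter(hit.instruments, study.snp_gene_map)
        if len(specific) == 0:
            results[key] = {"flag": NT, "status": "no_specific_instruments"}
            continue
        try:
            est = ivw_correlated(specific, inflation=config.inflation)
        except EstimationError:
            results[key] = {"flag": NT, "status": "estimation_failed"}
            continue
        ok = (est.pvalue < config.alpha_nominal
              and direction_consistency([hit.estimate, est]))
        results[key] = {"flag": PASS if ok else FAIL, "estimate": est,
                        "n_snps": len(specific)}
    return results


def run_coloc(
    hits: Sequence[ScreenResult],
    study: StudyData,
    config: StudyConfig,
    outcome_name: str | None = None,
) -> dict[tuple[str, str], ColocResult]:
    """Colocalize the full (unclumped) region statistics of each hit."""
    outcome_name = outcome_name or config.discovery_outcome
    out_indexed = study.outcomes[outcome_name].set_index("variant_id", drop=False)
    gene_by_id = {g.gene_id: g for g in study.genes}
    results: dict[tuple[str, str], ColocResult] = {}
    for hit in hits:
        gene = gene_by_id[hit.gene_id]
        exposure = study.exposures[hit.tissue]
        rows = exposure.loc[exposure["trait_id"] == hit.gene_id]
        qtls = cis_window_filter(_rows_to_assocs(rows), gene, config.cis_window)
        ids = [v.variant_id for v in qtls]
        out_rows = out_indexed.loc[out_indexed.index.intersection(ids)]
        from .summary_data import harmonize
        harm = harmonize(qtls, _rows_to_assocs(out_rows.reset_index(drop=True)))
        if not harm.exposure:
            continue
        results[(hit.gene_id, hit.tissue)] = coloc_posteriors(
            harm.exposure, harm.outcome, config.coloc_priors,
            gene_id=hit.gene_id, outcome_id=outcome_name)
    return results


def run_pqtl_validation(
    hits: Sequence[ScreenResult],
    study: StudyData,
    config: StudyConfig,
    outcome_name: str | None = None,
) -> dict[str, dict]:
    """Validate hit genes with protein-QTL instruments (p < 5e-6, trans allowed).

    Per source: the usual MR recipe without the cis-window restriction;
    support requires p < alpha.  Cross-source and eQTL-vs-pQTL direction
    concordance are recorded; sources disagreeing in sign fail support.
    """
    outcome_name = outcome_name or config.discovery_outcome
    out_indexed = study.outcomes[outcome_name].set_index("variant_id", drop=False)
    gene_by_id = {g.gene_id: g for g in study.genes}
    results: dict[str, dict] = {}
    for gene_id in sorted({h.gene_id for h in hits}):
        gene = gene_by_id[gene_id]
        per_source: dict[str, MrEstimate] = {}
        for source, table in sorted(study.pqtl.items()):
            if config.pqtl_sources and source not in config.pqtl_sources:
                continue
            rows = table.loc[(table["trait_id"] == gene_id)
                             & (table["pvalue"] < config.pqtl_p_threshold)]
            if rows.empty:
                continue
            ga = analyze_gene(gene, rows, out_indexed, study.ld[gene_id],
                              f"pqtl:{source}", outcome_name, config,
                              apply_cis_window=False)
            if ga.estimate is not None:
                per_source[source] = ga.estimate
        if not per_source:
            results[gene_id] = {"flag": NT, "sources": {}}
            continue
        ests = list(per_source.values())
        signs_agree = len(ests) < 2 or direction_consistency(ests)
        all_sig = all(e.pvalue < config.alpha_nominal for e in ests)
        eqtl_dirs = [h.estimate for h in hits
                     if h.gene_id == gene_id and h.estimate is not None]
        eqtl_concordant = (direction_consistency([eqtl_dirs[0], ests[0]])
                           if eqtl_dirs else None)
        flag = PASS if (all_sig and signs_agree) else FAIL
        results[gene_id] = {"flag": flag, "sources": per_source,
                            "signs_agree": signs_agree,
                            "eqtl_concordant": eqtl_concordant}
    return results


def _derive_seed(seed: int, *tags: str) -> int:
    import zlib
    h = seed & 0x7FFFFFFF
    for t in tags:
        h = (h * 1_000_003 + zlib.crc32(str(t).encode())) & 0x7FFFFFFF
    return h


# ---------------------------------------------------------------------------
# Evidence matrix
# ---------------------------------------------------------------------------

EVIDENCE_FLAGS = [
    "replication", "significant_max_likelihood", "significant_egger",
    "egger_intercept_pass", "cochran_q_pass", "i2_pass", "pqtl_support",
    "coloc_strong", "r2_001_robust", "specificity_robust",
    "direction_consistent",
]


def assemble_evidence(
    hits: Sequence[ScreenResult],
    replication: Mapping[tuple[str, str], dict],
    sensitivity: Mapping[tuple[str, str], dict],
    specificity: Mapping[tuple[str, str], dict],
    coloc: Mapping[tuple[str, str], ColocResult],
    pqtl: Mapping[str, dict],
    config: StudyConfig,
) -> pd.DataFrame:
    """One tri-state flag row per hit, ordered by descending pass count.

    Flags needing > 2 SNPs (Egger-based, heterogeneity, median/mode-backed
    diagnostics) are not-testable when J <= 2, matching the blank cells of a
    printed evidence table; an unpowered colocalization is blank, never a
    failure.
    """
    rows = []
    for hit in hits:
        key = (hit.gene_id, hit.tissue)
        J = len(hit.instruments) if hit.instruments else 0
        flags: dict[str, str] = {}

        rep = replication.get(key, {"flag": NT})
        flags["replication"] = rep["flag"]

        ml_est = egger_est = None
        if hit.instruments is not None and J >= 2:
            try:
                ml_est = max_likelihood(hit.instruments)
            except EstimationError:
                pass
        if hit.instruments is not None and J >= 3:
            try:
                egger_est = egger_correlated(hit.instruments,
                                             inflation=config.inflation)
            except EstimationError:
                pass
        flags["significant_max_likelihood"] = (
            NT if ml_est is None
            else PASS if ml_est.pvalue < config.alpha_nominal else FAIL)
        flags["significant_egger"] = (
            NT if egger_est is None
            else PASS if egger_est.pvalue < config.alpha_nominal else FAIL)
        if egger_est is not None:
            ok, _p = egger_intercept_test(egger_est)
            flags["egger_intercept_pass"] = PASS if ok else FAIL
        else:
            flags["egger_intercept_pass"] = NT
        if J >= 3 and hit.heterogeneity is not None:
            flags["cochran_q_pass"] = PASS if hit.heterogeneity.q_pass else FAIL
            flags["i2_pass"] = PASS if hit.heterogeneity.i2_pass else FAIL
        else:
            flags["cochran_q_pass"] = flags["i2_pass"] = NT

        flags["pqtl_support"] = pqtl.get(hit.gene_id, {"flag": NT})["flag"]

        cres = coloc.get(key)
        if cres is None or not cres.powered:
            flags["coloc_strong"] = NT
        else:
            flags["coloc_strong"] = PASS if cres.strong else FAIL

        flags["r2_001_robust"] = sensitivity.get(key, {"flag": NT})["flag"]
        flags["specificity_robust"] = specificity.get(key, {"flag": NT})["flag"]

        comparable = [e for e in (hit.estimate, ml_est, egger_est,
                                  rep.get("estimate")) if e is not None]
        flags["direction_consistent"] = (
            NT if len(comparable) < 2
            else PASS if direction_consistency(comparable) else FAIL)

        row = {"gene_id": hit.gene_id, "outcome_id": hit.outcome_id,
               "tissue": hit.tissue, "n_snps": J,
               "theta_hat": hit.estimate.theta_hat if hit.estimate else np.nan,
               **flags}
        row["n_pass"] = sum(1 for f in EVIDENCE_FLAGS if flags[f] == PASS)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["gene_id", "outcome_id", "tissue",
                                     "n_snps", "theta_hat", *EVIDENCE_FLAGS,
                                     "n_pass"])
    if not df.empty:
        df = df.sort_values(["n_pass", "gene_id", "tissue", "outcome_id"],
                            ascending=[False, True, True, True],
                            kind="mergesort").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def screen_table(results: Sequence[ScreenResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        e = r.estimate
        h = r.heterogeneity
        binary = e is not None and any(
            o.trait_type == BINARY for o in (r.instruments.outcome if r.instruments else []))
        lo, hi = e.confidence_interval() if e else (np.nan, np.nan)
        rows.append({
            "gene_id": r.gene_id, "outcome_id": r.outcome_id, "tissue": r.tissue,
            "status": r.status, "method": e.method if e else "",
            "n_snps": r.instruments and len(r.instruments) or 0,
            "theta_hat": e.theta_hat if e else np.nan,
            "se": e.se_theta if e else np.nan,
            "pvalue": e.pvalue if e else np.nan,
            "q_value": r.q_value if r.q_value is not None else np.nan,
            "or": np.exp(e.theta_hat) if e and binary else np.nan,
            "ci_low": np.exp(lo) if e and binary else lo,
            "ci_high": np.exp(hi) if e and binary else hi,
            "phi": e.phi if e else np.nan,
            "pvalue_dist": e.pvalue_dist if e else "",
            "q_stat": h.Q if h else np.nan,
            "q_df": h.df if h else np.nan,
            "q_pvalue": h.p_Q if h else np.nan,
            "i2": h.I2 if h else np.nan,
            "steiger_r2_exposure": r.steiger.r2_exposure if r.steiger else np.nan,
            "steiger_r2_outcome": r.steiger.r2_outcome if r.steiger else np.nan,
        })
    return pd.DataFrame(rows)


def coloc_table(results: Mapping[tuple[str, str], ColocResult]) -> pd.DataFrame:
    rows = []
    for (gene_id, tissue), c in sorted(results.items()):
        rows.append({"gene_id": gene_id, "outcome_id": c.outcome_id,
                     "tissue": tissue, "n_snps": c.n_snps,
                     "pph0": c.pph0, "pph1": c.pph1, "pph2": c.pph2,
                     "pph3": c.pph3, "pph4": c.pph4,
                     "powered": c.powered, "strong": c.strong})
    return pd.DataFrame(rows, columns=["gene_id", "outcome_id", "tissue",
                                       "n_snps", "pph0", "pph1", "pph2",
                                       "pph3", "pph4", "powered", "strong"])


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Everything run_full_study produced, plus the manifest describing it."""

    config: StudyConfig
    screens: dict[tuple[str, str], list[ScreenResult]]  # (tissue, outcome)
    replication: dict
    followup_aao: dict
    progression_screens: dict[tuple[str, str], list[ScreenResult]]
    sensitivity: dict
    specificity: dict
    coloc: dict
    pqtl: dict
    evidence: pd.DataFrame
    manifest: dict

    @property
    def discovery_hits(self) -> list[ScreenResult]:
        hits = []
        for (tissue, outcome), res in sorted(self.screens.items()):
            if outcome == self.config.discovery_outcome:
                hits.extend(r for r in res if r.significant)
        return hits


def run_full_study(
    study: StudyData,
    config: StudyConfig,
    out_dir=None,
) -> StudyResult:
    """Discovery -> replication -> follow-up -> sensitivity -> specificity ->
    coloc -> pQTL -> evidence matrix, with all artifacts written on request."""
    config.validate(study)

    screens: dict[tuple[str, str], list[ScreenResult]] = {}
    hits: list[ScreenResult] = []
    for tissue in config.tissues:
        res = run_screen(study, tissue, config.discovery_outcome, config)
        screens[(tissue, config.discovery_outcome)] = res
        hits.extend(r for r in res if r.significant)

    replication = run_replication(hits, study, config)

    followup_aao: dict = {}
    if config.age_at_onset_outcome:
        followup_aao = run_replication(hits, study, config,
                                       outcome_name=config.age_at_onset_outcome)

    progression_screens: dict[tuple[str, str], list[ScreenResult]] = {}
    prog_hits: list[ScreenResult] = []
    for outcome in config.progression_outcomes:
        for tissue in config.tissues:
            res = run_screen(study, tissue, outcome, config)
            progression_screens[(tissue, outcome)] = res
            prog_hits.extend(r for r in res if r.significant)

    sensitivity = run_sensitivity_r2_001(hits, study, config)
    specificity = run_specificity(hits, study, config)
    coloc = run_coloc(hits, study, config)
    pqtl = run_pqtl_validation(hits, study, config) if study.pqtl else {}

    evidence = assemble_evidence(hits, replication, sensitivity, specificity,
                                 coloc, pqtl, config)
    # progression hits get their own evidence rows (no replication cohort or
    # pQTL panel exists for them -> those flags are not testable)
    if prog_hits:
        prog_sens = {}
        prog_spec = {}
        prog_coloc = {}
        by_outcome: dict[str, list[ScreenResult]] = {}
        for h in prog_hits:
            by_outcome.setdefault(h.outcome_id, []).append(h)
        for outcome, hs in sorted(by_outcome.items()):
            prog_sens.update(run_sensitivity_r2_001(hs, study, config,
                                                    outcome_name=outcome))
            prog_spec.update(run_specificity(hs, study, config,
                                             outcome_name=outcome))
            prog_coloc.update(run_coloc(hs, study, config, outcome_name=outcome))
        prog_ev = assemble_evidence(prog_hits, {}, prog_sens, prog_spec,
                                    prog_coloc, {}, config)
        evidence = pd.concat([evidence, prog_ev], ignore_index=True)
        evidence = evidence.sort_values(
            ["n_pass", "gene_id", "tissue", "outcome_id"],
            ascending=[False, True, True, True],
            kind="mergesort").reset_index(drop=True)

    manifest = _build_manifest(study, config, screens, hits, replication,
                               progression_screens, evidence)
    result = StudyResult(config, screens, replication, followup_aao,
                         progression_screens, sensitivity, specificity,
                         coloc, pqtl, evidence, manifest)
    if out_dir is not None:
        write_study_result(result, out_dir)
    return result


def _build_manifest(study, config, screens, hits, replication,
                    progression_screens, evidence) -> dict:
    rep_name = config.replication_outcome
    rep = study.outcomes[rep_name]
    z = (rep["beta"] / rep["se"]).to_numpy()
    lam = genomic_lambda(z)
    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "config": _config_dict(config),
        "inputs": {
            "n_genes": len(study.genes),
            "tissues": {t: int(len(study.exposures[t])) for t in config.tissues},
            "outcomes": {k: int(len(v)) for k, v in sorted(study.outcomes.items())},
            "pqtl_sources": sorted(study.pqtl),
        },
        "replication_inflation": {"lambda": lam},
        "n_discovery_hits": len(hits),
        "n_progression_hits": int(sum(
            sum(r.significant for r in res) for res in progression_screens.values())),
        "n_evidence_rows": int(len(evidence)),
    }
    if rep["n_cases"].notna().all():
        manifest["replication_inflation"]["lambda_1000"] = lambda_1000(
            lam, int(rep["n_cases"].iloc[0]), int(rep["n_controls"].iloc[0]))
    return manifest


def _config_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def write_study_result(result: StudyResult, out_dir) -> None:
    """Write every result table plus the manifest; reruns are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _w(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, na_rep="NA",
                  float_format=FLOAT_FMT)

    for (tissue, outcome), res in sorted(result.screens.items()):
        _w(screen_table(res), f"screen_{tissue}_{outcome}.tsv")
    for (tissue, outcome), res in sorted(result.progression_screens.items()):
        _w(screen_table(res), f"screen_{tissue}_{outcome}.tsv")

    rep_rows = [{"gene_id": g, "tissue": t, "flag": v["flag"],
                 "pvalue": v["estimate"].pvalue if v.get("estimate") else np.nan,
                 "theta_hat": v["estimate"].theta_hat if v.get("estimate") else np.nan}
                for (g, t), v in sorted(result.replication.items())]
    _w(pd.DataFrame(rep_rows, columns=["gene_id", "tissue", "flag", "pvalue",
                                       "theta_hat"]), "replication.tsv")
    aao_rows = [{"gene_id": g, "tissue": t, "flag": v["flag"],
                 "pvalue": v["estimate"].pvalue if v.get("estimate") else np.nan,
                 "theta_hat": v["estimate"].theta_hat if v.get("estimate") else np.nan}
                for (g, t), v in sorted(result.followup_aao.items())]
    _w(pd.DataFrame(aao_rows, columns=["gene_id", "tissue", "flag", "pvalue",
                                       "theta_hat"]), "followup_age_at_onset.tsv")

    sens_rows = []
    for (g, t), v in sorted(result.sensitivity.items()):
        row = {"gene_id": g, "tissue": t, "flag": v["flag"],
               "n_snps": v.get("n_snps", 0)}
        for name, e in v.get("estimates", {}).items():
            row[f"theta_{name}"] = e.theta_hat
            row[f"p_{name}"] = e.pvalue
        sens_rows.append(row)
    _w(pd.DataFrame(sens_rows), "sensitivity_r2_001.tsv")

    spec_rows = [{"gene_id": g, "tissue": t, "flag": v["flag"],
                  "n_snps": v.get("n_snps", 0)}
                 for (g, t), v in sorted(result.specificity.items())]
    _w(pd.DataFrame(spec_rows, columns=["gene_id", "tissue", "flag", "n_snps"]),
       "specificity.tsv")

    _w(coloc_table(result.coloc), "coloc.tsv")

    pqtl_rows = []
    for g, v in sorted(result.pqtl.items()):
        for source, e in sorted(v.get("sources", {}).items()):
            pqtl_rows.append({"gene_id": g, "source": source, "flag": v["flag"],
                              "theta_hat": e.theta_hat, "pvalue": e.pvalue})
        if not v.get("sources"):
            pqtl_rows.append({"gene_id": g, "source": "", "flag": v["flag"],
                              "theta_hat": np.nan, "pvalue": np.nan})
    _w(pd.DataFrame(pqtl_rows, columns=["gene_id", "source", "flag",
                                        "theta_hat", "pvalue"]), "pqtl.tsv")

    _w(result.evidence, "evidence.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    with open(out / "summary.txt", "w") as fh:
        fh.write(render_summary(result))


def render_summary(result: StudyResult) -> str:
    """Plain-text forest-style per-gene summary of the evidence matrix."""
    lines = ["drug-target MR evidence summary", "=" * 32, ""]
    ev = result.evidence
    if ev.empty:
        lines.append("no significant gene-outcome pairs")
    for row in ev.itertuples(index=False):
        theta = getattr(row, "theta_hat")
        bar = "+" if theta > 0 else "-"
        lines.append(f"{row.gene_id:<10} {row.tissue:<6} {row.outcome_id:<18} "
                     f"theta={theta:+.3f} {bar * min(20, int(abs(theta) * 20) + 1)}")
        flagbits = ", ".join(
            f"{f}={getattr(row, f)}" for f in EVIDENCE_FLAGS)
        lines.append(f"    [{row.n_pass:2d} pass] {flagbits}")
    return "\n".join(lines) + "\n"
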