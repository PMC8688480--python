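"""Ground-truth-known synthetic GWAS/QTL summary statistics.

Simulation happens directly at the summary-statistic (marginal beta) level —
the only level any consumer in this package touches — which is orders of
magnitude faster than genotype-level simulation and exact for the quantities
that matter here.  Internally everything lives on the standardized-genotype /
standardized-trait scale, where for a region with LD correlation matrix rho
and true per-SNP effects gamma:

* marginal effects are rho @ gamma,
* estimates are drawn as  b_hat = rho @ gamma + L eps * se,  L = chol(rho),
  so sampling noise is LD-correlated exactly as in a real single cohort,
* se = 1/sqrt(n) for quantitative traits and 2/sqrt(n_eff) on the log-odds
  scale for binary traits, n_eff = 4/(1/n_cases + 1/n_controls).

Emitted tables are converted to the conventional per-allele scale by dividing
by sqrt(2 f (1-f)), so the serialized se matches 1/sqrt(2 f (1-f) n).

Scenarios (recorded per gene in the truth manifest):

* ``causal`` — cis-QTLs exist and expression causally shifts the outcome
  (theta != 0);
* ``null`` — cis-QTLs exist but theta = 0 (the MR null; these genes are what
  FDR control is measured on);
* ``pleiotropic_artifact`` — theta = 0 but the strongest QTL has a direct
  (horizontal-pleiotropic) outcome effect;
* ``linkage_distinct_variants`` — theta = 0; the outcome signal sits on a
  distinct variant in weak LD (rho^2 < 0.01) with the QTLs;
* ``reverse_causation`` — the outcome association is primary and the
  apparent QTL signal is downstream of it, so instruments explain more
  outcome than exposure variance.

One master seed fans out to per-table child seeds through a CRC32-tagged
SeedSequence scheme, so any single table regenerates byte-identically
without regenerating the rest.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .meta import meta_analyse_tables
from .summary_data import (
    BINARY, QUANTITATIVE, GeneAnnotation, InstrumentSet, LdMatrix,
    VariantAssociation,
)

_NONPALINDROMIC = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                   ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def child_rng(master_seed: int, *tags: str | int) -> np.random.Generator:
    """Deterministic per-table RNG: master seed + CRC32 of each tag."""
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for t in tags:
        entropy.append(zlib.crc32(str(t).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def make_ld(n_snps: int, ld_decay: float,
            variant_ids: Sequence[str] | None = None) -> LdMatrix:
    """AR(1) LD: rho_jk = ld_decay^|j-k|; positive definite by construction."""
    if not (0 <= ld_decay < 1):
        raise ValueError("ld_decay must lie in [0, 1)")
    idx = np.arange(n_snps)
    rho = ld_decay ** np.abs(idx[:, None] - idx[None, :])
    if variant_ids is None:
        variant_ids = [f"s{j + 1}" for j in range(n_snps)]
    return LdMatrix(variant_ids, rho)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutcomeSpec:
    """One outcome GWAS to emit: name, scale and sample sizes."""

    name: str
    trait_type: str = BINARY
    n: int | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    theta_key: str = "risk"  # which per-gene causal effect applies

    def effective_n(self) -> float:
        if self.trait_type == BINARY:
            return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)
        return float(self.n)

    def se_std(self) -> float:
        if self.trait_type == BINARY:
            return 2.0 / np.sqrt(self.effective_n())
        return 1.0 / np.sqrt(self.n)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions.

    Sample sizes mirror the blood eQTL resource (31,684), the prefrontal-
    cortex resource (1,387), the discovery PD-risk GWAS (13,708 cases /
    95,282 controls) and the replication cohort (8,036 / 5,803).  QTL effect
    magnitudes of 0.15-0.35 SD per allele correspond to top cis-eQTLs
    explaining ~2-10% of expression variance.
    """

    seed: int = 0
    n_genes: int = 10
    n_snps_per_region: int = 60
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    exposure_n: int = 31_684
    n_cases: int = 13_708
    n_controls: int = 95_282
    outcome_n: int | None = None  # quantitative outcomes
    theta_true: float = 0.3
    pleiotropy_mode: str = "none"  # none | balanced | directional
    alpha_pleio: float = 0.003
    scenario: str = "causal"
    n_causal_qtls: int = 3
    qtl_beta_range: tuple[float, float] = (0.15, 0.35)
    palindromic_fraction: float = 1.0 / 6.0
    allele_swap_fraction: float = 0.3   # outcome rows emitted on the other allele
    strand_flip_fraction: float = 0.15  # outcome rows emitted strand-complemented
    reverse_outcome_effect: float = 0.12  # std-scale direct outcome effect
    reverse_exposure_ratio: float = 0.3   # induced QTL effect / outcome effect
    artifact_effect: float = 0.10  # direct outcome effect of the pleiotropic SNP


SCENARIOS = ("causal", "null", "pleiotropic_artifact",
             "linkage_distinct_variants", "reverse_causation")


# ---------------------------------------------------------------------------
# Region truth
# ---------------------------------------------------------------------------

@dataclass
class RegionTruth:
    """Everything that is true (noise-free) about one gene region."""

    gene: GeneAnnotation
    variant_ids: list[str]
    positions: np.ndarray
    eaf: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    ld: LdMatrix
    gamma: np.ndarray                 # std-scale SNP -> exposure effects
    scenario: str
    theta: dict[str, float] = field(default_factory=dict)       # theta_key -> effect
    alpha: dict[str, np.ndarray] = field(default_factory=dict)  # theta_key -> direct effects

    def outcome_effects(self, theta_key: str) -> np.ndarray:
        b = self.theta.get(theta_key, 0.0) * self.gamma
        a = self.alpha.get(theta_key)
        return b if a is None else b + a


def _draw_alleles(rng: np.random.Generator, n: int, palindromic_fraction: float):
    ea, oa = [], []
    for j in range(n):
        if rng.random() < palindromic_fraction:
            pair = _PALINDROMIC[rng.integers(len(_PALINDROMIC))]
        else:
            pair = _NONPALINDROMIC[rng.integers(len(_NONPALINDROMIC))]
        ea.append(pair[0])
        oa.append(pair[1])
    return ea, oa


def build_region(
    rng: np.random.Generator,
    gene_index: int,
    scenario: str,
    config: SimulationConfig,
    theta: Mapping[str, float] | None = None,
) -> RegionTruth:
    """Lay out one gene region and draw its true causal architecture."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}")
    J = config.n_snps_per_region
    chrom = str(gene_index % 22 + 1)
    start = 1_000_000 + 100_000 * gene_index
    end = start + 30_000
    gene = GeneAnnotation(f"GENE{gene_index:04d}", f"G{gene_index:04d}", chrom,
                          start, end, druggability_tier="1")
    positions = np.linspace(start - 4_500, end + 4_500, J).astype(int)
    variant_ids = [f"rs{gene_index:04d}{j:03d}" for j in range(J)]
    maf = rng.uniform(*config.maf_range, size=J)
    eaf = np.where(rng.random(J) < 0.5, maf, 1.0 - maf)
    ea, oa = _draw_alleles(rng, J, config.palindromic_fraction)
    ld = make_ld(J, config.ld_decay, variant_ids)

    gamma = np.zeros(J)
    theta = dict(theta or {})
    alpha: dict[str, np.ndarray] = {}
    lo, hi = config.qtl_beta_range
    mag = rng.uniform(lo, hi, size=config.n_causal_qtls)
    sign = rng.choice([-1.0, 1.0], size=config.n_causal_qtls)

    if scenario == "linkage_distinct_variants":
        # QTLs confined to the region start; the outcome variant sits at the
        # far end, > 25 SNPs away, so rho^2 < 0.01 at the default LD decay
        qtl_pos = rng.choice(min(20, J // 3), size=config.n_causal_qtls, replace=False)
        gamma[qtl_pos] = mag * sign
        out_idx = int(rng.integers(J - max(5, J // 12), J))
        a = np.zeros(J)
        a[out_idx] = config.reverse_outcome_effect * rng.choice([-1.0, 1.0])
        alpha["risk"] = a
        theta.setdefault("risk", 0.0)
    elif scenario == "reverse_causation":
        # outcome association is primary; the QTL signal is induced downstream
        pos = rng.choice(J, size=config.n_causal_qtls, replace=False)
        delta = np.zeros(J)
        delta[pos] = config.reverse_outcome_effect * rng.choice([-1.0, 1.0], size=len(pos))
        alpha["risk"] = delta
        gamma = config.reverse_exposure_ratio * delta
        theta.setdefault("risk", 0.0)
    else:
        pos = rng.choice(J, size=config.n_causal_qtls, replace=False)
        gamma[pos] = mag * sign
        if scenario == "pleiotropic_artifact":
            a = np.zeros(J)
            top = pos[np.argmax(np.abs(gamma[pos]))]
            a[top] = config.artifact_effect * rng.choice([-1.0, 1.0])
            alpha["risk"] = a
            theta.setdefault("risk", 0.0)
        elif scenario == "null":
            theta.setdefault("risk", 0.0)
        else:  # causal
            theta.setdefault("risk", config.theta_true)

    return RegionTruth(gene, variant_ids, positions, eaf, ea, oa, ld,
                       gamma, scenario, theta, alpha)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def _emit_rows(
    region: RegionTruth,
    true_std_effects: np.ndarray,
    se_std: float,
    rng: np.random.Generator,
    trait_id: str,
    trait_type: str,
    n: float | None,
    n_cases: float | None,
    n_controls: float | None,
    swap_fraction: float = 0.0,
    strand_flip_fraction: float = 0.0,
) -> list[dict]:
    J = len(region.variant_ids)
    L = np.linalg.cholesky(region.ld.rho + 1e-10 * np.eye(J))
    marginal = region.ld.rho @ true_std_effects
    bhat_std = marginal + se_std * (L @ rng.standard_normal(J))
    scale = np.sqrt(2.0 * region.eaf * (1.0 - region.eaf))
    beta = bhat_std / scale
    se = se_std / scale
    z = bhat_std / se_std
    from scipy import stats as _st
    pvals = np.clip(2.0 * _st.norm.sf(np.abs(z)), 1e-320, 1.0)

    swap = rng.random(J) < swap_fraction
    flip_strand = rng.random(J) < strand_flip_fraction
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    rows = []
    for j in range(J):
        ea, oa, b, f = region.effect_alleles[j], region.other_alleles[j], beta[j], region.eaf[j]
        if swap[j]:
            ea, oa, b, f = oa, ea, -b, 1.0 - f
        if flip_strand[j]:
            ea, oa = comp[ea], comp[oa]
        rows.append({
            "variant_id": region.variant_ids[j], "chrom": region.gene.chrom,
            "pos": int(region.positions[j]), "effect_allele": ea, "other_allele": oa,
            "eaf": f, "beta": b, "se": se[j], "pvalue": pvals[j],
            "n": n, "n_cases": n_cases, "n_controls": n_controls,
            "trait_id": trait_id, "trait_type": trait_type,
        })
    return rows


def emit_exposure_study(
    regions: Sequence[RegionTruth],
    n: int,
    rng: np.random.Generator,
    gamma_attr: str = "gamma",
) -> pd.DataFrame:
    """Per-gene QTL association tables (canonical layout) for one tissue/source."""
    rows: list[dict] = []
    se_std = 1.0 / np.sqrt(n)
    for region in regions:
        rows.extend(_emit_rows(
            region, getattr(region, gamma_attr), se_std, rng,
            trait_id=region.gene.gene_id, trait_type=QUANTITATIVE,
            n=float(n), n_cases=None, n_controls=None))
    return pd.DataFrame(rows)


def emit_outcome_study(
    regions: Sequence[RegionTruth],
    spec: OutcomeSpec,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> pd.DataFrame:
    """One outcome GWAS covering every region's variants."""
    rows: list[dict] = []
    se_std = spec.se_std()
    for region in regions:
        effects = region.outcome_effects(spec.theta_key)
        rows.extend(_emit_rows(
            region, effects, se_std, rng,
            trait_id=spec.name, trait_type=spec.trait_type,
            n=(float(spec.n) if spec.n else
               float(spec.n_cases + spec.n_controls)),
            n_cases=spec.n_cases, n_controls=spec.n_controls,
            swap_fraction=config.allele_swap_fraction,
            strand_flip_fraction=config.strand_flip_fraction))
    return pd.DataFrame(rows)


def simulate_qtl_study(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[RegionTruth], dict[str, set[str]]]:
    """Exposure tables + region truth + SNP-gene map for a homogeneous gene set.

    Every gene follows ``config.scenario``.  The SNP-gene map assigns each
    variant to its own gene; for ``pleiotropic_artifact`` genes the strongest
    QTL is additionally mapped to a neighbouring gene so the specificity
    filter has something to remove.
    """
    rng = child_rng(config.seed, "qtl_truth")
    regions = [build_region(rng, i, config.scenario, config)
               for i in range(config.n_genes)]
    table = emit_exposure_study(regions, config.exposure_n,
                                child_rng(config.seed, "qtl_noise"))
    snp_gene_map = build_snp_gene_map(regions)
    return table, regions, snp_gene_map


def build_snp_gene_map(regions: Sequence[RegionTruth]) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    for k, region in enumerate(regions):
        for v in region.variant_ids:
            mapping.setdefault(v, set()).add(region.gene.gene_id)
        if region.scenario == "pleiotropic_artifact" and np.any(region.gamma != 0):
            top = int(np.argmax(np.abs(region.gamma)))
            neighbour = regions[(k + 1) % len(regions)].gene.gene_id
            mapping[region.variant_ids[top]].add(neighbour)
    return mapping


def simulate_outcome_study(
    config: SimulationConfig,
    regions: Sequence[RegionTruth],
    spec: OutcomeSpec | None = None,
    noise_tag: str = "outcome_noise",
) -> pd.DataFrame:
    """Outcome GWAS consistent with the exposure truth (see module docstring).

    ``pleiotropy_mode`` adds per-SNP direct effects on top of theta * gamma:
    balanced draws them mean-zero, directional with a common positive shift.
    """
    if spec is None:
        if config.outcome_n is not None:
            spec = OutcomeSpec("outcome", QUANTITATIVE, n=config.outcome_n)
        else:
            spec = OutcomeSpec("outcome", BINARY,
                               n_cases=config.n_cases, n_controls=config.n_controls)
    rng_alpha = child_rng(config.seed, noise_tag, "pleio")
    if config.pleiotropy_mode != "none":
        regions = [dc_replace(r, alpha=dict(r.alpha)) for r in regions]
        for region in regions:
            extra = rng_alpha.normal(0.0, config.alpha_pleio, size=len(region.variant_ids))
            if config.pleiotropy_mode == "directional":
                extra = np.abs(extra)
            base = region.alpha.get(spec.theta_key, 0.0)
            region.alpha[spec.theta_key] = base + extra
    return emit_outcome_study(regions, spec, child_rng(config.seed, noise_tag), config)


# ---------------------------------------------------------------------------
# Ready-made draws for calibration experiments
# ---------------------------------------------------------------------------

def simulate_instrument_set(
    seed: int,
    J: int = 10,
    theta: float = 0.0,
    pleiotropy_mode: str = "none",
    alpha_pleio: float = 0.003,
    ld_decay: float = 0.3,
    exposure_n: int = 31_684,
    n_cases: int = 13_708,
    n_controls: int = 95_282,
    qtl_beta_range: tuple[float, float] = (0.15, 0.35),
) -> InstrumentSet:
    """One harmonized post-clumping InstrumentSet drawn from the model.

    Instruments carry AR(1) correlation at ``ld_decay`` (default 0.3,
    i.e. pairwise r^2 < 0.2 as after clumping); exposure effects are strong
    cis-QTL-sized; the outcome is a binary GWAS on the log-odds scale.
    """
    rng = np.random.default_rng(seed)
    ids = [f"iv{j}" for j in range(J)]
    ld = make_ld(J, ld_decay, ids)
    gamma = rng.uniform(*qtl_beta_range, size=J)
    alpha = np.zeros(J)
    if pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, alpha_pleio, size=J)
    elif pleiotropy_mode == "directional":
        alpha = np.abs(rng.normal(0.0, alpha_pleio, size=J))
    sx = 1.0 / np.sqrt(exposure_n)
    n_eff = 4.0 / (1.0 / n_cases + 1.0 / n_controls)
    sy = 2.0 / np.sqrt(n_eff)
    L = np.linalg.cholesky(ld.rho + 1e-12 * np.eye(J))
    bx = ld.rho @ gamma + sx * (L @ rng.standard_normal(J))
    by = ld.rho @ (theta * gamma + alpha) + sy * (L @ rng.standard_normal(J))
    from scipy import stats as _st
    gene = GeneAnnotation("SIMGENE", "SIM", "1", 1_000_000, 1_030_000)
    exp_assoc, out_assoc = [], []
    for j in range(J):
        zx, zy = bx[j] / sx, by[j] / sy
        exp_assoc.append(VariantAssociation(
            ids[j], "1", 1_000_000 + 500 * j, "A", "G", bx[j], sx,
            float(np.clip(2 * _st.norm.sf(abs(zx)), 1e-320, 1.0)), "SIMGENE",
            eaf=0.5, n=float(exposure_n)))
        out_assoc.append(VariantAssociation(
            ids[j], "1", 1_000_000 + 500 * j, "A", "G", by[j], sy,
            float(np.clip(2 * _st.norm.sf(abs(zy)), 1e-320, 1.0)), "outcome",
            eaf=0.5, n_cases=float(n_cases), n_controls=float(n_controls),
            trait_type=BINARY))
    return InstrumentSet(gene, exp_assoc, out_assoc, ld, "sim")


def simulate_coloc_region(
    seed: int,
    scenario: str = "shared",
    n_snps: int = 200,
    ld_decay: float = 0.9,
    z_exposure: float = 9.0,
    z_outcome: float = 9.0,
    exposure_n: int = 31_684,
    outcome_n: int = 100_000,
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """A harmonized region pair for colocalization experiments.

    ``shared``: one causal variant drives both traits (H4 truth).
    ``distinct``: the two causal variants sit far apart in the AR(1) chain
    (pairwise rho^2 < 0.01 at the default decay), the H3 truth.
    """
    rng = np.random.default_rng(seed)
    ids = [f"c{j}" for j in range(n_snps)]
    ld = make_ld(n_snps, ld_decay, ids)
    sx = 1.0 / np.sqrt(exposure_n)
    sy = 1.0 / np.sqrt(outcome_n)
    gx = np.zeros(n_snps)
    gy = np.zeros(n_snps)
    if scenario == "shared":
        k = int(rng.integers(n_snps // 4, max(3 * n_snps // 4, n_snps // 4 + 1)))
        gx[k] = z_exposure * sx
        gy[k] = z_outcome * sy
    elif scenario == "distinct":
        k1 = int(rng.integers(0, n_snps // 8))
        k2 = int(rng.integers(7 * n_snps // 8, n_snps))
        gx[k1] = z_exposure * sx
        gy[k2] = z_outcome * sy
    else:
        raise ValueError("scenario must be 'shared' or 'distinct'")
    L = np.linalg.cholesky(ld.rho + 1e-12 * np.eye(n_snps))
    bx = ld.rho @ gx + sx * (L @ rng.standard_normal(n_snps))
    by = ld.rho @ gy + sy * (L @ rng.standard_normal(n_snps))
    from scipy import stats as _st
    px = np.clip(2 * _st.norm.sf(np.abs(bx / sx)), 1e-320, 1.0)
    py = np.clip(2 * _st.norm.sf(np.abs(by / sy)), 1e-320, 1.0)
    exp_assoc = [VariantAssociation(ids[j], "1", 10_000 + j, "A", "G",
                                    float(bx[j]), sx, float(px[j]), "GENE",
                                    eaf=0.5, n=float(exposure_n))
                 for j in range(n_snps)]
    out_assoc = [VariantAssociation(ids[j], "1", 10_000 + j, "A", "G",
                                    float(by[j]), sy, float(py[j]), "trait",
                                    eaf=0.5, n=float(outcome_n))
                 for j in range(n_snps)]
    return exp_assoc, out_assoc


# ---------------------------------------------------------------------------
# The default scenario suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SuiteConfig:
    """Composition and cohort sizes of the bundled synthetic study."""

    n_null: int = 100
    n_causal: int = 5
    n_pleiotropic: int = 2
    n_linkage: int = 2
    n_reverse: int = 2
    tissues: tuple[tuple[str, int], ...] = (("blood", 31_684), ("brain", 1_387))
    discovery: OutcomeSpec = OutcomeSpec("risk_discovery", BINARY,
                                         n_cases=13_708, n_controls=95_282)
    replication: OutcomeSpec = OutcomeSpec("risk_replication", BINARY,
                                           n_cases=8_036, n_controls=5_803)
    n_replication_substudies: int = 3
    age_at_onset: OutcomeSpec = OutcomeSpec("age_at_onset", QUANTITATIVE,
                                            n=17_996, theta_key="aao")
    progression: tuple[OutcomeSpec, ...] = (
        OutcomeSpec("prog_motor", QUANTITATIVE, n=4_093, theta_key="prog"),
        OutcomeSpec("prog_cognitive", QUANTITATIVE, n=4_093, theta_key="prog2"),
        OutcomeSpec("prog_dyskinesia", QUANTITATIVE, n=4_093, theta_key="prog3"),
    )
    pqtl_n: int = 3_301
    theta_risk: float = 0.3
    theta_aao: float = -0.3
    theta_prog: float = 0.5
    sim: SimulationConfig = SimulationConfig()

    @property
    def n_genes(self) -> int:
        return (self.n_null + self.n_causal + self.n_pleiotropic
                + self.n_linkage + self.n_reverse)


@dataclass
class ScenarioSuite:
    """In-memory bundle of every table the full study design consumes."""

    master_seed: int
    config: SuiteConfig
    genes: list[GeneAnnotation]
    regions: list[RegionTruth]
    exposures: dict[str, pd.DataFrame]
    outcomes: dict[str, pd.DataFrame]
    outcome_specs: dict[str, OutcomeSpec]
    pqtl: dict[str, pd.DataFrame]
    ld: dict[str, LdMatrix]
    snp_gene_map: dict[str, set[str]]
    truth: pd.DataFrame

    def write(self, out_dir) -> None:
        """Serialize the bundle to tab-delimited files under ``out_dir``."""
        from pathlib import Path
        from .instruments import write_snp_gene_map
        from .summary_data import write_ld_matrix
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.exposures.items():
            df.to_csv(out / f"exposure_{name}.tsv", sep="\t", index=False,
                      na_rep="NA", float_format="%.10g")
        for name, df in self.outcomes.items():
            df.to_csv(out / f"outcome_{name}.tsv", sep="\t", index=False,
                      na_rep="NA", float_format="%.10g")
        for name, df in self.pqtl.items():
            df.to_csv(out / f"pqtl_{name}.tsv", sep="\t", index=False,
                      na_rep="NA", float_format="%.10g")
        genes = pd.DataFrame([{
            "gene_id": g.gene_id, "symbol": g.symbol, "chrom": g.chrom,
            "start": g.start, "end": g.end,
            "druggability_tier": g.druggability_tier} for g in self.genes])
        genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False,
                          na_rep="NA", float_format="%.10g")
        write_snp_gene_map(self.snp_gene_map, out / "snp_gene_map.tsv")
        ld_dir = out / "ld"
        ld_dir.mkdir(exist_ok=True)
        for gene_id, ld in self.ld.items():
            write_ld_matrix(ld, ld_dir / f"{gene_id}.tsv")


def generate_scenario_suite(
    master_seed: int,
    config: SuiteConfig | None = None,
) -> ScenarioSuite:
    """The default ground-truth bundle exercising every pipeline stage.

    Per tissue: n_null theta=0 genes with real QTLs, n_causal genes with
    theta_risk = 0.3 (two of which also shift age at onset, two of which
    shift the first progression marker), plus pleiotropic-artifact, linkage
    and reverse-causation genes.  Outcomes: binary discovery and replication
    PD-risk analogues (the replication built by sample-size-weighted
    meta-analysis of 3 independent sub-studies), a quantitative age-at-onset
    analogue and three progression analogues, plus one blood pQTL-style
    source covering the causal genes and two null genes.
    """
    cfg = config or SuiteConfig()
    sim = cfg.sim
    rng_truth = child_rng(master_seed, "suite_truth")

    scenarios: list[str] = (
        ["null"] * cfg.n_null + ["causal"] * cfg.n_causal
        + ["pleiotropic_artifact"] * cfg.n_pleiotropic
        + ["linkage_distinct_variants"] * cfg.n_linkage
        + ["reverse_causation"] * cfg.n_reverse
    )
    regions: list[RegionTruth] = []
    causal_seen = 0
    for i, scenario in enumerate(scenarios):
        theta: dict[str, float] = {}
        if scenario == "causal":
            theta["risk"] = cfg.theta_risk
            if causal_seen < 2:
                theta["aao"] = cfg.theta_aao
            elif causal_seen < 4:
                theta["prog"] = cfg.theta_prog
            causal_seen += 1
        region = build_region(
            rng_truth, i, scenario,
            dc_replace(sim, theta_true=cfg.theta_risk), theta)
        regions.append(region)

    exposures = {
        tissue: emit_exposure_study(regions, n, child_rng(master_seed, "exposure", tissue))
        for tissue, n in cfg.tissues
    }

    outcome_specs: dict[str, OutcomeSpec] = {}
    outcomes: dict[str, pd.DataFrame] = {}
    disc = cfg.discovery
    outcomes[disc.name] = emit_outcome_study(
        regions, disc, child_rng(master_seed, "outcome", disc.name), sim)
    outcome_specs[disc.name] = disc

    # replication: independent sub-studies combined by sample-size weighting
    k = cfg.n_replication_substudies
    sub_cases = _split(cfg.replication.n_cases, k)
    sub_controls = _split(cfg.replication.n_controls, k)
    sub_tables = []
    for s in range(k):
        spec_s = OutcomeSpec(cfg.replication.name, BINARY,
                             n_cases=sub_cases[s], n_controls=sub_controls[s],
                             theta_key=cfg.replication.theta_key)
        sub = emit_outcome_study(
            regions, spec_s, child_rng(master_seed, "outcome", spec_s.name, s),
            dc_replace(sim, allele_swap_fraction=0.0, strand_flip_fraction=0.0))
        sub_tables.append(sub)
    outcomes[cfg.replication.name] = meta_analyse_tables(sub_tables)
    outcome_specs[cfg.replication.name] = cfg.replication

    for spec in (cfg.age_at_onset, *cfg.progression):
        outcomes[spec.name] = emit_outcome_study(
            regions, spec, child_rng(master_seed, "outcome", spec.name), sim)
        outcome_specs[spec.name] = spec

    # pQTL source: protein levels track expression for causal + two null genes
    pqtl_gene_idx = [i for i, r in enumerate(regions) if r.scenario == "causal"]
    pqtl_gene_idx += [i for i, r in enumerate(regions) if r.scenario == "null"][:2]
    pqtl_regions = [regions[i] for i in sorted(pqtl_gene_idx)]
    pqtl_df = emit_exposure_study(pqtl_regions, cfg.pqtl_n,
                                  child_rng(master_seed, "pqtl", "blood_pqtl"))
    pqtl = {"blood_pqtl": pqtl_df}

    truth_rows = []
    for tissue, _ in cfg.tissues:
        for region in regions:
            truth_rows.append({
                "gene_id": region.gene.gene_id, "tissue": tissue,
                "scenario": region.scenario,
                "theta_risk": region.theta.get("risk", 0.0),
                "theta_aao": region.theta.get("aao", 0.0),
                "theta_prog": region.theta.get("prog", 0.0),
            })
    truth = pd.DataFrame(truth_rows)

    return ScenarioSuite(
        master_seed=master_seed, config=cfg,
        genes=[r.gene for r in regions], regions=regions,
        exposures=exposures, outcomes=outcomes, outcome_specs=outcome_specs,
        pqtl=pqtl, ld={r.gene.gene_id: r.ld for r in regions},
        snp_gene_map=build_snp_gene_map(regions), truth=truth,
    )


def _split(total: int, k: int) -> list[int]:
    base = total // k
    out = [base] * k
    for i in range(total - base * k):
        out[i] += 1
    return out
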