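"""Instrument selection per gene: FDR-significant cis-QTLs, the cis window,
greedy LD clumping, Steiger directionality filtering, and SNP-gene specificity.

An instrument here is a cis-QTL: a variant associated with a gene's expression
(or protein level) that acts as a proxy for pharmacological modulation of the
gene product.  Clumping at r^2 < 0.2 deliberately keeps correlated instruments —
downstream estimators absorb the correlation through the LD matrix — because
more instruments mean more power and testable pleiotropy diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .summary_data import GeneAnnotation, InstrumentSet, VariantAssociation

DEFAULT_CIS_WINDOW = 5_000  # bp either side of the gene body
DEFAULT_CLUMP_R2 = 0.2
SENSITIVITY_CLUMP_R2 = 0.001


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; each q >= its p and q-values are monotone in the
    sorted sense.  p-values outside (0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cis_window_filter(
    qtls: Iterable[VariantAssociation],
    gene: GeneAnnotation,
    window: int = DEFAULT_CIS_WINDOW,
) -> list[VariantAssociation]:
    """Variants within ``window`` bp of the gene body, inclusive, on its chromosome."""
    lo, hi = gene.start - window, gene.end + window
    return [v for v in qtls if v.chrom == gene.chrom and lo <= v.pos <= hi]


def greedy_clump(
    instruments: InstrumentSet,
    r2_threshold: float = DEFAULT_CLUMP_R2,
) -> InstrumentSet:
    """Greedy LD clumping: keep index SNPs, drop their r^2 >= threshold proxies.

    Iteratively selects the remaining variant with the smallest exposure
    p-value (ties broken by lexicographically smaller variant_id, so the
    result is input-order invariant), then removes every remaining variant
    with squared correlation >= ``r2_threshold`` against any selected index.
    The surviving set has all pairwise rho^2 < threshold and always contains
    the globally smallest exposure p-value.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must lie in (0, 1]")
    order = sorted(
        range(len(instruments)),
        key=lambda i: (instruments.exposure[i].pvalue, instruments.exposure[i].variant_id),
    )
    rho2 = instruments.ld.rho ** 2
    selected: list[int] = []
    removed = np.zeros(len(instruments), dtype=bool)
    for i in order:
        if removed[i]:
            continue
        selected.append(i)
        removed |= rho2[i] >= r2_threshold
        removed[i] = True
    keep_ids = [instruments.exposure[i].variant_id for i in sorted(selected)]
    return instruments.subset(keep_ids)


def variance_explained(assoc: VariantAssociation) -> float:
    """Trait variance explained by one variant, r^2 = t^2 / (t^2 + n - 2).

    ``t`` is the association z/t statistic beta/se; ``n`` is the (effective,
    for binary traits) sample size.  Requires n > 2.
    """
    n = assoc.effective_n()
    if n <= 2:
        raise ValueError(f"{assoc.variant_id}: need n > 2 (got {n})")
    t2 = (assoc.beta / assoc.se) ** 2
    return t2 / (t2 + n - 2.0)


@dataclass(frozen=True)
class SteigerResult:
    """Gene-level directionality decision.

    ``keep`` is True iff the instruments jointly explain strictly more
    variance in the exposure than in the outcome; ties drop the gene.
    """

    gene_id: str
    r2_exposure: float
    r2_outcome: float

    @property
    def keep(self) -> bool:
        return self.r2_exposure > self.r2_outcome


def steiger_filter(instruments: InstrumentSet) -> SteigerResult:
    """Directionality check: does the signal flow exposure -> outcome?

    Sums per-instrument variance explained on each side.  A gene whose
    instruments explain more outcome than exposure variance is more plausibly
    a reverse-causation (or shared upstream) signal and is dropped wholesale.
    """
    r2_exp = float(sum(variance_explained(v) for v in instruments.exposure))
    r2_out = float(sum(variance_explained(v) for v in instruments.outcome))
    return SteigerResult(instruments.gene.gene_id, r2_exp, r2_out)


def specificity_filter(
    instruments: InstrumentSet,
    snp_gene_map: Mapping[str, set[str] | frozenset[str]],
) -> InstrumentSet:
    """Keep only variants associated with this gene's expression and no other's.

    A variant absent from the map is treated as non-specific and removed.
    May return an empty-subset InstrumentSet surrogate (None from callers'
    perspective when no variant survives) — callers skip MR for the gene with
    status ``no_specific_instruments``.
    """
    target = {instruments.gene.gene_id}
    keep = [
        v.variant_id
        for v in instruments.exposure
        if set(snp_gene_map.get(v.variant_id, ())) == target
    ]
    return instruments.subset(keep)


def read_snp_gene_map(path) -> dict[str, set[str]]:
    """Two-column tab-delimited (variant_id, gene_id) file, one row per pair."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("variant_id"):
            raise ValueError("snp-gene map must have a variant_id\tgene_id header")
        for line in fh:
            if not line.strip():
                continue
            variant, gene = line.rstrip("\n").split("\t")
            mapping.setdefault(variant, set()).add(gene)
    return mapping


def write_snp_gene_map(mapping: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\tgene_id\n")
        for variant in sorted(mapping):
            for gene in sorted(mapping[variant]):
                fh.write(f"{variant}\t{gene}\n")
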