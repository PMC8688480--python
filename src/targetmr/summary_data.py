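"""Data model and I/O for GWAS/QTL summary statistics, gene annotations and LD.

Variant-level association statistics are the package's atomic record: one SNP's
effect estimate for one trait (a gene's expression or protein level, or a disease
outcome).  Exposure and outcome studies are two-sample — they never share
individuals — so the only thing tying them together is the variant, and the first
analysis step is always allele harmonization: expressing the outcome association
on the same effect allele the exposure study used.

Coordinates are 1-based inclusive on GRCh37.  Tables are tab-delimited text with
a header row; missing values are serialized as "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window inside which a palindromic (A/T or G/C) variant cannot be
#: oriented by frequency and is excluded.
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)

#: canonical column order of the tab-delimited association layout
CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "n_cases", "n_controls", "trait_id",
    "trait_type",
]

QUANTITATIVE = "quantitative"
BINARY = "binary"


class FormatError(ValueError):
    """A table is structurally unreadable (e.g. a mandatory column is missing)."""


@dataclass(frozen=True)
class VariantAssociation:
    """Summary statistics of one variant for one trait.

    ``beta`` is per effect-allele copy: per-SD expression/protein for QTL
    exposures, log-odds for binary outcomes, per-SD for quantitative outcomes.
    For binary traits ``n_cases``/``n_controls`` are carried separately and
    ``n`` is their sum.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    trait_id: str
    eaf: float | None = None
    n: float | None = None
    n_cases: float | None = None
    n_controls: float | None = None
    trait_type: str = QUANTITATIVE

    def __post_init__(self) -> None:
        if self.effect_allele not in BASES or self.other_allele not in BASES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single A/C/G/T bases "
                f"(got {self.effect_allele!r}/{self.other_allele!r}); "
                "multi-allelic records are rejected")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if not (self.se > 0):
            raise ValueError(f"{self.variant_id}: se must be > 0 (got {self.se})")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.variant_id}: pvalue must be in (0,1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf outside [0,1]")
        if self.trait_type not in (QUANTITATIVE, BINARY):
            raise ValueError(f"{self.variant_id}: bad trait_type {self.trait_type!r}")

    @property
    def is_palindromic(self) -> bool:
        return self.other_allele == COMPLEMENT[self.effect_allele]

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def effective_n(self) -> float:
        """Sample size used in variance-explained formulas.

        Binary traits use the effective n = 4 / (1/n_cases + 1/n_controls).
        """
        if self.trait_type == BINARY:
            if not self.n_cases or not self.n_controls:
                raise ValueError(f"{self.variant_id}: binary trait needs case/control n")
            return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)
        if self.n is None:
            raise ValueError(f"{self.variant_id}: missing sample size")
        return float(self.n)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's coordinates plus its druggability tier (1 = approved/clinical)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    druggability_tier: str = "1"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


AUTOSOMES = frozenset(str(i) for i in range(1, 23))


def druggable_autosomal(genes: Iterable[GeneAnnotation]) -> list[GeneAnnotation]:
    """Keep autosomal genes only (the druggable-genome convention)."""
    return [g for g in genes if g.chrom in AUTOSOMES]


class LdMatrix:
    """Signed variant-variant dosage correlations, effect-allele aligned.

    Validated on construction: square, symmetric, unit diagonal, entries in
    [-1, 1], positive semi-definite up to numerical tolerance.
    """

    __slots__ = ("variant_ids", "rho", "_index")

    def __init__(self, variant_ids: Sequence[str], rho: np.ndarray):
        rho = np.asarray(rho, dtype=float)
        ids = list(variant_ids)
        if rho.ndim != 2 or rho.shape[0] != rho.shape[1] or rho.shape[0] != len(ids):
            raise ValueError("LD matrix must be square and match variant_ids")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in LD matrix")
        if not np.allclose(rho, rho.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(rho), 1.0, atol=1e-8):
            raise ValueError("LD matrix must have unit diagonal")
        if np.any(np.abs(rho) > 1 + 1e-8):
            raise ValueError("LD correlations must lie in [-1, 1]")
        if len(ids):
            w = np.linalg.eigvalsh((rho + rho.T) / 2.0)
            if w.min() < -1e-6:
                raise ValueError(f"LD matrix not PSD (min eigenvalue {w.min():.3g})")
        self.variant_ids = ids
        self.rho = rho
        self._index = {v: i for i, v in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def submatrix(self, variant_ids: Sequence[str]) -> "LdMatrix":
        idx = [self._index[v] for v in variant_ids]
        return LdMatrix(list(variant_ids), self.rho[np.ix_(idx, idx)])

    def correlation(self, a: str, b: str) -> float:
        return float(self.rho[self._index[a], self._index[b]])


@dataclass
class InstrumentSet:
    """Harmonized exposure+outcome statistics for one gene's instruments.

    The three components (exposure list, outcome list, LD submatrix) index the
    identical ordered variant list; every exposure/outcome pair shares its
    effect allele after harmonization.
    """

    gene: GeneAnnotation
    exposure: list[VariantAssociation]
    outcome: list[VariantAssociation]
    ld: LdMatrix
    tissue_label: str = ""

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.exposure]
        if [v.variant_id for v in self.outcome] != ids:
            raise ValueError("exposure/outcome variant lists differ")
        if self.ld.variant_ids != ids:
            raise ValueError("LD matrix variant order differs from associations")
        for e, o in zip(self.exposure, self.outcome):
            if e.effect_allele != o.effect_allele:
                raise ValueError(f"{e.variant_id}: effect alleles not harmonized")

    def __len__(self) -> int:
        return len(self.exposure)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.exposure]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(bx, sx, by, sy, rho) as numpy arrays, in variant order."""
        bx = np.array([v.beta for v in self.exposure])
        sx = np.array([v.se for v in self.exposure])
        by = np.array([v.beta for v in self.outcome])
        sy = np.array([v.se for v in self.outcome])
        return bx, sx, by, sy, self.ld.rho

    def subset(self, variant_ids: Sequence[str]) -> "InstrumentSet":
        keep = set(variant_ids)
        order = [v for v in self.variant_ids if v in keep]
        pos = {v.variant_id: i for i, v in enumerate(self.exposure)}
        idx = [pos[v] for v in order]
        return InstrumentSet(
            gene=self.gene,
            exposure=[self.exposure[i] for i in idx],
            outcome=[self.outcome[i] for i in idx],
            ld=self.ld.submatrix(order),
            tissue_label=self.tissue_label,
        )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_NUMERIC = {"pos": int, "eaf": float, "beta": float, "se": float,
            "pvalue": float, "n": float, "n_cases": float, "n_controls": float}
_MANDATORY = ["variant_id", "chrom", "pos", "effect_allele", "other_allele",
              "beta", "se", "pvalue", "trait_id"]


@dataclass
class ReadReport:
    """Parsed records plus a per-row account of the rejected ones."""

    records: list[VariantAssociation]
    rejections: list[tuple[int, str]] = field(default_factory=list)  # (line no, reason)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_association_table(path, dialect: Mapping[str, str] | None = None) -> ReadReport:
    """Read a tab-delimited association table into validated records.

    ``dialect`` maps canonical column names to the file's header names, so
    eQTLGen-like, PsychENCODE-like and outcome-GWAS-like layouts all load.
    Rows violating record invariants are rejected with a per-row report;
    row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if dialect:
        missing_src = [src for src in dialect.values() if src not in df.columns]
        if missing_src:
            raise FormatError(f"mapped column(s) missing from file: {missing_src}")
        df = df.rename(columns={src: dst for dst, src in dialect.items()})
    for col in _MANDATORY:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col}")

    records: list[VariantAssociation] = []
    rejections: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is header
        d = dict(zip(df.columns, row))
        try:
            kwargs = {
                "variant_id": d["variant_id"],
                "chrom": str(d["chrom"]),
                "effect_allele": str(d["effect_allele"]).upper(),
                "other_allele": str(d["other_allele"]).upper(),
                "trait_id": d["trait_id"],
                "trait_type": d.get("trait_type") or QUANTITATIVE,
            }
            for col, cast in _NUMERIC.items():
                raw = d.get(col)
                if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                    if col in ("eaf", "n", "n_cases", "n_controls"):
                        kwargs[col] = None
                        continue
                    raise ValueError(f"missing value in column {col}")
                try:
                    kwargs[col] = cast(float(raw)) if cast is int else cast(raw)
                except (TypeError, ValueError):
                    raise ValueError(f"unparseable numeric in column {col}: {raw!r}")
            records.append(VariantAssociation(**kwargs))
        except ValueError as exc:
            rejections.append((i, str(exc)))
    return ReadReport(records, rejections)


def write_association_table(records: Sequence[VariantAssociation], path) -> None:
    """Write records to the canonical tab-delimited layout (lossless round-trip)."""
    if not records:
        raise ValueError("no records to write")
    rows = []
    for r in records:
        rows.append({
            "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
            "effect_allele": r.effect_allele, "other_allele": r.other_allele,
            "eaf": r.eaf, "beta": r.beta, "se": r.se, "pvalue": r.pvalue,
            "n": r.n, "n_cases": r.n_cases, "n_controls": r.n_controls,
            "trait_id": r.trait_id, "trait_type": r.trait_type,
        })
    df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_ld_matrix(path) -> LdMatrix:
    """Square tab-delimited matrix with a variant-id header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError("LD matrix row and column variant ids differ")
    return LdMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path) -> None:
    df = pd.DataFrame(ld.rho, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationResult:
    """Paired, allele-aligned exposure/outcome lists plus the exclusion report."""

    exposure: list[VariantAssociation]
    outcome: list[VariantAssociation]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (variant, reason)


def _flip(v: VariantAssociation) -> VariantAssociation:
    """Re-express an association on the opposite effect allele."""
    return replace(
        v,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        beta=-v.beta,
        eaf=None if v.eaf is None else 1.0 - v.eaf,
    )


def _relabel(v: VariantAssociation, effect: str, other: str) -> VariantAssociation:
    """Rename alleles to their reverse-strand complements (stats unchanged)."""
    return replace(v, effect_allele=effect, other_allele=other)


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
) -> HarmonizationResult:
    """Align outcome associations to the exposure study's effect alleles.

    Keeps the intersection of variant ids (exposure order).  Swapped alleles
    sign-flip the outcome beta and reflect its eaf; strand flips (A<->T, C<->G
    complements) are relabelled; palindromic variants are kept only when both
    eafs are present and both fall outside ``palindromic_window``, in which
    case they are oriented by frequency.  Every dropped variant appears in the
    exclusion report with a reason code; irreconcilable allele pairs are
    excluded as ``allele_mismatch``, never silently kept.
    """
    lo, hi = palindromic_window
    out_by_id: dict[str, VariantAssociation] = {}
    for o in outcome:
        out_by_id.setdefault(o.variant_id, o)

    kept_e: list[VariantAssociation] = []
    kept_o: list[VariantAssociation] = []
    excluded: list[tuple[str, str]] = []
    exp_ids = set()
    for e in exposure:
        if e.variant_id in exp_ids:
            excluded.append((e.variant_id, "duplicate_exposure_record"))
            continue
        exp_ids.add(e.variant_id)
        o = out_by_id.get(e.variant_id)
        if o is None:
            excluded.append((e.variant_id, "missing_counterpart"))
            continue

        ea, oa = e.effect_allele, e.other_allele
        pair = (o.effect_allele, o.other_allele)
        if e.is_palindromic:
            if set(pair) != {ea, oa}:
                excluded.append((e.variant_id, "allele_mismatch"))
                continue
            if e.eaf is None or o.eaf is None:
                excluded.append((e.variant_id, "palindromic_ambiguous"))
                continue
            if lo <= e.eaf <= hi or lo <= o.eaf <= hi:
                excluded.append((e.variant_id, "palindromic_ambiguous"))
                continue
            # orient by frequency: minor/major side must agree after alignment
            o_aligned = o if pair == (ea, oa) else _flip(o)
            if (e.eaf < 0.5) != (o_aligned.eaf < 0.5):
                o_aligned = replace(_flip(o_aligned), effect_allele=ea, other_allele=oa)
            kept_e.append(e)
            kept_o.append(o_aligned)
            continue

        if pair == (ea, oa):
            kept_e.append(e)
            kept_o.append(o)
        elif pair == (oa, ea):
            kept_e.append(e)
            kept_o.append(_flip(o))
        elif pair == (COMPLEMENT[ea], COMPLEMENT[oa]):
            kept_e.append(e)
            kept_o.append(_relabel(o, ea, oa))
        elif pair == (COMPLEMENT[oa], COMPLEMENT[ea]):
            kept_e.append(e)
            kept_o.append(_flip(_relabel(o, oa, ea)))
        else:
            excluded.append((e.variant_id, "allele_mismatch"))
    return HarmonizationResult(kept_e, kept_o, excluded)


def build_instrument_set(
    gene: GeneAnnotation,
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    ld: LdMatrix,
    tissue_label: str = "",
    missing_ld: str = "drop",
) -> tuple[InstrumentSet | None, HarmonizationResult]:
    """Harmonize and assemble an InstrumentSet over the shared variant list.

    Variants absent from the LD matrix follow ``missing_ld``: "drop" (default,
    recorded in the exclusion report) or "error".
    """
    harm = harmonize(exposure, outcome)
    kept_e, kept_o = [], []
    for e, o in zip(harm.exposure, harm.outcome):
        if e.variant_id not in ld:
            if missing_ld == "error":
                raise KeyError(f"{e.variant_id} absent from LD matrix")
            harm.excluded.append((e.variant_id, "missing_ld"))
            continue
        kept_e.append(e)
        kept_o.append(o)
    harm.exposure, harm.outcome = kept_e, kept_o
    if not kept_e:
        return None, harm
    sub = ld.submatrix([v.variant_id for v in kept_e])
    return InstrumentSet(gene, kept_e, kept_o, sub, tissue_label), harm
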