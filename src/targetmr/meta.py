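"""Sample-size-weighted GWAS meta-analysis and genomic-inflation accounting.

The replication outcome is built METAL-style: per variant, each study's
p-value and effect direction become a signed z-score, combined with weights
proportional to sqrt(N).  Genomic inflation is summarized by lambda (the
median test statistic relative to its null median) and by lambda_1000, its
rescaling to a 1000-case/1000-control study so cohorts of different size are
comparable.  Inflation is reported, never applied as a correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: median of the chi-square distribution with 1 df
CHI2_1DF_MEDIAN = 0.4549364231195728


@dataclass(frozen=True)
class StudyEntry:
    """One study's evidence for one variant: effect sign, p-value, sample size."""

    beta_sign: float
    pvalue: float
    n: float

    def __post_init__(self) -> None:
        if not (0 < self.pvalue < 1):
            raise ValueError(
                "p-values must lie strictly in (0, 1); clamp extremes upstream "
                "with an explicit policy")
        if self.n <= 0:
            raise ValueError("sample size must be positive")


@dataclass(frozen=True)
class MetaResult:
    variant_id: str
    z_meta: float
    p_meta: float
    n_total: float
    weights: tuple[float, ...]
    z_inputs: tuple[float, ...]


def stouffer_meta(studies: Sequence[StudyEntry], variant_id: str = "") -> MetaResult:
    """Sample-size-weighted (Stouffer) combination of per-study evidence.

    z_i = sign(beta_i) * Phi^-1(1 - p_i/2); z_meta = sum w_i z_i / sqrt(sum
    w_i^2) with w_i = sqrt(N_i).  Extreme p-values are converted with
    scipy's inverse survival function, which is accurate in the far tail.
    """
    if not studies:
        raise ValueError("need at least one study")
    z = np.array([np.sign(s.beta_sign) * stats.norm.isf(s.pvalue / 2.0) for s in studies])
    w = np.array([np.sqrt(s.n) for s in studies])
    z_meta = float((w * z).sum() / np.sqrt((w**2).sum()))
    p_meta = min(1.0, max(float(2.0 * stats.norm.sf(abs(z_meta))), 1e-320))
    return MetaResult(variant_id, z_meta, p_meta,
                      float(sum(s.n for s in studies)), tuple(w), tuple(z))


def meta_analyse_tables(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Meta-analyse canonical association tables sharing a variant set.

    Input frames use the canonical layout plus per-study n (or case/control
    counts).  Output is again canonical: z is recombined across studies and
    beta/se are reconstructed on the per-allele scale from the pooled
    effective sample size, so the result feeds the pipeline directly as an
    outcome study.  Variant/allele metadata are taken from the first study;
    all studies are assumed pre-harmonized to it.
    """
    if not tables:
        raise ValueError("no studies supplied")
    base = tables[0].set_index("variant_id", drop=False)
    shared = base.index
    for t in tables[1:]:
        shared = shared.intersection(t["variant_id"])
    frames = [t.set_index("variant_id").loc[shared] for t in tables]

    def eff_n(df: pd.DataFrame) -> np.ndarray:
        if df["n_cases"].notna().all():
            return 4.0 / (1.0 / df["n_cases"] + 1.0 / df["n_controls"])
        return df["n"].to_numpy(dtype=float)

    zs = np.column_stack([
        np.sign(df["beta"].to_numpy()) * stats.norm.isf(
            np.clip(df["pvalue"].to_numpy(dtype=float), 1e-320, 1 - 1e-16) / 2.0)
        for df in frames
    ])
    ws = np.column_stack([np.sqrt(eff_n(df)) for df in frames])
    z_meta = (ws * zs).sum(axis=1) / np.sqrt((ws**2).sum(axis=1))
    p_meta = np.clip(2.0 * stats.norm.sf(np.abs(z_meta)), 1e-320, 1.0)

    out = base.loc[shared].copy()
    n_eff_total = (ws**2).sum(axis=1)
    eaf = out["eaf"].to_numpy(dtype=float)
    scale = np.sqrt(2.0 * eaf * (1.0 - eaf))
    # per-allele se consistent with the simulator's emission convention
    # (1/sqrt(2f(1-f) n) for quantitative traits, effective n with a factor
    # 2 on the log-odds scale for binary ones)
    binary = (out.get("trait_type") == "binary").all() if "trait_type" in out else False
    se = (2.0 if binary else 1.0) / (scale * np.sqrt(n_eff_total))
    out["beta"] = z_meta * se
    out["se"] = se
    out["pvalue"] = p_meta
    for col in ("n", "n_cases", "n_controls"):
        if all(col in t.columns for t in tables):
            vals = np.column_stack([df[col].to_numpy(dtype=float) for df in frames])
            out[col] = np.nansum(vals, axis=1)
    return out.reset_index(drop=True)


def genomic_lambda(zscores: Sequence[float]) -> float:
    """lambda = median(z^2) / median(chi-square_1), the genomic inflation factor."""
    z = np.asarray(zscores, dtype=float)
    if z.size == 0:
        raise ValueError("empty z-score vector")
    return float(np.median(z**2) / CHI2_1DF_MEDIAN)


def lambda_1000(lam: float, n_cases: int, n_controls: int) -> float:
    """Rescale lambda to an equivalent 1000-case/1000-control study.

    lambda_1000 = 1 + (lambda - 1) * (1/n_cases + 1/n_controls) / (2/1000).
    The identity holds at lambda = 1 and at n_cases = n_controls = 1000.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("case/control counts must be positive")
    return 1.0 + (lam - 1.0) * (1.0 / n_cases + 1.0 / n_controls) / (2.0 / 1000.0)
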