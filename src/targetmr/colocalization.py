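"""Bayesian colocalization of QTL and GWAS signals in a gene region.

Tests whether the exposure (expression/protein) association and the outcome
association in a region are driven by one shared causal variant (H4) or by
distinct variants in LD (H3) — the failure mode that produces spurious MR
hits.  Per-SNP evidence is the Wakefield approximate Bayes factor computed
from (beta, se) alone; the five-hypothesis posterior follows from summing
single-causal-variant configurations under the region priors.

Hypotheses: H0 no association with either trait; H1 exposure only; H2
outcome only; H3 both, distinct causal variants; H4 both, shared variant.

All configuration sums run in log space; the H3 mass S1*S2 - S12 is formed
by log-space subtraction, which is safe because S1*S2 >= S12 holds exactly
(all cross terms are positive), with equality only for a single-SNP region —
where PPH3 is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .summary_data import BINARY, VariantAssociation

#: region priors: per-SNP probability of association with exposure only (p1),
#: outcome only (p2), and both (p12)
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5

#: prior variance of true effects: 0.15^2 on the SD scale for quantitative
#: traits, 0.2^2 on the log-odds scale for binary traits
DEFAULT_W_QUANT = 0.15**2
DEFAULT_W_BINARY = 0.2**2

POWER_GATE = 0.8   # analysis attempted only when PPH3 + PPH4 >= 0.8
STRONG_PPH4 = 0.75  # strong evidence of colocalization


@dataclass(frozen=True)
class ColocPriors:
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    p12: float = DEFAULT_P12
    W_quant: float = DEFAULT_W_QUANT
    W_binary: float = DEFAULT_W_BINARY

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("priors must sum below 1")
        if self.W_quant <= 0 or self.W_binary <= 0:
            raise ValueError("prior effect variances must be positive")

    def prior_variance(self, trait_type: str) -> float:
        return self.W_binary if trait_type == BINARY else self.W_quant


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of H0..H4 for one gene-region/outcome pair."""

    gene_id: str
    outcome_id: str
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int

    def __post_init__(self) -> None:
        total = self.pph0 + self.pph1 + self.pph2 + self.pph3 + self.pph4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")

    @property
    def powered(self) -> bool:
        return self.pph3 + self.pph4 >= POWER_GATE

    @property
    def strong(self) -> bool:
        """Strong colocalization evidence; only meaningful when powered."""
        return self.powered and self.pph4 >= STRONG_PPH4

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.pph0, self.pph1, self.pph2, self.pph3, self.pph4)


def log_abf(assoc: VariantAssociation, W: float) -> float:
    """Wakefield log approximate Bayes factor for one association.

    With z = beta/se, V = se^2 and shrinkage r = W/(W+V):
    log ABF = 0.5 * (log(1 - r) + r * z^2).  Positive values favour a real
    effect; at z = 0 the ABF shrinks below 1.
    """
    if assoc.se <= 0:
        raise ValueError("se must be > 0")
    v = assoc.se**2
    r = W / (W + v)
    z = assoc.beta / assoc.se
    return 0.5 * (np.log1p(-r) + r * z * z)


def _log_abf_vector(assocs: Sequence[VariantAssociation], priors: ColocPriors) -> np.ndarray:
    return np.array([log_abf(a, priors.prior_variance(a.trait_type)) for a in assocs])


def coloc_posteriors(
    region_exposure: Sequence[VariantAssociation],
    region_outcome: Sequence[VariantAssociation],
    priors: ColocPriors = ColocPriors(),
    gene_id: str = "",
    outcome_id: str = "",
) -> ColocResult:
    """Five-hypothesis posterior for a harmonized region.

    Both lists must cover the same ordered variant set.  Unnormalized masses:
    L0 = 1, L1 = p1*S1, L2 = p2*S2, L3 = p1*p2*(S1*S2 - S12), L4 = p12*S12,
    where S1/S2 sum per-SNP ABFs and S12 sums their products.
    """
    ids_e = [a.variant_id for a in region_exposure]
    ids_o = [a.variant_id for a in region_outcome]
    if ids_e != ids_o:
        raise ValueError("exposure and outcome regions cover different variants")
    if not ids_e:
        raise ValueError("empty region")

    l1 = _log_abf_vector(region_exposure, priors)
    l2 = _log_abf_vector(region_outcome, priors)
    ls1 = float(logsumexp(l1))
    ls2 = float(logsumexp(l2))
    ls12 = float(logsumexp(l1 + l2))

    log_masses = np.empty(5)
    log_masses[0] = 0.0
    log_masses[1] = np.log(priors.p1) + ls1
    log_masses[2] = np.log(priors.p2) + ls2
    # log(S1*S2 - S12): S1*S2 >= S12 with equality iff a single SNP
    a, b = ls1 + ls2, ls12
    if len(ids_e) == 1 or a <= b + 1e-15:
        # one shared position cannot support distinct causal variants
        diff = b - a
        if diff > 1e-9:
            raise ValueError(
                f"catastrophic cancellation in H3 mass (S12/S1S2 = exp({diff:.3g}))")
        log_masses[3] = -np.inf
    else:
        log_masses[3] = np.log(priors.p1) + np.log(priors.p2) + a + np.log1p(-np.exp(b - a))
    log_masses[4] = np.log(priors.p12) + ls12

    post = np.exp(log_masses - logsumexp(log_masses))
    post /= post.sum()
    return ColocResult(gene_id, outcome_id, *map(float, post), len(ids_e))
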