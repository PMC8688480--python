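"""Heterogeneity and pleiotropy quality control.

A valid set of instruments for one exposure should agree, up to sampling
noise, on a single causal effect.  Cochran's Q (generalized to correlated
instruments) and its I^2 transform quantify disagreement; the MR-Egger
intercept tests for directional pleiotropy; direction consistency compares
the sign of the causal estimate across phases and methods.

Pass conventions (boundary values pass): Q passes iff p >= 0.05, I^2 passes
iff I^2 <= 0.50, Egger intercept passes iff p >= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .estimators import RIDGE, EstimationError, MrEstimate
from .summary_data import InstrumentSet

Q_PASS_P = 0.05
I2_PASS_MAX = 0.50
EGGER_INTERCEPT_PASS_P = 0.05


@dataclass(frozen=True)
class HeterogeneityResult:
    """Generalized Cochran's Q with its chi-square p-value and I^2."""

    gene_id: str
    outcome_id: str
    Q: float
    df: int
    p_Q: float
    I2: float

    @property
    def q_pass(self) -> bool:
        return self.p_Q >= Q_PASS_P

    @property
    def i2_pass(self) -> bool:
        return self.I2 <= I2_PASS_MAX


def generalized_q(instruments: InstrumentSet, theta_hat: float) -> HeterogeneityResult:
    """Q = (by - theta*bx)' Sigma^-1 (by - theta*bx), df = J - 1.

    With identity LD this reduces exactly to the classical first-order
    Q = sum_j w_j (theta_j - theta)^2 with w_j = bx_j^2 / sy_j^2.  Q is
    conventionally computed at the IVW theta_hat.  I^2 = max(0, (Q - df)/Q).
    """
    J = len(instruments)
    if J < 2:
        raise EstimationError("insufficient_instruments")
    bx, _, by, sy, rho = instruments.arrays()
    sigma = np.outer(sy, sy) * (rho + RIDGE * np.eye(J))
    resid = by - theta_hat * bx
    try:
        q = float(resid @ linalg.cho_solve(linalg.cho_factor(sigma, lower=True), resid))
    except linalg.LinAlgError as exc:
        raise EstimationError("ld_singular") from exc
    q = max(q, 0.0)
    df = J - 1
    p_q = max(float(stats.chi2.sf(q, df)), 1e-320)
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    out = instruments.outcome[0].trait_id if instruments.outcome else ""
    return HeterogeneityResult(instruments.gene.gene_id, out, q, df, p_q, i2)


def egger_intercept_test(egger: MrEstimate) -> tuple[bool, float]:
    """Two-sided test of the MR-Egger intercept against zero.

    Returns (pass, p) where pass means no detectable directional pleiotropy
    (p >= 0.05).  The p-value is the t(J-2) one already attached to the
    estimate; it is recomputed here defensively from theta_0/se.
    """
    if egger.method != "egger":
        raise ValueError("estimate is not an MR-Egger fit")
    if egger.intercept_theta0 is None or egger.se_intercept is None:
        raise ValueError("missing intercept fields")
    df = egger.n_snps - 2
    t = egger.intercept_theta0 / egger.se_intercept
    p = min(1.0, max(float(2.0 * stats.t.sf(abs(t), df)), 1e-320))
    return p >= EGGER_INTERCEPT_PASS_P, p


def direction_consistency(estimates: Sequence[MrEstimate]) -> bool:
    """Strict sign agreement of theta across >= 2 estimates.

    theta = 0 carries no direction and counts as inconsistent with any
    nonzero sign (and with another zero, by the same strict-sign rule).
    """
    if len(estimates) < 2:
        raise ValueError("need at least 2 estimates to compare")
    signs = {np.sign(e.theta_hat) for e in estimates}
    return len(signs) == 1 and 0.0 not in signs
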