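"""Causal-effect estimators for two-sample MR with correlated instruments.

Every estimator consumes a harmonized :class:`~targetmr.summary_data.InstrumentSet`
and returns an :class:`MrEstimate` of theta, the causal effect of a 1-SD
increase in the exposure (gene expression / protein level) on the outcome
(log-odds for binary outcomes, SD units for quantitative ones).

Correlation between instruments — deliberate, since clumping at r^2 < 0.2
retains LD-linked SNPs — is absorbed through generalized least squares with
the outcome-side covariance Sigma = D rho D, D = diag(se_Y).

Heterogeneity handling: the default is an exactly calibrated multiplicative
random-effects model — SEs scaled by phi = sqrt(Q/df) (unfloored) with t(df)
p-values for IVW at J >= 4 and for MR-Egger, fixed-effect normal inference for
smaller J.  Because the scale estimate phi^2 * df is chi-square(df) and
independent of the GLS coefficient, (theta_hat - theta)/se is exactly t(df)
under the model, so the nominal test size is exact.  The floored variant
phi = max(1, sqrt(Q/df)) with normal p-values, as used by the common MR
packages, is available as ``inflation="floored"`` (it is conservative: its
exact null rejection rate at alpha = 0.05 is ~0.039 at J = 10); ``"fixed"``
disables inflation entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import linalg, optimize, stats

from .summary_data import InstrumentSet

RIDGE = 1e-8  # added to the diagonal of rho before inversion

Inflation = Literal["multiplicative", "floored", "fixed"]
DEFAULT_INFLATION: Inflation = "multiplicative"


class EstimationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MrEstimate:
    """A causal-effect estimate, with Egger intercept fields when applicable."""

    gene_id: str
    outcome_id: str
    tissue_label: str
    method: str  # wald | ivw | egger | max_likelihood | weighted_median | weighted_mode
    theta_hat: float
    se_theta: float
    pvalue: float
    n_snps: int
    intercept_theta0: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None
    phi: float | None = None  # multiplicative SE inflation actually applied
    pvalue_dist: str = "normal"  # distribution behind pvalue ("normal" or "t(df)")

    def __post_init__(self) -> None:
        if not (self.se_theta > 0):
            raise ValueError("se_theta must be > 0")
        if not (0 < self.pvalue <= 1):
            raise ValueError("pvalue must be in (0, 1]")
        has_intercept = self.intercept_theta0 is not None
        if has_intercept != (self.method == "egger"):
            raise ValueError("intercept fields present iff method == 'egger'")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta_hat)

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return self.theta_hat - z * self.se_theta, self.theta_hat + z * self.se_theta


_P_FLOOR = 1e-320  # keep extreme p-values inside (0, 1]


def _two_sided_normal_p(z: float) -> float:
    return min(1.0, max(float(2.0 * stats.norm.sf(abs(z))), _P_FLOOR))


def _two_sided_t_p(t: float, df: int) -> float:
    return min(1.0, max(float(2.0 * stats.t.sf(abs(t), df)), _P_FLOOR))


def _labels(instruments: InstrumentSet) -> tuple[str, str, str]:
    out = instruments.outcome[0].trait_id if instruments.outcome else ""
    return instruments.gene.gene_id, out, instruments.tissue_label


def _sigma_factor(sy: np.ndarray, rho: np.ndarray):
    """Cholesky factorization of Sigma = D (rho + ridge I) D; raises ld_singular."""
    sigma = np.outer(sy, sy) * (rho + RIDGE * np.eye(len(sy)))
    try:
        return linalg.cho_factor(sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise EstimationError("ld_singular") from exc


def wald_ratio(
    bx: float, sx: float, by: float, sy: float,
    gene_id: str = "", outcome_id: str = "", tissue_label: str = "",
    second_order: bool = True,
) -> MrEstimate:
    """Single-instrument ratio estimate theta = by/bx.

    SE by the delta method; the second-order form sqrt(sy^2/bx^2 +
    by^2 sx^2 / bx^4) is the default, the first-order form sy/|bx| is a
    config switch.  p-value from the normal approximation.
    """
    if bx == 0:
        raise EstimationError("weak/degenerate instrument: bx = 0")
    theta = by / bx
    if second_order:
        se = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        se = sy / abs(bx)
    return MrEstimate(
        gene_id, outcome_id, tissue_label, "wald",
        theta, se, _two_sided_normal_p(theta / se), 1,
    )


def _wald_from_set(instruments: InstrumentSet, method: str) -> MrEstimate:
    bx, sx, by, sy, _ = instruments.arrays()
    gene, out, tissue = _labels(instruments)
    est = wald_ratio(bx[0], sx[0], by[0], sy[0], gene, out, tissue)
    return est


def ivw_correlated(
    instruments: InstrumentSet,
    inflation: Inflation = DEFAULT_INFLATION,
) -> MrEstimate:
    """Inverse-variance-weighted estimate generalized to correlated instruments.

    GLS through the origin: theta_hat = (bx' S^-1 bx)^-1 bx' S^-1 by with
    S = D rho D.  With identity LD this reduces to the textbook IVW mean of
    Wald ratios weighted by bx_j^2 / sy_j^2.  A single instrument delegates to
    the Wald ratio.  Random-effects SE inflation applies for J >= 4 (see
    module docstring); J < 4 is fixed-effect.
    """
    J = len(instruments)
    if J == 0:
        raise EstimationError("insufficient_instruments")
    if J == 1:
        return _wald_from_set(instruments, "ivw")
    bx, sx, by, sy, rho = instruments.arrays()
    if np.all(bx == 0):
        raise EstimationError("weak/degenerate instrument: all bx = 0")
    factor = _sigma_factor(sy, rho)
    sib = linalg.cho_solve(factor, bx)
    precision = float(bx @ sib)
    theta = float(sib @ by) / precision
    se_fixed = math.sqrt(1.0 / precision)

    resid = by - theta * bx
    q = float(resid @ linalg.cho_solve(factor, resid))
    df = J - 1
    phi, dist = 1.0, "normal"
    if J >= 4 and inflation != "fixed":
        if inflation == "floored":
            phi = max(1.0, math.sqrt(q / df))
        else:
            phi = math.sqrt(q / df)
            dist = f"t({df})"
    phi = max(phi, 1e-300)
    se = se_fixed * phi
    z = theta / se
    p = _two_sided_t_p(z, df) if dist.startswith("t") else _two_sided_normal_p(z)
    gene, out, tissue = _labels(instruments)
    return MrEstimate(gene, out, tissue, "ivw", theta, se, p, J,
                      phi=phi, pvalue_dist=dist)


def egger_correlated(
    instruments: InstrumentSet,
    inflation: Inflation = DEFAULT_INFLATION,
) -> MrEstimate:
    """MR-Egger under correlated instruments: GLS of by on [1, bx].

    Instruments are first oriented so every bx_j >= 0 (joint sign flip of
    bx_j, by_j and conjugation of rho by the sign vector), which the Egger
    intercept requires; the slope is the pleiotropy-robust causal estimate
    and the intercept theta_0 estimates the average directional pleiotropic
    effect.  Slope and intercept p-values are t(J-2).
    """
    J = len(instruments)
    if J < 3:
        raise EstimationError("insufficient_instruments")
    bx, sx, by, sy, rho = instruments.arrays()
    sign = np.where(bx >= 0, 1.0, -1.0)
    bx = bx * sign
    by = by * sign
    rho = rho * np.outer(sign, sign)
    factor = _sigma_factor(sy, rho)
    X = np.column_stack([np.ones(J), bx])
    SiX = linalg.cho_solve(factor, X)
    xtsx = X.T @ SiX  # 2x2
    try:
        cov_fixed = np.linalg.inv(xtsx)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("degenerate_design") from exc
    coef = cov_fixed @ (SiX.T @ by)
    intercept, slope = float(coef[0]), float(coef[1])

    resid = by - X @ coef
    q = float(resid @ linalg.cho_solve(factor, resid))
    df = J - 2
    if inflation == "fixed":
        phi = 1.0
    elif inflation == "floored":
        phi = max(1.0, math.sqrt(q / df))
    else:
        phi = math.sqrt(max(q, 0.0) / df)
    phi = max(phi, 1e-300)
    se_slope = math.sqrt(cov_fixed[1, 1]) * phi
    se_int = math.sqrt(cov_fixed[0, 0]) * phi
    gene, out, tissue = _labels(instruments)
    return MrEstimate(
        gene, out, tissue, "egger",
        slope, se_slope, _two_sided_t_p(slope / se_slope, df), J,
        intercept_theta0=intercept, se_intercept=se_int,
        p_intercept=_two_sided_t_p(intercept / se_int, df),
        phi=phi, pvalue_dist=f"t({df})",
    )


def max_likelihood(
    instruments: InstrumentSet,
    gtol: float = 1e-8,
    max_iter: int = 500,
) -> MrEstimate:
    """Joint-likelihood estimate allowing uncertainty in both association sets.

    Model: bx ~ N(gamma, Dx rho Dx), by ~ N(theta * gamma, Dy rho Dy), with
    zero cross-covariance (two-sample design); gamma in R^J are nuisance true
    SNP-exposure effects.  Maximized by quasi-Newton (BFGS) from gamma = bx,
    theta = IVW; the SE comes from the inverse observed information.  A single
    instrument collapses exactly to the Wald ratio.
    """
    J = len(instruments)
    if J == 0:
        raise EstimationError("insufficient_instruments")
    if J == 1:
        return _wald_from_set(instruments, "max_likelihood")
    bx, sx, by, sy, rho = instruments.arrays()
    ridge_rho = rho + RIDGE * np.eye(J)
    A = np.linalg.inv(np.outer(sx, sx) * ridge_rho)  # exposure precision
    B = np.linalg.inv(np.outer(sy, sy) * ridge_rho)  # outcome precision

    def negloglik(x: np.ndarray) -> float:
        theta, gamma = x[0], x[1:]
        rx = bx - gamma
        ry = by - theta * gamma
        return 0.5 * (rx @ A @ rx + ry @ B @ ry)

    def grad(x: np.ndarray) -> np.ndarray:
        theta, gamma = x[0], x[1:]
        rx = bx - gamma
        ry = by - theta * gamma
        g = np.empty_like(x)
        g[0] = -gamma @ B @ ry
        g[1:] = -(A @ rx) - theta * (B @ ry)
        return g

    theta0 = ivw_correlated(instruments, inflation="fixed").theta_hat
    x0 = np.concatenate([[theta0], bx])
    res = optimize.minimize(negloglik, x0, jac=grad, method="BFGS",
                            options={"gtol": gtol, "maxiter": max_iter})
    gnorm = float(np.linalg.norm(grad(res.x), np.inf))
    if not res.success and gnorm > 1e-5:
        raise EstimationError(
            f"max_likelihood did not converge (final |grad|_inf = {gnorm:.3g})")
    theta, gamma = float(res.x[0]), res.x[1:]
    ry = by - theta * gamma
    H = np.zeros((J + 1, J + 1))
    H[0, 0] = gamma @ B @ gamma
    H[0, 1:] = H[1:, 0] = -(B @ by) + 2.0 * theta * (B @ gamma)
    H[1:, 1:] = A + theta**2 * B
    se = math.sqrt(np.linalg.inv(H)[0, 0])
    gene, out, tissue = _labels(instruments)
    return MrEstimate(gene, out, tissue, "max_likelihood",
                      theta, se, _two_sided_normal_p(theta / se), J)


def _ratio_weights(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    """Per-SNP Wald ratios with first-order inverse-variance weights."""
    ratios = by / bx
    w = bx**2 / sy**2
    return ratios, w / w.sum()


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w)
    breakpoints = s - w / 2.0
    return float(np.interp(0.5, breakpoints, r))


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return phi * 0.9 * spread * len(ratios) ** (-1.0 / 5.0)


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h <= 0 or np.ptp(ratios) == 0:
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[int(np.argmax(dens))])


def _bootstrap_se(
    estimator, bx, sx, by, sy, boot_reps: int, seed: int,
) -> float:
    """Parametric bootstrap: resample (bx_j, by_j) from their sampling normals."""
    rng = np.random.default_rng(seed)
    J = len(bx)
    bxs = rng.normal(bx, sx, size=(boot_reps, J))
    bys = rng.normal(by, sy, size=(boot_reps, J))
    bxs[bxs == 0] = 1e-300
    stats_ = np.empty(boot_reps)
    for r in range(boot_reps):
        ratios, w = _ratio_weights(bxs[r], bys[r], sy)
        stats_[r] = estimator(ratios, w)
    return float(np.std(stats_, ddof=1))


def weighted_median(
    instruments: InstrumentSet, boot_reps: int = 1000, seed: int = 0,
) -> MrEstimate:
    """Weighted-median sensitivity estimator.

    Consistent when instruments carrying >= 50% of the weight are valid.
    The estimate interpolates the weighted empirical quantile function of the
    per-SNP ratios at 0.5; the SE is a seeded parametric bootstrap.
    """
    J = len(instruments)
    if J < 3:
        raise EstimationError("insufficient_instruments")
    bx, sx, by, sy, _ = instruments.arrays()
    if np.any(bx == 0):
        raise EstimationError("weak/degenerate instrument: bx = 0")
    ratios, w = _ratio_weights(bx, by, sy)
    theta = _weighted_median(ratios, w)
    se = _bootstrap_se(_weighted_median, bx, sx, by, sy, boot_reps, seed)
    se = max(se, 1e-300)
    gene, out, tissue = _labels(instruments)
    return MrEstimate(gene, out, tissue, "weighted_median",
                      theta, se, _two_sided_normal_p(theta / se), J)


def weighted_mode(
    instruments: InstrumentSet, phi: float = 1.0,
    boot_reps: int = 1000, seed: int = 0,
) -> MrEstimate:
    """Weighted-mode sensitivity estimator (mode of the smoothed ratio density).

    Consistent when the largest group of instruments sharing one ratio value
    is valid, however small.  Bandwidth = phi * 0.9 * min(sd, IQR/1.349) *
    J^(-1/5) on the ratio scale; SE by seeded parametric bootstrap.
    """
    J = len(instruments)
    if J < 3:
        raise EstimationError("insufficient_instruments")
    bx, sx, by, sy, _ = instruments.arrays()
    if np.any(bx == 0):
        raise EstimationError("weak/degenerate instrument: bx = 0")
    ratios, w = _ratio_weights(bx, by, sy)
    theta = _weighted_mode(ratios, w, phi)
    se = _bootstrap_se(lambda r, wt: _weighted_mode(r, wt, phi),
                       bx, sx, by, sy, boot_reps, seed)
    se = max(se, 1e-300)
    gene, out, tissue = _labels(instruments)
    return MrEstimate(gene, out, tissue, "weighted_mode",
                      theta, se, _two_sided_normal_p(theta / se), J)
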