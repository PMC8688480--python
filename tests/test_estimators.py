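"""Estimator correctness against independently coded oracles and closed forms."""

import numpy as np
import pytest
from scipy import optimize

from targetmr.estimators import (EstimationError, egger_correlated,
                                 ivw_correlated, max_likelihood, wald_ratio,
                                 weighted_median, weighted_mode)

from .conftest import ar1, make_instruments

RIDGE = 1e-8


# --- independently coded oracles (explicit matrix inverses) ----------------

def sigma_of(sy, rho):
    J = len(sy)
    return np.outer(sy, sy) * (np.asarray(rho) + RIDGE * np.eye(J))


def ivw_gls_oracle(bx, by, sy, rho):
    si = np.linalg.inv(sigma_of(sy, rho))
    prec = bx @ si @ bx
    theta = (bx @ si @ by) / prec
    return theta, np.sqrt(1.0 / prec)


def egger_wls_oracle(bx, by, sy, rho):
    sign = np.where(np.asarray(bx) >= 0, 1.0, -1.0)
    bx = bx * sign
    by = by * sign
    rho = np.asarray(rho) * np.outer(sign, sign)
    si = np.linalg.inv(sigma_of(sy, rho))
    X = np.column_stack([np.ones(len(bx)), bx])
    cov = np.linalg.inv(X.T @ si @ X)
    coef = cov @ (X.T @ si @ by)
    return coef[0], coef[1], np.sqrt(np.diag(cov))


def ml_grid_oracle(bx, sx, by, sy, rho):
    """Profile grid search + Brent refinement over theta; gamma by stacked
    least squares (whitened residuals), algebra independent of the package."""
    J = len(bx)
    Lxi = np.linalg.inv(np.linalg.cholesky(sigma_of(sx, rho)))
    Lyi = np.linalg.inv(np.linalg.cholesky(sigma_of(sy, rho)))

    def prof_nll(theta):
        A = np.vstack([Lxi, theta * Lyi])
        b = np.concatenate([Lxi @ bx, Lyi @ by])
        gamma, *_ = np.linalg.lstsq(A, b, rcond=None)
        r = A @ gamma - b
        return 0.5 * float(r @ r)

    center = np.median(np.asarray(by) / np.asarray(bx))
    grid = np.linspace(center - 2.0, center + 2.0, 801)
    vals = [prof_nll(t) for t in grid]
    k = int(np.argmin(vals))
    lo, hi = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
    res = optimize.minimize_scalar(prof_nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def random_fixture(rng, J=None):
    J = J or int(rng.integers(2, 9))
    rho = ar1(J, rng.uniform(0.0, 0.8))
    bx = rng.uniform(0.1, 0.5, J) * rng.choice([-1, 1], J)
    sx = rng.uniform(0.01, 0.03, J)
    sy = rng.uniform(0.01, 0.05, J)
    by = 0.3 * bx + rng.normal(0, 0.02, J)
    return bx, sx, by, sy, rho


# --- Wald ratio -------------------------------------------------------------

class TestWaldRatio:
    def test_unit_denominator(self):
        assert wald_ratio(1.0, 0.1, 0.5, 0.05).theta_hat == 0.5

    def test_zero_numerator_first_order_collapse(self):
        e = wald_ratio(0.5, 0.1, 0.0, 0.05)
        assert e.theta_hat == 0.0 and e.se_theta == pytest.approx(0.05 / 0.5)

    def test_second_order_delta_method(self):
        e = wald_ratio(0.5, 0.1, 0.2, 0.05)
        assert e.theta_hat == pytest.approx(0.4)
        assert e.se_theta == pytest.approx(np.sqrt(0.01 + 0.0064))

    def test_first_order_switch(self):
        e = wald_ratio(0.5, 0.1, 0.2, 0.05, second_order=False)
        assert e.se_theta == pytest.approx(0.1)

    def test_zero_denominator_rejected(self):
        with pytest.raises(EstimationError, match="weak"):
            wald_ratio(0.0, 0.1, 0.2, 0.05)


# --- IVW --------------------------------------------------------------------

class TestIvwCorrelated:
    def test_single_instrument_equals_wald(self):
        inst = make_instruments([0.5], [0.1], [0.2], [0.05])
        w = wald_ratio(0.5, 0.1, 0.2, 0.05)
        e = ivw_correlated(inst)
        assert (e.theta_hat, e.se_theta, e.pvalue) == \
            (w.theta_hat, w.se_theta, w.pvalue)

    def test_equal_weights_give_arithmetic_mean(self):
        inst = make_instruments([1.0, 1.0], [0.01, 0.01], [0.3, 0.5],
                                [0.1, 0.1], rho=np.eye(2))
        e = ivw_correlated(inst)
        assert e.theta_hat == pytest.approx(0.4, abs=1e-9)
        assert e.se_theta == pytest.approx(np.sqrt(1 / 200), rel=1e-6)
        assert e.phi == 1.0  # J < 4: fixed-effect

    def test_identity_ld_equals_classical_ivw(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            bx, sx, by, sy, _ = random_fixture(rng)
            J = len(bx)
            inst = make_instruments(bx, sx, by, sy, rho=np.eye(J))
            ratios = by / bx
            w = bx**2 / sy**2
            theta = np.sum(w * ratios) / w.sum()
            e = ivw_correlated(inst, inflation="fixed")
            assert e.theta_hat == pytest.approx(theta, abs=1e-10)
            assert e.se_theta == pytest.approx(np.sqrt(1 / w.sum()), rel=1e-6)

    def test_ar1_fixture_matches_gls_oracle(self):
        bx = np.array([0.2, 0.3, 0.4])
        sx = np.array([0.02, 0.02, 0.02])
        by = np.array([0.05, 0.12, 0.09])
        sy = np.array([0.03, 0.04, 0.05])
        rho = ar1(3, 0.5)
        e = ivw_correlated(make_instruments(bx, sx, by, sy, rho=rho),
                           inflation="fixed")
        theta, se = ivw_gls_oracle(bx, by, sy, rho)
        assert e.theta_hat == pytest.approx(theta, abs=1e-10)
        assert e.se_theta == pytest.approx(se, abs=1e-10)

    def test_joint_sign_flip_equivariance(self):
        rng = np.random.default_rng(3)
        bx, sx, by, sy, rho = random_fixture(rng, J=5)
        inst = make_instruments(bx, sx, by, sy, rho=rho)
        s = np.array([1, -1, 1, -1, 1.0])
        flipped = make_instruments(bx * s, sx, by * s, sy,
                                   rho=rho * np.outer(s, s))
        for est in (ivw_correlated, max_likelihood):
            assert est(inst).theta_hat == pytest.approx(
                est(flipped).theta_hat, abs=1e-8)

    def test_perfectly_correlated_pair_stays_finite(self):
        # rank-deficient rho is regularized by the 1e-8 ridge; the estimate
        # must remain finite and close to the shared Wald ratio
        rho = np.array([[1.0, 1.0], [1.0, 1.0]])
        inst = make_instruments([0.3, 0.3], [0.02] * 2, [0.15, 0.15],
                                [0.05] * 2, rho=rho)
        e = ivw_correlated(inst)
        assert np.isfinite(e.theta_hat) and np.isfinite(e.se_theta)
        assert e.theta_hat == pytest.approx(0.5, abs=1e-6)


# --- MR-Egger ---------------------------------------------------------------

class TestEggerCorrelated:
    def test_exact_affine_relation_recovered(self):
        bx = np.array([0.2, 0.4, 0.6])
        by = 0.04 + 0.5 * bx
        rho = ar1(3, 0.4)
        e = egger_correlated(make_instruments(bx, [0.02] * 3, by, [0.05] * 3,
                                              rho=rho))
        assert e.theta_hat == pytest.approx(0.5, abs=1e-9)
        assert e.intercept_theta0 == pytest.approx(0.04, abs=1e-9)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(5)
        bx, sx, by, sy, rho = random_fixture(rng, J=4)
        base = egger_correlated(make_instruments(bx, sx, by, sy, rho=rho))
        s = np.array([1, -1, -1, 1.0])
        flip = egger_correlated(make_instruments(
            bx * s, sx, by * s, sy, rho=rho * np.outer(s, s)))
        assert base.theta_hat == pytest.approx(flip.theta_hat, abs=1e-10)
        assert base.intercept_theta0 == pytest.approx(flip.intercept_theta0,
                                                      abs=1e-10)

    def test_identity_ld_matches_wls_oracle(self):
        rng = np.random.default_rng(9)
        bx, sx, by, sy, _ = random_fixture(rng, J=4)
        e = egger_correlated(make_instruments(bx, sx, by, sy, rho=np.eye(4)),
                             inflation="fixed")
        b0, b1, se = egger_wls_oracle(bx, by, sy, np.eye(4))
        assert e.theta_hat == pytest.approx(b1, abs=1e-10)
        assert e.intercept_theta0 == pytest.approx(b0, abs=1e-10)
        assert e.se_theta == pytest.approx(se[1], abs=1e-10)

    def test_too_few_instruments(self):
        inst = make_instruments([0.3, 0.2], [0.02] * 2, [0.1] * 2, [0.05] * 2)
        with pytest.raises(EstimationError, match="insufficient"):
            egger_correlated(inst)


# --- Maximum likelihood -----------------------------------------------------

class TestMaxLikelihood:
    def test_single_instrument_equals_wald(self):
        inst = make_instruments([0.5], [0.1], [0.2], [0.05])
        assert max_likelihood(inst).theta_hat == \
            wald_ratio(0.5, 0.1, 0.2, 0.05).theta_hat

    def test_noise_free_consistency(self):
        bx = np.array([0.2, 0.35, 0.5])
        theta = 0.7
        inst = make_instruments(bx, [1e-4] * 3, theta * bx, [1e-4] * 3,
                                rho=ar1(3, 0.3))
        assert max_likelihood(inst).theta_hat == pytest.approx(theta, abs=1e-6)

    def test_two_snp_grid_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            bx, sx, by, sy, rho = random_fixture(rng, J=2)
            e = max_likelihood(make_instruments(bx, sx, by, sy, rho=rho))
            assert e.theta_hat == pytest.approx(
                ml_grid_oracle(bx, sx, by, sy, rho), abs=1e-6)


# --- Weighted median / mode -------------------------------------------------

class TestWeightedMedian:
    def test_middle_of_equal_weight_triplet(self):
        inst = make_instruments([1.0] * 3, [0.01] * 3, [0.1, 0.4, 0.9],
                                [0.05] * 3)
        assert weighted_median(inst, boot_reps=50, seed=1).theta_hat == \
            pytest.approx(0.4)

    def test_majority_weight_dominates(self):
        # middle SNP carries ~89% of the weight -> estimate equals its ratio
        inst = make_instruments([1.0, 1.0, 1.0], [0.01] * 3, [0.1, 0.5, 0.9],
                                [0.2, 0.05, 0.2])
        assert weighted_median(inst, boot_reps=50, seed=1).theta_hat == \
            pytest.approx(0.5)

    def test_seed_reproducibility(self):
        inst = make_instruments([1.0, 0.8, 1.2], [0.02] * 3, [0.1, 0.4, 0.9],
                                [0.05] * 3)
        a = weighted_median(inst, boot_reps=100, seed=7)
        b = weighted_median(inst, boot_reps=100, seed=7)
        assert a.se_theta == b.se_theta  # bit-identical

    def test_too_few_instruments(self):
        with pytest.raises(EstimationError):
            weighted_median(make_instruments([1.0], [0.1], [0.1], [0.1]))


class TestWeightedMode:
    def test_point_mass(self):
        inst = make_instruments([1.0] * 3, [0.01] * 3, [0.7] * 3, [0.05] * 3)
        assert weighted_mode(inst, boot_reps=50, seed=1).theta_hat == \
            pytest.approx(0.7)

    def test_mode_ignores_outlier(self):
        bx = np.ones(5)
        by = np.array([0.48, 0.5, 0.5, 0.52, 3.0])
        inst = make_instruments(bx, [0.01] * 5, by, [0.05] * 5)
        t = weighted_mode(inst, boot_reps=50, seed=1).theta_hat
        assert abs(t - 0.5) < abs(t - 3.0)

    def test_seed_reproducibility(self):
        inst = make_instruments([1.0, 0.8, 1.2], [0.02] * 3, [0.1, 0.4, 0.9],
                                [0.05] * 3)
        assert weighted_mode(inst, boot_reps=100, seed=3).se_theta == \
            weighted_mode(inst, boot_reps=100, seed=3).se_theta
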