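"""MR estimators: hand-checked values, library oracles and simulations."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

import fitmr as fm
from fitmr.mr import _weighted_median
from conftest import harmonised_from


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bx,sx,by,sy,beta,se", [
    (1.0, 0.1, 0.5, 0.1, 0.5, 0.1),
    (2.0, 0.1, 1.0, 0.2, 0.5, 0.1),
])
def test_wald_ratio_arithmetic(bx, sx, by, sy, beta, se):
    est = fm.wald_ratio(bx, sx, by, sy)
    assert est.beta == pytest.approx(beta)
    assert est.se == pytest.approx(se)


def test_wald_ratio_null_and_error():
    est = fm.wald_ratio(1.0, 0.1, 0.0, 0.1)
    assert est.beta == 0 and est.p == 1
    with pytest.raises(fm.MrError):
        fm.wald_ratio(0.0, 0.1, 0.5, 0.1)


# ---------------------------------------------------------------------------
# IVW and Cochran's Q
# ---------------------------------------------------------------------------

def test_ivw_hand_value(simple_harmonised):
    est = fm.ivw(simple_harmonised, model="fixed")
    assert est.beta == pytest.approx(0.54)
    assert est.se == pytest.approx(1 / np.sqrt(125))


def test_ivw_identical_ratios_fixed_equals_random():
    h = harmonised_from([1, 1, 1], [0.01] * 3, [0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
    fixed = fm.ivw(h, "fixed")
    random = fm.ivw(h, "random")
    assert fixed.beta == pytest.approx(0.3)
    assert random.se == pytest.approx(fixed.se)
    assert fm.cochran_q(h).Q == pytest.approx(0.0)
    assert fm.cochran_q(h).p == pytest.approx(1.0)


def test_ivw_single_variant_degenerates_to_wald():
    h = harmonised_from([2.0], [0.1], [1.0], [0.2])
    est = fm.ivw(h, "fixed")
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.1)


def test_ivw_equals_weighted_least_squares_oracle():
    rng = np.random.default_rng(42)
    for _ in range(100):
        L = rng.integers(3, 30)
        bx = rng.uniform(0.05, 0.5, L)
        by = rng.normal(0, 0.1, L)
        sy = rng.uniform(0.01, 0.2, L)
        h = harmonised_from(bx, np.full(L, 0.01), by, sy)
        mine = fm.ivw(h, "fixed").beta
        oracle = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit().params[0]
        assert mine == pytest.approx(oracle, abs=1e-10)


def test_cochran_q_hand_value(simple_harmonised):
    est = fm.ivw(simple_harmonised, "fixed")
    het = fm.cochran_q(simple_harmonised, est.beta)
    assert het.Q == pytest.approx(0.8)
    assert het.df == 1
    assert np.sum(het.q_contributions) == pytest.approx(het.Q)


def test_q_p_uniform_under_homogeneity():
    """Under no pleiotropy the heterogeneity p-value is uniform on (0,1)."""
    rng = np.random.default_rng(7)
    ps = []
    for _ in range(500):
        L = 20
        bx = rng.uniform(0.05, 0.2, L)
        sy = np.full(L, 0.05)
        by = rng.normal(0.3 * bx, sy)
        h = harmonised_from(bx, np.full(L, 1e-6), by, sy)
        ps.append(fm.cochran_q(h).p)
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def test_egger_exact_fit():
    bx = np.array([1.0, 2.0, 3.0])
    by = 0.1 + 0.5 * bx
    h = harmonised_from(bx, [0.01] * 3, by, [0.1] * 3)
    est = fm.egger(h)
    assert est.beta == pytest.approx(0.5)
    assert est.intercept == pytest.approx(0.1)
    by0 = 0.5 * bx
    est0 = fm.egger(harmonised_from(bx, [0.01] * 3, by0, [0.1] * 3))
    assert est0.intercept == pytest.approx(0.0, abs=1e-12)


def test_egger_constrained_equals_ivw():
    rng = np.random.default_rng(3)
    for _ in range(20):
        L = 10
        bx = rng.uniform(0.05, 0.5, L)
        by = rng.normal(0, 0.1, L)
        sy = rng.uniform(0.01, 0.2, L)
        h = harmonised_from(bx, np.full(L, 0.01), by, sy)
        assert fm.egger(h, constrain_intercept=True).beta == pytest.approx(
            fm.ivw(h, "fixed").beta, abs=1e-12)


def test_egger_recovers_directional_intercept():
    """Mean pleiotropic effect 0.01 appears as the Egger intercept."""
    rng = np.random.default_rng(11)
    intercepts = []
    for _ in range(200):
        L = 50
        bx = rng.uniform(0.05, 0.2, L)
        sy = np.full(L, 0.01)
        by = rng.normal(-0.017 * bx + 0.01, sy)
        h = harmonised_from(bx, np.full(L, 1e-6), by, sy)
        intercepts.append(fm.egger(h).intercept)
    mean = np.mean(intercepts)
    sem = np.std(intercepts) / np.sqrt(len(intercepts))
    assert abs(mean - 0.01) < 3 * sem + 1e-4


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def test_weighted_median_hand_values():
    assert _weighted_median(np.array([0.4, 0.5, 0.9]), np.ones(3)) == pytest.approx(0.5)
    assert _weighted_median(np.array([0.4, 0.8]), np.ones(2)) == pytest.approx(0.6)
    assert _weighted_median(np.array([0.3, 0.3, 0.3]), np.ones(3)) == pytest.approx(0.3)


def test_weighted_median_estimator_and_penalised():
    h = harmonised_from([1, 1, 1], [0.01] * 3, [0.4, 0.5, 0.9], [0.1] * 3)
    est = fm.weighted_median(h, n_boot=200, seed=1)
    assert est.beta == pytest.approx(0.5)
    pen = fm.weighted_median(h, penalised=True, n_boot=200, seed=1)
    assert pen.method == "penalised_weighted_median"
    assert est.se > 0
    with pytest.raises(fm.MrError):
        fm.weighted_median(harmonised_from([1, 1], [0.01] * 2, [0.4, 0.5], [0.1] * 2))


# ---------------------------------------------------------------------------
# radial filtering
# ---------------------------------------------------------------------------

def test_radial_no_outliers_when_homogeneous():
    h = harmonised_from([1, 1, 1, 1], [0.01] * 4, [0.3] * 4, [0.1] * 4)
    filtered, outliers = fm.radial_outlier_filter(h)
    assert outliers == []
    assert len(filtered) == 4


def test_radial_removes_exactly_planted_outlier():
    rng = np.random.default_rng(0)
    L = 21
    bx = rng.uniform(0.1, 0.3, L)
    sy = np.full(L, 0.01)
    by = rng.normal(0.2 * bx, sy)
    by[7] = 0.2 * bx[7] + 10 * sy[7]  # gross outlier, 10 sigma off
    h = harmonised_from(bx, np.full(L, 1e-6), by, sy,
                        variant_ids=[f"v{i}" for i in range(L)])
    filtered, outliers = fm.radial_outlier_filter(h, alpha=0.001)
    assert outliers == ["v7"]
    _, _, het = fm.radial_fit(filtered)
    assert het.p > 0.001


def test_radial_fit_slope_matches_ivw(simple_harmonised):
    beta, _, het = fm.radial_fit(
        harmonised_from([1, 1, 1], [0.01] * 3, [0.5, 0.7, 0.6], [0.1, 0.2, 0.15]))
    h3 = harmonised_from([1, 1, 1], [0.01] * 3, [0.5, 0.7, 0.6], [0.1, 0.2, 0.15])
    assert beta == pytest.approx(fm.ivw(h3, "fixed").beta, abs=1e-12)
    assert np.sum(het.q_contributions) == pytest.approx(het.Q)


# ---------------------------------------------------------------------------
# Steiger filtering
# ---------------------------------------------------------------------------

def test_steiger_hand_arithmetic():
    # z_X = 10, n_X = 70k: rho2_X = 100/70100 = 1.43e-3
    # z_Y = 3, n_Y = 400k: rho2_Y = 9/400009 = 2.25e-5 -> kept
    h = harmonised_from([0.1], [0.01], [0.006], [0.002],
                        n_exp=70_000, n_out=400_000)
    kept, removed = fm.steiger_filter(h)
    assert len(kept) == 1 and removed == []


def test_steiger_removes_outcome_first_variant():
    h = harmonised_from([0.02, 0.1], [0.01, 0.01], [0.2, 0.0], [0.002, 0.002],
                        n_exp=70_000, n_out=70_000,
                        variant_ids=["reverse", "forward"])
    kept, removed = fm.steiger_filter(h)
    assert removed == ["reverse"]
    assert list(kept.df["variant_id"]) == ["forward"]  # z_Y = 0 always kept


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def test_presso_deterministic_and_detects_planted_outlier():
    rng = np.random.default_rng(5)
    L = 20
    bx = rng.uniform(0.1, 0.3, L)
    sy = np.full(L, 0.01)
    by = rng.normal(0.2 * bx, sy)
    by[3] += 12 * sy[3]
    h = harmonised_from(bx, np.full(L, 0.001), by, sy,
                        variant_ids=[f"v{i}" for i in range(L)])
    r1 = fm.mr_presso(h, n_sim=500, seed=9)
    r2 = fm.mr_presso(h, n_sim=500, seed=9)
    assert r1 == r2  # bit-identical under a fixed seed
    assert "v3" in r1.outliers
    assert r1.global_p < 0.05
    # the planted shift is upward, so removing it lowers the pooled estimate
    assert r1.estimate_after.beta < r1.estimate_before.beta
    assert r1.distortion > 0


def test_presso_null_global_p_not_small():
    rng = np.random.default_rng(12)
    ps = []
    for rep in range(40):
        L = 15
        bx = rng.uniform(0.1, 0.3, L)
        sy = np.full(L, 0.01)
        by = rng.normal(0.2 * bx, sy)
        h = harmonised_from(bx, np.full(L, 1e-6), by, sy)
        ps.append(fm.mr_presso(h, n_sim=200, seed=rep).global_p)
    assert np.mean(np.array(ps) < 0.05) <= 0.15


def test_presso_input_contracts():
    h = harmonised_from([1, 1, 1], [0.01] * 3, [0.3] * 3, [0.1] * 3)
    with pytest.raises(fm.MrError):
        fm.mr_presso(h)  # < 4 variants
    h4 = harmonised_from([1] * 4, [0.01] * 4, [0.3] * 4, [0.1] * 4)
    with pytest.raises(fm.MrError):
        fm.mr_presso(h4, n_sim=50)


# ---------------------------------------------------------------------------
# multivariable MR and mediation
# ---------------------------------------------------------------------------

def test_mvmr_exact_linear_system():
    bx = np.array([0.1, 0.2, 0.15, 0.3, 0.25])
    bm = np.array([0.05, -0.1, 0.2, 0.1, -0.05])
    by = 0.5 * bx + 0.2 * bm
    h = harmonised_from(bx, [0.01] * 5, by, [0.1] * 5,
                        mediators={"m": (bm, [0.01] * 5)})
    res = fm.mvmr(h)
    assert res.beta[0] == pytest.approx(0.5, abs=1e-10)
    assert res.beta[1] == pytest.approx(0.2, abs=1e-10)


def test_mvmr_zero_mediator_column_matches_univariate_ivw():
    bx = np.array([0.1, 0.2, 0.15, 0.3])
    by = np.array([0.06, 0.09, 0.08, 0.14])
    h = harmonised_from(bx, [0.01] * 4, by, [0.1] * 4,
                        mediators={"m": (np.zeros(4), [0.01] * 4)})
    res = fm.mvmr(h)
    assert res.beta[0] == pytest.approx(fm.ivw(h, "fixed").beta, abs=1e-12)
    assert res.beta[1] == 0.0


def test_mvmr_collinear_design_names_columns():
    bx = np.array([0.1, 0.2, 0.15, 0.3])
    h = harmonised_from(bx, [0.01] * 4, 0.5 * bx, [0.1] * 4,
                        mediators={"m": (2 * bx, [0.01] * 4)})
    with pytest.raises(fm.MrError, match="collinear"):
        fm.mvmr(h)


@pytest.mark.parametrize("total,direct,expected", [
    (-0.020, -0.015, 25.0),
    (-0.020, -0.020, 0.0),
    (-0.020, 0.0, 100.0),
])
def test_mediation_proportion_arithmetic(total, direct, expected):
    t = fm.wald_ratio(1, 0.1, total, 0.01)
    d = fm.wald_ratio(1, 0.1, direct, 0.01)
    assert fm.mediation_proportion(t, d).raw == pytest.approx(expected)


def test_mediation_truncation_keeps_raw():
    t = fm.wald_ratio(1, 0.1, -0.01, 0.01)
    d = fm.wald_ratio(1, 0.1, -0.02, 0.01)  # direct exceeds total
    res = fm.mediation_proportion(t, d)
    assert res.raw == pytest.approx(-100.0)
    assert res.reported == 0.0


# ---------------------------------------------------------------------------
# effect-size transformations
# ---------------------------------------------------------------------------

def test_or_from_logodds_hand_values():
    res = fm.or_from_logodds(0.0, 0.1)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.ci_low == pytest.approx(np.exp(-0.196), abs=1e-3)
    assert res.ci_high == pytest.approx(np.exp(0.196), abs=1e-3)
    assert res.p == 1.0


def test_per_sd_scale_and_commutation():
    est = fm.wald_ratio(1.0, 0.1, -0.0284, 0.0165)
    scaled = fm.per_sd_scale(est, 2.0)
    assert scaled.beta == pytest.approx(-0.0568)
    assert scaled.se == pytest.approx(0.033)
    # scaling then exponentiating == exponentiating then power-scaling
    a = fm.or_from_logodds(scaled.beta, scaled.se).odds_ratio
    b = fm.or_from_logodds(est.beta, est.se).odds_ratio ** 2.0
    assert a == pytest.approx(b)
    assert fm.per_sd_scale(est, 1.0).beta == est.beta
    with pytest.raises(fm.MrError):
        fm.per_sd_scale(est, 0.0)
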