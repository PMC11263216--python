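import numpy as np
import pytest
import statsmodels.api as sm

from lipidmr.estimators import (
    DegenerateInstrumentError,
    EggerEstimator,
    IVWEstimator,
    ModeEstimator,
    WeightedMedianEstimator,
    _kde_mode,
    egger,
    ivw,
    mode_estimate,
    run_all_methods,
    wald_ratio,
    wald_ratios,
    weighted_median,
)
from lipidmr.gwas_io import DataError

from conftest import make_harmonized


# ---------------------------------------------------------------------------
# Wald ratios


def test_wald_ratio_basic_and_degenerate():
    r = wald_ratio(0.1, 0.05, 0.02)
    assert r.theta == pytest.approx(0.5)
    assert r.se == pytest.approx(0.2)
    assert wald_ratio(0.1, 0.0, 0.02).theta == 0.0
    with pytest.raises(DegenerateInstrumentError):
        wald_ratio(0.0, 0.05, 0.02)


# ---------------------------------------------------------------------------
# IVW


def test_ivw_symmetric_pair():
    h = make_harmonized([1.0, 1.0], [0.4, 0.6], se_out=[0.1, 0.1])
    r = ivw(h, variance_model="fixed")
    assert r.beta == pytest.approx(0.5)
    assert r.se == pytest.approx(np.sqrt(1 / 200))


def test_ivw_single_ratio_is_wald_ratio():
    h = make_harmonized([0.1], [0.05], se_out=[0.02])
    r = ivw(h)
    assert r.beta == pytest.approx(0.5)
    assert r.se == pytest.approx(0.2)


def test_ivw_matches_wls_through_origin_oracle(rng):
    for _ in range(100):
        J = int(rng.integers(3, 30))
        x = rng.normal(0.15, 0.05, J)
        x[x == 0] = 0.1
        y = rng.normal(0.3 * x, 0.05)
        se_out = rng.uniform(0.01, 0.1, J)
        h = make_harmonized(x, y, se_out=se_out)
        fit = sm.WLS(y, x[:, None], weights=se_out ** -2).fit()
        mine = ivw(h, variance_model="multiplicative_random")
        assert mine.beta == pytest.approx(fit.params[0], abs=1e-10)
        # with the residual scale above 1, our SE equals the WLS SE exactly
        q_scale = mine.extra["cochran_q"] / (J - 1)
        if q_scale > 1:
            assert mine.se == pytest.approx(fit.bse[0], abs=1e-10)


def test_ivw_scale_and_sign_equivariance(rng):
    x = rng.normal(0.2, 0.05, 20)
    y = rng.normal(0.06, 0.02, 20)
    se_out = rng.uniform(0.01, 0.05, 20)
    base = ivw(make_harmonized(x, y, se_out=se_out)).beta
    assert ivw(make_harmonized(3 * x, y, se_out=se_out)).beta == pytest.approx(base / 3, rel=1e-9)
    assert ivw(make_harmonized(x, -y, se_out=se_out)).beta == pytest.approx(-base, rel=1e-9)


def test_ivw_empty_errors():
    with pytest.raises(DataError):
        IVWEstimator().fit(np.empty(0), np.empty(0), np.empty(0))


# ---------------------------------------------------------------------------
# MR-Egger


def test_egger_exact_interpolation():
    x = np.array([0.1, 0.2, 0.3])
    y = 0.3 * x + 0.01
    est = EggerEstimator().fit(x, y, np.full(3, 1e4))
    assert est.beta_ == pytest.approx(0.3, abs=1e-12)
    assert est.intercept_ == pytest.approx(0.01, abs=1e-12)
    assert est.rss_ == pytest.approx(0.0, abs=1e-20)


def test_egger_matches_weighted_regression_oracle(rng):
    for _ in range(100):
        J = int(rng.integers(4, 40))
        x = np.abs(rng.normal(0.2, 0.08, J)) + 0.02
        y = rng.normal(0.3 * x + 0.05, 0.1)
        se_out = rng.uniform(0.01, 0.05, J)
        w = se_out ** -2
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        est = EggerEstimator().fit(x, y, w)
        assert est.intercept_ == pytest.approx(fit.params[0], abs=1e-10)
        assert est.beta_ == pytest.approx(fit.params[1], abs=1e-10)
        if est.rss_ / (J - 2) > 1:  # above the residual-scale floor
            assert est.intercept_se_ == pytest.approx(fit.bse[0], abs=1e-10)
            assert est.se_ == pytest.approx(fit.bse[1], abs=1e-10)


def test_egger_recovers_directional_pleiotropy(rng):
    J = 100
    x = rng.uniform(0.1, 0.4, J)
    alpha = 0.05
    y = 0.3 * x + alpha + rng.normal(0, 0.005, J)
    est = EggerEstimator().fit(x, y, np.full(J, 0.005 ** -2))
    assert abs(est.intercept_ - alpha) < 3 * est.intercept_se_


def test_egger_orientation_invariance(rng):
    x = rng.uniform(0.1, 0.4, 20) * rng.choice([-1, 1], 20)
    y = rng.normal(0.3 * x, 0.02)
    w = np.full(20, 1e4)
    a = EggerEstimator().fit(x, y, w)
    b = EggerEstimator().fit(-x, -y, w)
    assert a.beta_ == pytest.approx(b.beta_)
    assert a.intercept_ == pytest.approx(b.intercept_)


def test_egger_requires_spread_and_three_instruments():
    with pytest.raises(DataError):
        EggerEstimator().fit([0.1, 0.2], [0.03, 0.06], [1.0, 1.0])
    with pytest.raises(DataError, match="singular"):
        EggerEstimator().fit([0.1, 0.1, 0.1], [0.01, 0.02, 0.03], np.ones(3))


# ---------------------------------------------------------------------------
# weighted median


def test_weighted_median_equal_weights_is_sample_median():
    h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.5, 0.9], se_out=[0.1] * 3)
    r = weighted_median(h, n_boot=0)
    assert r.beta == pytest.approx(0.5)


def test_weighted_median_dominant_weight_tracks_dominant_ratio():
    # one ratio carries ~99% of the weight
    h = make_harmonized([1.0, 1.0, 1.0], [0.1, 0.5, 0.9],
                        se_out=[0.001, 0.1, 0.1])
    r = weighted_median(h, n_boot=0)
    assert abs(r.beta - 0.1) < 0.05


def _wm_oracle(theta, w):
    """Independent loop-based weighted 50% quantile with interpolation."""
    order = np.argsort(theta)
    t = np.asarray(theta, float)[order]
    w = np.asarray(w, float)[order]
    total = w.sum()
    s_prev, cum = None, 0.0
    svals = []
    for wi in w:
        cum += wi
        svals.append((cum - wi / 2) / total)
    svals = np.array(svals)
    if 0.5 <= svals[0]:
        return t[0]
    if 0.5 >= svals[-1]:
        return t[-1]
    i = np.searchsorted(svals, 0.5)
    frac = (0.5 - svals[i - 1]) / (svals[i] - svals[i - 1])
    return t[i - 1] + frac * (t[i] - t[i - 1])


def test_weighted_median_matches_quantile_oracle(rng):
    for _ in range(50):
        J = int(rng.integers(3, 25))
        x = rng.uniform(0.05, 0.3, J)
        y = rng.normal(0.1 * x, 0.05)
        se_out = rng.uniform(0.01, 0.1, J)
        h = make_harmonized(x, y, se_out=se_out)
        r = weighted_median(h, n_boot=0)
        ratios = wald_ratios(h)
        assert r.beta == pytest.approx(
            _wm_oracle(ratios["theta"], ratios["weight"]), abs=1e-10)


def test_weighted_median_bootstrap_deterministic():
    h = make_harmonized([0.2, 0.25, 0.3, 0.18], [0.06, 0.07, 0.1, 0.05],
                        se_out=[0.02] * 4)
    a = weighted_median(h, n_boot=200, seed=42)
    b = weighted_median(h, n_boot=200, seed=42)
    assert a.se == b.se and a.pval == b.pval


# ---------------------------------------------------------------------------
# mode estimators


def test_mode_degenerate_all_equal():
    h = make_harmonized([0.1, 0.2, 0.4], [0.07, 0.14, 0.28], se_out=[0.01] * 3)
    r = mode_estimate(h, n_boot=0)
    assert r.beta == pytest.approx(0.7)
    assert r.se == 0.0


def test_mode_bimodal_majority():
    h = make_harmonized([1.0] * 4, [0.0, 0.0, 0.0, 1.0], se_out=[0.05] * 4)
    r = mode_estimate(h, weighted=False, n_boot=0)
    assert abs(r.beta) < 0.1


def test_mode_grid_argmax_matches_finer_grid(rng):
    for _ in range(20):
        J = 15
        theta = rng.normal(0.3, 0.1, J)
        w = rng.uniform(0.5, 2.0, J)
        coarse = _kde_mode(theta[None, :], w, 1.0, n_grid=512)[0]
        fine = _kde_mode(theta[None, :], w, 1.0, n_grid=5120)[0]
        h = 0.9 * min(np.std(theta, ddof=1),
                      (np.percentile(theta, 75) - np.percentile(theta, 25)) / 1.349) \
            * J ** -0.2
        step = (theta.max() - theta.min() + 6 * h) / 511
        assert abs(coarse - fine) <= step


def test_mode_scale_equivariance(rng):
    x = rng.uniform(0.1, 0.3, 12)
    y = rng.normal(0.2 * x, 0.02)
    se_out = np.full(12, 0.02)
    a = mode_estimate(make_harmonized(x, y, se_out=se_out), n_boot=0).beta
    b = mode_estimate(make_harmonized(2 * x, y, se_out=se_out), n_boot=0).beta
    assert b == pytest.approx(a / 2, rel=1e-9)


# ---------------------------------------------------------------------------
# run_all_methods


def test_run_all_methods_cardinality_and_determinism(rng):
    x = rng.uniform(0.1, 0.3, 26)
    y = rng.normal(0.3 * x, 0.02)
    h = make_harmonized(x, y, se_out=np.full(26, 0.02))
    res = run_all_methods(h, n_boot=100, seed=9)
    assert [r.method for r in res] == [
        "IVW", "MR-Egger", "weighted_median", "simple_mode", "weighted_mode"]
    res2 = run_all_methods(h, n_boot=100, seed=9)
    for a, b in zip(res, res2):
        assert (a.beta, a.se, a.pval) == (b.beta, b.se, b.pval)


def test_run_all_methods_two_instruments_ivw_only():
    h = make_harmonized([0.1, 0.2], [0.03, 0.06], se_out=[0.02, 0.02])
    res = run_all_methods(h, seed=1)
    assert [r.method for r in res] == ["IVW"]


def test_all_methods_sign_equivariance(rng):
    x = rng.uniform(0.1, 0.3, 20)
    y = rng.normal(0.25 * x, 0.02)
    se_out = np.full(20, 0.02)
    pos = run_all_methods(make_harmonized(x, y, se_out=se_out), n_boot=0, seed=0)
    neg = run_all_methods(make_harmonized(x, -y, se_out=se_out), n_boot=0, seed=0)
    for a, b in zip(pos, neg):
        assert b.beta == pytest.approx(-a.beta, rel=1e-9)


def test_mr_result_interval_and_or_consistency():
    h = make_harmonized([0.2, 0.25, 0.3], [0.06, 0.08, 0.09], se_out=[0.02] * 3)
    r = ivw(h)
    assert r.ci_low == pytest.approx(r.beta - 1.96 * r.se)
    assert r.or_ == pytest.approx(np.exp(r.beta))


def test_sklearn_param_interface():
    est = IVWEstimator(variance_model="fixed")
    assert est.get_params() == {"variance_model": "fixed"}
    est.set_params(variance_model="multiplicative_random")
    est.fit([0.1, 0.2], [0.03, 0.07], [100.0, 100.0])
    preds = est.predict([0.1, 0.2])
    assert preds == pytest.approx(est.beta_ * np.array([0.1, 0.2]))
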