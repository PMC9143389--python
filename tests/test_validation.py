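"""Metric battery vs independent brute-force oracles, plus criteria logic.

Every statistic is checked against a direct-summation oracle written from
the defining formulas with plain Python loops — deliberately sharing no
code with the implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twoqsar import (
    PredictionSet,
    ccc,
    criteria_check,
    error_stats,
    external_q2,
    kfold_cv,
    origin_regression,
    r_squared,
    residuals,
    rm2_family,
    validation_report,
    y_scramble,
)


# ---------------------------------------------------------------------------
# brute-force oracles: direct summation, no numpy vectorization
# ---------------------------------------------------------------------------

def oracle_all(y, yh, y_tr_mean=None, n_tr=None):
    n = len(y)
    d = [y[i] - yh[i] for i in range(n)]
    out = {}
    out["rmse"] = math.sqrt(sum(v * v for v in d) / n)
    out["mae"] = sum(abs(v) for v in d) / n
    dm = sum(d) / n
    out["s"] = math.sqrt(sum((v - dm) ** 2 for v in d) / (n - 1))
    out["delta_max"] = max(abs(v) for v in d)
    out["mean_error"] = dm
    my = sum(y) / n
    myh = sum(yh) / n
    ss_res = sum(v * v for v in d)
    out["r2_obs"] = 1 - ss_res / sum((y[i] - my) ** 2 for i in range(n))
    out["r2_pred"] = 1 - ss_res / sum((y[i] - myh) ** 2 for i in range(n))
    if y_tr_mean is not None:
        out["qf1"] = 1 - ss_res / sum((y[i] - y_tr_mean) ** 2
                                      for i in range(n))
        out["qf2"] = out["r2_obs"]
        out["qf3"] = 1 - (ss_res / n) / (
            sum((y[i] - y_tr_mean) ** 2 for i in range(n)) / n_tr)
    num = 2 * sum((y[i] - my) * (yh[i] - myh) for i in range(n))
    den = (sum((y[i] - my) ** 2 for i in range(n))
           + sum((yh[i] - myh) ** 2 for i in range(n))
           + n * (my - myh) ** 2)
    out["ccc"] = num / den
    k = sum(y[i] * yh[i] for i in range(n)) / sum(v * v for v in y)
    kp = sum(y[i] * yh[i] for i in range(n)) / sum(v * v for v in yh)
    out["k"] = k
    out["r0"] = 1 - (sum((yh[i] - k * y[i]) ** 2 for i in range(n))
                     / sum((yh[i] - myh) ** 2 for i in range(n)))
    out["r0p"] = 1 - (sum((y[i] - kp * yh[i]) ** 2 for i in range(n))
                      / sum((y[i] - my) ** 2 for i in range(n)))
    return out


def _pset(y, yh, **kw):
    return PredictionSet([f"p{i}" for i in range(len(y))],
                         np.asarray(y, float), np.asarray(yh, float), **kw)


# ---------------------------------------------------------------------------
# elementary contracts
# ---------------------------------------------------------------------------

class TestResiduals:
    def test_direct_and_antisymmetry(self):
        p = _pset([1.0, 2.0], [0.0, 4.0])
        np.testing.assert_array_equal(residuals(p), [1.0, -2.0])
        q = _pset([0.0, 4.0], [1.0, 2.0])
        np.testing.assert_array_equal(residuals(q), -residuals(p))

    def test_perfect_prediction_zero(self):
        p = _pset([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not residuals(p).any()


class TestErrorStats:
    def test_hand_computed(self):
        rmse, mae, s, dmax, me = error_stats(_pset([4.0, 3.0], [1.0, -1.0]))
        assert rmse == pytest.approx(math.sqrt(25 / 2))
        assert mae == pytest.approx(3.5)
        assert dmax == 4.0 and me == pytest.approx(3.5)

    def test_symmetric_residuals(self):
        rmse, mae, s, dmax, me = error_stats(_pset([1.0, -1.0], [0.0, 0.0]))
        assert (rmse, mae, dmax, me) == (1.0, 1.0, 1.0, 0.0)

    def test_all_zero(self):
        stats = error_stats(_pset([1.0, 2.0], [1.0, 2.0]))
        assert stats == (0.0, 0.0, 0.0, 0.0, 0.0)


class TestRSquared:
    def test_perfect_prediction_both_centerings(self):
        p = _pset([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert r_squared(p, "observed_mean") == 1.0
        assert r_squared(p, "predicted_mean") == 1.0

    def test_centering_modes_match_oracle(self):
        y, yh = [0.0, 1.0, 2.0], [0.0, 1.0, 5.0]
        o = oracle_all(y, yh)
        p = _pset(y, yh)
        assert r_squared(p, "observed_mean") == pytest.approx(o["r2_obs"])
        assert r_squared(p, "predicted_mean") == pytest.approx(o["r2_pred"])
        assert o["r2_obs"] != o["r2_pred"]

    def test_constant_observations_error(self):
        with pytest.raises(ZeroDivisionError):
            r_squared(_pset([2.0, 2.0], [1.0, 3.0]), "observed_mean")

    def test_documented_asymmetry_vs_ccc_symmetry(self):
        rng = np.random.default_rng(31)
        y = rng.normal(size=20)
        yh = y + rng.normal(scale=0.5, size=20)
        assert r_squared(_pset(y, yh)) != pytest.approx(
            r_squared(_pset(yh, y)), abs=1e-6)
        assert ccc(_pset(y, yh)) == pytest.approx(ccc(_pset(yh, y)),
                                                  abs=1e-12)


class TestExternalQ2:
    def test_perfect_prediction_all_one(self):
        p = _pset([0.0, 1.0, 2.0], [0.0, 1.0, 2.0],
                  reference_train_mean=0.5, reference_train_size=10)
        assert external_q2(p) == pytest.approx((1.0, 1.0, 1.0))

    def test_constant_external_mean_prediction_gives_qf2_zero(self):
        y = [0.0, 1.0, 2.0]
        p = _pset(y, [1.0, 1.0, 1.0], reference_train_mean=0.3,
                  reference_train_size=7)
        _, qf2, _ = external_q2(p)
        assert qf2 == pytest.approx(0.0, abs=1e-12)

    def test_worked_case_against_oracle(self):
        y = [0.1, -0.4, 1.2, 0.8, -1.0]
        yh = [0.0, -0.2, 1.0, 1.1, -0.7]
        o = oracle_all(y, yh, y_tr_mean=0.25, n_tr=12)
        p = _pset(y, yh, reference_train_mean=0.25, reference_train_size=12)
        qf1, qf2, qf3 = external_q2(p)
        assert qf1 == pytest.approx(o["qf1"], abs=1e-12)
        assert qf2 == pytest.approx(o["qf2"], abs=1e-12)
        assert qf3 == pytest.approx(o["qf3"], abs=1e-12)
        assert qf1 != pytest.approx(qf2, abs=1e-6)

    def test_qf1_equals_qf2_when_means_agree(self):
        rng = np.random.default_rng(32)
        y = rng.normal(size=15)
        yh = y + 0.3 * rng.normal(size=15)
        p = _pset(y, yh, reference_train_mean=float(np.mean(y)),
                  reference_train_size=40)
        qf1, qf2, _ = external_q2(p)
        assert qf1 == pytest.approx(qf2, abs=1e-12)

    def test_reference_required(self):
        with pytest.raises(ValueError):
            external_q2(_pset([0.0, 1.0], [0.0, 1.0]))


class TestCcc:
    def test_identity_and_discordance(self):
        y = np.array([-1.0, 0.0, 1.0])
        assert ccc(_pset(y, y)) == pytest.approx(1.0)
        assert ccc(_pset(y, -y)) == pytest.approx(-1.0)

    def test_location_shift_penalized(self):
        y = [0.0, 1.0, 2.0]
        o = oracle_all(y, [5.0, 6.0, 7.0])
        got = ccc(_pset(y, [5.0, 6.0, 7.0]))
        assert got == pytest.approx(o["ccc"], abs=1e-12)
        assert got < 1.0


class TestOriginRegression:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0])
        k, r0, r0p = origin_regression(_pset(y, y))
        assert (k, r0, r0p) == (pytest.approx(1.0), pytest.approx(1.0),
                                pytest.approx(1.0))

    def test_doubled_prediction_closed_form_slope(self):
        y = np.array([1.0, 2.0, 3.0])
        k, r0, _ = origin_regression(_pset(y, 2 * y))
        assert k == pytest.approx(float(np.sum(2 * y * y) / np.sum(y * y)))
        assert r0 == pytest.approx(1.0)  # perfectly proportional

    def test_orthogonal_vectors_r0_near_zero(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        yh = np.array([1.0, 1.0, -1.0, -1.0])
        k, r0, _ = origin_regression(_pset(y, yh))
        assert k == 0.0
        assert abs(r0) < 1e-9


class TestRm2Family:
    def test_fixed_point_when_all_equal(self):
        rm2, rm2p, avg, delta = rm2_family(0.8, 0.8, 0.8)
        assert (rm2, rm2p, avg, delta) == (0.8, 0.8, 0.8, 0.0)

    def test_literature_style_pair(self):
        # inputs chosen so rm2 = 0.91 and rm2' = 0.85 exactly:
        # r2 = 0.93 with r0 gap g, r0' gap g' solving 0.93(1-g) = target
        r2 = 0.93
        g = 1 - 0.91 / r2
        gp = 1 - 0.85 / r2
        rm2, rm2p, avg, delta = rm2_family(r2, r2 - g, r2 - gp)
        assert rm2 == pytest.approx(0.91, abs=1e-12)
        assert rm2p == pytest.approx(0.85, abs=1e-12)
        assert avg == pytest.approx(0.88, abs=1e-12)
        assert delta == pytest.approx(0.06, abs=1e-12)

    def test_variant_branches_hand_computed(self):
        rm2_p, *_ = rm2_family(0.9, 0.8, 0.8, variant="as_printed")
        rm2_s, *_ = rm2_family(0.9, 0.8, 0.8, variant="sqrt")
        assert rm2_p == pytest.approx(0.9 * (1 - 0.1))
        assert rm2_s == pytest.approx(0.9 * (1 - math.sqrt(0.1)))

    def test_out_of_range_input_warns(self):
        with pytest.warns(UserWarning):
            rm2_family(1.2, 0.5, 0.5)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_avg_and_delta_invariants(self, r2, r0, r0p):
        rm2, rm2p, avg, delta = rm2_family(r2, r0, r0p)
        assert avg == pytest.approx((rm2 + rm2p) / 2, abs=1e-12)
        assert delta == pytest.approx(abs(rm2 - rm2p), abs=1e-12)
        assert delta >= 0


# ---------------------------------------------------------------------------
# full battery vs oracle on random prediction sets
# ---------------------------------------------------------------------------

def test_battery_matches_bruteforce_oracle_many_seeds():
    """Implementation vs direct-summation oracle: 1000 seeded random sets."""
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = int(rng.integers(5, 21))
        y = rng.normal(size=n)
        yh = y + rng.normal(scale=rng.uniform(0.05, 2.0), size=n)
        y_tr_mean = float(rng.normal())
        n_tr = int(rng.integers(5, 100))
        o = oracle_all(list(y), list(yh), y_tr_mean=y_tr_mean, n_tr=n_tr)
        p = _pset(y, yh, reference_train_mean=y_tr_mean,
                  reference_train_size=n_tr)
        rmse, mae, s, dmax, me = error_stats(p)
        tol = dict(abs=1e-10)
        assert rmse == pytest.approx(o["rmse"], **tol)
        assert mae == pytest.approx(o["mae"], **tol)
        assert s == pytest.approx(o["s"], **tol)
        assert dmax == pytest.approx(o["delta_max"], **tol)
        assert me == pytest.approx(o["mean_error"], **tol)
        assert r_squared(p, "observed_mean") == pytest.approx(o["r2_obs"], **tol)
        assert r_squared(p, "predicted_mean") == pytest.approx(o["r2_pred"], **tol)
        qf1, qf2, qf3 = external_q2(p)
        assert qf1 == pytest.approx(o["qf1"], **tol)
        assert qf2 == pytest.approx(o["qf2"], **tol)
        assert qf3 == pytest.approx(o["qf3"], **tol)
        assert ccc(p) == pytest.approx(o["ccc"], **tol)
        k, r0, r0p = origin_regression(p)
        assert k == pytest.approx(o["k"], **tol)
        assert r0 == pytest.approx(o["r0"], **tol)
        assert r0p == pytest.approx(o["r0p"], **tol)


def test_validation_report_invariants():
    rng = np.random.default_rng(77)
    y = rng.normal(size=25)
    yh = y + 0.4 * rng.normal(size=25)
    p = _pset(y, yh, reference_train_mean=0.1, reference_train_size=50)
    rep = validation_report(p, kind="external")
    assert rep.rmse >= rep.mae >= 0
    assert rep.delta_max >= 0
    assert rep.rm2_avg == pytest.approx((rep.rm2 + rep.rm2_prime) / 2)
    assert rep.rm2_delta == pytest.approx(abs(rep.rm2 - rep.rm2_prime))


# ---------------------------------------------------------------------------
# criteria checker
# ---------------------------------------------------------------------------

def _report(**kw):
    base = dict(r2_or_q2=1.0, rmse=0.0, mae=0.0, s=0.0, delta_max=0.0,
                mean_error=0.0, k=1.0, r0_sq=1.0, r0_prime_sq=1.0,
                rm2=1.0, rm2_prime=1.0, rm2_avg=1.0, rm2_delta=0.0)
    base.update(kw)
    from twoqsar import ValidationReport
    return ValidationReport(**base)


class TestCriteriaCheck:
    def test_all_perfect_passes_everything(self):
        train = _report(q2_cv=1.0)
        ext = _report(qF1=1.0, qF2=1.0, qF3=1.0, ccc=1.0)
        verdicts = criteria_check(train, ext)
        assert verdicts["training"].overall and verdicts["external"].overall

    def test_cv_gap_training_only(self):
        train = _report(r2_or_q2=0.93, q2_cv=0.90)
        ext = _report(qF1=0.8, qF2=0.8, qF3=0.8, ccc=0.9)
        verdicts = criteria_check(train, ext)
        assert verdicts["training"].checks["cv_gap"] is True
        assert verdicts["external"].checks["cv_gap"] is None

    def test_boundary_gap_of_exactly_point_one_fails(self):
        # a printed gap |r2 - q2cv| = 0.10 is not strictly below 0.10
        train = _report(r2_or_q2=0.80, q2_cv=0.90)
        assert criteria_check(train)["training"].checks["cv_gap"] is False

    def test_slope_window(self):
        ok = _report(k=0.85)
        bad = _report(k=0.66)
        assert criteria_check(ok)["training"].checks["origin_fit"]
        assert not criteria_check(bad)["training"].checks["origin_fit"]

    def test_overall_excludes_not_applicable(self):
        train = _report(q2_cv=None)  # no CV statistic available
        v = criteria_check(train)["training"]
        assert v.checks["cv_gap"] is None and v.overall


# ---------------------------------------------------------------------------
# internal validation: k-fold CV and Y-scrambling
# ---------------------------------------------------------------------------

def _linear_fitter(X, y):
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return lambda Xq: np.column_stack([np.ones(len(Xq)), Xq]) @ coef


class TestKfoldCv:
    def test_noiseless_linear_data_near_perfect(self):
        rng = np.random.default_rng(40)
        X = rng.normal(size=(60, 2))
        y = X @ np.array([2.0, -1.0]) + 0.5
        assert kfold_cv(X, y, folds=10, fitter=_linear_fitter,
                        seed=1) >= 0.999

    def test_pure_noise_low_q2(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        assert kfold_cv(X, y, folds=10, fitter=_linear_fitter, seed=1) <= 0.1

    def test_seeded_determinism(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(50, 2))
        y = X[:, 0] + rng.normal(size=50)
        a = kfold_cv(X, y, folds=5, fitter=_linear_fitter, seed=3)
        b = kfold_cv(X, y, folds=5, fitter=_linear_fitter, seed=3)
        assert a == b

    def test_bad_fold_counts_rejected(self):
        X = np.zeros((10, 1))
        with pytest.raises(ValueError):
            kfold_cv(X, np.zeros(10), folds=1, fitter=_linear_fitter)


class TestYScramble:
    def test_planted_signal_survives_scrambling_control(self):
        rng = np.random.default_rng(43)
        X = rng.normal(size=(100, 3))
        y = X @ np.array([1.5, -1.0, 0.5]) + 0.2 * rng.normal(size=100)
        mean_rs2, per_rep = y_scramble(X, y, _linear_fitter, reps=25, seed=2)
        assert mean_rs2 < 0.15 and len(per_rep) == 25
        # unscrambled fit is strong
        model = _linear_fitter(X, y)
        p = _pset(y, model(X))
        assert r_squared(p) > 0.9

    def test_identity_permutation_recovers_unscrambled_r2(self):
        rng = np.random.default_rng(44)
        X = rng.normal(size=(30, 2))
        y = X[:, 0] + 0.3 * rng.normal(size=30)
        mean_rs2, _ = y_scramble(X, y, _linear_fitter, reps=1,
                                 permutations=[np.arange(30)])
        model = _linear_fitter(X, y)
        assert mean_rs2 == pytest.approx(r_squared(_pset(y, model(X))))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(45)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        _, a = y_scramble(X, y, _linear_fitter, reps=5, seed=9)
        _, b = y_scramble(X, y, _linear_fitter, reps=5, seed=9)
        assert a == b
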