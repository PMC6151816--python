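"""External predictivity statistics, including the bundled benchmark values."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from qsarval.data import BENCHMARK_ENDPOINTS, PairedPredictions, load_benchmark_pairs
from qsarval.exceptions import UndefinedStatisticError
from qsarval.validation_external import (
    ccc,
    external_report,
    golbraikh_tropsha,
    q2_f1,
    q2_f2,
    q2_f3,
    rm2_metrics,
)


def pp(obs, pred):
    obs = np.asarray(obs, float)
    return PairedPredictions([f"c{i}" for i in range(len(obs))], obs, pred)


@pytest.fixture
def fixture_parts():
    def load(endpoint):
        pairs = load_benchmark_pairs(endpoint)
        return pairs.part("test"), pairs.part("train")

    return load


class TestQ2Family:
    def test_perfect_predictions(self, rng):
        obs = rng.standard_normal(8)
        assert q2_f1(pp(obs, obs), train_mean=0.3) == pytest.approx(1.0)
        assert q2_f2(pp(obs, obs)) == pytest.approx(1.0)
        assert q2_f3(pp(obs, obs), pp(rng.standard_normal(8), np.zeros(8))) == pytest.approx(1.0)

    def test_mean_predictor_scores_zero(self, rng):
        obs = rng.standard_normal(8)
        tm = 1.234
        assert q2_f1(pp(obs, np.full(8, tm)), train_mean=tm) == pytest.approx(0.0)
        assert q2_f2(pp(obs, np.full(8, obs.mean()))) == pytest.approx(0.0)

    def test_q2f3_zero_when_mse_equals_train_variance(self, rng):
        train_obs = np.array([0.0, 1.0, 2.0, 3.0])  # variance about mean = 1.25
        obs = rng.standard_normal(4)
        pred = obs + np.sqrt(1.25)  # constant shift: MSE = 1.25
        train = pp(train_obs, train_obs)
        assert q2_f3(pp(obs, pred), train) == pytest.approx(0.0)

    def test_constant_test_responses_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            q2_f2(pp([1.0, 1.0, 1.0], [0.9, 1.0, 1.1]))

    @pytest.mark.parametrize("endpoint,expected", [
        ("X-Microtox", 0.8508), ("GSH+", 0.7502), ("GSH-", 0.7436),
        ("DNA+", 0.7482), ("DNA-", 0.7505),
    ])
    def test_q2f1_benchmark(self, fixture_parts, endpoint, expected):
        test, train = fixture_parts(endpoint)
        got = q2_f1(test, float(np.mean(train.observed)))
        assert got == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize("endpoint,expected", [
        ("X-Microtox", 0.8496), ("GSH+", 0.7502), ("GSH-", 0.7430),
        ("DNA+", 0.7228), ("DNA-", 0.7500),
    ])
    def test_q2f2_benchmark(self, fixture_parts, endpoint, expected):
        test, _ = fixture_parts(endpoint)
        assert q2_f2(test) == pytest.approx(expected, abs=1e-4)

    def test_q2f3_benchmark_xmicrotox(self, fixture_parts):
        test, train = fixture_parts("X-Microtox")
        assert q2_f3(test, train) == pytest.approx(0.9799, abs=1e-4)


class TestCCC:
    def test_identity_is_one(self, rng):
        obs = rng.standard_normal(10)
        assert ccc(pp(obs, obs)) == pytest.approx(1.0)

    def test_perfect_antiagreement_is_minus_one(self):
        assert ccc(pp([0.0, 1.0, 2.0], [2.0, 1.0, 0.0])) == pytest.approx(-1.0)

    def test_invariant_under_common_translation(self, rng):
        obs = rng.standard_normal(12)
        pred = obs + rng.normal(0, 0.2, 12)
        base = ccc(pp(obs, pred))
        both_shifted = ccc(pp(obs + 7.5, pred + 7.5))
        assert both_shifted == pytest.approx(base, rel=1e-10)

    def test_translation_shrinks_towards_zero(self, rng):
        obs = rng.standard_normal(12)
        pred = obs + rng.normal(0, 0.2, 12)
        base = abs(ccc(pp(obs, pred)))
        shifted = abs(ccc(pp(obs, pred + 5.0)))
        assert shifted < base

    def test_bounded_by_pearson(self, rng):
        obs = rng.standard_normal(15)
        pred = 0.5 * obs + rng.normal(0, 0.5, 15) + 1.0
        r = np.corrcoef(obs, pred)[0, 1]
        assert abs(ccc(pp(obs, pred))) <= abs(r) + 1e-12

    @pytest.mark.parametrize("endpoint,expected", [
        ("X-Microtox", 0.9115), ("GSH+", 0.8500), ("GSH-", 0.8703),
        ("DNA+", 0.8781), ("DNA-", 0.8787),
    ])
    def test_benchmark(self, fixture_parts, endpoint, expected):
        test, _ = fixture_parts(endpoint)
        assert ccc(test) == pytest.approx(expected, abs=1e-4)


def brute_force_rm2(obs, pred):
    """Oracle: explicit through-origin least squares in both directions."""
    r2 = np.corrcoef(obs, pred)[0, 1] ** 2

    def through_origin_r2(dep, indep):
        s = np.sum(dep * indep) / np.sum(indep**2)
        return 1 - np.sum((dep - s * indep) ** 2) / np.sum((dep - dep.mean()) ** 2)

    rm2 = r2 * (1 - np.sqrt(max(0, r2 - through_origin_r2(obs, pred))))
    rm2p = r2 * (1 - np.sqrt(max(0, r2 - through_origin_r2(pred, obs))))
    return (rm2 + rm2p) / 2, abs(rm2 - rm2p)


class TestRm2:
    def test_identity(self, rng):
        obs = rng.standard_normal(10)
        avg, delta = rm2_metrics(pp(obs, obs))
        assert avg == pytest.approx(1.0)
        assert delta == pytest.approx(0.0)

    def test_benchmark_xmicrotox(self, fixture_parts):
        test, _ = fixture_parts("X-Microtox")
        avg, delta = rm2_metrics(test)
        assert avg == pytest.approx(0.7185, abs=1e-4)
        assert delta == pytest.approx(0.1439, abs=1e-4)

    def test_matches_brute_force(self, rng):
        obs = rng.standard_normal(20) + 3.0
        pred = obs + rng.normal(0, 0.5, 20)
        got = rm2_metrics(pp(obs, pred))
        expected = brute_force_rm2(obs, pred)
        assert got[0] == pytest.approx(expected[0], rel=1e-10)
        assert got[1] == pytest.approx(expected[1], rel=1e-10)


class TestGolbraikhTropsha:
    def test_identity(self, rng):
        obs = rng.standard_normal(10) + 2.0
        k, kp, r02, r0p2, gt, gtp = golbraikh_tropsha(pp(obs, obs))
        assert k == pytest.approx(1.0)
        assert kp == pytest.approx(1.0)
        assert r02 == pytest.approx(1.0)
        assert r0p2 == pytest.approx(1.0)
        assert gt == pytest.approx(0.0, abs=1e-12)
        assert gtp == pytest.approx(0.0, abs=1e-12)

    def test_doubled_predictions_closed_form(self, rng):
        obs = np.abs(rng.standard_normal(10)) + 1.0
        k, kp, *_ = golbraikh_tropsha(pp(obs, 2 * obs))
        assert k == pytest.approx(0.5)
        assert kp == pytest.approx(2.0)

    @pytest.mark.parametrize("endpoint,ek,ekp,er02,er0p2", [
        ("X-Microtox", 1.0136, 0.9837, 0.8018, 0.8584),
        ("GSH+", 1.0596, 0.9119, 0.6964, 0.7709),
        ("DNA+", 0.8805, 1.0974, 0.8132, 0.8186),
    ])
    def test_benchmark(self, fixture_parts, endpoint, ek, ekp, er02, er0p2):
        test, _ = fixture_parts(endpoint)
        k, kp, r02, r0p2, _, _ = golbraikh_tropsha(test)
        assert k == pytest.approx(ek, abs=1e-4)
        assert kp == pytest.approx(ekp, abs=1e-4)
        assert r02 == pytest.approx(er02, abs=1e-4)
        assert r0p2 == pytest.approx(er0p2, abs=1e-4)


class TestReport:
    @pytest.mark.parametrize("endpoint,rmse_ext", [
        ("X-Microtox", 0.2040), ("DNA-", 0.4991),
    ])
    def test_rmse_ext_benchmark(self, fixture_parts, endpoint, rmse_ext):
        test, train = fixture_parts(endpoint)
        rep = external_report(test, train)
        assert rep.RMSE_ext == pytest.approx(rmse_ext, abs=1e-4)

    def test_perfect_predictions_all_ones(self, rng):
        obs = rng.standard_normal(9)
        tr_obs = rng.standard_normal(20)
        rep = external_report(pp(obs, obs), pp(tr_obs, tr_obs))
        assert rep.RMSE_ext == pytest.approx(0.0, abs=1e-12)
        for stat in ("Q2_F1", "Q2_F2", "Q2_F3", "CCC"):
            assert getattr(rep, stat) == pytest.approx(1.0)

    def test_undefined_stats_reported_with_reason(self):
        test = pp([2.0, 2.0, 2.0], [1.9, 2.0, 2.1])
        train = pp([0.0, 1.0, 2.0], [0.1, 0.9, 2.2])
        rep = external_report(test, train)
        assert rep.Q2_F2 is None
        assert "Q2_F2" in rep.undefined
        assert rep.Q2_F1 is not None  # training mean still varies the denominator


class TestOrderAndDominanceProperties:
    @pytest.mark.parametrize("endpoint", BENCHMARK_ENDPOINTS)
    def test_q2f2_never_exceeds_q2f1_on_benchmark(self, fixture_parts, endpoint):
        test, train = fixture_parts(endpoint)
        tm = float(np.mean(train.observed))
        assert q2_f2(test) <= q2_f1(test, tm) + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(
        data=arrays(np.float64, (2, 8),
                    elements=st.floats(-5, 5, allow_nan=False)),
        train_mean=st.floats(-3, 3, allow_nan=False),
    )
    def test_q2f2_never_exceeds_q2f1_random(self, data, train_mean):
        # the test-set mean minimizes the reference sum of squares
        obs, pred = data
        if np.ptp(obs) < 0.1:
            return
        assert q2_f2(pp(obs, pred)) <= q2_f1(pp(obs, pred), train_mean) + 1e-6

    @settings(derandomize=True, max_examples=50)
    @given(
        data=arrays(np.float64, (2, 7),
                    elements=st.floats(-4, 4, allow_nan=False)),
        perm=st.permutations(range(7)),
    )
    def test_pair_order_invariance(self, data, perm):
        obs, pred = data
        if np.ptp(obs) < 0.1 or np.ptp(pred) < 0.1:
            return
        idx = np.array(perm)
        a = external_report(pp(obs, pred), pp(obs, pred))
        b = external_report(pp(obs[idx], pred[idx]), pp(obs, pred))
        for stat in ("RMSE_ext", "Q2_F2", "CCC", "rm2_avg", "k"):
            va, vb = getattr(a, stat), getattr(b, stat)
            assert va == pytest.approx(vb, rel=1e-9, abs=1e-12)
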