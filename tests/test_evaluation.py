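"""Horizon metrics, IPCW curves, and contingency odds ratios."""

import numpy as np
import pandas as pd
import pytest

from conftest import auc_pairwise_oracle, make_survival, simulate_ph
from gcnsurv.cox_core import fit_cox
from gcnsurv.evaluation import (
    EVENT_BY_T,
    EVENT_FREE,
    INEVALUABLE,
    horizon_labels,
    horizon_metrics,
    prediction_error,
    time_dependent_auc,
    univariable_or,
)


class TestHorizonLabels:
    @pytest.mark.parametrize(
        "time,event,t,expect",
        [
            (2.0, 1, 3.0, EVENT_BY_T),
            (2.0, 0, 3.0, INEVALUABLE),
            (3.0, 0, 3.0, EVENT_FREE),  # survival to the horizon counts event-free
            (3.0, 1, 3.0, EVENT_BY_T),
            (4.0, 1, 3.0, EVENT_FREE),  # event after the horizon
        ],
    )
    def test_definition(self, time, event, t, expect):
        surv = make_survival([time, 10.0], [event, 0])
        assert horizon_labels(surv, t).iloc[0] == expect

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(ValueError):
            horizon_labels(make_survival([1.0], [1]), 0.0)


class TestHorizonMetrics:
    def test_perfect_separation(self):
        surv = make_survival([1, 1, 1, 9, 9, 9], [1, 1, 1, 0, 0, 0])
        lab = horizon_labels(surv, 5.0)
        out = horizon_metrics(np.array([5, 6, 7, 1, 2, 3.0]), lab)
        assert out.auc == 1.0
        assert out.accuracy == 1.0

    def test_constant_scores_half(self):
        surv = make_survival([1, 1, 9, 9.0], [1, 1, 0, 0])
        out = horizon_metrics(np.zeros(4), horizon_labels(surv, 5.0))
        assert out.auc == 0.5

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(10):
            n = 12
            time = rng.exponential(5, n)
            event = (rng.random(n) < 0.7).astype(int)
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            surv = make_survival(time, event)
            lab = horizon_labels(surv, 4.0)
            mask = lab.to_numpy() != INEVALUABLE
            y = (lab.to_numpy()[mask] == EVENT_BY_T).astype(int)
            if y.sum() in (0, y.size):
                continue
            out = horizon_metrics(scores, lab)
            expect = auc_pairwise_oracle(scores[mask][y == 1], scores[mask][y == 0])
            assert out.auc == pytest.approx(expect, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        time = rng.exponential(5, 30)
        event = np.ones(30, int)
        scores = rng.normal(size=30)
        surv = make_survival(time, event)
        lab = horizon_labels(surv, 4.0)
        a1 = horizon_metrics(scores, lab).auc
        a2 = horizon_metrics(np.exp(2 * scores) + 3, lab).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_flagged(self):
        surv = make_survival([1, 2, 2.5], [1, 1, 1])
        out = horizon_metrics(np.array([1.0, 2.0, 3.0]), horizon_labels(surv, 5.0))
        assert out.flagged and np.isnan(out.auc)


class TestTimeDependentAuc:
    def test_no_censoring_equals_horizon_auc(self, rng):
        n = 60
        scores = rng.normal(size=n)
        T = rng.exponential(5, n) / np.exp(0.8 * scores)
        surv = make_survival(T, np.ones(n, int))
        grid = np.array([2.0, 4.0])
        _, aucs = time_dependent_auc(scores, surv, grid)
        for t, a in zip(grid, aucs):
            expect = horizon_metrics(scores, horizon_labels(surv, t)).auc
            assert a == pytest.approx(expect, abs=1e-10)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(13)
        vals = []
        for _ in range(40):
            n = 120
            T = rng.exponential(5, n)
            C = rng.exponential(8, n)
            surv = make_survival(np.minimum(T, C), (T <= C).astype(int))
            _, a = time_dependent_auc(rng.normal(size=n), surv, [3.0])
            vals.append(a[0])
        assert abs(np.mean(vals) - 0.5) < 0.03

    def test_matches_ipcw_pairwise_oracle(self, rng):
        n = 25
        scores = rng.normal(size=n)
        T = rng.exponential(4, n) / np.exp(0.5 * scores)
        C = rng.exponential(6, n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
        surv = make_survival(time, event)
        t0 = 3.0
        # independent reverse Kaplan-Meier for the censoring distribution,
        # events ranked before censorings at tied times
        def G_of(u):
            g = 1.0
            for s in np.unique(time[(event == 0)]):
                if s >= u:
                    break
                n_risk = np.sum(time > s) + np.sum((time == s) & (event == 0))
                d = np.sum((time == s) & (event == 0))
                g *= 1 - d / n_risk
            return g

        num = den = 0.0
        for i in range(n):
            if not (event[i] == 1 and time[i] <= t0):
                continue
            wi = 1.0 / G_of(time[i])
            for j in range(n):
                if time[j] <= t0:
                    continue
                conc = 1.0 if scores[i] > scores[j] else (0.5 if scores[i] == scores[j] else 0.0)
                num += wi * conc
                den += wi
        expect = num / den
        _, a = time_dependent_auc(scores, surv, [t0])
        assert a[0] == pytest.approx(expect, abs=1e-10)

    def test_grid_beyond_range_dropped(self, rng):
        surv = make_survival([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.warns(UserWarning, match="beyond"):
            grid, _ = time_dependent_auc(np.array([3, 2, 1.0]), surv, [2.0, 99.0])
        assert list(grid) == [2.0]


class TestPredictionError:
    def test_perfect_predictions_zero_error(self):
        time = np.array([1.0, 2.0, 8.0, 9.0])
        event = np.array([1, 1, 0, 0])
        surv = make_survival(time, event)
        grid = np.array([3.0])
        S = np.array([[0.0], [0.0], [1.0], [1.0]])
        _, err = prediction_error(S, surv, grid)
        assert err[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_no_censoring(self, rng):
        n = 50
        T = rng.exponential(4, n)
        surv = make_survival(T, np.ones(n, int))
        grid = [float(np.median(T))]
        S = np.full((n, 1), 0.5)
        _, err = prediction_error(S, surv, grid)
        assert err[0] == pytest.approx(0.25, abs=1e-12)

    def test_matches_hand_weighted_oracle(self, rng):
        n = 20
        X, surv = simulate_ph(rng, n, [0.7], censor_scale=8.0)
        fit = fit_cox(X, surv)
        t0 = float(np.quantile(surv.time, 0.5))
        grid, err = prediction_error(fit, surv, [t0], X=X)
        from gcnsurv.cox_core import predict_survival
        from gcnsurv.evaluation import _censoring_km, _eval_km

        S = predict_survival(fit, X, np.array([t0]))[:, 0]
        uniq, G = _censoring_km(surv.time, surv.event)
        total = 0.0
        for i in range(n):
            if surv.event[i] == 1 and surv.time[i] <= t0:
                total += S[i] ** 2 / _eval_km(uniq, G, np.array([surv.time[i]]), left=True)[0]
            elif surv.time[i] > t0:
                total += (1 - S[i]) ** 2 / _eval_km(uniq, G, np.array([t0]))[0]
        assert err[0] == pytest.approx(total / n, abs=1e-12)

    def test_cross_check_scikit_survival(self, rng):
        from sksurv.metrics import brier_score as sks_brier
        from sksurv.util import Surv

        n = 80
        X, surv = simulate_ph(rng, n, [0.7], censor_scale=10.0)
        fit = fit_cox(X, surv)
        t0 = float(np.quantile(surv.time[surv.event == 1], 0.5))
        from gcnsurv.cox_core import predict_survival

        S = predict_survival(fit, X, np.array([t0]))
        y = Surv.from_arrays(surv.event.astype(bool), surv.time)
        _, expect = sks_brier(y, y, S, [t0])
        _, err = prediction_error(S, surv, [t0])
        assert err[0] == pytest.approx(expect[0], rel=0.02)


class TestUnivariableOr:
    def test_symmetric_table_or_one(self):
        x = np.repeat(["a", "b"], 100)
        y = np.tile([0, 1], 100)
        out = univariable_or(x, y, reference="a")
        assert out.odds_ratio == pytest.approx(1.0, abs=1e-12)

    def test_cross_product_equals_logistic(self, rng):
        for _ in range(5):
            a, b, c, d = rng.integers(5, 80, size=4)
            x = np.r_[np.zeros(a + b), np.ones(c + d)].astype(int).astype(str)
            y = np.r_[np.zeros(a), np.ones(b), np.zeros(c), np.ones(d)].astype(int)
            out = univariable_or(x, y, reference="0")
            expect = (d * a) / (c * b)
            assert out.odds_ratio == pytest.approx(expect, abs=1e-12)
            # and Wald p is a finite probability from the logistic fit
            assert 0 <= out.p <= 1

    def test_k_level_reference(self):
        # grade-style 3-level factor with known cross-products
        x = np.r_[np.repeat("g1", 169), np.repeat("g2", 394), np.repeat("g3", 274)]
        y = np.r_[
            np.repeat([0, 1], [133, 36]),
            np.repeat([0, 1], [221, 173]),
            np.repeat([0, 1], [158, 116]),
        ]
        out = univariable_or(x, y, reference="g1")
        assert out.odds_ratios["g2"] == pytest.approx((173 * 133) / (221 * 36), abs=1e-12)
        assert out.odds_ratios["g3"] == pytest.approx((116 * 133) / (158 * 36), abs=1e-12)
        assert out.p_values["g2"] < 0.001 and out.p_values["g3"] < 0.001

    def test_zero_cell_flagged(self):
        x = np.repeat(["a", "b"], [10, 10])
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        out = univariable_or(x, y, reference="a")
        assert "b" in out.flagged_levels
        assert np.isinf(out.odds_ratio)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError):
            univariable_or(["a", "b"], [1, 1])
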