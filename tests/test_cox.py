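"""Weighted Cox engine: partial likelihood, baseline, prediction, sandwich.

Independent oracles: a brute-force partial likelihood with explicit risk-set
loops (grid search), a counting-process Nelson-Aalen estimator, a delete-one
jackknife, lifelines for unweighted fits, and coefficients/variances frozen
from R survival::coxph for a weighted left-truncated fit.
"""
import numpy as np
import pytest

from ambicox import (
    CoxFit,
    breslow_baseline,
    fit_cox,
    predict_interval_survival,
    robust_variance,
)


def brute_force_loglik(beta, entry, exit_, event, x, w=None):
    """Direct weighted log partial likelihood with (entry, exit] risk sets
    and Breslow ties; written with explicit loops, independent of the
    fitting code."""
    entry, exit_, x = map(np.asarray, (entry, exit_, x))
    event = np.asarray(event, dtype=bool)
    w = np.ones(len(x)) if w is None else np.asarray(w, dtype=float)
    ll = 0.0
    for t in np.unique(exit_[event]):
        at_risk = (entry < t) & (t <= exit_)
        dead = event & (exit_ == t)
        s0 = np.sum(w[at_risk] * np.exp(beta * x[at_risk]))
        ll += np.sum(w[dead] * beta * x[dead]) - np.sum(w[dead]) * np.log(s0)
    return ll


def grid_argmax(entry, exit_, event, x, w=None, lo=-3.0, hi=3.0, step=1e-4):
    grid = np.arange(lo, hi + step, step)
    vals = [brute_force_loglik(b, entry, exit_, event, x, w) for b in grid]
    return grid[int(np.argmax(vals))]


def nelson_aalen(entry, exit_, event, weights=None):
    """Left-truncation-aware Nelson-Aalen estimator by direct counting."""
    entry, exit_ = np.asarray(entry), np.asarray(exit_)
    event = np.asarray(event, dtype=bool)
    w = np.ones(entry.size) if weights is None else np.asarray(weights, dtype=float)
    times = np.unique(exit_[event])
    cum, out = 0.0, []
    for t in times:
        at_risk = (entry < t) & (t <= exit_)
        d = w[event & (exit_ == t)].sum()
        cum += d / w[at_risk].sum()
        out.append(cum)
    return times, np.array(out)


THREE_SUBJECTS = dict(
    entry=[0.0, 0.0, 0.0], exit_=[1.0, 2.0, 3.0], event=[1, 1, 0], X=[[1.0], [0.0], [1.0]]
)


class TestPartialLikelihoodMaximum:
    def test_three_subject_closed_form(self):
        """The stationary point of e^b/(2e^b+1) * 1/(e^b+1) is b = -ln(2)/2."""
        fit = fit_cox(**THREE_SUBJECTS)
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(-np.log(2) / 2, abs=1e-9)
        bf = grid_argmax([0, 0, 0], [1, 2, 3], [1, 1, 0], [1, 0, 1])
        assert fit.coefficients[0] == pytest.approx(bf, abs=1e-3)

    @pytest.mark.parametrize("seed", range(6))
    def test_tiny_datasets_match_grid_search(self, seed):
        """On <= 5 subjects the Newton estimate agrees with an exhaustive
        grid search of the brute-force likelihood."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        exit_ = np.round(rng.uniform(1, 10, n), 2)
        entry = np.round(rng.uniform(0, 0.5, n) * exit_, 2)
        event = np.zeros(n, dtype=bool)
        event[rng.choice(n, size=max(2, n - 2), replace=False)] = True
        x = rng.integers(0, 2, n).astype(float)
        if len(np.unique(x)) < 2 or not event.any():
            pytest.skip("degenerate draw")
        fit = fit_cox(entry, exit_, event, x[:, None])
        if not fit.converged:
            pytest.skip("monotone likelihood draw")
        bf = grid_argmax(entry, exit_, event, x)
        assert fit.coefficients[0] == pytest.approx(bf, abs=1e-3)

    def test_loglik_at_maximum_beats_null(self):
        fit = fit_cox(**THREE_SUBJECTS)
        null = brute_force_loglik(0.0, [0, 0, 0], [1, 2, 3], [1, 1, 0], [1, 0, 1])
        assert fit.log_partial_likelihood >= null

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            fit_cox([0, 0], [1, 2], [0, 0], [[1.0], [0.0]])

    def test_non_positive_weight_raises(self):
        with pytest.raises(ValueError, match="non-positive weight"):
            fit_cox([0, 0, 0], [1, 2, 3], [1, 1, 0], [[1.0], [0.0], [1.0]], [1, 0, 1])

    def test_constant_covariate_raises(self):
        with pytest.raises(ValueError, match="constant covariate"):
            fit_cox([0, 0], [1, 2], [1, 1], [[1.0], [1.0]])

    def test_monotone_likelihood_flagged(self):
        # perfectly separated: all events carry x=1, all censored x=0
        fit = fit_cox([0] * 6, [1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0],
                      np.array([1, 1, 1, 0, 0, 0], dtype=float)[:, None])
        assert not fit.converged
        assert "monotone" in fit.diagnostics


class TestWeightingIdentity:
    def test_integer_weight_equals_duplicated_records(self):
        rng = np.random.default_rng(3)
        n = 40
        x = rng.standard_normal((n, 2))
        exit_ = rng.exponential(5, n) + 0.1
        entry = rng.uniform(0, 0.3, n) * exit_
        event = rng.random(n) < 0.6
        event[0] = True
        w = rng.integers(1, 4, n).astype(float)
        weighted = fit_cox(entry, exit_, event, x, w)
        idx = np.repeat(np.arange(n), w.astype(int))
        duplicated = fit_cox(entry[idx], exit_[idx], event[idx], x[idx])
        assert np.array_equal(weighted.coefficients, duplicated.coefficients)
        assert weighted.log_partial_likelihood == duplicated.log_partial_likelihood
        assert np.array_equal(weighted.baseline_cumhaz, duplicated.baseline_cumhaz)

    def test_weight_rescaling_invariance(self):
        """Scaling all weights by a constant leaves the estimate unchanged,
        and the sandwich is unchanged when weights are renormalized to sum
        to the sample size."""
        rng = np.random.default_rng(5)
        n = 60
        x = rng.standard_normal((n, 1))
        exit_ = rng.exponential(4, n) + 0.05
        entry = np.zeros(n)
        event = rng.random(n) < 0.7
        w = rng.uniform(0.5, 2.0, n)
        w = n * w / w.sum()
        base = fit_cox(entry, exit_, event, x, w)
        for c in (0.5, 7.0):
            scaled = fit_cox(entry, exit_, event, x, c * w)
            np.testing.assert_allclose(scaled.coefficients, base.coefficients,
                                       rtol=0, atol=1e-10)
        renorm = n * (3.0 * w) / (3.0 * w).sum()
        again = fit_cox(entry, exit_, event, x, renorm)
        np.testing.assert_allclose(again.covariance_robust, base.covariance_robust,
                                   rtol=1e-9)


class TestBaseline:
    def test_single_event_increment(self):
        # beta = 0, one event at t=1 with 4 subjects at risk
        t, ch = breslow_baseline([0.0], [0, 0, 0, 0], [1, 2, 3, 4], [1, 0, 0, 0])
        assert t.tolist() == [1.0]
        assert ch[0] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_zero_beta_equals_nelson_aalen(self, seed, rng):
        r = np.random.default_rng(seed)
        n = 50
        exit_ = r.exponential(5, n) + 0.01
        entry = r.uniform(0, 0.6, n) * exit_
        event = r.random(n) < 0.6
        event[:2] = True
        t_b, h_b = breslow_baseline([0.0], entry, exit_, event)
        t_na, h_na = nelson_aalen(entry, exit_, event)
        np.testing.assert_allclose(t_b, t_na)
        np.testing.assert_allclose(h_b, h_na, rtol=1e-12)

    def test_increments_invariant_to_weight_doubling(self):
        entry = [0, 0, 0, 0]
        exit_ = [1, 2, 3, 4]
        event = [1, 1, 0, 1]
        w = np.array([1.0, 2.0, 1.5, 1.0])
        beta = [0.3]
        X = np.array([[0.5], [1.0], [0.0], [2.0]])
        _, h1 = breslow_baseline(beta, entry, exit_, event, X, w)
        _, h2 = breslow_baseline(beta, entry, exit_, event, X, 2 * w)
        np.testing.assert_allclose(h1, h2, rtol=1e-14)

    def test_left_truncation_respected(self):
        """A subject entering exactly at an event time is excluded from that
        risk set under the (entry, exit] convention."""
        # event at t=2: subject entering at 2.0 must not count
        _, with_late = breslow_baseline([0.0], [0, 0, 2.0], [2, 3, 5], [1, 0, 0])
        assert with_late[0] == pytest.approx(1 / 2)
        # entering just before 2.0 does count
        _, with_early = breslow_baseline([0.0], [0, 0, 1.99], [2, 3, 5], [1, 0, 0])
        assert with_early[0] == pytest.approx(1 / 3)


class TestPrediction:
    @pytest.fixture
    def step_fit(self):
        """Hand-built fit: one baseline step of 0.1 at t=50, log-HR ln 2."""
        return CoxFit(
            coefficients=np.array([np.log(2)]),
            covariance_model=np.eye(1),
            covariance_robust=None,
            baseline_times=np.array([50.0]),
            baseline_cumhaz=np.array([0.1]),
            n_subjects=1, n_events=1, converged=True,
            log_partial_likelihood=0.0,
        )

    def test_empty_interval_is_one(self, step_fit):
        assert predict_interval_survival(step_fit, [1.0], 40.0, 40.0) == pytest.approx(1.0)

    def test_single_step_formula(self, step_fit):
        s = predict_interval_survival(step_fit, [1.0], 40.0, 60.0)
        assert s == pytest.approx(np.exp(-0.2))

    def test_interval_before_support_is_one(self, step_fit):
        assert predict_interval_survival(step_fit, [1.0], 10.0, 49.0) == pytest.approx(1.0)

    def test_interval_after_support_adds_nothing(self, step_fit):
        s = predict_interval_survival(step_fit, [1.0], 60.0, 90.0)
        assert s == pytest.approx(1.0)

    def test_reversed_interval_raises(self, step_fit):
        with pytest.raises(ValueError, match="t_start"):
            predict_interval_survival(step_fit, [1.0], 60.0, 40.0)

    def test_vectorized_rows(self, step_fit):
        z = np.array([[1.0], [0.0]])
        s = predict_interval_survival(step_fit, z, np.array([0.0, 0.0]),
                                      np.array([55.0, 55.0]))
        np.testing.assert_allclose(s, [np.exp(-0.2), np.exp(-0.1)])


class TestRobustVariance:
    def test_matches_r_survival_frozen_values(self):
        """Weighted left-truncated fit: coefficients, model SE, robust SE
        and log partial likelihood frozen from R survival::coxph
        (ties='breslow', per-subject id clustering)."""
        rng = np.random.default_rng(20240615)
        n = 80
        x1 = rng.standard_normal(n).round(4)
        x2 = rng.integers(0, 2, n).astype(float)
        t = (rng.exponential(1 / (0.12 * np.exp(0.6 * x1 - 0.4 * x2)))).round(4)
        c = rng.exponential(12, n).round(4)
        entry = (rng.uniform(0, 0.4) * np.minimum(t, c)).round(4)
        dur = np.minimum(t, c)
        event = (t <= c).astype(int)
        w = rng.uniform(0.5, 2.5, n).round(4)
        fit = fit_cox(entry, dur, event, np.column_stack([x1, x2]), w)
        np.testing.assert_allclose(
            fit.coefficients, [0.5744967839, -0.8541290351], atol=1e-8)
        np.testing.assert_allclose(
            fit.se_model, [0.1719243042, 0.2745490002], atol=1e-8)
        np.testing.assert_allclose(
            fit.se_robust, [0.1669705389, 0.2714653312], atol=1e-8)
        assert fit.log_partial_likelihood == pytest.approx(-203.5065427092, abs=1e-7)

    def test_agrees_with_lifelines_unweighted(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(1)
        n = 200
        x = rng.standard_normal((n, 2))
        t = rng.exponential(1 / (0.1 * np.exp(x @ [0.5, -0.3])))
        c = rng.exponential(15, n)
        entry = rng.uniform(0, 0.5, n) * np.minimum(t, c)
        dur, ev = np.minimum(t, c), (t <= c).astype(int)
        mine = fit_cox(entry, dur, ev, x)
        cph = lifelines.CoxPHFitter()
        cph.fit(
            pd.DataFrame({"e": entry, "d": dur, "ev": ev, "x1": x[:, 0], "x2": x[:, 1]}),
            duration_col="d", event_col="ev", entry_col="e", formula="x1+x2",
        )
        np.testing.assert_allclose(mine.coefficients, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(mine.se_model, cph.standard_errors_.values, atol=1e-5)

    def test_close_to_delete_one_jackknife(self):
        """Sandwich variance within 10% of the delete-one jackknife on n=50
        exponential data with one covariate."""
        rng = np.random.default_rng(3)
        n = 50
        x = rng.integers(0, 2, n).astype(float)[:, None]
        t = rng.exponential(1 / (0.2 * np.exp(0.5 * x[:, 0])))
        c = rng.exponential(40, n)
        dur, ev = np.minimum(t, c), t <= c
        entry = np.zeros(n)
        fit = fit_cox(entry, dur, ev, x)
        betas = []
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            betas.append(
                fit_cox(entry[keep], dur[keep], ev[keep], x[keep]).coefficients[0]
            )
        betas = np.array(betas)
        jk = (n - 1) / n * np.sum((betas - betas.mean()) ** 2)
        assert fit.covariance_robust[0, 0] == pytest.approx(jk, rel=0.10)

    def test_robust_approaches_model_variance_iid(self):
        """With unit weights on iid data the sandwich and the inverse
        information converge to each other."""
        rng = np.random.default_rng(4)
        n = 4000
        x = rng.standard_normal((n, 1))
        t = rng.exponential(1 / (0.1 * np.exp(0.4 * x[:, 0])))
        c = rng.exponential(20, n)
        fit = fit_cox(np.zeros(n), np.minimum(t, c), t <= c, x)
        ratio = fit.covariance_robust[0, 0] / fit.covariance_model[0, 0]
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_standalone_recomputation_matches_fit(self):
        rng = np.random.default_rng(9)
        n = 100
        x = rng.standard_normal((n, 2))
        dur = rng.exponential(5, n) + 0.01
        ev = rng.random(n) < 0.5
        ev[0] = True
        w = rng.uniform(0.5, 2, n)
        fit = fit_cox(np.zeros(n), dur, ev, x, w)
        V = robust_variance(fit, np.zeros(n), dur, ev, x, w)
        np.testing.assert_allclose(V, fit.covariance_robust, rtol=1e-8)


def test_json_round_trip(tmp_path):
    fit = fit_cox(**THREE_SUBJECTS, covariate_names=("z",))
    path = tmp_path / "fit.json"
    fit.to_json(path)
    back = CoxFit.from_json(path)
    np.testing.assert_allclose(back.coefficients, fit.coefficients)
    np.testing.assert_allclose(back.covariance_robust, fit.covariance_robust)
    np.testing.assert_allclose(back.baseline_cumhaz, fit.baseline_cumhaz)
    assert back.covariate_names == ("z",)
    assert back.converged == fit.converged
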