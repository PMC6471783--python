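"""Cluster-period logistic fits: IRLS, robust covariance, site effects."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, logit

from swproc import (
    ClusterPeriodLogit,
    SimParams,
    TwoByTwo,
    cluster_robust_cov,
    fit_logistic,
    generate_design,
    odds_ratio,
    simulate_trial,
    site_effect,
)
from swproc.swfit import validate_cells


def _one_site(events, deliveries, crossover):
    t = np.arange(len(events))
    return pd.DataFrame(
        {
            "cluster_id": "s1",
            "period": t,
            "treated": (t >= crossover).astype(int),
            "deliveries": deliveries,
            "events": events,
        }
    )


FIXTURE = _one_site([3, 5, 4, 8, 6, 9, 7, 10], [500, 520, 480, 510, 530, 525, 495, 505], 4)


class TestFitLogistic:
    def test_flat_data_gives_null_treatment_and_logit_intercept(self, flat_cells):
        res = fit_logistic(flat_cells, formula="pooled_common_trend")
        assert res.converged
        assert res.params["treated"] == pytest.approx(0.0, abs=1e-8)
        assert res.params["trend"] == pytest.approx(0.0, abs=1e-8)
        for c in range(4):
            assert res.params[f"centre[{c}]"] == pytest.approx(logit(0.1), abs=1e-8)

    def test_two_cell_fit_equals_closed_form_log_or(self):
        cells = _one_site([12, 30], [400, 450], 1)
        res = fit_logistic(cells, formula="site_no_trend")
        closed = odds_ratio(TwoByTwo(30, 420, 12, 388)).log_effect
        assert res.params["treated"] == pytest.approx(closed, abs=1e-10)

    def test_deterministic_fixture_is_bit_stable(self):
        a = fit_logistic(FIXTURE, formula="site")
        b = fit_logistic(FIXTURE, formula="site")
        assert a.params.to_numpy().tolist() == b.params.to_numpy().tolist()
        assert a.converged and a.n_iterations == b.n_iterations
        # frozen coefficients (independently reproduced with a GLM fit)
        assert a.params.to_numpy() == pytest.approx(
            [-4.221873104200409, 0.201297760756566, -0.346778393112821], abs=1e-9
        )
        assert a.bse.to_numpy() == pytest.approx(
            [0.315871108541552, 0.12629089835183, 0.578194918742831], abs=1e-8
        )

    def test_matches_statsmodels_glm(self, small_trial):
        sm = pytest.importorskip("statsmodels.api")
        res = fit_logistic(small_trial, formula="pooled")
        model = res.model
        y = np.column_stack([model.endog, model.n_trials - model.endog])
        glm = sm.GLM(y, model.exog, family=sm.families.Binomial()).fit()
        assert res.params.to_numpy() == pytest.approx(glm.params, abs=1e-7)
        assert res.bse.to_numpy() == pytest.approx(glm.bse, abs=1e-6)

    def test_matches_brute_force_likelihood_maximisation(self):
        # independent oracle: derivative-free Nelder-Mead on a likelihood
        # written from scratch here
        cells = FIXTURE
        t = cells["period"].to_numpy(float)
        X = np.column_stack([np.ones(len(cells)), t - t.mean(), cells["treated"].to_numpy(float)])
        y = cells["events"].to_numpy(float)
        n = cells["deliveries"].to_numpy(float)

        def negll(beta):
            eta = X @ beta
            return -np.sum(y * eta - n * np.logaddexp(0.0, eta))

        oracle = minimize(negll, x0=np.array([-4.0, 0.0, 0.0]), method="Nelder-Mead",
                          options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20_000})
        res = fit_logistic(cells, formula="site")
        assert res.params.to_numpy() == pytest.approx(oracle.x, abs=1e-4)

    def test_recovers_simulated_effect_and_trend(self, rng):
        # one site, 20 periods x 2000 deliveries, log-OR ln(0.7), trend -0.01
        t = np.arange(20)
        treated = (t >= 10).astype(int)
        eta = logit(0.02) - 0.01 * t + math.log(0.7) * treated
        cells = _one_site(rng.binomial(2000, expit(eta)), 2000, 10)
        res = fit_logistic(cells, formula="site")
        assert res.converged
        assert abs(res.params["treated"] - math.log(0.7)) < 3 * res.bse["treated"]

    def test_period_recentring_shifts_only_intercept(self):
        shifted = FIXTURE.assign(period=FIXTURE["period"] + 7)
        a = fit_logistic(FIXTURE, formula="site")
        b = fit_logistic(shifted, formula="site")
        # centring makes trend and treatment invariant to period relabelling
        assert b.params["trend"] == pytest.approx(a.params["trend"], abs=1e-9)
        assert b.params["treated"] == pytest.approx(a.params["treated"], abs=1e-9)

    def test_separation_is_flagged_not_silent(self):
        # zero events in every control cell: the treatment-arm contrast is
        # completely separated and the coefficient diverges
        cells = _one_site([0, 0, 0, 50, 50, 50], [100] * 6, 3)
        res = fit_logistic(cells, formula="site_no_trend")
        assert not res.converged

    def test_monotonicity_in_treated_events(self):
        base = fit_logistic(FIXTURE, formula="site").params["treated"]
        bumped = FIXTURE.copy()
        bumped.loc[bumped["treated"] == 1, "events"] += 3
        res = fit_logistic(bumped, formula="site")
        assert res.params["treated"] > base

    def test_input_validation(self):
        bad = FIXTURE.copy()
        bad.loc[0, "events"] = 10_000
        with pytest.raises(ValueError):
            validate_cells(bad)
        flip = FIXTURE.copy()
        flip.loc[7, "treated"] = 0  # switches intervention off again
        with pytest.raises(ValueError):
            validate_cells(flip)
        with pytest.raises(ValueError):
            fit_logistic(FIXTURE.assign(events=0), formula="site")


class TestClusterRobustCov:
    def test_duplicating_clusters_rescales_se_by_known_factor(self, small_trial):
        res = fit_logistic(small_trial, formula="pooled_common_trend")
        se1 = res.bse_robust["treated"]
        G = small_trial["cluster_id"].nunique()
        dup = pd.concat(
            [small_trial, small_trial.assign(cluster_id=small_trial["cluster_id"] + G)],
            ignore_index=True,
        )
        dres = fit_logistic(dup, formula="pooled_common_trend")
        # coefficients unchanged; sandwich halves, small-sample factor adjusts
        assert dres.params["treated"] == pytest.approx(res.params["treated"], abs=1e-8)
        expected = se1 * math.sqrt(0.5 * (2 * G / (2 * G - 1)) / (G / (G - 1)))
        assert dres.bse_robust["treated"] == pytest.approx(expected, rel=1e-6)

    def test_per_cell_grouping_matches_hc_form(self, small_trial):
        res = fit_logistic(small_trial, formula="pooled_common_trend")
        groups = np.arange(len(small_trial))
        hc = res.cluster_robust_cov(groups=groups)
        model = res.model
        resid = model.endog - model.n_trials * expit(model.exog @ res.params.to_numpy())
        scores = model.exog * resid[:, None]
        A_inv = res.cov_params.to_numpy()
        n = len(groups)
        expected = A_inv @ (scores.T @ scores) @ A_inv * (n / (n - 1))
        assert np.allclose(hc.to_numpy(), expected)

    def test_robust_close_to_model_se_when_well_specified(self, rng):
        # independent cells, large counts: sandwich ~ model covariance
        design = generate_design(30, 3, 1, seed=8)
        params = SimParams(baseline_event_rate=0.05, treatment_log_or=-0.2,
                           deliveries_per_period=np.full(30, 5000.0), seed=17)
        cells = simulate_trial(design, params)
        res = fit_logistic(cells, formula="pooled_common_trend")
        ratio = res.bse_robust["treated"] / res.bse["treated"]
        assert 0.8 < ratio < 1.2

    def test_needs_two_clusters(self):
        res = fit_logistic(FIXTURE, formula="site")
        with pytest.raises(ValueError):
            cluster_robust_cov(res)


class TestSiteEffect:
    def test_agrees_with_unadjusted_or_when_no_trend(self, rng):
        t = np.arange(20)
        treated = (t >= 10).astype(int)
        p = expit(logit(0.05) + math.log(0.6) * treated)
        cells = _one_site(rng.binomial(4000, p), 4000, 10)
        eff = site_effect(cells)
        pre = cells[cells["treated"] == 0]
        post = cells[cells["treated"] == 1]
        crude = odds_ratio(
            TwoByTwo(
                post["events"].sum(), (post["deliveries"] - post["events"]).sum(),
                pre["events"].sum(), (pre["deliveries"] - pre["events"]).sum(),
            )
        )
        assert eff.log_effect == pytest.approx(crude.log_effect, abs=3 * crude.se)

    def test_trend_adjustment_removes_secular_bias(self, rng):
        # strong rising trend, null treatment: the crude OR is biased away
        # from 1, the trend-adjusted estimate is centred on 0
        reps = 100
        adjusted, crude = np.empty(reps), np.empty(reps)
        t = np.arange(16)
        treated = (t >= 8).astype(int)
        p = expit(logit(0.02) + 0.08 * t)  # no treatment effect
        for r in range(reps):
            cells = _one_site(rng.binomial(3000, p), 3000, 8)
            adjusted[r] = site_effect(cells).log_effect
            pre, post = cells[cells["treated"] == 0], cells[cells["treated"] == 1]
            crude[r] = odds_ratio(
                TwoByTwo(post["events"].sum(), (post["deliveries"] - post["events"]).sum(),
                         pre["events"].sum(), (pre["deliveries"] - pre["events"]).sum())
            ).log_effect
        assert crude.mean() > 0.4  # clearly biased upward by the trend
        assert abs(adjusted.mean()) < 3 * adjusted.std(ddof=1) / np.sqrt(reps)

    def test_requires_both_phases(self):
        all_pre = FIXTURE.assign(treated=0)
        with pytest.raises(ValueError):
            site_effect(all_pre)

    def test_requires_single_site(self, small_trial):
        with pytest.raises(ValueError):
            site_effect(small_trial)
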