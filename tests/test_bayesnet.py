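"""Bayesian-network estimator: lag augmentation, node fits, ATE sampling."""

import numpy as np
import pandas as pd
import pytest

import nof1sim as n1
from nof1sim import (
    BayesianNetworkATE, augment_lags, estimate_ate, fit_network, total_effect,
)
from nof1sim.errors import SchemaError
from nof1sim.estimators.bayesnet import bn_structure

SINGLE_EDGE = n1.parse_graph({
    "nodes": [
        {"name": "treatment", "role": "treatment"},
        {"name": "pain", "role": "outcome", "noise": {"mean": 5.0, "sd": 1.0}},
    ],
    "edges": [{"source": "treatment", "target": "pain", "weight": -2.0}],
})


def single_edge_data(n=20000, seed=0, sd=1.0):
    rng = np.random.default_rng(seed)
    t = rng.integers(1, 3, n).astype(float)
    y = 5.0 - 2.0 * t + sd * rng.normal(size=n)
    return pd.DataFrame({"patient_id": 0, "day": np.arange(1, n + 1),
                         "treatment": t, "pain": y})


class TestAugmentLags:
    def test_three_day_patient_shift(self):
        df = pd.DataFrame({"patient_id": 0, "day": [1, 2, 3],
                           "treatment": [1, 2, 2], "pain": [5.0, 4.0, 3.0]})
        out = augment_lags(df)
        assert len(out) == 2
        assert out["treatment_lag1"].tolist() == [1.0, 2.0]
        assert out["pain_lag1"].tolist() == [5.0, 4.0]

    def test_lag_equals_current_within_periods(self, scen1_cohort):
        out = augment_lags(scen1_cohort)
        same_period = out.groupby("patient_id")["period"].shift(1) == out["period"]
        assert (out.loc[same_period.fillna(False), "treatment_lag1"]
                == out.loc[same_period.fillna(False), "treatment"]).all()

    def test_unsorted_days_rejected(self):
        df = pd.DataFrame({"patient_id": 0, "day": [2, 1],
                           "treatment": [1, 2], "pain": [5.0, 4.0]})
        with pytest.raises(SchemaError, match="sorted"):
            augment_lags(df)

    def test_time_adjusted_structure(self, graph, scen1_cohort):
        aug = augment_lags(scen1_cohort)
        g = bn_structure(graph, aug.columns, time_adjust=True)
        plain = bn_structure(graph, scen1_cohort.data.columns)
        assert set(g.nodes) - set(plain.nodes) == {"treatment_lag1", "pain_lag1"}
        for edge in [("treatment_lag1", "treatment"), ("treatment_lag1", "activity"),
                     ("treatment_lag1", "pain"), ("pain_lag1", "pain"),
                     ("activity", "treatment")]:
            assert g.has_edge(*edge)


class TestFitNetwork:
    def test_single_edge_consistency(self):
        net = fit_network(single_edge_data(), SINGLE_EDGE, prior_weight=1e-8)
        fit = net.nodes["pain"]
        assert fit.parents == ["treatment"]
        assert fit.coefs[0] == pytest.approx(-2.0, abs=0.05)
        assert fit.resid_sd == pytest.approx(1.0, abs=0.05)

    def test_parentless_node_posterior_mean(self):
        df = single_edge_data(n=50)
        net = fit_network(df, SINGLE_EDGE, prior_weight=2.0)
        y = df["treatment"].to_numpy()
        assert net.nodes["treatment"].intercept == pytest.approx(
            y.sum() / (len(y) + 2.0))

    def test_matches_ridge_oracle(self):
        rng = np.random.default_rng(1)
        df = single_edge_data(n=400, seed=2)
        df["activity"] = rng.normal(size=400)
        g = n1.parse_graph({
            "nodes": [{"name": "treatment", "role": "treatment"},
                      {"name": "activity"},
                      {"name": "pain", "role": "outcome"}],
            "edges": [{"source": "treatment", "target": "pain", "weight": -2.0},
                      {"source": "activity", "target": "pain", "weight": 0.3}],
        })
        lam = 3.0
        net = fit_network(df, g, prior_weight=lam)
        X = np.column_stack([np.ones(400), df["activity"], df["treatment"]])
        M = X.T @ X + np.diag([0.0, lam, lam])
        beta = np.linalg.solve(M, X.T @ df["pain"].to_numpy())
        fit = net.nodes["pain"]
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert dict(zip(fit.parents, fit.coefs))["activity"] == pytest.approx(
            beta[1], abs=1e-8)


class TestEstimateATE:
    def test_single_edge_ate(self):
        net = fit_network(single_edge_data(), SINGLE_EDGE, prior_weight=1e-8)
        ate = estimate_ate(net, n_samples=1000, seed=3)
        mc_se = np.sqrt(ate.outcomes_arm1.var() / 1000 + ate.outcomes_arm2.var() / 1000)
        assert ate.difference == pytest.approx(2.0, abs=4 * mc_se + 0.05)

    def test_sampled_ate_matches_path_tracing(self, graph, scen1_cohort):
        net = fit_network(scen1_cohort, graph)
        ate = estimate_ate(net, n_samples=4000, seed=11)
        closed_form = -total_effect(net)  # one unit of T (1 -> 2), sign flipped
        mc_se = np.sqrt(ate.outcomes_arm1.var() / 4000 + ate.outcomes_arm2.var() / 4000)
        assert ate.difference == pytest.approx(closed_form, abs=3 * mc_se)

    def test_variance_scales_inversely_with_sample_size(self):
        net = fit_network(single_edge_data(n=2000), SINGLE_EDGE)
        small = [estimate_ate(net, 100, seed=s).difference for s in range(40)]
        large = [estimate_ate(net, 10000, seed=1000 + s).difference
                 for s in range(40)]
        ratio = np.var(small) / np.var(large)
        assert 30 < ratio < 330


class TestModelObject:
    def test_methods_agree_without_temporal_dependence(self, graph):
        cfg = n1.scenario_config(1, innovation_sd=0.0, drift_mean=0.0)
        coh = n1.simulate_cohort(graph, cfg, 30, seed=21)
        plain = BayesianNetworkATE(coh, graph).fit(seed=5)
        lagged = BayesianNetworkATE(coh, graph, time_adjust=True).fit(seed=5)
        pain_fit = lagged.network.nodes["pain"]
        lag_coef = dict(zip(pain_fit.parents, pain_fit.coefs))["pain_lag1"]
        assert abs(lag_coef) < 0.06
        assert lagged.effect_difference == pytest.approx(
            plain.effect_difference, abs=0.2)
        assert plain.method == "bn" and lagged.method == "bn_time"

    def test_seeded_reproducibility(self, graph, scen1_cohort):
        a = BayesianNetworkATE(scen1_cohort, graph).fit(seed=9)
        b = BayesianNetworkATE(scen1_cohort, graph).fit(seed=9)
        assert a.effect_difference == b.effect_difference
        assert a.to_estimate().to_dict()["n_samples"] == 1000
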