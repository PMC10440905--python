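"""Simulator: design randomization, exposure decay, drift, outcomes, dropout."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import nof1sim as n1
from nof1sim.errors import ConfigError, Nof1SimError
from nof1sim.simulate import StudyDesign, missingness_mask

MINIMAL_GRAPH = n1.parse_graph({
    "nodes": [
        {"name": "treatment", "role": "treatment"},
        {"name": "pain", "role": "outcome", "noise": {"mean": 5.0, "sd": 1.0}},
    ],
    "edges": [{"source": "treatment", "target": "pain", "weight": -2.0}],
})


def manual_design(labels):
    labels = np.asarray(labels, dtype=np.int64)
    return StudyDesign(treatment=labels,
                       block=np.ones(len(labels), dtype=np.int64),
                       period=np.ones(len(labels), dtype=np.int64))


class TestDesign:
    def test_default_dimensions(self):
        d = n1.generate_design(0, n1.scenario_config(1))
        assert d.n_days == 112
        assert len(np.unique(d.period)) == 4
        assert all((d.period == p).sum() == 28 for p in range(1, 5))
        # within each block each treatment appears in exactly one period
        for b in (1, 2):
            counts = pd.Series(d.treatment[d.block == b]).value_counts()
            assert counts[1] == 28 and counts[2] == 28

    def test_one_block_one_day_periods(self):
        d = n1.generate_design(3, n1.scenario_config(1, blocks=1, period_length=1))
        assert d.n_days == 2
        assert sorted(d.treatment.tolist()) == [1, 2]

    def test_invalid_parameters(self):
        with pytest.raises(ConfigError):
            n1.scenario_config(1, period_length=0)

    def test_block_order_uniform(self):
        cfg = n1.scenario_config(1, blocks=1, period_length=1)
        first = [n1.generate_design(s, cfg).treatment[0] for s in range(10_000)]
        frac_ab = np.mean(np.asarray(first) == 1)
        assert abs(frac_ab - 0.5) < 0.015


class TestExposureDecay:
    def test_wash_in_worked_example(self):
        e = n1.exposure_decay([1, 1, 1], tau=2, gamma=1)
        assert np.allclose(e, [0.0, 0.5, 0.75, 0.875])

    def test_collapses_to_indicator_without_carry_over(self):
        t = np.array([1, 1, 0, 1, 0, 0, 1])
        assert np.array_equal(n1.exposure_decay(t, 1, 1)[1:], t.astype(float))

    def test_wash_out_closed_form(self):
        e = n1.exposure_decay([0, 0], tau=1, gamma=4, e0=1.0)
        assert np.allclose(e, [1.0, 0.75, 0.5625])

    def test_rejects_parameters_below_one(self):
        with pytest.raises(ConfigError):
            n1.exposure_decay([1, 0], tau=0.5, gamma=1)
        with pytest.raises(ConfigError):
            n1.exposure_decay([1, 2], tau=2, gamma=2)

    @settings(deadline=None, max_examples=60)
    @given(
        t=st.lists(st.integers(0, 1), min_size=1, max_size=60),
        tau=st.floats(1.0, 10.0),
        gamma=st.floats(1.0, 10.0),
    )
    def test_bounded_and_closed_form_under_constant_exposure(self, t, tau, gamma):
        e = n1.exposure_decay(t, tau, gamma)
        assert np.all((e >= 0.0) & (e <= 1.0))
        ones = np.ones(len(t))
        e_on = n1.exposure_decay(ones, tau, gamma)
        expect = 1.0 - (1.0 - 1.0 / tau) ** np.arange(len(t) + 1)
        assert np.allclose(e_on, expect, atol=1e-12)


class TestUnderlyingState:
    def test_deterministic_ramp(self):
        u = n1.simulate_underlying_state(10, drift_mean=0.1, innovation_sd=0.0, seed=0)
        assert np.isclose(u[10], 1.0)

    def test_zero_drift_constant(self):
        u = n1.simulate_underlying_state(20, 0.0, 0.0, seed=0)
        assert np.all(u == 0.0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            n1.simulate_underlying_state(5, 0.0, -1.0)

    def test_variance_grows_linearly(self):
        t = 10
        finals = [n1.simulate_underlying_state(t, 0.0, 1.0, seed=s)[t]
                  for s in range(5000)]
        assert abs(np.var(finals) / t - 1.0) < 0.08


class TestPatient:
    def test_noise_free_treatment_effects(self):
        cfg = n1.scenario_config(1, noise_scale=0.0, ordinal_outcome=False)
        d = manual_design([1] * 3 + [2] * 3)
        df = n1.simulate_patient(MINIMAL_GRAPH, d, cfg, seed=0)
        assert np.allclose(df.loc[df.treatment == 1, "pain"], 3.0)
        assert np.allclose(df.loc[df.treatment == 2, "pain"], 1.0)

    def test_carry_over_first_day_contribution(self):
        # day 1 of a treatment-1 period with no prior exposure: one wash-in
        # step gives E = 1/tau1 = 1/6, so the contribution is -2/6
        cfg = n1.scenario_config(2, noise_scale=0.0, ordinal_outcome=False)
        d = manual_design([1] * 5)
        df = n1.simulate_patient(MINIMAL_GRAPH, d, cfg, seed=0)
        assert np.isclose(df["pain"].iloc[0], 5.0 - 2.0 / 6.0)

    def test_threshold_above_support_all_zero(self):
        g = n1.parse_graph({
            "nodes": [
                {"name": "treatment", "role": "treatment"},
                {"name": "x", "distribution": {"kind": "gaussian", "params": [0.0, 1.0]},
                 "binary_threshold": 99.0},
                {"name": "pain", "role": "outcome", "noise": {"mean": 5.0, "sd": 0.0}},
            ],
            "edges": [{"source": "treatment", "target": "pain", "weight": -2.0},
                      {"source": "x", "target": "pain", "weight": 1.0}],
        })
        df = n1.simulate_patient(g, manual_design([1, 2, 1, 2]),
                                 n1.scenario_config(1), seed=1)
        assert np.all(df["x"] == 0.0)

    def test_constant_nodes_constant_across_days(self, graph):
        cfg = n1.scenario_config(1)
        df = n1.simulate_patient(graph, n1.generate_design(5, cfg), cfg, seed=5)
        for col in ("demographics", "education", "work", "prev_diagnosis",
                    "chronic_diseases"):
            assert df[col].nunique() == 1

    def test_outcome_on_ordinal_scale(self, scen1_cohort):
        pain = scen1_cohort.data["pain"]
        assert np.array_equal(pain, pain.round())
        assert pain.between(0, 10).all()


class TestCohort:
    def test_seed_determinism(self, graph):
        cfg = n1.scenario_config(2)
        a = n1.simulate_cohort(graph, cfg, 5, seed=9)
        b = n1.simulate_cohort(graph, cfg, 5, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seeds_differ(self, graph):
        cfg = n1.scenario_config(1)
        a = n1.simulate_cohort(graph, cfg, 5, seed=1)
        b = n1.simulate_cohort(graph, cfg, 5, seed=2)
        assert not a.data.equals(b.data)

    def test_no_carry_over_outcome_equals_indicator_generator(self, graph):
        """With tau = gamma = 1 the carry-over machinery is inert: forcing the
        scenario-2 parameters to 1 reproduces scenario 1 bit for bit."""
        cfg1 = n1.scenario_config(1)
        cfg2 = n1.scenario_config(2, carry_over=False, tau=(1.0, 1.0),
                                  gamma=(1.0, 1.0))
        a = n1.simulate_cohort(graph, cfg1, 4, seed=3)
        b = n1.simulate_cohort(graph, cfg2, 4, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_noise_free_population_contrast_is_exact(self, graph):
        cfg = n1.scenario_config(1, noise_scale=0.0, drift_mean=0.0)
        coh = n1.simulate_cohort(graph, cfg, 20, seed=4)
        est = n1.SampleMeanContrast(coh).fit()
        assert est.effect_difference == pytest.approx(2.0, abs=1e-12)


class TestMissingness:
    def test_disabled_mechanisms_leave_data_complete(self, scen1_cohort):
        out = n1.apply_missingness(scen1_cohort, seed=0, rate=0.0, block_length=None)
        assert not out.data["missing"].any()

    def test_random_dropout_rate(self):
        rng = np.random.default_rng(123)
        fracs = [missingness_mask(112, rng, rate=0.10, block_length=None).mean()
                 for _ in range(2000)]
        assert abs(np.mean(fracs) - 0.10) < 0.01

    def test_dropout_probability_increases_over_time(self):
        rng = np.random.default_rng(7)
        counts = np.zeros(112)
        for _ in range(4000):
            counts += missingness_mask(112, rng, rate=0.10, block_length=None)
        assert counts[-28:].mean() > 2.5 * counts[:28].mean()

    def test_vacation_block_is_one_run_of_ten(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = missingness_mask(112, rng, rate=0.0, block_length=10)
            assert m.sum() == 10
            starts = np.flatnonzero(np.r_[m[0], ~m[:-1] & m[1:]])
            assert len(starts) == 1  # exactly one maximal run of 10

    def test_short_record_rejected(self, graph):
        cfg = n1.scenario_config(1, blocks=1, period_length=4)
        coh = n1.simulate_cohort(graph, cfg, 2, seed=0)
        with pytest.raises(Nof1SimError):
            n1.apply_missingness(coh, seed=0, block_length=10)

    def test_mask_retains_values_and_is_deterministic(self, scen1_cohort):
        a = n1.apply_missingness(scen1_cohort, seed=8)
        b = n1.apply_missingness(scen1_cohort, seed=8)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert a.data["missing"].any()
        # in-memory values are retained alongside the mask
        assert not a.data.loc[a.data["missing"], "pain"].isna().any()
        per_patient = a.data.groupby("patient_id")["missing"].sum()
        assert (per_patient >= 10).all()
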