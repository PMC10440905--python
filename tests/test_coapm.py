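"""COAPM: exposure design columns, grid search, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

import nof1sim as n1
from nof1sim import COAPM, coapm_design
from nof1sim.simulate import exposure_decay


def synthetic_exact(n_patients=2, n_days=112, taus=(6.0, 5.0), gammas=(3.0, 4.0),
                    betas=(-2.0, -4.0), noise_sd=0.0, seed=0):
    """Data generated exactly from the COAPM regression equation."""
    rng = np.random.default_rng(seed)
    frames = []
    for pid in range(n_patients):
        # alternating 28-day periods, order flipped per patient
        order = [1, 2, 2, 1] if pid % 2 else [2, 1, 1, 2]
        treat = np.repeat(order, n_days // 4)
        e1 = exposure_decay((treat == 1).astype(float), taus[0], gammas[0])[1:]
        e2 = exposure_decay((treat == 2).astype(float), taus[1], gammas[1])[1:]
        x = rng.normal(size=n_days)
        y = 1.0 + betas[0] * e1 + betas[1] * e2 + 0.5 * x \
            + noise_sd * rng.normal(size=n_days)
        frames.append(pd.DataFrame({
            "patient_id": pid, "day": np.arange(1, n_days + 1),
            "treatment": treat, "x": x, "pain": y,
        }))
    return pd.concat(frames, ignore_index=True)


class TestDesignColumns:
    def test_identity_when_no_carry_over(self, scen1_cohort):
        tab = coapm_design(scen1_cohort, 1, 1, 1, 1)
        assert np.array_equal(tab["e1"], (tab["treatment"] == 1).astype(float))
        assert np.array_equal(tab["e2"], (tab["treatment"] == 2).astype(float))

    def test_degenerate_grid_point_reproduces_linear_model(self, scen1_cohort):
        co = COAPM(scen1_cohort, grid=[1]).fit()
        lm = n1.TrialLinearModel(scen1_cohort).fit()
        assert co.aliased
        assert co.effect_difference == pytest.approx(lm.effect_difference, abs=1e-9)

    def test_worked_example_first_three_days(self):
        df = pd.DataFrame({"patient_id": 0, "day": [1, 2, 3],
                           "treatment": [1, 1, 1], "pain": [1.0, 2.0, 3.0]})
        tab = coapm_design(df, 2, 1, 1, 1, covariates=[])
        assert np.allclose(tab["e1"], [0.5, 0.75, 0.875])

    def test_all_days_missing_patient_contributes_no_rows(self, scen1_cohort):
        df = scen1_cohort.data.copy()
        df.loc[df.patient_id == 0, "missing"] = True
        tab = coapm_design(df, 2, 2, 2, 2)
        assert 0 not in tab["patient_id"].to_numpy()

    def test_exposure_bounded_and_monotone_within_periods(self, scen2_cohort):
        tab = coapm_design(scen2_cohort, 6, 3, 5, 4)
        assert tab[["e1", "e2"]].to_numpy().min() >= 0.0
        assert tab[["e1", "e2"]].to_numpy().max() <= 1.0
        on1 = tab[tab.treatment == 1]
        for (_, _), sub in on1.groupby(["patient_id", (on1.day // 28)]):
            assert (np.diff(sub["e1"]) >= -1e-12).all()


class TestGridSearch:
    def test_noise_free_exact_recovery(self):
        df = synthetic_exact()
        res = COAPM(df, covariates=["x"]).fit()
        assert (res.tau1, res.gamma1, res.tau2, res.gamma2) == (6, 3, 5, 4)
        assert res.r_squared > 1 - 1e-10
        assert res.beta1 == pytest.approx(-2.0, abs=1e-8)
        assert res.beta2 == pytest.approx(-4.0, abs=1e-8)
        assert res.effect_difference == pytest.approx(2.0, abs=1e-8)

    def test_coordinate_search_estimates_effect_on_clean_data(self):
        # block-coordinate sweeps can stop in a local optimum of (tau, gamma),
        # but the effect-difference estimate there remains accurate
        df = synthetic_exact()
        coord = COAPM(df, covariates=["x"], search="coordinate").fit()
        grid = list(range(1, 11))
        assert {coord.tau1, coord.gamma1, coord.tau2, coord.gamma2} <= set(grid)
        assert coord.effect_difference == pytest.approx(2.0, abs=0.1)
        assert coord.r_squared > 0.95

    def test_coordinate_search_close_to_joint_under_noise(self):
        df = synthetic_exact(noise_sd=0.3, seed=3, n_patients=6)
        joint = COAPM(df, covariates=["x"], search="joint").fit()
        coord = COAPM(df, covariates=["x"], search="coordinate").fit()
        # the coordinate scheme may stop in a nearby local optimum, but the
        # effect estimate at its selection must be close to the joint optimum
        assert coord.effect_difference == pytest.approx(
            joint.effect_difference, abs=0.1)
        assert joint.r_squared >= coord.r_squared - 1e-12

    def test_ties_broken_toward_smallest_parameters(self):
        # outcome carries no treatment signal: every grid point fits equally
        # well, so the lexicographically smallest (1, 1, 1, 1) is selected
        df = synthetic_exact(betas=(0.0, 0.0))
        res = COAPM(df, covariates=["x"], grid=[1, 2, 3]).fit()
        assert (res.tau1, res.gamma1, res.tau2, res.gamma2) == (1, 1, 1, 1)

    def test_never_fits_worse_than_linear_model(self, scen2_cohort):
        full = COAPM(scen2_cohort).fit()
        degenerate = COAPM(scen2_cohort, grid=[1]).fit()
        assert full.r_squared >= degenerate.r_squared - 1e-12

    def test_refit_reproduces_selection(self, scen2_cohort):
        res = COAPM(scen2_cohort).fit()
        again = COAPM(scen2_cohort,
                      grid=sorted({int(res.tau1), int(res.gamma1),
                                   int(res.tau2), int(res.gamma2)})).fit()
        assert again.r_squared <= res.r_squared + 1e-12
        assert res.se > 0 and res.se_beta1 > 0

    def test_parameter_recovery_noise_reduced_simulations(self, graph):
        sel = []
        for rep in range(20):
            # continuous outcome: the ordinal rounding is a deliberate
            # misspecification that perturbs (tau, gamma) selection once the
            # noise no longer dithers the quantization steps
            cfg = n1.scenario_config(2, noise_scale=0.1, drift_mean=0.0,
                                     ordinal_outcome=False)
            coh = n1.simulate_cohort(graph, cfg, 12, seed=100 + rep)
            r = COAPM(coh, covariates=["activity", "stress", "sleep_quality"]).fit()
            sel.append((r.tau1, r.gamma1, r.tau2, r.gamma2))
        med = tuple(np.median(np.asarray(sel), axis=0))
        assert med == (6.0, 3.0, 5.0, 4.0)

    def test_exposure_evolves_through_missing_days(self, scen2_cohort):
        cohort = n1.apply_missingness(scen2_cohort, seed=2)
        evolving = COAPM(cohort).fit()
        collapsed = COAPM(cohort, evolve_through_missing=False).fit()
        assert np.isfinite(evolving.effect_difference)
        assert evolving.effect_difference != pytest.approx(
            collapsed.effect_difference)
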