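"""Kinetic model and cohort-generator behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from cocktail_lss import (
    ParameterError,
    PKParameters,
    bateman_concentration,
    censor_lloq,
    default_design,
    metabolite_auc,
    metabolite_concentration,
    parent_auc,
    simulate_cohort,
)
from conftest import make_constant_dataset

P = PKParameters(dose=10.0, bioavail_scale=700.0, ka=3.0, ke=0.14, vd_f=36.0)
PM = PKParameters(
    dose=10.0, bioavail_scale=112.0, ka=1.5, ke=0.2, vd_f=250.0, fm=0.5, km=0.25, metab_scale=6.0
)


class TestParentKinetics:
    def test_zero_at_dose_time(self):
        assert bateman_concentration(P, 0.0) == 0.0

    def test_instantaneous_absorption_limit(self):
        """With very fast absorption the curve approaches bolus decay S*D/V * e^-ke*t."""
        fast = PKParameters(dose=10.0, bioavail_scale=700.0, ka=5000.0, ke=0.14, vd_f=36.0)
        t = np.array([60.0, 240.0, 720.0])
        bolus = 700.0 * 10.0 / 36.0 * np.exp(-0.14 * t / 60.0)
        assert np.allclose(bateman_concentration(fast, t), bolus, rtol=1e-3)

    def test_total_auc_matches_dense_trapezoid(self):
        """AUC(0, inf) = S*D/(V*ke), checked against a 0.1-min-grid trapezoid."""
        grid = np.arange(0.0, 7200.0 * 60, 0.1)  # 7200 h horizon leaves no visible tail
        numeric = np.trapezoid(bateman_concentration(P, grid), grid) / 60.0
        closed = P.bioavail_scale * P.dose / (P.vd_f * P.ke)
        assert numeric == pytest.approx(closed, rel=1e-3)

    def test_rejects_invalid_parameters(self):
        with pytest.raises(ParameterError):
            PKParameters(dose=10.0, bioavail_scale=700.0, ka=-1.0, ke=0.14, vd_f=36.0)
        with pytest.raises(ParameterError):
            bateman_concentration(P, -5.0)


class TestMetaboliteKinetics:
    def test_initial_condition_zero(self):
        assert metabolite_concentration(PM, 0.0) == 0.0

    def test_no_formation_no_metabolite(self):
        none = PKParameters(
            dose=10.0, bioavail_scale=112.0, ka=1.5, ke=0.2, vd_f=250.0, fm=0.0, km=0.25
        )
        t = np.array([30.0, 120.0, 720.0])
        assert np.allclose(metabolite_concentration(none, t), 0.0)

    def test_matches_ode_solution(self):
        """Closed form vs a high-accuracy numerical solution of the formation ODE."""

        def rhs(t_h, y):
            cp = bateman_concentration(PM, t_h * 60.0)
            return [PM.metab_scale * PM.fm * PM.ke * cp - PM.km * y[0]]

        sol = solve_ivp(rhs, (0.0, 2.0), [0.0], rtol=1e-11, atol=1e-14, dense_output=True)
        numeric = sol.sol(2.0)[0]
        assert metabolite_concentration(PM, 120.0) == pytest.approx(numeric, rel=1e-6)

    def test_analytic_aucs_match_dense_grids(self):
        grid = np.arange(0.0, 720.0001, 0.05)
        cp = bateman_concentration(PM, grid)
        cm = metabolite_concentration(PM, grid)
        assert parent_auc(PM) == pytest.approx(np.trapezoid(cp, grid) / 60.0, rel=1e-4)
        assert metabolite_auc(PM) == pytest.approx(np.trapezoid(cm, grid) / 60.0, rel=1e-4)


class TestSimulateCohort:
    def test_record_count(self, default_sim):
        # 16 subjects x 2 phases x 7 analytes x 14 times
        assert len(default_sim.dataset.records) == 16 * 2 * 7 * 14

    def test_same_seed_identical_output(self, design, population):
        a = simulate_cohort(design, population, seed=7)
        b = simulate_cohort(design, population, seed=7)
        pd.testing.assert_frame_equal(a.dataset.records, b.dataset.records)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_degenerate_population_all_subjects_identical(self, population):
        """Zero BSV and zero residual error collapse the cohort to one profile."""
        from dataclasses import replace

        pop = population.noise_free()
        probes = {n: replace(p, bsv_cv={}) for n, p in pop.probes.items()}
        from cocktail_lss.simulate import Population

        pop = Population(probes=probes, error_model=pop.error_model)
        sim = simulate_cohort(default_design(pop, n_subjects=3), pop, seed=1)
        wide = sim.dataset.records.pivot_table(
            index=["phase", "analyte", "time_min"],
            columns="subject_id",
            values="conc_ng_ml",
        )
        assert np.allclose(wide[1], wide[2]) and np.allclose(wide[1], wide[3])

    def test_concentrations_non_negative(self, default_sim):
        assert (default_sim.dataset.records["conc_ng_ml"] >= 0).all()

    def test_calibrated_caffeine_median(self, default_sim):
        """Cohort median caffeine AUC(0-12h) lands in the published typical range."""
        from cocktail_lss import best_estimates

        met = best_estimates(default_sim.dataset, 1)
        median = met[met["probe"] == "caffeine"]["value"].median()
        assert 500.0 <= median <= 1600.0

    def test_truth_matches_dense_numeric_integration(self, noise_free_sim):
        """Analytic ground-truth AUCs agree with dense-grid integrals per subject."""
        params = noise_free_sim.parameters
        truth = noise_free_sim.truth
        grid = np.arange(0.0, 720.0001, 0.1)
        for _, row in params[params["probe"] == "caffeine"].head(4).iterrows():
            p = PKParameters(**{k: row[k] for k in (
                "dose", "bioavail_scale", "ka", "ke", "vd_f", "fm", "km", "metab_scale")})
            numeric = np.trapezoid(bateman_concentration(p, grid), grid) / 60.0
            stated = truth[
                (truth["subject_id"] == row["subject_id"])
                & (truth["probe"] == "caffeine")
                & (truth["phase"] == 1)
            ]["true_value"].iloc[0]
            assert stated == pytest.approx(numeric, rel=1e-3)

    def test_pure_scaling_profiles_share_shape(self, pure_scaling_sim):
        """With BSV only on the scale, profiles are scalar multiples of one shape."""
        rec = pure_scaling_sim.dataset.records
        sub = rec[(rec["analyte"] == "caffeine") & (rec["phase"] == 1) & (rec["time_min"] > 0)]
        wide = sub.pivot_table(index="time_min", columns="subject_id", values="conc_ng_ml")
        ratios = wide.div(wide[1], axis=0)
        assert np.allclose(ratios.std(axis=0), 0.0, atol=1e-9)

    def test_pm_subject_metabolite_mostly_blq(self, design, population):
        sim = simulate_cohort(design, population, seed=5, include_pm_subject=True)
        rec = sim.dataset.records
        pm = rec[(rec["subject_id"] == 16) & (rec["analyte"] == "alpha_oh_metoprolol")]
        assert pm["blq"].mean() > 0.5


class TestCensorLLOQ:
    def test_zero_lloq_flags_nothing(self):
        ds = make_constant_dataset(value=1.0)
        lloq = {a: 0.0 for a in ds.design.analytes}
        assert not censor_lloq(ds, lloq).records["blq"].any()

    def test_below_lloq_flagged_value_retained(self):
        ds = make_constant_dataset(value=0.5)
        lloq = {a: 1.0 for a in ds.design.analytes}
        out = censor_lloq(ds, lloq)
        assert out.records["blq"].all()
        assert (out.records["conc_ng_ml"] == 0.5).all()

    def test_missing_analyte_is_configuration_error(self):
        from cocktail_lss import ConfigurationError

        ds = make_constant_dataset()
        with pytest.raises(ConfigurationError):
            censor_lloq(ds, {"caffeine": 1.0})
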