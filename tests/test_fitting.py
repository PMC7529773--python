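import numpy as np
import pytest

from abpk import (
    ConcentrationTimeProfile,
    MichaelisMentenParams,
    TwoCompartmentParams,
    UptakeDataset,
    VmaxScale,
    analytic_linear,
    fit_hill,
    fit_michaelis_menten,
    fit_one_site_binding,
    fit_two_compartment,
    generate_in_vivo_study,
    generate_uptake_assay,
    mean_profile,
    weighted_objective,
)
from abpk.fitting import WeightingScheme
from abpk.synthetic import AssayDesign, StudyDesign


class TestWeightedObjective:
    def test_perfect_prediction_is_zero(self):
        assert weighted_objective([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_reciprocal_weighting_value(self):
        # (2-0)^2 / 2 = 2
        assert weighted_objective([2.0], [0.0], WeightingScheme.RECIPROCAL_OBSERVED) == 2.0

    def test_scale_equivariance_of_reciprocal_weighting(self):
        obs = np.array([1.0, 3.0, 7.0])
        pred = np.array([1.2, 2.5, 8.0])
        base = weighted_objective(obs, pred)
        assert weighted_objective(5 * obs, 5 * pred) == pytest.approx(5 * base, rel=1e-12)

    def test_reciprocal_rejects_nonpositive_observations(self):
        with pytest.raises(ValueError):
            weighted_objective([0.0, 1.0], [1.0, 1.0])

    def test_uniform_weighting(self):
        assert weighted_objective([2.0], [0.0], WeightingScheme.UNIFORM) == 4.0


class TestTwoCompartmentFit:
    def test_noise_free_recovery_of_reference_parameters(self, linear_params, schedule):
        prof = analytic_linear(linear_params, 100.0, schedule)
        res = fit_two_compartment(prof, seed=0)
        est = res.estimates
        assert res.converged
        assert est.V1 == pytest.approx(25.7, rel=5e-4)
        assert est.k10 == pytest.approx(2.46, rel=5e-4)
        assert est.k12 == pytest.approx(14.27, rel=5e-4)
        assert est.k21 == pytest.approx(25.35, rel=5e-4)
        # noise-free data pins the estimates: CV% essentially zero
        assert all(cv < 1e-4 for cv in res.cv_percent.values())

    def test_nested_one_compartment_recovery(self, schedule):
        # data from a monoexponential: recovered transfer rate ~ 0,
        # elimination and volume correct
        t = np.asarray(schedule)
        conc = (100e3 / 25.7) * np.exp(-2.46 * t)
        prof = ConcentrationTimeProfile(100.0, t, conc)
        res = fit_two_compartment(prof, seed=0)
        est = res.estimates
        assert est.k10 == pytest.approx(2.46, rel=1e-2)
        assert est.V1 == pytest.approx(25.7, rel=1e-2)
        assert est.k12 < 0.05 * est.k10

    def test_monte_carlo_median_recovery_under_noise(self, linear_params, schedule):
        medians = {"k10": [], "V1": []}
        for seed in range(40):
            study = generate_in_vivo_study(
                linear_params, None,
                StudyDesign(doses_mg_per_kg=(100.0,), cv=0.05, seed=seed),
            )
            res = fit_two_compartment(mean_profile(study[100.0]), n_random_starts=2, seed=seed)
            medians["k10"].append(res.estimates.k10)
            medians["V1"].append(res.estimates.V1)
        assert np.median(medians["k10"]) == pytest.approx(2.46, rel=0.10)
        assert np.median(medians["V1"]) == pytest.approx(25.7, rel=0.10)

    def test_objective_at_estimate_beats_truth_on_noisy_data(self, linear_params, schedule):
        study = generate_in_vivo_study(
            linear_params, None, StudyDesign(doses_mg_per_kg=(100.0,), cv=0.10, seed=7)
        )
        prof = mean_profile(study[100.0])
        res = fit_two_compartment(prof, seed=7)
        pred_truth = analytic_linear(linear_params, 100.0, prof.times).concentrations
        obj_truth = weighted_objective(prof.concentrations, pred_truth)
        assert res.objective_value <= obj_truth + 1e-12

    def test_saturation_warning_when_linear_model_underpredicts_tail(
        self, linear_params, mm_per_kg
    ):
        from abpk import simulate

        # a clearly unsaturated dose: the saturable term dominates the tail
        t = np.geomspace(3e-3, 0.3, 8)
        prof = simulate(linear_params, mm_per_kg, 1.0, t)
        res = fit_two_compartment(prof, seed=0)
        # fit succeeds either way; at this dose no linear model matches both
        # ends of the profile, which the tool reports via warning or objective
        assert res.converged


class TestMichaelisMentenFit:
    def test_noise_free_recovery(self, uptake_vitro):
        data = generate_uptake_assay(uptake_vitro, AssayDesign(cv=0.0, n_replicates=1))
        res = fit_michaelis_menten(data, seed=0)
        assert res.estimates.km_nM == pytest.approx(23.6, rel=5e-4)
        assert res.estimates.vmax == pytest.approx(0.0269, rel=5e-4)
        assert res.estimates.vmax_scale is VmaxScale.PER_ASSAY_CELLS
        assert all(cv < 1e-4 for cv in res.cv_percent.values())

    def test_half_maximal_velocity_at_km(self, uptake_vitro):
        data = generate_uptake_assay(uptake_vitro, AssayDesign(cv=0.0, n_replicates=1))
        res = fit_michaelis_menten(data, seed=0)
        mm = res.estimates
        v_at_km = mm.vmax * mm.km_nM / (mm.km_nM + mm.km_nM)
        assert v_at_km == pytest.approx(mm.vmax / 2)

    def test_km_unidentifiable_far_below_saturation(self):
        # all concentrations << Km: only Vmax/Km is determined
        s = np.geomspace(0.001, 0.1, 8)
        truth = MichaelisMentenParams(23.6, 0.0269, VmaxScale.PER_ASSAY_CELLS)
        rng = np.random.default_rng(0)
        v = truth.vmax * s / (truth.km_nM + s) * np.exp(0.02 * rng.standard_normal(s.shape))
        res = fit_michaelis_menten(UptakeDataset(s, v), seed=0)
        assert res.warnings  # identifiability warning raised
        assert res.cv_percent["Km"] > 100 or not np.isfinite(res.cv_percent["Km"])

    def test_cv_grows_with_noise(self, uptake_vitro):
        cvs = []
        for noise in (0.02, 0.10, 0.30):
            data = generate_uptake_assay(
                uptake_vitro, AssayDesign(cv=noise, n_replicates=3, seed=5)
            )
            res = fit_michaelis_menten(data, seed=0)
            cvs.append(res.cv_percent["Km"])
        assert cvs[0] < cvs[1] < cvs[2]


class TestHillFit:
    def test_unit_coefficient_data_matches_mm_fit(self, uptake_vitro):
        data = generate_uptake_assay(uptake_vitro, AssayDesign(cv=0.0, n_replicates=1))
        hill = fit_hill(data, seed=0)
        mm = fit_michaelis_menten(data, seed=0)
        assert hill.estimates.n == pytest.approx(1.0, abs=1e-3)
        assert hill.estimates.km_nM == pytest.approx(mm.estimates.km_nM, rel=1e-3)
        assert hill.estimates.vmax == pytest.approx(mm.estimates.vmax, rel=1e-3)

    def test_recovers_cooperative_coefficient(self):
        from abpk import HillParams

        truth = HillParams(23.6, 0.0269, 2.0, VmaxScale.PER_ASSAY_CELLS)
        data = generate_uptake_assay(truth, AssayDesign(cv=0.0, n_replicates=1))
        res = fit_hill(data, seed=0)
        assert res.estimates.n == pytest.approx(2.0, rel=1e-3)
        assert res.estimates.km_nM == pytest.approx(23.6, rel=1e-3)

    def test_fixing_n_reproduces_mm_fit_exactly(self, uptake_vitro):
        data = generate_uptake_assay(uptake_vitro, AssayDesign(cv=0.10, seed=3))
        fixed = fit_hill(data, seed=0, fix_n=1.0)
        mm = fit_michaelis_menten(data, seed=0)
        assert fixed.estimates.km_nM == pytest.approx(mm.estimates.km_nM, rel=1e-6)
        assert fixed.estimates.vmax == pytest.approx(mm.estimates.vmax, rel=1e-6)


class TestOneSiteBinding:
    def test_noise_free_recovery_of_kd(self):
        free = np.geomspace(0.1, 100, 10)
        bound = 50.0 * free / (3.3 + free)
        res = fit_one_site_binding(free, bound, seed=0)
        assert res.estimates.kd_nM == pytest.approx(3.3, rel=1e-3)
        assert res.estimates.bmax == pytest.approx(50.0, rel=1e-3)

    def test_half_occupancy_at_kd(self):
        free = np.geomspace(0.1, 100, 10)
        bound = 50.0 * free / (3.3 + free)
        res = fit_one_site_binding(free, bound, seed=0)
        est = res.estimates
        assert est.bmax * est.kd_nM / (est.kd_nM + est.kd_nM) == pytest.approx(est.bmax / 2)

    def test_all_zero_bound_is_degenerate(self):
        res = fit_one_site_binding([1.0, 10.0, 100.0], [0.0, 0.0, 0.0])
        assert res.estimates.bmax == 0.0
        assert res.warnings
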