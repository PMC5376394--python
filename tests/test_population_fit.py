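import warnings

import numpy as np
import numpy.testing as npt
import pytest

from cipropbpk.dataset import (Subject, frame_to_subjects, read_dataset,
                               subjects_to_frame, write_dataset)
from cipropbpk.pbpk_core import repeated_doses, total_clearance
from cipropbpk.physiology import ALL_TISSUES, Individual
from cipropbpk.population_fit import (OFV_SELECTION_THRESHOLD, PBPKLikelihood,
                                      PriorSpec, VarianceParameters,
                                      cv_from_omega, delta_ofv, fit,
                                      individual_model, omega_from_cv, pc_vpc)


class TestVarianceConversion:
    def test_omega_cv_round_trip(self):
        for cv in (0.1, 0.56, 1.2):
            assert cv_from_omega(omega_from_cv(cv)) == pytest.approx(cv, rel=1e-12)


class TestIndividualModel:
    def test_zero_eta_is_identity(self, truth_theta, typical_individual):
        p = individual_model(truth_theta, (0.0, 0.0), typical_individual)
        assert p.cl_nr == pytest.approx(truth_theta["cl_nr"])
        assert p.renal_cl_multiplier == 1.0
        for t in ALL_TISSUES:
            assert p.kp[t] == pytest.approx(truth_theta[f"kp_{t}"])

    def test_shared_kp_eta_doubles_every_tissue(self, truth_theta,
                                                typical_individual):
        p = individual_model(truth_theta, (0.0, np.log(2.0)), typical_individual)
        for t in ALL_TISSUES:
            assert p.kp[t] == pytest.approx(2.0 * truth_theta[f"kp_{t}"])
        assert p.f_secretion == truth_theta["f_secretion"]  # no IIV

    def test_clearance_eta_on_total_clearance(self, truth_theta,
                                              typical_individual):
        eta = 0.3
        p = individual_model(truth_theta, (eta, 0.0), typical_individual)
        base = individual_model(truth_theta, (0.0, 0.0), typical_individual)
        ratio = total_clearance(82.0, p) / total_clearance(82.0, base)
        assert ratio == pytest.approx(np.exp(eta), rel=1e-12)

    def test_simulated_clearance_cv_matches_design(self, truth_theta,
                                                   typical_individual):
        """With omega from a 56 % CV, the empirical CV of individual total
        clearance over many draws reproduces 56 %."""
        rng = np.random.default_rng(11)
        omega = omega_from_cv(0.56)
        etas = rng.normal(0.0, omega, size=2000)
        cls = np.array([total_clearance(
            82.0, individual_model(truth_theta, (e, 0.0), typical_individual))
            for e in etas])
        cv = cls.std(ddof=1) / cls.mean()
        assert cv == pytest.approx(0.56, abs=0.05)


def _noise_free_priors(truth_theta):
    return PriorSpec(modes=dict(truth_theta), cvs={k: 0.25 for k in truth_theta})


class TestFit:
    def test_requires_two_subjects(self, rich_noise_free_subjects, truth_theta):
        with pytest.raises(ValueError, match="2 subjects"):
            fit(rich_noise_free_subjects[:1], priors=_noise_free_priors(truth_theta))

    def test_rejects_empty_subject(self, rich_noise_free_subjects, truth_theta):
        s = rich_noise_free_subjects[0]
        empty = Subject(Individual("e", 70.0, "male", 80.0), s.doses,
                        np.zeros(0), np.zeros(0))
        with pytest.raises(ValueError, match="observation"):
            fit([*rich_noise_free_subjects, empty],
                priors=_noise_free_priors(truth_theta))

    def test_tight_priors_pin_estimates_to_modes(self, rich_noise_free_subjects,
                                                 truth_theta):
        """With vanishing prior uncertainty the data cannot move the
        estimates: starting 20 % off, the fit returns to the prior modes."""
        modes = {k: v * 1.1 for k, v in truth_theta.items()}
        priors = PriorSpec(modes=modes, cvs={k: 1e-6 for k in modes})
        start = {k: v * 1.2 for k, v in truth_theta.items()}
        res = fit(rich_noise_free_subjects, priors=priors, start=start,
                  variance_start=VarianceParameters(0.0, 0.0, 0.1),
                  estimate_variance=False, maxiter=150, gtol=1e-7)
        for k, mode in modes.items():
            assert res.theta[k] == pytest.approx(mode, rel=1e-3)

    def test_weak_priors_match_no_prior_fit(self, rich_noise_free_subjects,
                                            truth_theta):
        """With essentially flat priors and rich data, the penalized fit and
        the unpenalized fit coincide."""
        weak = PriorSpec(modes=dict(truth_theta), cvs={k: 1e3 for k in truth_theta})
        start = {k: v * 1.1 for k, v in truth_theta.items()}
        var0 = VarianceParameters(0.0, 0.0, 1e-3)
        kwargs = dict(start=start, variance_start=var0, estimate_variance=False,
                      maxiter=150, gtol=1e-7)
        res_weak = fit(rich_noise_free_subjects, priors=weak, **kwargs)
        res_none = fit(rich_noise_free_subjects, priors=None, **kwargs)
        for k in truth_theta:
            assert res_weak.theta[k] == pytest.approx(res_none.theta[k], rel=1e-2)

    def test_log_normal_scale_consistency_and_history(self,
                                                      rich_noise_free_subjects,
                                                      truth_theta):
        res = fit(rich_noise_free_subjects,
                  priors=_noise_free_priors(truth_theta),
                  variance_start=VarianceParameters(0.0, 0.0, 0.05),
                  estimate_variance=False, maxiter=30)
        for k, v in res.theta.items():
            assert v == pytest.approx(np.exp(res.theta_log[k]), rel=1e-12)
        # accepted outer iterations descend (tiny noise from warm-started
        # inner optimizations notwithstanding)
        increases = np.diff(res.history)
        assert np.all(increases <= 1e-3)
        assert res.objective == pytest.approx(res.history[-1], abs=1e-6)

    def test_standard_errors_available_on_request(self, rich_noise_free_subjects,
                                                  truth_theta):
        res = fit(rich_noise_free_subjects,
                  priors=_noise_free_priors(truth_theta),
                  variance_start=VarianceParameters(0.0, 0.0, 0.05),
                  estimate_variance=False, maxiter=20, compute_se=True)
        assert res.se_log is not None
        assert all(np.isfinite(v) and v >= 0 for v in res.se_log.values())
        assert res.rse["cl_nr"] == pytest.approx(100.0 * res.se_log["cl_nr"])
        frame = res.to_frame(_noise_free_priors(truth_theta))
        assert {"parameter", "prior_mode", "estimate_log", "se_log",
                "estimate", "rse_pct"} <= set(frame.columns)


class TestSubjectNll:
    def test_error_on_nonpositive_prediction(self, truth_theta):
        """An observation at the very start of dosing has zero predicted
        concentration and must be flagged, not silently log-transformed."""
        sub = Subject(Individual("z", 77.0, "male", 82.0),
                      repeated_doses(400.0, 12.0, 1.0, 2),
                      np.array([0.0, 2.0]), np.array([0.0, 0.5]))
        lik = PBPKLikelihood([sub])
        with pytest.raises(ValueError, match="non-positive"):
            lik.predict_log(truth_theta, (0.0, 0.0), 0)

    def test_joint_nll_matches_hand_gaussian(self, truth_theta):
        sub = Subject(Individual("g", 77.0, "male", 82.0),
                      repeated_doses(400.0, 12.0, 1.0, 2),
                      np.array([1.0, 6.0]), np.array([1.0, 0.2]))
        lik = PBPKLikelihood([sub])
        var = VarianceParameters(0.4, 0.3, 0.33)
        eta = (0.1, -0.2)
        pred = lik.predict_log(truth_theta, eta, 0)
        resid = sub.dv - pred
        expected = (0.5 * 2 * np.log(2 * np.pi * 0.33 ** 2)
                    + resid @ resid / (2 * 0.33 ** 2))
        for e, om in zip(eta, (0.4, 0.3)):
            expected += 0.5 * np.log(2 * np.pi * om ** 2) + e ** 2 / (2 * om ** 2)
        assert lik.subject_joint_nll(truth_theta, var, eta, 0) == pytest.approx(
            expected, rel=1e-12)


class TestModelSelection:
    def test_delta_ofv_orientation(self):
        assert delta_ofv(110.0, 95.0) == pytest.approx(15.0)
        assert delta_ofv(110.0, 95.0) > OFV_SELECTION_THRESHOLD
        assert delta_ofv(100.0, 95.0) < OFV_SELECTION_THRESHOLD


class TestDatasetRoundTrip:
    def test_subjects_survive_write_read(self, tmp_path,
                                         rich_noise_free_subjects):
        path = write_dataset(rich_noise_free_subjects, tmp_path / "cohort.csv")
        assert path.with_name(path.name + ".meta.json").exists()
        back = read_dataset(path)
        assert len(back) == len(rich_noise_free_subjects)
        for a, b in zip(back, rich_noise_free_subjects):
            assert a.individual == b.individual
            assert len(a.doses) == len(b.doses)
            npt.assert_allclose(a.obs_times, b.obs_times)
            npt.assert_allclose(a.dv, b.dv)

    def test_frame_round_trip_is_lossless(self, rich_noise_free_subjects):
        frame = subjects_to_frame(rich_noise_free_subjects)
        back = subjects_to_frame(frame_to_subjects(frame))
        npt.assert_allclose(frame["DV"].dropna(), back["DV"].dropna())
        assert frame.shape == back.shape

    def test_missing_column_rejected(self, rich_noise_free_subjects):
        frame = subjects_to_frame(rich_noise_free_subjects).drop(columns=["CRCL"])
        with pytest.raises(ValueError, match="CRCL"):
            frame_to_subjects(frame)


@pytest.fixture(scope="module")
def vpc_inputs(truth_theta):
    from cipropbpk.synthetic_cohort import (CohortDesign, generate_cohort,
                                            generate_observations)
    design = CohortDesign(n_subjects=8, seed=21)
    var = VarianceParameters.default()
    subjects = generate_observations(generate_cohort(design), truth_theta,
                                     var, design)
    return subjects, truth_theta, var


class TestPcVpc:
    def test_too_few_simulations_rejected(self, vpc_inputs):
        subjects, theta, var = vpc_inputs
        with pytest.raises(ValueError, match="n_sim"):
            pc_vpc(subjects, theta, var, n_sim=2)

    def test_low_simulation_count_warns(self, vpc_inputs):
        subjects, theta, var = vpc_inputs
        with pytest.warns(UserWarning, match="n_sim"):
            pc_vpc(subjects, theta, var, n_sim=30, n_bins=3, seed=1)

    def test_self_simulated_data_falls_inside_bands(self, vpc_inputs):
        """Data simulated from the model itself should sit inside the
        simulation-based confidence bands in (nearly) every bin."""
        subjects, theta, var = vpc_inputs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            table = pc_vpc(subjects, theta, var, n_sim=150, n_bins=4, seed=5)
        inside = ((table["obs_median"] >= table["median_ci_lo"])
                  & (table["obs_median"] <= table["median_ci_hi"]))
        assert inside.sum() >= len(table) - 1
        assert (table["n_obs"] > 0).all()

    def test_single_bin_correction_is_uniform(self, vpc_inputs):
        """With one bin every observation is divided by the same median
        population prediction."""
        subjects, theta, var = vpc_inputs
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            table = pc_vpc(subjects, theta, var, n_sim=25, n_bins=1, seed=2)
        assert len(table) == 1
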