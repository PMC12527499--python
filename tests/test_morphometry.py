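import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netatrophy import CohortData, SimulationConfig, fit_wscores, group_difference, t_to_z
from netatrophy.morphometry import wscores_for
from netatrophy.simulate import simulate_study


def _toy_cohort(tiny_scheme, n_per_group=10, shift=0.0, seed=0, constant_covs=False):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    thickness = rng.uniform(2.2, 2.8, (n, 6))
    thickness[n_per_group:] -= shift
    subjects = pd.DataFrame({
        "subject": [f"s{i}" for i in range(n)],
        "group": ["control"] * n_per_group + ["patient"] * n_per_group,
        "sex": np.zeros(n) if constant_covs else rng.integers(0, 2, n),
        "age": np.full(n, 30.0) if constant_covs else rng.uniform(20, 45, n),
        "education": np.full(n, 12.0) if constant_covs else rng.uniform(8, 18, n),
        "icv": np.full(n, 1.4e6) if constant_covs else rng.normal(1.4e6, 1e5, n),
    })
    return CohortData(frame=tiny_scheme, thickness=thickness, subjects=subjects)


class TestGroupDifference:
    def test_equals_pooled_two_sample_t_without_covariates(self, tiny_scheme):
        """With constant covariates the GLM t reduces to the pooled t."""
        cohort = _toy_cohort(tiny_scheme, shift=0.1, constant_covs=True)
        gdm = group_difference(cohort)
        controls, patients = cohort.split()
        for j in range(6):
            a, b = controls[:, j], patients[:, j]
            # textbook pooled two-sample t, thinning-positive orientation
            sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
            t_ref = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
            assert gdm.t[j] == pytest.approx(t_ref, abs=1e-8)

    def test_zero_difference_zero_noise(self, tiny_scheme):
        cohort = _toy_cohort(tiny_scheme, constant_covs=True)
        cohort.thickness[:] = 2.5  # identical values everywhere
        gdm = group_difference(cohort)
        np.testing.assert_array_equal(gdm.t, 0.0)
        np.testing.assert_array_equal(gdm.z, 0.0)
        assert not gdm.significant.any()

    def test_covariate_affine_invariance(self, study):
        cohort = study["cohort"]
        gdm = group_difference(cohort)
        rescaled = CohortData(
            frame=cohort.frame,
            thickness=cohort.thickness,
            subjects=cohort.subjects.assign(
                age=3.0 * cohort.subjects["age"] - 11.0,
                icv=cohort.subjects["icv"] / 1e6 + 2.0,
            ),
        )
        gdm2 = group_difference(rescaled)
        np.testing.assert_allclose(gdm.t, gdm2.t, atol=1e-8)

    def test_thinning_positive_sign(self, study):
        # planted atrophy: epicenter regions should carry positive t
        truth = study["truth"]
        gdm = group_difference(study["cohort"])
        assert np.all(gdm.t[truth.epicenters] > 0)

    def test_small_group_error(self, tiny_scheme):
        cohort = _toy_cohort(tiny_scheme)
        cohort.subjects.loc[1:, "group"] = "patient"
        with pytest.raises(ValueError, match="2 subjects"):
            group_difference(cohort)


class TestTToZ:
    def test_symmetry_and_zero(self):
        assert t_to_z(0.0, 10) == 0.0
        assert t_to_z(-2.2, 15) == pytest.approx(-t_to_z(2.2, 15))

    def test_asymptotic_identity(self):
        for t in (0.5, 1.5, 3.0):
            assert abs(t_to_z(t, 10**6) - t) < 0.01

    def test_matches_independent_cdf_evaluation(self):
        t, df = 2.5, 30
        p_two = 2 * (1 - stats.t.cdf(abs(t), df))
        z_ref = stats.norm.ppf(1 - p_two / 2)
        assert t_to_z(t, df) == pytest.approx(z_ref, abs=1e-8)

    def test_extreme_t_stays_finite_and_monotone(self):
        zs = [t_to_z(t, 20) for t in (10.0, 50.0, 200.0, 1e4)]
        assert all(np.isfinite(zs))
        assert zs == sorted(zs)

    def test_df_error(self):
        with pytest.raises(ValueError):
            t_to_z(1.0, 0)


class TestWScores:
    def test_patient_on_prediction_gets_zero(self, tiny_scheme):
        cohort = _toy_cohort(tiny_scheme, n_per_group=20, seed=3)
        wsm = fit_wscores(cohort)
        # build a synthetic patient lying exactly on the normative plane
        x = np.concatenate([[1.0], cohort.subjects.loc[25, ["sex", "age",
                                                            "education", "icv"]]])
        cohort.thickness[25] = wsm.coefficients @ x
        wsm2 = fit_wscores(cohort)
        row = np.flatnonzero(cohort.is_patient).tolist().index(25)
        np.testing.assert_allclose(wsm2.w[row], 0.0, atol=1e-10)

    def test_two_scales_thinner_gives_w_of_two(self, tiny_scheme):
        cohort = _toy_cohort(tiny_scheme, n_per_group=20, seed=4)
        wsm = fit_wscores(cohort)
        x = np.concatenate([[1.0], cohort.subjects.loc[22, ["sex", "age",
                                                            "education", "icv"]]])
        cohort.thickness[22] = wsm.coefficients @ x - 2.0 * wsm.residual_scale
        wsm2 = fit_wscores(cohort)
        row = np.flatnonzero(cohort.is_patient).tolist().index(22)
        np.testing.assert_allclose(wsm2.w[row], 2.0, atol=1e-10)

    def test_linearity_in_single_cell(self, tiny_scheme):
        cohort = _toy_cohort(tiny_scheme, n_per_group=20, seed=5)
        wsm = fit_wscores(cohort)
        delta = 0.07
        cohort.thickness[30, 2] += delta
        wsm2 = fit_wscores(cohort)
        row = np.flatnonzero(cohort.is_patient).tolist().index(30)
        diff = wsm2.w - wsm.w
        assert diff[row, 2] == pytest.approx(-delta / wsm.residual_scale[2], abs=1e-10)
        diff[row, 2] = 0.0
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)

    def test_in_sample_control_calibration(self):
        # 200 simulated controls: W mean ~ 0 exactly, sd ~ sqrt((n-p)/(n-1))
        cfg = SimulationConfig(seed=8, n_controls=200, n_patients=5)
        _, _, cohort, _ = simulate_study(cfg)
        wsm = fit_wscores(cohort)
        wc = wscores_for(cohort, wsm, np.flatnonzero(~cohort.is_patient))
        assert np.abs(wc.mean(axis=0)).max() < 0.05
        sds = wc.std(axis=0, ddof=1)
        assert sds.min() > 0.9 and sds.max() < 1.1

    def test_too_few_controls_error(self, tiny_scheme):
        cohort = _toy_cohort(tiny_scheme, n_per_group=4)
        with pytest.raises(ValueError, match="controls"):
            fit_wscores(cohort)
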