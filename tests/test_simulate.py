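import dataclasses

import numpy as np
import pytest

from netatrophy import (
    SimulationConfig,
    group_difference,
    simulate_cohort,
    simulate_connectomes,
    simulate_parcellation,
    simulate_study,
)
from netatrophy.simulate import _positions, atrophy_profile


class TestParcellation:
    def test_counts_and_unit_norm(self):
        scheme = simulate_parcellation(SimulationConfig(seed=2))
        assert scheme.n_regions == 68
        assert scheme.hemisphere_indices("left").size == 34
        np.testing.assert_allclose(np.linalg.norm(scheme.centroids, axis=1), 1.0,
                                   atol=1e-9)

    def test_deterministic(self):
        a = simulate_parcellation(SimulationConfig(seed=5))
        b = simulate_parcellation(SimulationConfig(seed=5))
        np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_odd_regions_error(self):
        with pytest.raises(ValueError, match="even"):
            SimulationConfig(n_regions=7)


class TestConnectomes:
    def test_edge_count_matches_density(self):
        cfg = SimulationConfig(seed=3, sc_density=0.25)
        scheme = simulate_parcellation(cfg)
        conn, _ = simulate_connectomes(scheme, cfg)
        m = int(round(0.25 * 68 * 67 / 2))
        edges = int((conn.sc[np.triu_indices(68, 1)] > 0).sum())
        # bridging for connectivity can add a handful of edges
        assert m <= edges <= m + 10

    def test_fc_bounds_and_symmetry(self, study):
        fc = study["connectomes"].fc
        off = fc[~np.eye(68, dtype=bool)]
        assert np.all(np.abs(off) < 1)
        assert np.all(np.diag(fc) == 0)
        np.testing.assert_allclose(fc, fc.T, atol=1e-12)

    def test_sc_nonnegative_zero_diag(self, study):
        sc = study["connectomes"].sc
        assert np.all(sc >= 0)
        assert np.all(np.diag(sc) == 0)

    def test_short_length_scale_keeps_shortest_edges(self):
        # with a vanishing length scale, distance dominates every bonus, so
        # the retained edges are exactly the globally shortest pairs
        cfg = SimulationConfig(seed=4, sc_length_scale=1e-6, sc_density=0.15)
        scheme = simulate_parcellation(cfg)
        conn, _ = simulate_connectomes(scheme, cfg)
        pos = _positions(scheme)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        iu = np.triu_indices(68, 1)
        m = int(round(0.15 * 68 * 67 / 2))
        shortest = set(np.argsort(d[iu])[:m].tolist())
        kept = set(np.flatnonzero(conn.sc[iu] > 0).tolist())
        # kept = shortest plus possibly a few bridging edges
        assert shortest <= kept
        assert len(kept - shortest) <= 10

    def test_deterministic(self):
        cfg = SimulationConfig(seed=9)
        scheme = simulate_parcellation(cfg)
        a, _ = simulate_connectomes(scheme, cfg)
        b, _ = simulate_connectomes(scheme, cfg)
        np.testing.assert_array_equal(a.sc, b.sc)
        np.testing.assert_array_equal(a.fc, b.fc)


class TestAtrophyProfile:
    def test_nonnegative_and_positive_when_connected(self, study):
        sc = study["connectomes"].sc
        prof = atrophy_profile(sc, [0, 1], decay=0.5)
        assert np.all(prof >= 0)
        assert np.all(prof > 0)  # connected graph, decay > 0
        assert prof.max() == 1.0

    def test_single_epicenter_is_expected_maximum(self):
        # over seeds, the planted epicenter has the largest mean atrophy effect
        n_seeds = 50
        total = np.zeros(68)
        r = 7
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, epicenters=(r,), n_controls=2,
                                   n_patients=2)
            scheme = simulate_parcellation(cfg)
            conn, latent = simulate_connectomes(scheme, cfg)
            _, truth = simulate_cohort(scheme, conn, cfg, latent=latent)
            total += truth.beta
        assert np.argmax(total) == r


class TestCohort:
    def test_deterministic(self):
        a = simulate_study(seed=13)
        b = simulate_study(seed=13)
        np.testing.assert_array_equal(a[2].thickness, b[2].thickness)
        np.testing.assert_array_equal(a[3].severity, b[3].severity)

    def test_noise_free_limit_exact(self):
        # no noise, no covariate effects, no factors: patient thickness is
        # exactly baseline - severity * beta
        cfg = SimulationConfig(seed=6, noise_sd=0.0, factor_sd=0.0,
                               age_slope=0.0, sex_offset=0.0, icv_slope=0.0,
                               baseline_sd=0.0, n_controls=5, n_patients=5)
        scheme = simulate_parcellation(cfg)
        conn, latent = simulate_connectomes(scheme, cfg)
        cohort, truth = simulate_cohort(scheme, conn, cfg, latent=latent)
        controls, patients = cohort.split()
        np.testing.assert_allclose(controls, cfg.baseline_mean, atol=1e-12)
        expected = cfg.baseline_mean - np.outer(truth.severity, truth.beta)
        np.testing.assert_allclose(patients, expected, atol=1e-12)

    def test_null_effect_gives_nominal_glm_rate(self):
        # spread_strength 0: no group difference, ~5% of regions reject at
        # the uncorrected 0.05 level
        rejections = 0
        total = 0
        for seed in range(60):
            cfg = SimulationConfig(seed=seed, spread_strength=0.0,
                                   n_regions=20, n_controls=25, n_patients=25)
            scheme, conn, cohort, truth = simulate_study(cfg)
            gdm = group_difference(cohort)
            rejections += int((gdm.p < 0.05).sum())
            total += cfg.n_regions
        rate = rejections / total
        assert 0.025 < rate < 0.08

    def test_clinical_missing_for_controls_only(self, study):
        cohort = study["cohort"]
        patients = cohort.is_patient
        for col in ("craving", "panss", "hars", "hdrs", "duration", "dose"):
            vals = cohort.subjects[col]
            assert vals[~patients].isna().all()
            assert vals[patients].notna().all()

    def test_severity_correlates_with_drug_use(self, study):
        truth = study["truth"]
        pat = study["cohort"].subjects.loc[study["cohort"].is_patient]
        for var in ("duration", "dose"):
            r = np.corrcoef(truth.severity, np.log(pat[var]))[0, 1]
            assert r > 0.3

    def test_biotype_gap_matches_planted_d(self):
        # pooled over seeds: severity gap ~ d * sd(severity)
        gaps, sds = [], []
        for seed in range(20):
            _, _, _, truth = simulate_study(seed=seed)
            s, b = truth.severity, truth.biotype
            gaps.append(s[b == 1].mean() - s[b == 2].mean())
            sds.append(s.std(ddof=1))
        ratio = np.mean(gaps) / np.mean(sds)
        assert 1.2 < ratio < 1.8  # target d = 1.5

    def test_invalid_configs_error(self):
        with pytest.raises(ValueError):
            SimulationConfig(sc_density=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(spread_decay=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(epicenters=(99,))
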