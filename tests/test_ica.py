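"""Spatial ICA decomposition and the two component labelers."""

import numpy as np
import pytest

from rscleanbench.cleaning import expand_motion_24
from rscleanbench.ica import (
    RuleConfig,
    label_by_ground_truth,
    label_by_rules,
    spatial_ica,
)
from rscleanbench.simulate import SimulationConfig, generate_cohort


def three_source_scene(rng, grid=(12, 12, 8), T=80):
    """Non-Gaussian sparse maps mixed by orthogonal timecourses."""
    mask = np.ones(grid, dtype=bool)
    V = mask.sum()
    maps = np.zeros((3, V))
    for k in range(3):
        idx = rng.choice(V, size=60, replace=False)
        maps[k, idx] = rng.exponential(2.0, size=60)
    Q, _ = np.linalg.qr(rng.normal(size=(T, 3)))
    data = np.zeros(grid + (T,))
    data[mask] = (Q @ maps).T * 10.0
    data += 100.0
    return data, mask, maps, Q


class TestSpatialIca:
    def test_recovers_planted_sources(self, rng):
        data, mask, maps, _ = three_source_scene(rng)
        dec = spatial_ica(data, mask, n_components=3, seed=0)
        got = dec.spatial_maps[:, mask]
        corr = np.abs(np.corrcoef(np.vstack([maps, got]))[:3, 3:])
        # every true source matched by exactly one component
        assert (corr.max(axis=1) > 0.95).all()

    def test_deterministic_given_seed(self, rng):
        data, mask, _, _ = three_source_scene(rng)
        a = spatial_ica(data, mask, n_components=3, seed=42)
        b = spatial_ica(data, mask, n_components=3, seed=42)
        np.testing.assert_array_equal(a.spatial_maps, b.spatial_maps)
        np.testing.assert_array_equal(a.timecourses, b.timecourses)

    def test_reconstruction_accounts_for_discarded_variance(self, rng):
        # pure noise is FastICA's hardest case; a loose tolerance lets it
        # terminate while the PCA reconstruction contract stays exact
        data = rng.normal(size=(10, 10, 6, 50)) + 50.0
        mask = np.ones((10, 10, 6), dtype=bool)
        dec = spatial_ica(data, mask, n_components=10, seed=1, tol=2e-2)
        M = data[mask]
        Mc = M - M.mean(axis=1, keepdims=True)
        Mc = Mc - Mc.mean(axis=0)
        total = (Mc**2).sum()
        resid = M - dec.reconstruct()
        discarded = 1.0 - dec.explained_variance.sum()
        assert (resid**2).sum() / total == pytest.approx(discarded, rel=1e-6)

    def test_variance_ordering_and_bounds(self, rng):
        data, mask, _, _ = three_source_scene(rng)
        dec = spatial_ica(data, mask, n_components=3, seed=3)
        ev = dec.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert 0.0 < ev.sum() <= 1.0 + 1e-9

    def test_maps_unit_variance_positive_skew(self, rng):
        data, mask, _, _ = three_source_scene(rng)
        dec = spatial_ica(data, mask, n_components=3, seed=4)
        within = dec.spatial_maps[:, mask]
        np.testing.assert_allclose(within.std(axis=1), 1.0, rtol=1e-6)
        skew = ((within - within.mean(axis=1, keepdims=True)) ** 3).mean(axis=1)
        assert np.all(skew >= -1e-9)

    def test_invalid_dimensionality(self, rng):
        data = rng.normal(size=(4, 4, 3, 10))
        with pytest.raises(ValueError):
            spatial_ica(data, np.ones((4, 4, 3), dtype=bool), n_components=10, seed=0)


@pytest.fixture(scope="module")
def artifact_only_cohort():
    cfg = SimulationConfig(
        grid_shape=(20, 24, 18),
        n_volumes=60,
        n_hc=1,
        n_ad=1,
        n_templates=4,
        network_amplitude=0.0,
        random_seed=21,
    )
    return cfg, *generate_cohort(cfg)


class TestLabelByGroundTruth:
    def test_artifact_only_components_labeled_noise(self, artifact_only_cohort):
        cfg, cohort, truth = artifact_only_cohort
        subj = cohort.subjects[0]
        dec = spatial_ica(subj.data, cohort.masks.brain, n_components=6, seed=0)
        labels = label_by_ground_truth(dec, truth)
        matched = [
            lab
            for j, lab in enumerate(labels)
            if max(
                abs(np.corrcoef(dec.spatial_maps[j][cohort.masks.brain], c.spatial_map[cohort.masks.brain])[0, 1])
                for c in truth.artifact_components
            )
            > 0.4
        ]
        assert matched and all(lab == "noise" for lab in matched)

    def test_noise_free_network_components_labeled_signal(self):
        amps = {k: 0.0 for k in SimulationConfig().artifact_amplitudes}
        cfg = SimulationConfig(
            grid_shape=(20, 24, 18),
            n_volumes=60,
            n_hc=1,
            n_ad=1,
            n_templates=4,
            artifact_amplitudes=amps,
            noise_sd=0.05,
            random_seed=5,
        )
        cohort, truth = generate_cohort(cfg)
        dec = spatial_ica(cohort.subjects[0].data, cohort.masks.brain, n_components=4, seed=0)
        labels = label_by_ground_truth(dec, truth)
        assert "noise" not in labels
        assert "signal" in labels

    def test_labels_invariant_under_sign_flip(self, artifact_only_cohort):
        cfg, cohort, truth = artifact_only_cohort
        dec = spatial_ica(cohort.subjects[0].data, cohort.masks.brain, n_components=6, seed=2)
        labels = list(label_by_ground_truth(dec, truth))
        dec.spatial_maps = -dec.spatial_maps
        dec.timecourses = -dec.timecourses
        assert label_by_ground_truth(dec, truth) == labels


class TestLabelByRules:
    def _decomp_from(self, maps, tcs, mask):
        from rscleanbench.ica import ComponentDecomposition

        return ComponentDecomposition(
            spatial_maps=maps,
            timecourses=tcs,
            explained_variance=np.full(maps.shape[0], 0.1),
            mask=mask,
            temporal_mean=np.zeros(mask.shape),
            spatial_mean_tc=np.zeros(tcs.shape[0]),
        )

    def test_motion_timecourse_flagged_noise(self, small_cohort, rng):
        cfg, cohort, truth = small_cohort
        subj = cohort.subjects[0]
        m24 = expand_motion_24(subj.motion6)
        mask = cohort.masks.brain
        maps = rng.normal(size=(1,) + mask.shape) * mask
        tcs = m24.values[:, [1]]
        dec = self._decomp_from(maps, tcs, mask)
        assert label_by_rules(dec, cohort.masks, m24, tr_s=cfg.tr_s) == ["noise"]

    def test_smooth_gm_component_is_signal(self, default_cohort):
        # 160 volumes: long enough that a smooth oscillation is not spanned
        # by the 24-column motion expansion by chance
        cohort, truth = default_cohort
        mask = cohort.masks.brain
        m24 = expand_motion_24(cohort.subjects[0].motion6)
        maps = (truth.template_maps[truth.dmn_index] * cohort.masks.gm)[None]
        t = np.arange(160) * 2.5
        tcs = np.sin(2 * np.pi * 0.05 * t)[:, None]
        dec = self._decomp_from(maps, tcs, mask)
        assert label_by_rules(dec, cohort.masks, m24, tr_s=2.5) == ["signal"]

    def test_rules_agree_with_oracle_on_default_cohort(self, default_cohort):
        """Rule-based and ground-truth labels agree for >= 80% of components."""
        from rscleanbench.preprocess import PreprocessConfig, preprocess_subject

        cohort, truth = default_cohort
        agreements = []
        for i, subj in enumerate(cohort.subjects[:8]):
            pre = preprocess_subject(subj.data, PreprocessConfig(), cohort.voxel_size_mm, 2.5)
            dec = spatial_ica(pre, cohort.masks.brain, n_components="auto", seed=100 + i)
            gt = label_by_ground_truth(dec, truth)
            gt_eff = ["noise" if l == "noise" else "signal" for l in gt]
            rules = label_by_rules(
                dec, cohort.masks, expand_motion_24(subj.motion6), tr_s=2.5
            )
            agreements.append(np.mean([a == b for a, b in zip(gt_eff, rules)]))
        assert np.mean(agreements) >= 0.8
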