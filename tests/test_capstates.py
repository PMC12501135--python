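"""Seed extraction, frame selection, clustering, CAP metrics and persistence."""

import numpy as np
import pytest

from eibdyn import capstates
from eibdyn.capstates import (SeedSpec, StateSequence, choose_k_consensus,
                              fit_caps, map_windows_to_frames, match_templates,
                              persistence_curve, seed_timecourse, select_frames,
                              sphere_mask, temporal_metrics)


def planted_frames(n_per_cluster, n_vox=60, n_clusters=3, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    patterns = rng.normal(0, 1, (n_clusters, n_vox)) * 2
    labels = np.repeat(np.arange(n_clusters), n_per_cluster)
    frames = patterns[labels] + rng.normal(0, noise, (labels.size, n_vox))
    return frames, labels, patterns


class TestSeedTimecourse:
    def test_sphere_mask_171_voxels_at_10mm(self):
        # 3 mm isotropic grid, seed at a voxel center: integer offsets with
        # 9(i^2+j^2+k^2) <= 100 give 171 voxels
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        mask = sphere_mask((15, 15, 15), affine, (21.0, 21.0, 21.0), 10.0)
        assert int(mask.sum()) == 171

    def test_zscore_contract(self):
        rng = np.random.default_rng(1)
        vol = rng.normal(0, 1, (6, 6, 6, 40))
        z = seed_timecourse(vol, np.diag([3.0, 3, 3, 1]), SeedSpec((7.5, 7.5, 7.5)))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1) < 1e-12

    def test_constant_volume_reports_zero_variance(self):
        vol = np.ones((6, 6, 6, 10))
        with pytest.raises(ValueError, match="zero variance"):
            seed_timecourse(vol, np.diag([3.0, 3, 3, 1]), SeedSpec((7.5, 7.5, 7.5)))

    def test_empty_mask_rejected(self):
        vol = np.ones((6, 6, 6, 10))
        with pytest.raises(ValueError, match="no voxels"):
            seed_timecourse(vol, np.diag([3.0, 3, 3, 1]),
                            SeedSpec((500.0, 500.0, 500.0), radius_mm=1.0))


class TestFrameSelection:
    def test_rule_application(self):
        z = np.array([-1.0, 0.5, 1.5, 2.0, -0.5])
        assert select_frames(z).tolist() == [2, 3]

    def test_threshold_minus_inf_selects_all(self):
        z = np.array([-1.0, 0.5, 1.5])
        assert select_frames(z, threshold=-np.inf).size == 3

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 1, 200)
        low = set(select_frames(z, 0.5).tolist())
        high = set(select_frames(z, 1.5).tolist())
        assert high <= low

    def test_two_sided_includes_negative_tail(self):
        z = np.array([-2.0, 0.0, 2.0])
        assert select_frames(z, 1.0, two_sided=True).tolist() == [0, 2]

    def test_none_selected_raises(self):
        with pytest.raises(ValueError, match="threshold"):
            select_frames(np.zeros(5), 1.0)


class TestConsensus:
    def test_planted_partition_recovers_k(self):
        frames, _, _ = planted_frames(40, n_clusters=4, noise=0.2, seed=3)
        k, stats = choose_k_consensus(frames, range(2, 7), n_subsamples=20, seed=0)
        assert k == 4
        assert stats[4] > 0.95

    def test_two_families_perfectly_stable_at_2(self):
        frames, _, _ = planted_frames(30, n_clusters=2, noise=0.05, seed=4)
        k, stats = choose_k_consensus(frames, range(2, 5), n_subsamples=15, seed=0)
        assert k == 2
        assert stats[2] == pytest.approx(1.0)

    def test_identical_frames_degenerate(self):
        frames = np.ones((50, 20))
        with pytest.warns(UserWarning, match="k=1"):
            k, _ = choose_k_consensus(frames, range(2, 4), n_subsamples=5)
        assert k == 1

    def test_deterministic_under_seed(self):
        frames, _, _ = planted_frames(20, n_clusters=3, seed=5)
        r1 = choose_k_consensus(frames, range(2, 5), n_subsamples=10, seed=9)
        r2 = choose_k_consensus(frames, range(2, 5), n_subsamples=10, seed=9)
        assert r1 == r2


class TestFitCaps:
    def test_recovers_planted_partition(self):
        frames, labels, _ = planted_frames(50, n_clusters=2, noise=0.0, seed=6)
        sel = np.arange(frames.shape[0])
        caps, seq = fit_caps(frames, 2, sel, frames.shape[0],
                             grid_shape=(60,), seed=0)
        # agreement up to permutation of CAP ids
        a = seq.labels[labels == 0]
        b = seq.labels[labels == 1]
        assert len(set(a.tolist())) == 1 and len(set(b.tolist())) == 1
        assert a[0] != b[0]

    def test_cap_map_is_mean_of_members(self):
        frames, _, _ = planted_frames(30, n_clusters=2, noise=0.3, seed=7)
        sel = np.arange(frames.shape[0])
        caps, seq = fit_caps(frames, 2, sel, frames.shape[0],
                             grid_shape=(60,), seed=0)
        for cap in (1, 2):
            members = frames[seq.labels[sel] == cap]
            assert np.allclose(caps.maps[cap - 1], members.mean(axis=0))

    def test_unselected_frames_are_cap0(self):
        frames, _, _ = planted_frames(10, n_clusters=2, seed=8)
        sel = np.arange(5, frames.shape[0] + 5)
        caps, seq = fit_caps(frames, 2, sel, frames.shape[0] + 10,
                             grid_shape=(60,), seed=0)
        assert np.all(seq.labels[:5] == 0)
        assert np.all(seq.labels[-5:] == 0)

    def test_identical_frames_k1(self):
        frames = np.tile(np.arange(20.0), (15, 1))
        caps, _ = fit_caps(frames, 1, np.arange(15), 15, grid_shape=(20,), seed=0)
        assert np.allclose(caps.maps[0], frames[0])


class TestTemplates:
    def _caps(self):
        frames, _, _ = planted_frames(30, n_clusters=2, noise=0.2, seed=9)
        caps, _ = fit_caps(frames, 2, np.arange(60), 60, grid_shape=(60,), seed=0)
        return caps

    def test_identical_template_r1(self):
        caps = self._caps()
        matches = match_templates(caps, {"self": caps.z_maps[0]})
        assert matches[0]["r"] == pytest.approx(1.0)
        assert matches[0]["accepted"]

    def test_random_template_rejected(self):
        caps = self._caps()
        rng = np.random.default_rng(10)
        matches = match_templates(caps, {"noise": rng.normal(0, 1, 60)})
        assert abs(matches[0]["r"]) < 0.3
        assert not matches[0]["accepted"]

    def test_threshold_is_strict(self):
        caps = self._caps()
        tmpl = caps.z_maps[0] + np.random.default_rng(11).normal(0, 3, 60)
        r = float(np.corrcoef(caps.z_maps[0], tmpl)[0, 1])
        matches = match_templates(caps, {"t": tmpl}, r_threshold=r)
        assert not matches[0]["accepted"]

    def test_grid_mismatch_raises(self):
        caps = self._caps()
        with pytest.raises(ValueError, match="resample"):
            match_templates(caps, {"bad": np.zeros(61)})


class TestTemporalMetrics:
    def test_hand_enumeration(self):
        seq = StateSequence(labels=np.array([0, 1, 1, 1, 0, 1]), k=1)
        m = {x.cap: x for x in temporal_metrics(seq)}
        assert m[1].occurrences_pct == pytest.approx(100 * 4 / 6)
        assert m[1].resilience == pytest.approx(2 / 5)
        assert m[1].in_degree == pytest.approx(2 / 5)
        assert m[1].out_degree == pytest.approx(1 / 5)

    def test_constant_sequence(self):
        seq = StateSequence(labels=np.ones(20, dtype=int), k=1)
        m = {x.cap: x for x in temporal_metrics(seq)}
        assert m[1].occurrences_pct == 100.0
        assert m[1].resilience == 1.0
        assert m[1].in_degree == 0.0
        assert m[1].out_degree == 0.0
        assert m[1].betweenness == 0.0

    def test_conservation_identities(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            k = int(rng.integers(1, 5))
            seq = StateSequence(labels=rng.integers(0, k + 1, 100), k=k)
            ms = temporal_metrics(seq)
            assert sum(m.occurrences_pct for m in ms) == pytest.approx(100.0)
            assert sum(m.resilience + m.in_degree for m in ms) == pytest.approx(1.0)
            assert sum(m.resilience + m.out_degree for m in ms) == pytest.approx(1.0)


class TestPersistence:
    def test_window_example(self):
        seq = StateSequence(labels=np.array([1, 1, 0, 1]), k=1)
        p = persistence_curve(seq, 1, [(0, 4)])
        assert p[0] == pytest.approx(1 / 2)

    def test_all_cap_window(self):
        seq = StateSequence(labels=np.ones(10, dtype=int), k=1)
        assert persistence_curve(seq, 1, [(0, 10)])[0] == 1.0

    def test_absent_cap_scores_zero(self):
        seq = StateSequence(labels=np.zeros(10, dtype=int), k=1)
        assert persistence_curve(seq, 1, [(0, 10)])[0] == 0.0

    def test_window_outside_timeline(self):
        seq = StateSequence(labels=np.zeros(10, dtype=int), k=1)
        with pytest.raises(ValueError, match="timeline"):
            persistence_curve(seq, 1, [(5, 20)])

    def test_grid_mapping_matches_window_count(self):
        from eibdyn.kinetics import window_indices
        grid = window_indices(112)
        fw = map_windows_to_frames(112, grid.windows, 224)
        assert len(fw) == 18
        assert fw[0] == (0, 120)  # 60 pairs -> 120 frames at 2 frames/pair
        assert fw[-1][1] <= 224
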