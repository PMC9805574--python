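"""Segmentation, tracking and statistics against the phantom's latent geometry."""

import numpy as np
import pytest

from fluoro4d.quantification import (
    CellTrack,
    SegmentationParams,
    area_intensity_stats,
    change_ratio_stats,
    segment_cells,
    split_medial_junctional,
    track_cells,
    zt_profiles,
)


def _apical_slice(channels, kind, t):
    return channels[kind].data[:, :, 0, t]


class TestSegmentation:
    def test_recovers_exact_cell_count(self, phantom_cfg, phantom_channels):
        lab = segment_cells(_apical_slice(phantom_channels, "ecad", 0))
        assert lab.max() == phantom_cfg.n_cells

    def test_constant_image_yields_no_cells(self):
        with pytest.warns(UserWarning, match="constant"):
            lab = segment_cells(np.full((32, 32), 2.0))
        assert lab.max() == 0

    def test_areas_match_polygon_oracle_within_5pct(self, phantom_geom, phantom_channels):
        """Watershed areas vs shoelace areas of the latent polygons, matched
        through the ground-truth label raster."""
        t = 0
        lab = segment_cells(_apical_slice(phantom_channels, "ecad", t))
        truth = phantom_geom.label_image(t)
        for c in range(phantom_geom.n_cells):
            tm = truth == c + 1
            # the segment label owning most of this cell's true pixels
            owner = np.bincount(lab[tm]).argmax()
            assert owner > 0
            seg_area = (lab == owner).sum()
            assert seg_area == pytest.approx(phantom_geom.areas[c, t], rel=0.05)

    def test_deterministic(self, phantom_channels):
        img = _apical_slice(phantom_channels, "ecad", 0)
        np.testing.assert_array_equal(segment_cells(img), segment_cells(img))


class TestTracking:
    def test_static_labels_full_tracks(self, rng):
        lab = np.zeros((32, 32), dtype=np.int32)
        lab[2:12, 2:12] = 1
        lab[16:30, 16:30] = 2
        tracks = track_cells([lab] * 4)
        assert len(tracks) == 2
        assert all(len(t) == 4 for t in tracks)

    def test_id_shuffle_does_not_break_links(self):
        lab = np.zeros((32, 32), dtype=np.int32)
        lab[2:12, 2:12] = 1
        lab[16:30, 16:30] = 2
        relabeled = np.where(lab == 1, 2, np.where(lab == 2, 1, 0))
        tracks = track_cells([lab, relabeled, lab])
        assert len(tracks) == 2
        assert all(len(t) == 3 for t in tracks)
        tr1 = next(t for t in tracks if t.labels[0] == 1)
        assert tr1.labels == [1, 2, 1]

    def test_phantom_identity_recovery(self, phantom_cfg, phantom_geom, phantom_channels):
        """>=95% of ground-truth identities survive tracking over the movie
        (segmented labels matched against the latent label raster)."""
        T = phantom_cfg.grid[3]
        labs = [segment_cells(_apical_slice(phantom_channels, "ecad", t)) for t in range(T)]
        tracks = track_cells(labs)
        full = [t for t in tracks if len(t) == T]
        correct = 0
        for tr in full:
            truth_ids = []
            for t, lbl in zip(tr.frames, tr.labels):
                truth = phantom_geom.label_image(t)
                truth_ids.append(np.bincount(truth[labs[t] == lbl]).argmax())
            correct += len(set(truth_ids)) == 1
        assert len(full) >= 0.95 * phantom_cfg.n_cells
        assert correct >= 0.95 * len(full)


class TestMedialJunctional:
    def test_partition_exact(self, phantom_channels):
        lab = segment_cells(_apical_slice(phantom_channels, "ecad", 0))
        medial, junctional, flagged = split_medial_junctional(lab, width_px=3)
        for c in range(1, lab.max() + 1):
            cell = lab == c
            med, jun = medial == c, junctional == c
            assert not (med & jun).any()
            np.testing.assert_array_equal(med | jun, cell)

    def test_intensity_decomposition_conserves_total(self, phantom_channels):
        lab = segment_cells(_apical_slice(phantom_channels, "ecad", 0))
        myo = _apical_slice(phantom_channels, "myo", 0).astype(np.float64)
        medial, junctional, _ = split_medial_junctional(lab, width_px=3)
        for c in range(1, lab.max() + 1):
            total = myo[lab == c].sum()
            parts = myo[medial == c].sum() + myo[junctional == c].sum()
            assert parts == pytest.approx(total, rel=1e-12)

    def test_width_zero_rejected(self):
        with pytest.raises(ValueError):
            split_medial_junctional(np.ones((8, 8), dtype=int), width_px=0)

    def test_activated_cells_have_brighter_medial_pool(self, phantom_geom, phantom_cfg, phantom_channels):
        t = phantom_cfg.grid[3] - 1
        truth = phantom_geom.label_image(t)
        myo = phantom_channels["myo"].data[:, :, 0, t]
        medial, _, _ = split_medial_junctional(truth, width_px=3)
        act, inact = [], []
        for c in range(phantom_geom.n_cells):
            m = medial == c + 1
            if not m.any():
                continue
            (act if phantom_geom.activated[c] else inact).append(myo[m].mean())
        assert np.mean(act) > np.mean(inact)


class TestProfiles:
    def test_constant_volume_flat_profiles(self):
        from fluoro4d.io5d import View, Volume4D

        v = Volume4D(np.full((8, 8, 5, 4), 3.25), View.XYZ_T)
        np.testing.assert_allclose(zt_profiles(v, "t", 2), 3.25)
        np.testing.assert_allclose(zt_profiles(v, "z", 1), 3.25)

    def test_z_profile_slope_matches_decay(self, phantom_cfg, phantom_channels):
        prof = zt_profiles(phantom_channels["ecad"], "t", 0)
        slope = np.polyfit(np.arange(len(prof)), np.log(prof), 1)[0]
        assert slope == pytest.approx(-phantom_cfg.z_decay, rel=0.05)

    def test_t_profile_of_activated_cells_non_decreasing(self, phantom_geom, phantom_cfg, phantom_channels):
        mask = np.isin(phantom_geom.label_image(0), np.nonzero(phantom_geom.activated)[0] + 1)
        prof = zt_profiles(phantom_channels["myo"], "z", 0, mask=mask)
        assert (np.diff(prof) >= -1e-6).all()

    def test_empty_mask_rejected(self, phantom_channels):
        with pytest.raises(ValueError, match="mask"):
            zt_profiles(phantom_channels["myo"], "z", 0, mask=np.zeros((96, 96), bool))


class TestAreaIntensityStats:
    def test_equal_intensities_flat(self, rng):
        areas = rng.uniform(50, 200, size=20)
        stats = area_intensity_stats(areas, np.full(20, 5.0), n_bins=4)
        assert stats["spearman_rho"] == 0.0
        assert np.allclose(stats["bin_mean_intensity"], 5.0)

    def test_equal_count_bins(self, rng):
        stats = area_intensity_stats(rng.uniform(1, 9, 23), rng.uniform(0, 1, 23), n_bins=5)
        counts = stats["bin_counts"]
        assert counts.sum() == 23 and counts.max() - counts.min() <= 1

    def test_phantom_negative_correlation(self, phantom_geom, phantom_cfg, phantom_channels):
        myo = phantom_channels["myo"]
        areas, intens = [], []
        for t in range(phantom_cfg.grid[3]):
            truth = phantom_geom.label_image(t)
            img = myo.data[:, :, 0, t]
            for c in range(phantom_geom.n_cells):
                areas.append(phantom_geom.areas[c, t])
                intens.append(img[truth == c + 1].mean())
        stats = area_intensity_stats(areas, intens)
        assert stats["spearman_rho"] < 0

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="3"):
            area_intensity_stats([1, 2], [3, 4])


class TestChangeRatio:
    def test_hand_built_track_passes(self):
        tr = CellTrack(frames=[0, 1, 2, 3], labels=[1] * 4, areas=[100, 95, 90, 85], intensities=[1.0, 1.05, 1.1, 1.15])
        frac, n = change_ratio_stats([tr], window_frames=3, intensity_thresh=0.10)
        assert (frac, n) == (1.0, 1)  # 15% rise > 10% threshold

    def test_static_phantom_no_qualifying_cells(self):
        tr = CellTrack(frames=[0, 1, 2, 3], labels=[1] * 4, areas=[100] * 4, intensities=[1.0] * 4)
        frac, n = change_ratio_stats([tr], window_frames=3)
        assert (frac, n) == (0.0, 0)

    def test_fraction_increases_with_shrink_rate(self):
        """Computed from latent geometry over 20 seeds: faster contraction
        means more shrinking cells pass the 10% intensity-rise criterion."""
        from fluoro4d.phantom import PhantomConfig, render_channel, sample_geometry

        def fraction(shrink, seed):
            cfg = PhantomConfig(grid=(48, 48, 4, 5), n_cells=9, shrink_rate=shrink, noise=(0.0, 0.0), seed=seed)
            g = sample_geometry(cfg)
            myo = render_channel(g, "myo", cfg)
            tracks = []
            for c in range(g.n_cells):
                tr = CellTrack()
                for t in range(g.n_frames):
                    m = g.label_image(t) == c + 1
                    tr.frames.append(t)
                    tr.labels.append(c + 1)
                    tr.areas.append(g.areas[c, t])
                    tr.intensities.append(myo.data[:, :, 0, t][m].mean())
                tracks.append(tr)
            return change_ratio_stats(tracks, window_frames=3)[0]

        lo = np.mean([fraction(0.01, s) for s in range(20)])
        hi = np.mean([fraction(0.10, s) for s in range(20)])
        assert hi > 0
        assert hi > lo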