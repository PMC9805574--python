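"""DA/DI edit contracts: locality, idempotence, exact affine behaviour."""

import numpy as np
import pytest

from fluoro4d.io5d import View, Volume4D
from fluoro4d.manipulation import (
    RegionSpec,
    digital_activate,
    digital_inactivate,
    draw_boundary,
    freeze_region,
    response_map,
)


@pytest.fixture
def vol(rng):
    return Volume4D(rng.uniform(0, 1, size=(24, 24, 4, 5)).astype(np.float32), View.XYZ_T)


@pytest.fixture
def disk_mask():
    yy, xx = np.mgrid[:24, :24]
    return (xx - 12) ** 2 + (yy - 12) ** 2 < 36


class TestErase:
    def test_locality_bit_exact(self, vol, disk_mask):
        r = RegionSpec(mode="erase", mask=disk_mask, t_range=(1, 3))
        out = digital_inactivate(vol, r)
        m = np.broadcast_to(disk_mask[:, :, None], vol.data.shape[:3])
        untouched = np.ones_like(vol.data, dtype=bool)
        untouched[:, :, :, 1:3] &= ~m[..., None][..., 0:1].repeat(2, axis=3)
        np.testing.assert_array_equal(out.data[untouched], vol.data[untouched])

    def test_idempotent(self, vol, disk_mask):
        r = RegionSpec(mode="erase", mask=disk_mask)
        once = digital_inactivate(vol, r)
        twice = digital_inactivate(once, r)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_erases_to_background_level_on_phantom(self, phantom_channels, disk_mask):
        myo = phantom_channels["myo"]
        mask = np.zeros(myo.data.shape[:2], bool)
        mask[30:60, 30:60] = True
        r = RegionSpec(mode="erase", mask=mask)
        out = digital_inactivate(myo, r)
        region = mask[:, :, None, None] & np.ones(myo.data.shape, bool)
        assert out.data[region].mean() <= myo.data[region].mean()

    def test_full_slice_mask_rejected(self, vol):
        r = RegionSpec(mode="erase", mask=np.ones((24, 24), bool))
        with pytest.raises(ValueError, match="inestimable"):
            digital_inactivate(vol, r)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            RegionSpec(mode="erase", mask=np.zeros((4, 4), bool))


class TestGain:
    def test_gain_one_identity(self, vol, disk_mask):
        r = RegionSpec(mode="gain", mask=disk_mask, gain=1.0)
        out = digital_activate(vol, r)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_gain_two_doubles_contrast_exactly(self, vol, disk_mask):
        r = RegionSpec(mode="gain", mask=disk_mask, gain=2.0)
        out = digital_activate(vol, r)
        for t in range(vol.data.shape[3]):
            for z in range(vol.data.shape[2]):
                bg = np.median(vol.data[:, :, z, t][~disk_mask])
                expect = bg + 2.0 * (vol.data[:, :, z, t][disk_mask] - bg)
                np.testing.assert_allclose(out.data[:, :, z, t][disk_mask], expect, rtol=1e-6, atol=1e-6)

    def test_locality(self, vol, disk_mask):
        r = RegionSpec(mode="gain", mask=disk_mask, gain=3.0)
        out = digital_activate(vol, r)
        np.testing.assert_array_equal(out.data[~disk_mask], vol.data[~disk_mask])

    def test_clip_bounds_respected(self, vol, disk_mask):
        r = RegionSpec(mode="gain", mask=disk_mask, gain=50.0)
        out = digital_activate(vol, r, clip=(-1, 1))
        assert out.data.max() <= 1.0 and out.data.min() >= -1.0

    def test_nonpositive_gain_rejected(self, disk_mask):
        with pytest.raises(ValueError, match="gain"):
            RegionSpec(mode="gain", mask=disk_mask, gain=0.0)


class TestFreeze:
    def test_full_domain_freeze_gives_static_video(self, vol):
        mask = np.ones(vol.data.shape[:2], bool)
        r = RegionSpec(mode="freeze", mask=mask)
        out = freeze_region(vol, r, t0=0)
        for t in range(vol.data.shape[3]):
            np.testing.assert_array_equal(out.data[:, :, :, t], vol.data[:, :, :, 0])

    def test_in_region_temporal_variance_zero_after_t0(self, vol, disk_mask):
        r = RegionSpec(mode="freeze", mask=disk_mask)
        out = freeze_region(vol, r, t0=1)
        region = out.data[disk_mask][:, :, 1:]  # (n_px, Z, T>=t0)
        assert np.ptp(region, axis=-1).max() == 0.0

    def test_locality(self, vol, disk_mask):
        r = RegionSpec(mode="freeze", mask=disk_mask)
        out = freeze_region(vol, r, t0=0)
        np.testing.assert_array_equal(out.data[~disk_mask], vol.data[~disk_mask])


class TestDraw:
    def test_zero_length_polyline_identity(self, vol):
        r = RegionSpec(mode="draw", draw_polyline=np.zeros((1, 2)))
        out = draw_boundary(vol, r)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_drawn_pixels_not_darker(self, vol):
        r = RegionSpec(mode="draw", draw_polyline=[[2, 2], [20, 20]], draw_intensity=0.8)
        out = draw_boundary(vol, r)
        assert (out.data >= vol.data - 1e-7).all()

    def test_polyline_outside_domain_rejected(self, vol):
        r = RegionSpec(mode="draw", draw_polyline=[[2, 2], [99, 2]])
        with pytest.raises(ValueError, match="outside"):
            draw_boundary(vol, r)

    def test_drawn_line_splits_cell_downstream(self, phantom_cfg, phantom_geom, phantom_channels):
        """Drawing a membrane across the largest cell yields one extra label
        from the segmentation module — the digital cell-splitting edit."""
        from fluoro4d.quantification import segment_cells

        ecad = phantom_channels["ecad"]
        t = 0
        n_before = segment_cells(ecad.data[:, :, 0, t]).max()
        big = int(np.argmax(phantom_geom.areas[:, t]))
        poly = phantom_geom.polygon_coords(big, t)
        cen = poly.mean(axis=0)
        # a chord through the centroid, clipped to the domain
        lo = np.clip(cen - [14, 0], 0, 95)
        hi = np.clip(cen + [14, 0], 0, 95)
        r = RegionSpec(
            mode="draw",
            draw_polyline=[lo, hi],
            draw_intensity=float(ecad.data[:, :, 0, t].max()),
            draw_sigma=phantom_cfg.membrane_width_px,
        )
        edited = draw_boundary(ecad, r)
        n_after = segment_cells(edited.data[:, :, 0, t]).max()
        assert n_after == n_before + 1


class TestResponseMap:
    def test_identical_inputs_zero(self, vol):
        diff, summary = response_map(vol, vol, mask=np.ones(vol.data.shape[:2], bool))
        assert np.abs(diff.data).max() == 0.0
        assert summary["mean_abs_inside"] == 0.0

    def test_antisymmetry(self, vol, rng):
        other = vol.with_data(vol.data + rng.normal(0, 0.1, vol.data.shape).astype(np.float32))
        d1, _ = response_map(vol, other)
        d2, _ = response_map(other, vol)
        np.testing.assert_allclose(d1.data, -d2.data, atol=1e-7)

    def test_shape_mismatch_rejected(self, vol):
        other = Volume4D(np.zeros((8, 8, 4, 5)), View.XYZ_T)
        with pytest.raises(ValueError, match="mismatch"):
            response_map(vol, other)

    def test_summary_localizes_edit(self, vol, disk_mask):
        r = RegionSpec(mode="gain", mask=disk_mask, gain=2.0)
        out = digital_activate(vol, r)
        _, summary = response_map(vol, out, mask=disk_mask)
        assert summary["mean_abs_inside"] > summary["mean_abs_outside"] == 0.0
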