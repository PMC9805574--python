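"""Frechet-distance numerics and multi-view FID behaviour."""

import numpy as np
import pytest

from fluoro4d.evaluation import (
    RandomProjectionEmbedding,
    fid_2d,
    fid_volumetric,
    frechet_distance,
    frechet_distance_sqrtm,
)
from fluoro4d.io5d import View, Volume4D
from fluoro4d.phantom import PhantomConfig, make_dataset


def _spd(rng, d):
    a = rng.normal(size=(d, d))
    return a @ a.T + d * np.eye(d)


class TestFrechetDistance:
    def test_identical_gaussians_zero(self, rng):
        mu = rng.normal(size=4)
        cov = _spd(rng, 4)
        assert frechet_distance(mu, cov, mu, cov) == pytest.approx(0.0, abs=1e-8)

    def test_mean_shift_closed_form(self):
        # equal identity covariances: distance reduces to |d_mu|^2 = 3^2+4^2
        assert frechet_distance([0, 0], np.eye(2), [3, 4], np.eye(2)) == pytest.approx(25.0, abs=1e-8)

    def test_commuting_covariances_closed_form(self):
        # S1=4I, S2=I: Tr(4I + I - 2*sqrt(4I)) = Tr(I) = 2
        got = frechet_distance([0, 0], 4 * np.eye(2), [0, 0], np.eye(2))
        assert got == pytest.approx(2.0, abs=1e-8)
        # brute-force eigendecomposition of S1 S2 agrees
        w = np.linalg.eigvals(4 * np.eye(2) @ np.eye(2))
        oracle = 4 * 2 + 1 * 2 - 2 * np.sum(np.sqrt(w.real))
        assert got == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("dim", [2, 5, 16])
    def test_matches_schur_oracle_on_random_spd(self, dim, rng):
        for _ in range(10):
            mu1, mu2 = rng.normal(size=dim), rng.normal(size=dim)
            c1, c2 = _spd(rng, dim), _spd(rng, dim)
            a = frechet_distance(mu1, c1, mu2, c2)
            b = frechet_distance_sqrtm(mu1, c1, mu2, c2)
            assert a == pytest.approx(b, abs=1e-8 * max(1, abs(b)))

    def test_symmetry(self, rng):
        mu1, mu2 = rng.normal(size=6), rng.normal(size=6)
        c1, c2 = _spd(rng, 6), _spd(rng, 6)
        assert frechet_distance(mu1, c1, mu2, c2) == pytest.approx(
            frechet_distance(mu2, c2, mu1, c1), rel=1e-9
        )

    def test_scale_covariance_of_mean_term(self, rng):
        mu1, mu2 = rng.normal(size=3), rng.normal(size=3)
        base = frechet_distance(mu1, np.zeros((3, 3)), mu2, np.zeros((3, 3)))
        scaled = frechet_distance(3 * mu1, np.zeros((3, 3)), 3 * mu2, np.zeros((3, 3)))
        assert scaled == pytest.approx(9 * base, rel=1e-9)

    def test_rejects_asymmetric_covariance(self, rng):
        c = _spd(rng, 3)
        c[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            frechet_distance(np.zeros(3), c, np.zeros(3), np.eye(3))


class TestEmbedding:
    def test_deterministic_and_fixed_dim(self, rng):
        emb = RandomProjectionEmbedding(dim=8, input_shape=(16, 16), seed=3)
        batch = [rng.uniform(size=(20, 24)) for _ in range(5)]
        v1, v2 = emb.embed(batch), emb.embed(batch)
        assert v1.shape == (5, 8)
        np.testing.assert_array_equal(v1, v2)


def _vols(rng, n, shape=(16, 16, 4, 5)):
    return [Volume4D(rng.uniform(size=shape).astype(np.float32), View.XYZ_T) for _ in range(n)]


class TestFID2D:
    def test_identical_sets_zero(self, rng):
        vols = _vols(rng, 3)
        emb = RandomProjectionEmbedding(dim=6, input_shape=(16, 16), seed=0)
        res = fid_2d(vols, vols, emb)
        assert res.value == pytest.approx(0.0, abs=1e-6)
        assert res.view == "XY"

    def test_slice_count(self, rng):
        vols = _vols(rng, 1, shape=(8, 8, 16, 10))
        emb = RandomProjectionEmbedding(dim=4, input_shape=(8, 8), seed=0)
        res = fid_2d(vols, vols, emb)
        assert res.n_real == 160  # 16 z * 10 t

    def test_separates_phantom_families(self):
        """Different cluster densities are farther apart than two seeds of the
        same density, consistently over repetitions."""
        emb = RandomProjectionEmbedding(dim=8, input_shape=(24, 24), seed=0)
        wins = 0
        for rep in range(5):
            kw = dict(grid=(48, 48, 4, 3), n_cells=9, noise=(0.0, 0.0))
            same_a, _ = make_dataset(PhantomConfig(seed=100 + rep, **kw), 2, "ecad", "myo")
            same_b, _ = make_dataset(PhantomConfig(seed=200 + rep, **kw), 2, "ecad", "myo")
            kw2 = dict(kw, cluster_rate=1.5)
            far, _ = make_dataset(PhantomConfig(seed=300 + rep, **kw2), 2, "ecad", "myo")
            ecad_a = [p[0] for p in same_a]
            ecad_b = [p[0] for p in same_b]
            ecad_far = [p[0] for p in far]
            near = fid_2d(ecad_a, ecad_b, emb).value
            apart = fid_2d(ecad_a, ecad_far, emb).value
            wins += apart > near
        assert wins >= 4

    def test_empty_set_rejected(self, rng):
        emb = RandomProjectionEmbedding(dim=4, input_shape=(8, 8), seed=0)
        with pytest.raises(ValueError, match="empty"):
            fid_2d([], _vols(rng, 1), emb)


class TestFIDVolumetric:
    def test_identical_zero_and_counts(self, rng):
        vols = _vols(rng, 1, shape=(8, 8, 16, 10))
        emb = RandomProjectionEmbedding(dim=4, input_shape=(8, 8, 8), seed=0)
        res_t = fid_volumetric(vols, vols, emb, axis="T")
        res_z = fid_volumetric(vols, vols, emb, axis="Z")
        assert res_t.value == pytest.approx(0.0, abs=1e-6)
        assert res_t.n_real == 10 and res_t.view == "XYZ"  # one XYZ sample per t
        assert res_z.n_real == 16 and res_z.view == "XYT"  # one XYT sample per z

    def test_t_shuffle_hurts_temporal_view_only(self):
        """Temporally shuffled predictions score worse in the XYT view, while
        the per-timepoint XYZ view cannot see the permutation.

        Predictions are emulated as second noise realizations of the same
        tissue geometry (per-frame content right, temporal order breakable),
        over 5 independent repetitions."""
        from fluoro4d.phantom import render_channel, sample_geometry

        kw = dict(grid=(32, 32, 4, 6), n_cells=9, noise=(50.0, 0.01))
        rng = np.random.default_rng(0)
        emb = RandomProjectionEmbedding(dim=6, input_shape=(16, 16, 4), seed=0)
        for rep in range(5):
            cfgs = [PhantomConfig(seed=10 * rep + i, **kw) for i in range(3)]
            geoms = [sample_geometry(c) for c in cfgs]
            reals = [render_channel(g, "myo", c) for g, c in zip(geoms, cfgs)]
            fakes = [
                render_channel(g, "myo", c, noise_seed=777 + i)
                for i, (g, c) in enumerate(zip(geoms, cfgs))
            ]
            shuffled = []
            for v in fakes:
                perm = rng.permutation(v.data.shape[3])
                while (perm == np.arange(len(perm))).all():
                    perm = rng.permutation(v.data.shape[3])
                shuffled.append(v.with_data(v.data[:, :, :, perm]))
            fid_z_plain = fid_volumetric(reals, fakes, emb, axis="Z").value
            fid_z_shuf = fid_volumetric(reals, shuffled, emb, axis="Z").value
            assert fid_z_shuf > fid_z_plain
            # per-frame content is identical up to ordering, and axis=T pools
            # per-timepoint volumes as an unordered set: score unchanged
            fid_t_plain = fid_volumetric(reals, fakes, emb, axis="T").value
            fid_t_shuf = fid_volumetric(reals, shuffled, emb, axis="T").value
            assert fid_t_shuf == pytest.approx(fid_t_plain, rel=1e-9)
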