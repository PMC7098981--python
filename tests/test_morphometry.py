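import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from femhead.errors import EmptyRegionError
from femhead.head_geometry import SphereFit, partition
from femhead.morphometry import (bone_volume_fraction,
                                 connectivity_density, degree_of_anisotropy,
                                 local_thickness, plate_metrics,
                                 summarize_regions, trabecular_number)
from femhead.phantom import rod_lattice_fraction
from femhead.preprocess import FabricTensor
from femhead.volume_io import BinaryVolume

from conftest import digital_ball


def brute_force_thickness(phase: np.ndarray) -> np.ndarray:
    """Independent oracle: exhaustive largest-containing-sphere search.

    For every phase voxel the inscribed-sphere radius is the pairwise
    distance to the nearest background voxel centre minus half a voxel;
    the thickness at p is twice the largest such radius over all spheres
    containing p.  Pure pairwise distances — no EDT, no painting.
    """
    P = np.argwhere(phase).astype(float)
    B = np.argwhere(~phase).astype(float)
    r = np.empty(len(P))
    for i in range(0, len(P), 1024):
        r[i : i + 1024] = cdist(P[i : i + 1024], B).min(axis=1) - 0.5
    th = np.zeros(len(P))
    for i in range(0, len(P), 1024):
        dd = cdist(P[i : i + 1024], P)
        cover = dd <= r[None, :] + 1e-9
        th[i : i + 1024] = 2 * np.where(cover, r[None, :], -np.inf).max(axis=1)
    out = np.zeros(phase.shape, np.float32)
    out[tuple(P.astype(int).T)] = th
    return out


class TestBVTV:
    def test_full_voi(self):
        seg = BinaryVolume(np.ones((5, 5, 5), bool), 60.0)
        assert bone_volume_fraction(seg, np.ones((5, 5, 5), bool)) == 100.0

    def test_checkerboard_is_half(self):
        idx = np.indices((6, 6, 6)).sum(axis=0)
        seg = BinaryVolume(idx % 2 == 0, 60.0)
        assert bone_volume_fraction(seg, np.ones((6, 6, 6), bool)) == 50.0

    def test_rod_lattice_matches_analytic_fraction(self):
        """Digital rod lattice (pitch 20, radius 4) vs the analytic
        overlap-corrected volume fraction."""
        from femhead.phantom import LatticeSpec, _lattice_mask

        n, vs = 120, 60.0
        ax = (np.arange(n) - n / 2) * vs
        q = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        lat = LatticeSpec(pitch_um=20 * vs, element_thickness_um=8 * vs)
        mask = _lattice_mask(q, lat)
        seg = BinaryVolume(mask, vs)
        measured = bone_volume_fraction(seg, np.ones(mask.shape, bool))
        expected = 100 * rod_lattice_fraction(20 * vs, 8 * vs)
        assert measured == pytest.approx(expected, rel=0.03)

    def test_empty_voi_raises(self):
        seg = BinaryVolume(np.ones((4, 4, 4), bool), 60.0)
        with pytest.raises(EmptyRegionError):
            bone_volume_fraction(seg, np.zeros((4, 4, 4), bool))


class TestLocalThickness:
    def test_slab_reads_its_thickness(self):
        data = np.zeros((9, 9, 11), bool)
        data[:, :, 2:9] = True  # 7-voxel slab
        th = local_thickness(BinaryVolume(data, 60.0), "bone")
        vals = th.values[np.isfinite(th.values)]
        assert np.all(np.abs(vals - 7 * 60.0) <= 60.0)

    def test_ball_max_thickness_is_diameter(self):
        ball = digital_ball(10, margin=3, voxel_size=60.0)
        th = local_thickness(ball, "bone")
        assert np.nanmax(th.values) == pytest.approx(20 * 60.0, abs=60.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_blob_equals_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        blob = ndi.gaussian_filter(rng.standard_normal((22, 22, 22)), 2.2) > 0.02
        blob[[0, -1], :, :] = blob[:, [0, -1], :] = blob[:, :, [0, -1]] = False
        if not blob.any():
            pytest.skip("degenerate draw")
        th = local_thickness(BinaryVolume(blob, 1.0), "bone")
        oracle = brute_force_thickness(blob)
        got = np.where(np.isfinite(th.values), th.values, 0)
        np.testing.assert_allclose(got, oracle, atol=1e-5)

    def test_invariant_under_axis_permutation(self):
        rng = np.random.default_rng(3)
        blob = ndi.gaussian_filter(rng.standard_normal((18, 18, 18)), 2.0) > 0.05
        th0 = local_thickness(BinaryVolume(blob, 1.0), "bone").values
        th1 = local_thickness(BinaryVolume(blob.transpose(2, 0, 1), 1.0), "bone").values
        v0 = np.where(np.isfinite(th0), th0, 0)
        v1 = np.where(np.isfinite(th1), th1, 0)
        np.testing.assert_allclose(v0.transpose(2, 0, 1), v1, atol=1e-5)

    def test_separation_restricted_to_voi(self):
        """Background outside the analysis mask never enters Tb.Sp."""
        data = np.zeros((20, 20, 20), bool)
        data[8:12, 8:12, :] = True
        mask = BinaryVolume(data, 50.0)
        voi = np.zeros_like(data)
        voi[6:14, 6:14, :] = True
        th = local_thickness(mask, "background", voi=voi)
        assert np.all(np.isnan(th.values[~(voi & ~data)]))
        # the narrow 2-voxel gap ring inside the VOI bounds the separation
        vals = th.values[np.isfinite(th.values)]
        assert vals.max() <= 8 * 50.0

    def test_empty_phase_raises(self):
        with pytest.raises(EmptyRegionError):
            local_thickness(BinaryVolume(np.zeros((5, 5, 5), bool), 60.0), "bone")


class TestTrabecularNumber:
    @pytest.mark.parametrize("bvtv,th_um,expected", [(100.0, 1000.0, 1.0),
                                                     (20.0, 200.0, 1.0),
                                                     (30.0, 150.0, 2.0)])
    def test_arithmetic(self, bvtv, th_um, expected):
        assert trabecular_number(bvtv, th_um) == pytest.approx(expected)

    def test_zero_thickness_returns_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(trabecular_number(50.0, 0.0))

    def test_identity_with_bvtv_and_thickness(self):
        """Tb.N × Tb.Th(mm) = BV/TV/100 holds exactly by construction."""
        tbn = trabecular_number(37.5, 240.0)
        assert tbn * 0.240 == pytest.approx(0.375)


class TestConnectivityDensity:
    def test_solid_ball_has_no_handles(self):
        ball = digital_ball(8, margin=2, voxel_size=100.0)
        voi = np.ones(ball.shape, bool)
        assert connectivity_density(ball, BinaryVolume(voi, 100.0)) == 0.0

    def test_torus_one_handle_per_unit_volume(self):
        n, vox = 21, 100.0
        c = n // 2
        xx, yy, zz = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        tor = ((np.sqrt((xx - c) ** 2 + (yy - c) ** 2) - 6) ** 2 + (zz - c) ** 2) <= 6
        voi = BinaryVolume(np.ones(tor.shape, bool), vox)
        expected = 1.0 / voi.volume_mm3()
        assert connectivity_density(BinaryVolume(tor, vox), voi) == pytest.approx(expected)

    @pytest.mark.parametrize("n_rungs", [2, 4, 7])
    def test_ladder_has_rungs_minus_one_loops(self, n_rungs):
        """A ladder with n rungs embeds n−1 independent loops (β1)."""
        length = 6 * (n_rungs - 1) + 3
        data = np.zeros((length, 9, 9), bool)
        data[:, 2, 4] = True  # rail 1
        data[:, 6, 4] = True  # rail 2
        for k in range(n_rungs):
            data[6 * k + 1, 2:7, 4] = True
        vox = 100.0
        voi = BinaryVolume(np.ones(data.shape, bool), vox)
        got = connectivity_density(BinaryVolume(data, vox), voi)
        assert got == pytest.approx((n_rungs - 1) / voi.volume_mm3())

    def test_disjoint_union_additive_without_purification(self):
        n, vox = 23, 100.0
        xx, yy, zz = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        t1 = ((np.sqrt((xx - 6) ** 2 + (yy - 6) ** 2) - 4) ** 2 + (zz - 6) ** 2) <= 3
        t2 = ((np.sqrt((xx - 15) ** 2 + (yy - 15) ** 2) - 4) ** 2 + (zz - 15) ** 2) <= 3
        voi = BinaryVolume(np.ones((n, n, n), bool), vox)
        both = connectivity_density(BinaryVolume(t1 | t2, vox), voi, purify=False)
        assert both == pytest.approx(
            connectivity_density(BinaryVolume(t1, vox), voi, purify=False)
            + connectivity_density(BinaryVolume(t2, vox), voi, purify=False)
            - 1.0 / voi.volume_mm3()  # (1−χ) counts the extra component
        )

    def test_empty_bone_warns_and_returns_zero(self):
        seg = BinaryVolume(np.zeros((6, 6, 6), bool), 100.0)
        with pytest.warns(UserWarning):
            assert connectivity_density(seg, BinaryVolume(np.ones((6, 6, 6), bool), 100.0)) == 0.0


class TestDegreeOfAnisotropy:
    def _fabric(self, lams):
        return FabricTensor(tensor=np.diag(1 / np.array(lams) ** 2),
                            eigenvalues=np.array(lams), eigenvectors=np.eye(3))

    def test_isotropy_gives_zero(self):
        assert degree_of_anisotropy(self._fabric([2.0, 2.0, 2.0])) == 0.0

    def test_half_ratio(self):
        assert degree_of_anisotropy(self._fabric([2.0, 1.5, 1.0])) == pytest.approx(0.5)

    def test_oriented_rods_more_anisotropic_than_spheres(self):
        from femhead.preprocess import estimate_fabric
        from test_preprocess import _rod_lattice, _sphere_packing

        da_rods = degree_of_anisotropy(estimate_fabric(_rod_lattice(n=48), n_directions=64, seed=0))
        da_iso = degree_of_anisotropy(estimate_fabric(_sphere_packing(n=48), n_directions=64, seed=0))
        assert da_rods > da_iso


class TestPlateMetrics:
    def _shell(self, vox=100.0, r_out=20, t=5, margin=3):
        n = 2 * (r_out + margin) + 1
        c = n // 2
        ax = np.arange(n)
        d2 = ((ax - c) ** 2)[:, None, None] + ((ax - c) ** 2)[None, :, None] \
            + ((ax - c) ** 2)[None, None, :]
        shell = (d2 <= r_out**2) & (d2 > (r_out - t) ** 2)
        sphere = SphereFit(center=np.full(3, c * vox), radius=r_out * vox, rms_residual=0.0)
        trab = BinaryVolume(d2 <= (r_out - t) ** 2, vox)
        labels = partition(trab, SphereFit(center=sphere.center,
                                           radius=(r_out - t) * vox, rms_residual=0.0))
        return BinaryVolume(shell, vox), labels

    def test_dense_shell_zero_porosity_thickness_matches(self):
        cort, labels = self._shell()
        seg = BinaryVolume(cort.data.copy(), cort.voxel_size)
        out = plate_metrics(cort, seg, labels)
        overall = out[out["octant"] == "overall"].iloc[0]
        assert overall["Pl_Po"] == 0.0
        assert overall["Pl_Th"] == pytest.approx(5 * 100.0, abs=100.0)

    def test_punched_porosity_recovered(self):
        cort, labels = self._shell()
        rng = np.random.default_rng(5)
        seg_data = cort.data & (rng.random(cort.shape) >= 0.10)
        out = plate_metrics(cort, BinaryVolume(seg_data, cort.voxel_size), labels)
        overall = out[out["octant"] == "overall"].iloc[0]
        assert overall["Pl_Po"] == pytest.approx(10.0, abs=1.0)

    def test_empty_mask_gives_missing_values(self):
        cort, labels = self._shell()
        empty = BinaryVolume(np.zeros(cort.shape, bool), cort.voxel_size)
        out = plate_metrics(empty, cort, labels)
        assert out["Pl_Th"].isna().all()
        assert len(out) == 9  # 8 octants + overall


class TestSummarizeRegions:
    @pytest.fixture(scope="class")
    def uniform_summary(self, small_phantom):
        _, _, truth = small_phantom
        seg = truth.bone
        labels = partition(truth.trabecular, truth.trabecular_sphere)
        trab_bone = BinaryVolume(seg.data & truth.trabecular.data, seg.voxel_size)
        th_bone = local_thickness(trab_bone, "bone")
        th_bg = local_thickness(seg, "background", voi=truth.trabecular)
        return summarize_regions(seg, labels, th_bone, th_bg), labels

    def test_uniform_structure_homogeneous_bvtv(self):
        """A statistically uniform isotropic structure yields nearly equal
        BV/TV in all 32 sub-regions (no spatial bias in the partition)."""
        n, vox = 121, 100.0
        bone = np.indices((n, n, n)).sum(axis=0) % 2 == 0  # voxel-scale uniform
        c = n // 2
        ax = np.arange(n)
        d2 = ((ax - c) ** 2)[:, None, None] + ((ax - c) ** 2)[None, :, None] \
            + ((ax - c) ** 2)[None, None, :]
        trab = BinaryVolume(d2 <= 55**2, vox)
        labels = partition(trab, SphereFit(center=np.full(3, c * vox),
                                           radius=55 * vox, rms_residual=0.0))
        seg = BinaryVolume(bone, vox)
        vals = [bone_volume_fraction(seg, np.isin(labels.labels, list(r["labels"])))
                for _, r in labels.sub_table.iterrows()]
        assert max(vals) - min(vals) <= 3.0

    def test_macro_bvtv_is_voxel_weighted_mean_of_subs(self, uniform_summary):
        table, labels = uniform_summary
        for layer in ("MTB", "STB"):
            for band in ("inf", "sup"):
                macro = table[(table["kind"] == "macro") & (table["layer"] == layer)
                              & (table["band"] == band)].iloc[0]
                subs = table[(table["kind"] == "sub") & (table["layer"] == layer)
                             & (table["band"] == band)]
                weighted = (subs["BV_TV"] * subs["voxel_count"]).sum() / subs["voxel_count"].sum()
                assert macro["BV_TV"] == pytest.approx(weighted, abs=1e-9)

    def test_densified_octant_has_max_bvtv(self, small_phantom):
        spec, _, truth = small_phantom
        labels = partition(truth.trabecular, truth.trabecular_sphere)
        dense_voi = labels.region_mask("STB-sup-PPL")
        seg = BinaryVolume(truth.bone.data | dense_voi, truth.bone.voxel_size)
        trab_bone = BinaryVolume(seg.data & truth.trabecular.data, seg.voxel_size)
        th_bone = local_thickness(trab_bone, "bone")
        th_bg = local_thickness(seg, "background", voi=truth.trabecular)
        table = summarize_regions(seg, labels, th_bone, th_bg)
        sub = table[table["kind"] == "sub"].set_index("name")
        assert sub["BV_TV"].idxmax() == "STB-sup-PPL"
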