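"""Deformation-field machinery: integration, warping, composition, Jacobian."""

import numpy as np
import pytest

from mr4dctreg import (DisplacementField, Grid, LabelMap,
                       VelocityField, Volume, compose, integrate_svf,
                       integrate_svf_euler, jacobian_report, read_field,
                       upsample_field, warp, write_field)
from mr4dctreg.grids import BinaryMask

from conftest import smooth_svf


def const_field(grid, vec, provenance="integrated"):
    u = np.zeros((3,) + grid.shape)
    for c in range(3):
        u[c] = vec[c]
    return DisplacementField(grid, u, provenance=provenance)


class TestIntegration:
    def test_zero_svf_gives_zero_ddf(self):
        g = Grid((8, 8, 8))
        d = integrate_svf(VelocityField(g, np.zeros((3,) + g.shape)))
        assert np.all(d.u == 0.0)

    def test_constant_svf_is_translation(self):
        g = Grid((24, 24, 24))
        u = np.zeros((3,) + g.shape)
        u[2] = 1.5
        d = integrate_svf(VelocityField(g, u))
        interior = (slice(None), slice(4, -4), slice(4, -4), slice(4, -4))
        assert np.max(np.abs(d.u[interior] - u[interior])) < 1e-4

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_euler_oracle(self, seed):
        g = Grid((24, 24, 24))
        v = VelocityField(g, smooth_svf(g, seed))
        d_ss = integrate_svf(v)
        d_euler = integrate_svf_euler(v, steps=256)
        assert np.max(np.abs(d_ss.u - d_euler.u)) <= 0.1

    def test_inverse_composition_near_identity(self):
        g = Grid((24, 24, 24))
        u = smooth_svf(g, 3)
        fwd = integrate_svf(VelocityField(g, u))
        bwd = integrate_svf(VelocityField(g, -u))
        both = compose(fwd, bwd)
        interior = (slice(None), slice(4, -4), slice(4, -4), slice(4, -4))
        assert np.max(np.abs(both.u[interior])) <= 0.05

    def test_smooth_family_has_no_foldings(self):
        g = Grid((24, 24, 24))
        for seed in range(3):
            d = integrate_svf(VelocityField(g, smooth_svf(g, seed)))
            assert jacobian_report(d).foldings_fraction < 1e-3

    def test_nonfinite_velocity_rejected(self):
        g = Grid((4, 4, 4))
        u = np.zeros((3,) + g.shape)
        u[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            VelocityField(g, u)


class TestWarp:
    def test_zero_field_is_identity(self, rng):
        g = Grid((8, 8, 8))
        v = Volume(g, rng.random(g.shape))
        out = warp(v, const_field(g, (0, 0, 0)))
        assert np.allclose(out.data, v.data)

    def test_integer_translation_equals_shift(self, rng):
        g = Grid((10, 10, 10))
        v = Volume(g, rng.random(g.shape))
        out = warp(v, const_field(g, (2, 0, 0)))
        expect = np.zeros_like(v.data)
        expect[:-2] = v.data[2:]
        assert np.allclose(out.data, expect)

    def test_label_warp_conserves_id_set(self, phantom_study):
        lab = phantom_study.record.labels_ct[50]
        fld = phantom_study.gt_fields[0]
        out = warp(lab, fld, interpolation="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(lab.data))

    def test_grid_mismatch_rejected(self, rng):
        v = Volume(Grid((8, 8, 8)), rng.random((8, 8, 8)))
        fld = const_field(Grid((6, 6, 6)), (0, 0, 0))
        with pytest.raises(ValueError):
            warp(v, fld)

    def test_nearest_required_for_labels(self):
        g = Grid((4, 4, 4))
        lab = LabelMap(g, np.zeros(g.shape, np.int32))
        with pytest.raises(ValueError):
            warp(lab, const_field(g, (0, 0, 0)), interpolation="trilinear")


class TestCompose:
    def test_identity_element(self):
        g = Grid((12, 12, 12))
        u = smooth_svf(g, 5, max_mag=2.0)
        phi = DisplacementField(g, u)
        zero = const_field(g, (0, 0, 0))
        assert np.allclose(compose(zero, phi).u, phi.u, atol=1e-9)
        assert np.allclose(compose(phi, zero).u, phi.u, atol=1e-9)

    def test_translation_group(self):
        g = Grid((16, 16, 16))
        a = const_field(g, (2, 0, 0))
        b = const_field(g, (0, 3, 0))
        both = compose(a, b)
        interior = (slice(None), slice(4, -4), slice(4, -4), slice(4, -4))
        expect = np.array([2.0, 3.0, 0.0]).reshape(3, 1, 1, 1)
        assert np.max(np.abs(both.u[interior] - expect)) < 1e-9

    def test_warp_once_matches_sequential(self, phantom_study):
        ct = phantom_study.record.ct[50]
        from mr4dctreg import normalize_intensity
        img = normalize_intensity(ct)
        g = ct.grid
        phi1 = DisplacementField(g, smooth_svf(g, 11, max_mag=2.0))
        phi2 = DisplacementField(g, smooth_svf(g, 12, max_mag=2.0))
        seq = warp(warp(img, phi1), phi2)
        once = warp(img, compose(phi1, phi2))
        single_err = np.mean(np.abs(warp(img, phi1).data - img.data))
        diff = np.mean(np.abs(seq.data - once.data))
        assert diff <= 2.0 * single_err

    def test_associative_within_tolerance(self):
        g = Grid((16, 16, 16))
        f1 = DisplacementField(g, smooth_svf(g, 1, max_mag=1.5))
        f2 = DisplacementField(g, smooth_svf(g, 2, max_mag=1.5))
        f3 = DisplacementField(g, smooth_svf(g, 3, max_mag=1.5))
        left = compose(compose(f1, f2), f3)
        right = compose(f1, compose(f2, f3))
        interior = (slice(None), slice(3, -3), slice(3, -3), slice(3, -3))
        assert np.max(np.abs(left.u[interior] - right.u[interior])) < 0.1


class TestUpsample:
    def test_same_grid_identity(self):
        g = Grid((8, 8, 8), (2, 2, 2))
        phi = DisplacementField(g, smooth_svf(g, 4, max_mag=1.0))
        out = upsample_field(phi, g)
        assert np.allclose(out.u, phi.u, atol=1e-12)

    def test_physical_displacement_preserved(self):
        coarse = Grid((8, 8, 8), (2, 2, 2))
        fine = Grid((16, 16, 16), (1, 1, 1), (-0.5, -0.5, -0.5))
        phi = const_field(coarse, (1.0, 1.0, 1.0))
        out = upsample_field(phi, fine)
        assert np.allclose(out.u, 2.0, atol=1e-9)

    def test_linear_ramp_reproduced_exactly(self):
        coarse = Grid((8, 8, 8), (2, 2, 2))
        fine = Grid((16, 16, 16), (1, 1, 1), (-0.5, -0.5, -0.5))
        idx = np.stack(np.meshgrid(*[np.arange(8.0)] * 3, indexing="ij"))
        u = np.zeros((3, 8, 8, 8))
        u[2] = 0.25 * idx[2]
        out = upsample_field(DisplacementField(coarse, u), fine)
        # interior fine voxels: the ramp in physical mm is linear, so the
        # trilinear interpolation is exact there
        zmm = fine.world_coordinates()[2]
        expect_mm = 0.25 * zmm  # u_mm = 0.25 * (z_vox_coarse) * 2mm = 0.25*zmm
        interior = (slice(2, -2),) * 3
        assert np.allclose(out.u[2][interior], expect_mm[interior], atol=1e-9)

    def test_extent_mismatch_rejected(self):
        coarse = Grid((8, 8, 8), (2, 2, 2))
        wrong = Grid((16, 16, 16), (1, 1, 1), (10.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            upsample_field(const_field(coarse, (0, 0, 0)), wrong)


class TestJacobian:
    def test_zero_field_fixed_point(self):
        g = Grid((8, 8, 8))
        rep = jacobian_report(const_field(g, (0, 0, 0)))
        assert np.allclose(rep.det, 1.0)
        assert rep.foldings_fraction == 0.0
        assert rep.std_log_jacobian == 0.0

    def test_translation_det_one(self):
        g = Grid((8, 8, 8))
        rep = jacobian_report(const_field(g, (1.7, -0.3, 2.2)))
        assert np.allclose(rep.det, 1.0)
        assert rep.std_log_jacobian == 0.0

    def test_uniform_expansion_det(self):
        g = Grid((12, 12, 12))
        idx = np.stack(np.meshgrid(*[np.arange(12.0)] * 3, indexing="ij"))
        rep = jacobian_report(DisplacementField(g, 0.1 * idx))
        interior = (slice(1, -1),) * 3
        assert np.allclose(rep.det[interior], 1.331, atol=1e-6)

    def test_constructed_folding_count(self):
        g = Grid((8, 8, 8))
        u = np.zeros((3,) + g.shape)
        # flip one cell: strong negative z-gradient folds a column of voxels
        u[2, 4, 4, 3] = 3.0
        u[2, 4, 4, 5] = -3.0
        rep = jacobian_report(DisplacementField(g, u))
        brute = np.sum(rep.det <= 0.0)
        assert rep.foldings_fraction == brute / u[0].size
        assert brute > 0

    def test_masked_variant(self):
        g = Grid((8, 8, 8))
        z = np.arange(8.0).reshape(1, 1, 8)
        u = np.zeros((3,) + g.shape)
        u[2] = 0.2 * np.maximum(z - 4.0, 0.0)  # expansion only above z = 4
        phi = DisplacementField(g, u)
        m = np.zeros(g.shape, bool)
        m[:, :, :3] = True  # restrict to the identity region
        rep = jacobian_report(phi, BinaryMask(g, m))
        assert rep.foldings_fraction_masked == 0.0
        assert rep.std_log_jacobian > 0.0
        assert rep.std_log_jacobian_masked < rep.std_log_jacobian


class TestFieldIO:
    def test_roundtrip_preserves_warped_labels(self, tmp_path, phantom_study):
        from mr4dctreg import dice
        fld = phantom_study.gt_fields[0]
        lab = phantom_study.record.labels_ct[50]
        write_field(fld, tmp_path / "f.nii.gz")
        back = read_field(tmp_path / "f.nii.gz")
        assert back.provenance == "ground-truth"
        w1 = warp(lab, fld, interpolation="nearest")
        w2 = warp(lab, back, interpolation="nearest")
        for oid in lab.registry:
            d = dice(w1.organ_mask(oid), w2.organ_mask(oid))
            assert d >= 1.0 - 1e-3
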