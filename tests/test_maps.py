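"""Geometry, PSF reslicing and STEAM-box extraction."""

import numpy as np
import pytest

from mrsiquant.maps import (MRSIGeometry, SteamVoxelGeometry, VoxelMap, load_map,
                            psf_kernel, reslice_to_mrsi, save_map,
                            steam_region_mean, tissue_fractions_to_mrsi)


def dft_truncation_oracle(plane, matrix):
    """Brute-force k-space truncation by explicit DFT sums.

    Independent of the FFT-based implementation: every retained spatial
    frequency is accumulated by a literal double sum over the input grid
    and re-evaluated on the coarse output grid.
    """
    n1, n2 = plane.shape
    m1, m2 = matrix
    out = np.zeros((m1, m2), dtype=complex)
    i1 = np.arange(n1)[:, None]
    i2 = np.arange(n2)[None, :]
    for k1 in range(-(m1 // 2), m1 - m1 // 2):
        for k2 in range(-(m2 // 2), m2 - m2 // 2):
            coef = np.sum(plane * np.exp(-2j * np.pi * (k1 * i1 / n1 + k2 * i2 / n2)))
            for p1 in range(m1):
                for p2 in range(m2):
                    out[p1, p2] += coef * np.exp(2j * np.pi * (k1 * p1 / m1 + k2 * p2 / m2))
    return out.real / (n1 * n2)


def hr_map(plane, nz=1, fov=240.0):
    sp = (fov / plane.shape[0], fov / plane.shape[1], 5.0)
    vol = np.repeat(np.asarray(plane, dtype=float)[:, :, None], nz, axis=2)
    return VoxelMap.axis_aligned(vol, sp, (0.0, 0.0, 0.0), "a.u.")


GEOM8 = MRSIGeometry(fov_mm=(240.0, 240.0), matrix=(8, 8), slice_thickness_mm=12.0)


class TestReslice:
    def test_constant_field_is_fixed_point(self):
        out = reslice_to_mrsi(hr_map(np.full((32, 32), 0.7)), GEOM8)
        assert np.allclose(out.values, 0.7, atol=1e-12)

    def test_constant_fixed_point_hamming(self):
        out = reslice_to_mrsi(hr_map(np.full((32, 32), 0.7)), GEOM8, window="weighted")
        assert np.allclose(out.values, 0.7, atol=1e-12)

    @pytest.mark.parametrize("pos", [(16, 16), (5, 23)])
    def test_impulse_matches_bruteforce_dft(self, pos):
        plane = np.zeros((32, 32))
        plane[pos] = 1.0
        got = reslice_to_mrsi(hr_map(plane), GEOM8).values[:, :, 0]
        want = dft_truncation_oracle(plane, (8, 8))
        assert np.max(np.abs(got - want)) < 1e-9
        # integral (mean * area) is conserved by the truncation
        assert abs(got.mean() - plane.mean()) < 1e-12

    def test_checkerboard_matches_bruteforce_dft(self):
        n = np.arange(32)
        plane = np.cos(2 * np.pi * 4 * n[:, None] / 32) * np.cos(2 * np.pi * 4 * n[None, :] / 32)
        got = reslice_to_mrsi(hr_map(plane), GEOM8).values[:, :, 0]
        want = dft_truncation_oracle(plane, (8, 8))
        assert np.max(np.abs(got - want)) < 1e-9

    def test_nyquist_amplitude_halved(self):
        # at the MRSI Nyquist frequency only one of the +/- components is
        # retained by the asymmetric even-size window: amplitude drops to 1/2
        n = np.arange(32)
        plane = np.cos(2 * np.pi * 4 * n[:, None] / 32) * np.ones((1, 32))
        out = reslice_to_mrsi(hr_map(plane), GEOM8).values[:, :, 0]
        assert np.max(np.abs(out)) == pytest.approx(0.5, abs=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(42)
        x, y = rng.random((32, 32)), rng.random((32, 32))
        a, b = 2.3, -0.7
        lhs = reslice_to_mrsi(hr_map(a * x + b * y), GEOM8).values
        rhs = (a * reslice_to_mrsi(hr_map(x), GEOM8).values
               + b * reslice_to_mrsi(hr_map(y), GEOM8).values)
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    @pytest.mark.parametrize("window", ["uniform", "weighted"])
    def test_psf_kernel_integrates_to_one(self, window):
        ker = psf_kernel((64, 64), (20, 20), window)
        assert abs(ker.sum() - 1.0) < 1e-9

    def test_nan_propagates(self):
        plane = np.full((32, 32), 0.7)
        plane[4, 4] = np.nan
        out = reslice_to_mrsi(hr_map(plane), GEOM8).values[:, :, 0]
        assert np.isnan(out[1, 1])
        assert np.isfinite(out[6, 6])

    def test_non_overlapping_slab_errors(self):
        far = VoxelMap.axis_aligned(np.ones((32, 32, 2)), (7.5, 7.5, 5.0),
                                    (0.0, 0.0, 500.0), "a.u.")
        with pytest.raises(ValueError):
            reslice_to_mrsi(far, GEOM8)

    def test_offset_grid_resampled(self):
        # HR grid larger than and offset from the FOV: constant stays constant
        big = VoxelMap.axis_aligned(np.full((80, 80, 2), 0.7), (4.0, 4.0, 5.0),
                                    (3.0, -2.0, 0.0), "a.u.")
        out = reslice_to_mrsi(big, GEOM8)
        assert np.allclose(out.values, 0.7, atol=1e-9)


class TestTissueFractions:
    def test_pure_wm_slab(self):
        shape = (32, 32, 2)
        probs = {"wm": hr_map(np.ones((32, 32)), 2), "gm": hr_map(np.zeros((32, 32)), 2),
                 "csf": hr_map(np.zeros((32, 32)), 2)}
        fr = tissue_fractions_to_mrsi(probs, GEOM8)
        assert np.allclose(fr.f_wm, 1.0) and np.allclose(fr.f_gm, 0.0) and np.allclose(fr.f_csf, 0.0)
        assert fr.check_partition()

    def test_half_boundary_box_counting(self):
        # left half WM, right half CSF: a voxel column on the boundary is
        # checked against direct counting of HR voxel centers per MRSI box
        wm = np.zeros((32, 32))
        wm[:16] = 1.0
        probs = {"wm": hr_map(wm), "gm": hr_map(np.zeros((32, 32))),
                 "csf": hr_map(1.0 - wm)}
        fr = tissue_fractions_to_mrsi(probs, GEOM8)
        # 32/8 = 4 HR voxels per MRSI voxel; the split at HR row 16 falls on
        # an MRSI voxel border, so voxels are pure: rows 0-3 WM, 4-7 CSF
        assert np.allclose(fr.f_wm[:4], 1.0) and np.allclose(fr.f_csf[4:], 1.0)
        # an off-border split: move boundary to HR row 18 -> voxel 4 is half/half
        wm2 = np.zeros((32, 32))
        wm2[:18] = 1.0
        fr2 = tissue_fractions_to_mrsi({"wm": hr_map(wm2), "gm": hr_map(np.zeros((32, 32))),
                                        "csf": hr_map(1.0 - wm2)}, GEOM8)
        assert np.allclose(fr2.f_wm[4], 0.5) and np.allclose(fr2.f_csf[4], 0.5)

    def test_zero_csf_probability(self):
        probs = {"wm": hr_map(np.full((32, 32), 0.4)), "gm": hr_map(np.full((32, 32), 0.6)),
                 "csf": hr_map(np.zeros((32, 32)))}
        fr = tissue_fractions_to_mrsi(probs, GEOM8)
        assert np.allclose(fr.f_csf, 0.0)

    def test_out_of_range_probability_errors(self):
        probs = {"wm": hr_map(np.full((32, 32), 1.2)), "gm": hr_map(np.full((32, 32), -0.2)),
                 "csf": hr_map(np.zeros((32, 32)))}
        with pytest.raises(ValueError):
            tissue_fractions_to_mrsi(probs, GEOM8)

    def test_psf_fractions_sum_to_one(self):
        wm = np.zeros((32, 32))
        wm[:18] = 1.0
        probs = {"wm": hr_map(wm), "gm": hr_map(np.zeros((32, 32))), "csf": hr_map(1.0 - wm)}
        fr = tissue_fractions_to_mrsi(probs, GEOM8, use_psf=True)
        assert fr.check_partition(atol=1e-9)


class TestSteamRegionMean:
    def test_constant_map(self):
        m = VoxelMap.axis_aligned(np.full((20, 20, 10), 3.25), 2.5, unit="ms")
        assert steam_region_mean(m, SteamVoxelGeometry()) == pytest.approx(3.25)

    def test_two_voxel_enumeration(self):
        # grid spacing 10mm; box of 20x10x10 centered between two voxel
        # centers covers exactly the voxels valued 40 and 60
        vals = np.zeros((4, 4, 4))
        vals[1, 1, 1], vals[2, 1, 1] = 40.0, 60.0
        m = VoxelMap.axis_aligned(vals, 10.0, unit="ms")
        xs, ys, zs = m.axis_centers()
        center = ((xs[1] + xs[2]) / 2, ys[1], zs[1])
        box = SteamVoxelGeometry(center, (20.0, 10.0, 10.0))
        assert steam_region_mean(m, box) == pytest.approx(50.0)

    def test_nan_aware_mean_and_count(self):
        vals = np.full((10, 10, 10), 2.0)
        vals[5, 5, 5] = np.nan
        m = VoxelMap.axis_aligned(vals, 2.5, unit="fraction")
        box = SteamVoxelGeometry((0.0, 0.0, 0.0), (10.0, 10.0, 10.0))
        mean, n = steam_region_mean(m, box, return_count=True)
        assert mean == pytest.approx(2.0)
        assert n == 4 ** 3 - 1

    def test_empty_intersection_errors(self):
        m = VoxelMap.axis_aligned(np.ones((10, 10, 10)), 2.5, unit="ms")
        with pytest.raises(ValueError):
            steam_region_mean(m, SteamVoxelGeometry((500.0, 0.0, 0.0)))


class TestGeometryTypes:
    def test_nominal_voxel_volume(self):
        g = MRSIGeometry((240.0, 240.0), (20, 20), 12.0)
        assert g.voxel_volume_mm3 == pytest.approx(12 * 12 * 12)

    def test_interp_voxel_volume(self):
        g = MRSIGeometry((240.0, 240.0), (20, 20), 12.0, interp_matrix=(32, 32))
        assert g.interp_voxel_volume_mm3 == pytest.approx(7.5 * 7.5 * 12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            MRSIGeometry(matrix=(1, 20))
        with pytest.raises(ValueError):
            VoxelMap(np.ones((2, 2, 2)), np.zeros((4, 4)))

    def test_grid_csv_export(self, tmp_path):
        from mrsiquant.maps import grid_to_csv

        g = MRSIGeometry(matrix=(4, 4), fov_mm=(48.0, 48.0))
        m = VoxelMap(np.arange(16.0).reshape(4, 4, 1), g.affine, "a.u.")
        df = grid_to_csv(m, tmp_path / "grid.csv", value_name="sw")
        assert list(df.columns) == ["x_index", "y_index", "sw"]
        assert len(df) == 16
        assert df.set_index(["x_index", "y_index"]).loc[(2, 3), "sw"] == 11.0

    def test_nifti_roundtrip(self, tmp_path):
        m = VoxelMap.axis_aligned(np.random.default_rng(0).random((8, 8, 3)),
                                  (7.5, 7.5, 4.0), (1.0, -2.0, 3.0), "ms")
        save_map(m, tmp_path / "t1.nii.gz", sidecar={"tr_ms": 30.0})
        back = load_map(tmp_path / "t1.nii.gz")
        assert back.unit == "ms"
        assert np.allclose(back.values, m.values)
        assert np.allclose(back.affine, m.affine)
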