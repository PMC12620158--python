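"""STEAM signal correction and synthetic water-reference calibration."""

import math

import numpy as np
import pytest

from mrsiquant.maps import MRSIGeometry, SteamVoxelGeometry, VoxelMap
from mrsiquant.phantom import PhantomConfig, generate_phantom
from mrsiquant.steam import (SteamAcquisition, SteamCorrectionFactors,
                             SteamLocalValues, correct_steam_signal, k_factor,
                             steam_correction_factors, synthesize_water_reference)

GEOM = MRSIGeometry((240.0, 240.0), (20, 20), 12.0, interp_matrix=(32, 32))


def acq(amplitude=1.0, **kw):
    return SteamAcquisition(amplitude, **kw)


def loc(**kw):
    base = dict(t1_steam_ms=1000.0, t2star_steam_ms=47.0, b1_steam=1.0,
                h2o_mean_steam=0.7, t2_steam_ms=59.0)
    base.update(kw)
    return SteamLocalValues(**base)


class TestCorrectionFactors:
    def test_perfect_flip_gives_unit_b1corr(self):
        f = steam_correction_factors(acq(), loc(b1_steam=1.0), GEOM)
        assert f.b1corr == pytest.approx(1.0)

    def test_t1corr_reciprocal_of_steam_attenuation(self):
        # oracle: 1 / ((1 - exp(-9.98)) * exp(-0.01))
        f = steam_correction_factors(acq(), loc(t1_steam_ms=1000.0), GEOM)
        assert f.t1corr == pytest.approx(1.0101, abs=5e-5)

    def test_t2corr_exponential(self):
        f = steam_correction_factors(acq(), loc(t2_steam_ms=59.0), GEOM)
        assert f.t2corr == pytest.approx(math.exp(20.0 / 59.0), rel=1e-12)
        assert f.t2corr == pytest.approx(1.4035, abs=5e-5)

    def test_voxelcorr_from_reconstructed_volume(self):
        # 7.5 x 7.5 x 12 mm^3 reconstructed voxel over the 10^3 mm^3 STEAM box
        f = steam_correction_factors(acq(), loc(), GEOM)
        assert f.voxelcorr == pytest.approx(0.675, rel=1e-12)

    def test_all_factors_approach_unity_in_ideal_limit(self):
        ideal_geom = MRSIGeometry((100.0, 100.0), (10, 10), 1.0)  # 10x10x1 = 100 mm3
        a = SteamAcquisition(1.0, tr_ms=1e9, te_ms=1e-6, tm_ms=1e-6,
                             geometry=SteamVoxelGeometry(dims_mm=(10.0, 10.0, 1.0)))
        f = steam_correction_factors(a, loc(), ideal_geom)
        assert f.t1corr == pytest.approx(1.0, abs=1e-6)
        assert f.t2corr == pytest.approx(1.0, abs=1e-6)
        assert f.b1corr == pytest.approx(1.0, abs=1e-9)
        assert f.voxelcorr == pytest.approx(1.0, abs=1e-12)

    def test_relaxation_factors_undo_attenuation(self):
        f = steam_correction_factors(acq(), loc(), GEOM)
        assert f.t1corr >= 1.0 and f.t2corr >= 1.0

    def test_flip_angle_overrange_errors(self):
        with pytest.raises(ValueError):
            steam_correction_factors(acq(), loc(b1_steam=2.01), GEOM)

    def test_b1_modes_agree_at_nominal_90(self):
        f1 = steam_correction_factors(acq(), loc(b1_steam=0.9), GEOM)
        f2 = steam_correction_factors(acq(), loc(b1_steam=0.9), GEOM,
                                      b1_mode="cubed_numerator")
        assert f1.b1corr == pytest.approx(f2.b1corr, rel=1e-12)

    def test_as_printed_t1_mode_is_the_attenuation(self):
        f = steam_correction_factors(acq(), loc(), GEOM, t1_mode="as_printed")
        frec = steam_correction_factors(acq(), loc(), GEOM)
        assert f.t1corr == pytest.approx(1.0 / frec.t1corr, rel=1e-12)


class TestCorrectSignal:
    def test_identity_with_unit_factors(self):
        f = SteamCorrectionFactors(1.0, 1.0, 1.0, 1.0)
        out = correct_steam_signal(acq(1.0), loc(), GEOM, half_signal=False, factors=f)
        assert out == pytest.approx(1.0)

    def test_product_of_forced_factors(self):
        f = SteamCorrectionFactors(1.0101, 1.4035, 1.0379, 0.675)
        out = correct_steam_signal(acq(1.0), loc(), GEOM, half_signal=True, factors=f)
        assert out == pytest.approx(2 * 1.0101 * 1.4035 * 1.0379 * 0.675, rel=1e-12)
        assert out == pytest.approx(1.9864, abs=5e-4)

    def test_linearity_in_amplitude(self):
        a = correct_steam_signal(acq(1.0), loc(), GEOM)
        b = correct_steam_signal(acq(2.0), loc(), GEOM)
        assert b == pytest.approx(2 * a, rel=1e-12)


class TestSynthesizeReference:
    def grid(self, value):
        g = MRSIGeometry()
        return VoxelMap(np.full(g.matrix + (1,), value), g.affine, "fraction")

    def test_self_calibration_uniform_map(self):
        ref = synthesize_water_reference(123.4, self.grid(0.7), 0.7)
        assert np.allclose(ref.values, 123.4)

    def test_arithmetic_example(self):
        ref = synthesize_water_reference(100.0, self.grid(0.56), 0.70)
        assert np.allclose(ref.values, 80.0)

    def test_scale_invariance_of_h2o_map(self):
        h = self.grid(0.56)
        a = synthesize_water_reference(100.0, h, 0.70)
        b = synthesize_water_reference(100.0, h.with_values(3.0 * h.values), 3.0 * 0.70)
        assert np.allclose(a.values, b.values)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            synthesize_water_reference(100.0, self.grid(0.5), 0.0)


class TestKFactor:
    def _uniform_wm_truth(self, sw_scale=1.0, seed=11):
        # flat B1 (no transmit inhomogeneity): the box-mean flip-angle
        # correction is then exact and K reflects only gain mismatch
        cfg = PhantomConfig(seed=seed, wm_core_halfwidth_mm=200.0, csf_pockets=(),
                            b1_center=1.0, b1_edge_drop=0.0)
        truth = generate_phantom(cfg)
        if sw_scale != 1.0:
            truth.sw.values *= sw_scale
        return truth

    def _k(self, truth):
        from mrsiquant.steam import correct_steam_signal
        loc_ = SteamLocalValues.from_maps(truth.hr["t1"], truth.hr["t2star"],
                                          truth.hr["b1"], truth.hr["h2o"],
                                          truth.steam.geometry)
        sv_corr = correct_steam_signal(truth.steam, loc_, truth.geom)
        water_maps = {
            "t1": truth.geom.empty_map().with_values(
                np.full(truth.geom.matrix + (1,), truth.config.tissues["wm"].t1_ms)),
            "t2": truth.geom.empty_map().with_values(
                np.full(truth.geom.matrix + (1,), truth.config.tissues["wm"].t2_ms)),
        }
        return k_factor(truth.sw, truth.fractions_box, water_maps, sv_corr,
                        tr_ms=truth.sm.tr_ms, te_ms=truth.sm.te_ms)

    def test_consistent_phantom_gives_unity(self):
        # all-WM phantom, no receive-field mismatch: K = 1
        assert self._k(self._uniform_wm_truth()) == pytest.approx(1.0, abs=1e-6)

    def test_scaled_water_grid_recovers_scale(self):
        assert self._k(self._uniform_wm_truth(sw_scale=1.1)) == pytest.approx(1.1, abs=1e-6)

    def test_no_qualifying_wm_voxel_errors(self, phantom_clean):
        truth = self._uniform_wm_truth()
        fr = truth.fractions_box
        fr.f_wm = np.full_like(fr.f_wm, 0.5)
        with pytest.raises(ValueError, match="STEAM voxel"):
            k_factor(truth.sw, fr, {}, 1.0)


class TestAcquisitionValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SteamAcquisition(-1.0)
        with pytest.raises(ValueError):
            SteamAcquisition(1.0, alpha_deg=200.0)
        with pytest.raises(ValueError):
            SteamAcquisition(1.0, tr_ms=15.0, tm_ms=10.0, te_ms=20.0)

    def test_json_roundtrip(self, tmp_path):
        a = SteamAcquisition(2.5, geometry=SteamVoxelGeometry((30.0, 30.0, 0.0)))
        a.to_json(tmp_path / "steam.json")
        back = SteamAcquisition.from_json(tmp_path / "steam.json")
        assert back.amplitude == 2.5
        assert back.geometry.center_mm == (30.0, 30.0, 0.0)
        assert back.tr_ms == 10000.0 and back.te_ms == 20.0 and back.tm_ms == 10.0

    def test_t2_defaults_to_constant_calibration(self):
        v = SteamLocalValues(t1_steam_ms=900.0, t2star_steam_ms=47.0,
                             b1_steam=1.0, h2o_mean_steam=0.65)
        assert v.t2_steam_ms == pytest.approx(59.0)
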