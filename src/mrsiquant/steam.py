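"""STEAM water calibration and synthesis of the 2D spectroscopic water reference.

A short single-voxel STEAM acquisition of unsuppressed water (10 s)
replaces the ~8 min unsuppressed MRSI water scan.  Its amplitude is
corrected for

* the stimulated-echo half signal (a STEAM echo carries half the
  magnetization of a spin echo),
* T1 relaxation during the sequence (including the mixing time TM),
* T2 decay over the echo time,
* transmit (B1+) miscalibration of the flip angle, and
* the voxel-volume difference between the STEAM box and an MRSI voxel.

The corrected amplitude calibrates the quantitative water-content map:
scaled by the resliced H2O map and normalized by the mean water content
inside the STEAM box, it yields a per-MRSI-voxel water reference that is
already free of water-relaxation weighting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .maps import MRSIGeometry, SteamVoxelGeometry, TissueFractionMap, VoxelMap, steam_region_mean
from .relaxometry import RelaxationTable, t2_from_t2star, water_attenuation_se

__all__ = [
    "SteamAcquisition",
    "SteamLocalValues",
    "SteamCorrectionFactors",
    "steam_correction_factors",
    "correct_steam_signal",
    "synthesize_water_reference",
    "k_factor",
]


@dataclass
class SteamAcquisition:
    """Single-voxel unsuppressed STEAM water measurement."""

    amplitude: float
    tr_ms: float = 10000.0
    te_ms: float = 20.0
    tm_ms: float = 10.0
    alpha_deg: float = 90.0
    geometry: SteamVoxelGeometry = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.geometry is None:
            self.geometry = SteamVoxelGeometry()
        if self.amplitude <= 0:
            raise ValueError("STEAM amplitude must be > 0")
        if not (0.0 < self.alpha_deg < 180.0):
            raise ValueError("flip angle must lie in (0, 180) degrees")
        if self.tr_ms <= self.tm_ms + self.te_ms / 2.0:
            raise ValueError("need TR > TM + TE/2 for a STEAM steady state")

    def to_json(self, path) -> None:
        doc = asdict(self)
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path) -> "SteamAcquisition":
        doc = json.loads(Path(path).read_text())
        geo = doc.pop("geometry", None)
        if geo is not None:
            geo = SteamVoxelGeometry(tuple(geo["center_mm"]), tuple(geo["dims_mm"]))
        return cls(geometry=geo, **doc)


@dataclass
class SteamLocalValues:
    """qMRI values of water inside the STEAM box.

    ``t2_steam_ms`` defaults to the constant T2*→T2 calibration unless a
    measured T2 is supplied.
    """

    t1_steam_ms: float
    t2star_steam_ms: float
    b1_steam: float
    h2o_mean_steam: float
    t2_steam_ms: float | None = None

    def __post_init__(self) -> None:
        for name in ("t1_steam_ms", "t2star_steam_ms", "b1_steam", "h2o_mean_steam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t2_steam_ms is None:
            self.t2_steam_ms = t2_from_t2star(self.t2star_steam_ms)

    @classmethod
    def from_maps(cls, t1_map: VoxelMap, t2star_map: VoxelMap, b1_map: VoxelMap,
                  h2o_map: VoxelMap, box: SteamVoxelGeometry,
                  t2_map: VoxelMap | None = None,
                  table: RelaxationTable | None = None) -> "SteamLocalValues":
        """Extract box means of T1, T2*, B1+ and water content at the STEAM voxel."""
        vals = cls(
            t1_steam_ms=steam_region_mean(t1_map, box),
            t2star_steam_ms=steam_region_mean(t2star_map, box),
            b1_steam=steam_region_mean(b1_map, box),
            h2o_mean_steam=steam_region_mean(h2o_map, box),
            t2_steam_ms=steam_region_mean(t2_map, box) if t2_map is not None else None,
        )
        if t2_map is None and table is not None:
            vals.t2_steam_ms = t2_from_t2star(vals.t2star_steam_ms, table)
        return vals


@dataclass
class SteamCorrectionFactors:
    t1corr: float
    t2corr: float
    b1corr: float
    voxelcorr: float

    @property
    def product(self) -> float:
        return self.t1corr * self.t2corr * self.b1corr * self.voxelcorr

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        d["product"] = self.product
        return d


def steam_t1_attenuation(t1_ms: float, tr_ms: float, te_ms: float, tm_ms: float) -> float:
    """Longitudinal STEAM attenuation (1 - exp((TE/2 + TM - TR)/T1)) * exp(-TM/T1)."""
    return (1.0 - math.exp((te_ms / 2.0 + tm_ms - tr_ms) / t1_ms)) * math.exp(-tm_ms / t1_ms)


def steam_correction_factors(acq: SteamAcquisition, loc: SteamLocalValues,
                             mrsi_geom: MRSIGeometry,
                             b1_mode: str = "as_printed",
                             t1_mode: str = "reciprocal") -> SteamCorrectionFactors:
    """Relaxation, B1+ and voxel-size correction factors for the STEAM signal.

    All factors are reciprocals of signal attenuations, so multiplying the
    measured amplitude by them undoes the corresponding loss:

    * ``t1corr`` = 1 / [(1 - exp((TE/2 + TM - TR)/T1)) * exp(-TM/T1)]
      (``t1_mode='as_printed'`` returns the attenuation itself instead,
      for comparison with a pipeline that multiplies it in directly);
    * ``t2corr`` = exp(TE/T2);
    * ``b1corr`` = sin(a) / sin(B1+ * a)^3, or the fully cubed-numerator
      form sin^3(a)/sin^3(B1+ * a) with ``b1_mode='cubed_numerator'``
      (identical at the nominal a = 90 deg);
    * ``voxelcorr`` = MRSI voxel volume / STEAM voxel volume, using the
      geometry's reconstructed (interpolated) voxel volume when one is set.
    """
    t1a = steam_t1_attenuation(loc.t1_steam_ms, acq.tr_ms, acq.te_ms, acq.tm_ms)
    t1corr = t1a if t1_mode == "as_printed" else 1.0 / t1a
    t2corr = math.exp(acq.te_ms / loc.t2_steam_ms)
    a = math.radians(acq.alpha_deg)
    eff = loc.b1_steam * acq.alpha_deg
    if eff <= 0.0 or eff >= 180.0:
        raise ValueError("effective flip angle B1+*alpha outside (0, 180) degrees")
    if b1_mode == "cubed_numerator":
        b1corr = (math.sin(a) / math.sin(loc.b1_steam * a)) ** 3
    else:
        b1corr = math.sin(a) / math.sin(loc.b1_steam * a) ** 3
    voxelcorr = mrsi_geom.interp_voxel_volume_mm3 / acq.geometry.volume_mm3
    return SteamCorrectionFactors(t1corr, t2corr, b1corr, voxelcorr)


def correct_steam_signal(acq: SteamAcquisition, loc: SteamLocalValues,
                         mrsi_geom: MRSIGeometry,
                         half_signal: bool = True,
                         factors: SteamCorrectionFactors | None = None,
                         **factor_kwargs) -> float:
    """Fully corrected STEAM water amplitude (svSTEAMWcorr).

    amplitude * 2 (stimulated-echo half signal, toggleable) * t1corr *
    t2corr * b1corr * voxelcorr.  NaN in any factor propagates.
    """
    if factors is None:
        factors = steam_correction_factors(acq, loc, mrsi_geom, **factor_kwargs)
    half = 2.0 if half_signal else 1.0
    return acq.amplitude * half * factors.product


def synthesize_water_reference(sv_corr: float, h2o_mrsi: VoxelMap,
                               h2o_mean_steam: float) -> VoxelMap:
    """Scale the resliced water-content map into a spectroscopic water reference.

    reference(v) = sv_corr * H2O_MRSI(v) / mean(H2O over the STEAM box).
    The result is already corrected for water relaxation (the STEAM
    amplitude was), so downstream quantification applies no water
    relaxation term.
    """
    if not np.isfinite(h2o_mean_steam) or h2o_mean_steam <= 0:
        raise ValueError("mean water content in the STEAM box must be finite and > 0")
    return h2o_mrsi.with_values(sv_corr * h2o_mrsi.values / h2o_mean_steam, unit="a.u.")


def k_factor(mrsi_water_ref: VoxelMap, fractions: TissueFractionMap,
             water_maps: dict[str, VoxelMap], sv_corr: float,
             tr_ms: float = 2000.0, te_ms: float = 40.0,
             wm_threshold: float = 0.98) -> float:
    """Receive-field re-calibration between the STEAM voxel and the MRSI slice.

    Needed only when the STEAM voxel sits outside the slice whose receive
    normalization the MRSI shares.  K is the relaxation-corrected acquired
    MRSI water signal of the purest-WM voxel (f_WM > 0.98) divided by the
    fully corrected STEAM amplitude (which already carries the voxel-size
    correction onto the MRSI grid).

    ``water_maps`` must provide ``t1`` and ``t2`` maps on the MRSI grid
    (resliced measured maps, or a T2 estimated from T2*).
    """
    fwm = np.where(np.isfinite(fractions.f_wm), fractions.f_wm, -np.inf)
    if fwm.max() <= wm_threshold:
        raise ValueError(
            "no MRSI voxel with WM fraction > {:.2f}; place the STEAM voxel "
            "inside the MRSI slice instead of applying K".format(wm_threshold))
    idx = np.unravel_index(int(np.argmax(fwm)), fwm.shape)
    sw = mrsi_water_ref.values[:, :, 0][idx[:2]] if mrsi_water_ref.values.ndim == 3 else mrsi_water_ref.values[idx]
    t1 = water_maps["t1"].values[:, :, 0][idx[:2]]
    t2 = water_maps["t2"].values[:, :, 0][idx[:2]]
    att = water_attenuation_se(float(t1), float(t2), tr_ms, te_ms)
    return float(sw / att / sv_corr)
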