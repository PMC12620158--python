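"""Metabolite concentration maps by three water-referencing strategies.

All three share the same skeleton: a metabolite amplitude is divided by a
water reference, corrected for metabolite relaxation and CSF partial
volume, and scaled by the molality of water.  They differ only in where
the water reference and the water-relaxation correction come from:

* ``proposed`` — the synthetic STEAM-calibrated water reference, which is
  already relaxation-corrected, so no water term appears;
* ``ref`` — the acquired unsuppressed MRSI water grid, relaxation-corrected
  per compartment with literature T1/T2 and literature water densities;
* ``ref_qmri`` — the acquired water grid, relaxation-corrected voxel-wise
  with measured T1/T2/H2O maps.

Molal output is mmol per kg of (non-CSF) tissue water; molar output is
mmol per liter of tissue, related voxel-wise by
``molar = molal * (H2O - fCSF) / (1 - fCSF) * rho_w``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import MRSIGeometry, TissueFractionMap, VoxelMap, reslice_to_mrsi
from .relaxometry import RelaxationTable, t2_from_t2star, water_attenuation_se

__all__ = [
    "MetaboliteAmplitudeSet",
    "ConcentrationResult",
    "metabolite_relaxation_factor",
    "csf_water_fraction",
    "molal_to_molar",
    "quantify_proposed",
    "quantify_ref_literature",
    "quantify_ref_qmri",
]


@dataclass
class MetaboliteAmplitudeSet:
    """Fitted metabolite amplitude grids plus the MRSI sequence timing."""

    amplitudes: dict[str, VoxelMap]
    tr_ms: float = 2000.0
    te_ms: float = 40.0

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.amplitudes.values()}
        if len(shapes) > 1:
            raise ValueError("all metabolite maps must share the MRSI grid")
        for name, m in self.amplitudes.items():
            v = m.values[np.isfinite(m.values)]
            if v.size and v.min() < 0:
                raise ValueError(f"negative amplitudes in {name!r}")

    @property
    def names(self) -> list[str]:
        return list(self.amplitudes)


@dataclass
class ConcentrationResult:
    """Per-metabolite molal/molar maps with validity mask and provenance."""

    molal: dict[str, np.ndarray]
    molar: dict[str, np.ndarray]
    mask: np.ndarray
    method: str  # "ref", "ref_qmri" or "proposed"
    h2o_used: np.ndarray            # water-content map the method used
    f_csf_used: np.ndarray
    rho_w: float
    provenance: dict = field(default_factory=dict)

    def check_molar_molal_invariant(self, atol: float = 1e-9) -> float:
        """Max deviation of molar/molal from (H2O - fCSF)/(1 - fCSF)*rho_w."""
        factor = (self.h2o_used - self.f_csf_used) / (1.0 - self.f_csf_used) * self.rho_w
        worst = 0.0
        for name in self.molal:
            a, b = self.molal[name], self.molar[name]
            ok = self.mask & np.isfinite(a) & np.isfinite(b) & (np.abs(a) > 0)
            dev = np.abs(b[ok] - a[ok] * factor[ok])
            scale = np.maximum(np.abs(b[ok]), 1.0)
            if dev.size:
                worst = max(worst, float(np.max(dev / scale)))
        if worst > atol:
            raise AssertionError(f"molar/molal invariant violated: {worst:.3e}")
        return worst


def metabolite_relaxation_factor(t1m_ms, t2m_ms, tr_ms, te_ms):
    """Metabolite relaxation attenuation RM = exp(-TE/T2M)*(1-exp(-TR/T1M))."""
    t1 = np.asarray(t1m_ms, dtype=float)
    t2 = np.asarray(t2m_ms, dtype=float)
    if np.any(t1 <= 0) or np.any(t2 <= 0) or tr_ms <= 0 or te_ms < 0:
        raise ValueError("relaxation times and TR must be > 0, TE >= 0")
    r = np.exp(-te_ms / t2) * (1.0 - np.exp(-tr_ms / t1))
    return float(r) if np.isscalar(t1m_ms) else r


def csf_water_fraction(f_csf, d_csf, h2o):
    """CSF fraction of the voxel's water mass: f_CSF * d_CSF / H2O.

    Values >= 1 (all water attributed to CSF) are left in place but make
    the voxel invalid downstream; H2O <= 0 yields NaN.
    """
    f = np.asarray(f_csf, dtype=float)
    w = np.asarray(h2o, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(w > 0, f * d_csf / w, np.nan)
    return float(out) if (np.isscalar(f_csf) and np.isscalar(h2o)) else out


def molal_to_molar(molal, h2o, f_csf, rho_w: float = 1.0):
    """Convert mmol/kg water to mmol/L tissue.

    molar = molal * (H2O - fCSF) / (1 - fCSF) * rho_w; fCSF = 1 yields NaN.
    """
    m = np.asarray(molal, dtype=float)
    w = np.asarray(h2o, dtype=float)
    f = np.asarray(f_csf, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(f < 1.0, m * (w - f) / (1.0 - f) * rho_w, np.nan)
    return float(out) if np.isscalar(molal) else out


def _as_plane(x) -> np.ndarray:
    if isinstance(x, VoxelMap):
        x = x.values
    x = np.asarray(x, dtype=float)
    return x[:, :, 0] if x.ndim == 3 else x


def _finalize(molal: dict[str, np.ndarray], mask: np.ndarray, method: str,
              h2o_used: np.ndarray, f_csf: np.ndarray, table: RelaxationTable,
              provenance: dict) -> ConcentrationResult:
    molal = {k: np.where(mask, v, np.nan) for k, v in molal.items()}
    molar = {k: molal_to_molar(v, h2o_used, f_csf, table.rho_w_kg_per_l)
             for k, v in molal.items()}
    return ConcentrationResult(molal, molar, mask, method, h2o_used, f_csf,
                               table.rho_w_kg_per_l, provenance)


def _rm_factors(sm: MetaboliteAmplitudeSet, table: RelaxationTable) -> dict[str, float]:
    rms = {}
    for name in sm.names:
        if name not in table.metabolites:
            raise KeyError(f"no relaxation entry for metabolite {name!r}")
        met = table.metabolites[name]
        rms[name] = metabolite_relaxation_factor(met.t1_ms, met.t2_ms, sm.tr_ms, sm.te_ms)
    return rms


def quantify_proposed(sm: MetaboliteAmplitudeSet, water_ref: VoxelMap,
                      fractions: TissueFractionMap, h2o_mrsi: VoxelMap,
                      table: RelaxationTable | None = None,
                      k: float = 1.0) -> ConcentrationResult:
    """Quantification against the synthetic STEAM-MRSI water reference.

    molal = (SM / reference) / (1 - fCSF_H2O) / RM * H2Omolal * k.
    No water-relaxation term: the reference is already corrected.
    Voxels with fCSF >= 0.95, non-positive reference, or no non-CSF water
    are masked invalid.
    """
    table = table or RelaxationTable()
    w = _as_plane(water_ref)
    h2o = _as_plane(h2o_mrsi)
    fcsf = np.asarray(fractions.f_csf, dtype=float)
    fch = csf_water_fraction(fcsf, table.d_csf, h2o)
    mask = (np.isfinite(w) & (w > 0) & np.isfinite(h2o) & np.isfinite(fcsf)
            & (fcsf < 0.95) & ((h2o - fcsf * table.d_csf) > 0))
    rms = _rm_factors(sm, table)
    molal = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in sm.names:
            s = _as_plane(sm.amplitudes[name])
            molal[name] = (s / w) / (1.0 - fch) / rms[name] * table.h2o_molal_mmol_per_kg * k
    mask = mask & np.all([np.isfinite(_as_plane(m)) for m in sm.amplitudes.values()], axis=0)
    prov = {"method": "proposed", "k": k, "rm": rms,
            "h2o_molal": table.h2o_molal_mmol_per_kg, "d_csf": table.d_csf}
    return _finalize(molal, mask, "proposed", h2o, fcsf, table, prov)


def quantify_ref_literature(sm: MetaboliteAmplitudeSet, sw: VoxelMap,
                            fractions: TissueFractionMap,
                            table: RelaxationTable | None = None) -> ConcentrationResult:
    """Literature-value water scaling against the acquired MRSI water grid.

    Compartment molal water fractions f_c^H2O = f_c*a_c / sum_j f_j*a_j
    (a = compartment water densities) weight literature spin-echo water
    attenuations A_c; the water content entering the molar conversion is
    the segmentation-based estimate sum_j f_j*a_j.  Voxels dominated by
    CSF (fCSF >= 0.95) are flagged unreliable.
    """
    table = table or RelaxationTable()
    w = _as_plane(sw)
    f = fractions.as_dict()
    alpha = {c: table.water[c].density for c in ("gm", "wm", "csf")}
    w_est = sum(f[c] * alpha[c] for c in ("gm", "wm", "csf"))
    with np.errstate(invalid="ignore", divide="ignore"):
        fh2o = {c: np.where(w_est > 0, f[c] * alpha[c] / w_est, np.nan)
                for c in ("gm", "wm", "csf")}
        att = {c: water_attenuation_se(table.water[c].t1_ms, table.water[c].t2_ms,
                                       sm.tr_ms, sm.te_ms) for c in ("gm", "wm", "csf")}
        a_eff = sum(fh2o[c] * att[c] for c in ("gm", "wm", "csf"))
    fcsf = np.asarray(fractions.f_csf, dtype=float)
    fch = fh2o["csf"]
    mask = (np.isfinite(w) & (w > 0) & np.isfinite(w_est) & (w_est > 0)
            & np.isfinite(fcsf) & (fcsf < 0.95)
            & ((w_est - fcsf * alpha["csf"]) > 0))
    rms = _rm_factors(sm, table)
    molal = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in sm.names:
            s = _as_plane(sm.amplitudes[name])
            molal[name] = (s / w) * a_eff / ((1.0 - fch) * rms[name]) * table.h2o_molal_mmol_per_kg
    mask = mask & np.all([np.isfinite(_as_plane(m)) for m in sm.amplitudes.values()], axis=0)
    prov = {"method": "ref", "attenuations": att, "densities": alpha, "rm": rms,
            "h2o_molal": table.h2o_molal_mmol_per_kg}
    return _finalize(molal, mask, "ref", w_est, fcsf, table, prov)


def quantify_ref_qmri(sm: MetaboliteAmplitudeSet, sw: VoxelMap,
                      fractions: TissueFractionMap,
                      qmri: dict[str, VoxelMap],
                      table: RelaxationTable | None = None,
                      geom: MRSIGeometry | None = None,
                      attenuation_mode: str = "hr") -> ConcentrationResult:
    """Measured-map water scaling against the acquired MRSI water grid.

    ``qmri`` holds high-resolution ``t1``, ``h2o`` and either ``t2`` or
    ``t2star`` maps (T2* falls back to the constant T2 calibration).
    With ``attenuation_mode='hr'`` (default) the water attenuation is
    evaluated per HR voxel and PSF-averaged weighted by water content —
    signal formation is linear in attenuation — giving the effective
    attenuation <H2O*A>/<H2O>; ``'mrsi'`` evaluates A at the resliced
    T1/T2 instead.
    """
    table = table or RelaxationTable()
    if geom is None:
        raise ValueError("quantify_ref_qmri needs the MRSI geometry for reslicing")
    t1 = qmri["t1"]
    if "t2" in qmri and qmri["t2"] is not None:
        t2_vals = qmri["t2"].values
    else:
        t2_vals = t2_from_t2star(qmri["t2star"].values, table)
    h2o_hr = qmri["h2o"]
    with np.errstate(invalid="ignore", divide="ignore"):
        a_hr = water_attenuation_se(t1.values, t2_vals, sm.tr_ms, sm.te_ms)
    h2o_mrsi = _as_plane(reslice_to_mrsi(h2o_hr, geom))
    if attenuation_mode == "hr":
        wa = reslice_to_mrsi(h2o_hr.with_values(h2o_hr.values * a_hr), geom)
        with np.errstate(invalid="ignore", divide="ignore"):
            a_eff = _as_plane(wa) / h2o_mrsi
    elif attenuation_mode == "mrsi":
        t1_m = _as_plane(reslice_to_mrsi(t1, geom))
        t2_m = _as_plane(reslice_to_mrsi(h2o_hr.with_values(np.broadcast_to(t2_vals, t1.values.shape).copy()), geom))
        a_eff = water_attenuation_se(t1_m, t2_m, sm.tr_ms, sm.te_ms)
    else:
        raise ValueError("attenuation_mode must be 'hr' or 'mrsi'")
    w = _as_plane(sw)
    fcsf = np.asarray(fractions.f_csf, dtype=float)
    fch = csf_water_fraction(fcsf, table.d_csf, h2o_mrsi)
    mask = (np.isfinite(w) & (w > 0) & np.isfinite(h2o_mrsi) & (h2o_mrsi > 0)
            & np.isfinite(a_eff) & (a_eff > 0) & np.isfinite(fcsf) & (fcsf < 0.95)
            & ((h2o_mrsi - fcsf * table.d_csf) > 0))
    rms = _rm_factors(sm, table)
    molal = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name in sm.names:
            s = _as_plane(sm.amplitudes[name])
            molal[name] = (s / w) * a_eff / ((1.0 - fch) * rms[name]) * table.h2o_molal_mmol_per_kg
    mask = mask & np.all([np.isfinite(_as_plane(m)) for m in sm.amplitudes.values()], axis=0)
    prov = {"method": "ref_qmri", "attenuation_mode": attenuation_mode, "rm": rms,
            "h2o_molal": table.h2o_molal_mmol_per_kg, "d_csf": table.d_csf}
    return _finalize(molal, mask, "ref_qmri", h2o_mrsi, fcsf, table, prov)
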