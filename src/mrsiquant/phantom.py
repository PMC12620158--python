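"""Seeded digital phantom: co-registered qMRI maps plus simulated MRSI signals.

The phantom emulates a 2D MRSI brain-slab study with known ground truth:
a white-matter core, a gray-matter rim, CSF pockets, and optionally a
lesion with elevated T1/T2/water content.  Signals follow the same
physical model the quantification inverts:

* unsuppressed MRSI water:
  ``SW(v) = g * V * rho_w * H2Omolal * <H2O * A_w(T1,T2)>_PSF``
* metabolite amplitude:
  ``SM(v) = g * V * RM * c_molal * rho_w * <H2O - f_CSF * d_CSF>_PSF``
* STEAM water amplitude (half signal, transmit-scaled flip):
  ``0.5 * g * V_steam * rho_w * H2Omolal
  * <H2O * E1(T1) * E2(T2) * sin(B1+ * a)^3>_box / sin(a)``

with ``<.>_PSF`` the k-space-truncation reslicing operator and
``<.>_box`` the STEAM-box average.  Noise, when enabled, is
multiplicative Gaussian on the measured amplitudes only (metabolite grid,
water grid, STEAM scalar) — the qMRI maps stay clean by default, as map
noise is dominated by amplitude noise in practice and can be added
separately for robustness studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .maps import (MRSIGeometry, SteamVoxelGeometry, TissueFractionMap, VoxelMap,
                   reslice_to_mrsi, steam_region_mean, tissue_fractions_to_mrsi)
from .quantify import (ConcentrationResult, MetaboliteAmplitudeSet,
                       metabolite_relaxation_factor, quantify_proposed,
                       quantify_ref_literature, quantify_ref_qmri)
from .relaxometry import CompartmentWater, RelaxationTable, water_attenuation_se
from .steam import (SteamAcquisition, SteamLocalValues, correct_steam_signal,
                    synthesize_water_reference)

__all__ = ["TissueParams", "LesionSpec", "PhantomConfig", "PhantomTruth",
           "generate_phantom", "add_noise", "cohort_configs"]


@dataclass
class TissueParams:
    """True water properties of one phantom tissue class."""

    t1_ms: float
    t2star_ms: float
    t2_ms: float
    h2o: float


def _default_tissues() -> dict[str, TissueParams]:
    # WM T2 = 59 = 47 * 59/47 satisfies the constant T2*->T2 calibration;
    # CSF water content is normalized to 1, matching water-content mapping
    # conventions.
    return {
        "wm": TissueParams(830.0, 47.0, 59.0, 0.65),
        "gm": TissueParams(1300.0, 58.0, 110.0, 0.78),
        "csf": TissueParams(4300.0, 200.0, 500.0, 1.0),
    }


@dataclass
class LesionSpec:
    """A box lesion with water properties elevated above normal WM."""

    center_mm: tuple[float, float] = (-30.0, 0.0)
    size_mm: tuple[float, float] = (36.0, 36.0)
    t1_factor: float = 1.5
    t2_factor: float = 1.5
    t2star_factor: float = 1.5
    h2o_factor: float = 1.4
    label: str = "wm"  # what segmentation (blind to the lesion) calls it


@dataclass
class PhantomConfig:
    hr_shape: tuple[int, int, int] = (96, 96, 24)
    hr_spacing_mm: float = 2.5
    fov_mm: tuple[float, float] = (240.0, 240.0)
    matrix: tuple[int, int] = (20, 20)
    slice_thickness_mm: float = 12.0
    tissues: dict[str, TissueParams] = field(default_factory=_default_tissues)
    calibrated_wm: bool = True  # force WM T2 = (lit T2/T2*) * T2*
    wm_core_halfwidth_mm: float = 60.0
    csf_pockets: tuple = (((0.0, 84.0), (24.0, 24.0)), ((0.0, -84.0), (24.0, 24.0)))
    lesion: LesionSpec | None = None
    concentrations_molal: dict[str, float] = field(
        default_factory=lambda: {"tNAA": 13.0, "tCr": 9.3, "tCho": 2.6})
    table: RelaxationTable = field(default_factory=RelaxationTable)
    b1_center: float = 1.1
    b1_edge_drop: float = 0.25  # quadratic fall-off to the FOV corner
    gain: float = 1.0
    noise_sigma: float = 0.0
    steam_center_mm: tuple[float, float, float] = (30.0, 30.0, 0.0)
    steam_dims_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    steam_tr_ms: float = 10000.0
    steam_te_ms: float = 20.0
    steam_tm_ms: float = 10.0
    steam_alpha_deg: float = 90.0
    mrsi_tr_ms: float = 2000.0
    mrsi_te_ms: float = 40.0
    seed: int = 0

    def geometry(self) -> MRSIGeometry:
        return MRSIGeometry(self.fov_mm, self.matrix, self.slice_thickness_mm)

    def steam_geometry(self) -> SteamVoxelGeometry:
        return SteamVoxelGeometry(self.steam_center_mm, self.steam_dims_mm)


def add_noise(signals, sigma: float, rng) -> np.ndarray:
    """Multiplicative Gaussian perturbation: s * (1 + sigma * N(0,1))."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    s = np.asarray(signals, dtype=float)
    if sigma == 0:
        return s.copy()
    return s * (1.0 + sigma * rng.standard_normal(s.shape))


@dataclass
class PhantomTruth:
    """Everything the generator produced, including every intermediate."""

    config: PhantomConfig
    geom: MRSIGeometry
    hr: dict[str, VoxelMap]            # t1, t2, t2star, b1, h2o, label + prob_*
    probs: dict[str, VoxelMap]
    steam: SteamAcquisition
    sm: MetaboliteAmplitudeSet
    sw: VoxelMap
    h2o_mrsi: VoxelMap
    fractions_psf: TissueFractionMap
    fractions_box: TissueFractionMap
    truth_molal: dict[str, float]
    truth_molar: dict[str, np.ndarray]
    intermediates: dict

    # -- convenience: run each quantification on this phantom ---------------
    def matched_table(self) -> RelaxationTable:
        """A relaxation table whose literature values equal the phantom truth."""
        cfg = self.config
        water = {t: CompartmentWater(p.t1_ms, p.t2_ms, p.h2o)
                 for t, p in cfg.tissues.items()}
        t = cfg.table
        return RelaxationTable(water=water, metabolites=dict(t.metabolites),
                               wm_t2_literature_ms=t.wm_t2_literature_ms,
                               wm_t2star_literature_ms=t.wm_t2star_literature_ms,
                               d_csf=t.d_csf, rho_w_kg_per_l=t.rho_w_kg_per_l,
                               h2o_molal_mmol_per_kg=t.h2o_molal_mmol_per_kg)

    def run_proposed(self, table: RelaxationTable | None = None,
                     use_psf_fractions: bool = True, k: float = 1.0) -> ConcentrationResult:
        table = table or self.config.table
        loc = SteamLocalValues.from_maps(self.hr["t1"], self.hr["t2star"],
                                         self.hr["b1"], self.hr["h2o"],
                                         self.steam.geometry, table=table)
        sv_corr = correct_steam_signal(self.steam, loc, self.geom)
        ref = synthesize_water_reference(sv_corr, self.h2o_mrsi, loc.h2o_mean_steam)
        fr = self.fractions_psf if use_psf_fractions else self.fractions_box
        return quantify_proposed(self.sm, ref, fr, self.h2o_mrsi, table, k=k)

    def run_ref_literature(self, table: RelaxationTable | None = None,
                           use_psf_fractions: bool = True) -> ConcentrationResult:
        table = table or self.config.table
        fr = self.fractions_psf if use_psf_fractions else self.fractions_box
        return quantify_ref_literature(self.sm, self.sw, fr, table)

    def run_ref_qmri(self, table: RelaxationTable | None = None,
                     use_psf_fractions: bool = True,
                     use_measured_t2: bool = True) -> ConcentrationResult:
        table = table or self.config.table
        fr = self.fractions_psf if use_psf_fractions else self.fractions_box
        qmri = {"t1": self.hr["t1"], "h2o": self.hr["h2o"]}
        if use_measured_t2:
            qmri["t2"] = self.hr["t2"]
        else:
            qmri["t2star"] = self.hr["t2star"]
        return quantify_ref_qmri(self.sm, self.sw, fr, qmri, table, geom=self.geom)


def _tissue_masks(cfg: PhantomConfig, xs: np.ndarray, ys: np.ndarray):
    """HR in-plane boolean masks for wm/gm/csf (+ lesion), z-invariant."""
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    wm = (np.abs(X) < cfg.wm_core_halfwidth_mm) & (np.abs(Y) < cfg.wm_core_halfwidth_mm)
    csf = np.zeros_like(wm)
    for (cx, cy), (sx, sy) in cfg.csf_pockets:
        csf |= (np.abs(X - cx) < sx / 2.0) & (np.abs(Y - cy) < sy / 2.0)
    csf &= ~wm
    gm = ~wm & ~csf
    lesion = np.zeros_like(wm)
    if cfg.lesion is not None:
        les = cfg.lesion
        lesion = ((np.abs(X - les.center_mm[0]) < les.size_mm[0] / 2.0)
                  & (np.abs(Y - les.center_mm[1]) < les.size_mm[1] / 2.0))
        if not lesion.any():
            raise ValueError("lesion box lies outside the field of view")
    return wm, gm, csf, lesion


def generate_phantom(config: PhantomConfig | None = None, **overrides) -> PhantomTruth:
    """Build the full phantom bundle; identical seeds give identical output."""
    cfg = replace(config or PhantomConfig(), **overrides) if overrides else (config or PhantomConfig())
    geom = cfg.geometry()
    table = cfg.table
    rng = np.random.default_rng(cfg.seed)

    if cfg.calibrated_wm:
        fac = table.t2star_to_t2_factor
        tis = dict(cfg.tissues)
        tis["wm"] = replace(tis["wm"], t2_ms=tis["wm"].t2star_ms * fac)
        cfg = replace(cfg, tissues=tis)

    nx, ny, nz = cfg.hr_shape
    sp = cfg.hr_spacing_mm
    mk = lambda arr, unit: VoxelMap.axis_aligned(arr, sp, (0.0, 0.0, 0.0), unit)
    probe = mk(np.zeros(cfg.hr_shape), "a.u.")
    xs, ys, zs = probe.axis_centers()
    wm2d, gm2d, csf2d, les2d = _tissue_masks(cfg, xs, ys)

    def paint(attr: str) -> np.ndarray:
        plane = np.zeros((nx, ny))
        for t, m in (("wm", wm2d), ("gm", gm2d), ("csf", csf2d)):
            plane[m] = getattr(cfg.tissues[t], attr)
        return np.repeat(plane[:, :, None], nz, axis=2)

    t1 = paint("t1_ms")
    t2 = paint("t2_ms")
    t2s = paint("t2star_ms")
    h2o = paint("h2o")
    if cfg.lesion is not None:
        les3d = np.repeat(les2d[:, :, None], nz, axis=2)
        t1 = np.where(les3d, t1 * cfg.lesion.t1_factor, t1)
        t2 = np.where(les3d, t2 * cfg.lesion.t2_factor, t2)
        t2s = np.where(les3d, t2s * cfg.lesion.t2star_factor, t2s)
        h2o = np.where(les3d, np.minimum(h2o * cfg.lesion.h2o_factor, 1.0), h2o)

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    rmax2 = (cfg.fov_mm[0] / 2.0) ** 2 + (cfg.fov_mm[1] / 2.0) ** 2
    b1_2d = cfg.b1_center - cfg.b1_edge_drop * (X ** 2 + Y ** 2) / rmax2
    b1 = np.repeat(b1_2d[:, :, None], nz, axis=2)

    # segmentation probabilities: one-hot, blind to any lesion
    seg = {"wm": wm2d, "gm": gm2d, "csf": csf2d}
    if cfg.lesion is not None and cfg.lesion.label in seg:
        pass  # lesion voxels already carry their host label
    probs = {t: mk(np.repeat(m[:, :, None].astype(float), nz, axis=2), "fraction")
             for t, m in seg.items()}
    label = mk(np.repeat((wm2d * 2 + gm2d * 1 + csf2d * 3)[:, :, None], nz, axis=2).astype(float), "a.u.")

    hr = {"t1": mk(t1, "ms"), "t2": mk(t2, "ms"), "t2star": mk(t2s, "ms"),
          "b1": mk(b1, "relative"), "h2o": mk(h2o, "fraction"), "label": label}

    # --- forward model -----------------------------------------------------
    rho_w = table.rho_w_kg_per_l
    hm = table.h2o_molal_mmol_per_kg
    vol = geom.voxel_volume_mm3
    a_w = water_attenuation_se(t1, t2, cfg.mrsi_tr_ms, cfg.mrsi_te_ms)
    sw_clean = cfg.gain * vol * rho_w * hm * reslice_to_mrsi(
        hr["h2o"].with_values(h2o * a_w), geom).values[:, :, 0]

    met_water = h2o - probs["csf"].values * table.d_csf  # non-CSF water fraction
    met_water_mrsi = reslice_to_mrsi(hr["h2o"].with_values(met_water), geom).values[:, :, 0]
    sm_clean: dict[str, np.ndarray] = {}
    for name in sorted(cfg.concentrations_molal):
        met = table.metabolites[name]
        rm = metabolite_relaxation_factor(met.t1_ms, met.t2_ms, cfg.mrsi_tr_ms, cfg.mrsi_te_ms)
        sm_clean[name] = (cfg.gain * vol * rm * cfg.concentrations_molal[name]
                          * rho_w * met_water_mrsi)

    box = cfg.steam_geometry()
    alpha = math.radians(cfg.steam_alpha_deg)
    e1 = ((1.0 - np.exp((cfg.steam_te_ms / 2.0 + cfg.steam_tm_ms - cfg.steam_tr_ms) / t1))
          * np.exp(-cfg.steam_tm_ms / t1))
    e2 = np.exp(-cfg.steam_te_ms / t2)
    steam_field = h2o * e1 * e2 * np.sin(b1 * alpha) ** 3 / math.sin(alpha)
    steam_clean = (0.5 * cfg.gain * box.volume_mm3 * rho_w * hm
                   * steam_region_mean(mk(steam_field, "a.u."), box))

    # Voxels whose true metabolite water mass rings to <= 0 (Gibbs overshoot
    # inside CSF pockets) have no fittable signal; a spectral fitter would
    # reject them, so they are emitted as NaN rather than negative numbers.
    sm_clean = {name: np.where(v > 0, v, np.nan) for name, v in sm_clean.items()}

    # --- noise (fixed draw order for determinism) --------------------------
    sm_noisy = {name: add_noise(sm_clean[name], cfg.noise_sigma, rng)
                for name in sorted(sm_clean)}
    sw_noisy = add_noise(sw_clean, cfg.noise_sigma, rng)
    steam_noisy = float(add_noise(np.array(steam_clean), cfg.noise_sigma, rng))

    sm = MetaboliteAmplitudeSet(
        {name: VoxelMap(v[:, :, None], geom.affine, "a.u.") for name, v in sm_noisy.items()},
        tr_ms=cfg.mrsi_tr_ms, te_ms=cfg.mrsi_te_ms)
    sw = VoxelMap(sw_noisy[:, :, None], geom.affine, "a.u.")
    steam = SteamAcquisition(steam_noisy, cfg.steam_tr_ms, cfg.steam_te_ms,
                             cfg.steam_tm_ms, cfg.steam_alpha_deg, box)

    h2o_mrsi = reslice_to_mrsi(hr["h2o"], geom)
    fractions_psf = tissue_fractions_to_mrsi(probs, geom, use_psf=True)
    fractions_box = tissue_fractions_to_mrsi(probs, geom, use_psf=False)

    h2o_plane = h2o_mrsi.values[:, :, 0]
    fcsf_plane = fractions_psf.f_csf
    with np.errstate(invalid="ignore", divide="ignore"):
        molar_factor = np.where(fcsf_plane < 1.0,
                                (h2o_plane - fcsf_plane) / (1.0 - fcsf_plane) * rho_w,
                                np.nan)
    truth_molar = {name: c * molar_factor for name, c in cfg.concentrations_molal.items()}

    return PhantomTruth(
        config=cfg, geom=geom, hr=hr, probs=probs, steam=steam, sm=sm, sw=sw,
        h2o_mrsi=h2o_mrsi, fractions_psf=fractions_psf, fractions_box=fractions_box,
        truth_molal=dict(cfg.concentrations_molal), truth_molar=truth_molar,
        intermediates={"sw_clean": sw_clean, "sm_clean": sm_clean,
                       "steam_clean": steam_clean, "a_w_hr": a_w,
                       "met_water_mrsi": met_water_mrsi,
                       "molar_factor": molar_factor},
    )


def cohort_configs(seeds, noise_sigma: float = 0.01,
                   jitter: float = 0.05, **common) -> list[PhantomConfig]:
    """Subject-like phantom configs: per-seed jitter of tissue T1/T2*/H2O.

    WM stays calibrated (T2 = 1.255 * T2*); true concentrations are shared
    across subjects, as in a healthy cohort.
    """
    configs = []
    for seed in seeds:
        # keyed stream: keeps the subject-parameter draws independent of
        # the measurement-noise draws inside generate_phantom(seed)
        rng = np.random.default_rng([int(seed), 2257])
        tissues = {}
        for t, p in _default_tissues().items():
            f = lambda: 1.0 + jitter * (2.0 * rng.random() - 1.0)
            h2o = min(p.h2o * f(), 1.0) if t != "csf" else 1.0
            tissues[t] = TissueParams(p.t1_ms * f(), p.t2star_ms * f(),
                                      p.t2_ms * f(), h2o)
        configs.append(PhantomConfig(tissues=tissues, noise_sigma=noise_sigma,
                                     calibrated_wm=True, seed=int(seed), **common))
    return configs
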