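"""Water/metabolite relaxation: literature table, T2 fitting, attenuation.

Two routes to a water T2 value coexist in this pipeline:

* a measured multi-TE spin-echo fit (monoexponential, voxel-wise), and
* a constant calibration from T2*, ``T2 = T2* * (WM T2 / WM T2*)`` with
  the literature white-matter pair 59 ms / 47 ms, i.e. a factor of 1.255.

The second is what makes the fast protocol possible: the effective decay
T2* is available from a multi-echo gradient echo, and in normal-appearing
white matter its ratio to true T2 is stable enough to serve as a constant
conversion at the single calibration voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "CompartmentWater",
    "MetaboliteRelaxation",
    "RelaxationTable",
    "fit_t2_mono",
    "fit_t2_map",
    "t2_from_t2star",
    "water_attenuation_se",
]


@dataclass
class CompartmentWater:
    """Literature water properties of one tissue compartment."""

    t1_ms: float
    t2_ms: float
    density: float  # relative water content (fraction of voxel volume)


@dataclass
class MetaboliteRelaxation:
    t1_ms: float
    t2_ms: float


def _default_water() -> dict[str, CompartmentWater]:
    # Editable literature defaults (assumed values, meant to be overridden
    # with the user's preferred literature source).
    return {
        "gm": CompartmentWater(1300.0, 110.0, 0.78),
        "wm": CompartmentWater(830.0, 80.0, 0.65),
        "csf": CompartmentWater(4300.0, 500.0, 0.97),
    }


def _default_metabolites() -> dict[str, MetaboliteRelaxation]:
    # Tissue-averaged literature values; a single pair per metabolite.
    return {
        "tNAA": MetaboliteRelaxation(1400.0, 250.0),
        "tCr": MetaboliteRelaxation(1350.0, 160.0),
        "tCho": MetaboliteRelaxation(1150.0, 220.0),
    }


@dataclass
class RelaxationTable:
    """Fully user-overridable relaxation and water-density constants.

    ``h2o_molal_mmol_per_kg`` defaults to 55100 (55.1 mol/kg expressed in
    mmol/kg, the convention that puts metabolite outputs on the usual
    mmol scale); the physical molality of pure water, 55510 mmol/kg, is
    available via :meth:`physical_water_preset`.
    """

    water: dict[str, CompartmentWater] = field(default_factory=_default_water)
    metabolites: dict[str, MetaboliteRelaxation] = field(default_factory=_default_metabolites)
    wm_t2_literature_ms: float = 59.0
    wm_t2star_literature_ms: float = 47.0
    d_csf: float = 1.0          # CSF water density used in the CSF molal fraction
    rho_w_kg_per_l: float = 1.0  # density of pure water
    h2o_molal_mmol_per_kg: float = 55100.0

    def __post_init__(self) -> None:
        for name, c in self.water.items():
            if c.t1_ms <= 0 or c.t2_ms <= 0:
                raise ValueError(f"non-positive relaxation time for {name!r}")
            if not (0.0 < c.density <= 1.2):
                raise ValueError(f"water density for {name!r} outside (0, 1.2]")
        for name, m in self.metabolites.items():
            if m.t1_ms <= 0 or m.t2_ms <= 0:
                raise ValueError(f"non-positive relaxation time for {name!r}")

    @property
    def t2star_to_t2_factor(self) -> float:
        return self.wm_t2_literature_ms / self.wm_t2star_literature_ms

    @classmethod
    def physical_water_preset(cls, **kwargs) -> "RelaxationTable":
        kwargs.setdefault("h2o_molal_mmol_per_kg", 55510.0)
        return cls(**kwargs)

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "water": {k: asdict(v) for k, v in self.water.items()},
            "metabolites": {k: asdict(v) for k, v in self.metabolites.items()},
            "constants": {
                "wm_t2_literature_ms": self.wm_t2_literature_ms,
                "wm_t2star_literature_ms": self.wm_t2star_literature_ms,
                "d_csf": self.d_csf,
                "rho_w_kg_per_l": self.rho_w_kg_per_l,
                "h2o_molal_mmol_per_kg": self.h2o_molal_mmol_per_kg,
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RelaxationTable":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            water={k: CompartmentWater(**v) for k, v in doc["water"].items()},
            metabolites={k: MetaboliteRelaxation(**v) for k, v in doc["metabolites"].items()},
            **doc.get("constants", {}),
        )


# --------------------------------------------------------------------------
# T2 estimation
# --------------------------------------------------------------------------

def fit_t2_mono(signals, tes, refine: bool = False):
    """Fit S(TE) = S0 * exp(-TE / T2) to multi-TE spin-echo amplitudes.

    Log-linear weighted least squares (weights S^2, the small-noise
    maximum-likelihood weighting for log-transformed data), with an
    optional nonlinear refinement.  Returns ``(t2_ms, s0)``; degenerate
    input (non-positive or non-decaying signal, < 2 valid points) yields
    ``(nan, nan)``.
    """
    s = np.asarray(signals, dtype=float)
    te = np.asarray(tes, dtype=float)
    ok = np.isfinite(s) & (s > 0) & np.isfinite(te)
    if ok.sum() < 2 or len(np.unique(te[ok])) < 2:
        return float("nan"), float("nan")
    s, te = s[ok], te[ok]
    w = s ** 2
    y = np.log(s)
    sw = w.sum()
    tbar = (w * te).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (te - tbar) ** 2).sum()
    if sxx == 0:
        return float("nan"), float("nan")
    slope = (w * (te - tbar) * (y - ybar)).sum() / sxx
    if slope >= 0:  # non-decaying
        return float("nan"), float("nan")
    t2 = -1.0 / slope
    s0 = float(np.exp(ybar - slope * tbar))
    if refine:
        from scipy.optimize import curve_fit

        try:
            popt, _ = curve_fit(lambda t, a, r: a * np.exp(-t / r), te, s,
                                p0=(s0, t2), maxfev=2000)
            s0, t2 = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass
    if t2 <= 0:
        return float("nan"), float("nan")
    return float(t2), float(s0)


def fit_t2_map(signal_stack: np.ndarray, tes) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise monoexponential T2 fit over the last axis of a stack.

    ``signal_stack`` has shape (..., n_te).  Vectorized log-linear WLS;
    voxels with degenerate input come back NaN in both outputs.
    """
    s = np.asarray(signal_stack, dtype=float)
    te = np.asarray(tes, dtype=float)
    ok = np.isfinite(s) & (s > 0)
    w = np.where(ok, s ** 2, 0.0)
    y = np.where(ok, np.log(np.where(ok, s, 1.0)), 0.0)
    sw = w.sum(axis=-1)
    good = ok.sum(axis=-1) >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        tbar = (w * te).sum(axis=-1) / sw
        ybar = (w * y).sum(axis=-1) / sw
        dt = te - tbar[..., None]
        sxx = (w * dt ** 2).sum(axis=-1)
        slope = (w * dt * (y - ybar[..., None])).sum(axis=-1) / sxx
        t2 = -1.0 / slope
        s0 = np.exp(ybar - slope * tbar)
    bad = ~good | ~np.isfinite(t2) | (t2 <= 0) | (slope >= 0)
    t2 = np.where(bad, np.nan, t2)
    s0 = np.where(bad, np.nan, s0)
    return t2, s0


def t2_from_t2star(t2star_ms, table: RelaxationTable | None = None):
    """Constant-calibration T2 estimate: T2* times the literature WM T2/T2*.

    With the default table this is t2star * 59/47 (factor 1.255).
    Accepts scalars or arrays; non-positive input maps to NaN.
    """
    table = table or RelaxationTable()
    t = np.asarray(t2star_ms, dtype=float)
    out = np.where(t > 0, t * table.t2star_to_t2_factor, np.nan)
    return float(out) if np.isscalar(t2star_ms) else out


def water_attenuation_se(t1_ms, t2_ms, tr_ms, te_ms):
    """Spin-echo water signal attenuation exp(-TE/T2) * (1 - exp(-TR/T1)).

    The factor both reference methods divide out of the acquired
    unsuppressed water signal.  Accepts scalars or broadcastable arrays.
    """
    t1 = np.asarray(t1_ms, dtype=float)
    t2 = np.asarray(t2_ms, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.exp(-te_ms / t2) * (1.0 - np.exp(-tr_ms / t1))
        a = np.where((t1 > 0) & (t2 > 0), a, np.nan)
    if np.isscalar(t1_ms) and np.isscalar(t2_ms):
        return float(a)
    return a
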