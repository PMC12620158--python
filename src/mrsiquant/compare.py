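"""ROI aggregation and Bland-Altman agreement between quantification methods.

The agreement convention follows standard method-comparison practice:
differences ``d = a - b`` (order logged), bias = mean(d), SD = sample
(n-1) standard deviation of d, limits of agreement = bias +/- 1.96*SD.
Percent forms are normalized by the grand mean of the pair means
(a+b)/2, the x-axis convention of a Bland-Altman plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maps import MRSIGeometry
from .quantify import ConcentrationResult

__all__ = ["RoiDefinition", "AgreementReport", "quadrant_rois",
           "roi_summarize", "bland_altman", "friedman_test"]


@dataclass
class RoiDefinition:
    """A named voxel mask on the MRSI grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} is empty")


def quadrant_rois(matrix: tuple[int, int] = (20, 20), margin: int = 2) -> list[RoiDefinition]:
    """Four disjoint anterior/posterior/left/right blocks inside the VOI.

    ``margin`` voxels are excluded at the grid border (edge-of-VOI voxels
    are conventionally discarded because of the imperfect slice profile).
    The y axis is taken as posterior->anterior, x as left->right.
    """
    nx, ny = matrix
    lox, hix = margin, nx - margin
    loy, hiy = margin, ny - margin
    sx, sy = (hix - lox) // 3, (hiy - loy) // 3

    def block(x0, x1, y0, y1):
        m = np.zeros(matrix, dtype=bool)
        m[x0:x1, y0:y1] = True
        return m

    return [
        RoiDefinition("anterior", block(lox + sx, hix - sx, hiy - sy, hiy)),
        RoiDefinition("posterior", block(lox + sx, hix - sx, loy, loy + sy)),
        RoiDefinition("left", block(lox, lox + sx, loy + sy, hiy - sy)),
        RoiDefinition("right", block(hix - sx, hix, loy + sy, hiy - sy)),
    ]


def roi_summarize(conc: ConcentrationResult, rois, scale: str = "molar") -> pd.DataFrame:
    """NaN-aware mean and sample SD per ROI per metabolite.

    ``scale`` selects molar (mmol/L) or molal (mmol/kg) maps.  Raises if
    an ROI has no valid voxel after masking.
    """
    maps = conc.molar if scale == "molar" else conc.molal
    rows = []
    for roi in rois:
        for name, arr in maps.items():
            vals = arr[roi.mask & conc.mask]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise ValueError(f"ROI {roi.name!r} is fully masked for {name!r}")
            rows.append({
                "roi": roi.name, "metabolite": name, "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            })
    return pd.DataFrame(rows)


@dataclass
class AgreementReport:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    bias_pct: float
    sd_pct: float
    n: int
    order: str = "a - b"
    per_roi: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        d = {"bias": self.bias, "sd": self.sd, "loa_low": self.loa_low,
             "loa_high": self.loa_high, "bias_pct": self.bias_pct,
             "sd_pct": self.sd_pct, "n": self.n, "order": self.order}
        if self.per_roi is not None:
            d["per_roi"] = self.per_roi.to_dict(orient="records")
        return d


def bland_altman(a, b, labels=None) -> AgreementReport:
    """Bland-Altman agreement between paired measurements a and b.

    Differences are a - b; percent bias/SD are relative to the grand mean
    of the pair means.  ``labels`` (optional, e.g. ROI names per pair)
    adds a per-label breakdown.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise ValueError("need at least 2 valid pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    grand = float(((a + b) / 2.0).mean())
    per_roi = None
    if labels is not None:
        labels = np.asarray(labels).ravel()[ok]
        rows = []
        for lab in pd.unique(labels):
            dl = d[labels == lab]
            rows.append({"label": lab, "n": int(dl.size), "bias": float(dl.mean()),
                         "sd": float(dl.std(ddof=1)) if dl.size > 1 else 0.0})
        per_roi = pd.DataFrame(rows)
    return AgreementReport(
        bias=bias, sd=sd,
        loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd,
        bias_pct=100.0 * bias / grand, sd_pct=100.0 * sd / grand,
        n=int(a.size), per_roi=per_roi)


def friedman_test(*method_values):
    """Friedman repeated-measures test across methods (delegated to scipy)."""
    from scipy.stats import friedmanchisquare

    stat, p = friedmanchisquare(*method_values)
    return float(stat), float(p)


def bland_altman_plot(a, b, path, title: str = "Bland-Altman") -> None:
    """Write a Bland-Altman scatter (mean vs difference) to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = bland_altman(a, b)
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2.0, a - b, s=14)
    for y, style in ((rep.bias, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a - b)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
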