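"""Voxel-map data model, MRSI grid geometry, and PSF-aware reslicing.

MRSI samples k-space on a coarse phase-encode grid (e.g. 20x20 over a
240 mm field of view), so each spectroscopic voxel sees the tissue through
the broad point spread function (PSF) of a truncated Fourier series rather
than a sharp box.  High-resolution quantitative maps (T1, T2*, B1+, water
content, tissue probabilities) therefore have to be resliced into MRSI
space with that PSF before they can be compared with, or used to
synthesize, spectroscopic signals.

All geometry here is axis-aligned: the inputs are assumed co-registered
and expressed in a common scanner frame (mm), which is how they leave a
scanner-side alignment step.  Voxel indices are 0-based and refer to voxel
centers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelMap",
    "MRSIGeometry",
    "SteamVoxelGeometry",
    "TissueFractionMap",
    "reslice_to_mrsi",
    "tissue_fractions_to_mrsi",
    "steam_region_mean",
    "psf_kernel",
    "load_map",
    "save_map",
    "grid_to_csv",
]

VALID_UNITS = ("ms", "fraction", "relative", "a.u.", "mmol/kg", "mmol/L")


# --------------------------------------------------------------------------
# data model
# --------------------------------------------------------------------------

@dataclass
class VoxelMap:
    """A 3D scalar field with world geometry (mm) and a unit tag.

    NaN marks invalid voxels; every operation propagates NaN and the
    validity mask is simply ``~np.isnan(values)``.
    """

    values: np.ndarray
    affine: np.ndarray
    unit: str = "a.u."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D array with size >= 1 per axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        """Validity mask: True where the voxel holds a finite value."""
        return np.isfinite(self.values)

    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm (requires an axis-aligned affine)."""
        lin = self.affine[:3, :3]
        if np.max(np.abs(lin - np.diag(np.diag(lin)))) > 1e-9 * max(1.0, np.max(np.abs(lin))):
            raise NotImplementedError("only axis-aligned (diagonal) affines are supported")
        return np.abs(np.diag(lin))

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        sp = np.diag(self.affine[:3, :3])
        orig = self.affine[:3, 3]
        return tuple(orig[a] + sp[a] * np.arange(self.shape[a]) for a in range(3))  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VoxelMap":
        return VoxelMap(values, self.affine.copy(), unit or self.unit)

    @staticmethod
    def axis_aligned(values: np.ndarray, spacing_mm, center_mm=(0.0, 0.0, 0.0),
                     unit: str = "a.u.") -> "VoxelMap":
        """Build a map on an axis-aligned grid centered at ``center_mm``."""
        values = np.asarray(values, dtype=float)
        sp = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
        ctr = np.asarray(center_mm, dtype=float)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(sp)
        # origin = world position of voxel (0,0,0) center
        aff[:3, 3] = ctr - sp * (np.asarray(values.shape) - 1) / 2.0
        return VoxelMap(values, aff, unit)


@dataclass
class MRSIGeometry:
    """The spectroscopic phase-encode grid (a single 2D slice).

    ``matrix`` is the acquired phase-encode matrix, which sets the PSF.
    ``interp_matrix``, when given, is the reconstruction (zero-filled)
    matrix, whose voxel volume is the one a scanner reports as the
    "interpolated resolution"; it is used for voxel-volume bookkeeping
    only, never for the PSF.
    """

    fov_mm: tuple[float, float] = (240.0, 240.0)
    matrix: tuple[int, int] = (20, 20)
    slice_thickness_mm: float = 12.0
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    weighting: str = "uniform"  # k-space averaging: "uniform" or "weighted"
    interp_matrix: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if min(self.matrix) < 2:
            raise ValueError("matrix entries must be >= 2")
        if min(self.fov_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("fov and slice thickness must be > 0")
        if self.weighting not in ("uniform", "weighted"):
            raise ValueError("weighting must be 'uniform' or 'weighted'")

    @property
    def voxel_size_mm(self) -> tuple[float, float, float]:
        """Nominal (acquired) voxel edges: fov/matrix in-plane x thickness."""
        return (self.fov_mm[0] / self.matrix[0],
                self.fov_mm[1] / self.matrix[1],
                self.slice_thickness_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        """Nominal voxel volume = (fov_x/matrix_x)*(fov_y/matrix_y)*thickness."""
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz

    @property
    def interp_voxel_volume_mm3(self) -> float:
        """Reconstructed voxel volume if an interpolation matrix is set."""
        if self.interp_matrix is None:
            return self.voxel_volume_mm3
        return (self.fov_mm[0] / self.interp_matrix[0]
                * self.fov_mm[1] / self.interp_matrix[1]
                * self.slice_thickness_mm)

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-world transform of the (nx, ny, 1) MRSI grid."""
        vx, vy, vz = self.voxel_size_mm
        aff = np.eye(4)
        aff[:3, :3] = np.diag([vx, vy, vz])
        aff[0, 3] = self.center_mm[0] - vx * (self.matrix[0] - 1) / 2.0
        aff[1, 3] = self.center_mm[1] - vy * (self.matrix[1] - 1) / 2.0
        aff[2, 3] = self.center_mm[2]
        return aff

    def slab_z(self) -> tuple[float, float]:
        z0 = self.center_mm[2] - self.slice_thickness_mm / 2.0
        return z0, z0 + self.slice_thickness_mm

    def empty_map(self, unit: str = "a.u.") -> VoxelMap:
        return VoxelMap(np.zeros(self.matrix + (1,)), self.affine, unit)


@dataclass
class SteamVoxelGeometry:
    """The single-voxel STEAM box (default 10 x 10 x 10 mm^3)."""

    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dims_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)

    def __post_init__(self) -> None:
        if min(self.dims_mm) <= 0:
            raise ValueError("STEAM box edges must be > 0")

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.dims_mm))

    def bounds(self) -> np.ndarray:
        c = np.asarray(self.center_mm)
        d = np.asarray(self.dims_mm)
        return np.stack([c - d / 2.0, c + d / 2.0])


@dataclass
class TissueFractionMap:
    """Per-MRSI-voxel GM/WM/CSF volume fractions."""

    f_gm: np.ndarray
    f_wm: np.ndarray
    f_csf: np.ndarray
    geometry: MRSIGeometry | None = None

    def __post_init__(self) -> None:
        self.f_gm = np.asarray(self.f_gm, dtype=float)
        self.f_wm = np.asarray(self.f_wm, dtype=float)
        self.f_csf = np.asarray(self.f_csf, dtype=float)
        if not (self.f_gm.shape == self.f_wm.shape == self.f_csf.shape):
            raise ValueError("fraction maps must share one grid")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.f_gm) & np.isfinite(self.f_wm) & np.isfinite(self.f_csf)

    def check_partition(self, atol: float = 1e-6) -> bool:
        """Fractions sum to one on valid voxels."""
        s = self.f_gm + self.f_wm + self.f_csf
        return bool(np.all(np.abs(s[self.mask] - 1.0) <= atol))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"gm": self.f_gm, "wm": self.f_wm, "csf": self.f_csf}


# --------------------------------------------------------------------------
# PSF reslicing
# --------------------------------------------------------------------------

def _kspace_window(matrix: tuple[int, int], weighting: str) -> np.ndarray:
    """Separable k-space weighting over the retained phase encodes.

    Normalized to 1 at DC so constant fields are fixed points.
    """
    if weighting == "uniform":
        return np.ones(matrix)
    wx = np.hamming(matrix[0] + 1)[:-1] if matrix[0] % 2 == 0 else np.hamming(matrix[0])
    wy = np.hamming(matrix[1] + 1)[:-1] if matrix[1] % 2 == 0 else np.hamming(matrix[1])
    # roll so the window peak sits on DC (center index n//2 after fftshift)
    wx = np.roll(wx, matrix[0] // 2 - int(np.argmax(wx)))
    wy = np.roll(wy, matrix[1] // 2 - int(np.argmax(wy)))
    win = np.outer(wx, wy)
    return win / win[matrix[0] // 2, matrix[1] // 2]


def _fourier_truncate(plane: np.ndarray, matrix: tuple[int, int], weighting: str) -> np.ndarray:
    """Downsample a 2D field by retaining the central MRSI k-space block.

    This is the ideal PSF model of phase-encoded MRSI: the coarse grid
    measures exactly the low spatial frequencies of the object.
    """
    nx, ny = plane.shape
    mx, my = matrix
    if mx > nx or my > ny:
        raise ValueError("MRSI matrix exceeds the high-resolution grid")
    k = np.fft.fftshift(np.fft.fft2(plane))
    cx, cy = nx // 2, ny // 2
    block = k[cx - mx // 2: cx - mx // 2 + mx, cy - my // 2: cy - my // 2 + my]
    block = block * _kspace_window(matrix, weighting)
    out = np.fft.ifft2(np.fft.ifftshift(block)) * (mx * my) / (nx * ny)
    return out.real


def psf_kernel(hr_shape: tuple[int, int], matrix: tuple[int, int],
               weighting: str = "uniform") -> np.ndarray:
    """In-plane PSF at HR resolution: response of reslicing to a unit impulse.

    Expressed as averaging weights that sum to 1: a constant field stays
    constant under convolution with this kernel.
    """
    imp = np.zeros(hr_shape)
    imp[hr_shape[0] // 2, hr_shape[1] // 2] = 1.0
    kx = np.fft.fftshift(np.fft.fft2(imp))
    cx, cy = hr_shape[0] // 2, hr_shape[1] // 2
    mx, my = matrix
    full = np.zeros(hr_shape, dtype=complex)
    full[cx - mx // 2: cx - mx // 2 + mx, cy - my // 2: cy - my // 2 + my] = (
        kx[cx - mx // 2: cx - mx // 2 + mx, cy - my // 2: cy - my // 2 + my]
        * _kspace_window(matrix, weighting)
    )
    ker = np.fft.ifft2(np.fft.ifftshift(full)).real
    return ker / ker.sum()


def _slab_planes(hr_map: VoxelMap, geom: MRSIGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Average the HR volume through the MRSI slab (box profile in z).

    Returns the slab-averaged 2D plane (NaN filled with the valid mean)
    and the per-pixel fraction of contributing HR voxels that were NaN.
    """
    xs, ys, zs = hr_map.axis_centers()
    z0, z1 = geom.slab_z()
    inz = (zs > z0) & (zs < z1)
    if not inz.any():
        raise ValueError("high-resolution map does not overlap the MRSI slab")
    sub = hr_map.values[:, :, inz]
    nanfrac = np.mean(~np.isfinite(sub), axis=2)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        plane = np.nanmean(np.where(np.isfinite(sub), sub, np.nan), axis=2)
    return plane, nanfrac


def _inplane_on_fov(plane: np.ndarray, hr_map: VoxelMap, geom: MRSIGeometry) -> np.ndarray:
    """Express the slab plane on a grid spanning exactly the MRSI FOV.

    Fast path: the HR grid already spans the FOV (same extent and center).
    Otherwise the plane is linearly resampled onto an oversampled FOV grid.
    """
    xs, ys, _ = hr_map.axis_centers()
    sp = hr_map.spacing()
    ext_x = xs[-1] - xs[0] + sp[0]
    ext_y = ys[-1] - ys[0] + sp[1]
    ctr_x = (xs[0] + xs[-1]) / 2.0
    ctr_y = (ys[0] + ys[-1]) / 2.0
    tol = 1e-6
    if (abs(ext_x - geom.fov_mm[0]) < tol and abs(ext_y - geom.fov_mm[1]) < tol
            and abs(ctr_x - geom.center_mm[0]) < tol and abs(ctr_y - geom.center_mm[1]) < tol):
        return plane
    # overlap check before resampling
    if (xs[-1] < geom.center_mm[0] - geom.fov_mm[0] / 2 or xs[0] > geom.center_mm[0] + geom.fov_mm[0] / 2
            or ys[-1] < geom.center_mm[1] - geom.fov_mm[1] / 2 or ys[0] > geom.center_mm[1] + geom.fov_mm[1] / 2):
        raise ValueError("high-resolution map does not overlap the MRSI FOV in-plane")
    from scipy.ndimage import map_coordinates

    ov = (max(4 * geom.matrix[0], int(np.ceil(geom.fov_mm[0] / sp[0]))),
          max(4 * geom.matrix[1], int(np.ceil(geom.fov_mm[1] / sp[1]))))
    gx = (geom.center_mm[0] - geom.fov_mm[0] / 2
          + geom.fov_mm[0] * (np.arange(ov[0]) + 0.5) / ov[0])
    gy = (geom.center_mm[1] - geom.fov_mm[1] / 2
          + geom.fov_mm[1] * (np.arange(ov[1]) + 0.5) / ov[1])
    ix = np.interp(gx, xs, np.arange(len(xs)))
    iy = np.interp(gy, ys, np.arange(len(ys)))
    coords = np.meshgrid(ix, iy, indexing="ij")
    return map_coordinates(plane, coords, order=1, mode="nearest")


def reslice_to_mrsi(hr_map: VoxelMap, geom: MRSIGeometry,
                    window: str | None = None) -> VoxelMap:
    """Reslice a high-resolution map into MRSI space with the MRSI PSF.

    Through-slice the slab is box-averaged; in-plane the field is reduced
    to the MRSI matrix by k-space truncation (optionally Hamming-weighted
    to mimic weighted phase-encode averaging).  The operation is linear and
    keeps constant fields constant.  NaNs in the covered region propagate:
    an MRSI voxel whose nominal box contains any invalid HR voxel is NaN.
    """
    weighting = window if window is not None else geom.weighting
    plane, nanfrac = _slab_planes(hr_map, geom)
    anynan = nanfrac > 0
    if anynan.any():
        fill = np.nanmean(plane)
        plane = np.where(np.isfinite(plane), plane, fill)
    fov_plane = _inplane_on_fov(plane, hr_map, geom)
    out = _fourier_truncate(fov_plane, geom.matrix, weighting)
    if anynan.any():
        ind = _inplane_on_fov(anynan.astype(float), hr_map, geom)
        bad = _box_average_plane(ind, geom) > 1e-9
        out = np.where(bad, np.nan, out)
    return VoxelMap(out[:, :, None], geom.affine, hr_map.unit)


def _box_average_plane(plane: np.ndarray, geom: MRSIGeometry) -> np.ndarray:
    """Box-average a FOV-spanning plane onto the MRSI matrix (no PSF)."""
    nx, ny = plane.shape
    mx, my = geom.matrix
    bx = (np.arange(nx) * mx) // nx
    by = (np.arange(ny) * my) // ny
    out = np.zeros((mx, my))
    cnt = np.zeros((mx, my))
    np.add.at(out, (bx[:, None].repeat(ny, 1), by[None, :].repeat(nx, 0)), plane)
    np.add.at(cnt, (bx[:, None].repeat(ny, 1), by[None, :].repeat(nx, 0)), 1.0)
    return out / cnt


def _hr_to_mrsi_index(hr_map: VoxelMap, geom: MRSIGeometry):
    """Map HR voxel centers to MRSI voxel indices (None outside)."""
    xs, ys, zs = hr_map.axis_centers()
    vx, vy, _ = geom.voxel_size_mm
    x0 = geom.center_mm[0] - geom.fov_mm[0] / 2.0
    y0 = geom.center_mm[1] - geom.fov_mm[1] / 2.0
    ix = np.floor((xs - x0) / vx).astype(int)
    iy = np.floor((ys - y0) / vy).astype(int)
    z0, z1 = geom.slab_z()
    okx = (ix >= 0) & (ix < geom.matrix[0])
    oky = (iy >= 0) & (iy < geom.matrix[1])
    okz = (zs > z0) & (zs < z1)
    return ix, iy, okx, oky, okz


def tissue_fractions_to_mrsi(prob_maps_or_labels, geom: MRSIGeometry,
                             use_psf: bool = False,
                             label_values: dict[str, int] | None = None) -> TissueFractionMap:
    """Reduce HR tissue probabilities (or a label map) to MRSI voxel fractions.

    ``prob_maps_or_labels`` is either a dict with keys gm/wm/csf of
    :class:`VoxelMap` probability maps summing to 1 per HR voxel, or a
    single integer label map (default labels gm=1, wm=2, csf=3).

    Box averaging over the nominal MRSI voxel is the default, the common
    practice for partial-volume correction.  With ``use_psf`` the same
    k-space truncation operator as :func:`reslice_to_mrsi` is applied
    instead; PSF-weighted fractions are consistent with signal formation
    but can slightly over/undershoot [0, 1] near sharp tissue boundaries
    (Gibbs ringing) and are deliberately not clipped, so that linearity
    against the resliced maps is exact.
    """
    if isinstance(prob_maps_or_labels, VoxelMap):
        labels = label_values or {"gm": 1, "wm": 2, "csf": 3}
        lab = prob_maps_or_labels
        probs = {t: lab.with_values((lab.values == v).astype(float), unit="fraction")
                 for t, v in labels.items()}
    else:
        probs = dict(prob_maps_or_labels)
    for t, p in probs.items():
        v = p.values[np.isfinite(p.values)]
        if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError(f"probabilities for {t!r} outside [0, 1]")
    total = sum(p.values for p in probs.values())
    if np.nanmax(np.abs(total - 1.0)) > 1e-6:
        raise ValueError("tissue probabilities must sum to 1 per voxel")

    out: dict[str, np.ndarray] = {}
    if use_psf:
        for t, p in probs.items():
            out[t] = reslice_to_mrsi(p, geom).values[:, :, 0]
    else:
        for t, p in probs.items():
            plane, _ = _slab_planes(p, geom)
            fov = _inplane_on_fov(plane, hr_map=p, geom=geom)
            out[t] = _box_average_plane(fov, geom)
    s = out["gm"] + out["wm"] + out["csf"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = {t: np.where(s != 0, v / s, np.nan) for t, v in out.items()}
    return TissueFractionMap(out["gm"], out["wm"], out["csf"], geometry=geom)


def steam_region_mean(hr_map: VoxelMap, box: SteamVoxelGeometry,
                      return_count: bool = False):
    """NaN-aware mean of HR voxels whose centers fall inside the STEAM box.

    This is the spatial average used both for the water-content
    normalization of the synthetic reference and for extracting T1, T2*
    and B1+ at the STEAM location.
    """
    xs, ys, zs = hr_map.axis_centers()
    lo, hi = box.bounds()
    selx = (xs > lo[0]) & (xs < hi[0])
    sely = (ys > lo[1]) & (ys < hi[1])
    selz = (zs > lo[2]) & (zs < hi[2])
    if not (selx.any() and sely.any() and selz.any()):
        raise ValueError("STEAM box does not contain any high-resolution voxel center")
    sub = hr_map.values[np.ix_(np.where(selx)[0], np.where(sely)[0], np.where(selz)[0])]
    valid = np.isfinite(sub)
    n = int(valid.sum())
    mean = float(np.nanmean(sub)) if n else float("nan")
    if return_count:
        return mean, n
    return mean


# --------------------------------------------------------------------------
# I/O: NIfTI with JSON sidecar, CSV tables
# --------------------------------------------------------------------------

def save_map(vmap: VoxelMap, path, sidecar: dict | None = None) -> None:
    """Write a map as NIfTI-1 plus a JSON sidecar carrying the unit."""
    path = Path(path)
    nib.save(nib.Nifti1Image(vmap.values, vmap.affine), str(path))
    meta = {"unit": vmap.unit}
    if sidecar:
        meta.update(sidecar)
    side = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    side = side.parent / (side.name + ".json")
    side.write_text(json.dumps(meta, indent=2))


def load_map(path) -> VoxelMap:
    """Read a NIfTI map; the unit comes from its JSON sidecar if present."""
    path = Path(path)
    img = nib.load(str(path))
    side = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    side = side.parent / (side.name + ".json")
    unit = "a.u."
    if side.exists():
        unit = json.loads(side.read_text()).get("unit", "a.u.")
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    return VoxelMap(data, img.affine, unit)


def grid_to_csv(vmap: VoxelMap, path, value_name: str = "value") -> pd.DataFrame:
    """Export an MRSI-grid map as a tidy per-voxel CSV table."""
    nx, ny = vmap.shape[:2]
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    df = pd.DataFrame({
        "x_index": ii.ravel(),
        "y_index": jj.ravel(),
        value_name: vmap.values[:, :, 0].ravel(),
    })
    df.to_csv(path, index=False)
    return df
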