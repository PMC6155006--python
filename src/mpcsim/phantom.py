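"""Synthetic micro-XCT phantoms: voxelize a network + mineral state.

Volumes are rendered on a (z, y, x) grid — z is axial depth h, origin
at the centre of the cortical face — by sampling each voxel centre
against the analytic scene (envelope, tubule cylinders, deposit annuli,
interstitial field).  Tissue classes get distinct mean densities
(mg/cc), the density map is converted to 16-bit grayscale through a
linear calibration, then optionally blurred (PSF) and corrupted with
additive Gaussian noise.  A ground-truth label volume with the same
geometry is returned alongside.

Scan presets follow micro-XCT magnifications: 2X (10 µm/voxel), 10X
(5 µm/voxel), 20X (1 µm/voxel) and 40X (0.5 µm/voxel), 1200 slices per
reconstruction; the 4X preset's pitch is not standard and defaults to
8 µm (flagged in the docs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import tifffile
from scipy import ndimage

from .geometry import MPCNetwork, envelope_radius

__all__ = [
    "ScanPreset",
    "PRESETS",
    "Tomogram",
    "Calibration",
    "TissueDensities",
    "VoxelizationError",
    "LABELS",
    "voxelize",
    "voxelize_iodine",
]


class VoxelizationError(ValueError):
    pass


#: ground-truth label codes
LABELS: Dict[str, int] = {
    "air": 0,
    "soft_tissue": 1,
    "lumen": 2,
    "tubule_wall": 3,
    "intratubular_mineral": 4,   # wall deposit annulus inside the lumen
    "wall_mineral": 5,           # mineralized distal wall shell
    "interstitial_mineral": 6,
}


@dataclass(frozen=True)
class ScanPreset:
    """Acquisition preset: magnification name, voxel pitch, noise model."""

    name: str
    voxel_size: float  # µm/voxel
    n_slices: int = 1200
    noise_sd: float = 60.0  # grayscale units
    psf_sigma: float = 0.7  # voxels

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.n_slices <= 0:
            raise ValueError("voxel_size and n_slices must be positive")


PRESETS: Dict[str, ScanPreset] = {
    "2X": ScanPreset("2X", 10.0),
    "4X": ScanPreset("4X", 8.0),  # pitch not standard; placeholder value
    "10X": ScanPreset("10X", 5.0),
    "20X": ScanPreset("20X", 1.0),
    "40X": ScanPreset("40X", 0.5),
}


@dataclass(frozen=True)
class Calibration:
    """Linear grayscale -> mineral density map: density = slope*gray + intercept."""

    slope: float = 0.05  # mg/cc per grayscale unit
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def to_density(self, gray: np.ndarray) -> np.ndarray:
        return gray.astype(np.float32) * self.slope + self.intercept

    def to_gray(self, density: np.ndarray) -> np.ndarray:
        return (np.asarray(density, dtype=np.float32) - self.intercept) / self.slope


@dataclass(frozen=True)
class TissueDensities:
    """Mean rendered densities per tissue class, mg/cc."""

    soft_tissue: float = 50.0
    lumen: float = 0.0
    wall_deposit: float = 800.0
    interstitial: float = 1200.0
    air: float = 0.0


@dataclass
class Tomogram:
    """Calibrated grayscale 3D volume with voxel-size metadata.

    ``volume`` is uint16 grayscale ordered (z, y, x); the transverse
    origin sits at the volume centre, z=0 at the first slice.
    """

    volume: np.ndarray
    voxel_size: float  # µm
    calibration: Calibration
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # (x, y, h) of voxel (0,0,0)
    axis_order: str = "zyx"
    labels: Optional[np.ndarray] = None  # ground truth, same shape

    def density(self) -> np.ndarray:
        """Calibrated mineral-density volume, mg/cc (float32)."""
        return self.calibration.to_density(self.volume)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.volume.shape  # type: ignore[return-value]

    def voxel_centre(self, iz: int, iy: int, ix: int) -> np.ndarray:
        """(x, y, h) µm of a voxel centre."""
        ox, oy, oh = self.origin
        v = self.voxel_size
        return np.array([ox + (ix + 0.5) * v, oy + (iy + 0.5) * v, oh + (iz + 0.5) * v])

    # -- I/O ---------------------------------------------------------
    def _meta(self) -> dict:
        return {
            "voxel_size_um": self.voxel_size,
            "calibration_slope": self.calibration.slope,
            "calibration_intercept": self.calibration.intercept,
            "origin_um": list(self.origin),
            "axis_order": self.axis_order,
        }

    def to_tiff(self, path: str) -> None:
        """Multi-page TIFF + JSON sidecar (and ``<path>.labels.tif`` if present)."""
        tifffile.imwrite(path, self.volume)
        with open(str(path) + ".json", "w") as fh:
            json.dump(self._meta(), fh, indent=1)
        if self.labels is not None:
            tifffile.imwrite(str(path) + ".labels.tif", self.labels.astype(np.uint8))

    @classmethod
    def from_tiff(cls, path: str) -> "Tomogram":
        vol = tifffile.imread(path)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        labels = None
        import os

        lp = str(path) + ".labels.tif"
        if os.path.exists(lp):
            labels = tifffile.imread(lp)
        return cls(
            volume=vol,
            voxel_size=meta["voxel_size_um"],
            calibration=Calibration(meta["calibration_slope"],
                                    meta["calibration_intercept"]),
            origin=tuple(meta["origin_um"]),
            axis_order=meta["axis_order"],
            labels=labels,
        )

    def to_nrrd(self, path: str) -> None:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(self.volume)
        img.SetSpacing((self.voxel_size,) * 3)
        for k, v in self._meta().items():
            img.SetMetaData(k, json.dumps(v))
        sitk.WriteImage(img, path)

    @classmethod
    def from_nrrd(cls, path: str) -> "Tomogram":
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        meta = {k: json.loads(img.GetMetaData(k)) for k in img.GetMetaDataKeys()
                if k.startswith(("voxel", "calibration", "origin", "axis"))}
        return cls(
            volume=sitk.GetArrayFromImage(img),
            voxel_size=float(meta.get("voxel_size_um", img.GetSpacing()[0])),
            calibration=Calibration(meta.get("calibration_slope", 0.05),
                                    meta.get("calibration_intercept", 0.0)),
            origin=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
            axis_order=str(meta.get("axis_order", "zyx")),
        )


def _grid(network: MPCNetwork, preset: ScanPreset,
          shape: Optional[Tuple[int, int, int]]) -> Tuple[Tuple[int, int, int],
                                                          Tuple[float, float, float]]:
    env = network.envelope
    v = preset.voxel_size
    need_z = int(np.ceil(env.depth / v)) + 1
    need_xy = int(np.ceil(2.0 * (env.R_o + 2 * v) / v))
    if shape is None:
        nz = min(need_z, preset.n_slices)
        if need_z > preset.n_slices:
            raise VoxelizationError(
                f"envelope needs {need_z} slices but preset provides "
                f"{preset.n_slices}; required grid ({need_z}, {need_xy}, {need_xy})"
            )
        shape = (nz, need_xy, need_xy)
    nz, ny, nx = shape
    if nz * v < env.depth - 1e-6 or ny * v < 2 * env.R_o - 1e-6 or nx * v < 2 * env.R_o - 1e-6:
        raise VoxelizationError(
            f"field of view {shape} at {v} µm/voxel does not cover the envelope; "
            f"required grid ({need_z}, {need_xy}, {need_xy})"
        )
    # put the envelope axis on a voxel centre: thinning algorithms erase
    # tubes that sit perfectly symmetric between voxels
    cy, cx = (ny - 1) // 2, (nx - 1) // 2
    origin = (-(cx + 0.5) * v, -(cy + 0.5) * v, 0.0)
    return shape, origin


def _paint_scene(
    network: MPCNetwork,
    state,
    shape: Tuple[int, int, int],
    origin: Tuple[float, float, float],
    v: float,
    densities: TissueDensities,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render density + label volumes by voxel-centre sampling."""
    nz, ny, nx = shape
    env = network.envelope
    dens = np.full(shape, densities.air, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint8)

    # envelope: soft tissue
    zc = origin[2] + (np.arange(nz) + 0.5) * v
    yc = origin[1] + (np.arange(ny) + 0.5) * v
    xc = origin[0] + (np.arange(nx) + 0.5) * v
    r2 = yc[:, None] ** 2 + xc[None, :] ** 2
    env_r = np.array([envelope_radius(env, min(z, env.depth)) if z >= 0 else 0.0
                      for z in zc])
    inside = r2[None, :, :] <= (env_r**2)[:, None, None]
    dens[inside] = densities.soft_tissue
    labels[inside] = LABELS["soft_tissue"]

    # interstitial mineral field (resampled nearest onto the voxel grid)
    if state is not None and np.any(state.interstitial_field > 0):
        gi = state.interstitial_field
        go, gp = state.grid_origin, state.grid_pitch
        iz = np.clip(((zc - go[2]) / gp).astype(int), 0, gi.shape[0] - 1)
        iy = np.clip(((yc - go[1]) / gp).astype(int), 0, gi.shape[1] - 1)
        ix = np.clip(((xc - go[0]) / gp).astype(int), 0, gi.shape[2] - 1)
        field = gi[np.ix_(iz, iy, ix)]
        m = (field > 0) & inside
        dens[m] = np.maximum(dens[m], field[m])
        labels[m] = LABELS["interstitial_mineral"]

    # tubules: paint wall shell, lumen, deposit annulus per segment
    for s in network.segments:
        dep = float(state.wall_deposit[s.id]) if state is not None else 0.0
        wall_md = (
            float(state.wall_mineral_density[s.id]) if state is not None else 0.0
        )
        r_lum = s.radius
        r_eff = max(r_lum - dep, 0.0)
        r_out = r_lum + s.wall_thickness
        lo = np.minimum(s.p0, s.p1) - r_out - v
        hi = np.maximum(s.p0, s.p1) + r_out + v
        iz0, iz1 = _rng(lo[2], hi[2], origin[2], v, nz)
        iy0, iy1 = _rng(lo[1], hi[1], origin[1], v, ny)
        ix0, ix1 = _rng(lo[0], hi[0], origin[0], v, nx)
        if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
            continue
        Z, Y, X = np.meshgrid(zc[iz0:iz1], yc[iy0:iy1], xc[ix0:ix1], indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)
        d = _dist_to_segment(pts, s.p0, s.p1)
        sub_d = dens[iz0:iz1, iy0:iy1, ix0:ix1]
        sub_l = labels[iz0:iz1, iy0:iy1, ix0:ix1]
        wall = (d <= r_out) & (d > r_lum)
        if wall_md > 0:
            sub_d[wall] = wall_md
            sub_l[wall] = LABELS["wall_mineral"]
        else:
            sub_d[wall] = densities.soft_tissue
            sub_l[wall] = LABELS["tubule_wall"]
        lum = d <= r_lum
        sub_d[lum] = densities.lumen
        sub_l[lum] = LABELS["lumen"]
        if dep > 0:
            annulus = (d <= r_lum) & (d > r_eff)
            sub_d[annulus] = densities.wall_deposit
            sub_l[annulus] = LABELS["intratubular_mineral"]
    return dens, labels


def _rng(lo: float, hi: float, org: float, v: float, n: int) -> Tuple[int, int]:
    i0 = max(int(np.floor((lo - org) / v)), 0)
    i1 = min(int(np.ceil((hi - org) / v)) + 1, n)
    return i0, i1


def _dist_to_segment(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    d = p1 - p0
    L2 = float(d @ d)
    if L2 < 1e-12:
        return np.linalg.norm(pts - p0, axis=-1)
    t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
    return np.linalg.norm(pts - (p0 + t[..., None] * d), axis=-1)


def _finish(dens: np.ndarray, labels: np.ndarray, preset: ScanPreset,
            calibration: Calibration, origin, seed: int) -> Tomogram:
    gray = calibration.to_gray(dens)
    if preset.psf_sigma > 0:
        gray = ndimage.gaussian_filter(gray, preset.psf_sigma)
    if preset.noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, preset.noise_sd, size=gray.shape)
    vol = np.clip(np.rint(gray), 0, 65535).astype(np.uint16)
    return Tomogram(
        volume=vol,
        voxel_size=preset.voxel_size,
        calibration=calibration,
        origin=origin,
        labels=labels,
    )


def voxelize(
    network: MPCNetwork,
    state=None,
    preset: ScanPreset = PRESETS["10X"],
    seed: int = 0,
    shape: Optional[Tuple[int, int, int]] = None,
    densities: TissueDensities = TissueDensities(),
    calibration: Calibration = Calibration(),
) -> Tomogram:
    """Render a calibrated grayscale tomogram of the mineralized scene.

    Deterministic for a fixed seed.  Ground-truth labels ride along in
    ``Tomogram.labels``; pass ``shape`` to control the grid (it must
    cover the envelope) or let it default to the tight bounding grid.
    """
    shape, origin = _grid(network, preset, shape)
    dens, labels = _paint_scene(network, state, shape, origin,
                                preset.voxel_size, densities)
    return _finish(dens, labels, preset, calibration, origin, seed)


def voxelize_iodine(
    network: MPCNetwork,
    preset: ScanPreset = PRESETS["10X"],
    seed: int = 0,
    shape: Optional[Tuple[int, int, int]] = None,
    lumen_gray: float = 30000.0,
    tissue_gray: float = 8000.0,
    background_gray: float = 1000.0,
) -> Tomogram:
    """Inverse-contrast (iodine-stained) rendering: lumina bright.

    Emulates the stained acquisition used for tubule architecture:
    open tubule lumina appear bright against darker parenchyma so the
    zonation stage can segment and skeletonize them.  Mineral states are
    not rendered (the stain scan images patent tubules).
    """
    shape, origin = _grid(network, preset, shape)
    nz, ny, nx = shape
    v = preset.voxel_size
    env = network.envelope
    gray = np.full(shape, background_gray, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.uint8)
    zc = origin[2] + (np.arange(nz) + 0.5) * v
    yc = origin[1] + (np.arange(ny) + 0.5) * v
    xc = origin[0] + (np.arange(nx) + 0.5) * v
    r2 = yc[:, None] ** 2 + xc[None, :] ** 2
    env_r = np.array([envelope_radius(env, min(z, env.depth)) if z >= 0 else 0.0
                      for z in zc])
    inside = r2[None, :, :] <= (env_r**2)[:, None, None]
    gray[inside] = tissue_gray
    labels[inside] = LABELS["soft_tissue"]
    for s in network.segments:
        r_lum = s.radius
        lo = np.minimum(s.p0, s.p1) - r_lum - v
        hi = np.maximum(s.p0, s.p1) + r_lum + v
        iz0, iz1 = _rng(lo[2], hi[2], origin[2], v, nz)
        iy0, iy1 = _rng(lo[1], hi[1], origin[1], v, ny)
        ix0, ix1 = _rng(lo[0], hi[0], origin[0], v, nx)
        if iz0 >= iz1 or iy0 >= iy1 or ix0 >= ix1:
            continue
        Z, Y, X = np.meshgrid(zc[iz0:iz1], yc[iy0:iy1], xc[ix0:ix1], indexing="ij")
        d = _dist_to_segment(np.stack([X, Y, Z], axis=-1), s.p0, s.p1)
        lum = d <= r_lum
        gray[iz0:iz1, iy0:iy1, ix0:ix1][lum] = lumen_gray
        labels[iz0:iz1, iy0:iy1, ix0:ix1][lum] = LABELS["lumen"]
    if preset.psf_sigma > 0:
        gray = ndimage.gaussian_filter(gray, preset.psf_sigma)
    if preset.noise_sd > 0:
        rng = np.random.default_rng(seed)
        gray = gray + rng.normal(0.0, preset.noise_sd, size=gray.shape)
    vol = np.clip(np.rint(gray), 0, 65535).astype(np.uint16)
    return Tomogram(
        volume=vol,
        voxel_size=preset.voxel_size,
        calibration=Calibration(),
        origin=origin,
        labels=labels,
    )
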