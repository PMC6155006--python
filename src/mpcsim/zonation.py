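"""Functional zonation: skeleton-based tubule sizing and peak statistics.

From an inverse-contrast (iodine-mode) tomogram the tubule lumina are
thresholded, skeletonized in 3D, and sized with the Euclidean distance
transform: the local diameter at a skeleton voxel is twice its distance
to the nearest background voxel centre (validated as close to unbiased
on analytic cylinders).  Diameters are pooled per axial zone,
histogrammed, fitted
with a Gaussian mixture (order chosen by BIC), and peak pairs are
compared with the half-width-at-half-maximum rule: two peaks differ
significantly iff |mean_a - mean_b| >= HWHM_a + HWHM_b, with
HWHM = sigma*sqrt(2 ln 2).

Tubule fraction is the segmented lumen volume over the tissue volume
within each zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .geometry import EnvelopeSpec
from .phantom import Tomogram

__all__ = [
    "HWHM_FACTOR",
    "GaussianPeak",
    "PeakComparison",
    "ZoneProfile",
    "skeletonize_and_size",
    "fit_peaks",
    "peak_significance",
    "tubule_fraction",
    "zone_profiles",
]

#: HWHM of a Gaussian = sigma * sqrt(2 ln 2)
HWHM_FACTOR = float(np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GaussianPeak:
    mean: float  # µm
    sd: float  # µm
    weight: float

    @property
    def hwhm(self) -> float:
        return self.sd * HWHM_FACTOR


@dataclass(frozen=True)
class PeakComparison:
    """HWHM significance rule for a pair of Gaussian peaks."""

    peak_a: GaussianPeak
    peak_b: GaussianPeak
    significant: bool
    criterion_value: float  # HWHM_a + HWHM_b, µm
    separation: float  # |mean_a - mean_b|, µm


@dataclass
class ZoneProfile:
    """Per-zone diameter readout."""

    zone: str
    diameters: np.ndarray  # µm
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: List[GaussianPeak] = field(default_factory=list)
    tubule_fraction: Optional[float] = None
    degenerate: bool = False


def _auto_threshold(gray: np.ndarray) -> float:
    """Lumen threshold at half-maximum between tissue and lumen levels.

    The image has three classes (background, parenchyma, bright lumina);
    multi-Otsu separates them, then the cut is placed halfway between
    the tissue and lumen class means — the half-maximum criterion that
    preserves object size under PSF blur (plain Otsu splits at the
    tissue level and a class-boundary cut shrinks blurred thin tubules).
    """
    flat = gray.ravel()
    if flat.size > 2_000_000:
        flat = flat[:: flat.size // 2_000_000 + 1]
    if np.unique(flat).size < 3:
        return float(threshold_otsu(flat)) if np.unique(flat).size > 1 else float(flat[0])
    # 1-D 3-medians (background / parenchyma / lumen), quantile-initialized
    # and deterministic; medians resist the PSF-blurred edge voxels that
    # smear the histogram between the class modes
    # top class initialized at the maximum: bright lumina can be an
    # arbitrarily small voxel fraction, so no fixed quantile is safe
    c = np.array([np.quantile(flat, 0.02), np.quantile(flat, 0.5),
                  float(flat.max())])
    if c[0] == c[1] or c[1] == c[2]:
        c = np.quantile(flat, [0.0, 0.5, 1.0]).astype(float)
    for _ in range(25):
        cuts = (c[:-1] + c[1:]) / 2.0
        lab = np.searchsorted(cuts, flat)
        new = np.array([
            np.median(flat[lab == i]) if np.any(lab == i) else c[i]
            for i in range(3)
        ])
        if np.allclose(new, c):
            break
        c = new
    tissue_level, lumen_level = float(c[1]), float(c[2])
    return 0.5 * (tissue_level + lumen_level)


def peak_significance(peak_a: GaussianPeak, peak_b: GaussianPeak) -> PeakComparison:
    """Two peaks differ significantly iff their separation is at least
    the sum of their half-widths at half-maximum (boundary inclusive)."""
    if peak_a.sd <= 0 or peak_b.sd <= 0:
        raise ValueError("peak standard deviations must be positive")
    crit = peak_a.hwhm + peak_b.hwhm
    sep = abs(peak_a.mean - peak_b.mean)
    return PeakComparison(peak_a, peak_b, bool(sep >= crit), crit, sep)


def skeletonize_and_size(
    tomogram: Tomogram,
    threshold: Optional[float] = None,
    min_diameter: float = 0.0,
    smooth_sigma: float = 0.0,
) -> pd.DataFrame:
    """Skeletonize the bright tubule lumina and size them locally.

    Returns a DataFrame with one row per non-junction skeleton voxel:
    voxel indices, world position (µm), axial depth ``h_um`` and local
    ``diameter_um`` (2*EDT).  ``threshold`` defaults to an automatic
    three-class split of the grayscale histogram.  Branch/junction and
    endpoint voxels are excluded (the distance transform is biased
    there).
    """
    gray = tomogram.volume.astype(np.float32)
    if smooth_sigma > 0:
        gray = ndimage.gaussian_filter(gray, smooth_sigma)
    if threshold is None:
        threshold = _auto_threshold(gray)
    mask = gray > threshold
    if not mask.any():
        warnings.warn("empty lumen mask; no tubules found", stacklevel=2)
        return pd.DataFrame(
            columns=["iz", "iy", "ix", "x_um", "y_um", "h_um", "diameter_um"]
        )
    skel = skeletonize(mask)
    edt = ndimage.distance_transform_edt(mask)
    # neighbour count on the skeleton: keep simple path voxels (2 neighbours)
    kernel = np.ones((3, 3, 3), dtype=np.uint8)
    kernel[1, 1, 1] = 0
    nb = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
    keep = skel & (nb == 2)
    if not keep.any():
        keep = skel
    zz, yy, xx = np.nonzero(keep)
    v = tomogram.voxel_size
    # local radius = max EDT within the 3x3x3 neighbourhood of the
    # skeleton voxel: thinning may park the skeleton a voxel off the true
    # axis, where the raw EDT understates the radius; the neighbourhood
    # maximum recovers the centred value (validated on analytic
    # cylinders: < 4% bias across 17.5-175 µm at 5 µm/voxel)
    edt_max = ndimage.maximum_filter(edt, size=3)
    diam = 2.0 * edt_max[zz, yy, xx] * v
    ox, oy, oh = tomogram.origin
    df = pd.DataFrame(
        {
            "iz": zz,
            "iy": yy,
            "ix": xx,
            "x_um": ox + (xx + 0.5) * v,
            "y_um": oy + (yy + 0.5) * v,
            "h_um": oh + (zz + 0.5) * v,
            "diameter_um": diam,
        }
    )
    return df[df.diameter_um >= min_diameter].reset_index(drop=True)


def fit_peaks(
    diameters: Sequence[float],
    k_max: int = 3,
    seed: int = 0,
    reg_covar: float = 1e-6,
) -> Tuple[List[GaussianPeak], bool]:
    """Gaussian-mixture fit of a diameter sample; order chosen by BIC.

    Returns (peaks sorted by ascending mean, degenerate_flag).  Requires
    at least 20 samples; an all-equal sample yields a single zero-width
    peak with the degenerate flag set.  ``reg_covar`` floors component
    variances — pass the squared measurement resolution (e.g. half a
    voxel, squared) so BIC cannot split sub-resolution quantization
    spikes into separate peaks.
    """
    from sklearn.mixture import GaussianMixture

    d = np.asarray(diameters, dtype=float).reshape(-1, 1)
    if d.shape[0] < 20:
        raise ValueError(f"need >= 20 diameter samples, got {d.shape[0]}")
    if np.ptp(d) < 1e-12:
        return [GaussianPeak(float(d[0, 0]), 0.0, 1.0)], True
    best = None
    best_bic = np.inf
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=3,
            random_state=seed, reg_covar=reg_covar,
        ).fit(d)
        bic = gm.bic(d)
        if bic < best_bic:
            best_bic, best = bic, gm
    order = np.argsort(best.means_[:, 0])
    peaks = [
        GaussianPeak(
            float(best.means_[i, 0]),
            float(np.sqrt(best.covariances_[i, 0, 0])),
            float(best.weights_[i]),
        )
        for i in order
    ]
    return peaks, False


def tubule_fraction(
    lumen_mask: np.ndarray,
    tissue_mask: np.ndarray,
    zone_index: np.ndarray,
) -> Dict[str, float]:
    """Per-zone lumen/tissue volume ratio in [0, 1].

    ``zone_index`` assigns each slice (or voxel) a zone code 0..3;
    zones with no tissue are omitted (fraction undefined).
    """
    if lumen_mask.shape != tissue_mask.shape:
        raise ValueError("masks must be aligned")
    out: Dict[str, float] = {}
    for zi, zone in enumerate(("Z1", "Z2", "Z3", "Z4")):
        m = zone_index == zi
        tis = int((tissue_mask & m).sum()) if m.any() else 0
        if tis == 0:
            continue
        lum = int((lumen_mask & m & tissue_mask).sum())
        out[zone] = lum / tis
    return out


def zone_profiles(
    tomogram: Tomogram,
    envelope: EnvelopeSpec,
    threshold: Optional[float] = None,
    zone_bands: Tuple[float, float, float] = (0.25, 0.5, 0.75),
    k_max: int = 3,
    seed: int = 0,
    min_samples: int = 20,
    smooth_sigma: float = 0.0,
) -> Dict[str, ZoneProfile]:
    """Full zonation readout of an iodine-mode tomogram.

    Skeleton diameters are pooled by the zone of their depth,
    histogrammed (Freedman-Diaconis binning), mixture-fitted, and
    combined with per-zone tubule fractions.
    """
    df = skeletonize_and_size(tomogram, threshold=threshold,
                              smooth_sigma=smooth_sigma)
    gray = tomogram.volume.astype(np.float32)
    if smooth_sigma > 0:
        gray = ndimage.gaussian_filter(gray, smooth_sigma)
    thr = _auto_threshold(gray) if threshold is None else threshold
    lumen = gray > thr
    # tissue mask: inside the envelope (labels when present, else geometry)
    if tomogram.labels is not None:
        tissue = tomogram.labels > 0
    else:
        tissue = np.ones_like(lumen)
    nz = tomogram.shape[0]
    v = tomogram.voxel_size
    hs = tomogram.origin[2] + (np.arange(nz) + 0.5) * v
    hs = np.clip(hs, 0.0, envelope.depth)
    zcode = np.searchsorted(np.array(zone_bands) * envelope.depth, hs, side="right")
    zone_index = np.broadcast_to(zcode[:, None, None], tomogram.shape)
    fractions = tubule_fraction(lumen, tissue, zone_index)

    profiles: Dict[str, ZoneProfile] = {}
    for zi, zone in enumerate(("Z1", "Z2", "Z3", "Z4")):
        dz = df[
            np.searchsorted(np.array(zone_bands) * envelope.depth,
                            np.clip(df.h_um, 0, envelope.depth),
                            side="right") == zi
        ]
        diam = dz.diameter_um.to_numpy()
        if diam.size == 0:
            continue
        edges = np.histogram_bin_edges(diam, bins="fd")
        counts, _ = np.histogram(diam, bins=edges)
        prof = ZoneProfile(zone=zone, diameters=diam, bin_edges=edges,
                           counts=counts, tubule_fraction=fractions.get(zone))
        if diam.size >= min_samples:
            prof.peaks, prof.degenerate = fit_peaks(
                diam, k_max=k_max, seed=seed,
                reg_covar=(0.5 * tomogram.voxel_size) ** 2,
            )
        profiles[zone] = prof
    return profiles


def profiles_to_frame(profiles: Dict[str, ZoneProfile]) -> pd.DataFrame:
    """Flatten zone profiles to a CSV-friendly table."""
    rows = []
    for zone, p in profiles.items():
        if p.peaks:
            for i, pk in enumerate(p.peaks):
                rows.append({
                    "zone": zone, "peak": i, "peak_mean_um": pk.mean,
                    "peak_sd_um": pk.sd, "weight": pk.weight,
                    "tubule_fraction": p.tubule_fraction,
                    "n_samples": int(p.diameters.size),
                })
        else:
            rows.append({
                "zone": zone, "peak": None, "peak_mean_um": None,
                "peak_sd_um": None, "weight": None,
                "tubule_fraction": p.tubule_fraction,
                "n_samples": int(p.diameters.size),
            })
    return pd.DataFrame(rows)
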