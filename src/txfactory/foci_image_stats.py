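"""Nuclear-foci image statistics.

Segments H4K16ac-like foci inside a nuclear mask, measures their circularity
(shape factor, 4*pi*area/perimeter**2: 1 for a circle, pi/4 for a square) and
quantifies focus disassembly through the coefficient of variation (SD/mean)
of the pixel intensity over the nuclear area, compared across treatment
groups of nuclei.

The shape factor uses a contour-length perimeter: the binary region is
lightly Gaussian-smoothed and the 0.5-level contour extracted, which
suppresses the pixel-lattice staircase that otherwise inflates perimeters of
smooth objects by ~5%.  Discs of radius >= 10 px score >= 0.98 under this
estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = [
    "FocusMeasurement",
    "NucleusStats",
    "segment_foci",
    "shape_factor",
    "measure_foci",
    "intensity_cv",
    "treatment_comparison",
]

_CONTOUR_SIGMA = 1.0


@dataclass(frozen=True)
class FocusMeasurement:
    label: int
    area_px: float
    perimeter_px: float
    shape_factor: float
    centroid: tuple[float, float]
    mean_intensity: float


@dataclass(frozen=True)
class NucleusStats:
    """Pixel-intensity statistics over a nuclear mask (population SD)."""

    image_id: str
    mean_intensity: float
    sd_intensity: float
    cv: float


def segment_foci(image: np.ndarray, nuclear_mask: np.ndarray, min_area_px: int = 5) -> np.ndarray:
    """Label foci: Otsu bimodal split of the within-mask intensities, then
    connected components of at least ``min_area_px`` pixels.

    Returns an integer label image (0 = background).
    """
    image = np.asarray(image)
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    if image.ndim != 2:
        raise ValueError("a single-channel 2D image is required")
    if nuclear_mask.shape != image.shape:
        raise ValueError("mask shape must match the image")
    if not nuclear_mask.any():
        raise ValueError("the nuclear mask is empty")
    inside = image[nuclear_mask].astype(float)
    if np.ptp(inside) == 0:
        return np.zeros(image.shape, dtype=int)
    thr = threshold_otsu(inside)
    fg = (image > thr) & nuclear_mask
    labels = measure.label(fg, connectivity=2)
    # drop components below the area floor, relabel compactly
    out = np.zeros_like(labels)
    nxt = 1
    for r in measure.regionprops(labels):
        if r.area >= min_area_px:
            out[labels == r.label] = nxt
            nxt += 1
    return out


def _contour_geometry(region_mask: np.ndarray) -> tuple[float, float]:
    """Perimeter and enclosed (shoelace) area of the smoothed 0.5-contour."""
    padded = np.pad(region_mask.astype(float), 4)
    smoothed = gaussian_filter(padded, _CONTOUR_SIGMA)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        return math.nan, math.nan
    perim = 0.0
    area = 0.0
    for c in contours:
        d = np.diff(c, axis=0)
        perim += float(np.hypot(d[:, 0], d[:, 1]).sum())
        x, y = c[:-1, 0], c[:-1, 1]
        xn, yn = np.roll(c[:, 0], -1)[:-1], np.roll(c[:, 1], -1)[:-1]
        area += 0.5 * abs(float(np.dot(x, yn) - np.dot(y, xn)))
    return perim, area


def shape_factor(region_mask: np.ndarray) -> float:
    """Circularity 4*pi*A/P**2 of a connected binary region.

    Degenerate regions too small to carry a contour (one or two pixels)
    return NaN rather than a spurious value.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("the region is empty")
    perim, area = _contour_geometry(region_mask)
    if not math.isfinite(perim) or perim == 0:
        return math.nan
    return 4.0 * math.pi * area / perim**2


def measure_foci(image: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-focus area, perimeter, shape factor, centroid and mean intensity."""
    rows = []
    for r in measure.regionprops(labels, intensity_image=image):
        sub = labels[r.slice] == r.label
        perim, area = _contour_geometry(sub)
        sf = 4.0 * math.pi * area / perim**2 if (math.isfinite(perim) and perim > 0) else math.nan
        rows.append(
            dict(
                label=r.label,
                area_px=float(r.area),
                perimeter_px=perim,
                shape_factor=sf,
                centroid_y=float(r.centroid[0]),
                centroid_x=float(r.centroid[1]),
                mean_intensity=float(r.intensity_mean),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["label", "area_px", "perimeter_px", "shape_factor", "centroid_y", "centroid_x", "mean_intensity"],
    )


def intensity_cv(image: np.ndarray, nuclear_mask: np.ndarray, image_id: str = "") -> NucleusStats:
    """Coefficient of variation (population SD / mean) of the intensity over
    the nuclear mask; high for focal staining, low for dispersed staining."""
    image = np.asarray(image, dtype=float)
    nuclear_mask = np.asarray(nuclear_mask, dtype=bool)
    if nuclear_mask.shape != image.shape:
        raise ValueError("mask shape must match the image")
    if not nuclear_mask.any():
        raise ValueError("the nuclear mask is empty")
    vals = image[nuclear_mask]
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("mean intensity over the mask must be positive")
    sd = float(vals.std(ddof=0))
    return NucleusStats(image_id=image_id, mean_intensity=mean, sd_intensity=sd, cv=sd / mean)


def treatment_comparison(
    image_groups: dict,
    min_cells_per_group: int = 200,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare per-nucleus intensity CV between treatment groups.

    ``image_groups`` maps a group name to a sequence of (image, mask) pairs,
    one per nucleus.  Returns (per-group summary, pairwise differences of
    mean CV with a percentile bootstrap interval).  Groups smaller than
    ``min_cells_per_group`` are analysed but flagged with a warning.
    """
    rng = np.random.default_rng(seed)
    cvs = {}
    rows = []
    for name, images in image_groups.items():
        vals = np.array([intensity_cv(img, msk).cv for img, msk in images])
        if vals.size < min_cells_per_group:
            warnings.warn(
                f"group {name!r} has {vals.size} nuclei, below the recommended "
                f"minimum of {min_cells_per_group}"
            )
        cvs[name] = vals
        rows.append(
            dict(
                group=name, n=int(vals.size),
                cv_mean=float(vals.mean()),
                cv_sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                undersized=vals.size < min_cells_per_group,
            )
        )
    summary = pd.DataFrame(rows)

    pair_rows = []
    names = list(cvs)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = cvs[names[i]], cvs[names[j]]
            diff = float(a.mean() - b.mean())
            boot = np.empty(n_bootstrap)
            for k in range(n_bootstrap):
                boot[k] = rng.choice(a, size=a.size).mean() - rng.choice(b, size=b.size).mean()
            lo, hi = np.percentile(boot, [2.5, 97.5])
            pair_rows.append(
                dict(group_a=names[i], group_b=names[j],
                     cv_diff=diff, ci_low=float(lo), ci_high=float(hi))
            )
    pairs = pd.DataFrame(pair_rows, columns=["group_a", "group_b", "cv_diff", "ci_low", "ci_high"])
    return summary, pairs
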