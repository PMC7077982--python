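"""c-Fos-style puncta quantification on grayscale images.

The workflow mirrors the classic particle-analysis recipe: threshold the
image so only puncta are foreground, split clumped puncta with a
distance-transform watershed, then count and measure particles inside a
hand-drawn region of interest. Density is puncta per mm^2 of ROI;
coverage is the percent of the ROI area covered by detected puncta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Point, Polygon
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "RegionOfInterest",
    "PunctaResult",
    "threshold_image",
    "watershed_split",
    "analyze_particles",
    "count_puncta",
]


@dataclass(frozen=True)
class RegionOfInterest:
    """Polygonal ROI in pixel coordinates, with the physical pixel size."""

    vertices_px: np.ndarray  # (n, 2) as (row, col)
    pixel_size_um: float

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices_px, dtype=np.float64).reshape(-1, 2)
        if verts.shape[0] < 3:
            raise ValueError("ROI polygon needs at least 3 vertices")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError("ROI polygon is self-intersecting or degenerate")
        if poly.area <= 0:
            raise ValueError("ROI polygon has zero area")
        object.__setattr__(self, "vertices_px", verts)

    @classmethod
    def rectangle(
        cls, top: float, left: float, bottom: float, right: float,
        pixel_size_um: float,
    ) -> "RegionOfInterest":
        verts = [(top, left), (top, right), (bottom, right), (bottom, left)]
        return cls(np.asarray(verts), pixel_size_um)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices_px)

    @property
    def area_um2(self) -> float:
        return self.polygon().area * self.pixel_size_um**2

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6

    def contains(self, row: float, col: float) -> bool:
        # boundary counts as inside so edge centroids are not dropped
        p = Point(row, col)
        poly = self.polygon()
        return poly.contains(p) or poly.touches(p)


@dataclass(frozen=True)
class PunctaResult:
    """Per-ROI particle analysis summary."""

    count: int
    density_per_mm2: float
    coverage_percent: float
    areas_um2: np.ndarray

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas_um2, dtype=np.float64)
        if self.count != areas.size:
            raise ValueError("count must equal the number of per-punctum areas")
        if not (-1e-9 <= self.coverage_percent <= 100 + 1e-9):
            raise ValueError("coverage must lie in [0, 100]")
        object.__setattr__(self, "areas_um2", areas)


def threshold_image(
    image: np.ndarray, level: float | None = None, method: str = "otsu"
) -> np.ndarray:
    """Boolean foreground mask: intensity >= level.

    The level is either fixed (``level``) or chosen automatically
    (Otsu, the default) — an automatic, reproducible stand-in for the
    operator-set threshold of the original workflow.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if level is None:
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if np.ptp(image) == 0:
            raise ValueError("cannot auto-threshold a constant image")
        level = threshold_otsu(image)
    return image >= level


def watershed_split(
    mask: np.ndarray, smoothing_sigma: float | None = None,
    min_distance_px: int | None = None,
) -> np.ndarray:
    """Label a binary mask, splitting touching blobs by watershed.

    Seeds are the local maxima of the (lightly smoothed) Euclidean distance
    transform; the light smoothing suppresses the spurious multiple maxima
    a single noisy disk would otherwise produce, while a minimum peak
    separation of about half the typical blob radius keeps the two maxima
    of a touching pair distinct. Defaults are derived from the mask's
    typical blob size and were validated on constructed touching-disk
    pairs and noisy synthetic fixtures.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    typical_radius = float(distance.max())
    sigma = smoothing_sigma if smoothing_sigma is not None else max(
        0.15 * typical_radius, 0.8
    )
    smoothed = gaussian(distance, sigma=sigma)
    min_dist = min_distance_px if min_distance_px is not None else max(
        int(round(0.5 * typical_radius)), 1
    )
    peak_coords = peak_local_max(
        smoothed, min_distance=min_dist, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peak_coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return cc_label(mask).astype(np.int32)
    labels = watershed(-smoothed, markers=markers, mask=mask)
    # any blob that received no seed keeps its own label
    missed = mask & (labels == 0)
    if missed.any():
        extra = cc_label(missed)
        extra[extra > 0] += labels.max()
        labels = labels + extra
    return labels.astype(np.int32)


def analyze_particles(
    labels: np.ndarray,
    roi: RegionOfInterest,
    min_area_um2: float = 4.0,
) -> PunctaResult:
    """Count and measure labelled particles inside the ROI.

    Particles whose centroid lies inside the ROI polygon and whose area is
    at least ``min_area_um2`` are counted. Density = count / ROI area
    (per mm^2); coverage = summed particle area / ROI area * 100. The
    default minimum area rejects single-pixel noise.
    """
    labels = np.asarray(labels)
    if roi.area_um2 <= 0:
        raise ValueError("ROI has zero area")
    px_area_um2 = roi.pixel_size_um**2
    areas: list[float] = []
    for region in regionprops(labels):
        area_um2 = region.area * px_area_um2
        if area_um2 < min_area_um2:
            continue
        cy, cx = region.centroid
        if roi.contains(cy, cx):
            areas.append(area_um2)
    areas_arr = np.asarray(areas)
    total_area = float(areas_arr.sum()) if areas_arr.size else 0.0
    coverage = min(100.0, 100.0 * total_area / roi.area_um2)
    return PunctaResult(
        count=len(areas),
        density_per_mm2=len(areas) / roi.area_mm2,
        coverage_percent=coverage,
        areas_um2=areas_arr,
    )


def count_puncta(
    image: np.ndarray,
    roi: RegionOfInterest,
    level: float | None = None,
    min_area_um2: float = 4.0,
) -> PunctaResult:
    """Full pipeline: threshold -> watershed split -> particle analysis."""
    mask = threshold_image(image, level=level)
    labels = watershed_split(mask)
    return analyze_particles(labels, roi, min_area_um2=min_area_um2)
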