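"""Marker-controlled watershed counting of red cells in smear images.

Pipeline: large-scale background correction → global threshold (Otsu) →
distance transform of the foreground mask → h-maxima markers → watershed
split of touching cells → area filtering (platelet-scale debris rejected)
and morphometrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk, h_maxima
from skimage.segmentation import watershed

__all__ = [
    "CountingParams",
    "SegmentationLabels",
    "CellRecord",
    "CountResult",
    "correct_background",
    "segment",
    "count_cells",
    "count_pipeline",
]


@dataclass(frozen=True)
class CountingParams:
    """Counting configuration.

    Areas are µm² at the object plane and converted to px² through
    ``pixel_size_um``.  Defaults suit a human blood smear: an RBC projects
    roughly 50 µm², platelets well under 20 µm².
    """

    min_area_um2: float = 20.0
    max_area_um2: float = 150.0
    pixel_size_um: float = 0.5
    h_maxima_depth: float = 0.10  # fraction of the distance-map maximum
    threshold_method: str = "otsu"
    background_correction: str = "morphological"
    cells_dark: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("need 0 < min_area < max_area")

    @property
    def min_area_px(self) -> float:
        return self.min_area_um2 / self.pixel_size_um**2

    @property
    def max_area_px(self) -> float:
        return self.max_area_um2 / self.pixel_size_um**2


@dataclass
class SegmentationLabels:
    """Label image (0 = background, labels contiguous 1..N) plus the
    provenance of each label: 'threshold' for untouched components,
    'watershed' for components split from a larger mask region."""

    labels: np.ndarray
    provenance: dict[int, str] = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())


@dataclass
class CellRecord:
    centroid_px: tuple[float, float]
    area_um2: float
    eccentricity: float
    mean_intensity: float


@dataclass
class CountResult:
    n_cells: int
    records: list[CellRecord]
    rejected: dict[str, int]


def correct_background(
    image: np.ndarray,
    method: str = "morphological",
    radius_px: int = 40,
    cells_dark: bool = True,
) -> np.ndarray:
    """Remove slowly-varying illumination (mean-preserving).

    ``morphological``: grey closing (dark objects) / opening (bright) with a
    structuring element much larger than a cell estimates the background,
    which is then divided out.  ``polynomial``: a least-squares 2-D
    quadratic surface plays the same role.  Contrast polarity is never
    inverted.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expects a grayscale image")
    if method == "morphological":
        if 2 * radius_px + 1 >= min(img.shape):
            raise ValueError("structuring element must be smaller than the image")
        # the background is smooth by assumption, so estimate it on a 4x
        # downsampled copy (the closing cost scales with footprint area)
        ds = 4 if min(img.shape) >= 16 * 4 else 1
        small = img[::ds, ::ds]
        r_small = max(radius_px // ds, 2)
        op = ndimage.grey_closing if cells_dark else ndimage.grey_opening
        bg_small = op(small, footprint=disk(r_small))
        bg_small = ndimage.uniform_filter(bg_small, size=max(r_small // 2, 1))
        bg = np.asarray(
            ndimage.zoom(bg_small, (img.shape[0] / small.shape[0],
                                    img.shape[1] / small.shape[1]), order=1)
        )
        if bg.shape != img.shape:  # zoom rounding
            bg = np.pad(bg, ((0, img.shape[0] - bg.shape[0]),
                             (0, img.shape[1] - bg.shape[1])), mode="edge")
    elif method == "polynomial":
        rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        r = rows.ravel() / img.shape[0]
        c = cols.ravel() / img.shape[1]
        A = np.stack([np.ones_like(r), r, c, r * c, r**2, c**2], axis=1)
        coef, *_ = np.linalg.lstsq(A, img.ravel(), rcond=None)
        bg = (A @ coef).reshape(img.shape)
    else:
        raise ValueError(f"unknown background method {method!r}")
    bg = np.maximum(bg, 1e-6 * bg.max() if bg.max() > 0 else 1e-6)
    corrected = img / bg * bg.mean()
    return corrected * img.mean() / max(corrected.mean(), 1e-12)


def segment(image: np.ndarray, params: CountingParams) -> SegmentationLabels:
    """Marker-controlled watershed segmentation of a background-corrected
    grayscale image.

    Foreground comes from a global Otsu threshold (cells darker than
    background by default); touching cells are split by flooding the
    negated distance transform from h-maxima markers.  An empty foreground
    yields zero labels, not an error.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expects a grayscale image")
    work = -img if params.cells_dark else img
    if work.max() - work.min() < 1e-12:
        return SegmentationLabels(np.zeros(img.shape, dtype=np.int32))
    thr = threshold_otsu(work)
    mask = work > thr
    # red cells have central pallor: fill interior holes so the distance
    # relief has one dome per cell, not a ring
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return SegmentationLabels(np.zeros(img.shape, dtype=np.int32))

    distance = ndimage.distance_transform_edt(mask)
    # smooth the relief so jagged mask edges do not seed spurious maxima
    distance = ndimage.gaussian_filter(distance, 1.0)
    depth = params.h_maxima_depth * distance.max()
    peaks = h_maxima(distance, max(depth, 1e-6))
    markers, n_markers = ndimage.label(peaks)
    if n_markers == 0:
        markers, _ = ndimage.label(mask)
        labels = markers
    else:
        labels = watershed(-distance, markers, mask=mask)

    # relabel contiguously and record provenance (split vs plain component)
    comp, _ = ndimage.label(mask)
    out = np.zeros_like(labels, dtype=np.int32)
    provenance: dict[int, str] = {}
    next_id = 1
    for lab in range(1, int(labels.max()) + 1):
        sel = labels == lab
        if not sel.any():
            continue
        out[sel] = next_id
        comp_ids = np.unique(comp[sel])
        comp_ids = comp_ids[comp_ids > 0]
        n_sibs = (
            int((np.unique(labels[comp == comp_ids[0]]) > 0).sum())
            if len(comp_ids)
            else 1
        )
        provenance[next_id] = "watershed" if n_sibs > 1 else "threshold"
        next_id += 1
    return SegmentationLabels(out, provenance)


def count_cells(
    seg: SegmentationLabels,
    params: CountingParams,
    intensity_image: np.ndarray | None = None,
) -> CountResult:
    """Area-filter the segmentation and summarise morphometrics.

    Objects below ``min_area`` (platelet-scale, optically dense debris) or
    above ``max_area`` are rejected and tallied by reason.
    """
    labels = seg.labels
    records: list[CellRecord] = []
    rejected = {"too_small": 0, "too_large": 0}
    props = regionprops(
        labels, intensity_image=intensity_image if intensity_image is not None else None
    )
    for p in props:
        area_um2 = p.area * params.pixel_size_um**2
        if area_um2 < params.min_area_um2:
            rejected["too_small"] += 1
            continue
        if area_um2 > params.max_area_um2:
            rejected["too_large"] += 1
            continue
        records.append(
            CellRecord(
                centroid_px=tuple(float(c) for c in p.centroid),
                area_um2=float(area_um2),
                eccentricity=float(p.eccentricity),
                mean_intensity=(
                    float(p.intensity_mean) if intensity_image is not None else float("nan")
                ),
            )
        )
    return CountResult(len(records), records, rejected)


def count_pipeline(
    image: np.ndarray, params: CountingParams | None = None
) -> tuple[CountResult, SegmentationLabels]:
    """Background correction → segmentation → counting, in one call.

    Colour input is reduced to the green channel (best cell/background
    contrast for unstained smears) before correction.
    """
    params = params or CountingParams()
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., 1]
    corrected = correct_background(
        img, method=params.background_correction, cells_dark=params.cells_dark
    )
    seg = segment(corrected, params)
    return count_cells(seg, params, intensity_image=img), seg
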