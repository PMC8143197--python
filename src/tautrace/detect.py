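"""Frame-level image operations.

Local-background estimation, neurite-seed punctum detection with explicit
size and intensity rules, soma-aggregate detection within tracked cell
patches, baseline subtraction of no-lysate counts, and a threshold-based
neurite-area surrogate.

Detection rules are deliberately simple and fully specified: a punctum is a
connected component of pixels exceeding the local background by a fixed
intensity threshold (default 10,000 gray levels), accepted when its
equivalent diameter falls in a 0.1-4 µm band.  Larger bright objects (cell
bodies, cell clusters) are rejected and, after dilation, exclude nearby
detections to avoid overcounting within clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage import measure, morphology as skmorph

DEFAULT_THRESHOLD_GRAY = 10000.0
DEFAULT_DIAMETER_BAND_UM = (0.1, 4.0)
DEFAULT_BACKGROUND_RADIUS_PX = 15


# ----------------------------------------------------------------------
def local_background(frame: np.ndarray, radius_px: int = DEFAULT_BACKGROUND_RADIUS_PX,
                     stride: int | None = None) -> np.ndarray:
    """Per-pixel local background via a windowed median of given radius.

    The median is exact at every evaluated pixel.  For large frames it is
    evaluated on a coarse grid (default stride ``radius_px // 3``) and
    bilinearly interpolated, which is accurate for backgrounds varying on
    scales larger than the window; pass ``stride=1`` for the dense filter.
    """
    frame = np.asarray(frame)
    radius_px = int(radius_px)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    h, w = frame.shape
    if 2 * radius_px + 1 > min(h, w):
        raise ValueError("background radius larger than the image")
    if stride is None:
        stride = 1 if min(h, w) <= 96 else max(1, radius_px // 3)

    f = frame.astype(np.float32)
    pad = np.pad(f, radius_px, mode="reflect")
    windows = sliding_window_view(pad, (2 * radius_px + 1, 2 * radius_px + 1))
    gy = np.arange(0, h, stride)
    gx = np.arange(0, w, stride)
    if gy[-1] != h - 1:
        gy = np.append(gy, h - 1)
    if gx[-1] != w - 1:
        gx = np.append(gx, w - 1)
    sub = windows[np.ix_(gy, gx)]
    bg = np.median(sub.reshape(gy.size, gx.size, -1), axis=-1)
    if stride == 1:
        return bg.astype(np.float64)
    interp = RegularGridInterpolator((gy, gx), bg)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()], axis=-1)
    return interp(pts).reshape(h, w)


# ----------------------------------------------------------------------
@dataclass
class SeedDetection:
    """One accepted neurite-seed punctum."""

    frame_index: int
    centroid_px: tuple[float, float]  # (x, y)
    area_px: int
    equivalent_diameter_um: float
    peak_minus_background_gray: float


def min_area_px(diameter_band_um: tuple[float, float], pixel_size_um: float) -> int:
    """Pixel-area floor implied by the lower diameter bound.

    A 0.1 µm object is sub-pixel at typical 10x sampling, so the effective
    floor is one pixel.
    """
    d_min = diameter_band_um[0]
    area_um2 = np.pi * (d_min / 2.0) ** 2
    return max(1, int(np.ceil(area_um2 / pixel_size_um**2)))


def detect_neurite_seeds(
    frame: np.ndarray,
    pixel_size_um: float,
    intensity_threshold_gray: float = DEFAULT_THRESHOLD_GRAY,
    diameter_band_um: tuple[float, float] = DEFAULT_DIAMETER_BAND_UM,
    exclusion_mask: np.ndarray | None = None,
    background: np.ndarray | None = None,
    background_radius_px: int = DEFAULT_BACKGROUND_RADIUS_PX,
    frame_index: int = 0,
) -> list[SeedDetection]:
    """Detect small bright puncta above local background.

    Connected components (8-connectivity) of pixels exceeding
    ``background + intensity_threshold_gray`` are measured; components with
    equivalent diameter above the band maximum are rejected and, dilated by
    2 px, veto any detection they touch (large-bright-area exclusion).
    Components smaller than the pixel-area floor implied by the band
    minimum are rejected.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel calibration is required")
    if intensity_threshold_gray <= 0:
        raise ValueError("intensity threshold must be positive")
    frame = np.asarray(frame)
    if background is None:
        background = local_background(frame, background_radius_px)
    fg = frame.astype(np.float64) - background
    mask = fg > intensity_threshold_gray
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return []

    props = measure.regionprops(labels, intensity_image=fg)
    d_max = diameter_band_um[1]
    a_min = min_area_px(diameter_band_um, pixel_size_um)

    def equiv_diam_um(area):
        return 2.0 * np.sqrt(area / np.pi) * pixel_size_um

    # pass 1: large bright areas -> exclusion mask
    big = np.zeros(frame.shape, bool)
    for p in props:
        if equiv_diam_um(p.area) > d_max:
            big[labels == p.label] = True
    excl = ndimage.binary_dilation(big, structure=skmorph.disk(2))
    if exclusion_mask is not None:
        excl = excl | np.asarray(exclusion_mask, bool)

    out: list[SeedDetection] = []
    for p in props:
        if equiv_diam_um(p.area) > d_max or p.area < a_min:
            continue
        comp = labels == p.label
        if (comp & excl).any():
            continue
        cy, cx = p.centroid
        out.append(
            SeedDetection(
                frame_index=frame_index,
                centroid_px=(float(cx), float(cy)),
                area_px=int(p.area),
                equivalent_diameter_um=float(equiv_diam_um(p.area)),
                peak_minus_background_gray=float(p.intensity_max),
            )
        )
    return out


def detections_to_frame(dets: list[SeedDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame_index": [d.frame_index for d in dets],
            "x_px": [d.centroid_px[0] for d in dets],
            "y_px": [d.centroid_px[1] for d in dets],
            "area_px": [d.area_px for d in dets],
            "equivalent_diameter_um": [d.equivalent_diameter_um for d in dets],
            "peak_minus_background_gray": [d.peak_minus_background_gray for d in dets],
        }
    )


# ----------------------------------------------------------------------
@dataclass
class SeedCountSeries:
    """Per-well neurite-seed counts over time, before/after baseline subtraction."""

    well_id: str
    time_h: np.ndarray
    raw_counts: np.ndarray
    baseline_mean: float = 0.0
    line: str | None = None
    dose_ug: float | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, float)
        self.raw_counts = np.asarray(self.raw_counts, float)
        if self.time_h.shape != self.raw_counts.shape:
            raise ValueError("time and count vectors must have equal length")

    @property
    def corrected_counts(self) -> np.ndarray:
        return self.raw_counts - self.baseline_mean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well_id": self.well_id,
                "line": self.line,
                "dose_ug": self.dose_ug,
                "replicate": self.replicate,
                "time_h": self.time_h,
                "raw": self.raw_counts,
                "baseline": self.baseline_mean,
                "corrected": self.corrected_counts,
            }
        )


def count_series(
    stack,
    intensity_threshold_gray: float = DEFAULT_THRESHOLD_GRAY,
    diameter_band_um: tuple[float, float] = DEFAULT_DIAMETER_BAND_UM,
    background_radius_px: int = DEFAULT_BACKGROUND_RADIUS_PX,
    backgrounds: np.ndarray | None = None,
) -> SeedCountSeries:
    """Per-frame neurite-seed counts for one well's reporter channel."""
    from .simulate import CHANNEL_REPORTER

    if stack.n_frames < 2:
        raise ValueError("need at least two frames")
    counts = np.empty(stack.n_frames)
    for f in range(stack.n_frames):
        frame = stack.pixels[f, CHANNEL_REPORTER]
        bg = None if backgrounds is None else backgrounds[f]
        dets = detect_neurite_seeds(
            frame,
            stack.pixel_size_um,
            intensity_threshold_gray,
            diameter_band_um,
            background=bg,
            background_radius_px=background_radius_px,
            frame_index=f,
        )
        counts[f] = len(dets)
    return SeedCountSeries(
        well_id=stack.well_id, time_h=stack.frame_times_h, raw_counts=counts
    )


def sum_series(a: SeedCountSeries, b: SeedCountSeries,
               well_id: str | None = None) -> SeedCountSeries:
    """Elementwise sum of two technical replicates on the same time grid."""
    if not np.allclose(a.time_h, b.time_h):
        raise ValueError("time grids differ")
    return SeedCountSeries(
        well_id=well_id or f"{a.well_id}+{b.well_id}",
        time_h=a.time_h.copy(),
        raw_counts=a.raw_counts + b.raw_counts,
        baseline_mean=a.baseline_mean + b.baseline_mean,
        line=a.line,
        dose_ug=a.dose_ug,
        replicate=a.replicate,
    )


def subtract_baseline(
    series: SeedCountSeries, no_lysate: SeedCountSeries | list[SeedCountSeries]
) -> SeedCountSeries:
    """Subtract the overall mean no-lysate count (quantification noise).

    The baseline is the grand mean of the no-lysate raw counts over all
    time points (and wells, if several are given); negative corrected
    counts are retained so that downstream area-under-curve statistics stay
    unbiased.
    """
    refs = no_lysate if isinstance(no_lysate, list) else [no_lysate]
    for r in refs:
        if r.time_h.shape != series.time_h.shape or not np.allclose(
            r.time_h, series.time_h
        ):
            raise ValueError("baseline series must share the time grid")
    baseline = float(np.mean(np.concatenate([r.raw_counts for r in refs])))
    return SeedCountSeries(
        well_id=series.well_id,
        time_h=series.time_h.copy(),
        raw_counts=series.raw_counts.copy(),
        baseline_mean=baseline,
        line=series.line,
        dose_ug=series.dose_ug,
        replicate=series.replicate,
    )


# ----------------------------------------------------------------------
def detect_soma_aggregate(
    patch_stack: np.ndarray,
    soma_mask: np.ndarray,
    nuclear_mask: np.ndarray,
    intensity_threshold_gray: float = DEFAULT_THRESHOLD_GRAY,
    min_area_px: int = 4,
    background_stack: np.ndarray | None = None,
    background_radius_px: int = DEFAULT_BACKGROUND_RADIUS_PX,
):
    """Flag aggregate-positive frames in a tracked-cell patch series.

    ``patch_stack`` is ``T x H x W`` reporter-channel patches centred on the
    tracked soma.  A frame is positive when at least one connected
    component inside ``soma_mask`` exceeds the local background by the
    intensity threshold with area >= ``min_area_px``.  Returns
    ``(flags, descriptors)`` where ``descriptors`` is a per-frame DataFrame
    of component count, total/largest component area, largest-component
    area fraction and nuclear-overlap fraction, consumed by the morphology
    classifier.
    """
    patch_stack = np.asarray(patch_stack)
    if patch_stack.size == 0:
        raise ValueError("empty patch")
    T = patch_stack.shape[0]
    soma_mask = np.asarray(soma_mask, bool)
    nuclear_mask = np.asarray(nuclear_mask, bool)
    flags = np.zeros(T, bool)
    rows = []
    bg_stride = max(1, background_radius_px // 3)
    for f in range(T):
        frame = patch_stack[f]
        if background_stack is None:
            bg = local_background(frame, background_radius_px, stride=bg_stride)
        else:
            bg = background_stack[f]
        fg = frame.astype(np.float64) - bg
        mask = (fg > intensity_threshold_gray) & soma_mask
        labels = measure.label(mask, connectivity=2)
        areas = np.bincount(labels.ravel())[1:]
        areas = areas[areas >= min_area_px]
        if areas.size == 0:
            rows.append(
                dict(frame_index=f, n_components=0, total_area_px=0,
                     largest_area_px=0, largest_area_fraction=0.0,
                     nuclear_overlap_fraction=0.0)
            )
            continue
        flags[f] = True
        # restrict descriptors to the accepted (large-enough) components
        counts = np.bincount(labels.ravel())
        keep_labels = np.flatnonzero(counts >= min_area_px)
        keep_labels = keep_labels[keep_labels > 0]
        accepted = np.isin(labels, keep_labels)
        total = int(accepted.sum())
        largest = int(areas.max())
        overlap = float((accepted & nuclear_mask).sum()) / total
        rows.append(
            dict(
                frame_index=f,
                n_components=int(areas.size),
                total_area_px=total,
                largest_area_px=largest,
                largest_area_fraction=largest / total,
                nuclear_overlap_fraction=overlap,
            )
        )
    return flags, pd.DataFrame(rows)


# ----------------------------------------------------------------------
@dataclass
class NeuriteAreaMeasure:
    frame_index: int
    neurite_area_um2: float
    soma_area_um2: float


def neurite_area(
    frame: np.ndarray,
    pixel_size_um: float,
    soma_threshold_gray: float = 3000.0,
    neurite_threshold_gray: float = 600.0,
    background_radius_px: int = DEFAULT_BACKGROUND_RADIUS_PX,
    frame_index: int = 0,
    background: np.ndarray | None = None,
) -> NeuriteAreaMeasure:
    """Threshold-based neurite/soma area surrogate.

    Somata are bright above-background regions (dilated to absorb their
    rims); neurites are the remaining dimmer above-background pixels.  The
    two masks are disjoint by construction.
    """
    frame = np.asarray(frame)
    if background is None:
        background = local_background(frame, background_radius_px)
    fg = frame.astype(np.float64) - background
    soma = ndimage.binary_dilation(
        fg > soma_threshold_gray, structure=skmorph.disk(2)
    )
    neurite = (fg > neurite_threshold_gray) & ~soma
    px_area = pixel_size_um**2
    return NeuriteAreaMeasure(
        frame_index=frame_index,
        neurite_area_um2=float(neurite.sum() * px_area),
        soma_area_um2=float(soma.sum() * px_area),
    )
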