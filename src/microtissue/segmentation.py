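"""Top-view silhouette segmentation of compacting micro-tissues.

Two strategies, mirroring the two-route measurement design:

* **Strategy A** — binarize the frame at a grey-value threshold (automatic
  between-class-variance selection by default), keep the largest connected
  component, fill its holes, count pixels, convert to absolute area.
* **Strategy B** (fallback) — compute a gradient-magnitude edge map,
  binarize it, scale the binary edge mask to the frame's intensity maximum
  and subtract it from the original frame (clamping at zero), binarize the
  result at a low threshold to isolate the carved tissue outline, then
  largest-component + hole-fill as in A.  Because a closed outline fills
  to the full silhouette, B only needs detectable edges, not separable
  absolute intensities — which is exactly when A fails (strong illumination
  gradients, weak contrast).

:func:`segment_frame` runs A and falls back to B whenever A raises any
quality flag.  Failure is always reported through flags, never as silent
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters

# quality flags
FLAG_DEGENERATE = "degenerate-threshold"
FLAG_NO_TISSUE = "no-tissue"
FLAG_IMPLAUSIBLE = "implausible-area"
FLAG_OFF_CENTER = "off-center"


@dataclass(frozen=True)
class ImageFrame:
    """One grayscale frame with physical pixel size and acquisition time."""

    pixels: np.ndarray           # 2-D, integer or unit-interval float
    pixel_size: float            # micrometers per pixel
    timestamp: float = 0.0       # hours

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class SegConfig:
    """Segmentation configuration.

    The strategy-A validity heuristics (fallback triggers) flag a mask
    whose area is below ``min_area_frac`` or above ``max_area_frac`` of
    the frame, that misses a central region of interest of fractional
    half-width ``roi_frac``, or whose automatic threshold separates the
    histogram too weakly (between-class variance fraction below
    ``min_bimodality`` — an affine-invariant bimodality measure, so the
    auto threshold's invariance to positive affine intensity maps is
    preserved).
    """

    threshold: float | str = "auto"
    tissue_dark: bool = True
    min_area_frac: float = 0.005
    max_area_frac: float = 0.45
    roi_frac: float = 0.25
    min_bimodality: float = 0.92
    edge_sigma: float = 1.0
    close_edges: bool = True
    b_final_threshold_frac: float = 0.05
    b_erode_px: int = 2
    connectivity: int = 2           # 8-connectivity for components
    hole_connectivity: int = 1      # 4-connectivity for background holes


@dataclass
class SegmentationResult:
    mask: np.ndarray
    pixel_count: int
    area: float                      # mm^2
    strategy_used: str               # 'A' or 'B'
    threshold_used: float | None
    quality_flags: list[str] = field(default_factory=list)
    fallback_from_a: list[str] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return bool(self.quality_flags)


class DegenerateThresholdError(ValueError):
    """Automatic thresholding found no separable intensity classes."""


class EmptyMaskError(ValueError):
    """A binary mask contained no foreground pixels."""


def pixels_to_area(pixel_count: int, pixel_size: float) -> float:
    """Convert a pixel count to absolute area in mm^2."""
    if pixel_count < 0:
        raise ValueError("pixel_count must be non-negative")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return pixel_count * pixel_size**2 * 1.0e-6


def binarize(
    image: np.ndarray, threshold: float | str = "auto", tissue_dark: bool = True
) -> tuple[np.ndarray, float]:
    """Threshold a frame; returns (mask, threshold_used).

    With ``threshold='auto'`` the threshold maximizes between-class
    variance over the frame histogram (Otsu).  The mask is True on the
    tissue side (darker than the threshold by default).
    """
    img = np.asarray(image, dtype=float)
    if threshold == "auto":
        if np.ptp(img) == 0:
            raise DegenerateThresholdError("constant-intensity frame")
        thr = float(filters.threshold_otsu(img))
    else:
        thr = float(threshold)
        lo, hi = img.min(), img.max()
        if not lo <= thr <= hi:
            raise ValueError(f"threshold {thr} outside frame intensity range [{lo}, {hi}]")
    mask = img < thr if tissue_dark else img > thr
    return mask, thr


def _bimodality(image: np.ndarray, thr: float, tissue_dark: bool) -> float:
    """Between-class variance fraction at the chosen threshold (0..1)."""
    img = np.asarray(image, dtype=float)
    total = img.var()
    if total == 0:
        return 0.0
    fg = img < thr if tissue_dark else img > thr
    p = fg.mean()
    if p in (0.0, 1.0):
        return 0.0
    return float(p * (1 - p) * (img[fg].mean() - img[~fg].mean()) ** 2 / total)


def largest_component_fill(
    mask: np.ndarray, connectivity: int = 2, hole_connectivity: int = 1
) -> np.ndarray:
    """Largest connected component with interior holes filled.

    Components use 8-connectivity (``connectivity=2``) and hole
    identification 4-connectivity by default.  Ties on component size are
    broken by the smallest top-left-most (row-major) pixel index.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("mask has no foreground pixels")
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best_size = sizes.max()
    tied = np.flatnonzero(sizes == best_size)
    if len(tied) > 1:
        first_idx = {
            lab: np.flatnonzero(labels.ravel() == lab)[0] for lab in tied
        }
        best = min(tied, key=lambda lab: first_idx[lab])
    else:
        best = tied[0]
    comp = labels == best
    hole_structure = ndimage.generate_binary_structure(2, hole_connectivity)
    return ndimage.binary_fill_holes(comp, structure=hole_structure)


def _roi_slices(shape: tuple[int, int], roi_frac: float) -> tuple[slice, slice]:
    h, w = shape
    dr, dc = int(round(h * roi_frac)), int(round(w * roi_frac))
    return (
        slice(h // 2 - dr, h // 2 + dr + 1),
        slice(w // 2 - dc, w // 2 + dc + 1),
    )


def _validate(mask: np.ndarray, config: SegConfig) -> list[str]:
    flags = []
    frac = mask.mean()
    if frac < config.min_area_frac or frac > config.max_area_frac:
        flags.append(FLAG_IMPLAUSIBLE)
    rs, cs = _roi_slices(mask.shape, config.roi_frac)
    if not mask[rs, cs].any():
        flags.append(FLAG_OFF_CENTER)
    return flags


def _failure(frame: ImageFrame, strategy: str, flags: list[str],
             thr: float | None = None) -> SegmentationResult:
    return SegmentationResult(
        mask=np.zeros(frame.pixels.shape, dtype=bool),
        pixel_count=0,
        area=0.0,
        strategy_used=strategy,
        threshold_used=thr,
        quality_flags=flags,
    )


def segment_strategy_a(frame: ImageFrame, config: SegConfig | None = None) -> SegmentationResult:
    """Threshold -> largest component -> hole fill -> pixel count -> area."""
    config = config or SegConfig()
    try:
        raw, thr = binarize(frame.pixels, config.threshold, config.tissue_dark)
    except DegenerateThresholdError:
        return _failure(frame, "A", [FLAG_DEGENERATE])
    flags: list[str] = []
    if config.threshold == "auto" and _bimodality(
        frame.pixels, thr, config.tissue_dark
    ) < config.min_bimodality:
        flags.append(FLAG_NO_TISSUE)
    try:
        mask = largest_component_fill(raw, config.connectivity, config.hole_connectivity)
    except EmptyMaskError:
        return _failure(frame, "A", flags + [FLAG_NO_TISSUE], thr)
    flags.extend(_validate(mask, config))
    count = int(mask.sum())
    return SegmentationResult(
        mask=mask,
        pixel_count=count,
        area=pixels_to_area(count, frame.pixel_size),
        strategy_used="A",
        threshold_used=thr,
        quality_flags=flags,
    )


def segment_strategy_b(frame: ImageFrame, config: SegConfig | None = None) -> SegmentationResult:
    """Edge map -> binarize -> subtract from frame -> binarize -> component fill.

    The binary edge mask is scaled to the frame maximum before subtraction,
    carving the tissue outline down to zero; a low fixed threshold
    (``b_final_threshold_frac`` of the frame maximum) then isolates the
    closed outline, which hole-filling turns into the full silhouette.
    """
    config = config or SegConfig()
    img = np.asarray(frame.pixels, dtype=float)
    if not config.tissue_dark:
        img = img.max() - img     # reduce bright-tissue case to the dark one
    smoothed = ndimage.gaussian_filter(img, config.edge_sigma)
    edges = filters.sobel(smoothed)
    try:
        edge_mask, _ = binarize(edges, "auto", tissue_dark=False)
    except DegenerateThresholdError:
        return _failure(frame, "B", [FLAG_DEGENERATE])
    if config.close_edges:
        edge_mask = ndimage.binary_closing(edge_mask, structure=np.ones((3, 3), bool))
    carved = np.clip(img - edge_mask * img.max(), 0.0, None)
    low_thr = config.b_final_threshold_frac * img.max()
    outline = carved < low_thr
    try:
        mask = largest_component_fill(outline, config.connectivity, config.hole_connectivity)
    except EmptyMaskError:
        return _failure(frame, "B", [FLAG_NO_TISSUE])
    if config.b_erode_px > 0:
        # the binarized edge outline straddles the true boundary with a
        # support of roughly (sobel half-width + smoothing sigma) pixels;
        # filling it therefore overshoots by about that much on all sides
        eroded = ndimage.binary_erosion(mask, iterations=config.b_erode_px)
        if eroded.any():
            mask = ndimage.binary_fill_holes(
                eroded, structure=ndimage.generate_binary_structure(2, config.hole_connectivity)
            )
    flags = _validate(mask, config)
    count = int(mask.sum())
    return SegmentationResult(
        mask=mask,
        pixel_count=count,
        area=pixels_to_area(count, frame.pixel_size),
        strategy_used="B",
        threshold_used=float(low_thr),
        quality_flags=flags,
    )


def segment_frame(frame: ImageFrame, config: SegConfig | None = None) -> SegmentationResult:
    """Strategy A with automatic fallback to strategy B.

    Returns A's result if it raises no quality flag; otherwise B's result
    (with ``fallback_from_a`` recording why A was rejected).  If both fail,
    the returned failure result carries both flag sets.
    """
    config = config or SegConfig()
    res_a = segment_strategy_a(frame, config)
    if not res_a.quality_flags:
        return res_a
    res_b = segment_strategy_b(frame, config)
    res_b.fallback_from_a = list(res_a.quality_flags)
    return res_b
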