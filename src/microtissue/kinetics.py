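"""Compaction read-outs from per-frame areas: the 48 h relative surface
area and the intact-vs-released classification with release-time estimate.

Release detection operationalizes what was a visual call in the wet-lab
assay: a tissue is declared released at the first frame where its mask
overlaps fewer than two post anchor regions, sustained for at least two
consecutive frames (a single frame for the final frame of a two-frame
endpoint series), because partial detachment from one post can precede
full release.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Post
from .segmentation import ImageFrame, SegConfig, segment_frame


@dataclass
class AreaSeries:
    """Per-frame silhouette areas for one tendon's micro-tissue."""

    tendon_id: str | int
    timestamps: np.ndarray       # hours, strictly increasing, first = 0
    areas: np.ndarray            # mm^2
    flags: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.timestamps.ndim != 1 or len(self.timestamps) != len(self.areas):
            raise ValueError("timestamps and areas must be 1-D and equal length")
        if len(self.timestamps) and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.timestamps) and self.timestamps[0] != 0:
            raise ValueError("first timestamp must be 0 (constraint-release moment)")
        if not self.flags:
            self.flags = [[] for _ in self.timestamps]


@dataclass
class CompactionResult:
    tendon_id: str | int
    relative_area_48h: float | None   # percent; None if it could not be computed
    status: str                       # 'intact' or 'released'
    release_time: float | None        # hours; set iff status == 'released'


def _endpoint_index(series: AreaSeries, target: float, tol: float = 1.0) -> int:
    deltas = np.abs(series.timestamps - target)
    i = int(np.argmin(deltas))
    if deltas[i] > tol:
        raise ValueError(f"no frame within +/-{tol} h of t = {target} h")
    if series.flags[i]:
        raise ValueError(f"frame at t = {series.timestamps[i]} h is flagged: {series.flags[i]}")
    return i


def relative_area(series: AreaSeries, end_time: float = 48.0, tol: float = 1.0) -> float:
    """Surface area at 48 h relative to 0 h, in percent.

    Endpoint frames are matched within +/-1 h (hourly sampling); both must
    be unflagged.  Scale-invariant: areas enter only through their ratio.
    """
    i0 = _endpoint_index(series, 0.0, tol)
    i1 = _endpoint_index(series, end_time, tol)
    a0 = series.areas[i0]
    if a0 <= 0:
        raise ValueError("zero or negative area at 0 h")
    return 100.0 * float(series.areas[i1] / a0)


def _post_overlap_count(mask: np.ndarray, anchors: list[Post]) -> int:
    rows, cols = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    n = 0
    for p in anchors:
        disk = (rows - p.row) ** 2 + (cols - p.col) ** 2 <= p.radius**2
        if (mask & disk).any():
            n += 1
    return n


def classify_release(
    series: AreaSeries,
    masks: np.ndarray,
    post_layout: tuple[Post, ...] | list[Post],
    min_posts: int = 2,
    persistence: int = 2,
) -> CompactionResult:
    """Classify a tissue as intact or released from its per-frame masks.

    ``post_layout`` must provide the anchor regions (posts not released at
    t = 0); classification is refused, never guessed, when it is missing.
    """
    if masks is None or len(masks) != len(series.timestamps):
        raise ValueError("masks must be aligned to the series frames")
    anchors = [p for p in post_layout if not p.released_at_start]
    if not anchors:
        raise ValueError("post layout has no anchor regions; cannot classify")

    n_frames = len(series.timestamps)
    detached = np.array(
        [_post_overlap_count(np.asarray(masks[i], dtype=bool), anchors) < min_posts
         for i in range(n_frames)]
    )
    needed = 1 if n_frames == 2 else persistence
    for i in range(n_frames):
        if not detached[i]:
            continue
        run = 1
        j = i + 1
        while j < n_frames and detached[j]:
            run += 1
            j += 1
        is_final = i == n_frames - 1
        if run >= needed or (is_final and n_frames == 2):
            try:
                rel = relative_area(series)
            except ValueError:
                rel = None
            return CompactionResult(
                tendon_id=series.tendon_id,
                relative_area_48h=rel,
                status="released",
                release_time=float(series.timestamps[i]),
            )
    try:
        rel = relative_area(series)
    except ValueError:
        rel = None
    return CompactionResult(
        tendon_id=series.tendon_id,
        relative_area_48h=rel,
        status="intact",
        release_time=None,
    )


def endpoint_series(
    frame0: ImageFrame,
    frame48: ImageFrame,
    config: SegConfig | None = None,
    tendon_id: str | int = "",
) -> tuple[AreaSeries, np.ndarray]:
    """Two-frame series (0 h / 48 h acquisition path) via segment_frame.

    Returns the series and the stacked segmentation masks; segmentation
    failures propagate as per-frame flags.
    """
    results = [segment_frame(frame0, config), segment_frame(frame48, config)]
    series = AreaSeries(
        tendon_id=tendon_id,
        timestamps=np.array([frame0.timestamp, frame48.timestamp]),
        areas=np.array([r.area for r in results]),
        flags=[list(r.quality_flags) for r in results],
    )
    return series, np.stack([r.mask for r in results])
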