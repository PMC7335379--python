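"""Gel/blot band densitometry.

Band intensities are quantified as background-corrected window sums with a
two-stage subtractive correction: a global (whole-image, outside-lane
median) background removes illumination offsets exactly, and a local
(flanking-rows-within-lane median) background removes lane-specific
staining offsets and smooth gradients.  Downstream statistics: the
housekeeping (tubulin) ratio, the MMP2 active fraction
active / (active + pro), and the Tukey-fence loading-control outlier rule
(flag, never remove).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class MigrationMap:
    """Least-squares log-linear map between molecular weight and row:
    ``row = intercept + slope * log10(kDa)`` (slope < 0)."""

    intercept: float
    slope: float

    def row_of(self, kda: float) -> float:
        if kda <= 0:
            raise ValueError("molecular weight must be positive")
        return self.intercept + self.slope * np.log10(kda)

    def kda_of(self, row: float) -> float:
        return float(10.0 ** ((row - self.intercept) / self.slope))


@dataclass
class BandMeasurement:
    lane: str
    target: str
    molecular_weight: float | tuple[float, float]   # kDa; tuple for a range (tubulin 50-55)
    raw_intensity: float                            # A.U., after global subtraction
    global_background: float                        # A.U. per pixel
    local_background: float                         # A.U. per pixel
    corrected_intensity: float                      # A.U., clamped at 0
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class BandConfig:
    kda_halfwidth: float = 3.0        # band window half-width in kDa-equivalent
    local_flank_rows: int = 6         # rows on each side for local background
    detection_sigmas: float = 5.0     # below-detection flag threshold


def calibrate_migration(ladder_rows, ladder_weights) -> MigrationMap:
    """Fit the log-linear migration map from ladder band positions.

    Requires at least two points with weights strictly decreasing as rows
    increase (heavier proteins migrate less far).
    """
    rows = np.asarray(ladder_rows, dtype=float)
    weights = np.asarray(ladder_weights, dtype=float)
    if rows.shape != weights.shape or rows.size < 2:
        raise ValueError("need >= 2 matched ladder points")
    if np.any(weights <= 0):
        raise ValueError("ladder weights must be positive")
    order = np.argsort(rows)
    if not np.all(np.diff(weights[order]) < 0):
        raise ValueError("ladder weights must decrease strictly with row")
    slope, intercept = np.polyfit(np.log10(weights), rows, 1)
    return MigrationMap(intercept=float(intercept), slope=float(slope))


def _oriented(image: np.ndarray, polarity: str) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if polarity == "bright-bands-on-dark":
        return img
    if polarity == "dark-bands-on-light":
        return img.max() - img
    raise ValueError(f"unknown polarity {polarity!r}")


def global_background(image: np.ndarray, lane_windows, polarity: str) -> float:
    """Median per-pixel intensity of the oriented image outside all lanes."""
    work = _oriented(image, polarity)
    outside = np.ones(work.shape[1], dtype=bool)
    for lo, hi in lane_windows:
        outside[lo:hi] = False
    if not outside.any():
        return float(np.median(work))
    return float(np.median(work[:, outside]))


def _band_rows(
    target_kda, migration: MigrationMap, halfwidth: float, n_rows: int
) -> tuple[int, int]:
    if isinstance(target_kda, (tuple, list)):
        lo_kda, hi_kda = min(target_kda), max(target_kda)
    else:
        lo_kda = hi_kda = float(target_kda)
    r_top = migration.row_of(hi_kda + halfwidth)     # heavier -> smaller row
    r_bot = migration.row_of(max(lo_kda - halfwidth, 1e-6))
    r0, r1 = int(np.floor(min(r_top, r_bot))), int(np.ceil(max(r_top, r_bot)))
    if r0 < 0 or r1 >= n_rows:
        raise ValueError(f"band window rows [{r0}, {r1}] clipped by image edge")
    return r0, r1


def quantify_band(
    image: np.ndarray,
    lane_window: tuple[int, int],
    target_kda,
    migration: MigrationMap,
    polarity: str = "bright-bands-on-dark",
    config: BandConfig | None = None,
    lane_windows=None,
    target_name: str = "",
    lane_id: str = "",
) -> BandMeasurement:
    """Background-corrected intensity of one band.

    ``raw_intensity`` is the window sum after subtracting the global
    (outside-lane median) background; ``corrected_intensity`` additionally
    subtracts the local background (median of the flanking in-lane rows,
    per pixel, times the window pixel count) and is clamped at zero.
    """
    config = config or BandConfig()
    work = _oriented(image, polarity)
    lo, hi = lane_window
    if not (0 <= lo < hi <= work.shape[1]):
        raise ValueError("lane window outside image")
    g_bg = global_background(image, lane_windows or [lane_window], polarity)
    work = work - g_bg

    r0, r1 = _band_rows(target_kda, migration, config.kda_halfwidth, work.shape[0])
    window = work[r0 : r1 + 1, lo:hi]
    raw = float(window.sum())

    m = config.local_flank_rows
    flank_top = work[max(r0 - m, 0) : r0, lo:hi]
    flank_bot = work[r1 + 1 : r1 + 1 + m, lo:hi]
    sides = [f.ravel() for f in (flank_top, flank_bot) if f.size]
    if not sides:
        raise ValueError("band window clipped by image edge; no flanking rows")
    flank = np.concatenate(sides)
    # pooled flank median, unless the two flanks disagree beyond noise —
    # then a neighboring band (e.g. pro-MMP2 beside active MMP2) is
    # leaking into one flank and the dimmer side is the honest estimate
    local_bg = float(np.median(flank))
    if len(sides) == 2:
        med = [float(np.median(s)) for s in sides]
        mad = float(np.median(np.abs(flank - local_bg))) * 1.4826
        sem = 1.2533 * mad / np.sqrt(min(len(s) for s in sides))
        if abs(med[0] - med[1]) > 4.0 * sem:
            local_bg = min(med)
    corrected = max(raw - local_bg * window.size, 0.0)

    flags: list[str] = []
    noise = float(np.median(np.abs(flank - local_bg))) * 1.4826   # MAD -> sigma
    if corrected < config.detection_sigmas * noise * np.sqrt(window.size):
        flags.append("below-detection")

    return BandMeasurement(
        lane=lane_id,
        target=target_name,
        molecular_weight=target_kda,
        raw_intensity=raw,
        global_background=g_bg,
        local_background=local_bg,
        corrected_intensity=corrected,
        flags=flags,
    )


def housekeeping_ratio(target: BandMeasurement, tubulin: BandMeasurement) -> float:
    """Target intensity normalized to the tubulin loading control."""
    if tubulin.corrected_intensity <= 0 or "below-detection" in tubulin.flags:
        raise ValueError(
            f"tubulin band in lane {tubulin.lane!r} is zero or below detection; "
            "ratio undefined"
        )
    return target.corrected_intensity / tubulin.corrected_intensity


def mmp2_active_fraction(active: BandMeasurement, pro: BandMeasurement) -> float:
    """Active MMP2 divided by total (active + pro-MMP2); in [0, 1]."""
    total = active.corrected_intensity + pro.corrected_intensity
    if total <= 0:
        raise ValueError("both MMP2 bands are zero; active fraction undefined")
    return active.corrected_intensity / total


def loading_outliers(tubulin_intensities) -> np.ndarray:
    """Tukey-fence outlier flags for the loading control.

    Flags values below Q1 - 1.5 IQR or above Q3 + 1.5 IQR, with quartiles
    by linear interpolation of the sorted order statistics.  Flagged
    samples are annotated, not removed — exclusion is a downstream choice.
    """
    x = np.asarray(tubulin_intensities, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need at least 4 loading-control values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
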