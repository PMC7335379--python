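"""Parameter containers for the synthetic-data generators.

Defaults reproduce the study conditions of the hamstring tendon-derived-cell
micro-tissue cohort: 36 patients contributing 41 tendons (ages 12-55 y,
mean 27.9, sd 12.9; 20/36 male; 30/41 semitendinosus), with read-out effect
sizes matching the published regression layer (relative-area age slope
0.96 %/y; pro-collagen ~5-fold higher below a ~25 y threshold, inducing a
linear age slope near -15 ng/ml/y; intact/released age log-odds 0.19 with
a ~24% overall release rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class CohortParams:
    """Demographic structure of the simulated cohort.

    ``p_semitendinosus`` is the probability that a single-tendon patient's
    tendon is semitendinosus; patients drawn as two-tendon contributors
    (probability ``p_second_tendon``) always contribute one semitendinosus
    and one gracilis tendon, sharing age and gender.
    """

    n_patients: int = 36
    age_range: tuple[float, float] = (12.0, 55.0)
    mean_age: float = 27.9
    sd_age: float = 12.9
    p_male: float = 20.0 / 36.0
    p_semitendinosus: float = 25.0 / 31.0
    p_second_tendon: float = 5.0 / 36.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if self.sd_age <= 0:
            raise ValueError("sd_age must be positive")
        for name in ("p_male", "p_semitendinosus", "p_second_tendon"):
            _check_prob(name, getattr(self, name))


#: Width (years) of the logistic transition between the pro-collagen plateaus.
PROCOL_TRANSITION_WIDTH_Y = 2.0


@dataclass(frozen=True)
class EffectParams:
    """Effect structure used to generate per-tendon read-outs.

    The generative model is the inverse of the fitted regression layer:
    linear-in-age for the continuous read-outs (gender/tendon effects
    default to 0, none being significant in the calibration data), a
    two-plateau sigmoid for pro-collagen, and a logistic model for the
    intact/released outcome (intact coded 1).  ``release_intercept`` is
    the numerically solved value that puts the expected release rate at
    10/41 under the default cohort distribution; see
    :func:`microtissue.readouts.solve_release_intercept`.
    """

    procol_high_plateau: float = 608.0          # ng/ml, young plateau
    procol_low_plateau: float = 121.6           # ng/ml, old plateau
    procol_threshold_age: float = 25.0          # years
    procol_noise_sd: float = 130.0              # ng/ml
    area_age_slope: float = 0.96                # percent per year
    area_intercept: float = 35.0                # percent (unreported; invented)
    area_gender_coef: float = 0.0               # percent (male = 1)
    area_tendon_coef: float = 0.0               # percent (semitendinosus = 1)
    area_noise_sd: float = 24.0                 # percent
    release_age_coef: float = 0.19              # log-odds of intact, per year
    release_male_coef: float = 1.6              # log-odds
    release_semitend_coef: float = -2.7         # log-odds
    release_intercept: float = -2.0             # log-odds, solved for 10/41
    asma_lognormal_params: tuple[float, float] = (math.log(2.0), 0.75)
    tnmd_lognormal_params: tuple[float, float] = (math.log(0.05), 0.5)
    mmp2_active_fraction_mean: float = 0.45
    mmp2_active_fraction_sd: float = 0.05
    mmp2_intensity_age_slope: float = -0.17     # A.U. per year
    mmp2_intensity_intercept: float = 30.0      # A.U.
    mmp2_intensity_noise_sd: float = 17.0       # A.U.

    def __post_init__(self) -> None:
        if not self.procol_high_plateau > self.procol_low_plateau:
            raise ValueError("procol_high_plateau must exceed procol_low_plateau")
        m, s = self.mmp2_active_fraction_mean, self.mmp2_active_fraction_sd
        if not (0.0 <= m - 3 * s and m + 3 * s <= 1.0):
            raise ValueError("mmp2 active fraction mean +/- 3 sd must lie in [0, 1]")
        for name in ("procol_noise_sd", "area_noise_sd", "mmp2_active_fraction_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("asma_lognormal_params", "tnmd_lognormal_params"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sigma must be non-negative")


@dataclass(frozen=True)
class Post:
    """A constraining micro-post: center (row, col) in pixels, radius in
    pixels, and whether its constraint is released at t = 0 (the four
    outermost posts of the default 2x4 array)."""

    row: float
    col: float
    radius: float
    released_at_start: bool = False


def default_post_layout(frame_size: tuple[int, int] = (320, 320),
                        radius: float = 5.0) -> tuple[Post, ...]:
    """Eight posts in a 2x4 array centered in the frame; the four corner
    (outermost) posts are flagged as released at t = 0, leaving the tissue
    anchored to the four inner posts."""
    cy = (frame_size[0] - 1) / 2.0
    cx = (frame_size[1] - 1) / 2.0
    posts = []
    for dy in (-25.0, 25.0):
        for dx, outer in ((-110.0, True), (-31.0, False), (31.0, False), (110.0, True)):
            posts.append(Post(cy + dy, cx + dx, radius, released_at_start=outer))
    return tuple(posts)


def compact_post_layout(frame_size: tuple[int, int] = (320, 320),
                        radius: float = 4.0) -> tuple[Post, ...]:
    """A tighter 2x4 array (same topology as :func:`default_post_layout`)
    for scenes whose plateau silhouette is small relative to the frame."""
    cy = (frame_size[0] - 1) / 2.0
    cx = (frame_size[1] - 1) / 2.0
    posts = []
    for dy in (-14.0, 14.0):
        for dx, outer in ((-105.0, True), (-18.0, False), (18.0, False), (105.0, True)):
            posts.append(Post(cy + dy, cx + dx, radius, released_at_start=outer))
    return tuple(posts)


@dataclass(frozen=True)
class TissueSceneParams:
    """One micro-tissue time-lapse scene.

    The silhouette area follows the phenomenological decay
    ``A(t) = plateau + (initial - plateau) * exp(-rate * t)`` until
    ``release_time`` (if any), after which the tissue detaches from all
    posts and collapses to a compact blob clear of the anchor regions.
    """

    frame_size: tuple[int, int] = (320, 320)
    pixel_size: float = 8.0                     # micrometers per pixel
    post_layout: tuple[Post, ...] = field(default_factory=default_post_layout)
    initial_area: float = 1.8                   # mm^2
    plateau_area: float = 0.75                  # mm^2
    compaction_rate: float = 0.12               # per hour
    release_time: float | None = None           # hours
    frame_interval: float = 1.0                 # hours
    n_frames: int = 49
    noise_sd: float = 0.01                      # fraction of intensity range
    illumination_gradient: float = 0.0          # fraction of intensity range
    background_level: float = 0.78              # fraction of intensity range
    tissue_contrast: float = 0.40               # fraction of intensity range
    released_area: float = 0.15                 # mm^2, collapsed blob size
    release_drift_px: float = 60.0              # lateral drift after detachment
    seed: int = 0

    @property
    def n_posts(self) -> int:
        return len(self.post_layout)

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not self.plateau_area < self.initial_area:
            raise ValueError("plateau_area must be smaller than initial_area")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.compaction_rate < 0 or self.frame_interval <= 0:
            raise ValueError("compaction_rate >= 0 and frame_interval > 0 required")
        if self.release_time is not None and not 0 <= self.release_time <= self.duration:
            raise ValueError("release_time must lie within [0, duration]")
        for p in self.post_layout:
            if not (0 <= p.row < self.frame_size[0] and 0 <= p.col < self.frame_size[1]):
                raise ValueError("post center outside frame")

    def area_at(self, t: float) -> float:
        """Closed-form silhouette area (mm^2) at time t, ignoring release."""
        return self.plateau_area + (self.initial_area - self.plateau_area) * math.exp(
            -self.compaction_rate * t
        )


@dataclass(frozen=True)
class GelSceneParams:
    """One rendered gel/blot image with programmed band amounts.

    ``migration_calibration`` is ``(a, b)`` in ``row = a + b * log10(kDa)``
    (heavier proteins migrate less, so b < 0).  One renderer serves blot
    and zymograph fixtures via ``polarity``.
    """

    image_size: tuple[int, int] = (360, 520)
    lanes: tuple[tuple[str, tuple[tuple[float, float], ...]], ...] = ()
    ladder_weights: tuple[float, ...] = (250.0, 150.0, 100.0, 75.0, 50.0, 37.0, 25.0)
    migration_calibration: tuple[float, float] = (685.8, -273.5)
    band_sigma: tuple[float, float] = (3.0, 8.0)     # (row, col) pixels
    background_level: float = 0.08                   # intensity fraction
    background_gradient: float = 0.0                 # intensity fraction
    polarity: str = "bright-bands-on-dark"
    noise_sd: float = 0.003                          # intensity fraction
    lane_width: int = 36                             # pixels
    lane_margin: int = 20                            # pixels before first lane
    peak_per_unit: float = 6.0e-4                    # peak intensity per A.U.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("bright-bands-on-dark", "dark-bands-on-light"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        for lane_id, bands in self.lanes:
            for kda, amount in bands:
                if kda <= 0:
                    raise ValueError(f"non-positive molecular weight in lane {lane_id}")
                if amount < 0:
                    raise ValueError(f"negative amount in lane {lane_id}")
                row = self.row_of(kda)
                if not 0 <= row < self.image_size[0]:
                    raise ValueError(
                        f"band at {kda} kDa (row {row:.0f}) outside image in lane {lane_id}"
                    )

    def row_of(self, kda: float) -> float:
        a, b = self.migration_calibration
        return a + b * math.log10(kda)

    def lane_window(self, index: int) -> tuple[int, int]:
        """Column window (lo, hi) of the lane at position ``index``."""
        lo = self.lane_margin + index * (self.lane_width + 8)
        return lo, lo + self.lane_width

    def lane_windows(self) -> dict[str, tuple[int, int]]:
        return {lane_id: self.lane_window(i) for i, (lane_id, _) in enumerate(self.lanes)}


def params_from_dict(cls, d: dict):
    """Build a params dataclass from a plain dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    d = dict(d)
    for key in ("age_range", "frame_size", "image_size", "band_sigma",
                "asma_lognormal_params", "tnmd_lognormal_params",
                "migration_calibration"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return cls(**d)
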