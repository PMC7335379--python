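"""Brightfield time-lapse rendering of compacting micro-tissues.

Each frame contains a darker star-convex tissue silhouette spanning the
anchored posts, the post array itself, additive Gaussian noise and an
optional linear illumination gradient.  The ground-truth mask is built by
selecting exactly ``round(A(t) / pixel_area)`` pixels of a smooth radial
potential, so the reported ground-truth area (pixel count x pixel area)
matches the closed-form decay law to within half a pixel area.

After a release event the tissue detaches from every post: the silhouette
collapses to a compact blob centered in the post array, sized to stay
clear of all anchor regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .params import TissueSceneParams

_MM2_PER_UM2 = 1.0e-6


@dataclass
class RenderedScene:
    """Output of :func:`render_timelapse`."""

    stack: np.ndarray          # (n_frames, H, W) uint16
    masks: np.ndarray          # (n_frames, H, W) bool, ground truth
    areas: np.ndarray          # (n_frames,) mm^2, ground truth
    timestamps: np.ndarray     # (n_frames,) hours
    released: np.ndarray      # (n_frames,) bool, ground-truth release state
    params: TissueSceneParams


def _blob_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    n_pixels: int,
    aspect: float,
    harmonics: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    """Exactly ``n_pixels`` pixels of an elliptical star-convex potential."""
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = (rows - center[0]) / (1.0 / np.sqrt(aspect))
    dx = (cols - center[1]) / np.sqrt(aspect)
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    mod = np.ones_like(r)
    for k, (a, phi) in enumerate(zip(harmonics, phases), start=2):
        mod += a * np.cos(k * theta + phi)
    potential = r / np.maximum(mod, 0.5)
    flat = potential.ravel()
    idx = np.argpartition(flat, n_pixels - 1)[:n_pixels]
    mask = np.zeros(flat.shape, dtype=bool)
    mask[idx] = True
    return mask.reshape(shape)


def _post_disks(shape: tuple[int, int], posts) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    disks = np.zeros(shape, dtype=bool)
    for p in posts:
        disks |= (rows - p.row) ** 2 + (cols - p.col) ** 2 <= p.radius**2
    return disks


def render_timelapse(scene: TissueSceneParams) -> RenderedScene:
    """Render a seeded time-lapse with per-frame ground truth."""
    H, W = scene.frame_size
    rng = np.random.default_rng(scene.seed)
    px_area_mm2 = scene.pixel_size**2 * _MM2_PER_UM2
    anchored = [p for p in scene.post_layout if not p.released_at_start]
    if anchored:
        cy = float(np.mean([p.row for p in anchored]))
        cx = float(np.mean([p.col for p in anchored]))
    else:
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0

    # per-scene shape irregularity, fixed across frames
    harmonics = rng.uniform(-0.02, 0.02, size=4)
    phases = rng.uniform(0.0, 2 * np.pi, size=4)

    timestamps = np.arange(scene.n_frames) * scene.frame_interval
    stack = np.empty((scene.n_frames, H, W), dtype=np.uint16)
    masks = np.empty((scene.n_frames, H, W), dtype=bool)
    areas = np.empty(scene.n_frames)
    released = np.zeros(scene.n_frames, dtype=bool)

    post_img = _post_disks((H, W), scene.post_layout)
    grad = (
        scene.illumination_gradient * (np.arange(W) / max(W - 1, 1) - 0.5)
        if scene.illumination_gradient
        else None
    )

    span = scene.initial_area - scene.plateau_area
    for i, t in enumerate(timestamps):
        is_released = scene.release_time is not None and t >= scene.release_time
        released[i] = is_released
        if is_released:
            area_t = min(scene.released_area, scene.plateau_area)
            # collapsed, rounder blob drifted laterally clear of all posts
            mask = _blob_mask(
                (H, W), (cy, cx + scene.release_drift_px),
                max(1, round(area_t / px_area_mm2)),
                aspect=1.0, harmonics=harmonics * 0.5, phases=phases,
            )
            mask &= ~ndimage.binary_dilation(post_img, iterations=2)
        else:
            area_t = scene.area_at(t)
            # anisotropy grows as the tissue compacts toward the plateau
            progress = 1.0 - (area_t - scene.plateau_area) / span
            aspect = 1.0 + 0.6 * progress
            mask = _blob_mask(
                (H, W), (cy, cx), max(1, round(area_t / px_area_mm2)),
                aspect=aspect, harmonics=harmonics, phases=phases,
            )
        masks[i] = mask
        areas[i] = mask.sum() * px_area_mm2

        soft = ndimage.gaussian_filter(mask.astype(float), 1.0)
        img = np.full((H, W), scene.background_level)
        img -= scene.tissue_contrast * soft
        img[post_img] = np.minimum(img[post_img], 0.25)
        if grad is not None:
            img += grad[None, :]
        if scene.noise_sd > 0:
            img += rng.normal(0.0, scene.noise_sd, size=(H, W))
        stack[i] = (np.clip(img, 0.0, 1.0) * 65535).astype(np.uint16)

    return RenderedScene(stack, masks, areas, timestamps, released, scene)
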