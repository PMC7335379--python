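"""Rendering of gel/blot images with programmed band amounts.

Bands are anisotropic 2-D Gaussian intensity bumps whose integrated
magnitude is proportional to the programmed amount, placed at the
log-linear migration position of their molecular weight and the center of
their lane, superimposed on a background level + optional horizontal
gradient + noise.  One renderer serves Western-blot and zymograph
fixtures: ``bright-bands-on-dark`` adds bands to the background (blot
chemiluminescence, cleared zymograph bands), ``dark-bands-on-light``
returns exactly one minus the bright rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import GelSceneParams


@dataclass
class RenderedGel:
    image: np.ndarray            # 2-D float in [0, 1]
    truth: pd.DataFrame          # lane, molecular_weight_kda, amount_au, row, col
    params: GelSceneParams


def make_ladder_lane(
    ladder_weights, amount: float = 500.0, lane_id: str = "ladder"
) -> tuple[str, tuple[tuple[float, float], ...]]:
    """A lane definition holding one fixed-amount band per ladder weight."""
    return lane_id, tuple((float(w), float(amount)) for w in ladder_weights)


def render_gel(scene: GelSceneParams) -> RenderedGel:
    """Render a seeded gel image and its ground-truth band table."""
    H, W = scene.image_size
    rng = np.random.default_rng(scene.seed)
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    sig_r, sig_c = scene.band_sigma

    signal = np.zeros((H, W))
    truth_rows = []
    for i, (lane_id, bands) in enumerate(scene.lanes):
        lo, hi = scene.lane_window(i)
        if hi > W:
            raise ValueError(f"lane {lane_id} window exceeds image width")
        c = (lo + hi - 1) / 2.0
        for kda, amount in bands:
            r = scene.row_of(kda)
            signal += (
                amount
                * scene.peak_per_unit
                * np.exp(-((rows - r) ** 2) / (2 * sig_r**2))
                * np.exp(-((cols - c) ** 2) / (2 * sig_c**2))
            )
            truth_rows.append(
                {
                    "lane": lane_id,
                    "molecular_weight_kda": kda,
                    "amount_au": amount,
                    "row": r,
                    "col": c,
                }
            )

    background = np.full((H, W), scene.background_level)
    if scene.background_gradient:
        background += scene.background_gradient * (cols / max(W - 1, 1) - 0.5)
    if scene.noise_sd > 0:
        background += rng.normal(0.0, scene.noise_sd, size=(H, W))

    bright = np.clip(background + signal, 0.0, 1.0)
    image = bright if scene.polarity == "bright-bands-on-dark" else 1.0 - bright
    return RenderedGel(image=image, truth=pd.DataFrame(truth_rows), params=scene)
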