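"""File formats: multi-page 16-bit TIFF stacks with JSON sidecars, and the
CSV table conventions shared across the pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

SIDECAR_SUFFIX = ".json"

COHORT_COLUMNS = ["patient_id", "tendon_id", "age_y", "gender", "tendon"]


def write_stack(path, stack: np.ndarray, pixel_size: float, timestamps) -> None:
    """Write a (frames, rows, cols) stack as multi-page 16-bit grayscale
    TIFF with a JSON sidecar holding pixel size (um/px) and frame
    timestamps (h)."""
    path = Path(path)
    stack = np.asarray(stack)
    if stack.dtype != np.uint16:
        stack = np.clip(stack, 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "pixel_size_um": float(pixel_size),
        "timestamps_h": [float(t) for t in timestamps],
    }
    path.with_suffix(path.suffix + SIDECAR_SUFFIX).write_text(
        json.dumps(sidecar, indent=1) + "\n"
    )


def read_stack(path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read a stack and its sidecar; returns (stack, pixel_size, timestamps)."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar = json.loads(path.with_suffix(path.suffix + SIDECAR_SUFFIX).read_text())
    return stack, float(sidecar["pixel_size_um"]), np.asarray(sidecar["timestamps_h"])


def write_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV output (fixed float format, empty for missing)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.8g", na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
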