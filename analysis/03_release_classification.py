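#!/usr/bin/env python
"""Classify intact vs released micro-tissues on a seeded scene battery.

Half the scenes carry a programmed release event; classification runs on
the segmentation masks (not the ground truth) and is scored against the
programmed status and release time.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import microtissue as mt
from microtissue import io as mio
from microtissue.kinetics import AreaSeries, classify_release

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=3)
parser.add_argument("--scenes", type=int, default=30)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

rng = np.random.default_rng(args.seed)
rows = []
for k in range(args.scenes):
    programmed = k % 2 == 1
    rt = float(rng.uniform(3.0, 45.0)) if programmed else None
    scene = mt.TissueSceneParams(seed=args.seed * 2000 + k, release_time=rt)
    r = mt.render_timelapse(scene)
    results = [
        mt.segment_frame(mt.ImageFrame(r.stack[i], scene.pixel_size,
                                       float(r.timestamps[i])))
        for i in range(scene.n_frames)
    ]
    series = AreaSeries(k, r.timestamps, [x.area for x in results],
                        [list(x.quality_flags) for x in results])
    cr = classify_release(series, np.stack([x.mask for x in results]),
                          scene.post_layout)
    rows.append({
        "scene": k, "programmed_release_h": rt,
        "status": cr.status, "estimated_release_h": cr.release_time,
        "relative_area_pct": cr.relative_area_48h,
        "correct": (cr.status == "released") == programmed,
    })
df = pd.DataFrame(rows)
mio.write_csv(df, args.out / "release_classification.csv")

errs = (df.dropna(subset=["programmed_release_h", "estimated_release_h"])
          .eval("abs(estimated_release_h - programmed_release_h)"))
print(f"status accuracy: {df.correct.mean() * 100:.0f}% on {len(df)} scenes")
print(f"release-time error: max {errs.max():.2f} h (one frame interval = 1 h)")
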