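"""End-to-end orchestration of the synthetic study:

cohort -> read-outs -> time-lapse images -> segmentation -> compaction ->
gel rendering -> densitometry -> merged table -> regression results.

Every stage writes its artifact under the run directory; a manifest of
SHA-256 hashes over the CSV/text outputs makes reruns checkable for
byte-identity.  All randomness derives from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import densitometry as dens
from . import io as mio
from .config import RunConfig
from .gel_render import make_ladder_lane, render_gel
from .kinetics import AreaSeries, classify_release
from .params import GelSceneParams, TissueSceneParams, compact_post_layout
from .readouts import generate_readouts
from .cohort import generate_cohort
from .segmentation import ImageFrame, segment_frame
from .stats import ModelInput, fit_linear, fit_logistic, format_results_text, qq_normality, results_table
from .tissue_render import render_timelapse

# blot/zymograph band assignments (kDa)
TENOMODULIN_KDA = 37.0
ASMA_KDA = 42.0
TUBULIN_KDA = (50.0, 55.0)
TUBULIN_RENDER_KDA = 52.5
MMP2_ACTIVE_KDA = 62.0
MMP2_PRO_KDA = 72.0
MMP9_KDA = 92.0

_REL_AREA_CLAMP = (12.0, 90.0)
_TUBULIN_BASE_AU = 400.0
_MMP2_SCALE = 10.0


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _log(lines: list[str], message: str) -> None:
    lines.append(message)
    print(message)


def _tendon_scene(cfg: RunConfig, row: pd.Series, rng: np.random.Generator
                  ) -> TissueSceneParams:
    rel = float(np.clip(row.relative_area_pct, *_REL_AREA_CLAMP))
    initial = 1.5
    release_time = None if row.intact else float(rng.uniform(2.0, 37.0))
    overrides = dict(cfg.scene_overrides)
    overrides.update(
        n_frames=2,
        frame_interval=48.0,
        post_layout=compact_post_layout(),
        initial_area=initial,
        plateau_area=initial * rel / 100.0,
        released_area=0.05,
        release_time=release_time,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return TissueSceneParams(**overrides)


def run_demo(cfg: RunConfig) -> Path:
    """Execute the full synthetic pipeline; returns the run directory."""
    t_start = time.perf_counter()
    out = Path(cfg.out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "gels").mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0]))

    # --- stage 1: cohort and generative read-outs -----------------------
    stage = "simulate-cohort"
    try:
        records = generate_cohort(cfg.cohort)
        cohort_df = pd.DataFrame([r.__dict__ for r in records])
        mio.write_csv(cohort_df, out / "cohort.csv")
        readouts = generate_readouts(records, cfg.effects, seed=cfg.seed + 1)
        mio.write_csv(readouts, out / "readouts.csv")
        _log(log, f"[{stage}] n_patients={cfg.cohort.n_patients} "
                  f"n_tendons={len(records)} seed={cfg.seed}")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # --- stage 2: render endpoint image pairs ---------------------------
    stage = "simulate-images"
    scenes = {}
    try:
        for _, row in readouts.iterrows():
            scene = _tendon_scene(cfg, row, rng)
            rendered = render_timelapse(scene)
            scenes[int(row.tendon_id)] = (scene, rendered)
            mio.write_stack(
                out / "images" / f"tendon_{int(row.tendon_id):03d}.tif",
                rendered.stack, scene.pixel_size, rendered.timestamps,
            )
        _log(log, f"[{stage}] rendered {len(scenes)} two-frame stacks "
                  f"({scene.frame_size[0]}x{scene.frame_size[1]}, "
                  f"{scene.pixel_size} um/px)")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # --- stage 3: segmentation ------------------------------------------
    stage = "segment"
    area_rows = []
    seg_masks = {}
    try:
        for tendon_id, (scene, rendered) in scenes.items():
            masks = []
            for i, t in enumerate(rendered.timestamps):
                frame = ImageFrame(rendered.stack[i], scene.pixel_size, float(t))
                res = segment_frame(frame, cfg.segmentation)
                masks.append(res.mask)
                area_rows.append(
                    {
                        "tendon_id": tendon_id,
                        "frame_index": i,
                        "timestamp_h": float(t),
                        "strategy": res.strategy_used,
                        "pixel_count": res.pixel_count,
                        "area_mm2": res.area,
                        "flags": ";".join(res.quality_flags),
                    }
                )
            seg_masks[tendon_id] = np.stack(masks)
        areas_df = pd.DataFrame(area_rows)
        mio.write_csv(areas_df, out / "areas.csv")
        n_b = int((areas_df["strategy"] == "B").sum())
        _log(log, f"[{stage}] {len(areas_df)} frames segmented "
                  f"({n_b} via strategy B fallback)")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # --- stage 4: compaction read-outs ----------------------------------
    stage = "compaction"
    try:
        comp_rows = []
        for tendon_id, (scene, rendered) in scenes.items():
            sub = [r for r in area_rows if r["tendon_id"] == tendon_id]
            series = AreaSeries(
                tendon_id=tendon_id,
                timestamps=np.array([r["timestamp_h"] for r in sub]),
                areas=np.array([r["area_mm2"] for r in sub]),
                flags=[r["flags"].split(";") if r["flags"] else [] for r in sub],
            )
            result = classify_release(series, seg_masks[tendon_id], scene.post_layout)
            comp_rows.append(
                {
                    "tendon_id": tendon_id,
                    "relative_area_pct": result.relative_area_48h,
                    "status": result.status,
                    "release_time_h": result.release_time,
                }
            )
        compaction = pd.DataFrame(comp_rows)
        mio.write_csv(compaction, out / "compaction.csv")
        n_rel = int((compaction["status"] == "released").sum())
        _log(log, f"[{stage}] {n_rel}/{len(compaction)} micro-tissues released")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # --- stage 5: gels and densitometry ---------------------------------
    # released micro-tissues are not processed for further analyses
    stage = "quantify-gel"
    try:
        ro = readouts.set_index("tendon_id")
        intact_ids = [
            tid
            for tid in compaction.loc[compaction.status == "intact", "tendon_id"]
            if pd.notna(ro.loc[tid, "tenomodulin_ratio"])
        ]
        band_rows, ratio_rows = [], []
        loading_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xB1]))
        groups = [
            intact_ids[i : i + cfg.n_lanes_per_gel]
            for i in range(0, len(intact_ids), cfg.n_lanes_per_gel)
        ]
        for g_idx, group in enumerate(groups):
            loadings = _TUBULIN_BASE_AU * loading_rng.lognormal(0.0, 0.2, len(group))
            blot_lanes = [make_ladder_lane(GelSceneParams().ladder_weights)]
            zymo_lanes = [make_ladder_lane(GelSceneParams().ladder_weights)]
            for tid, loading in zip(group, loadings):
                r = ro.loc[tid]
                blot_lanes.append(
                    (f"t{tid}", (
                        (TENOMODULIN_KDA, float(r.tenomodulin_ratio * loading)),
                        (ASMA_KDA, float(r.asma_ratio * loading)),
                        (TUBULIN_RENDER_KDA, float(loading)),
                    ))
                )
                frac = float(np.clip(r.mmp2_active_fraction, 0.05, 0.95))
                active = max(float(r.mmp2_active_au), 1.0) * _MMP2_SCALE
                zymo_lanes.append(
                    (f"t{tid}", (
                        (MMP2_ACTIVE_KDA, active),
                        (MMP2_PRO_KDA, active * (1.0 - frac) / frac),
                    ))
                )
            for kind, lanes in (("blot", blot_lanes), ("zymo", zymo_lanes)):
                gel_seed = int(
                    np.random.default_rng(
                        np.random.SeedSequence(
                            [cfg.seed, 0xE1, g_idx, int(kind == "zymo")]
                        )
                    ).integers(0, 2**31 - 1)
                )
                scene = GelSceneParams(lanes=tuple(lanes), seed=gel_seed)
                gel = render_gel(scene)
                mio.write_stack(
                    out / "gels" / f"{kind}_{g_idx:02d}.tif",
                    (gel.image * 65535).astype(np.uint16),
                    1.0, [0.0],
                )
                windows = list(scene.lane_windows().values())
                ladder_truth = gel.truth[gel.truth.lane == "ladder"]
                migration = dens.calibrate_migration(
                    ladder_truth.row.to_numpy(), ladder_truth.molecular_weight_kda.to_numpy()
                )
                targets = (
                    (("tenomodulin", TENOMODULIN_KDA), ("asma", ASMA_KDA),
                     ("tubulin", TUBULIN_KDA))
                    if kind == "blot"
                    else (("mmp2_active", MMP2_ACTIVE_KDA), ("mmp2_pro", MMP2_PRO_KDA),
                          ("mmp9", MMP9_KDA))
                )
                for lane_idx, (lane_id, _) in enumerate(scene.lanes):
                    if lane_id == "ladder":
                        continue
                    for name, kda in targets:
                        m = dens.quantify_band(
                            gel.image, scene.lane_window(lane_idx), kda, migration,
                            polarity=scene.polarity, lane_windows=windows,
                            target_name=name, lane_id=lane_id,
                        )
                        band_rows.append(
                            {
                                "gel": f"{kind}_{g_idx:02d}",
                                "lane": lane_id,
                                "tendon_id": int(lane_id[1:]),
                                "target": name,
                                "molecular_weight_kda": str(kda),
                                "raw_intensity": m.raw_intensity,
                                "global_background": m.global_background,
                                "local_background": m.local_background,
                                "corrected_intensity": m.corrected_intensity,
                                "flags": ";".join(m.flags),
                            }
                        )
        bands = pd.DataFrame(band_rows)
        mio.write_csv(bands, out / "bands.csv")

        piv = bands.pivot_table(
            index="tendon_id", columns="target", values="corrected_intensity"
        )
        tubulin_flags = dens.loading_outliers(piv["tubulin"].to_numpy())
        for i, (tid, row) in enumerate(piv.iterrows()):
            ratio_rows.append(
                {
                    "tendon_id": tid,
                    "tenomodulin_ratio": row["tenomodulin"] / row["tubulin"],
                    "asma_ratio": row["asma"] / row["tubulin"],
                    "mmp2_active_au": row["mmp2_active"] / _MMP2_SCALE,
                    "mmp2_active_fraction": row["mmp2_active"]
                    / (row["mmp2_active"] + row["mmp2_pro"]),
                    "loading_outlier": bool(tubulin_flags[i]),
                }
            )
        ratios = pd.DataFrame(ratio_rows)
        mio.write_csv(ratios, out / "ratios.csv")
        _log(log, f"[{stage}] {len(groups)} blot + {len(groups)} zymograph gels, "
                  f"{len(bands)} band measurements, "
                  f"{int(tubulin_flags.sum())} loading outliers")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # --- stage 6: merge and regression layer ----------------------------
    stage = "analyze"
    try:
        merged = cohort_df.merge(
            compaction[["tendon_id", "relative_area_pct", "status"]], on="tendon_id"
        )
        merged["intact"] = (merged["status"] == "intact").astype(int)
        merged = merged.merge(
            readouts[["tendon_id", "pro_collagen_ng_ml"]], on="tendon_id", how="left"
        )
        merged = merged.merge(ratios, on="tendon_id", how="left")
        mio.write_csv(merged, out / "merged.csv")

        results = []
        try:
            results.append(
                fit_logistic(ModelInput.from_frame(merged, "intact", "intact/released"))
            )
        except ValueError as e:
            # e.g. quasi-complete separation at study scale (all gracilis
            # intact); the fit is refused with a diagnostic, not guessed
            _log(log, f"[{stage}] intact/released logistic model refused: {e}")
        lin_models = [
            ("relative_area_pct", "surface area 48 h (%)"),
            ("pro_collagen_ng_ml", "pro-collagen I (ng/ml)"),
            ("tenomodulin_ratio", "tenomodulin / tubulin (-)"),
            ("asma_ratio", "aSMA / tubulin (-)"),
            ("mmp2_active_au", "active MMP2 (A.U.)"),
            ("mmp2_active_fraction", "MMP2 active fraction (-)"),
        ]
        qq_rows = []
        for col, name in lin_models:
            inp = ModelInput.from_frame(merged, col, name)
            try:
                res = fit_linear(inp)
            except ValueError as e:
                _log(log, f"[{stage}] {name} linear model refused: {e}")
                continue
            results.append(res)
            resid = inp.y - inp.design() @ np.array(
                [res.intercept[0]] + [res.terms[c][0] for c in
                                      ("age", "gender_male", "tendon_semitendinosus")]
            )
            theo, samp, corr = qq_normality(resid)
            qq_rows.extend(
                {"readout": name, "theoretical_quantile": t, "sample_quantile": s,
                 "ppcc": corr}
                for t, s in zip(theo, samp)
            )
        if cfg.exclude_outliers == "sensitivity":
            keep = merged["loading_outlier"] != True  # noqa: E712 (NaN-safe keep)
            sub = merged[keep]
            if sub["pro_collagen_ng_ml"].notna().sum() > 6:
                results.append(
                    fit_linear(
                        ModelInput.from_frame(sub, "pro_collagen_ng_ml",
                                              "pro-collagen I (ng/ml)"),
                        variant="excluding-outliers",
                    )
                )
        if not results:
            raise ValueError("no read-out model could be fitted")
        table = results_table(results)
        mio.write_csv(table, out / "table2.csv")
        (out / "table2.txt").write_text(format_results_text(table) + "\n")
        mio.write_csv(pd.DataFrame(qq_rows), out / "qq_pairs.csv")
        _log(log, f"[{stage}] {len(results)} models fitted "
                  f"(alpha={cfg.alpha}, outliers={cfg.exclude_outliers})")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # --- manifest + log --------------------------------------------------
    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.suffix in (".csv", ".txt") and path.name != "log.txt":
            manifest[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    _log(log, f"[done] {len(manifest)} hashed artifacts in "
              f"{time.perf_counter() - t_start:.1f} s")
    (out / "log.txt").write_text("\n".join(log) + "\n")
    return out
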