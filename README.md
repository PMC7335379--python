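# microtissue

Analysis pipeline for an in vitro micro-tissue remodeling assay used to
probe patient-specific tendon-cell behavior. Tendon-derived cells seeded
in collagen-I gels compact the gel around an array of constraining
micro-posts; releasing the outer posts triggers further remodeling, which
is monitored by brightfield time-lapse imaging. The pipeline quantifies

- **compaction** — the top-view silhouette area over 48 h, segmented from
  the images, summarized as the relative area `100 · A(48 h) / A(0 h)`;
- **release events** — whether a micro-tissue detached from its remaining
  posts (a binary outcome strongly tied to patient age);
- **protein read-outs** — gel/blot band densitometry with two-stage
  background correction: tenomodulin and α-SMA normalized to the tubulin
  loading control, active and pro-MMP2 from zymographs, and the MMP2
  active fraction `active / (active + pro)`;
- **the inference layer** — per read-out multiple regression on age,
  gender (♂ = 1) and tendon type (semitendinosus = 1): ordinary least
  squares with multiple R² for continuous read-outs, and a logistic GLM
  with McFadden pseudo-R² `1 − ℓ(model)/ℓ(intercept-only)` for
  intact/released, at α = 0.05.

It is written for researchers who run (or re-analyze) this class of
compaction assay and need the image analysis, densitometry and statistics
reproducible end to end. Because no raw study data are public, the
package includes a first-class synthetic-data generator that emulates the
study conditions — cohort demographics (36 patients / ~41 tendons, ages
12–55), time-lapse stacks with ground-truth masks, and gel images with
programmed band amounts — so every stage is testable against known truth.

## Segmentation

Strategy A binarizes a frame at a grey-value threshold (automatic
between-class-variance selection), keeps the largest connected component
and fills its holes; the pixel count converts to absolute area via
`area = n_px · (pixel size)²`. When intensity alone cannot separate the
silhouette (quality flags: degenerate threshold, weak bimodality,
implausible area, off-center), the pipeline falls back to strategy B:
Sobel edge magnitude → binarize → subtract the scaled edge mask from the
frame → binarize the carved outline → largest component + hole fill.

## Worked example

The numbered scripts under `analysis/` run the study stages at the
published design scale. The full demo (cohort → images → segmentation →
compaction → gels → densitometry → regression table):

```bash
python analysis/06_demo_pipeline.py --seed 3
# or: microtissue demo --config configs/demo.yaml
```

prints, among others:

```
read-out | age (est, se, p) | ... | fit | n
intact/released [all] | 0.209, 0.0871, 0.0165* | ... | pseudo-R2=0.397 (a) | 42
surface area 48 h (%) [all] | 1.58, 0.398, 0.000318* | ... | R2=0.325 | 42
pro-collagen I (ng/ml) [all] | -19.9, 2.84, 1.06e-07* | ... | R2=0.63 | 33
...
(a) pseudo-R2, since multiple R2 is not defined for logistic regression
```

Reading this: each row is one read-out's multiple regression. In this
synthetic draw the age effects on release (log-odds 0.209 per year of
*staying intact*), on relative area (+1.58 % per year — older patients'
tissues compact less) and on pro-collagen (−19.9 ng/ml per year, driven
by a ~5-fold step down around 25 y) are significant, while gender and
tendon type are not — the qualitative pattern the assay is designed to
expose. n drops from 42 to 33 for the biochemical rows because released
micro-tissues are not processed further.

Single stages, e.g. segmentation accuracy against rendered ground truth:

```bash
python analysis/02_segmentation_accuracy.py --seed 3
# clean:     median |error| 0.00%  (strategy A everywhere)
# corrupted: median |error| 0.45%  (fallback to strategy B everywhere)
```

## Layout

- `src/microtissue/` — library: `cohort`/`readouts` (synthetic cohort and
  effect structure), `tissue_render`/`gel_render` (image synthesis with
  ground truth), `segmentation`, `kinetics`, `densitometry`, `stats`,
  `config`/`pipeline`/`cli` (orchestration).
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `docs/methods.md` — models, parameter choices, and limitations.
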