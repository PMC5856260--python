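# fibroquant

Fully automated histomorphometry of Masson's-trichrome-stained lung
sections, built around trainable SVM pixel classification on whole-slide
image pyramids. Two detection models produce two fibrosis readouts per
slide:

1. A **low-magnification 4-class model** (background, fibrotic masses,
   alveolar tissue, bronchi incl. their constitutive peri-bronchial
   collagen) computed on the pyramid level nearest one megapixel with a
   large structure-size window. It yields the **% fibrotic masses**
   readout (mass / (mass + alveolar tissue), bronchi and background
   excluded from the normalization) and the *exclusion map* defining the
   alveolar region of interest.
2. A **high-magnification 3-class model** (collagen, lung tissue,
   background) applied to the full-resolution image inside the alveolar
   ROI only. The image is processed in 512×512 tiles in a map-reduce
   fashion (tiles read with a structure-size halo so the tiled result is
   bit-identical to untiled classification). It yields **% alveolar
   collagen** (collagen / (collagen + lung tissue)) and a derived
   **% total collagen**.

Per-pixel features are single-pixel intensities plus windowed mean, min,
max, variance and the edge factor `1/(|W|-1) · Σ (p′−p)²` per colour
channel. Models are trained from polygon annotations (GeoJSON), sampling
40,000 pixels uniformly over the pooled annotation regions, and evaluated
by stratified 10-fold cross-validation. Group statistics use mean ± SEM
and the two-sided Mann-Whitney U test (exact for small tie-free samples).

Because scanned slides are gigabytes and not shippable, the package
includes a first-class **synthetic slide generator**
(`fibroquant.synthetic`) that renders trichrome-like pyramidal slides —
lacy alveolar septa, dense fibrotic masses, ring-shaped bronchi with
collagen collars, controllable stain drift (hue ±15°, gain 0.8–1.2) —
together with exact per-pixel ground-truth label maps and simulated rater
annotations, so the whole pipeline is testable offline.

## CLI

```sh
fibroquant synth    --out study/ --groups "saline:10:0.01-0.04:0.01-0.03,bleo:10:0.3-0.5:0.06-0.15"
fibroquant train    --slides study/slides --annotations study/annotations.geojson \
                    --classes background,fibrotic_mass,alveolar_tissue,bronchus \
                    --structure-size 25 --out low.fqm
fibroquant cv       --slides study/slides --annotations study/annotations.geojson \
                    --classes background,lung_tissue,collagen --folds 10
fibroquant quantify --config config.yaml     # batch over a slide directory
fibroquant stats    --table out/study_table.csv --out comparisons
```

`quantify` reads a YAML config naming `slides_dir`, `low_model`,
`high_model`, `output_dir`, optional `metadata` (CSV with slide_id,
animal_id, group, timepoint) and QC settings; it writes
`study_table.csv` with one row per slide. Exit codes: 0 ok, 2 config
error, 3 partial failure (failed slides become failure rows, the batch
continues). Collapsed/empty slides are QC-flagged automatically and
excluded from group statistics; a manual override list is supported.

## Layout

- `fibroquant.synthetic` — slide generator, ground truth, rater simulation, studies
- `fibroquant.features` — per-pixel feature extraction (exact integer SAT backend)
- `fibroquant.classifier` — training sets, SVM, cross-validation, persistence
- `fibroquant.roi` — exclusion map, alveolar ROI, % fibrotic masses, QC
- `fibroquant.quantify` — tile grid, map/reduce, collagen readouts
- `fibroquant.stats` / `fibroquant.batch` / `fibroquant.cli` — statistics, batch runs, CLI
- `fibroquant.evaluation` — shared evaluation protocols (fixtures, CV benchmark, recovery)
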