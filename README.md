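# swirotome

Analysis pipeline for detecting middle-ear effusions in shortwave-infrared
(SWIR) otoscopy frames: region-of-interest (ROI) segmentation of the
tympanic membrane, ROI intensity parameterization, and three escalating
classification schemes evaluated by repeated stratified hold-out
cross-validation. Because no clinical recordings are deposited, the package
bundles a first-class synthetic SWIR frame generator with ground-truth ROI
masks and effusion labels, and every downstream stage is exercised on it.

## Components

| Module | What it does |
| --- | --- |
| `swirotome.dataio` | Frames (16-bit PNG/TIFF), {0,1} masks, JSON polygon annotations, CSV cohort manifests; rasterization with a fixed pixel-center convention |
| `swirotome.synthetic` | Seeded cohort generator: elliptical membrane disc, per-ear baseline/texture random effects, AR(1) flicker, sensor noise, cerumen/hair/defocus/border artifacts excluded from the truth ROI |
| `swirotome.segmentation` | Six classical baselines (static/adaptive threshold, k-means, Hough circle, active contour, blur detection) and a trainable two-class encoder–decoder (numpy, SGD + momentum, translation augmentation) |
| `swirotome.features` | Input Set 1 (mean ROI intensity) and Input Set 2 (11 global ROI statistics: mean/median, IQR-restricted, above/below-median, max–median/median–min/IQR differences) |
| `swirotome.classify` | Case 1 (depth-1 tree on mean intensity), Case 2 (tree on all 11 features), Case 3 (200-tree balanced random forest with OOB-tuned threshold); 10× stratified 62/38 hold-outs, ear- or frame-grouped; confusion metrics, balanced accuracy, ROC/AUC |
| `swirotome.pipeline` / `swirotome.cli` | Deterministic end-to-end orchestration with YAML configs and JSON/CSV reports |

## CLI

```bash
# everything: simulate -> (segment) -> featurize -> evaluate all cases
swirotome run-all --config cfg.yaml --seed 42 --out runs/

# or stage by stage
swirotome simulate --seed 42 --out data/
swirotome segment-train --dataset data/ --out model.npz
swirotome segment-apply --dataset data/ --model model.npz --out masks/
swirotome featurize --dataset data/ --out features.csv
swirotome evaluate --features features.csv --case 3 --out case3.json
```

Exit codes: 0 success, 2 configuration error, 3 stage failure. By default
the pipeline classifies on truth masks and trains the semantic segmenter
separately; set `segmentation_source: semantic` (or `classical:<method>`)
in the YAML config to route predicted masks into featurization.

Minimal `cfg.yaml`:

```yaml
synthetic: {n_ears: 55, prevalence: 0.35}
split: {n_iterations: 10, train_fraction: 0.62, grouping: ear}
cases: [1, 2, 3]
seed: 42
```

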