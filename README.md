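# slicevit

Slice-level vision-transformer pipeline for multi-class classification of
volumetric brain images (AD / HC / MCI), exercised end to end on synthetic
NIfTI cohorts that emulate preprocessed neuroimaging data.

The package implements:

- **Synthetic cohorts** (`slicevit.cohort`) — NIfTI volumes with the exact
  study geometry (4-D functional 45×54×45×T, T∈[124,200] with mode 140;
  3-D structural grey-matter maps 91×109×91), class-conditional Gaussian
  intensity foci, an ellipsoidal brain mask with zero background,
  optional empty slices, and per-subject random streams.
- **Decomposition** (`slicevit.decompose`) — volume → 2-D PNG slices along
  z (and t), dropping the last ten z-slices and every slice whose raw
  intensity sum is zero; lossless per-volume windowed quantization (8- or
  16-bit) and a slice manifest whose filenames round-trip (subject, z, t).
- **Splits & experiments** (`slicevit.splits`) — stratified subject-level
  80/10/10 splits with a floor/floor/remainder convention (reproducing the
  published 226/27/31 and 1167/144/149 triples), label-merging schemes
  (`AD_HC_MCI`, `ADMCI_HC`, `AD_HCMCI`, `AD_HC`, `HC_MCI`) over reused
  splits, and a healthy-control noise-insertion challenge that corrupts
  training labels only.
- **Models** (`slicevit.models`) — five transformer classifiers built from
  one configuration type on a pure-NumPy autodiff engine (`slicevit.nn`):
  a 224-pixel 16-head vanilla ViT, its 8-head twin, a re-attention
  (head-mixing) variant, a class-attention variant, and the optimized
  56-pixel (fMRI) / 112-pixel (sMRI) 8-head model. Exact trainable
  parameter accounting reproduces the published table:

  | model       | input     | params      |
  |-------------|-----------|-------------|
  | CaIT        | 3×224×224 | 120,707,075 |
  | DeepViT     | 3×224×224 |  53,532,867 |
  | ViT-vanilla | 3×224×224 |  53,532,675 |
  | ViT-224-8   | 3×224×224 |  40,949,763 |
  | OViTAD      | 3×56×56   |  38,406,147 |

  The unstated internals (patch size, embedding width, head width, bias
  placement) were fixed by an exact constraint search against these counts
  (`solve_width_config`); the solver ships for audit.
- **Training** (`slicevit.train`) — the published regimen (40 epochs, batch
  64, Adam lr 3e-5, gamma 0.7, step 1), per-epoch histories, checkpoints
  on validation-accuracy improvement, best-model selection, deterministic
  slice-level prediction with probabilities.
- **Evaluation** (`slicevit.evaluate`) — classification reports (per-class
  and macro/weighted precision/recall/F1, accuracy), vote-for-majority
  subject aggregation, mean ± std repetition summaries and normalized
  confusion matrices.
- **Attention** (`slicevit.attention`) — post-softmax per-head/per-depth
  attention grids and the global attention feature map (pixel × Σ of the
  final feature vector, min-max normalized to 0–255, CIVIDIS rendering).

## CLI

```sh
slicevit synth --modality smri --n-ad 10 --n-hc 10 --n-mci 10 \
    --effect-size 2.5 --seed 0 --out runs/cohort
slicevit decompose --in runs/cohort --out runs/slices
slicevit split --cohort runs/cohort/cohort.csv --seed 0 --out runs/split.csv
slicevit train --slices runs/slices/slices.csv --split runs/split.csv \
    --variant ovitad --experiment AD_HC_MCI --seed 0 --out runs/model
slicevit predict --checkpoint runs/model/checkpoint_epoch000.npz \
    --manifest runs/model/manifest.csv --out runs/preds.csv
slicevit evaluate --predictions runs/preds.csv --out runs/eval
slicevit params                      # parameter table for all five variants
slicevit run-all --config exp.yaml --out runs/full   # synth→…→visualize
```

`run-all` reads a YAML experiment config (model, modality, scheme, seed
list, cohort/training overrides) and writes a self-describing run
directory: manifests, splits, histories, checkpoints, slice- and
subject-level reports, repetition summaries, confusion matrices and
attention panels.

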