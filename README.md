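# cellchannel

Does the choice of label-free imaging modality matter for CNN-based
immune-cell classification?  `cellchannel` is a tested, reusable
implementation of the full analysis pipeline behind that question —
aimed at computational biologists who want to study the pipeline itself
on controlled synthetic data, where every cell's type, size and marker
intensity is known by construction.

Two hematopoietic progenitor populations are modelled: an **LMPP-like**
type (lymphoid-primed multipotential progenitor; surface-marker negative)
and a **proB-like** type (committed B-cell progenitor; marker positive).
The pipeline mirrors a real imaging workflow:

1. **Simulation** — dishes of round cells in four channels: phase-contrast
   (Ph, dark body + bright halo), DIC-like and bright-field-like texture
   channels, and a fluorescence marker channel with log-normal per-cell
   totals (log-mean separation Δ between the types) on a smooth
   illumination background with per-dish batch gains.
2. **Segmentation** — Otsu threshold, morphological closing, border
   clearing, hole filling; watershed on the Gaussian-smoothed Euclidean
   distance transform to split touching cells; area filter keeping
   2000 px < area < 8000 px (52.81–211.2 µm² at 162.5 nm/px).
3. **Cropping** — 150×150 per-cell, per-channel crops centered on the
   region centroid; binary contour crops; cell size = region pixel count;
   the marker channel is flat-fielded by dividing by its own σ = 200 px
   Gaussian blur before cropping.
4. **Gating** — per cell, l = total flattened marker intensity within
   30 px of the crop center and F = ln(l / max l); a two-component
   Gaussian mixture on F labels cells LMPP-like / proB-like / unused
   (posterior < 80% in both components).
5. **Preprocessing** — circular mask of radius 50 px, inside-mask mean
   normalised to 1, and per-dish class counts trimmed to
   C\* = min₍dish,type₎ C₍dish,type₎.
6. **Classification & evaluation** — a small CNN (four 5×5 conv layers of
   widths 16/16/32/32, doubled for multi-channel input; 3×3 stride-2
   max-pools; dropout 0.1; 2000-node dense layer; 2-node softmax; Adam
   α = 1e-4, batch 32, early stopping with patience 5, ≤ 30 epochs) and an
   RBF-SVM (γ = 1) on cell size alone; dish-wise cross-validation (dish *n*
   is the test set of validation *n*) with Mann–Whitney AUC, and an
   experiment grid over channel combinations, focal offsets, training-set
   sizes and init seeds.

The marker channel defines the labels and is never a classifier input.
The CNN engine is written in NumPy with numba kernels (no deep-learning
framework required); gradients are verified against independent oracles.
See `docs/methods.md` for the full model description and design decisions.

## Worked example

```python
from cellchannel import (SyntheticConfig, generate_experiment,
                         ChannelConfig, crossvalidate)
from cellchannel.config import PipelineConfig
from cellchannel.pipeline import segment_and_crop
from cellchannel.labelling import label_records
from cellchannel.preprocessing import group_labelled_records, trim_to_balance
from cellchannel.classifiers import TrainSpec

cfg = SyntheticConfig(n_dishes=3, fields_per_dish=3, field_shape=(1024, 1024),
                      cells_per_field=35, size_means=(3200., 5200.),
                      texture_effect=2.0, placement_margin_px=80, seed=11)
fields = generate_experiment(cfg)
records = segment_and_crop(fields, PipelineConfig(synthetic=cfg))
model = label_records(records)                       # GMM marker gating
balanced = trim_to_balance(group_labelled_records(records), seed=0)

res = crossvalidate(records, balanced, config=ChannelConfig.single("dic"),
                    classifier="cnn", train_spec=TrainSpec(max_epochs=8))
print([round(v["auc"], 3) for v in res.validations])
```

Output:

```
[0.976, 1.0, 0.998]
```

Three dish-level validations, one AUC each: with a strong synthetic size +
texture difference between the types, the DIC-channel CNN separates the two
progenitor classes almost perfectly on every held-out dish.  The same data
through the size-only SVM gives `[0.979, 0.994, 0.989]` — the configured
size effect alone is highly informative.  On a null configuration
(equal sizes, zero texture effect) both classifiers fall to chance
(mean AUC ≈ 0.46–0.53, inside the 99% permutation band around 0.5).

A command-line interface covers the same stages
(`cellchannel simulate / segment / crop / label / preprocess / train /
evaluate / report / run-all`), reading YAML configs and writing TIFFs,
CSV manifests and JSON run manifests.

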