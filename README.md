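# colonyquant

Automated quantification of red/white yeast colony color assays: plate
segmentation → colony cropping → 5-class color classification →
per-plate non-white percentage.

Adenine-auxotrophic yeast accumulate a red pigment on limiting-adenine
plates, so colony color reports silencing of an *ade6⁺* reporter (and
many other genetic/epigenetic events). Scoring thousands of colonies by
eye is slow and irreproducible; `colonyquant` replaces it with a
two-stage pipeline — a U-net-style semantic segmenter that separates
colonies from the plate, and a convolutional classifier that assigns
each cropped colony to one of five classes (`white`, `red`, `pink`,
`variegating`, `bad_segmentation`). Per plate it reports

```
pct_non_white = 100 · (red + pink + variegating) / (all properly segmented)
```

where `bad_segmentation` (merged clusters of overlapping colonies) is
excluded from the denominator. A synthetic plate generator with
pixel-exact ground truth makes every stage trainable and testable with
no external photographs; both networks are compact numpy implementations
that train in about a minute each on one CPU at desk scale.

## Worked example

```bash
# 1. synthesize data
colonyquant simulate plates --n 60 --size 128 --colonies 30 --seed 1 --out data/train_plates
colonyquant simulate crops  --n 1476 --seed 0 --out data/train_crops
colonyquant simulate plates --n 8  --size 128 --colonies 30 --seed 2 --out data/assay

# 2. train both stages (desk profiles, CPU)
colonyquant train-seg --manifest data/train_plates/manifest.csv --profile desk --seed 0 --out models/seg.npz
colonyquant train-clf --manifest data/train_crops/labels.csv    --profile desk --seed 0 --out models/clf.npz

# 3. run the full pipeline and compare to ground truth
colonyquant predict --images data/assay --seg-weights models/seg.npz \
    --clf-weights models/clf.npz --out results/assay --area-min 6 --seed 0
colonyquant evaluate --truth data/assay/manifest.csv \
    --pred results/assay/plate_report.csv --out results/assay/diffs.csv
```

Typical output:

```
final val dice: 0.9457
best val accuracy: 0.9898
wrote report for 8 plates to results/assay
mean absolute difference: 0.839 percentage points
```

`plate_report.csv` then holds one row per plate, e.g.

```
plate_id,n_white,n_red,n_pink,n_variegating,n_bad,n_properly_segmented,pct_non_white,status
plate_0000,7,5,14,4,0,30,76.66666666666667,ok
```

meaning: 30 properly segmented colonies, 23 of them non-white → 76.67%
non-white. The dice line is the segmenter's validation mask overlap
(1.0 = perfect), the accuracy line the classifier's five-class
validation accuracy, and the final line the mean absolute gap between
predicted and true per-plate non-white percentages. `--area-min 6` is
the colony-size filter (400 px at full 1024-px resolution) scaled to the
128-px desk plates; see `docs/methods.md`.

Everything is also available as a library:

```python
from colonyquant import SynthPlateSpec, render_plate
import numpy as np

image, truth = render_plate(SynthPlateSpec(image_size=128, n_colonies=30),
                            np.random.default_rng(0))
print(truth.class_counts(), truth.true_nonwhite_pct)
```

## Layout

| module | role |
| --- | --- |
| `colonyquant.synthgen` | synthetic plates, crops, masks, manifests |
| `colonyquant.segmentation` | U-net-style segmenter, dice, training profiles |
| `colonyquant.postprocess` | border clearing, opening, region measures, filter, crops |
| `colonyquant.classification` | 5-class CNN, augmentation, TTA, training |
| `colonyquant.aggregate` | per-plate summaries, evaluation, full pipeline |
| `colonyquant.cli` | `colonyquant` command-line interface |
| `colonyquant.nn`, `colonyquant.schedules` | numpy network engine, cyclical LR schedules |
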