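# Methods

## The assay and the statistic

Adenine-auxotrophic yeast accumulate a red vacuolar pigment when grown on
limiting-adenine indicator plates, while cells with a functional adenine
pathway stay white. Reading out colony color therefore scores genetic and
epigenetic events — most prominently heterochromatin-mediated silencing of
an *ade6⁺* reporter — one colony at a time. The per-plate readout is the
non-white percentage

```
pct_non_white = 100 · (n_red + n_pink + n_variegating)
                      / (n_all_properly_segmented)
```

where properly segmented excludes `bad_segmentation` regions (clusters of
small overlapping colonies that cannot be attributed to a single clone).
A plate with no properly segmented colonies is reported as *undefined*,
never as 0%, so empty or failed plates cannot bias experiment-level means.

## Pipeline

1. **Center-crop / resize** the plate photograph to a square at the
   segmenter's input size.
2. **Semantic segmentation**: an encoder-decoder convolutional network
   with skip connections maps the RGB image to per-pixel foreground
   probability; binarization at an inclusive threshold (default 0.5,
   exposed as `--threshold`).
3. **Mask clean-up**: the mask is resized back to the original
   (center-cropped) resolution, components touching the frame are removed
   (border clearing — this is what eliminates the bright plate-rim
   artifact), and a morphological opening with a disk element removes
   speckle. The opening radius is 2 px at the 1024-px working scale and is
   scaled proportionally for other image sizes.
4. **Region analysis**: 8-connected components are labelled; each region
   gets an area, bounding box (0-based, half-open), centroid, and the
   eccentricity of the ellipse with the same normalized second central
   moments (`0` for a disk). Regions are kept iff eccentricity ≤ 0.6
   **and** area ≥ 400 px, both inclusive. The area threshold is stated at
   the ~1024-px plate scale; for other scales it should be scaled with
   the squared resolution ratio (the desk-scale runs at 128 px use
   `round(400·(128/1024)²) = 6`).
5. **Classification**: each kept region is cropped (bounding box plus 10%
   padding), resized to 50×50, and scored by a 5-class convolutional
   network over {white, red, pink, variegating, bad_segmentation}.
   Test-time augmentation averages the class posterior over the original
   crop plus four randomly augmented copies (the training augmentation
   family). Argmax ties break by the fixed class order white < red <
   pink < variegating < bad_segmentation.
6. **Aggregation** into per-plate counts and `pct_non_white`.

## Networks and training

No deep-learning framework is part of this package's dependency set; both
networks are small convolutional nets implemented directly on numpy
(im2col convolutions, SGD with momentum 0.9, seeded initialization).
Backward passes are verified against finite differences in the test
suite. Layer parameters are partitioned into thirds in network order so
cyclical schedules can apply *differential learning rates* per third.

**Segmenter** (`small-unet`): a three-level U-net-style encoder-decoder
(base width 12 channels in the desk profile; 3→c→2c→4c and back with skip
concatenations, 1×1 head). Loss is binary cross-entropy with logits with
the positive class weighted by the background/foreground pixel ratio
(clipped to ≤ 2), and the head bias is initialized at the foreground
prior log-odds. Both measures remove the all-background local minimum
that plain BCE exhibits on foreground-sparse plates; dice at threshold
0.5 is the validation metric and selects the saved epoch.

*Desk profile*: 128-px plates, batch 2, weight decay 1e-7, one all-layer
triangular cycle — 1 epoch rising, 8 falling, maximum rates
(0.05, 0.1, 0.2) across thirds, minima 1/20 of the maxima. Nine epochs
train in about one minute on one CPU and reach validation dice ≈ 0.95 on
60 synthetic plates. A last-layer warmup stage is supported but not used
here: warming up a randomly initialized head against random encoder
features only entrenches the background-only solution.

*Full-size profile*: the staged 512→1024-px recipe with a pretrained
Resnet-34 encoder (warmup cycle min 8e-3 / max 4e-2, 1 epoch up, 7 down;
all-layer cycles with thirds at (1e-4, 1e-3, 1e-2), then 20 cycles of 20
epochs at (4e-5, 2e-4, 4e-3), minima 1/20 of maxima). The stage ledger is
a first-class config object and its schedule arithmetic is tested, but
executing it requires a GPU-class deep-learning stack and a pretrained
encoder, neither of which this package ships.

**Classifier** (`small-cnn`): three 3×3 conv layers (12/24/48 channels,
each followed by ReLU and 2×2 max-pool) and two fully connected layers
(64 hidden units, 5 logits); categorical cross-entropy; inputs resized
(not padded) to 50×50 and normalized as x/255 − 0.5 (constants recorded
in the weights sidecar). Training stages: (0) last layer, no
augmentation, 1 epoch at a constant rate; (1) last layer, augmented,
cosine-annealed 1-epoch warm restarts (3 cycles); (2) all layers, sets of
warm-restart cycles of increasing length (1, 2, 4 epochs) with
differential maximum rates across thirds and cosine annealing to 0.
Early stopping watches validation log loss with patience 3 during stage
2 (the operationalization of "stop when over-fitting appears"); the
returned weights are those of the best validation log loss.

*Desk profile*: batch 16, warmup rate 2e-2, one set of (1, 2, 4) cycles —
11 epochs, ≈ 1 minute on one CPU. Maximum rates (0.01, 0.03, 0.06):
the full-size profile's (1.1e-4, 3.3e-4, 1e-3) are fine-tuning rates for
a pretrained Resnet-34 and are far too small to train a from-scratch
net in 11 epochs. *Full-size profile*: batch 128, 17 sets — 51 cycles /
119 epochs total.

**Augmentation.** Segmentation pairs: rotation up to ±4°, horizontal
flip, brightness/contrast jitter on the image only; the identical
geometric transform is applied to the mask with nearest-neighbour
resampling so it stays boolean. Classifier crops: rotation up to ±10°, a
random dihedral-8 element, zoom up to 1.1× (zoom in, center-crop back),
brightness/contrast jitter. Draw order is fixed, so a given generator
state reproduces the transform exactly.

## Synthetic plates

The generator emulates the features of indicator-plate photographs that
the pipeline must cope with, not their photorealism:

* a bright agar disk (plate radius 0.49× the image side) on a dark
  background, with an optional bright rim ring whose outer edge crosses
  the frame border — naive thresholding picks the rim up, and border
  clearing is what removes it;
* round colonies with antialiased edges, a slight radial dome shading,
  per-colony multiplicative color jitter, additive Gaussian pixel noise
  (σ = 3 on the 0–255 scale) and a smooth illumination gradient (±8%);
* five phenotypes: white ≈ (230, 225, 210), red ≈ (170, 40, 40),
  pink ≈ (220, 140, 150); variegating colonies carry 2–6 angular sectors
  alternating white/red; bad-segmentation regions are 2–4 mutually
  overlapping disks forming one connected component. An aged-white
  ring-morphology artifact (pinkish perimeter ring) exists behind
  `ring_probability` but defaults to off.
* colony radii 3–5% of the image side (≈ 4–6 px at 128 px, matching small
  colonies on a whole-plate photograph); placement by rejection sampling
  with a clearance gap unless overlap is explicitly allowed, raising
  after bounded retries when a requested count cannot be placed.

Class frequencies default to the label mix of a hand-scored colony pool
(36% white / 18% red / 21% pink / 22% variegating / 3% clusters). The
ground truth records the exact foreground mask, every colony's phenotype
and the per-plate non-white percentage. All randomness derives from one
seed, with one counter-derived stream per plate/crop, so datasets are
order-independent and byte-reproducible; ~20% of items are flagged as a
validation split (stratified by class for crop datasets, matching the
reference counts 537/273/310/318/38 → a 295-crop validation set at
n = 1476).

What the generator does **not** model: agar texture, lens/camera effects,
condensation, colony size–phenotype correlation (slow-growing silenced
colonies), or touching chains of many colonies. Passing desk-scale tests
therefore demonstrates that the pipeline machinery is correct and
recovers known ground truth under noise — not that the shipped desk
weights transfer to real photographs, which require training on real
labeled plates at the full-size profile.

## Numerical and design choices

* Binarization and selection thresholds are inclusive; 0.5 is the
  symmetric default for a probability mask.
* 8-connectivity for labelling (configurable via scikit-image semantics).
* TTA averages probability vectors, not logits, and renormalizes.
* Plates whose properly-segmented count is zero carry an `undefined`
  status; `compare_to_truth` keeps them in the table and excludes them
  from the mean absolute difference.
* Pooled white/non-white evaluation drops pairs whose *true* label is
  `bad_segmentation`, mirroring the class's exclusion from the plate
  denominator. Restricted to the pairs actually pooled, pooled accuracy
  can only exceed five-class accuracy; unrestricted it need not (a
  correctly predicted cluster that is dropped removes a correct pair).
* CSV reports start with a `# seed=N` comment line; identical inputs and
  seed reproduce every output byte for byte (single-threaded numpy).

## Desk-scale problem sizes

The self-contained evaluation (tests and `scripts/acceptance.py`) uses
1476 crops (training ≈ 1 min), 60 training plates for the segmenter
(≈ 1 min), and 20 evaluation plates at 128 px with ~30 well-separated
colonies each whose true non-white fraction sweeps 0–100%. End-to-end,
the pipeline recovers per-plate non-white percentages with a mean
absolute error of roughly 0.3–1.4 percentage points across seeds, with
five-class crop validation accuracy ≈ 98% and pooled accuracy ≈ 99–100%.

## Known limitations

* Only the small random-init architectures are executable; configs naming
  pretrained encoders raise with the supported list.
* Multi-resolution training stages (512→1024) require rebuilding the
  network and are not wired for the small net.
* No watershed splitting of touching colonies — merged regions are meant
  to be filtered out by the roundness/size rule, as in the assay's
  protocol.
* The eccentricity filter also discards genuinely round colonies whose
  predicted masks are ragged; at desk scale this loses a few percent of
  colonies and is the main contributor to the residual per-plate error.
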