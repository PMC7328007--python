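"""Shared fixtures: synthetic datasets and desk-trained models.

The expensive artifacts (the 1476-crop classifier dataset, the trained
classifier, the 60-plate segmenter dataset, the trained segmenter, and
the 20-plate evaluation sweep) are session-scoped so the whole suite
trains each network exactly once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from colonyquant.classification import desk_clf_config, save_classifier, train_classifier
from colonyquant.segmentation import desk_seg_config, save_segmenter, train_segmenter
from colonyquant.synthgen import (
    SynthPlateSpec,
    generate_crop_dataset,
    generate_plate_dataset,
)

CROP_COUNTS = (537, 273, 310, 318, 38)


@pytest.fixture(scope="session")
def crop_dataset(tmp_path_factory) -> tuple[Path, pd.DataFrame]:
    """1476 labeled synthetic crops with the reference class counts."""
    out = tmp_path_factory.mktemp("crops")
    spec = SynthPlateSpec(image_size=128, seed=0)
    manifest = generate_crop_dataset(spec, 1476, CROP_COUNTS, out, seed=0)
    return out, manifest


@pytest.fixture(scope="session")
def trained_classifier(crop_dataset):
    """Desk-profile classifier trained on the session crop dataset."""
    crop_dir, manifest = crop_dataset
    model, history = train_classifier(manifest, desk_clf_config(0), data_dir=crop_dir)
    return model, history


@pytest.fixture(scope="session")
def plate_dataset(tmp_path_factory) -> tuple[Path, pd.DataFrame]:
    """60 synthetic plates (128 px, ~30 colonies) for segmenter training."""
    out = tmp_path_factory.mktemp("plates")
    spec = SynthPlateSpec(image_size=128, n_colonies=30, seed=0)
    manifest = generate_plate_dataset(spec, 60, out, seed=1)
    return out, manifest


@pytest.fixture(scope="session")
def trained_segmenter(plate_dataset):
    """Desk-profile segmenter trained on the session plate dataset."""
    plate_dir, _ = plate_dataset
    model, history = train_segmenter(plate_dir / "manifest.csv", desk_seg_config(0))
    return model, history


@pytest.fixture(scope="session")
def eval_plates(tmp_path_factory) -> tuple[Path, pd.DataFrame]:
    """20 evaluation plates whose true non-white fraction sweeps 0-100%."""
    out = tmp_path_factory.mktemp("eval_plates")
    spec = SynthPlateSpec(image_size=128, n_colonies=30, seed=0)
    mixtures = []
    for i in range(20):
        nw = i / 19
        mixtures.append((1.0 - nw, 0.35 * nw, 0.35 * nw, 0.30 * nw, 0.03))
    manifest = generate_plate_dataset(spec, 20, out, seed=2, class_mixtures=mixtures)
    return out, manifest


@pytest.fixture(scope="session")
def saved_weights(tmp_path_factory, trained_segmenter, trained_classifier):
    """Both trained models saved to disk, for CLI-level tests."""
    out = tmp_path_factory.mktemp("weights")
    save_segmenter(trained_segmenter[0], out / "seg.npz")
    save_classifier(trained_classifier[0], out / "clf.npz")
    return out / "seg.npz", out / "clf.npz"
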