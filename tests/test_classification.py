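"""Colony classifier: augmentation bounds, TTA, training behaviour."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from colonyquant.classification import (
    ClassProbabilities,
    ClfAugmentSpec,
    ClfTrainConfig,
    SmallCNN,
    _resize_crop,
    augment_crop,
    build_classifier,
    classify_crops,
    desk_clf_config,
    load_classifier,
    predict_with_tta,
    save_classifier,
    train_classifier,
)
from colonyquant.postprocess import ColonyCrop
from colonyquant.synthgen import CLASS_NAMES

IDENTITY_AUG = ClfAugmentSpec(
    max_rotation_deg=0.0, dihedral=False, brightness=0.0, contrast=0.0, max_zoom=1.0
)


def _crop(seed=0, size=50):
    px = np.random.default_rng(seed).integers(0, 255, (size, size, 3), dtype=np.uint8)
    return px


class TestClassProbabilities:
    def test_simplex_enforced(self):
        with pytest.raises(ValueError):
            ClassProbabilities(np.array([0.5, 0.5, 0.5, 0.0, 0.0]))

    def test_argmax_tie_breaks_by_class_order(self):
        cp = ClassProbabilities(np.array([0.3, 0.3, 0.2, 0.1, 0.1]))
        assert cp.argmax_label.value == "white"


class TestBuildClassifier:
    def test_five_logits(self):
        model = build_classifier(desk_clf_config(0))
        x = SmallCNN.normalize(_crop()[None])
        assert model.forward(x).shape == (1, 5)

    def test_probabilities_sum_to_one(self):
        model = build_classifier(desk_clf_config(0))
        probs = model.predict_proba_batch(_crop()[None])
        assert probs.sum() == pytest.approx(1.0)

    def test_seeded_init_deterministic(self):
        a, b = SmallCNN(50, 3), SmallCNN(50, 3)
        for pa, pb in zip(a.named_params().values(), b.named_params().values()):
            assert np.array_equal(pa.value, pb.value)

    def test_three_groups_cover_all_params(self):
        model = SmallCNN(50, 0)
        groups = model.layer_groups()
        assert len(groups) == 3
        assert {id(p) for g in groups for p in g} == {
            id(p) for p in model.named_params().values()
        }

    def test_unknown_backbone_raises(self):
        config = desk_clf_config(0)
        config.backbone = "vgg16"
        with pytest.raises(ValueError, match="small-cnn"):
            build_classifier(config)


class TestAugmentCrop:
    def test_identity_draw_returns_input(self):
        crop = _crop()
        out = augment_crop(crop, IDENTITY_AUG, np.random.default_rng(0))
        assert np.array_equal(out, crop)

    def test_output_dims_preserved(self):
        crop = _crop(size=37)
        for seed in range(5):
            out = augment_crop(crop, ClfAugmentSpec(), np.random.default_rng(seed))
            assert out.shape == crop.shape

    def test_same_rng_state_reproduces(self):
        crop = _crop()
        a = augment_crop(crop, ClfAugmentSpec(), np.random.default_rng(4))
        b = augment_crop(crop, ClfAugmentSpec(), np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_zoom_draw_bounded(self):
        aug = ClfAugmentSpec(max_zoom=1.1)
        rng = np.random.default_rng(0)
        for _ in range(50):
            rng.uniform(-aug.max_rotation_deg, aug.max_rotation_deg)
            rng.integers(0, 8)
            z = rng.uniform(1.0, aug.max_zoom)
            assert 1.0 <= z <= 1.1
            rng.uniform(-aug.brightness, aug.brightness)
            rng.uniform(-aug.contrast, aug.contrast)


class TestTTA:
    def test_zero_augments_equals_plain_prediction(self):
        model = SmallCNN(50, 0)
        crop = _crop()
        cp = predict_with_tta(model, crop, n_augments=0, rng=np.random.default_rng(0))
        plain = model.predict_proba_batch(crop[None])[0]
        assert cp.probs == pytest.approx(plain, abs=1e-12)

    def test_identity_only_augmentations_equal_plain(self):
        model = SmallCNN(50, 0)
        crop = _crop()
        cp = predict_with_tta(
            model, crop, n_augments=4, rng=np.random.default_rng(0), aug=IDENTITY_AUG
        )
        plain = model.predict_proba_batch(crop[None])[0]
        assert cp.probs == pytest.approx(plain, abs=1e-6)

    def test_probabilities_on_simplex(self):
        model = SmallCNN(50, 0)
        cp = predict_with_tta(model, _crop(3), rng=np.random.default_rng(1))
        assert cp.probs.sum() == pytest.approx(1.0)
        assert (cp.probs >= 0).all()

    def test_negative_augments_rejected(self):
        with pytest.raises(ValueError):
            predict_with_tta(SmallCNN(50, 0), _crop(), n_augments=-1)


class TestClassifyCrops:
    def _crops(self, n=4):
        return [
            ColonyCrop(_crop(i, 20), plate_id="p1", region_id=i, bbox=(0, 0, 20, 20))
            for i in range(n)
        ]

    def test_row_conservation(self):
        model = SmallCNN(50, 0)
        table = classify_crops(model, self._crops(5), tta=False)
        assert len(table) == 5
        assert (table["status"] == "ok").all()

    def test_tta_changes_probs_not_row_count(self):
        model = SmallCNN(50, 0)
        off = classify_crops(model, self._crops(3), tta=False, seed=0)
        on = classify_crops(model, self._crops(3), tta=True, seed=0)
        assert len(off) == len(on)
        assert list(off.columns) == list(on.columns)

    def test_unreadable_file_flagged_not_dropped(self, tmp_path):
        bad = tmp_path / "broken.jpg"
        bad.write_bytes(b"not a jpeg")
        model = SmallCNN(50, 0)
        table = classify_crops(model, [bad], tta=False)
        assert len(table) == 1
        assert table["status"].iloc[0].startswith("error")


class TestTraining:
    def test_missing_class_raises_with_name(self, crop_dataset):
        crop_dir, manifest = crop_dataset
        reduced = manifest[manifest["label"] != "pink"]
        with pytest.raises(ValueError, match="pink"):
            train_classifier(reduced, desk_clf_config(0), data_dir=crop_dir)

    def test_desk_training_reaches_accuracy(self, trained_classifier):
        _, history = trained_classifier
        assert history["val_accuracy"].max() > 0.80
        assert len(history) <= 15

    def test_trained_model_separates_pure_colors(self, trained_classifier, crop_dataset):
        """Saturated red and white single colonies get the right labels."""
        model, _ = trained_classifier
        crop_dir, manifest = crop_dataset
        val = manifest[manifest["split"] == "valid"]
        for label in ("white", "red"):
            path = crop_dir / val[val["label"] == label]["crop_path"].iloc[0]
            px = np.asarray(Image.open(path).convert("RGB"))
            probs = model.predict_proba_batch(_resize_crop(px, model.input_size)[None])[0]
            assert CLASS_NAMES[probs.argmax()] == label

    def test_pooled_accuracy_at_least_five_class(self, trained_classifier, crop_dataset):
        from colonyquant.aggregate import evaluate_classifier

        model, _ = trained_classifier
        crop_dir, manifest = crop_dataset
        val = manifest[manifest["split"] == "valid"]
        images = np.stack(
            [
                _resize_crop(np.asarray(Image.open(crop_dir / p).convert("RGB")), 50)
                for p in val["crop_path"]
            ]
        )
        preds = []
        for start in range(0, len(images), 128):
            preds.append(model.predict_proba_batch(images[start : start + 128]).argmax(1))
        names = [CLASS_NAMES[i] for i in np.concatenate(preds)]
        report = evaluate_classifier(list(val["label"]), names)
        assert report.pooled_binary_accuracy >= report.accuracy

    def test_label_permutation_destroys_signal(self, crop_dataset):
        """Shuffled labels drive validation accuracy to ~majority-class share."""
        crop_dir, manifest = crop_dataset
        rng = np.random.default_rng(0)
        # small stratified subsample to keep the control run fast
        sub = manifest.groupby("label", group_keys=False).head(60)
        permuted = sub.copy()
        permuted["label"] = rng.permutation(permuted["label"].to_numpy())
        config = ClfTrainConfig(
            batch_size=16, warmup_lr=0.02, n_sets=1, max_lrs=(0.01, 0.03, 0.06), seed=0
        )
        _, history = train_classifier(permuted, config, data_dir=crop_dir)
        majority = permuted[permuted["split"] == "valid"]["label"].value_counts(normalize=True).max()
        assert history["val_accuracy"].iloc[-1] <= majority + 0.15
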