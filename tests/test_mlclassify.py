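import numpy as np
import pytest

from endograd.imgio import EndospermMask, SectionImage
from endograd.mlclassify import (TrainingSet, classify_pixels, classify_replicates,
                                 fit_class_model, replicate_agreement)
from endograd.synthgrain import generate_training_rois

from conftest import square_mask
from oracles import gaussian_argmax


def _training(protein_px, background_px, replicate_id=1):
    return TrainingSet(rois=[("protein", protein_px),
                             ("background", background_px)],
                       replicate_id=replicate_id)


BG = np.array([[200, 200, 200], [201, 200, 199], [199, 201, 200], [200, 199, 201]],
              dtype=float)


class TestFitClassModel:
    def test_class_mean_is_sample_mean(self):
        px = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]], dtype=float)
        model = fit_class_model(_training(px, BG))
        np.testing.assert_allclose(model.means[model.labels.index("protein")],
                                   [0.5, 0.5, 0.5])

    def test_single_colour_class_gets_ridge_covariance(self):
        px = np.tile([50.0, 60.0, 70.0], (5, 1))
        model = fit_class_model(_training(px, BG), regularisation=1e-3)
        cov = model.covariances[model.labels.index("protein")]
        np.testing.assert_allclose(cov, 1e-3 * np.eye(3))

    def test_priors_equal_across_classes(self):
        model = fit_class_model(_training(np.tile([5.0, 5, 5], (8, 1)), BG))
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_too_few_pixels_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            _training(np.zeros((3, 3)), BG)

    def test_degenerate_class_without_ridge_rejected(self):
        px = np.tile([50.0, 60.0, 70.0], (5, 1))
        with pytest.raises(ValueError, match="degenerate|regularisation"):
            fit_class_model(_training(px, BG), regularisation=0.0)

    def test_needs_both_protein_and_background(self):
        with pytest.raises(ValueError, match="background"):
            TrainingSet(rois=[("protein", BG)])
        with pytest.raises(ValueError, match="protein"):
            TrainingSet(rois=[("background", BG)])


class TestClassifyPixels:
    def test_pixel_at_protein_mean_is_protein(self):
        mask = square_mask(side=7, origin=0, canvas=8)
        pixels = np.full((8, 8, 3), 200, dtype=np.uint8)
        pixels[2, 2] = (40, 40, 90)
        image = SectionImage(pixels=pixels, scale=1.0)
        protein_px = np.array([[40, 40, 90]] * 4, dtype=float) + \
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        model = fit_class_model(_training(protein_px, BG))
        out = classify_pixels(image, mask, model)
        assert out.protein[2, 2]
        assert out.protein.sum() == 1

    def test_matches_brute_force_gaussian_argmax(self):
        rng = np.random.default_rng(123)
        mask = square_mask(side=7, origin=0, canvas=8)
        for _ in range(20):
            pixels = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
            image = SectionImage(pixels=pixels, scale=1.0)
            prot = rng.normal(80, 30, size=(12, 3))
            bg = rng.normal(170, 30, size=(12, 3))
            model = fit_class_model(_training(prot, bg))
            out = classify_pixels(image, mask, model)
            expected_cls = gaussian_argmax(pixels[mask.region], model.means,
                                           model.covariances, model.priors)
            expected = np.zeros((8, 8), dtype=bool)
            expected[mask.region] = np.isin(expected_cls, model.protein_indices)
            np.testing.assert_array_equal(out.protein, expected)

    def test_equidistant_pixel_goes_to_lower_class_index(self):
        # classes symmetric about the pixel, identical covariances: tie
        mask = square_mask(side=1, origin=0, canvas=2)
        pixels = np.full((2, 2, 3), 100, dtype=np.uint8)
        image = SectionImage(pixels=pixels, scale=1.0)
        jitter = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float)
        # sorted labels put "background" (index 0) before "protein" (index 1)
        model = fit_class_model(TrainingSet(rois=[
            ("background", np.tile([90.0, 100, 100], (4, 1)) + jitter),
            ("protein", np.tile([110.0, 100, 100], (4, 1)) + jitter)]))
        out = classify_pixels(image, mask, model)
        assert not out.protein.any()  # tie resolved to class index 0

    def test_protein_confined_to_endosperm_mask(self, small_scene):
        config, image, mask, truth = small_scene
        ts, _ = generate_training_rois(image, truth, seed=5)
        out = classify_pixels(image, mask, fit_class_model(ts))
        assert not (out.protein & ~mask.region).any()

    def test_contrast_separation_never_hurts_accuracy(self):
        rng = np.random.default_rng(9)
        mask = square_mask(side=31, origin=0, canvas=32)
        region = mask.region
        truth = rng.random((32, 32)) < 0.3
        truth &= region
        accs = []
        for sep in (20.0, 60.0, 120.0):
            pixels = np.full((32, 32, 3), 150.0)
            pixels += rng.normal(0, 12, size=pixels.shape)
            pixels[truth] -= sep
            pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
            image = SectionImage(pixels=pixels, scale=1.0)
            prot = np.clip(rng.normal(150 - sep, 12, (40, 3)), 0, 255)
            bg = np.clip(rng.normal(150, 12, (40, 3)), 0, 255)
            out = classify_pixels(image, mask, fit_class_model(_training(prot, bg)))
            accs.append((out.protein[region] == truth[region]).mean())
        assert accs == sorted(accs)


class TestReplicates:
    def test_identical_training_sets_give_identical_masks(self, small_scene):
        config, image, mask, truth = small_scene
        ts, _ = generate_training_rois(image, truth, seed=5)
        masks = classify_replicates(image, mask, [ts, ts, ts])
        assert len(masks) == 3
        for pm in masks[1:]:
            np.testing.assert_array_equal(pm.protein, masks[0].protein)

    def test_single_training_set_gives_singleton(self, small_scene):
        config, image, mask, truth = small_scene
        ts, _ = generate_training_rois(image, truth, seed=5)
        assert len(classify_replicates(image, mask, [ts])) == 1

    def test_replicates_agree_on_well_separated_stain(self, small_scene):
        config, image, mask, truth = small_scene
        trainings = [generate_training_rois(image, truth, seed=s, replicate_id=i + 1)[0]
                     for i, s in enumerate((101, 202, 303))]
        masks = classify_replicates(image, mask, trainings)
        agree = replicate_agreement(masks, mask)
        assert agree.min() >= 0.99
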