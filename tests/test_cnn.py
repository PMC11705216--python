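"""Image preprocessing, the experimental architecture, augmentation, and
holdout CNN training."""

import numpy as np
import pytest

import seroblot as sb
from seroblot.cnn import (ArchitectureSpec, AugmentConfig, ConvBlock,
                          build_ecnn, build_network, preprocess_image,
                          prepare_tensors)
from seroblot.metrics import HoldoutConfig
from seroblot.nn import softmax
from seroblot.synth import StripImage


class TestPreprocess:
    def test_output_shapes_per_mode(self, small_cohort):
        strip = small_cohort[0]
        assert preprocess_image(strip, "gray", size=64).shape == (64, 64, 1)
        assert preprocess_image(strip, "color", size=64).shape == (64, 64, 3)
        assert preprocess_image(strip, "fourier", size=64).shape == (64, 15, 1)

    def test_constant_image_fourier_has_dc_column_only(self):
        strip = StripImage(np.full((64, 16), 180.0), "cancer", "c")
        out = preprocess_image(strip, "fourier", size=64)[:, :, 0]
        assert np.all(out[:, 1:] == 0.0)  # flat rows: every non-DC bin is zero
        assert np.all(out[:, 0] == 1.0)   # DC is the min-max maximum

    def test_sinusoidal_rows_dominate_their_frequency_bin(self):
        cols = np.arange(64)
        row = 128.0 + 100.0 * np.sin(2 * np.pi * 5 * cols / 64)
        strip = StripImage(np.clip(np.tile(row, (64, 1)), 0, 255), "cancer", "s")
        out = preprocess_image(strip, "fourier", size=64)[:, :, 0]
        off_dc = out[:, 1:]
        assert np.argmax(off_dc.mean(axis=0)) == 4  # column 5 of the spectrum
        assert preprocess_image(strip, "fourier", size=64).max() == 1.0

    def test_values_in_unit_interval(self, small_cohort):
        for mode in ("color", "gray", "fourier"):
            out = preprocess_image(small_cohort[3], mode, size=32)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_unknown_mode_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            preprocess_image(small_cohort[0], "hsv")


class TestBuildECNN:
    def test_filter_sequence_and_pools(self):
        spec = build_ecnn(9, 3, (256, 256, 1))
        assert tuple(b.filters for b in spec.conv_blocks) == (20, 40, 80)
        assert all(b.kernel == 9 for b in spec.conv_blocks)
        assert [b.pool for b in spec.conv_blocks] == [(2, 2), (2, 2), None]

    def test_output_width_matches_classes(self):
        spec = build_ecnn(3, 2, (64, 64, 1))
        assert spec.n_classes == 2

    def test_narrow_fourier_input_pools_rows_only(self):
        spec = build_ecnn(3, 3, (256, 15, 1))
        assert spec.conv_blocks[0].pool == (2, 1)

    def test_forward_pass_is_probability_simplex(self):
        rng = np.random.default_rng(0)
        net = build_network(build_ecnn(3, 3, (32, 32, 1)), rng)
        probs = softmax(net.forward(
            rng.standard_normal((2, 1, 32, 32)).astype(np.float32)))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            build_ecnn(3, 3, (2, 64, 1))
        with pytest.raises(ValueError):
            build_ecnn(5, 3, (64, 64, 1))  # kernel outside the grid


class TestAugmentation:
    def test_counts_reach_target_750_total(self, small_cohort):
        aug = sb.augment_dataset(small_cohort, AugmentConfig(target_per_class=20,
                                                             seed=0))
        counts = {lab: sum(s.label == lab for s in aug)
                  for lab in sb.CLASS_ORDER}
        assert counts == {"cancer": 20, "benign": 20, "healthy": 20}

    def test_originals_retained_untouched(self, small_cohort):
        aug = sb.augment_dataset(small_cohort, AugmentConfig(target_per_class=12,
                                                             seed=1))
        by_id = {s.patient_id: s for s in aug}
        for orig in small_cohort:
            assert np.array_equal(by_id[orig.patient_id].pixels, orig.pixels)
            assert by_id[orig.patient_id].label == orig.label

    def test_synthetic_images_keep_source_label(self, small_cohort):
        aug = sb.augment_dataset(small_cohort, AugmentConfig(target_per_class=12,
                                                             seed=1))
        for s in aug:
            if "_aug" in s.patient_id:
                source = s.patient_id.split("_aug")[0]
                src = next(o for o in small_cohort if o.patient_id == source)
                assert s.label == src.label

    def test_tiny_classes_topped_up(self):
        strips = sb.generate_cohort(
            sb.CohortConfig(n_cancer=1, n_benign=1, n_healthy=1, seed=2))
        aug = sb.augment_dataset(strips, AugmentConfig(target_per_class=5, seed=0))
        assert len(aug) == 15

    def test_class_already_at_target_unchanged(self, small_cohort):
        aug = sb.augment_dataset(small_cohort, AugmentConfig(target_per_class=8,
                                                             seed=0))
        assert len(aug) == len(small_cohort)

    def test_deterministic_under_seed(self, small_cohort):
        cfg = AugmentConfig(target_per_class=11, seed=4)
        a = sb.augment_dataset(small_cohort, cfg)
        b = sb.augment_dataset(small_cohort, cfg)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_target_below_class_size_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            sb.augment_dataset(small_cohort, AugmentConfig(target_per_class=5))


@pytest.fixture(scope="module")
def separable_dataset(separable_strips):
    return prepare_tensors(separable_strips, "gray", size=16)


class TestTrainAndEvaluate:
    def test_separable_fixture_reaches_perfect_accuracy(self, separable_dataset):
        spec = ArchitectureSpec((16, 16, 1), (ConvBlock(4, 3, pool=(2, 2)),),
                                (), 2)
        res = sb.train_and_evaluate(
            spec, separable_dataset, sb.TrainConfig(epochs=5, seed=0),
            HoldoutConfig(n_runs=2, seed=0), aggregation="per_class",
            positive_class="cancer")
        assert res.mean_report.accuracy == 100.0

    def test_seeded_rerun_reproduces_accuracies(self, separable_dataset):
        spec = ArchitectureSpec((16, 16, 1), (ConvBlock(3, 3, pool=(2, 2)),),
                                (), 2)
        args = (spec, separable_dataset, sb.TrainConfig(epochs=3, seed=7),
                HoldoutConfig(n_runs=2, seed=7))
        a = sb.train_and_evaluate(*args)
        b = sb.train_and_evaluate(*args)
        assert a.accuracies == b.accuracies

    def test_training_loss_decreases_on_separable_runs(self, separable_dataset):
        """Optimizer smoke: loss trajectories fall on at least 8 of 10 seeds."""
        from seroblot.nn import train_network

        x, labels = separable_dataset
        y = np.array([0 if lab == "cancer" else 1 for lab in labels])
        spec = ArchitectureSpec((16, 16, 1), (ConvBlock(3, 3, pool=(2, 2)),),
                                (), 2)
        monotone = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            net = build_network(spec, rng)
            hist = train_network(net, x, y, epochs=4, rng=rng)
            if all(b <= a + 1e-6 for a, b in zip(hist, hist[1:])):
                monotone += 1
        assert monotone >= 8


def test_architecture_yaml_round_trip(tmp_path):
    spec = build_ecnn(7, 3, (64, 64, 1))
    path = tmp_path / "arch.yaml"
    spec.to_yaml(path)
    assert ArchitectureSpec.from_yaml(path) == spec
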