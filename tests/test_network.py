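"""Architecture arithmetic, splitting, training and prediction contracts."""

import numpy as np
import pytest

from codoncnn.encoding import EncodedCohort
from codoncnn.network import (
    ConvNetClassifier,
    EncoderConfig,
    TrainConfig,
    _avgpool_forward,
    build_model,
    encoder_depth,
    pooled_lengths,
    predict,
    split_dataset,
    train,
)


def _random_cohort(rng, transcripts, n_samples, labels=None):
    indices = {
        tid: rng.integers(0, 64, (n_samples, n)).astype(np.int16)
        for tid, n in transcripts
    }
    return EncodedCohort(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        transcript_ids=[t for t, _ in transcripts],
        codon_counts=dict(transcripts),
        indices=indices,
        labels=labels,
    )


class TestEncoderDepth:
    @pytest.mark.parametrize(
        "codon_count,expected",
        [(1125, 4), (6, 1), (1, 1), (37, 3), (36, 2), (7, 2), (216, 3)],
    )
    def test_depth_examples(self, codon_count, expected):
        assert encoder_depth(codon_count, 6) == expected

    def test_matches_iterative_oracle_and_reaches_one(self):
        """Ceil-mode pooling applied depth times maps any N in 1..10^4 to 1."""
        for n in range(1, 10_001):
            length, steps = n, 0
            while length > 1:
                length = -(-length // 6)
                steps += 1
            assert encoder_depth(n, 6) == max(steps, 1)
            assert pooled_lengths(n, 6, encoder_depth(n, 6))[-1] == 1

    def test_actual_pooling_layer_shapes(self):
        rng = np.random.default_rng(0)
        for n in (1, 5, 6, 7, 35, 36, 37, 215, 216, 217, 1125):
            x = rng.normal(size=(2, n, 3)).astype(np.float32)
            for _ in range(encoder_depth(n, 6)):
                x, _ = _avgpool_forward(x, 6)
            assert x.shape[1] == 1


class TestBuildModel:
    def test_depth_and_head_shape_for_36_codons(self):
        model = build_model([("tx", 36)], EncoderConfig(), class_count=7)
        assert model.encoders[0].depth == 2
        model.initialize(np.random.default_rng(0))
        assert model.params["head_W"].shape == (6, 7)

    def test_head_input_dimension_scales_with_transcripts(self):
        transcripts = [(f"t{i}", 100) for i in range(985)]
        model = build_model(transcripts, EncoderConfig(output_channels=6), 7)
        assert model.head_input_dim == 5910

    def test_forward_shape_contract(self):
        rng = np.random.default_rng(1)
        transcripts = [("a", 40), ("b", 9)]
        cohort = _random_cohort(rng, transcripts, 5)
        model = build_model(transcripts, class_count=4)
        model.initialize(rng)
        logits = model.forward(cohort, np.arange(5))
        assert logits.shape == (5, 4)
        assert np.all(np.isfinite(logits))

    def test_class_count_guard(self):
        with pytest.raises(ValueError):
            build_model([("t", 10)], class_count=1)

    def test_head_permutation_equivariance(self):
        """Permuting transcripts and their head blocks leaves logits unchanged."""
        rng = np.random.default_rng(3)
        transcripts = [("a", 40), ("b", 9), ("c", 100)]
        cohort = _random_cohort(rng, transcripts, 6)
        model = build_model(transcripts, class_count=3)
        model.initialize(rng)
        logits = model.forward(cohort, np.arange(6))

        perm = [2, 0, 1]
        permuted = [transcripts[i] for i in perm]
        model2 = build_model(permuted, class_count=3)
        C = model.config.output_channels
        params2 = {}
        for new_t, (tid, _n) in enumerate(permuted):
            for key in model.params:
                if key.startswith(("conv_W/", "conv_b/", "affine_w/", "affine_b/")):
                    prefix, rest = key.split("/", 1)
                    if rest.split("/")[0] == tid:
                        params2[key] = model.params[key].copy()
        blocks = [
            model.params["head_W"][i * C : (i + 1) * C] for i in range(len(transcripts))
        ]
        params2["head_W"] = np.concatenate([blocks[i] for i in perm])
        params2["head_b"] = model.params["head_b"].copy()
        model2.params = params2
        assert np.allclose(model2.forward(cohort, np.arange(6)), logits, atol=1e-5)


class TestSplitDataset:
    def test_sizes_follow_ratio(self):
        tr, va, te = split_dataset(100, (7, 1, 2), seed=0)
        assert (len(tr), len(va), len(te)) == (70, 10, 20)
        all_idx = np.concatenate([tr, va, te])
        assert sorted(all_idx.tolist()) == list(range(100))

    def test_same_seed_same_partition(self):
        a = split_dataset(57, (7, 1, 2), seed=5)
        b = split_dataset(57, (7, 1, 2), seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_different_seed_differs(self):
        a = split_dataset(100, (7, 1, 2), seed=1)
        b = split_dataset(100, (7, 1, 2), seed=2)
        assert not np.array_equal(a[0], b[0])

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(100, (0, 0, 1), seed=0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2, (7, 1, 2), seed=0)


class TestTrainPredict:
    TRANSCRIPTS = [("a", 30), ("b", 80)]

    def _labeled_cohort(self, rng, n=24, k=3):
        labels = np.arange(n) % k
        return _random_cohort(rng, self.TRANSCRIPTS, n, labels=labels)

    def test_single_class_training_predicts_that_class(self):
        # all samples share one sequence set and one label: the degenerate
        # optimum is to predict that label everywhere
        rng = np.random.default_rng(0)
        row = {tid: rng.integers(0, 64, n).astype(np.int16) for tid, n in self.TRANSCRIPTS}
        indices = {tid: np.tile(row[tid], (16, 1)) for tid, _ in self.TRANSCRIPTS}
        cohort = EncodedCohort(
            sample_ids=[f"S{i}" for i in range(16)],
            transcript_ids=[t for t, _ in self.TRANSCRIPTS],
            codon_counts=dict(self.TRANSCRIPTS),
            indices=indices,
            labels=np.full(16, 1),
        )
        model = build_model(self.TRANSCRIPTS, class_count=3)
        train(model, cohort, np.arange(12), np.arange(12, 16), TrainConfig(epochs=5, seed=0))
        _, pred = predict(model, cohort, np.arange(12, 16))
        assert np.all(pred == 1)
        assert model.history["val_accuracy"][-1] == 1.0

    def test_same_seed_bitwise_identical_history(self):
        rng = np.random.default_rng(2)
        cohort = self._labeled_cohort(rng)
        histories = []
        for _ in range(2):
            model = build_model(self.TRANSCRIPTS, class_count=3)
            train(model, cohort, np.arange(18), np.arange(18, 24), TrainConfig(epochs=4, seed=9))
            histories.append(model.history["train_loss"])
        assert histories[0] == histories[1]

    def test_label_out_of_range_rejected_before_training(self):
        rng = np.random.default_rng(2)
        cohort = _random_cohort(rng, self.TRANSCRIPTS, 8, labels=np.full(8, 5))
        model = build_model(self.TRANSCRIPTS, class_count=3)
        with pytest.raises(ValueError, match="labels"):
            train(model, cohort, np.arange(6), np.arange(6, 8), TrainConfig(epochs=1))

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        cohort = _random_cohort(rng, [("a", 31), ("b", 80)], 8, labels=np.zeros(8, int))
        model = build_model(self.TRANSCRIPTS, class_count=3)
        with pytest.raises(ValueError, match="codon count"):
            train(model, cohort, np.arange(6), np.arange(6, 8), TrainConfig(epochs=1))

    def test_zero_head_predicts_lowest_index(self):
        rng = np.random.default_rng(4)
        cohort = _random_cohort(rng, self.TRANSCRIPTS, 5)
        model = build_model(self.TRANSCRIPTS, class_count=4)
        model.initialize(rng)
        model.params["head_W"][:] = 0.0
        model.params["head_b"][:] = 0.0
        scores, pred = predict(model, cohort, np.arange(5))
        assert np.allclose(scores, scores[:, [0]])
        assert np.all(pred == 0)

    def test_head_scaling_raises_matching_class_score(self):
        """Scores are linear in head weights for fixed encoder outputs."""
        rng = np.random.default_rng(5)
        cohort = _random_cohort(rng, self.TRANSCRIPTS, 3)
        model = build_model(self.TRANSCRIPTS, class_count=3)
        model.initialize(rng)
        model.params["head_b"][:] = 0.0
        base = model.forward(cohort, np.arange(3))
        model.params["head_W"][:, 2] *= 3.0
        scaled = model.forward(cohort, np.arange(3))
        assert np.allclose(scaled[:, 2], 3.0 * base[:, 2], rtol=1e-4)
        assert np.allclose(scaled[:, :2], base[:, :2])

    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        cohort = self._labeled_cohort(rng)
        model = build_model(self.TRANSCRIPTS, class_count=3)
        train(model, cohort, np.arange(18), np.arange(18, 24), TrainConfig(epochs=2, seed=3))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ConvNetClassifier.load(path)
        a, _ = predict(model, cohort, np.arange(24))
        b, _ = predict(loaded, cohort, np.arange(24))
        assert np.array_equal(a, b)
        assert loaded.history == model.history
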