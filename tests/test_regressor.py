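"""CNN regressor: encoding, augmentation, training, prediction, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import curvsense as cv
from curvsense.peptides import AA20
from curvsense.regressor import encode_batch, predict_encoded
from curvsense.surrogate import LabeledSequence


def _records(seqs_ddfs):
    return [LabeledSequence(cv.Peptide(s), d) for s, d in seqs_ddfs]


class TestEncoding:
    def test_homopolymer_layout(self):
        mat = cv.encode("A" * 7)
        assert mat.shape == (24, 20)
        assert mat[:7, 0].sum() == 7
        assert mat[7:].sum() == 0

    @given(st.text(alphabet=AA20, min_size=7, max_size=24))
    @settings(deadline=None)
    def test_row_sums_and_round_trip(self, seq):
        mat = cv.encode(seq)
        sums = mat.sum(axis=1)
        assert set(np.unique(sums)) <= {0.0, 1.0}
        assert mat.sum() == len(seq)
        assert cv.decode(mat) == seq

    @pytest.mark.parametrize("seq", ["AAAAAA", "A" * 25])
    def test_length_domain(self, seq):
        with pytest.raises(ValueError):
            cv.encode(seq)


class TestAugmentation:
    def _dataset(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return _records(
            ("".join(rng.choice(list(AA20), size=24)), float(-rng.uniform(0, 30)))
            for _ in range(n)
        )

    def test_fragment_lengths_in_range(self):
        data = self._dataset()
        out = cv.augment_split(data, rng=1)
        lengths = {len(r.peptide) for r in out if len(r.peptide) < 24}
        assert lengths <= set(range(7, 18))
        assert {len(r.peptide) for r in out} - lengths == {24}

    def test_pairs_sum_to_24_and_labels_proportional(self):
        data = _records([("ACDEFGHIKLMNPQRSTVWYACDE", -12.0)])
        out = cv.augment_split(data, rng=3)
        assert len(out) == 3
        orig, f1, f2 = out
        assert len(f1.peptide) + len(f2.peptide) == 24
        assert f1.sequence + f2.sequence == orig.sequence
        for frag in (f1, f2):
            assert frag.ddf == pytest.approx(-12.0 * len(frag.peptide) / 24)
            assert 7 <= len(frag.peptide) <= 17

    def test_triples_dataset_without_collisions(self):
        data = self._dataset(n=60, seed=4)
        out = cv.augment_split(data, rng=5)
        assert len(out) <= 3 * len(data)
        seqs = [r.sequence for r in out]
        assert len(set(seqs)) == len(seqs)  # no duplicates survive

    def test_duplicate_fragments_discarded_first_wins(self):
        # identical inputs produce identical fragments: kept once
        seq = "W" * 24
        data = _records([(seq, -10.0), (seq, -20.0)])
        out = cv.augment_split(data, rng=0)
        assert [r.sequence for r in out].count(seq) == 1
        assert out[0].ddf == -10.0

    def test_requires_reference_length(self):
        with pytest.raises(ValueError, match="reference length"):
            cv.augment_split(_records([("A" * 23, -1.0)]), rng=0)


class TestTraining:
    def test_constant_labels_learned_degenerately(self):
        rng = np.random.default_rng(2)
        data = _records(
            ("".join(rng.choice(list(AA20), size=12)), -7.5) for _ in range(150)
        )
        model, metrics = cv.train(
            data, cv.CNNSpec(((8, 3, 2), (8, 3, 2)), 16),
            cv.TrainConfig(seed=0, max_epochs=5),
        )
        preds = cv.predict(model, [r.peptide for r in data[:20]])
        assert np.allclose(preds, -7.5, atol=0.5)
        assert min(metrics.val_mse) < 0.25

    def test_shuffled_labels_are_unlearnable(self):
        rng = np.random.default_rng(8)
        data = cv.generate_dataset(400, (7, 24), cv.SurrogateParams(noise_sd=0.5), rng=rng)
        labels = np.array([r.ddf for r in data])
        rng.shuffle(labels)
        shuffled = [LabeledSequence(r.peptide, float(l)) for r, l in zip(data, labels)]
        _, metrics = cv.train(
            shuffled, cv.CNNSpec(((16, 5, 2), (16, 5, 2)), 32),
            cv.TrainConfig(seed=0, max_epochs=15),
        )
        assert metrics.final_r2 <= 0.1

    def test_too_little_data_rejected(self):
        data = _records([("A" * 12, -1.0)] * 50)
        with pytest.raises(ValueError, match="at least 100"):
            cv.train(data)


class TestPrediction:
    def test_recovers_surrogate_within_tolerance(self, trained_model, surrogate_dataset):
        model, _ = trained_model
        _, test_data = surrogate_dataset
        preds = cv.predict(model, [r.peptide for r in test_data])
        truth = np.array([cv.toy_ddf(r.peptide) for r in test_data])
        within = np.mean(np.abs(preds - truth) <= 3.0)
        assert within >= 0.9

    def test_batch_order_invariance(self, trained_model, surrogate_dataset):
        model, _ = trained_model
        _, test_data = surrogate_dataset
        peps = [r.peptide for r in test_data[:50]]
        fwd = cv.predict(model, peps)
        rev = cv.predict(model, peps[::-1])[::-1]
        assert np.allclose(fwd, rev)
        single = cv.predict(model, peps[0])
        assert np.allclose(single[0], fwd[0])

    def test_training_fit_at_least_as_good_as_validation(self, trained_model, surrogate_dataset):
        model, metrics = trained_model
        train_data, _ = surrogate_dataset
        fit = cv.evaluate(model, train_data)
        assert fit["mse"] <= min(metrics.val_mse) * 1.05

    def test_out_of_range_length_rejected(self, trained_model):
        model, _ = trained_model
        with pytest.raises(ValueError):
            cv.predict(model, "AAAA")


class TestEvaluateMetrics:
    def test_perfect_predictions(self, trained_model, surrogate_dataset):
        # relabel a dataset with the model's own outputs: MSE 0, R^2 1
        model, _ = trained_model
        _, test_data = surrogate_dataset
        peps = [r.peptide for r in test_data[:40]]
        preds = cv.predict(model, peps)
        relabeled = [LabeledSequence(p, float(v)) for p, v in zip(peps, preds)]
        m = cv.evaluate(model, relabeled)
        assert m["mse"] == pytest.approx(0.0, abs=1e-18)
        assert m["r2"] == pytest.approx(1.0)

    def test_rmse_is_sqrt_mse_on_real_model(self, trained_model, surrogate_dataset):
        model, _ = trained_model
        _, test_data = surrogate_dataset
        m = cv.evaluate(model, test_data)
        assert m["rmse"] == pytest.approx(np.sqrt(m["mse"]), abs=1e-12)
        assert m["r2"] <= 1.0

    def test_mean_only_predictor_has_zero_r2(self, trained_model, surrogate_dataset):
        # R^2 definition: predicting the mean of y gives SS_res = SS_tot
        _, test_data = surrogate_dataset
        y = np.array([r.ddf for r in test_data])
        ss_res = np.sum((y - y.mean()) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot == pytest.approx(0.0)


class TestPersistence:
    def test_save_load_round_trip(self, trained_model, surrogate_dataset, tmp_path):
        model, _ = trained_model
        _, test_data = surrogate_dataset
        cv.save_model(model, tmp_path / "model")
        reloaded = cv.load_model(tmp_path / "model")
        peps = [r.peptide for r in test_data[:30]]
        assert np.allclose(cv.predict(model, peps), cv.predict(reloaded, peps))
        assert (tmp_path / "model" / "spec.json").exists()
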