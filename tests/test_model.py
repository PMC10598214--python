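import math

import numpy as np
import pytest

import pepprior as pp
from pepprior import (
    EarlyStopping,
    HeadConfig,
    InterfaceModel,
    MLPHead,
    OneHotContextBackend,
    ProteinSequence,
    TinyTransformerBackend,
    TrainingConfig,
    bce_loss,
    train,
)
from pepprior.dataset import LabeledSequence
from pepprior.model import _sequence_loss_and_grads, dataset_loss


class TestBceLoss:
    def test_half_probability_positive_is_ln2(self):
        assert bce_loss(np.array([0.5]), np.array([1])) == pytest.approx(math.log(2), abs=1e-9)

    def test_perfect_prediction_is_near_zero(self):
        loss = bce_loss(np.array([1.0, 0.0]), np.array([1, 0]))
        assert 0 <= loss < 1e-6

    def test_weight_scales_linearly(self):
        p, y = np.array([0.5]), np.array([1])
        assert bce_loss(p, y, weight=2.0) == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        assert bce_loss(p, np.ones(20)) == pytest.approx(bce_loss(1 - p, np.zeros(20)))

    def test_empty_mask_is_zero(self):
        assert bce_loss(np.array([0.3]), np.array([1]), mask=np.array([False])) == 0.0

    def test_masked_positions_excluded(self):
        p = np.array([0.5, 0.01])
        y = np.array([1, 1])
        masked = bce_loss(p, y, mask=np.array([True, False]))
        assert masked == pytest.approx(math.log(2), abs=1e-9)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bce_loss(np.array([1.5]), np.array([1]))


class TestGradients:
    def _numerical_check(self, backend, keys, ls, tol=1e-4):
        rng = np.random.default_rng(1)
        head = MLPHead(backend.dim, HeadConfig(hidden_sizes=(8, 6, 4)), seed=2)
        model = InterfaceModel(backend, head)
        _, grads = _sequence_loss_and_grads(model, ls, True)

        params = {f"head.{k}": v for k, v in head.parameters().items()}
        params.update({f"backend.{k}": v for k, v in backend.trainable_parameters().items()})
        eps = 1e-6
        for key in keys:
            arr = params[key]
            flat_idx = rng.integers(arr.size, size=min(5, arr.size))
            for fi in flat_idx:
                idx = np.unravel_index(fi, arr.shape)
                orig = arr[idx]
                arr[idx] = orig + eps
                hi, _ = _sequence_loss_and_grads(model, ls, False)
                arr[idx] = orig - eps
                lo, _ = _sequence_loss_and_grads(model, ls, False)
                arr[idx] = orig
                num = (hi - lo) / (2 * eps)
                ana = grads[key][idx]
                assert abs(num - ana) <= tol * max(1.0, abs(num)), key

    def test_head_gradients_match_numerical(self):
        rng = np.random.default_rng(7)
        ls = LabeledSequence(
            "s", "MKVLLACDEF",
            rng.integers(0, 2, 10),
            rng.random(10) > 0.2,
            weight=1.7,
        )
        backend = OneHotContextBackend(radius=1)
        keys = [f"head.W{i}" for i in range(4)] + [f"head.b{i}" for i in range(4)]
        self._numerical_check(backend, keys, ls)

    def test_backend_finetune_gradients_match_numerical(self):
        rng = np.random.default_rng(8)
        ls = LabeledSequence("s", "MKVLLACD", rng.integers(0, 2, 8), None, weight=1.0)
        backend = TinyTransformerBackend(dim=6, n_blocks=3, seed=4, trainable_last_k=2)
        self._numerical_check(backend, ["backend.block1.Wq", "backend.block2.W1"], ls)


class TestEarlyStopping:
    def test_injected_schedule_stops_after_patience(self):
        stopper = EarlyStopping(patience=2)
        decisions = [stopper.update(v) for v in [1.0, 0.9, 0.95, 0.97]]
        assert decisions == [False, False, False, True]
        assert stopper.best_epoch == 2

    def test_strictly_decreasing_never_triggers(self):
        stopper = EarlyStopping(patience=1)
        assert not any(stopper.update(v) for v in np.linspace(1.0, 0.1, 30))
        assert stopper.best_epoch == 30


def tiny_dataset(rng, n_seqs, length=30, prefix="t"):
    """Linearly separable fixture: K residues are positive, others negative."""
    out = []
    for i in range(n_seqs):
        residues = "".join(rng.choice(list("KAVD"), length))
        labels = np.array([1 if c == "K" else 0 for c in residues])
        out.append(LabeledSequence(f"{prefix}{i}", residues, labels))
    return out


class TestPredict:
    def test_zeroed_output_layer_gives_half(self):
        backend = OneHotContextBackend(radius=0)
        head = MLPHead(backend.dim, seed=0)
        head.weights[3][:] = 0.0
        head.biases[3][:] = 0.0
        track = InterfaceModel(backend, head).predict(ProteinSequence("s", "MKV"))
        np.testing.assert_array_equal(track.p, 0.5)

    def test_prediction_deterministic(self):
        backend = OneHotContextBackend(radius=2)
        model = InterfaceModel(backend, MLPHead(backend.dim, seed=1))
        seq = ProteinSequence("s", "MKVLLACDEF")
        np.testing.assert_array_equal(model.predict(seq).p, model.predict(seq).p)


class TestTrain:
    def test_separable_fixture_loss_decreases(self):
        rng = np.random.default_rng(0)
        backend = OneHotContextBackend(radius=0)
        model, report = train(
            backend, HeadConfig(hidden_sizes=(16, 8, 4)),
            tiny_dataset(rng, 12), tiny_dataset(np.random.default_rng(99), 4, prefix="v"),
            TrainingConfig(max_epochs=10, patience=10, seed=0),
        )
        assert report.train_losses[-1] < report.train_losses[0]
        assert report.best_epoch == int(np.argmin(report.val_losses)) + 1

    def test_reproducible_given_seed(self):
        rng1, rng2 = np.random.default_rng(0), np.random.default_rng(0)
        cfg = TrainingConfig(max_epochs=3, patience=5, seed=42)
        m1, r1 = train(OneHotContextBackend(0), HeadConfig((8, 6, 4)),
                       tiny_dataset(rng1, 6), tiny_dataset(np.random.default_rng(1), 3, prefix="v"), cfg)
        m2, r2 = train(OneHotContextBackend(0), HeadConfig((8, 6, 4)),
                       tiny_dataset(rng2, 6), tiny_dataset(np.random.default_rng(1), 3, prefix="v"), cfg)
        assert r1.val_losses == r2.val_losses
        seq = ProteinSequence("q", "KAVDKAVD")
        np.testing.assert_array_equal(m1.predict(seq).p, m2.predict(seq).p)

    def test_frozen_backend_outputs_bit_identical_after_training(self):
        backend = TinyTransformerBackend(dim=8, n_blocks=2, seed=3, trainable_last_k=0)
        seq = ProteinSequence("probe", "MKVLLACDEF")
        before = backend.embed(seq).copy()
        train(backend, HeadConfig((8, 6, 4)),
              tiny_dataset(np.random.default_rng(0), 6),
              tiny_dataset(np.random.default_rng(1), 3, prefix="v"),
              TrainingConfig(max_epochs=2, patience=5, seed=0))
        np.testing.assert_array_equal(backend.embed(seq), before)

    def test_finetuned_backend_parameters_change(self):
        backend = TinyTransformerBackend(dim=8, n_blocks=2, seed=3, trainable_last_k=1)
        before = {k: v.copy() for k, v in backend.trainable_parameters().items()}
        train(backend, HeadConfig((8, 6, 4)),
              tiny_dataset(np.random.default_rng(0), 6),
              tiny_dataset(np.random.default_rng(1), 3, prefix="v"),
              TrainingConfig(max_epochs=2, patience=5, seed=0))
        changed = any(
            not np.array_equal(before[k], v)
            for k, v in backend.trainable_parameters().items()
        )
        assert changed

    def test_weight_doubling_doubles_loss(self):
        rng = np.random.default_rng(0)
        data = tiny_dataset(rng, 4)
        backend = OneHotContextBackend(0)
        model = InterfaceModel(backend, MLPHead(backend.dim, seed=0))
        base = dataset_loss(model, data)
        doubled = [
            LabeledSequence(ls.sequence_id, ls.residues, ls.labels, ls.mask, 2.0)
            for ls in data
        ]
        assert dataset_loss(model, doubled) == pytest.approx(2 * base)

    def test_overlapping_train_val_ids_rejected(self):
        data = tiny_dataset(np.random.default_rng(0), 3)
        with pytest.raises(ValueError, match="overlap"):
            train(OneHotContextBackend(0), HeadConfig((8, 6, 4)), data, data[:1],
                  TrainingConfig(max_epochs=1))

    def test_empty_sets_rejected(self):
        data = tiny_dataset(np.random.default_rng(0), 3)
        with pytest.raises(ValueError, match="nonempty"):
            train(OneHotContextBackend(0), HeadConfig((8, 6, 4)), [], data,
                  TrainingConfig(max_epochs=1))

    def test_all_masked_training_set_rejected(self):
        data = tiny_dataset(np.random.default_rng(0), 2)
        masked = [
            LabeledSequence(ls.sequence_id, ls.residues, ls.labels,
                            np.zeros(len(ls.residues), dtype=bool))
            for ls in data
        ]
        other = tiny_dataset(np.random.default_rng(5), 2)
        other = [LabeledSequence("v" + ls.sequence_id, ls.residues, ls.labels) for ls in other]
        with pytest.raises(ValueError, match="masked"):
            train(OneHotContextBackend(0), HeadConfig((8, 6, 4)), masked, other,
                  TrainingConfig(max_epochs=1))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        backend = TinyTransformerBackend(dim=8, n_blocks=2, seed=3)
        model = InterfaceModel(backend, MLPHead(8, HeadConfig((8, 6, 4)), seed=1))
        path = tmp_path / "model.npz"
        model.save(path, meta={"note": "roundtrip"})
        loaded = InterfaceModel.load(path)
        seq = ProteinSequence("s", "MKVLLACDEF")
        np.testing.assert_array_equal(model.predict(seq).p, loaded.predict(seq).p)
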