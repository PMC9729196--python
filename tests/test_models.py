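"""Training, scoring contract, weight maps and model persistence."""

import numpy as np
import pytest

from nbpoly.evaluation import roc_auc
from nbpoly.models import (
    ModelSpec,
    PolyreactivityModel,
    PolyreactivityResults,
    encode_onehot_matrix,
    load_model,
    save_model,
    score_sequences,
    train_model,
)
from nbpoly.numbering import FrameConfig, assign_frame
from nbpoly.features import one_hot_encode
from nbpoly.seqio import LabeledPool, NanobodyRecord
from nbpoly.synthetic import SyntheticConfig, generate_pools
from nbpoly.util import AA_ALPHABET, ModelIOError


def _pool_from(records, label):
    pool = LabeledPool(label)
    for r in records:
        pool.add(r)
    return pool


def _random_records(rng, n, prefix="r"):
    recs = []
    for i in range(n):
        l3 = int(rng.integers(6, 23))
        cdrs = tuple(
            "".join(rng.choice(list(AA_ALPHABET), size=k)) for k in (8, 8, l3)
        )
        recs.append(NanobodyRecord(f"{prefix}{i}", "".join(cdrs), *cdrs))
    return recs


class TestTrainModel:
    def test_separable_pools_reach_auc_1(self, rng):
        """Noiseless planted weights: the one-hot LR separates perfectly."""
        cfg = SyntheticConfig(n_per_class=300, sigma=0.0, seed=5)
        pools = generate_pools(cfg)
        model = train_model(ModelSpec("onehot_lr", l2=0.01), pools.low, pools.high)
        recs = pools.all_records()
        labels = [1 if r.source_pool == "low" else 0 for r in recs]
        assert roc_auc(model.score(recs), labels) > 0.999

    def test_label_shuffled_pools_give_chance_auc(self, rng):
        cfg = SyntheticConfig(n_per_class=1000, seed=6, position_weights={}, motif_weights={})
        pools = generate_pools(cfg)
        recs = pools.all_records()
        perm = rng.permutation(len(recs))
        heldout = set(perm[:600].tolist())
        train = [recs[i] for i in range(len(recs)) if i not in heldout]
        test = [recs[i] for i in heldout]
        model = train_model(
            ModelSpec("onehot_lr"),
            _pool_from([r for r in train if r.source_pool == "low"], 1),
            _pool_from([r for r in train if r.source_pool == "high"], 0),
        )
        labels = [1 if r.source_pool == "low" else 0 for r in test]
        assert 0.40 < roc_auc(model.score(test), labels) < 0.60

    def test_single_class_input_rejected(self, small_pools):
        empty = LabeledPool(0)
        with pytest.raises(ValueError):
            PolyreactivityModel(small_pools.low, empty)

    def test_lr_training_seed_independent(self, small_pools):
        a = train_model(ModelSpec("onehot_lr", seed=1), small_pools.low, small_pools.high)
        b = train_model(ModelSpec("onehot_lr", seed=99), small_pools.low, small_pools.high)
        assert np.allclose(a.params["coef"], b.params["coef"], atol=1e-5)


class TestPlantedSignalRecovery:
    """All four model families separate planted-signal pools well.

    Problem sizes differ per family to keep training tractable: the convex
    LR models at 20,000/class, the GRU at 4,000/class, and the CNN at
    10,000/class where its generalization stabilizes.
    """

    def _heldout(self, n_per_class, n_test, rng_seed=0):
        pools = generate_pools(SyntheticConfig(n_per_class=n_per_class, sigma=0.5, seed=3))
        recs = pools.all_records()
        rng = np.random.default_rng(rng_seed)
        perm = rng.permutation(len(recs))
        test_idx = set(perm[:n_test].tolist())
        train = [recs[i] for i in range(len(recs)) if i not in test_idx]
        test = [recs[i] for i in test_idx]
        return (
            _pool_from([r for r in train if r.source_pool == "low"], 1),
            _pool_from([r for r in train if r.source_pool == "high"], 0),
            test,
            [1 if r.source_pool == "low" else 0 for r in test],
        )

    def test_lr_heldout_auc_above_09(self):
        low, high, test, labels = self._heldout(20000, 6000)
        for spec in (ModelSpec("onehot_lr", seed=0), ModelSpec("kmer_lr", seed=0)):
            model = train_model(spec, low, high)
            auc = roc_auc(model.score(test), labels)
            assert auc > 0.9, f"{spec.kind}: AUC {auc:.3f}"

    def test_rnn_heldout_auc_above_09(self):
        low, high, test, labels = self._heldout(4000, 1500)
        model = train_model(ModelSpec("rnn", seed=0, epochs=10), low, high)
        auc = roc_auc(model.score(test), labels)
        assert auc > 0.9, f"rnn: AUC {auc:.3f}"

    def test_cnn_heldout_auc_above_09(self):
        low, high, test, labels = self._heldout(10000, 3000)
        model = train_model(ModelSpec("cnn", seed=0, epochs=20, patience=4), low, high)
        auc = roc_auc(model.score(test), labels)
        assert auc > 0.9, f"cnn: AUC {auc:.3f}"


class TestScoring:
    def test_onehot_score_matches_dot_product_oracle(self, lr_suite, rng):
        model = lr_suite["onehot_lr"]
        recs = _random_records(rng, 100)
        scores = model.score(recs)
        cfg = model.frame_config
        for rec, s in zip(recs, scores):
            vec = one_hot_encode(assign_frame(*rec.cdr_triple, cfg))
            expected = vec @ model.params["coef"] + model.params["intercept"][0]
            assert s == pytest.approx(expected, abs=1e-10)

    def test_duplicate_records_identical_scores(self, lr_suite, rng):
        rec = _random_records(rng, 1)[0]
        for model in lr_suite.values():
            a, b = model.score([rec, rec])
            assert a == b

    def test_planted_negative_motif_decreases_score(self, rng):
        """Appending a penalized motif to CDR3 strictly lowers the score."""
        cfg = FrameConfig()
        coef = np.zeros(cfg.n_slots * 20)
        # penalize arginine at the last CDR3 slots
        for slot in ("116", "117"):
            coef[cfg.slot_order.index(slot) * 20 + AA_ALPHABET.index("R")] = -3.0
        spec = ModelSpec("onehot_lr")
        model = PolyreactivityResults(
            spec, cfg, {"coef": coef, "intercept": np.zeros(1)}, {}
        )
        base = NanobodyRecord("p", "", "GSIFSSNA", "ITSGGSTN", "ADYWGS")
        worse = NanobodyRecord("q", "", "GSIFSSNA", "ITSGGSTN", "ADYWRR")
        s_base, s_worse = model.score([base, worse])
        assert s_worse < s_base

    def test_score_failure_is_per_record(self, lr_suite):
        good = NanobodyRecord("g", "", "GSIFSSNA", "ITSGGSTN", "ARDYWG")
        bad = NanobodyRecord("b", "", "GSIF", "ITSGGSTN", "ARDYWG")  # CDR1 too short
        scores, failures = score_sequences(lr_suite["onehot_lr"], [good, bad])
        assert [s.id for s in scores] == ["g"]
        assert failures[0][0] == "b" and "CDR1" in failures[0][1]


class TestWeightMaps:
    def test_reshape_round_trip(self, lr_suite):
        model = lr_suite["onehot_lr"]
        table = model.position_weight_map()
        assert table.to_numpy().ravel() == pytest.approx(model.params["coef"])

    def test_planted_arginine_penalty_recovered(self, small_pools):
        """Arginine at planted slots carries a negative recovered weight."""
        model = train_model(ModelSpec("onehot_lr"), small_pools.low, small_pools.high)
        table = model.position_weight_map()
        assert table.loc["36", "R"] < 0
        assert table.loc["106", "R"] < 0
        assert table.loc["106", "D"] > 0

    def test_never_occupied_slot_has_small_weights(self, small_pools):
        """L2 keeps weights of slots absent from training data near zero.

        CDR1 is fixed at length 8, so the central CDR1 slots 31-34 are gaps
        in every record.
        """
        model = train_model(ModelSpec("onehot_lr"), small_pools.low, small_pools.high)
        table = model.position_weight_map()
        assert np.abs(table.loc["31"].to_numpy()).max() < 1e-6

    def test_motif_table_is_permutation_and_truncates(self, lr_suite):
        model = lr_suite["kmer_lr"]
        top, bottom = model.motif_scores(10)
        assert len(top) == len(bottom) == 10
        empty_top, empty_bottom = model.motif_scores(0)
        assert empty_top.empty and empty_bottom.empty
        full_top, _ = model.motif_scores(10**9)
        assert sorted(full_top["motif"]) == sorted(set(full_top["motif"]))
        assert len(full_top) == 8420

    def test_wrong_kind_rejected(self, lr_suite):
        with pytest.raises(ValueError):
            lr_suite["kmer_lr"].position_weight_map()
        with pytest.raises(ValueError):
            lr_suite["onehot_lr"].motif_scores(5)


class TestPersistence:
    def test_lr_round_trip_identical_scores(self, tmp_path, lr_suite, rng):
        recs = _random_records(rng, 20)
        for kind, model in lr_suite.items():
            path = tmp_path / f"{kind}.npz"
            save_model(model, path)
            back = load_model(path)
            assert np.array_equal(back.score(recs), model.score(recs))

    def test_nn_round_trip_tolerance(self, tmp_path, small_pools, rng):
        model = train_model(
            ModelSpec("cnn", epochs=2, seed=0), small_pools.low, small_pools.high
        )
        path = tmp_path / "cnn.npz"
        save_model(model, path)
        back = load_model(path)
        recs = _random_records(rng, 50)
        assert np.abs(back.score(recs) - model.score(recs)).max() < 1e-6

    def test_corrupt_archive_raises(self, tmp_path):
        path = tmp_path / "junk.npz"
        path.write_bytes(b"not a model")
        with pytest.raises(ModelIOError):
            load_model(path)

    def test_version_mismatch_raises(self, tmp_path, lr_suite, monkeypatch):
        import nbpoly.models as m

        path = tmp_path / "old.npz"
        monkeypatch.setattr(m, "_ARCHIVE_VERSION", "0", raising=True)
        save_model(lr_suite["onehot_lr"], path)
        monkeypatch.undo()
        with pytest.raises(ModelIOError, match="version"):
            load_model(path)
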