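"""Supervised polyreactivity classifiers with a common scoring contract.

Four model families are trained on the low (class 1) versus high (class 0)
polyreactivity pools:

* ``onehot_lr`` — logistic regression on the aligned one-hot embedding;
  weights are directly interpretable per (IMGT slot, residue),
* ``kmer_lr``   — logistic regression on 1-/2-/3-mer counts (8,420 motifs),
* ``cnn``       — a three-block 1D convolutional network on the aligned
  one-hot grid (20 -> 32 -> 64 -> 128 channels, batch norm, ReLU, max
  pooling) with a dense head,
* ``rnn``       — a two-layer GRU (hidden size 128) over the unaligned
  padded one-hot sequence.

All four emit the same score: the log-odds of the *low*-polyreactivity
class, so a high score always means low predicted polyreactivity.

The API follows the fit/results pattern: build a
:class:`PolyreactivityModel` from two pools, call :meth:`fit` to obtain a
:class:`PolyreactivityResults` carrying the trained parameters, scoring,
weight maps and a text summary.  Functional wrappers (``train_model``,
``score_sequences``, ...) are provided for pipeline use.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from . import _nn
from .features import kmer_vocabulary, one_hot_encode
from .numbering import FrameConfig, assign_frame
from .seqio import LabeledPool, NanobodyRecord
from .util import AA_ALPHABET, ModelIOError

__all__ = [
    "ModelSpec",
    "PolyreactivityScore",
    "PolyreactivityModel",
    "PolyreactivityResults",
    "train_model",
    "train_suite",
    "score_sequences",
    "position_weight_map",
    "motif_score_table",
    "save_model",
    "load_model",
    "encode_onehot_matrix",
    "encode_kmer_matrix",
    "encode_rnn_tensor",
]

MODEL_KINDS = ("onehot_lr", "kmer_lr", "cnn", "rnn")
_ARCHIVE_VERSION = "1"


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and training hyperparameters for one classifier.

    ``l2`` is the L2 penalty strength for the logistic regressions (the
    sklearn ``C`` is ``1/l2``).  Neural-net fields are ignored by the LR
    kinds and vice versa.  The seed fully determines initialization and the
    minibatch order, so training is reproducible.
    """

    kind: str
    l2: float = 1.0
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 256
    hidden_size: int = 128
    n_layers: int = 2
    val_frac: float = 0.1
    patience: int = 3
    k_max: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")


@dataclass
class PolyreactivityScore:
    """Log-odds of the low-polyreactivity class; higher = less polyreactive."""

    id: str
    value: float
    model_kind: str


# ---------------------------------------------------------------------------
# batch encoders
# ---------------------------------------------------------------------------


def encode_onehot_matrix(records: list[NanobodyRecord], config: FrameConfig) -> np.ndarray:
    """(n_records, n_slots * 20) aligned one-hot matrix."""
    X = np.zeros((len(records), config.n_slots * 20))
    for i, rec in enumerate(records):
        X[i] = one_hot_encode(assign_frame(rec.cdr1, rec.cdr2, rec.cdr3, config))
    return X


def encode_kmer_matrix(records: list[NanobodyRecord], k_max: int = 3) -> sp.csr_matrix:
    """Sparse (n_records, n_motifs) count matrix over the fixed vocabulary."""
    _, index = kmer_vocabulary(k_max)
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for rec in records:
        row: dict[int, int] = {}
        for cdr in rec.cdr_triple:
            L = len(cdr)
            for k in range(1, k_max + 1):
                for i in range(L - k + 1):
                    j = index[cdr[i : i + k]]
                    row[j] = row.get(j, 0) + 1
        items = sorted(row.items())
        indices.extend(j for j, _ in items)
        data.extend(c for _, c in items)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.array(data, float), np.array(indices), np.array(indptr)),
        shape=(len(records), len(index)),
    )


def _rnn_max_len(config: FrameConfig) -> int:
    return config.cdr1_len + max(config.cdr2_lens) + config.max_cdr3


def encode_rnn_tensor(
    records: list[NanobodyRecord], config: FrameConfig, dtype=np.float32
) -> np.ndarray:
    """Unaligned one-hot (n, max_len, 20); sequences end-padded with zeros."""
    T = _rnn_max_len(config)
    X = np.zeros((len(records), T, 20), dtype=dtype)
    aa_index = {a: i for i, a in enumerate(AA_ALPHABET)}
    for i, rec in enumerate(records):
        seq = rec.cdr_concat
        for t, c in enumerate(seq):
            X[i, t, aa_index[c]] = 1.0
    return X


def _encode_for_kind(kind, records, config, k_max, dtype=np.float32):
    if kind == "onehot_lr":
        return encode_onehot_matrix(records, config)
    if kind == "kmer_lr":
        return encode_kmer_matrix(records, k_max)
    if kind == "cnn":
        X = encode_onehot_matrix(records, config).astype(dtype)
        return X.reshape(len(records), config.n_slots, 20).transpose(0, 2, 1).copy()
    return encode_rnn_tensor(records, config, dtype)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class PolyreactivityModel:
    """Untrained classifier bound to its training pools.

    Parameters
    ----------
    low, high
        The labelled pools; class 1 is the low-polyreactivity pool.
    spec
        Architecture/hyperparameters; defaults to a one-hot logistic
        regression.
    frame_config
        CDR slot layout shared by encoder and models.
    """

    def __init__(
        self,
        low: LabeledPool,
        high: LabeledPool,
        spec: ModelSpec | None = None,
        frame_config: FrameConfig | None = None,
    ):
        if len(low) == 0 or len(high) == 0:
            raise ValueError("both pools must be non-empty")
        if low.label != 1 or high.label != 0:
            raise ValueError("expected pools labelled low=1 and high=0")
        self.low = low
        self.high = high
        self.spec = spec or ModelSpec("onehot_lr")
        self.frame_config = frame_config or FrameConfig()

    @classmethod
    def from_pools(cls, low, high, kind="onehot_lr", frame_config=None, **hyper):
        return cls(low, high, ModelSpec(kind=kind, **hyper), frame_config)

    def fit(self) -> "PolyreactivityResults":
        spec = self.spec
        records = self.low.record_list() + self.high.record_list()
        y = np.concatenate([np.ones(len(self.low)), np.zeros(len(self.high))])
        X = _encode_for_kind(spec.kind, records, self.frame_config, spec.k_max)
        meta = {
            "n_low": len(self.low),
            "n_high": len(self.high),
            "frame_hash": self.frame_config.config_hash(),
        }
        if spec.kind in ("onehot_lr", "kmer_lr"):
            clf = LogisticRegression(
                C=1.0 / spec.l2, solver="lbfgs", max_iter=5000, tol=1e-8
            )
            clf.fit(X, y)
            params = {"coef": clf.coef_.ravel().copy(), "intercept": np.atleast_1d(clf.intercept_).copy()}
            return PolyreactivityResults(spec, self.frame_config, params, meta)
        if spec.kind == "cnn":
            net = _nn.build_cnn(self.frame_config.n_slots, spec.seed)
        else:
            net = _nn.build_gru(
                _rnn_max_len(self.frame_config), spec.seed, spec.hidden_size, spec.n_layers
            )
        history = _nn.fit_network(
            net,
            X,
            y,
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            lr=spec.learning_rate,
            seed=spec.seed,
            val_frac=spec.val_frac,
            patience=spec.patience,
        )
        meta["history"] = history
        return PolyreactivityResults(spec, self.frame_config, {"net": net}, meta)


class PolyreactivityResults:
    """A trained classifier: parameters, scoring, diagnostics, persistence."""

    def __init__(self, spec: ModelSpec, frame_config: FrameConfig, params: dict, meta: dict):
        self.spec = spec
        self.frame_config = frame_config
        self.params = params
        self.meta = meta

    @property
    def kind(self) -> str:
        return self.spec.kind

    # ---- scoring -----------------------------------------------------
    def check_record(self, record: NanobodyRecord) -> str | None:
        """Reason the record fails the frame-compatible filters, or None."""
        cfg = self.frame_config
        for region, cdr in enumerate(record.cdr_triple):
            if any(c not in AA_ALPHABET for c in cdr):
                return f"CDR{region + 1} contains a non-standard residue"
            if not cfg.cdr_length_ok(region, len(cdr)):
                return f"CDR{region + 1} length {len(cdr)} outside library bounds"
        return None

    def score(self, records: list[NanobodyRecord]) -> np.ndarray:
        """Log-odds of the low class for records that pass the filters."""
        for rec in records:
            reason = self.check_record(rec)
            if reason is not None:
                raise ValueError(f"record {rec.id!r}: {reason}")
        if not records:
            return np.empty(0)
        X = _encode_for_kind(self.kind, records, self.frame_config, self.spec.k_max)
        if self.kind in ("onehot_lr", "kmer_lr"):
            return np.asarray(X @ self.params["coef"]).ravel() + self.params["intercept"][0]
        return _nn.predict_logits(self.params["net"], X).astype(float)

    # ---- interpretation ----------------------------------------------
    def position_weight_map(self) -> pd.DataFrame:
        """(slot x residue) weight table; positive = low polyreactivity."""
        if self.kind != "onehot_lr":
            raise ValueError("position weight map is defined for onehot_lr only")
        slots = self.frame_config.slot_order
        w = self.params["coef"].reshape(len(slots), 20)
        return pd.DataFrame(w, index=list(slots), columns=list(AA_ALPHABET))

    def motif_scores(self, top_n: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Top motifs for the low (descending) and high (ascending) extremes."""
        if self.kind != "kmer_lr":
            raise ValueError("motif scores are defined for kmer_lr only")
        vocab, _ = kmer_vocabulary(self.spec.k_max)
        df = pd.DataFrame({"motif": list(vocab), "weight": self.params["coef"]})
        ranked = df.sort_values(["weight", "motif"], ascending=[False, True]).reset_index(drop=True)
        top_n = max(0, min(top_n, len(ranked)))
        return ranked.head(top_n), ranked.tail(top_n).iloc[::-1].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Polyreactivity classifier",
            "=" * 40,
            f"kind:            {self.kind}",
            f"train n (low):   {self.meta.get('n_low')}",
            f"train n (high):  {self.meta.get('n_high')}",
            f"frame hash:      {self.meta.get('frame_hash')}",
            f"seed:            {self.spec.seed}",
        ]
        if self.kind in ("onehot_lr", "kmer_lr"):
            lines.append(f"L2 strength:     {self.spec.l2}")
            lines.append(f"n parameters:    {self.params['coef'].size + 1}")
        else:
            hist = self.meta.get("history", {})
            n_params = sum(
                p.size for l in self.params["net"].layers for p in l.params.values()
            )
            lines.append(f"n parameters:    {n_params}")
            if hist.get("val_loss"):
                lines.append(f"best val loss:   {min(hist['val_loss']):.4f}")
        lines.append("score: log-odds(low class); high score = low predicted polyreactivity")
        return "\n".join(lines)

    # ---- persistence -------------------------------------------------
    def save(self, path) -> None:
        arrays = {}
        if self.kind in ("onehot_lr", "kmer_lr"):
            arrays["coef"] = self.params["coef"]
            arrays["intercept"] = self.params["intercept"]
        else:
            for i, layer in enumerate(self.params["net"].layers):
                for k, v in layer.params.items():
                    arrays[f"layer{i}.{k}"] = v
                if isinstance(layer, _nn.BatchNorm1D):
                    arrays[f"layer{i}.__rm"] = layer.running_mean
                    arrays[f"layer{i}.__rv"] = layer.running_var
        header = {
            "version": _ARCHIVE_VERSION,
            "spec": asdict(self.spec),
            "frame": asdict(self.frame_config),
            "meta": {k: v for k, v in self.meta.items() if k != "history"},
        }
        arrays["__header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @staticmethod
    def load(path) -> "PolyreactivityResults":
        try:
            with np.load(path) as npz:
                arrays = {k: npz[k] for k in npz.files}
            header = json.loads(arrays.pop("__header").tobytes().decode())
        except Exception as exc:
            raise ModelIOError(f"cannot read model archive {path}: {exc}") from exc
        if header.get("version") != _ARCHIVE_VERSION:
            raise ModelIOError(
                f"archive version {header.get('version')!r} unsupported "
                f"(expected {_ARCHIVE_VERSION})"
            )
        spec = ModelSpec(**header["spec"])
        frame = FrameConfig(**header["frame"])
        if spec.kind in ("onehot_lr", "kmer_lr"):
            params = {"coef": arrays["coef"], "intercept": arrays["intercept"]}
        else:
            if spec.kind == "cnn":
                net = _nn.build_cnn(frame.n_slots, spec.seed)
            else:
                net = _nn.build_gru(_rnn_max_len(frame), spec.seed, spec.hidden_size, spec.n_layers)
            for i, layer in enumerate(net.layers):
                for k in layer.params:
                    layer.params[k] = arrays[f"layer{i}.{k}"].copy()
                if isinstance(layer, _nn.BatchNorm1D):
                    layer.running_mean = arrays[f"layer{i}.__rm"].copy()
                    layer.running_var = arrays[f"layer{i}.__rv"].copy()
            params = {"net": net}
        return PolyreactivityResults(spec, frame, params, header["meta"])


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def train_model(spec: ModelSpec, low: LabeledPool, high: LabeledPool, frame_config=None):
    return PolyreactivityModel(low, high, spec, frame_config).fit()


def train_suite(low, high, kinds=MODEL_KINDS, frame_config=None, seed=0, **hyper):
    """Train one model per kind; returns {kind: PolyreactivityResults}."""
    return {
        kind: train_model(ModelSpec(kind=kind, seed=seed, **hyper), low, high, frame_config)
        for kind in kinds
    }


def score_sequences(model: PolyreactivityResults, records: list[NanobodyRecord]):
    """Score records; per-record failures are collected, not fatal.

    Returns ``(scores, failures)``: a list of :class:`PolyreactivityScore`
    for passing records and a list of ``(id, reason)`` for the rest.
    """
    valid, failures = [], []
    for rec in records:
        reason = model.check_record(rec)
        if reason is None:
            valid.append(rec)
        else:
            failures.append((rec.id, reason))
    values = model.score(valid)
    scores = [
        PolyreactivityScore(rec.id, float(v), model.kind) for rec, v in zip(valid, values)
    ]
    return scores, failures


def position_weight_map(model: PolyreactivityResults) -> pd.DataFrame:
    return model.position_weight_map()


def motif_score_table(model: PolyreactivityResults, top_n: int = 10):
    return model.motif_scores(top_n)


def save_model(model: PolyreactivityResults, path) -> None:
    model.save(path)


def load_model(path) -> PolyreactivityResults:
    return PolyreactivityResults.load(path)
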