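"""Generalization-aware splits and the evaluation metrics.

Naive random splits overestimate classifier accuracy on deep-sequenced
display libraries because near-duplicate clones land on both sides.  Here
records are k-means-clustered on the aligned one-hot embedding, whole
clusters are held out as the test set, and any training record within a
configured Levenshtein distance of (or above a configured identity fraction
to) any test record is removed from the training set.  Metrics are the
rank-based ROC AUC (Mann-Whitney, average-rank ties) and Spearman rank
correlation against measured polyreactivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .features import baseline_descriptors
from .models import PolyreactivityResults, encode_onehot_matrix
from .numbering import FrameConfig
from .seqio import NanobodyRecord

__all__ = [
    "SplitPlan",
    "EvalReport",
    "levenshtein",
    "identity_fraction",
    "cluster_split",
    "roc_auc",
    "spearman_rho",
    "evaluate",
]


def levenshtein(a: str, b: str) -> int:
    """Minimal number of substitutions, insertions and deletions."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def identity_fraction(a: str, b: str) -> float:
    """Aligned matches over the longer length: 1 - d(a,b)/max(|a|,|b|)."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - levenshtein(a, b) / m


@dataclass
class SplitPlan:
    """A cluster-based train/test split with achieved dissimilarity stats."""

    cluster_id: dict[str, int]
    test_clusters: tuple[int, ...]
    train_ids: list[str]
    test_ids: list[str]
    min_edit: int
    max_identity: float
    n_removed: int
    achieved_min_distance: int | None = None
    achieved_max_identity: float | None = None
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": i, "cluster": self.cluster_id[i], "role": "train"} for i in self.train_ids
        ] + [{"id": i, "cluster": self.cluster_id[i], "role": "test"} for i in self.test_ids]
        return pd.DataFrame(rows)


def cluster_split(
    records: list[NanobodyRecord],
    n_clusters: int = 5,
    min_edit: int = 10,
    max_identity: float = 0.75,
    seed: int = 0,
    n_test_clusters: int = 1,
    frame_config: FrameConfig | None = None,
    compute_achieved: bool = True,
) -> SplitPlan:
    """K-means cluster the records and hold out whole clusters as the test set.

    Clustering runs on the aligned one-hot embedding (Euclidean k-means).
    The ``n_test_clusters`` smallest clusters are held out; a training
    record is then removed if its concatenated-CDR Levenshtein distance to
    any test record is <= ``min_edit`` *or* its identity fraction exceeds
    ``max_identity``.  Achieved post-filter statistics are recorded when
    ``compute_achieved`` (quadratic in the split size).
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    config = frame_config or FrameConfig()
    X = encode_onehot_matrix(records, config)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=4)
    labels = km.fit_predict(X)

    # hold out the cluster(s) whose size is closest to the balanced share,
    # so the test set is neither a singleton nor most of the data
    sizes = np.bincount(labels, minlength=n_clusters)
    target = len(records) / n_clusters
    test_clusters = tuple(
        int(c) for c in np.argsort(np.abs(sizes - target), kind="stable")[:n_test_clusters]
    )
    cluster_id = {rec.id: int(lab) for rec, lab in zip(records, labels)}

    test_recs = [r for r, lab in zip(records, labels) if lab in test_clusters]
    cand_train = [r for r, lab in zip(records, labels) if lab not in test_clusters]
    test_strs = [r.cdr_concat for r in test_recs]

    kept = []
    removed = 0
    for rec in cand_train:
        s = rec.cdr_concat
        ok = True
        for t in test_strs:
            m = max(len(s), len(t))
            # remove when d <= min_edit or identity > ceiling, i.e.
            # d < (1 - max_identity) * m
            bound = max(min_edit, int(np.ceil((1.0 - max_identity) * m)) - 1)
            d = edlib.align(s, t, task="distance", k=bound)["editDistance"]
            if d != -1:
                ok = False
                break
        if ok:
            kept.append(rec)
        else:
            removed += 1
    if not kept:
        raise ValueError(
            f"dissimilarity constraints removed all {len(cand_train)} training "
            f"records (min_edit={min_edit}, max_identity={max_identity})"
        )

    plan = SplitPlan(
        cluster_id=cluster_id,
        test_clusters=test_clusters,
        train_ids=[r.id for r in kept],
        test_ids=[r.id for r in test_recs],
        min_edit=min_edit,
        max_identity=max_identity,
        n_removed=removed,
        seed=seed,
    )
    if compute_achieved and kept and test_recs:
        dmin = None
        idmax = 0.0
        for rec in kept:
            s = rec.cdr_concat
            for t in test_strs:
                d = levenshtein(s, t)
                m = max(len(s), len(t))
                ident = 1.0 - d / m if m else 1.0
                if dmin is None or d < dmin:
                    dmin = d
                idmax = max(idmax, ident)
        plan.achieved_min_distance = dmin
        plan.achieved_max_identity = idmax
    return plan


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with average-rank tie handling.

    Probability that a random class-1 (low polyreactivity) item outscores a
    random class-0 item, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def spearman_rho(x, y) -> float:
    """Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


DESCRIPTOR_NAMES = ("isoelectric_point", "hydrophobicity", "cdr3_length", "n_arginine")


def _descriptor_scores(records: list[NanobodyRecord]) -> dict[str, np.ndarray]:
    """Descriptors oriented as polyreactivity scores (high = low predicted).

    Acidic pI, lower hydrophobicity, shorter CDR3 and fewer arginines are the
    literature hallmarks of low polyreactivity, so each descriptor is negated
    to match the models' orientation.
    """
    desc = [baseline_descriptors(r) for r in records]
    return {
        "isoelectric_point": -np.array([d.isoelectric_point for d in desc]),
        "hydrophobicity": -np.array([d.hydrophobicity for d in desc]),
        "cdr3_length": -np.array([d.cdr3_length for d in desc], dtype=float),
        "n_arginine": -np.array([d.n_arginine for d in desc], dtype=float),
    }


@dataclass
class EvalReport:
    auc: dict[str, float] = field(default_factory=dict)
    spearman: dict[str, float] = field(default_factory=dict)
    score_distributions: dict[str, dict[int, np.ndarray]] = field(default_factory=dict)
    n_test: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, auc in self.auc.items():
            rows.append({"scorer": name, "metric": "auc", "value": auc})
        for name, rho in self.spearman.items():
            rows.append({"scorer": name, "metric": "spearman", "value": rho})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Evaluation on {self.n_test} held-out records", "-" * 40]
        for name, auc in sorted(self.auc.items(), key=lambda kv: -kv[1]):
            lines.append(f"AUC  {name:<20s} {auc:.3f}")
        for name, rho in self.spearman.items():
            lines.append(f"rho  {name:<20s} {rho:.3f}")
        return "\n".join(lines)


def evaluate(
    models: dict[str, PolyreactivityResults],
    records: list[NanobodyRecord],
    split: SplitPlan | None = None,
    descriptors: bool = True,
    measured: dict[str, float] | None = None,
) -> EvalReport:
    """AUCs on the held-out set and Spearman against measured values.

    ``records`` must carry pool labels; with a ``split`` only its test ids
    are evaluated, otherwise all records are.  When ``measured`` is given,
    the Spearman rank correlation of every model's score against the
    measured polyreactivity values is added (over the ids present; omitted
    with a warning when more than half are missing).
    """
    by_id = {r.id: r for r in records}
    if split is not None:
        test_recs = [by_id[i] for i in split.test_ids]
    else:
        test_recs = list(records)
    test_recs = sorted(test_recs, key=lambda r: r.id)  # record-order invariant
    labels = np.array([1 if r.source_pool == "low" else 0 for r in test_recs])
    report = EvalReport(n_test=len(test_recs))

    scorers: dict[str, np.ndarray] = {}
    for kind, model in models.items():
        scorers[kind] = model.score(test_recs)
    if descriptors:
        scorers.update(_descriptor_scores(test_recs))
    if len(set(labels)) == 2:
        for name, vals in scorers.items():
            report.auc[name] = roc_auc(vals, labels)
            report.score_distributions[name] = {
                1: vals[labels == 1],
                0: vals[labels == 0],
            }

    if measured is not None:
        ids = [r.id for r in test_recs if r.id in measured]
        if len(ids) < max(3, 0.5 * len(test_recs)):
            warnings.warn("measured values missing for most records; Spearman omitted")
        else:
            recs = [by_id[i] for i in ids]
            mvals = np.array([measured[i] for i in ids])
            for kind, model in models.items():
                report.spearman[kind] = spearman_rho(model.score(recs), mvals)
    return report
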