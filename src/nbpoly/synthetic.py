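"""Synthetic sorted-pool and index-set generator.

Emulates the statistical structure of FACS-sorted yeast-display pools so the
whole pipeline is testable without the request-only NGS data: clones carry a
fixed CDR1 length of 8, CDR2 of 8 or 9 (9 or 10 in extended-CDR2 mode) with
moderate per-position diversity, and CDR3 of length 6-22 with extensive
diversity.  Each clone receives a latent "low-polyreactivity propensity"

    latent = b + sum_slots W(slot, residue) + sum_motifs M(motif) * count + N(0, sigma)

linear in exactly the features the logistic-regression models see (planted
per-slot weights ``W`` and motif weights ``M``), which makes
parameter-recovery tests sharp.  An optional pairwise-interaction term adds
position dependencies the linear models cannot capture.  Labels come from
thresholding the latent at its median (balanced pools) or from Bernoulli
draws on its logistic transform.  The index-set generator samples clones
stratified across the latent range and reports a noisy monotone transform of
the latent as the "measured" polyreactivity score (same orientation as the
models: high = low polyreactivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .numbering import FrameConfig, assign_frame
from .seqio import DEFAULT_FRAMEWORK, FrameworkTemplate, LabeledPool, NanobodyRecord, build_pools
from .util import AA_ALPHABET

__all__ = ["SyntheticConfig", "SyntheticPoolSet", "generate_pools", "generate_index_set", "latent_score"]


def _default_position_weights() -> dict:
    """Planted per-(IMGT slot, residue) effects, in latent units.

    Basic residues and bulky aromatics at exposed loop positions are
    penalized (polyreactive); acidic substitutions at the same positions are
    favoured — mirroring the charge/aromaticity determinants the field
    reports for nonspecific binding.  Effects sit on slots that are occupied
    at every legal CDR length (CDR1 tail, CDR2 anchor positions, the first
    and last three CDR3 slots), so a typical clone carries several planted
    contributions and the latent spans a wide range.
    """
    weights: dict[tuple[str, str], float] = {}
    for slot in ("35", "36"):  # CDR1 tail
        for res in "RK":
            weights[(slot, res)] = -2.0
        for res in "DE":
            weights[(slot, res)] = 2.0
    for slot in ("58", "64"):  # CDR2
        weights[(slot, "R")] = -2.0
        weights[(slot, "W")] = -2.0
        weights[(slot, "D")] = 2.0
    weights[("64", "P")] = 2.0
    for slot in ("105", "106", "107", "115", "116", "117"):  # CDR3 ends
        for res in "RK":
            weights[(slot, res)] = -2.0
        for res in "DE":
            weights[(slot, res)] = 2.0
        weights[(slot, "W")] = -2.0
    return weights


def _default_motif_weights() -> dict:
    """Planted motif effects: composition terms (1-mers) act anywhere in the
    CDRs — arginine, lysine and tryptophan content raise polyreactivity,
    acidic content lowers it — plus a few position-free 2-mer motifs."""
    return {
        "R": -1.0, "K": -0.8, "W": -0.8, "D": 1.0, "E": 0.8,
        "RR": -2.0, "WW": -1.5, "DE": 1.5,
    }


# Consensus residues for the moderately diverse CDR1/CDR2 loops (one
# dominant residue per position, the rest of the mass spread uniformly).
_CDR1_CONSENSUS = "GSIFSSNA"
_CDR2_CONSENSUS = "ITSGGSTNYA"  # long enough for extended CDR2


def _cdr3_background() -> np.ndarray:
    """Mildly skewed CDR3 composition typical of synthetic VHH libraries."""
    probs = {a: 1.0 for a in AA_ALPHABET}
    probs.update({"Y": 2.0, "S": 2.0, "G": 1.8, "R": 1.5, "D": 1.3, "A": 1.3, "C": 0.3, "M": 0.5})
    v = np.array([probs[a] for a in AA_ALPHABET])
    return v / v.sum()


@dataclass
class SyntheticConfig:
    """Study conditions for the simulated sorted pools."""

    n_per_class: int = 20000
    sigma: float = 0.5  # latent noise s.d.
    intercept: float = 0.0
    labeling: str = "threshold"  # or "bernoulli"
    cdr2_len_probs: dict = field(default_factory=lambda: {8: 0.5, 9: 0.5})
    cdr3_len_probs: dict | None = None  # default: triangular peak at 14 over 6..22
    cdr12_dominant_prob: float = 0.7
    position_weights: dict = field(default_factory=_default_position_weights)
    motif_weights: dict = field(default_factory=_default_motif_weights)
    interaction_weight: float = 0.0  # pairwise (slot 106 R, slot 109 W) synergy
    extended_cdr2: bool = False
    index_noise_sd: float = 0.25
    seed: int = 0
    framework: FrameworkTemplate = field(default_factory=lambda: DEFAULT_FRAMEWORK)

    def frame_config(self) -> FrameConfig:
        return FrameConfig(extended_cdr2=self.extended_cdr2)

    def resolved_cdr3_len_probs(self) -> dict:
        if self.cdr3_len_probs is not None:
            return self.cdr3_len_probs
        lengths = np.arange(6, 23)
        w = 1.0 + np.minimum(lengths - 6, 22 - lengths).astype(float)  # peak mid-range
        w /= w.sum()
        return dict(zip(lengths.tolist(), w.tolist()))

    def resolved_cdr2_len_probs(self) -> dict:
        if self.extended_cdr2 and set(self.cdr2_len_probs) == {8, 9}:
            return {9: self.cdr2_len_probs[8], 10: self.cdr2_len_probs[9]}
        return self.cdr2_len_probs


@dataclass
class SyntheticPoolSet:
    low: LabeledPool
    high: LabeledPool
    latents: dict[str, float]  # noise-free planted score per retained id
    config: SyntheticConfig

    def all_records(self) -> list[NanobodyRecord]:
        return self.low.record_list() + self.high.record_list()


def _slot_distributions(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Per-slot residue probabilities for CDR1/2; CDR3 shares one background."""
    frame = config.frame_config()
    dists = {}
    p_dom = config.cdr12_dominant_prob
    for slots, consensus in (
        (frame.cdr1_slots, _CDR1_CONSENSUS),
        (frame.cdr2_slots, _CDR2_CONSENSUS),
    ):
        # consensus indexed over occupied-when-full positions; harmless to
        # define a distribution for every slot
        for i, slot in enumerate(slots):
            v = np.full(20, (1.0 - p_dom) / 19)
            v[AA_ALPHABET.index(consensus[i % len(consensus)])] = p_dom
            dists[slot] = v
    bg3 = _cdr3_background()
    for slot in frame.cdr3_slots:
        dists[slot] = bg3
    return dists


def _count_motif(seq: str, motif: str) -> int:
    k = len(motif)
    return sum(1 for i in range(len(seq) - k + 1) if seq[i : i + k] == motif)


def latent_score(record: NanobodyRecord, config: SyntheticConfig) -> float:
    """Noise-free planted score of a record (the simulation's ground truth)."""
    frame = assign_frame(*record.cdr_triple, config.frame_config())
    s = config.intercept
    for (slot, res), w in config.position_weights.items():
        if frame.occupancy.get(slot) == res:
            s += w
    for motif, w in config.motif_weights.items():
        s += w * sum(_count_motif(cdr, motif) for cdr in record.cdr_triple)
    if config.interaction_weight:
        if frame.occupancy.get("106") == "R" and frame.occupancy.get("109") == "W":
            s += config.interaction_weight
    return s


def _sample_records(config: SyntheticConfig, n: int, rng, id_prefix: str) -> list[NanobodyRecord]:
    frame = config.frame_config()
    dists = _slot_distributions(config)
    cdr2_lens, cdr2_p = zip(*sorted(config.resolved_cdr2_len_probs().items()))
    cdr3_lens, cdr3_p = zip(*sorted(config.resolved_cdr3_len_probs().items()))
    len2 = rng.choice(cdr2_lens, size=n, p=np.asarray(cdr2_p) / np.sum(cdr2_p))
    len3 = rng.choice(cdr3_lens, size=n, p=np.asarray(cdr3_p) / np.sum(cdr3_p))

    # draw residues slot-wise (vectorized over records), then assemble only
    # the occupied slots of each record
    draws = {
        slot: rng.choice(list(AA_ALPHABET), size=n, p=dist) for slot, dist in dists.items()
    }
    from .numbering import _middle_out, _occupied_cdr3  # deterministic slot choice

    records = []
    aa = AA_ALPHABET
    for i in range(n):
        c1 = "".join(draws[s][i] for s in _middle_out(frame.cdr1_slots, frame.cdr1_len))
        c2 = "".join(draws[s][i] for s in _middle_out(frame.cdr2_slots, int(len2[i])))
        c3 = "".join(draws[s][i] for s in _occupied_cdr3(frame, int(len3[i])))
        records.append(
            NanobodyRecord(
                id=f"{id_prefix}{i:06d}",
                aa_seq=config.framework.assemble(c1, c2, c3),
                cdr1=c1,
                cdr2=c2,
                cdr3=c3,
            )
        )
    return records


def generate_pools(config: SyntheticConfig) -> SyntheticPoolSet:
    """Simulate the two sorted pools under the planted latent model.

    Deterministic for a fixed config seed.  All emitted records pass the
    library filters; pool sizes are close to (not exactly) ``n_per_class``
    after CDR-level deduplication.
    """
    if config.n_per_class < 1:
        raise ValueError("n_per_class must be positive")
    if abs(sum(config.resolved_cdr3_len_probs().values()) - 1.0) > 1e-6:
        raise ValueError("CDR3 length probabilities must sum to 1")
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_class
    records = _sample_records(config, n, rng, "syn")
    latents = np.array([latent_score(r, config) for r in records])
    noisy = latents + rng.normal(0.0, config.sigma, size=n)
    if config.labeling == "threshold":
        labels = noisy > np.median(noisy)
    elif config.labeling == "bernoulli":
        centred = noisy - np.median(noisy)
        labels = rng.random(n) < 1.0 / (1.0 + np.exp(-centred))
    else:
        raise ValueError(f"unknown labeling mode {config.labeling!r}")
    for rec, lab in zip(records, labels):
        rec.source_pool = "low" if lab else "high"
    low, high, _report = build_pools(records, config=config.frame_config())
    latent_map = dict(zip((r.id for r in records), latents.tolist()))
    retained = {r.id for r in low} | {r.id for r in high}
    latent_map = {k: v for k, v in latent_map.items() if k in retained}
    return SyntheticPoolSet(low=low, high=high, latents=latent_map, config=config)


def generate_index_set(
    config: SyntheticConfig, n: int = 48
) -> tuple[list[NanobodyRecord], dict[str, float]]:
    """An index-set analogue: clones spanning the polyreactivity range.

    Draws a large candidate sample, stratifies it into latent quartiles and
    samples ``n/4`` clones per quartile, so every latent quartile holds at
    least ``floor(n/8)`` records.  The "measured" value is the latent plus
    Gaussian measurement noise (``index_noise_sd``), i.e. an idealized
    per-clone binding measurement on the model score scale.
    """
    if n < 3:
        raise ValueError("index set needs n >= 3")
    rng = np.random.default_rng(config.seed + 1_000_003)
    candidates = _sample_records(config, max(40 * n, 400), rng, "idx")
    latents = np.array([latent_score(r, config) for r in candidates])
    # rank-based stratification: robust to atoms in the discrete latent
    order = np.argsort(latents, kind="stable")
    quarters = np.array_split(order, 4)
    chosen: list[int] = []
    per_bin = [n // 4] * 4
    for i in range(n - sum(per_bin)):
        per_bin[i % 4] += 1
    for b, idx in enumerate(quarters):
        take = min(per_bin[b], len(idx))
        chosen.extend(rng.choice(idx, size=take, replace=False).tolist())
    records = [candidates[i] for i in chosen]
    measured = {
        candidates[i].id: float(latents[i] + rng.normal(0.0, config.index_noise_sd))
        for i in chosen
    }
    return records, measured


def index_set_frame(records: list[NanobodyRecord], measured: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "aa_seq": [r.aa_seq for r in records],
            "cdr1": [r.cdr1 for r in records],
            "cdr2": [r.cdr2 for r in records],
            "cdr3": [r.cdr3 for r in records],
            "measured": [measured[r.id] for r in records],
        }
    )
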