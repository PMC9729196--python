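"""Sequence encoders and biochemical descriptors.

Two encoders feed the supervised models: an aligned one-hot embedding over
the fixed CDR slot grid (position-aware; gaps encode as all-zero so logistic
weights stay per-amino-acid interpretable) and a position-free k-mer count
embedding (motifs of length 1-3 counted within each CDR, never across CDR
boundaries).  Four classical biochemical descriptors — isoelectric point,
mean hydrophobicity, CDR3 length, and CDR arginine count — serve as
literature baselines for polyreactivity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .numbering import CDRFrame, FrameConfig, assign_frame
from .seqio import NanobodyRecord
from .util import AA_ALPHABET, AA_INDEX

__all__ = [
    "DescriptorSet",
    "one_hot_encode",
    "kmer_encode",
    "kmer_vocabulary",
    "isoelectric_point",
    "net_charge",
    "hydrophobicity_index",
    "baseline_descriptors",
    "PKA_SETS",
    "HYDROPHOBICITY_SCALES",
]


# ---------------------------------------------------------------------------
# encodings
# ---------------------------------------------------------------------------


def one_hot_encode(frame: CDRFrame) -> np.ndarray:
    """Aligned one-hot vector of length ``n_slots * 20``.

    Slot order follows the frame config's display order; residue order is
    the fixed alphabet ``ACDEFGHIKLMNPQRSTVWY``.  Gap slots are all-zero, so
    the vector sums to the total CDR length.
    """
    slots = frame.config.slot_order
    vec = np.zeros(len(slots) * 20)
    for i, slot in enumerate(slots):
        res = frame.occupancy.get(slot)
        if res is None:
            continue
        if res not in AA_INDEX:
            raise ValueError(f"non-standard residue {res!r} at slot {slot}")
        vec[i * 20 + AA_INDEX[res]] = 1.0
    return vec


@lru_cache(maxsize=4)
def kmer_vocabulary(k_max: int = 3) -> tuple[tuple[str, ...], dict]:
    """All motifs of length 1..k_max in (length, lexicographic) order."""
    vocab = []
    for k in range(1, k_max + 1):
        vocab.extend("".join(p) for p in itertools.product(AA_ALPHABET, repeat=k))
    index = {m: i for i, m in enumerate(vocab)}
    return tuple(vocab), index


def kmer_encode(cdr1: str, cdr2: str, cdr3: str, k_max: int = 3) -> dict[str, int]:
    """Count k-mers (k = 1..k_max) within each CDR, summed across CDRs.

    Windows never span a CDR boundary; an empty CDR contributes nothing.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    counts: dict[str, int] = {}
    for cdr in (cdr1, cdr2, cdr3):
        for c in cdr:
            if c not in AA_INDEX:
                raise ValueError(f"non-standard residue {c!r}")
        for k in range(1, k_max + 1):
            for i in range(len(cdr) - k + 1):
                motif = cdr[i : i + k]
                counts[motif] = counts.get(motif, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# biochemical descriptors
# ---------------------------------------------------------------------------

# pKa tables: N-terminus, C-terminus and the seven ionizable side chains.
PKA_SETS = {
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    },
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "C": 9.0, "D": 4.05, "E": 4.45, "H": 5.98, "K": 10.0, "R": 12.0, "Y": 10.0,
    },
    "sillero": {
        "Nterm": 8.2, "Cterm": 3.2,
        "C": 9.0, "D": 4.0, "E": 4.5, "H": 6.4, "K": 10.4, "R": 12.0, "Y": 10.0,
    },
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")

HYDROPHOBICITY_SCALES = {
    # Kyte-Doolittle
    "kd": {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
        "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
        "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
        "Y": -1.3, "V": 4.2,
    },
    # Eisenberg consensus
    "eisenberg": {
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29, "Q": -0.85,
        "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38, "L": 1.06, "K": -1.50,
        "M": 0.64, "F": 1.19, "P": 0.12, "S": -0.18, "T": -0.05, "W": 0.81,
        "Y": 0.26, "V": 1.08,
    },
}


def net_charge(aa_seq: str, pH: float, pka_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge at ``pH`` (monotone non-increasing)."""
    pka = PKA_SETS[pka_set]
    charge = 1.0 / (1.0 + 10 ** (pH - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - pH))
    for res in _POSITIVE:
        n = aa_seq.count(res)
        if n:
            charge += n / (1.0 + 10 ** (pH - pka[res]))
    for res in _NEGATIVE:
        n = aa_seq.count(res)
        if n:
            charge -= n / (1.0 + 10 ** (pka[res] - pH))
    return charge


def isoelectric_point(aa_seq: str, pka_set: str = "emboss", tol: float = 1e-4) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero.

    Found by bisection on [0, 14]; the charge function is monotone so the
    root exists and is unique.
    """
    if not aa_seq:
        raise ValueError("empty sequence")
    for c in aa_seq:
        if c not in AA_INDEX:
            raise ValueError(f"non-standard residue {c!r}")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(aa_seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobicity_index(aa_seq: str, scale: str = "kd") -> float:
    """Arithmetic mean of per-residue hydrophobicity scale values."""
    if not aa_seq:
        raise ValueError("empty sequence")
    table = HYDROPHOBICITY_SCALES[scale]
    try:
        return sum(table[c] for c in aa_seq) / len(aa_seq)
    except KeyError as exc:
        raise ValueError(f"residue {exc} missing from scale {scale!r}") from exc


@dataclass
class DescriptorSet:
    isoelectric_point: float
    hydrophobicity: float
    cdr3_length: int
    n_arginine: int


def baseline_descriptors(
    record: NanobodyRecord,
    region: str = "cdrs_only",
    pka_set: str = "emboss",
    scale: str = "kd",
) -> DescriptorSet:
    """The four baseline descriptors for one record.

    ``region`` selects whether pI and hydrophobicity are computed on the
    full sequence or on the concatenated CDRs (the framework is constant in
    the library, so CDRs-only is the default).  The arginine count is always
    over CDR residues.
    """
    if region == "full_seq":
        seq = record.aa_seq
    elif region == "cdrs_only":
        seq = record.cdr_concat
    else:
        raise ValueError(f"unknown region {region!r}")
    return DescriptorSet(
        isoelectric_point=isoelectric_point(seq, pka_set),
        hydrophobicity=hydrophobicity_index(seq, scale),
        cdr3_length=len(record.cdr3),
        n_arginine=record.cdr_concat.count("R"),
    )
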