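"""Deterministic IMGT-style CDR slot assignment for fixed-framework nanobodies.

The synthetic yeast-display library diversifies three CDR loops on a constant
framework, so variable-length CDRs can be aligned to a fixed grid of IMGT-like
slots without profile-HMM numbering:

* CDR1 occupies slots 27-38 (12 slots; library CDR1 length is fixed at 8),
* CDR2 occupies slots 56-65 (10 slots), optionally extended by one slot
  ("65.1") when the extra variable position at the end of CDR2 is modelled,
* CDR3 occupies slots 105-117 (13 canonical slots) plus insertion slots
  111.x/112.x for loops longer than 13 (up to a configurable maximum, 22).

Within a CDR, residues are placed "middle-out": the first ``ceil(L/2)``
residues fill the lowest-numbered slots, the last ``floor(L/2)`` residues the
highest, and central slots are left as gaps.  CDR3 loops longer than 13 fill
all canonical slots and put the remaining residues on insertion slots in the
fixed order 112.1, 111.1, 112.2, 111.2, ...  Insertion slots are displayed in
the IMGT convention: ascending after 111 (111.1, 111.2, ...) then descending
into 112 (..., 112.2, 112.1).

The module also implements the dual mutation nomenclature used throughout the
package, e.g. ``G26D^27``: wild-type residue, 1-based position in the full
amino-acid sequence, new residue, and the IMGT slot as a superscript.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache

from .util import AA_ALPHABET

__all__ = [
    "FrameConfig",
    "CDRFrame",
    "MutationLabel",
    "assign_frame",
    "frame_to_cdrs",
    "mutation_codec",
    "format_mutation",
]


@dataclass(frozen=True)
class FrameConfig:
    """Layout of the fixed CDR slot grid.

    Parameters
    ----------
    cdr2_start
        First IMGT label of the CDR2 window.  Strict IMGT puts CDR2 at 56-65;
        some analyses include position 55, hence configurable.
    extended_cdr2
        Model one extra variable position at the end of CDR2 (one extension
        slot appended after the last canonical CDR2 slot).  Shifts the allowed
        CDR2 lengths from {8, 9} to {9, 10}.
    max_cdr3
        Largest CDR3 loop representable (number of CDR3 slots).
    min_cdr3
        Shortest CDR3 accepted by the library filters.
    """

    cdr2_start: int = 56
    extended_cdr2: bool = False
    max_cdr3: int = 22
    min_cdr3: int = 6
    cdr1_len: int = 8

    # ---- slot layout -------------------------------------------------
    @property
    def cdr1_slots(self) -> tuple[str, ...]:
        return tuple(str(i) for i in range(27, 39))

    @property
    def cdr2_slots(self) -> tuple[str, ...]:
        end = self.cdr2_start + 9
        labels = [str(i) for i in range(self.cdr2_start, end + 1)]
        if self.extended_cdr2:
            labels.append(f"{end}.1")
        return tuple(labels)

    @property
    def cdr2_lens(self) -> tuple[int, ...]:
        return (9, 10) if self.extended_cdr2 else (8, 9)

    @property
    def cdr3_slots(self) -> tuple[str, ...]:
        """CDR3 slots in display (canonical reading) order."""
        n_ins = max(0, self.max_cdr3 - 13)
        fill = self.cdr3_fill_order
        ins111 = sorted(
            (s for s in fill if s.startswith("111.")),
            key=lambda s: int(s.split(".")[1]),
        )
        ins112 = sorted(
            (s for s in fill if s.startswith("112.")),
            key=lambda s: -int(s.split(".")[1]),
        )
        assert len(ins111) + len(ins112) == n_ins
        return tuple(
            [str(i) for i in range(105, 112)]
            + ins111
            + ins112
            + [str(i) for i in range(112, 118)]
        )

    @property
    def cdr3_fill_order(self) -> tuple[str, ...]:
        """Insertion slots in the order they are occupied as CDR3 grows."""
        n_ins = max(0, self.max_cdr3 - 13)
        fill: list[str] = []
        i = 1
        while len(fill) < n_ins:
            fill.append(f"112.{i}")
            if len(fill) < n_ins:
                fill.append(f"111.{i}")
            i += 1
        return tuple(fill)

    @property
    def slot_order(self) -> tuple[str, ...]:
        """All slots of the frame in display order (CDR1, CDR2, CDR3)."""
        return self.cdr1_slots + self.cdr2_slots + self.cdr3_slots

    @property
    def n_slots(self) -> int:
        return len(self.slot_order)

    def region_slots(self, region: int) -> tuple[str, ...]:
        return (self.cdr1_slots, self.cdr2_slots, self.cdr3_slots)[region]

    def cdr_length_ok(self, region: int, length: int) -> bool:
        if region == 0:
            return length == self.cdr1_len
        if region == 1:
            return length in self.cdr2_lens
        return self.min_cdr3 <= length <= self.max_cdr3

    def config_hash(self) -> str:
        import hashlib

        key = f"{self.cdr2_start}|{self.extended_cdr2}|{self.max_cdr3}|{self.min_cdr3}|{self.cdr1_len}"
        return hashlib.md5(key.encode()).hexdigest()[:12]


@dataclass
class CDRFrame:
    """One nanobody's CDRs laid onto the fixed slot grid.

    ``occupancy`` maps slot label -> residue for occupied slots only; all
    other slots of the config are gaps.
    """

    config: FrameConfig
    occupancy: dict[str, str]

    def residue(self, slot: str) -> str:
        """Residue at ``slot``, or ``"-"`` for a gap."""
        return self.occupancy.get(slot, "-")

    def region_string(self, region: int) -> str:
        return "".join(
            self.occupancy[s]
            for s in self.config.region_slots(region)
            if s in self.occupancy
        )

    def occupied_slots(self, region: int) -> list[str]:
        """Occupied slot labels of a region, in display order."""
        return [s for s in self.config.region_slots(region) if s in self.occupancy]

    def to_tsv(self) -> str:
        lines = ["slot\tresidue"]
        for s in self.config.slot_order:
            lines.append(f"{s}\t{self.residue(s)}")
        return "\n".join(lines) + "\n"


def _middle_out(slots: tuple[str, ...], length: int) -> list[str]:
    """Slots occupied by a CDR of ``length`` residues: low end first."""
    head = math.ceil(length / 2)
    tail = length - head
    chosen = list(slots[:head])
    if tail:
        chosen += list(slots[len(slots) - tail :])
    return chosen


def _occupied_cdr3(config: FrameConfig, length: int) -> list[str]:
    canonical = tuple(str(i) for i in range(105, 118))
    if length <= 13:
        return _middle_out(canonical, length)
    occupied = set(canonical) | set(config.cdr3_fill_order[: length - 13])
    return [s for s in config.cdr3_slots if s in occupied]


def assign_frame(cdr1: str, cdr2: str, cdr3: str, config: FrameConfig | None = None) -> CDRFrame:
    """Place the three CDR strings onto the fixed slot grid.

    Raises ``ValueError`` naming the CDR when a loop exceeds its slot
    capacity.  Lengths below the library filters are representable (the
    frame just has more gaps); callers enforce filters separately.
    """
    config = config or FrameConfig()
    occupancy: dict[str, str] = {}
    for region, seq in enumerate((cdr1, cdr2, cdr3)):
        slots = config.region_slots(region)
        if len(seq) > len(slots):
            raise ValueError(
                f"CDR{region + 1} length {len(seq)} exceeds frame capacity {len(slots)}"
            )
        if region == 2:
            chosen = _occupied_cdr3(config, len(seq))
        else:
            chosen = _middle_out(slots, len(seq))
        for slot, res in zip(chosen, seq):
            occupancy[slot] = res
    return CDRFrame(config=config, occupancy=occupancy)


def frame_to_cdrs(frame: CDRFrame) -> tuple[str, str, str]:
    """Exact inverse of :func:`assign_frame` for all legal lengths."""
    return (
        frame.region_string(0),
        frame.region_string(1),
        frame.region_string(2),
    )


# ---------------------------------------------------------------------------
# dual mutation nomenclature
# ---------------------------------------------------------------------------

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])\^(\S+)$")
_DEL_RE = re.compile(r"^([A-Z])(\d+)del\^(\S+)$")
_INS_RE = re.compile(r"^ins(\d+)([A-Z])\^(\S+)$")


@dataclass(frozen=True)
class MutationLabel:
    """One edit in dual nomenclature (sequential position + IMGT slot).

    ``seq_pos`` is the 1-based index into the full amino-acid sequence; for
    insertions it is the position the new residue occupies counted in the
    parent frame (the residue is inserted *before* that position).
    """

    seq_pos: int
    imgt_pos: str
    wt_res: str
    new_res: str
    edit_kind: str  # "sub" | "ins" | "del"

    def __post_init__(self):
        if self.edit_kind == "sub":
            if not (self.wt_res and self.new_res):
                raise ValueError("substitution needs wt and new residues")
        elif self.edit_kind == "del":
            if self.new_res:
                raise ValueError("deletion carries no new residue")
        elif self.edit_kind == "ins":
            if self.wt_res:
                raise ValueError("insertion carries no wild-type residue")
        else:
            raise ValueError(f"unknown edit kind {self.edit_kind!r}")


def format_mutation(label: MutationLabel) -> str:
    if label.edit_kind == "sub":
        return f"{label.wt_res}{label.seq_pos}{label.new_res}^{label.imgt_pos}"
    if label.edit_kind == "del":
        return f"{label.wt_res}{label.seq_pos}del^{label.imgt_pos}"
    return f"ins{label.seq_pos}{label.new_res}^{label.imgt_pos}"


def mutation_codec(label_text: str, aa_seq: str, frame: CDRFrame) -> MutationLabel:
    """Parse a dual-nomenclature label and validate it against ``aa_seq``.

    The wild-type residue must match ``aa_seq`` at the stated position and
    the IMGT slot must exist in the frame's configuration.
    """
    m = _DEL_RE.match(label_text)
    if m:
        wt, pos, imgt = m.group(1), int(m.group(2)), m.group(3)
        label = MutationLabel(pos, imgt, wt, "", "del")
    else:
        m = _INS_RE.match(label_text)
        if m:
            pos, new, imgt = int(m.group(1)), m.group(2), m.group(3)
            label = MutationLabel(pos, imgt, "", new, "ins")
        else:
            m = _SUB_RE.match(label_text)
            if not m:
                raise ValueError(f"unparseable mutation label {label_text!r}")
            wt, pos, new, imgt = m.group(1), int(m.group(2)), m.group(3), m.group(4)
            label = MutationLabel(pos, imgt, wt, new, "sub")

    if label.imgt_pos not in frame.config.slot_order:
        raise ValueError(f"unknown IMGT slot {label.imgt_pos!r} in {label_text!r}")
    if label.edit_kind in ("sub", "del"):
        if not 1 <= label.seq_pos <= len(aa_seq):
            raise ValueError(f"position {label.seq_pos} outside sequence of length {len(aa_seq)}")
        actual = aa_seq[label.seq_pos - 1]
        if actual != label.wt_res:
            raise ValueError(
                f"label {label_text!r}: wild-type {label.wt_res} does not match "
                f"residue {actual} at position {label.seq_pos}"
            )
    if label.new_res and label.new_res not in AA_ALPHABET:
        raise ValueError(f"non-standard residue {label.new_res!r}")
    return label
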