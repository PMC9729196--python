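"""In silico mutational scanning and rescue-mutation design.

Every single and double edit (substitutions, insertions, deletions) of a
clone's CDRs that keeps the loops within library length bounds is
enumerated, scored with the trained models (higher score = lower predicted
polyreactivity), and ranked.  A rescue panel is then drawn from the ranking
with the selection rules used for experimental follow-up: the three
top-scoring single mutations per CDR (diversified across positions and
residue classes), the top double mutant within each CDR, and the top double
mutant for each CDR pair that contributes at least one novel constituent
single — never introducing a cysteine, and breaking near-ties on the
one-hot score in favour of the higher k-mer score.

Edits are expressed internally as ``(kind, cdr_index, position, residue)``
in parent CDR coordinates and externally as dual-nomenclature
:class:`~nbpoly.numbering.MutationLabel` objects.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .numbering import CDRFrame, FrameConfig, MutationLabel, assign_frame, format_mutation
from .seqio import DEFAULT_FRAMEWORK, FrameworkTemplate, NanobodyRecord
from .util import AA_ALPHABET, RESIDUE_CLASS

__all__ = [
    "Edit",
    "VariantProposal",
    "RescuePanel",
    "enumerate_singles",
    "enumerate_doubles",
    "rank_variants",
    "select_rescue_panel",
    "apply_mutations",
]


@dataclass(frozen=True)
class Edit:
    """One edit in parent-CDR coordinates.

    ``pos`` is 0-based within the CDR; for insertions the residue is placed
    *before* ``pos`` (``pos`` may equal the CDR length).
    """

    kind: str  # "sub" | "del" | "ins"
    cdr: int  # 0, 1, 2
    pos: int
    res: str = ""

    def sort_key(self):
        return (self.cdr, self.pos, {"sub": 0, "del": 1, "ins": 2}[self.kind], self.res)


@dataclass
class VariantProposal:
    parent_id: str
    edits: tuple[Edit, ...]
    labels: tuple[MutationLabel, ...]
    cdr1: str
    cdr2: str
    cdr3: str
    scores: dict[str, float] = field(default_factory=dict)
    ranks: dict[str, int] = field(default_factory=dict)

    @property
    def edit_text(self) -> str:
        if not self.labels:
            return "parent"
        return "+".join(format_mutation(lab) for lab in self.labels)

    @property
    def cdr_triple(self):
        return (self.cdr1, self.cdr2, self.cdr3)


def _apply_edits_to_cdrs(triple: tuple[str, str, str], edits: tuple[Edit, ...]):
    """Apply edits (parent coordinates, descending position within a CDR)."""
    cdrs = list(triple)
    for e in sorted(edits, key=lambda e: (e.cdr, -e.pos)):
        s = cdrs[e.cdr]
        if e.kind == "sub":
            cdrs[e.cdr] = s[: e.pos] + e.res + s[e.pos + 1 :]
        elif e.kind == "del":
            cdrs[e.cdr] = s[: e.pos] + s[e.pos + 1 :]
        else:
            cdrs[e.cdr] = s[: e.pos] + e.res + s[e.pos :]
    return tuple(cdrs)


def _edit_labels(
    record: NanobodyRecord,
    edits: tuple[Edit, ...],
    mutant_triple: tuple[str, str, str],
    config: FrameConfig,
    template: FrameworkTemplate,
) -> tuple[MutationLabel, ...]:
    """Dual-nomenclature labels: sequential position plus IMGT slot."""
    parent_frame = assign_frame(*record.cdr_triple, config)
    labels = []
    for e in edits:
        offset = record.aa_seq.find(record.cdr_triple[e.cdr]) if record.aa_seq else -1
        if offset < 0:  # fall back to template layout
            offset = template.cdr_offset(e.cdr, *record.cdr_triple)
        seq_pos = offset + e.pos + 1  # 1-based
        if e.kind in ("sub", "del"):
            imgt = parent_frame.occupied_slots(e.cdr)[e.pos]
            wt = record.cdr_triple[e.cdr][e.pos]
            labels.append(
                MutationLabel(seq_pos, imgt, wt, e.res if e.kind == "sub" else "", e.kind)
            )
        else:
            # slot of the inserted residue in the mutant's own frame: apply
            # only this edit so the slot is independent of sibling edits
            solo = _apply_edits_to_cdrs(record.cdr_triple, (e,))
            mutant_frame = assign_frame(*solo, config)
            imgt = mutant_frame.occupied_slots(e.cdr)[e.pos]
            labels.append(MutationLabel(seq_pos, imgt, "", e.res, "ins"))
    return tuple(labels)


def apply_mutations(aa_seq: str, labels: tuple[MutationLabel, ...]) -> str:
    """Apply dual-nomenclature labels to a full sequence (parent coords)."""
    seq = aa_seq
    for lab in sorted(labels, key=lambda l: -l.seq_pos):
        i = lab.seq_pos - 1
        if lab.edit_kind == "sub":
            if seq[i] != lab.wt_res:
                raise ValueError(f"wild-type mismatch at {lab.seq_pos}")
            seq = seq[:i] + lab.new_res + seq[i + 1 :]
        elif lab.edit_kind == "del":
            seq = seq[:i] + seq[i + 1 :]
        else:
            seq = seq[:i] + lab.new_res + seq[i:]
    return seq


def _cdr_bounds(config: FrameConfig, region: int) -> tuple[int, int]:
    if region == 0:
        return config.cdr1_len, config.cdr1_len
    if region == 1:
        return min(config.cdr2_lens), max(config.cdr2_lens)
    return config.min_cdr3, config.max_cdr3


def _raw_single_edits(record: NanobodyRecord, edit_kinds, config: FrameConfig):
    """All candidate single edits before result-level deduplication."""
    edits = []
    for region, cdr in enumerate(record.cdr_triple):
        lo, hi = _cdr_bounds(config, region)
        L = len(cdr)
        if "sub" in edit_kinds:
            for pos in range(L):
                for res in AA_ALPHABET:
                    if res != cdr[pos]:
                        edits.append(Edit("sub", region, pos, res))
        if "del" in edit_kinds and L - 1 >= lo:
            for pos in range(L):
                edits.append(Edit("del", region, pos))
        if "ins" in edit_kinds and L + 1 <= hi:
            for pos in range(L + 1):
                for res in AA_ALPHABET:
                    edits.append(Edit("ins", region, pos, res))
    return edits


def _make_variant(record, edits, config, template) -> VariantProposal:
    triple = _apply_edits_to_cdrs(record.cdr_triple, edits)
    labels = _edit_labels(record, edits, triple, config, template)
    return VariantProposal(record.id, tuple(edits), labels, *triple)


def enumerate_singles(
    record: NanobodyRecord,
    edit_kinds: frozenset = frozenset({"sub", "ins", "del"}),
    config: FrameConfig | None = None,
    template: FrameworkTemplate = DEFAULT_FRAMEWORK,
) -> list[VariantProposal]:
    """All single-edit variants whose CDRs stay within library bounds.

    Substitutions contribute 19 per CDR position; deletions and insertions
    are included only where the CDR length stays within bounds.  Variants
    yielding identical CDR triples (e.g. inserting a residue on either side
    of an identical one) are deduplicated, keeping the first in canonical
    edit order.
    """
    config = config or FrameConfig()
    seen = {record.cdr_triple}  # exclude identity results
    out = []
    for e in sorted(_raw_single_edits(record, edit_kinds, config), key=Edit.sort_key):
        triple = _apply_edits_to_cdrs(record.cdr_triple, (e,))
        if triple in seen:
            continue
        seen.add(triple)
        out.append(_make_variant(record, (e,), config, template))
    return out


def enumerate_doubles(
    record: NanobodyRecord,
    edit_kinds: frozenset = frozenset({"sub", "ins", "del"}),
    config: FrameConfig | None = None,
    template: FrameworkTemplate = DEFAULT_FRAMEWORK,
    max_variants: int = 5_000_000,
):
    """Stream all unordered pairs of compatible single edits.

    Compatible means the two edits target distinct (CDR, position) sites —
    so application in parent coordinates is unambiguous — and the combined
    CDR lengths stay within bounds.  Pairs reproducing the parent or a
    triple already emitted are skipped.  Raises ``OverflowError`` beyond
    ``max_variants`` rather than truncating silently.
    """
    config = config or FrameConfig()
    raw = sorted(_raw_single_edits(record, edit_kinds, config), key=Edit.sort_key)
    seen = {record.cdr_triple}
    n = 0
    delta = {"sub": 0, "del": -1, "ins": 1}
    for a, b in itertools.combinations(raw, 2):
        if a.cdr == b.cdr and a.pos == b.pos:
            continue
        # combined length change per CDR must stay within bounds
        ok = True
        for region in {a.cdr, b.cdr}:
            lo, hi = _cdr_bounds(config, region)
            L = len(record.cdr_triple[region])
            L += sum(delta[e.kind] for e in (a, b) if e.cdr == region)
            if not lo <= L <= hi:
                ok = False
                break
        if not ok:
            continue
        triple = _apply_edits_to_cdrs(record.cdr_triple, (a, b))
        if triple in seen:
            continue
        seen.add(triple)
        n += 1
        if n > max_variants:
            raise OverflowError(f"double-mutant scan exceeds {max_variants} variants")
        yield _make_variant(record, (a, b), config, template)


def rank_variants(
    suite: dict[str, "PolyreactivityResults"],
    variants,
    parent: NanobodyRecord,
    template: FrameworkTemplate = DEFAULT_FRAMEWORK,
    batch_size: int = 4096,
) -> pd.DataFrame:
    """Score and rank variants with every model in the suite.

    Returns one row per variant (the parent is included as the zero-edit
    reference) with ``score_<kind>`` and ``rank_<kind>`` columns.  Rank 1 is
    the best (highest) score; ties break lexicographically on the edit
    label.  Variants failing a model's input contract are recorded in the
    ``error`` column and excluded from that model's ranking.
    """
    if not suite:
        raise ValueError("model suite is empty")
    config = next(iter(suite.values())).frame_config
    parent_variant = VariantProposal(parent.id, (), (), *parent.cdr_triple)
    all_variants = [parent_variant] + list(variants)

    rows = []
    for v in all_variants:
        rows.append(
            {
                "variant": v.edit_text,
                "cdr1": v.cdr1,
                "cdr2": v.cdr2,
                "cdr3": v.cdr3,
                "n_edits": len(v.edits),
                "error": "",
                "_obj": v,
            }
        )
    df = pd.DataFrame(rows)

    records = [
        NanobodyRecord(id=r["variant"], aa_seq="", cdr1=r["cdr1"], cdr2=r["cdr2"], cdr3=r["cdr3"])
        for r in rows
    ]
    any_model = next(iter(suite.values()))
    bad = {}
    for i, rec in enumerate(records):
        reason = any_model.check_record(rec)
        if reason is not None:
            bad[i] = reason
    if bad:
        df.loc[list(bad), "error"] = [bad[i] for i in bad]
    good_idx = [i for i in range(len(records)) if i not in bad]
    good_records = [records[i] for i in good_idx]

    for kind, model in suite.items():
        scores = np.full(len(records), np.nan)
        for start in range(0, len(good_records), batch_size):
            chunk = good_records[start : start + batch_size]
            scores[np.array(good_idx[start : start + batch_size])] = model.score(chunk)
        df[f"score_{kind}"] = scores
        order = df.loc[good_idx].sort_values(
            [f"score_{kind}", "variant"], ascending=[False, True]
        ).index
        ranks = pd.Series(np.nan, index=df.index)
        ranks.loc[order] = np.arange(1, len(order) + 1)
        df[f"rank_{kind}"] = ranks
        for i in good_idx:
            df.at[i, "_obj"].scores[kind] = float(scores[i])
            df.at[i, "_obj"].ranks[kind] = int(ranks.loc[i])
    return df


@dataclass
class RescuePanel:
    selections: list[tuple[pd.Series, tuple[str, ...]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for row, tags in self.selections:
            d = {k: v for k, v in row.items() if k != "_obj"}
            d["tags"] = ",".join(tags)
            rows.append(d)
        return pd.DataFrame(rows)

    @property
    def variant_names(self) -> list[str]:
        return [row["variant"] for row, _ in self.selections]


def _introduces_cysteine(variant: VariantProposal) -> bool:
    return any(lab.new_res == "C" for lab in variant.labels)


def _edit_cdrs(variant: VariantProposal) -> set[int]:
    return {e.cdr for e in variant.edits}


def _pick_with_tiebreak(cands: pd.DataFrame, epsilon: float):
    """Best candidate by one-hot score, preferring higher k-mer within epsilon.

    Returns (row, used_kmer_tiebreak).
    """
    if cands.empty:
        return None, False
    cands = cands.sort_values(["score_onehot_lr", "variant"], ascending=[False, True])
    best = cands.iloc[0]
    near = cands[cands["score_onehot_lr"] >= best["score_onehot_lr"] - epsilon]
    if len(near) > 1 and "score_kmer_lr" in near:
        alt = near.sort_values(["score_kmer_lr", "variant"], ascending=[False, True]).iloc[0]
        if alt["variant"] != best["variant"]:
            return alt, True
    return best, False


def select_rescue_panel(ranked: pd.DataFrame, epsilon: float = 0.1) -> RescuePanel:
    """Draw the rescue panel from a ranking that includes both LR models.

    Rules: per CDR, the three top-scoring single mutations, diversified so
    no two picks share both position and residue class; the top-scoring
    double within each CDR; for each CDR pair, the top-scoring spanning
    double with at least one constituent single not already selected.
    Cysteine-introducing edits are excluded before selection.  Candidates
    whose one-hot scores differ by at most ``epsilon`` are tie-broken on the
    k-mer score (tagged ``kmer_tiebreak``).
    """
    for col in ("score_onehot_lr", "score_kmer_lr"):
        if col not in ranked.columns:
            raise ValueError(f"ranking lacks {col}; panel selection needs both LR models")
    pool = ranked[(ranked["n_edits"] > 0) & (ranked["error"] == "")].copy()
    pool = pool[~pool["_obj"].map(_introduces_cysteine).astype(bool)]

    selections: list[tuple[pd.Series, tuple[str, ...]]] = []
    selected_single_labels: set[str] = set()

    # --- top-3 singles per CDR ---------------------------------------
    singles = pool[pool["n_edits"] == 1]
    for region in (0, 1, 2):
        cands = singles[singles["_obj"].map(lambda v, r=region: _edit_cdrs(v) == {r}).astype(bool)]
        cands = cands.sort_values(["score_onehot_lr", "variant"], ascending=[False, True])
        picked: list[pd.Series] = []
        used: set[tuple[int, str]] = set()  # (position, residue class)
        remaining = cands
        while len(picked) < 3 and not remaining.empty:
            row, tie = _pick_with_tiebreak(remaining, epsilon)
            if row is None:
                break
            v: VariantProposal = row["_obj"]
            lab = v.labels[0]
            key = (lab.seq_pos, RESIDUE_CLASS.get(lab.new_res or lab.wt_res, "other"))
            remaining = remaining[remaining["variant"] != row["variant"]]
            if key in used:
                continue  # diversity rule: vary position/residue class
            used.add(key)
            picked.append((row, tie))
        if len(picked) < 3:
            warnings.warn(f"fewer than 3 eligible single mutations in CDR{region + 1}")
        for row, tie in picked:
            tags = (f"top_single_cdr{region + 1}",) + (("kmer_tiebreak",) if tie else ())
            selections.append((row, tags))
            selected_single_labels.add(row["variant"])

    # --- top double within each CDR ----------------------------------
    doubles = pool[pool["n_edits"] == 2]
    for region in (0, 1, 2):
        cands = doubles[doubles["_obj"].map(lambda v, r=region: _edit_cdrs(v) == {r}).astype(bool)]
        row, tie = _pick_with_tiebreak(cands, epsilon)
        if row is not None:
            tags = ("top_double_within_cdr",) + (("kmer_tiebreak",) if tie else ())
            selections.append((row, tags))
            for lab in row["_obj"].labels:
                selected_single_labels.add(format_mutation(lab))

    # --- top cross-CDR double per CDR pair, needing a novel single ----
    for pair in ((0, 1), (0, 2), (1, 2)):
        cands = doubles[doubles["_obj"].map(lambda v, p=pair: _edit_cdrs(v) == set(p)).astype(bool)]
        cands = cands.sort_values(["score_onehot_lr", "variant"], ascending=[False, True])
        while not cands.empty:
            row, tie = _pick_with_tiebreak(cands, epsilon)
            if row is None:
                break
            labels = [format_mutation(lab) for lab in row["_obj"].labels]
            if any(lab not in selected_single_labels for lab in labels):
                tags = ("top_double_cross_cdr",) + (("kmer_tiebreak",) if tie else ())
                selections.append((row, tags))
                selected_single_labels.update(labels)
                break
            cands = cands[cands["variant"] != row["variant"]]
    return RescuePanel(selections)
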