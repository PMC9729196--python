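"""Variant enumeration closed forms, ranking and rescue-panel rules."""

import itertools

import numpy as np
import pytest

from nbpoly.design import (
    Edit,
    apply_mutations,
    enumerate_doubles,
    enumerate_singles,
    rank_variants,
    select_rescue_panel,
)
from nbpoly.models import ModelSpec, PolyreactivityResults
from nbpoly.numbering import FrameConfig
from nbpoly.seqio import DEFAULT_FRAMEWORK, NanobodyRecord, extract_cdrs
from nbpoly.util import AA_ALPHABET


def _record(c1="GSIFSSNA", c2="ITSGGSTNY", c3="ARDYWGTQV"):
    return NanobodyRecord("parent", DEFAULT_FRAMEWORK.assemble(c1, c2, c3), c1, c2, c3)


def _planted_model(weights: dict, intercept=0.0):
    """One-hot LR results object with hand-planted weights."""
    cfg = FrameConfig()
    coef = np.zeros(cfg.n_slots * 20)
    for (slot, res), w in weights.items():
        coef[cfg.slot_order.index(slot) * 20 + AA_ALPHABET.index(res)] = w
    return PolyreactivityResults(
        ModelSpec("onehot_lr"), cfg, {"coef": coef, "intercept": np.array([intercept])}, {}
    )


def _kmer_model(weights: dict, intercept=0.0):
    from nbpoly.features import kmer_vocabulary

    vocab, index = kmer_vocabulary(3)
    coef = np.zeros(len(vocab))
    for motif, w in weights.items():
        coef[index[motif]] = w
    return PolyreactivityResults(
        ModelSpec("kmer_lr"), FrameConfig(), {"coef": coef, "intercept": np.array([intercept])}, {}
    )


def oracle_singles(record, edit_kinds, config=None):
    """Generate-and-deduplicate reference enumeration."""
    config = config or FrameConfig()
    bounds = [(8, 8), (8, 9), (6, 22)]
    results = set()
    for region, cdr in enumerate(record.cdr_triple):
        lo, hi = bounds[region]
        if "sub" in edit_kinds:
            for pos, res in itertools.product(range(len(cdr)), AA_ALPHABET):
                if res != cdr[pos]:
                    t = list(record.cdr_triple)
                    t[region] = cdr[:pos] + res + cdr[pos + 1 :]
                    results.add(tuple(t))
        if "del" in edit_kinds and len(cdr) - 1 >= lo:
            for pos in range(len(cdr)):
                t = list(record.cdr_triple)
                t[region] = cdr[:pos] + cdr[pos + 1 :]
                results.add(tuple(t))
        if "ins" in edit_kinds and len(cdr) + 1 <= hi:
            for pos, res in itertools.product(range(len(cdr) + 1), AA_ALPHABET):
                t = list(record.cdr_triple)
                t[region] = cdr[:pos] + res + cdr[pos:]
                results.add(tuple(t))
    results.discard(record.cdr_triple)
    return results


class TestEnumerateSingles:
    def test_substitution_count_494_for_total_length_26(self):
        rec = _record()  # 8 + 9 + 9 = 26 CDR residues
        variants = enumerate_singles(rec, edit_kinds=frozenset({"sub"}))
        assert len(variants) == 19 * 26 == 494

    def test_cdr3_at_max_length_has_no_insertions(self):
        rec = _record(c3="A" * 22)
        variants = enumerate_singles(rec, edit_kinds=frozenset({"ins"}))
        assert all("ins" not in v.edit_text or v.edits[0].cdr != 2 for v in variants)
        cdr3_ins = [v for v in variants if v.edits[0].cdr == 2]
        assert cdr3_ins == []

    def test_matches_generate_and_dedup_oracle(self, rng):
        for _ in range(5):
            c2 = "".join(rng.choice(list(AA_ALPHABET), size=rng.choice([8, 9])))
            c3 = "".join(rng.choice(list(AA_ALPHABET), size=rng.integers(6, 23)))
            rec = _record(c2=c2, c3=c3)
            for kinds in ({"sub"}, {"sub", "del", "ins"}):
                variants = enumerate_singles(rec, edit_kinds=frozenset(kinds))
                assert {v.cdr_triple for v in variants} == oracle_singles(rec, kinds)
                assert len(variants) == len({v.cdr_triple for v in variants})

    def test_edits_reproduce_stated_triple_via_labels(self):
        """Applying the dual-nomenclature labels to the parent sequence and
        re-extracting CDRs reproduces each variant's stated triple."""
        rec = _record()
        for v in enumerate_singles(rec):
            mutant = apply_mutations(rec.aa_seq, v.labels)
            assert extract_cdrs(mutant) == v.cdr_triple


class TestEnumerateDoubles:
    def test_substitution_pairs_closed_form(self):
        rec = _record(c2="ITSGGSTN", c3="ARDYWG")  # total length 22
        n = sum(1 for _ in enumerate_doubles(rec, edit_kinds=frozenset({"sub"})))
        L = 22
        assert n == (L * (L - 1) // 2) * 19 * 19

    def test_same_site_pairs_excluded(self):
        rec = _record(c3="ARDYWG")
        for v in enumerate_doubles(rec, edit_kinds=frozenset({"sub"})):
            (a, b) = v.edits
            assert (a.cdr, a.pos) != (b.cdr, b.pos)

    def test_identity_restoring_pairs_excluded(self):
        rec = _record(c2="ITSGGSTNY", c3="ARDYWG")  # CDR2 len 9: del allowed
        for v in enumerate_doubles(rec, edit_kinds=frozenset({"del", "ins"})):
            assert v.cdr_triple != rec.cdr_triple

    def test_overflow_guard(self):
        rec = _record()
        with pytest.raises(OverflowError):
            list(enumerate_doubles(rec, max_variants=10))

    def test_double_labels_reproduce_triples(self, rng):
        rec = _record(c3="ARDYWG")
        sample = itertools.islice(enumerate_doubles(rec), 0, 2000, 7)
        for v in sample:
            mutant = apply_mutations(rec.aa_seq, v.labels)
            assert extract_cdrs(mutant) == v.cdr_triple


class TestRankVariants:
    def test_planted_penalty_reversal_ranks_above_parent(self):
        rec = _record(c2="ITSGGSTRY")  # R at CDR2 position 8 -> slot 64
        model = _planted_model({("64", "R"): -3.0, ("64", "P"): 1.0})
        variants = enumerate_singles(rec, edit_kinds=frozenset({"sub"}))
        ranked = rank_variants({"onehot_lr": model}, variants, rec)
        best = ranked.sort_values("rank_onehot_lr").iloc[0]
        assert best["variant"].startswith("R") and best["variant"].endswith("P^64")
        parent_rank = ranked[ranked["variant"] == "parent"]["rank_onehot_lr"].iloc[0]
        assert best["rank_onehot_lr"] < parent_rank

    def test_parent_reference_always_present(self, lr_suite):
        rec = _record()
        ranked = rank_variants(lr_suite, enumerate_singles(rec)[:10], rec)
        assert (ranked["variant"] == "parent").sum() == 1

    def test_ranking_is_permutation(self, lr_suite):
        rec = _record()
        ranked = rank_variants(lr_suite, enumerate_singles(rec)[:50], rec)
        ranks = sorted(ranked["rank_onehot_lr"].dropna())
        assert ranks == list(range(1, len(ranks) + 1))


class TestRescuePanel:
    def _suite(self):
        onehot = _planted_model(
            {
                ("36", "R"): -3.0, ("36", "D"): 2.0,
                ("58", "W"): -2.5, ("58", "E"): 2.0,
                ("106", "R"): -3.0, ("106", "D"): 2.5, ("107", "K"): -2.0,
            }
        )
        kmer = _kmer_model({"R": -1.0, "D": 1.0, "E": 0.8})
        return {"onehot_lr": onehot, "kmer_lr": kmer}

    def _ranked(self, suite=None):
        rec = _record(c1="GSIFSSRA", c2="ITWGGSTNY", c3="ARKYWGTQV")
        suite = suite or self._suite()
        variants = enumerate_singles(rec, edit_kinds=frozenset({"sub"})) + list(
            enumerate_doubles(rec, edit_kinds=frozenset({"sub"}))
        )
        return rec, rank_variants(suite, variants, rec)

    def test_panel_structure_when_all_eligible(self):
        _, ranked = self._ranked()
        panel = select_rescue_panel(ranked)
        frame = panel.to_frame()
        tags = frame["tags"].str.split(",").map(lambda t: t[0])
        assert (tags.str.startswith("top_single_cdr1")).sum() == 3
        assert (tags.str.startswith("top_single_cdr2")).sum() == 3
        assert (tags.str.startswith("top_single_cdr3")).sum() == 3
        assert (tags == "top_double_within_cdr").sum() == 3
        assert (tags == "top_double_cross_cdr").sum() == 3

    def test_no_cysteine_in_panel(self):
        _, ranked = self._ranked()
        panel = select_rescue_panel(ranked)
        assert all("C^" not in v and not v.endswith("C") for v in panel.variant_names)

    def test_cysteine_top_hit_skipped_for_next_best(self):
        # make cysteine the best edit at slot 36 under one-hot
        suite = self._suite()
        cfg = suite["onehot_lr"].frame_config
        coef = suite["onehot_lr"].params["coef"]
        coef[cfg.slot_order.index("36") * 20 + AA_ALPHABET.index("C")] = 10.0
        _, ranked = self._ranked(suite)
        panel = select_rescue_panel(ranked)
        assert len(panel.selections) > 0
        assert not any(
            lab.new_res == "C" for row, _ in panel.selections for lab in row["_obj"].labels
        )

    def test_kmer_tiebreak_prefers_higher_kmer_score(self):
        """Two one-hot-equivalent edits: the one with better k-mer score wins."""
        onehot = _planted_model({("36", "D"): 2.0, ("36", "E"): 2.0})
        kmer = _kmer_model({"E": 1.0})  # k-mer prefers E
        rec = _record(c1="GSIFSSRA", c2="ITWGGSTNY", c3="ARKYWGTQV")
        variants = enumerate_singles(rec, edit_kinds=frozenset({"sub"}))
        ranked = rank_variants({"onehot_lr": onehot, "kmer_lr": kmer}, variants, rec)
        panel = select_rescue_panel(ranked, epsilon=0.1)
        cdr1_rows = [
            (row, tags) for row, tags in panel.selections if "top_single_cdr1" in tags
        ]
        first_row, first_tags = cdr1_rows[0]
        assert first_row["variant"].endswith("E^36")
        assert "kmer_tiebreak" in first_tags

    def test_panel_deterministic(self):
        _, ranked = self._ranked()
        p1 = select_rescue_panel(ranked)
        p2 = select_rescue_panel(ranked)
        assert p1.variant_names == p2.variant_names
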