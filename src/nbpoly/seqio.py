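"""Reading, translating, filtering and pooling nanobody sequences.

The pipeline starts from merged/trimmed amplicon reads (paired-end merging and
quality control are upstream concerns): reads are translated in a fixed frame,
the nanobody region is recovered by anchoring on the highly conserved final
beta-strand (FR4) motif, CDRs are located with a framework template, library
length filters are applied, and surviving clones are deduplicated by CDR
triple into two labelled pools (low / high polyreactivity).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

from .numbering import FrameConfig
from .util import AA_ALPHABET, ParseError

__all__ = [
    "RawRead",
    "NanobodyRecord",
    "LabeledPool",
    "FilterReport",
    "FrameworkTemplate",
    "DEFAULT_FRAMEWORK",
    "DEFAULT_ANCHOR",
    "load_sequences",
    "translate_reads",
    "extract_nanobody",
    "extract_cdrs",
    "build_pools",
    "write_pool_tsv",
    "read_pool_tsv",
]

DEFAULT_ANCHOR = "WGQGTQVTVSS"  # canonical nanobody FR4 / final beta strand


@dataclass
class RawRead:
    """One merged nucleotide read."""

    id: str
    nucleotide_seq: str
    quality: list[int] | None = None

    def __post_init__(self):
        if not self.nucleotide_seq:
            raise ParseError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.nucleotide_seq):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.nucleotide_seq)}"
            )


@dataclass
class NanobodyRecord:
    """One clone: full amino-acid sequence plus its CDR decomposition."""

    id: str
    aa_seq: str
    cdr1: str = ""
    cdr2: str = ""
    cdr3: str = ""
    source_pool: str = "unlabeled"  # "low" | "high" | "unlabeled"
    read_count: int = 1

    @property
    def cdr_triple(self) -> tuple[str, str, str]:
        return (self.cdr1, self.cdr2, self.cdr3)

    @property
    def cdr_concat(self) -> str:
        return self.cdr1 + self.cdr2 + self.cdr3


@dataclass
class FrameworkTemplate:
    """Constant framework regions used to locate CDRs and rebuild sequences.

    The library diversifies only the CDRs, so CDR boundaries can be found by
    exact framework matching.  Defaults are a representative synthetic VHH
    scaffold ending in the canonical FR4 beta strand.
    """

    fr1: str = "QVQLVESGGGLVQAGGSLRLSCAAS"
    fr2: str = "WYRQAPGKQRELVA"
    fr3: str = "DSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCNA"
    fr4: str = DEFAULT_ANCHOR

    def assemble(self, cdr1: str, cdr2: str, cdr3: str) -> str:
        return self.fr1 + cdr1 + self.fr2 + cdr2 + self.fr3 + cdr3 + self.fr4

    def cdr_offset(self, region: int, cdr1: str, cdr2: str, cdr3: str) -> int:
        """0-based start of a CDR in the assembled full sequence."""
        if region == 0:
            return len(self.fr1)
        if region == 1:
            return len(self.fr1) + len(cdr1) + len(self.fr2)
        return len(self.fr1) + len(cdr1) + len(self.fr2) + len(cdr2) + len(self.fr3)


DEFAULT_FRAMEWORK = FrameworkTemplate()


class LabeledPool:
    """Deduplicated CDR triples with a class label and read counts.

    ``label`` is 1 for the low-polyreactivity pool and 0 for the high pool
    (the classifiers' positive class is "low").  ``n_unique_seq`` counts
    distinct full amino-acid sequences seen before CDR-level deduplication;
    ``n_unique_cdr`` counts distinct CDR triples retained.
    """

    def __init__(self, label: int):
        if label not in (0, 1):
            raise ValueError("label must be 0 (high) or 1 (low)")
        self.label = label
        self.records: dict[tuple[str, str, str], NanobodyRecord] = {}
        self._seen_seqs: set[str] = set()

    @property
    def name(self) -> str:
        return "low" if self.label == 1 else "high"

    @property
    def n_unique_cdr(self) -> int:
        return len(self.records)

    @property
    def n_unique_seq(self) -> int:
        return len(self._seen_seqs)

    def add(self, record: NanobodyRecord) -> None:
        self._seen_seqs.add(record.aa_seq)
        key = record.cdr_triple
        if key in self.records:
            self.records[key].read_count += record.read_count
        else:
            self.records[key] = replace(record, source_pool=self.name)

    def remove(self, key: tuple[str, str, str]) -> None:
        self.records.pop(key, None)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def record_list(self) -> list[NanobodyRecord]:
        return list(self.records.values())


@dataclass
class FilterReport:
    """Per-pool tallies; input = retained + filtered + ambiguous."""

    input: dict[str, int] = field(default_factory=lambda: {"low": 0, "high": 0})
    retained: dict[str, int] = field(default_factory=lambda: {"low": 0, "high": 0})
    filtered: dict[str, int] = field(default_factory=lambda: {"low": 0, "high": 0})
    ambiguous: dict[str, int] = field(default_factory=lambda: {"low": 0, "high": 0})
    reasons: dict[str, int] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["pool\tinput\tretained\tfiltered\tambiguous"]
        for pool in ("low", "high"):
            lines.append(
                f"{pool}\t{self.input[pool]}\t{self.retained[pool]}"
                f"\t{self.filtered[pool]}\t{self.ambiguous[pool]}"
            )
        for reason, n in sorted(self.reasons.items()):
            lines.append(f"# {reason}\t{n}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def load_sequences(path, format: str):
    """Load ``fasta``/``fastq`` files as :class:`RawRead`, ``tsv`` as records.

    Order and identifiers are preserved.  A TSV needs at least ``id`` and
    ``aa_seq`` columns; ``cdr1/2/3``, ``label`` (or ``source_pool``) and
    ``read_count`` are used when present.
    """
    if format in ("fasta", "fastq"):
        reads = []
        try:
            for rec in SeqIO.parse(str(path), format):
                qual = rec.letter_annotations.get("phred_quality")
                reads.append(RawRead(rec.id, str(rec.seq), qual))
        except ValueError as exc:  # Biopython names the offending record
            raise ParseError(f"{path}: {exc}") from exc
        if not reads:
            warnings.warn(f"{path}: no records parsed")
        return reads
    if format == "tsv":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or "id" not in reader.fieldnames:
                raise ParseError(f"{path}: TSV needs an 'id' column")
            for i, row in enumerate(reader, start=2):
                if not row.get("aa_seq"):
                    raise ParseError(f"{path} line {i}: missing aa_seq")
                label = row.get("label", row.get("source_pool", "unlabeled"))
                pool = {"1": "low", "0": "high"}.get(label, label)
                records.append(
                    NanobodyRecord(
                        id=row["id"],
                        aa_seq=row["aa_seq"],
                        cdr1=row.get("cdr1", ""),
                        cdr2=row.get("cdr2", ""),
                        cdr3=row.get("cdr3", ""),
                        source_pool=pool,
                        read_count=int(row.get("read_count", 1) or 1),
                    )
                )
        if not records:
            warnings.warn(f"{path}: no records parsed")
        return records
    raise ValueError(f"unknown format {format!r}")


def translate_reads(reads: list[RawRead], frame: int = 0) -> list[tuple[str, str]]:
    """Translate reads in a fixed frame with the standard genetic code.

    Translation stops at the first stop codon; a trailing partial codon is
    dropped; codons containing N translate to 'X' (such records are excluded
    later at filter time).  Reads with fewer than 3 usable nucleotides are
    skipped with a warning.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    out = []
    skipped = 0
    for read in reads:
        nt = read.nucleotide_seq[frame:]
        nt = nt[: len(nt) - len(nt) % 3]
        if len(nt) < 3:
            skipped += 1
            continue
        aa = str(Seq(nt).translate(to_stop=True))
        out.append((read.id, aa))
    if skipped:
        warnings.warn(f"{skipped} read(s) shorter than one codon skipped")
    return out


def extract_nanobody(aa: str, anchor: str = DEFAULT_ANCHOR) -> str | None:
    """Prefix of ``aa`` up to and including the first FR4 anchor occurrence.

    Returns ``None`` when the anchor is absent (e.g. frameshifted or
    truncated reads).
    """
    if not anchor:
        raise ValueError("anchor must be non-empty")
    idx = aa.find(anchor)
    if idx < 0:
        return None
    n_occ = aa.count(anchor)
    if n_occ > 1:
        warnings.warn(f"anchor occurs {n_occ} times; using first occurrence")
    return aa[: idx + len(anchor)]


def extract_cdrs(aa: str, template: FrameworkTemplate = DEFAULT_FRAMEWORK):
    """Locate the CDRs of ``aa`` by exact framework matching.

    Returns ``(cdr1, cdr2, cdr3)`` or ``None`` when the framework regions are
    not all present in order.
    """
    pos = 0
    bounds = []
    for frag in (template.fr1, template.fr2, template.fr3, template.fr4):
        idx = aa.find(frag, pos)
        if idx < 0:
            return None
        bounds.append((idx, idx + len(frag)))
        pos = idx + len(frag)
    cdr1 = aa[bounds[0][1] : bounds[1][0]]
    cdr2 = aa[bounds[1][1] : bounds[2][0]]
    cdr3 = aa[bounds[2][1] : bounds[3][0]]
    return cdr1, cdr2, cdr3


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def _filter_reason(rec: NanobodyRecord, config: FrameConfig) -> str | None:
    for region, cdr in enumerate(rec.cdr_triple):
        if any(c not in AA_ALPHABET for c in cdr):
            return "nonstandard_residue"
    if len(rec.cdr1) != config.cdr1_len:
        return "cdr1_length"
    if len(rec.cdr2) not in config.cdr2_lens:
        return "cdr2_length"
    if not config.min_cdr3 <= len(rec.cdr3) <= config.max_cdr3:
        return "cdr3_length"
    return None


def build_pools(
    records: list[NanobodyRecord],
    extended_cdr2: bool = False,
    config: FrameConfig | None = None,
):
    """Filter, deduplicate and split labelled records into low/high pools.

    Library filters: CDR1 length 8, CDR2 length in {8, 9} ({9, 10} in
    extended-CDR2 mode), CDR3 length in [6, 22], standard residues only.
    Duplicate CDR triples within a pool are collapsed with summed read
    counts; triples appearing in *both* pools carry contradictory labels and
    are removed from both (tallied as ambiguous).

    Returns ``(low_pool, high_pool, FilterReport)``.
    """
    if config is None:
        config = FrameConfig(extended_cdr2=extended_cdr2)
    low, high = LabeledPool(1), LabeledPool(0)
    report = FilterReport()
    for rec in records:
        if rec.source_pool not in ("low", "high"):
            raise ValueError(f"record {rec.id!r} lacks a pool label")
        report.input[rec.source_pool] += 1
        reason = _filter_reason(rec, config)
        if reason is not None:
            report.filtered[rec.source_pool] += 1
            report.reasons[reason] = report.reasons.get(reason, 0) + 1
            continue
        (low if rec.source_pool == "low" else high).add(rec)

    shared = set(low.records) & set(high.records)
    for key in shared:
        report.ambiguous["low"] += 1
        report.ambiguous["high"] += 1
        low.remove(key)
        high.remove(key)
    report.retained["low"] = report.input["low"] - report.filtered["low"] - report.ambiguous["low"]
    report.retained["high"] = (
        report.input["high"] - report.filtered["high"] - report.ambiguous["high"]
    )
    return low, high, report


POOL_COLUMNS = ["id", "aa_seq", "cdr1", "cdr2", "cdr3", "label", "read_count"]


def write_pool_tsv(path, *pools: LabeledPool) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(POOL_COLUMNS)
        for pool in pools:
            for rec in pool:
                writer.writerow(
                    [rec.id, rec.aa_seq, rec.cdr1, rec.cdr2, rec.cdr3, pool.label, rec.read_count]
                )


def read_pool_tsv(path) -> tuple[LabeledPool, LabeledPool]:
    """Inverse of :func:`write_pool_tsv` (low pool first)."""
    low, high = LabeledPool(1), LabeledPool(0)
    for rec in load_sequences(path, "tsv"):
        if rec.source_pool == "low":
            low.add(rec)
        elif rec.source_pool == "high":
            high.add(rec)
        else:
            raise ParseError(f"{path}: record {rec.id!r} has no pool label")
    return low, high
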