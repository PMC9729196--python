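"""Shared constants and exceptions."""

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"  # fixed residue order used by all encoders
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# Residue classes used by the rescue-panel diversity heuristic.
RESIDUE_CLASS = {}
for _cls, _members in {
    "charged": "DEKRH",
    "aromatic": "FWY",
    "polar": "STNQ",
    "aliphatic": "GAVLIPM",
    "special": "C",
}.items():
    for _a in _members:
        RESIDUE_CLASS[_a] = _cls


class ParseError(ValueError):
    """A record in an input file violates its format's contract."""


class ModelIOError(RuntimeError):
    """A model archive is missing, corrupt, or of an unsupported version."""
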