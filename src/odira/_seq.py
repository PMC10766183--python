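"""Low-level DNA string helpers shared across the package.

Sequences are plain uppercase Python strings over the alphabet ACGTN.
Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# N is never a valid pairing partner: it does not count as a match in arm
# detection or read anchoring.
_PAIR = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    """Watson-Crick partner of a single base; N has none and returns ''. """
    return _PAIR.get(base, "")


def pairs(a: str, b: str) -> bool:
    """True iff single bases *a* and *b* are Watson-Crick partners (N never pairs)."""
    return _PAIR.get(a) == b if a in _PAIR else False


def is_dna(seq: str) -> bool:
    return all(c in "ACGTN" for c in seq)
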