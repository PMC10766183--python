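"""Split-read detection and inverted-junction characterization.

A split read is a read whose sequence cannot be explained by one contiguous
exact match to the reference but decomposes into a maximal exact prefix
match and a maximal exact suffix match at two non-contiguous reference
locations. Reads whose two segments map to opposite strands of the same
contig are foldback (inverted-junction) evidence: the breakpoint homology
shared by both segments is exactly the inverted-repeat arm at which the
template switch occurred, and the gap between the two arm copies on the
reference is the spacer (interruption).

Mapping is exact-match anchor-and-extend on a k-mer index (default k=20):
the junctions of interest are exact sequence features of short reads against
small (<= ~1 Mb) references, so no scoring matrix or gapped alignment is
needed.

Junctions are deduplicated into a canonical (contig, position, arm, spacer,
loop side) tuple. Support is counted in *unique fragments* — reads sharing
the outer 5' mapping coordinate and strand are treated as PCR copies of one
fragment — and junctions below the support threshold (default 2) are
discarded as likely PCR artifacts.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import revcomp

TELOMERE_RE_C = re.compile(r"(?:C{1,3}A)+")
TELOMERE_RE_G = re.compile(r"(?:G{1,3}T)+")


class Category(str, Enum):
    INVERTED = "INVERTED"
    DIRECT = "DIRECT"
    DE_NOVO_TELOMERE = "DE_NOVO_TELOMERE"
    TELOMERE_TRANSLOCATION = "TELOMERE_TRANSLOCATION"
    INTERNAL_TRANSLOCATION = "INTERNAL_TRANSLOCATION"
    UNCLASSIFIED = "UNCLASSIFIED"


class LoopSide(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Orientation(str, Enum):
    CJ = "CJ"
    TJ = "TJ"
    NONPRODUCTIVE = "NONPRODUCTIVE"
    NA = "NA"


@dataclass(frozen=True)
class SplitSegment:
    """One mapped piece of a split read (reference coords half-open)."""

    contig: str
    start: int
    end: int
    strand: str               # '+' or '-'
    read_start: int
    read_end: int
    unique: bool = True       # False when equally good alternative placements exist

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SplitRead:
    read_id: str
    sequence: str
    prefix: Optional[SplitSegment]
    suffix: Optional[SplitSegment]
    unmapped_tail: str = ""   # read bases left uncovered when one side fails to map
    category: Optional[Category] = None

    @property
    def homology(self) -> int:
        """Breakpoint homology: read bases consistent with both segments."""
        if self.prefix is None or self.suffix is None:
            return 0
        return max(0, self.prefix.read_end - self.suffix.read_start)

    @property
    def fragment_signature(self) -> tuple:
        """(contig, outer 5' mapping coordinate, strand) of the prefix segment.

        Reads from the same sequenced fragment (PCR duplicates) share it.
        """
        seg = self.prefix if self.prefix is not None else self.suffix
        outer = seg.start if seg.strand == "+" else seg.end
        return (seg.contig, outer, seg.strand)


@dataclass
class InvertedJunction:
    """A characterized foldback breakpoint."""

    contig: str
    pos: int                  # midpoint of the spacer interval
    arm_len: int
    spacer_len: int
    loop_side: LoopSide
    n_reads: int = 0
    n_unique_fragments: int = 0
    orientation: Orientation = Orientation.NA
    population: str = ""

    def __post_init__(self):
        if self.arm_len < 0 or self.spacer_len < 0:
            raise ValueError("arm_len and spacer_len must be >= 0")
        if self.n_unique_fragments > self.n_reads:
            raise ValueError("n_unique_fragments cannot exceed n_reads")
        self.loop_side = LoopSide(self.loop_side)
        self.orientation = Orientation(self.orientation)

    @property
    def secondary_deletion(self) -> bool:
        """Spacer > 1 kb: one arm likely lost to a secondary deletion."""
        return self.spacer_len > 1000

    def key(self) -> tuple:
        return (self.contig, self.pos, self.arm_len, self.spacer_len,
                self.loop_side.value)


# ---------------------------------------------------------------------------
# Reference index


class KmerIndex:
    """Exact k-mer index of the forward strands of a set of contigs."""

    def __init__(self, contigs: Sequence[tuple[str, str]], k: int = 20):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.names = [name for name, _ in contigs]
        self.seqs = {name: seq.upper() for name, seq in contigs}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.seqs.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((name, i))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


# ---------------------------------------------------------------------------
# Split-read discovery


def _extend_prefix(read: str, seq: str, name: str, pos: int, strand: str,
                   k: int) -> SplitSegment:
    """Grow a prefix anchor match as far right into the read as it stays exact."""
    n, L = len(seq), len(read)
    if strand == "+":
        m = k
        while m < L and pos + m < n and read[m] == seq[pos + m]:
            m += 1
        return SplitSegment(name, pos, pos + m, "+", 0, m)
    # '-' strand: revcomp(read[:k]) sits at seq[pos:pos+k]; extending the
    # read rightward walks the reference leftward.
    m = k
    while m < L and pos - (m - k) - 1 >= 0 and read[m] == _COMP.get(seq[pos - (m - k) - 1]):
        m += 1
    left = pos - (m - k)
    return SplitSegment(name, left, pos + k, "-", 0, m)


def _extend_suffix(read: str, seq: str, name: str, pos: int, strand: str,
                   k: int) -> SplitSegment:
    """Grow a suffix anchor match as far left into the read as it stays exact."""
    n, L = len(seq), len(read)
    if strand == "+":
        m = k
        while m < L and pos - (m - k) - 1 >= 0 and read[L - m - 1] == seq[pos - (m - k) - 1]:
            m += 1
        start = pos - (m - k)
        return SplitSegment(name, start, start + m, "+", L - m, L)
    # '-' strand: revcomp(read[-k:]) sits at seq[pos:pos+k]; extending the
    # read leftward walks the reference rightward.
    m = k
    while m < L and pos + k + (m - k) < n and read[L - m - 1] == _COMP.get(seq[pos + k + (m - k)]):
        m += 1
    return SplitSegment(name, pos, pos + k + (m - k), "-", L - m, L)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _best_anchor(index: KmerIndex, read: str, side: str) -> tuple[Optional[SplitSegment], bool]:
    """Longest maximal exact match anchored at the read's start or end.

    Returns (segment, unique); segment is None when the anchor k-mer is absent
    from the reference on either strand.
    """
    k = index.k
    anchor = read[:k] if side == "prefix" else read[-k:]
    if "N" in anchor:
        return None, True
    candidates: list[SplitSegment] = []
    for name, pos in index.hits(anchor):
        seq = index.seqs[name]
        seg = (_extend_prefix if side == "prefix" else _extend_suffix)(
            read, seq, name, pos, "+", k)
        candidates.append(seg)
    for name, pos in index.hits(revcomp(anchor)):
        seq = index.seqs[name]
        seg = (_extend_prefix if side == "prefix" else _extend_suffix)(
            read, seq, name, pos, "-", k)
        candidates.append(seg)
    if not candidates:
        return None, True
    best_len = max(s.read_end - s.read_start for s in candidates)
    best = [s for s in candidates if s.read_end - s.read_start == best_len]
    # deterministic representative: lowest (contig, start, strand)
    best.sort(key=lambda s: (s.contig, s.start, s.strand))
    unique = len(best) == 1
    return replace(best[0], unique=unique), unique


def find_split_reads(reads: Iterable[tuple[str, str]],
                     reference: Sequence[tuple[str, str]] | KmerIndex,
                     k: int = 20) -> list[SplitRead]:
    """Detect reads mapping to two non-contiguous reference locations.

    *reads* yields (read id, sequence). A read explained by one contiguous
    exact match is not emitted. A read with one mappable side and >= k
    unmapped tail bases is emitted with a single segment (telomere-addition
    candidates). Both-sided candidates require the two maximal matches to
    jointly cover the read.
    """
    index = reference if isinstance(reference, KmerIndex) else KmerIndex(reference, k)
    reads = list(reads)
    if index.k > min((len(r[1]) for r in reads), default=index.k):
        raise ValueError("k exceeds read length")
    out: list[SplitRead] = []
    for read_id, seq in reads:
        seq = seq.upper()
        sr = _split_one(index, read_id, seq)
        if sr is not None:
            out.append(sr)
    return out


def _split_one(index: KmerIndex, read_id: str, seq: str) -> Optional[SplitRead]:
    L = len(seq)
    k = index.k
    prefix, _ = _best_anchor(index, seq, "prefix")
    if prefix is not None and prefix.read_end == L:
        return None                      # fully contiguous
    suffix, _ = _best_anchor(index, seq, "suffix")
    if suffix is not None and suffix.read_start == 0:
        return None                      # fully contiguous on the other anchor
    if prefix is None and suffix is None:
        return None                      # unmappable, not split evidence
    if prefix is None or suffix is None:
        seg = prefix if prefix is not None else suffix
        tail = seq[seg.read_end:] if prefix is not None else seq[: seg.read_start]
        if len(tail) < k:
            return None
        return SplitRead(read_id, seq, prefix, suffix, unmapped_tail=tail)
    if prefix.read_end + (L - suffix.read_start) < L:
        return None   # middle bases consistent with neither side (errors at the seam)
    return SplitRead(read_id, seq, prefix, suffix)


# ---------------------------------------------------------------------------
# Classification


def _is_telomeric(seq: str, min_fraction: float = 0.9) -> bool:
    """True if *seq* is essentially a tandem C1-3A / G1-3T telomere repeat."""
    if not seq:
        return False
    best = 0
    for rx in (TELOMERE_RE_C, TELOMERE_RE_G):
        for m in rx.finditer(seq):
            best = max(best, m.end() - m.start())
    for rx in (TELOMERE_RE_C, TELOMERE_RE_G):
        for m in rx.finditer(revcomp(seq)):
            best = max(best, m.end() - m.start())
    return best / len(seq) >= min_fraction


def _overlaps(intervals: Sequence[tuple[str, int, int]], seg: SplitSegment) -> bool:
    return any(c == seg.contig and seg.start < e and s < seg.end
               for c, s, e in intervals)


def classify_split_read(sr: SplitRead,
                        repeat_annotation: Sequence[tuple[str, int, int]] = (),
                        telomere_annotation: Sequence[tuple[str, int, int]] = ()) -> Category:
    """Assign exactly one of the five junction categories (or UNCLASSIFIED).

    Precedence: telomere-motif and telomere-interval checks come before the
    repeat-annotation fallback; INVERTED/DIRECT require both segments
    uniquely mapped to the same contig.
    """
    if sr.prefix is None or sr.suffix is None:
        cat = (Category.DE_NOVO_TELOMERE if _is_telomeric(sr.unmapped_tail)
               else Category.UNCLASSIFIED)
        sr.category = cat
        return cat
    p, s = sr.prefix, sr.suffix
    if _overlaps(telomere_annotation, p) != _overlaps(telomere_annotation, s):
        # unique sequence joined onto an existing telomere
        sr.category = Category.TELOMERE_TRANSLOCATION
        return sr.category
    if p.contig == s.contig and p.unique and s.unique:
        sr.category = Category.INVERTED if p.strand != s.strand else Category.DIRECT
        return sr.category
    if p.contig != s.contig or _overlaps(repeat_annotation, p) or _overlaps(repeat_annotation, s):
        sr.category = Category.INTERNAL_TRANSLOCATION
        return sr.category
    sr.category = Category.UNCLASSIFIED
    return sr.category


# ---------------------------------------------------------------------------
# Inverted-junction characterization


def characterize_inverted_junction(sr: SplitRead) -> InvertedJunction:
    """Arm, spacer, loop side and canonical position of a foldback read.

    The breakpoint homology h is the inverted-repeat arm: the reference
    carries reverse-complement-identical h-mers at the junction-facing ends
    of the two segments. The spacer is the distance between the inner
    boundaries of the two arm copies, and the reported position is the
    midpoint of the spacer interval.
    """
    if sr.category is not Category.INVERTED:
        raise ValueError("read is not an inverted-junction candidate")
    p, s = sr.prefix, sr.suffix
    if p.contig != s.contig:
        raise ValueError("foldback segments must share a contig")
    h = sr.homology
    # Reference intervals of the two arm copies: h bases at the junction-facing
    # end of each segment. For a '+' segment the junction-facing end is the end
    # reached last by the read; for '-' it is the low-coordinate end (prefix)
    # or high-coordinate end (suffix).
    if p.strand == "-":                    # fold toward higher coordinates
        arm_a = (p.start, p.start + h)
        arm_b = (s.start, s.start + h)
        loop = LoopSide.LEFT
    else:                                  # fold toward lower coordinates
        arm_a = (p.end - h, p.end)
        arm_b = (s.end - h, s.end)
        loop = LoopSide.RIGHT
    left, right = sorted([arm_a, arm_b])
    spacer = right[0] - left[1]
    if spacer < 0:
        # over-extension by chance homology past the arm: trim the surplus
        # symmetrically, giving the odd base to the lower coordinate
        shift = -spacer
        left = (left[0], left[1] - (shift + 1) // 2)
        right = (right[0] + shift // 2, right[1])
        spacer = 0
    pos = (left[1] + right[0]) // 2
    return InvertedJunction(contig=p.contig, pos=pos, arm_len=h,
                            spacer_len=spacer, loop_side=loop,
                            n_reads=1, n_unique_fragments=1)


# ---------------------------------------------------------------------------
# Dedup / threshold / orientation


def dedupe_and_threshold(records: Iterable[tuple[InvertedJunction, tuple]],
                         min_support: int = 2) -> list[InvertedJunction]:
    """Collapse per-read junction calls and apply the unique-fragment threshold.

    *records* yields (junction, fragment signature) pairs; junctions with
    identical canonical keys merge, reads with identical signatures count as
    one fragment, and junctions supported by fewer than *min_support* unique
    fragments are dropped as PCR-artifact candidates.
    """
    groups: dict[tuple, list[tuple[InvertedJunction, tuple]]] = defaultdict(list)
    for j, sig in records:
        groups[j.key()].append((j, sig))
    out = []
    for key, members in sorted(groups.items()):
        j0 = members[0][0]
        n_reads = len(members)
        n_frag = len({sig for _, sig in members})
        if n_frag < min_support:
            continue
        out.append(replace_counts(j0, n_reads, n_frag))
    return out


def replace_counts(j: InvertedJunction, n_reads: int, n_frag: int) -> InvertedJunction:
    return InvertedJunction(contig=j.contig, pos=j.pos, arm_len=j.arm_len,
                            spacer_len=j.spacer_len, loop_side=j.loop_side,
                            n_reads=n_reads, n_unique_fragments=n_frag,
                            orientation=j.orientation, population=j.population)


def orient_relative_to_locus(junction: InvertedJunction, locus: int,
                             locus_contig: Optional[str] = None) -> Orientation:
    """Productive-orientation call relative to a focal (selected) locus.

    With the centromere at lower coordinates, a centromere-proximal junction
    (left of the locus) is productive only with its hairpin loop on the left
    (CJ); a telomere-proximal junction only with the loop on the right (TJ).
    """
    if locus_contig is not None and junction.contig != locus_contig:
        return Orientation.NA
    left_of = junction.pos < locus
    if left_of and junction.loop_side is LoopSide.LEFT:
        return Orientation.CJ
    if not left_of and junction.loop_side is LoopSide.RIGHT:
        return Orientation.TJ
    return Orientation.NONPRODUCTIVE


# ---------------------------------------------------------------------------
# Pipeline convenience + depth


def call_junctions(reads: Iterable[tuple[str, str]],
                   reference: Sequence[tuple[str, str]] | KmerIndex,
                   k: int = 20, min_support: int = 2,
                   locus: Optional[int] = None,
                   repeat_annotation: Sequence[tuple[str, int, int]] = (),
                   telomere_annotation: Sequence[tuple[str, int, int]] = ()) -> list[InvertedJunction]:
    """FASTQ-to-junction-table pipeline: split, classify, characterize, filter."""
    split = find_split_reads(list(reads), reference, k=k)
    records = []
    for sr in split:
        if classify_split_read(sr, repeat_annotation, telomere_annotation) is Category.INVERTED:
            j = characterize_inverted_junction(sr)
            records.append((j, sr.fragment_signature))
    junctions = dedupe_and_threshold(records, min_support=min_support)
    if locus is not None:
        junctions = [replace_orientation(j, orient_relative_to_locus(j, locus))
                     for j in junctions]
    return junctions


def replace_orientation(j: InvertedJunction, orientation: Orientation) -> InvertedJunction:
    return InvertedJunction(contig=j.contig, pos=j.pos, arm_len=j.arm_len,
                            spacer_len=j.spacer_len, loop_side=j.loop_side,
                            n_reads=j.n_reads, n_unique_fragments=j.n_unique_fragments,
                            orientation=orientation, population=j.population)


def binned_depth(reads: Iterable[tuple[str, str]],
                 reference: Sequence[tuple[str, str]] | KmerIndex,
                 bin_size: int = 500, k: int = 20) -> dict[str, np.ndarray]:
    """Per-bin coverage normalized by the genome-wide median (copy number).

    Each read is anchored by its first error-free k-mer and assumed to cover
    read-length reference bases from the anchor; split reads contribute both
    segments. Raises on zero median coverage (no reads).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    index = reference if isinstance(reference, KmerIndex) else KmerIndex(reference, k)
    cov = {name: np.zeros(len(seq), dtype=np.int64) for name, seq in index.seqs.items()}
    n_placed = 0
    for read_id, seq in reads:
        seq = seq.upper()
        placed = _place_for_depth(index, seq, cov)
        n_placed += placed
    if n_placed == 0:
        raise ValueError("no reads could be placed on the reference")
    bins = {}
    for name, c in cov.items():
        n_bins = (len(c) + bin_size - 1) // bin_size
        sums = np.add.reduceat(c, np.arange(0, len(c), bin_size))
        widths = np.diff(np.append(np.arange(0, len(c), bin_size), len(c)))
        bins[name] = sums / widths
    med = np.median(np.concatenate([b for b in bins.values()]))
    if med == 0:
        raise ValueError("median coverage is zero; cannot normalize")
    return {name: b / med for name, b in bins.items()}


def _place_for_depth(index: KmerIndex, seq: str, cov: dict[str, np.ndarray]) -> int:
    k = index.k
    L = len(seq)
    # try a few anchor offsets in case the first k-mer carries an error
    for off in (0, k, 2 * k, L - k):
        if off < 0 or off + k > L:
            continue
        kmer = seq[off : off + k]
        hits = index.hits(kmer)
        if len(hits) == 1:
            name, pos = hits[0]
            start = max(0, pos - off)
            cov[name][start : start + L] += 1
            return 1
        hits = index.hits(revcomp(kmer))
        if len(hits) == 1:
            name, pos = hits[0]
            start = max(0, pos - (L - off - k))
            cov[name][start : start + L] += 1
            return 1
    return 0
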