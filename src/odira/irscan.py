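"""Enumeration of interrupted inverted repeats (IIRs).

An IIR is a pair of reverse-complementary arms S[l1:l2] / S[r1:r2]
(l1 < l2 <= r1 < r2) separated by a spacer of s = r1 - l2 bases on the same
strand. These short, closely spaced structures are the substrate of
replication-fork template switching, so their genome-wide inventory is the
"potential" baseline against which junction usage is measured.

Only *maximal* arms are reported: an IIR qualifies when the arm match can be
extended neither outward (mismatch at l1-1 / r2, or sequence boundary) nor
inward (mismatch at l2 / r1-1, or the arms would touch). Sub-arms of a
longer perfect arm are therefore not reported separately. Arms never match
through N. Perfect palindromes (s = 0) are included; arms longer than
max_arm are found with their true length and then filtered, since the
length bound is an observation, not a limit of the mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import pairs

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# complement codes: A<->T (0,3), C<->G (1,2); N (4) pairs with nothing
_COMP_CODE = np.array([3, 2, 1, 0, 5], dtype=np.int8)


@dataclass(frozen=True)
class InterruptedInvertedRepeat:
    contig: str
    l1: int
    l2: int
    r1: int
    r2: int

    def __post_init__(self):
        if not (self.l1 < self.l2 <= self.r1 < self.r2):
            raise ValueError("require l1 < l2 <= r1 < r2")
        if self.l2 - self.l1 != self.r2 - self.r1:
            raise ValueError("arm lengths differ")

    @property
    def arm_len(self) -> int:
        return self.l2 - self.l1

    @property
    def spacer_len(self) -> int:
        return self.r1 - self.l2

    @property
    def total_len(self) -> int:
        return self.r2 - self.l1

    def verify(self, sequence: str) -> bool:
        """Check the reverse-complement arm identity against *sequence*."""
        a = self.arm_len
        return all(pairs(sequence[self.l1 + t], sequence[self.r2 - 1 - t])
                   for t in range(a))


def _encode(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.int8)
    for base, v in _ENC.items():
        code[ord(base)] = v
    return code[arr]


def scan_iirs(sequence: str, min_arm: int = 2, max_arm: int = 14,
              max_spacer: int = 250, contig: str = "seq") -> list[InterruptedInvertedRepeat]:
    """All maximal-arm IIRs with arm in [min_arm, max_arm], spacer <= max_spacer.

    Strategy: for every candidate innermost base pair (i, j = i + d + 1 with
    spacer d <= max_spacer), keep it when the next-inner pair mismatches (or
    the arms would touch), then extend outward to the maximal arm. Sorted by
    left-arm start l1.
    """
    if min_arm < 1:
        raise ValueError("min_arm must be >= 1")
    if max_arm < min_arm or max_spacer < 0:
        raise ValueError("need max_arm >= min_arm and max_spacer >= 0")
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_arm:
        raise ValueError("sequence shorter than 2*min_arm")
    enc = _encode(seq)
    comp = _COMP_CODE[enc]                     # comp[i] pairs with enc[i]

    out: list[InterruptedInvertedRepeat] = []
    # gap = j - i; spacer of the innermost pair is gap - 1
    for gap in range(1, max_spacer + 2):
        m = enc[gap:] == comp[:-gap]           # m[i]: (i, i+gap) pair
        if gap >= 3:
            inner = enc[gap - 1 : -1] == comp[1 : -(gap - 1)]  # (i+1, i+gap-1)
            innermost = m & ~inner
        else:
            innermost = m                      # arms would touch: always innermost
        # require arm >= 2 (one outward extension) before entering Python
        if min_arm >= 2:
            outer = np.zeros(len(m), dtype=bool)
            if gap + 2 <= n - 1:
                o = enc[gap + 2 :] == comp[: -(gap + 2)]   # (i-1, i+gap+1)
                outer[1 : 1 + len(o)] = o
            innermost &= outer
        for i in np.flatnonzero(innermost):
            i = int(i)
            j = i + gap
            # extend outward
            a = 1
            while i - a >= 0 and j + a < n and enc[j + a] == comp[i - a]:
                a += 1
            # maximality outward holds by construction of the while loop;
            # innermost-ness was checked above
            if not (min_arm <= a <= max_arm):
                continue
            l1, l2 = i - a + 1, i + 1
            r1, r2 = j, j + a
            out.append(InterruptedInvertedRepeat(contig, l1, l2, r1, r2))
    out.sort(key=lambda r: (r.l1, r.r1))
    return out


def bin_density(iirs, bin_size: int = 1000, region: tuple[int, int] | None = None,
                by_arm_len: bool = False):
    """Per-bin IIR counts (bin of the left-arm start l1).

    Returns a numpy array of counts, or a dict arm_len -> counts when
    *by_arm_len* is set. The region defaults to [0, max l1 + 1).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    iirs = list(iirs)
    if region is None:
        hi = max((r.l1 for r in iirs), default=0) + 1
        region = (0, hi)
    lo, hi = region
    if any(r.l1 < lo or r.l1 >= hi for r in iirs):
        raise ValueError("region does not cover all IIRs")
    n_bins = max(1, -(-(hi - lo) // bin_size))
    edges = lo + bin_size * np.arange(n_bins + 1)

    def _hist(rs):
        counts, _ = np.histogram([r.l1 for r in rs], bins=edges)
        return counts

    if not by_arm_len:
        return _hist(iirs)
    by_len: dict[int, list] = {}
    for r in iirs:
        by_len.setdefault(r.arm_len, []).append(r)
    return {a: _hist(rs) for a, rs in sorted(by_len.items())}


def size_spacing_histograms(iirs, normalize: bool = False) -> dict[str, dict[int, float]]:
    """Histograms of arm length, spacer length, and total IIR length (r2 - l1)."""
    iirs = list(iirs)
    out = {}
    for key, values in (("arm_len", [r.arm_len for r in iirs]),
                        ("spacer_len", [r.spacer_len for r in iirs]),
                        ("total_len", [r.total_len for r in iirs])):
        hist: dict[int, float] = {}
        for v in values:
            hist[v] = hist.get(v, 0) + 1
        if normalize and iirs:
            hist = {k: v / len(iirs) for k, v in hist.items()}
        out[key] = dict(sorted(hist.items()))
    return out
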