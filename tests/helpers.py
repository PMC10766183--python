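"""Independent oracles used by the test suite.

These deliberately use naive algorithms (quadratic search, full
enumeration) so they share no code path with the implementations they
check.
"""

from __future__ import annotations

import itertools

_PAIR = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _pairs(a: str, b: str) -> bool:
    return _PAIR.get(a) == b if a in _PAIR else False


def brute_force_iirs(s: str, min_arm: int = 2, max_arm: int = 14,
                     max_spacer: int = 250) -> list[tuple[int, int, int, int]]:
    """Every (l1, l2, r1, r2) maximal-arm IIR, found the slow, obvious way.

    Tries every candidate inner boundary (l2, r1) with spacer 0..max_spacer
    and grows the arm one base pair at a time from the inside out; the grown
    arm is outward-maximal by construction, and the candidate is kept only
    when inward extension is blocked too (mismatch at l2/r1-1, or the arms
    would touch).
    """
    n = len(s)
    out = []
    for l2 in range(1, n):
        for r1 in range(l2, min(n, l2 + max_spacer + 1)):
            a = 0
            while (l2 - 1 - a >= 0 and r1 + a < n
                   and _pairs(s[l2 - 1 - a], s[r1 + a])):
                a += 1
            if not (min_arm <= a <= max_arm):
                continue
            inward_blocked = (r1 - l2 <= 1) or not _pairs(s[l2], s[r1 - 1])
            if inward_blocked:
                out.append((l2 - a, l2, r1, r1 + a))
    return sorted(out)


def permutation_mann_whitney_p(a, b) -> float:
    """Two-sided Mann-Whitney p by enumerating every group assignment."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = _midranks(pooled)
    mean_u = n_a * len(b) / 2

    def u_for(idx):
        return sum(ranks[i] for i in idx) - n_a * (n_a + 1) / 2

    obs = abs(u_for(range(n_a)) - mean_u)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_for(idx) - mean_u) >= obs - 1e-9:
            hits += 1
    return hits / total


def _midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def textbook_chi2_2x2(a, b, c, d) -> float:
    """Pearson statistic for a 2x2 table by the closed form n(ad-bc)^2 / products."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
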