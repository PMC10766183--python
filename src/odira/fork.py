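"""Mechanistic replication-fork constraints on template switching.

Two constraints narrow which interrupted inverted repeats can produce
junctions:

* the lagging-strand gap: a template switch needs the partner repeat copy
  still single-stranded on the lagging-strand template, so the spacer must
  not exceed the current Okazaki gap g (0 to ~165 bp in yeast), while
  repeats closer together than a hairpin threshold (default 40 bp) tend to
  self-hybridize on the displaced leading strand instead;
* fork direction: a centromere-proximal junction requires a fork moving
  toward the centromere (leftward, with the centromere at lower
  coordinates), a telomere-proximal junction a rightward fork, so the
  nearest active origin determines which junction orientations a position
  can generate.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .caller import Orientation


class SwitchOutcome(str, Enum):
    SELF_HAIRPIN = "SELF_HAIRPIN"
    NO_TEMPLATE = "NO_TEMPLATE"
    PRODUCTIVE = "PRODUCTIVE"


class ForkDirection(str, Enum):
    LEFTWARD = "LEFTWARD"
    RIGHTWARD = "RIGHTWARD"


@dataclass(frozen=True)
class ForkParams:
    okazaki_len: int = 165       # bp; Okazaki fragment length in yeast
    gap_model: str = "uniform"   # 'uniform' on [0, okazaki_len] or 'fixed'
    fixed_gap: int = 82          # bp, used when gap_model == 'fixed'
    hairpin_threshold: int = 40  # bp; spacers below this self-hybridize

    def __post_init__(self):
        if self.okazaki_len <= 0:
            raise ValueError("okazaki_len must be > 0")
        if self.hairpin_threshold < 0:
            raise ValueError("hairpin_threshold must be >= 0")
        if self.gap_model not in ("uniform", "fixed"):
            raise ValueError("gap_model must be 'uniform' or 'fixed'")


@dataclass
class OriginMap:
    """Replication origins on one contig: (position, active) pairs."""

    origins: list[tuple[int, bool]]
    contig_end: int | None = None

    def __post_init__(self):
        pos = [p for p, _ in self.origins]
        if pos != sorted(pos):
            raise ValueError("origin positions must be sorted")
        if self.contig_end is not None and any(p > self.contig_end for p in pos):
            raise ValueError("origin beyond contig end")

    @property
    def active_positions(self) -> list[int]:
        return [p for p, active in self.origins if active]


def classify_switch(spacer: int, gap: int,
                    params: ForkParams = ForkParams()) -> SwitchOutcome:
    """Outcome of an attempted template switch at spacer s given gap g.

    s < hairpin threshold: the displaced repeats self-hybridize
    (SELF_HAIRPIN); s > g: the partner copy is already covered by an
    Okazaki fragment (NO_TEMPLATE); otherwise PRODUCTIVE. Boundaries:
    s == threshold and s == g are both productive.
    """
    if spacer < 0 or gap < 0:
        raise ValueError("spacer and gap must be >= 0")
    if spacer < params.hairpin_threshold:
        return SwitchOutcome.SELF_HAIRPIN
    if spacer > gap:
        return SwitchOutcome.NO_TEMPLATE
    return SwitchOutcome.PRODUCTIVE


def productive_spacer_density(spacers,
                              params: ForkParams = ForkParams()) -> np.ndarray:
    """Relative productivity of each spacer under a uniform gap on
    [0, okazaki_len]: density(s) = 1[s >= t_h] * max(0, 1 - s/okazaki_len).

    Zero outside [t_h, okazaki_len], non-increasing on the support — the
    mechanism behind the 40-80 bp enrichment of junction spacings.
    """
    if params.gap_model != "uniform":
        raise ValueError("density is defined for the uniform gap model")
    s = np.asarray(spacers, dtype=float)
    dens = np.maximum(0.0, 1.0 - s / params.okazaki_len)
    dens[s < params.hairpin_threshold] = 0.0
    return dens


def fork_direction(position: int, origins: OriginMap) -> ForkDirection:
    """Direction of the fork replicating *position* under equal fork speed
    and simultaneous firing: the nearer active origin wins; a position at an
    origin is taken by its rightward-leaving fork; equidistant positions
    (inter-origin midpoints) break LEFTWARD."""
    active = origins.active_positions
    if not active:
        raise ValueError("no active origin")
    i = bisect.bisect_right(active, position)
    left = active[i - 1] if i > 0 else None
    right = active[i] if i < len(active) else None
    if left is not None and position == left:
        return ForkDirection.RIGHTWARD
    if left is None:
        return ForkDirection.LEFTWARD
    if right is None:
        return ForkDirection.RIGHTWARD
    d_left = position - left
    d_right = right - position
    if d_left < d_right:
        return ForkDirection.RIGHTWARD
    return ForkDirection.LEFTWARD    # nearer origin to the right, or a tie


def junction_fork_compatibility(orientation: Orientation, position: int,
                                origins: OriginMap) -> bool:
    """Can a junction of this orientation arise at this position?

    A CJ needs the region replicated by a leftward (centromere-bound) fork,
    a TJ a rightward fork.
    """
    orientation = Orientation(orientation)
    if orientation not in (Orientation.CJ, Orientation.TJ):
        raise ValueError(f"orientation must be CJ or TJ, got {orientation}")
    direction = fork_direction(position, origins)
    if orientation is Orientation.CJ:
        return direction is ForkDirection.LEFTWARD
    return direction is ForkDirection.RIGHTWARD
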