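"""Forward model of the aCGH "waterfall" signature of palindromic junctions.

Random-primed Cy-dye labeling is performed on large (~20 kb) genomic
fragments; fragments that span a palindromic (foldback) junction snap back
after denaturation, and the re-formed duplex — the region within
min(a, b) of the junction, where a and b are the distances from the
junction to the fragment ends — is unavailable for priming. Shearing the
DNA only *after* labeling therefore depresses the signal in a ramp out to
half a fragment length from the junction. With fragmentation *before*
labeling (~500 bp), snap-back can exclude at most half a shear fragment
(250 bp), and the junction appears as a sharp copy-number step instead:
the diagnostic contrast for inverted junctions.

With c_far total copies on the amplified side of which k meet at the
palindrome (k = 2 for a 1-to-3 inverted triplication junction), uniform
junction phase within a length-L fragment gives the closed form

    c(d) = c_far - k * max(0, 1 - 2 d / L)

for distance d >= 0 into the amplified side: c(0) = c_far - k and the ramp
completes (c = c_far) exactly at d = L / 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class LabelingModel:
    fragment_len: int = 20_000          # L, bp; labeling fragment size
    protocol: str = "shear_after_labeling"
    shear_size: int = 500               # bp, fragment size when shearing first
    c_near: float = 1.0                 # copies on the unamplified side
    c_far: float = 3.0                  # copies on the amplified side
    k: int = 2                          # junction-adjacent palindromic copies

    def __post_init__(self):
        if self.fragment_len <= 0 or self.shear_size <= 0:
            raise ValueError("fragment sizes must be > 0")
        if self.protocol not in ("shear_after_labeling", "shear_before_labeling"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if not (self.c_far >= self.c_near >= 0):
            raise ValueError("require c_far >= c_near >= 0")
        if not 0 <= self.k <= self.c_far:
            raise ValueError("require 0 <= k <= c_far")

    @property
    def effective_len(self) -> int:
        """Fragment length governing the exclusion ramp."""
        return (self.fragment_len if self.protocol == "shear_after_labeling"
                else self.shear_size)


@dataclass
class AcghProfile:
    positions: np.ndarray               # probe positions, bp, strictly increasing
    signal: np.ndarray                  # linear copy-number scale
    noise_sd: Optional[np.ndarray] = None   # per-probe standard error, if known

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.positions.ndim != 1 or self.positions.shape != self.signal.shape:
            raise ValueError("positions and signal must be matching 1-D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")

    def log2_ratio(self, reference: float = 1.0) -> np.ndarray:
        """Convenience transform for comparison with conventional aCGH plots."""
        return np.log2(np.maximum(self.signal, 1e-9) / reference)


def expected_profile(model: LabelingModel, distances) -> np.ndarray:
    """Closed-form expected copy number at distances d >= 0 from the junction
    into the amplified side: c(d) = c_far - k * max(0, 1 - 2d/L)."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    L = model.effective_len
    excl = np.maximum(0.0, 1.0 - 2.0 * d / L)
    return model.c_far - model.k * excl


def simulate_labeling(junction_pos: float, probes, model: LabelingModel,
                      n_fragments: int, seed: int) -> AcghProfile:
    """Monte-Carlo labeled-coverage simulation around one palindromic junction.

    Probes left of the junction see the near side (c_near copies, fully
    labeled); probes right of it see c_far copies of which k form the
    palindrome. Fragments of length L = model.effective_len fall with uniform
    phase; a palindromic-lineage fragment spanning the junction leaves
    positions within min(a, b) of the junction unlabeled (a, b = distances
    from the junction to the fragment ends). The per-probe signal is labeled
    coverage divided by the single-copy expectation.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    rng = np.random.default_rng(seed)
    probes = np.asarray(probes, dtype=float)
    L = float(model.effective_len)
    d = probes - junction_pos            # signed distance; > 0 on amplified side

    signal = np.where(d < 0, model.c_near, float(model.c_far)).astype(float)
    se = np.zeros_like(signal)
    if model.k > 0:
        # Sample n_fragments realizations of the fragment that contains the
        # fold, with uniform phase: the fold sits at distance a ~ U(0, L)
        # from one end, b = L - a from the other. Genomic positions within
        # min(a, b) of the junction lie on both palindromic arms *inside*
        # this fragment, snap back to duplex, and go unlabeled; positions
        # further out fall in fully labeled neighboring fragments.
        a = rng.uniform(0.0, L, size=n_fragments)
        excl = np.minimum(a, L - a)                   # unlabeled radius, <= L/2
        dd = d[d >= 0]
        # fraction of realizations in which a probe at distance d is unlabeled
        p_unlab = np.searchsorted(np.sort(excl), dd, side="left")
        p_unlab = 1.0 - p_unlab / n_fragments
        signal[d >= 0] = model.c_far - model.k * p_unlab
        se[d >= 0] = model.k * np.sqrt(p_unlab * (1 - p_unlab) / n_fragments)
    return AcghProfile(positions=probes, signal=signal, noise_sd=se)


@dataclass
class WaterfallFit:
    found: bool
    junction_pos: float = float("nan")
    ramp_width: float = float("nan")     # L/2: distance over which c rises
    c_near: float = float("nan")
    c_far: float = float("nan")
    residual_rms: float = float("nan")

    def summary(self) -> str:
        if not self.found:
            return "no junction detected (flat profile)"
        return (f"junction @ {self.junction_pos:.0f} bp; ramp width "
                f"{self.ramp_width:.0f} bp; copy number {self.c_near:.2f} -> "
                f"{self.c_far:.2f}; rms residual {self.residual_rms:.3f}")


def _waterfall_curve(x, j, half_width, c_near, c_far):
    """Piecewise-linear waterfall: c_near left of j, linear rise to c_far
    completing at j + half_width."""
    ramp = np.clip((x - j) / max(half_width, 1e-9), 0.0, 1.0)
    return c_near + (c_far - c_near) * ramp


def detect_waterfall(profile: AcghProfile,
                     min_step: float = 0.3) -> WaterfallFit:
    """Least-squares fit of the waterfall family to a copy-number profile.

    Free parameters: junction position, ramp half-width (L/2), c_near,
    c_far. A profile whose fitted rise is below *min_step* (or whose raw
    dynamic range is negligible) yields found=False rather than an error.
    """
    x, y = profile.positions, profile.signal
    if len(x) < 4 or float(np.ptp(y)) < min_step:
        return WaterfallFit(found=False)
    span = x[-1] - x[0]
    lo = np.percentile(y, 5)
    hi = np.percentile(y, 95)
    # initialize the junction where the signal first crosses the midpoint
    mid = (lo + hi) / 2
    above = np.nonzero(y >= mid)[0]
    j0 = x[above[0]] if len(above) else x[len(x) // 2]
    p0 = np.array([j0 - span * 0.05, span * 0.2, lo, hi])
    bounds = ([x[0] - span, span * 1e-3, 0.0, 0.0],
              [x[-1] + span, 2 * span, np.inf, np.inf])

    def resid(p):
        return _waterfall_curve(x, *p) - y

    fit = least_squares(resid, p0, bounds=bounds)
    j, hw, cn, cf = fit.x
    if cf - cn < min_step:
        return WaterfallFit(found=False)
    rms = float(np.sqrt(np.mean(fit.fun ** 2)))
    return WaterfallFit(True, float(j), float(hw), float(cn), float(cf), rms)
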