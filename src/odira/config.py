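"""Run-wide configuration.

`RunConfig` collects every tunable the pipeline stages share: the bounds of
the interrupted-inverted-repeat search (arm 2-14 bp, spacer <= 250 bp), the
read-simulation conditions (150 bp reads at ~125x with a 1e-3 per-base
substitution rate), the replication-fork parameters (165 bp Okazaki
fragments, 40 bp self-hairpin threshold), the labeling fragment size used by
the aCGH model (20 kb), and the two-independent-fragment support threshold
for calling a junction real rather than a PCR artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    min_arm: int = 2          # bp, smallest inverted-repeat arm reported
    max_arm: int = 14         # bp, largest arm retained by default filters
    max_spacer: int = 250     # bp, maximum interruption between the arms
    read_len: int = 150       # bp
    depth: float = 125.0      # fold coverage
    error_rate: float = 0.001  # per-base substitution probability
    okazaki_len: int = 165    # bp, Okazaki fragment length in budding yeast
    hairpin_threshold: int = 40  # bp, spacers below this self-hybridize
    fragment_len: int = 20_000   # bp, labeling fragment size (aCGH model)
    min_support: int = 2      # unique fragments required per junction

    def __post_init__(self) -> None:
        if self.min_arm < 1:
            raise ValueError(f"min_arm must be >= 1, got {self.min_arm}")
        if self.min_arm > self.max_arm:
            raise ValueError("min_arm must not exceed max_arm")
        if self.max_spacer < 0:
            raise ValueError("max_spacer must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.read_len < 1 or self.depth <= 0:
            raise ValueError("read_len and depth must be positive")
        if self.okazaki_len <= 0 or self.hairpin_threshold < 0:
            raise ValueError("okazaki_len > 0 and hairpin_threshold >= 0 required")
        if self.fragment_len <= 0:
            raise ValueError("fragment_len must be > 0")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, logged by every stage."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
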