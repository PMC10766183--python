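"""Synthetic genomes, rearranged molecules, and read simulation.

This module stands in for the sequencing data of sulfate-limited chemostat
populations: an ~80-100 kb chromosome-end contig with planted interrupted
inverted repeats (IIRs), the extrachromosomal and chromosomal products of
fork template switching built from it, and 150 bp single-end reads at the
study coverage (~125x, 1e-3 substitution rate) pooled over subclones, plus
singleton chimeric foldback reads emulating PCR artifacts.

Molecule construction rules (S = source contig, E = its length; an IIR has
left arm A1 = S[l1:l2], spacer P = S[l2:r1], right arm A2 = S[r1:r2] with
A2 = revcomp(A1)):

* inverted linear (one template switch at the centromere-proximal fork):
  IL = revcomp(S[r2:E]) + S[l1:E] — the telomere-bound flank twice in
  inverted orientation around one central copy of A1+P+A2.
* triplication (both switches, integrated): for a centromere-proximal IIR c
  and a telomere-proximal IIR t,
  T = S[0:t_r2] + revcomp(S[c_r2:t_l1]) + S[c_l1:E] — the amplified segment
  appears three times with the middle copy inverted.
* inverted dimeric circle: C = Jc + S[c_r2:t_l1] + Jt + revcomp(S[c_r2:t_l1])
  with Jx the IIR block A1+P+A2; topology circular.

The background genome is i.i.d. uniform over ACGT; spontaneous background
IIRs are expected and tolerated. Telomeric contig ends, when requested, are
tandem C{1,3}A (left) / G{1,3}T (right) repeats of >= 100 bp.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import revcomp
from .irscan import InterruptedInvertedRepeat

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedIIR:
    """A planted interrupted inverted repeat with ground-truth coordinates."""

    l1: int
    l2: int
    r1: int
    r2: int
    arm_seq: str

    def __post_init__(self):
        if not (self.l1 < self.l2 <= self.r1 < self.r2):
            raise ValueError("require l1 < l2 <= r1 < r2")
        a = self.l2 - self.l1
        if a != self.r2 - self.r1 or a != len(self.arm_seq):
            raise ValueError("inconsistent arm length")

    @property
    def arm_len(self) -> int:
        return self.l2 - self.l1

    @property
    def spacer_len(self) -> int:
        return self.r1 - self.l2

    @property
    def junction_pos(self) -> int:
        """Midpoint of the spacer interval — the canonical junction position."""
        return (self.l2 + self.r1) // 2

    def verify(self, sequence: str) -> bool:
        return (sequence[self.l1:self.l2] == self.arm_seq
                and sequence[self.r1:self.r2] == revcomp(self.arm_seq))

    def shifted(self, delta: int) -> "PlantedIIR":
        return PlantedIIR(self.l1 + delta, self.l2 + delta,
                          self.r1 + delta, self.r2 + delta, self.arm_seq)


@dataclass
class SyntheticGenome:
    contigs: list[tuple[str, str]]
    truth: dict[str, list[PlantedIIR]]
    telomeric_ends: bool = False

    def sequence(self, contig: str) -> str:
        return dict(self.contigs)[contig]


@dataclass
class Molecule:
    label: str
    sequence: str
    topology: str = "linear"            # 'linear' | 'circular'
    # truth junctions carried by this molecule: (source position, 'CJ'|'TJ', loop side)
    truth_junctions: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be linear or circular")


@dataclass
class MoleculeSet:
    molecules: list[tuple[Molecule, float]]   # (molecule, abundance fraction)

    def __post_init__(self):
        total = sum(a for _, a in self.molecules)
        if any(a < 0 for _, a in self.molecules):
            raise ValueError("abundances must be >= 0")
        if self.molecules and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")

    def truth_junctions(self) -> list[tuple[int, str, str]]:
        seen = []
        for mol, _ in self.molecules:
            for tj in mol.truth_junctions:
                if tj not in seen:
                    seen.append(tj)
        return seen


def _telomere_repeat(rng: np.random.Generator, end: str, min_len: int = 120) -> str:
    """Tandem C{1,3}A (left end) or G{1,3}T (right end) repeat."""
    units = []
    length = 0
    while length < min_len:
        k = int(rng.integers(1, 4))
        unit = "C" * k + "A" if end == "left" else "G" * k + "T"
        units.append(unit)
        length += len(unit)
    return "".join(units)


def build_genome(seed: int, length: int,
                 iir_specs: Sequence[tuple] = (),
                 telomeric_ends: bool = False,
                 contig: str = "chrR") -> SyntheticGenome:
    """Random genome with planted IIRs.

    *iir_specs* entries are (arm_len, spacer_len, position) with position the
    left-arm start; an optional 4th element fixes the arm sequence. Planted
    IIRs must not overlap. With *telomeric_ends*, >= 100 bp telomere repeats
    are appended on both ends and truth coordinates shift accordingly.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=length)
    planted: list[PlantedIIR] = []
    spans = []
    for spec in iir_specs:
        arm_len, spacer_len, pos = spec[:3]
        arm = spec[3].upper() if len(spec) > 3 else None
        if arm_len < 2:
            raise ValueError("planted arm_len must be >= 2")
        span = 2 * arm_len + spacer_len
        if pos < 0 or pos + span > length:
            raise ValueError("planted IIR exceeds contig bounds")
        for s0, s1 in spans:
            if pos < s1 and s0 < pos + span:
                raise ValueError("planted IIRs overlap")
        spans.append((pos, pos + span))
        if arm is None:
            arm = "".join(rng.choice(BASES, size=arm_len))
        seq[pos : pos + arm_len] = list(arm)
        seq[pos + arm_len + spacer_len : pos + span] = list(revcomp(arm))
        _block_arm_extension(seq, rng, pos, arm_len, spacer_len)
        planted.append(PlantedIIR(pos, pos + arm_len,
                                  pos + arm_len + spacer_len, pos + span, arm))
    sequence = "".join(seq)
    if telomeric_ends:
        left = _telomere_repeat(rng, "left")
        right = _telomere_repeat(rng, "right")
        sequence = left + sequence + right
        planted = [p.shifted(len(left)) for p in planted]
    genome = SyntheticGenome(contigs=[(contig, sequence)],
                             truth={contig: planted},
                             telomeric_ends=telomeric_ends)
    for p in planted:
        assert p.verify(sequence)
    return genome


def _block_arm_extension(seq: np.ndarray, rng: np.random.Generator,
                         pos: int, arm_len: int, spacer_len: int) -> None:
    """Ensure a planted (arm, spacer) IIR is maximal at exactly that arm.

    Resamples the base just outside the right arm so it cannot pair with the
    base just outside the left arm, and the last spacer base so it cannot
    pair with the first, preventing chance outward/inward arm extension.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    l1, l2 = pos, pos + arm_len
    r1, r2 = pos + arm_len + spacer_len, pos + 2 * arm_len + spacer_len
    if l1 - 1 >= 0 and r2 < len(seq):
        while seq[r2] == comp[seq[l1 - 1]]:
            seq[r2] = BASES[rng.integers(0, 4)]
    if spacer_len >= 2:
        while seq[r1 - 1] == comp[seq[l2]]:
            seq[r1 - 1] = BASES[rng.integers(0, 4)]


def _iir_block(seq: str, iir: PlantedIIR) -> str:
    return seq[iir.l1 : iir.r2]


def make_inverted_linear(genome: SyntheticGenome, iir: PlantedIIR,
                         contig: Optional[str] = None,
                         label: str = "inverted_linear") -> Molecule:
    """Hairpin-derived inverted linear: telomeric flank twice around one fold.

    IL = revcomp(S[r2:E]) + S[l1:E]; a single centromere-proximal junction
    (loop LEFT) sits at the fold.
    """
    contig = contig or genome.contigs[0][0]
    seq = genome.sequence(contig)
    if iir.r2 > len(seq):
        raise ValueError("IIR outside contig")
    il = revcomp(seq[iir.r2 :]) + seq[iir.l1 :]
    return Molecule(label, il, "linear",
                    truth_junctions=[(iir.junction_pos, "CJ", "LEFT")])


def make_triplication(genome: SyntheticGenome, cj_iir: PlantedIIR,
                      tj_iir: PlantedIIR, contig: Optional[str] = None,
                      label: str = "triplication") -> Molecule:
    """Chromosomal inverted triplication: amplified segment three times,
    middle copy inverted, CJ (loop LEFT) and TJ (loop RIGHT) at its edges."""
    contig = contig or genome.contigs[0][0]
    seq = genome.sequence(contig)
    if not cj_iir.r2 <= tj_iir.l1:
        raise ValueError("CJ IIR must lie entirely left of the TJ IIR")
    if tj_iir.r2 > len(seq):
        raise ValueError("TJ IIR outside contig")
    t = (seq[: tj_iir.r2]
         + revcomp(seq[cj_iir.r2 : tj_iir.l1])
         + seq[cj_iir.l1 :])
    return Molecule(label, t, "linear",
                    truth_junctions=[(cj_iir.junction_pos, "CJ", "LEFT"),
                                     (tj_iir.junction_pos, "TJ", "RIGHT")])


def make_dimeric_circle(genome: SyntheticGenome, cj_iir: PlantedIIR,
                        tj_iir: PlantedIIR, contig: Optional[str] = None,
                        label: str = "dimeric_circle") -> Molecule:
    """Inverted dimeric circle: two inverted copies of the captured segment
    seamed by the two IIR blocks; reads crossing the seams give CJ- and
    TJ-type junctions."""
    contig = contig or genome.contigs[0][0]
    seq = genome.sequence(contig)
    if not cj_iir.r2 <= tj_iir.l1:
        raise ValueError("CJ IIR must lie entirely left of the TJ IIR")
    if tj_iir.r2 > len(seq):
        raise ValueError("TJ IIR outside contig")
    mid = seq[cj_iir.r2 : tj_iir.l1]
    c = _iir_block(seq, cj_iir) + mid + _iir_block(seq, tj_iir) + revcomp(mid)
    return Molecule(label, c, "circular",
                    truth_junctions=[(cj_iir.junction_pos, "CJ", "LEFT"),
                                     (tj_iir.junction_pos, "TJ", "RIGHT")])


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(molecules: MoleculeSet, depth: float, read_len: int,
                   error_rate: float, seed: int) -> list[tuple[str, str]]:
    """Uniform single-end reads over a molecule population.

    Read counts per molecule are proportional to abundance x length so that
    per-base coverage of a molecule equals depth x abundance. Strand is
    uniform; substitution errors are i.i.d. at *error_rate*; circular
    molecules wrap around. Read names encode molecule, start, and strand as
    ``label|start|strand|serial`` (ground truth for tests).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    serial = 0
    for mol, abundance in molecules.molecules:
        L = len(mol.sequence)
        if abundance == 0:
            continue
        if mol.topology == "linear" and L < read_len:
            warnings.warn(f"molecule {mol.label} shorter than read length; skipped")
            continue
        n_reads = int(round(depth * abundance * L / read_len))
        if mol.topology == "circular":
            starts = rng.integers(0, L, size=n_reads)
            doubled = mol.sequence + mol.sequence   # wraparound sampling
            source = doubled
        else:
            starts = rng.integers(0, L - read_len + 1, size=n_reads)
            source = mol.sequence
        strands = rng.integers(0, 2, size=n_reads)
        for start, flip in zip(starts, strands):
            frag = source[start : start + read_len]
            if flip:
                frag = revcomp(frag)
            frag = _add_errors(frag, error_rate, rng)
            strand = "-" if flip else "+"
            reads.append((f"{mol.label}|{int(start)}|{strand}|{serial}", frag))
            serial += 1
    return reads


def _add_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    arr = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        cur = arr[pos]
        choices = [b for b in "ACGT" if b != cur]
        arr[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Population simulation


@dataclass
class Subclone:
    """One lineage in a simulated population: its molecules and frequency."""

    name: str
    molecules: list[Molecule]
    frequency: float


def simulate_population(genome: SyntheticGenome, subclones: Sequence[Subclone],
                        artifact_rate: float, seed: int,
                        depth: float = 125.0, read_len: int = 150,
                        error_rate: float = 0.001,
                        population: str = "pop") -> tuple[list[tuple[str, str]], list[dict]]:
    """Pooled reads across subclones plus singleton PCR-artifact foldbacks.

    Each subclone contributes its molecules at its frequency. Afterwards,
    ``artifact_rate x N`` chimeric foldback reads are injected, each built
    from a distinct random inverted junction so that every artifact junction
    is supported by exactly one fragment. Returns (reads, truth table);
    truth rows are dicts with population, pos, type, loop_side.
    """
    freqs = [sc.frequency for sc in subclones]
    if any(f < 0 for f in freqs):
        raise ValueError("subclone frequencies must be >= 0")
    if abs(sum(freqs) - 1.0) > 1e-9:
        raise ValueError("subclone frequencies must sum to 1")
    rng = np.random.default_rng(seed)
    # simulate each subclone separately so every molecule is covered at
    # depth x subclone frequency
    reads: list[tuple[str, str]] = []
    serial_seed = int(rng.integers(0, 2**31 - 1))
    for i, sc in enumerate(subclones):
        if sc.frequency == 0:
            continue
        sub_mols = MoleculeSet([(m, 1.0 / len(sc.molecules)) for m in sc.molecules])
        sub_reads = simulate_reads(sub_mols,
                                   depth=depth * sc.frequency * len(sc.molecules),
                                   read_len=read_len, error_rate=error_rate,
                                   seed=(serial_seed + i) % 2**31)
        reads.extend((f"{sc.name}:{rid}", s) for rid, s in sub_reads)
    n_artifacts = int(round(artifact_rate * len(reads)))
    contig, seq = genome.contigs[0]
    reads.extend(_artifact_foldbacks(seq, n_artifacts, read_len, rng))
    truth = []
    for sc in subclones:
        if sc.frequency == 0:
            continue
        for mol in sc.molecules:
            for pos, jtype, loop in mol.truth_junctions:
                row = {"population": population, "subclone": sc.name,
                       "pos": pos, "type": jtype, "loop_side": loop}
                if row not in truth:
                    truth.append(row)
    return reads, truth


def _artifact_foldbacks(seq: str, n: int, read_len: int,
                        rng: np.random.Generator) -> list[tuple[str, str]]:
    """Chimeric foldback reads at distinct random positions (PCR artifacts)."""
    out = []
    used = set()
    E = len(seq)
    attempts = 0
    while len(out) < n and attempts < 50 * (n + 1):
        attempts += 1
        pos = int(rng.integers(read_len, E - read_len))
        if pos in used:
            continue
        used.add(pos)
        x = int(rng.integers(30, read_len - 30))
        frag = revcomp(seq[pos : pos + x]) + seq[pos : pos + read_len - x]
        # foldback: prefix maps '-', suffix '+' at the same spot -> arm 0 junction
        out.append((f"artifact|{pos}|{len(out)}", frag))
    return out
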