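"""Sequence and tabular I/O.

FASTA/FASTQ go through Biopython's SeqIO; tables are tab-separated text
with a commented header line. All coordinates written are 0-based,
half-open (stated in the table headers); BED output follows the same
convention natively.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import is_dna
from .caller import InvertedJunction, LoopSide, Orientation

JUNCTION_COLUMNS = ["contig", "pos", "arm_len", "spacer_len", "loop_side",
                    "orientation", "n_reads", "n_unique_fragments"]


def read_sequences(path) -> list[tuple[str, str]]:
    """Read a FASTA file into [(contig id, uppercase sequence), ...].

    Order is preserved; sequences must be DNA over ACGTN after uppercasing.
    """
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if not is_dna(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"{path}: record {rec.id} contains non-DNA characters {bad}")
            records.append((rec.id, seq))
    except ValueError:
        raise
    except Exception as exc:  # Biopython raises assorted types on malformed input
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: empty or header-less FASTA")
    return records


def write_sequences(records: Iterable[tuple[str, str]], path,
                    descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    recs = [SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
            for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    """Write (name, sequence) reads with a flat Sanger quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            q = chr(quality + 33) * len(seq)
            fh.write(f"@{name}\n{seq}\n+\n{q}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_junction_table(junctions: Sequence[InvertedJunction], path) -> None:
    """TSV junction table (0-based, half-open coordinates)."""
    with open(path, "w", newline="") as fh:
        fh.write("# coordinates: 0-based\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(JUNCTION_COLUMNS)
        for j in junctions:
            w.writerow([j.contig, j.pos, j.arm_len, j.spacer_len,
                        j.loop_side.value, j.orientation.value,
                        j.n_reads, j.n_unique_fragments])


def read_junction_table(path) -> list[InvertedJunction]:
    out = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if not rows:
        raise ValueError(f"{path}: missing header")
    header = rows[0]
    if header != JUNCTION_COLUMNS:
        raise ValueError(f"{path}: unexpected columns {header}")
    for row in rows[1:]:
        rec = dict(zip(header, row))
        try:
            loop = LoopSide(rec["loop_side"])
            orient = Orientation(rec["orientation"])
        except ValueError as exc:
            raise ValueError(f"{path}: unknown token in row {row}: {exc}") from exc
        out.append(InvertedJunction(
            contig=rec["contig"], pos=int(rec["pos"]),
            arm_len=int(rec["arm_len"]), spacer_len=int(rec["spacer_len"]),
            loop_side=loop, orientation=orient,
            n_reads=int(rec["n_reads"]),
            n_unique_fragments=int(rec["n_unique_fragments"])))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    """BED (0-based half-open) of (contig, start, end, name)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for contig, start, end, name in intervals:
            w.writerow([contig, start, end, name])


def read_bed(path) -> list[tuple[str, int, int]]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith(("#", "track", "browser")):
                continue
            out.append((row[0], int(row[1]), int(row[2])))
    return out


def write_tsv(rows: Iterable[Sequence], columns: Sequence[str], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(columns)
        for row in rows:
            w.writerow(list(row))
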