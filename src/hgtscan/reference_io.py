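"""On-disk artifacts: reference FASTA + species map, FASTQ, and TSV outputs.

Coordinate convention: everything in memory is 0-based half-open; every TSV
written or read here is 1-based inclusive, like the common genome-browser
formats.  ``to_external`` / ``to_internal`` are the only two places the
conversion happens.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO


class ReferenceError(ValueError):
    """Malformed or inconsistent reference inputs."""


@dataclass
class ReferenceDatabase:
    """Reference genome collection with a sequence -> species assignment."""

    sequences: dict[str, str]
    species_of: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {n: len(s) for n, s in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)


def load_reference(fasta_path: str | Path, species_map_path: str | Path) -> ReferenceDatabase:
    """Load a FASTA plus its 2-column (sequence, species) TSV map.

    Every sequence must appear in the map; duplicates and empty references
    are hard errors so later stages can trust the namespace.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in sequences:
            raise ReferenceError(f"duplicate sequence name: {rec.id}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise ReferenceError(f"no sequences found in {fasta_path}")
    mp = pd.read_csv(species_map_path, sep="\t", header=None, names=["sequence", "species"], dtype=str)
    if mp["sequence"].duplicated().any():
        dups = mp.loc[mp["sequence"].duplicated(), "sequence"].tolist()
        raise ReferenceError(f"duplicate map entries: {dups}")
    species_of = dict(zip(mp["sequence"], mp["species"]))
    missing = sorted(set(sequences) - set(species_of))
    if missing:
        raise ReferenceError(f"sequences missing from species map: {missing}")
    species_of = {n: species_of[n] for n in sequences}
    return ReferenceDatabase(sequences=sequences, species_of=species_of)


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_read_pairs(fq1: str | Path, fq2: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq1, seq2) from a pair of FASTQ files, gzip-transparent."""
    with _open_text(fq1) as h1, _open_text(fq2) as h2:
        for r1, r2 in zip(SeqIO.parse(h1, "fastq"), SeqIO.parse(h2, "fastq")):
            yield r1.id, str(r1.seq).upper(), str(r2.seq).upper()


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def write_fastq_pair(
    path1: str | Path, path2: str | Path, pairs: list[tuple[str, str, str]]
) -> None:
    """Write (id, seq1, seq2) triples as two plain FASTQ files (quality 'I')."""
    with open(path1, "w") as h1, open(path2, "w") as h2:
        for rid, s1, s2 in pairs:
            h1.write(f"@{rid}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            h2.write(f"@{rid}/2\n{s2}\n+\n{'I' * len(s2)}\n")


# ---------------------------------------------------------------------------
# coordinate conversion

def to_external(pos0: int) -> int:
    """0-based internal position -> 1-based output coordinate."""
    return pos0 + 1


def to_internal(pos1: int) -> int:
    """1-based table coordinate -> 0-based internal position."""
    return pos1 - 1


# ---------------------------------------------------------------------------
# output tables

BREAKPOINT_COLUMNS = [
    "genome_a", "pos_a", "genome_b", "pos_b",
    "split_reads", "junction_reads", "microhomology_len",
]

EVENT_COLUMNS = [
    "recipient_genome", "insertion_pos",
    "donor_genome", "transfer_start", "transfer_end",
    "direction", "support",
]


@dataclass(frozen=True)
class BreakpointRecord:
    """One supported junction between loci on two genomes (1-based output)."""

    genome_a: str
    pos_a: int
    genome_b: str
    pos_b: int
    split_reads: int
    junction_reads: int
    microhomology_len: int | None = None


@dataclass(frozen=True)
class EventRecord:
    """One complete transfer: donor interval plus recipient insertion site."""

    recipient_genome: str
    insertion_pos: int
    donor_genome: str
    transfer_start: int
    transfer_end: int
    direction: str  # forward | reverse
    support: float


def write_breakpoints(path: str | Path, records: list[BreakpointRecord]) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=BREAKPOINT_COLUMNS)
    df = df.sort_values(["genome_a", "pos_a", "genome_b", "pos_b"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_breakpoints(path: str | Path) -> list[BreakpointRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_a": str, "genome_b": str})
    out = []
    for row in df.itertuples(index=False):
        mh = row.microhomology_len
        out.append(
            BreakpointRecord(
                genome_a=row.genome_a, pos_a=int(row.pos_a),
                genome_b=row.genome_b, pos_b=int(row.pos_b),
                split_reads=int(row.split_reads),
                junction_reads=int(row.junction_reads),
                microhomology_len=None if pd.isna(mh) else int(mh),
            )
        )
    return out


def write_events(path: str | Path, records: list[EventRecord]) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=EVENT_COLUMNS)
    df = df.sort_values(
        ["recipient_genome", "insertion_pos", "donor_genome", "transfer_start"],
        kind="mergesort",
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[EventRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"recipient_genome": str, "donor_genome": str, "direction": str})
    return [
        EventRecord(
            recipient_genome=r.recipient_genome, insertion_pos=int(r.insertion_pos),
            donor_genome=r.donor_genome, transfer_start=int(r.transfer_start),
            transfer_end=int(r.transfer_end), direction=r.direction,
            support=float(r.support),
        )
        for r in df.itertuples(index=False)
    ]
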