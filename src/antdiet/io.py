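"""Light-weight read container plus FASTQ/FASTA/TSV round-trips.

Reads are held as a plain :class:`Read` named tuple rather than Bio.SeqRecord
objects: a sequencing run is ~3 million reads and SeqRecord construction
dominates runtime at that scale.  Biopython is still used for the actual
FASTQ/FASTA parsing and writing so the on-disk formats stay canonical
(Sanger Phred+33).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class Read(NamedTuple):
    """A single (possibly MID-tagged) amplicon read."""

    id: str
    seq: str
    qual: np.ndarray  # per-base Phred scores, int8/int16

    @property
    def mean_quality(self) -> float:
        if len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        return float(np.mean(self.qual)) if len(self.qual) else 0.0


def read_fastq(path: str | Path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            Read(
                rec.id,
                str(rec.seq),
                np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return out


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    def _records() -> Iterator[SeqRecord]:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.qual]
            yield rec

    with open(path, "w") as fh:
        SeqIO.write(_records(), fh, "fastq")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Sequence[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_tsv(rows: Iterable[dict], path: str | Path, columns: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), delimiter="\t")
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def read_tsv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
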