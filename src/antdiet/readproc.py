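"""Read-processing cascade: quality filter, MID demultiplexing, length
filter, dereplication and translation-based denoising.

Every stage conserves reads: retained + discarded (+ unassigned) equals the
input count, and each returns its discards so the accounting can be audited.

The quality filter is a whole-read criterion (no trimming): by default a
read passes when its *mean* Phred score reaches the threshold, the common
behaviour of the Galaxy/fastx filters this cascade mirrors; a
fraction-of-bases mode is available.  MID matching is exact — MIDs are only
10 bases and a 1-mismatch tolerance would let tag jumps and sequencing
errors cross samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import Read
from .simulate import MID_LEN, revcomp

INVERTEBRATE_MITO_TABLE = 5

PASSED = "passed"
REMOVED_SINGLETON = "removed_singleton"
REMOVED_STOP_CODON = "removed_stop_codon"
REMOVED_FRAMESHIFT = "removed_frameshift"
REMOVED_AMBIGUOUS = "removed_ambiguous"


def quality_filter(
    reads: Iterable[Read],
    q_threshold: float = 20.0,
    mode: str = "mean",
    min_fraction: float = 0.9,
) -> tuple[list[Read], list[Read]]:
    """Whole-read Phred filter.

    ``mode='mean'`` retains a read iff its mean Phred score is >=
    ``q_threshold`` (boundary inclusive); ``mode='fraction'`` retains it iff
    at least ``min_fraction`` of bases are >= the threshold.
    """
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    if mode not in ("mean", "fraction"):
        raise ValueError(f"unknown quality filter mode {mode!r}")
    retained, discarded = [], []
    for read in reads:
        if len(read.qual) != len(read.seq):
            raise ValueError(
                f"read {read.id!r}: malformed quality string "
                f"({len(read.qual)} scores for {len(read.seq)} bases)"
            )
        if mode == "mean":
            ok = read.mean_quality >= q_threshold
        else:
            ok = np.mean(read.qual >= q_threshold) >= min_fraction
        (retained if ok else discarded).append(read)
    return retained, discarded


def demultiplex(
    reads: Iterable[Read],
    mid_map: Mapping[tuple[str, str], str],
    strip: bool = True,
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Split reads by exact dual-MID match; strip the MIDs from assigned reads.

    The forward MID is matched at the 5' end and the reverse MID as its
    reverse complement at the 3' end.  Reads failing either match land in
    the unassigned bin untouched.
    """
    if len(set(mid_map.values())) != len(mid_map):
        raise ValueError("duplicate (forward, reverse) MID pair in map")
    lookup = {(f, revcomp(r)): s for (f, r), s in mid_map.items()}
    for f, r in mid_map:
        if len(f) != MID_LEN or len(r) != MID_LEN:
            raise ValueError("MIDs must be 10 bases long")
    assigned: dict[str, list[Read]] = {s: [] for s in mid_map.values()}
    unassigned: list[Read] = []
    for read in reads:
        if len(read.seq) < 2 * MID_LEN + 1:
            unassigned.append(read)
            continue
        key = (read.seq[:MID_LEN], read.seq[-MID_LEN:])
        sample = lookup.get(key)
        if sample is None:
            unassigned.append(read)
        elif strip:
            assigned[sample].append(
                Read(read.id, read.seq[MID_LEN:-MID_LEN], read.qual[MID_LEN:-MID_LEN])
            )
        else:
            assigned[sample].append(read)
    return assigned, unassigned


def length_filter(
    reads: Iterable[Read], expected_len: int, tolerance: int | None = None
) -> tuple[list[Read], list[Read]]:
    """Drop too-short and too-long reads: keep |len - expected| <= tolerance.

    Default tolerance is 10 % of the expected amplicon length (131 -> 13,
    211 -> 21).
    """
    if tolerance is None:
        tolerance = round(0.1 * expected_len)
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    retained, discarded = [], []
    for read in reads:
        (retained if abs(len(read.seq) - expected_len) <= tolerance else discarded).append(read)
    return retained, discarded


@dataclass
class HaplotypeTable:
    """Dereplicated unique sequences with per-sample abundances.

    ``counts`` is a sequences x samples DataFrame of read counts *after*
    singleton removal; ``removed`` holds what each filter took out, so that
    the sum over ``counts`` and ``removed`` equals the input read count.
    ``flags`` maps each input haplotype to its fate.
    """

    counts: pd.DataFrame
    flags: pd.Series
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def dereplicate(
    reads_by_sample: Mapping[str, Sequence[Read]],
    min_reads: int = 2,
    per_sample: bool = True,
) -> HaplotypeTable:
    """Collapse identical sequences and remove rare haplotypes.

    ``per_sample=True`` mirrors processing each individual's file on its
    own: cells with fewer than ``min_reads`` identical reads are zeroed per
    sample; a haplotype is flagged removed only when nothing survives
    anywhere.  ``per_sample=False`` applies the rule to the total abundance
    across samples.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    samples = list(reads_by_sample)
    counts: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        for read in reads:
            row = counts.setdefault(read.seq, dict.fromkeys(samples, 0))
            row[sample] += 1
    if not counts:
        empty = pd.DataFrame(columns=samples, dtype=int)
        return HaplotypeTable(empty, pd.Series(dtype=object), empty.copy())
    full = pd.DataFrame.from_dict(counts, orient="index", columns=samples).fillna(0).astype(int)
    full = full.sort_index()
    if per_sample:
        kept = full.where(full >= min_reads, 0)
    else:
        kept = full.where(full.sum(axis=1) >= min_reads, 0)
    removed = full - kept
    flags = pd.Series(
        np.where(kept.sum(axis=1) > 0, PASSED, REMOVED_SINGLETON),
        index=full.index,
        dtype=object,
    )
    return HaplotypeTable(kept[kept.sum(axis=1) > 0], flags, removed[removed.sum(axis=1) > 0])


def _translate(seq: str, frame: int, table: int) -> str:
    core = seq[frame:]
    core = core[: len(core) - len(core) % 3]
    return str(Seq(core).translate(table=table))


def choose_frame(
    reference_amplicons: Iterable[str], table: int = INVERTEBRATE_MITO_TABLE
) -> int:
    """Reading-frame offset maximising stop-free translations of references.

    Ties break toward the smallest offset, so a set that is stop-free in
    every frame yields 0.
    """
    refs = list(reference_amplicons)
    if not refs:
        raise ValueError("need at least one reference amplicon")
    best_frame, best_frac = 0, -1.0
    for frame in range(3):
        frac = np.mean(["*" not in _translate(s, frame, table) for s in refs])
        if frac > best_frac:
            best_frame, best_frac = frame, float(frac)
    return best_frame


def translation_filter(
    table: HaplotypeTable,
    expected_len: int,
    frame: int,
    genetic_code: int = INVERTEBRATE_MITO_TABLE,
) -> HaplotypeTable:
    """Remove pseudogene-like haplotypes.

    A haplotype is dropped when (a) its length offset from the expected
    amplicon length is not a multiple of 3 (frameshifting indel proxy), (b)
    its in-frame translation under the invertebrate mitochondrial code
    contains a stop codon, or (c) it contains non-ACGT bases (flagged, not a
    crash).  Survivors pass through unchanged.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    keep_idx, flags = [], table.flags.copy()
    removed_rows = []
    for seq in table.counts.index:
        if set(seq) - set("ACGT"):
            flags.loc[seq] = REMOVED_AMBIGUOUS
        elif (len(seq) - expected_len) % 3 != 0:
            flags.loc[seq] = REMOVED_FRAMESHIFT
        elif "*" in _translate(seq, frame, genetic_code):
            flags.loc[seq] = REMOVED_STOP_CODON
        else:
            keep_idx.append(seq)
            continue
        removed_rows.append(seq)
    removed = pd.concat([table.removed, table.counts.loc[removed_rows]]) if removed_rows else table.removed
    return HaplotypeTable(table.counts.loc[keep_idx], flags, removed)
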