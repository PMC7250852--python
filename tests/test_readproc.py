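"""Quality filter, demultiplexing, length filter, dereplication, translation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from antdiet.io import Read
from antdiet.readproc import (
    PASSED,
    REMOVED_AMBIGUOUS,
    REMOVED_FRAMESHIFT,
    REMOVED_SINGLETON,
    REMOVED_STOP_CODON,
    choose_frame,
    demultiplex,
    dereplicate,
    length_filter,
    quality_filter,
    translation_filter,
)
from antdiet.simulate import revcomp


def _read(seq, q, rid="r1"):
    qual = np.full(len(seq), q, dtype=np.int16) if np.isscalar(q) else np.asarray(q)
    return Read(rid, seq, qual)


class TestQualityFilter:
    def test_boundary_inclusive(self):
        kept, gone = quality_filter([_read("ACGT" * 10, 20)], 20)
        assert len(kept) == 1 and not gone

    def test_mean_below_threshold_discarded(self):
        # mean 19.9: nine bases at 20, one at 19.0... use explicit values
        quals = [20] * 9 + [19]
        kept, gone = quality_filter([_read("A" * 10, quals)], 20)
        assert not kept and len(gone) == 1

    def test_brute_force_recount(self):
        rng = np.random.default_rng(8)
        reads = [
            _read("ACGT" * 5, rng.integers(5, 40, size=20), rid=f"r{i}")
            for i in range(1000)
        ]
        kept, gone = quality_filter(reads, 20)
        expected = sum(np.mean(r.qual) >= 20 for r in reads)
        assert len(kept) == expected
        assert len(kept) + len(gone) == 1000

    def test_empty_input_ok(self):
        assert quality_filter([], 20) == ([], [])

    def test_malformed_quality_names_read(self):
        bad = Read("oops", "ACGT", np.array([30, 30]))
        with pytest.raises(ValueError, match="oops"):
            quality_filter([bad], 20)

    def test_fraction_mode(self):
        r = _read("A" * 10, [30] * 9 + [2])
        kept, _ = quality_filter([r], 20, mode="fraction", min_fraction=0.9)
        assert kept
        kept, _ = quality_filter([r], 20, mode="fraction", min_fraction=0.95)
        assert not kept


F1, R1 = "ACACACACAC", "GTGTGTGTGT"
MAP = {(F1, R1): "spider_01"}


def _tagged(amp, fmid=F1, rmid=R1, rid="r1"):
    seq = fmid + amp + revcomp(rmid)
    return _read(seq, 30, rid=rid)


class TestDemultiplex:
    def test_exact_match_assigns_and_strips(self):
        amp = "ACGTACGTACGT"
        by_sample, un = demultiplex([_tagged(amp)], MAP)
        assert not un
        (read,) = by_sample["spider_01"]
        assert read.seq == amp
        assert len(read.qual) == len(amp)

    def test_one_mismatch_unassigned(self):
        bad = "T" + F1[1:]
        _, un = demultiplex([_tagged("ACGT" * 3, fmid=bad)], MAP)
        assert len(un) == 1

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            demultiplex([], {(F1, R1): "a", (F1, R1.lower()): "a"})

    def test_counts_match_simulator_ground_truth(self, noiseless_run):
        readset, truth, mid_map = noiseless_run
        by_sample, un = demultiplex(readset.reads, mid_map)
        assert not un
        expected = truth.groupby("true_sample").size()
        for sample, reads in by_sample.items():
            assert len(reads) == expected[sample]

    def test_conservation(self, noiseless_run):
        readset, _, mid_map = noiseless_run
        by_sample, un = demultiplex(readset.reads, mid_map)
        assert sum(map(len, by_sample.values())) + len(un) == len(readset.reads)


class TestLengthFilter:
    @pytest.mark.parametrize(
        "length,expected,tol,kept",
        [(131, 131, 13, True), (117, 131, 13, False), (144, 131, 13, True),
         (145, 131, 13, False)],
    )
    def test_window(self, length, expected, tol, kept):
        retained, discarded = length_filter([_read("A" * length, 30)], expected, tol)
        assert bool(retained) is kept
        assert len(retained) + len(discarded) == 1

    def test_default_tolerance_is_ten_percent(self):
        kept, _ = length_filter([_read("A" * 118, 30)], 131)
        assert kept  # |118-131| = 13 = round(0.1*131)

    def test_brute_force_recount(self):
        rng = np.random.default_rng(3)
        reads = [_read("A" * int(n), 30, rid=f"r{i}")
                 for i, n in enumerate(rng.integers(100, 160, size=500))]
        kept, gone = length_filter(reads, 131, 13)
        assert len(kept) == sum(abs(len(r.seq) - 131) <= 13 for r in reads)
        assert len(kept) + len(gone) == 500


class TestDereplicate:
    def test_collapse_and_retain(self):
        reads = {"s1": [_read("ACGT", 30, rid=f"r{i}") for i in range(5)]}
        table = dereplicate(reads)
        assert table.counts.loc["ACGT", "s1"] == 5
        assert table.flags.loc["ACGT"] == PASSED

    def test_singleton_removed(self):
        table = dereplicate({"s1": [_read("ACGT", 30)]})
        assert table.counts.empty
        assert table.flags.loc["ACGT"] == REMOVED_SINGLETON
        assert table.removed.loc["ACGT", "s1"] == 1

    def test_per_sample_vs_total_mode(self):
        reads = {
            "s1": [_read("ACGT", 30, rid="a")],
            "s2": [_read("ACGT", 30, rid="b")],
        }
        per_sample = dereplicate(reads, per_sample=True)
        assert per_sample.counts.empty  # 1 read in each file: both removed
        total = dereplicate(reads, per_sample=False)
        assert total.counts.loc["ACGT"].sum() == 2

    def test_hash_group_oracle(self):
        rng = np.random.default_rng(12)
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(400)]
        reads = {
            "s1": [_read(s, 30, rid=f"a{i}") for i, s in enumerate(seqs[:200])],
            "s2": [_read(s, 30, rid=f"b{i}") for i, s in enumerate(seqs[200:])],
        }
        table = dereplicate(reads, min_reads=1)  # no removal: pure collapse
        from collections import Counter

        for sample, sample_reads in reads.items():
            expected = Counter(r.seq for r in sample_reads)
            got = table.counts[sample]
            assert {s: c for s, c in got.items() if c} == dict(expected)

    def test_read_conservation(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(300)]
        reads = {"s1": [_read(s, 30, rid=f"r{i}") for i, s in enumerate(seqs)]}
        table = dereplicate(reads, min_reads=2)
        assert int(table.counts.sum().sum() + table.removed.sum().sum()) == 300


class TestTranslationFilter:
    def _table(self, seqs):
        counts = pd.DataFrame({"s1": [5] * len(seqs)}, index=seqs)
        flags = pd.Series(PASSED, index=counts.index, dtype=object)
        from antdiet.readproc import HaplotypeTable

        return HaplotypeTable(counts, flags, pd.DataFrame(columns=["s1"]))

    def test_in_frame_stop_removed(self):
        # frame 0: TAA right at the start is an in-frame stop (invertebrate
        # mitochondrial code keeps TGA/AGA/AGG coding, TAA/TAG terminate)
        seq = "TAA" + "GCT" * 42 + "GC"  # 131-mer
        out = translation_filter(self._table([seq]), 131, frame=0)
        assert out.flags.loc[seq] == REMOVED_STOP_CODON
        assert seq not in out.counts.index

    def test_tga_is_not_a_stop(self):
        seq = "TGA" + "GCT" * 42 + "GC"  # TGA = Trp in the invertebrate code
        out = translation_filter(self._table([seq]), 131, frame=0)
        assert out.flags.loc[seq] == PASSED

    def test_frameshift_length_removed(self):
        seq = "GCT" * 43 + "G"  # 130 bases vs expected 131: offset 1 % 3 != 0
        out = translation_filter(self._table([seq]), 131, frame=0)
        assert out.flags.loc[seq] == REMOVED_FRAMESHIFT

    def test_inframe_length_offset_kept(self):
        seq = "GCT" * 43 + "GCTGC"  # 134 = 131 + 3
        out = translation_filter(self._table([seq]), 131, frame=0)
        assert out.flags.loc[seq] == PASSED

    def test_ambiguous_base_flagged_not_crash(self):
        seq = "GCN" + "GCT" * 42 + "GC"
        out = translation_filter(self._table([seq]), 131, frame=0)
        assert out.flags.loc[seq] == REMOVED_AMBIGUOUS

    def test_clean_references_all_pass(self, tiny_library):
        amps = [t.seq_short for t in tiny_library]
        frame = choose_frame(amps)
        out = translation_filter(self._table(amps), 131, frame)
        assert (out.flags == PASSED).all()

    def test_read_conservation(self):
        seqs = ["TAA" + "GCT" * 42 + "GC", "GCT" * 43 + "GC"]
        table = self._table(seqs)
        before = int(table.counts.sum().sum())
        out = translation_filter(table, 131, frame=0)
        assert int(out.counts.sum().sum() + out.removed.sum().sum()) == before


class TestChooseFrame:
    def test_recovers_designated_frame(self, tiny_library):
        assert choose_frame([t.seq_short for t in tiny_library]) == 1
        assert choose_frame([t.seq_long for t in tiny_library]) == 2

    def test_tie_breaks_to_smallest(self):
        assert choose_frame(["GCTGCTGCTGCT"]) == 0  # stop-free in all frames

    def test_exhaustive_agreement(self):
        """Brute-force: the returned frame maximises the stop-free fraction."""
        from antdiet.readproc import _translate

        rng = np.random.default_rng(21)
        for _ in range(20):
            refs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
            fracs = [
                np.mean(["*" not in _translate(s, f, 5) for s in refs])
                for f in range(3)
            ]
            assert choose_frame(refs) == int(np.argmax(fracs))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            choose_frame([])


def test_quality_and_demultiplex_commute(noiseless_run):
    """On reads with exact MIDs the two filters can run in either order."""
    readset, _, mid_map = noiseless_run
    reads = readset.reads
    q_then_d, _ = quality_filter(reads, 20)
    by_sample_a, _ = demultiplex(q_then_d, mid_map)
    by_sample_b_raw, _ = demultiplex(reads, mid_map)
    by_sample_b = {
        s: quality_filter(rs, 20)[0] for s, rs in by_sample_b_raw.items()
    }
    for sample in by_sample_a:
        assert [r.id for r in by_sample_a[sample]] == [r.id for r in by_sample_b[sample]]
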