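"""Rare-MOTU cut-off filtering at global and individual level."""

import numpy as np
import pandas as pd
import pytest

from antdiet.cluster import MOTU, MOTUTable
from antdiet.sweep import (
    CutoffSweepResult,
    apply_global_cutoff,
    apply_individual_cutoff,
    eligible_individuals,
    run_sweep,
    select_threshold,
)
from antdiet.taxonomy import TaxonAssignment


def table_from_frame(frame: pd.DataFrame) -> MOTUTable:
    motus = [
        MOTU(mid, f"SEQ_{mid}", [f"SEQ_{mid}"], frame.loc[mid])
        for mid in frame.index
    ]
    return MOTUTable(motus, list(frame.columns), "ant_specific", 4)


def genus_assignments(frame, genus_of=None):
    out = {}
    for mid in frame.index:
        genus = (genus_of or {}).get(mid, f"Genus_{mid}")
        out[mid] = TaxonAssignment(
            mid, [], "genus", genus, best_identity=95.0, role="prey",
            lineage=("Animalia", "Hymenoptera", "Formicidae", "Formicinae",
                     genus, ""),
        )
    return out


class TestGlobalCutoff:
    def test_strict_less_than_boundary(self):
        """m = 0.005 % of 1,000,000 = 50: a 49-read MOTU goes, 50 stays."""
        frame = pd.DataFrame(
            {"s1": [49, 50, 999_901]}, index=["m1", "m2", "m3"]
        )
        table = table_from_frame(frame)
        assert table.total_reads == 1_000_000
        filtered, removed = apply_global_cutoff(table, 0.005)
        assert [m.id for m in filtered.motus] == ["m2", "m3"]
        assert list(removed.index) == ["m1"]

    def test_zero_threshold_identity(self):
        frame = pd.DataFrame({"s1": [1, 2, 3]}, index=["a", "b", "c"])
        filtered, removed = apply_global_cutoff(table_from_frame(frame), 0.0)
        assert len(filtered) == 3 and removed.empty

    def test_brute_force_recount(self):
        rng = np.random.default_rng(4)
        frame = pd.DataFrame(
            rng.integers(0, 200, size=(40, 6)),
            index=[f"m{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(6)],
        )
        table = table_from_frame(frame)
        t = 0.8
        filtered, _ = apply_global_cutoff(table, t)
        minimum = t / 100 * frame.to_numpy().sum()
        expected = {mid for mid in frame.index if frame.loc[mid].sum() >= minimum}
        assert {m.id for m in filtered.motus} == expected

    def test_custom_total_denominator(self):
        frame = pd.DataFrame({"s1": [5, 95]}, index=["a", "b"])
        filtered, _ = apply_global_cutoff(table_from_frame(frame), 1.0, total_valid=1000)
        assert {m.id for m in filtered.motus} == {"b"}  # min 10 reads


class TestIndividualCutoff:
    def test_per_sample_minimum_arithmetic(self):
        """0.5 % of a 10,000-read individual -> 50-read per-cell minimum."""
        frame = pd.DataFrame(
            {"s1": [49, 50, 9_901], "s2": [100, 0, 0]},
            index=["m1", "m2", "m3"],
        )
        filtered, log = apply_individual_cutoff(table_from_frame(frame), 0.5)
        got = filtered.to_frame()
        assert got.loc["m1", "s1"] == 0  # 49 < 50
        assert got.loc["m1", "s2"] == 100  # 100 >= 0.5 % of 100
        assert got.loc["m2", "s1"] == 50
        assert {(r["motu_id"], r["sample"]) for r in log.to_dict("records")} == {("m1", "s1")}

    def test_zero_threshold_identity(self):
        frame = pd.DataFrame({"s1": [1, 5]}, index=["a", "b"])
        filtered, _ = apply_individual_cutoff(table_from_frame(frame), 0.0)
        pd.testing.assert_frame_equal(filtered.to_frame(), frame)

    def test_v_s_computed_before_filtering(self):
        # one dominant and one rare MOTU: the rare cell is judged against the
        # sample's FULL yield, not the post-removal yield
        frame = pd.DataFrame({"s1": [4, 996]}, index=["rare", "big"])
        filtered, _ = apply_individual_cutoff(table_from_frame(frame), 0.5)
        assert "rare" not in filtered.to_frame().index  # 4 < 5 = 0.5 % of 1000

    def test_brute_force_recount(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame(
            rng.integers(0, 100, size=(30, 5)),
            index=[f"m{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(5)],
        )
        t = 2.0
        filtered, _ = apply_individual_cutoff(table_from_frame(frame), t)
        expected = frame.copy()
        for s in frame.columns:
            minimum = t / 100 * frame[s].sum()
            expected.loc[frame[s] < minimum, s] = 0
        expected = expected[expected.sum(axis=1) > 0]
        pd.testing.assert_frame_equal(filtered.to_frame(), expected)

    def test_monotone_nesting(self):
        rng = np.random.default_rng(2)
        frame = pd.DataFrame(
            rng.integers(0, 50, size=(20, 4)),
            index=[f"m{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(4)],
        )
        table = table_from_frame(frame)
        prev_g = prev_i = None
        for t in (0.0, 0.5, 1.0, 2.0, 5.0):
            g, _ = apply_global_cutoff(table, t)
            i, _ = apply_individual_cutoff(table, t)
            ids_g = {m.id for m in g.motus}
            ids_i = {m.id for m in i.motus}
            if prev_g is not None:
                assert ids_g <= prev_g and ids_i <= prev_i
                # no cell ever increases
                cur = i.to_frame().reindex(index=frame.index, columns=frame.columns).fillna(0)
                assert (cur.to_numpy() <= frame.to_numpy()).all()
            prev_g, prev_i = ids_g, ids_i


class TestRunSweep:
    def test_single_genus_flat_zero_indices(self):
        frame = pd.DataFrame({"s1": [100], "s2": [80]}, index=["m1"])
        table = table_from_frame(frame)
        res = run_sweep(table, genus_assignments(frame), (0.0, 0.01, 0.02), "global")
        assert (res.records["levins"] == 0).all()  # B_A = 0 for one category
        assert (res.records["shannon"] == 0).all()
        assert (res.records["n_motus"] == 1).all()

    def test_all_above_largest_threshold_flat(self):
        frame = pd.DataFrame(
            {"s1": [500, 400], "s2": [300, 200]}, index=["m1", "m2"]
        )
        table = table_from_frame(frame)
        res = run_sweep(table, genus_assignments(frame), (0.0, 0.5, 1.0), "global")
        assert res.records["n_motus"].nunique() == 1
        assert res.records["levins"].nunique() == 1
        assert res.records["shannon"].nunique() == 1

    def test_noise_motus_drop_then_flatten(self):
        """1-4-read noise MOTUs vanish in the first step of the sweep; the
        curve is steepest before the 5-read-equivalent threshold."""
        rng = np.random.default_rng(6)
        n_noise = 40
        noise = pd.DataFrame(
            {"s1": rng.integers(1, 5, size=n_noise), "s2": 0},
            index=[f"noise{i}" for i in range(n_noise)],
        )
        real = pd.DataFrame(
            {"s1": [400_000, 300_000], "s2": [200_000, 99_900]},
            index=["real1", "real2"],
        )
        frame = pd.concat([real, noise])
        frame["s2"] = frame["s2"].astype(int)
        table = table_from_frame(frame)
        total = table.total_reads
        five_read_t = 100 * 5 / total
        thresholds = (0.0, five_read_t, 0.001, 0.002, 0.005, 0.01)
        res = run_sweep(table, genus_assignments(frame), thresholds, "global")
        drops = -np.diff(res.records["n_motus"].to_numpy())
        assert drops[0] == max(drops)
        assert drops[0] >= n_noise * 0.9
        assert (drops[1:] <= 1).all()

    def test_thresholds_must_increase(self):
        frame = pd.DataFrame({"s1": [10]}, index=["m1"])
        with pytest.raises(ValueError, match="strictly increasing"):
            run_sweep(table_from_frame(frame), genus_assignments(frame),
                      (0.0, 0.0, 0.1), "global")

    def test_empty_post_filter_undefined_not_crash(self):
        frame = pd.DataFrame({"s1": [2, 3]}, index=["m1", "m2"])
        table = table_from_frame(frame)
        res = run_sweep(table, genus_assignments(frame), (0.0, 50.0, 90.0), "global")
        last = res.records.iloc[-1]
        assert last["n_motus"] == 0
        assert np.isnan(last["levins"]) and np.isnan(last["shannon"])


class TestSelectThreshold:
    def _result(self, levins, shannon, thresholds=None):
        n = len(levins)
        thresholds = thresholds or [0.001 * (i + 1) for i in range(n)]
        rec = pd.DataFrame(
            {"threshold": thresholds, "n_motus": range(n, 0, -1),
             "n_prey_genera": 3, "levins": levins, "shannon": shannon}
        )
        return CutoffSweepResult("global", rec)

    def test_plateau_selects_largest_stable_end(self):
        """Indices constant over 0.001-0.005 then diverging -> 0.005."""
        thresholds = [0.0, 0.0002, 0.0005, 0.001, 0.002, 0.003, 0.004, 0.005,
                      0.006, 0.007]
        lev = [0.9, 0.7, 0.5, 0.4, 0.4, 0.4, 0.4, 0.4, 0.3, 0.2]
        sha = [1.9, 1.7, 1.5, 1.4, 1.4, 1.4, 1.4, 1.4, 1.2, 1.0]
        res = self._result(lev, sha, thresholds)
        t, fallback = select_threshold(res, epsilon=1e-6, window=3)
        assert t == 0.005 and not fallback

    def test_strictly_monotone_takes_fallback(self):
        lev = [0.9, 0.8, 0.7, 0.6, 0.5]
        sha = [2.0, 1.8, 1.6, 1.4, 1.2]
        _, fallback = select_threshold(self._result(lev, sha), epsilon=0.0)
        assert fallback

    def test_exhaustive_window_scan_agreement(self):
        """Brute-force scan over all windows agrees with the implementation."""
        rng = np.random.default_rng(13)
        for trial in range(25):
            n = 9
            lev = np.round(rng.random(n), 2)
            sha = np.round(rng.random(n) * 2, 2)
            # inject a plateau of random width at a random position
            w = int(rng.integers(3, 6))
            start = int(rng.integers(0, n - w + 1))
            lev[start : start + w] = lev[start]
            sha[start : start + w] = sha[start]
            res = self._result(list(lev), list(sha))
            eps, window = 1e-9, 3
            stable_ends = [
                end for end in range(window - 1, n)
                if all(
                    abs(lev[i + 1] - lev[i]) <= eps and abs(sha[i + 1] - sha[i]) <= eps
                    for i in range(end - window + 1, end)
                )
            ]
            got, fallback = select_threshold(res, epsilon=eps, window=window)
            if stable_ends:
                assert not fallback
                assert got == res.records["threshold"].iloc[max(stable_ends)]
            else:
                assert fallback

    def test_too_few_thresholds(self):
        with pytest.raises(ValueError):
            select_threshold(self._result([0.1, 0.2], [1, 2]))


def test_eligible_individuals_more_than_five_motus():
    rng = np.random.default_rng(3)
    frame = pd.DataFrame(
        {"rich": [10] * 8 + [0] * 2, "poor": [10] * 3 + [0] * 7},
        index=[f"m{i}" for i in range(10)],
    )
    assert eligible_individuals(table_from_frame(frame)) == ["rich"]
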