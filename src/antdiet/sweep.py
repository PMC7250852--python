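"""Rare-MOTU cut-off sweeps at two levels, with stability-based selection.

Rare MOTUs are mostly erroneous (sequencing errors, chimeras, tag jumps,
cross-contamination), so the pipeline removes MOTUs below a *relative*
abundance threshold and asks where the diversity indices stop changing:

* global level — thresholds expressed as a percentage of the run's total
  valid reads; a MOTU whose total count falls below the implied minimum is
  removed entirely ("contained less sequences than" the cut-off, so a count
  exactly at the minimum survives);
* individual level — thresholds as a percentage of each sample's valid
  reads (computed before filtering); cells below the per-sample minimum are
  zeroed and all-zero MOTUs dropped.

The default grids are the ones swept in the source protocol (0-0.01 % of
total reads; 0-1 % per individual); the suggested operating points are
0.005 % globally and 0.5 % per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import MOTU, MOTUTable
from .niche import IncidenceMatrix, levins_index, prey_category, shannon_index
from .taxonomy import TaxonAssignment

GLOBAL_THRESHOLDS = (
    0.0, 0.0002, 0.0005, 0.001, 0.002, 0.003, 0.004,
    0.005, 0.006, 0.007, 0.008, 0.009, 0.01,
)
INDIVIDUAL_THRESHOLDS = (0.0, 0.01, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_GLOBAL_CUTOFF = 0.005
DEFAULT_INDIVIDUAL_CUTOFF = 0.5
MIN_MOTUS_PER_INDIVIDUAL = 5  # sweep eligibility: individuals with > 5 MOTUs


def _rebuild(table: MOTUTable, frame: pd.DataFrame) -> MOTUTable:
    by_id = {m.id: m for m in table.motus}
    motus = []
    for motu_id in frame.index:
        old = by_id[motu_id]
        motus.append(
            MOTU(motu_id, old.representative, old.members, frame.loc[motu_id])
        )
    return MOTUTable(motus, table.samples, table.primer_set, table.d)


def apply_global_cutoff(
    table: MOTUTable, t_percent: float, total_valid: int | None = None
) -> tuple[MOTUTable, pd.DataFrame]:
    """Remove MOTUs with fewer total reads than t_percent of the run total.

    ``total_valid`` defaults to the table's own read total (valid reads of
    that primer set's run); pass a different denominator to restrict it to
    prey-assigned reads.  Returns the filtered table and a removal log.
    """
    if t_percent < 0:
        raise ValueError("t_percent must be >= 0")
    frame = table.to_frame()
    total = table.total_reads if total_valid is None else int(total_valid)
    minimum = t_percent / 100.0 * total
    totals = frame.sum(axis=1)
    keep = totals >= minimum  # strict less-than removal
    removed = pd.DataFrame(
        {"reads": totals[~keep], "threshold_pct": t_percent, "min_reads": minimum}
    )
    return _rebuild(table, frame[keep]), removed


def apply_individual_cutoff(
    table: MOTUTable, t_percent: float
) -> tuple[MOTUTable, pd.DataFrame]:
    """Zero MOTU x sample cells below t_percent of that sample's valid reads.

    Per-sample valid totals are computed on the *pre-filter* table (the
    sample's sequencing yield).  MOTUs left with all-zero rows are dropped.
    """
    if t_percent < 0:
        raise ValueError("t_percent must be >= 0")
    frame = table.to_frame()
    if frame.empty:
        return _rebuild(table, frame), pd.DataFrame(columns=["motu_id", "sample", "reads"])
    v_s = frame.sum(axis=0)  # per-sample valid reads, before filtering
    minima = t_percent / 100.0 * v_s
    zeroed = frame.lt(minima, axis=1) & (frame > 0)
    log_rows = [
        {"motu_id": frame.index[ri], "sample": frame.columns[ci], "reads": int(frame.iat[ri, ci])}
        for ri, ci in zip(*np.nonzero(zeroed.to_numpy()))
    ]
    filtered = frame.where(~zeroed, 0)
    filtered = filtered[filtered.sum(axis=1) > 0]
    return _rebuild(table, filtered), pd.DataFrame(
        log_rows, columns=["motu_id", "sample", "reads"]
    )


@dataclass
class CutoffSweepResult:
    """Per-threshold MOTU counts and genus-level diversity indices."""

    level: str  # "global" | "individual"
    records: pd.DataFrame  # threshold, n_motus, n_prey_genera, levins, shannon
    selected_threshold: float | None = None
    fallback_used: bool = False

    @property
    def thresholds(self) -> list[float]:
        return list(self.records["threshold"])


def _prey_genus_indices(
    table: MOTUTable,
    assignments: Mapping[str, TaxonAssignment],
    n_categories: int | None,
) -> tuple[int, int, float, float]:
    """(n_motus, n_prey_genera, B_A, H) for one filtered table."""
    frame = table.to_frame()
    prey_ids = [
        m for m in frame.index
        if m in assignments and prey_category(assignments[m]) is not None
    ]
    n_motus = len(prey_ids)
    if not prey_ids:
        return 0, 0, float("nan"), float("nan")
    cats: dict[str, list[str]] = {}
    genera = set()
    for motu_id in prey_ids:
        asg = assignments[motu_id]
        cat = prey_category(asg)
        cats.setdefault(cat, []).append(motu_id)
        if asg.assigned_rank in ("species", "genus"):
            genera.add(cat)
    positives = pd.Series(
        {
            cat: int((frame.loc[ids].sum(axis=0) > 0).sum())
            for cat, ids in cats.items()
        }
    ).sort_index()
    positives = positives[positives > 0]
    if positives.empty:
        return n_motus, len(genera), float("nan"), float("nan")
    p = (positives / positives.sum()).to_numpy()
    h = shannon_index(p)
    n_cat = len(positives) if n_categories is None else n_categories
    if n_cat < 2:
        return n_motus, len(genera), float("nan"), h
    _, b_a = levins_index(p, n_cat)
    return n_motus, len(genera), b_a, h


def run_sweep(
    table: MOTUTable,
    assignments: Mapping[str, TaxonAssignment],
    thresholds: Sequence[float] | None = None,
    level: str = "global",
    total_valid: int | None = None,
    fixed_n_categories: bool = True,
) -> CutoffSweepResult:
    """Apply each cut-off threshold in turn and record MOTU counts and
    genus-level diversity indices.

    With ``fixed_n_categories`` (default) the Levins' denominator ``n`` is
    the category count of the unfiltered table, held constant so B_A values
    are comparable along the sweep; otherwise n follows the detected
    categories at each threshold.
    """
    if level not in ("global", "individual"):
        raise ValueError("level must be 'global' or 'individual'")
    if thresholds is None:
        thresholds = GLOBAL_THRESHOLDS if level == "global" else INDIVIDUAL_THRESHOLDS
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")

    n_fixed: int | None = None
    if fixed_n_categories:
        base_cats = {
            prey_category(assignments[m.id])
            for m in table.motus
            if m.id in assignments and prey_category(assignments[m.id]) is not None
        }
        n_fixed = max(len(base_cats), 2)

    rows = []
    for t in thresholds:
        if level == "global":
            filtered, _ = apply_global_cutoff(table, t, total_valid=total_valid)
        else:
            filtered, _ = apply_individual_cutoff(table, t)
        n_motus, n_genera, b_a, h = _prey_genus_indices(filtered, assignments, n_fixed)
        rows.append(
            {
                "threshold": t,
                "n_motus": n_motus,
                "n_prey_genera": n_genera,
                "levins": b_a,
                "shannon": h,
            }
        )
    records = pd.DataFrame(rows)
    result = CutoffSweepResult(level, records)
    if len(records) >= 3:
        result.selected_threshold, result.fallback_used = select_threshold(result)
    return result


def eligible_individuals(
    table: MOTUTable, min_motus: int = MIN_MOTUS_PER_INDIVIDUAL
) -> list[str]:
    """Samples with more than ``min_motus`` MOTUs (individual-sweep entry)."""
    frame = table.to_frame()
    if frame.empty:
        return []
    per_sample = (frame > 0).sum(axis=0)
    return sorted(per_sample.index[per_sample > min_motus])


def select_threshold(
    sweep: CutoffSweepResult, epsilon: float = 1e-6, window: int = 3
) -> tuple[float, bool]:
    """Largest threshold ending a stability window of both indices.

    Scans windows of ``window`` consecutive thresholds; within a window
    every adjacent change of both B_A and H must be <= epsilon (absolute).
    Returns (threshold, fallback_used); if no window is stable the
    threshold minimising the summed adjacent index change is returned with
    the fallback flag set.
    """
    rec = sweep.records
    if len(rec) < 3:
        raise ValueError("need at least 3 thresholds to select one")
    if window < 2 or window > len(rec):
        raise ValueError("window must be in [2, n_thresholds]")
    lev = rec["levins"].to_numpy()
    sha = rec["shannon"].to_numpy()
    d_lev = np.abs(np.diff(lev))
    d_sha = np.abs(np.diff(sha))
    best = None
    for end in range(window - 1, len(rec)):
        span = slice(end - window + 1, end)  # adjacent diffs inside window
        if np.all(d_lev[span] <= epsilon) and np.all(d_sha[span] <= epsilon):
            best = float(rec["threshold"].iloc[end])
    if best is not None:
        return best, False
    # fallback: threshold whose neighbourhood changes least
    change = np.nansum([d_lev, d_sha], axis=0)
    total = np.convolve(change, np.ones(window - 1), mode="valid")
    end = int(np.nanargmin(total)) + window - 1
    return float(rec["threshold"].iloc[end]), True


def write_sweep(results: Sequence[CutoffSweepResult], path) -> None:
    from .io import write_tsv

    rows = []
    for res in results:
        for rec in res.records.to_dict("records"):
            rows.append({"level": res.level, **rec})
    write_tsv(
        rows, path,
        ["level", "threshold", "n_motus", "n_prey_genera", "levins", "shannon"],
    )
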