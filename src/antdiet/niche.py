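"""Trophic-niche breadth from incidence data and acceptance trials.

Realised niche: filtered, taxonomically assigned MOTU tables are converted
to binary incidence (which predator individuals carry DNA of which prey
category — ant genera at genus level, other prey at order level), and
breadth is computed on the normalised positive-individual proportions:

* Levins' measure ``B = 1 / sum(p_i^2)`` with standardised form
  ``B_A = (B - 1) / (n - 1)`` in [0, 1];
* Shannon index ``H = -sum(p_i ln p_i)`` (natural log), in [0, ln n].

Fundamental niche: laboratory acceptance trials (each prey type offered to
each predator individual at most once) are summarised per prey type, each
type's acceptance frequency is compared against the overall mean acceptance
with an exact two-sided binomial test, and B_A is computed over pooled
categories (all ants merged into one), mirroring how such experiments are
analysed in the feeding-specialisation literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import MOTUTable
from .taxonomy import TaxonAssignment

ANT_FAMILY = "Formicidae"
RARE_PREY_FRACTION = 0.05


def prey_category(assignment: TaxonAssignment, ant_family: str = ANT_FAMILY) -> str | None:
    """Prey category label for incidence: ant genera, other prey by order.

    Returns None for predator-assigned or off-target MOTUs (not prey).
    """
    if assignment.excluded_offtarget or assignment.role != "prey":
        return None
    lineage = assignment.lineage
    family = lineage[2] if lineage else ""
    if family == ant_family:
        if assignment.assigned_rank in ("species", "genus"):
            return lineage[4]  # genus
        return assignment.assigned_name  # e.g. unresolved "Formicidae"
    if assignment.assigned_rank in ("species", "genus", "family") and lineage:
        return lineage[1]  # order
    return assignment.assigned_name


@dataclass
class IncidenceMatrix:
    """Binary individuals x prey-category matrix."""

    matrix: pd.DataFrame  # 0/1 entries

    @property
    def individuals(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def categories(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_categories(self) -> int:
        return self.matrix.shape[1]

    def positive_counts(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    def proportions(self) -> pd.Series:
        """Normalised positive counts (sum to 1 over detected categories)."""
        counts = self.positive_counts()
        total = counts.sum()
        if total == 0:
            raise ValueError("no positive cells: proportions undefined")
        return counts / total


def to_incidence(
    table: MOTUTable,
    assignments: Mapping[str, TaxonAssignment],
    ant_family: str = ANT_FAMILY,
) -> IncidenceMatrix:
    """Binary conversion: individual x prey category, 1 iff any reads survive."""
    counts = table.to_frame()  # MOTU x sample
    cats: dict[str, list[str]] = {}
    for motu_id in counts.index:
        asg = assignments.get(motu_id)
        if asg is None:
            continue
        cat = prey_category(asg, ant_family)
        if cat is not None:
            cats.setdefault(cat, []).append(motu_id)
    data = {
        cat: (counts.loc[motus].sum(axis=0) > 0).astype(int)
        for cat, motus in sorted(cats.items())
    }
    matrix = pd.DataFrame(data, index=counts.columns, dtype=int)
    if matrix.empty:
        matrix = pd.DataFrame(index=list(counts.columns), dtype=int)
    return IncidenceMatrix(matrix)


def levins_index(p: Sequence[float], n: int) -> tuple[float, float]:
    """Levins' niche breadth B = 1/sum(p^2) and standardised B_A = (B-1)/(n-1).

    ``p`` must be proportions summing to 1 over the detected categories;
    ``n`` is the number of possible categories (>= 2, else undefined).
    """
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-8:
        raise ValueError(f"proportions sum to {arr.sum()}, expected 1")
    if n < 2:
        raise ValueError("standardised Levins' index undefined for n < 2")
    b = 1.0 / float((arr**2).sum())
    return b, (b - 1.0) / (n - 1.0)


def shannon_index(p: Sequence[float]) -> float:
    """Shannon diversity H = -sum(p ln p), with 0 ln 0 = 0."""
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any():
        raise ValueError("proportions must be non-negative")
    if abs(arr.sum() - 1.0) > 1e-8:
        raise ValueError(f"proportions sum to {arr.sum()}, expected 1")
    nz = arr[arr > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class NicheProfile:
    """Niche-breadth summary for one predator species."""

    proportions: pd.Series
    B: float | None
    B_A: float | None
    H: float | None
    n: int


def niche_profile(incidence: IncidenceMatrix, n: int | None = None) -> NicheProfile:
    """Indices from an incidence matrix; undefined values are None, never 0.

    ``n`` overrides the category count (e.g. to hold the denominator fixed
    across cut-off treatments); default is the number of detected
    categories.
    """
    if incidence.n_categories == 0 or incidence.positive_counts().sum() == 0:
        return NicheProfile(pd.Series(dtype=float), None, None, None, 0)
    p = incidence.proportions()
    n_cat = incidence.n_categories if n is None else n
    h = shannon_index(p.to_numpy())
    if n_cat < 2:
        return NicheProfile(p, None, None, h, n_cat)
    b, b_a = levins_index(p.to_numpy(), n_cat)
    return NicheProfile(p, b, b_a, h, n_cat)


def flag_rare_prey(
    incidence: IncidenceMatrix, threshold_fraction: float = RARE_PREY_FRACTION
) -> list[str]:
    """Prey categories found in fewer than ``threshold_fraction`` of the
    studied predators (default 5 %) — too rare to matter as a food source."""
    if not 0.0 <= threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in [0, 1]")
    n_ind = len(incidence.individuals)
    if n_ind == 0:
        return []
    frac = incidence.positive_counts() / n_ind
    return sorted(frac.index[frac < threshold_fraction])


# ---------------------------------------------------------------------------
# fundamental niche: acceptance trials
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ("individual", "prey_type", "offered", "accepted", "category")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check acceptance-trial invariants; returns the offered subset."""
    missing = set(TRIAL_COLUMNS[:4]) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    if (trials["accepted"].astype(bool) & ~trials["offered"].astype(bool)).any():
        raise ValueError("a prey type cannot be accepted without being offered")
    offered = trials[trials["offered"].astype(bool)]
    dup = offered.duplicated(subset=["individual", "prey_type"])
    if dup.any():
        raise ValueError("each prey type may be offered to an individual only once")
    return offered


@dataclass
class AcceptanceResult:
    per_prey: pd.DataFrame  # prey_type, n_offered, n_accepted, acceptance, p_value, direction
    overall_mean: float
    B: float | None
    B_A: float | None
    n_pooled: int


def acceptance_analysis(trials: pd.DataFrame, alpha: float = 0.05) -> AcceptanceResult:
    """Fundamental-niche statistics from laboratory acceptance trials.

    Per prey type: acceptance frequency and an exact two-sided binomial test
    of k acceptances in n offers against the overall mean acceptance as the
    null probability.  B_A is computed over pooled categories (column
    ``category``; all ant species are pooled into one category so prey
    categorisation is homogeneous), on renormalised acceptance proportions.
    """
    offered = validate_trials(trials)
    if offered.empty:
        raise ValueError("no offered trials to analyse")
    if "category" not in offered.columns:
        offered = offered.assign(category=offered["prey_type"])
    overall = float(offered["accepted"].astype(bool).mean())

    rows = []
    for prey, grp in offered.groupby("prey_type", sort=True):
        n, k = len(grp), int(grp["accepted"].astype(bool).sum())
        if n == 0:
            continue
        pval = stats.binomtest(k, n, overall, alternative="two-sided").pvalue
        direction = "average"
        if pval < alpha:
            direction = "above" if k / n > overall else "below"
        rows.append(
            {
                "prey_type": prey,
                "n_offered": n,
                "n_accepted": k,
                "acceptance": k / n,
                "p_value": float(pval),
                "direction": direction,
            }
        )
    per_prey = pd.DataFrame(rows)

    pooled = offered.groupby("category", sort=True)["accepted"].apply(
        lambda s: s.astype(bool).mean()
    )
    n_pooled = len(pooled)
    total = pooled.sum()
    if n_pooled >= 2 and total > 0:
        b, b_a = levins_index((pooled / total).to_numpy(), n_pooled)
    else:
        b = b_a = None
    return AcceptanceResult(per_prey, overall, b, b_a, n_pooled)
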