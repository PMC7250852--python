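"""Identity-threshold taxonomy assignment against a local reference library.

A MOTU representative is compared to every reference amplicon by global
(end-to-end) alignment and assigned by unanimity rules on the
high-identity hit set:

* all hits above 98 % agree on one species  -> species;
* all hits above 93 % agree on one genus    -> genus;
* >93 % hits span several genera of one family -> family;
* hits span several families -> order (or "unidentified");
* the best hit is an off-target (bacterial/fungal) reference -> the MOTU is
  excluded from prey counts altogether.

Unanimity, not merely the best hit, governs each rank: a tie at identical
best identity across two genera demotes the assignment to family level,
which keeps the outcome deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .cluster import MOTU, MOTUTable
from .simulate import ReferenceTaxon

SPECIES_PCT = 98.0
GENUS_PCT = 93.0

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2

_NON_ACGT = re.compile("[^ACGT]")


def percent_identity(query: str, reference: str) -> float:
    """Identity over the full global alignment, in [0, 100].

    Scoring is fixed (match +1, mismatch -1, gap -2) for reproducibility;
    identity = 100 x matched columns / alignment columns.  Non-ACGT symbols
    never match anything (including each other).
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    # map ambiguity codes to symbols that cannot match across sequences
    q = _NON_ACGT.sub("N", query.upper())
    r = _NON_ACGT.sub("n", reference.upper())
    alignment = _aligner.align(q, r)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns


@dataclass
class TaxonAssignment:
    """Outcome of the similarity rules for one MOTU."""

    motu_id: str
    best_hits: list[tuple[str, float]]
    assigned_rank: str  # species | genus | family | order | unidentified
    assigned_name: str
    excluded_offtarget: bool = False
    best_identity: float = 0.0
    role: str = "prey"  # role of the best-hit reference
    lineage: tuple[str, ...] = ()


def assign_motu(
    motu: MOTU,
    library: Sequence[ReferenceTaxon],
    species_pct: float = SPECIES_PCT,
    genus_pct: float = GENUS_PCT,
    primer_set: str | None = None,
) -> TaxonAssignment:
    """Apply the 98 % / 93 % unanimity rules to one MOTU representative."""
    if not library:
        raise ValueError("reference library is empty")
    primer = primer_set or (
        "ant_specific" if len(motu.representative) < (131 + 211) / 2 else "general"
    )
    hits = [
        (t, percent_identity(motu.representative, t.amplicon(primer)))
        for t in library
    ]
    hits.sort(key=lambda h: (-h[1], h[0].id))
    best_taxon, best_id = hits[0]
    listed = [(t.id, round(pid, 4)) for t, pid in hits[:5]]

    if best_taxon.role == "offtarget":
        return TaxonAssignment(
            motu.id, listed, "unidentified", best_taxon.kingdom,
            excluded_offtarget=True, best_identity=best_id,
            role="offtarget", lineage=best_taxon.lineage,
        )

    def _result(rank: str, name: str, taxon: ReferenceTaxon) -> TaxonAssignment:
        return TaxonAssignment(
            motu.id, listed, rank, name, best_identity=best_id,
            role=taxon.role, lineage=taxon.lineage,
        )

    over_sp = [t for t, pid in hits if pid > species_pct]
    if over_sp and len({t.species for t in over_sp}) == 1:
        return _result("species", over_sp[0].species, over_sp[0])
    over_gen = [t for t, pid in hits if pid > genus_pct]
    if over_gen:
        if len({t.genus for t in over_gen}) == 1:
            return _result("genus", over_gen[0].genus, over_gen[0])
        if len({t.family for t in over_gen}) == 1:
            return _result("family", over_gen[0].family, over_gen[0])
        if len({t.order for t in over_gen}) == 1:
            return _result("order", over_gen[0].order, over_gen[0])
        return TaxonAssignment(
            motu.id, listed, "unidentified", "unidentified arthropod",
            best_identity=best_id, role="prey", lineage=(),
        )
    return TaxonAssignment(
        motu.id, listed, "unidentified", "unidentified",
        best_identity=best_id, role=best_taxon.role, lineage=(),
    )


def assign_table(
    table: MOTUTable,
    library: Sequence[ReferenceTaxon],
    species_pct: float = SPECIES_PCT,
    genus_pct: float = GENUS_PCT,
) -> dict[str, TaxonAssignment]:
    primer = table.primer_set or None
    return {
        m.id: assign_motu(m, library, species_pct, genus_pct, primer_set=primer)
        for m in table.motus
    }


def screen_offtarget(
    assignments: dict[str, TaxonAssignment], table: MOTUTable | None = None
) -> tuple[dict[str, TaxonAssignment], list[dict]]:
    """Drop MOTUs whose best hit is a bacterial/fungal (off-target) reference.

    Returns the retained assignments plus a log of exclusions (with read
    counts when a MOTU table is supplied) — off-target amplicons are not
    prey and must not enter incidence data.
    """
    totals = {m.id: m.total_reads for m in table.motus} if table is not None else {}
    kept, log = {}, []
    for motu_id, asg in assignments.items():
        if asg.excluded_offtarget:
            log.append(
                {
                    "motu_id": motu_id,
                    "kingdom": asg.assigned_name,
                    "best_identity": asg.best_identity,
                    "reads": totals.get(motu_id, 0),
                }
            )
        else:
            kept[motu_id] = asg
    return kept, log


def write_assignments(assignments: dict[str, TaxonAssignment], path) -> None:
    from .io import write_tsv

    rows = [
        {
            "motu_id": a.motu_id,
            "rank": a.assigned_rank,
            "name": a.assigned_name,
            "best_identity": round(a.best_identity, 4),
            "n_hits": len(a.best_hits),
            "excluded": a.excluded_offtarget,
        }
        for a in assignments.values()
    ]
    write_tsv(rows, path, ["motu_id", "rank", "name", "best_identity", "n_hits", "excluded"])
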