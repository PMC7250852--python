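"""Synthetic reference libraries and gut-content amplicon reads.

No raw sequencing data accompanies the study system this package models, so
every downstream stage is validated against simulations with known ground
truth.  The simulator emulates a dual-primer gut-content metabarcoding
experiment on ant-eating spiders:

* a short ant-specific COI amplicon (131 bp) and a longer general
  invertebrate amplicon (211 bp), both MID-tagged per predator individual;
* predator (spider) DNA dominating the template pool, imperfectly
  suppressed by a blocking oligo when the general primers are used;
* degraded prey DNA from several ant genera plus occasional non-ant prey;
* off-target bacterial/fungal amplicons;
* Ion-Torrent-style substitution and (homopolymer-weighted) indel errors,
  PCR chimeras, tag jumps and cross-contamination.

Reference sequences are *constructed* so that the downstream similarity
rules are decidable: within a genus pairwise identity is > 93 %, between
genera of one subfamily-level clade it is in (88 %, 93 %], and between
clades it is <= 88 %.  The identity bands are verified, not assumed (see
tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import Read, write_fasta, write_fastq, write_tsv

SHORT_LEN = 131  # ant-specific amplicon, COI base positions 327-457
LONG_LEN = 211  # general-invertebrate amplicon, COI base positions 17-227
SHORT_FRAME = 1  # base 327 is a 3rd codon position -> first full codon at +1
LONG_FRAME = 2  # base 17 is a 2nd codon position -> first full codon at +2
MID_LEN = 10

PRIMER_SETS = ("ant_specific", "general")

# invertebrate mitochondrial code: only TAA and TAG terminate
_STOPS = {"TAA", "TAG"}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# mutation budgets per level, chosen so the identity bands close:
#   within genus: 2*s substitutions;  across genera of a clade: 2*g + 2*s
_SPECIES_MUT = {SHORT_LEN: 3, LONG_LEN: 5}  # short: 6/131 -> 95.4 % identity
_GENUS_MUT = {SHORT_LEN: 3, LONG_LEN: 6}  # short: 12/131 -> 90.8 % identity

ANT_SUBFAMILIES = (
    "Formicinae",
    "Myrmicinae",
    "Ponerinae",
    "Dolichoderinae",
    "Dorylinae",
    "Pseudomyrmecinae",
)
_GENUS_POOL = {
    "Formicinae": ("Formica", "Lasius", "Camponotus", "Cataglyphis", "Polyergus", "Plagiolepis"),
    "Myrmicinae": ("Myrmica", "Tetramorium", "Messor", "Aphaenogaster", "Temnothorax", "Pheidole"),
}
_PREDATORS = (
    ("Callilepis", "nocturna"),
    ("Callilepis", "schuszteri"),
    ("Nomisia", "exornata"),
)
_OFFTARGETS = (
    ("Bacteria", "Proteobacteria", "Pseudomonadaceae", "Pseudomonas"),
    ("Fungi", "Ascomycota", "Trichocomaceae", "Aspergillus"),
)


@dataclass(frozen=True)
class ReferenceTaxon:
    """A reference marker sequence with lineage and ecological role."""

    id: str
    kingdom: str
    order: str
    family: str
    subfamily: str
    genus: str
    species: str
    role: str  # predator | prey | offtarget
    seq_short: str
    seq_long: str

    @property
    def lineage(self) -> tuple[str, ...]:
        return (self.kingdom, self.order, self.family, self.subfamily, self.genus, self.species)

    def amplicon(self, primer_set: str) -> str:
        if primer_set == "ant_specific":
            return self.seq_short
        if primer_set == "general":
            return self.seq_long
        raise ValueError(f"unknown primer set {primer_set!r}")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# reference library construction
# ---------------------------------------------------------------------------


def _has_stop(seq: str, frame: int) -> bool:
    for i in range(frame, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS:
            return True
    return False


def _frame_ok(seq: str, frame: int) -> bool:
    """Stop-free in the designated frame, >=1 stop in every other frame."""
    if _has_stop(seq, frame):
        return False
    return all(_has_stop(seq, f) for f in range(3) if f != frame)


def _random_coding_seq(rng: np.random.Generator, length: int, frame: int) -> str:
    """Random DNA, stop-free in `frame` only (so frame choice is decidable)."""
    for _ in range(200):
        seq = "".join(chr(b) for b in rng.choice(_BASES, size=length))
        chars = list(seq)
        for i in range(frame, length - 2, 3):
            while "".join(chars[i : i + 3]) in _STOPS:
                chars[i + 2] = chr(rng.choice(_BASES))
        seq = "".join(chars)
        if _frame_ok(seq, frame):
            return seq
    raise RuntimeError("failed to draw a frame-decidable coding sequence")


def _mutate(
    rng: np.random.Generator, seq: str, positions: Sequence[int], frame: int
) -> str:
    """Substitute each position with a different base without creating a stop
    codon in the designated frame."""
    chars = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != seq[p]]
        rng.shuffle(choices)
        for b in choices:
            chars[p] = b
            codon_start = p - (p - frame) % 3
            if codon_start < frame:
                break  # before the first full codon
            codon = "".join(chars[codon_start : codon_start + 3])
            if codon not in _STOPS:
                break
        else:  # pragma: no cover - every non-stop alternative is a stop
            raise RuntimeError("failed to place a substitution")
    return "".join(chars)


def _protected_positions(seq: str, frame: int) -> set[int]:
    """Positions inside off-frame stop codons: mutating them could make the
    reading frame ambiguous for frame selection."""
    protected: set[int] = set()
    for f in range(3):
        if f == frame:
            continue
        for i in range(f, len(seq) - 2, 3):
            if seq[i : i + 3] in _STOPS:
                protected.update((i, i + 1, i + 2))
    return protected


def _identity_sub_only(a: str, b: str) -> float:
    """Percent identity for equal-length, substitution-separated sequences."""
    matches = sum(x == y for x, y in zip(a, b))
    return 100.0 * matches / len(a)


def _clade_names(index: int) -> tuple[str, str, str, str]:
    """(kingdom, order, family, subfamily) for prey clade `index`."""
    sub = (
        ANT_SUBFAMILIES[index]
        if index < len(ANT_SUBFAMILIES)
        else f"Subfamily{index + 1:02d}"
    )
    return ("Animalia", "Hymenoptera", "Formicidae", sub)


def _genus_name(subfamily: str, g: int) -> str:
    pool = _GENUS_POOL.get(subfamily, ())
    return pool[g] if g < len(pool) else f"{subfamily[:4]}genus{g + 1:02d}"


def build_reference_library(
    n_families: int,
    n_genera_per_family: int,
    n_species_per_genus: int,
    seed: int,
    n_predators: int = 0,
    n_offtargets: int = 0,
) -> list[ReferenceTaxon]:
    """Construct a prey reference library with decidable identity bands.

    ``n_families`` counts subfamily-level clades (the prey are ant genera,
    which all share the family Formicidae); identity between clades is
    <= 88 %, between genera of one clade in (88 %, 93 %], within a genus
    > 93 %.  Optionally appends predator (spider) and off-target
    (bacterial/fungal) references whose sequences sit far outside all
    bands.  Deterministic under ``seed``.
    """
    if min(n_families, n_genera_per_family, n_species_per_genus) < 1:
        raise ValueError("all counts must be >= 1")
    for length in (SHORT_LEN, LONG_LEN):
        need = n_genera_per_family * (
            _GENUS_MUT[length] + n_species_per_genus * _SPECIES_MUT[length]
        )
        if need > length:
            raise ValueError(
                f"identity-band construction infeasible: {need} disjoint "
                f"mutation sites needed but amplicon is {length} bases"
            )
    rng = np.random.default_rng(seed)

    taxa: list[ReferenceTaxon] = []
    ancestors: dict[int, str] = {SHORT_LEN: [], LONG_LEN: []}

    def _draw_far(length: int, frame: int, floor: float = 80.0) -> str:
        # keep unrelated sequences comfortably below the 88 % band
        for _ in range(100):
            cand = _random_coding_seq(rng, length, frame)
            if all(_identity_sub_only(cand, a) < floor for a in ancestors[length]):
                ancestors[length].append(cand)
                return cand
        raise RuntimeError("failed to separate clade ancestors")

    for ci in range(n_families):
        kingdom, order, family, subfamily = _clade_names(ci)
        clade_seq = {
            SHORT_LEN: _draw_far(SHORT_LEN, SHORT_FRAME),
            LONG_LEN: _draw_far(LONG_LEN, LONG_FRAME),
        }
        # disjoint substitution sites per amplicon length, avoiding the
        # ancestor's off-frame stop codons so frame choice stays decidable
        sites = {}
        for length, frame in ((SHORT_LEN, SHORT_FRAME), (LONG_LEN, LONG_FRAME)):
            g, s = _GENUS_MUT[length], _SPECIES_MUT[length]
            need = n_genera_per_family * (g + n_species_per_genus * s)
            free = sorted(set(range(length)) - _protected_positions(clade_seq[length], frame))
            if need > len(free):
                raise ValueError(
                    f"identity-band construction infeasible: {need} disjoint "
                    f"mutation sites needed but only {len(free)} available"
                )
            sites[length] = rng.choice(free, size=need, replace=False)
        for gi in range(n_genera_per_family):
            genus = _genus_name(subfamily, gi)
            genus_seq = {}
            for length, frame in ((SHORT_LEN, SHORT_FRAME), (LONG_LEN, LONG_FRAME)):
                g, s = _GENUS_MUT[length], _SPECIES_MUT[length]
                block = g + n_species_per_genus * s
                pos = sites[length][gi * block : gi * block + g]
                genus_seq[length] = _mutate(rng, clade_seq[length], pos, frame)
            for si in range(n_species_per_genus):
                species = f"{genus}_sp{si + 1:02d}"
                seqs = {}
                for length, frame in ((SHORT_LEN, SHORT_FRAME), (LONG_LEN, LONG_FRAME)):
                    g, s = _GENUS_MUT[length], _SPECIES_MUT[length]
                    block = g + n_species_per_genus * s
                    start = gi * block + g + si * s
                    pos = sites[length][start : start + s]
                    seqs[length] = _mutate(rng, genus_seq[length], pos, frame)
                taxa.append(
                    ReferenceTaxon(
                        id=f"prey_{ci:02d}_{gi:02d}_{si:02d}",
                        kingdom=kingdom,
                        order=order,
                        family=family,
                        subfamily=subfamily,
                        genus=genus,
                        species=species,
                        role="prey",
                        seq_short=seqs[SHORT_LEN],
                        seq_long=seqs[LONG_LEN],
                    )
                )

    for pi in range(n_predators):
        genus, species = _PREDATORS[pi % len(_PREDATORS)]
        taxa.append(
            ReferenceTaxon(
                id=f"predator_{pi:02d}",
                kingdom="Animalia",
                order="Araneae",
                family="Gnaphosidae",
                subfamily="",
                genus=genus,
                species=f"{genus}_{species}",
                role="predator",
                seq_short=_draw_far(SHORT_LEN, SHORT_FRAME),
                seq_long=_draw_far(LONG_LEN, LONG_FRAME),
            )
        )
    for oi in range(n_offtargets):
        kingdom, phylum, fam, genus = _OFFTARGETS[oi % len(_OFFTARGETS)]
        taxa.append(
            ReferenceTaxon(
                id=f"offtarget_{oi:02d}",
                kingdom=kingdom,
                order=phylum,
                family=fam,
                subfamily="",
                genus=genus,
                species=f"{genus}_sp{oi + 1:02d}",
                role="offtarget",
                seq_short=_draw_far(SHORT_LEN, SHORT_FRAME),
                seq_long=_draw_far(LONG_LEN, LONG_FRAME),
            )
        )
    return taxa


def library_to_frame(taxa: Iterable[ReferenceTaxon]) -> pd.DataFrame:
    cols = ["id", "kingdom", "order", "family", "subfamily", "genus", "species", "role"]
    return pd.DataFrame([{c: getattr(t, c) for c in cols} for t in taxa])


def write_library(taxa: Sequence[ReferenceTaxon], outdir: str | Path) -> None:
    """Emit FASTA (per primer set) + lineage TSV for a reference library."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([(t.id, t.seq_short) for t in taxa], outdir / "reference_short.fasta")
    write_fasta([(t.id, t.seq_long) for t in taxa], outdir / "reference_long.fasta")
    df = library_to_frame(taxa)
    write_tsv(df.to_dict("records"), outdir / "reference_taxonomy.tsv", df.columns)


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of one simulated sequencing run.

    ``diet`` maps individual id -> {prey taxon id -> relative template
    abundance} (each individual's proportions must sum to 1).  Error and
    artifact rates are per base (``sub_rate``, ``indel_rate``,
    ``homopolymer_indel_rate``) or per read (``chimera_rate``,
    ``tag_jump_rate``, ``contaminant_rate``, ``cross_contamination_rate``).
    ``seed`` fully determines the output.
    """

    diet: Mapping[str, Mapping[str, float]]
    predator_taxon: str | None = None
    predator_template_fraction: float = 0.9
    blocking_efficacy: float = 0.5
    primer_failure: frozenset[tuple[str, str]] = frozenset()
    reads_per_individual: int | Mapping[str, int] = 2000
    sub_rate: float = 0.002
    indel_rate: float = 0.0002
    homopolymer_indel_rate: float = 0.002
    chimera_rate: float = 0.0005
    pcr_error_rate: float = 0.0001  # reads from early-PCR-amplified error templates
    tag_jump_rate: float = 0.001
    contaminant_rate: float = 0.0002
    cross_contamination_rate: float = 0.0
    q20_fail_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "predator_template_fraction": self.predator_template_fraction,
            "blocking_efficacy": self.blocking_efficacy,
            "sub_rate": self.sub_rate,
            "indel_rate": self.indel_rate,
            "homopolymer_indel_rate": self.homopolymer_indel_rate,
            "chimera_rate": self.chimera_rate,
            "pcr_error_rate": self.pcr_error_rate,
            "tag_jump_rate": self.tag_jump_rate,
            "contaminant_rate": self.contaminant_rate,
            "cross_contamination_rate": self.cross_contamination_rate,
            "q20_fail_fraction": self.q20_fail_fraction,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for ind, props in self.diet.items():
            total = sum(props.values())
            if props and abs(total - 1.0) > 1e-9:
                raise ValueError(f"diet of {ind!r} sums to {total}, expected 1")

    @property
    def individuals(self) -> list[str]:
        return list(self.diet)

    def depth(self, individual: str) -> int:
        if isinstance(self.reads_per_individual, Mapping):
            return int(self.reads_per_individual[individual])
        return int(self.reads_per_individual)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "diet": {k: dict(v) for k, v in self.diet.items()},
            "predator_taxon": self.predator_taxon,
            "predator_template_fraction": self.predator_template_fraction,
            "blocking_efficacy": self.blocking_efficacy,
            "primer_failure": sorted(list(p) for p in self.primer_failure),
            "reads_per_individual": (
                dict(self.reads_per_individual)
                if isinstance(self.reads_per_individual, Mapping)
                else self.reads_per_individual
            ),
            "sub_rate": self.sub_rate,
            "indel_rate": self.indel_rate,
            "homopolymer_indel_rate": self.homopolymer_indel_rate,
            "chimera_rate": self.chimera_rate,
            "pcr_error_rate": self.pcr_error_rate,
            "tag_jump_rate": self.tag_jump_rate,
            "contaminant_rate": self.contaminant_rate,
            "cross_contamination_rate": self.cross_contamination_rate,
            "q20_fail_fraction": self.q20_fail_fraction,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def assign_mids(individuals: Sequence[str], seed: int) -> dict[tuple[str, str], str]:
    """Unique 10-base forward/reverse MID pair per individual."""
    rng = np.random.default_rng(seed)
    mids: set[str] = set()

    def _draw() -> str:
        while True:
            mid = "".join(chr(b) for b in rng.choice(_BASES, size=MID_LEN))
            if mid not in mids:
                mids.add(mid)
                return mid

    return {( _draw(), _draw()): ind for ind in individuals}


@dataclass
class TaggedReadSet:
    """Reads from one simulated (or real) sequencing run."""

    reads: list[Read]
    primer_set: str
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.reads)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _homopolymer_mask(row: np.ndarray) -> np.ndarray:
    """Positions inside a homopolymer run of length >= 2."""
    same_prev = np.zeros(len(row), dtype=bool)
    same_prev[1:] = row[1:] == row[:-1]
    mask = same_prev.copy()
    mask[:-1] |= same_prev[1:]
    return mask


def _apply_indels(
    rng: np.random.Generator,
    seq: np.ndarray,
    n_plain: int,
    n_homo: int,
) -> np.ndarray:
    out = list(seq)
    for _ in range(n_plain + n_homo):
        if n_homo > 0:
            homo = np.flatnonzero(_homopolymer_mask(np.asarray(out, dtype=np.uint8)))
            pos = int(rng.choice(homo)) if len(homo) else int(rng.integers(len(out)))
            n_homo -= 1
        else:
            pos = int(rng.integers(len(out)))
        if rng.random() < 0.5 and len(out) > 1:
            del out[pos]
        else:
            out.insert(pos, out[pos])
    return np.asarray(out, dtype=np.uint8)


def inject_chimeras(
    reads: list[Read], rate: float, seed: int | np.random.Generator
) -> tuple[list[Read], list[dict]]:
    """Replace a Binomial(n, rate) subset of reads with two-parent chimeras.

    A chimera is the prefix of one randomly chosen read joined to the suffix
    of another at a uniform breakpoint; read count is conserved.  Returns the
    new read list plus one record per chimera (index, parents, breakpoint).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate == 0.0 or not reads:
        return list(reads), []
    if len({r.seq for r in reads}) < 2:
        raise ValueError("chimera injection needs >= 2 distinct parent sequences")
    out = list(reads)
    n_chim = rng.binomial(len(reads), rate)
    targets = rng.choice(len(reads), size=n_chim, replace=False)
    records = []
    for idx in targets:
        i, j = rng.choice(len(reads), size=2, replace=False)
        a, b = reads[int(i)], reads[int(j)]
        bp = int(rng.integers(1, min(len(a.seq), len(b.seq))))
        seq = a.seq[:bp] + b.seq[bp:]
        qual = np.concatenate([a.qual[:bp], b.qual[bp:]])
        out[int(idx)] = Read(reads[int(idx)].id, seq, qual)
        records.append(
            {"index": int(idx), "read_id": reads[int(idx)].id,
             "parent_a": a.id, "parent_b": b.id, "breakpoint": bp}
        )
    return out, records


def _template_weights(
    config: SimulationConfig,
    library_by_id: Mapping[str, ReferenceTaxon],
    individual: str,
    primer_set: str,
) -> tuple[list[str], np.ndarray, float]:
    """(prey taxa, normalised prey weights, effective predator probability)."""
    fails = config.primer_failure
    p_pred = 0.0
    if config.predator_taxon is not None and (primer_set, config.predator_taxon) not in fails:
        p_pred = config.predator_template_fraction
        if primer_set == "general":
            p_pred *= 1.0 - config.blocking_efficacy
    prey, w = [], []
    for taxon, prop in config.diet[individual].items():
        if taxon not in library_by_id:
            raise KeyError(f"diet taxon {taxon!r} missing from reference library")
        if (primer_set, taxon) in fails or prop == 0.0:
            continue
        prey.append(taxon)
        w.append(prop)
    weights = np.asarray(w, dtype=float)
    if weights.sum() == 0.0 and p_pred == 0.0:
        raise ValueError(f"no amplifiable template for individual {individual!r}")
    if weights.sum() > 0:
        weights = weights / weights.sum()
    return prey, weights, p_pred


def simulate_gut_reads(
    config: SimulationConfig,
    library: Sequence[ReferenceTaxon],
    primer_set: str = "ant_specific",
    mid_map: Mapping[tuple[str, str], str] | None = None,
) -> tuple[TaggedReadSet, pd.DataFrame, dict[tuple[str, str], str]]:
    """Simulate one MID-tagged sequencing run with full ground truth.

    Each read is ``forward MID + amplicon (with injected errors) +
    reverse-complemented reverse MID``.  The returned ground-truth table has
    one row per read: its true source individual and taxon, the individual
    whose MID pair it ends up carrying (tag jumps reassign it, or make the
    pair unassignable), the artifact class and whether its quality string
    passes a mean-Q20 filter.
    """
    if primer_set not in PRIMER_SETS:
        raise ValueError(f"unknown primer set {primer_set!r}")
    config.validate()
    rng = np.random.default_rng(config.seed)
    by_id = {t.id: t for t in library}
    offtargets = [t.id for t in library if t.role == "offtarget"]
    individuals = config.individuals
    if mid_map is None:
        mid_map = assign_mids(individuals, int(rng.integers(2**31)))
    else:
        if len(set(mid_map.values())) != len(mid_map):
            raise ValueError("MID map is not injective over (forward, reverse) pairs")
        for f, r in mid_map:
            if len(f) != MID_LEN or len(r) != MID_LEN:
                raise ValueError("MIDs must be 10 bases")
    pair_of = {ind: pair for pair, ind in mid_map.items()}
    missing = [i for i in individuals if i not in pair_of]
    if missing:
        raise ValueError(f"no MID pair for individuals {missing}")

    amp_of = {t.id: t.amplicon(primer_set) for t in library}
    enc = {tid: np.frombuffer(amp.encode(), dtype=np.uint8) for tid, amp in amp_of.items()}
    L = SHORT_LEN if primer_set == "ant_specific" else LONG_LEN

    all_diet_taxa = sorted({t for props in config.diet.values() for t in props})
    reads: list[Read] = []
    truth_rows: list[dict] = []
    serial = 0

    for ind in individuals:
        n = config.depth(ind)
        if n == 0:
            continue
        prey, prey_w, p_pred = _template_weights(config, by_id, ind, primer_set)

        # per-read source category
        u = rng.random(n)
        is_contam = u < config.contaminant_rate if offtargets else np.zeros(n, bool)
        u2 = rng.random(n)
        is_cross = (~is_contam) & (u2 < config.cross_contamination_rate)
        u3 = rng.random(n)
        is_pred = (~is_contam) & (~is_cross) & (u3 < p_pred)
        is_prey = ~(is_contam | is_cross | is_pred)
        if is_prey.any() and prey_w.sum() == 0.0:
            is_pred |= is_prey  # all prey blocked by primer failure
            is_prey[:] = False

        taxon_ids = np.empty(n, dtype=object)
        artifact = np.full(n, "clean", dtype=object)
        taxon_ids[is_contam] = rng.choice(offtargets, size=int(is_contam.sum())) if offtargets else None
        artifact[is_contam] = "contaminant"
        if is_cross.any():
            picks = rng.choice(len(all_diet_taxa), size=int(is_cross.sum()))
            taxon_ids[is_cross] = np.asarray(all_diet_taxa, dtype=object)[picks]
            artifact[is_cross] = "cross_contamination"
        if config.predator_taxon is not None:
            taxon_ids[is_pred] = config.predator_taxon
        if is_prey.any():
            picks = rng.choice(len(prey), size=int(is_prey.sum()), p=prey_w)
            taxon_ids[is_prey] = np.asarray(prey, dtype=object)[picks]

        # clean amplicon matrix (uint8 base codes as ascii bytes)
        mat = np.empty((n, L), dtype=np.uint8)
        for tid in set(taxon_ids):
            mask = taxon_ids == tid
            mat[mask] = enc[tid]

        # erroneous templates amplified early in PCR: a read template picks
        # up several substitutions and is re-amplified, yielding a small
        # burst of identical error reads (the classic source of rare MOTUs)
        n_err = rng.binomial(n, config.pcr_error_rate) if n > 0 else 0
        if n_err:
            targets = rng.choice(n, size=n_err, replace=False)
            pos = 0
            while pos < n_err:
                burst = int(min(rng.geometric(0.5), 4, n_err - pos))
                src = int(rng.integers(n))
                row = mat[src].copy()
                # 6+ substitutions: far enough that the error cluster cannot
                # chain into its source MOTU through 1-sub sequencing variants
                k = int(rng.integers(6, 10))
                sites = rng.choice(L, size=k, replace=False)
                codes = np.searchsorted(_BASES, row[sites])
                row[sites] = _BASES[(codes + rng.integers(1, 4, size=k)) % 4]
                label = f"pcrerr:{taxon_ids[src]}"
                for idx in targets[pos : pos + burst]:
                    mat[idx] = row
                    artifact[idx] = "pcr_error"
                    taxon_ids[idx] = label
                pos += burst

        # chimeras on the clean pool (PCR stage, before sequencing errors)
        n_chim = rng.binomial(n, config.chimera_rate) if n > 1 else 0
        if n_chim and len({amp_of[t] for t in set(taxon_ids) if t in amp_of}) >= 2:
            targets = rng.choice(n, size=n_chim, replace=False)
            for idx in targets:
                i, j = rng.choice(n, size=2, replace=False)
                bp = int(rng.integers(1, L))
                row = np.concatenate([mat[i, :bp], mat[j, bp:]])
                label = f"chimera:{taxon_ids[i]}+{taxon_ids[j]}"
                mat[idx] = row
                artifact[idx] = "chimera"
                taxon_ids[idx] = label

        # substitutions, vectorised
        if config.sub_rate > 0:
            sub_mask = rng.random((n, L)) < config.sub_rate
            n_subs = int(sub_mask.sum())
            if n_subs:
                shift = rng.integers(1, 4, size=n_subs).astype(np.uint8)
                codes = np.searchsorted(_BASES, mat[sub_mask])
                mat[sub_mask] = _BASES[(codes + shift) % 4]

        # indels: only reads drawn with >= 1 event are touched individually
        n_plain = rng.binomial(L, config.indel_rate, size=n)
        n_homo = rng.binomial(L, config.homopolymer_indel_rate, size=n)
        # homopolymer rate applies only within runs (~1/4 of positions)
        n_homo = rng.binomial(n_homo, 0.25)
        indel_reads = set(np.flatnonzero((n_plain + n_homo) > 0).tolist())

        # quality model: two components, pass/fail mean Q20 by construction
        fail_q = rng.random(n) < config.q20_fail_fraction
        qmat = np.clip(
            np.rint(rng.normal(33.0, 2.5, size=(n, L + 2 * MID_LEN + 8))), 25, 40
        ).astype(np.int16)
        bad = np.clip(
            np.rint(rng.normal(14.0, 2.5, size=(int(fail_q.sum()), qmat.shape[1]))), 3, 19
        ).astype(np.int16)
        qmat[fail_q] = bad

        # tag jumps: reverse MID swapped with another individual's
        jump = rng.random(n) < config.tag_jump_rate
        fmid, rmid = pair_of[ind]
        rmid_rc = revcomp(rmid)

        others = [i2 for i2 in individuals if i2 != ind]
        for k in range(n):
            seq_arr = mat[k]
            if k in indel_reads:
                seq_arr = _apply_indels(rng, seq_arr, int(n_plain[k]), int(n_homo[k]))
            amp = seq_arr.tobytes().decode("ascii")
            assigned = ind
            r_rc = rmid_rc
            if jump[k] and others:
                donor = others[int(rng.integers(len(others)))]
                r_rc = revcomp(pair_of[donor][1])
                assigned = ""  # (fmid, donor rmid) matches no sample
                artifact[k] = "tag_jump" if artifact[k] == "clean" else artifact[k]
            seq = fmid + amp + r_rc
            rid = f"r{serial:08d}"
            serial += 1
            qual = qmat[k, : len(seq)]
            if len(qual) < len(seq):  # rare: many insertions in one read
                qual = np.concatenate([qual, np.full(len(seq) - len(qual), qual[-1])])
            reads.append(Read(rid, seq, qual))
            truth_rows.append(
                {
                    "read_id": rid,
                    "true_sample": ind,
                    "assigned_sample": assigned,
                    "taxon_id": taxon_ids[k],
                    "role": by_id[taxon_ids[k]].role if taxon_ids[k] in by_id else "artifact",
                    "artifact": artifact[k],
                    "q20_pass": not fail_q[k],
                }
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "true_sample", "assigned_sample",
            "taxon_id", "role", "artifact", "q20_pass",
        ],
    )
    readset = TaggedReadSet(reads, primer_set, provenance=f"sim(seed={config.seed})")
    return readset, truth, dict(mid_map)


def write_run(
    readset: TaggedReadSet,
    truth: pd.DataFrame,
    mid_map: Mapping[tuple[str, str], str],
    config: SimulationConfig,
    outdir: str | Path,
) -> None:
    """Emit FASTQ + ground-truth TSV + MID map TSV + config YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fastq(readset.reads, outdir / f"reads_{readset.primer_set}.fastq")
    truth.to_csv(outdir / f"truth_{readset.primer_set}.tsv", sep="\t", index=False)
    write_tsv(
        (
            {"sample": ind, "forward_mid": f, "reverse_mid": r}
            for (f, r), ind in mid_map.items()
        ),
        outdir / "mid_map.tsv",
        ["sample", "forward_mid", "reverse_mid"],
    )
    config.to_yaml(outdir / "config.yaml")
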