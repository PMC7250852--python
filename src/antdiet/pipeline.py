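"""End-to-end pipeline: simulate -> read processing -> MOTU clustering ->
taxonomy -> cut-off sweeps -> niche profiles, with a per-stage manifest.

The manifest records input and output read counts for every stage so that
each emitted read is accounted for in exactly one terminal bin
(clustered-into-MOTU, discarded-with-reason, or unassigned).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cluster as _cluster
from . import niche as _niche
from . import readproc as _readproc
from . import simulate as _simulate
from . import sweep as _sweep
from . import taxonomy as _taxonomy
from .io import Read
from .simulate import (
    LONG_LEN,
    SHORT_LEN,
    ReferenceTaxon,
    SimulationConfig,
    TaggedReadSet,
    build_reference_library,
    simulate_gut_reads,
)

PRIMER_PARAMS = {  # amplicon length and swarm-style linkage threshold d
    "ant_specific": {"amplicon_length": SHORT_LEN, "d": 4},
    "general": {"amplicon_length": LONG_LEN, "d": 5},
}


@dataclass
class PipelineConfig:
    """All tunables of the analysis cascade, serialisable to YAML."""

    primer_set: str = "ant_specific"
    q_threshold: float = 20.0
    length_tolerance: int | None = None  # default: 10 % of amplicon length
    min_haplotype_reads: int = 2
    species_pct: float = 98.0
    genus_pct: float = 93.0
    global_thresholds: tuple[float, ...] = _sweep.GLOBAL_THRESHOLDS
    individual_thresholds: tuple[float, ...] = _sweep.INDIVIDUAL_THRESHOLDS
    global_cutoff: float = _sweep.DEFAULT_GLOBAL_CUTOFF
    individual_cutoff: float = _sweep.DEFAULT_INDIVIDUAL_CUTOFF
    rare_prey_fraction: float = _niche.RARE_PREY_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primer_set not in PRIMER_PARAMS:
            raise ValueError(f"unknown primer set {self.primer_set!r}")
        if not 0 <= self.genus_pct <= self.species_pct <= 100:
            raise ValueError("need 0 <= genus_pct <= species_pct <= 100")
        if self.rare_prey_fraction < 0 or self.rare_prey_fraction > 1:
            raise ValueError("rare_prey_fraction must be in [0, 1]")

    @property
    def amplicon_length(self) -> int:
        return PRIMER_PARAMS[self.primer_set]["amplicon_length"]

    @property
    def d(self) -> int:
        return PRIMER_PARAMS[self.primer_set]["d"]

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["global_thresholds"] = list(self.global_thresholds)
        data["individual_thresholds"] = list(self.individual_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("global_thresholds", "individual_thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PipelineResult:
    """Bundle of every stage's output plus the run manifest."""

    config: PipelineConfig
    haplotypes: _readproc.HaplotypeTable
    motu_table: _cluster.MOTUTable
    assignments: dict[str, _taxonomy.TaxonAssignment]
    offtarget_log: list[dict]
    sweeps: dict[str, _sweep.CutoffSweepResult]
    treatments: dict[str, _cluster.MOTUTable]
    incidence: dict[str, _niche.IncidenceMatrix]
    profiles: dict[str, _niche.NicheProfile]
    rare_prey: dict[str, list[str]]
    manifest: list[dict]
    truth: pd.DataFrame | None = None
    unassigned: int = 0


def process_reads(
    readset: TaggedReadSet,
    mid_map: Mapping[tuple[str, str], str],
    library: Sequence[ReferenceTaxon],
    config: PipelineConfig,
) -> PipelineResult:
    """Run the full cascade on an in-memory read set."""
    manifest: list[dict] = []

    def log(stage: str, n_in: int, n_out: int, **params) -> None:
        manifest.append({"stage": stage, "in": n_in, "out": n_out, **params})

    reads = readset.reads
    kept, q_discard = _readproc.quality_filter(reads, config.q_threshold)
    log("quality_filter", len(reads), len(kept), q_threshold=config.q_threshold)

    by_sample, unassigned = _readproc.demultiplex(kept, mid_map)
    n_assigned = sum(len(v) for v in by_sample.values())
    log("demultiplex", len(kept), n_assigned, unassigned=len(unassigned))

    exp_len = config.amplicon_length
    trimmed: dict[str, list[Read]] = {}
    n_len_removed = 0
    for sample, sample_reads in by_sample.items():
        ok, bad = _readproc.length_filter(sample_reads, exp_len, config.length_tolerance)
        trimmed[sample] = ok
        n_len_removed += len(bad)
    n_trimmed = sum(len(v) for v in trimmed.values())
    log("length_filter", n_assigned, n_trimmed, expected_len=exp_len)

    haplos = _readproc.dereplicate(trimmed, min_reads=config.min_haplotype_reads)
    log(
        "dereplicate", n_trimmed, haplos.total_reads,
        min_reads=config.min_haplotype_reads,
        n_haplotypes=int(haplos.counts.shape[0]),
    )

    ref_amps = [t.amplicon(config.primer_set) for t in library]
    frame = _readproc.choose_frame(ref_amps)
    haplos_t = _readproc.translation_filter(haplos, exp_len, frame)
    log(
        "translation_filter", haplos.total_reads, haplos_t.total_reads,
        frame=frame, n_haplotypes=int(haplos_t.counts.shape[0]),
    )

    motu_table = _cluster.cluster_haplotypes(haplos_t, config.d, config.primer_set)
    log("cluster", haplos_t.total_reads, motu_table.total_reads, d=config.d,
        n_motus=len(motu_table))

    assignments = _taxonomy.assign_table(
        motu_table, library, config.species_pct, config.genus_pct
    )
    kept_asg, off_log = _taxonomy.screen_offtarget(assignments, motu_table)
    log("taxonomy", len(motu_table), len(kept_asg),
        excluded_offtarget=len(off_log))

    sweeps = {
        "global": _sweep.run_sweep(
            motu_table, kept_asg, config.global_thresholds, level="global"
        ),
    }
    eligible = _sweep.eligible_individuals(motu_table)
    indiv_table = motu_table
    if eligible and len(eligible) < len(motu_table.samples):
        frame_all = motu_table.to_frame()[eligible]
        indiv_table = _sweep._rebuild(motu_table, frame_all[frame_all.sum(axis=1) > 0])
    sweeps["individual"] = _sweep.run_sweep(
        indiv_table, kept_asg, config.individual_thresholds, level="individual"
    )

    no_cut = motu_table
    global_cut, _ = _sweep.apply_global_cutoff(motu_table, config.global_cutoff)
    indiv_cut, _ = _sweep.apply_individual_cutoff(motu_table, config.individual_cutoff)
    treatments = {
        "no_cutoff": no_cut,
        f"global_{config.global_cutoff}": global_cut,
        f"individual_{config.individual_cutoff}": indiv_cut,
    }
    incidence, profiles, rare = {}, {}, {}
    for name, tbl in treatments.items():
        inc = _niche.to_incidence(tbl, kept_asg)
        incidence[name] = inc
        profiles[name] = _niche.niche_profile(inc)
        rare[name] = _niche.flag_rare_prey(inc, config.rare_prey_fraction)
        log(f"niche[{name}]", len(tbl), inc.n_categories)

    return PipelineResult(
        config=config,
        haplotypes=haplos_t,
        motu_table=motu_table,
        assignments=assignments,
        offtarget_log=off_log,
        sweeps=sweeps,
        treatments=treatments,
        incidence=incidence,
        profiles=profiles,
        rare_prey=rare,
        manifest=manifest,
        unassigned=len(unassigned),
    )


def run_pipeline(
    pipeline_config: PipelineConfig,
    sim_config: SimulationConfig,
    library: Sequence[ReferenceTaxon],
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Simulate a sequencing run and process it end to end.

    Identical configs and seeds yield identical bundles; when ``outdir`` is
    given, every stage table plus a JSON manifest is written there.
    """
    readset, truth, mid_map = simulate_gut_reads(
        sim_config, library, pipeline_config.primer_set
    )
    result = process_reads(readset, mid_map, library, pipeline_config)
    result.truth = truth
    result.manifest.insert(
        0,
        {"stage": "simulate", "in": 0, "out": len(readset),
         "seed": sim_config.seed, "primer_set": pipeline_config.primer_set},
    )
    if outdir is not None:
        write_bundle(result, library, outdir)
    return result


def write_bundle(
    result: PipelineResult, library: Sequence[ReferenceTaxon], outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _simulate.write_library(list(library), outdir / "library")
    result.config.to_yaml(outdir / "pipeline_config.yaml")
    _cluster.write_motu_table(
        result.motu_table, outdir / "motu_table.tsv", outdir / "motu_representatives.fasta"
    )
    _taxonomy.write_assignments(result.assignments, outdir / "assignments.tsv")
    _sweep.write_sweep(list(result.sweeps.values()), outdir / "sweep.tsv")
    selected = {
        level: {"threshold": s.selected_threshold, "fallback": s.fallback_used}
        for level, s in result.sweeps.items()
    }
    (outdir / "selected_thresholds.json").write_text(json.dumps(selected, indent=2))
    for name, inc in result.incidence.items():
        inc.matrix.to_csv(outdir / f"incidence_{name}.tsv", sep="\t")
    niche_json = {
        name: {
            "B": prof.B, "B_A": prof.B_A, "H": prof.H, "n": prof.n,
            "proportions": {k: float(v) for k, v in prof.proportions.items()},
            "rare_prey": result.rare_prey[name],
        }
        for name, prof in result.profiles.items()
    }
    (outdir / "niche_profiles.json").write_text(json.dumps(niche_json, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SIZE_CLASSES = ("tiny", "small", "paper_like")


def random_diets(
    prey_ids: Sequence[str],
    n_individuals: int,
    rng: np.random.Generator,
    min_taxa: int = 2,
    max_taxa: int = 4,
    prefix: str = "spider",
) -> dict[str, dict[str, float]]:
    """Random per-individual diets: 2-4 prey taxa, no share below ~2.5 %."""
    diets = {}
    for i in range(n_individuals):
        k = int(rng.integers(min_taxa, max_taxa + 1))
        taxa = rng.choice(len(prey_ids), size=min(k, len(prey_ids)), replace=False)
        w = 0.1 + rng.random(len(taxa))
        w = w / w.sum()
        diets[f"{prefix}_{i + 1:03d}"] = {
            prey_ids[int(t)]: float(p) for t, p in zip(taxa, w)
        }
    return diets


def make_fixture(
    size_class: str, seed: int
) -> tuple[list[ReferenceTaxon], SimulationConfig, PipelineConfig]:
    """Self-contained dataset recipes for tests and demos.

    tiny: 4 individuals x 250 reads (unit-test scale); small: 10 x 5,000;
    paper_like: 70 individuals x 15,900 reads, so that roughly 10^6 reads
    survive the quality filter and the 0.005 % global cut-off corresponds
    to a ~50-read minimum MOTU size while erroneous (chimeric) MOTUs stay
    below 5 reads.
    """
    if size_class not in SIZE_CLASSES:
        raise ValueError(f"size_class must be one of {SIZE_CLASSES}")
    rng = np.random.default_rng(seed)
    lib_seed = int(rng.integers(2**31))
    if size_class == "tiny":
        library = build_reference_library(2, 2, 1, lib_seed, n_predators=1, n_offtargets=1)
        n_ind, depth = 4, 250
    elif size_class == "small":
        library = build_reference_library(2, 3, 1, lib_seed, n_predators=1, n_offtargets=2)
        n_ind, depth = 10, 5000
    else:
        library = build_reference_library(2, 3, 2, lib_seed, n_predators=1, n_offtargets=2)
        n_ind, depth = 70, 15900
    prey = [t.id for t in library if t.role == "prey"]
    predator = next(t.id for t in library if t.role == "predator")
    sim = SimulationConfig(
        diet=random_diets(prey, n_ind, rng),
        predator_taxon=predator,
        predator_template_fraction=0.9,
        blocking_efficacy=0.5,
        # the ant-specific primers do not amplify the spider host
        primer_failure=frozenset({("ant_specific", predator)}),
        reads_per_individual=depth,
        sub_rate=0.002,
        indel_rate=0.0002,
        homopolymer_indel_rate=0.002,
        chimera_rate=0.0005,
        pcr_error_rate=0.0005 if size_class == "paper_like" else 0.0001,
        tag_jump_rate=0.001,
        contaminant_rate=0.0002,
        cross_contamination_rate=0.0,
        q20_fail_fraction=0.1,
        seed=int(rng.integers(2**31)),
    )
    return library, sim, PipelineConfig(seed=seed)
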