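# Methods

This note documents the models, parameter choices and known limitations of
`antdiet`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem

Myrmecophagous spiders digest their prey externally, so diet must be
inferred from degraded prey DNA in the gut. Gut-content metabarcoding
amplifies a COI fragment from the gut extract with tagged primers, but the
template pool is dominated by the predator's own DNA (a blocking oligo
suppresses it only partially), the prey DNA is degraded and low-copy, and
PCR plus single-molecule sequencing inject errors, chimeras and tag jumps.
The analysis must therefore separate a genuine prey signal from a large
cloud of rare artifacts before any statement about niche breadth is made.

## Simulated world

The simulator is a stated world, not a tuning dial: its defaults encode the
experimental design this package models, and values the design does not fix
were chosen once as field-realistic conventions and not revisited.

**Amplicons.** Two primer sets: ant-specific, 131 bases (COI positions
327–457, 1-based inclusive), and general invertebrate, 211 bases (positions
17–227). Position 327 is a third codon position and position 17 a second,
so the first complete codon starts at offset 1 (short) and 2 (long); the
library generator keeps reference amplicons stop-free in exactly that frame
(invertebrate mitochondrial code, stops TAA/TAG only) and guarantees at
least one stop in the other frames, so `choose_frame` is decidable.

**Reference library.** Sequences are constructed, not sampled, so the
taxonomy rules have deterministic answers. Clades (ant subfamilies within
Formicidae — the top level is a subfamily because all ant prey share one
family) start from independent random coding sequences (pairwise identity
< 80 %). Within a clade, genera differ by 2×3 fixed substitutions + species
contributions (short amplicon; 2×6 for the long), species within a genus by
2×3 (short; 2×5 long), all at disjoint sites. The resulting bands —
within-genus > 93 %, within-clade across genera (88 %, 93 %], across clades
≤ 88 % — are verified in tests by exhaustive pairwise global alignment, and
an infeasible request (too many taxa for disjoint sites) fails loudly.
Predator (Gnaphosidae spider) and off-target (Proteobacteria, Ascomycota)
references are unrelated random coding sequences.

**Template mixture.** Per read: off-target contaminant with probability
`contaminant_rate` (2×10⁻⁴); otherwise predator with probability
`predator_template_fraction` (0.9), multiplied by `1 − blocking_efficacy`
(blocking 0.5) for the general primers; otherwise a prey taxon by the
individual's diet proportions. Primer failures (e.g. the ant-specific
primers never amplify the spider) zero the corresponding weight. Fixture
diets give each individual 2–4 prey taxa with no share below ~2.5 %.

**Errors.** Substitutions at 0.002/base; indels at 0.0002/base plus an
extra 0.002/base inside homopolymer runs (the Ion Torrent failure mode),
approximated by length-dependent probability rather than flowgram
simulation. Chimeras replace a Binomial(n, 0.0005) subset of reads with a
prefix+suffix recombination of two random reads at a uniform breakpoint.
Tag jumps (0.001/read) swap the reverse MID with another individual's,
producing an unassignable MID pair. Quality strings come from a
two-component model (good ≈ Q33, bad ≈ Q14, 10 % bad reads), so the
mean-Q20 filter has a deterministic outcome per read. MID bases themselves
are error-free; demultiplexing is exact-match, so MID errors would only
shift reads into the unassigned bin, which tag jumps already exercise.

**PCR error bursts.** With probability `pcr_error_rate` a read comes from
an *early-PCR-amplified* error template: a template that picked up 6–9
random substitutions in an early cycle and was re-amplified, emitting a
small burst (truncated geometric, 1–4) of identical error reads. This is
the mechanism behind rare erroneous MOTUs in real data: purely i.i.d.
per-read errors almost never produce two identical copies of the same wrong
sequence in one individual, so per-individual singleton removal would
delete every artifact and the rare-MOTU cut-off analysis would have nothing
to do. The 6–9 substitution range keeps the error cluster from chaining
back into its source MOTU through surviving single-substitution sequencing
variants (single linkage at d = 4 can bridge a distance-5 gap via a 1+4
chain). Amplified *chimeras* were deliberately not used for this purpose:
mosaic variants between related parents form ladders that chain
single-linkage clusters across genera.

**What the simulator does not model.** PCR cycle-by-cycle kinetics (bias is
a static per-taxon multiplier), flowgram-level signal, primer-site
mismatch-dependent amplification, secondary predation, and co-amplified
nuclear pseudogenes (the translation filter is exercised by error-injected
haplotypes instead). A green end-to-end test therefore establishes that the
cascade recovers a known incidence structure under realistic error *rates*,
not that it would be robust to every artefact class of a real run.

## Pipeline conventions

* **Quality filter**: whole-read mean Phred ≥ 20 (the common Galaxy filter
  behaviour; a per-base-fraction mode is available). No trimming.
* **Demultiplexing**: exact dual-MID match at the read ends (forward at
  5′, reverse-complemented reverse MID at 3′), MIDs stripped on assignment.
* **Length window**: expected ± 10 % (131 → ±13, 211 → ±21).
* **Dereplication**: per-individual by default (cells with < 2 identical
  reads are zeroed per sample), mirroring per-individual file processing; a
  total-abundance mode exists.
* **Translation filter**: frameshifts are detected by the
  length-offset-mod-3 proxy rather than reference alignment — reproducible
  without a reference and faithful to "indels causing reading frame
  shifts". Haplotypes with ambiguity codes are flagged and removed, not
  errors.
* **Clustering**: single-linkage transitive closure with per-link
  Levenshtein distance ≤ d (swarm's documented semantics, no fastidious
  phase), grown greedily from the most abundant unclustered seed; ties
  break lexicographically, making partition, MOTU numbering and
  representative choice deterministic. Edit distance (banded, numba) rather
  than Hamming because indels are frequent. At high per-taxon depth,
  single linkage chains congeneric species (6 substitutions apart) into one
  genus-level MOTU via shared 1-substitution error haplotypes; this is
  faithful to the algorithm and harmless at the genus-level resolution the
  niche analysis uses.
* **Percent identity**: end-to-end global alignment, match +1, mismatch −1,
  gap −2 (fixed for reproducibility); identity = matched columns / total
  alignment columns. Non-ACGT symbols are mapped so they can never match.
* **Assignment rules**: unanimity of the >98 % (species) and >93 % (genus)
  hit sets, not merely the best hit; mixed genera demote to family, mixed
  families to order; a best hit with an off-target role excludes the MOTU
  from prey counts. A tie at identical best identity across genera demotes
  one rank, deterministically.
* **Cut-off boundary semantics**: a MOTU "containing fewer sequences than"
  the implied minimum is removed, so a count exactly at the minimum
  survives. Per-individual minima are computed on the *pre-filter* column
  totals (the sample's sequencing yield). "Total valid reads" defaults to
  all clustered reads of the run (prey + predator for that primer set);
  a prey-only denominator can be passed explicitly.
* **Sweep indices**: computed at the prey-genus level on incidence
  proportions; the Levins' denominator n is held fixed at the unfiltered
  table's category count so B_A is comparable along the sweep (a
  detected-categories mode exists). Undefined indices (empty table, one
  category) are NaN/None, never silently 0.
* **Threshold selection**: the largest threshold ending a window (default
  3 thresholds) in which every adjacent change of both B_A and H is ≤
  epsilon (10⁻⁶ on clean fixtures; 0.01 is suggested for noisy data). If
  no window is stable, the least-changing threshold is returned with a
  fallback flag. The suggested operating points are 0.005 % (global) and
  0.5 % (per individual). Note the source protocol's summary states the
  individual-level threshold inconsistently as 0.05 % in one place and
  0.5 % in its methods and results; this package defaults to 0.5 % and
  makes the value a parameter.
* **Acceptance trials**: exact two-sided binomial test (scipy `binomtest`,
  point-probability method) of each prey type's acceptances against the
  overall mean acceptance as null; B_A over pooled categories (ants merged
  into one of 10) on renormalised acceptance proportions. The
  repeated-measures (GEE) analysis of trial order is out of scope; trial
  records retain enough structure for an external fit.
* **Rare prey**: categories detected in < 5 % of individuals are flagged
  as unreliable food-source evidence (configurable fraction).

## Numerical and degenerate-input choices

* B_A requires n ≥ 2 (explicit error below); proportions must sum to 1
  within 10⁻⁸; 0·ln 0 ≡ 0 in H.
* Empty read sets, empty post-filter tables and all-zero incidence are
  legal inputs that produce empty outputs or None/NaN indices, not crashes;
  malformed quality strings and unknown diet taxa fail loudly with the
  offending read/taxon named.
* One RNG stream (PCG64) per simulation run, seeded from the config;
  fixture seeds derive sub-seeds below 2³¹. Identical config + seed gives
  byte-identical FASTQ/TSV output (tested).
* The divergence equivalent of the 5-bp cut-off over the 211-base general
  amplicon is 2.37 %; the package reports unrounded values (printed
  summaries elsewhere round it to 2.3 %).

## Fixture scales

`tiny` (4 × 250 reads) for unit tests, `small` (10 × 5,000) for demos and
the acceptance script, `paper_like` (70 × 15,900 raw → ~10⁶ reads past the
quality filter) to exercise the regime where the 0.005 % global cut-off
means a ~45-read minimum MOTU size while erroneous MOTUs hold 2–4 reads.
`paper_like` sets `cross_contamination_rate = 0`: colliding
cross-contaminated reads (≥ 2 identical in a wrong individual) survive
per-sample singleton removal and are only removed by the per-individual
cut-off, which the global-cut-off recovery test deliberately does not
apply; the mechanism is exercised in unit tests instead.

## Known limitations

* Identity bands are guaranteed by construction only for the generated
  libraries; real reference libraries can violate them, in which case the
  98/93 % rules still apply but their accuracy depends on the library.
* The simulator's artifact classes are independent per read (apart from
  PCR error bursts); correlated failure modes (index hopping gradients,
  per-sample quality collapse) are not modelled.
* Swarm's fastidious phase and abundance-gradient cluster breaking are not
  implemented; at extreme depth single-linkage chaining is expected and
  documented above.
* No niche-overlap statistics; niches are compared descriptively.
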