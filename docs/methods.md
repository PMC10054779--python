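# Methods

This note records the models behind each pipeline stage, the parameters
that matter (with defaults and rationale), the numerical choices made where
the procedure was genuinely open, what the synthetic-data generators do and
do not emulate, and known limitations.

## Alignment conventions

All pairwise alignment runs through Biopython's `PairwiseAligner`
(`lactobin.align`); three fixed scoring schemes cover the pipeline:

| use | scheme |
|---|---|
| OTU clustering, taxonomy, identity reporting | global, match +1 / mismatch −1 / gap −2 (linear), terminal gaps free |
| contig screening, r-protein census | local Smith–Waterman, BLOSUM62, BLAST-style affine gaps (a gap of length *k* costs 11 + *k*·1) |
| 16S discovery on contigs | local, match +2 / mismatch −3 / gap open 5 / extend 2 |

Global identity is `identical columns / aligned columns`, counting internal
gap columns as differences and excluding terminal-gap overhangs. **Coverage
floor.** Free terminal gaps exist to forgive small trimming overhangs
between equal-locus sequences, but for *unrelated* pairs the optimal scored
alignment degenerates to a handful of lucky columns with everything else in
free end gaps — which would read as near-100% identity and collapse
unrelated OTUs into one cluster. The identity denominator is therefore
never allowed below 90% of the shorter sequence's length
(`GlobalAlignment.MIN_COVERAGE = 0.9`). For genuinely homologous pairs the
aligned region spans the shorter sequence and the floor is inactive.

The Smith–Waterman gap convention matters when comparing scores: Biopython
charges its `open` score on the first gap position, BLAST charges
open + extend; the package uses the BLAST convention (open 11, extend 1
means a length-1 gap costs 12), and its scores are verified against an
independent Gotoh dynamic-programming oracle in the test suite.

## Amplicon arm

**Merging.** The reverse read is reverse-complemented and the longest
overlap of ≥ `min_overlap` (default 20) bases with mismatch fraction
≤ `max_mismatch_frac` (default 0.1) is accepted. In the overlap, the
higher-quality base wins (forward base on a tie) and the consensus quality
is the max of the two — a deliberate simplification of posterior-quality
merging; it preserves the property the downstream Q33 filter needs, namely
that planted low-quality errors stay low-quality.

**Screening.** Pass requires (a) the forward primer at the 5′ end and the
reverse complement of the reverse primer at the 3′ end, matched exactly
under IUPAC degeneracy (no mismatches — "intact" primers), with orientation
fixed by locating the forward primer on either strand; (b) merged length in
[400, 580] bp; (c) mean Phred ≥ 33. Primers are trimmed from retained
reads. The primer pair is required configuration, not a constant.

**Clustering.** Greedy abundance-ordered centroid clustering
(UCLUST-style): uniques sorted by count descending (ties: longer sequence,
then lexicographic representative id) join the earliest-founded centroid
within radius 0.04, else found a new OTU. The radius suits the V1–V3
locus, whose variability exceeds the V4 region for which the conventional
3% was calibrated. Deterministic by construction; the member-radius
invariant is re-checked post hoc in tests.

**Chimera screen.** A bespoke two-parent crossover model: for each
sufficiently abundant parent (≥ 2× the query's count) the query is globally
aligned once, giving a per-position match profile; prefix sums then score
every ordered parent pair at every breakpoint in O(1). The query is
chimeric iff the best crossover — both segments ≥ 0.95 identity to their
parents — beats the best single parent by ≥ 0.02. The parameters were
chosen so that crossovers of parents ≥ 8% divergent are detectable (the
crossover gains ~half the parent divergence) while sequencing noise
(~1% errors) cannot fabricate a 2-point gain. Multi-parent chimeras are out
of scope and the generator only plants single-breakpoint chimeras, so the
measured ≥ 80% sensitivity says nothing about three-parent artifacts.

**Enrichment rule.** Per donor at day *d*: enriched iff relative abundance
in every supplemented replicate strictly exceeds the control, and
`max(supplemented) / max(control, pseudo) ≥ min_fold` with `pseudo = 1e-5`
and `min_fold = 5`. The all-replicates rule mirrors how the second donor's
candidate was reported (all three cultures above control); the fold floor
excludes noise-level fluctuation; the pseudo-abundance keeps zero-count
controls finite. Both reported study cases (fold 6740 and 934) reproduce
under this rule, and both are pinned in tests.

**Taxonomy** is top-hit global percent identity against a user-supplied
16S reference FASTA — an explicit stand-in for classifier-based
assignment, matching how results are reported (best match + identity).

## Metagenome arm

**Gene calling** is a maximal-ORF caller (both strands, three frames,
starts ATG/GTG/TTG, nearest in-frame stop, bacterial code 11, start
translated as M, ≥ 30 aa), an explicit stand-in for an annotation
service's gene models. Within a frame only the longest ORF per stop is
reported; ORFs without a stop are not. Codons containing N translate to X.

**Contig screening.** Every predicted protein is aligned against every
reference protein; the best hit per CDS (highest score, ties to the
lexicographically smaller reference id) passes at ≥ 50% identity and ≥ 70%
coverage. Coverage is relative to the *query* (contig-predicted) protein —
the screen asks whether the contig's proteins are substantially explained
by the reference; the reference-relative alternative is available via the
hit fields. A contig is selected on ≥ 1 passing CDS (`min_hits`
configurable): at the stringent identity threshold one strong protein match
is already unlikely by chance, and requiring more would cost short contigs.
Raising either threshold provably never grows the selected set (tested).

**Assembly statistics.** N50 is the length at which the descending
cumulative length first reaches half the total; verified against the
set-based characterization max{L : 2·Σ(x ≥ L) ≥ total} on random multisets.

**Ribosomal-protein census.** Panel of 21 SSU (S1p–S21p) and 33 LSU
markers (L1p–L6p, L7/L12p, L9p–L11p, L13p–L25p, L27p–L36p), names
configurable via the marker FASTA's `marker=`/`subunit=` tags. A marker is
found iff some bin protein hits some reference of that marker at ≥ 30%
identity and ≥ 50% *reference* coverage — looser than the binning screen
because r-proteins are short and deeply conserved, and reference-relative
because the bin protein may carry mispredicted ends. These thresholds are
artifact choices; the source analysis used annotation labels, so exact
reproduction of its found/missing lists is not claimed.

**16S discovery** reports the aligned span of each reference against each
contig (both strands), merging overlapping hits by score, with span
≥ 1200 bp and identity ≥ 80%. The reported "length" is the aligned span,
which equals the true gene length only for near-full-length matches. Only
one hit per (reference, strand, contig) is considered — tandem rRNA copies
on one contig would need iterative masking, which is not implemented.

**Genome size** is bracketed by the min/max of user-supplied related genome
sizes, exactly as done for a candidate with a congeneric genus.

## Pathway templates

Templates live in a versioned data file
(`lactobin/data/pathway_templates.tsv`): glycolysis from glucose-6P plus
its fermentative branches (the pathway starts at glucose-6P because PTS
import, not hexokinase, was observed), butyrate synthesis, and chorismate
synthesis with its quinate branch. Steps keep the source figure-key
numbering; interchangeable enzymes are one OR-step with merged numbering
(glycolysis 2/3; the pyruvate-node routes 14/15/16; butyrate 2/4/5 and —
package choice — 3/6, both crotonyl-CoA-forming). EC matching is exact,
with prefix matching for partial ECs ending in `-`; name matching is
case-insensitive substring on normalized text, used only for steps keyed
without an EC (phosphate acyltransferase, Bcd-EtfAB). Completeness is the
satisfied fraction of *required* steps; branch/entry steps (gluconeogenesis
enzymes, lactate dehydrogenase, the chorismate entry steps 7–8) are
reported but optional, so the quinate→chorismate route reads complete when
only the entry steps are absent. In the butyrate template the
phosphotransbutyrylase + butyrate-kinase terminus (steps 8–9) is required
and the CoA-transferase (step 10) optional, reflecting the canonical
butyrate-producing route. End products (formate, acetate, lactate,
ethanol, butyrate) are scored from the pyruvate node via sub-templates;
acetate's one-enzyme synthetase route satisfies both steps of its two-step
encoding. Transporter/complex presence panels are single-step items
transcribed from the analysis text and evaluated the same way.

## Synthetic data: the stated world

`simulate_community` draws per-donor baseline weights lognormal(σ = 1.5),
multiplies per-sample noise factors lognormal(σ = 0.3) truncated at ±3σ,
plants the enrichment target as a rare resident (half the smallest drawn
weight — the study's candidates sat at 0.005–0.05% in controls), and
multiplies the target's weight by `fold` (default 100) in supplemented
samples at the enrichment day before renormalizing. The ±3σ truncation
makes the guarantee exact: supplemented relative abundance strictly exceeds
control whenever `fold > exp(6σ_noise)` ≈ 6.

`simulate_amplicon_reads` draws molecules multinomially, converts a
`chimera_rate` fraction into single-breakpoint crossovers (breakpoint
uniform in the middle 20–80%), reads both amplicon ends at 300 bp, and
plants i.i.d. substitution errors with quality 12 at errors and 38
elsewhere — the Q33 mean filter is exercised by the error mix rather than
by a learned quality-profile simulator. Indel errors, run-specific quality
decay and strain microdiversity are *not* modeled, so green tests establish
correctness of the screening logic, not robustness to real MiSeq artifacts.

`simulate_metagenome` mutates each reference protein to the target
amino-acid identity (default 0.60; off-target genomes at 0.25), back-
translates with uniform synonymous codons (amino-acid identity is the
controlled variable because the screening thresholds act on amino acids),
joins genes with intergenic spacers, and fragments into 2–8 kb contigs.
Spacers are built from a stop-codon-saturated, start-codon-free repeat so
ORF calls begin exactly at planted gene starts; real intergenic DNA is less
cooperative, so ORF-boundary noise is understated. Ribosomal-protein genes
and one 16S gene are embedded verbatim, the 16S among ordinary protein
genes as on a real contig. Genes cut by a contig boundary lose their start
or stop and are not called — which is faithful: real bins also lose
fragment-edge markers.

All generators are bit-reproducible given their seed; pipeline runs derive
per-stage substreams from a single seed via `stage_rng`.

## Limitations

- The chimera detector and generator share the two-parent single-breakpoint
  model; sensitivity against multi-parent artifacts is unmeasured.
- Greedy centroid clustering is order-dependent by design (stabilized by
  the documented tie-breaks), not a global optimum.
- The contig screen is O(CDS × references) full alignment without seeding
  heuristics; it is meant for curated reference proteomes, not database
  search.
- Statistics published from the original study's raw sequence data
  (deposited in a public archive) and supplementary contig sets are
  reproducible with these tools given those downloads, but are not asserted
  by the offline test suite.
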