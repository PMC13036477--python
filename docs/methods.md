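# Methods

This note documents the models, parameters and design choices behind
`fieldamp`, and what the simulated tests do and do not demonstrate about
real data.

## The workflow being modelled

The package implements a two-step metabarcoding design built for field
deployment with isothermal amplification (RPA) and Nanopore sequencing:

1. **Barcoding arm.** Long amplicons (~600 bp of 16S rRNA) from individual
   specimens are sequenced at modest depth; per specimen, reads are
   clustered and polished into a consensus barcode labelled with the
   field-identified species.
2. **Reference augmentation.** Consensus barcodes are concatenated into a
   MIDORI2-style public reference database as `LOCAL_` records, giving a
   combined, site-specific database.
3. **eDNA arm.** Short amplicons (~250 bp, nested inside the barcoding
   marker so every barcode covers every eDNA read) from water samples are
   demultiplexed, filtered, dereplicated and assigned taxonomy by best-hit
   percent identity against both the base and the combined database.
4. **Evaluation.** Counts are tabulated per sample and taxon, a noise floor
   and a negative-control filter are applied, and correct-assignment
   proportions against a locality checklist are compared between databases
   with risk ratios.

## Synthetic data: what it emulates and what it does not

`simdata` generates the full study in silico.  A random ancestor sequence is
mutated into a community of `n_taxa` species: genus ancestors diverge at
`divergence/2` per site (so between-genus pairwise distance ≈ `divergence`,
default 0.10), and roughly a quarter of taxa form congeneric pairs at ~1/4
of that divergence — close enough that species- and genus-level assignment
genuinely differ.  Each taxon carries a log-normal relative abundance
(σ = 1.5, emulating strongly uneven communities), an elevation range on a
0–3000 m gradient, and an aquatic or terrestrial life history; terrestrial
taxa shed little DNA into streams and are down-weighted by a detectability
factor (default 0.05), reproducing in kind the observation that
water-borne eDNA detects stream-associated species far more consistently.
Non-target "bycatch" taxa (assigned a mammalian lineage) contribute a
configurable fraction of eDNA reads (default 0.35, matching the roughly
40% non-target share seen in practice).

Reads are `index_f + forward primer + marker + revcomp(reverse primer) +
revcomp(index_r)`; degenerate primer positions are realized per molecule;
the error process is i.i.d. per base (substitution, insertion, deletion)
with quality values drawn around separate means for correct (~Q20) and
erroneous (~Q8) bases; about half the reads are emitted
reverse-complemented; a negative control receives a trace contamination
fraction (default 0.5% of a sample's depth).  The default primers are the
assay's actual eDNA and barcoding primer pairs.

The i.i.d. error model is deliberate: it keeps every oracle analytic
(binomial substitution counts, closed-loop demultiplexing at zero error)
at the cost of realism.  **Not** modelled: homopolymer-biased errors,
chimeras, signal-level artefacts, PCR/RPA amplification bias, degraded-DNA
length distributions.  Passing tests therefore demonstrate correctness of
the computational pipeline under controlled error, not performance bounds
on real Nanopore data.

The pipeline's default error rate is ~1% of bases (p_sub = 0.005,
p_ins = p_del = 0.0025), the operating regime of R10.4 chemistry with
super-accurate basecalling.  This matters for the dual-threshold design: at
1% error a read from a species with an exact local barcode usually clears
the 99% identity cutoff, while a read matched only to a ~1.5%-diverged
non-local relative does not — which is precisely the contrast the combined
database exploits.

The simulated base database contains one independently "re-sequenced"
conspecific entry (1% divergence) per community species *except* the
reference-absent ones, for which it instead contains a close non-local
relative (1.5% divergence) — labelled as a congener when the community
retains one, otherwise as a separate genus.  This mirrors the property of
large public databases that drives misassignment: the nearest reference to
a locally unsequenced species is a different, often allopatric taxon that
still passes a permissive identity threshold.

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| `min_mean_phred` | 12 | error-probability-averaged read quality, strict `>` |
| `length_window_edna` | [172, 212] bp | closed insert-length window, eDNA marker |
| `length_window_barcode` | [520, 580] bp | closed window, barcoding marker |
| `identity_thresholds` | 95, 99 % | permissive / stringent best-hit acceptance |
| `noise_floor` | 5 reads | per-sample per-taxon counts ≤ floor zeroed |
| `index_edit_tolerance` | 2 | per-index Levenshtein tolerance in demux |
| `primer_edit_tolerance` | 3 | IUPAC-aware primer location tolerance |

"Average Phred" is the quality of the mean error probability,
`−10·log₁₀(mean 10^(−qᵢ/10))`, not the arithmetic mean of Phred values;
this is the meaningful average and is stricter on mixed-quality reads.
Quality filtering runs **before** dereplication because identical sequences
can carry different quality strings; with exact (100%) dereplication the
two orders otherwise agree.

## Demultiplexing

Both read orientations are searched: the leading window (20 + tol + 5
bases) for a sample's forward index and the trailing window for the
reverse complement of its reverse index, each as an edlib infix match
within the tolerance.  A sample needs both indexes; candidates are ranked
by summed distance and a tie between samples yields `UNASSIGNED(ambiguous)`
rather than an arbitrary call — conservatism over yield, since a
misassigned read corrupts two samples.  Index 20-mers generated by
`simulate_sample_sheet` are kept at pairwise edit distance ≥ 8, so
tolerance-2 matching cannot be ambiguous by construction.  Primer location
uses edlib's equality pairs to let IUPAC degeneracies match compatible
bases; a read whose primers cannot be located keeps its untrimmed insert
but is flagged.

## Consensus barcoding

Greedy centroid clustering visits reads by length descending; a read joins
the first cluster whose centroid it matches at ≥ 85% identity in either
orientation.  The threshold compares two error-bearing reads, so it sits
below the template-level intuition: at 5% per-read error, same-template
reads pair near 90% identity, while reads from templates below ~94% mutual
identity stay separated.  Congeneric templates (16S is slow; congeners sit
at ~97–99%) will co-cluster — a known limitation for mixed swabs, handled
upstream by single-specimen sampling.

The draft is the cluster medoid (minimum summed edit distance to ≤ 30
sampled mates); up to three polishing rounds globally align every read to
the draft (full-DP affine-gap alignment: match +2, mismatch −3, gap open
−5, extend −2), stack columns, and take a per-column majority over
{A, C, G, T, deletion}, accepting an insertion where more than half of the
reads carry one.  Ties keep the current draft base (stability), otherwise
resolve lexicographically.  Iteration stops at a fixed point.  Terminal
columns with aligned-base support below 50% of reads are trimmed — an
algorithmic stand-in for the manual removal of divergent consensus ends,
not a claim about how any particular curation was done.  Specimens with
fewer than three reads are refused (`insufficient_reads`) instead of
risking a low-coverage consensus.  Subsampling caps (≤ 300 reads per
specimen, ≤ 30 medoid mates) bound runtime; all sampling is seeded.

Under the simulator, 30× coverage at 5% total error recovers the template
at ≥ 99.5% identity across seeds — the property that makes Nanopore
barcodes safe to use as reference sequences.

## Assignment

A shared-distinct-k-mer prescreen (k = 11, both orientations) ranks
references; the top candidates (10 by default) are aligned locally with
the conventional nucleotide scoring (+2/−3, gap 5 + 2L).  Percent identity
is matches over alignment columns, gaps included in the denominator;
IUPAC-compatible subject positions count as matches.  The best hit is the
maximum score, with ties resolved by identity, then local-before-base
provenance, then ascending accession — a total order, so hit tables are
reproducible run to run (unlike file-order tie behaviour in BLAST-style
tools).  Hits spanning less than 80% of the query are discarded as
spurious short local matches — a guard, not a reconstruction of any
particular tool's default.  There is no E-value model: acceptance is by
identity threshold alone, applied independently at 95% and 99% to the
single best hit.  Dereplicated sequences are assigned once and counts
re-expanded by their collapsed sizes.

## Count tables and filters

The order is fixed: tabulate → noise floor → control removal.  Because the
floor runs first, trace contamination of ≤ 5 reads in the negative control
is zeroed before the control filter inspects it and does not trigger
removal of the taxon; the test suite documents that permuting the two
filters changes results.  Per-site richness aggregates as the union of
post-filter detections across a site's field × RPA replicates.  The
replication gain is split by collapsing RPA replicates first (union over
each field replicate's first RPA replicate = field gain; remainder up to
the site union = RPA gain); this decomposition is a defined, documented
stand-in — the attribution has no canonical definition.  Elevational
summaries report ln(mean read count across **all** replicates in a cohort,
zeros included), with a zero mean reported as absent rather than −∞.

## Evaluation

Correctness is checklist membership at the table's rank; reads assigned to
non-target classes (bycatch) are reported but excluded from target-class
denominators.  The risk ratio of correct assignment between databases uses
the log-normal Wald interval — the standard two-proportion interval, which
at the magnitudes involved reproduces published intervals of this form to
printed precision.  Counts reconstructed from printed percentages use
round-half-away-from-zero.  `risk_ratio` refuses x₂ = 0 rather than
silently applying a continuity correction.  No p-value is computed for the
ratios; none is needed for the interval.

## Primer elongation

RPA prefers ~25–30-base primers, so short PCR seeds are extended across
adjacent conserved alignment columns.  Columns with > 50% gaps are removed
(strictly greater; a 50% column survives).  Each remaining column collapses
to the IUPAC code covering every base at frequency ≥ 0.05 (the
minor-frequency threshold is a formalization of what is otherwise a visual
screen, and is exposed as a parameter).  All windows containing the seed,
within the length range and allowed growth direction, are enumerated and
ranked: fewest degeneracies, then highest mean conservation, then longest,
then leftmost — a total order verified against brute-force enumeration.
Thermodynamic screening is out of scope; a crude reverse-complement
self-overlap check (≥ 8 bases) is provided as a warning only.

## Numerical and scale choices

Pipeline demonstrations and tests run at desk scale — 6–13 sites, ~100–250
reads per sample, 12-species communities — chosen so a full simulated run
completes in about a minute while every filter (noise floor, control
removal, dual thresholds) still has non-trivial work to do.  Oracle-based
checks use 150–500 random pairs/trials with sequence lengths of 40–70
bases for the quadratic reference implementations.  All randomness flows
through seeded `numpy` generators; identical configuration and seed give
byte-identical artifacts.

## Known limitations

- The error model is positionally independent; homopolymer-dominated
  Nanopore error modes are not represented, so consensus accuracy on real
  reads will be somewhat worse than simulated at equal nominal error.
- Greedy length-descending clustering is order-dependent by design
  (documented, deterministic); it is not an optimal partition.
- The MIDORI2 header parser is tolerant by intent and degrades to UNKNOWN
  ranks rather than failing on unrecognized grammar variants.
- OTU clustering below 100% identity, LCA-style multi-hit classification,
  occupancy modelling and rarefaction are deliberately out of scope.
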