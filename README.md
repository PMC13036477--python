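# fieldamp

Field-deployable eDNA metabarcoding with de novo reference assembly.

Biodiversity monitoring in remote, understudied ecosystems is limited by two
things: laboratory infrastructure and reference sequence data.  `fieldamp`
implements, as a tested Python pipeline, a two-step workflow built around
isothermal amplification (RPA) and portable Nanopore sequencing in which both
problems are attacked at once.  Noisy long reads (~600 bp 16S amplicons) from
individual specimens — e.g., amphibian skin swabs — are polished into
consensus barcodes that are concatenated into a public mitochondrial rRNA
reference database (MIDORI2-style).  Short eDNA amplicons (~250 bp, nested
inside the barcoding marker) from water samples at the same sites are then
assigned taxonomy against both the base and the combined database by best-hit
percent identity, and the gain in assignment accuracy is quantified with risk
ratios.

The package is aimed at molecular-ecology practitioners who want to simulate,
test or re-run this style of workflow without wet-lab data or downloads:
every stage runs on reads produced by the built-in Nanopore-like simulator.

## The statistics at the core

Reads are demultiplexed by dual 20-base indexes within a bounded edit
distance, quality-filtered (error-probability-averaged Phred
`Q = −10·log₁₀(mean 10^(−qᵢ/10)) > 12`, insert length 172–212 bp for the
eDNA marker, 520–580 bp for the barcoding marker), dereplicated exactly, and
assigned to the single best local-alignment hit, accepted at dual identity
thresholds (95% and 99%).  Per-sample taxon counts ≤ 5 are zeroed as noise
and taxa detected in the negative control are removed everywhere.

Accuracy against a locality checklist is compared between databases with
the relative risk of correct assignment and its log-normal Wald interval:

    RR = (x₁/n₁) / (x₂/n₂),
    CI = exp( ln RR ± z₀.₉₇₅ · √(1/x₁ − 1/n₁ + 1/x₂ − 1/n₂) )

where `xᵢ/nᵢ` are correct/total target-class reads under each database.

## Worked example

A full simulated run — 6 stream sites on an elevation gradient, two field
replicates each, 12 amphibian species of which 4 lack any base-database
reference, plus bycatch taxa and a negative control:

```python
from fieldamp.pipeline import PipelineConfig, run_all

report = run_all(PipelineConfig.small(seed=1), "out/")
print(report["stages"]["demux"])
for key, comp in report["evaluation"]["comparisons"].items():
    print(key, round(comp["rr"], 3))
print(report["evaluation"]["species_detected"])
```

prints (seed 1):

```
{'n_assigned': 1795, 'n_ambiguous': 0, 'n_no_match': 6}
species|95 1.813
genus|95 1.167
species|99 1.0
genus|99 1.0
{'base|95': 5, 'combined|95': 8, 'base|99': 1, 'combined|99': 8}
```

Reading this: essentially every pooled read is demultiplexed to its sample;
augmenting the reference database with the locally built consensus barcodes
makes correct species-level assignment 1.8× more likely at the 95% identity
cutoff (and the genus-level gain is smaller than the species-level gain, as
expected — genus calls survive a missing conspecific reference, species calls
do not), and raises the number of checklist species detected from 5 to 8 at
95%, and from 1 to 8 at the stringent 99% cutoff.

The same pipeline is exposed as a CLI (`fieldamp run --seed 1 --out-dir out/`),
with each stage also available standalone: `fieldamp simulate | demux |
filter | derep | consensus | build-db | assign | table | summarize |
evaluate | primers`.

## Layout

- `src/fieldamp/io_core.py` — FASTQ/FASTA/sample-sheet I/O, run configuration
- `src/fieldamp/simdata.py` — synthetic communities + Nanopore-like reads
- `src/fieldamp/demux.py` — dual-index demultiplexing, primer trimming
- `src/fieldamp/readqc.py` — quality/length filtering, exact dereplication
- `src/fieldamp/consensus.py` — specimen barcode clustering + polishing
- `src/fieldamp/refdb.py` — reference database parsing and augmentation
- `src/fieldamp/assign.py` — k-mer prescreen + best-hit identity assignment
- `src/fieldamp/community.py` — count tables, noise floor, control filter,
  detection and elevational summaries
- `src/fieldamp/evaluate.py` — checklist scoring, risk ratios, reports
- `src/fieldamp/primerscan.py` — degenerate primer elongation from alignments
- `src/fieldamp/pipeline.py`, `cli.py` — orchestration and the `fieldamp` CLI

See `docs/methods.md` for the model, parameter and design documentation.
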