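"""End-to-end orchestration of the two-step workflow.

simulate → demultiplex → filter → dereplicate (eDNA arm) / consensus
(barcoding arm) → database augmentation → dual-threshold assignment against
the base and combined databases → count tables → accuracy evaluation.

The barcoding arm runs before the eDNA arm so locally generated consensus
barcodes are in the combined database when eDNA queries are assigned — the
same ordering a field deployment follows.  Every stage writes plain-text
artifacts (FASTQ/FASTA/TSV/JSON) so any stage can be re-run standalone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from fieldamp import assign, community, consensus, demux, evaluate, readqc, refdb, simdata
from fieldamp.io_core import (RunConfig, SequenceRecord, write_fastq, write_fasta,
                              write_sample_sheet)

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Study design + error model + filtering thresholds for a simulated run.

    Defaults mirror the case study's design in kind: 13 stream sites along an
    elevation gradient, 2 field × 2 RPA replicates per site, a community in
    which a third of the species lack any base-database reference, non-target
    bycatch taxa, and one negative amplification control.
    """

    n_taxa: int = 12
    n_reference_absent: int = 4
    n_bycatch: int = 3
    divergence: float = 0.10
    n_sites: int = 13
    field_replicates: int = 2
    rpa_replicates: int = 2
    reads_per_sample: int = 250
    barcode_reads_per_specimen: int = 40
    # R10.4 chemistry with super-accurate basecalling: ~1% residual error
    p_sub: float = 0.005
    p_ins: float = 0.0025
    p_del: float = 0.0025
    base_db_divergence: float = 0.01
    decoy_divergence: float = 0.015
    seed: int = 0
    run: RunConfig = dataclasses.field(default_factory=RunConfig)

    @classmethod
    def small(cls, seed: int = 0) -> "PipelineConfig":
        """A desk-scale configuration for tests and quick demonstrations."""
        return cls(n_taxa=12, n_reference_absent=4, n_bycatch=2, n_sites=6,
                   field_replicates=2, rpa_replicates=1, reads_per_sample=120,
                   barcode_reads_per_specimen=30, seed=seed)


def _lineage_for(taxon: simdata.Taxon) -> refdb.TaxonomyLineage:
    class_ = "Mammalia" if taxon.is_bycatch else "Amphibia"
    order = "Rodentia" if taxon.is_bycatch else "Anura"
    return refdb.TaxonomyLineage(
        kingdom="Animalia", phylum="Chordata", class_=class_, order=order,
        family=f"{taxon.genus_name}idae", genus=taxon.genus_name,
        species=taxon.species_name,
    )


def _reference_absent_species(com: simdata.SyntheticCommunity, n_absent: int) -> list[str]:
    """Choose which community species lack any base-database record.

    Roughly half are members of congeneric pairs (their reads can be
    misassigned to the remaining congener at the species level) and the rest
    are singleton genera, preferring aquatic species so they are actually
    detectable in water samples (their decoy relatives carry a different
    genus label, exercising genus-level misassignment too).
    """
    by_genus: dict[str, list[str]] = {}
    for t in com.taxa:
        by_genus.setdefault(t.genus_name, []).append(t.species_name)
    n_paired = max(1, n_absent // 2)
    absent: list[str] = []
    for members in by_genus.values():
        if len(members) > 1 and len(absent) < n_paired:
            absent.append(members[-1])
    singles = [t for t in com.taxa
               if len(by_genus[t.genus_name]) == 1 and t is not com.taxa[0]]
    for t in sorted(singles, key=lambda t: t.life_history != "aquatic"):
        if len(absent) >= n_absent:
            break
        absent.append(t.species_name)
    for t in com.taxa:  # fill from anywhere if the community is pair-poor
        if len(absent) >= n_absent:
            break
        if t.species_name not in absent and t is not com.taxa[0]:
            absent.append(t.species_name)
    return absent[:n_absent]


def build_base_db(
    com: simdata.SyntheticCommunity,
    absent_species: list[str],
    divergence: float,
    seed: int,
    decoy_divergence: float = 0.015,
) -> refdb.ReferenceDB:
    """A GenBank-like base database.

    Contains every community taxon except the reference-absent ones, each as
    an independently re-sequenced conspecific entry (``divergence`` from the
    truth), plus — as a large public database would — close *non-local*
    relatives of each reference-absent species at ``decoy_divergence``.  A
    decoy is labelled as a non-local congener when the absent species has a
    congener in the community, and as a separate non-local genus otherwise,
    so best hits against the base database can be wrong at the species level
    (and occasionally the genus level) while still passing an identity
    threshold.  Bycatch taxa are always present.
    """
    rng = np.random.default_rng(seed)
    records = []
    genera = {t.genus_name for t in com.taxa}
    congeneric = {t.species_name for t in com.taxa
                  if sum(u.genus_name == t.genus_name for u in com.taxa) > 1}
    for i, taxon in enumerate(com.all_taxa):
        if taxon.species_name not in absent_species:
            seq = simdata._mutate(rng, taxon.true_sequence_long, divergence)
            records.append(refdb.ReferenceRecord(
                f"GB{i:05d}.1", _lineage_for(taxon), seq, provenance="base"))
        else:
            seq = simdata._mutate(rng, taxon.true_sequence_long, decoy_divergence)
            if taxon.species_name in congeneric:
                genus = taxon.genus_name
            else:
                genus = f"Ghostgenus{i:02d}"
            lineage = refdb.TaxonomyLineage(
                kingdom="Animalia", phylum="Chordata", class_="Amphibia",
                order="Anura", family=f"{genus}idae", genus=genus,
                species=f"{genus} nonlocal{i:02d}")
            records.append(refdb.ReferenceRecord(
                f"GB{i:05d}.1", lineage, seq, provenance="base"))
    return refdb.ReferenceDB(records)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full workflow; returns the run report (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = config.seed
    report: dict = {"parameters": dataclasses.asdict(config), "stages": {}}

    # --- simulate -----------------------------------------------------------
    com = simdata.simulate_references(
        config.n_taxa, divergence=config.divergence, seed=rng_seed,
        n_bycatch=config.n_bycatch)
    absent = _reference_absent_species(com, config.n_reference_absent)
    sheet, specimen_map = simdata.simulate_sample_sheet(
        n_sites=config.n_sites, field_replicates=config.field_replicates,
        rpa_replicates=config.rpa_replicates,
        barcode_species=[t.species_name for t in com.taxa], seed=rng_seed + 1)
    model = simdata.ErrorModel(config.p_sub, config.p_ins, config.p_del)
    reads, truth = simdata.simulate_reads(
        com, sheet, model, config.reads_per_sample, seed=rng_seed + 2,
        specimen_map=specimen_map)
    # barcode specimens get their own (smaller) depth
    barcode_ids = set(specimen_map)
    keep = []
    per_specimen: dict[str, int] = {}
    for rec, (_, sample_id, _) in zip(reads, truth.itertuples(index=False)):
        if sample_id in barcode_ids:
            per_specimen[sample_id] = per_specimen.get(sample_id, 0) + 1
            if per_specimen[sample_id] > config.barcode_reads_per_specimen:
                continue
        keep.append(rec.id)
    keep_set = set(keep)
    reads = [r for r in reads if r.id in keep_set]
    truth = truth[truth.read_id.isin(keep_set)].reset_index(drop=True)

    write_fastq(reads, outdir / "pooled.fastq")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    write_fasta(simdata.community_fasta(com), outdir / "community.fasta")
    report["stages"]["simulate"] = {"n_reads": len(reads), "n_taxa": config.n_taxa,
                                    "reference_absent": absent}

    # --- demultiplex --------------------------------------------------------
    results = list(demux.demultiplex(
        reads, sheet, tol_index=config.run.index_edit_tolerance,
        tol_primer=config.run.primer_edit_tolerance, primers=simdata.DEFAULT_PRIMERS))
    summary = demux.demux_summary(results)
    by_sample: dict[str, list[SequenceRecord]] = {}
    for r in results:
        if r.assigned:
            by_sample.setdefault(r.sample_id, []).append(r.insert)
    report["stages"]["demux"] = {
        "n_assigned": sum(1 for r in results if r.assigned),
        "n_ambiguous": summary.get("ambiguous", 0),
        "n_no_match": summary.get("no_match", 0),
    }

    # --- filter + dereplicate / consensus -----------------------------------
    filtered: dict[str, list[SequenceRecord]] = {}
    tallies = {"edna": {"kept": 0, "length": 0, "quality": 0},
               "barcode": {"kept": 0, "length": 0, "quality": 0}}
    for row in sheet:
        recs = by_sample.get(row.sample_id, [])
        kept, tally = readqc.filter_reads(recs, row.marker, config.run)
        filtered[row.sample_id] = kept
        for k in tallies[row.marker]:
            tallies[row.marker][k] += tally.get(k, 0)
    report["stages"]["filter"] = tallies

    # barcoding arm: consensus per specimen, then augment
    barcodes = []
    consensus_records = []
    species_lineage = {t.species_name: _lineage_for(t) for t in com.all_taxa}
    for sample_id, species_name in specimen_map.items():
        result = consensus.consensus_barcode(
            filtered.get(sample_id, []), seed=rng_seed + 3)
        if result.consensus is not None:
            barcodes.append((result, species_lineage[species_name], sample_id))
            consensus_records.append(SequenceRecord(
                f"LOCAL_{sample_id}", result.consensus.bases, None,
                f"{species_name} n_reads={result.n_supporting_reads} "
                f"cluster_fraction={result.cluster_fraction:.2f}"))
        else:
            log.warning("specimen %s (%s): %s", sample_id, species_name, result.status)
    write_fasta(consensus_records, outdir / "barcodes.fasta")
    report["stages"]["consensus"] = {"n_barcodes": len(barcodes),
                                     "n_specimens": len(specimen_map)}

    base_db = build_base_db(com, absent, config.base_db_divergence, rng_seed + 4,
                            decoy_divergence=config.decoy_divergence)
    combined_db = refdb.augment(base_db, barcodes)
    refdb.write_reference_fasta(base_db, outdir / "refdb_base.fasta")
    refdb.write_reference_fasta(combined_db, outdir / "refdb_combined.fasta")
    report["stages"]["refdb"] = {"n_base": len(base_db), "n_combined": len(combined_db)}

    # eDNA arm: dereplicate and assign against both databases
    queries = []
    n_unique = 0
    for row in sheet:
        if row.marker != "edna":
            continue
        derep = readqc.dereplicate(filtered.get(row.sample_id, []))
        n_unique += len(derep)
        for i, u in enumerate(derep):
            queries.append((f"{row.sample_id};uniq{i:05d}", row.sample_id, u.size, u.bases))
    thresholds = config.run.identity_thresholds
    hits_base = assign.assign_table(queries, base_db, thresholds)
    hits_combined = assign.assign_table(queries, combined_db, thresholds)
    hits_base.to_csv(outdir / "hits_base.tsv", sep="\t", index=False)
    hits_combined.to_csv(outdir / "hits_combined.tsv", sep="\t", index=False)
    report["stages"]["assign"] = {
        "n_queries": len(queries), "n_unique": n_unique,
        "reads_assigned": {
            f"{label}@{t:g}": int(hits[hits[assign.pass_column(t)]]["size"].sum())
            for label, hits in (("base", hits_base), ("combined", hits_combined))
            for t in thresholds},
    }

    # --- tables + evaluation -------------------------------------------------
    checklist = evaluate.Checklist.from_species(
        [t.species_name for t in com.taxa])
    acc = evaluate.compare_databases(
        hits_base, hits_combined, sheet, checklist,
        thresholds=thresholds, noise_floor=config.run.noise_floor)
    report["evaluation"] = acc.to_jsonable()

    control_ids = [r.sample_id for r in sheet.negative_controls]
    table = community.tabulate(hits_combined, sheet, rank="species",
                               threshold=thresholds[0])
    table = community.apply_noise_floor(table, config.run.noise_floor)
    table, removed = community.remove_control_taxa(table, control_ids)
    edna_ids = [r.sample_id for r in sheet
                if r.marker == "edna" and not r.is_negative_control]
    table.counts = table.counts.loc[edna_ids]
    table.sample_meta = table.sample_meta.loc[edna_ids]
    table.counts.to_csv(outdir / "counts_species_95.tsv", sep="\t")
    report["stages"]["table"] = {"n_taxa": int(table.counts.shape[1]),
                                 "control_removed_taxa": removed}
    if table.counts.size and table.total_reads:
        report["detection"] = community.detection_stats(table, sheet)
        edges = list(np.linspace(0, 3000, 7))
        elev = community.elevational_summary(table, sheet, edges)
        elev.to_csv(outdir / "elevational_ln_mean.tsv", sep="\t")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
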