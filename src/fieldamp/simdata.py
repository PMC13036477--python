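"""Synthetic communities, reference sequences and Nanopore-like dual-indexed reads.

Emulates the product of the wet-lab side of the workflow: a nested marker
design (a ~250 bp eDNA amplicon contained within a ~600 bp barcoding
amplicon), per-read substitution/insertion/deletion errors with quality
strings, dual 20-base indexes on both ends, skewed (log-normal) community
abundances, non-target "bycatch" taxa, and a negative control carrying a
trace contamination fraction.

The error model is i.i.d. per base — no homopolymer-aware component — which
keeps every downstream oracle analytic (binomial error counts, closed-loop
demultiplexing).  Homopolymer-biased errors are an extension point, not a
current feature.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import edlib
import numpy as np
import pandas as pd

from fieldamp.io_core import SequenceRecord, SampleSheet, SampleRow, revcomp, IUPAC_CODES

# Primer set of the assay: the eDNA pair amplifies the short nested marker,
# forward primer + universal 16Sbr amplify the long barcoding marker.
PRIMER_EDNA_F = "CCTCGCCTGTTTACCAAAAACAYCGCCT"
PRIMER_EDNA_R = "AAGCTCCATRGGGTCTTCTCGTCTWRT"
PRIMER_16SBR = "CCGGTCTGAACTCAGATCACGT"

#: marker -> (forward primer, reverse primer), IUPAC-degenerate.
DEFAULT_PRIMERS: dict[str, tuple[str, str]] = {
    "edna": (PRIMER_EDNA_F, PRIMER_EDNA_R),
    "barcode": (PRIMER_EDNA_F, PRIMER_16SBR),
}

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class ErrorModel:
    """Per-base i.i.d. read error process with quality-string generation."""

    p_sub: float = 0.02
    p_ins: float = 0.01
    p_del: float = 0.01
    quality_correct: float = 20.0
    quality_error: float = 8.0

    def __post_init__(self) -> None:
        if min(self.p_sub, self.p_ins, self.p_del) < 0:
            raise ValueError("error probabilities must be >= 0")
        if self.p_sub + self.p_ins + self.p_del >= 1:
            raise ValueError("p_sub + p_ins + p_del must be < 1")


@dataclasses.dataclass
class Taxon:
    species_name: str
    genus_name: str
    true_sequence_long: str
    true_sequence_short: str
    relative_abundance: float
    life_history: str  # "aquatic" | "terrestrial"
    elevation_range: tuple[int, int]
    is_bycatch: bool = False

    def __post_init__(self) -> None:
        if self.true_sequence_short not in self.true_sequence_long:
            raise ValueError(
                f"{self.species_name}: short marker is not nested in the long marker"
            )


@dataclasses.dataclass
class SyntheticCommunity:
    taxa: list[Taxon]
    bycatch_taxa: list[Taxon] = dataclasses.field(default_factory=list)

    @property
    def all_taxa(self) -> list[Taxon]:
        return self.taxa + self.bycatch_taxa

    def by_species(self) -> dict[str, Taxon]:
        return {t.species_name: t for t in self.all_taxa}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site independently with probability `rate`."""
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


# Long template layout: the short nested marker sits at a fixed offset inside
# the long barcoding insert, mirroring the nested amplicon design.
_SHORT_OFFSET = 160


def simulate_references(
    n_taxa: int,
    seq_len: int = 550,
    divergence: float = 0.10,
    seed: int = 0,
    short_len: int = 192,
    n_bycatch: int = 0,
    aquatic_fraction: float = 0.5,
    elevation_span: tuple[int, int] = (0, 3000),
    abundance_sigma: float = 1.5,
) -> SyntheticCommunity:
    """Generate a community of related reference sequences.

    Sequences descend from one random ancestor: each genus ancestor is mutated
    at ``divergence / 2`` per site (so between-genus pairwise distance is
    ~``divergence``) and congeneric species pairs diverge at ~1/4 of that, so
    species- vs genus-level assignment differ meaningfully.  Roughly a quarter
    of taxa are placed in congeneric pairs.

    Taxa receive log-normal relative abundances, an aquatic or terrestrial
    life history, and an elevation range; bycatch taxa are flagged non-target
    and generated from a distant ancestor.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    if seq_len < short_len + _SHORT_OFFSET:
        raise ValueError(
            f"seq_len {seq_len} too short to nest a {short_len}-base marker "
            f"at offset {_SHORT_OFFSET}"
        )
    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, seq_len)

    n_pairs = n_taxa // 4
    genera: list[list[int]] = []  # genus -> list of species ordinals
    i = 0
    for _ in range(n_pairs):
        genera.append([i, i + 1])
        i += 2
    while i < n_taxa:
        genera.append([i])
        i += 1

    taxa: list[Taxon] = []
    raw_abund = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_taxa)
    lo, hi = elevation_span
    for g, members in enumerate(genera):
        genus_name = f"Genus{g:02d}"
        genus_anc = _mutate(rng, ancestor, divergence / 2)
        for sp_idx, ordinal in enumerate(members):
            # within-genus split at 1/4 the between-genus divergence
            seq = _mutate(rng, genus_anc, divergence / 8) if len(members) > 1 else genus_anc
            life = "aquatic" if rng.random() < aquatic_fraction else "terrestrial"
            center = rng.uniform(lo, hi)
            width = rng.uniform(800, 1500)
            erange = (max(lo, int(center - width / 2)), min(hi, int(center + width / 2)))
            taxa.append(Taxon(
                species_name=f"{genus_name} species{ordinal:02d}",
                genus_name=genus_name,
                true_sequence_long=seq,
                true_sequence_short=seq[_SHORT_OFFSET:_SHORT_OFFSET + short_len],
                relative_abundance=float(raw_abund[ordinal]),
                life_history=life,
                elevation_range=erange,
            ))
    # guarantee at least one aquatic taxon spanning the whole gradient, so
    # every site yields target reads
    taxa[0] = dataclasses.replace(taxa[0], life_history="aquatic", elevation_range=(lo, hi))

    total = sum(t.relative_abundance for t in taxa)
    taxa = [dataclasses.replace(t, relative_abundance=t.relative_abundance / total)
            for t in taxa]

    bycatch: list[Taxon] = []
    if n_bycatch:
        by_abund = rng.lognormal(0.0, abundance_sigma, size=n_bycatch)
        by_abund /= by_abund.sum()
        for b in range(n_bycatch):
            seq = _mutate(rng, _random_seq(rng, seq_len), 0.0)
            bycatch.append(Taxon(
                species_name=f"Bygenus{b:02d} bycatch{b:02d}",
                genus_name=f"Bygenus{b:02d}",
                true_sequence_long=seq,
                true_sequence_short=seq[_SHORT_OFFSET:_SHORT_OFFSET + short_len],
                relative_abundance=float(by_abund[b]),
                life_history="aquatic",
                elevation_range=(lo, hi),
                is_bycatch=True,
            ))
    return SyntheticCommunity(taxa=taxa, bycatch_taxa=bycatch)


def mean_pairwise_distance(sequences: list[str]) -> float:
    """Brute-force all-pairs normalized edit distance (oracle helper)."""
    n = len(sequences)
    if n < 2:
        return 0.0
    total = 0.0
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(sequences[i], sequences[j], mode="NW")["editDistance"]
            total += d / max(len(sequences[i]), len(sequences[j]))
            count += 1
    return total / count


def simulate_sample_sheet(
    n_sites: int = 13,
    field_replicates: int = 2,
    rpa_replicates: int = 2,
    elevations: Optional[list[int]] = None,
    barcode_species: Optional[list[str]] = None,
    seed: int = 0,
    min_index_distance: int = 8,
) -> tuple[SampleSheet, dict[str, str]]:
    """Build a dual-indexed sample sheet plus a specimen -> species map.

    Emits one eDNA sample per (site, field replicate, RPA replicate), one
    barcoding sample per entry of ``barcode_species``, and one negative
    control.  Index 20-mers are drawn randomly but kept at pairwise edit
    distance >= ``min_index_distance`` so tolerant demultiplexing stays
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    if elevations is None:
        elevations = [int(e) for e in np.linspace(300, 2700, n_sites)]
    if len(elevations) != n_sites:
        raise ValueError("elevations length must equal n_sites")

    n_edna = n_sites * field_replicates * rpa_replicates
    n_barcode = len(barcode_species or [])
    n_needed = 2 * (n_edna + n_barcode + 1)

    indexes: list[str] = []
    while len(indexes) < n_needed:
        cand = _random_seq(rng, 20)
        if all(
            edlib.align(cand, x, mode="NW", k=min_index_distance - 1)["editDistance"] == -1
            for x in indexes
        ):
            indexes.append(cand)
    it = iter(indexes)

    rows: list[SampleRow] = []
    for s in range(n_sites):
        for f in range(1, field_replicates + 1):
            for r in range(1, rpa_replicates + 1):
                rows.append(SampleRow(
                    sample_id=f"S{s:02d}_F{f}_R{r}", index_f=next(it), index_r=next(it),
                    marker="edna", site_id=f"site{s:02d}", elevation_m=elevations[s],
                    field_replicate=f, rpa_replicate=r, is_negative_control=False,
                ))
    specimen_map: dict[str, str] = {}
    for b, species in enumerate(barcode_species or []):
        sid = f"BC{b:02d}"
        specimen_map[sid] = species
        rows.append(SampleRow(
            sample_id=sid, index_f=next(it), index_r=next(it),
            marker="barcode", site_id="specimen", elevation_m=0,
            field_replicate=1, rpa_replicate=1, is_negative_control=False,
        ))
    rows.append(SampleRow(
        sample_id="NEG", index_f=next(it), index_r=next(it),
        marker="edna", site_id="control", elevation_m=0,
        field_replicate=1, rpa_replicate=1, is_negative_control=True,
    ))
    return SampleSheet(rows), specimen_map


def _realize_primer(rng: np.random.Generator, primer: str) -> str:
    """Replace IUPAC degeneracies with a random compatible concrete base."""
    out = []
    for c in primer:
        opts = IUPAC_CODES[c]
        out.append(opts if len(opts) == 1 else opts[rng.integers(len(opts))])
    return "".join(out)


def _apply_errors(
    rng: np.random.Generator, template: str, model: ErrorModel
) -> tuple[str, list[int], int]:
    """Apply the i.i.d. error process; return (read, qualities, n_substitutions)."""
    out: list[str] = []
    quals: list[int] = []
    n_sub = 0

    def _q(mean: float) -> int:
        return int(np.clip(rng.normal(mean, 3.0), 2, 41))

    for base in template:
        if rng.random() < model.p_del:
            continue
        if rng.random() < model.p_ins:
            out.append(str(rng.choice(_BASES)))
            quals.append(_q(model.quality_error))
        if rng.random() < model.p_sub:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[rng.integers(3)])
            quals.append(_q(model.quality_error))
            n_sub += 1
        else:
            out.append(base)
            quals.append(_q(model.quality_correct))
    if not out:  # pathological all-deleted read
        out, quals = ["N"], [2]
    return "".join(out), quals, n_sub


def simulate_reads(
    community: SyntheticCommunity,
    sheet: SampleSheet,
    model: ErrorModel,
    reads_per_sample: int,
    seed: int = 0,
    specimen_map: Optional[dict[str, str]] = None,
    primers: Optional[dict[str, tuple[str, str]]] = None,
    contamination_fraction: float = 0.005,
    terrestrial_detectability: float = 0.05,
    bycatch_fraction: float = 0.35,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate a pooled dual-indexed sequencing run.

    Each read is ``index_f + forward primer + marker + revcomp(reverse primer)
    + revcomp(index_r)`` with the error process applied over the whole
    molecule; ~50% of reads are emitted reverse-complemented.  eDNA samples
    draw taxa whose elevation range contains the site elevation, weighted by
    relative abundance (terrestrial taxa shed less DNA into streams and are
    down-weighted by ``terrestrial_detectability``); ``bycatch_fraction`` of
    eDNA reads come from non-target taxa; barcode samples draw only their
    specimen's species; the negative control receives
    ``contamination_fraction × reads_per_sample`` reads from arbitrary taxa.

    Returns the pooled reads (shuffled, as a sequencing run would interleave
    samples) and a truth table with one row per read:
    (read_id, sample_id, species_name).
    """
    if reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be > 0")
    rng = np.random.default_rng(seed)
    primers = primers or DEFAULT_PRIMERS
    specimen_map = specimen_map or {}
    species = community.by_species()

    reads: list[SequenceRecord] = []
    truth_rows: list[tuple[str, str, str]] = []
    counter = 0

    for row in sheet:
        if row.is_negative_control:
            n_reads = max(1, round(contamination_fraction * reads_per_sample))
            pool = community.all_taxa
            weights = np.ones(len(pool))
        elif row.marker == "barcode":
            if row.sample_id not in specimen_map:
                raise ValueError(f"barcode sample {row.sample_id} missing from specimen map")
            n_reads = reads_per_sample
            pool = [species[specimen_map[row.sample_id]]]
            weights = np.ones(1)
        else:
            n_reads = reads_per_sample
            local = [t for t in community.taxa
                     if t.elevation_range[0] <= row.elevation_m <= t.elevation_range[1]]
            if not local:
                raise ValueError(f"no taxa available at elevation {row.elevation_m}")
            w_local = np.array([
                t.relative_abundance
                * (terrestrial_detectability if t.life_history == "terrestrial" else 1.0)
                for t in local
            ])
            w_local = w_local / w_local.sum() * (1 - bycatch_fraction if community.bycatch_taxa else 1.0)
            pool = list(local)
            weights = list(w_local)
            if community.bycatch_taxa:
                w_by = np.array([t.relative_abundance for t in community.bycatch_taxa])
                w_by = w_by / w_by.sum() * bycatch_fraction
                pool += community.bycatch_taxa
                weights = np.concatenate([w_local, w_by])
            weights = np.asarray(weights)

        weights = weights / weights.sum()
        fwd_primer, rev_primer = primers[row.marker]
        picks = rng.choice(len(pool), size=n_reads, p=weights)
        for p in picks:
            taxon = pool[p]
            marker_seq = (taxon.true_sequence_long if row.marker == "barcode"
                          else taxon.true_sequence_short)
            template = (
                row.index_f
                + _realize_primer(rng, fwd_primer)
                + marker_seq
                + revcomp(_realize_primer(rng, rev_primer))
                + revcomp(row.index_r)
            )
            bases, quals, _ = _apply_errors(rng, template, model)
            read_id = f"read{counter:07d}"
            counter += 1
            if rng.random() < 0.5:
                bases, quals = revcomp(bases), list(reversed(quals))
            reads.append(SequenceRecord(read_id, bases, quals))
            truth_rows.append((read_id, row.sample_id, taxon.species_name))

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame(
        [truth_rows[i] for i in order],
        columns=["read_id", "sample_id", "species_name"],
    )
    return reads, truth


def community_fasta(community: SyntheticCommunity) -> list[SequenceRecord]:
    """Long-marker template of every taxon, as FASTA-ready records."""
    recs = []
    for i, t in enumerate(community.all_taxa):
        recs.append(SequenceRecord(
            f"TAXON{i:03d}", t.true_sequence_long, None,
            f"{t.species_name} life_history={t.life_history}",
        ))
    return recs
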