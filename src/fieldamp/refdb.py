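"""MIDORI2-style reference databases and their augmentation with local barcodes.

Two header dialects are parsed: ``midori2`` (accession.version followed by a
semicolon-delimited lineage whose tokens end in ``_taxid``) and ``simple``
(``accession|kingdom|phylum|class|order|family|genus|species``).  The simple
dialect is the canonical internal format; the midori2 parser is tolerant —
unparseable rank tokens become UNKNOWN with a logged warning, never a crash —
because the exact header grammar varies by database release.

Augmentation appends polished consensus barcodes as ``LOCAL_``-prefixed
records with ``provenance="local"``, skipping sequences identical to an
existing record of the same species, so base-vs-combined comparisons can
trace every assignment back to its source.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Optional

from fieldamp.consensus import ConsensusResult
from fieldamp.io_core import SequenceRecord, read_fasta, write_fasta

log = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class_", "order", "family", "genus", "species")
UNKNOWN = "UNKNOWN"


@dataclasses.dataclass(frozen=True)
class TaxonomyLineage:
    kingdom: str = UNKNOWN
    phylum: str = UNKNOWN
    class_: str = UNKNOWN
    order: str = UNKNOWN
    family: str = UNKNOWN
    genus: str = UNKNOWN
    species: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.species != UNKNOWN:
            if self.genus == UNKNOWN:
                raise ValueError(f"species {self.species!r} without a genus")
            first_word = self.species.split()[0]
            if not first_word.startswith(self.genus):
                raise ValueError(
                    f"genus {self.genus!r} is not a prefix of species {self.species!r}"
                )

    def rank(self, rank: str) -> str:
        return getattr(self, "class_" if rank == "class" else rank)


@dataclasses.dataclass
class ReferenceRecord:
    accession: str
    lineage: TaxonomyLineage
    bases: str
    provenance: str = "base"  # "base" | "local"


class ReferenceDB:
    """Accession-unique reference records with ranked lineages."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        self.records: list[ReferenceRecord] = []
        self._by_accession: dict[str, ReferenceRecord] = {}
        for rec in records:
            self._add(rec)

    def _add(self, rec: ReferenceRecord) -> None:
        if rec.accession in self._by_accession:
            raise ValueError(f"duplicate accession {rec.accession!r}")
        self.records.append(rec)
        self._by_accession[rec.accession] = rec
        self.__dict__.pop("_kmer_cache", None)  # invalidate assign-module index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, accession: str) -> ReferenceRecord:
        return self._by_accession[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    def copy(self) -> "ReferenceDB":
        return ReferenceDB(dataclasses.replace(r) for r in self.records)


_MIDORI_TOKEN = re.compile(r"^(?:[a-z_]+_)?(.+?)_\d+$")


def _parse_midori_lineage(accession: str, tail: str) -> TaxonomyLineage:
    tokens = [t for t in tail.split(";") if t]
    names = []
    for tok in tokens:
        m = _MIDORI_TOKEN.match(tok.strip())
        if m:
            names.append(m.group(1).replace("_", " "))
        else:
            log.warning("reference %s: unparseable rank token %r", accession, tok)
            names.append(UNKNOWN)
    # the last seven tokens map onto kingdom..species; shorter lineages fill
    # from the species end with UNKNOWN at higher ranks
    names = names[-7:]
    names = [UNKNOWN] * (7 - len(names)) + names
    fields = dict(zip(RANKS, names))
    try:
        return TaxonomyLineage(**fields)
    except ValueError as exc:
        log.warning("reference %s: inconsistent lineage (%s); degrading to genus", accession, exc)
        fields["species"] = UNKNOWN
        try:
            return TaxonomyLineage(**fields)
        except ValueError:
            return TaxonomyLineage()


def _parse_simple_header(header: str) -> tuple[str, TaxonomyLineage]:
    parts = header.split("|")
    if len(parts) != 8:
        raise ValueError(f"simple-dialect header needs 8 '|'-fields, got {len(parts)}: {header!r}")
    accession = parts[0]
    names = [p.strip().replace("_", " ") or UNKNOWN for p in parts[1:]]
    return accession, TaxonomyLineage(**dict(zip(RANKS, names)))


def parse_reference_fasta(path: str | Path, dialect: str = "simple") -> ReferenceDB:
    """Parse a reference FASTA into a :class:`ReferenceDB`."""
    if dialect not in ("midori2", "simple"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    for rec in read_fasta(path):
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        if dialect == "simple":
            accession, lineage = _parse_simple_header(rec.id)
        else:
            accession = rec.id.split(";")[0]
            tail = header[len(accession):].lstrip(" ;")
            lineage = _parse_midori_lineage(accession, tail)
        records.append(ReferenceRecord(accession, lineage, rec.bases))
    return ReferenceDB(records)


def write_reference_fasta(db: ReferenceDB, path: str | Path) -> int:
    """Write the simple dialect (lossless round-trip)."""
    recs = []
    for r in db:
        lin = r.lineage
        # spaces in binomials become underscores so the header stays one token
        header = "|".join(
            [r.accession] + [lin.rank(x.rstrip("_")).replace(" ", "_") for x in RANKS])
        recs.append(SequenceRecord(header, r.bases))
    return write_fasta(recs, path)


def augment(
    base: ReferenceDB,
    barcodes: Iterable[tuple[ConsensusResult, TaxonomyLineage, str]],
) -> ReferenceDB:
    """Concatenate local consensus barcodes into a copy of the base database.

    Each barcode is a ``(consensus, lineage, local_id)`` triple; species labels
    come from field identification (the sample sheet / checklist), never from
    sequence inference.  A barcode whose sequence is identical to an existing
    record of the same species is skipped with a log note, which makes the
    operation idempotent.
    """
    out = base.copy()
    existing = {(r.bases, r.lineage.species) for r in out}
    for result, lineage, local_id in barcodes:
        if result.consensus is None:
            log.warning("barcode %s: no consensus (%s); skipped", local_id, result.status)
            continue
        accession = f"LOCAL_{local_id}"
        key = (result.consensus.bases, lineage.species)
        if key in existing:
            log.info("barcode %s: identical sequence for %s already present; skipped",
                     local_id, lineage.species)
            continue
        if accession in out:
            raise ValueError(f"local identifier collision: {accession}")
        out._add(ReferenceRecord(accession, lineage, result.consensus.bases, provenance="local"))
        existing.add(key)
    return out
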