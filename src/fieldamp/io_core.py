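"""Readers/writers for the formats the pipeline touches, plus shared run configuration.

All downstream stages consume :class:`SequenceRecord` / :class:`SampleSheet`
objects produced here; no stage re-reads raw files itself.

FASTQ is fixed to 4-line records with Phred+33 encoding (modern Nanopore
output); other encodings are rejected, never guessed.  FASTA output is
unwrapped (one sequence line per record) so round-trips are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

log = logging.getLogger(__name__)

#: IUPAC nucleotide degeneracy codes -> the set of concrete bases each covers.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Inverse lookup: frozenset of bases -> IUPAC code.
IUPAC_FROM_SET: dict[frozenset, str] = {
    frozenset(v): k for k, v in IUPAC_CODES.items()
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class SequenceRecord:
    """A read or reference sequence with optional per-base Phred qualities.

    ``bases`` are uppercased on construction and restricted to IUPAC nucleotide
    symbols; ``quality``, when present, is a list of Phred integers (0-93) of
    the same length as ``bases``.
    """

    id: str
    bases: str
    quality: Optional[list[int]] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        self.bases = self.bases.upper()
        if len(self.bases) < 1:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.bases) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"record {self.id}: non-IUPAC symbols {sorted(bad)}")
        if self.quality is not None:
            if len(self.quality) != len(self.bases):
                raise ValueError(
                    f"record {self.id}: quality length {len(self.quality)} "
                    f"!= sequence length {len(self.bases)}"
                )
            if any(q < 0 or q > 93 for q in self.quality):
                raise ValueError(f"record {self.id}: Phred values outside 0-93")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "SequenceRecord":
        qual = None if self.quality is None else list(reversed(self.quality))
        return SequenceRecord(self.id, revcomp(self.bases), qual, self.description)


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield records from a 4-line Phred+33 FASTQ file, in file order.

    A malformed record (quality/sequence length mismatch, bad header) raises
    ``ValueError`` naming the offending record id and line number.
    """
    path = Path(path)
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"{path}:{lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            lineno += 3
            ident, _, desc = header[1:].partition(" ")
            if not plus.startswith("+"):
                raise ValueError(f"{path}:{lineno - 1}: record {ident}: missing '+' separator")
            if len(qual) != len(seq):
                raise ValueError(
                    f"{path}:{lineno}: record {ident}: quality line length "
                    f"{len(qual)} != sequence length {len(seq)}"
                )
            quality = [ord(c) - 33 for c in qual]
            if any(q < 0 or q > 93 for q in quality):
                raise ValueError(f"{path}:{lineno}: record {ident}: quality outside Phred+33 range")
            yield SequenceRecord(ident, seq, quality, desc)


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write records as 4-line Phred+33 FASTQ. Returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.id}: cannot write FASTQ without qualities")
            head = f"@{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(f"{head}\n{rec.bases}\n+\n")
            fh.write("".join(chr(q + 33) for q in rec.quality) + "\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Yield records from a FASTA file (wrapped or not)."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield SequenceRecord(rec.id, str(rec.seq), None, rec.description[len(rec.id):].strip())


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write unwrapped FASTA (one sequence line per record)."""
    bio = (
        _BioSeqRecord(Seq(r.bases), id=r.id, description=r.description)
        for r in records
    )
    return SeqIO.write(bio, str(path), "fasta-2line")


SAMPLE_SHEET_COLUMNS = [
    "sample_id", "index_f", "index_r", "marker", "site_id",
    "elevation_m", "field_replicate", "rpa_replicate", "is_negative_control",
]

_INDEX_LEN = 20


@dataclasses.dataclass(frozen=True)
class SampleRow:
    sample_id: str
    index_f: str
    index_r: str
    marker: str  # "edna" | "barcode"
    site_id: str
    elevation_m: int
    field_replicate: int
    rpa_replicate: int
    is_negative_control: bool


class SampleSheet:
    """Dual 20-base index pairs -> samples, with site/replicate metadata.

    Invariants enforced on construction: unique sample ids, unique
    ``(index_f, index_r)`` pairs, exactly 20-base indexes.
    """

    def __init__(self, rows: Sequence[SampleRow]):
        self.rows: list[SampleRow] = list(rows)
        seen_ids: set[str] = set()
        seen_pairs: set[tuple[str, str]] = set()
        for i, row in enumerate(self.rows):
            if row.sample_id in seen_ids:
                raise ValueError(f"sample sheet row {i}: duplicate sample_id {row.sample_id!r}")
            seen_ids.add(row.sample_id)
            for name, idx in (("index_f", row.index_f), ("index_r", row.index_r)):
                if len(idx) != _INDEX_LEN:
                    raise ValueError(
                        f"sample sheet row {i} ({row.sample_id}): {name} has length "
                        f"{len(idx)}, expected {_INDEX_LEN}"
                    )
                if set(idx) - set("ACGT"):
                    raise ValueError(
                        f"sample sheet row {i} ({row.sample_id}): {name} has non-ACGT bases"
                    )
            pair = (row.index_f, row.index_r)
            if pair in seen_pairs:
                raise ValueError(
                    f"sample sheet row {i} ({row.sample_id}): duplicate index pair {pair}"
                )
            seen_pairs.add(pair)
            if row.marker not in ("edna", "barcode"):
                raise ValueError(f"sample sheet row {i}: unknown marker {row.marker!r}")
            if row.elevation_m < 0 or row.field_replicate < 1 or row.rpa_replicate < 1:
                raise ValueError(f"sample sheet row {i} ({row.sample_id}): bad metadata values")
        self.by_id: dict[str, SampleRow] = {r.sample_id: r for r in self.rows}

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[SampleRow]:
        return iter(self.rows)

    @property
    def negative_controls(self) -> list[SampleRow]:
        return [r for r in self.rows if r.is_negative_control]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows],
                            columns=SAMPLE_SHEET_COLUMNS)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Parse the TSV sample sheet dialect ('#'-prefixed comment lines ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path}: missing columns {sorted(missing)}")
    rows = []
    for _, rec in df.iterrows():
        rows.append(SampleRow(
            sample_id=str(rec.sample_id),
            index_f=str(rec.index_f).upper(),
            index_r=str(rec.index_r).upper(),
            marker=str(rec.marker),
            site_id=str(rec.site_id),
            elevation_m=int(rec.elevation_m),
            field_replicate=int(rec.field_replicate),
            rpa_replicate=int(rec.rpa_replicate),
            is_negative_control=str(rec.is_negative_control).strip().lower()
            in ("1", "true", "yes"),
        ))
    return SampleSheet(rows)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RunConfig:
    """Pipeline-wide thresholds.

    Defaults are the workflow's operating point: mean Phred > 12, insert length
    windows 172-212 bp (eDNA marker) and 520-580 bp (barcoding marker), dual
    identity thresholds 95%/99%, per-sample-per-taxon noise floor of 5 reads,
    and edit-distance tolerances of 2 (indexes) / 3 (primers).
    """

    min_mean_phred: float = 12.0
    length_window_edna: tuple[int, int] = (172, 212)
    length_window_barcode: tuple[int, int] = (520, 580)
    identity_thresholds: tuple[float, ...] = (95.0, 99.0)
    noise_floor: int = 5
    index_edit_tolerance: int = 2
    primer_edit_tolerance: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.index_edit_tolerance < 0 or self.primer_edit_tolerance < 0:
            raise ValueError("edit tolerances must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise floor must be >= 0")
        for t in self.identity_thresholds:
            if not 0 < t <= 100:
                raise ValueError(f"identity threshold {t} outside (0, 100]")
        for lo, hi in (self.length_window_edna, self.length_window_barcode):
            if lo > hi:
                raise ValueError("length window lower bound exceeds upper bound")

    def length_window(self, marker: str) -> tuple[int, int]:
        if marker == "edna":
            return self.length_window_edna
        if marker == "barcode":
            return self.length_window_barcode
        raise ValueError(f"unknown marker {marker!r}")
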