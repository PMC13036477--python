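"""Quality/length filtering and exact dereplication.

"Average Phred" is the quality of the mean error probability,
``Q = -10·log10(mean_i 10^(-q_i/10))``, not the arithmetic mean of Phred
values — the mathematically meaningful average, and stricter on mixed-quality
reads.  Filtering happens before dereplication because identical sequences
may carry different quality strings.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Iterator

import numpy as np

from fieldamp.io_core import SequenceRecord, RunConfig


def mean_phred(record: SequenceRecord) -> float:
    """Error-probability-averaged Phred quality of a read."""
    if not record.quality:
        raise ValueError(f"record {record.id}: no quality values")
    q = np.asarray(record.quality, dtype=float)
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def filter_reads(
    stream: Iterable[SequenceRecord],
    marker: str,
    config: RunConfig,
) -> tuple[list[SequenceRecord], Counter]:
    """Keep reads with mean Phred strictly above the minimum and length inside
    the marker's closed window; tally rejections by cause."""
    lo, hi = config.length_window(marker)  # raises on unknown marker
    kept: list[SequenceRecord] = []
    tally: Counter = Counter()
    for rec in stream:
        if not lo <= len(rec) <= hi:
            tally["length"] += 1
        elif mean_phred(rec) <= config.min_mean_phred:
            tally["quality"] += 1
        else:
            kept.append(rec)
            tally["kept"] += 1
    return kept, tally


@dataclasses.dataclass
class UniqueSequence:
    bases: str
    size: int
    member_ids: list[str]


@dataclasses.dataclass
class DereplicatedSet:
    """Unique sequences with collapsed read counts, ordered by size descending
    (ties broken by first occurrence)."""

    uniques: list[UniqueSequence]

    @property
    def total_size(self) -> int:
        return sum(u.size for u in self.uniques)

    def __len__(self) -> int:
        return len(self.uniques)

    def __iter__(self) -> Iterator[UniqueSequence]:
        return iter(self.uniques)

    def to_records(self, prefix: str = "uniq") -> list[SequenceRecord]:
        """FASTA-ready records with Vsearch-style ``;size=N`` annotations."""
        return [
            SequenceRecord(f"{prefix}{i:06d};size={u.size}", u.bases)
            for i, u in enumerate(self.uniques)
        ]


def dereplicate(stream: Iterable[SequenceRecord]) -> DereplicatedSet:
    """Collapse exactly identical sequences (N counts as a literal character)."""
    order: dict[str, int] = {}
    buckets: dict[str, UniqueSequence] = {}
    for rec in stream:
        if rec.bases in buckets:
            u = buckets[rec.bases]
            u.size += 1
            u.member_ids.append(rec.id)
        else:
            order[rec.bases] = len(order)
            buckets[rec.bases] = UniqueSequence(rec.bases, 1, [rec.id])
    uniques = sorted(buckets.values(), key=lambda u: (-u.size, order[u.bases]))
    return DereplicatedSet(uniques)
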