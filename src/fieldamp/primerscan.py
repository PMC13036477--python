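"""Primer elongation from a curated multiple alignment.

Isothermal (RPA) amplification wants long primers (~25-30 bases), so existing
short PCR primers are extended across adjacent conserved alignment columns
while minimising introduced degeneracies.  The procedure: drop columns with
more than 50% gaps, profile base frequencies and conservation per column,
collapse each column to an IUPAC consensus covering every base at or above a
minor-frequency threshold, then enumerate all allowed extension windows of a
seed primer and rank them (fewest degeneracies, then highest mean
conservation, then longest).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from fieldamp.io_core import IUPAC_FROM_SET, revcomp

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclasses.dataclass
class AlignmentProfile:
    """Per-column base frequencies (among non-gap rows), gap fraction and
    conservation (the maximal base frequency)."""

    freqs: np.ndarray  # (L, 4) over A,C,G,T; rows sum to 1 where any base present
    gap_fraction: np.ndarray  # (L,)
    conservation: np.ndarray  # (L,)

    def __len__(self) -> int:
        return len(self.gap_fraction)


def _check_rows(rows: Sequence[str]) -> list[str]:
    rows = [r.upper() for r in rows]
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    return rows


def profile_alignment(rows: Sequence[str]) -> AlignmentProfile:
    rows = _check_rows(rows)
    length = len(rows[0])
    counts = np.zeros((length, 4))
    gaps = np.zeros(length)
    for row in rows:
        for i, c in enumerate(row):
            if c in _BASE_IDX:
                counts[i, _BASE_IDX[c]] += 1
            else:
                gaps[i] += 1
    non_gap = counts.sum(axis=1)
    freqs = np.divide(counts, non_gap[:, None], where=non_gap[:, None] > 0,
                      out=np.zeros_like(counts))
    return AlignmentProfile(
        freqs=freqs,
        gap_fraction=gaps / len(rows),
        conservation=freqs.max(axis=1),
    )


def trim_gappy_columns(rows: Sequence[str], max_gap_fraction: float = 0.5) -> list[str]:
    """Remove alignment columns with gap fraction strictly above the cutoff
    (a column at exactly 50% gaps is retained); row order is preserved."""
    rows = _check_rows(rows)
    prof = profile_alignment(rows)
    keep = [i for i in range(len(prof)) if prof.gap_fraction[i] <= max_gap_fraction]
    return ["".join(r[i] for i in keep) for r in rows]


def iupac_consensus(freqs: Sequence[float], minor_freq_threshold: float = 0.05) -> str:
    """IUPAC code covering every base whose frequency reaches the threshold."""
    arr = np.asarray(freqs, dtype=float)
    if arr.shape != (4,):
        raise ValueError("freqs must be 4 values over A,C,G,T")
    if arr.sum() == 0:
        raise ValueError("all-gap column has no consensus")
    bases = {b for b, i in _BASE_IDX.items() if arr[i] >= minor_freq_threshold}
    if not bases:  # nothing reaches the threshold: fall back to the majority base
        bases = {max(_BASE_IDX, key=lambda b: arr[_BASE_IDX[b]])}
    return IUPAC_FROM_SET[frozenset(bases)]


@dataclasses.dataclass
class PrimerCandidate:
    sequence: str
    start: int  # alignment interval, 0-based half-open
    end: int
    n_degenerate: int
    mean_conservation: float

    @property
    def length(self) -> int:
        return self.end - self.start


def elongate_primer(
    rows: Sequence[str],
    seed_interval: tuple[int, int],
    direction: str = "both",  # "5prime" | "3prime" | "both"
    target_len_range: tuple[int, int] = (25, 30),
    max_degeneracy: int = 3,
    minor_freq_threshold: float = 0.05,
) -> list[PrimerCandidate]:
    """Enumerate and rank every extension of a seed primer binding interval.

    All windows containing the seed, with length inside ``target_len_range``
    and growth restricted to the allowed direction(s), are scored; candidates
    exceeding ``max_degeneracy`` degenerate positions are dropped.  Ranking
    is total: degeneracies ascending, mean conservation descending, length
    descending, start position ascending.
    """
    rows = _check_rows(rows)
    prof = profile_alignment(rows)
    length = len(prof)
    s0, e0 = seed_interval
    if not (0 <= s0 < e0 <= length):
        raise ValueError(f"seed interval {seed_interval} outside alignment of length {length}")
    lo, hi = target_len_range
    if e0 - s0 > hi:
        raise ValueError(f"seed of {e0 - s0} bases exceeds upper length bound {hi}")
    if direction not in ("5prime", "3prime", "both"):
        raise ValueError(f"unknown direction {direction!r}")

    starts = range(0, s0 + 1) if direction in ("5prime", "both") else [s0]
    candidates: list[PrimerCandidate] = []
    for s in starts:
        ends = (range(e0, length + 1) if direction in ("3prime", "both") else [e0])
        for e in ends:
            if not lo <= e - s <= hi:
                continue
            cols = range(s, e)
            try:
                seq = "".join(iupac_consensus(prof.freqs[i], minor_freq_threshold)
                              for i in cols)
            except ValueError:  # all-gap column inside the window
                continue
            n_deg = sum(1 for c in seq if c not in "ACGT")
            if n_deg > max_degeneracy:
                continue
            candidates.append(PrimerCandidate(
                seq, s, e, n_deg, float(np.mean(prof.conservation[s:e]))))
    candidates.sort(key=lambda c: (c.n_degenerate, -c.mean_conservation, -c.length, c.start))
    return candidates


def self_complement_warning(primer: str, min_overlap: int = 8) -> bool:
    """Crude artefact screen: True when the primer shares a reverse-complement
    self-overlap of at least ``min_overlap`` bases (hairpin/dimer risk)."""
    rc = revcomp(primer)
    for i in range(len(primer) - min_overlap + 1):
        if primer[i:i + min_overlap] in rc:
            return True
    return False
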