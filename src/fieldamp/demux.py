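"""Dual-index demultiplexing within a bounded edit distance, plus primer trimming.

Each pooled read is searched in both orientations: the leading window for a
sample's forward index and the trailing window for the reverse complement of
its reverse index, each within ``tol_index`` edits.  A sample matches only if
both indexes match; if two or more samples tie at the minimal summed distance
the read is left unassigned as ambiguous — conservatism over yield.  Primers
(IUPAC-aware) are then located within ``tol_primer`` edits and trimmed;
failure to find a primer leaves the insert untrimmed but flagged.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Iterator, Optional

import edlib

from fieldamp.io_core import SequenceRecord, SampleSheet, revcomp, IUPAC_CODES

#: edlib equality pairs letting degenerate primer symbols match compatible bases.
_IUPAC_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC_CODES.items()
    if len(bases) > 1
    for base in bases
]

# extra slack beyond index length + tolerance when searching read ends;
# RPA adapter slop is small, so a bounded window keeps the search linear.
_WINDOW_PAD = 5


def edit_distance(a: str, b: str, cap: int) -> int:
    """Levenshtein distance of ``a`` vs ``b``, exact whenever the true distance
    is <= ``cap``; returns ``cap + 1`` as the exceeded sentinel otherwise."""
    if not a or not b:
        raise ValueError("edit_distance requires non-empty sequences")
    d = edlib.align(a, b, mode="NW", k=cap)["editDistance"]
    return cap + 1 if d == -1 else d


@dataclasses.dataclass
class DemuxResult:
    read_id: str
    sample_id: Optional[str]  # None when unassigned
    reason: Optional[str] = None  # "no_match" | "ambiguous" when unassigned
    orientation: Optional[str] = None  # "forward" | "reverse"
    insert: Optional[SequenceRecord] = None
    primers_trimmed: bool = False

    @property
    def assigned(self) -> bool:
        return self.sample_id is not None


def _infix_distance(pattern: str, text: str, tol: int) -> tuple[int, Optional[tuple[int, int]]]:
    """Best edit distance of ``pattern`` anywhere inside ``text`` (infix mode);
    returns (distance-or-sentinel, (start, end_exclusive) of the best hit)."""
    res = edlib.align(pattern, text, mode="HW", k=tol, task="locations")
    if res["editDistance"] == -1:
        return tol + 1, None
    start, end = res["locations"][0]
    return res["editDistance"], (start, end + 1)


def _find_primer(pattern: str, text: str, tol: int) -> Optional[tuple[int, int]]:
    res = edlib.align(pattern, text, mode="HW", k=tol, task="locations",
                      additionalEqualities=_IUPAC_EQUALITIES)
    if res["editDistance"] == -1:
        return None
    start, end = res["locations"][0]
    return start, end + 1


def _match_read(
    bases: str, sheet: SampleSheet, tol: int, window: int
) -> list[tuple[int, str, str, int, int]]:
    """All candidate (total_distance, sample_id, orientation, f_end, r_start)."""
    out = []
    for orientation in ("forward", "reverse"):
        seq = bases if orientation == "forward" else revcomp(bases)
        head = seq[:window]
        tail = seq[-window:]
        tail_off = len(seq) - len(tail)
        for row in sheet:
            d_f, loc_f = _infix_distance(row.index_f, head, tol)
            if d_f > tol:
                continue
            d_r, loc_r = _infix_distance(revcomp(row.index_r), tail, tol)
            if d_r > tol:
                continue
            out.append((d_f + d_r, row.sample_id, orientation,
                        loc_f[1], tail_off + loc_r[0]))
    return out


def demultiplex(
    reads: Iterable[SequenceRecord],
    sheet: SampleSheet,
    tol_index: int = 2,
    tol_primer: int = 3,
    primers: Optional[dict[str, tuple[str, str]]] = None,
) -> Iterator[DemuxResult]:
    """Assign each read to the unique sample whose dual indexes both match.

    Yields one :class:`DemuxResult` per input read (the assigned + unassigned
    streams partition the input).  Assigned inserts are emitted in forward
    sense with indexes removed and, when located, primers trimmed.
    """
    if len(sheet) == 0:
        raise ValueError("empty sample sheet")
    window = 20 + tol_index + _WINDOW_PAD

    for read in reads:
        candidates = _match_read(read.bases, sheet, tol_index, window)
        if not candidates:
            yield DemuxResult(read.id, None, reason="no_match")
            continue
        best = min(c[0] for c in candidates)
        top = [c for c in candidates if c[0] == best]
        top_samples = {c[1] for c in top}
        if len(top_samples) > 1:
            yield DemuxResult(read.id, None, reason="ambiguous")
            continue
        dist, sample_id, orientation, f_end, r_start = top[0]

        rec = read if orientation == "forward" else read.reverse_complement()
        core = rec.bases[f_end:r_start]
        core_q = None if rec.quality is None else rec.quality[f_end:r_start]

        trimmed = False
        row = sheet.by_id[sample_id]
        if primers and row.marker in primers:
            fwd, rev = primers[row.marker]
            loc_f = _find_primer(fwd, core[: len(fwd) + tol_primer + _WINDOW_PAD], tol_primer)
            rc_rev = revcomp(rev)
            tail_window = len(rc_rev) + tol_primer + _WINDOW_PAD
            tail_text = core[-tail_window:]
            loc_r = _find_primer(rc_rev, tail_text, tol_primer)
            if loc_f is not None and loc_r is not None:
                start = loc_f[1]
                end = len(core) - len(tail_text) + loc_r[0]
                if start < end:
                    core = core[start:end]
                    core_q = None if core_q is None else core_q[start:end]
                    trimmed = True
        if not core:
            yield DemuxResult(read.id, None, reason="no_match")
            continue
        insert = SequenceRecord(read.id, core, core_q)
        yield DemuxResult(read.id, sample_id, orientation=orientation,
                          insert=insert, primers_trimmed=trimmed)


def demux_summary(results: Iterable[DemuxResult]) -> Counter:
    """Tally: per-sample assigned counts plus 'ambiguous' / 'no_match'."""
    tally: Counter = Counter()
    for r in results:
        tally[r.sample_id if r.assigned else r.reason] += 1
    return tally
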