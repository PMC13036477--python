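"""Best-hit taxonomic assignment at dual percent-identity thresholds.

A shared-k-mer prescreen (both orientations) ranks reference candidates, the
top candidates are aligned locally (match +2, mismatch −3, gap open −5,
gap extend −2 — conventional nucleotide defaults), and the single best hit
(max score; ties broken by identity, then local-before-base provenance, then
accession) is tested against each identity threshold independently.  Percent
identity is computed over alignment columns with gaps in the denominator;
IUPAC-degenerate subject positions compatible with the query base count as
matches.  A minimum alignment-length fraction (default 0.8 of the query)
guards against spurious short local hits.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from fieldamp.io_core import IUPAC_CODES, revcomp
from fieldamp.refdb import ReferenceDB, TaxonomyLineage, RANKS

_ALPHABET = "ACGTRYSWKMBDHVN"


def _iupac_matrix() -> substitution_matrices.Array:
    m = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = 2.0 if set(IUPAC_CODES[a]) & set(IUPAC_CODES[b]) else -3.0
    return m


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _iupac_matrix()
    aligner.open_gap_score = -7  # a length-L gap costs 5 + 2L
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


@dataclasses.dataclass
class AssignmentHit:
    query_id: str
    subject_accession: str
    percent_identity: float
    alignment_length: int
    score: int
    subject_lineage: TaxonomyLineage
    subject_provenance: str
    orientation: str = "forward"


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _kmer_index(db: ReferenceDB, k: int) -> dict[str, tuple[str, ...]]:
    cache = getattr(db, "_kmer_cache", None)
    if cache is not None and cache[0] == k:
        return cache[1]
    index: dict[str, list[str]] = {}
    for rec in db:
        for km in _kmers(rec.bases, k):
            index.setdefault(km, []).append(rec.accession)
    frozen = {km: tuple(accs) for km, accs in index.items()}
    db._kmer_cache = (k, frozen)
    return frozen


def _prescreen_detail(
    query: str, db: ReferenceDB, k: int, top_n: int
) -> list[tuple[str, str]]:
    """Candidates as (accession, best orientation), ranked by shared distinct
    k-mers descending, accession ascending."""
    if len(query) < k:
        raise ValueError(f"query shorter than k={k}")
    index = _kmer_index(db, k)
    scores: dict[str, tuple[int, str]] = {}
    for orientation, seq in (("forward", query), ("reverse", revcomp(query))):
        counts: Counter = Counter()
        for km in _kmers(seq, k):
            for acc in index.get(km, ()):
                counts[acc] += 1
        for acc, c in counts.items():
            if acc not in scores or c > scores[acc][0]:
                scores[acc] = (c, orientation)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1][0], kv[0]))
    return [(acc, orient) for acc, (c, orient) in ranked[:top_n]]


def kmer_prescreen(query: str, db: ReferenceDB, k: int = 11, top_n: int = 50) -> list[str]:
    """Reference accessions sharing the most distinct k-mers with the query."""
    return [acc for acc, _ in _prescreen_detail(query, db, k, top_n)]


def align_identity(query: str, subject: str) -> tuple[float, int, int]:
    """Local alignment of query vs subject: (percent identity, columns, score)."""
    if not query or not subject:
        raise ValueError("align_identity requires non-empty sequences")
    alignments = _ALIGNER.align(subject, query)
    aln = alignments[0]
    t_blocks, q_blocks = aln.aligned
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)  # gap columns
        for off in range(te - ts):
            s, q = subject[ts + off], query[qs + off]
            if set(IUPAC_CODES[s]) & set(IUPAC_CODES[q]):
                matches += 1
        columns += te - ts
        prev_t, prev_q = te, qe
    if columns == 0:
        return 0.0, 0, 0
    return float(100.0 * matches / columns), int(columns), int(round(aln.score))


def best_hit(
    query: str,
    db: ReferenceDB,
    thresholds: Sequence[float] = (95.0, 99.0),
    query_id: str = "query",
    k: int = 11,
    top_n: int = 50,
    align_top: int = 10,
    min_aln_fraction: float = 0.8,
) -> tuple[Optional[AssignmentHit], dict[float, bool]]:
    """The single best reference hit, tested against each threshold.

    Candidates from the prescreen (at most ``align_top`` aligned) are ordered
    by score descending, identity descending, local provenance before base,
    accession ascending; hits spanning fewer than ``min_aln_fraction`` of the
    query's length are discarded.  Returns ``(hit_or_None, {threshold: pass})``.
    """
    if len(db) == 0:
        raise ValueError("empty reference database")
    candidates = _prescreen_detail(query, db, k, top_n)[:align_top]
    best: Optional[AssignmentHit] = None
    best_key = None
    for acc, orientation in candidates:
        rec = db[acc]
        oriented = query if orientation == "forward" else revcomp(query)
        pid, columns, score = align_identity(oriented, rec.bases)
        if columns < min_aln_fraction * len(query):
            continue
        key = (-score, -pid, rec.provenance != "local", acc)
        if best_key is None or key < best_key:
            best_key = key
            best = AssignmentHit(query_id, acc, pid, columns, score,
                                 rec.lineage, rec.provenance, orientation)
    if best is None:
        return None, {t: False for t in thresholds}
    return best, {t: best.percent_identity >= t for t in thresholds}


def pass_column(threshold: float) -> str:
    return f"pass_{threshold:g}"


def assign_table(
    queries: Iterable[tuple[str, str, int, str]],
    db: ReferenceDB,
    thresholds: Sequence[float] = (95.0, 99.0),
    **kwargs,
) -> pd.DataFrame:
    """Assign many queries; one row per query, unassigned rows included.

    ``queries`` yields ``(query_id, sample_id, size, bases)`` tuples —
    dereplicated unique sequences carry their collapsed read count as
    ``size`` so downstream tabulation can re-expand counts.
    """
    rows = []
    for query_id, sample_id, size, bases in queries:
        hit, passes = best_hit(bases, db, thresholds, query_id=query_id, **kwargs)
        row: dict = {"query_id": query_id, "sample_id": sample_id, "size": size}
        if hit is None:
            row.update(accession=None, identity=float("nan"), aln_len=0, score=0,
                       provenance=None, orientation=None)
            lineage = TaxonomyLineage()
        else:
            row.update(accession=hit.subject_accession, identity=hit.percent_identity,
                       aln_len=hit.alignment_length, score=hit.score,
                       provenance=hit.subject_provenance, orientation=hit.orientation)
            lineage = hit.subject_lineage
        for rank in RANKS:
            row[rank] = getattr(lineage, rank)
        for t in thresholds:
            row[pass_column(t)] = passes[t]
        rows.append(row)
    return pd.DataFrame(rows)
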