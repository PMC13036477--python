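"""Polished consensus barcodes from noisy single-specimen long reads.

Reads are greedily clustered by centroid identity (both orientations
checked), the dominant cluster's medoid read seeds a draft, and up to three
rounds of global alignment + per-column majority voting polish it.  Terminal
columns supported by fewer than half the cluster's reads are stripped,
automating the manual removal of divergent sequence ends that plagues
low-coverage long-read consensus building.  Specimens with fewer than three
reads are refused rather than risking an erroneous consensus.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Optional

import edlib
import numpy as np
from Bio import Align

from fieldamp.io_core import SequenceRecord, revcomp

_MAX_ROUNDS = 3
_MEDOID_SAMPLE = 30
_MAX_CLUSTER_READS = 300


@dataclasses.dataclass
class ReadCluster:
    centroid: str
    members: list[SequenceRecord]  # stored re-oriented to the centroid

    @property
    def size(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class ConsensusResult:
    consensus: Optional[SequenceRecord]
    n_supporting_reads: int
    cluster_fraction: float
    trimmed_left: int = 0
    trimmed_right: int = 0
    converged: bool = False
    status: str = "ok"  # "ok" | "insufficient_reads"


def _identity(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_reads(
    reads: list[SequenceRecord], identity_threshold: float = 0.85
) -> list[ReadCluster]:
    """Greedy centroid clustering, reads visited by length descending.

    A read joins the first existing cluster whose centroid identity (better
    of the two orientations) reaches the threshold, else founds a new
    cluster.  Clusters are returned ordered by size descending.

    The threshold compares two *reads*, both carrying independent sequencing
    error, so it must sit below the template-level separation one has in
    mind: at ~5% per-read error, same-template reads pair at only ~90%
    identity.  The default 0.85 keeps those together while still splitting
    templates below ~94% mutual identity; congeneric templates (~97-99%
    identical 16S) land in one cluster regardless — a documented limitation
    for mixed swabs.
    """
    if len(reads) < 3:
        raise ValueError("insufficient reads: consensus building needs >= 3 reads")
    clusters: list[ReadCluster] = []
    for read in sorted(reads, key=lambda r: -len(r)):
        placed = False
        for cl in clusters:
            fwd = _identity(read.bases, cl.centroid)
            rc = read.reverse_complement()
            rev = _identity(rc.bases, cl.centroid)
            if max(fwd, rev) >= identity_threshold:
                cl.members.append(read if fwd >= rev else rc)
                placed = True
                break
        if not placed:
            clusters.append(ReadCluster(read.bases, [read]))
    return sorted(clusters, key=lambda c: -c.size)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def _column_votes(
    aligner: Align.PairwiseAligner, draft: str, reads: list[str]
) -> tuple[list[Counter], list[Counter], np.ndarray]:
    """Stack read-vs-draft alignments into per-column base/deletion votes,
    per-gap insertion votes, and per-column aligned-base support counts."""
    n = len(draft)
    votes: list[Counter] = [Counter() for _ in range(n)]
    inserts: list[Counter] = [Counter() for _ in range(n + 1)]
    support = np.zeros(n, dtype=int)
    for read in reads:
        aln = next(iter(aligner.align(draft, read)))
        t_blocks, q_blocks = aln.aligned
        if len(t_blocks) == 0:
            continue
        first, last = t_blocks[0][0], t_blocks[-1][1]
        covered = np.zeros(n, dtype=bool)
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            for k in range(te - ts):
                votes[ts + k][read[qs + k]] += 1
                support[ts + k] += 1
                covered[ts + k] = True
        # deletions: spanned draft columns with no aligned read base
        for i in range(first, last):
            if not covered[i]:
                votes[i]["-"] += 1
        # insertions: query advances between blocks while target does not
        for b in range(len(t_blocks) - 1):
            te, ts_next = t_blocks[b][1], t_blocks[b + 1][0]
            qe, qs_next = q_blocks[b][1], q_blocks[b + 1][0]
            if qs_next > qe and ts_next == te:
                inserts[te][read[qe:qs_next]] += 1
    return votes, inserts, support


def _vote_base(counter: Counter, current: str) -> str:
    if not counter:
        return current
    top = max(counter.values())
    winners = [b for b, c in counter.items() if c == top]
    if current in winners:  # stability: keep the draft base on ties
        return current
    return sorted(winners)[0]


def polish(cluster: list[SequenceRecord], seed: int = 0) -> ConsensusResult:
    """Medoid draft + iterative majority-vote polishing of one read cluster.

    Per column the majority symbol over {A,C,G,T,deletion} wins; an insertion
    between columns is accepted when more than half of the reads carry one.
    Iteration stops when a round leaves the draft unchanged (converged) or
    after three rounds.  Cluster fraction is filled in by the caller when the
    cluster is one of several.
    """
    if not cluster:
        raise ValueError("empty cluster")
    rng = np.random.default_rng(seed)
    reads = list(cluster)
    if len(reads) > _MAX_CLUSTER_READS:
        keep = rng.choice(len(reads), size=_MAX_CLUSTER_READS, replace=False)
        reads = [reads[i] for i in sorted(keep)]
    seqs = [r.bases for r in reads]

    # medoid draft: minimum summed edit distance to <= 30 sampled mates
    mates = seqs
    if len(seqs) > _MEDOID_SAMPLE:
        idx = rng.choice(len(seqs), size=_MEDOID_SAMPLE, replace=False)
        mates = [seqs[i] for i in idx]
    draft = min(seqs, key=lambda s: sum(
        edlib.align(s, m, mode="NW")["editDistance"] for m in mates))

    aligner = _make_aligner()
    converged = False
    for _ in range(_MAX_ROUNDS):
        votes, inserts, _ = _column_votes(aligner, draft, seqs)
        half = len(seqs) / 2
        out: list[str] = []
        for i in range(len(draft)):
            if sum(c for s, c in inserts[i].items()) > half:
                out.append(inserts[i].most_common(1)[0][0])
            base = _vote_base(votes[i], draft[i])
            if base != "-":
                out.append(base)
        if sum(c for s, c in inserts[len(draft)].items()) > half:
            out.append(inserts[len(draft)].most_common(1)[0][0])
        new_draft = "".join(out)
        if new_draft == draft:
            converged = True
            break
        draft = new_draft

    # end trimming: strip terminal columns aligned in < 50% of reads
    _, _, support = _column_votes(aligner, draft, seqs)
    half = len(seqs) / 2
    left = 0
    while left < len(draft) and support[left] < half:
        left += 1
    right = len(draft)
    while right > left and support[right - 1] < half:
        right -= 1
    trimmed = draft[left:right]
    if not trimmed:
        trimmed, left, right = draft, 0, len(draft)

    rec = SequenceRecord("consensus", trimmed)
    return ConsensusResult(
        consensus=rec,
        n_supporting_reads=len(cluster),
        cluster_fraction=1.0,
        trimmed_left=left,
        trimmed_right=len(draft) - right,
        converged=converged,
    )


def consensus_barcode(
    reads: list[SequenceRecord],
    min_reads: int = 3,
    identity_threshold: float = 0.85,
    seed: int = 0,
) -> ConsensusResult:
    """Cluster a specimen's filtered reads and polish the dominant cluster."""
    if len(reads) < min_reads:
        return ConsensusResult(None, len(reads), 0.0, status="insufficient_reads")
    clusters = cluster_reads(reads, identity_threshold)
    top = clusters[0]
    result = polish(top.members, seed=seed)
    result.cluster_fraction = top.size / len(reads)
    return result
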