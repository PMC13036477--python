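import numpy as np
import pytest

from fieldamp import demux, simdata
from fieldamp.io_core import SampleRow, SampleSheet, SequenceRecord, revcomp


def levenshtein_full_dp(a: str, b: str) -> int:
    """Independent full dynamic-programming Levenshtein oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


class TestEditDistance:
    def test_identity(self):
        assert demux.edit_distance("ACGT", "ACGT", 2) == 0

    def test_two_substitutions_equal_full_dp(self):
        a = "ACGTTGCAAGGCTTACCGAT"
        b = "ACCTTGCAAGGCTTACCGAA"
        assert demux.edit_distance(a, b, 2) == 2 == levenshtein_full_dp(a, b)

    def test_exceeding_cap_returns_sentinel(self):
        assert demux.edit_distance("AAAA", "TTTT", 2) == 3  # sentinel = cap + 1

    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = simdata._random_seq(rng, int(rng.integers(10, 40)))
            b = simdata._random_seq(rng, int(rng.integers(10, 40)))
            true = levenshtein_full_dp(a, b)
            cap = int(rng.integers(1, 12))
            got = demux.edit_distance(a, b, cap)
            assert got == (true if true <= cap else cap + 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            demux.edit_distance("", "A", 1)


def _sheet(pairs):
    rows = []
    for i, (f, r) in enumerate(pairs):
        rows.append(SampleRow(f"S{i}", f, r, "edna", "site0", 100, 1, 1, False))
    return SampleSheet(rows)


IDX_A = "ACGTTGCAAGGCTTACCGAT"  # aperiodic: shifted self-matches stay distant
IDX_B = "TTGGCCAATTGGCCAATTGG"
IDX_C = "GATCGATCGATCGATCGATC"
INSERT = "ACCTGGATCATTTACGGCTAGCGATACCATGGATCGATTACA"


def _read(index_f, index_r, insert=INSERT):
    return SequenceRecord("r0", index_f + insert + revcomp(index_r))


class TestDemultiplex:
    def test_exact_read_assigned_both_orientations(self):
        sheet = _sheet([(IDX_A, IDX_B)])
        (fwd,) = demux.demultiplex([_read(IDX_A, IDX_B)], sheet)
        assert fwd.assigned and fwd.sample_id == "S0" and fwd.orientation == "forward"
        rc = _read(IDX_A, IDX_B).reverse_complement()
        (rev,) = demux.demultiplex([rc], sheet)
        assert rev.assigned and rev.orientation == "reverse"
        assert rev.insert.bases == fwd.insert.bases  # emitted in forward sense

    def test_tolerance_boundary_on_mutated_index(self):
        # two interior substitutions (edge errors can be absorbed by the
        # free ends of infix matching)
        mutated = IDX_A[:7] + "C" + IDX_A[8:13] + "G" + IDX_A[14:]
        assert demux.edit_distance(IDX_A, mutated, 5) == 2
        read = SequenceRecord("r1", mutated + INSERT + revcomp(IDX_B))
        sheet = _sheet([(IDX_A, IDX_B)])
        (hit,) = demux.demultiplex([read], sheet, tol_index=2)
        assert hit.assigned
        (miss,) = demux.demultiplex([read], sheet, tol_index=1)
        assert not miss.assigned and miss.reason == "no_match"

    def test_equidistant_tie_is_ambiguous(self):
        # index region one substitution away from both samples' index_f
        f1 = "A" + IDX_C[1:]
        f2 = "C" + IDX_C[1:]
        middle = "G" + IDX_C[1:]
        sheet = _sheet([(f1, IDX_B), (f2, IDX_B)])
        (res,) = demux.demultiplex([SequenceRecord("r2", middle + INSERT + revcomp(IDX_B))],
                                   sheet, tol_index=2)
        assert not res.assigned and res.reason == "ambiguous"

    def test_empty_sheet_rejected(self):
        with pytest.raises(ValueError):
            list(demux.demultiplex([], SampleSheet([])))

    def test_primer_trimming_recovers_insert(self):
        fwd, rev = simdata.DEFAULT_PRIMERS["edna"]
        rng = np.random.default_rng(3)
        body = (IDX_A + simdata._realize_primer(rng, fwd) + INSERT
                + revcomp(simdata._realize_primer(rng, rev)) + revcomp(IDX_B))
        sheet = _sheet([(IDX_A, IDX_B)])
        (res,) = demux.demultiplex([SequenceRecord("r3", body)], sheet,
                                   primers=simdata.DEFAULT_PRIMERS)
        assert res.primers_trimmed
        assert res.insert.bases == INSERT


@pytest.fixture(scope="module")
def simulated_pool():
    com = simdata.simulate_references(6, divergence=0.10, seed=2, n_bycatch=1)
    sheet, smap = simdata.simulate_sample_sheet(n_sites=3, field_replicates=1,
                                                rpa_replicates=1, seed=3)
    reads, truth = simdata.simulate_reads(com, sheet, simdata.ErrorModel(0.02, 0.005, 0.005),
                                          60, seed=4, specimen_map=smap)
    return reads, truth, sheet


class TestDemuxProperties:
    def test_partition_every_read_once(self, simulated_pool):
        reads, truth, sheet = simulated_pool
        results = list(demux.demultiplex(reads, sheet))
        assert sorted(r.read_id for r in results) == sorted(r.id for r in reads)

    def test_tolerance_monotonicity(self, simulated_pool):
        reads, truth, sheet = simulated_pool
        counts = []
        for tol in (0, 1, 2, 3):
            res = demux.demultiplex(reads, sheet, tol_index=tol)
            counts.append(sum(1 for r in res if r.assigned))
        assert counts == sorted(counts)

    def test_zero_error_closed_loop(self):
        com = simdata.simulate_references(5, divergence=0.10, seed=5)
        sheet, _ = simdata.simulate_sample_sheet(n_sites=2, field_replicates=1,
                                                 rpa_replicates=1, seed=6)
        reads, truth = simdata.simulate_reads(com, sheet, simdata.ErrorModel(0, 0, 0),
                                              25, seed=7)
        res = list(demux.demultiplex(reads, sheet, tol_index=0,
                                     primers=simdata.DEFAULT_PRIMERS))
        tr = dict(zip(truth.read_id, truth.sample_id))
        assert all(r.assigned and r.sample_id == tr[r.read_id] for r in res)
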