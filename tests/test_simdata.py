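import numpy as np
import pytest
from scipy import stats

from fieldamp import simdata
from fieldamp.io_core import revcomp


class TestSimulateReferences:
    def test_zero_divergence_gives_identical_sequences(self):
        com = simdata.simulate_references(6, divergence=0.0, seed=0)
        seqs = {t.true_sequence_long for t in com.taxa}
        assert len(seqs) == 1

    def test_seeded_determinism(self):
        a = simdata.simulate_references(8, divergence=0.10, seed=42)
        b = simdata.simulate_references(8, divergence=0.10, seed=42)
        assert [t.true_sequence_long for t in a.taxa] == [t.true_sequence_long for t in b.taxa]
        assert [t.species_name for t in a.taxa] == [t.species_name for t in b.taxa]

    def test_mean_pairwise_distance_matches_brute_force_oracle(self):
        com = simdata.simulate_references(20, divergence=0.10, seed=1)
        d = simdata.mean_pairwise_distance([t.true_sequence_long for t in com.taxa])
        assert 0.08 <= d <= 0.12  # within ±20% of the requested divergence

    def test_congeneric_pairs_are_closer_than_between_genus(self):
        com = simdata.simulate_references(20, divergence=0.10, seed=1)
        by_genus = {}
        for t in com.taxa:
            by_genus.setdefault(t.genus_name, []).append(t)
        pairs = [v for v in by_genus.values() if len(v) == 2]
        assert pairs
        within = np.mean([simdata.mean_pairwise_distance(
            [a.true_sequence_long, b.true_sequence_long]) for a, b in pairs])
        assert within < 0.10 / 2

    def test_short_marker_nested_in_long(self):
        com = simdata.simulate_references(6, seed=3)
        for t in com.all_taxa:
            assert t.true_sequence_short in t.true_sequence_long

    def test_abundances_normalized(self):
        com = simdata.simulate_references(10, seed=2, n_bycatch=3)
        assert sum(t.relative_abundance for t in com.taxa) == pytest.approx(1.0)
        assert sum(t.relative_abundance for t in com.bycatch_taxa) == pytest.approx(1.0)
        assert all(t.is_bycatch for t in com.bycatch_taxa)

    def test_too_short_template_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            simdata.simulate_references(4, seq_len=100)


@pytest.fixture(scope="module")
def tiny_setup():
    com = simdata.simulate_references(6, divergence=0.10, seed=7, n_bycatch=1)
    sheet, smap = simdata.simulate_sample_sheet(
        n_sites=2, field_replicates=1, rpa_replicates=1,
        barcode_species=[com.taxa[0].species_name], seed=8)
    return com, sheet, smap


class TestSimulateReads:
    def test_zero_error_marker_equals_template(self, tiny_setup):
        com, sheet, smap = tiny_setup
        reads, truth = simdata.simulate_reads(
            com, sheet, simdata.ErrorModel(0, 0, 0), 15, seed=9, specimen_map=smap)
        by_species = com.by_species()
        by_id = {r.id: r for r in reads}
        for row in truth.itertuples(index=False):
            marker = (by_species[row.species_name].true_sequence_long
                      if row.sample_id in smap
                      else by_species[row.species_name].true_sequence_short)
            read = by_id[row.read_id].bases
            assert marker in read or revcomp(marker) in read

    def test_truth_table_covers_every_read_exactly_once(self, tiny_setup):
        com, sheet, smap = tiny_setup
        reads, truth = simdata.simulate_reads(
            com, sheet, simdata.ErrorModel(), 10, seed=9, specimen_map=smap)
        assert sorted(truth.read_id) == sorted(r.id for r in reads)
        assert truth.read_id.is_unique

    def test_read_conservation_including_control(self, tiny_setup):
        com, sheet, smap = tiny_setup
        n = 100
        reads, truth = simdata.simulate_reads(
            com, sheet, simdata.ErrorModel(), n, seed=10, specimen_map=smap,
            contamination_fraction=0.01)
        n_regular = sum(1 for r in sheet if not r.is_negative_control)
        expected = n_regular * n + max(1, round(0.01 * n))
        assert len(reads) == expected
        neg = truth[truth.sample_id == "NEG"]
        assert len(neg) == max(1, round(0.01 * n))

    def test_seeded_determinism(self, tiny_setup):
        com, sheet, smap = tiny_setup
        a = simdata.simulate_reads(com, sheet, simdata.ErrorModel(), 10, seed=11,
                                   specimen_map=smap)
        b = simdata.simulate_reads(com, sheet, simdata.ErrorModel(), 10, seed=11,
                                   specimen_map=smap)
        assert [(r.id, r.bases, r.quality) for r in a[0]] == \
               [(r.id, r.bases, r.quality) for r in b[0]]

    def test_substitution_count_within_binomial_ci(self):
        rng = np.random.default_rng(0)
        model = simdata.ErrorModel(p_sub=0.05, p_ins=0.0, p_del=0.0)
        template = simdata._random_seq(rng, 10_000)
        _, _, n_sub = simdata._apply_errors(rng, template, model)
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.05)
        assert lo <= n_sub <= hi

    def test_rejects_nonpositive_depth(self, tiny_setup):
        com, sheet, smap = tiny_setup
        with pytest.raises(ValueError):
            simdata.simulate_reads(com, sheet, simdata.ErrorModel(), 0, specimen_map=smap)

    def test_error_model_validation(self):
        with pytest.raises(ValueError):
            simdata.ErrorModel(p_sub=0.6, p_ins=0.3, p_del=0.2)
        with pytest.raises(ValueError):
            simdata.ErrorModel(p_sub=-0.1)


class TestSampleSheetGeneration:
    def test_index_separation(self):
        sheet, _ = simdata.simulate_sample_sheet(n_sites=2, seed=0)
        import edlib
        idx = [r.index_f for r in sheet] + [r.index_r for r in sheet]
        for i in range(len(idx)):
            for j in range(i + 1, len(idx)):
                d = edlib.align(idx[i], idx[j], mode="NW")["editDistance"]
                assert d >= 8

    def test_one_negative_control(self):
        sheet, smap = simdata.simulate_sample_sheet(
            n_sites=3, barcode_species=["Genus00 species00"], seed=1)
        assert len(sheet.negative_controls) == 1
        assert set(smap) == {"BC00"}
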