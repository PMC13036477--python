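import math

import numpy as np
import pandas as pd
import pytest

from fieldamp import community
from fieldamp.community import TaxonCountTable
from fieldamp.io_core import SampleRow, SampleSheet


_INDEXES = [a * 10 + b * 10 for a in "ACGT" for b in "ACGT"]


def _sheet(rows):
    out = []
    for i, (sid, site, elev, frep, rrep, neg) in enumerate(rows):
        out.append(SampleRow(sid, _INDEXES[i], _INDEXES[-(i + 1)],
                             "edna", site, elev, frep, rrep, neg))
    return SampleSheet(out)


def _hits(rows, thresholds=(95.0, 99.0)):
    df = pd.DataFrame(rows, columns=["query_id", "sample_id", "size", "class_",
                                     "genus", "species", "pass_95", "pass_99"])
    for r in ("kingdom", "phylum", "order", "family"):
        df[r] = "UNKNOWN"
    return df


SHEET = _sheet([
    ("s1", "siteA", 500, 1, 1, False),
    ("s2", "siteA", 500, 2, 1, False),
    ("neg", "ctrl", 0, 1, 1, True),
])


class TestTabulate:
    def test_sizes_sum_into_cells(self):
        hits = _hits([
            ("q1", "s1", 7, "Amphibia", "G", "G x", True, False),
            ("q2", "s1", 4, "Amphibia", "G", "G x", True, False),
        ])
        table = community.tabulate(hits, SHEET, "species", 95.0)
        assert table.counts.loc["s1", "G x"] == 11

    def test_threshold_pass_respected(self):
        hits = _hits([("q1", "s1", 9, "Amphibia", "G", "G x", True, False)])
        t95 = community.tabulate(hits, SHEET, "species", 95.0)
        t99 = community.tabulate(hits, SHEET, "species", 99.0)
        assert t95.counts.loc["s1", "G x"] == 9
        assert "G x" not in t99.counts.columns

    def test_unknown_sample_rejected(self):
        hits = _hits([("q1", "sX", 1, "Amphibia", "G", "G x", True, False)])
        with pytest.raises(ValueError, match="sX"):
            community.tabulate(hits, SHEET, "species", 95.0)

    def test_totals_conserved(self, small_run):
        hits = small_run["hits_combined"]
        table = community.tabulate(hits, small_run["sheet"], "species", 95.0)
        expected = hits[hits.pass_95 & (hits.species != "UNKNOWN")]["size"].sum()
        assert table.total_reads == expected


def _table(data, samples=None, rank="species"):
    samples = samples or ["s1", "s2", "neg"]
    counts = pd.DataFrame(data, index=samples).fillna(0).astype(int)
    meta = SHEET.to_frame().set_index("sample_id").loc[samples]
    classes = {t: "Amphibia" for t in counts.columns}
    return TaxonCountTable(counts, rank, 95.0, classes, meta)


class TestNoiseFloor:
    @pytest.mark.parametrize("value,expected", [(5, 0), (6, 6), (0, 0), (1, 0)])
    def test_floor_boundaries(self, value, expected):
        table = _table({"tax": [value, 10, 0]})
        out = community.apply_noise_floor(table, 5)
        assert out.counts.loc["s1", "tax"] == expected

    def test_idempotent(self):
        table = _table({"a": [3, 8, 0], "b": [6, 5, 2]})
        once = community.apply_noise_floor(table)
        twice = community.apply_noise_floor(once)
        assert once.counts.equals(twice.counts)


class TestControlRemoval:
    def test_contaminated_taxon_removed_everywhere(self):
        table = _table({"dirty": [40, 8, 12], "clean": [20, 30, 0]})
        out, removed = community.remove_control_taxa(table, ["neg"])
        assert removed == ["dirty"]
        assert list(out.counts.columns) == ["clean"]
        assert "neg" not in out.counts.index

    def test_trace_contamination_survives_if_floored_first(self):
        table = _table({"tax": [40, 8, 3]})  # 3 control reads: below the floor
        floored = community.apply_noise_floor(table, 5)
        out, removed = community.remove_control_taxa(floored, ["neg"])
        assert removed == []
        assert out.counts.loc["s1", "tax"] == 40

    def test_order_of_operations_matters(self):
        """Floor-then-control keeps a taxon with trace control counts;
        control-then-floor would delete it."""
        table = _table({"tax": [40, 8, 3]})
        flipped, removed_first = community.remove_control_taxa(table, ["neg"])
        assert removed_first == ["tax"]  # control filter first: taxon gone
        correct, removed = community.remove_control_taxa(
            community.apply_noise_floor(table, 5), ["neg"])
        assert removed == [] and "tax" in correct.counts.columns

    def test_empty_control_removes_nothing(self):
        table = _table({"a": [9, 9, 0]})
        out, removed = community.remove_control_taxa(table, ["neg"])
        assert removed == [] and out.counts.loc["s1", "a"] == 9

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError):
            community.remove_control_taxa(_table({"a": [1, 1, 0]}), ["nope"])

    def test_filters_only_remove(self):
        table = _table({"a": [9, 4, 0], "b": [7, 8, 6]})
        out, _ = community.remove_control_taxa(
            community.apply_noise_floor(table), ["neg"])
        for s in out.counts.index:
            for t in out.counts.columns:
                assert out.counts.loc[s, t] <= table.counts.loc[s, t]


class TestDetectionStats:
    def test_hand_computed_site_union(self):
        # replicates detect {A,B} and {B,C}: sample mean 2, site richness 3
        table = _table({"A": [10, 0, 0], "B": [10, 10, 0], "C": [0, 10, 0]})
        stats = community.detection_stats(table, SHEET)
        assert stats["mean_species_per_indexed_sample"] == pytest.approx(2.0)
        assert stats["mean_species_per_site"] == pytest.approx(3.0)
        assert stats["pct_increase"] == 50

    def test_single_sample_per_site_no_increase(self):
        sheet = _sheet([("s1", "siteA", 500, 1, 1, False),
                        ("s2", "siteB", 900, 1, 1, False)])
        counts = pd.DataFrame({"A": [10, 10]}, index=["s1", "s2"])
        meta = sheet.to_frame().set_index("sample_id")
        table = TaxonCountTable(counts, "species", 95.0, {"A": "Amphibia"}, meta)
        assert community.detection_stats(table, sheet)["pct_increase"] == 0

    def test_printed_means_give_68pct(self):
        assert community.pct_increase(1.74, 2.92) == 68


class TestElevationalSummary:
    def test_ln_of_mean_including_zeros(self):
        table = _table({"X": [0, 8, 0]})
        out = community.elevational_summary(table, SHEET, [0, 1000])
        assert out.loc["X", "0-1000"] == pytest.approx(math.log(4.0))

    def test_absent_is_nan_not_neg_inf(self):
        table = _table({"X": [0, 0, 0]})
        out = community.elevational_summary(table, SHEET, [0, 1000])
        assert np.isnan(out.loc["X", "0-1000"])

    def test_single_count_of_one_is_zero_not_absent(self):
        sheet = _sheet([("s1", "siteA", 500, 1, 1, False)])
        counts = pd.DataFrame({"X": [1]}, index=["s1"])
        meta = sheet.to_frame().set_index("sample_id")
        table = TaxonCountTable(counts, "species", 95.0, {"X": "Amphibia"}, meta)
        out = community.elevational_summary(table, sheet, [0, 1000])
        assert out.loc["X", "0-1000"] == 0.0

    def test_bad_bin_edges_rejected(self):
        with pytest.raises(ValueError):
            community.elevational_summary(_table({"X": [1, 1, 0]}), SHEET, [1000, 1000])
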