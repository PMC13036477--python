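"""Accuracy scoring against a locality checklist and risk-ratio statistics.

A taxon assigned from eDNA counts as *correct* when it appears on the
checklist of species/genera confirmed for the study area; reads assigned to
non-target classes (mammalian/fish "bycatch" and the like) are reported but
never enter the target-class correctness denominators.

The relative risk of correct assignment between two databases uses the
log-normal Wald interval:

    RR = (x1/n1) / (x2/n2)
    CI = exp( ln RR ± z · sqrt(1/x1 − 1/n1 + 1/x2 − 1/n2) )

which is the standard two-proportion interval for ratios of this size.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from fieldamp.community import TaxonCountTable, tabulate, apply_noise_floor, remove_control_taxa
from fieldamp.io_core import SampleSheet
from fieldamp.refdb import UNKNOWN


@dataclasses.dataclass
class Checklist:
    """Taxa confirmed for the study area (visual/acoustic surveys + literature)."""

    species: set[str]
    genera: set[str]
    other_expected: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        for sp in self.species:
            genus = sp.split()[0]
            if genus not in self.genera:
                raise ValueError(f"checklist species {sp!r}: genus {genus!r} not in genus set")

    @classmethod
    def from_species(cls, species: Sequence[str], other_expected: Sequence[str] = ()) -> "Checklist":
        sp = set(species)
        return cls(sp, {s.split()[0] for s in sp}, set(other_expected))

    def contains(self, taxon: str, rank: str) -> bool:
        return taxon in (self.species if rank == "species" else self.genera)


def read_checklist(path) -> Checklist:
    """TSV with a ``species`` column (binomials); optional ``expected`` flag."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "species" not in df.columns:
        raise ValueError(f"checklist {path}: missing 'species' column")
    return Checklist.from_species(list(df["species"].dropna()))


def reconstruct_count(pct: float, n: int) -> int:
    """A count printed only as a percentage, recovered by round-half-away-from-zero."""
    return int(math.floor(pct / 100.0 * n + 0.5))


def risk_ratio(
    x1: int, n1: int, x2: int, n2: int, conf: float = 0.95
) -> tuple[float, float, float]:
    """Relative risk (x1/n1)/(x2/n2) with the log-normal Wald interval."""
    if not (0 < x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 < x <= n")
    if x2 == 0:
        raise ValueError("x2 = 0: risk ratio undefined (apply a continuity "
                         "correction explicitly if needed)")
    rr = (x1 / n1) / (x2 / n2)
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    se = math.sqrt(1 / x1 - 1 / n1 + 1 / x2 - 1 / n2)
    return rr, rr * math.exp(-z * se), rr * math.exp(z * se)


def score_assignments(
    table: TaxonCountTable,
    checklist: Checklist,
    target_class: str = "Amphibia",
) -> dict:
    """Split target-class reads into checklist-correct vs incorrect.

    Percentages use the stated denominators: class reads for correctness,
    all above-threshold reads for the class share.
    """
    if table.counts.size == 0 or table.total_reads == 0:
        raise ValueError("empty count table")
    totals = table.counts.sum(axis=0)
    n_total = int(totals.sum())
    target_taxa = [t for t in totals.index if table.taxon_class.get(t) == target_class]
    n_target = int(totals[target_taxa].sum())
    n_correct = int(sum(totals[t] for t in target_taxa
                        if checklist.contains(t, table.rank)))
    n_incorrect = n_target - n_correct
    return {
        "n_target_reads": n_target,
        "n_total_reads_above_threshold": n_total,
        "n_correct": n_correct,
        "n_incorrect": n_incorrect,
        "pct_correct": 100.0 * n_correct / n_target if n_target else float("nan"),
        "pct_target_of_total": 100.0 * n_target / n_total if n_total else float("nan"),
        "species_detected": sorted(
            t for t in target_taxa
            if totals[t] > 0 and checklist.contains(t, table.rank)
        ),
    }


@dataclasses.dataclass
class AccuracyReport:
    """Per (database, rank, threshold) accuracy plus database-comparison RRs."""

    entries: dict  # (db_label, rank, threshold) -> score_assignments dict
    comparisons: dict  # (rank, threshold) -> {"rr":, "ci_low":, "ci_high":}
    species_detected: dict  # (db_label, threshold) -> int

    def to_jsonable(self) -> dict:
        return {
            "schema_version": 1,
            "entries": {f"{d}|{r}|{t:g}": v for (d, r, t), v in self.entries.items()},
            "comparisons": {f"{r}|{t:g}": v for (r, t), v in self.comparisons.items()},
            "species_detected": {f"{d}|{t:g}": v for (d, t), v in self.species_detected.items()},
        }


def _build_table(hits, sheet, rank, threshold, noise_floor, control_ids) -> TaxonCountTable:
    table = tabulate(hits, sheet, rank=rank, threshold=threshold)
    table = apply_noise_floor(table, noise_floor)
    if control_ids:
        table, _ = remove_control_taxa(table, control_ids)
    else:
        mask = ~table.sample_meta["is_negative_control"].astype(bool)
        table.counts = table.counts.loc[mask[mask].index]
        table.sample_meta = table.sample_meta.loc[mask[mask].index]
    return table


def compare_databases(
    hits_base: pd.DataFrame,
    hits_combined: pd.DataFrame,
    sheet: SampleSheet,
    checklist: Checklist,
    thresholds: Sequence[float] = (95.0, 99.0),
    ranks: Sequence[str] = ("species", "genus"),
    target_class: str = "Amphibia",
    noise_floor: int = 5,
    conf: float = 0.95,
) -> AccuracyReport:
    """Base-vs-combined database accuracy report from two hit tables over the
    same query set (tabulated, noise-floored, control-filtered identically)."""
    if set(hits_base["query_id"]) != set(hits_combined["query_id"]):
        raise ValueError("hit tables were not produced from the same query set")
    control_ids = [r.sample_id for r in sheet.negative_controls]
    entries: dict = {}
    comparisons: dict = {}
    detected: dict = {}
    for threshold in thresholds:
        for rank in ranks:
            scores = {}
            for label, hits in (("base", hits_base), ("combined", hits_combined)):
                table = _build_table(hits, sheet, rank, threshold, noise_floor, control_ids)
                try:
                    s = score_assignments(table, checklist, target_class)
                except ValueError:
                    s = {"n_target_reads": 0, "n_total_reads_above_threshold": 0,
                         "n_correct": 0, "n_incorrect": 0,
                         "pct_correct": float("nan"), "pct_target_of_total": float("nan"),
                         "species_detected": []}
                entries[(label, rank, threshold)] = s
                scores[label] = s
                if rank == "species":
                    detected[(label, threshold)] = len(s["species_detected"])
            b, c = scores["base"], scores["combined"]
            if c["n_correct"] > 0 and b["n_correct"] > 0:
                rr, lo, hi = risk_ratio(c["n_correct"], c["n_target_reads"],
                                        b["n_correct"], b["n_target_reads"], conf)
                comparisons[(rank, threshold)] = {"rr": rr, "ci_low": lo, "ci_high": hi}
    return AccuracyReport(entries, comparisons, detected)
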