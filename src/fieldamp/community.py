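"""Per-sample taxon count tables, noise floor, control filtering and summaries.

The filtering order is fixed: tabulate → noise floor → negative-control taxon
removal.  Because the floor runs first, trace contamination of ≤ 5 reads in a
control is zeroed before the control filter looks at it and does not trigger
taxon removal — a documented consequence of applying the rules in this order.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from fieldamp.assign import pass_column
from fieldamp.io_core import SampleSheet
from fieldamp.refdb import UNKNOWN


@dataclasses.dataclass
class TaxonCountTable:
    """Samples × taxa integer read counts at one rank and identity threshold."""

    counts: pd.DataFrame  # index: sample_id, columns: taxon names
    rank: str  # "species" | "genus"
    threshold: float
    taxon_class: dict[str, str]  # taxon -> class name (e.g. "Amphibia")
    sample_meta: pd.DataFrame  # index: sample_id; site_id, elevation_m, replicates

    def copy(self) -> "TaxonCountTable":
        return TaxonCountTable(self.counts.copy(), self.rank, self.threshold,
                               dict(self.taxon_class), self.sample_meta.copy())

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())


def tabulate(
    hits: pd.DataFrame,
    sheet: SampleSheet,
    rank: str = "species",
    threshold: float = 95.0,
) -> TaxonCountTable:
    """Sum dereplicated sizes into sample × taxon cells for one threshold.

    Only hits passing the threshold whose lineage names the rank contribute;
    queries resolving to UNKNOWN at the rank are excluded (they cannot be
    tabulated under a taxon name).
    """
    if rank not in ("species", "genus"):
        raise ValueError(f"unsupported rank {rank!r}")
    col = pass_column(threshold)
    if col not in hits.columns:
        raise ValueError(f"hit table lacks column {col!r}")
    known_samples = {r.sample_id for r in sheet}
    extra = set(hits["sample_id"]) - known_samples
    if extra:
        raise ValueError(f"hit table references samples absent from the sheet: {sorted(extra)}")

    passed = hits[hits[col] & (hits[rank] != UNKNOWN)]
    pivot = (passed.groupby(["sample_id", rank])["size"].sum()
             .unstack(fill_value=0).astype(int))
    sample_ids = [r.sample_id for r in sheet]
    pivot = pivot.reindex(index=sample_ids, fill_value=0)
    pivot.columns.name = None
    pivot.index.name = "sample_id"

    taxon_class = (passed.groupby(rank)["class_"].first().to_dict()
                   if len(passed) else {})
    meta = sheet.to_frame().set_index("sample_id")
    return TaxonCountTable(pivot, rank, threshold, taxon_class, meta)


def apply_noise_floor(table: TaxonCountTable, floor: int = 5) -> TaxonCountTable:
    """Zero every cell with count <= floor (read counts that small are noise)."""
    out = table.copy()
    values = out.counts.to_numpy()
    values[values <= floor] = 0
    out.counts = pd.DataFrame(values, index=table.counts.index,
                              columns=table.counts.columns)
    return out


def remove_control_taxa(
    table: TaxonCountTable, control_sample_ids: Sequence[str]
) -> tuple[TaxonCountTable, list[str]]:
    """Delete any taxon detected (count > 0) in a negative control from all
    samples, then drop the control rows themselves."""
    missing = [c for c in control_sample_ids if c not in table.counts.index]
    if missing:
        raise ValueError(f"control samples absent from table: {missing}")
    out = table.copy()
    removed: list[str] = []
    if control_sample_ids:
        control = out.counts.loc[list(control_sample_ids)]
        removed = sorted(control.columns[(control > 0).any(axis=0)])
        out.counts = out.counts.drop(columns=removed)
        out.counts = out.counts.drop(index=list(control_sample_ids))
        out.sample_meta = out.sample_meta.drop(index=list(control_sample_ids))
        for t in removed:
            out.taxon_class.pop(t, None)
    return out, removed


def pct_increase(mean_per_sample: float, mean_per_site: float) -> int:
    """Relative gain of per-site over per-sample mean richness, rounded to the
    nearest whole percent."""
    if mean_per_sample <= 0:
        return 0
    return int(round(100.0 * (mean_per_site - mean_per_sample) / mean_per_sample))


def detection_stats(table: TaxonCountTable, sheet: SampleSheet) -> dict:
    """Replicate-aggregation detection summary.

    Per-indexed-sample richness is the number of taxa detected (cell > 0);
    per-site richness is the richness of the union over that site's field ×
    RPA replicates.  The replication gain is decomposed by first collapsing
    RPA replicates: the union over each field replicate's first RPA replicate
    isolates the field-replication gain, and the remainder up to the full
    site union is attributed to RPA replication.  The split is a defined
    stand-in for replicate attribution, not a universal statistic.
    """
    meta = table.sample_meta
    samples = [s for s in table.counts.index if not meta.loc[s, "is_negative_control"]]
    if not samples:
        raise ValueError("no non-control samples in table")
    det = table.counts.loc[samples] > 0

    richness = det.sum(axis=1)
    mean_sample = float(richness.mean())

    site_rich: list[float] = []
    gain_field_total = 0.0
    gain_rpa_total = 0.0
    for site, grp in meta.loc[samples].groupby("site_id"):
        ids = list(grp.index)
        if not ids:
            continue
        union = det.loc[ids].any(axis=0).sum()
        site_rich.append(float(union))
        site_mean = float(det.loc[ids].sum(axis=1).mean())
        # first RPA replicate of each field replicate
        firsts = [grp[grp.field_replicate == f].sort_values("rpa_replicate").index[0]
                  for f in sorted(grp.field_replicate.unique())]
        field_union = det.loc[firsts].any(axis=0).sum()
        gain_field_total += max(0.0, float(field_union) - site_mean)
        gain_rpa_total += max(0.0, float(union) - float(field_union))
    mean_site = float(np.mean(site_rich))
    total_gain = gain_field_total + gain_rpa_total
    return {
        "mean_species_per_indexed_sample": mean_sample,
        "mean_species_per_site": mean_site,
        "pct_increase": pct_increase(mean_sample, mean_site),
        "attribution_field_pct": (100.0 * gain_field_total / total_gain
                                  if total_gain > 0 else float("nan")),
        "attribution_rpa_pct": (100.0 * gain_rpa_total / total_gain
                                if total_gain > 0 else float("nan")),
    }


def elevational_summary(
    table: TaxonCountTable,
    sheet: SampleSheet,
    bin_edges: Sequence[float],
) -> pd.DataFrame:
    """Per-taxon ln(mean read count across all replicates) per elevation cohort.

    The cohort mean includes zero cells (every replicate counts, not only
    detections); a zero mean is reported as absent (NaN), never as −∞.
    Returns a taxa × cohort DataFrame; cohort labels are "lo-hi" strings.
    """
    edges = list(bin_edges)
    if any(nxt <= prev for prev, nxt in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    meta = table.sample_meta
    samples = [s for s in table.counts.index if not meta.loc[s, "is_negative_control"]]
    elev = meta.loc[samples, "elevation_m"].astype(float)
    labels = [f"{int(lo)}-{int(hi)}" for lo, hi in zip(edges, edges[1:])]
    cohort = pd.cut(elev, bins=edges, labels=labels, include_lowest=True)

    out = pd.DataFrame(index=sorted(table.counts.columns), columns=labels, dtype=float)
    for label in labels:
        ids = [s for s in samples if cohort.loc[s] == label]
        if not ids:
            continue
        means = table.counts.loc[ids].mean(axis=0)
        for taxon, m in means.items():
            out.loc[taxon, label] = math.log(m) if m > 0 else float("nan")
    return out
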