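"""Quality-control filters for crossover calls and marker panels.

The call-level filters mirror the standard pedigree-recombination
cleaning cascade: drop low-confidence calls (probability <= 0.5),
drop calls overlapping assembly blacklist regions, remove clustered
double-crossover pairs that recur with shared boundary markers across
meioses of one parent (a genotyping-error signature), and remove whole
meioses whose genome-wide crossover count is a robust outlier
(outside median +/- 4 * 1.4826 * MAD, per sex).  Marker-level QC
excludes markers by missingness, duo Mendelian inconsistency, and
flagged genotyping-error probability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    min_call_probability: float = 0.5
    double_xo_cluster_bp: float = 1_000_000.0
    mad_constant: float = 1.4826
    sd_multiplier: float = 4.0
    max_missing_fraction: float = 0.05
    marker_error_probability: float = 0.9
    blacklist_regions: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.min_call_probability, self.double_xo_cluster_bp,
                  self.mad_constant, self.sd_multiplier,
                  self.max_missing_fraction, self.marker_error_probability):
            if v <= 0:
                raise ValueError("filter thresholds must be positive")
        for chrom, s, e in self.blacklist_regions:
            if e < s or s < 0:
                raise ValueError(f"invalid blacklist region {chrom}:{s}-{e}")


@dataclass
class FilterReport:
    rule: str
    n_input: int
    n_removed: int
    removed_ids: list = field(default_factory=list)

    @property
    def n_surviving(self) -> int:
        return self.n_input - self.n_removed


def _report(rule, calls_in, kept_mask) -> FilterReport:
    removed = calls_in.index[~kept_mask].tolist()
    rep = FilterReport(rule, len(calls_in), len(removed), removed)
    log.info("%s: %d in, %d removed, %d kept", rule, rep.n_input, rep.n_removed, rep.n_surviving)
    return rep


def filter_low_probability_calls(
    calls: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain calls with probability strictly greater than the threshold."""
    if "probability" not in calls.columns:
        raise ValueError("calls table lacks a 'probability' column")
    keep = calls["probability"].values > config.min_call_probability
    return calls[keep].copy(), _report("low_probability", calls, keep)


def filter_blacklist_regions(
    records: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove records whose interval overlaps any blacklist region.

    Works for crossover calls (left_bp/right_bp) or marker tables with
    a point position (pos) treated as a 1-bp interval.
    """
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in config.blacklist_regions:
        if e <= s:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    if "left_bp" in records.columns:
        lo, hi = records["left_bp"].values, records["right_bp"].values
    else:
        lo = records["pos"].values
        hi = lo + 1
    keep = np.ones(len(records), dtype=bool)
    for i, (chrom, a, b) in enumerate(zip(records["chrom"].values, lo, hi)):
        t = trees.get(chrom)
        if t is not None and t.overlap(a, b):
            keep[i] = False
    return records[keep].copy(), _report("blacklist", records, keep)


def _clustered_pairs(calls: pd.DataFrame, cluster_bp: float) -> list[dict]:
    """Successive crossover pairs per meiosis x chromosome whose inner
    gap (next left boundary minus previous right boundary) is within
    ``cluster_bp``."""
    pairs = []
    for (mid, chrom), sub in calls.groupby(["meiosis_id", "chrom"], sort=False):
        sub = sub.sort_values("left_bp")
        idx = sub.index.to_numpy()
        left = sub["left_bp"].to_numpy()
        right = sub["right_bp"].to_numpy()
        for i in range(len(sub) - 1):
            inner_gap = left[i + 1] - right[i]
            if inner_gap <= cluster_bp:
                pairs.append({
                    "meiosis_id": mid,
                    "parent_id": sub["parent_id"].iloc[0],
                    "chrom": chrom,
                    "rows": (idx[i], idx[i + 1]),
                    "boundaries": frozenset(
                        (left[i], right[i], left[i + 1], right[i + 1])
                    ),
                })
    return pairs


def filter_clustered_double_crossovers(
    calls: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove recurrent clustered double-crossover pairs.

    A pair of successive calls in one meiosis is *clustered* when the
    inner gap between their bounding intervals is within
    ``double_xo_cluster_bp``.  Clustered pairs are removed only when at
    least two meioses of the same parent carry clustered pairs on the
    same chromosome sharing an identical interval-boundary coordinate —
    the signature of a genotyping error at a shared marker.
    """
    pairs = _clustered_pairs(calls, config.double_xo_cluster_bp)
    drop: set = set()
    by_parent: dict[tuple, list[dict]] = {}
    for p in pairs:
        by_parent.setdefault((p["parent_id"], p["chrom"]), []).append(p)
    for group in by_parent.values():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if a["meiosis_id"] != b["meiosis_id"] and a["boundaries"] & b["boundaries"]:
                    drop.update(a["rows"])
                    drop.update(b["rows"])
    keep = ~calls.index.isin(drop)
    return calls[keep].copy(), _report("clustered_double_xo", calls, keep)


def robust_count_bounds(counts: np.ndarray, config: FilterConfig) -> tuple[float, float]:
    """Outlier bounds median +/- sd_multiplier * 1.4826 * MAD.

    If MAD is zero the non-robust standard deviation is used; if that
    is also zero no record can be an outlier (infinite bounds).
    """
    m = float(np.median(counts))
    mad = float(np.median(np.abs(counts - m)))
    sd = config.mad_constant * mad
    if sd == 0.0:
        sd = float(np.std(counts))
    if sd == 0.0:
        return -np.inf, np.inf
    return m - config.sd_multiplier * sd, m + config.sd_multiplier * sd


def filter_outlier_meioses(
    calls: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop whole meioses with biologically abnormal genome-wide counts,
    bounds computed per sex from the robust MAD estimate of spread."""
    counts = calls.groupby("meiosis_id").size()
    sex_of = calls.groupby("meiosis_id")["parent_sex"].first()
    bad: list[str] = []
    for sex in sex_of.unique():
        ids = sex_of.index[sex_of == sex]
        c = counts.loc[ids].to_numpy(dtype=float)
        if len(c) < 2:
            warnings.warn(f"{sex}: fewer than 2 meioses; outlier filter skipped")
            continue
        lo, hi = robust_count_bounds(c, config)
        bad.extend(ids[(c < lo) | (c > hi)])
    keep = ~calls["meiosis_id"].isin(bad)
    rep = _report("outlier_meioses", calls, keep)
    rep.removed_ids = bad  # report whole meioses, not call rows
    return calls[keep].copy(), rep


def genotype_qc(markers: pd.DataFrame, config: FilterConfig,
                duo_genotypes: pd.DataFrame | None = None) -> list:
    """Marker exclusion list from missingness, Mendelian and error filters.

    ``markers``: marker_id plus optional missing_fraction and
    error_prob columns.  ``duo_genotypes``: long table (marker_id,
    parent_gt, child_gt) with genotypes as two-letter strings; a marker
    is Mendelian-inconsistent when any duo shows opposite homozygotes.
    """
    excluded: set = set()
    if "missing_fraction" in markers.columns:
        bad = markers.loc[
            markers["missing_fraction"] > config.max_missing_fraction, "marker_id"
        ]
        excluded.update(bad)
    if "error_prob" in markers.columns:
        bad = markers.loc[
            markers["error_prob"] > config.marker_error_probability, "marker_id"
        ]
        excluded.update(bad)
    if duo_genotypes is not None and len(duo_genotypes):
        pg = duo_genotypes["parent_gt"].astype(str)
        cg = duo_genotypes["child_gt"].astype(str)
        hom_p = pg.str[0] == pg.str[1]
        hom_c = cg.str[0] == cg.str[1]
        conflict = hom_p & hom_c & (pg.str[0] != cg.str[0])
        excluded.update(duo_genotypes.loc[conflict, "marker_id"])
    return sorted(excluded)


def apply_all_filters(
    calls: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, list[FilterReport]]:
    """Standard cascade: probability -> blacklist -> clustered double
    crossovers -> outlier meioses."""
    reports = []
    for fn in (filter_low_probability_calls, filter_blacklist_regions,
               filter_clustered_double_crossovers, filter_outlier_meioses):
        calls, rep = fn(calls, config)
        reports.append(rep)
    return calls, reports
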