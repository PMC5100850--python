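"""Broad- and fine-scale recombination landscape statistics.

Covers the telomeric share of recombination, Lorenz-style concentration
curves with chromosome bootstrap bands, feature-anchored rate profiles
(TSS, CpG islands, or arbitrary BED anchors) in 10-kb offset bins,
density thinning of CpG islands, and the marker-framework thinning /
crossover-interval expansion used to match the resolution of a denser
dataset before cross-species comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap


def telomere_proportion(gmap: GeneticMap, window_bp: float = 5_000_000,
                        telomere_end: str = "distal") -> float:
    """Fraction of total genetic map length within ``window_bp`` of each
    chromosome's telomeric end, pooled genome-wide.

    Dog autosomes are acrocentric; the telomeric end of the single arm
    is taken at the distal (high-coordinate) side by default.
    Chromosomes shorter than the window contribute fully.
    """
    total = gmap.total_cm()
    if total <= 0:
        raise ValueError("map has zero genetic length")
    in_window = 0.0
    for chrom in gmap.chromosomes():
        sub = gmap.chrom_table(chrom)
        starts, ends = sub["start"].values, sub["end"].values
        cm = sub["rate_cM_per_Mb"].values * (ends - starts) / 1e6
        chrom_len = ends[-1]
        if window_bp >= chrom_len:
            warnings.warn(f"{chrom}: telomere window covers whole chromosome")
        if telomere_end == "distal":
            lo, hi = max(chrom_len - window_bp, starts[0]), chrom_len
        else:
            lo, hi = starts[0], min(starts[0] + window_bp, chrom_len)
        ov = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0, None)
        frac = np.divide(ov, ends - starts)
        in_window += float((cm * frac).sum())
    return in_window / total


@dataclass
class ConcentrationCurve:
    """Cumulative genetic vs. physical proportion, intervals sorted by
    rate descending (a Lorenz-type majorization curve)."""

    physical: np.ndarray  # cumulative physical proportion, starts 0 ends 1
    genetic: np.ndarray   # cumulative genetic proportion
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None
    grid: np.ndarray | None = None  # physical grid of the bands

    def sequence_fraction_at(self, q: float) -> float:
        """Minimal physical proportion of the genome holding a genetic
        proportion ``q`` of recombination."""
        return float(np.interp(q, self.genetic, self.physical))


def _sorted_cumulative(lengths: np.ndarray, cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rates = cm / lengths
    order = np.argsort(-rates, kind="stable")
    phys = np.concatenate([[0.0], np.cumsum(lengths[order])]) / lengths.sum()
    gen = np.concatenate([[0.0], np.cumsum(cm[order])]) / cm.sum()
    return phys, gen


def concentration_curve(
    gmap: GeneticMap, gap_bp: float = 1_000_000, bootstrap_n: int = 1000, seed: int = 0
) -> ConcentrationCurve:
    """Concentration of recombination across the genome.

    Intervals physically longer than ``gap_bp`` (assembly gaps,
    centromeric stretches with no markers) are removed first.
    Bootstrap bands resample chromosomes with replacement.
    """
    df = gmap.intervals
    lengths = (df["end"] - df["start"]).values.astype(float)
    keep = lengths <= gap_bp
    df = df[keep]
    lengths = lengths[keep]
    cm = df["rate_cM_per_Mb"].values * lengths / 1e6
    if cm.sum() <= 0:
        raise ValueError("map has no recombination after gap removal")
    phys, gen = _sorted_cumulative(lengths, cm)
    curve = ConcentrationCurve(phys, gen)

    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        chroms = np.array(list(dict.fromkeys(df["chrom"])))
        grid = np.linspace(0.0, 1.0, 201)
        boot = np.empty((bootstrap_n, len(grid)))
        per_chrom = {c: (lengths[df["chrom"].values == c], cm[df["chrom"].values == c])
                     for c in chroms}
        for b in range(bootstrap_n):
            pick = rng.choice(chroms, size=len(chroms), replace=True)
            ls = np.concatenate([per_chrom[c][0] for c in pick])
            cs = np.concatenate([per_chrom[c][1] for c in pick])
            if cs.sum() <= 0:
                boot[b] = grid
                continue
            p, g = _sorted_cumulative(ls, cs)
            boot[b] = np.interp(grid, p, g)
        curve.grid = grid
        curve.band_lo, curve.band_hi = np.percentile(boot, [2.5, 97.5], axis=0)
    return curve


@dataclass
class FeatureProfile:
    anchor_type: str
    bin_bp: float
    offsets: np.ndarray           # bin left edges relative to anchor
    mean_rates: np.ndarray        # physical-length-weighted mean cM/Mb per bin
    anchor_count: int = 0
    sex: str = "sex-averaged"


def profile_around_anchors(
    gmap: GeneticMap,
    anchors: pd.DataFrame,
    bin_bp: float = 10_000,
    flank_bp: float = 500_000,
    anchor_type: str = "generic",
) -> FeatureProfile:
    """Mean recombination rate in fixed offset bins around anchor points.

    ``anchors``: chrom, pos (anchor point, e.g. a TSS) and optional
    strand; minus-strand anchors have their offset axis flipped so
    negative offsets are always upstream.  Rates are averaged across
    anchors weighting each bin's contribution by the physical length of
    map coverage inside it.
    """
    if len(anchors) == 0:
        raise ValueError("no anchors supplied")
    n_bins = int(2 * flank_bp / bin_bp)
    offsets = -flank_bp + np.arange(n_bins) * bin_bp
    num = np.zeros(n_bins)
    den = np.zeros(n_bins)
    by_chrom = {c: gmap.chrom_table(c) for c in gmap.chromosomes()}
    n_used = 0
    for _, a in anchors.iterrows():
        sub = by_chrom.get(a["chrom"])
        if sub is None:
            continue
        n_used += 1
        strand = a.get("strand", "+") if hasattr(a, "get") else "+"
        starts, ends = sub["start"].values, sub["end"].values
        rates = sub["rate_cM_per_Mb"].values
        for i, off in enumerate(offsets):
            if strand == "-":
                lo, hi = a["pos"] - (off + bin_bp), a["pos"] - off
            else:
                lo, hi = a["pos"] + off, a["pos"] + off + bin_bp
            ov = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0, None)
            num[i] += float((rates * ov).sum())
            den[i] += float(ov.sum())
    if n_used == 0:
        raise ValueError("no anchors on the map's chromosomes")
    mean = np.divide(num, den, out=np.full(n_bins, np.nan), where=den > 0)
    return FeatureProfile(anchor_type, bin_bp, offsets, mean, n_used, gmap.sex)


def thin_cpg_islands(
    islands: pd.DataFrame, window_bp: float = 500_000, max_per_window: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Cap island density: per non-overlapping window, retain at most
    ``max_per_window`` islands chosen uniformly at random (seeded).

    Windows are tiled from coordinate 0 per chromosome; an island is
    assigned to the window containing its start.
    """
    rng = np.random.default_rng(seed)
    keep_idx = []
    for chrom, sub in islands.groupby("chrom", sort=False):
        win = (sub["start"].values // window_bp).astype(int)
        for w in np.unique(win):
            idx = sub.index[win == w].to_numpy()
            if len(idx) > max_per_window:
                idx = rng.choice(idx, size=max_per_window, replace=False)
            keep_idx.extend(idx.tolist())
    return islands.loc[sorted(keep_idx)].copy()


def thin_marker_framework(
    dense: dict[str, np.ndarray],
    reference: dict[str, np.ndarray],
    tolerance: float = 0.05,
    max_iter: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Thin a dense marker set until its inter-marker spacing matches a
    coarser reference set.

    Iteratively removes markers until the inter-marker gap distributions
    agree: (1) markers inside *clusters* — gaps far tighter than anything
    typical of the reference — are removed first (removing one merges the
    tight gap into a neighbour), then (2) while the overall median gap is
    still below the reference's, markers are removed uniformly at random,
    which for near-Poisson marker placement preserves the gap
    distribution's shape while stretching its scale.  Convergence
    requires the medians to agree within ``tolerance`` (relative) and the
    gap distributions to be close (max quantile difference over the
    10th-90th percentile range below 20% of the corresponding reference
    quantile or median, whichever is larger — a quantile distance is
    robust to lattice-valued gaps where an empirical-CDF supremum is
    not).  Raises on non-convergence.
    """
    rng = np.random.default_rng(seed)
    ref_gaps = np.concatenate([np.diff(np.sort(v)) for v in reference.values()])
    ref_gaps = ref_gaps[ref_gaps > 0]
    ref_med = float(np.median(ref_gaps))
    thr_tight = min(float(np.quantile(ref_gaps, 0.05)), 0.5 * ref_med)
    work = {c: np.sort(np.asarray(v, dtype=float)) for c, v in dense.items()}

    def gaps_of(d):
        g = np.concatenate([np.diff(v) for v in d.values() if len(v) > 1])
        return g[g >= 0]

    def converged(d):
        g = gaps_of(d)
        if len(g) == 0:
            return False
        med = np.median(g)
        if abs(med - ref_med) / ref_med > tolerance:
            return False
        qs = np.linspace(0.1, 0.9, 17)
        qd = np.quantile(g, qs)
        qr = np.quantile(ref_gaps, qs)
        return float(np.max(np.abs(qd - qr) / np.maximum(qr, ref_med))) < 0.20

    for _ in range(max_iter):
        if converged(work):
            return work
        med = float(np.median(gaps_of(work)))
        med_ok = med >= ref_med * (1.0 - tolerance / 2)
        dropped_any = False
        for c in work:
            v = work[c]
            if len(v) < 3:
                continue
            g = np.diff(v)
            tight = np.where(g < thr_tight)[0]
            # one flank per tight gap, never two adjacent markers in one
            # sweep: merging a tight gap must not chain into a new large gap
            cand = []
            last = -2
            for t in tight:
                if t > last + 1 and 0 < t + 1 < len(v) - 1:
                    cand.append(t + 1)
                    last = t
            drop: set[int] = set()
            if cand:
                drop.update(cand)  # clusters present: remove those only
            elif not med_ok:
                # uniform removal scaled by how far the median must move
                frac = 0.7 * float(np.clip(1.0 - med / ref_med, 0.02, 0.3))
                interior = np.arange(1, len(v) - 1)
                n = max(1, int(frac * len(interior)))
                drop.update(rng.choice(interior, size=n, replace=False).tolist())
            if drop:
                work[c] = np.delete(v, sorted(drop))
                dropped_any = True
        if not dropped_any:
            break
    if converged(work):
        return work
    med = float(np.median(gaps_of(work)))
    raise RuntimeError(
        f"marker thinning failed to converge in {max_iter} iterations "
        f"(median gap {med:.0f} vs reference {ref_med:.0f})"
    )


def expand_crossovers_to_framework(
    calls: pd.DataFrame, framework: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Snap call boundaries outward to the nearest framework markers.

    Left boundaries move to the nearest framework marker <= them, right
    boundaries to the nearest marker >= them; intervals only widen.
    Calls without a flanking marker on either side are dropped with a
    warning.
    """
    rows = []
    n_dropped = 0
    for _, r in calls.iterrows():
        mk = framework.get(r["chrom"])
        if mk is None or len(mk) == 0:
            n_dropped += 1
            continue
        mk = np.sort(mk)
        li = np.searchsorted(mk, r["left_bp"], side="right") - 1
        ri = np.searchsorted(mk, r["right_bp"], side="left")
        if li < 0 or ri >= len(mk):
            n_dropped += 1
            continue
        row = r.copy()
        row["left_bp"], row["right_bp"] = float(mk[li]), float(mk[ri])
        rows.append(row)
    if n_dropped:
        warnings.warn(f"{n_dropped} calls lacked flanking framework markers; dropped")
    return pd.DataFrame(rows).reset_index(drop=True) if rows else calls.iloc[0:0].copy()
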