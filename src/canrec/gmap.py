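"""Sex-specific genetic map construction.

A genetic map is an ordered set of contiguous physical intervals per
chromosome, each carrying a recombination rate (cM/Mb) and a cumulative
genetic position (cM).  Maps are built from filtered crossover calls by

1. distributing each crossover's unit mass over the marker intervals its
   bounding interval overlaps (proportional to physical overlap, or all
   to the midpoint interval),
2. dividing interval mass by the *effective* number of meioses — the
   count of parent-child duos whose informative span (first to last
   heterozygous parental marker) fully contains the interval — to obtain
   a recombination fraction, and
3. converting fractions to genetic distance with Haldane's map function
   d = -(1/2) ln(1 - 2r).

The effective-meioses denominator corrects for runs of homozygosity in
inbred pedigrees, where crossovers are invisible and a fixed-n
denominator would shrink the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAP_COLUMNS = ["chrom", "start", "end", "rate_cM_per_Mb", "cum_cM"]


def haldane(r):
    """Genetic distance in Morgans for recombination fraction ``r``.

    d = -(1/2) ln(1 - 2r).  Raises for r >= 0.5 (infinite distance) or
    r < 0.
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    out = -0.5 * np.log1p(-2.0 * r)
    return float(out) if out.ndim == 0 else out


def inverse_haldane(d):
    """Recombination fraction for genetic distance ``d`` Morgans: r = (1-e^{-2d})/2."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    out = 0.5 * -np.expm1(-2.0 * d)
    return float(out) if out.ndim == 0 else out


@dataclass
class GeneticMap:
    """Per-chromosome interval map with rates and cumulative genetic position.

    ``intervals`` holds columns chrom, start, end (bp, 0-based half-open,
    contiguous per chromosome), rate_cM_per_Mb, and cum_cM (cumulative
    genetic position at the interval *end*).
    """

    intervals: pd.DataFrame
    sex: str = "sex-averaged"

    def __post_init__(self) -> None:
        df = self.intervals
        missing = [c for c in MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"map missing columns: {missing}")
        for chrom, sub in df.groupby("chrom", sort=False):
            if not (sub["start"].values < sub["end"].values).all():
                raise ValueError(f"{chrom}: empty or inverted interval")
            if not (sub["start"].values[1:] == sub["end"].values[:-1]).all():
                raise ValueError(f"{chrom}: intervals not contiguous")
            if np.any(np.diff(sub["cum_cM"].values) < -1e-9):
                raise ValueError(f"{chrom}: cumulative cM decreases")
        if (df["rate_cM_per_Mb"].values < -1e-12).any():
            raise ValueError("negative recombination rate")

    @classmethod
    def from_rates(cls, chrom, starts, ends, rates, sex="sex-averaged"):
        """Build a single-chromosome map (or concatenate per chrom) from rates."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        rates = np.asarray(rates, dtype=float)
        cm = np.cumsum(rates * (ends - starts) / 1e6)
        df = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends,
             "rate_cM_per_Mb": rates, "cum_cM": cm}
        )
        return cls(df, sex=sex)

    # -- queries -------------------------------------------------------
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.intervals["chrom"]))

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        sub = self.intervals[self.intervals["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return sub

    def chrom_cm(self, chrom: str) -> float:
        """Total genetic length of one chromosome, cM."""
        return float(self.chrom_table(chrom)["cum_cM"].iloc[-1])

    def total_cm(self) -> float:
        return float(sum(self.chrom_cm(c) for c in self.chromosomes()))

    def _grids(self, chrom):
        sub = self.chrom_table(chrom)
        bp = np.concatenate(([sub["start"].iloc[0]], sub["end"].values))
        cm = np.concatenate(([0.0], sub["cum_cM"].values))
        return bp.astype(float), cm.astype(float)

    def cm_at(self, chrom: str, bp) -> np.ndarray | float:
        """Cumulative genetic position (cM) at physical position(s) bp."""
        grid_bp, grid_cm = self._grids(chrom)
        return np.interp(bp, grid_bp, grid_cm)

    def bp_at(self, chrom: str, cm) -> np.ndarray | float:
        """Inverse of :meth:`cm_at` by piecewise-linear interpolation.

        Requires a strictly increasing cumulative map (no zero-rate
        plateaus); otherwise the map is not invertible.
        """
        grid_bp, grid_cm = self._grids(chrom)
        if np.any(np.diff(grid_cm) <= 0):
            raise ValueError(f"{chrom}: genetic map not strictly monotone, cannot invert")
        return np.interp(cm, grid_cm, grid_bp)


# ---------------------------------------------------------------------
# effective meioses


@dataclass
class EffectiveMeiosisProfile:
    """Piecewise-constant duo coverage: per marker interval, the number of
    informative spans fully containing it."""

    profile: dict[str, pd.DataFrame] = field(default_factory=dict)  # chrom -> start,end,n_eff

    def n_eff(self, chrom: str) -> np.ndarray:
        return self.profile[chrom]["n_eff"].values


def effective_meioses(spans: pd.DataFrame, marker_intervals: dict[str, np.ndarray]) -> EffectiveMeiosisProfile:
    """Count, per marker interval, the duos whose informative span contains it.

    Parameters
    ----------
    spans : DataFrame with columns duo_id, chrom, first_het_bp, last_het_bp.
    marker_intervals : chrom -> sorted breakpoint array (n+1 edges for n
        intervals).

    An interval [a, b) counts a duo iff first_het_bp <= a and
    last_het_bp >= b (full containment).
    """
    import warnings

    prof = EffectiveMeiosisProfile()
    for chrom, edges in marker_intervals.items():
        edges = np.asarray(edges, dtype=float)
        starts, ends = edges[:-1], edges[1:]
        sub = spans[spans["chrom"] == chrom] if len(spans) else spans
        n = np.zeros(len(starts), dtype=int)
        if len(sub) == 0:
            warnings.warn(f"{chrom}: no informative spans; zero effective meioses")
        else:
            lo = sub["first_het_bp"].values[:, None]
            hi = sub["last_het_bp"].values[:, None]
            n = ((lo <= starts[None, :]) & (hi >= ends[None, :])).sum(axis=0)
        prof.profile[chrom] = pd.DataFrame({"start": starts, "end": ends, "n_eff": n})
    return prof


# ---------------------------------------------------------------------
# map building


def build_map(
    calls: pd.DataFrame,
    profile: EffectiveMeiosisProfile,
    marker_intervals: dict[str, np.ndarray],
    sex: str,
    assignment: str = "overlap",
) -> GeneticMap:
    """Estimate a sex-specific map from filtered crossover calls.

    Each call's unit mass is spread over the marker intervals overlapped
    by its bounding interval [left_bp, right_bp), proportionally to
    physical overlap (``assignment='overlap'``) or entirely to the
    interval containing the physical midpoint (``assignment='midpoint'``).
    Per-interval recombination fraction = mass / n_eff; Haldane converts
    to genetic distance; rates are cM per Mb.
    """
    if assignment not in ("overlap", "midpoint"):
        raise ValueError("assignment must be 'overlap' or 'midpoint'")
    pieces = []
    for chrom, edges in marker_intervals.items():
        edges = np.asarray(edges, dtype=float)
        starts, ends = edges[:-1], edges[1:]
        mass = np.zeros(len(starts))
        sub = calls[calls["chrom"] == chrom] if len(calls) else calls
        for left, right in zip(
            sub["left_bp"].values if len(sub) else [],
            sub["right_bp"].values if len(sub) else [],
        ):
            if assignment == "midpoint":
                mid = 0.5 * (left + right)
                i = np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, len(starts) - 1)
                mass[i] += 1.0
            else:
                ov = np.minimum(ends, right) - np.maximum(starts, left)
                ov = np.clip(ov, 0.0, None)
                tot = ov.sum()
                if tot <= 0:  # degenerate zero-width call: use midpoint
                    mid = 0.5 * (left + right)
                    i = np.clip(np.searchsorted(edges, mid, side="right") - 1, 0, len(starts) - 1)
                    mass[i] += 1.0
                else:
                    mass += ov / tot
        n_eff = profile.profile[chrom]["n_eff"].values.astype(float)
        if np.any((mass > 1e-12) & (n_eff <= 0)):
            raise ValueError(
                f"{chrom}: crossover mass in interval with zero effective meioses"
            )
        r = np.divide(mass, n_eff, out=np.zeros_like(mass), where=n_eff > 0)
        r = np.minimum(r, 0.499999)  # guard: fraction estimates near/above 1/2
        d_cm = haldane(r) * 100.0
        length_mb = (ends - starts) / 1e6
        pieces.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends,
                 "rate_cM_per_Mb": d_cm / length_mb,
                 "cum_cM": np.cumsum(d_cm)}
            )
        )
    return GeneticMap(pd.concat(pieces, ignore_index=True), sex=sex)


def sex_average(map_f: GeneticMap, map_m: GeneticMap) -> GeneticMap:
    """Unweighted per-interval mean of female and male genetic distances."""
    f, m = map_f.intervals, map_m.intervals
    if len(f) != len(m) or not (
        (f["chrom"].values == m["chrom"].values).all()
        and np.allclose(f["start"], m["start"])
        and np.allclose(f["end"], m["end"])
    ):
        raise ValueError("sex_average requires identical interval grids")
    rate = 0.5 * (f["rate_cM_per_Mb"].values + m["rate_cM_per_Mb"].values)
    out = f.copy()
    out["rate_cM_per_Mb"] = rate
    cm = rate * (out["end"].values - out["start"].values) / 1e6
    out["cum_cM"] = np.concatenate(
        [np.cumsum(cm[out["chrom"].values == c]) for c in dict.fromkeys(out["chrom"])]
    )
    return GeneticMap(out, sex="sex-averaged")


def reverse_chromosomes(obj, chroms, chrom_lengths: dict[str, int]):
    """Mirror physical coordinates x -> length - x on the given chromosomes.

    Accepts a GeneticMap or a crossover-call DataFrame (left_bp/right_bp
    columns); an involution either way.
    """
    for c in chroms:
        if c not in chrom_lengths:
            raise KeyError(f"unknown chromosome {c!r}")
    if isinstance(obj, GeneticMap):
        df = obj.intervals.copy()
        for c in chroms:
            m = df["chrom"] == c
            L = chrom_lengths[c]
            s = L - df.loc[m, "end"].values
            e = L - df.loc[m, "start"].values
            df.loc[m, "start"], df.loc[m, "end"] = s, e
        parts = []
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start").reset_index(drop=True)
            cm = sub["rate_cM_per_Mb"].values * (sub["end"].values - sub["start"].values) / 1e6
            sub["cum_cM"] = np.cumsum(cm)
            parts.append(sub)
        return GeneticMap(pd.concat(parts, ignore_index=True), sex=obj.sex)
    df = obj.copy()
    for c in chroms:
        m = df["chrom"] == c
        L = chrom_lengths[c]
        left = L - df.loc[m, "right_bp"].values
        right = L - df.loc[m, "left_bp"].values
        df.loc[m, "left_bp"], df.loc[m, "right_bp"] = left, right
    return df


def smooth_and_correlate(map_a: GeneticMap, map_b: GeneticMap, window_bp: float = 5e6) -> float:
    """Pearson correlation of rates smoothed in non-overlapping windows.

    Rates are physical-length-weighted means per window; correlation is
    computed over windows covered by both maps on shared chromosomes.
    """
    def window_rates(gm: GeneticMap) -> dict[tuple[str, int], float]:
        out = {}
        for chrom in gm.chromosomes():
            sub = gm.chrom_table(chrom)
            starts = sub["start"].values
            ends = sub["end"].values
            rates = sub["rate_cM_per_Mb"].values
            last = ends[-1]
            n_win = int(np.ceil(last / window_bp))
            for w in range(n_win):
                lo, hi = w * window_bp, (w + 1) * window_bp
                ov = np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0, None)
                if ov.sum() > 0:
                    out[(chrom, w)] = float((rates * ov).sum() / ov.sum())
        return out

    ra, rb = window_rates(map_a), window_rates(map_b)
    shared = sorted(set(ra) & set(rb))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared windows; cannot correlate")
    a = np.array([ra[k] for k in shared])
    b = np.array([rb[k] for k in shared])
    return float(np.corrcoef(a, b)[0, 1])
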