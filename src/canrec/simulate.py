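"""Synthetic meiosis generator.

Crossovers are placed on the genetic scale by a two-pathway model:

* an *interference* pathway — a stationary renewal process of chiasmata
  with gamma(shape nu, rate 2*nu*(1-p)) inter-arrival distances
  (Morgans), each chiasma independently retained with probability 1/2
  (chromatid thinning), and
* an *escape* pathway — a homogeneous Poisson process at rate p per
  Morgan on the chromatid.

The union has expected count L crossovers on a chromosome of genetic
length L Morgans for any nu.  Stationarity of the renewal pathway is
obtained by burn-in: the process starts 20 mean chiasma inter-arrivals
before the chromosome origin.

Genetic positions are mapped to bp through the inverse of a supplied
sex-specific genetic map; the default maps concentrate male
recombination near the distal (telomeric) chromosome end, emulating the
strong male telomeric bias of canine pedigree data.

Downstream observability is emulated by per-duo informative spans
(events outside the first/last heterozygous parental marker are
invisible), marker-grid localisation of retained events to bounding
intervals (default grid spacing 100 kb, the approximate median
resolution of array-based pedigree calls), and optional injection of
labelled artifacts: shared-boundary clustered double-crossover pairs
and outlier meioses with abnormal counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genome
from .gmap import GeneticMap

TELOMERE_WINDOW_BP = 5_000_000


@dataclass
class ArtifactRates:
    """Rates of injected artifacts.

    ``cluster_groups`` is the expected number of shared-boundary
    double-crossover cluster groups (each group = 2 meioses of one
    parent x 2 calls = 4 records).  ``outlier_fraction`` is the per-
    meiosis probability of being turned into a count outlier.
    """

    cluster_groups: float = 0.0
    outlier_fraction: float = 0.0
    outlier_multiplier: float = 4.0  # outlier count ~ multiplier x expected


@dataclass
class SimConfig:
    """Conditions for one simulated pedigree dataset.

    Defaults mirror the canine study design: 204 meioses per sex over
    the 38 canFam3.1 autosomes, sex-specific genetic lengths summing to
    2162 cM (female) and 1816 cM (male), gamma-model interference
    shapes of 5.22 (female) and 3.73 (male), no escape pathway, male
    recombination concentrated at the distal 5 Mb.
    """

    n_meioses_per_sex: int = 204
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(genome.CANFAM3_AUTOSOME_BP)
    )
    genetic_lengths: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "female": genome.default_genetic_lengths("female"),
            "male": genome.default_genetic_lengths("male"),
        }
    )  # sex -> chrom -> cM
    nu: dict[str, float] | float = field(
        default_factory=lambda: {"female": 5.22, "male": 3.73}
    )
    p_escape: dict[str, float] | float = 0.0
    telomere_bias: dict[str, float] | float = field(
        default_factory=lambda: {"female": 1.15, "male": 6.5}
    )  # distal-window rate multiplier relative to interior
    censor_fraction: float = 0.1
    marker_spacing_bp: float = 100_000.0
    children_per_parent: int = 4
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    seed: int = 0

    def __post_init__(self) -> None:
        for sex in ("female", "male"):
            if self.get_nu(sex) <= 0:
                raise ValueError("nu must be > 0")
            if not 0.0 <= self.get_p(sex) <= 1.0:
                raise ValueError("p_escape must lie in [0, 1]")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for sex in self.genetic_lengths:
            if any(l <= 0 for l in self.genetic_lengths[sex].values()):
                raise ValueError("genetic lengths must be positive")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must lie in [0, 1)")

    def _per_sex(self, attr, sex):
        v = getattr(self, attr)
        return float(v[sex]) if isinstance(v, dict) else float(v)

    def get_nu(self, sex: str) -> float:
        return self._per_sex("nu", sex)

    def get_p(self, sex: str) -> float:
        return self._per_sex("p_escape", sex)

    def get_bias(self, sex: str) -> float:
        return self._per_sex("telomere_bias", sex)


def true_map(config: SimConfig, sex: str) -> GeneticMap:
    """The generating genetic map for one sex.

    Two-segment per chromosome: interior at relative rate 1 and the
    distal telomeric window at the sex's telomere-bias multiplier,
    normalised so the chromosome total equals the configured genetic
    length.
    """
    rows = []
    for chrom, P in config.chrom_lengths.items():
        cm_total = config.genetic_lengths[sex][chrom]
        bias = config.get_bias(sex)
        w = min(TELOMERE_WINDOW_BP, 0.5 * P)
        interior = P - w
        # relative mass: interior*1 + w*bias
        denom = interior + w * bias
        rate_int = cm_total / denom * 1e6  # cM/Mb
        rate_tel = rate_int * bias
        rows.append((chrom, 0.0, interior, rate_int))
        rows.append((chrom, interior, float(P), rate_tel))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "rate_cM_per_Mb"])
    parts = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.copy()
        sub["cum_cM"] = np.cumsum(
            sub["rate_cM_per_Mb"].values * (sub["end"].values - sub["start"].values) / 1e6
        )
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True)
    # keep chromosome order of the config
    out["chrom"] = pd.Categorical(out["chrom"], categories=list(config.chrom_lengths), ordered=True)
    out = out.sort_values(["chrom", "start"], ignore_index=True)
    out["chrom"] = out["chrom"].astype(str)
    return GeneticMap(out, sex=sex)


def _stationary_gamma_renewal(rng: np.random.Generator, nu: float, rate: float, L: float) -> np.ndarray:
    """Event positions in [0, L] of a stationary gamma renewal process.

    Inter-arrivals ~ gamma(shape nu, rate ``rate``); stationarity by
    burn-in of 20 mean inter-arrivals before 0.
    """
    if rate <= 0 or L <= 0:
        return np.empty(0)
    mean_gap = nu / rate
    start = -20.0 * mean_gap
    span = L - start
    # draw in blocks until past L
    n_guess = max(8, int(span / mean_gap * 1.5) + 8)
    gaps = rng.gamma(nu, 1.0 / rate, size=n_guess)
    pos = start + np.cumsum(gaps)
    while pos[-1] < L:
        gaps = rng.gamma(nu, 1.0 / rate, size=n_guess)
        pos = np.concatenate([pos, pos[-1] + np.cumsum(gaps)])
    return pos[(pos >= 0.0) & (pos <= L)]


def simulate_crossover_positions(
    rng: np.random.Generator, nu: float, p: float, L: float
) -> tuple[np.ndarray, np.ndarray]:
    """Crossover positions (Morgans) on [0, L] and their pathway labels.

    Returns (positions sorted, is_escape bool array).  Interference
    chiasmata arrive as gamma(nu, 2*nu*(1-p)) and are thinned by 1/2;
    escapes are Poisson at rate p per Morgan.
    """
    xs_int = np.empty(0)
    if p < 1.0:
        chiasmata = _stationary_gamma_renewal(rng, nu, 2.0 * nu * (1.0 - p), L)
        keep = rng.random(len(chiasmata)) < 0.5
        xs_int = chiasmata[keep]
    n_esc = rng.poisson(p * L)
    xs_esc = rng.uniform(0.0, L, size=n_esc)
    pos = np.concatenate([xs_int, xs_esc])
    esc = np.concatenate([np.zeros(len(xs_int), bool), np.ones(n_esc, bool)])
    order = np.argsort(pos)
    return pos[order], esc[order]


def simulate_crossovers(config: SimConfig) -> pd.DataFrame:
    """Simulate true crossovers for every meiosis x chromosome.

    Returns a table with columns meiosis_id, parent_id, child_id,
    parent_sex, chrom, pos_morgan, pos_bp, pathway
    ('interference'|'escape'), artifact (False throughout; artifacts are
    injected later).  Sorted by meiosis, chromosome, position.
    """
    rng = np.random.default_rng(config.seed)
    maps = {sex: true_map(config, sex) for sex in ("female", "male")}
    rows = []
    for sex in ("female", "male"):
        gm = maps[sex]
        nu, p = config.get_nu(sex), config.get_p(sex)
        for i in range(config.n_meioses_per_sex):
            parent = f"{sex[0]}P{i // config.children_per_parent:03d}"
            child = f"{sex[0]}C{i:04d}"
            mid = f"{sex[0]}M{i:04d}"
            for chrom in config.chrom_lengths:
                L = config.genetic_lengths[sex][chrom] / 100.0  # Morgans
                pos_m, esc = simulate_crossover_positions(rng, nu, p, L)
                if len(pos_m) == 0:
                    continue
                pos_bp = gm.bp_at(chrom, pos_m * 100.0)
                for x, b, e in zip(pos_m, np.atleast_1d(pos_bp), esc):
                    rows.append(
                        (mid, parent, child, sex, chrom, x, float(b),
                         "escape" if e else "interference", False)
                    )
    df = pd.DataFrame(
        rows,
        columns=["meiosis_id", "parent_id", "child_id", "parent_sex", "chrom",
                 "pos_morgan", "pos_bp", "pathway", "artifact"],
    )
    return df


def meiosis_index(config: SimConfig) -> pd.DataFrame:
    """All meioses of the design (id, parent, child, sex), including those
    that happened to receive zero crossovers."""
    rows = []
    for sex in ("female", "male"):
        for i in range(config.n_meioses_per_sex):
            rows.append(
                (f"{sex[0]}M{i:04d}", f"{sex[0]}P{i // config.children_per_parent:03d}",
                 f"{sex[0]}C{i:04d}", sex)
            )
    return pd.DataFrame(rows, columns=["meiosis_id", "parent_id", "child_id", "parent_sex"])


def marker_grid(config: SimConfig, chrom: str) -> np.ndarray:
    """Uniform marker grid on one chromosome (deterministic given config)."""
    P = config.chrom_lengths[chrom]
    s = config.marker_spacing_bp
    return np.arange(0.0, P + s, s)


def censor_informative_spans(
    events: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply informative-span censoring and marker-grid localisation.

    Per duo x chromosome a random informative span is drawn whose
    expected censored fraction of the chromosome is
    ``config.censor_fraction`` (split between the two ends).  True
    events outside the span are dropped; retained events are reported
    as the marker-grid bounding interval containing the true position,
    with a call probability near 1.

    Returns (observed calls, informative spans).  Call coordinates are
    0-based half-open.
    """
    rng = np.random.default_rng(config.seed + 1)
    idx = meiosis_index(config)
    span_rows = []
    spans: dict[tuple[str, str], tuple[float, float]] = {}
    for _, m in idx.iterrows():
        for chrom, P in config.chrom_lengths.items():
            cut = config.censor_fraction * P / 2.0
            lo = rng.uniform(0.0, 2.0 * cut) if cut > 0 else 0.0
            hi = P - (rng.uniform(0.0, 2.0 * cut) if cut > 0 else 0.0)
            if hi <= lo:  # pathological draw on a short chromosome
                warnings.warn(f"{chrom}: informative span collapsed; clipping")
                lo, hi = 0.0, float(P)
            spans[(m["meiosis_id"], chrom)] = (lo, hi)
            span_rows.append((m["meiosis_id"], chrom, lo, hi))
    span_df = pd.DataFrame(
        span_rows, columns=["duo_id", "chrom", "first_het_bp", "last_het_bp"]
    )

    call_rows = []
    for _, ev in events.iterrows():
        lo, hi = spans[(ev["meiosis_id"], ev["chrom"])]
        x = ev["pos_bp"]
        if not (lo <= x <= hi):
            continue
        grid = marker_grid(config, ev["chrom"])
        i = int(np.clip(np.searchsorted(grid, x, side="right") - 1, 0, len(grid) - 2))
        prob = 1.0 - rng.beta(1.0, 15.0) * 0.5  # high-confidence genuine calls
        call_rows.append(
            (ev["meiosis_id"], ev["parent_id"], ev["child_id"], ev["parent_sex"],
             ev["chrom"], float(grid[i]), float(grid[i + 1]), prob, bool(ev["artifact"]))
        )
    calls = pd.DataFrame(
        call_rows,
        columns=["meiosis_id", "parent_id", "child_id", "parent_sex", "chrom",
                 "left_bp", "right_bp", "probability", "artifact"],
    )
    return calls, span_df


def inject_artifacts(calls: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Add labelled artifact calls: shared-boundary clustered
    double-crossover groups and outlier meioses.

    Cluster groups: a parent is chosen, a boundary marker position B on
    a random chromosome, and two meioses of that parent each receive a
    pair of calls [B - s, B) and [B, B + s) whose inner gap (0) is well
    within the 1-Mb clustering window and which share the boundary B.
    Outlier meioses: a meiosis receives extra random calls inflating
    its genome-wide count to ``outlier_multiplier`` times the sex's
    expected count.  All injected records have artifact=True.
    """
    rng = np.random.default_rng(config.seed + 2)
    rates = config.artifact_rates
    out = [calls]
    idx = meiosis_index(config)
    s = config.marker_spacing_bp

    n_groups = rng.poisson(rates.cluster_groups) if rates.cluster_groups > 0 else 0
    for _ in range(n_groups):
        parent = rng.choice(idx["parent_id"].unique())
        kids = idx[idx["parent_id"] == parent]
        if len(kids) < 2:
            continue
        two = kids.sample(2, random_state=int(rng.integers(2**31)))
        chrom = str(rng.choice(list(config.chrom_lengths)))
        grid = marker_grid(config, chrom)
        j = int(rng.integers(2, len(grid) - 3))
        B = grid[j]
        for _, m in two.iterrows():
            for left, right in ((B - s, B), (B, B + s)):
                out.append(pd.DataFrame([{
                    "meiosis_id": m["meiosis_id"], "parent_id": parent,
                    "child_id": m["child_id"], "parent_sex": m["parent_sex"],
                    "chrom": chrom, "left_bp": float(left), "right_bp": float(right),
                    "probability": 0.99, "artifact": True,
                }]))

    if rates.outlier_fraction > 0:
        for _, m in idx.iterrows():
            if rng.random() >= rates.outlier_fraction:
                continue
            sex = m["parent_sex"]
            expected = sum(config.genetic_lengths[sex].values()) / 100.0
            n_extra = int(rates.outlier_multiplier * expected)
            for _ in range(n_extra):
                chrom = str(rng.choice(list(config.chrom_lengths)))
                grid = marker_grid(config, chrom)
                j = int(rng.integers(0, len(grid) - 1))
                out.append(pd.DataFrame([{
                    "meiosis_id": m["meiosis_id"], "parent_id": m["parent_id"],
                    "child_id": m["child_id"], "parent_sex": sex,
                    "chrom": chrom, "left_bp": float(grid[j]),
                    "right_bp": float(grid[j + 1]),
                    "probability": 0.95, "artifact": True,
                }]))

    res = pd.concat(out, ignore_index=True)
    return res.sort_values(
        ["meiosis_id", "chrom", "left_bp"], ignore_index=True, kind="stable"
    )


def simulate_dataset(config: SimConfig) -> dict:
    """End-to-end synthetic dataset: truth, spans, observed calls (with
    artifacts), the generating maps, and the meiosis index."""
    truth = simulate_crossovers(config)
    observed, spans = censor_informative_spans(truth, config)
    observed = inject_artifacts(observed, config)
    return {
        "truth": truth,
        "spans": spans,
        "calls": observed,
        "maps": {sex: true_map(config, sex) for sex in ("female", "male")},
        "meioses": meiosis_index(config),
    }
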