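"""Crossover-interference inference.

Two models of inter-crossover spacing on the genetic (Morgan) scale:

**Gamma model.**  Chiasmata on the four-chromatid bundle form a
stationary renewal process with gamma(shape nu, rate 2*nu) inter-arrival
distances; each chiasma involves a given chromatid with probability 1/2
(chromatid thinning).  The observed crossover process then has
inter-arrival density

    f*(x) = sum_{j>=1} (1/2)^j Gamma(x; j*nu, 2*nu),

i.e. a geometric mixture over the number of skipped chiasmata, with
mean inter-crossover distance 1 Morgan.  nu = 1 recovers a homogeneous
Poisson process (no interference); nu > 1 spaces events apart.

**Gamma-escape model** (two-pathway / Housworth-Stahl).  A proportion p
of crossovers "escape" interference: the observed process is the
superposition of an interfering pathway (chiasma inter-arrivals
gamma(nu, 2*nu*(1-p)), thinned by 1/2) and an independent Poisson
pathway at rate p per Morgan.  The likelihood of an observed sequence
sums over all 2^k assignments of its k events to the two pathways.

Both likelihoods are full stationary-renewal likelihoods with end
effects: the first event enters through the equilibrium first-arrival
density, the region beyond the last event through the inter-arrival
survival function, and empty chromosomes through the probability of
observing no event — so zero-crossover chromosomes carry information
and censored observable spans are handled by using the span's genetic
length as L.

Fitting is bounded maximum likelihood; confidence intervals come from a
percentile bootstrap over meioses (resampling whole meioses preserves
within-meiosis dependence across chromosomes); model choice uses
BIC = -2 ln L + k ln n with n the number of meiosis-chromosome
sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

# geometric thinning weights (1/2)^j are truncated once below 1e-12
_J_MAX = 39
_J = np.arange(1, _J_MAX + 1)
_LOG_W = -_J * np.log(2.0)

NU_BOUNDS = (0.1, 200.0)
ESCAPE_ENUM_CAP = 20


@dataclass
class CrossoverSequence:
    """Ordered crossover positions of one meiosis on one chromosome.

    Positions and the observable length L are in Morgans, measured from
    the start of the observable region.
    """

    meiosis_id: str
    sex: str
    chrom: str
    L: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.L <= 0:
            raise ValueError("genetic length must be positive")
        if len(self.positions):
            if np.any(np.diff(self.positions) < 0):
                raise ValueError("positions must be sorted")
            if self.positions[0] < 0 or self.positions[-1] > self.L:
                raise ValueError("positions outside [0, L]")

    @property
    def k(self) -> int:
        return len(self.positions)


def to_genetic_scale(calls: pd.DataFrame, gmap, meioses: pd.DataFrame | None = None) -> list[CrossoverSequence]:
    """Convert filtered calls to Morgan-scale sequences under a map.

    Each call is placed at the genetic image of the physical midpoint of
    its bounding interval; L is the chromosome's genetic length under
    the map.  ``meioses`` (meiosis_id, parent_sex) enumerates the
    meioses of the design so chromosomes with zero calls still yield
    (informative) empty sequences; defaults to the meioses present in
    ``calls``.
    """
    chroms = gmap.chromosomes()
    chrom_L = {c: gmap.chrom_cm(c) / 100.0 for c in chroms}
    if meioses is None:
        meioses = calls[["meiosis_id", "parent_sex"]].drop_duplicates()
    by_mc: dict[tuple[str, str], list[float]] = {}
    for _, row in calls.iterrows():
        chrom = row["chrom"]
        if chrom not in chrom_L:
            raise ValueError(f"call on {chrom!r} outside map support")
        mid = 0.5 * (row["left_bp"] + row["right_bp"])
        sub = gmap.chrom_table(chrom)
        if not (sub["start"].iloc[0] <= mid <= sub["end"].iloc[-1]):
            raise ValueError(f"call midpoint {mid} outside map support on {chrom}")
        x = float(gmap.cm_at(chrom, mid)) / 100.0
        by_mc.setdefault((row["meiosis_id"], chrom), []).append(x)
    seqs = []
    for _, m in meioses.iterrows():
        for chrom in chroms:
            xs = sorted(by_mc.get((m["meiosis_id"], chrom), []))
            xs = np.clip(xs, 0.0, chrom_L[chrom])
            seqs.append(
                CrossoverSequence(m["meiosis_id"], m["parent_sex"], chrom,
                                  chrom_L[chrom], np.asarray(xs))
            )
    return seqs


# ---------------------------------------------------------------------
# stationary thinned-gamma renewal primitives
#
# All take the interference-pathway crossover rate c per Morgan
# (c = 1 for the pure gamma model, 1-p under escape); chiasma
# inter-arrivals are gamma(nu, 2*nu*c).


def _log_interarrival_pdf(x: np.ndarray, nu: float, c: float) -> np.ndarray:
    """log f*(x): geometric mixture of gamma(j*nu, 2*nu*c) densities."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    a = _J[None, :] * nu
    rate = 2.0 * nu * c
    with np.errstate(divide="ignore"):
        logx = np.log(x)[:, None]
    lp = (a * np.log(rate) + (a - 1.0) * logx - rate * x[:, None]
          - special.gammaln(a))
    return special.logsumexp(_LOG_W[None, :] + lp, axis=1)


def _log_survival(y: np.ndarray, nu: float, c: float) -> np.ndarray:
    """log P(next crossover farther than y) = log sum_j (1/2)^j S_j(y)."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    a = _J[None, :] * nu
    sf = special.gammaincc(a, 2.0 * nu * c * y[:, None])
    w = np.exp(_LOG_W)[None, :]
    # the truncated tail j > J_MAX contributes at most 2^-J_MAX ~ 2e-12
    total = (w * sf).sum(axis=1) + np.exp(_LOG_W[-1])
    return np.log(np.clip(total, 1e-300, None))


def _log_p0(L: np.ndarray, nu: float, c: float) -> np.ndarray:
    """log P(no crossover on [0, L]) for the stationary thinned process.

    P0(L) = 1 - c * int_0^L S(t) dt with the integral in closed form per
    mixture component: int_0^L S_j = L*S_j(L) + (j/(2c)) F_{j nu + 1}(L).
    """
    L = np.atleast_1d(np.asarray(L, dtype=float))
    a = _J[None, :] * nu
    z = 2.0 * nu * c * L[:, None]
    sf = special.gammaincc(a, z)
    cdf1 = special.gammainc(a + 1.0, z)
    w = np.exp(_LOG_W)[None, :]
    integral = (w * (L[:, None] * sf + (_J[None, :] / (2.0 * c)) * cdf1)).sum(axis=1)
    # truncated-tail correction: remaining weight 2^-J behaves like sf~1
    integral += np.exp(_LOG_W[-1]) * L
    p0 = 1.0 - c * integral
    return np.log(np.clip(p0, 1e-300, 1.0))


def _renewal_loglik_parts(firsts, gaps, tails, empty_L, nu, c):
    """Total log-likelihood from pre-gathered sequence pieces."""
    total = 0.0
    if len(empty_L):
        total += _log_p0(np.asarray(empty_L), nu, c).sum()
    if len(firsts):
        # equilibrium first-arrival density g(x) = c * S(x)
        total += len(firsts) * np.log(c) + _log_survival(np.asarray(firsts), nu, c).sum()
        total += _log_survival(np.asarray(tails), nu, c).sum()
    if len(gaps):
        total += _log_interarrival_pdf(np.asarray(gaps), nu, c).sum()
    return float(total)


def _gather(seqs: list[CrossoverSequence]):
    firsts, gaps, tails, empty_L = [], [], [], []
    for s in seqs:
        if s.k == 0:
            empty_L.append(s.L)
        else:
            firsts.append(s.positions[0])
            tails.append(s.L - s.positions[-1])
            gaps.extend(np.diff(s.positions))
    return (np.asarray(firsts), np.asarray(gaps),
            np.asarray(tails), np.asarray(empty_L))


def gamma_loglik(seqs: list[CrossoverSequence], nu: float) -> float:
    """Log-likelihood of the sequences under the gamma model at shape nu."""
    if not np.isfinite(nu) or nu <= 0:
        raise ValueError("nu must be finite and > 0")
    firsts, gaps, tails, empty_L = _gather(seqs)
    ll = _renewal_loglik_parts(firsts, gaps, tails, empty_L, nu, 1.0)
    if not np.isfinite(ll):
        raise FloatingPointError(f"non-finite log-likelihood at nu={nu}")
    return ll


def naive_gamma_loglik(seqs: list[CrossoverSequence], nu: float) -> float:
    """Naive i.i.d. gamma(nu, 2*nu) likelihood on the observed gaps only.

    Sensitivity-analysis mode: ignores chromatid thinning, censoring and
    end effects, so it is biased for pedigree data — use
    :func:`gamma_loglik` for inference.
    """
    if not np.isfinite(nu) or nu <= 0:
        raise ValueError("nu must be finite and > 0")
    _, gaps, _, _ = _gather(seqs)
    if len(gaps) == 0:
        return 0.0
    a, rate = nu, 2.0 * nu
    return float(np.sum(a * np.log(rate) + (a - 1.0) * np.log(gaps)
                        - rate * gaps - special.gammaln(a)))


class EscapeDesign:
    """Pre-enumerated pathway assignments for the gamma-escape likelihood.

    For each sequence, all 2^k assignments of its k events to the
    escape (Poisson, rate p) vs. interference (thinned gamma renewal,
    rate 1-p) pathway are flattened into index arrays once, so each
    likelihood evaluation is a handful of vectorized gamma calls
    followed by a grouped logsumexp.
    """

    def __init__(self, seqs: list[CrossoverSequence]):
        self.seqs = seqs
        self.sum_L = float(sum(s.L for s in seqs))
        self.ks = np.array([s.k for s in seqs])
        over = self.ks > ESCAPE_ENUM_CAP
        if over.any():
            raise ValueError(
                f"{int(over.sum())} sequence(s) exceed the escape enumeration "
                f"cap of {ESCAPE_ENUM_CAP} events; exclude them before fitting"
            )
        pair_seq, pair_nesc, pair_empty_L = [], [], []
        firsts, f_pair, gaps, g_pair, tails = [], [], [], [], []
        empty_pair, empty_L = [], []
        pid = 0
        for si, s in enumerate(seqs):
            x = s.positions
            for mask in range(1 << s.k):
                esc = [(mask >> i) & 1 for i in range(s.k)]
                xg = x[[not e for e in esc]] if s.k else x
                pair_seq.append(si)
                pair_nesc.append(sum(esc))
                if len(xg) == 0:
                    empty_pair.append(pid)
                    empty_L.append(s.L)
                else:
                    firsts.append(xg[0])
                    f_pair.append(pid)
                    tails.append(s.L - xg[-1])
                    for d in np.diff(xg):
                        gaps.append(d)
                        g_pair.append(pid)
                pid += 1
        self.n_pairs = pid
        self.pair_seq = np.array(pair_seq)
        self.pair_nesc = np.array(pair_nesc, dtype=float)
        self.empty_pair = np.array(empty_pair, dtype=int)
        self.empty_L = np.array(empty_L)
        self.firsts = np.array(firsts)
        self.f_pair = np.array(f_pair, dtype=int)
        self.tails = np.array(tails)
        self.gaps = np.array(gaps)
        self.g_pair = np.array(g_pair, dtype=int)
        # sequences appear in contiguous pair blocks
        self.seq_starts = np.searchsorted(self.pair_seq, np.arange(len(seqs)))

    def loglik(self, nu: float, p: float) -> float:
        if not np.isfinite(nu) or nu <= 0:
            raise ValueError("nu must be finite and > 0")
        if not 0.0 <= p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        c = 1.0 - p
        if c < 1e-12:  # pure Poisson limit: only the all-escape assignment
            return float((self.ks * np.log(max(p, 1e-300))).sum() - p * self.sum_L)
        val = np.zeros(self.n_pairs)
        if len(self.empty_pair):
            val[self.empty_pair] += _log_p0(self.empty_L, nu, c)
        if len(self.firsts):
            sv = _log_survival(np.concatenate([self.firsts, self.tails]), nu, c)
            n = len(self.firsts)
            np.add.at(val, self.f_pair, np.log(c) + sv[:n] + sv[n:])
        if len(self.gaps):
            np.add.at(val, self.g_pair, _log_interarrival_pdf(self.gaps, nu, c))
        has_esc = self.pair_nesc > 0
        if p > 0:
            val[has_esc] += self.pair_nesc[has_esc] * np.log(p)
        else:
            val[has_esc] = -np.inf
        # grouped logsumexp over each sequence's contiguous pair block
        mx = np.maximum.reduceat(val, self.seq_starts)
        mx = np.where(np.isfinite(mx), mx, 0.0)
        shifted = np.exp(val - mx[self.pair_seq])
        sums = np.add.reduceat(shifted, self.seq_starts)
        return float((mx + np.log(sums)).sum() - p * self.sum_L)


def gamma_escape_loglik(seqs: list[CrossoverSequence], nu: float, p: float) -> float:
    """Log-likelihood under the two-pathway gamma-escape model.

    Exact 2^k enumeration over pathway assignments per sequence;
    identical to :func:`gamma_loglik` at p=0 and to a homogeneous
    Poisson likelihood at p=1.
    """
    return EscapeDesign(seqs).loglik(nu, p)


# ---------------------------------------------------------------------
# fitting


@dataclass
class InterferenceFit:
    model: str  # 'gamma' | 'gamma_escape'
    nu: float
    p: float
    loglik: float
    bic: float
    n_obs: int
    nu_ci: tuple[float, float] | None = None
    p_ci: tuple[float, float] | None = None
    bootstrap_nu: np.ndarray | None = field(default=None, repr=False)
    bootstrap_p: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model, "nu": self.nu, "p": self.p,
            "loglik": self.loglik, "bic": self.bic, "n_obs": self.n_obs,
            "nu_ci": list(self.nu_ci) if self.nu_ci else None,
            "p_ci": list(self.p_ci) if self.p_ci else None,
        }


def bic(loglik: float, k_params: int, n: int) -> float:
    """Bayesian Information Criterion, -2 ln L + k ln n."""
    if n <= 0:
        raise ValueError("n must be positive")
    return -2.0 * loglik + k_params * np.log(n)


def _mle(seqs: list[CrossoverSequence], model: str) -> tuple[float, float, float]:
    lo, hi = np.log(NU_BOUNDS[0]), np.log(NU_BOUNDS[1])
    if model == "gamma":
        res = optimize.minimize_scalar(
            lambda t: -gamma_loglik(seqs, np.exp(t)),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:
            raise RuntimeError(f"gamma MLE failed: {res}")
        return float(np.exp(res.x)), 0.0, float(-res.fun)
    if model == "gamma_escape":
        design = EscapeDesign(seqs)
        best = None
        for x0 in ((np.log(4.0), 0.05), (np.log(20.0), 0.05), (np.log(2.0), 0.2)):
            res = optimize.minimize(
                lambda t: -design.loglik(np.exp(t[0]), float(np.clip(t[1], 0.0, 1.0))),
                x0=np.array(x0), method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 400},
            )
            t = res.x
            if not (lo - 1e-9 <= t[0] <= hi + 1e-9):
                continue
            if best is None or -res.fun > best[2]:
                best = (float(np.exp(t[0])), float(np.clip(t[1], 0.0, 1.0)), float(-res.fun))
        if best is None:
            raise RuntimeError("gamma-escape MLE failed from all starts")
        return best
    raise ValueError(f"unknown model {model!r}")


def fit(
    seqs: list[CrossoverSequence],
    model: str = "gamma",
    bootstrap_n: int = 1000,
    seed: int = 0,
) -> InterferenceFit:
    """Bounded MLE with percentile bootstrap over meioses.

    BIC uses n = number of meiosis-chromosome sequences and k = 1
    (gamma) or 2 (gamma-escape) free parameters.
    """
    if not any(s.k >= 1 for s in seqs):
        raise ValueError("need at least one sequence with a crossover")
    nu, p, ll = _mle(seqs, model)
    k_params = 1 if model == "gamma" else 2
    out = InterferenceFit(model, nu, p, ll, bic(ll, k_params, len(seqs)), len(seqs))
    if bootstrap_n and bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        by_meiosis: dict[str, list[CrossoverSequence]] = {}
        for s in seqs:
            by_meiosis.setdefault(s.meiosis_id, []).append(s)
        ids = sorted(by_meiosis)
        nus, ps = [], []
        for _ in range(bootstrap_n):
            pick = rng.choice(len(ids), size=len(ids), replace=True)
            bs = [s for i in pick for s in by_meiosis[ids[i]]]
            try:
                bnu, bp, _ = _mle(bs, model)
            except (RuntimeError, ValueError):
                continue
            nus.append(bnu)
            ps.append(bp)
        if len(nus) >= max(10, bootstrap_n // 2):
            out.bootstrap_nu = np.array(nus)
            out.bootstrap_p = np.array(ps)
            out.nu_ci = tuple(np.percentile(nus, [2.5, 97.5]))
            out.p_ci = tuple(np.percentile(ps, [2.5, 97.5]))
        else:
            warnings.warn("too many bootstrap refits failed; CIs omitted")
    return out


def compare_models(fit_gamma: InterferenceFit, fit_escape: InterferenceFit) -> tuple[str, float]:
    """Return (preferred model name, delta BIC = BIC_gamma - BIC_escape)."""
    if fit_gamma.n_obs != fit_escape.n_obs:
        raise ValueError("fits must use identical sequence sets (n mismatch)")
    delta = fit_gamma.bic - fit_escape.bic
    return (fit_escape.model if delta > 0 else fit_gamma.model, float(delta))


def stratified_fit(
    seqs: list[CrossoverSequence],
    ages: dict[str, float] | None = None,
    labels: dict[str, object] | None = None,
    n_bins: int = 7,
    model: str = "gamma",
    min_meioses: int = 10,
    bootstrap_n: int = 0,
    seed: int = 0,
) -> dict[object, InterferenceFit]:
    """Independent fits per stratum.

    Strata come either from explicit per-meiosis ``labels`` or from
    equal-frequency binning of per-meiosis ``ages`` into ``n_bins``.
    Strata with fewer than ``min_meioses`` meioses are skipped with a
    warning.
    """
    if (ages is None) == (labels is None):
        raise ValueError("provide exactly one of ages or labels")
    if ages is not None:
        ids = sorted(ages)
        vals = np.array([ages[i] for i in ids])
        qs = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
        bin_of = np.clip(np.searchsorted(qs, vals, side="right") - 1, 0, n_bins - 1)
        labels = {i: int(b) for i, b in zip(ids, bin_of)}
    by_label: dict[object, list[CrossoverSequence]] = {}
    for s in seqs:
        if s.meiosis_id in labels:
            by_label.setdefault(labels[s.meiosis_id], []).append(s)
    fits = {}
    for lab in sorted(by_label, key=str):
        sub = by_label[lab]
        n_meioses = len({s.meiosis_id for s in sub})
        if n_meioses < min_meioses or not any(s.k for s in sub):
            warnings.warn(f"stratum {lab!r}: too few meioses ({n_meioses}); skipped")
            continue
        fits[lab] = fit(sub, model=model, bootstrap_n=bootstrap_n, seed=seed)
    return fits
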