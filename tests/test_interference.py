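"""Interference likelihoods, model fitting, and model comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from canrec.gmap import GeneticMap
from canrec.interference import (ESCAPE_ENUM_CAP, CrossoverSequence,
                                 EscapeDesign, InterferenceFit, bic,
                                 compare_models, fit, gamma_escape_loglik,
                                 gamma_loglik, naive_gamma_loglik,
                                 stratified_fit, to_genetic_scale,
                                 _log_interarrival_pdf, _log_p0,
                                 _log_survival)
from canrec.simulate import simulate_crossover_positions

from conftest import make_calls, uniform_map


def seq(positions, L=1.0, mid="m0", sex="female", chrom="chr1"):
    return CrossoverSequence(mid, sex, chrom, L, np.asarray(positions, float))


def simulate_seqs(nu, p, n_meioses, Ls, seed):
    rng = np.random.default_rng(seed)
    out = []
    for m in range(n_meioses):
        for ci, L in enumerate(Ls):
            pos, _ = simulate_crossover_positions(rng, nu, p, L)
            out.append(seq(pos, L=L, mid=f"m{m}", chrom=f"chr{ci}"))
    return out


class TestGeneticScale:
    def test_linear_map_midpoint(self):
        gm = uniform_map(rate=1.0, length_bp=100e6, sex="female")
        calls = make_calls([("m0", "p", "female", "chr1", 49e6, 51e6, 0.9)])
        seqs = to_genetic_scale(calls, gm)
        (s,) = [x for x in seqs if x.k]
        assert s.positions[0] == pytest.approx(0.5)
        assert s.L == pytest.approx(1.0)

    def test_piecewise_map_integration(self):
        gm = GeneticMap.from_rates("chr1", [0, 50e6], [50e6, 100e6],
                                   [2.0, 0.0], sex="female")
        calls = make_calls([("m0", "p", "female", "chr1", 74e6, 76e6, 0.9)])
        (s,) = [x for x in to_genetic_scale(calls, gm) if x.k]
        assert s.positions[0] == pytest.approx(1.0)

    def test_empty_sequences_retained(self):
        gm = uniform_map(sex="female")
        meioses = pd.DataFrame({"meiosis_id": ["m0", "m1"],
                                "parent_sex": ["female", "female"]})
        seqs = to_genetic_scale(make_calls([]), gm, meioses=meioses)
        assert len(seqs) == 2 and all(s.k == 0 for s in seqs)

    def test_call_outside_map_errors(self):
        gm = uniform_map(sex="female")
        calls = make_calls([("m0", "p", "female", "chr9", 1e6, 2e6, 0.9)])
        with pytest.raises(ValueError, match="outside map support"):
            to_genetic_scale(calls, gm)


class TestPoissonLimit:
    def test_zero_count_closed_form(self):
        assert gamma_loglik([seq([], L=1.0)], nu=1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_order_statistics_density_free_of_positions(self):
        # at nu=1 the likelihood is exp(-L) regardless of event placement
        for pos in ([0.2, 0.7], [0.01, 0.02], [0.5, 0.99]):
            assert gamma_loglik([seq(pos, L=1.0)], 1.0) == pytest.approx(-1.0, abs=1e-9)

    def test_total_equals_minus_sum_L(self):
        rng = np.random.default_rng(0)
        seqs = []
        total_L = 0.0
        for i in range(20):
            L = rng.uniform(0.2, 2.0)
            k = rng.integers(0, 4)
            seqs.append(seq(np.sort(rng.uniform(0, L, k)), L=L, mid=f"m{i}"))
            total_L += L
        assert gamma_loglik(seqs, 1.0) == pytest.approx(-total_L, rel=1e-9)


class TestEscapeModel:
    def test_degenerate_p0_equals_gamma(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            nu = float(rng.uniform(0.5, 40.0))
            seqs = simulate_seqs(max(nu, 1.0), 0.1, 5, [0.8], seed=trial)
            a = gamma_escape_loglik(seqs, nu, 0.0)
            b = gamma_loglik(seqs, nu)
            assert a == pytest.approx(b, abs=1e-9)

    def test_p1_is_pure_poisson(self):
        assert gamma_escape_loglik([seq([], L=1.0)], 5.0, 1.0) == pytest.approx(-1.0)
        s = seq([0.3, 0.6], L=1.0)
        # Poisson rate 1: density e^{-L} per configuration
        assert gamma_escape_loglik([s], 5.0, 1.0) == pytest.approx(-1.0, abs=1e-9)

    def test_enumeration_cap_errors(self):
        s = seq(np.linspace(0.01, 0.99, ESCAPE_ENUM_CAP + 1), L=1.0)
        with pytest.raises(ValueError, match="cap"):
            gamma_escape_loglik([s], 5.0, 0.1)

    def test_mixture_likelihood_exceeds_pure_models_on_mixed_data(self):
        seqs = simulate_seqs(20.0, 0.1, 120, [1.0] * 8, seed=9)
        ll_mix = gamma_escape_loglik(seqs, 20.0, 0.1)
        assert ll_mix > gamma_loglik(seqs, 20.0)
        assert ll_mix > gamma_loglik(seqs, 1.0)


class TestNormalization:
    # L small enough that P(k >= 3), excluded from the quadrature, is
    # negligible; negative interference (nu < 1) clusters events so it
    # needs a shorter interval
    @pytest.mark.parametrize("nu,c,L", [(2.0, 1.0, 0.1), (5.0, 0.9, 0.1),
                                        (0.8, 1.0, 0.04)])
    def test_density_integrates_to_one_small_L(self, nu, c, L):
        g = lambda x: c * np.exp(_log_survival(np.array([x]), nu, c)[0])
        f = lambda x: np.exp(_log_interarrival_pdf(np.array([x]), nu, c)[0])
        S = lambda y: np.exp(_log_survival(np.array([y]), nu, c)[0])
        p0 = np.exp(_log_p0(np.array([L]), nu, c)[0])
        p1, _ = integrate.quad(lambda x: g(x) * S(L - x), 0, L)
        p2, _ = integrate.dblquad(lambda x2, x1: g(x1) * f(x2 - x1) * S(L - x2),
                                  0, L, lambda x1: x1, lambda x1: L)
        assert p0 + p1 + p2 == pytest.approx(1.0, abs=1e-4)

    def test_mean_rate_is_one_per_morgan(self):
        # stationary thinned process: P(event in [0,dx]) ~ dx
        dx = 1e-6
        for nu in (1.0, 5.0, 30.0):
            p_no = np.exp(_log_p0(np.array([dx]), nu, 1.0)[0])
            assert (1 - p_no) / dx == pytest.approx(1.0, rel=1e-3)


class TestFitting:
    def test_gamma_mle_recovers_truth(self):
        seqs = simulate_seqs(5.0, 0.0, 150, np.full(10, 0.8), seed=1)
        res = fit(seqs, "gamma", bootstrap_n=0)
        assert res.nu == pytest.approx(5.0, rel=0.25)
        assert res.p == 0.0 and res.n_obs == len(seqs)

    def test_bootstrap_ci_covers_truth(self):
        seqs = simulate_seqs(4.0, 0.0, 80, np.full(8, 0.8), seed=2)
        res = fit(seqs, "gamma", bootstrap_n=40, seed=0)
        assert res.nu_ci is not None
        lo, hi = res.nu_ci
        assert lo < 4.0 < hi
        assert lo <= res.nu <= hi

    def test_escape_fit_recovers_both_parameters(self):
        seqs = simulate_seqs(15.0, 0.08, 150, np.full(10, 0.8), seed=3)
        res = fit(seqs, "gamma_escape", bootstrap_n=0)
        assert res.nu == pytest.approx(15.0, rel=0.4)
        assert res.p == pytest.approx(0.08, abs=0.05)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            fit([seq([], L=1.0)], "gamma", bootstrap_n=0)

    def test_deterministic_given_seed(self):
        seqs = simulate_seqs(3.0, 0.0, 40, [0.8] * 4, seed=5)
        a = fit(seqs, "gamma", bootstrap_n=20, seed=11)
        b = fit(seqs, "gamma", bootstrap_n=20, seed=11)
        assert a.nu == b.nu and a.nu_ci == b.nu_ci


class TestNaiveMode:
    def test_naive_ignores_censoring_terms(self):
        # a single gap at nu=1: naive density is exp(1, rate 2), the full
        # likelihood is the Poisson configuration density exp(-L)
        s = seq([0.3, 0.5], L=1.0)
        assert naive_gamma_loglik([s], 1.0) == pytest.approx(np.log(2) - 0.4)
        assert naive_gamma_loglik([s], 1.0) != pytest.approx(gamma_loglik([s], 1.0))

    def test_naive_underestimates_interference_under_thinning(self):
        # observed gaps are geometric mixtures over skipped chiasmata, so a
        # plain gamma fit to gaps is pulled toward weaker interference
        seqs = simulate_seqs(8.0, 0.0, 300, [1.5] * 4, seed=13)
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda t: -naive_gamma_loglik(seqs, np.exp(t)),
                              bounds=(np.log(0.1), np.log(200)), method="bounded")
        assert np.exp(res.x) < 0.8 * 8.0


class TestModelComparison:
    def test_bic_closed_form(self):
        assert bic(-100.0, 2, 50) == pytest.approx(200 + 2 * np.log(50), abs=1e-3)
        assert bic(-100.0, 2, 50) == pytest.approx(207.824, abs=1e-3)

    def test_bic_monotone_in_n(self):
        ns = [10, 100, 1000]
        vals = [bic(-50.0, 2, n) for n in ns]
        assert vals == sorted(vals)

    def test_penalty_prefers_smaller_model_at_equal_loglik(self):
        g = InterferenceFit("gamma", 5.0, 0.0, -100.0, bic(-100.0, 1, 50), 50)
        e = InterferenceFit("gamma_escape", 5.0, 0.0, -100.0, bic(-100.0, 2, 50), 50)
        name, delta = compare_models(g, e)
        assert name == "gamma" and delta < 0

    def test_mismatched_n_errors(self):
        g = InterferenceFit("gamma", 5.0, 0.0, -100.0, 210.0, 50)
        e = InterferenceFit("gamma_escape", 5.0, 0.0, -100.0, 215.0, 60)
        with pytest.raises(ValueError, match="n mismatch"):
            compare_models(g, e)

    def test_escape_preferred_on_mixture_data(self):
        seqs = simulate_seqs(25.0, 0.12, 150, np.full(8, 0.9), seed=7)
        g = fit(seqs, "gamma", bootstrap_n=0)
        e = fit(seqs, "gamma_escape", bootstrap_n=0)
        name, delta = compare_models(g, e)
        assert name == "gamma_escape" and delta > 0


class TestStratifiedFit:
    def test_single_stratum_equals_fit(self):
        seqs = simulate_seqs(3.0, 0.0, 30, [0.8] * 4, seed=8)
        labels = {s.meiosis_id: "all" for s in seqs}
        res = stratified_fit(seqs, labels=labels, model="gamma")
        direct = fit(seqs, "gamma", bootstrap_n=0)
        assert res["all"].nu == pytest.approx(direct.nu, rel=1e-6)

    def test_two_strata_ordered(self):
        a = simulate_seqs(2.0, 0.0, 60, [0.9] * 6, seed=9)
        b = simulate_seqs(30.0, 0.0, 60, [0.9] * 6, seed=10)
        for s in b:
            s.meiosis_id = "x" + s.meiosis_id
        labels = {s.meiosis_id: ("lo" if not s.meiosis_id.startswith("x") else "hi")
                  for s in a + b}
        res = stratified_fit(a + b, labels=labels, model="gamma")
        assert res["lo"].nu < res["hi"].nu

    def test_age_binning_equal_frequency(self):
        seqs = simulate_seqs(4.0, 0.0, 70, [0.9] * 4, seed=11)
        ids = sorted({s.meiosis_id for s in seqs})
        ages = {m: float(i) for i, m in enumerate(ids)}
        res = stratified_fit(seqs, ages=ages, n_bins=7, model="gamma")
        assert len(res) == 7

    def test_small_stratum_skipped_with_warning(self):
        seqs = simulate_seqs(4.0, 0.0, 12, [0.9] * 4, seed=12)
        labels = {s.meiosis_id: ("tiny" if s.meiosis_id == "m0" else "rest")
                  for s in seqs}
        with pytest.warns(UserWarning, match="too few"):
            res = stratified_fit(seqs, labels=labels, model="gamma")
        assert "tiny" not in res and "rest" in res


class TestInputValidation:
    def test_invalid_nu_and_p(self):
        s = seq([0.5], L=1.0)
        with pytest.raises(ValueError):
            gamma_loglik([s], 0.0)
        with pytest.raises(ValueError):
            gamma_escape_loglik([s], 5.0, 1.5)

    def test_sequence_invariants(self):
        with pytest.raises(ValueError):
            CrossoverSequence("m", "f", "c", 1.0, np.array([0.9, 0.2]))
        with pytest.raises(ValueError):
            CrossoverSequence("m", "f", "c", 1.0, np.array([1.4]))
        with pytest.raises(ValueError):
            CrossoverSequence("m", "f", "c", 0.0, np.array([]))
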