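import math

import numpy as np
import pandas as pd
import pytest

from rivevol.adaptive_dynamics import (
    AdaptiveParams,
    AgeWeights,
    DynamicsData,
    LocusEffects,
    ModelConstants,
    PriorSpec,
    delta_p,
    evolvability,
    fit_model,
    forward_recursion,
    genetic_load,
    neg_log_posterior,
    neg_log_posterior_gradient,
    optimum,
    selection_gradient,
    va_locus,
    va_small,
    variance_explained,
)
from rivevol.io_datamodel import FlowSeries
from rivevol.synthetic_data import (
    SimScenario,
    sample_observations,
    simulate_flow,
    simulate_trajectory,
)


def brute_force_va(p, eff: LocusEffects):
    """HWE enumeration oracle: per-sex breeding values from a weighted
    least-squares regression of genotypic value on allele dosage."""
    q = 1 - p
    freqs = np.array([p * p, 2 * p * q, q * q])  # dosage of +a allele: 2, 1, 0
    dosage = np.array([2.0, 1.0, 0.0])
    out = {}
    bv = {}
    for sex, a, d in (("F", eff.a_f, eff.d_f), ("M", eff.a_m, eff.d_m)):
        vals = np.array([a, d, -a])
        # weighted linear regression on dosage
        wmean_x = freqs @ dosage
        wmean_y = freqs @ vals
        slope = (freqs @ ((dosage - wmean_x) * (vals - wmean_y))) / (
            freqs @ (dosage - wmean_x) ** 2
        )
        fitted = wmean_y + slope * (dosage - wmean_x)
        bv[sex] = fitted
        out[sex] = float(freqs @ (fitted - wmean_y) ** 2)
    ca = float(
        freqs
        @ (
            (bv["F"] - freqs @ bv["F"])
            * (bv["M"] - freqs @ bv["M"])
        )
    )
    combined = float(freqs @ (((bv["F"] + bv["M"]) / 2 - freqs @ ((bv["F"] + bv["M"]) / 2)) ** 2))
    return out["F"], out["M"], ca, combined


class TestVaLocus:
    def test_extreme_frequencies(self):
        eff = LocusEffects(1.0, 0.5, 0.8, -0.2)
        for p in (0.0, 1.0):
            res = va_locus(p, eff)
            assert res["va_f"] == res["va_m"] == res["ca_fm"] == res["combined"] == 0.0

    def test_symmetric_example(self):
        res = va_locus(0.5, LocusEffects(1.0, 0.0, 1.0, 0.0))
        assert res["va_f"] == pytest.approx(0.5)
        assert res["va_m"] == pytest.approx(0.5)
        assert res["ca_fm"] == pytest.approx(0.5)
        assert res["combined"] == pytest.approx(0.5)

    def test_bias_arithmetic(self):
        cov = np.zeros((4, 4))
        cov[0, 0] = cov[2, 2] = 0.04  # Var[a] per sex
        res = va_locus(0.5, LocusEffects(1.0, 0.0, 1.0, 0.0, cov))
        # bias = 2pq Var[a] = 0.5 * 0.04 = 0.02
        assert res["va_f"] == pytest.approx(0.48)
        assert res["va_m"] == pytest.approx(0.48)

    def test_brute_force_grid(self):
        rng = np.random.default_rng(0)
        for p in np.arange(0.01, 1.0, 0.07):
            a_f, d_f, a_m, d_m = rng.normal(0.0, 0.5, 4)
            eff = LocusEffects(a_f, d_f, a_m, d_m)
            res = va_locus(p, eff)
            bf_f, bf_m, bf_ca, bf_comb = brute_force_va(p, eff)
            assert res["va_f"] == pytest.approx(bf_f, abs=1e-12)
            assert res["va_m"] == pytest.approx(bf_m, abs=1e-12)
            assert res["ca_fm"] == pytest.approx(bf_ca, abs=1e-12)
            assert max(res["combined"], 0.0) == pytest.approx(
                max(bf_comb, 0.0), abs=1e-12
            )

    def test_invalid_cov_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            LocusEffects(1, 0, 1, 0, np.triu(np.ones((4, 4))))


class TestVaSmall:
    def test_arithmetic(self):
        assert va_small(0.5, 0.31, [0.05, 0.02]) == pytest.approx(0.085)
        assert va_small(1.0, 0.31, [0.0, 0.0]) == pytest.approx(0.31)

    def test_clamped_at_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            assert va_small(0.0, 0.31, [0.05, 0.02]) == 0.0
        assert "clamped" in caplog.text

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            va_small(-0.1, 0.31, [0.0])


class TestOptimumAndGradient:
    def test_reference_flow(self):
        assert optimum(3.0, 9.26, 1.5, 3.0) == 9.26

    def test_flow_cut_arithmetic(self):
        theta = optimum(math.log(17.0), 9.26, 1.0, math.log(41.0))
        assert theta == pytest.approx(9.26 + math.log(17.0 / 41.0), abs=1e-12)
        assert theta == pytest.approx(8.380, abs=1e-3)
        # about 4.4 kg
        assert math.exp(theta) / 1000.0 == pytest.approx(4.4, abs=0.1)

    def test_zero_slope(self):
        assert optimum(5.0, 9.26, 0.0, 3.0) == 9.26

    def test_gradient_at_optimum(self):
        beta, s = selection_gradient(9.0, 9.0, -2.0, vp=0.31)
        assert beta == 0.0 and s == 0.0

    def test_gradient_arithmetic(self):
        beta, s = selection_gradient(9.5, 9.0, 0.0, vp=0.31)
        assert beta == pytest.approx(-0.5)
        assert s == pytest.approx(-0.155)
        assert selection_gradient(10.0, 9.0, -2.0) == pytest.approx(
            -math.exp(-2.0), abs=1e-12
        )


class TestDeltaP:
    def test_no_selection(self):
        assert delta_p(0.3, LocusEffects(1.0, 0.2, 0.8, -0.1), 0.0) == 0.0

    def test_arithmetic(self):
        dp = delta_p(0.5, LocusEffects(1.0, 0.0, 1.0, 0.0), 0.1)
        assert dp == pytest.approx(0.025)

    def test_degenerate_denominator(self):
        # a + d(1-2p) = 0 at p = 0.25 with a = -0.5, d = 1
        with pytest.raises(ZeroDivisionError, match="sex F"):
            delta_p(0.25, LocusEffects(-0.5, 1.0, 1.0, 0.0), 0.1)

    @staticmethod
    def brute_force_delta_p(p, eff, beta):
        """One generation of deterministic HWE selection with linearized
        relative fitness 1 + beta * (value - mean), averaged over sexes."""
        q = 1 - p
        freqs = np.array([p * p, 2 * p * q, q * q])
        dosage = np.array([2.0, 1.0, 0.0])
        dps = []
        for a, d in ((eff.a_f, eff.d_f), (eff.a_m, eff.d_m)):
            vals = np.array([a, d, -a])
            w = 1.0 + beta * (vals - freqs @ vals)
            after = freqs * w / (freqs @ w)
            dps.append(after @ dosage / 2.0 - p)
        return float(np.mean(dps))

    def test_first_order_agreement(self):
        eff = LocusEffects(0.6, 0.1, 0.4, -0.2)
        for p in (0.2, 0.5, 0.8):
            beta = 1e-3
            exact = self.brute_force_delta_p(p, eff, beta)
            approx = delta_p(p, eff, beta)
            assert approx == pytest.approx(exact, rel=1e-4)

    def test_small_beta_regime_one_percent(self):
        eff = LocusEffects(0.43, 0.15, 0.66, -0.15)
        exact = self.brute_force_delta_p(0.6, eff, 0.05)
        assert delta_p(0.6, eff, 0.05) == pytest.approx(exact, rel=0.01)


class TestEvolvabilityAndLoad:
    def test_evolvability_values(self):
        assert evolvability(0.0) == 0.0
        assert evolvability(0.05) == pytest.approx(5.127, abs=1e-3)
        assert evolvability(0.1) == pytest.approx(10.517, abs=1e-3)

    def test_load_trivial(self):
        assert genetic_load(9.0, 9.0, -2.0, 0.0) == 0.0

    def test_load_closed_form_and_monte_carlo(self):
        load = genetic_load(9.26, 9.26, -2.0, 0.31)
        expected = 1.0 - (1.0 + 0.31 * math.exp(-2.0)) ** -0.5
        assert load == pytest.approx(expected, abs=1e-12)
        rng = np.random.default_rng(0)
        z = rng.normal(9.26, math.sqrt(0.31), 2_000_000)
        w = np.exp(-0.5 * math.exp(-2.0) * (z - 9.26) ** 2)
        assert load == pytest.approx(1.0 - w.mean(), abs=1e-3)

    def test_load_monotone_in_distance(self):
        loads = [genetic_load(9.26 + dz, 9.26, -2.0, 0.31) for dz in (0, 0.2, 0.5, 1.0)]
        assert all(np.diff(loads) > 0)


def _flow_series(start=1940, end=2000, base=41.0, cut_year=1953, cut_to=20.5):
    years = np.arange(start, end + 1)
    flow = np.where(years >= cut_year, cut_to, base)
    return FlowSeries(pd.Series(flow, index=pd.Index(years, name="year")))


def _zero_effects():
    return {"locus_a": LocusEffects(0.0, 0.0, 0.0, 0.0)}


class TestForwardRecursion:
    def test_fixed_point(self):
        params = AdaptiveParams(
            q=-1.0, theta_ref=9.26, b=1.0, delta=0.5, h2=0.5, sigma_e2=0.01,
            z_init=np.full(8, 9.26), p_init=np.array([0.6]),
        )
        flow = _flow_series(cut_year=3000)  # constant flow
        eff = {"locus_a": LocusEffects(0.4, 0.1, 0.5, -0.1)}
        traj = forward_recursion(params, ModelConstants(), AgeWeights(), eff, flow)
        assert np.allclose(traj["zbar"], 9.26, atol=1e-12)
        assert np.allclose(traj["p_locus_a"], 0.6, atol=1e-12)

    def test_independent_scalar_oracle(self):
        """With zero-effect loci, the model reduces to a scalar recursion
        that a hand-coded loop reproduces to 1e-12."""
        h2, vp, q, b = 0.4, 0.31, -1.0, 1.0
        params = AdaptiveParams(
            q=q, theta_ref=9.26, b=b, delta=0.5, h2=h2, sigma_e2=0.01,
            z_init=np.full(8, 9.26), p_init=np.array([0.5]),
        )
        flow = _flow_series()
        weights = AgeWeights()
        traj = forward_recursion(
            params, ModelConstants(), weights, _zero_effects(), flow
        )

        # hand-coded scalar recursion
        va = h2 * vp
        years = flow.flow.index.to_numpy()
        lnf = np.log(flow.flow.to_numpy())
        z = {y: 9.26 for y in range(years[0] - 8, years[0])}
        resp = {y: 0.0 for y in z}
        for i, y in enumerate(years):
            zt = sum(
                w * (z[y - k] + resp[y - k])
                for k, w in zip(weights.lags, weights.weights)
            )
            theta = 9.26 + b * (lnf[i] - lnf[0])
            beta = -math.exp(q) * (zt - theta)
            z[y] = zt
            resp[y] = va * beta
        expected = np.array([z[y] for y in years])
        assert np.allclose(traj["zbar"].to_numpy(), expected, atol=1e-12)

    def test_geometric_relaxation_toward_new_optimum(self):
        params = AdaptiveParams(
            q=0.0, theta_ref=9.26, b=1.0, delta=0.5, h2=0.5, sigma_e2=0.01,
            z_init=np.full(8, 9.26), p_init=np.array([0.5]),
        )
        traj = forward_recursion(
            params, ModelConstants(), AgeWeights(), _zero_effects(), _flow_series()
        )
        theta_new = traj["theta"].iloc[-1]
        gaps = (traj.loc[1953:, "zbar"] - theta_new).to_numpy()
        assert gaps[0] > gaps[-1] >= 0
        assert (np.diff(gaps) <= 1e-12).all()

    def test_age_shift_delays_adaptation(self):
        params = AdaptiveParams(
            q=0.0, theta_ref=9.26, b=1.0, delta=0.5, h2=0.5, sigma_e2=0.01,
            z_init=np.full(8, 9.26), p_init=np.array([0.5]),
        )
        kw = dict(
            constants=ModelConstants(),
            effects=_zero_effects(),
            flow=_flow_series(),
        )
        base = forward_recursion(params, weights=AgeWeights(), **kw)
        shifted = forward_recursion(params, weights=AgeWeights(shift=2), **kw)

        # the shifted population lags behind: larger optimum gap each year
        gap_base = (base.loc[1960:, "zbar"] - base.loc[1960:, "theta"]).to_numpy()
        gap_shift = (shifted.loc[1960:, "zbar"] - shifted.loc[1960:, "theta"]).to_numpy()
        assert (gap_shift > gap_base + 1e-9).all()
        # and the shifted response is best aligned with the base response at
        # a positive lag (cross-correlation of the yearly changes)
        db = np.diff(base["zbar"].to_numpy())
        ds = np.diff(shifted["zbar"].to_numpy())
        lags = range(0, 6)
        cors = [np.corrcoef(db[: len(db) - l], ds[l:])[0, 1] for l in lags]
        assert int(np.argmax(cors)) >= 1


def _paper_like_setup(seed=0):
    sc = SimScenario(seed=seed)
    flow = simulate_flow(sc)
    traj = simulate_trajectory(sc, flow)
    pheno, ac = sample_observations(traj, sc, np.random.default_rng(seed))
    data = DynamicsData(pheno, ac, flow)
    return sc, data


class TestNegLogPosterior:
    def test_priors_only_zero_at_prior_means(self):
        sc, data = _paper_like_setup()
        empty = DynamicsData(
            phenotypes=pd.DataFrame(
                {"mean_ln_mass": [], "se_ln_mass": []},
                index=pd.Index([], name="year"),
            ),
            allele_counts=pd.DataFrame(columns=["locus", "year", "A", "T"]),
            flow=data.flow,
        )
        from scipy.special import expit

        priors = PriorSpec()
        params = AdaptiveParams(
            q=priors.q[0],
            theta_ref=8.8,  # no prior on theta_ref / b / delta / sigma_e2
            b=0.3,
            delta=0.7,
            h2=float(expit(priors.logit_h2[0])),
            sigma_e2=0.02,
            z_init=np.full(8, priors.z_init[0]),
            p_init=expit(np.array([m for m, _ in priors.logit_p])),
        )
        nll = neg_log_posterior(
            params, empty, priors, sc.constants(), sc.weights, sc.effects
        )
        assert nll == pytest.approx(0.0, abs=1e-10)

    def test_residual_free_case(self):
        """When predictions equal observations exactly, the Gaussian part
        reduces to its normalization terms."""
        sc, data = _paper_like_setup()
        params = sc.params
        traj = forward_recursion(
            params, sc.constants(), sc.weights, sc.effects, data.flow
        )
        years = data.phenotypes.index
        perfect = data.phenotypes.copy()
        perfect["mean_ln_mass"] = (
            traj.loc[years, "zbar"].to_numpy()
            + params.delta * traj.loc[years, "s"].to_numpy()
        )
        clean = DynamicsData(
            perfect,
            pd.DataFrame(columns=["locus", "year", "A", "T"]),
            data.flow,
        )
        priors = PriorSpec()
        nll = neg_log_posterior(
            params, clean, priors, sc.constants(), sc.weights, sc.effects
        )
        var = params.sigma_e2 + perfect["se_ln_mass"].to_numpy() ** 2
        norm_terms = 0.5 * np.sum(np.log(2 * np.pi * var))
        from scipy.special import logit

        penalty = (
            0.5 * ((params.q + 2.0) / 1.0) ** 2
            + 0.5 * np.sum(((params.z_init - 9.26) / 0.14) ** 2)
            + 0.5 * (logit(params.h2) / 1.0) ** 2
            + 0.5 * ((logit(params.p_init[0]) - 0.99) / 0.20) ** 2
            + 0.5 * ((logit(params.p_init[1]) - 2.94) / 0.80) ** 2
        )
        assert nll == pytest.approx(norm_terms + penalty, abs=1e-8)

    def test_gradient_check(self):
        sc, data = _paper_like_setup(seed=3)
        priors = PriorSpec()
        grad = neg_log_posterior_gradient(
            sc.params, data, priors, sc.constants(), sc.weights, sc.effects
        )
        # independent higher-order stencil
        from rivevol.adaptive_dynamics import _objective_factory, _pack

        fun = _objective_factory(
            data, priors, sc.constants(), sc.weights, sc.effects,
            len(sc.params.z_init), len(sc.params.p_init),
        )
        x = _pack(sc.params)
        g4 = np.empty_like(x)
        for i in range(len(x)):
            h = 1e-4 * max(1.0, abs(x[i]))
            xs = [x.copy() for _ in range(4)]
            xs[0][i] += 2 * h
            xs[1][i] += h
            xs[2][i] -= h
            xs[3][i] -= 2 * h
            g4[i] = (-fun(xs[0]) + 8 * fun(xs[1]) - 8 * fun(xs[2]) + fun(xs[3])) / (
                12 * h
            )
        assert np.linalg.norm(grad - g4) / np.linalg.norm(g4) < 1e-6


class TestFitModel:
    def test_single_seed_recovery(self):
        sc, data = _paper_like_setup(seed=11)
        fit = fit_model(
            data, PriorSpec(), sc.constants(), sc.weights, sc.effects,
            n_restarts=2, seed=0,
        )
        lo, hi = fit.wald_interval("b")
        assert lo <= 1.0 <= hi
        lo, hi = fit.wald_interval("q")
        assert lo <= -2.0 <= hi
        assert fit.converged

    def test_delta_recovery_within_2se(self):
        sc, data = _paper_like_setup(seed=21)
        fit = fit_model(
            data, PriorSpec(), sc.constants(), sc.weights, sc.effects,
            n_restarts=2, seed=1,
        )
        assert abs(fit.params.delta - 0.5) < max(2 * fit.se["delta"], 0.45)

    def test_too_few_years_rejected(self):
        sc, data = _paper_like_setup(seed=2)
        short = DynamicsData(
            data.phenotypes.iloc[:5], data.allele_counts, data.flow
        )
        with pytest.raises(ValueError, match="10 observed years"):
            fit_model(short, PriorSpec(), sc.constants(), sc.weights, sc.effects)


class TestVarianceExplained:
    def test_sums_to_100(self):
        sc, data = _paper_like_setup(seed=5)
        fit = fit_model(
            data, PriorSpec(), sc.constants(), sc.weights, sc.effects,
            n_restarts=1, seed=0,
        )
        ve = variance_explained(fit, data)
        total = ve["explained_pct"] + ve["measurement_pct"] + ve["residual_pct"]
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_perfect_model_limit(self):
        sc, data = _paper_like_setup(seed=6)

        class FakeFit:
            params = sc.params

        FakeFit.params.sigma_e2 = 0.0
        noiseless = data.phenotypes.copy()
        noiseless["se_ln_mass"] = 0.0
        ve = variance_explained(FakeFit, DynamicsData(noiseless, None, data.flow))
        assert ve["explained_pct"] == pytest.approx(100.0)
        assert ve["measurement_pct"] == 0.0 and ve["residual_pct"] == 0.0

    def test_pure_noise_explains_nothing(self):
        rng = np.random.default_rng(7)
        sc = SimScenario(seed=7, flow_schedule=(), params=sc_params_noise())
        flow = simulate_flow(sc)
        traj = simulate_trajectory(sc, flow)
        pheno, ac = sample_observations(traj, sc, rng, genotyped=())
        data = DynamicsData(pheno, ac, flow)
        fit = fit_model(
            data, PriorSpec(), sc.constants(), sc.weights, sc.effects,
            n_restarts=1, seed=0,
        )
        ve = variance_explained(fit, data)
        assert abs(ve["explained_pct"]) < 25.0

    def test_too_few_years(self):
        sc, data = _paper_like_setup(seed=8)

        class FakeFit:
            params = sc.params

        with pytest.raises(ValueError):
            variance_explained(
                FakeFit, DynamicsData(data.phenotypes.iloc[:2], None, data.flow)
            )


def sc_params_noise():
    """Flat-truth parameters: no optimum shift, no selection."""
    return AdaptiveParams(
        q=-30.0, theta_ref=9.26, b=0.0, delta=0.5, h2=0.5, sigma_e2=0.04,
        z_init=np.full(8, 9.26), p_init=np.array([0.73, 0.95]),
    )


def test_wald_type_one_error_for_b():
    """Without selection or optimum movement, the b = 0 Wald interval
    should cover zero at roughly its nominal rate."""
    n_seeds = 100
    cover = 0
    for seed in range(n_seeds):
        sc = SimScenario(seed=seed, params=sc_params_noise())
        flow = simulate_flow(sc)
        traj = simulate_trajectory(sc, flow)
        pheno, ac = sample_observations(traj, sc, np.random.default_rng(seed))
        data = DynamicsData(pheno, ac, flow)
        fit = fit_model(
            data, PriorSpec(), sc.constants(), sc.weights, sc.effects,
            n_restarts=1, seed=seed,
        )
        lo, hi = fit.wald_interval("b")
        cover += lo <= 0.0 <= hi
    assert cover >= int(0.85 * n_seeds)


def test_age_weights_validation():
    with pytest.raises(ValueError):
        AgeWeights(weights=(0.5, 0.5, 0.2, 0.0, 0.0))
    w = AgeWeights(shift=2)
    assert w.effective_lags == (6, 7, 8, 9, 10)
    assert w.max_lag == 10
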