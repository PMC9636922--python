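"""Moving-optimum state-space model of trait and allele-frequency dynamics.

The trait is mean ln body mass (ln grams) of returning adults.  Each year,
quadratic stabilizing selection acts around an optimum that tracks the log
of the June--September waterflow.  The additive genetic variance is
decomposed into two focal large-effect loci (with sex-specific additive and
dominance effects, bias-corrected for estimation error in those effects)
plus a constant small-effect component.  Generations overlap: the cohort
returning in year t is a fixed-weight mixture of egg years t-k.

Throughout, the tracked allele at a focal locus is the one whose homozygote
carries genotypic value +a (the "large" allele); frequencies here refer to
that allele.

Fitting is penalized maximum likelihood: Gaussian penalties on a subset of
parameters are added to the negative log likelihood of the observed annual
trait means and of binomial allele counts at genotyped years.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

__all__ = [
    "AgeWeights",
    "LocusEffects",
    "AdaptiveParams",
    "PriorSpec",
    "ModelConstants",
    "DynamicsData",
    "AdaptiveFit",
    "va_locus",
    "va_small",
    "optimum",
    "selection_gradient",
    "delta_p",
    "forward_recursion",
    "neg_log_posterior",
    "neg_log_posterior_gradient",
    "fit_model",
    "variance_explained",
    "evolvability",
    "genetic_load",
]

log = logging.getLogger(__name__)

_P_EPS = 1e-9

# Cov-term order used everywhere a flat error-covariance vector appears:
# Var[aF], Var[dF], Cov[aF,dF], Var[aM], Var[dM], Cov[aM,dM],
# Cov[aF,aM], Cov[aF,dM], Cov[dF,aM], Cov[dF,dM]
_N_COV_TERMS = 10


def _maybe_njit(func):
    try:  # pragma: no cover - exercised implicitly
        from numba import njit

        return njit(cache=False, fastmath=False)(func)
    except Exception:  # pragma: no cover
        return func


@dataclass(frozen=True)
class AgeWeights:
    """Cohort (egg-year) weights for returning adults.

    ``weights[j]`` is the proportion of returners that were eggs
    ``lags[j]`` years earlier.  ``shift`` adds a constant to every lag.
    """

    lags: tuple[int, ...] = (4, 5, 6, 7, 8)
    weights: tuple[float, ...] = (0.114, 0.336, 0.308, 0.181, 0.061)
    shift: int = 0

    def __post_init__(self) -> None:
        if len(self.lags) != len(self.weights):
            raise ValueError("lags and weights differ in length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if not math.isclose(sum(self.weights), 1.0, abs_tol=1e-12):
            raise ValueError("weights must sum to 1")

    @property
    def effective_lags(self) -> tuple[int, ...]:
        return tuple(k + self.shift for k in self.lags)

    @property
    def max_lag(self) -> int:
        return max(self.effective_lags)


@dataclass(frozen=True)
class LocusEffects:
    """Sex-specific additive/dominance effects of one locus on ln mass.

    ``cov`` is the 4x4 error covariance of (a_f, d_f, a_m, d_m); it feeds
    the bias corrections of the genetic-variance formulas.  Loci without an
    estimated dominance effect carry d = 0 with zero covariance rows.
    """

    a_f: float
    d_f: float
    a_m: float
    d_m: float
    cov: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (4, 4):
            raise ValueError("cov must be 4x4 ordered (a_f, d_f, a_m, d_m)")
        if not np.allclose(c, c.T):
            raise ValueError("cov must be symmetric")
        if np.linalg.eigvalsh(c).min() < -1e-10:
            raise ValueError("cov must be positive semi-definite")
        object.__setattr__(self, "cov", c)

    def cov_terms(self) -> np.ndarray:
        c = self.cov
        return np.array(
            [
                c[0, 0], c[1, 1], c[0, 1],
                c[2, 2], c[3, 3], c[2, 3],
                c[0, 2], c[0, 3], c[1, 2], c[1, 3],
            ]
        )


@dataclass
class AdaptiveParams:
    """Free parameters of the dynamics model (natural scales)."""

    q: float  # log selection strength
    theta_ref: float  # optimum in the reference year, ln g
    b: float  # slope of the optimum on ln flow
    delta: float  # fraction of selection before observation, in (0,1)
    h2: float  # heritability, in (0,1)
    sigma_e2: float  # residual variance of annual means
    z_init: np.ndarray  # pre-start cohort trait means, oldest first
    p_init: np.ndarray  # pre-start tracked-allele frequency per focal locus

    def __post_init__(self) -> None:
        self.z_init = np.asarray(self.z_init, dtype=float)
        self.p_init = np.asarray(self.p_init, dtype=float)
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must lie in (0,1)")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0,1)")
        if self.sigma_e2 < 0:
            raise ValueError("sigma_e2 must be non-negative")


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian penalty terms (mean, sd) on the stated scales."""

    z_init: tuple[float, float] = (9.26, 0.14)
    q: tuple[float, float] = (-2.0, 1.0)
    logit_h2: tuple[float, float] = (0.0, 1.0)
    logit_p: tuple[tuple[float, float], ...] = ((0.99, 0.20), (2.94, 0.80))

    def __post_init__(self) -> None:
        sds = [self.z_init[1], self.q[1], self.logit_h2[1]] + [
            s for _, s in self.logit_p
        ]
        if any(s <= 0 for s in sds):
            raise ValueError("prior SDs must be positive")


@dataclass(frozen=True)
class ModelConstants:
    """Quantities held fixed during fitting."""

    vp: float = 0.31  # within-year phenotypic variance, (ln g)^2
    ref_year: int = 1940

    def __post_init__(self) -> None:
        if self.vp <= 0:
            raise ValueError("vp must be positive")


# ---------------------------------------------------------------------------
# scalar kernels (numba-compiled when available; plain Python otherwise)


def _va_kernel(p, a_f, d_f, a_m, d_m, ct):
    """Return (va_f, va_m, ca_fm) for one locus at frequency p.

    ct is the flat error-covariance vector in the module-level order.
    """
    w = 1.0 - 2.0 * p
    h = 2.0 * p * (1.0 - p)
    alpha_f = a_f + d_f * w
    alpha_m = a_m + d_m * w
    va_f = h * alpha_f * alpha_f - h * (ct[0] + w * w * ct[1] + 2.0 * w * ct[2])
    va_m = h * alpha_m * alpha_m - h * (ct[3] + w * w * ct[4] + 2.0 * w * ct[5])
    ca = h * alpha_f * alpha_m - h * (ct[6] + w * ct[7] + w * ct[8] + w * w * ct[9])
    return va_f, va_m, ca


def _delta_p_kernel(p, beta, a_f, d_f, a_m, d_m, va_f, va_m, ca):
    w = 1.0 - 2.0 * p
    den_f = a_f + d_f * w
    den_m = a_m + d_m * w
    out = 0.0
    # a locus with no effect in a sex contributes no response through it
    if abs(den_f) > 1e-12:
        out += (va_f + ca) * beta / (8.0 * den_f)
    if abs(den_m) > 1e-12:
        out += (va_m + ca) * beta / (8.0 * den_m)
    return out


def _forward_kernel(
    n_years,
    n_pre,
    lags,
    wts,
    ln_flow,
    q,
    theta_ref,
    b,
    va_sm,
    z_pre,
    p_pre,
    eff,  # (n_loci, 4): a_f, d_f, a_m, d_m
    covt,  # (n_loci, 10)
    vp,
):
    n_loci = eff.shape[0]
    n_tot = n_pre + n_years
    zbar = np.empty(n_tot)
    resp = np.zeros(n_tot)  # V_A(t) * beta_t
    p = np.empty((n_loci, n_tot))
    dp = np.zeros((n_loci, n_tot))
    theta = np.empty(n_years)
    beta = np.empty(n_years)
    va_loc = np.empty((n_loci, n_years))
    va_tot = np.empty(n_years)
    clipped = 0

    for j in range(n_pre):
        zbar[j] = z_pre[j]
        for i in range(n_loci):
            p[i, j] = p_pre[i]

    x0 = ln_flow[0]
    for t in range(n_years):
        idx = n_pre + t
        z = 0.0
        for j in range(len(lags)):
            k = idx - lags[j]
            z += wts[j] * (zbar[k] + resp[k])
        zbar[idx] = z
        for i in range(n_loci):
            pv = 0.0
            for j in range(len(lags)):
                k = idx - lags[j]
                pv += wts[j] * (p[i, k] + dp[i, k])
            if pv < _P_EPS:
                pv = _P_EPS
                clipped += 1
            elif pv > 1.0 - _P_EPS:
                pv = 1.0 - _P_EPS
                clipped += 1
            p[i, idx] = pv

        th = theta_ref + b * (ln_flow[t] - x0)
        be = -math.exp(q) * (z - th)
        theta[t] = th
        beta[t] = be

        vt = va_sm
        for i in range(n_loci):
            va_f, va_m, ca = _va_kernel(
                p[i, idx], eff[i, 0], eff[i, 1], eff[i, 2], eff[i, 3], covt[i]
            )
            vai = 0.25 * (va_f + va_m + 2.0 * ca)
            if vai < 0.0:
                vai = 0.0
            va_loc[i, t] = vai
            vt += vai
            dp[i, idx] = _delta_p_kernel(
                p[i, idx], be, eff[i, 0], eff[i, 1], eff[i, 2], eff[i, 3],
                va_f, va_m, ca,
            )
        va_tot[t] = vt
        resp[idx] = vt * be

    return zbar[n_pre:], theta, beta, va_loc, va_tot, p[:, n_pre:], dp[:, n_pre:], clipped


_va_kernel = _maybe_njit(_va_kernel)
_delta_p_kernel = _maybe_njit(_delta_p_kernel)
_forward_kernel = _maybe_njit(_forward_kernel)


# ---------------------------------------------------------------------------
# public operations


def va_locus(p: float, effects: LocusEffects) -> dict:
    """Additive-variance contribution of one locus at frequency ``p``.

    Returns the female and male variance terms, their cross-sex covariance
    term, and the combined contribution (va_f + va_m + 2 ca_fm) / 4, each
    bias-corrected for estimation error in the effects.  The combined value
    is clamped at zero (the corrections can push it negative).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    va_f, va_m, ca = _va_kernel(
        float(p), effects.a_f, effects.d_f, effects.a_m, effects.d_m,
        effects.cov_terms(),
    )
    combined = 0.25 * (va_f + va_m + 2.0 * ca)
    if combined < 0.0:
        log.warning("bias-corrected locus variance negative (%.3g); clamped to 0", combined)
        combined = 0.0
    return {"va_f": va_f, "va_m": va_m, "ca_fm": ca, "combined": combined}


def va_small(
    h2: float, vp: float, va_focal_init: Sequence[float]
) -> float:
    """Small-effect additive variance: h2*VP minus the initial focal-locus
    variances, clamped at zero with a warning."""
    if h2 < 0 or vp < 0 or any(v < 0 for v in va_focal_init):
        raise ValueError("inputs must be non-negative")
    raw = h2 * vp - float(np.sum(va_focal_init))
    if raw < 0:
        log.warning("small-effect variance negative (%.4g); clamped to 0", raw)
        return 0.0
    return raw


def optimum(ln_flow_t: float, theta_ref: float, b: float, ln_flow_ref: float) -> float:
    """Optimum trait value: theta_ref + b * (ln flow_t - ln flow_ref)."""
    return theta_ref + b * (ln_flow_t - ln_flow_ref)


def selection_gradient(zbar: float, theta: float, q: float, vp: float | None = None):
    """Selection gradient beta = -exp(q)(zbar - theta); with ``vp`` also
    returns the selection differential s = VP * beta."""
    beta = -math.exp(q) * (zbar - theta)
    if vp is None:
        return beta
    return beta, vp * beta


def delta_p(p: float, effects: LocusEffects, beta: float) -> float:
    """Per-generation allele-frequency change from the sex-specific
    weak-selection approximation."""
    w = 1.0 - 2.0 * p
    for sex, den in (("F", effects.a_f + effects.d_f * w), ("M", effects.a_m + effects.d_m * w)):
        if abs(den) < 1e-12:
            raise ZeroDivisionError(
                f"degenerate effect configuration: a + d(1-2p) vanishes for sex {sex}"
            )
    va_f, va_m, ca = _va_kernel(
        float(p), effects.a_f, effects.d_f, effects.a_m, effects.d_m,
        effects.cov_terms(),
    )
    return _delta_p_kernel(
        float(p), float(beta), effects.a_f, effects.d_f, effects.a_m, effects.d_m,
        va_f, va_m, ca,
    )


def evolvability(va) -> np.ndarray | float:
    """Percent expected trait change under unit selection: 100 (e^Va - 1)."""
    return 100.0 * np.expm1(va)


def genetic_load(zbar, theta, q: float, vp: float):
    """Relative fitness loss of N(zbar, VP) under Gaussian stabilizing
    selection W(z) = exp(-exp(q)(z-theta)^2/2), relative to W(theta)."""
    g = math.exp(q)
    zbar = np.asarray(zbar, dtype=float)
    theta = np.asarray(theta, dtype=float)
    load = 1.0 - (1.0 + g * vp) ** -0.5 * np.exp(
        -g * (zbar - theta) ** 2 / (2.0 * (1.0 + g * vp))
    )
    return load if load.ndim else float(load)


def _stack_effects(effects: Sequence[LocusEffects]):
    eff = np.array([[e.a_f, e.d_f, e.a_m, e.d_m] for e in effects], dtype=float)
    covt = np.array([e.cov_terms() for e in effects], dtype=float)
    return eff, covt


def forward_recursion(
    params: AdaptiveParams,
    constants: ModelConstants,
    weights: AgeWeights,
    effects: Mapping[str, LocusEffects],
    flow,
) -> pd.DataFrame:
    """Deterministic trajectory from the start year through the end of the
    flow series.

    Pre-start cohort years use the ``z_init``/``p_init`` parameters with no
    selection response (no flow covariate exists there).  Returns one row
    per model year with the trait mean before selection, the optimum,
    selection gradient and differential, per-locus and total additive
    variance, allele frequencies and their selection responses,
    evolvability, and genetic load.
    """
    locus_names = list(effects)
    eff, covt = _stack_effects([effects[k] for k in locus_names])
    flow_s = flow.flow if hasattr(flow, "flow") else pd.Series(flow)
    years = flow_s.index.to_numpy()
    if years[0] > constants.ref_year:
        raise ValueError("flow series must start at or before the reference year")
    sel = years >= constants.ref_year
    years = years[sel]
    ln_flow = np.log(flow_s.to_numpy(dtype=float)[sel])

    n_pre = weights.max_lag
    z_pre = np.asarray(params.z_init, dtype=float)
    if len(z_pre) < n_pre:  # pad the oldest value when the lags are shifted
        z_pre = np.concatenate([np.full(n_pre - len(z_pre), z_pre[0]), z_pre])
    z_pre = z_pre[-n_pre:]

    va_init = [
        va_locus(params.p_init[i], effects[locus_names[i]])["combined"]
        for i in range(len(locus_names))
    ]
    va_sm = va_small(params.h2, constants.vp, va_init)

    zbar, theta, beta, va_loc, va_tot, p, dp, clipped = _forward_kernel(
        len(years),
        n_pre,
        np.asarray(weights.effective_lags, dtype=np.int64),
        np.asarray(weights.weights, dtype=float),
        ln_flow,
        params.q,
        params.theta_ref,
        params.b,
        va_sm,
        z_pre,
        np.asarray(params.p_init, dtype=float),
        eff,
        covt,
        constants.vp,
    )
    if clipped:
        log.warning("allele frequency clipped to [eps, 1-eps] %d times", clipped)

    out = pd.DataFrame(
        {
            "year": years,
            "zbar": zbar,
            "theta": theta,
            "beta": beta,
            "s": constants.vp * beta,
            "va_small": va_sm,
            "va_total": va_tot,
            "evolvability_pct": evolvability(va_tot),
            "load": genetic_load(zbar, theta, params.q, constants.vp),
        }
    ).set_index("year")
    for i, name in enumerate(locus_names):
        out[f"va_{name}"] = va_loc[i]
        out[f"p_{name}"] = p[i]
        out[f"dp_{name}"] = dp[i]
    return out


# ---------------------------------------------------------------------------
# observation model and fitting


@dataclass
class DynamicsData:
    """Aligned observations for the fit.

    ``phenotypes`` indexes year with columns mean_ln_mass and se_ln_mass
    (NaN rows are treated as missing).  ``allele_counts`` is a DataFrame
    with columns locus, year, A, T giving counts of the tracked (large)
    allele at genotyped years inside the modeled period.  ``flow`` covers
    the reference year through the last modeled year.
    """

    phenotypes: pd.DataFrame
    allele_counts: pd.DataFrame
    flow: "FlowSeries"


def _pack(params: AdaptiveParams) -> np.ndarray:
    return np.concatenate(
        [
            [
                params.q,
                params.theta_ref,
                params.b,
                logit(params.delta),
                logit(params.h2),
                0.5 * math.log(max(params.sigma_e2, 1e-12)),
            ],
            params.z_init,
            logit(np.clip(params.p_init, 1e-12, 1 - 1e-12)),
        ]
    )


def _unpack(x: np.ndarray, n_init: int, n_loci: int) -> AdaptiveParams:
    tiny = 1e-12  # keep logit-scale parameters inside the open interval
    return AdaptiveParams(
        q=float(x[0]),
        theta_ref=float(x[1]),
        b=float(x[2]),
        delta=float(np.clip(expit(x[3]), tiny, 1 - tiny)),
        h2=float(np.clip(expit(x[4]), tiny, 1 - tiny)),
        sigma_e2=float(math.exp(2.0 * x[5])),
        z_init=x[6 : 6 + n_init].copy(),
        p_init=expit(x[6 + n_init : 6 + n_init + n_loci]),
    )


def _objective_factory(data, priors, constants, weights, effects, n_init, n_loci):
    """Compile the penalized negative log likelihood into a fast function
    of the packed parameter vector (all pandas lookups done once here)."""
    locus_names = list(effects)
    eff, covt = _stack_effects([effects[k] for k in locus_names])
    flow_s = data.flow.flow
    years_all = flow_s.index.to_numpy()
    sel = years_all >= constants.ref_year
    model_years = years_all[sel]
    ln_flow = np.log(flow_s.to_numpy(dtype=float)[sel])
    year_pos = {int(y): i for i, y in enumerate(model_years)}

    ph = data.phenotypes.dropna(subset=["mean_ln_mass"])
    ph = ph[ph.index.isin(year_pos)]
    ph_idx = np.array([year_pos[int(y)] for y in ph.index], dtype=np.int64)
    zobs = ph["mean_ln_mass"].to_numpy(dtype=float)
    se2 = ph["se_ln_mass"].fillna(0.0).to_numpy(dtype=float) ** 2

    ac = data.allele_counts
    ac_loc = np.array(
        [locus_names.index(l) for l in ac["locus"]], dtype=np.int64
    ) if len(ac) else np.empty(0, dtype=np.int64)
    ac_idx = np.array(
        [year_pos[int(y)] for y in ac["year"]], dtype=np.int64
    ) if len(ac) else np.empty(0, dtype=np.int64)
    ac_a = ac["A"].to_numpy(dtype=float) if len(ac) else np.empty(0)
    ac_t = ac["T"].to_numpy(dtype=float) if len(ac) else np.empty(0)
    # binomial coefficient (constant in the parameters)
    binom_const = float(
        np.sum(gammaln(ac_t + 1) - gammaln(ac_a + 1) - gammaln(ac_t - ac_a + 1))
    )

    lags = np.asarray(weights.effective_lags, dtype=np.int64)
    wts = np.asarray(weights.weights, dtype=float)
    n_pre = int(lags.max())
    vp = constants.vp
    n_years = len(model_years)

    pz_m, pz_s = priors.z_init
    pq_m, pq_s = priors.q
    ph2_m, ph2_s = priors.logit_h2
    pp = priors.logit_p

    def fun(x: np.ndarray) -> float:
        q = x[0]
        theta_ref = x[1]
        b = x[2]
        delta = expit(x[3])
        h2 = expit(x[4])
        sigma_e2 = math.exp(2.0 * x[5])
        z_init = x[6 : 6 + n_init]
        lp = x[6 + n_init : 6 + n_init + n_loci]
        p_init = expit(lp)

        z_pre = z_init
        if n_init < n_pre:
            z_pre = np.concatenate([np.full(n_pre - n_init, z_init[0]), z_init])
        z_pre = z_pre[-n_pre:]

        va_init = 0.0
        for i in range(n_loci):
            vf, vm, ca = _va_kernel(
                p_init[i], eff[i, 0], eff[i, 1], eff[i, 2], eff[i, 3], covt[i]
            )
            va_init += max(0.25 * (vf + vm + 2.0 * ca), 0.0)
        va_sm = max(h2 * vp - va_init, 0.0)

        try:
            zbar, theta, beta, _, _, p, dp, _ = _forward_kernel(
                n_years, n_pre, lags, wts, ln_flow,
                q, theta_ref, b, va_sm, z_pre, p_init, eff, covt, vp,
            )
        except (ZeroDivisionError, OverflowError):
            return 1e12

        pred = zbar[ph_idx] + delta * vp * beta[ph_idx]
        var = sigma_e2 + se2
        nll = 0.5 * np.sum(np.log(2.0 * np.pi * var) + (zobs - pred) ** 2 / var)

        if len(ac_a):
            pr = p[ac_loc, ac_idx] + delta * dp[ac_loc, ac_idx]
            pr = np.clip(pr, _P_EPS, 1.0 - _P_EPS)
            nll -= binom_const + np.sum(
                ac_a * np.log(pr) + (ac_t - ac_a) * np.log1p(-pr)
            )

        nll += 0.5 * np.sum(((z_init - pz_m) / pz_s) ** 2)
        nll += 0.5 * ((q - pq_m) / pq_s) ** 2
        nll += 0.5 * ((x[4] - ph2_m) / ph2_s) ** 2
        for i in range(n_loci):
            if i < len(pp):
                m, s = pp[i]
                nll += 0.5 * ((lp[i] - m) / s) ** 2
        return float(nll) if np.isfinite(nll) else 1e12

    return fun


def neg_log_posterior(
    params: AdaptiveParams,
    data: DynamicsData,
    priors: PriorSpec,
    constants: ModelConstants,
    weights: AgeWeights,
    effects: Mapping[str, LocusEffects],
) -> float:
    """Penalized negative log likelihood of the observed annual trait means
    and allele counts under the deterministic trajectory implied by
    ``params``.

    Observed means contribute Gaussian terms with variance sigma_e^2 +
    SE_t^2 around zbar_t + delta * s_t; allele counts of the tracked large
    allele contribute binomial terms with success probability p + delta*dp
    (clamped away from 0/1); priors contribute Gaussian penalties.  Years
    without observations contribute nothing.
    """
    fun = _objective_factory(
        data, priors, constants, weights, effects,
        len(params.z_init), len(params.p_init),
    )
    return fun(_pack(params))


def _fd_gradient(fun, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    f_args = x.copy()
    for i in range(len(x)):
        h = rel_step * max(1.0, abs(x[i]))
        f_args[i] = x[i] + h
        fp = fun(f_args)
        f_args[i] = x[i] - h
        fm = fun(f_args)
        f_args[i] = x[i]
        g[i] = (fp - fm) / (2.0 * h)
    return g


def neg_log_posterior_gradient(
    params: AdaptiveParams,
    data: DynamicsData,
    priors: PriorSpec,
    constants: ModelConstants,
    weights: AgeWeights,
    effects: Mapping[str, LocusEffects],
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Central-difference gradient of the objective in the packed
    (internal-scale) parameterization."""
    n_init, n_loci = len(params.z_init), len(params.p_init)
    fun = _objective_factory(data, priors, constants, weights, effects, n_init, n_loci)
    return _fd_gradient(fun, _pack(params), rel_step)


def _fd_hessian(fun, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((n, n))
    f0 = fun(x)
    fp = np.empty(n)
    fm = np.empty(n)
    for i in range(n):
        xi = x.copy()
        xi[i] = x[i] + h[i]
        fp[i] = fun(xi)
        xi[i] = x[i] - h[i]
        fm[i] = fun(xi)
    for i in range(n):
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
        for j in range(i + 1, n):
            xij = x.copy()
            xij[i] += h[i]
            xij[j] += h[j]
            fpp = fun(xij)
            xij = x.copy()
            xij[i] -= h[i]
            xij[j] -= h[j]
            fmm = fun(xij)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h[i] * h[j])
    return hess


@dataclass
class AdaptiveFit:
    """Result of :func:`fit_model`."""

    params: AdaptiveParams
    se: dict
    cov_internal: np.ndarray
    x_internal: np.ndarray
    nll: float
    trajectory: pd.DataFrame
    n_obs: int
    converged: bool
    restarts: list

    def wald_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        idx = {"q": 0, "theta_ref": 1, "b": 2}[name]
        z = norm.ppf(0.5 + level / 2.0)
        est = self.x_internal[idx]
        sd = math.sqrt(max(self.cov_internal[idx, idx], 0.0))
        return est - z * sd, est + z * sd


def fit_model(
    data: DynamicsData,
    priors: PriorSpec,
    constants: ModelConstants,
    weights: AgeWeights,
    effects: Mapping[str, LocusEffects],
    start: AdaptiveParams | None = None,
    n_restarts: int = 10,
    seed: int | None = None,
    gtol: float = 1e-6,
    jitter_sd: float = 0.3,
) -> AdaptiveFit:
    """Minimize the penalized negative log likelihood by quasi-Newton from
    jittered starts; standard errors come from the finite-difference
    Hessian at the optimum (delta method for natural-scale parameters)."""
    n_obs = int(data.phenotypes["mean_ln_mass"].notna().sum())
    if n_obs < 10:
        raise ValueError("need at least 10 observed years to fit")
    n_init = 8  # pre-start cohort years carried as free parameters
    locus_names = list(effects)
    n_loci = len(locus_names)
    if start is None:
        start = AdaptiveParams(
            q=priors.q[0],
            theta_ref=priors.z_init[0],
            b=1.0,
            delta=0.5,
            h2=float(expit(priors.logit_h2[0])),
            sigma_e2=0.01,
            z_init=np.full(n_init, priors.z_init[0]),
            p_init=expit(np.array([m for m, _ in priors.logit_p[:n_loci]])),
        )
    x0 = _pack(start)
    fun = _objective_factory(
        data, priors, constants, weights, effects, len(start.z_init), n_loci
    )
    rng = np.random.default_rng(seed)
    results = []
    for r in range(max(1, n_restarts)):
        xs = x0 if r == 0 else x0 + rng.normal(0.0, jitter_sd, size=x0.shape)
        res = minimize(
            fun,
            xs,
            method="BFGS",
            jac=lambda x: _fd_gradient(fun, x),
            options={"gtol": gtol, "maxiter": 500},
        )
        results.append(res)
    finite = [r for r in results if np.isfinite(r.fun)]
    if not finite:
        raise RuntimeError(
            "all restarts failed: " + "; ".join(str(r.message) for r in results)
        )
    best = min(finite, key=lambda r: r.fun)
    converged = bool(best.success or np.linalg.norm(best.jac, np.inf) < 1e-3)
    if not converged:
        log.warning("optimizer did not formally converge: %s", best.message)

    hess = _fd_hessian(fun, best.x)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    params = _unpack(best.x, len(start.z_init), n_loci)
    diag = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    # delta-method SEs for the natural-scale transforms
    se = {
        "q": diag[0],
        "theta_ref": diag[1],
        "b": diag[2],
        "delta": diag[3] * params.delta * (1 - params.delta),
        "h2": diag[4] * params.h2 * (1 - params.h2),
        "sigma_e2": diag[5] * 2.0 * params.sigma_e2,
    }
    traj = forward_recursion(params, constants, weights, effects, data.flow)
    return AdaptiveFit(
        params=params,
        se=se,
        cov_internal=cov,
        x_internal=best.x,
        nll=float(best.fun),
        trajectory=traj,
        n_obs=n_obs,
        converged=converged,
        restarts=[(float(r.fun), bool(r.success)) for r in results],
    )


def variance_explained(fit: AdaptiveFit, data: DynamicsData) -> dict:
    """Partition the variance of the observed annual means into
    model-explained, measurement, and residual percentages (sums to 100)."""
    ph = data.phenotypes.dropna(subset=["mean_ln_mass"])
    if len(ph) < 3:
        raise ValueError("need at least 3 observed years")
    var_obs = float(np.var(ph["mean_ln_mass"].to_numpy(), ddof=1))
    meas = float(np.mean(ph["se_ln_mass"].fillna(0.0).to_numpy() ** 2)) / var_obs * 100.0
    resid = fit.params.sigma_e2 / var_obs * 100.0
    return {
        "explained_pct": 100.0 - meas - resid,
        "measurement_pct": meas,
        "residual_pct": resid,
    }
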