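"""Temporal drift-null test for allele-frequency change.

The drift intensity zeta = g / (2 Ne) for each pair of consecutive sampling
periods is estimated from a panel of neutral biallelic loci.  Observed
allele counts are binomial draws around latent frequencies; latent
frequencies evolve between periods by a normal approximation to
Wright--Fisher drift, truncated (and renormalized) to [0, 1]:

    x_t | x_{t-1} ~ N(x_{t-1}, x_{t-1} (1 - x_{t-1}) zeta_t)  on [0, 1]

Initial frequencies get flat Beta(1, 1) priors and zeta_t a uniform prior.
Sampling is Metropolis-within-Gibbs: random-walk updates of the latent
frequencies (vectorized across loci) and of log zeta, with proposal scales
adapted during burn-in only.

Focal-locus frequencies are estimated separately with closed-form
Beta(1 + A, 1 + T - A) posteriors; drift envelopes and drift probabilities
are computed from the truncated-normal transition law.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import beta as beta_dist

from .io_datamodel import NEUTRAL, AlleleCountTable, GenotypePanel

__all__ = [
    "DriftConfig",
    "DriftPosterior",
    "FocalPosterior",
    "fit_drift_model",
    "focal_posterior",
    "drift_envelope",
    "drift_probability",
    "gelman_rubin",
    "wc_fst",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DriftConfig:
    """MCMC settings.  Defaults are desk-scale; ``full()`` restores the
    long-run settings (770k iterations, 370k burn-in, thin 40)."""

    n_chains: int = 2
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    zeta_bounds: tuple[float, float] = (1e-4, 1.0)
    seed: int | None = None
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        lo, hi = self.zeta_bounds
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("zeta bounds must satisfy 0 < lower < upper <= 1")

    @classmethod
    def full(cls, **kw) -> "DriftConfig":
        return cls(n_iter=770_000, burn_in=370_000, thin=40, **kw)


@dataclass
class DriftPosterior:
    """Posterior draws and diagnostics from :func:`fit_drift_model`.

    ``zeta`` has shape (n_chains, n_draws, n_intervals); ``x`` has shape
    (n_chains, n_draws, n_loci, n_periods).
    """

    zeta: np.ndarray
    x: np.ndarray
    loci: list
    periods: list
    rhat: dict = field(default_factory=dict)
    converged: bool = True

    def zeta_draws(self, interval: int = 0) -> np.ndarray:
        return self.zeta[:, :, interval].reshape(-1)

    def zeta_summary(self, interval: int = 0) -> dict:
        d = self.zeta_draws(interval)
        lo, med, hi = np.quantile(d, [0.025, 0.5, 0.975])
        return {"median": float(med), "ci_low": float(lo), "ci_high": float(hi)}


def _trunc_norm_logpdf(x, mu, var):
    """Log density of N(mu, var) renormalized to [0, 1]."""
    sd = np.sqrt(var)
    z = ndtr((1.0 - mu) / sd) - ndtr(-mu / sd)
    return -0.5 * np.log(2.0 * np.pi * var) - (x - mu) ** 2 / (2.0 * var) - np.log(z)


def _binom_loglik(a, t, x):
    return a * np.log(x) + (t - a) * np.log1p(-x)


def fit_drift_model(
    counts: AlleleCountTable, config: DriftConfig = DriftConfig()
) -> DriftPosterior:
    """Joint posterior of drift intensities and latent neutral frequencies.

    ``counts`` should be restricted to neutral loci.  One zeta is shared by
    all loci per consecutive period pair.  Non-convergence (any R-hat above
    the threshold) flags the result instead of raising.
    """
    A, T, loci, periods = counts.matrix()
    L, P = A.shape
    if P < 2:
        raise ValueError("need at least two sampling periods")
    fixed = ((A == 0) | (A == T)).all(axis=1)
    if fixed.any():
        raise ValueError(
            f"{fixed.sum()} loci are fixed in every period; rerun count_alleles "
            "with drop_fixed=True"
        )
    poly = L - int(fixed.sum())
    if poly < 10:
        log.warning("only %d polymorphic loci; zeta will be poorly resolved", poly)

    lo, hi = config.zeta_bounds
    n_kept = (config.n_iter - config.burn_in) // config.thin
    zeta_out = np.empty((config.n_chains, n_kept, P - 1))
    x_out = np.empty((config.n_chains, n_kept, L, P))
    rng_master = np.random.default_rng(config.seed)

    obs = T > 0
    for chain in range(config.n_chains):
        rng = np.random.default_rng(rng_master.integers(2**63))
        x = np.where(obs, (A + 1.0) / (T + 2.0), 0.5)
        x = np.clip(x, 0.02, 0.98)
        zeta = np.exp(rng.uniform(math.log(lo), math.log(math.sqrt(hi * lo)), P - 1))
        x_scale = np.full((L, P), 0.05)
        z_scale = np.full(P - 1, 0.5)
        x_acc = np.zeros((L, P))
        z_acc = np.zeros(P - 1)
        kept = 0
        for it in range(config.n_iter):
            # --- latent frequencies, one period column at a time -------------
            for t in range(P):
                prop = x[:, t] + rng.normal(0.0, x_scale[:, t])
                valid = (prop > 0.0) & (prop < 1.0)
                cur = np.where(obs[:, t], _binom_loglik(A[:, t], T[:, t], x[:, t]), 0.0)
                new = np.where(
                    obs[:, t] & valid,
                    _binom_loglik(A[:, t], T[:, t], np.where(valid, prop, 0.5)),
                    0.0,
                )
                if t > 0:
                    var = x[:, t - 1] * (1.0 - x[:, t - 1]) * zeta[t - 1]
                    cur += _trunc_norm_logpdf(x[:, t], x[:, t - 1], var)
                    new += np.where(
                        valid,
                        _trunc_norm_logpdf(np.where(valid, prop, 0.5), x[:, t - 1], var),
                        -np.inf,
                    )
                if t < P - 1:
                    var_cur = x[:, t] * (1.0 - x[:, t]) * zeta[t]
                    cur += _trunc_norm_logpdf(x[:, t + 1], x[:, t], var_cur)
                    safe = np.where(valid, prop, 0.5)
                    var_new = safe * (1.0 - safe) * zeta[t]
                    new += np.where(
                        valid,
                        _trunc_norm_logpdf(x[:, t + 1], safe, var_new),
                        -np.inf,
                    )
                accept = valid & (np.log(rng.uniform(size=L)) < new - cur)
                x[accept, t] = prop[accept]
                x_acc[:, t] += accept

            # --- zeta per interval, random walk on log scale ----------------
            for t in range(P - 1):
                prop = zeta[t] * math.exp(rng.normal(0.0, z_scale[t]))
                if lo <= prop <= hi:
                    var_cur = x[:, t] * (1.0 - x[:, t]) * zeta[t]
                    var_new = x[:, t] * (1.0 - x[:, t]) * prop
                    cur = _trunc_norm_logpdf(x[:, t + 1], x[:, t], var_cur).sum()
                    new = _trunc_norm_logpdf(x[:, t + 1], x[:, t], var_new).sum()
                    # log-scale walk: Jacobian term log(prop/zeta)
                    if math.log(rng.uniform()) < new - cur + math.log(prop / zeta[t]):
                        zeta[t] = prop
                        z_acc[t] += 1

            # --- adapt proposal scales during burn-in -----------------------
            if it < config.burn_in and (it + 1) % 100 == 0:
                frac = x_acc / 100.0
                x_scale *= np.exp(np.clip(frac - 0.3, -0.3, 0.3))
                x_scale = np.clip(x_scale, 1e-4, 0.5)
                zfrac = z_acc / 100.0
                z_scale *= np.exp(np.clip(zfrac - 0.3, -0.3, 0.3))
                z_scale = np.clip(z_scale, 0.01, 3.0)
                x_acc[:] = 0.0
                z_acc[:] = 0.0

            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                zeta_out[chain, kept] = zeta
                x_out[chain, kept] = x
                kept += 1

    rhat = {}
    converged = True
    if config.n_chains >= 2:
        for t in range(P - 1):
            r = gelman_rubin(zeta_out[:, :, t])
            rhat[f"zeta_{periods[t]}_{periods[t + 1]}"] = r
            converged &= r <= config.rhat_threshold
        x_r = np.array(
            [
                [gelman_rubin(x_out[:, :, l, t]) for t in range(P)]
                for l in range(L)
            ]
        )
        rhat["x_max"] = float(np.nanmax(x_r))
        converged &= rhat["x_max"] <= config.rhat_threshold
    if not converged:
        log.warning("drift MCMC flagged non-converged: %s", rhat)
    return DriftPosterior(zeta_out, x_out, loci, periods, rhat, converged)


@dataclass
class FocalPosterior:
    """Per-period Beta posteriors of a focal-locus frequency and the
    posteriors of consecutive-period changes."""

    locus: str
    periods: list
    freq_draws: np.ndarray  # (n_periods, n_draws)
    change_draws: np.ndarray  # (n_periods - 1, n_draws)

    def freq_summary(self, j: int) -> dict:
        lo, med, hi = np.quantile(self.freq_draws[j], [0.025, 0.5, 0.975])
        return {"median": float(med), "ci_low": float(lo), "ci_high": float(hi)}

    def change_summary(self, j: int = 0) -> dict:
        lo, med, hi = np.quantile(self.change_draws[j], [0.025, 0.5, 0.975])
        return {"median": float(med), "ci_low": float(lo), "ci_high": float(hi)}


def focal_posterior(
    counts: AlleleCountTable,
    n_draws: int = 20_000,
    seed: int | None = None,
) -> dict[str, FocalPosterior]:
    """Beta(1 + A, 1 + T - A) posterior per (focal locus, period), with
    consecutive-period change posteriors from independent draws.  Periods
    with T = 0 are skipped with a warning."""
    rng = np.random.default_rng(seed)
    out = {}
    A, T, loci, periods = counts.matrix()
    for i, locus in enumerate(loci):
        keep = [j for j in range(len(periods)) if T[i, j] > 0]
        skipped = [periods[j] for j in range(len(periods)) if T[i, j] == 0]
        if skipped:
            log.warning("locus %s: skipping periods with no data: %s", locus, skipped)
        draws = np.stack(
            [
                rng.beta(1.0 + A[i, j], 1.0 + T[i, j] - A[i, j], size=n_draws)
                for j in keep
            ]
        )
        changes = draws[1:] - draws[:-1] if len(keep) > 1 else np.empty((0, n_draws))
        out[locus] = FocalPosterior(locus, [periods[j] for j in keep], draws, changes)
    return out


def _abs_change_cdf(c, p0, sd):
    """P(|X - p0| <= c) for X ~ N(p0, sd^2) truncated to [0, 1]."""
    znorm = ndtr((1.0 - p0) / sd) - ndtr(-p0 / sd)
    upper = np.minimum(c, 1.0 - p0)
    lower = np.maximum(-c, -p0)
    return (ndtr(upper / sd) - ndtr(lower / sd)) / znorm


def drift_envelope(
    p0,
    zeta_draws: np.ndarray,
    quantile: float = 0.95,
) -> np.ndarray | float:
    """Posterior-mean ``quantile`` of |allele-frequency change| under pure
    drift from starting frequency ``p0`` (scalar or grid)."""
    p0_arr = np.atleast_1d(np.asarray(p0, dtype=float))
    if ((p0_arr <= 0) | (p0_arr >= 1)).any():
        raise ValueError("p0 must lie in (0, 1)")
    zeta_draws = np.atleast_1d(np.asarray(zeta_draws, dtype=float))
    if (zeta_draws == 0).all():
        res = np.zeros_like(p0_arr)
        return res if np.ndim(p0) else 0.0

    pp = p0_arr[:, None]
    sd = np.sqrt(pp * (1.0 - pp) * zeta_draws[None, :])
    lo = np.zeros_like(sd)
    hi = np.ones_like(sd)
    for _ in range(60):  # vectorized bisection for the quantile of |change|
        mid = 0.5 * (lo + hi)
        below = _abs_change_cdf(mid, pp, sd) < quantile
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    env = (0.5 * (lo + hi)).mean(axis=1)
    return env if np.ndim(p0) else float(env[0])


def drift_probability(
    change_draws: np.ndarray,
    p0_draws: np.ndarray,
    zeta_draws: np.ndarray,
    seed: int | None = None,
    monte_carlo: bool = False,
    mc_samples: int = 200,
) -> float:
    """Mean posterior probability that pure drift produces an absolute
    frequency change at least as large as the observed one.

    Draw vectors are resampled to a common length; for each joint draw
    (observed change, starting frequency, zeta) the tail probability
    P(|drift change| >= |observed change|) is evaluated under the
    truncated-normal transition (closed form by default, Monte Carlo when
    ``monte_carlo``)."""
    rng = np.random.default_rng(seed)
    n = max(len(change_draws), len(p0_draws), len(zeta_draws))

    def _resample(v):
        v = np.asarray(v, dtype=float)
        return v if len(v) == n else v[rng.integers(len(v), size=n)]

    d = np.abs(_resample(change_draws))
    p0 = np.clip(_resample(p0_draws), 1e-9, 1 - 1e-9)
    zeta = _resample(zeta_draws)
    sd = np.sqrt(p0 * (1.0 - p0) * zeta)
    if monte_carlo:
        from scipy.stats import truncnorm

        a, b = (0.0 - p0) / sd, (1.0 - p0) / sd
        sims = truncnorm.rvs(
            a, b, loc=p0, scale=sd, size=(mc_samples, n), random_state=rng
        )
        tail = (np.abs(sims - p0) >= d).mean(axis=0)
    else:
        tail = 1.0 - _abs_change_cdf(d, p0, sd)
    return float(tail.mean())


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_iter).  Classic (non-split) PSRF:
    sqrt(((n-1)/n W + B/n) / W)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b_over_n = means.var(ddof=1)
    if w == 0.0:
        return 1.0
    var_plus = (n - 1) / n * w + b_over_n
    # the (n-1)/n shrinkage can push the ratio below 1; PSRF is >= 1
    return float(max(np.sqrt(var_plus / w), 1.0))


def _wc_components(p1, n1, het1, p2, n2, het2):
    """Weir-Cockerham (1984) a, b, c variance components for one biallelic
    locus and two populations, from sample frequencies, sample sizes (in
    individuals), and heterozygote counts."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (het1 + het2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def wc_fst(panel_a: GenotypePanel, panel_b: GenotypePanel) -> float:
    """Multi-locus Weir-Cockerham theta between two panels (ratio of sums
    over shared polymorphic neutral loci)."""
    shared = [
        l
        for l in panel_a.loci_of_class(NEUTRAL)
        if l in set(panel_b.loci_of_class(NEUTRAL))
    ]
    num = den = 0.0
    used = 0
    for locus in shared:
        ca = panel_a.calls[locus].dropna()
        cb = panel_b.calls[locus].dropna()
        n1, n2 = len(ca), len(cb)
        if n1 < 2 or n2 < 2:
            continue
        a1, a2 = ca.sum(), cb.sum()
        t1, t2 = 2 * n1, 2 * n2
        if (a1 == 0 and a2 == 0) or (a1 == t1 and a2 == t2):
            continue  # monomorphic overall
        het1 = int((ca == 1).sum())
        het2 = int((cb == 1).sum())
        va, vb, vc = _wc_components(a1 / t1, n1, het1, a2 / t2, n2, het2)
        num += va
        den += va + vb + vc
        used += 1
    if used == 0:
        raise ValueError("no shared polymorphic neutral loci between panels")
    return float(num / den)
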