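"""Sex-specific genetic effects of the focal loci on ln body mass.

The effect model is ordinary least squares on individual ln mass with, per
focal locus and sex, an additive regressor coded -1/0/+1 on the genotypes
(the +1 homozygote carries two copies of the *large* allele, i.e. zero
copies of the tracked small allele) and, where estimated, a heterozygote
dominance indicator.  Genotype regressors are centered on their
within-year, within-sex means, and the catch period enters as a fixed
factor in interaction with sex.  Under this coding the homozygote mass
ratio is exp(2a).

Downstream consumers (the adaptive-dynamics model) take the estimated
effects together with their full error covariance, which feeds the
variance bias corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .adaptive_dynamics import LocusEffects
from .io_datamodel import CatchTable, GenotypePanel

__all__ = [
    "EffectModelFit",
    "fit_effect_model",
    "join_genotypes_catch",
    "genotype_mass_ratio",
    "hwe_mean",
    "predict_change_fraction",
    "stocking_comparison",
]

log = logging.getLogger(__name__)

SEXES = ("F", "M")


@dataclass
class EffectModelFit:
    """OLS fit of the sex-specific locus-effect model.

    ``params``/``cov`` cover the genetic-effect terms only, in the order of
    ``names`` (e.g. ``a_vgll3_F``, ``d_vgll3_F``, ...); period-by-sex
    factor estimates live in ``nuisance``.
    """

    names: list
    params: np.ndarray
    cov: np.ndarray
    n_used: int
    n_excluded: int
    nuisance: pd.Series
    loci: list
    dominance_loci: list

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def se(self, name: str) -> float:
        i = self.names.index(name)
        return float(np.sqrt(self.cov[i, i]))

    def locus_effects(self, locus: str) -> LocusEffects:
        """Package one locus's effects for the dynamics model, with its
        4x4 error covariance ordered (a_F, d_F, a_M, d_M)."""
        want = [f"a_{locus}_F", f"d_{locus}_F", f"a_{locus}_M", f"d_{locus}_M"]
        vals = np.zeros(4)
        cov = np.zeros((4, 4))
        idx = {n: self.names.index(n) for n in want if n in self.names}
        for i, n in enumerate(want):
            if n in idx:
                vals[i] = self.params[idx[n]]
        for i, ni in enumerate(want):
            for j, nj in enumerate(want):
                if ni in idx and nj in idx:
                    cov[i, j] = self.cov[idx[ni], idx[nj]]
        return LocusEffects(vals[0], vals[1], vals[2], vals[3], cov)


def join_genotypes_catch(panel: GenotypePanel, catch: CatchTable) -> pd.DataFrame:
    """Inner-join focal genotype calls to catch records on individual_id."""
    if "individual_id" not in catch.records.columns:
        raise ValueError("catch table lacks individual_id; cannot join")
    focal = panel.loci_of_class("focal")
    df = panel.calls[focal].join(panel.individuals[["sex", "origin", "period"]])
    merged = catch.records.merge(
        df, left_on="individual_id", right_index=True, suffixes=("", "_panel")
    )
    return merged


def _build_design(
    df: pd.DataFrame, loci: list, dominance_loci: list
) -> tuple[np.ndarray, list, pd.DataFrame]:
    """Centered genetic regressors plus period-x-sex cell-mean columns."""
    cols = {}
    names = []
    for locus in loci:
        # calls count the tracked small allele: 0 copies -> large homozygote
        code = 1.0 - df[locus]
        het = (df[locus] == 1).astype(float)
        for sex in SEXES:
            in_sex = (df["sex"] == sex).astype(float)
            ccode = code - code.groupby([df["year"], df["sex"]]).transform("mean")
            name = f"a_{locus}_{sex}"
            cols[name] = (ccode * in_sex).to_numpy()
            names.append(name)
            if locus in dominance_loci:
                chet = het - het.groupby([df["year"], df["sex"]]).transform("mean")
                name = f"d_{locus}_{sex}"
                cols[name] = (chet * in_sex).to_numpy()
                names.append(name)
    X = pd.DataFrame(cols, index=df.index)
    cells = pd.get_dummies(
        df["period"].astype(str) + ":" + df["sex"].astype(str), prefix="cell"
    ).astype(float)
    design = pd.concat([X, cells], axis=1)
    return design.to_numpy(), names, design


def fit_effect_model(
    data: pd.DataFrame,
    loci: list = ("vgll3", "six6"),
    dominance_loci: list = ("vgll3",),
) -> EffectModelFit:
    """Fit the within-year sex-specific effect model.

    ``data`` holds one row per fish with columns mass_kg, year, period,
    sex, origin, and one genotype column per focal locus (tracked-allele
    counts 0/1/2).  Hatchery fish and fish with unknown sex or a missing
    focal genotype are excluded (counted in ``n_excluded``).
    """
    loci = list(loci)
    dominance_loci = list(dominance_loci)
    n_input = len(data)
    df = data.copy()
    if "period" not in df.columns:
        df["period"] = df["year"].astype(str)
    keep = (
        df["sex"].isin(SEXES)
        & df[loci].notna().all(axis=1)
        & (df.get("origin", pd.Series("wild", index=df.index)) != "hatchery")
        & (df["mass_kg"] > 0)
    )
    df = df[keep].reset_index(drop=True)
    if df.empty:
        raise ValueError("no usable records after exclusions")
    for locus in loci:
        if df[locus].nunique() < 2:
            raise ValueError(f"locus {locus} is monomorphic in the usable data")

    y = np.log(df["mass_kg"].to_numpy() * 1000.0)
    X, names, design = _build_design(df, loci, dominance_loci)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the offending genetic term for the error message
        for j, nm in enumerate(names):
            rest = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(rest) == rank:
                raise ValueError(f"singular design: term {nm} is not identifiable")
        raise ValueError("singular design matrix")
    res = sm.OLS(y, X).fit()
    k = len(names)
    return EffectModelFit(
        names=names,
        params=res.params[:k],
        cov=res.cov_params()[:k, :k],
        n_used=len(df),
        n_excluded=n_input - len(df),
        nuisance=pd.Series(res.params[k:], index=design.columns[k:]),
        loci=loci,
        dominance_loci=dominance_loci,
    )


def genotype_mass_ratio(
    fit: EffectModelFit,
    locus: str,
    sex: str,
    n_draws: int = 50_000,
    seed: int | None = None,
) -> dict:
    """Large-homozygote / small-homozygote mass ratio exp(2a) with a
    Monte-Carlo percentile CI from the coefficient error covariance."""
    rng = np.random.default_rng(seed)
    name = f"a_{locus}_{sex}"
    a_hat = fit.coef(name)
    i = fit.names.index(name)
    sd = np.sqrt(max(fit.cov[i, i], 0.0))
    draws = rng.normal(a_hat, sd, size=n_draws) if sd > 0 else np.full(n_draws, a_hat)
    ratios = np.exp(2.0 * draws)
    lo, hi = np.quantile(ratios, [0.025, 0.975])
    return {
        "ratio": float(np.exp(2.0 * a_hat)),
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def hwe_mean(p: float, a: float, d: float = 0.0) -> float:
    """Mean genotypic value at frequency ``p`` of the +a allele under HWE:
    a (2p - 1) + 2 d p (1 - p)."""
    return a * (2.0 * p - 1.0) + 2.0 * d * p * (1.0 - p)


def predict_change_fraction(
    effects: dict,
    p_before: dict,
    p_after: dict,
    observed_delta: float,
    sex: str,
) -> float:
    """Fraction of an observed ln-mass change predicted by allele-frequency
    change at the focal loci.

    ``effects`` maps locus -> :class:`LocusEffects`; ``p_before``/
    ``p_after`` map locus -> frequency of the large (+a) allele.  The
    predicted change is the sum over loci of HWE mean genotypic values at
    the after-frequencies minus the same at the before-frequencies, using
    the requested sex's effects.
    """
    if observed_delta == 0:
        raise ValueError("observed_delta must be nonzero")
    pred = 0.0
    for locus, eff in effects.items():
        a = eff.a_f if sex == "F" else eff.a_m
        d = eff.d_f if sex == "F" else eff.d_m
        pb, pa = p_before[locus], p_after[locus]
        if not (0.0 <= pb <= 1.0 and 0.0 <= pa <= 1.0):
            raise ValueError("frequencies must lie in [0, 1]")
        pred += hwe_mean(pa, a, d) - hwe_mean(pb, a, d)
    return pred / observed_delta


def stocking_comparison(
    panel: GenotypePanel,
    locus: str,
    n_draws: int = 20_000,
    seed: int | None = None,
) -> dict:
    """Compare tracked-allele frequencies between wild and hatchery fish.

    Returns (i) per group-x-period Beta(1 + A, 1 + T - A) posterior
    summaries and (ii) the hatchery-vs-wild log-odds contrast from a
    quasi-binomial GLM with period and origin as fixed effects.
    """
    rng = np.random.default_rng(seed)
    meta = panel.individuals
    calls = panel.calls[locus]
    groups = {}
    rows = []
    for origin in ("wild", "hatchery"):
        sel = meta["origin"] == origin
        if not sel.any():
            raise ValueError(f"no individuals with origin {origin!r}")
        for period in panel.periods:
            vals = calls[sel & (meta["period"] == period)].dropna()
            if len(vals) == 0:
                continue
            a, t = int(vals.sum()), 2 * len(vals)
            draws = rng.beta(1.0 + a, 1.0 + t - a, size=n_draws)
            lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
            groups[(origin, period)] = {
                "A": a,
                "T": t,
                "median": float(med),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
            rows.append({"origin": origin, "period": period, "A": a, "T": t})

    agg = pd.DataFrame(rows)
    endog = agg[["A"]].assign(fail=agg["T"] - agg["A"]).to_numpy(dtype=float)
    X = pd.get_dummies(agg["period"], drop_first=True).astype(float)
    X.insert(0, "const", 1.0)
    X["hatchery"] = (agg["origin"] == "hatchery").astype(float)
    res = sm.GLM(endog, X.to_numpy(), family=sm.families.Binomial()).fit()
    j = list(X.columns).index("hatchery")
    # quasi-binomial: scale the binomial SEs by the Pearson dispersion
    mu = res.predict(X.to_numpy())
    t_tot = endog.sum(axis=1)
    pearson_x2 = float(
        np.sum((endog[:, 0] - t_tot * mu) ** 2 / (t_tot * mu * (1.0 - mu)))
    )
    df_resid = len(agg) - X.shape[1]
    dispersion = pearson_x2 / df_resid if df_resid > 0 else np.nan
    coef = float(res.params[j])
    se = float(res.bse[j]) * float(np.sqrt(dispersion))
    if np.isfinite(se) and se > 1e-10:
        pval = float(2.0 * stats.t.sf(abs(coef) / se, df_resid))
    else:
        # degenerate dispersion estimate (perfect fit or no residual df)
        pval = 1.0 if abs(coef) < 1e-6 else 0.0
    return {
        "groups": groups,
        "log_odds_diff": coef,
        "se": se,
        "p_value": pval,
    }
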