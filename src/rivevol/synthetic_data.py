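"""Synthetic data generator with known ground truth.

Generates the three input tables (genotypes + locus metadata, catch
records, waterflow series) with the statistical structure the analysis
assumes: a step-decreasing flow series, a deterministic moving-optimum
trajectory for the trait mean and focal-allele frequencies, neutral loci
drifting between sampling periods with intensity zeta, and individual
catch masses log-normal around the year mean with total within-year
variance VP.

Genotyped individuals are sampled from the catch of their period year, so
genotype and catch tables join on ``individual_id`` for effect-model
fitting.  Every output is reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .adaptive_dynamics import (
    AdaptiveParams,
    AgeWeights,
    LocusEffects,
    ModelConstants,
    forward_recursion,
)
from .io_datamodel import (
    FOCAL,
    NEUTRAL,
    CatchTable,
    FlowSeries,
    GenotypePanel,
)
from .locus_effects import hwe_mean

__all__ = [
    "SimScenario",
    "SyntheticDataset",
    "default_effects",
    "simulate_flow",
    "simulate_trajectory",
    "sample_catch",
    "sample_genotypes",
    "sample_observations",
    "generate",
]

log = logging.getLogger(__name__)


def default_effects() -> dict[str, LocusEffects]:
    """Paper-like sex-specific effects (ln-mass units, +a = large allele)."""
    return {
        "vgll3": LocusEffects(a_f=0.43, d_f=0.15, a_m=0.66, d_m=-0.15),
        "six6": LocusEffects(a_f=0.33, d_f=0.0, a_m=0.28, d_m=0.0),
    }


def _default_params() -> AdaptiveParams:
    return AdaptiveParams(
        q=-2.0,
        theta_ref=9.26,
        b=1.0,
        delta=0.5,
        h2=0.5,
        sigma_e2=0.01,
        z_init=np.full(8, 9.26),
        p_init=np.array([0.73, 0.95]),
    )


@dataclass
class SimScenario:
    """Everything needed to generate one synthetic study."""

    seed: int = 0
    start_year: int = 1940
    end_year: int = 2016
    flow_base: float = 41.0
    # (year, new flow): defaults mirror step cuts to 60/50/40% of base
    flow_schedule: tuple = ((1953, 24.6), (1962, 20.5), (1975, 16.4))
    flow_noise_sd: float = 0.0  # sd of lognormal annual noise on flow
    params: AdaptiveParams = field(default_factory=_default_params)
    effects: dict = field(default_factory=default_effects)
    vp: float = 0.31
    weights: AgeWeights = field(default_factory=AgeWeights)
    n_neutral_loci: int = 67
    neutral_init: np.ndarray | None = None  # drawn U(0.1, 0.9) when None
    zeta: tuple = (0.002, 0.03)  # per inter-sample interval
    drift_method: str = "truncnorm"  # or "wright_fisher"
    wf_generations: int = 6
    sample_plan: tuple = ((1940, 80), (1987, 120), (2016, 149))
    missing_rate: float = 0.0
    catch_n_per_year: int = 150
    hatchery_fraction: float = 0.0
    hatchery_logit_offset: float = 0.0

    def constants(self) -> ModelConstants:
        return ModelConstants(vp=self.vp, ref_year=self.start_year)

    def locus_names(self) -> list:
        return list(self.effects)


@dataclass
class SyntheticDataset:
    panel: GenotypePanel
    catch: CatchTable
    flow: FlowSeries
    trajectory: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.panel.write(outdir / "genotypes.csv", outdir / "loci.csv")
        self.catch.write(outdir / "catch.csv")
        self.flow.write(outdir / "flow.csv")
        self.trajectory.reset_index().to_csv(outdir / "trajectory.csv", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------


def simulate_flow(scenario: SimScenario, rng: np.random.Generator | None = None) -> FlowSeries:
    """Piecewise-constant flow series with optional lognormal noise."""
    rng = rng or np.random.default_rng(scenario.seed)
    years = np.arange(scenario.start_year, scenario.end_year + 1)
    flow = np.full(len(years), float(scenario.flow_base))
    for year, value in scenario.flow_schedule:
        if not scenario.start_year <= year <= scenario.end_year:
            raise ValueError(f"flow schedule year {year} outside simulated range")
        flow[years >= year] = float(value)
    if scenario.flow_noise_sd > 0:
        flow = flow * np.exp(rng.normal(0.0, scenario.flow_noise_sd, len(years)))
    return FlowSeries(pd.Series(flow, index=pd.Index(years, name="year")))


def simulate_trajectory(scenario: SimScenario, flow: FlowSeries) -> pd.DataFrame:
    """True deterministic trajectory, extended back through the pre-start
    cohort years (no selection there) so samplers can index them."""
    traj = forward_recursion(
        scenario.params, scenario.constants(), scenario.weights, scenario.effects, flow
    )
    n_pre = scenario.weights.max_lag
    z_pre = np.asarray(scenario.params.z_init, dtype=float)
    if len(z_pre) < n_pre:
        z_pre = np.concatenate([np.full(n_pre - len(z_pre), z_pre[0]), z_pre])
    z_pre = z_pre[-n_pre:]
    pre_years = np.arange(scenario.start_year - n_pre, scenario.start_year)
    pre = pd.DataFrame(index=pd.Index(pre_years, name="year"), columns=traj.columns, dtype=float)
    pre["zbar"] = z_pre
    pre["beta"] = 0.0
    pre["s"] = 0.0
    for i, name in enumerate(scenario.locus_names()):
        pre[f"p_{name}"] = scenario.params.p_init[i]
        pre[f"dp_{name}"] = 0.0
    return pd.concat([pre, traj])


def _genotype_probs(p_large: float) -> np.ndarray:
    """HWE probabilities of tracked-small-allele counts (0, 1, 2)."""
    q = 1.0 - p_large
    return np.array([p_large**2, 2.0 * p_large * q, q * q])


def _genetic_sd2(effects: dict, p_large: dict, sex: str) -> float:
    """HWE genotypic variance of the summed focal-locus values for one sex."""
    total = 0.0
    for locus, eff in effects.items():
        a = eff.a_f if sex == "F" else eff.a_m
        d = eff.d_f if sex == "F" else eff.d_m
        p = p_large[locus]
        probs = _genotype_probs(p)
        vals = np.array([a, d, -a])
        mean = float(probs @ vals)
        total += float(probs @ (vals - mean) ** 2)
    return total


def sample_catch(
    trajectory: pd.DataFrame,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
) -> CatchTable:
    """Individual catch records for every modeled year.

    ln masses are normal around the observed-scale year mean (zbar +
    delta*s) with the genotype deviation plus residual noise scaled so the
    total within-year, within-sex variance equals VP.  Focal genotypes and
    sex are kept as columns so genotype sampling and effect-model fixtures
    can reuse them; writers drop the genotype columns.
    """
    rng = rng or np.random.default_rng(scenario.seed)
    loci = scenario.locus_names()
    rows = []
    for year in range(scenario.start_year, scenario.end_year + 1):
        t = trajectory.loc[year]
        n = scenario.catch_n_per_year
        # the observation model's residual year effect (plasticity etc.)
        year_effect = rng.normal(0.0, np.sqrt(scenario.params.sigma_e2))
        mu = t["zbar"] + scenario.params.delta * t["s"] + year_effect
        p_large = {l: float(t[f"p_{l}"] + scenario.params.delta * t[f"dp_{l}"]) for l in loci}
        sexes = np.where(rng.uniform(size=n) < 0.5, "F", "M")
        origins = np.where(
            rng.uniform(size=n) < scenario.hatchery_fraction, "hatchery", "wild"
        )
        calls = {}
        for locus in loci:
            probs_w = _genotype_probs(p_large[locus])
            if scenario.hatchery_logit_offset != 0.0:
                from scipy.special import expit, logit

                p_h = float(expit(logit(p_large[locus]) + scenario.hatchery_logit_offset))
            else:
                p_h = p_large[locus]
            probs_h = _genotype_probs(p_h)
            c = np.empty(n, dtype=int)
            for grp, probs in (("wild", probs_w), ("hatchery", probs_h)):
                sel = origins == grp
                c[sel] = rng.choice(3, size=sel.sum(), p=probs)
            calls[locus] = c
        ln_mass = np.full(n, float(mu))
        for sex in ("F", "M"):
            sel = sexes == sex
            dev = np.zeros(sel.sum())
            for locus in loci:
                eff = scenario.effects[locus]
                a = eff.a_f if sex == "F" else eff.a_m
                d = eff.d_f if sex == "F" else eff.d_m
                vals = np.array([a, d, -a])
                probs = _genotype_probs(p_large[locus])
                dev += vals[calls[locus][sel]] - float(probs @ np.array([a, d, -a]))
            resid_var = scenario.vp - _genetic_sd2(scenario.effects, p_large, sex)
            if resid_var < 0:
                log.warning("genetic variance exceeds VP in %d; clamping residual", year)
                resid_var = 1e-6
            ln_mass[sel] += dev + rng.normal(0.0, np.sqrt(resid_var), sel.sum())
        mass_kg = np.exp(ln_mass) / 1000.0
        sea_age = 1 + (ln_mass > 8.2).astype(int) + (ln_mass > 8.9).astype(int) + (
            ln_mass > 9.4
        ).astype(int)
        rec = pd.DataFrame(
            {
                "individual_id": [f"Y{year}_{i}" for i in range(n)],
                "year": year,
                "mass_kg": mass_kg,
                "sea_age": sea_age,
                "smolt_age": 2 + (rng.uniform(size=n) < 0.4).astype(int),
                "sex": sexes,
                "origin": origins,
            }
        )
        for locus in loci:
            rec[locus] = calls[locus]
        rows.append(rec)
    return CatchTable(pd.concat(rows, ignore_index=True))


def _drift_step(p: np.ndarray, zeta: float, method: str, wf_g: int, rng) -> np.ndarray:
    """One inter-sample drift transition for a vector of frequencies."""
    if zeta == 0.0:
        return p.copy()
    if method == "truncnorm":
        out = p.copy()
        free = (p > 0.0) & (p < 1.0)  # fixed loci cannot drift
        sd = np.sqrt(p[free] * (1.0 - p[free]) * zeta)
        a, b = (0.0 - p[free]) / sd, (1.0 - p[free]) / sd
        out[free] = truncnorm.rvs(a, b, loc=p[free], scale=sd, random_state=rng)
        return out
    if method == "wright_fisher":
        two_ne = max(2, int(round(wf_g / zeta)))  # zeta = g / (2 Ne)
        out = p.copy()
        for _ in range(wf_g):
            out = rng.binomial(two_ne, out) / two_ne
        return out
    raise ValueError(f"unknown drift method {method!r}")


def sample_genotypes(
    trajectory: pd.DataFrame,
    scenario: SimScenario,
    catch: CatchTable,
    rng: np.random.Generator | None = None,
) -> GenotypePanel:
    """Genotype panel over the scenario's sampling periods.

    Neutral frequencies drift between consecutive periods with the
    scenario's zeta; focal calls are taken from the catch records of the
    sampled individuals (which were drawn at the trajectory frequencies).
    """
    rng = rng or np.random.default_rng(scenario.seed)
    loci_focal = scenario.locus_names()
    n_neutral = scenario.n_neutral_loci
    neutral_names = [f"snp{i:03d}" for i in range(1, n_neutral + 1)]

    if scenario.neutral_init is None:
        p_neutral = rng.uniform(0.1, 0.9, size=n_neutral)
    else:
        p_neutral = np.asarray(scenario.neutral_init, dtype=float).copy()
    zetas = scenario.zeta
    if len(zetas) < len(scenario.sample_plan) - 1:
        raise ValueError("scenario.zeta must cover every inter-sample interval")

    frames = []
    meta_rows = []
    truth_freqs = {}
    for j, (year, n) in enumerate(scenario.sample_plan):
        if j > 0:
            p_neutral = _drift_step(
                p_neutral,
                float(zetas[j - 1]),
                scenario.drift_method,
                scenario.wf_generations,
                rng,
            )
        truth_freqs[str(year)] = p_neutral.copy()
        pool = catch.records[catch.records["year"] == year]
        if len(pool) < n:
            raise ValueError(
                f"catch plan provides {len(pool)} fish in {year}; need {n} genotyped"
            )
        pick = pool.iloc[rng.choice(len(pool), size=n, replace=False)]
        calls = pd.DataFrame(
            rng.binomial(2, p_neutral, size=(n, n_neutral)).astype(float),
            columns=neutral_names,
            index=pick["individual_id"],
        )
        for locus in loci_focal:
            calls[locus] = pick[locus].to_numpy(dtype=float)
        if scenario.missing_rate > 0:
            mask = rng.uniform(size=calls.shape) < scenario.missing_rate
            calls = calls.mask(mask)
        frames.append(calls)
        meta_rows.append(
            pd.DataFrame(
                {
                    "period": str(year),
                    "sex": pick["sex"].to_numpy(),
                    "origin": pick["origin"].to_numpy(),
                },
                index=pick["individual_id"],
            )
        )
    individuals = pd.concat(meta_rows)
    individuals.index.name = "individual_id"
    loci_meta = pd.DataFrame(
        {
            "class": [NEUTRAL] * n_neutral + [FOCAL] * len(loci_focal),
            "tracked_allele": ["A"] * n_neutral + ["E"] * len(loci_focal),
        },
        index=pd.Index(neutral_names + loci_focal, name="locus_id"),
    )
    panel = GenotypePanel(individuals, pd.concat(frames), loci_meta)
    panel.neutral_truth = truth_freqs  # generator bookkeeping for tests
    return panel


def sample_observations(
    trajectory: pd.DataFrame,
    scenario: SimScenario,
    rng: np.random.Generator | None = None,
    genotyped: tuple | None = None,
):
    """Draw annual-mean and allele-count observations straight from the
    model's observation layer (no individual fish), for fast
    parameter-recovery studies.

    Returns a :class:`rivevol.adaptive_dynamics.DynamicsData`-shaped pair
    (phenotypes DataFrame, allele-count DataFrame); allele counts are of
    the large (+a) allele at the ``genotyped`` (year, n_individuals)
    entries (defaults to the scenario sample plan, post-start years only).
    """
    from .adaptive_dynamics import DynamicsData  # local to avoid cycle at import

    rng = rng or np.random.default_rng(scenario.seed)
    years = np.arange(scenario.start_year, scenario.end_year + 1)
    n = scenario.catch_n_per_year
    se = np.sqrt(scenario.vp / n)
    t = trajectory.loc[years]
    zobs = (
        t["zbar"].to_numpy()
        + scenario.params.delta * t["s"].to_numpy()
        + rng.normal(0.0, np.sqrt(scenario.params.sigma_e2), len(years))
        + rng.normal(0.0, se, len(years))
    )
    pheno = pd.DataFrame(
        {"mean_ln_mass": zobs, "se_ln_mass": se},
        index=pd.Index(years, name="year"),
    )
    if genotyped is None:
        genotyped = tuple(
            (y, m) for y, m in scenario.sample_plan if y > scenario.start_year
        )
    rows = []
    for year, m in genotyped:
        tt = trajectory.loc[year]
        for locus in scenario.locus_names():
            pr = float(
                np.clip(
                    tt[f"p_{locus}"] + scenario.params.delta * tt[f"dp_{locus}"],
                    0.0,
                    1.0,
                )
            )
            total = 2 * m
            rows.append(
                {
                    "locus": locus,
                    "year": int(year),
                    "A": int(rng.binomial(total, pr)),
                    "T": total,
                }
            )
    return pheno, pd.DataFrame(rows, columns=["locus", "year", "A", "T"])


def generate(scenario: SimScenario, outdir=None) -> SyntheticDataset:
    """Run the full generator: flow -> trajectory -> catch -> genotypes."""
    rng = np.random.default_rng(scenario.seed)
    flow = simulate_flow(scenario, np.random.default_rng(rng.integers(2**63)))
    trajectory = simulate_trajectory(scenario, flow)
    catch = sample_catch(trajectory, scenario, np.random.default_rng(rng.integers(2**63)))
    panel = sample_genotypes(
        trajectory, scenario, catch, np.random.default_rng(rng.integers(2**63))
    )
    truth = {
        "params": {
            "q": scenario.params.q,
            "theta_ref": scenario.params.theta_ref,
            "b": scenario.params.b,
            "delta": scenario.params.delta,
            "h2": scenario.params.h2,
            "sigma_e2": scenario.params.sigma_e2,
            "z_init": scenario.params.z_init,
            "p_init": scenario.params.p_init,
        },
        "effects": {
            k: {"a_f": e.a_f, "d_f": e.d_f, "a_m": e.a_m, "d_m": e.d_m}
            for k, e in scenario.effects.items()
        },
        "zeta": list(scenario.zeta),
        "neutral_frequencies": {k: v for k, v in panel.neutral_truth.items()},
        "seed": scenario.seed,
    }
    ds = SyntheticDataset(panel, catch, flow, trajectory, truth)
    if outdir is not None:
        ds.write(outdir)
    return ds
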