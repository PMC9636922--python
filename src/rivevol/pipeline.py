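"""Orchestration: run the full analysis end to end with one seed.

Stages (simulate -> drift-test -> effects -> fit-dynamics -> report) read
and write the CSV/JSON formats of the other modules.  A global seed is
expanded into per-stage sub-seeds by stable hashing of the stage name, so
adding a stage never shifts another stage's random stream.  Each run writes
a manifest (config hash, versions, per-stage seeds) sufficient for a
byte-identical re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptive_dynamics import (
    AdaptiveParams,
    AgeWeights,
    DynamicsData,
    LocusEffects,
    ModelConstants,
    PriorSpec,
    fit_model,
    variance_explained,
)
from .drift_null import (
    DriftConfig,
    drift_envelope,
    drift_probability,
    fit_drift_model,
    focal_posterior,
)
from .io_datamodel import (
    FOCAL,
    NEUTRAL,
    annual_summary,
    count_alleles,
    filter_call_rate,
    period_year,
    read_catch,
    read_flow,
    read_genotypes,
)
from .locus_effects import (
    fit_effect_model,
    genotype_mass_ratio,
    join_genotypes_catch,
)
from .rates_summaries import decompose_mass_change, percent_of_reference, rate_of_change
from .synthetic_data import SimScenario, default_effects, generate

__all__ = ["RunConfig", "stage_seed", "validate_inputs", "run_pipeline"]

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage sub-seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


@dataclasses.dataclass
class RunConfig:
    """Either real input paths or a synthetic scenario -- never both."""

    genotypes: str | None = None
    loci: str | None = None
    catch: str | None = None
    flow: str | None = None
    scenario: SimScenario | None = None
    seed: int = 0
    out: str = "runs/run0"
    min_call_rate: float = 0.7
    drift: DriftConfig = dataclasses.field(default_factory=DriftConfig)
    priors: PriorSpec = dataclasses.field(default_factory=PriorSpec)
    weights: AgeWeights = dataclasses.field(default_factory=AgeWeights)
    vp: float = 0.31
    ref_year: int = 1940
    n_restarts: int = 3
    generation_time: float = 6.0

    def __post_init__(self) -> None:
        real = all(x is not None for x in (self.genotypes, self.loci, self.catch, self.flow))
        if (self.scenario is None) == (not real):
            raise ValueError("supply exactly one of (real input paths, scenario)")

    @property
    def synthetic(self) -> bool:
        return self.scenario is not None


def load_scenario(path) -> SimScenario:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "params" in raw:
        p = raw.pop("params")
        kwargs["params"] = AdaptiveParams(
            q=p.get("q", -2.0),
            theta_ref=p.get("theta_ref", 9.26),
            b=p.get("b", 1.0),
            delta=p.get("delta", 0.5),
            h2=p.get("h2", 0.5),
            sigma_e2=p.get("sigma_e2", 0.01),
            z_init=np.asarray(p.get("z_init", [9.26] * 8), dtype=float),
            p_init=np.asarray(p.get("p_init", [0.73, 0.95]), dtype=float),
        )
    if "effects" in raw:
        kwargs["effects"] = {
            name: LocusEffects(e["a_f"], e.get("d_f", 0.0), e["a_m"], e.get("d_m", 0.0))
            for name, e in raw.pop("effects").items()
        }
    for key in ("flow_schedule", "sample_plan", "zeta"):
        if key in raw:
            raw[key] = tuple(tuple(v) if isinstance(v, list) else v for v in raw[key])
    kwargs.update(raw)
    return SimScenario(**kwargs)


def validate_inputs(config: RunConfig) -> dict:
    """Schema checks across the input tables; fatal issues vs warnings."""
    errors: list[str] = []
    warnings: list[str] = []
    if config.synthetic:
        return {"errors": errors, "warnings": warnings}
    try:
        panel = read_genotypes(config.genotypes, config.loci)
    except Exception as exc:  # noqa: BLE001 - report, do not crash validation
        errors.append(f"genotypes: {exc}")
        panel = None
    try:
        catch = read_catch(config.catch)
        raw = pd.read_csv(config.catch)
        bad = raw.index[~(raw["mass_kg"] > 0)].tolist()
        for row in bad:
            errors.append(f"catch: non-positive mass at row {row + 2}")
    except Exception as exc:
        errors.append(f"catch: {exc}")
        catch = None
    try:
        flow = read_flow(config.flow)
    except Exception as exc:
        errors.append(f"flow: {exc}")
        flow = None
    if panel is not None and not panel.loci_of_class(FOCAL):
        errors.append("genotypes: no focal loci declared")
    if panel is not None and catch is not None:
        catch_years = set(int(y) for y in catch.years)
        for period in panel.periods:
            if period_year(period) not in catch_years:
                warnings.append(f"genotype period {period} has no catch records")
    if flow is not None and catch is not None:
        if flow.flow.index.max() < max(catch.years):
            warnings.append("flow series ends before the last catch year")
    return {"errors": errors, "warnings": warnings}


def _config_hash(config: RunConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    payload = enc(config)
    payload.pop("out", None)  # the output location does not shape results
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_drift_stage(panel, config: RunConfig, outdir: Path) -> dict:
    counts = count_alleles(panel, drop_fixed=True)
    neutral = counts.restrict(NEUTRAL)
    focal = counts.restrict(FOCAL)
    drift_cfg = dataclasses.replace(
        config.drift, seed=stage_seed(config.seed, "drift")
    )
    post = fit_drift_model(neutral, drift_cfg)
    focals = focal_posterior(focal, seed=stage_seed(config.seed, "drift-focal"))

    rows = []
    for locus, fp in focals.items():
        for j in range(len(fp.periods) - 1):
            ch = fp.change_summary(j)
            prob = drift_probability(
                fp.change_draws[j],
                fp.freq_draws[j],
                post.zeta_draws(min(j, post.zeta.shape[2] - 1)),
                seed=stage_seed(config.seed, f"driftprob-{locus}-{j}"),
            )
            rows.append(
                {
                    "locus": locus,
                    "from": fp.periods[j],
                    "to": fp.periods[j + 1],
                    "change_median": ch["median"],
                    "ci_low": ch["ci_low"],
                    "ci_high": ch["ci_high"],
                    "drift_probability": prob,
                }
            )
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "drift_summary.csv", index=False)

    grid = np.linspace(0.02, 0.98, 49)
    env_rows = {"p0": grid}
    for t in range(post.zeta.shape[2]):
        env_rows[f"envelope_{post.periods[t]}_{post.periods[t + 1]}"] = drift_envelope(
            grid, post.zeta_draws(t)
        )
    pd.DataFrame(env_rows).to_csv(outdir / "drift_envelope.csv", index=False)
    pd.DataFrame(
        [{"parameter": k, "rhat": v} for k, v in post.rhat.items()]
    ).to_csv(outdir / "drift_diagnostics.csv", index=False)
    zeta = {
        f"{post.periods[t]}->{post.periods[t + 1]}": post.zeta_summary(t)
        for t in range(post.zeta.shape[2])
    }
    return {"zeta": zeta, "converged": post.converged, "summary": rows}


def run_effects_stage(panel, catch, config: RunConfig, outpath: Path) -> dict:
    merged = join_genotypes_catch(panel, catch)
    focal = panel.loci_of_class(FOCAL)
    dominance = [l for l in focal if l == "vgll3"] or focal[:1]
    fit = fit_effect_model(merged, loci=focal, dominance_loci=dominance)
    ratios = {}
    for locus in focal:
        for sex in ("F", "M"):
            ratios[f"{locus}_{sex}"] = genotype_mass_ratio(
                fit, locus, sex, seed=stage_seed(config.seed, f"ratio-{locus}-{sex}")
            )
    payload = {
        "effects": {
            locus: {
                "a_f": fit.locus_effects(locus).a_f,
                "d_f": fit.locus_effects(locus).d_f,
                "a_m": fit.locus_effects(locus).a_m,
                "d_m": fit.locus_effects(locus).d_m,
                "cov": fit.locus_effects(locus).cov.tolist(),
            }
            for locus in focal
        },
        "ratios": ratios,
        "n_used": fit.n_used,
        "n_excluded": fit.n_excluded,
    }
    with open(outpath, "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def load_effects(path) -> dict[str, LocusEffects]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        name: LocusEffects(
            e["a_f"], e["d_f"], e["a_m"], e["d_m"], np.asarray(e.get("cov", np.zeros((4, 4))))
        )
        for name, e in payload["effects"].items()
    }


def run_dynamics_stage(panel, catch, flow, effects, config: RunConfig, outdir: Path) -> dict:
    constants = ModelConstants(vp=config.vp, ref_year=config.ref_year)
    pheno = annual_summary(catch).table[["mean_ln_mass", "se_ln_mass"]]
    pheno = pheno[pheno.index >= config.ref_year]
    counts = count_alleles(panel, drop_fixed=False).restrict(FOCAL)
    rows = []
    for _, row in counts.table.iterrows():
        year = period_year(row["period"])
        if year <= config.ref_year or row["T"] == 0:
            continue  # initial-period information enters through the priors
        rows.append(
            {
                "locus": row["locus"],
                "year": year,
                # panel tracks the small allele; the dynamics model tracks
                # the large (+a) allele
                "A": int(row["T"] - row["A"]),
                "T": int(row["T"]),
            }
        )
    data = DynamicsData(
        phenotypes=pheno,
        allele_counts=pd.DataFrame(rows, columns=["locus", "year", "A", "T"]),
        flow=flow,
    )
    fit = fit_model(
        data,
        config.priors,
        constants,
        config.weights,
        effects,
        n_restarts=config.n_restarts,
        seed=stage_seed(config.seed, "dynamics"),
    )
    fit.trajectory.reset_index().to_csv(outdir / "trajectory_fit.csv", index=False)
    ve = variance_explained(fit, data)
    payload = {
        "params": {
            "q": fit.params.q,
            "theta_ref": fit.params.theta_ref,
            "b": fit.params.b,
            "delta": fit.params.delta,
            "h2": fit.params.h2,
            "sigma_e2": fit.params.sigma_e2,
            "p_init": fit.params.p_init.tolist(),
        },
        "se": {k: float(v) for k, v in fit.se.items()},
        "variance_explained": ve,
        "nll": fit.nll,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
    }
    with open(outdir / "fit.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def run_report_stage(catch, config: RunConfig, outpath: Path) -> dict:
    series = annual_summary(catch)
    obs = series.observed()
    first_window = obs.index[: min(10, len(obs))]
    last_window = obs.index[-min(10, len(obs)) :]
    ln = np.log(catch.records["mass_kg"] * 1000.0)
    mean_before = float(
        ln[catch.records["year"].isin(first_window)].mean()
    )
    mean_after = float(ln[catch.records["year"].isin(last_window)].mean())
    years = float(last_window[-1] - first_window[0])
    rate = rate_of_change(
        mean_before,
        mean_after,
        years=years,
        generation_time=config.generation_time,
        sd_ln=float(np.sqrt(config.vp)),
    )
    kg_before = float(catch.records.loc[catch.records["year"].isin(first_window), "mass_kg"].mean())
    kg_after = float(catch.records.loc[catch.records["year"].isin(last_window), "mass_kg"].mean())
    payload = {
        "rate": dataclasses.asdict(rate),
        "percent_of_reference": percent_of_reference(kg_after, kg_before),
    }
    if catch.records["sea_age"].notna().any():
        before = catch.restrict_years(first_window)
        after = catch.restrict_years(last_window)
        try:
            payload["decomposition"] = decompose_mass_change(before, after)
        except ValueError as exc:
            payload["decomposition_error"] = str(exc)
    with open(outpath, "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in order; returns the run directory."""
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    report = validate_inputs(config)
    if report["errors"]:
        raise ValueError("input validation failed: " + "; ".join(report["errors"]))
    for msg in report["warnings"]:
        log.warning("validate: %s", msg)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stage_seeds": {},
        "stages": [],
    }
    stage = "simulate"
    try:
        if config.synthetic:
            scenario = dataclasses.replace(
                config.scenario, seed=stage_seed(config.seed, "simulate")
            )
            manifest["stage_seeds"]["simulate"] = scenario.seed
            dataset = generate(scenario, outdir / "inputs")
            panel = read_genotypes(outdir / "inputs/genotypes.csv", outdir / "inputs/loci.csv")
            catch = read_catch(outdir / "inputs/catch.csv")
            flow = read_flow(outdir / "inputs/flow.csv")
            manifest["stages"].append("simulate")
        else:
            panel = read_genotypes(config.genotypes, config.loci)
            catch = read_catch(config.catch)
            flow = read_flow(config.flow)

        panel = filter_call_rate(panel, config.min_call_rate)

        stage = "drift-test"
        drift_out = run_drift_stage(panel, config, outdir)
        manifest["stages"].append(stage)

        stage = "effects"
        effects_payload = run_effects_stage(panel, catch, config, outdir / "effects.json")
        manifest["stages"].append(stage)

        stage = "fit-dynamics"
        effects = load_effects(outdir / "effects.json")
        dyn = run_dynamics_stage(panel, catch, flow, effects, config, outdir)
        manifest["stages"].append(stage)

        stage = "report"
        run_report_stage(catch, config, outdir / "summary.json")
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.synthetic:
        truth = dataset.truth
        comparison = {
            "b": {"truth": truth["params"]["b"], "estimate": dyn["params"]["b"]},
            "q": {"truth": truth["params"]["q"], "estimate": dyn["params"]["q"]},
            "zeta": {
                "truth": truth["zeta"],
                "estimate": drift_out["zeta"],
            },
        }
        with open(outdir / "truth_vs_estimate.json", "w") as fh:
            json.dump(comparison, fh, indent=2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir
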