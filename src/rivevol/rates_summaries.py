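"""Headline phenotype-only summaries: evolution rates and decompositions."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_datamodel import CatchTable

__all__ = [
    "RateResult",
    "rate_of_change",
    "percent_of_reference",
    "decompose_mass_change",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RateResult:
    delta_ln: float
    years: float
    generations: float
    sd_ln: float
    darwins: float
    haldanes: float


def rate_of_change(
    mean_before: float,
    mean_after: float,
    years: float,
    generation_time: float,
    sd_ln: float,
) -> RateResult:
    """Rates of change of a ln-scale trait.

    darwins = delta_ln per million years; haldanes = delta_ln per
    phenotypic SD per generation.
    """
    if years <= 0 or sd_ln <= 0 or generation_time <= 0:
        raise ValueError("years, sd_ln and generation_time must be positive")
    delta = mean_after - mean_before
    generations = years / generation_time
    return RateResult(
        delta_ln=delta,
        years=years,
        generations=generations,
        sd_ln=sd_ln,
        darwins=delta / (years * 1e-6),
        haldanes=delta / (sd_ln * generations),
    )


def percent_of_reference(mean_t: float, mean_ref: float) -> float:
    """100 * mean_t / mean_ref (full precision; round at reporting time)."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * mean_t / mean_ref


def _age_stats(catch: CatchTable) -> pd.DataFrame:
    r = catch.records.dropna(subset=["sea_age"])
    if r.empty:
        raise ValueError("no records with sea_age")
    ln = np.log(r["mass_kg"].to_numpy() * 1000.0)
    df = pd.DataFrame({"age": r["sea_age"].astype(int).to_numpy(), "ln": ln})
    g = df.groupby("age")["ln"]
    return pd.DataFrame({"prop": g.count() / len(df), "mean_ln": g.mean()})


def decompose_mass_change(
    catch_before: CatchTable, catch_after: CatchTable
) -> dict:
    """Split the change in mean ln mass into an age-composition share and a
    within-age share.

    Uses the exact symmetric (averaged-counterfactual) decomposition

        delta = sum_a (pi2_a - pi1_a) * (mu1_a + mu2_a)/2
              + sum_a (pi1_a + pi2_a)/2 * (mu2_a - mu1_a)

    where pi are sea-age proportions and mu within-age mean ln masses.  Age
    classes present in only one period are pooled into the nearest class
    present in both (with a warning).  Shares are percentages of the total
    change and sum to 100.
    """
    s1 = _age_stats(catch_before)
    s2 = _age_stats(catch_after)
    common = sorted(set(s1.index) & set(s2.index))
    if not common:
        raise ValueError("no sea-age class present in both periods")

    def _pool(stats: pd.DataFrame) -> pd.DataFrame:
        extra = [a for a in stats.index if a not in common]
        if extra:
            log.warning("pooling sea-age classes %s into nearest shared class", extra)
        out = {a: [stats.loc[a, "prop"], stats.loc[a, "mean_ln"]] for a in common}
        for a in extra:
            tgt = min(common, key=lambda c: (abs(c - a), c))
            p_old, m_old = out[tgt]
            p_add, m_add = stats.loc[a, "prop"], stats.loc[a, "mean_ln"]
            out[tgt] = [
                p_old + p_add,
                (p_old * m_old + p_add * m_add) / (p_old + p_add),
            ]
        df = pd.DataFrame(out, index=["prop", "mean_ln"]).T
        return df

    s1, s2 = _pool(s1), _pool(s2)
    pi1, mu1 = s1["prop"].to_numpy(), s1["mean_ln"].to_numpy()
    pi2, mu2 = s2["prop"].to_numpy(), s2["mean_ln"].to_numpy()
    age_term = float(np.sum((pi2 - pi1) * (mu1 + mu2) / 2.0))
    within_term = float(np.sum((pi1 + pi2) / 2.0 * (mu2 - mu1)))
    total = age_term + within_term
    if total == 0:
        raise ValueError("no change in mean ln mass; shares undefined")
    return {
        "delta_ln": total,
        "share_sea_age_pct": 100.0 * age_term / total,
        "share_within_age_pct": 100.0 * within_term / total,
    }
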