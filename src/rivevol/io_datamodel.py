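"""Shared data model and CSV input/output.

The package operates on four tabular objects:

* :class:`GenotypePanel` -- individuals x biallelic loci, with sampling
  period, sex, and origin metadata.  Calls are counts of the *tracked*
  allele (0, 1, 2, or missing).
* :class:`AlleleCountTable` -- per (locus, period) counts of the tracked
  allele out of the total number of alleles observed.
* :class:`CatchTable` -- individual catch records (year, mass, ages).
* :class:`AnnualPhenotypeSeries` / :class:`FlowSeries` -- annual summaries
  of ln body mass and of the June--September waterflow covariate.

Masses are accepted in kilograms and analyzed as natural log grams.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GenotypePanel",
    "AlleleCountTable",
    "CatchTable",
    "AnnualPhenotypeSeries",
    "FlowSeries",
    "read_genotypes",
    "read_catch",
    "read_flow",
    "filter_call_rate",
    "count_alleles",
    "annual_summary",
]

log = logging.getLogger(__name__)

NEUTRAL = "neutral"
FOCAL = "focal"

_META_COLS = ("individual_id", "period", "sex", "origin")


class FormatError(ValueError):
    """Raised when an input table violates the expected schema."""


def _period_sort_key(label: str) -> tuple[int, str]:
    """Order period labels by the first 4-digit year they contain."""
    for i in range(len(label) - 3):
        chunk = label[i : i + 4]
        if chunk.isdigit():
            return (int(chunk), label)
    return (10**9, label)


def period_year(label: str) -> int:
    """First 4-digit year embedded in a period label (e.g. '1925-1926' -> 1925)."""
    year, _ = _period_sort_key(str(label))
    if year >= 10**9:
        raise FormatError(f"period label {label!r} contains no 4-digit year")
    return year


@dataclass
class GenotypePanel:
    """Biallelic calls for a set of individuals plus locus metadata.

    Attributes
    ----------
    individuals : DataFrame indexed by individual_id with columns
        ``period``, ``sex`` (F/M/unknown), ``origin`` (wild/hatchery/unknown).
    calls : DataFrame (individuals x loci) of floats in {0, 1, 2, NaN};
        each value counts copies of the locus's tracked allele.
    loci : DataFrame indexed by locus_id with columns ``class``
        (neutral/focal) and ``tracked_allele``.
    """

    individuals: pd.DataFrame
    calls: pd.DataFrame
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.individuals.index):
            self.calls = self.calls.reindex(self.individuals.index)
        missing = set(self.calls.columns) - set(self.loci.index)
        if missing:
            raise FormatError(f"loci table lacks metadata for {sorted(missing)}")
        bad = ~self.loci["class"].isin([NEUTRAL, FOCAL])
        if bad.any():
            raise FormatError(
                f"unknown locus class for {list(self.loci.index[bad])}"
            )
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise FormatError("genotype calls must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def periods(self) -> list[str]:
        return sorted(set(self.individuals["period"]), key=_period_sort_key)

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing calls per individual."""
        return self.calls.notna().mean(axis=1)

    def loci_of_class(self, cls: str) -> list[str]:
        return list(self.loci.index[self.loci["class"] == cls])

    def subset_loci(self, loci: Sequence[str]) -> "GenotypePanel":
        return GenotypePanel(
            self.individuals.copy(),
            self.calls[list(loci)].copy(),
            self.loci.loc[list(loci)].copy(),
        )

    def subset_individuals(self, ids: Sequence) -> "GenotypePanel":
        idx = pd.Index(ids)
        return GenotypePanel(
            self.individuals.loc[idx].copy(),
            self.calls.loc[idx].copy(),
            self.loci.copy(),
        )

    def write(self, genotypes_path, loci_path) -> None:
        """Write the canonical two-file CSV representation."""
        out = self.individuals.reset_index()
        out = out.rename(columns={out.columns[0]: "individual_id"})
        calls = self.calls.copy()
        # canonical dialect: integer calls, empty string for missing
        for c in calls.columns:
            calls[c] = calls[c].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
        out = pd.concat([out, calls.reset_index(drop=True)], axis=1)
        out.to_csv(genotypes_path, index=False)
        self.loci.reset_index().rename(
            columns={self.loci.index.name or "index": "locus_id"}
        ).to_csv(loci_path, index=False)


@dataclass
class AlleleCountTable:
    """Long-format counts: one row per (locus, period) with A and T.

    ``A`` counts tracked alleles among genotyped individuals; ``T`` is the
    total number of alleles observed (2 x non-missing individuals).
    """

    table: pd.DataFrame  # columns: locus, period, A, T
    classes: pd.Series  # locus -> neutral/focal

    def __post_init__(self) -> None:
        t = self.table
        if not {"locus", "period", "A", "T"} <= set(t.columns):
            raise FormatError("count table needs locus, period, A, T columns")
        if ((t["A"] < 0) | (t["A"] > t["T"])).any():
            raise FormatError("allele counts must satisfy 0 <= A <= T")

    @property
    def periods(self) -> list[str]:
        return sorted(set(self.table["period"]), key=_period_sort_key)

    @property
    def loci(self) -> list[str]:
        return list(dict.fromkeys(self.table["locus"]))

    def restrict(self, cls: str) -> "AlleleCountTable":
        keep = [l for l in self.loci if self.classes.get(l) == cls]
        sub = self.table[self.table["locus"].isin(keep)].reset_index(drop=True)
        return AlleleCountTable(sub, self.classes[self.classes.index.isin(keep)])

    def matrix(self) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
        """Return (A, T) as loci x periods integer arrays (missing -> T=0)."""
        periods = self.periods
        loci = self.loci
        A = np.zeros((len(loci), len(periods)), dtype=np.int64)
        T = np.zeros_like(A)
        pos = {(l, p): None for l in loci for p in periods}
        li = {l: i for i, l in enumerate(loci)}
        pi = {p: j for j, p in enumerate(periods)}
        for _, row in self.table.iterrows():
            A[li[row["locus"]], pi[row["period"]]] = int(row["A"])
            T[li[row["locus"]], pi[row["period"]]] = int(row["T"])
        return A, T, loci, periods


@dataclass
class CatchTable:
    """Individual catch records; ``records`` has columns year, mass_kg and
    optionally date, sea_age, smolt_age, sex, origin, individual_id."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        r = self.records
        if not {"year", "mass_kg"} <= set(r.columns):
            raise FormatError("catch table needs year and mass_kg columns")
        bad = ~(r["mass_kg"] > 0)
        if bad.any():
            log.warning("dropping %d catch records with non-positive mass", bad.sum())
            self.records = r[~bad].reset_index(drop=True)

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.records["year"].unique())

    def restrict_years(self, years: Iterable[int]) -> "CatchTable":
        ys = set(int(y) for y in years)
        return CatchTable(
            self.records[self.records["year"].isin(ys)].reset_index(drop=True)
        )

    def write(self, path) -> None:
        cols = [
            c
            for c in (
                "individual_id",
                "year",
                "date",
                "mass_kg",
                "sea_age",
                "smolt_age",
                "sex",
                "origin",
            )
            if c in self.records.columns
        ]
        self.records[cols].to_csv(path, index=False)


@dataclass
class AnnualPhenotypeSeries:
    """Per-year summaries of ln mass (ln grams); years with no records carry
    NaN so data gaps stay explicit and contribute nothing downstream."""

    table: pd.DataFrame  # index: year; columns n, mean_ln_mass, se_ln_mass, mean_mass_kg

    @property
    def years(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def observed(self) -> pd.DataFrame:
        return self.table[self.table["n"] > 0]


@dataclass
class FlowSeries:
    """Annual June--September mean waterflow in m^3/s, contiguous in year."""

    flow: pd.Series  # index: year

    def __post_init__(self) -> None:
        if (self.flow <= 0).any():
            raise FormatError("waterflow must be positive")
        years = self.flow.index.to_numpy()
        if len(years) > 1 and not np.array_equal(
            years, np.arange(years[0], years[-1] + 1)
        ):
            raise FormatError("flow series must be contiguous in year")

    @property
    def ln_flow(self) -> pd.Series:
        return np.log(self.flow)

    def write(self, path) -> None:
        self.flow.rename("flow_m3s").rename_axis("year").reset_index().to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# readers


def _apply_mapping(df: pd.DataFrame, mapping: Mapping[str, str] | None) -> pd.DataFrame:
    if mapping:
        df = df.rename(columns={v: k for k, v in mapping.items()})
    return df


def read_genotypes(
    path,
    loci_path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> GenotypePanel:
    """Read the two-file genotype format (calls + locus metadata).

    ``column_map`` maps canonical metadata names (individual_id, period,
    sex, origin) to the headers actually present in the file.  Columns not
    named in the metadata set are treated as loci; call values other than
    0/1/2 become missing.
    """
    df = _apply_mapping(pd.read_csv(path, sep=sep, dtype=str), column_map)
    for col in ("individual_id", "period"):
        if col not in df.columns:
            raise FormatError(f"genotype file lacks mandatory column {col!r}")
    for col in ("sex", "origin"):
        if col not in df.columns:
            df[col] = "unknown"
    loci_df = _apply_mapping(pd.read_csv(loci_path, sep=sep, dtype=str), column_map)
    if not {"locus_id", "class"} <= set(loci_df.columns):
        raise FormatError("loci file needs locus_id and class columns")
    if "tracked_allele" not in loci_df.columns:
        loci_df["tracked_allele"] = ""
    loci_df = loci_df.set_index("locus_id")

    locus_cols = [c for c in df.columns if c not in _META_COLS and c != "date"]
    unknown = set(locus_cols) - set(loci_df.index)
    if unknown:
        raise FormatError(f"loci file lacks metadata for columns {sorted(unknown)}")
    calls = df[locus_cols].apply(pd.to_numeric, errors="coerce").astype(float)
    bad = ~(calls.isna() | calls.isin([0, 1, 2]))
    if bad.to_numpy().any():
        raise FormatError("non-biallelic genotype coding (calls must be 0/1/2)")
    individuals = df[list(_META_COLS)].set_index("individual_id")
    calls.index = individuals.index
    return GenotypePanel(individuals, calls, loci_df.loc[locus_cols])


def read_catch(path, column_map: Mapping[str, str] | None = None) -> CatchTable:
    df = _apply_mapping(pd.read_csv(path), column_map)
    if not {"year", "mass_kg"} <= set(df.columns):
        raise FormatError("catch file needs year and mass_kg columns")
    df["year"] = df["year"].astype(int)
    df["mass_kg"] = df["mass_kg"].astype(float)
    for col in ("sea_age", "smolt_age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return CatchTable(df)


def read_flow(path, column_map: Mapping[str, str] | None = None) -> FlowSeries:
    df = _apply_mapping(pd.read_csv(path), column_map)
    if not {"year", "flow_m3s"} <= set(df.columns):
        raise FormatError("flow file needs year and flow_m3s columns")
    s = df.set_index(df["year"].astype(int))["flow_m3s"].astype(float)
    return FlowSeries(s.sort_index())


# ---------------------------------------------------------------------------
# operations


def filter_call_rate(panel: GenotypePanel, min_rate: float) -> GenotypePanel:
    """Drop individuals whose non-missing call fraction is below ``min_rate``."""
    if not 0.0 <= min_rate <= 1.0:
        raise ValueError("min_rate must lie in [0, 1]")
    rate = panel.call_rate()
    keep = rate >= min_rate
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("call-rate filter removed %d of %d individuals", n_removed, len(keep))
    return panel.subset_individuals(panel.individuals.index[keep])


def count_alleles(panel: GenotypePanel, drop_fixed: bool = True) -> AlleleCountTable:
    """Tally tracked alleles per (locus, period).

    ``A`` sums calls over non-missing individuals; ``T = 2 x`` the number of
    non-missing individuals.  With ``drop_fixed``, loci fixed (A = 0 or
    A = T) in *every* period are removed.  A (locus, period) cell with no
    genotyped individual is kept with T = 0, flagging it missing.
    """
    if not panel.periods:
        raise FormatError("panel has no sampling periods")
    rows = []
    for locus in panel.calls.columns:
        col = panel.calls[locus]
        for period in panel.periods:
            sel = panel.individuals["period"] == period
            vals = col[sel].dropna()
            rows.append(
                {
                    "locus": locus,
                    "period": period,
                    "A": int(vals.sum()),
                    "T": 2 * len(vals),
                }
            )
    table = pd.DataFrame(rows)
    if drop_fixed:
        fixed = (
            table.assign(fix=(table["A"] == 0) | (table["A"] == table["T"]))
            .groupby("locus")["fix"]
            .all()
        )
        drop = set(fixed.index[fixed])
        if drop:
            log.info("dropping %d loci fixed in all periods", len(drop))
        table = table[~table["locus"].isin(drop)].reset_index(drop=True)
    classes = panel.loci["class"].copy()
    classes = classes[classes.index.isin(set(table["locus"]))]
    return AlleleCountTable(table, classes)


def annual_summary(
    catch: CatchTable, year_range: tuple[int, int] | None = None
) -> AnnualPhenotypeSeries:
    """Annual mean and SE of ln mass (mass converted kg -> g before logging).

    The mean is the mean of per-record ln values, not the ln of the mean.
    Years inside ``year_range`` with no records are kept with n = 0 and NaN
    summaries.  A single-record year has undefined SE (NaN).
    """
    r = catch.records
    if r.empty:
        raise FormatError("catch table has no usable records")
    ln_mass = np.log(r["mass_kg"].to_numpy() * 1000.0)
    df = pd.DataFrame({"year": r["year"].to_numpy(), "ln": ln_mass, "kg": r["mass_kg"]})
    g = df.groupby("year")
    out = pd.DataFrame(
        {
            "n": g["ln"].count(),
            "mean_ln_mass": g["ln"].mean(),
            "se_ln_mass": g["ln"].std(ddof=1) / np.sqrt(g["ln"].count()),
            "mean_mass_kg": g["kg"].mean(),
        }
    )
    if year_range is None:
        year_range = (int(out.index.min()), int(out.index.max()))
    full = pd.RangeIndex(year_range[0], year_range[1] + 1, name="year")
    out = out.reindex(full)
    out["n"] = out["n"].fillna(0).astype(int)
    return AnnualPhenotypeSeries(out)
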