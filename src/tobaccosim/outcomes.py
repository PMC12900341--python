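"""Aggregation of replication results into prevalence estimates.

Per replication and year, weighted prevalences are tabulated for the
reporting subgroups (US total, non-Hispanic Black, all other
race/ethnicities, below FPL, at/above FPL) and measures (each of the
five states, the cigarette-smoker aggregate, and the menthol share
among cigarette smokers). Across replications the point estimate is
the mean and the 95% uncertainty interval the empirical 2.5th-97.5th
percentile range (linear interpolation between order statistics).
All reported values are percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import TobaccoState
from .synthetic import BenchmarkSeries

SUBGROUPS = ["us_total", "non_hispanic_black", "other_race", "below_fpl", "at_above_fpl"]
MEASURES = [
    "cigarette",
    "menthol",
    "nonmenthol",
    "ecig_dual",
    "former",
    "never",
    "menthol_share",
]

_STATE_MEASURE = {
    "never": int(TobaccoState.NEVER),
    "former": int(TobaccoState.FORMER),
    "menthol": int(TobaccoState.MENTHOL),
    "nonmenthol": int(TobaccoState.NONMENTHOL),
    "ecig_dual": int(TobaccoState.ECIG_DUAL),
}


def _subgroup_mask(df: pd.DataFrame, subgroup: str) -> pd.Series:
    if subgroup == "us_total":
        return pd.Series(True, index=df.index)
    if subgroup == "non_hispanic_black":
        return df["race_group"] == "non_hispanic_black"
    if subgroup == "other_race":
        return df["race_group"] == "other"
    if subgroup == "below_fpl":
        return df["poverty"] == "below_fpl"
    if subgroup == "at_above_fpl":
        return df["poverty"] == "at_above_fpl"
    raise KeyError(f"unknown subgroup {subgroup!r}")


def tabulate(results, subgroups: list[str] | None = None) -> pd.DataFrame:
    """Per-replication prevalence rows.

    Returns a long frame with columns (rr_index, pop_index,
    seed_index, year, subgroup, measure, value). Values are
    percentages. Replication-years in which a subgroup has no living
    weight (or no cigarette smokers, for the menthol share) are
    omitted; the count of omitted rows is stored in
    ``frame.attrs['n_missing']``.
    """
    subgroups = subgroups or SUBGROUPS
    rows = []
    n_missing = 0
    for res in results:
        sw = res.state_weights
        for subgroup in subgroups:
            mask = _subgroup_mask(sw, subgroup)
            sub = sw[mask]
            pv = sub.pivot_table(
                index="year", columns="state", values="weight", aggfunc="sum"
            ).reindex(columns=[1, 2, 3, 4, 5], fill_value=0.0)
            total = pv.sum(axis=1)
            for year, tot in total.items():
                if tot <= 0:
                    n_missing += 1
                    continue
                vals = {
                    m: 100.0 * pv.loc[year, c] / tot for m, c in _STATE_MEASURE.items()
                }
                vals["cigarette"] = vals["menthol"] + vals["nonmenthol"]
                smokers = pv.loc[year, 3] + pv.loc[year, 4]
                if smokers > 0:
                    vals["menthol_share"] = 100.0 * pv.loc[year, 3] / smokers
                else:
                    n_missing += 1
                    vals["menthol_share"] = None
                for m, v in vals.items():
                    if v is None:
                        continue
                    rows.append(
                        {
                            "rr_index": res.rr_index,
                            "pop_index": res.pop_index,
                            "seed_index": res.seed_index,
                            "year": int(year),
                            "subgroup": subgroup,
                            "measure": m,
                            "value": float(v),
                        }
                    )
    out = pd.DataFrame(rows)
    out.attrs["n_missing"] = n_missing
    return out


@dataclass
class OutcomeTable:
    """Mean and 95% uncertainty interval per (year, subgroup, measure)."""

    data: pd.DataFrame  # columns: year, subgroup, measure, mean, ui_low, ui_high
    n_replications: int = 0
    notes: dict = field(default_factory=dict)

    def lookup(self, year: int, subgroup: str, measure: str) -> tuple[float, float, float]:
        row = self.data.query(
            "year == @year and subgroup == @subgroup and measure == @measure"
        )
        if len(row) != 1:
            raise KeyError((year, subgroup, measure))
        r = row.iloc[0]
        return float(r["mean"]), float(r["ui_low"]), float(r["ui_high"])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def aggregate(per_replication: pd.DataFrame) -> OutcomeTable:
    """Across-replication mean and empirical 95% uncertainty interval."""
    reps = per_replication[["rr_index", "pop_index", "seed_index"]].drop_duplicates()
    if len(reps) < 2:
        raise ValueError("aggregation needs at least two replications")

    def _agg(g: pd.Series) -> pd.Series:
        v = g.to_numpy()
        lo, hi = np.percentile(v, [2.5, 97.5], method="linear")
        return pd.Series({"mean": v.mean(), "ui_low": lo, "ui_high": hi})

    out = (
        per_replication.groupby(["year", "subgroup", "measure"])["value"]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    return OutcomeTable(out, n_replications=len(reps))


def compare_to_benchmark(
    table: OutcomeTable,
    benchmark: BenchmarkSeries,
    subgroup: str = "us_total",
    measure: str = "cigarette",
) -> pd.DataFrame:
    """Year-by-year validation of model prevalence against a benchmark.

    For every overlapping year: the model mean and UI, the benchmark
    estimate and CI (converted to percent), whether the model mean
    falls inside the benchmark CI, and whether the two intervals
    overlap. Summary counts live in ``report.attrs``.
    """
    model_years = set(table.data.query("subgroup == @subgroup and measure == @measure")["year"])
    years = sorted(model_years & set(benchmark.years))
    if not years:
        raise ValueError("no overlapping years between model and benchmark")
    bench = benchmark.data.set_index("year")
    rows = []
    for year in years:
        mean, lo, hi = table.lookup(year, subgroup, measure)
        b = bench.loc[year]
        b_est, b_lo, b_hi = (
            100 * float(b["prevalence"]),
            100 * float(b["ci_low"]),
            100 * float(b["ci_high"]),
        )
        contained = b_lo <= mean <= b_hi
        overlap = (lo <= b_hi) and (b_lo <= hi)
        rows.append(
            {
                "year": year,
                "model_mean": mean,
                "model_ui_low": lo,
                "model_ui_high": hi,
                "benchmark": b_est,
                "benchmark_ci_low": b_lo,
                "benchmark_ci_high": b_hi,
                "contained": contained,
                "overlap": overlap,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["n_years"] = len(report)
    report.attrs["n_contained"] = int(report["contained"].sum())
    report.attrs["n_overlap"] = int(report["overlap"].sum())
    return report
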