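"""Annual mortality risk with smoker-status adjustment.

Persons younger than 55 die with the plain life-table probability for
their age and sex. From age 55 on, the life-table probability is split
into status-specific rates using relative risks (RRs) for current and
former smokers and the population shares of never/former/current
smokers, such that the share-weighted average of the status-specific
rates reproduces the life-table value exactly:

    q(age, sex) = r_never * (p_never + sum_b p_former_b * RR_former_b
                                       + p_current * RR_current)

so ``r_never = q / mean_RR``. Former-smoker RRs depend on the number of
years since quitting, binned as <2, 2-4, 5-9, 10-19, 20-29, 30-39,
40-49 and >=50 years, and decline toward 1 with longer abstinence.
Menthol and non-menthol smokers share one current-smoker RR, and
e-cigarette/dual users are assigned the current-smoker RR as well.

Life tables come in three calendar regimes (2016, 2017, and 2018 for
2018 and every later year).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import CURRENT_USER_STATES, TobaccoState

#: Years-quit bins: (label, inclusive lower, exclusive upper).
YEARS_QUIT_BINS = [
    ("lt2", 0, 2),
    ("2-4", 2, 5),
    ("5-9", 5, 10),
    ("10-19", 10, 20),
    ("20-29", 20, 30),
    ("30-39", 30, 40),
    ("40-49", 40, 50),
    ("ge50", 50, np.inf),
]
_BIN_EDGES = np.array([b[1] for b in YEARS_QUIT_BINS[1:]])
BIN_LABELS = [b[0] for b in YEARS_QUIT_BINS]

ADJUSTED_MIN_AGE = 55
REGIMES = (2016, 2017, 2018)
_SEXES = ("female", "male")


def years_quit_bin(years_quit) -> np.ndarray:
    """Bin label index (0..7) for each years-quit value."""
    return np.digitize(np.asarray(years_quit), _BIN_EDGES)


def years_quit_bin_label(years_quit: int) -> str:
    return BIN_LABELS[int(years_quit_bin([years_quit])[0])]


@dataclass
class MortalityTable:
    """Annual death probability q by age, sex and life-table regime.

    ``data`` columns: age, sex, regime_year, q.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"age", "sex", "regime_year", "q"}
        if not need <= set(self.data.columns):
            raise ValueError(f"mortality table needs columns {sorted(need)}")
        if ((self.data["q"] < 0) | (self.data["q"] > 1)).any():
            raise ValueError("death probabilities must lie in [0, 1]")
        self._ages = np.sort(self.data["age"].unique())
        self._amin = int(self._ages.min())
        # q_array[regime][age - amin, sex_index]
        self._q = {}
        for regime in REGIMES:
            sub = self.data[self.data["regime_year"] == regime]
            arr = np.full((len(self._ages), 2), np.nan)
            for si, sex in enumerate(_SEXES):
                s = sub[sub["sex"] == sex].set_index("age")["q"]
                arr[:, si] = s.reindex(self._ages).to_numpy()
            if np.isnan(arr).any():
                raise ValueError(f"incomplete life table for regime {regime}")
            self._q[regime] = arr

    @staticmethod
    def regime_for_year(year: int) -> int:
        if year <= 2016:
            return 2016
        if year == 2017:
            return 2017
        return 2018

    def q(self, age: int, sex: str, year: int) -> float:
        return float(
            self._q[self.regime_for_year(year)][int(age) - self._amin, _SEXES.index(sex)]
        )

    def q_vector(self, ages, male, year: int) -> np.ndarray:
        ages = np.asarray(ages, dtype=int)
        sexidx = np.asarray(male, dtype=int)
        return self._q[self.regime_for_year(year)][ages - self._amin, sexidx]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MortalityTable":
        return cls(pd.read_csv(path))


def _age_group_of(age: int, groups: list[str]) -> str:
    for g in groups:
        lo, hi = g.split("-")
        if int(lo) <= age <= int(hi):
            return g
    raise KeyError(f"age {age} not covered by RR age groups {groups}")


@dataclass
class SmokingMortalityAdjustment:
    """Status-specific death rates for ages 55+ per life-table regime.

    ``rates[regime]`` is an array of shape (n_ages, 2 sexes, 10 slots)
    over ages ``ADJUSTED_MIN_AGE..max_age``; slot 0 is never, slot 1
    current (shared by menthol, non-menthol and e-cig/dual), slots 2-9
    the former-smoker years-quit bins in order. Rates are capped at 1
    (with a warning recorded in ``capped_cells``).
    """

    rates: dict[int, np.ndarray]
    max_age: int
    capped_cells: list[tuple] = None  # type: ignore[assignment]

    def rate(self, age: int, sex: str, slot: int, year: int) -> float:
        regime = MortalityTable.regime_for_year(year)
        return float(self.rates[regime][age - ADJUSTED_MIN_AGE, _SEXES.index(sex), slot])


def solve_adjusted_rates(
    table: MortalityTable,
    rr_table: pd.DataFrame,
    prevalence: pd.DataFrame,
) -> SmokingMortalityAdjustment:
    """Solve status-specific rates conserving the life-table average.

    ``rr_table`` columns: age_group, sex, status, years_quit_bin, rr
    (plus optional CI columns); ``prevalence`` columns: age_group,
    sex, status, years_quit_bin, share, with shares summing to 1 within
    each (age_group, sex). Implied rates above 1 are capped at 1 and
    reported; conservation then no longer holds exactly for those
    cells, which is recorded rather than re-solved.
    """
    groups = sorted(rr_table["age_group"].unique())
    max_age = max(int(g.split("-")[1]) for g in groups)
    rates = {}
    capped: list[tuple] = []
    for regime in REGIMES:
        arr = np.zeros((max_age - ADJUSTED_MIN_AGE + 1, 2, 2 + len(BIN_LABELS)))
        for si, sex in enumerate(_SEXES):
            for g in groups:
                cell = (rr_table["age_group"] == g) & (rr_table["sex"] == sex)
                rr_cur = float(rr_table.loc[cell & (rr_table["status"] == "current"), "rr"].iloc[0])
                former_rr = rr_table.loc[cell & (rr_table["status"] == "former")]
                rr_by_bin = former_rr.set_index("years_quit_bin")["rr"]
                rr_former = [float(rr_by_bin[b]) for b in BIN_LABELS]
                pcell = (prevalence["age_group"] == g) & (prevalence["sex"] == sex)
                prev = prevalence.loc[pcell]
                p_never = float(prev.loc[prev["status"] == "never", "share"].sum())
                p_cur = float(prev.loc[prev["status"] == "current", "share"].sum())
                fprev = prev.loc[prev["status"] == "former"].set_index("years_quit_bin")["share"]
                p_former = [float(fprev.get(b, 0.0)) for b in BIN_LABELS]
                total = p_never + p_cur + sum(p_former)
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"prevalence shares for ({g}, {sex}) sum to {total}, not 1"
                    )
                mean_rr = p_never + p_cur * rr_cur + sum(
                    p * r for p, r in zip(p_former, rr_former)
                )
                lo, hi = (int(x) for x in g.split("-"))
                for age in range(max(lo, ADJUSTED_MIN_AGE), hi + 1):
                    q = table.q(age, sex, regime)
                    r_never = q / mean_rr
                    row = [r_never, r_never * rr_cur] + [r_never * r for r in rr_former]
                    for slot, val in enumerate(row):
                        if val > 1.0:
                            capped.append((regime, age, sex, slot, val))
                            warnings.warn(
                                f"status-specific rate {val:.3f} capped at 1 for "
                                f"(age {age}, {sex}, slot {slot})",
                                stacklevel=2,
                            )
                            row[slot] = 1.0
                    arr[age - ADJUSTED_MIN_AGE, si, :] = row
        rates[regime] = arr
    return SmokingMortalityAdjustment(rates=rates, max_age=max_age, capped_cells=capped)


_CURRENT_CODES = np.array([int(s) for s in sorted(CURRENT_USER_STATES)])


def death_probabilities(
    ages,
    male,
    state_current,
    years_quit,
    year: int,
    table: MortalityTable,
    adjustment: SmokingMortalityAdjustment,
) -> np.ndarray:
    """Vectorized annual death probability for each person."""
    ages = np.asarray(ages, dtype=int)
    male = np.asarray(male, dtype=int)
    cur = np.asarray(state_current, dtype=int)
    yq = np.asarray(years_quit, dtype=int)

    out = table.q_vector(ages, male, year)
    old = ages >= ADJUSTED_MIN_AGE
    if old.any():
        former = cur == int(TobaccoState.FORMER)
        if (former & old & (yq < 1)).any():
            raise ValueError("former smokers must carry years_quit >= 1")
        slot = np.ones(len(ages), dtype=int)  # default: current-smoker slot
        slot[cur == int(TobaccoState.NEVER)] = 0
        slot[former] = 2 + years_quit_bin(yq[former])
        regime = MortalityTable.regime_for_year(year)
        arr = adjustment.rates[regime]
        out = out.copy()
        out[old] = arr[ages[old] - ADJUSTED_MIN_AGE, male[old], slot[old]]
    return out


def death_probability(
    person,
    year: int,
    adjustment: SmokingMortalityAdjustment,
    table: MortalityTable,
) -> float:
    """Annual death probability of one :class:`PersonRecord`."""
    if not person.alive:
        raise ValueError("death probability is defined for living persons")
    if person.state_current is TobaccoState.FORMER and person.years_quit < 1:
        raise ValueError("former smoker without years_quit")
    return float(
        death_probabilities(
            [person.age],
            [person.sex == "male"],
            [int(person.state_current)],
            [person.years_quit],
            year,
            table,
            adjustment,
        )[0]
    )


def draw_rr_set(rr_table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """One sampled RR set from the fixture's 95% confidence intervals.

    Each RR is drawn from the lognormal whose 2.5/97.5 percent
    quantiles match the CI bounds (a degenerate CI returns the point
    value). After sampling, former-smoker RRs within each (age group,
    sex) are repaired to be non-increasing in years quit (running
    minimum over the bin order) and floored at 1.
    """
    out = rr_table.copy().reset_index(drop=True)
    mu = np.log(out["rr"].to_numpy())
    lo = out["ci_low"].to_numpy()
    hi = out["ci_high"].to_numpy()
    sigma = np.where(hi > lo, (np.log(hi) - np.log(lo)) / (2 * 1.959963984540054), 0.0)
    draws = np.exp(mu + sigma * rng.standard_normal(len(out)))
    never = out["status"] == "never"
    draws[never.to_numpy()] = 1.0
    out["rr"] = draws

    order = {b: i for i, b in enumerate(BIN_LABELS)}
    former = out[out["status"] == "former"]
    for (g, sex), sub in former.groupby(["age_group", "sex"]):
        sub = sub.sort_values("years_quit_bin", key=lambda s: s.map(order))
        vals = np.minimum.accumulate(sub["rr"].to_numpy())
        out.loc[sub.index, "rr"] = np.maximum(vals, 1.0)
    out.loc[out["status"] == "current", "rr"] = np.maximum(
        out.loc[out["status"] == "current", "rr"], 1.0
    )
    return out
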