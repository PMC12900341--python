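"""Simulated population: person records, weighting, and population dynamics.

A :class:`Population` is a columnar container (backed by a pandas
DataFrame) of person-level records. Each record carries fixed
demographics, a survey weight (the number of real-world persons the
record represents), the current and prior-year tobacco-use states that
drive the second-order transition model, and a years-since-quit counter
for former smokers.

This module also implements the population-level operations of the
simulator: building the initial population from a longitudinal panel,
calibrating weights to an external smoking-prevalence benchmark,
injecting annual cohorts of 18-year-olds, retiring persons who age out
of the 18-64 reporting range, and weighted-bootstrap resampling for the
uncertainty design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import CIGARETTE_STATES, TobaccoState

SEX_VALUES = ("male", "female")
RACE_VALUES = ("non_hispanic_black", "other")
POVERTY_VALUES = ("below_fpl", "at_above_fpl")
INIT_AGE_VALUES = ("not_smoking", "lt18", "ge18")

#: Column order of the serialized population CSV.
POPULATION_COLUMNS = [
    "person_id",
    "age",
    "sex",
    "race_group",
    "poverty",
    "init_age_cat",
    "state_prior",
    "state_current",
    "years_quit",
    "weight",
]

MIN_AGE = 18
MAX_AGE = 64


@dataclass
class PersonRecord:
    """One simulated individual.

    ``years_quit`` is meaningful only when ``state_current`` is FORMER
    (then it is >= 1); it is 0 otherwise. ``weight`` is the survey
    weight: the number of population persons this record represents.
    """

    person_id: str
    age: int
    sex: str
    race_group: str
    poverty: str
    init_age_cat: str
    state_prior: TobaccoState
    state_current: TobaccoState
    years_quit: int = 0
    weight: float = 1.0
    alive: bool = True

    def __post_init__(self) -> None:
        self.state_prior = TobaccoState(self.state_prior)
        self.state_current = TobaccoState(self.state_current)
        _validate_record(self)


def _validate_record(rec: PersonRecord) -> None:
    if rec.weight <= 0:
        raise ValueError("weight must be positive")
    if rec.age < MIN_AGE:
        raise ValueError(f"age must be >= {MIN_AGE}")
    if rec.sex not in SEX_VALUES:
        raise ValueError(f"sex must be one of {SEX_VALUES}")
    if rec.race_group not in RACE_VALUES:
        raise ValueError(f"race_group must be one of {RACE_VALUES}")
    if rec.poverty not in POVERTY_VALUES:
        raise ValueError(f"poverty must be one of {POVERTY_VALUES}")
    if rec.init_age_cat not in INIT_AGE_VALUES:
        raise ValueError(f"init_age_cat must be one of {INIT_AGE_VALUES}")
    if rec.state_current is TobaccoState.NEVER and rec.state_prior is not TobaccoState.NEVER:
        raise ValueError("a current never smoker must also have prior state NEVER")
    if rec.state_current is TobaccoState.FORMER:
        if rec.years_quit < 1:
            raise ValueError("years_quit must be >= 1 for a former smoker")
    elif rec.years_quit != 0:
        raise ValueError("years_quit must be 0 unless state_current is FORMER")


@dataclass
class Population:
    """Weighted collection of persons at a single reference year.

    ``data`` holds one row per person with the columns of
    :data:`POPULATION_COLUMNS` plus a boolean ``alive`` column. Dead
    persons are retained for audit but excluded from every tally.
    """

    data: pd.DataFrame
    reference_year: int

    def __post_init__(self) -> None:
        df = self.data
        if "alive" not in df.columns:
            df = df.assign(alive=True)
        self.data = df.reset_index(drop=True)
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: list[PersonRecord], reference_year: int) -> "Population":
        df = pd.DataFrame(
            {
                "person_id": [r.person_id for r in records],
                "age": np.array([r.age for r in records], dtype=np.int32),
                "sex": [r.sex for r in records],
                "race_group": [r.race_group for r in records],
                "poverty": [r.poverty for r in records],
                "init_age_cat": [r.init_age_cat for r in records],
                "state_prior": np.array([int(r.state_prior) for r in records], dtype=np.int8),
                "state_current": np.array(
                    [int(r.state_current) for r in records], dtype=np.int8
                ),
                "years_quit": np.array([r.years_quit for r in records], dtype=np.int32),
                "weight": np.array([r.weight for r in records], dtype=np.float64),
                "alive": [r.alive for r in records],
            }
        )
        return cls(df, reference_year)

    def iter_records(self):
        for row in self.data.itertuples(index=False):
            yield PersonRecord(
                person_id=row.person_id,
                age=int(row.age),
                sex=row.sex,
                race_group=row.race_group,
                poverty=row.poverty,
                init_age_cat=row.init_age_cat,
                state_prior=TobaccoState(row.state_prior),
                state_current=TobaccoState(row.state_current),
                years_quit=int(row.years_quit),
                weight=float(row.weight),
                alive=bool(row.alive),
            )

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        if df["person_id"].duplicated().any():
            raise ValueError("person_ids must be unique")
        if (df["weight"] <= 0).any():
            raise ValueError("all weights must be positive")
        if (df["age"] < MIN_AGE).any():
            raise ValueError(f"all ages must be >= {MIN_AGE}")
        never = df["state_current"] == int(TobaccoState.NEVER)
        if (df.loc[never, "state_prior"] != int(TobaccoState.NEVER)).any():
            raise ValueError("current never smokers must have prior state NEVER")
        former = df["state_current"] == int(TobaccoState.FORMER)
        if (df.loc[former, "years_quit"] < 1).any():
            raise ValueError("former smokers must carry years_quit >= 1")
        if (df.loc[~former, "years_quit"] != 0).any():
            raise ValueError("years_quit defined only for former smokers")

    # -- summaries -----------------------------------------------------

    def __len__(self) -> int:
        return int(self.data["alive"].sum())

    @property
    def living(self) -> pd.DataFrame:
        return self.data[self.data["alive"]]

    @property
    def total_weight(self) -> float:
        return float(self.living["weight"].sum())

    def smoking_prevalence(self, include_ecig_dual: bool = False) -> float:
        """Weighted share of living persons who currently smoke cigarettes.

        The default aggregate is MENTHOL + NONMENTHOL, matching the
        cigarette-prevalence definition of the cross-sectional survey
        benchmarks; ``include_ecig_dual`` folds ECIG_DUAL in as well.
        """
        live = self.living
        if len(live) == 0:
            return float("nan")
        codes = {int(s) for s in CIGARETTE_STATES}
        if include_ecig_dual:
            codes.add(int(TobaccoState.ECIG_DUAL))
        mask = live["state_current"].isin(codes)
        return float(live.loc[mask, "weight"].sum() / live["weight"].sum())

    def copy(self) -> "Population":
        return Population(self.data.copy(), self.reference_year)

    # -- serialization -------------------------------------------------

    def to_csv(self, path) -> None:
        self.living[POPULATION_COLUMNS].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, reference_year: int) -> "Population":
        df = pd.read_csv(path, dtype={"person_id": str})
        missing = set(POPULATION_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"population CSV missing columns: {sorted(missing)}")
        df = df[POPULATION_COLUMNS].copy()
        df["alive"] = True
        return cls(df, reference_year)


# ---------------------------------------------------------------------
# Population dynamics
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class WeightCalibration:
    """Multiplicative weight adjustment to hit a smoking-prevalence target.

    ``smoker_factor`` multiplies the weights of current cigarette
    smokers and ``nonsmoker_factor`` those of everyone else; the factors
    are the closed-form pair that moves the weighted prevalence exactly
    to ``target_prevalence`` while conserving the total weight.
    """

    target_prevalence: float
    smoker_factor: float
    nonsmoker_factor: float


@dataclass
class CohortSpec:
    """Specification of one year's entering cohort of 18-year-olds.

    ``state_distribution`` maps state -> share at age 18 (sums to 1);
    ``prior_state_distribution`` maps state-at-18 -> {state-at-17:
    conditional share}. A NEVER 18-year-old always has prior NEVER.
    ``demographic_mix`` maps (sex, race_group, poverty) marginal shares
    for entrants (each a dict name -> share).
    """

    year: int
    entry_weight: float
    state_distribution: dict[TobaccoState, float]
    prior_state_distribution: dict[TobaccoState, dict[TobaccoState, float]]
    demographic_mix: dict[str, dict[str, float]] = field(default_factory=dict)
    n_entrants: int = 500

    def __post_init__(self) -> None:
        tot = sum(self.state_distribution.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("state_distribution shares must sum to 1")
        for state, cond in self.prior_state_distribution.items():
            if abs(sum(cond.values()) - 1.0) > 1e-9:
                raise ValueError("conditional prior-state shares must sum to 1")
            if TobaccoState(state) is TobaccoState.NEVER:
                if cond.get(TobaccoState.NEVER, 0.0) != 1.0:
                    raise ValueError("prior state must be NEVER when current is NEVER")


def build_initial_population(
    panel,
    reference_wave: int,
    reference_year: int = 2016,
    rng: np.random.Generator | None = None,
    mean_baseline_years_quit: float = 12.0,
) -> Population:
    """Build the starting population from a weighted longitudinal panel.

    For each panel person the state at ``reference_wave`` becomes
    ``state_current``, the state at the preceding wave becomes
    ``state_prior``, demographics are taken at wave 1, and the survey
    weight is carried over unchanged.

    For former smokers, ``years_quit`` is the count of consecutive
    observed FORMER waves ending at the reference wave; a person who is
    FORMER at every observed wave additionally receives a pre-panel quit
    duration drawn from a geometric distribution with the given mean
    (the panel itself cannot say how long ago a long-quit person
    stopped). Pass a seeded ``rng`` for reproducibility; with
    ``rng=None`` the pre-panel duration is its integer mean.
    """
    df = panel.data
    waves = sorted(df["wave"].unique())
    if reference_wave not in waves or (reference_wave - 1) not in waves:
        raise ValueError(
            f"reference wave {reference_wave} and its predecessor must be in the panel"
        )
    if len(df) == 0:
        return Population(pd.DataFrame(columns=POPULATION_COLUMNS), reference_year)

    wide = df.pivot(index="person_id", columns="wave", values="state")
    missing = wide[[w for w in waves if w <= reference_wave]].isna().any(axis=1)
    if missing.any():
        raise ValueError("all persons must be observed in every wave up to the reference")

    base = df[df["wave"] == 1].set_index("person_id")
    base = base.loc[wide.index]

    state_current = wide[reference_wave].astype(int)
    state_prior = wide[reference_wave - 1].astype(int)

    # consecutive FORMER waves ending at the reference wave
    runs = np.zeros(len(wide), dtype=np.int64)
    always_former = np.ones(len(wide), dtype=bool)
    still = np.ones(len(wide), dtype=bool)
    for w in range(reference_wave, 0, -1):
        is_f = wide[w].to_numpy() == int(TobaccoState.FORMER)
        still &= is_f
        runs += still.astype(np.int64)
        always_former &= is_f
    former_now = state_current.to_numpy() == int(TobaccoState.FORMER)
    years_quit = np.where(former_now, runs, 0)
    n_always = int((former_now & always_former).sum())
    if n_always:
        mean_extra = max(mean_baseline_years_quit - reference_wave, 0.0)
        if rng is None:
            extra = np.full(n_always, int(round(mean_extra)))
        else:
            p = 1.0 / (mean_extra + 1.0)
            extra = rng.geometric(p, size=n_always) - 1
        years_quit = years_quit.copy()
        years_quit[former_now & always_former] += np.minimum(extra, 60)

    out = pd.DataFrame(
        {
            "person_id": wide.index.astype(str),
            "age": (base["age"].to_numpy() + (reference_wave - 1)).astype(np.int32),
            "sex": base["sex"].to_numpy(),
            "race_group": base["race_group"].to_numpy(),
            "poverty": base["poverty"].to_numpy(),
            "init_age_cat": base["init_age_cat"].to_numpy(),
            "state_prior": state_prior.to_numpy().astype(np.int8),
            "state_current": state_current.to_numpy().astype(np.int8),
            "years_quit": years_quit.astype(np.int32),
            "weight": base["weight"].to_numpy().astype(np.float64),
        }
    )
    return Population(out, reference_year)


def calibrate_weights(
    pop: Population,
    target_prevalence: float,
    include_ecig_dual: bool = False,
) -> tuple[Population, WeightCalibration]:
    """Rescale weights so the weighted cigarette prevalence hits a target.

    The closed-form factors are ``a = target * W / W_s`` for smokers and
    ``b = (1 - target) * W / W_n`` for non-smokers (W, W_s, W_n the
    total, smoker and non-smoker weight sums), which hit the target
    exactly while conserving the total weight exactly.
    """
    if not (0.0 < target_prevalence < 1.0):
        raise ValueError("target_prevalence must be in (0, 1)")
    df = pop.data
    codes = {int(s) for s in CIGARETTE_STATES}
    if include_ecig_dual:
        codes.add(int(TobaccoState.ECIG_DUAL))
    smoker = df["state_current"].isin(codes) & df["alive"]
    nonsmoker = ~df["state_current"].isin(codes) & df["alive"]
    w_total = float(df.loc[df["alive"], "weight"].sum())
    w_s = float(df.loc[smoker, "weight"].sum())
    w_n = float(df.loc[nonsmoker, "weight"].sum())
    if w_s == 0 or w_n == 0:
        raise ValueError("calibration needs at least one smoker and one non-smoker")
    a = target_prevalence * w_total / w_s
    b = (1.0 - target_prevalence) * w_total / w_n
    new = df.copy()
    new.loc[smoker, "weight"] *= a
    new.loc[nonsmoker, "weight"] *= b
    return (
        Population(new, pop.reference_year),
        WeightCalibration(target_prevalence, a, b),
    )


def _draw_categorical(rng: np.random.Generator, values, probs, size: int) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(values), size=size, p=probs)
    return np.asarray(values, dtype=object)[idx]


def inject_cohort(
    pop: Population, spec: CohortSpec, rng: np.random.Generator
) -> Population:
    """Add one year's entering cohort of 18-year-olds.

    ``spec.n_entrants`` synthetic persons are added with equal weights
    summing to ``spec.entry_weight``, states drawn from the cohort state
    distribution, prior (age-17) states from the conditional prior
    distribution, and demographics from the entering-cohort mix.
    """
    n = spec.n_entrants
    if n <= 0:
        return pop
    states = list(spec.state_distribution)
    shares = [spec.state_distribution[s] for s in states]
    cur = _draw_categorical(rng, [int(s) for s in states], shares, n).astype(np.int8)
    prior = np.empty(n, dtype=np.int8)
    for s_idx, s in enumerate([int(s) for s in states]):
        mask = cur == s
        k = int(mask.sum())
        if k == 0:
            continue
        cond = spec.prior_state_distribution[TobaccoState(s)]
        pv = list(cond)
        prior[mask] = _draw_categorical(
            rng, [int(p) for p in pv], [cond[p] for p in pv], k
        ).astype(np.int8)

    mix = spec.demographic_mix
    sex_mix = mix.get("sex", {"male": 0.5, "female": 0.5})
    race_mix = mix.get("race_group", {"non_hispanic_black": 0.14, "other": 0.86})
    pov_mix = mix.get("poverty", {"below_fpl": 0.18, "at_above_fpl": 0.82})
    sex = _draw_categorical(rng, list(sex_mix), list(sex_mix.values()), n)
    race = _draw_categorical(rng, list(race_mix), list(race_mix.values()), n)
    pov = _draw_categorical(rng, list(pov_mix), list(pov_mix.values()), n)

    ever = cur != int(TobaccoState.NEVER)
    init_cat = np.where(ever, "lt18", "not_smoking").astype(object)
    # entrants who initiated exactly at 18 (current use new this year)
    new_at_18 = ever & (prior == int(TobaccoState.NEVER))
    init_cat[new_at_18] = "ge18"

    former = cur == int(TobaccoState.FORMER)
    years_quit = np.where(former, 1, 0).astype(np.int32)

    entrants = pd.DataFrame(
        {
            "person_id": [f"cohort{spec.year}_{i}" for i in range(n)],
            "age": np.full(n, 18, dtype=np.int32),
            "sex": sex,
            "race_group": race,
            "poverty": pov,
            "init_age_cat": init_cat,
            "state_prior": prior,
            "state_current": cur,
            "years_quit": years_quit,
            "weight": np.full(n, spec.entry_weight / n, dtype=np.float64),
            "alive": True,
        }
    )
    merged = pd.concat([pop.data, entrants], ignore_index=True)
    return Population(merged, pop.reference_year)


def retire_aged_out(pop: Population) -> tuple[Population, float]:
    """Drop persons older than the 64-year reporting ceiling.

    Returns the trimmed population and the living weight removed
    (recorded as aged-out, not dead).
    """
    df = pop.data
    out = (df["age"] > MAX_AGE) & df["alive"]
    aged_out_weight = float(df.loc[out, "weight"].sum())
    kept = df[df["age"] <= MAX_AGE].reset_index(drop=True)
    return Population(kept, pop.reference_year), aged_out_weight


def resample_population(pop: Population, rng: np.random.Generator) -> Population:
    """Weighted bootstrap variant of the population.

    Samples persons with replacement with probability proportional to
    weight and resets every weight to total/n, producing an equally
    sized variant with the same total weight. Used to build the initial
    population versions of the uncertainty design.
    """
    df = pop.living
    n = len(df)
    if n == 0:
        raise ValueError("cannot resample an empty population")
    w = df["weight"].to_numpy()
    probs = w / w.sum()
    idx = rng.choice(n, size=n, replace=True, p=probs)
    new = df.iloc[idx].reset_index(drop=True).copy()
    new["person_id"] = [f"bs{i}" for i in range(n)]
    new["weight"] = w.sum() / n
    return Population(new, pop.reference_year)
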