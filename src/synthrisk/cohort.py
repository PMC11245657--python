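"""Synthetic multi-region population with suicide outcomes.

The generator emulates the statistical structure of a provincial health
administrative cohort: ~18 health regions with strongly varying suicide
rates, sex-specific yearly rates (males declining from 27 to 20 per 100,000
across 2002-2019, females stable near 6-7 per 100,000), lookback-window
event predictors, deprivation quantiles, and case-control sampling with a
1% yearly control fraction.

Outcomes are drawn from a *known* logistic model: for every person-year a
candidate index date is drawn uniformly within the year, the lookback
predictors are evaluated at that date, and suicide occurs with probability
``invlogit(b0 + beta . x + region_offset)``.  A suicide terminates the
person's panel.  Between-predictor dependence comes from a single latent
severity factor per person; regional heterogeneity is covariate-mediated
(regions shift the severity mean, rurality and deprivation) with an
optional direct regional intercept offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .features import EventIndex, assign_quantile_groups

SEXES = ("male", "female")


@dataclass(frozen=True)
class EventProcess:
    """Per-year occurrence model for one event type.

    Yearly occurrence probability for a person with latent severity ``z`` is
    ``invlogit(base_logit + severity_loading * z)``; the event date is
    uniform within the year.
    """

    base_logit: float
    severity_loading: float


@dataclass
class RegionEffects:
    """Region-level parameters (arrays of length n_regions).

    ``severity_shift`` moves the latent severity mean of the region's
    residents (covariate-mediated risk); ``intercept_offset`` is a direct
    shift of the outcome logit (zero by default, so that an individual-level
    model without region terms can in principle explain all regional
    variation); ``budget_per_capita`` feeds the ``regional_budget`` covariate.
    """

    population_share: np.ndarray
    severity_shift: np.ndarray
    rural_fraction: np.ndarray
    deprivation_shift: np.ndarray
    budget_per_capita: np.ndarray
    intercept_offset: np.ndarray

    def validate(self, n_regions: int) -> None:
        for name in (
            "population_share",
            "severity_shift",
            "rural_fraction",
            "deprivation_shift",
            "budget_per_capita",
            "intercept_offset",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n_regions,):
                raise ValueError(f"region_effects.{name} must have length {n_regions}")
            setattr(self, name, arr)
        if not np.isclose(self.population_share.sum(), 1.0):
            raise ValueError("population shares must sum to 1")
        if (self.population_share <= 0).any():
            raise ValueError("population shares must be positive")
        if ((self.rural_fraction < 0) | (self.rural_fraction > 1)).any():
            raise ValueError("rural fractions must lie in [0,1]")


@dataclass
class PopulationConfig:
    """Full parameterisation of the simulated world."""

    n_persons: int
    seed: int
    n_regions: int = 18
    years: tuple[int, int] = (2002, 2019)
    sex_mix: float = 0.49  # male fraction
    #: per-100,000 yearly suicide rate schedule, per sex
    baseline_rate_by_sex_year: dict[str, dict[int, float]] = field(default_factory=dict)
    #: per-sex named coefficients on the population scale; key "Intercept"
    #: may be a float (used as-is) or None (calibrated each year so the
    #: sex-year marginal rate matches the schedule)
    true_coefficients: dict[str, dict[str, float | None]] = field(default_factory=dict)
    event_process_params: dict[str, EventProcess] = field(default_factory=dict)
    region_effects: RegionEffects | None = None
    missingness_rates: dict[str, float] = field(default_factory=dict)
    control_fraction: float = 0.01

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError(f"invalid year range {self.years}")
        if not 0 <= self.sex_mix <= 1:
            raise ValueError("sex_mix must lie in [0,1]")
        if not 0 < self.control_fraction <= 1:
            raise ValueError("control_fraction must lie in (0,1]")
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        for sex, sched in self.baseline_rate_by_sex_year.items():
            for year, rate in sched.items():
                if rate < 0:
                    raise ValueError(f"negative rate for {sex} {year}")
                if not y0 <= year <= y1:
                    raise ValueError(f"rate year {year} outside {self.years}")
        for rates in self.missingness_rates.values():
            if not 0 <= rates < 1:
                raise ValueError("missingness rates must lie in [0,1)")
        if self.region_effects is not None:
            self.region_effects.validate(self.n_regions)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def _default_region_effects(n_regions: int = 18) -> RegionEffects:
    """The stated world's regional structure: one large metropolitan region,
    several mid-size regions, and a handful of small northern regions with
    much higher latent severity (hence much higher suicide rates)."""
    share = np.array(
        [0.25, 0.12, 0.10, 0.08, 0.07, 0.06, 0.05, 0.04, 0.04, 0.035,
         0.03, 0.025, 0.02, 0.02, 0.015, 0.015, 0.015, 0.015]
    )
    severity = np.array(
        [-0.35, -0.15, -0.10, -0.05, 0.00, 0.00, 0.05, 0.05, 0.10, 0.15,
         0.20, 0.25, 0.40, 0.60, 0.80, 1.05, 1.40, 1.90]
    )
    rural = np.array(
        [0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45,
         0.50, 0.55, 0.60, 0.70, 0.80, 0.85, 0.90, 0.95]
    )
    deprivation = np.array(
        [-0.20, -0.10, -0.05, 0.00, 0.00, 0.05, 0.05, 0.10, 0.10, 0.15,
         0.15, 0.20, 0.25, 0.30, 0.40, 0.50, 0.70, 0.90]
    )
    budget = np.array(
        [380.0, 340.0, 320.0, 310.0, 300.0, 295.0, 290.0, 285.0, 280.0, 275.0,
         270.0, 265.0, 255.0, 245.0, 235.0, 225.0, 210.0, 195.0]
    )
    if n_regions != 18:
        raise ValueError("default region effects are defined for 18 regions")
    return RegionEffects(
        population_share=share,
        severity_shift=severity,
        rural_fraction=rural,
        deprivation_shift=deprivation,
        budget_per_capita=budget,
        intercept_offset=np.zeros(18),
    )


def _default_rate_schedule(years: tuple[int, int]) -> dict[str, dict[int, float]]:
    """Males decline linearly 27 -> 20 per 100,000 over 2002-2019; females
    are stable at 6.5 per 100,000."""
    y0, y1 = years
    male = {}
    for y in range(y0, y1 + 1):
        frac = (y - 2002) / (2019 - 2002)
        male[y] = float(np.clip(27.0 - 7.0 * frac, 20.0, 27.0))
    female = {y: 6.5 for y in range(y0, y1 + 1)}
    return {"male": male, "female": female}


#: per-year occurrence models for every base event type referenced by the
#: reference coefficient tables.  Mental-health service contacts and
#: psychiatric diagnoses load strongly on the latent severity factor;
#: somatic diagnoses only weakly.  "Rural town" is residence, handled via
#: the regional rural fraction rather than an occurrence process.
DEFAULT_EVENT_PROCESSES: dict[str, EventProcess] = {
    "Hospitalisation for Suicide attempt": EventProcess(-5.2, 1.3),
    "Emergency room visits for Physical health reasons": EventProcess(-1.7, 0.4),
    "Emergency room visits for mental health reasons": EventProcess(-3.4, 1.1),
    "Outpatient psychiatrist visits for mental health reasons": EventProcess(-3.1, 1.1),
    "Outpatient GP visits for Physical health reasons": EventProcess(0.3, 0.15),
    "Outpatient GP visits for mental health reasons": EventProcess(-2.2, 0.9),
    "Psychotherapy visits with a GP": EventProcess(-3.0, 0.8),
    "Hospitalisation for Physical health reasons": EventProcess(-2.4, 0.3),
    "Hospitalisation for mental health reasons": EventProcess(-4.0, 1.2),
    # continuous days-of-stay in the source tables; modelled as occurrence
    "Duration of hospitalisation for Physical health reasons": EventProcess(-2.4, 0.3),
    "Mood and anxiety disorders": EventProcess(-2.6, 1.1),
    "Bipolar disorders": EventProcess(-4.5, 1.0),
    "Substance use disorders": EventProcess(-3.4, 1.2),
    "Personality disorders": EventProcess(-4.2, 1.2),
    "Dementia": EventProcess(-4.8, 0.1),
    "Respiratory disorders": EventProcess(-2.2, 0.2),
    "Other mental disorders": EventProcess(-3.0, 0.9),
    "Symptoms, Signs and Ill-defined Conditions": EventProcess(-1.5, 0.3),
    "Non-intentional trauma": EventProcess(-2.8, 0.5),
    "Infectious disease": EventProcess(-2.0, 0.2),
    "Endocrine system disorder": EventProcess(-2.6, 0.2),
    "Genito-urinary disorders": EventProcess(-2.4, 0.2),
    "Cancer": EventProcess(-3.8, 0.1),
}

#: per-variable missing fractions within the documented 0.87%-4.12% band
DEFAULT_MISSINGNESS = {
    "Material deprivation_2": 0.0412,
    "Material deprivation_3": 0.0412,
    "Rural town_60m": 0.0145,
    "Rural town_48m": 0.0097,
    "Charlson score": 0.0087,
}


def default_true_coefficients() -> dict[str, dict[str, float | None]]:
    """True data-generating coefficients: the packaged reference models,
    with intercepts left to per-year calibration against the rate schedule."""
    from .io import load_fixture_model

    out: dict[str, dict[str, float | None]] = {}
    for sex in SEXES:
        spec = load_fixture_model(sex)
        coefs: dict[str, float | None] = {"Intercept": None}
        coefs.update(spec.coefficients)
        out[sex] = coefs
    return out


def default_config(n_persons: int = 500_000, seed: int = 0, **overrides) -> PopulationConfig:
    """The package's stated world; see docs/methods.md for parameter rationale."""
    years = overrides.pop("years", (2002, 2019))
    schedule = overrides.pop("baseline_rate_by_sex_year", _default_rate_schedule(years))
    cfg = PopulationConfig(
        n_persons=n_persons,
        seed=seed,
        years=years,
        baseline_rate_by_sex_year=schedule,
        true_coefficients=overrides.pop("true_coefficients", default_true_coefficients()),
        event_process_params=overrides.pop(
            "event_process_params", dict(DEFAULT_EVENT_PROCESSES)
        ),
        region_effects=_default_region_effects(),
        missingness_rates=overrides.pop("missingness_rates", dict(DEFAULT_MISSINGNESS)),
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class PersonPanel:
    """Person-year records plus the companion long-format event table.

    ``rows`` has one record per person per year while the person is alive
    (a suicide terminates the panel); ``events`` holds (person_id,
    event_type, event_date) with dates as fractional years.
    """

    rows: pd.DataFrame
    events: pd.DataFrame
    config: PopulationConfig | None = None

    def __post_init__(self) -> None:
        self._event_index: EventIndex | None = None

    @property
    def event_index(self) -> EventIndex:
        if self._event_index is None:
            self._event_index = EventIndex(self.events)
        return self._event_index

    @property
    def years(self) -> list[int]:
        ys = np.unique(self.rows["year"].to_numpy())
        return [int(y) for y in ys]

    def __len__(self) -> int:
        return len(self.rows)

    def region_population(self, year: int, sex: str | None = None) -> pd.Series:
        rows = self.rows[self.rows["year"] == year]
        if sex is not None:
            rows = rows[rows["sex"] == sex]
        return rows.groupby("region_id", observed=True).size()

    def to_dir(self, path) -> None:
        from .io import atomic_write_csv

        atomic_write_csv(self.rows, f"{path}/panel.csv")
        atomic_write_csv(self.events, f"{path}/events.csv")

    @classmethod
    def from_dir(cls, path) -> "PersonPanel":
        rows = pd.read_csv(f"{path}/panel.csv")
        events = pd.read_csv(f"{path}/events.csv")
        return cls(rows=rows, events=events)


@dataclass
class CaseControlSample:
    """Case-control subset of a panel: all cases plus sampled controls."""

    rows: pd.DataFrame  # includes 'label' in {case, control} and sampling_year
    event_index: EventIndex

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_cases(self) -> int:
        return int((self.rows["label"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.rows["label"] == "control").sum())


# ---------------------------------------------------------------------------
# generation


def _calibrate_intercept(linear_predictor: np.ndarray, target_rate: float) -> float:
    """Intercept c with mean(invlogit(c + s)) equal to the target prevalence."""
    if target_rate <= 0:
        return -np.inf
    s = linear_predictor

    def f(c: float) -> float:
        return float(expit(c + s).mean() - target_rate)

    return float(brentq(f, -40.0, 10.0, xtol=1e-12))


def generate_population(config: PopulationConfig) -> PersonPanel:
    """Simulate the panel: persons, event histories, and yearly outcomes."""
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    y0, y1 = config.years
    re_ = config.region_effects or _default_region_effects(config.n_regions)
    re_.validate(config.n_regions)

    # --- static person attributes -------------------------------------
    person_id = np.arange(n, dtype=np.int64)
    sex_male = rng.random(n) < config.sex_mix
    region = rng.choice(config.n_regions, size=n, p=re_.population_share)
    age0 = np.clip(rng.normal(45.0, 19.0, size=n), 15.0, 95.0)
    z = rng.normal(re_.severity_shift[region], 1.0)
    rural = rng.random(n) < re_.rural_fraction[region]
    charlson = rng.poisson(0.25 * np.exp(0.3 * np.clip(z, 0, None))).astype(np.int8)
    dep_soc = 0.45 * z + rng.normal(re_.deprivation_shift[region], 1.0)
    dep_mat = 0.45 * z + rng.normal(re_.deprivation_shift[region], 1.0)
    dep_soc_q = assign_quantile_groups(dep_soc, 5).astype(np.int8)
    dep_mat_q = assign_quantile_groups(dep_mat, 5).astype(np.int8)

    # --- event histories (5 burn-in years for the 60m windows) ---------
    burn0 = y0 - 5
    ev_pid, ev_code, ev_date = [], [], []
    event_types = list(config.event_process_params) + ["Rural town"]
    for code, name in enumerate(event_types):
        if name == "Rural town":
            # residence state: one event per year for rural residents
            ids = person_id[rural]
            for year in range(burn0, y1 + 1):
                ev_pid.append(ids)
                ev_code.append(np.full(ids.size, code, dtype=np.int16))
                ev_date.append(np.full(ids.size, year + 0.5))
            continue
        proc = config.event_process_params[name]
        p = expit(proc.base_logit + proc.severity_loading * z)
        for year in range(burn0, y1 + 1):
            hit = rng.random(n) < p
            ids = person_id[hit]
            ev_pid.append(ids)
            ev_code.append(np.full(ids.size, code, dtype=np.int16))
            ev_date.append(year + rng.random(ids.size))
    events = pd.DataFrame(
        {
            "person_id": np.concatenate(ev_pid),
            "event_type": pd.Categorical.from_codes(
                np.concatenate(ev_code), categories=event_types
            ),
            "event_date": np.concatenate(ev_date),
        }
    )
    event_index = EventIndex(events)

    # --- yearly outcomes from the true logistic model ------------------
    from .features import compute_predictor_columns

    budget = {
        (r, y): re_.budget_per_capita[r] * (1 + 0.01 * (y - y0))
        for r in range(config.n_regions)
        for y in range(y0, y1 + 1)
    }
    alive = np.ones(n, dtype=bool)
    chunks = []
    for year in range(y0, y1 + 1):
        idx_date = year + rng.random(n)
        live = np.flatnonzero(alive)
        rows = pd.DataFrame(
            {
                "person_id": person_id[live],
                "year": np.int16(year),
                "sex": np.where(sex_male[live], "male", "female"),
                "age": (age0[live] + (year - y0)).astype(np.float32),
                "region_id": (region[live] + 1).astype(np.int8),
                "deprivation_social": dep_soc_q[live],
                "deprivation_material": dep_mat_q[live],
                "charlson": charlson[live],
                "regional_budget": np.array(
                    [budget[(r, year)] for r in region[live]], dtype=np.float32
                ),
                "index_date": idx_date[live],
            }
        )
        outcome = np.zeros(len(rows), dtype=np.int8)
        for sex in SEXES:
            m = (rows["sex"] == sex).to_numpy()
            if not m.any():
                continue
            coefs = dict(config.true_coefficients.get(sex, {"Intercept": -np.inf}))
            b0 = coefs.pop("Intercept", None)
            names = list(coefs)
            sub = rows.loc[m]
            x = compute_predictor_columns(
                sub, event_index, sub["index_date"].to_numpy(), names
            )
            s = x.to_numpy() @ np.array([coefs[k] for k in names])
            s = s + re_.intercept_offset[sub["region_id"].to_numpy() - 1]
            if b0 is None:
                target = config.baseline_rate_by_sex_year[sex][year] / 1e5
                b0 = _calibrate_intercept(s, target)
            p = expit(b0 + s)
            outcome[m] = rng.random(m.sum()) < p
        rows["outcome"] = outcome
        chunks.append(rows)
        alive[live[outcome == 1]] = False

    panel_rows = pd.concat(chunks, ignore_index=True)
    panel = PersonPanel(rows=panel_rows, events=events, config=config)
    panel._event_index = event_index
    return panel


def sample_case_control(
    panel: PersonPanel,
    year_range: tuple[int, int],
    control_fraction: float | None = None,
    seed: int | None = None,
) -> CaseControlSample:
    """All suicide cases in the year range plus a yearly random sample of
    living individuals as controls; a person can serve as a control once."""
    if control_fraction is None:
        control_fraction = panel.config.control_fraction if panel.config else 0.01
    if control_fraction <= 0 or control_fraction > 1:
        raise ValueError("control_fraction must lie in (0,1]")
    years = panel.years
    if year_range[0] < years[0] or year_range[1] > years[-1]:
        raise ValueError(f"year_range {year_range} outside panel years {years[0]}-{years[-1]}")
    if seed is None:
        seed = (panel.config.seed + 1) if panel.config else 0
    rng = np.random.default_rng(seed)

    rows = panel.rows
    in_range = (rows["year"] >= year_range[0]) & (rows["year"] <= year_range[1])
    cases = rows[in_range & (rows["outcome"] == 1)].copy()
    cases["label"] = "case"
    cases["sampling_year"] = cases["year"]

    taken: set[int] = set()
    control_chunks = []
    for year in range(year_range[0], year_range[1] + 1):
        living = rows[(rows["year"] == year) & (rows["outcome"] == 0)]
        if taken:
            living = living[~living["person_id"].isin(taken)]
        pick = rng.random(len(living)) < control_fraction
        chosen = living[pick].copy()
        taken.update(chosen["person_id"].tolist())
        chosen["label"] = "control"
        chosen["sampling_year"] = year
        control_chunks.append(chosen)
    controls = pd.concat(control_chunks, ignore_index=True) if control_chunks else cases.iloc[:0]
    out = pd.concat([cases, controls], ignore_index=True)
    return CaseControlSample(rows=out, event_index=panel.event_index)


def split_train_validation(
    panel: PersonPanel, split_year: int
) -> tuple[PersonPanel, PersonPanel]:
    """Partition the panel by year: train < split_year <= validation."""
    years = panel.years
    if not years[0] < split_year <= years[-1]:
        raise ValueError(
            f"split_year {split_year} must lie strictly inside {years[0]}-{years[-1]}"
        )
    train_mask = panel.rows["year"] < split_year
    train = PersonPanel(
        rows=panel.rows[train_mask].reset_index(drop=True),
        events=panel.events,
        config=panel.config,
    )
    valid = PersonPanel(
        rows=panel.rows[~train_mask].reset_index(drop=True),
        events=panel.events,
        config=panel.config,
    )
    train._event_index = panel.event_index
    valid._event_index = panel.event_index
    return train, valid
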