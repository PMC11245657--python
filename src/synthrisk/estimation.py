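"""Model-based synthetic estimation of regional suicide risk.

A fitted individual-level logistic model is converted into a region-level
estimator in two stages: (1) each model predictor is aggregated over the
region's population — the within-region *proportion* for binary/indicator
predictors, the within-region *mean* for continuous ones; (2) the model
coefficients are applied to these aggregates, giving a regional logit that
is converted into a probability (the synthetic estimate of the region's
suicide risk), and then a rate per 100,000.

Two methodological points deserve attention:

* **Intercept correction.**  A case-control design that keeps all cases and
  a fraction ``f`` of non-cases inflates the intercept by ``ln(1/f)``;
  before population-scale prediction the intercept must be shifted by
  ``ln(f)`` (:func:`intercept_correction`).  Slopes are unaffected.
* **Jensen gap.**  The synthetic estimate evaluates the inverse-logit at
  the *mean* covariates rather than averaging individual probabilities;
  :func:`jensen_gap_diagnostic` quantifies the resulting approximation,
  which vanishes as slopes shrink or regions become homogeneous.

Lookback windows are evaluated for everyone at a common per-year reference
date (December 31), since regionwide aggregates need a common clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import EventIndex, WindowSpec, compute_predictor_columns
from .model import ModelSpec


@dataclass
class RegionProfile:
    """Per region/year/sex covariate aggregates for one model."""

    region_id: int
    year: int
    sex: str
    aggregates: dict[str, float]
    population_count: int

    def __post_init__(self) -> None:
        if self.population_count <= 0:
            raise ValueError("population_count must be positive")
        for name, v in self.aggregates.items():
            if WindowSpec.parse(name) is not None and not 0 <= v <= 1:
                raise ValueError(f"indicator aggregate {name!r}={v} outside [0,1]")


@dataclass
class RegionEstimate:
    """Synthetic regional risk estimate on the population scale."""

    region_id: int
    year: int
    sex: str
    logit_value: float
    probability: float = field(default=None)  # type: ignore[assignment]
    rate_per_100k: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        p = float(expit(self.logit_value))
        if self.probability is None:
            self.probability = p
        elif not math.isclose(self.probability, p, rel_tol=1e-12, abs_tol=1e-15):
            raise ValueError("probability must equal inverse-logit(logit_value)")
        r = self.probability * 1e5
        if self.rate_per_100k is None:
            self.rate_per_100k = r
        elif not math.isclose(self.rate_per_100k, r, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("rate_per_100k must equal probability * 100,000")


def _population_rows(panel, year: int, sex: str) -> pd.DataFrame:
    rows = panel.rows
    return rows[(rows["year"] == year) & (rows["sex"] == sex)]


def _region_design(
    rows: pd.DataFrame, event_index: EventIndex, model: ModelSpec, year: int
) -> pd.DataFrame:
    """Per-person predictor values at the December 31 reference date."""
    ref = np.full(len(rows), year + 1.0)
    return compute_predictor_columns(rows, event_index, ref, model.predictors)


def aggregate_region_profile(
    panel, model: ModelSpec, year: int, sex: str
) -> list[RegionProfile]:
    """Stage one: aggregate every model predictor by region.

    The aggregation population is the full panel population of that
    year/sex (not the outcome-enriched case-control sample).  Raises if any
    region of the panel has no eligible person.
    """
    rows = _population_rows(panel, year, sex)
    all_regions = sorted(panel.rows["region_id"].unique())
    present = set(rows["region_id"].unique())
    empty = [int(r) for r in all_regions if r not in present]
    if empty:
        raise ValueError(f"regions with zero eligible persons in {year}/{sex}: {empty}")
    design = _region_design(rows, panel.event_index, model, year)
    design = design.assign(region_id=rows["region_id"].to_numpy())
    grouped = design.groupby("region_id", observed=True)
    means = grouped.mean()
    counts = grouped.size()
    return [
        RegionProfile(
            region_id=int(rid),
            year=year,
            sex=sex,
            aggregates={k: float(means.loc[rid, k]) for k in model.predictors},
            population_count=int(counts.loc[rid]),
        )
        for rid in means.index
    ]


def intercept_correction(model: ModelSpec) -> ModelSpec:
    """Move the intercept from the case-control to the population scale.

    With sampling fraction ``f`` the corrected intercept is
    ``b0 + ln(f)`` (a decrease of ``ln(1/f)``); slopes are unchanged and
    ``f = 1`` is the identity.  The returned spec has ``f = 1`` so the
    correction is idempotent.
    """
    f = model.control_sampling_fraction
    if not 0 < f <= 1:
        raise ValueError("control_sampling_fraction must lie in (0,1]")
    if f == 1.0:
        return model
    return replace(
        model,
        intercept=model.intercept + math.log(f),
        control_sampling_fraction=1.0,
        metadata={**model.metadata, "intercept_corrected": True, "original_f": f},
        display_rows=None,
    )


def predict_region(profile: RegionProfile, model: ModelSpec) -> RegionEstimate:
    """Stage two: apply the coefficients to the regional aggregates."""
    eta = float(model.linear_predictor(profile.aggregates))
    return RegionEstimate(
        region_id=profile.region_id, year=profile.year, sex=profile.sex, logit_value=eta
    )


def jensen_gap_diagnostic(
    panel, model: ModelSpec, region_id: int, year: int, sex: str
) -> tuple[float, float, float]:
    """(mean individual probability, probability at mean covariates, gap).

    The gap is the intrinsic approximation of synthetic estimation; it is
    exactly zero for a degenerate (homogeneous) region and shrinks with the
    slope magnitudes.
    """
    rows = _population_rows(panel, year, sex)
    rows = rows[rows["region_id"] == region_id]
    if len(rows) == 0:
        raise ValueError(f"region {region_id} has no eligible persons in {year}/{sex}")
    design = _region_design(rows, panel.event_index, model, year)
    p_ind = float(np.mean(model.predict_probability(design)))
    p_agg = float(expit(model.linear_predictor({k: float(design[k].mean()) for k in design})))
    return p_ind, p_agg, p_ind - p_agg


class SyntheticEstimator:
    """Region-level synthetic estimator derived from a fitted model.

    By default the case-control intercept is corrected to the population
    scale on construction (logged in ``spec.metadata``); pass
    ``correct_intercept=False`` only when the supplied model is already on
    the population scale.
    """

    def __init__(self, model: ModelSpec, correct_intercept: bool = True):
        self.source_spec = model
        self.spec = intercept_correction(model) if correct_intercept else model
        self.intercept_corrected = correct_intercept and model.control_sampling_fraction < 1

    def predict_profiles(self, profiles: list[RegionProfile]) -> list[RegionEstimate]:
        return [predict_region(p, self.spec) for p in profiles]

    def predict_panel(
        self, panel, years=None, sex: str | None = None
    ) -> pd.DataFrame:
        """Regional estimates for every requested panel year.

        Returns a tidy frame (region_id, year, sex, logit, probability,
        rate_per_100k, population_count).
        """
        sexes = [sex] if sex else ["male", "female"]
        years = list(years) if years is not None else panel.years
        records = []
        for s in sexes:
            for year in years:
                profiles = aggregate_region_profile(panel, self.spec, year, s)
                for prof, est in zip(profiles, self.predict_profiles(profiles)):
                    records.append(
                        {
                            "region_id": est.region_id,
                            "year": year,
                            "sex": s,
                            "logit": est.logit_value,
                            "probability": est.probability,
                            "rate_per_100k": est.rate_per_100k,
                            "population_count": prof.population_count,
                        }
                    )
        return pd.DataFrame(records)
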