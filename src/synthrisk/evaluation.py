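"""Validation of regional risk forecasts against observed suicide rates.

Predicted and observed regional rates are compared with three indicators:
mean absolute error (MAE), root mean square error (RMSE), and the top-k
overlap — the fraction of the k observed highest-risk regions that the
model also places in its own top k.  MAE/RMSE are computed on rates per
1,000 population by default (configurable), and the unit is always carried
in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import SyntheticEstimator
from .model import ModelSpec

_UNIT_DIV = {"per_1000": 100.0, "per_100k": 1.0}  # divisor applied to per-100k rates


def observed_rates(
    panel, year: int, sex: str | None = None, by_region: bool = True
) -> pd.Series | float:
    """Observed suicide rate per 100,000: cases / population x 1e5."""
    rows = panel.rows
    rows = rows[rows["year"] == year]
    if sex is not None:
        rows = rows[rows["sex"] == sex]
    if len(rows) == 0:
        raise ValueError(f"zero population for {year}/{sex}")
    if by_region:
        grouped = rows.groupby("region_id", observed=True)
        pop = grouped.size()
        cases = grouped["outcome"].sum()
        return (cases / pop * 1e5).rename("rate_per_100k")
    return float(rows["outcome"].sum() / len(rows) * 1e5)


def mae(predicted, observed) -> float:
    """Mean absolute difference."""
    p, o = _paired(predicted, observed)
    return float(np.mean(np.abs(p - o)))


def rmse(predicted, observed) -> float:
    """Root mean squared difference."""
    p, o = _paired(predicted, observed)
    return float(np.sqrt(np.mean((p - o) ** 2)))


def _paired(predicted, observed):
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size == 0:
        raise ValueError("empty input")
    return p, o


def top_k_overlap(predicted_rates: pd.Series, observed_rates_: pd.Series, k: int = 5) -> float:
    """|top-k(predicted) intersect top-k(observed)| / k.

    Both inputs are rate vectors indexed by region; ties are broken
    deterministically by rate descending then region identifier ascending.
    """
    pred = pd.Series(predicted_rates)
    obs = pd.Series(observed_rates_)
    if set(pred.index) != set(obs.index):
        raise ValueError("predicted and observed must cover identical regions")
    if len(pred) < k:
        raise ValueError(f"need at least k={k} regions, got {len(pred)}")

    def topk(s: pd.Series) -> set:
        order = sorted(s.index, key=lambda r: (-s[r], r))
        return set(order[:k])

    return len(topk(pred) & topk(obs)) / k


def subgroup_validation(
    panel,
    model: ModelSpec,
    age_bands: list[tuple[float, float]],
    year: int,
    sex: str,
    correct_intercept: bool = True,
) -> pd.DataFrame:
    """Observed vs synthetic-predicted rates within age subgroups.

    ``age_bands`` are inclusive-exclusive [lo, hi) intervals that must be
    disjoint; the synthetic aggregation is restricted to each band.  Empty
    bands yield a flagged row rather than an error.
    """
    for i, (lo, hi) in enumerate(age_bands):
        if hi <= lo:
            raise ValueError(f"invalid age band {age_bands[i]}")
        for lo2, hi2 in age_bands[i + 1 :]:
            if lo < hi2 and lo2 < hi:
                raise ValueError("age bands must be disjoint")
    est = SyntheticEstimator(model, correct_intercept=correct_intercept)
    rows_all = panel.rows
    records = []
    for lo, hi in age_bands:
        mask = (
            (rows_all["year"] == year)
            & (rows_all["sex"] == sex)
            & (rows_all["age"] >= lo)
            & (rows_all["age"] < hi)
        )
        sub_rows = rows_all[mask]
        label = f"{lo:g}-{hi:g}"
        if len(sub_rows) == 0:
            records.append(
                {"age_band": label, "n": 0, "observed_per_100k": np.nan,
                 "predicted_per_100k": np.nan, "abs_diff_per_100k": np.nan, "empty": True}
            )
            continue
        sub_panel = type(panel)(rows=sub_rows.reset_index(drop=True), events=panel.events,
                                config=panel.config)
        sub_panel._event_index = panel.event_index
        obs = observed_rates(sub_panel, year, sex, by_region=False)
        pred_df = est.predict_panel(sub_panel, years=[year], sex=sex)
        w = pred_df["population_count"]
        pred = float(np.average(pred_df["rate_per_100k"], weights=w))
        records.append(
            {"age_band": label, "n": int(len(sub_rows)), "observed_per_100k": obs,
             "predicted_per_100k": pred, "abs_diff_per_100k": abs(obs - pred),
             "empty": False}
        )
    return pd.DataFrame(records)


@dataclass
class EvalReport:
    """Yearly regional-forecast evaluation.

    ``metrics`` mirrors the year x sex table of MAE, RMSE and top-k overlap;
    ``yearly_rates`` holds provincial observed vs predicted rates per
    100,000; ``regional`` the per-region detail.
    """

    metrics: pd.DataFrame
    yearly_rates: pd.DataFrame
    regional: pd.DataFrame
    unit: str
    k: int
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Regional suicide-risk forecast evaluation (MAE/RMSE unit: {self.unit}; "
            f"top-{self.k} overlap)",
            "denominator: simulated region-year panel population",
        ]
        for flag in self.flags:
            lines.append(f"FLAG: {flag}")
        lines.append(self.metrics.to_string(index=False))
        return "\n".join(lines)

    def to_dir(self, path) -> None:
        from .io import atomic_write_csv

        atomic_write_csv(self.metrics, f"{path}/metrics.csv")
        atomic_write_csv(self.yearly_rates, f"{path}/yearly_rates.csv")
        atomic_write_csv(self.regional, f"{path}/regional.csv")


def yearly_report(
    panel_train,
    panel_valid,
    models: dict[str, ModelSpec],
    k: int = 5,
    unit: str = "per_1000",
    correct_intercept: bool = True,
) -> EvalReport:
    """Apply the synthetic estimators to every year of both panels and
    tabulate MAE, RMSE and top-k overlap per year and sex."""
    if unit not in _UNIT_DIV:
        raise ValueError(f"unknown unit {unit!r}")
    div = _UNIT_DIV[unit]
    missing_sex = {"male", "female"} - set(models)
    if missing_sex:
        raise ValueError(f"models must cover both sexes; missing {sorted(missing_sex)}")
    metrics_rows, rate_rows, regional_rows, flags = [], [], [], []
    for period, panel in (("development", panel_train), ("validation", panel_valid)):
        if panel is None or len(panel.rows) == 0:
            continue
        for sex, spec in models.items():
            est = SyntheticEstimator(spec, correct_intercept=correct_intercept)
            pred_df = est.predict_panel(panel, sex=sex)
            for year in panel.years:
                py = pred_df[pred_df["year"] == year].set_index("region_id")
                if len(py) == 0:
                    flags.append(f"no regional estimate for {year}/{sex}")
                    continue
                obs = observed_rates(panel, year, sex, by_region=True)
                obs = obs.reindex(py.index)
                pred = py["rate_per_100k"]
                w = py["population_count"]
                metrics_rows.append(
                    {
                        "period": period,
                        "year": year,
                        "sex": sex,
                        "mae": mae(pred / div, obs / div),
                        "rmse": rmse(pred / div, obs / div),
                        "top_k_overlap": top_k_overlap(pred, obs, k=k),
                    }
                )
                obs_prov = float(np.average(obs, weights=w))
                pred_prov = float(np.average(pred, weights=w))
                rate_rows.append(
                    {
                        "period": period,
                        "year": year,
                        "sex": sex,
                        "observed_per_100k": obs_prov,
                        "predicted_per_100k": pred_prov,
                        "abs_diff_per_100k": abs(obs_prov - pred_prov),
                    }
                )
                for rid in py.index:
                    regional_rows.append(
                        {
                            "period": period,
                            "year": year,
                            "sex": sex,
                            "region_id": int(rid),
                            "observed_per_100k": float(obs[rid]),
                            "predicted_per_100k": float(pred[rid]),
                            "abs_diff_per_100k": float(abs(obs[rid] - pred[rid])),
                            "population_count": int(w[rid]),
                        }
                    )
    return EvalReport(
        metrics=pd.DataFrame(metrics_rows),
        yearly_rates=pd.DataFrame(rate_rows),
        regional=pd.DataFrame(regional_rows),
        unit=unit,
        k=k,
        flags=flags,
    )
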