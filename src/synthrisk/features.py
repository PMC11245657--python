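"""Predictor derivation from event histories.

The individual-level suicide model uses three kinds of predictors:

* binary *lookback-window* indicators — did an event of a given type
  (hospitalisation for a suicide attempt, an emergency-room visit, a
  mood/anxiety diagnosis, ...) occur within a fixed number of months before
  the person's index date;
* continuous covariates (age in years, Charlson comorbidity score, regional
  mental-health budget);
* ordinal area-deprivation quantile groups, entered as dummy columns.

Dates are represented throughout as fractional calendar years (2005.37 is
mid-May 2005); a window of ``w`` months is ``w / 12`` years.  The window is
half-open on the left: an event counts iff it falls in
``(index_date - w, index_date]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Lookback windows (months) that appear in the published coefficient tables.
ALLOWED_WINDOWS = (3, 6, 12, 24, 36, 48, 60)

_WINDOW_RE = re.compile(r"^(?P<base>.+?)\s*_(?P<months>\d+)m$")


@dataclass(frozen=True)
class WindowSpec:
    """A lookback-window predictor: ``event_type`` within ``window_months``."""

    event_type: str
    window_months: int

    def __post_init__(self) -> None:
        if self.window_months <= 0:
            raise ValueError("window_months must be positive")
        if self.window_months not in ALLOWED_WINDOWS:
            raise ValueError(
                f"window_months must be one of {ALLOWED_WINDOWS}, "
                f"got {self.window_months}"
            )

    @property
    def name(self) -> str:
        """Canonical predictor name, e.g. ``suicide_attempt_hosp_60m``."""
        return f"{self.event_type}_{self.window_months}m"

    @classmethod
    def parse(cls, name: str) -> "WindowSpec | None":
        """Parse a canonical ``<event_type>_<w>m`` name; None if not one."""
        m = _WINDOW_RE.match(name)
        if m is None:
            return None
        months = int(m.group("months"))
        if months not in ALLOWED_WINDOWS:
            return None
        return cls(m.group("base"), months)


def derive_window_indicator(history, index_date: float, spec: WindowSpec) -> int:
    """Indicator that >=1 event of ``spec.event_type`` occurred in the window.

    ``history`` is an iterable of ``(event_type, event_date)`` pairs (dates in
    fractional years).  Returns 1 iff an event of the requested type lies in
    ``(index_date - w, index_date]``.  An empty history gives 0; a history
    that never mentions the event type at all raises ``KeyError`` only when
    ``strict`` bookkeeping is needed upstream — here absence simply means 0,
    but an event type containing no parseable name is rejected.
    """
    if not spec.event_type:
        raise ValueError("unknown event_type: empty name")
    lo = index_date - spec.window_months / 12.0
    for event_type, date in history:
        if event_type == spec.event_type and lo < date <= index_date:
            return 1
    return 0


class EventIndex:
    """Sorted per-type event index for vectorised lookback-window queries.

    Built once from a long-format event table (person_id, event_type,
    event_date); answers "did person *i* have an event of type *t* in
    ``(d_i - w, d_i]``" for whole arrays of persons/index dates at once via
    ``searchsorted`` on a composite (person, date) key.
    """

    # composite key = person_id * _SPAN + (date - _DATE0); dates must lie in
    # [_DATE0, _DATE0 + _SPAN)
    _DATE0 = 1900.0
    _SPAN = 256.0

    def __init__(self, events: pd.DataFrame):
        self._keys: dict[str, np.ndarray] = {}
        if len(events) == 0:
            return
        dates = events["event_date"].to_numpy(dtype=np.float64)
        if dates.min() < self._DATE0 or dates.max() >= self._DATE0 + self._SPAN:
            raise ValueError("event dates outside supported range 1900-2156")
        for event_type, grp in events.groupby("event_type", sort=False, observed=True):
            pid = grp["person_id"].to_numpy(dtype=np.float64)
            d = grp["event_date"].to_numpy(dtype=np.float64)
            key = pid * self._SPAN + (d - self._DATE0)
            key.sort()
            self._keys[str(event_type)] = key

    @property
    def event_types(self) -> list[str]:
        return list(self._keys)

    def window_indicator(
        self,
        event_type: str,
        person_ids: np.ndarray,
        index_dates: np.ndarray,
        window_months: int,
    ) -> np.ndarray:
        """Vector of {0,1}: any event of ``event_type`` in the half-open window."""
        person_ids = np.asarray(person_ids, dtype=np.float64)
        index_dates = np.asarray(index_dates, dtype=np.float64)
        keys = self._keys.get(event_type)
        if keys is None:
            return np.zeros(len(person_ids), dtype=np.int8)
        base = person_ids * self._SPAN - self._DATE0
        lo = np.searchsorted(keys, base + index_dates - window_months / 12.0, side="right")
        hi = np.searchsorted(keys, base + index_dates, side="right")
        return (hi > lo).astype(np.int8)


def assign_quantile_groups(
    scores, n_groups: int = 5, norms=None
) -> np.ndarray:
    """Map continuous scores to ordinal groups 1..n_groups by reference cuts.

    Cut points are the ``1/n_groups`` quantiles of ``norms`` (the population
    reference distribution); group 1 is the lowest-score (most privileged)
    band and scores below the reference minimum clamp to group 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty scores")
    if norms is None:
        norms = scores
    norms = np.asarray(norms, dtype=float)
    if norms.size == 0:
        raise ValueError("empty reference distribution")
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    qs = np.quantile(norms, np.linspace(0, 1, n_groups + 1)[1:-1])
    return (np.searchsorted(qs, scores, side="left") + 1).astype(np.int64)


@dataclass
class FeatureMatrix:
    """Design matrix aligned to a case-control sample, with a missingness mask.

    ``data`` holds the predictor columns (NaN where missing); ``mask`` is a
    boolean frame of identical shape, True where the entry is missing.
    """

    data: pd.DataFrame
    mask: pd.DataFrame = None  # type: ignore[assignment]
    outcome: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.data.isna()
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ValueError("duplicate column names in feature matrix")
        if not self.data.columns.equals(self.mask.columns):
            raise ValueError("mask columns must match data columns")

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


#: published display names -> panel column names
COLUMN_ALIASES = {
    "Age": "age",
    "Charlson score": "charlson",
    "Regional mental budget": "regional_budget",
    "Material deprivation": "deprivation_material",
    "Social deprivation": "deprivation_social",
}

_DUMMY_RE = re.compile(r"^(?P<base>.+?)\s*_(?P<group>[1-9])$")


def _resolve_column(rows: pd.DataFrame, name: str) -> str | None:
    if name in rows.columns:
        return name
    alias = COLUMN_ALIASES.get(name)
    return alias if alias is not None and alias in rows.columns else None


def compute_predictor_columns(
    rows: pd.DataFrame,
    event_index: EventIndex,
    index_dates: np.ndarray,
    predictors: list[str],
) -> pd.DataFrame:
    """Evaluate named predictors for panel ``rows`` at per-row index dates.

    Window-suffixed names (``*_<w>m``) are looked up in the event index;
    quantile-group dummies (``Material deprivation_2``,
    ``deprivation_social_4``, ...) come from the stored ordinal groups;
    anything else must be a column of ``rows``, directly or through the
    published-name aliases in :data:`COLUMN_ALIASES`.
    """
    pid = rows["person_id"].to_numpy()
    out = {}
    for name in predictors:
        spec = WindowSpec.parse(name)
        if spec is not None:
            out[name] = event_index.window_indicator(
                spec.event_type, pid, index_dates, spec.window_months
            ).astype(float)
            continue
        col = _resolve_column(rows, name)
        if col is not None:
            out[name] = rows[col].to_numpy(dtype=float)
            continue
        dummy = _DUMMY_RE.match(name)
        if dummy is not None:
            base = _resolve_column(rows, dummy.group("base"))
            if base is not None:
                grp = rows[base].to_numpy()
                out[name] = (grp == int(dummy.group("group"))).astype(float)
                continue
        raise KeyError(f"cannot derive predictor {name!r}")
    return pd.DataFrame(out, index=rows.index)


def build_feature_matrix(
    sample,
    window_specs: list[WindowSpec] = (),
    continuous: list[str] = (),
    ordinal: dict[str, int] | None = None,
    missingness: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> FeatureMatrix:
    """Build the design matrix for a case-control sample.

    Parameters
    ----------
    sample
        A ``CaseControlSample`` (rows carry person_id, index_date, covariate
        columns) or any object with ``rows`` / ``event_index`` attributes.
    window_specs
        Lookback-window indicator predictors.
    continuous
        Names of continuous covariate columns to carry over.
    ordinal
        Mapping ordinal column -> number of groups; each is expanded to
        dummy columns ``<col>_2 .. <col>_G`` (group 1 is the reference).
    missingness
        Per-column missing fractions to inject (set to NaN and masked);
        requires ``rng``.
    """
    window_specs = list(window_specs)
    names = [s.name for s in window_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate window predictor names")
    rows = sample.rows
    idx_dates = rows["index_date"].to_numpy(dtype=float)
    predictors = names + list(continuous)
    df = compute_predictor_columns(rows, sample.event_index, idx_dates, predictors)
    for col, n_groups in (ordinal or {}).items():
        src = _resolve_column(rows, col)
        if src is None:
            raise KeyError(f"ordinal column {col!r} not found")
        grp = rows[src].to_numpy()
        for g in range(2, n_groups + 1):
            dname = f"{col}_{g}"
            if dname in df.columns:
                raise ValueError(f"duplicate predictor name {dname!r}")
            df[dname] = (grp == g).astype(float)
    if len(set(df.columns)) != len(df.columns):
        raise ValueError("duplicate predictor names")
    if missingness:
        if rng is None:
            raise ValueError("missingness injection requires rng")
        for col, rate in missingness.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missingness rate for {col!r} outside [0,1)")
            if col in df.columns and rate > 0:
                hit = rng.random(len(df)) < rate
                df.loc[hit, col] = np.nan
    outcome = rows["outcome"].reset_index(drop=True) if "outcome" in rows else None
    df = df.reset_index(drop=True)
    return FeatureMatrix(data=df, outcome=outcome)


def handle_missing(matrix: FeatureMatrix, strategy: str = "complete-case") -> FeatureMatrix:
    """Resolve missing entries: ``complete-case`` drops rows, ``impute``
    fills continuous columns with the column mean and {0,1}/ordinal columns
    with the column mode."""
    if strategy not in ("complete-case", "impute"):
        raise ValueError(f"unknown missing-data strategy {strategy!r}")
    df = matrix.data
    if not matrix.mask.to_numpy().any():
        return FeatureMatrix(df.copy(), outcome=matrix.outcome)
    if strategy == "complete-case":
        keep = ~matrix.mask.any(axis=1)
        out = df.loc[keep].reset_index(drop=True)
        y = matrix.outcome[keep.to_numpy()].reset_index(drop=True) if matrix.outcome is not None else None
        return FeatureMatrix(out, outcome=y)
    out = df.copy()
    for col in out.columns:
        if not out[col].isna().any():
            continue
        vals = out[col].dropna()
        # binary indicators take the mode; anything else the mean
        if set(np.unique(vals)) <= {0.0, 1.0}:
            fill = vals.mode().iloc[0]
        else:
            fill = vals.mean()
        out[col] = out[col].fillna(fill)
    y = matrix.outcome.reset_index(drop=True) if matrix.outcome is not None else None
    return FeatureMatrix(out, outcome=y)
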