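"""Sex-specific case-control logistic models of individual suicide risk.

The modelling workflow mirrors standard clinical risk-model practice:

1. screen candidate predictors with cross-validated LASSO logistic
   regression, dropping predictors shrunk to zero;
2. flag strongly correlated survivors (|r| >= 0.60) and keep one member of
   each pair according to an explicit priority ordering;
3. fit a maximum-likelihood logistic model and prune it by backward
   selection on AIC (BIC reported alongside);
4. assess discrimination (C statistic) and calibration (Brier score,
   decile calibration table).

Because the training data are a case-control sample that keeps all cases
and a fraction ``f`` of non-cases, the slopes estimate their population
values but the intercept is inflated by ``ln(1/f)``; see
:func:`synthrisk.estimation.intercept_correction`.

:class:`CaseControlSuicideModel` / :class:`CaseControlSuicideResults`
package these steps in a statsmodels-like model/results pair; the
module-level functions are the underlying operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix, WindowSpec, build_feature_matrix, handle_missing
from .metrics import brier_score, c_statistic, calibration_bins


class SeparationError(RuntimeError):
    """Raised when a predictor perfectly separates cases from controls."""


@dataclass
class ModelSpec:
    """A fitted (or loaded) sex-specific logistic model.

    ``intercept`` and ``coefficients`` live on whatever scale the model was
    estimated on; ``control_sampling_fraction`` records the case-control
    design fraction ``f`` needed to move the intercept to the population
    scale.  ``display_rows`` preserves the verbatim strings of a coefficient
    table read from disk so that write(read(file)) is byte-identical.
    """

    sex: str
    intercept: float
    coefficients: dict[str, float]
    control_sampling_fraction: float = 1.0
    training_period: tuple[int, int] | None = None
    standard_errors: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    selection_trace: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    display_rows: list[tuple[str, str, str, str]] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.control_sampling_fraction <= 1:
            raise ValueError("control_sampling_fraction must lie in (0,1]")
        if "Constant" in self.coefficients or "Intercept" in self.coefficients:
            raise ValueError("the intercept has its own field, not a coefficient entry")

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients)

    def odds_ratio(self, name: str) -> float:
        return float(np.exp(self.coefficients[name]))

    def linear_predictor(self, aggregates: dict[str, float] | pd.DataFrame) -> np.ndarray:
        """eta = b0 + beta . x for a covariate dict or a DataFrame of rows."""
        if isinstance(aggregates, dict):
            missing = set(self.coefficients) - set(aggregates)
            extra = set(aggregates) - set(self.coefficients)
            if missing or extra:
                raise KeyError(
                    f"covariate name mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
                )
            return self.intercept + sum(
                b * aggregates[k] for k, b in self.coefficients.items()
            )
        missing = set(self.coefficients) - set(aggregates.columns)
        if missing:
            raise KeyError(f"covariate name mismatch: missing {sorted(missing)}")
        x = aggregates[self.predictors].to_numpy(dtype=float)
        beta = np.array([self.coefficients[k] for k in self.predictors])
        return self.intercept + x @ beta

    def predict_probability(self, covariates) -> np.ndarray:
        return expit(self.linear_predictor(covariates))

    def window_specs(self) -> list[WindowSpec]:
        """Window metadata parsed from the coefficient names."""
        specs = [WindowSpec.parse(n) for n in self.coefficients]
        return [s for s in specs if s is not None]


@dataclass
class FitDiagnostics:
    """Discrimination/calibration of a fitted model on its training sample."""

    c_statistic: float
    c_ci: tuple[float, float]
    brier: float
    calibration: pd.DataFrame
    n_obs: int
    n_cases: int
    converged: bool
    llf: float
    aic: float
    bic: float

    def __post_init__(self) -> None:
        lo, hi = self.c_ci
        if not lo <= self.c_statistic <= hi:
            raise ValueError("C-statistic CI must bracket the point estimate")
        if int(self.calibration["n"].sum()) != self.n_obs:
            raise ValueError("calibration bin counts must sum to n")


# ---------------------------------------------------------------------------
# screening


@dataclass
class LassoScreenResult:
    selected: list[str]
    coefficients: dict[str, float]  # original (unstandardised) scale
    penalty: float  # chosen lambda

    def __iter__(self):
        return iter(self.selected)


def lasso_screen(
    matrix: FeatureMatrix | pd.DataFrame,
    outcome=None,
    penalty_grid=None,
    cv: int = 5,
    seed: int = 0,
) -> LassoScreenResult:
    """L1-penalised logistic screen; predictors with nonzero coefficients
    at the deviance-optimal penalty survive.

    Columns are standardised internally; reported coefficients are mapped
    back to the original scale.  ``penalty_grid`` is a grid of penalty
    strengths lambda (0 means unpenalised); a scalar fixes the penalty, a
    grid is resolved by stratified cross-validated deviance.
    """
    X, y = _as_xy(matrix, outcome)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate predictors")
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise ValueError("degenerate outcome: all observations share one class")
    arr = X.to_numpy(dtype=float)
    mu, sd = arr.mean(axis=0), arr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (arr - mu) / sd

    def lam_to_c(lam: float) -> float:
        return 1e12 if lam <= 0 else 1.0 / (lam * len(y))

    if penalty_grid is None:
        penalty_grid = np.logspace(-5, 0, 16)
    penalty_grid = np.atleast_1d(np.asarray(penalty_grid, dtype=float))
    if penalty_grid.size == 1:
        lam = float(penalty_grid[0])
        with warnings.catch_warnings():
            # sklearn's l1 penalty spelling is mid-deprecation; not our concern
            warnings.filterwarnings("ignore", message=".*penalty.*")
            est = LogisticRegression(
                penalty="l1", C=lam_to_c(lam), solver="liblinear", tol=1e-9,
                max_iter=2000,
            ).fit(Z, y)
        coef_std = est.coef_[0]
    else:
        Cs = [lam_to_c(l) for l in penalty_grid]
        cv_ = StratifiedKFold(cv, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            warnings.filterwarnings("ignore", message=".*penalty.*")
            est = LogisticRegressionCV(
                Cs=Cs,
                penalty="l1",
                solver="liblinear",
                scoring="neg_log_loss",
                cv=cv_,
                tol=1e-8,
                max_iter=2000,
                refit=True,
            ).fit(Z, y)
        lam = float(penalty_grid[list(Cs).index(est.C_[0])]) if est.C_[0] in Cs else float(
            1.0 / (est.C_[0] * len(y))
        )
        coef_std = est.coef_[0]
    coefs = coef_std / sd
    selected = [c for c, b in zip(X.columns, coefs) if b != 0.0]
    return LassoScreenResult(
        selected=selected,
        coefficients={c: float(b) for c, b in zip(X.columns, coefs)},
        penalty=lam,
    )


@dataclass
class CorrelationFilterResult:
    flagged: list[tuple[str, str, float]]
    retained: list[str]
    constant: list[str]


def correlation_filter(
    matrix: FeatureMatrix | pd.DataFrame,
    selected: list[str],
    threshold: float = 0.60,
    priority: list[str] | None = None,
) -> CorrelationFilterResult:
    """Flag predictor pairs with |Pearson r| >= threshold and retain one
    member per pair.

    For binary-binary pairs Pearson r is the phi coefficient, so a single
    coefficient covers all column types.  ``priority`` lists predictors in
    descending order of preference (the stand-in for subject-matter
    judgment); by default the order of ``selected`` is the priority.
    Constant columns have undefined correlation: they are reported
    separately and retained.
    """
    df = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    missing = set(selected) - set(df.columns)
    if missing:
        raise KeyError(f"selected predictors not in matrix: {sorted(missing)}")
    priority = list(priority) if priority is not None else list(selected)
    rank = {name: i for i, name in enumerate(priority)}
    sub = df[selected]
    const = [c for c in selected if sub[c].nunique(dropna=True) <= 1]
    live = [c for c in selected if c not in const]
    flagged: list[tuple[str, str, float]] = []
    if len(live) >= 2:
        corr = sub[live].corr().to_numpy()
        for i in range(len(live)):
            for j in range(i + 1, len(live)):
                r = corr[i, j]
                if np.isfinite(r) and abs(r) >= threshold:
                    flagged.append((live[i], live[j], float(r)))
    dropped: set[str] = set()
    for a, b, _r in sorted(flagged, key=lambda t: -abs(t[2])):
        if a in dropped or b in dropped:
            continue
        dropped.add(b if rank.get(a, 1 << 30) <= rank.get(b, 1 << 30) else a)
    retained = [c for c in selected if c not in dropped]
    return CorrelationFilterResult(flagged=flagged, retained=retained, constant=const)


# ---------------------------------------------------------------------------
# fitting


def _as_xy(matrix, outcome):
    if isinstance(matrix, FeatureMatrix):
        X = matrix.data
        if outcome is None:
            outcome = matrix.outcome
    else:
        X = matrix
    if outcome is None:
        raise ValueError("outcome required")
    return X, np.asarray(outcome, dtype=float)


def quasi_separating_columns(X: pd.DataFrame, y: np.ndarray) -> list[str]:
    """Binary columns with an outcome-pure level (an empty 2x2 cell).

    Their ML coefficient diverges; model development drops them from the
    candidate set before fitting, mirroring standard practice with sparse
    cells in case-control samples.
    """
    y = np.asarray(y, dtype=float)
    bad = []
    for col in X.columns:
        v = X[col].to_numpy()
        u = np.unique(v)
        if u.size != 2:
            continue
        for val in u:
            m = v == val
            if y[m].size and y[m].min() == y[m].max():
                bad.append(col)
                break
    return bad


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        v = X[col].to_numpy()
        uniq = np.unique(v)
        if uniq.size != 2:
            continue
        hi = v == uniq[-1]
        if (y[hi].size and y[hi].min() == y[hi].max()) and (
            y[~hi].size and y[~hi].min() == y[~hi].max()
        ) and y[hi].mean() != y[~hi].mean():
            raise SeparationError(f"predictor {col!r} perfectly separates the outcome")


def fit_logistic(
    matrix: FeatureMatrix | pd.DataFrame,
    outcome=None,
    predictors: list[str] | None = None,
    sex: str = "unspecified",
    control_sampling_fraction: float = 1.0,
    training_period: tuple[int, int] | None = None,
    n_calibration_bins: int = 10,
) -> tuple[ModelSpec, FitDiagnostics]:
    """Maximum-likelihood logistic fit with Wald inference and diagnostics.

    Constant predictors are dropped with a warning; perfect separation
    raises :class:`SeparationError` naming the offending predictor; missing
    values are a hard error (resolve them with
    :func:`synthrisk.features.handle_missing` first).
    """
    X, y = _as_xy(matrix, outcome)
    if predictors is not None:
        missing = set(predictors) - set(X.columns)
        if missing:
            raise KeyError(f"unknown predictors: {sorted(missing)}")
        X = X[list(predictors)]
    if X.isna().to_numpy().any():
        raise ValueError("feature matrix contains missing values; resolve them first")
    keep = []
    for col in X.columns:
        if X[col].nunique() <= 1:
            warnings.warn(f"dropping constant predictor {col!r}", UserWarning, stacklevel=2)
        else:
            keep.append(col)
    X = X[keep]
    _check_separation(X, y)
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.filterwarnings("ignore", message=".*Maximum Likelihood optimization failed.*")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
            if "separat" in str(exc).lower():
                _raise_named_separation(X, y, exc)
            res = sm.Logit(y, design).fit(disp=0, maxiter=500, method="bfgs")
    if np.abs(res.params).max() > 40:
        _raise_named_separation(X, y, None)
    names = ["Constant"] + keep
    params = dict(zip(names, res.params))
    bse = dict(zip(names, res.bse))
    pvals = dict(zip(names, res.pvalues))
    spec = ModelSpec(
        sex=sex,
        intercept=float(params.pop("Constant")),
        coefficients={k: float(v) for k, v in params.items()},
        control_sampling_fraction=control_sampling_fraction,
        training_period=training_period,
        standard_errors={k: float(v) for k, v in bse.items()},
        p_values={k: float(v) for k, v in pvals.items()},
        metadata={"p_value_method": "Wald"},
    )
    p = res.predict(design)
    cases, controls = p[y == 1], p[y == 0]
    cstat, ci = c_statistic(cases, controls)
    diag = FitDiagnostics(
        c_statistic=cstat,
        c_ci=ci,
        brier=brier_score(p, y),
        calibration=calibration_bins(p, y, n_calibration_bins),
        n_obs=len(y),
        n_cases=int(y.sum()),
        converged=bool(res.mle_retvals.get("converged", True)),
        llf=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic),
    )
    return spec, diag


def _raise_named_separation(X, y, exc) -> None:
    for col in X.columns:
        v = X[col].to_numpy()
        for thr in np.unique(v)[:-1]:
            hi = v > thr
            if not y[hi].size or not y[~hi].size:
                continue
            if (
                y[hi].mean() in (0.0, 1.0)
                and y[~hi].mean() in (0.0, 1.0)
                and y[hi].mean() != y[~hi].mean()
            ):
                raise SeparationError(
                    f"predictor {col!r} perfectly separates the outcome"
                ) from exc
    raise SeparationError(
        f"(quasi-)separation detected among predictors {list(X.columns)}"
    ) from exc


def backward_select(
    matrix: FeatureMatrix | pd.DataFrame,
    outcome=None,
    start_set: list[str] | None = None,
    criterion: str = "AIC",
    **fit_kwargs,
) -> tuple[ModelSpec, FitDiagnostics]:
    """Backward elimination on an information criterion.

    At each step the predictor whose removal most decreases the criterion is
    eliminated; the procedure stops when no removal improves it.  The full
    trace (eliminated predictor, AIC and BIC at each accepted step) is
    stored in ``ModelSpec.selection_trace``.
    """
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    X, y = _as_xy(matrix, outcome)
    current = list(start_set) if start_set is not None else list(X.columns)
    if not current:
        raise ValueError("start_set must be nonempty")

    def crit(d: FitDiagnostics) -> float:
        return d.aic if criterion == "AIC" else d.bic

    spec, diag = fit_logistic(X, y, predictors=current, **fit_kwargs)
    current = spec.predictors  # constant columns may have been dropped
    trace = [
        {"removed": None, "AIC": diag.aic, "BIC": diag.bic, "criterion": crit(diag)}
    ]
    while len(current) > 1:
        best = None
        for name in current:
            reduced = [c for c in current if c != name]
            s_i, d_i = fit_logistic(X, y, predictors=reduced, **fit_kwargs)
            if best is None or crit(d_i) < crit(best[2]):
                best = (name, s_i, d_i)
        if best is None or crit(best[2]) >= crit(diag):
            break
        name, spec, diag = best
        current = [c for c in current if c != name]
        trace.append(
            {"removed": name, "AIC": diag.aic, "BIC": diag.bic, "criterion": crit(diag)}
        )
    spec.selection_trace = trace
    spec.metadata["selection_criterion"] = criterion
    return spec, diag


# ---------------------------------------------------------------------------
# model / results objects


class CaseControlSuicideModel:
    """Individual-level suicide risk model on a case-control sample.

    Parameters
    ----------
    features
        :class:`~synthrisk.features.FeatureMatrix` (with outcome) for one sex.
    sex
        "male" or "female"; carried into the fitted spec.
    control_fraction
        The design's yearly control sampling fraction ``f``.
    training_period
        (first, last) training year, recorded in the spec.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        outcome=None,
        sex: str = "unspecified",
        control_fraction: float = 1.0,
        training_period: tuple[int, int] | None = None,
    ):
        if features.mask.to_numpy().any():
            features = handle_missing(features, "complete-case")
        self.features = features
        self.outcome = np.asarray(
            features.outcome if outcome is None else outcome, dtype=float
        )
        self.sex = sex
        self.control_fraction = control_fraction
        self.training_period = training_period

    @classmethod
    def from_sample(
        cls,
        sample,
        sex: str,
        window_specs,
        continuous=(),
        ordinal=None,
        control_fraction: float = 0.01,
        training_period=None,
        missingness=None,
        missing_strategy: str = "complete-case",
        seed: int = 0,
    ) -> "CaseControlSuicideModel":
        """Build the design matrix for one sex directly from a
        :class:`~synthrisk.cohort.CaseControlSample`."""
        rows = sample.rows[sample.rows["sex"] == sex]
        sub = type(sample)(rows=rows.reset_index(drop=True), event_index=sample.event_index)
        fm = build_feature_matrix(
            sub,
            window_specs=window_specs,
            continuous=continuous,
            ordinal=ordinal,
            missingness=missingness,
            rng=np.random.default_rng(seed),
        )
        fm.outcome = (sub.rows["label"] == "case").astype(float).reset_index(drop=True)
        fm = handle_missing(fm, missing_strategy)
        if training_period is None and len(rows):
            years = rows["year"]
            training_period = (int(years.min()), int(years.max()))
        return cls(
            fm,
            sex=sex,
            control_fraction=control_fraction,
            training_period=training_period,
        )

    def screen(
        self,
        penalty_grid=None,
        correlation_threshold: float = 0.60,
        priority: list[str] | None = None,
        seed: int = 0,
    ) -> list[str]:
        """LASSO screen followed by the correlation filter; returns the
        candidate predictor set for model fitting."""
        lasso = lasso_screen(self.features, self.outcome, penalty_grid, seed=seed)
        filt = correlation_filter(
            self.features, lasso.selected, correlation_threshold, priority
        )
        self.screen_result_ = (lasso, filt)
        return filt.retained

    def fit(
        self,
        predictors: list[str] | None = None,
        selection: str | None = "backward",
        criterion: str = "AIC",
    ) -> "CaseControlSuicideResults":
        start = list(predictors) if predictors is not None else self.features.columns
        sparse = quasi_separating_columns(self.features.data[start], self.outcome)
        if sparse:
            warnings.warn(
                f"dropping predictors with outcome-pure cells: {sparse}",
                UserWarning,
                stacklevel=2,
            )
            start = [c for c in start if c not in sparse]
        if not start:
            raise ValueError("no usable predictors after sparse-cell screening")
        kwargs = dict(
            sex=self.sex,
            control_sampling_fraction=self.control_fraction,
            training_period=self.training_period,
        )
        if selection == "backward":
            spec, diag = backward_select(
                self.features, self.outcome, start, criterion, **kwargs
            )
        elif selection is None:
            spec, diag = fit_logistic(self.features, self.outcome, start, **kwargs)
        else:
            raise ValueError(f"unknown selection {selection!r}")
        return CaseControlSuicideResults(self, spec, diag)


class CaseControlSuicideResults:
    """Fitted-model results: estimates, uncertainty, diagnostics, summary."""

    def __init__(self, model, spec: ModelSpec, diagnostics: FitDiagnostics):
        self.model = model
        self.spec = spec
        self.diagnostics = diagnostics

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {"Constant": self.spec.intercept, **self.spec.coefficients}, name="coefficient"
        )

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.spec.standard_errors, name="std err")

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.spec.p_values, name="P>|z|")

    def predict(self, covariates) -> np.ndarray:
        return self.spec.predict_probability(covariates)

    def synthetic_estimator(self, correct_intercept: bool = True):
        from .estimation import SyntheticEstimator

        return SyntheticEstimator(self.spec, correct_intercept=correct_intercept)

    def save(self, path) -> None:
        from .io import write_model

        write_model(self.spec, path)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            f"Case-control logistic model for suicide ({self.spec.sex})",
            f"Training period: {self.spec.training_period}, "
            f"control sampling fraction f={self.spec.control_sampling_fraction}",
            f"n={d.n_obs} ({d.n_cases} cases), converged={d.converged}",
            f"C statistic {d.c_statistic:.3f} "
            f"(95% CI {d.c_ci[0]:.3f}-{d.c_ci[1]:.3f}); Brier {d.brier:.4f}",
            f"AIC {d.aic:.1f}  BIC {d.bic:.1f}",
            "",
            f"{'predictor':<45s}{'coef':>10s}{'OR':>8s}{'p':>10s}",
        ]
        rows = [("Constant", self.spec.intercept)] + list(self.spec.coefficients.items())
        for name, b in rows:
            orr = f"{np.exp(b):.2f}" if name != "Constant" else "-"
            p = self.spec.p_values.get(name)
            lines.append(
                f"{name:<45s}{b:>10.3f}{orr:>8s}{(f'{p:.3g}' if p is not None else '-'):>10s}"
            )
        return "\n".join(lines)
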