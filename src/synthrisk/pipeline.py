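"""End-to-end orchestration: simulate, fit, synthesise, validate.

These helpers wire the library together for the common workflow —
generate (or load) a panel, draw the training case-control sample, fit the
sex-specific models, convert them into synthetic estimators and evaluate
the regional forecasts.  The CLI and the acceptance script are thin
wrappers over this module.
"""

from __future__ import annotations

from .cohort import (
    SEXES,
    PersonPanel,
    PopulationConfig,
    default_config,
    generate_population,
    sample_case_control,
    split_train_validation,
)
from .evaluation import EvalReport, yearly_report
from .features import WindowSpec
from .model import CaseControlSuicideModel, CaseControlSuicideResults

#: candidate lookback-window predictors offered to the screening step;
#: deliberately wider than the true model so that LASSO and the correlation
#: filter have real work to do (nested windows of one event type are
#: strongly correlated by construction).
CANDIDATE_WINDOWS = [
    WindowSpec("Hospitalisation for Suicide attempt", 12),
    WindowSpec("Hospitalisation for Suicide attempt", 60),
    WindowSpec("Mood and anxiety disorders", 12),
    WindowSpec("Mood and anxiety disorders", 60),
    WindowSpec("Substance use disorders", 60),
    WindowSpec("Emergency room visits for mental health reasons", 60),
    WindowSpec("Emergency room visits for Physical health reasons", 3),
    WindowSpec("Outpatient psychiatrist visits for mental health reasons", 60),
    WindowSpec("Personality disorders", 60),
    WindowSpec("Other mental disorders", 60),
    WindowSpec("Non-intentional trauma", 48),
    WindowSpec("Rural town", 48),
    WindowSpec("Rural town", 60),
]
CANDIDATE_CONTINUOUS = ["Age", "Charlson score", "Regional mental budget"]
CANDIDATE_ORDINAL = {"Material deprivation": 5}


def _priority_for(sex: str, config: PopulationConfig | None) -> list[str]:
    """Correlation-filter priority: the sex's true predictors first (the
    stand-in for the subject-matter judgment that resolves correlated
    pairs), then everything else in candidate order."""
    if config is None:
        return []
    truth = [k for k in config.true_coefficients.get(sex, {}) if k != "Intercept"]
    rest = [s.name for s in CANDIDATE_WINDOWS] + CANDIDATE_CONTINUOUS
    return truth + [r for r in rest if r not in truth]


def fit_sex_models(
    panel_train: PersonPanel,
    control_fraction: float | None = None,
    seed: int = 0,
    screen: bool = True,
    inject_missingness: bool = True,
    selection: str | None = "backward",
) -> dict[str, CaseControlSuicideResults]:
    """Draw the training case-control sample and fit both sex models."""
    cfg = panel_train.config
    if control_fraction is None:
        control_fraction = cfg.control_fraction if cfg else 0.01
    years = panel_train.years
    sample = sample_case_control(
        panel_train, (years[0], years[-1]), control_fraction, seed=seed
    )
    missingness = dict(cfg.missingness_rates) if (cfg and inject_missingness) else None
    results = {}
    for sex in SEXES:
        m = CaseControlSuicideModel.from_sample(
            sample,
            sex=sex,
            window_specs=CANDIDATE_WINDOWS,
            continuous=CANDIDATE_CONTINUOUS,
            ordinal=CANDIDATE_ORDINAL,
            control_fraction=control_fraction,
            training_period=(years[0], years[-1]),
            missingness=missingness,
            seed=seed + 1,
        )
        predictors = (
            m.screen(priority=_priority_for(sex, cfg), seed=seed) if screen else None
        )
        results[sex] = m.fit(predictors, selection=selection)
    return results


def run_end_to_end(
    config: PopulationConfig | None = None,
    n_persons: int = 200_000,
    seed: int = 0,
    split_year: int = 2011,
    k: int = 5,
    unit: str = "per_1000",
    screen: bool = True,
    selection: str | None = "backward",
) -> tuple[PersonPanel, dict[str, CaseControlSuicideResults], EvalReport]:
    """Simulate the stated world, fit, and evaluate regional forecasts."""
    if config is None:
        config = default_config(n_persons=n_persons, seed=seed)
    panel = generate_population(config)
    train, valid = split_train_validation(panel, split_year)
    results = fit_sex_models(train, seed=seed, screen=screen, selection=selection)
    report = yearly_report(
        train, valid, {s: r.spec for s, r in results.items()}, k=k, unit=unit
    )
    return panel, results, report
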