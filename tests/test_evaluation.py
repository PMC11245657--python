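"""Forecast evaluation: observed rates, MAE/RMSE, top-k overlap, reports."""

import numpy as np
import pandas as pd
import pytest

from synthrisk.evaluation import (
    mae,
    observed_rates,
    rmse,
    subgroup_validation,
    top_k_overlap,
    yearly_report,
)
from synthrisk.model import ModelSpec

from conftest import make_panel


class TestObservedRates:
    def test_definition(self):
        rows = [{"year": 2019, "person_id": i, "outcome": 1 if i < 27 else 0}
                for i in range(100_000)]
        panel = make_panel(rows)
        assert observed_rates(panel, 2019, "male", by_region=False) == 27.0

    def test_zero_cases(self):
        panel = make_panel([{"year": 2019, "person_id": i} for i in range(100)])
        assert observed_rates(panel, 2019, "male", by_region=False) == 0.0

    def test_empty_population_rejected(self):
        panel = make_panel([{"year": 2018, "person_id": 0}])
        with pytest.raises(ValueError, match="zero population"):
            observed_rates(panel, 2019, "male")

    def test_regional_rates_recompose_to_provincial(self):
        rows = []
        pid = 0
        for region, n, k in [(1, 40, 3), (2, 25, 1), (3, 35, 2)]:
            for i in range(n):
                rows.append({"year": 2019, "person_id": pid, "region_id": region,
                             "outcome": 1 if i < k else 0})
                pid += 1
        panel = make_panel(rows)
        regional = observed_rates(panel, 2019, "male", by_region=True)
        pops = panel.rows.groupby("region_id").size()
        recomposed = float(np.average(regional, weights=pops.loc[regional.index]))
        assert recomposed == pytest.approx(
            observed_rates(panel, 2019, "male", by_region=False)
        )


class TestErrorMetrics:
    def test_identical_vectors(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_computation(self):
        assert mae([1.0, 2.0], [2.0, 4.0]) == pytest.approx(1.5)
        assert rmse([1.0, 2.0], [2.0, 4.0]) == pytest.approx(np.sqrt(2.5))

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([], [])


class TestTopKOverlap:
    def _rates(self, order, base=100.0):
        return pd.Series({r: base - i for i, r in enumerate(order)})

    def test_identical_rankings(self):
        r = self._rates(list("ABCDEF"))
        assert top_k_overlap(r, r, k=5) == 1.0

    def test_disjoint_sets(self):
        pred = pd.Series({"A": 9, "B": 8, "C": 2, "D": 1})
        obs = pd.Series({"A": 1, "B": 2, "C": 8, "D": 9})
        assert top_k_overlap(pred, obs, k=2) == 0.0

    def test_six_region_enumeration(self):
        pred = self._rates(list("ABCDEF"))
        obs = self._rates(["A", "B", "C", "D", "F", "E"])
        assert top_k_overlap(pred, obs, k=5) == 0.8

    def test_invariant_under_monotone_transform(self, rng):
        regions = list(range(10))
        pred = pd.Series(rng.random(10), index=regions)
        obs = pd.Series(rng.random(10), index=regions)
        v1 = top_k_overlap(pred, obs, k=4)
        v2 = top_k_overlap(np.exp(3 * pred), np.exp(3 * obs), k=4)
        assert v1 == v2

    def test_deterministic_tie_break_by_region_id(self):
        # regions 2 and 3 tie at the k-boundary: lower id wins, both times
        pred = pd.Series({1: 10.0, 2: 5.0, 3: 5.0, 4: 1.0})
        obs = pd.Series({1: 10.0, 2: 5.0, 3: 5.0, 4: 1.0})
        assert top_k_overlap(pred, obs, k=2) == 1.0

    def test_too_few_regions_rejected(self):
        r = self._rates(list("ABC"))
        with pytest.raises(ValueError, match="k=5"):
            top_k_overlap(r, r, k=5)

    def test_mismatched_regions_rejected(self):
        with pytest.raises(ValueError, match="identical regions"):
            top_k_overlap(self._rates(list("ABC")), self._rates(list("ABD")), k=2)


def _exact_world():
    """Panel whose observed rates equal the model's predictions exactly.

    Three regions, homogeneous within region; outcome counts chosen so that
    cases/population coincides with invlogit(b0 + beta * charlson).
    """
    beta = float(np.log(0.25))  # p = 1/2, 1/5, 1/17 at charlson 0, 1, 2
    spec = {s: ModelSpec(sex=s, intercept=0.0, coefficients={"charlson": beta})
            for s in ("male", "female")}
    rows = []
    pid = 0
    for sex in ("male", "female"):
        for year in (2010, 2011):
            for region, charlson, n, k in [(1, 0, 1000, 500), (2, 1, 1000, 200),
                                           (3, 2, 1700, 100)]:
                for i in range(n):
                    rows.append({"year": year, "person_id": pid, "sex": sex,
                                 "region_id": region, "charlson": charlson,
                                 "outcome": 1 if i < k else 0})
                    pid += 1
    return make_panel(rows), spec


class TestSubgroupValidation:
    def test_all_inclusive_band_reproduces_provincial(self):
        panel, models = _exact_world()
        out = subgroup_validation(panel, models["male"], [(15.0, 120.0)], 2011, "male")
        assert out.loc[0, "observed_per_100k"] == pytest.approx(
            observed_rates(panel, 2011, "male", by_region=False)
        )
        assert out.loc[0, "abs_diff_per_100k"] == pytest.approx(0.0, abs=1e-6)

    def test_band_recomposition(self, small_world):
        bands = [(15.0, 40.0), (40.0, 60.0), (60.0, 200.0)]
        from synthrisk.io import load_fixture_model

        out = subgroup_validation(small_world, load_fixture_model("male"),
                                  bands, 2019, "male")
        total = float(
            np.average(out["observed_per_100k"], weights=out["n"])
        )
        assert total == pytest.approx(
            observed_rates(small_world, 2019, "male", by_region=False)
        )

    def test_overlapping_bands_rejected(self, small_world):
        from synthrisk.io import load_fixture_model

        with pytest.raises(ValueError, match="disjoint"):
            subgroup_validation(small_world, load_fixture_model("male"),
                                [(15.0, 50.0), (40.0, 80.0)], 2019, "male")

    def test_empty_band_flagged_not_fatal(self):
        panel, models = _exact_world()
        out = subgroup_validation(panel, models["male"],
                                  [(15.0, 120.0), (120.0, 130.0)], 2011, "male")
        assert bool(out.loc[1, "empty"]) is True


class TestYearlyReport:
    def test_perfect_world_self_consistency(self):
        panel, models = _exact_world()
        from synthrisk.cohort import split_train_validation

        train, valid = split_train_validation(panel, 2011)
        report = yearly_report(train, valid, models, k=3, unit="per_1000")
        assert (report.metrics["mae"] < 1e-9).all()
        assert (report.metrics["rmse"] < 1e-9).all()
        assert (report.metrics["top_k_overlap"] == 1.0).all()

    def test_report_row_count(self):
        panel, models = _exact_world()
        from synthrisk.cohort import split_train_validation

        train, valid = split_train_validation(panel, 2011)
        report = yearly_report(train, valid, models, k=3)
        # one row per period-year per sex
        assert len(report.metrics) == 2 * 2
        assert set(report.metrics["sex"]) == {"male", "female"}

    def test_mae_never_exceeds_rmse(self):
        panel, models = _exact_world()
        from synthrisk.cohort import split_train_validation

        train, valid = split_train_validation(panel, 2011)
        report = yearly_report(train, valid, models, k=3)
        assert (report.metrics["mae"] <= report.metrics["rmse"] + 1e-12).all()

    def test_missing_sex_rejected(self):
        panel, models = _exact_world()
        with pytest.raises(ValueError, match="female"):
            yearly_report(panel, panel, {"male": models["male"]})

    def test_unit_must_be_known(self):
        panel, models = _exact_world()
        with pytest.raises(ValueError, match="unit"):
            yearly_report(panel, panel, models, unit="per_million")
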