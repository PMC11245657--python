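"""Lookback-window indicators, quantile groups, and matrix assembly."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from synthrisk.features import (
    EventIndex,
    FeatureMatrix,
    WindowSpec,
    assign_quantile_groups,
    build_feature_matrix,
    compute_predictor_columns,
    derive_window_indicator,
    handle_missing,
)


class TestWindowSpec:
    def test_canonical_name_and_parse(self):
        spec = WindowSpec("Mood and anxiety disorders", 60)
        assert spec.name == "Mood and anxiety disorders_60m"
        assert WindowSpec.parse(spec.name) == spec
        # trailing space before the suffix (as printed in some tables)
        assert WindowSpec.parse("Rural town _48m") == WindowSpec("Rural town", 48)
        assert WindowSpec.parse("Age") is None

    @pytest.mark.parametrize("months", [0, -3, 7, 120])
    def test_rejects_bad_windows(self, months):
        with pytest.raises(ValueError):
            WindowSpec("x", months)


class TestWindowIndicator:
    def test_event_inside_window(self):
        hist = [("hosp", 2005.0 - 2 / 12)]
        assert derive_window_indicator(hist, 2005.0, WindowSpec("hosp", 3)) == 1

    def test_event_outside_window(self):
        hist = [("hosp", 2005.0 - 61 / 12)]
        assert derive_window_indicator(hist, 2005.0, WindowSpec("hosp", 60)) == 0

    def test_interval_membership_multiple_windows(self):
        # events 5 and 50 months before the index date
        hist = [("hosp", 2005.0 - 5 / 12), ("hosp", 2005.0 - 50 / 12)]
        got = [
            derive_window_indicator(hist, 2005.0, WindowSpec("hosp", w))
            for w in (3, 6, 60)
        ]
        assert got == [0, 1, 1]

    def test_vectorised_index_matches_scalar_oracle(self, rng):
        n_persons, n_events = 40, 300
        events = pd.DataFrame(
            {
                "person_id": rng.integers(0, n_persons, n_events),
                "event_type": rng.choice(["a", "b"], n_events),
                "event_date": 2000 + 10 * rng.random(n_events),
            }
        )
        index = EventIndex(events)
        pids = np.arange(n_persons)
        dates = 2004 + 4 * rng.random(n_persons)
        histories = {
            p: list(
                zip(
                    events.loc[events.person_id == p, "event_type"],
                    events.loc[events.person_id == p, "event_date"],
                )
            )
            for p in pids
        }
        for etype in ("a", "b"):
            for w in (3, 12, 60):
                fast = index.window_indicator(etype, pids, dates, w)
                slow = [
                    derive_window_indicator(histories[p], d, WindowSpec(etype, w))
                    for p, d in zip(pids, dates)
                ]
                assert fast.tolist() == slow

    def test_window_monotonicity(self, rng):
        events = pd.DataFrame(
            {
                "person_id": rng.integers(0, 30, 200),
                "event_type": "a",
                "event_date": 2000 + 8 * rng.random(200),
            }
        )
        index = EventIndex(events)
        pids = np.arange(30)
        dates = np.full(30, 2007.3)
        prev = np.zeros(30)
        for w in (3, 6, 12, 24, 36, 48, 60):
            cur = index.window_indicator("a", pids, dates, w)
            assert (cur >= prev).all()
            prev = cur


class TestQuantileGroups:
    def test_self_quantiling_near_equal_sizes(self, rng):
        scores = rng.normal(size=1000)
        groups = assign_quantile_groups(scores, 5, norms=scores)
        counts = np.bincount(groups)[1:]
        assert counts.sum() == 1000
        assert counts.max() - counts.min() <= 1

    def test_below_reference_minimum_clamps_to_group_1(self):
        assert assign_quantile_groups([-100.0], 5, norms=np.arange(100.0))[0] == 1

    def test_cut_points_from_reference(self):
        # brute-force: quintile cuts of 1..100 put 51 in the middle group
        norms = np.arange(1.0, 101.0)
        assert assign_quantile_groups([51.0], 5, norms=norms)[0] == 3

    def test_groups_order_isomorphic_to_scores(self, rng):
        scores = rng.normal(size=500)
        groups = assign_quantile_groups(scores, 5)
        order = np.argsort(scores)
        assert (np.diff(groups[order]) >= 0).all()

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            assign_quantile_groups([], 5, norms=[1.0])
        with pytest.raises(ValueError):
            assign_quantile_groups([1.0], 5, norms=[])


def _sample(rows: pd.DataFrame, events: pd.DataFrame | None = None):
    ev = events if events is not None else pd.DataFrame(
        [], columns=["person_id", "event_type", "event_date"]
    )
    return SimpleNamespace(rows=rows, event_index=EventIndex(ev))


class TestBuildFeatureMatrix:
    def _rows(self, n):
        return pd.DataFrame(
            {
                "person_id": np.arange(n),
                "index_date": np.full(n, 2005.5),
                "age": np.linspace(20, 60, n),
                "deprivation_material": np.tile([1, 2, 3, 4, 5], n // 5 + 1)[:n],
                "outcome": np.zeros(n),
            }
        )

    def test_empty_history_gives_zero_indicators(self):
        sample = _sample(self._rows(10))
        fm = build_feature_matrix(sample, [WindowSpec("hosp", 60)])
        assert (fm.data["hosp_60m"] == 0).all()

    def test_row_alignment(self):
        sample = _sample(self._rows(25))
        fm = build_feature_matrix(
            sample, [WindowSpec("hosp", 60)], continuous=["age"]
        )
        assert len(fm) == 25
        assert fm.columns == ["hosp_60m", "age"]

    def test_ordinal_dummies(self):
        sample = _sample(self._rows(10))
        fm = build_feature_matrix(sample, ordinal={"deprivation_material": 5})
        assert set(fm.columns) == {f"deprivation_material_{g}" for g in (2, 3, 4, 5)}
        # each person is in exactly one non-reference group or the reference
        assert fm.data.sum(axis=1).isin([0.0, 1.0]).all()

    def test_published_alias_names(self):
        sample = _sample(self._rows(10))
        fm = build_feature_matrix(
            sample, continuous=["Age"], ordinal={"Material deprivation": 5}
        )
        assert "Age" in fm.columns and "Material deprivation_2" in fm.columns

    def test_duplicate_names_rejected(self):
        sample = _sample(self._rows(10))
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_matrix(
                sample, [WindowSpec("hosp", 60), WindowSpec("hosp", 60)]
            )

    def test_unknown_predictor_rejected(self):
        sample = _sample(self._rows(10))
        with pytest.raises(KeyError):
            compute_predictor_columns(
                sample.rows, sample.event_index, np.full(10, 2005.5), ["nope"]
            )

    def test_injected_missingness_fraction(self, rng):
        n, rate = 10_000, 0.04
        sample = _sample(self._rows(n))
        fm = build_feature_matrix(
            sample, continuous=["age"], missingness={"age": rate}, rng=rng
        )
        lo, hi = binom.ppf([0.005, 0.995], n, rate)
        assert lo <= fm.mask["age"].sum() <= hi


class TestHandleMissing:
    def _fm(self):
        df = pd.DataFrame(
            {"a": [1.0, 3.0, np.nan, 5.0], "b": [0.0, 1.0, 1.0, np.nan]}
        )
        return FeatureMatrix(df, outcome=pd.Series([0.0, 1.0, 0.0, 1.0]))

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        fm = FeatureMatrix(df)
        out = handle_missing(fm, "complete-case")
        pd.testing.assert_frame_equal(out.data, df)

    def test_complete_case_row_count(self):
        out = handle_missing(self._fm(), "complete-case")
        assert len(out) == 2 and not out.mask.to_numpy().any()
        assert out.outcome.tolist() == [0.0, 1.0]

    def test_mean_imputation(self):
        df = pd.DataFrame({"x": [1.0, 3.0, np.nan]})
        out = handle_missing(FeatureMatrix(df), "impute")
        assert out.data["x"].tolist() == [1.0, 3.0, 2.0]

    def test_mode_imputation_for_binary(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 1.0, np.nan]})
        out = handle_missing(FeatureMatrix(df), "impute")
        assert out.data["x"].iloc[-1] == 1.0

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            handle_missing(self._fm(), "drop-columns")
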