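"""Preprocessing rules: residence inference, carry-forward, filters,
outcome transform, deprivation categories, VIF screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neighsdq import (
    LongCohort,
    carry_forward_sweep7,
    categorize_imd,
    compute_vif,
    filter_analysis_sample,
    infer_residence,
    transform_outcome,
)
from neighsdq.errors import DomainError

from conftest import base_row, make_cohort_df, full_person


def cohort_with_lsoa(pattern: dict[int, str | None], pid: str = "A") -> LongCohort:
    rows = []
    for s in range(1, 8):
        ls = pattern.get(s, f"L0")
        rows.append(base_row(pid, s, lsoa_id=ls if ls is not None else np.nan))
    return LongCohort(make_cohort_df(rows))


class TestInferResidence:
    def test_gap_flanked_by_same_lsoa_is_filled(self):
        cohort = cohort_with_lsoa({3: None})
        out, n = infer_residence(cohort)
        assert n == 1
        assert (out.df["lsoa_id"] == "L0").all()
        assert out.df.loc[out.df["sweep"] == 3, "lsoa_inferred"].all()

    def test_gap_flanked_by_different_lsoas_stays_missing(self):
        pattern = {s: "A1" for s in (1, 2)} | {3: None} | {s: "B1" for s in (4, 5, 6, 7)}
        out, n = infer_residence(cohort_with_lsoa(pattern))
        assert n == 0
        assert out.df.loc[out.df["sweep"] == 3, "lsoa_id"].isna().all()

    def test_leading_missing_has_no_before_flank(self):
        out, n = infer_residence(cohort_with_lsoa({1: None}))
        assert n == 0
        assert out.df.loc[out.df["sweep"] == 1, "lsoa_id"].isna().all()

    def test_multi_sweep_gap_filled_when_flanks_agree(self):
        out, n = infer_residence(cohort_with_lsoa({3: None, 4: None}))
        assert n == 2
        assert (out.df["lsoa_id"] == "L0").all()

    def test_idempotent_and_never_overwrites(self):
        pattern = {2: "X9", 4: None}
        cohort = cohort_with_lsoa(pattern)
        once, _ = infer_residence(cohort)
        twice, n2 = infer_residence(once)
        assert n2 == 0
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert (once.df.loc[once.df["sweep"] == 2, "lsoa_id"] == "X9").all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        pattern=st.lists(
            st.one_of(st.none(), st.sampled_from(["L1", "L2", "L3"])),
            min_size=7,
            max_size=7,
        )
    )
    def test_property_never_overwrites_and_idempotent(self, pattern):
        cohort = cohort_with_lsoa({s: v for s, v in zip(range(1, 8), pattern)})
        once, _ = infer_residence(cohort)
        observed = cohort.df["lsoa_id"].notna()
        assert (once.df.loc[observed, "lsoa_id"] == cohort.df.loc[observed, "lsoa_id"]).all()
        twice, n2 = infer_residence(once)
        assert n2 == 0
        pd.testing.assert_frame_equal(once.df, twice.df)
        # every filled cell equals both its nearest observed neighbours
        filled = once.df["lsoa_inferred"]
        for idx in once.df.index[filled]:
            s = int(once.df.loc[idx, "sweep"])
            before = [v for t, v in zip(range(1, s), pattern[: s - 1]) if v is not None]
            after = [v for v in pattern[s:] if v is not None]
            assert before and after
            assert before[-1] == after[0] == once.df.loc[idx, "lsoa_id"]

    def test_filled_rows_recover_exposures_from_lookup(self):
        cohort = cohort_with_lsoa({3: None})
        df = cohort.df.copy()
        df.loc[df["sweep"] == 3, ["pm25", "imd_decile"]] = np.nan
        lookup = pd.DataFrame(
            {"lsoa_id": ["L0"], "sweep": [3], "pm25": [13.5], "imd_decile": [4]}
        )
        out, n = infer_residence(LongCohort(df), exposure_lookup=lookup)
        assert n == 1
        row = out.df[out.df["sweep"] == 3].iloc[0]
        assert row["pm25"] == 13.5 and row["imd_decile"] == 4


class TestCarryForward:
    def test_sweep6_values_copied_to_sweep7(self):
        rows = full_person("A", imd_decile=4)
        rows[6]["imd_decile"] = np.nan
        rows[6]["poverty"] = np.nan
        out = carry_forward_sweep7(LongCohort(make_cohort_df(rows)))
        s7 = out.df[out.df["sweep"] == 7].iloc[0]
        assert s7["imd_decile"] == 4 and s7["poverty"] == 0
        assert not s7["excluded"]

    def test_mover_between_sweep6_and_7_excluded(self):
        rows = full_person("A")
        rows[6]["lsoa_id"] = "ELSEWHERE"
        out = carry_forward_sweep7(LongCohort(make_cohort_df(rows)))
        assert out.df.loc[out.df["sweep"] == 7, "excluded"].all()
        assert 7 not in set(out.modeled_rows()["sweep"])

    def test_absent_at_sweep6_excluded(self):
        rows = [base_row("A", s) for s in (1, 2, 3, 4, 5, 7)]
        out = carry_forward_sweep7(LongCohort(make_cohort_df(rows)))
        assert out.df.loc[out.df["sweep"] == 7, "excluded"].all()

    def test_existing_sweep7_value_overwritten_uniformly(self):
        rows = full_person("A", poverty=0)
        rows[5]["poverty"] = 1  # sweep 6
        rows[6]["poverty"] = 0  # sweep 7, inconsistent with the rule
        out = carry_forward_sweep7(LongCohort(make_cohort_df(rows)))
        assert out.df.loc[out.df["sweep"] == 7, "poverty"].iloc[0] == 1


class TestFilterAnalysisSample:
    def test_second_born_twin_removed(self):
        rows = full_person("A") + full_person("B", birth_order_in_multiple=2)
        out = filter_analysis_sample(LongCohort(make_cohort_df(rows)))
        assert set(out.df["person_id"]) == {"A"}

    def test_any_sweep_outside_england_removes_person(self):
        rows = full_person("A")
        rows[3]["country"] = "Wales"
        out = filter_analysis_sample(LongCohort(make_cohort_df(rows + full_person("B"))))
        assert set(out.df["person_id"]) == {"B"}

    def test_incomplete_residence_history_removed(self):
        rows = full_person("A")
        rows[0]["lsoa_id"] = np.nan  # leading gap, unrecoverable
        out = filter_analysis_sample(LongCohort(make_cohort_df(rows + full_person("B"))))
        assert set(out.df["person_id"]) == {"B"}

    def test_all_eligible_input_is_noop_and_idempotent(self, three_person_cohort):
        once = filter_analysis_sample(three_person_cohort)
        pd.testing.assert_frame_equal(once.df, three_person_cohort.df)
        twice = filter_analysis_sample(once)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert set(map(tuple, twice.df[["person_id", "sweep"]].values)) <= set(
            map(tuple, three_person_cohort.df[["person_id", "sweep"]].values)
        )


class TestTransformOutcome:
    @pytest.mark.parametrize("sdq,expected", [(0, 0.0), (40, np.log(41)), (7, np.log(8))])
    def test_log1p_values(self, sdq, expected):
        assert transform_outcome(sdq) == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(DomainError):
            transform_outcome(41)
        with pytest.raises(DomainError):
            transform_outcome(-1)

    def test_bijection_on_score_range(self):
        vals = transform_outcome(np.arange(41))
        assert np.all(np.diff(vals) > 0)  # strictly increasing => injective
        assert len(np.unique(vals)) == 41

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.integers(0, 40), b=st.integers(0, 40))
    def test_property_strictly_monotone(self, a, b):
        if a < b:
            assert transform_outcome(a) < transform_outcome(b)
        elif a == b:
            assert transform_outcome(a) == transform_outcome(b)


class TestCategorizeImd:
    @pytest.mark.parametrize(
        "decile,expected",
        [
            (1, "most_deprived"),
            (2, "most_deprived"),
            (3, "most_deprived"),
            (4, "moderately_deprived"),
            (5, "moderately_deprived"),
            (7, "moderately_deprived"),
            (8, "least_deprived"),
            (10, "least_deprived"),
        ],
    )
    def test_category_boundaries(self, decile, expected):
        assert categorize_imd(decile) == expected

    @pytest.mark.parametrize("bad", [0, 11, 2.5])
    def test_out_of_domain(self, bad):
        with pytest.raises(DomainError):
            categorize_imd(bad)


class TestVif:
    def test_orthogonal_columns_have_unit_vif(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(400)
        a -= a.mean()
        b = rng.standard_normal(400)
        b -= b.mean()
        b -= a * (a @ b) / (a @ a)  # exactly uncorrelated given the intercept
        out = compute_vif(pd.DataFrame({"a": a, "b": b}))
        assert np.allclose(out["vif"], 1.0, atol=1e-9)
        assert not out["flagged"].any()

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(100)
        out = compute_vif(pd.DataFrame({"a": a, "b": a.copy(), "c": rng.standard_normal(100)}))
        assert np.isinf(out.loc["a", "vif"]) and np.isinf(out.loc["b", "vif"])
        assert out.loc[["a", "b"], "flagged"].all()

    def test_correlation_half_gives_four_thirds(self):
        # closed form: VIF = 1/(1 - 0.5^2) = 4/3 for two columns with r = 0.5
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        e = rng.standard_normal(2000)
        # enforce exact sample correlation 0.5: centre, orthogonalise, rescale
        x_c = x - x.mean()
        e_c = e - e.mean()
        e_o = e_c - x_c * (x_c @ e_c) / (x_c @ x_c)
        x_std = x_c / x_c.std()
        e_std = e_o / e_o.std()
        yv = 0.5 * x_std + np.sqrt(0.75) * e_std
        out = compute_vif(pd.DataFrame({"x": x_std, "y": yv}))
        assert np.allclose(out["vif"], 4.0 / 3.0, atol=1e-9)

    def test_matches_statsmodels_oracle(self):
        sm_outliers = pytest.importorskip("statsmodels.stats.outliers_influence")
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 4))
        X[:, 3] = 0.7 * X[:, 0] + 0.3 * rng.standard_normal(200)
        ours = compute_vif(pd.DataFrame(X, columns=list("abcd")))["vif"].values
        Xc = np.column_stack([np.ones(200), X])
        theirs = [
            sm_outliers.variance_inflation_factor(Xc, j) for j in range(1, 5)
        ]
        assert np.allclose(ours, theirs, rtol=1e-8)

    def test_vif_never_below_one(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 6))
        out = compute_vif(pd.DataFrame(X))
        assert (out["vif"] >= 1.0 - 1e-9).all()
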