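"""Parameter matrix, derivative transform, panel sums and subset search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uromir.panel import (
    DerivativeMatrix,
    PARAMETER_DEFS,
    SEVEN_PARAM_SUBSET,
    ParameterMatrix,
    build_parameter_matrix,
    choose_cutoff,
    classify,
    derivative,
    derivative_matrix,
    fit_reference,
    panel_sum,
    search_best_panel,
)

TARGETS = ("miR-122", "miR-1271", "miR-15b", "miR-16", "miRTC", "cel-miR-39")


def cohort_frame(rows: dict[str, tuple[str, dict[str, float]]]) -> pd.DataFrame:
    data = {
        subj: {"group": grp, **cts} for subj, (grp, cts) in rows.items()
    }
    return pd.DataFrame.from_dict(data, orient="index")


def flat_cohort(ct=30.0, **overrides):
    cts = {t: ct for t in TARGETS}
    cts.update(overrides)
    return cts


class TestParameterMatrix:
    def test_equal_cts_zero_all_delta_parameters(self):
        pm = build_parameter_matrix(
            cohort_frame({"s1": ("ccRCC", flat_cohort(30.0)), "s2": ("HS", flat_cohort(30.0))})
        )
        row = pm.values.loc["s1"]
        assert all(row[f"p{i}"] == 30.0 for i in (1, 2, 3))
        assert all(row[f"p{i}"] == 0.0 for i in range(4, 13))

    def test_mir122_mir16_delta(self):
        pm = build_parameter_matrix(
            cohort_frame(
                {
                    "s1": ("ccRCC", flat_cohort(30.0, **{"miR-122": 28.0, "miR-16": 25.0})),
                    "s2": ("HS", flat_cohort(30.0)),
                }
            )
        )
        assert pm.values.loc["s1", "p4"] == pytest.approx(3.0)

    def test_parameter_8_is_mir1271_minus_mirtc(self):
        assert PARAMETER_DEFS[8] == ("miR-1271", "miRTC")
        pm = build_parameter_matrix(
            cohort_frame(
                {
                    "s1": ("ccRCC", flat_cohort(30.0, **{"miR-1271": 29.0, "miRTC": 24.0})),
                    "s2": ("HS", flat_cohort(30.0)),
                }
            )
        )
        assert pm.values.loc["s1", "p8"] == pytest.approx(5.0)

    def test_missing_target_names_subject_and_target(self):
        frame = cohort_frame({"s1": ("ccRCC", flat_cohort(30.0))})
        frame = frame.drop(columns=["miRTC"])
        with pytest.raises(ValueError, match="s1.*miRTC"):
            build_parameter_matrix(frame)

    def test_gate_failed_subjects_are_dropped(self):
        frame = cohort_frame(
            {"s1": ("ccRCC", flat_cohort()), "s2": ("HS", flat_cohort())}
        )
        frame["gate_ok"] = [True, False]
        pm = build_parameter_matrix(frame)
        assert list(pm.values.index) == ["s1"]


def _pm(case_vals, hs_vals, col="p1"):
    n1, n2 = len(case_vals), len(hs_vals)
    values = pd.DataFrame({f"p{i}": 0.0 for i in range(1, 13)}, index=[f"x{i}" for i in range(n1 + n2)])
    values[col] = list(case_vals) + list(hs_vals)
    groups = pd.Series(["ccRCC"] * n1 + ["HS"] * n2, index=values.index)
    return ParameterMatrix(values, groups)


class TestReferenceFit:
    def test_mean_sd_direction_lower(self):
        ref = fit_reference(_pm([1, 2, 3], [10, 11, 12]))
        row = ref.table.loc["p1"]
        assert row["m"] == pytest.approx(2.0)
        assert row["s"] == pytest.approx(1.0)  # sample SD, n-1
        assert row["direction"] == "lower"

    def test_direction_higher_by_symmetry(self):
        ref = fit_reference(_pm([10, 11, 12], [1, 2, 3]))
        assert ref.table.loc["p1", "direction"] == "higher"

    def test_equal_means_default_lower_with_warning(self):
        with pytest.warns(UserWarning, match="direction defaults"):
            ref = fit_reference(_pm([1, 2, 3], [1, 2, 3]))
        assert ref.table.loc["p1", "direction"] == "lower"

    def test_single_subject_group_errors(self):
        with pytest.raises(ValueError, match=">=2 subjects"):
            fit_reference(_pm([1], [2, 3]))


class TestDerivative:
    def test_boundary_zero_for_lower_direction(self):
        assert derivative(32.0, m=30.0, s=2.0, direction="lower") == 0.0

    def test_lower_direction_formula(self):
        assert derivative(28.0, m=30.0, s=2.0, direction="lower") == pytest.approx(-4.0)

    def test_higher_direction_formula(self):
        assert derivative(6.0, m=5.0, s=1.0, direction="higher") == pytest.approx(-2.0)

    @given(
        v=st.floats(-50, 50),
        m=st.floats(-10, 40),
        s=st.floats(0, 5),
        eps=st.floats(0.001, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity_in_value(self, v, m, s, eps):
        """Strictly increasing for 'lower', strictly decreasing for 'higher'."""
        assert derivative(v + eps, m, s, "lower") > derivative(v, m, s, "lower")
        assert derivative(v + eps, m, s, "higher") < derivative(v, m, s, "higher")

    def test_refit_is_bitwise_reproducible(self):
        rng = np.random.default_rng(11)
        values = pd.DataFrame(
            rng.normal(30, 3, size=(10, 12)), columns=[f"p{i}" for i in range(1, 13)]
        )
        groups = pd.Series(["ccRCC"] * 5 + ["HS"] * 5, index=values.index)
        pm = ParameterMatrix(values, groups)
        d1 = derivative_matrix(pm, fit_reference(pm)).values
        d2 = derivative_matrix(pm, fit_reference(pm)).values
        assert d1.equals(d2)


class TestPanelSum:
    def test_published_spot_sums(self, discovery_derivs):
        scores = panel_sum(discovery_derivs, SEVEN_PARAM_SUBSET)
        assert scores["ccRCC 2"] == pytest.approx(-27.24, abs=0.01)
        assert scores["ccRCC 13"] == pytest.approx(-7.11, abs=0.01)
        assert scores["HS 11"] == pytest.approx(31.68, abs=0.01)

    def test_zero_rows_sum_to_zero(self):
        derivs = DerivativeMatrix(
            pd.DataFrame(0.0, index=["a"], columns=[f"p{i}" for i in range(1, 13)]),
            pd.Series(["ccRCC"], index=["a"]),
        )
        for subset in ((1,), (2, 4, 5), tuple(range(1, 13))):
            assert panel_sum(derivs, subset)["a"] == 0.0

    @given(perm=st.permutations(list(range(1, 13))), k=st.integers(1, 11))
    @settings(max_examples=30, deadline=None)
    def test_additivity_over_disjoint_subsets(self, perm, k, discovery_derivs):
        a, b = perm[:k], perm[k:]
        total = panel_sum(discovery_derivs, perm)
        assert np.allclose(
            total, panel_sum(discovery_derivs, a) + panel_sum(discovery_derivs, b)
        )

    def test_invalid_subset_errors(self, discovery_derivs):
        with pytest.raises(ValueError, match="outside 1-12"):
            panel_sum(discovery_derivs, [0, 5])
        with pytest.raises(ValueError, match="nonempty"):
            panel_sum(discovery_derivs, [])


class TestClassify:
    def test_boundary_is_healthy(self):
        assert classify(-7.11) == "diseased"
        assert classify(-6.31) == "healthy"
        assert classify(-6.7) == "healthy"  # strict inequality at the cutoff


def test_youden_midpoint_cutoff_matches_published(discovery_derivs):
    """The midpoint rule lands at -6.71 on the discovery scores,
    consistent with the published -6.7 cutoff."""
    scores = panel_sum(discovery_derivs, SEVEN_PARAM_SUBSET)
    case = (discovery_derivs.groups == "ccRCC").to_numpy()
    assert choose_cutoff(scores.to_numpy(), case) == pytest.approx(-6.71)


class TestSearch:
    def test_perfect_singleton_wins(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(0, 1, size=(12, 12)), columns=[f"p{i}" for i in range(1, 13)]
        )
        values["p6"] = [-5.0] * 6 + [5.0] * 6  # perfect separator, lower = case
        groups = pd.Series(["ccRCC"] * 6 + ["HS"] * 6, index=values.index)
        res = search_best_panel(DerivativeMatrix(values, groups), sizes=[1])
        assert res.subset == (6,)
        assert res.metrics.auc == 1.0

    def test_subject_order_invariance(self, discovery_derivs):
        res1 = search_best_panel(discovery_derivs)
        shuffled = DerivativeMatrix(
            discovery_derivs.values.iloc[::-1], discovery_derivs.groups.iloc[::-1]
        )
        res2 = search_best_panel(shuffled)
        assert res1.subset == res2.subset
        assert res1.metrics.auc == pytest.approx(res2.metrics.auc)

    def test_empty_sizes_error(self, discovery_derivs):
        with pytest.raises(ValueError, match="empty"):
            search_best_panel(discovery_derivs, sizes=[])

    def test_published_subset_auc_is_096(self, discovery_derivs):
        from uromir.diagnostics import roc_auc

        scores = panel_sum(discovery_derivs, SEVEN_PARAM_SUBSET)
        auc, p = roc_auc(scores.to_numpy(), (discovery_derivs.groups == "ccRCC").to_numpy())
        assert round(auc, 2) == 0.96
        assert p < 0.0001
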