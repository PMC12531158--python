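"""Composite-index construction: indicator formulas, entropy weighting,
TOPSIS scoring, and the invariants that make the index a valid composite."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

import fsispace as f
from fsispace import synth
from fsispace.index import (
    DEFAULT_INDICATORS,
    IndicatorSpec,
    entropy_weights,
    normalize_indicators,
    topsis_scores,
)


def entropy_weights_oracle(x: np.ndarray) -> np.ndarray:
    """Literal step-by-step evaluation of the entropy-weight formula."""
    n, k = x.shape
    w = np.empty(k)
    d = np.empty(k)
    for j in range(k):
        col = x[:, j]
        p = col / col.sum()
        e = 0.0
        for pi in p:
            if pi > 0:
                e -= pi * np.log(pi)
        e /= np.log(n)
        d[j] = 1 - e
    return d / d.sum()


def topsis_oracle(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Literal evaluation of weighted distances to ideal/anti-ideal."""
    v = x * w
    ideal = v.max(axis=0)
    anti = v.min(axis=0)
    scores = np.empty(len(x))
    for i in range(len(x)):
        dp = np.sqrt(((v[i] - ideal) ** 2).sum())
        dn = np.sqrt(((v[i] - anti) ** 2).sum())
        scores[i] = 0.5 if dp + dn == 0 else dn / (dp + dn)
    return scores


def _as_matrix(arr):
    return pd.DataFrame(np.asarray(arr, float))


class TestIndicators:
    def test_formulas_match_declared_units(self, default_panel):
        panel, _ = default_panel
        m = f.compute_indicators(panel)
        assert m.shape[1] == 12
        one = panel.data.iloc[10]
        key = (one["unit"], one["year"])
        assert m.loc[key, "asset_liability_ratio"] == pytest.approx(
            one["total_liabilities"] / one["total_assets"]
        )
        assert m.loc[key, "bed_turnover"] == pytest.approx(
            one["discharges"] / one["beds"]
        )

    def test_ratio_and_growth_values(self):
        rows = []
        for y, rev in ((2010, 100.0), (2011, 110.0)):
            rows.append(
                {"unit": "a", "region": "east", "year": y,
                 "total_liabilities": 34.0, "total_assets": 100.0,
                 "total_revenue": rev}
            )
        panel = f.PanelDataset(pd.DataFrame(rows))
        spec = [
            IndicatorSpec("alr", "solvency", "cost", "ratio",
                          "total_liabilities", "total_assets"),
            IndicatorSpec("growth", "development_capacity", "benefit", "growth",
                          field="total_revenue", scale=100.0),
        ]
        m = f.compute_indicators(panel, spec)
        assert m.loc[("a", 2011), "alr"] == pytest.approx(0.34)
        assert m.loc[("a", 2011), "growth"] == pytest.approx(10.0)
        # first year back-filled with earliest computed growth
        assert m.loc[("a", 2010), "growth"] == pytest.approx(10.0)

    def test_zero_denominator_names_offender(self):
        rows = [
            {"unit": "a", "region": "east", "year": 2010, "num": 1.0, "den": 0.0},
            {"unit": "b", "region": "east", "year": 2010, "num": 1.0, "den": 1.0},
        ]
        panel = f.PanelDataset(pd.DataFrame(rows))
        spec = [IndicatorSpec("r", "solvency", "benefit", "ratio", "num", "den")]
        with pytest.raises(ZeroDivisionError, match="'r'.*a"):
            f.compute_indicators(panel, spec)


class TestNormalization:
    @pytest.mark.parametrize(
        "direction,expected",
        [("benefit", [0, 0.5, 1]), ("cost", [1, 0.5, 0])],
    )
    def test_minmax(self, direction, expected):
        m = _as_matrix([[2], [4], [6]])
        m.columns = ["c"]
        spec = [IndicatorSpec("c", "solvency", direction, "ratio", "a", "b")]
        out, flags = normalize_indicators(m, spec)
        assert out["c"].tolist() == pytest.approx(expected)
        assert flags == ()

    def test_constant_column_flagged_half(self):
        m = _as_matrix([[3, 1], [3, 2], [3, 4]])
        m.columns = ["c0", "c1"]
        spec = [
            IndicatorSpec("c0", "solvency", "benefit", "ratio", "a", "b"),
            IndicatorSpec("c1", "solvency", "benefit", "ratio", "a", "b"),
        ]
        out, flags = normalize_indicators(m, spec)
        assert (out["c0"] == 0.5).all()
        assert flags == ("c0",)


class TestEntropyWeights:
    def test_identical_columns_share_weight(self):
        m = _as_matrix([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]])
        w = entropy_weights(m)
        assert w.tolist() == pytest.approx([0.5, 0.5])

    def test_constant_column_gets_zero(self):
        m = _as_matrix([[0.5, 0.0], [0.5, 1.0]])
        w = entropy_weights(m)
        assert w.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert w.iloc[1] == pytest.approx(1.0)

    def test_matches_literal_formula_oracle(self):
        x = np.array([[0, 1], [0.2, 0.8], [0.8, 0.2], [1, 0]])
        w = entropy_weights(_as_matrix(x))
        np.testing.assert_allclose(w.to_numpy(), entropy_weights_oracle(x), atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="single row"):
            entropy_weights(_as_matrix([[0.3, 0.7]]))


class TestTopsis:
    def test_extreme_rows_score_zero_and_one(self):
        m = _as_matrix([[1, 1], [0.4, 0.6], [0, 0]])
        w = pd.Series([0.5, 0.5], index=m.columns)
        out = topsis_scores(m, w)
        assert out.scores.iloc[0] == pytest.approx(1.0)
        assert out.scores.iloc[-1] == pytest.approx(0.0)

    def test_matches_distance_oracle(self):
        x = np.array([[1, 0], [0.5, 0.5], [0, 1]])
        w = np.array([0.5, 0.5])
        out = topsis_scores(_as_matrix(x), pd.Series(w, index=[0, 1]))
        np.testing.assert_allclose(out.scores.to_numpy(), topsis_oracle(x, w), atol=1e-12)

    def test_identical_rows_score_half(self):
        m = _as_matrix([[0.3, 0.3], [0.3, 0.3]])
        w = pd.Series([0.5, 0.5], index=m.columns)
        out = topsis_scores(m, w)
        assert (out.scores == 0.5).all()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=3, max_size=3),
        min_size=3,
        max_size=6,
    )
)
def test_entropy_topsis_oracle_property(rows):
    """On arbitrary small normalized matrices, entropy weights and TOPSIS
    agree with the literal formula oracles."""
    x = np.asarray(rows, float)
    colsums = x.sum(axis=0)
    col_e = np.array([entropy_col_defined(x[:, j]) for j in range(x.shape[1])])
    if np.any(colsums == 0) or not col_e.any():
        return  # weights undefined; rejected upstream by preconditions
    m = _as_matrix(x)
    w = entropy_weights(m)
    if not np.isfinite(w).all():
        return
    np.testing.assert_allclose(w.to_numpy(), entropy_weights_oracle(x), atol=1e-10)
    out = topsis_scores(m, w)
    np.testing.assert_allclose(
        out.scores.to_numpy(), topsis_oracle(x, w.to_numpy()), atol=1e-10
    )
    assert w.sum() == pytest.approx(1.0, abs=1e-9)
    assert ((out.scores >= -1e-12) & (out.scores <= 1 + 1e-12)).all()


def entropy_col_defined(col):
    """True when a column carries information (non-uniform shares)."""
    if col.sum() == 0:
        return False
    p = col / col.sum()
    p = p[p > 0]
    return len(p) > 0 and not np.allclose(p, p[0])


class TestFullIndex:
    def test_dominant_unit_scores_highest(self):
        rng = np.random.default_rng(0)
        rows = []
        for u in ("a", "b", "c"):
            for y in (2010, 2011):
                base = 3.0 if u == "a" else rng.uniform(1, 2)
                rows.append(
                    {"unit": u, "region": "east", "year": y,
                     "num1": base, "den1": 1.0, "num2": base * 2, "den2": 1.0}
                )
        panel = f.PanelDataset(pd.DataFrame(rows))
        spec = [
            IndicatorSpec("i1", "solvency", "benefit", "ratio", "num1", "den1"),
            IndicatorSpec("i2", "profitability", "benefit", "ratio", "num2", "den2"),
        ]
        out = f.build_sustainability_index(panel, spec)
        wide = out.scores.unstack("year")
        assert (wide.loc["a"] >= wide.drop("a").max()).all()

    def test_unit_order_permutation_invariance(self, default_panel):
        panel, _ = default_panel
        out1 = f.build_sustainability_index(panel)
        shuffled = f.PanelDataset(
            panel.data.sample(frac=1, random_state=3).reset_index(drop=True)
        )
        out2 = f.build_sustainability_index(shuffled)
        s1 = out1.scores.sort_index()
        s2 = out2.scores.sort_index()
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_affine_rescaling_of_raw_column_invariance(self, default_panel):
        panel, _ = default_panel
        out1 = f.build_sustainability_index(panel)
        scaled = panel.data.copy()
        scaled["total_liabilities"] = scaled["total_liabilities"] * 3.0
        scaled["total_assets"] = scaled["total_assets"] * 3.0
        out2 = f.build_sustainability_index(f.PanelDataset(scaled))
        np.testing.assert_allclose(
            out1.scores.to_numpy(), out2.scores.to_numpy(), atol=1e-10
        )

    def test_recovers_latent_quality_ranking(self, default_panel):
        panel, truth = default_panel
        idx = f.build_sustainability_index(panel)
        latent = synth.truth_scores(truth).loc[idx.scores.index]
        rho = spearmanr(idx.scores.to_numpy(), latent.to_numpy()).statistic
        assert rho > 0.9

    def test_weights_sum_and_score_bounds(self, default_panel):
        panel, _ = default_panel
        idx = f.build_sustainability_index(panel)
        assert idx.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert (idx.weights >= 0).all()
        assert idx.scores.between(0, 1).all()
        assert set(idx.dimension_scores.columns) == {
            "solvency", "profitability", "operational_efficiency",
            "development_capacity",
        }


def test_dominance_preserved_after_direction_adjustment():
    """If row a weakly dominates row b on the normalized matrix, its
    TOPSIS score is at least b's."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        x = rng.random((5, 4))
        x[0] = x[1] + rng.random(4) * 0.2  # row 0 dominates row 1
        m = _as_matrix(np.clip(x, 0, 1))
        w = pd.Series(rng.dirichlet(np.ones(4)), index=m.columns)
        out = topsis_scores(m, w)
        assert out.scores.iloc[0] >= out.scores.iloc[1] - 1e-12
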