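"""Composite financial-sustainability index: indicators, entropy weights, TOPSIS.

The index aggregates 12 indicators in four dimensions (solvency,
profitability, operational efficiency, development capacity) into a
per-unit-year score in [0, 1].  Weights are objective: an indicator's
weight is proportional to the information divergence (1 - entropy) of its
normalized cross-observation distribution.  Scores are the TOPSIS relative
closeness D- / (D+ + D-) to the ideal / anti-ideal rows of the weighted
matrix.

Normalization and entropy weighting are applied to the POOLED unit-year
matrix (not per year) so that scores are comparable over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import PanelDataset

Dimension = Literal[
    "solvency", "profitability", "operational_efficiency", "development_capacity"
]

DIMENSIONS: tuple[str, ...] = (
    "solvency",
    "profitability",
    "operational_efficiency",
    "development_capacity",
)


@dataclass(frozen=True)
class IndicatorSpec:
    """Declarative definition of one indicator.

    ``kind`` selects the formula:

    * ``ratio``       -> numerator / denominator * scale
    * ``diff_ratio``  -> (numerator - denominator) / numerator * scale
    * ``growth``      -> (x_t - x_{t-1}) / x_{t-1} * scale  on ``field``
    """

    name: str
    dimension: Dimension
    direction: Literal["benefit", "cost"]
    kind: Literal["ratio", "diff_ratio", "growth"]
    numerator: str | None = None
    denominator: str | None = None
    field: str | None = None
    scale: float = 1.0


#: The default 12-indicator specification.  Directions: asset-liability
#: ratio (debt burden) and average length of stay (longer stays = lower
#: efficiency) are cost indicators; everything else is benefit.
DEFAULT_INDICATORS: tuple[IndicatorSpec, ...] = (
    IndicatorSpec("asset_liability_ratio", "solvency", "cost", "ratio",
                  "total_liabilities", "total_assets"),
    IndicatorSpec("current_ratio", "solvency", "benefit", "ratio",
                  "current_assets", "current_liabilities"),
    IndicatorSpec("cash_ratio", "solvency", "benefit", "ratio",
                  "cash", "current_liabilities"),
    IndicatorSpec("surplus_ratio", "profitability", "benefit", "diff_ratio",
                  "medical_revenue", "medical_expenditure"),
    IndicatorSpec("total_asset_return", "profitability", "benefit", "ratio",
                  "net_income", "total_assets", scale=100.0),
    IndicatorSpec("net_profit_margin", "profitability", "benefit", "ratio",
                  "net_income", "total_revenue", scale=100.0),
    IndicatorSpec("bed_turnover", "operational_efficiency", "benefit", "ratio",
                  "discharges", "beds"),
    IndicatorSpec("avg_length_of_stay", "operational_efficiency", "cost", "ratio",
                  "patient_days", "discharges"),
    IndicatorSpec("outpatient_per_staff", "operational_efficiency", "benefit", "ratio",
                  "outpatient_visits", "staff"),
    IndicatorSpec("fixed_asset_growth", "development_capacity", "benefit", "growth",
                  field="fixed_assets", scale=100.0),
    IndicatorSpec("revenue_growth", "development_capacity", "benefit", "growth",
                  field="total_revenue", scale=100.0),
    IndicatorSpec("equipment_renewal", "development_capacity", "benefit", "ratio",
                  "new_equipment_investment", "total_equipment_value", scale=100.0),
)


@dataclass
class CompositeIndexPanel:
    """Sustainability scores plus the weights that produced them."""

    scores: pd.Series                  # (unit, year) -> score in [0, 1]
    dimension_scores: pd.DataFrame     # (unit, year) x dimension
    weights: pd.Series                 # indicator -> weight, sums to 1
    degenerate: tuple[str, ...] = ()   # constant columns flagged upstream

    def wide(self) -> pd.DataFrame:
        """Scores as a units x years matrix."""
        return self.scores.unstack("year")


def compute_indicators(
    panel: PanelDataset, spec: Sequence[IndicatorSpec] = DEFAULT_INDICATORS
) -> pd.DataFrame:
    """Evaluate each indicator formula; rows indexed by (unit, year).

    Growth indicators need the previous year; the first panel year is
    back-filled with the unit's earliest computed growth value so the
    pooled matrix stays balanced.
    """
    df = panel.data.sort_values(["unit", "year"])
    out = pd.DataFrame(index=pd.MultiIndex.from_frame(df[["unit", "year"]]))
    for ind in spec:
        if ind.kind in ("ratio", "diff_ratio"):
            for fld in (ind.numerator, ind.denominator):
                if fld not in df.columns:
                    raise KeyError(f"indicator {ind.name!r} needs missing field {fld!r}")
            num = df[ind.numerator].to_numpy(float)
            den = df[ind.denominator].to_numpy(float)
            denom = num if ind.kind == "diff_ratio" else den
            if np.any(denom == 0):
                i = int(np.argmax(denom == 0))
                raise ZeroDivisionError(
                    f"zero denominator for indicator {ind.name!r} at "
                    f"({df['unit'].iloc[i]}, {df['year'].iloc[i]})"
                )
            val = (num - den) / num if ind.kind == "diff_ratio" else num / den
            out[ind.name] = val * ind.scale
        else:  # growth
            if ind.field not in df.columns:
                raise KeyError(f"indicator {ind.name!r} needs missing field {ind.field!r}")
            g = (
                df.groupby("unit", sort=False)[ind.field]
                .transform(lambda s: s.pct_change())
                .to_numpy(float)
            )
            series = pd.Series(g * ind.scale, index=out.index)
            out[ind.name] = series.groupby("unit").transform(lambda s: s.bfill())
    return out


def normalize_indicators(
    m: pd.DataFrame, spec: Sequence[IndicatorSpec]
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Min-max normalize over the pooled rows.

    Benefit columns map x -> (x - min)/(max - min); cost columns reverse.
    Constant columns are set to 0.5 and flagged as degenerate.
    """
    directions = {s.name: s.direction for s in spec}
    out = pd.DataFrame(index=m.index)
    degenerate: list[str] = []
    for col in m.columns:
        x = m[col].to_numpy(float)
        lo, hi = np.min(x), np.max(x)
        if hi == lo:
            out[col] = 0.5
            degenerate.append(col)
            continue
        z = (x - lo) / (hi - lo)
        if directions.get(col, "benefit") == "cost":
            z = 1.0 - z
        out[col] = z
    return out, tuple(degenerate)


def entropy_weights(m: pd.DataFrame) -> pd.Series:
    """Entropy weights of a normalized (non-negative) matrix.

    p_ij = x_ij / sum_i x_ij;  e_j = -(1/ln n) sum_i p_ij ln p_ij with
    0 ln 0 := 0;  d_j = 1 - e_j;  w_j = d_j / sum_j d_j.
    """
    x = m.to_numpy(float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("entropy weights undefined for a single row")
    if np.any(x < 0):
        raise ValueError("entropy weights require non-negative cells")
    colsum = x.sum(axis=0)
    if np.any(colsum == 0):
        # an all-zero column carries no information; treated like a
        # degenerate (uniform) column below via p = 0 everywhere
        colsum = np.where(colsum == 0, 1.0, colsum)
    p = x / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    d = 1.0 - e
    if d.sum() <= 0:
        raise ValueError("all columns are uniform; entropy weights undefined")
    w = d / d.sum()
    return pd.Series(w, index=m.columns, name="weight")


def topsis_scores(
    m: pd.DataFrame,
    w: pd.Series,
    spec: Sequence[IndicatorSpec] | None = None,
    degenerate: tuple[str, ...] = (),
) -> CompositeIndexPanel:
    """TOPSIS relative closeness on a normalized matrix.

    The weighted matrix is v = x * w; ideal/anti-ideal rows are the
    column-wise max/min of v; the score is D- / (D+ + D-).  When a row is
    equidistant from identical ideal points (all rows identical) it scores
    0.5.  ``dimension_scores`` repeats the procedure on each dimension's
    columns with the same weights.
    """
    def closeness(sub: pd.DataFrame, wsub: pd.Series) -> np.ndarray:
        v = sub.to_numpy(float) * wsub.to_numpy(float)
        ideal, anti = v.max(axis=0), v.min(axis=0)
        d_pos = np.sqrt(((v - ideal) ** 2).sum(axis=1))
        d_neg = np.sqrt(((v - anti) ** 2).sum(axis=1))
        tot = d_pos + d_neg
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(tot > 0, d_neg / tot, 0.5)
        return c

    w = w.loc[m.columns]
    scores = pd.Series(closeness(m, w), index=m.index, name="score")
    dims = pd.DataFrame(index=m.index)
    if spec is not None:
        by_dim: dict[str, list[str]] = {}
        for s in spec:
            if s.name in m.columns:
                by_dim.setdefault(s.dimension, []).append(s.name)
        for dim, cols in by_dim.items():
            dims[dim] = closeness(m[cols], w.loc[cols])
    return CompositeIndexPanel(scores, dims, w, degenerate)


def build_sustainability_index(
    panel: PanelDataset, spec: Sequence[IndicatorSpec] = DEFAULT_INDICATORS
) -> CompositeIndexPanel:
    """Raw panel -> composite index: indicators, pooled normalization,
    entropy weights, TOPSIS.  Weights are computed once on the pooled
    matrix so scores are comparable across years."""
    m = compute_indicators(panel, spec)
    norm, degenerate = normalize_indicators(m, spec)
    w = entropy_weights(norm)
    return topsis_scores(norm, w, spec, degenerate)


def scores_panel(index: CompositeIndexPanel, panel: PanelDataset) -> PanelDataset:
    """Attach composite scores to a panel as an ``fsi`` value field."""
    extra = index.scores.rename("fsi").reset_index()
    return panel.with_fields(extra)
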