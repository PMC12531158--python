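"""Spatial weight matrices: contiguity, distance-decay, k-nearest-neighbor.

All spatial stages share the :class:`WeightMatrix` contract: an n x n
non-negative matrix with zero diagonal, optionally row-standardized so
each non-isolated row sums to one (the spatial lag Wx is then a neighbor
average, and the admissible interval for autoregressive parameters is
(1/omega_min, 1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core import AdjacencyStructure

Kind = Literal["contiguity", "economic_distance", "knn", "custom"]


@dataclass(frozen=True)
class WeightMatrix:
    units: tuple[str, ...]
    w: np.ndarray
    row_standardized: bool = False
    kind: Kind = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.w, float)
        n = len(self.units)
        if w.shape != (n, n):
            raise ValueError(f"weight matrix shape {w.shape} != ({n}, {n})")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have a zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "w", w)

    @property
    def n(self) -> int:
        return len(self.units)

    @property
    def s0(self) -> float:
        """Sum of all weights (the Moran normalizer S0)."""
        return float(self.w.sum())

    @property
    def isolated(self) -> tuple[str, ...]:
        rs = self.w.sum(axis=1)
        return tuple(u for u, s in zip(self.units, rs) if s == 0)

    def lag(self, x: np.ndarray | pd.Series) -> np.ndarray:
        """Spatial lag Wx (a neighbor mean when row-standardized)."""
        if isinstance(x, pd.Series):
            x = x.loc[list(self.units)].to_numpy(float)
        return self.w @ np.asarray(x, float)

    def eigenvalues(self) -> np.ndarray:
        """Real spectrum of W (similarity-transformed when row-standardized).

        A row-standardized binary-contiguity matrix is similar to the
        symmetric D^{-1/2} A D^{-1/2}, so its spectrum is real; general
        asymmetric weights fall back to the real parts of eig().
        """
        w = self.w
        if np.allclose(w, w.T):
            return np.linalg.eigvalsh(w)
        rs = w.sum(axis=1)
        base = w * np.where(rs > 0, rs, 1.0)[:, None]  # undo row scaling
        if np.allclose(base, base.T):
            d = np.where(rs > 0, rs, 1.0)
            sym = base / np.sqrt(np.outer(d, d))
            ev = np.linalg.eigvalsh(sym)
            if len(self.isolated) == 0:
                return ev
        return np.sort(np.real(np.linalg.eigvals(w)))


def contiguity_weights(adj: AdjacencyStructure) -> WeightMatrix:
    """Binary 0/1 weights from an undirected contiguity structure."""
    n = len(adj.units)
    pos = {u: i for i, u in enumerate(adj.units)}
    w = np.zeros((n, n))
    for e in adj.edges:
        a, b = tuple(e)
        w[pos[a], pos[b]] = w[pos[b], pos[a]] = 1.0
    wm = WeightMatrix(tuple(adj.units), w, kind="contiguity")
    if wm.isolated:
        warnings.warn(f"isolated unit(s) with no neighbors: {wm.isolated}")
    return wm


def distance_weights(
    units: Sequence[str],
    d: np.ndarray,
    scheme: Literal["inverse", "inverse_squared"] = "inverse",
    cutoff: float | None = None,
) -> WeightMatrix:
    """Inverse-distance weights w_ij = 1/d_ij (or 1/d_ij^2), zeroed beyond
    ``cutoff``.  Requires a symmetric distance matrix with zero diagonal
    and strictly positive off-diagonal entries."""
    d = np.asarray(d, float)
    n = len(units)
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] <= 0):
        raise ValueError("off-diagonal distances must be strictly positive")
    with np.errstate(divide="ignore"):
        w = np.where(off, 1.0 / d, 0.0)
    if scheme == "inverse_squared":
        w = np.where(off, w**2, 0.0)
    elif scheme != "inverse":
        raise ValueError(f"unknown scheme {scheme!r}")
    if cutoff is not None:
        w = np.where(d <= cutoff, w, 0.0)
        np.fill_diagonal(w, 0.0)
    wm = WeightMatrix(tuple(units), w, kind="economic_distance")
    if wm.isolated:
        warnings.warn(f"cutoff isolates unit(s): {wm.isolated}")
    return wm


def economic_distance_matrix(values: pd.Series) -> np.ndarray:
    """|x_i - x_j| distances from a unit-indexed attribute (e.g. GDP pc).

    Exact ties would give a zero distance; they are nudged to the smallest
    positive gap so inverse weights stay finite."""
    x = values.to_numpy(float)
    d = np.abs(x[:, None] - x[None, :])
    off = ~np.eye(len(x), dtype=bool)
    if np.any(d[off] == 0):
        positive = d[off][d[off] > 0]
        eps = positive.min() if len(positive) else 1.0
        d = np.where(off & (d == 0), eps, d)
    return d


def knn_weights(units: Sequence[str], d: np.ndarray, k: int) -> WeightMatrix:
    """Row-wise k-nearest-neighbor weights (asymmetry allowed).

    Ties at the k-th neighbor are broken by unit-id order, making builds
    deterministic."""
    d = np.asarray(d, float)
    n = len(units)
    if not 0 < k < n:
        raise ValueError(f"k must be in 1..{n - 1}, got {k}")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    order_key = np.argsort(np.asarray(units, object), kind="stable")
    rank_of_unit = np.empty(n, int)
    rank_of_unit[order_key] = np.arange(n)
    w = np.zeros((n, n))
    for i in range(n):
        cand = [(d[i, j], rank_of_unit[j], j) for j in range(n) if j != i]
        cand.sort()
        for _, _, j in cand[:k]:
            w[i, j] = 1.0
    return WeightMatrix(tuple(units), w, kind="knn")


def row_standardize(wm: WeightMatrix) -> WeightMatrix:
    """Divide each non-zero row by its sum; idempotent; zero rows kept."""
    rs = wm.w.sum(axis=1)
    scale = np.where(rs > 0, rs, 1.0)
    return replace(wm, w=wm.w / scale[:, None], row_standardized=True)


def read_distance_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Square CSV with a unit-id header row and index column."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column unit ids differ")
    return list(df.index), df.to_numpy(float)
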