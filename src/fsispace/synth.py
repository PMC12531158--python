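"""Synthetic provincial panels with known ground truth.

The main generator emulates the statistical structure the analysis
assumes: a balanced 31-unit x 13-year panel with east/central/west
regional heterogeneity, a three-phase upward trend with a transient
negative shock, a spatial-Durbin outcome process, covariates with
regional location shifts, and raw financial fields back-generated so the
composite-index pipeline reproduces a noisy monotone transform of the
latent index.  Every data-generating parameter is recorded in a truth
record so downstream recovery tests never hard-code constants.

Smaller special-purpose generators (AR(1) catch-up panels, convergence
clubs, neighbor-dependent class dynamics) provide clean ground truth for
the convergence and Markov estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .core import AdjacencyStructure, PanelDataset, load_china_adjacency, load_table2_fixture
from .weights import WeightMatrix, contiguity_weights, row_standardize

COVARIATES = (
    "fiscal_ratio", "insurance_coverage", "drg_intensity", "log_gdp_pc",
    "urbanization", "aging", "log_density", "doctors_per_1000",
    "demand_intensity",
)

#: Regional location shift of each covariate (east, central, west), on the
#: standardized-anomaly scale the structural equation uses.
DEFAULT_COV_SHIFTS: dict[str, tuple[float, float, float]] = {
    "fiscal_ratio": (0.06, 0.0, -0.06),
    "insurance_coverage": (0.05, 0.0, -0.05),
    "drg_intensity": (0.08, 0.0, -0.08),
    "log_gdp_pc": (0.15, 0.0, -0.15),
    "urbanization": (0.10, 0.0, -0.10),
    "aging": (0.05, 0.02, -0.05),
    "log_density": (0.12, 0.0, -0.12),
    "doctors_per_1000": (0.06, 0.0, -0.06),
    "demand_intensity": (-0.04, 0.0, 0.04),
}

#: Default structural coefficients (outcome units per covariate anomaly)
#: and spatial-lag coefficients.  The pairs reproduce published direct /
#: total effect magnitudes under the default contiguity weights; see
#: :func:`solve_coefficients`.
DEFAULT_EFFECT_TARGETS: dict[str, tuple[float, float]] = {
    # covariate: (direct effect, total effect)
    "fiscal_ratio": (0.312, 0.401),
    "insurance_coverage": (0.194, 0.261),
    "drg_intensity": (0.156, 0.197),
    "log_gdp_pc": (0.247, 0.320),
    "urbanization": (0.174, 0.226),
    "aging": (-0.095, -0.123),
    "log_density": (0.071, 0.090),
    "doctors_per_1000": (0.136, 0.179),
    "demand_intensity": (-0.081, -0.102),
}


@dataclass
class SyntheticConfig:
    """Full description of the data-generating process."""

    n_units: int = 31
    n_years: int = 13
    start_year: int = 2010
    region_split: tuple[int, int, int] = (11, 8, 12)
    adjacency: str = "china_fixture"        # china_fixture | ring_lattice | random_planar
    rho: float = 0.289
    beta: dict[str, float] | None = None     # None -> solved from effect targets
    theta: dict[str, float] | None = None
    effect_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_TARGETS)
    )
    noise_sd: float = 0.03
    cov_scale: float = 0.12
    unit_effect_sd: float = 0.12
    trend_base: float = 0.458
    trend_slopes: tuple[float, float, float] = (0.009, 0.020, 0.006)
    phase_bounds: tuple[int, int] = (6, 10)  # year indices starting phases 2, 3
    shock_year: int = 2020
    shock_magnitude: float = -0.031
    shock_duration: int = 1
    region_offsets: tuple[float, float, float] = (0.149, 0.042, -0.094)
    convergence_rate: float = 0.0
    dispersion_path: tuple[tuple[int, float], ...] = ((0, 1.0), (6, 0.76), (12, 0.90))
    indicator_noise_sd: float = 0.015
    seed: int = 0

    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


def generate_adjacency(kind: str, n: int, seed: int = 0) -> AdjacencyStructure:
    """Connected synthetic spatial structures for non-China runs."""
    if n < 3:
        raise ValueError("need at least 3 units")
    units = [f"u{i:02d}" for i in range(n)]
    if kind == "ring_lattice":
        pairs = [(units[i], units[(i + 1) % n]) for i in range(n)]
        return AdjacencyStructure.from_edge_list(pairs, units)
    if kind == "random_planar":
        rng = np.random.default_rng(seed)
        pts = rng.random((n, 2))
        tri = Delaunay(pts)
        pairs = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
                pairs.add((units[i], units[j]))
        adj = AdjacencyStructure.from_edge_list(sorted(pairs), units)
        g = nx.Graph(sorted(tuple(sorted(e)) for e in adj.edges))
        assert nx.is_connected(g), "Delaunay triangulation should be connected"
        return adj
    raise ValueError(f"unknown adjacency kind {kind!r}")


def solve_coefficients(
    wm: WeightMatrix, rho: float, targets: Mapping[str, tuple[float, float]]
) -> tuple[dict[str, float], dict[str, float]]:
    """Back out (beta_r, theta_r) giving requested direct/total effects.

    Under a row-standardized W the average row sum of (I - rho W)^{-1} is
    1/(1 - rho) and of (I - rho W)^{-1} W is rho/(1-rho)+... — both are
    computed exactly here, giving a 2x2 linear system per covariate:

        beta * m1 + theta * m2 = direct    (average diagonals)
        beta * t1 + theta * t2 = total     (average row sums)
    """
    n = wm.n
    M = np.linalg.inv(np.eye(n) - rho * wm.w)
    MW = M @ wm.w
    m1, m2 = np.trace(M) / n, np.trace(MW) / n
    t1, t2 = M.sum() / n, MW.sum() / n
    A = np.array([[m1, m2], [t1, t2]])
    beta, theta = {}, {}
    for name, (direct, total) in targets.items():
        b, t = np.linalg.solve(A, [direct, total])
        beta[name] = float(b)
        theta[name] = float(t)
    return beta, theta


def _build_weights(cfg: SyntheticConfig) -> tuple[WeightMatrix, list[str], list[str]]:
    if cfg.adjacency == "china_fixture":
        if cfg.n_units != 31:
            raise ValueError("china_fixture implies 31 units")
        adj = load_china_adjacency()
        t2 = load_table2_fixture()
        regions = t2.set_index("province").loc[list(adj.units), "region"].tolist()
    else:
        adj = generate_adjacency(cfg.adjacency, cfg.n_units, cfg.seed)
        ne, nc, nw = cfg.region_split
        if ne + nc + nw != cfg.n_units:
            raise ValueError("region split must sum to n_units")
        regions = ["east"] * ne + ["central"] * nc + ["west"] * nw
    return row_standardize(contiguity_weights(adj)), list(adj.units), regions


def _trend_path(cfg: SyntheticConfig) -> np.ndarray:
    s1, s2, s3 = cfg.trend_slopes
    b1, b2 = cfg.phase_bounds
    path = [cfg.trend_base]
    for t in range(1, cfg.n_years):
        slope = s1 if t < b1 else (s2 if t < b2 else s3)
        path.append(path[-1] + slope)
    return np.array(path)


def _dispersion(cfg: SyntheticConfig) -> np.ndarray:
    t = np.arange(cfg.n_years)
    if cfg.convergence_rate > 0:
        return np.exp(-cfg.convergence_rate * t)
    xs, ys = zip(*cfg.dispersion_path)
    return np.interp(t, xs, ys)


def generate_panel(cfg: SyntheticConfig) -> tuple[PanelDataset, dict]:
    """Generate a raw panel (financial fields + covariates) and the truth
    record.

    The latent index is built per year from cross-sectional deviations
    d_t = region_offset + a_i + (I - rho W)^{-1}(Xc_t beta + W Xc_t theta
    + eps_t) (Xc pooled-centered covariates, a_i persistent unit effects)
    as
        y_t = trend_t + shock_t + mean(d_t) + g(t) * (d_t - mean(d_t)),
    where g(t) is the dispersion path producing the V-shaped
    fall-then-rise of cross-sectional spread.  The deterministic
    components enter after the spatial multiplier so phase slopes and the
    shock magnitude appear on the index scale exactly as configured; with
    g identically 1 (recovery configurations) the index obeys the
    spatial-Durbin structural equation exactly.  The index is affinely
    squashed into (0, 1) only if it strays outside; the map is recorded.
    """
    if not -1 < cfg.rho < 1:
        raise ValueError(f"rho must be in (-1, 1), got {cfg.rho}")
    rng = np.random.default_rng(cfg.seed)
    wm, units, regions = _build_weights(cfg)
    n, T = cfg.n_units, cfg.n_years
    years = cfg.years()
    region_idx = np.array([("east", "central", "west").index(r) for r in regions])

    beta, theta = cfg.beta, cfg.theta
    if beta is None or theta is None:
        beta, theta = solve_coefficients(wm, cfg.rho, cfg.effect_targets)

    # covariates: region shift + persistent unit component + AR(1) anomaly
    cov = {}
    for name in COVARIATES:
        shifts = np.array(DEFAULT_COV_SHIFTS[name])[region_idx]
        a_i = rng.normal(0, cfg.cov_scale * 0.5, n)
        x = np.empty((T, n))
        e = rng.normal(0, cfg.cov_scale, n)
        for t in range(T):
            x[t] = shifts + a_i + e
            e = 0.5 * e + rng.normal(0, cfg.cov_scale * np.sqrt(0.75), n)
        cov[name] = x

    trend = _trend_path(cfg)
    shock = np.zeros(T)
    if cfg.shock_magnitude:
        i0 = cfg.shock_year - cfg.start_year
        for d in range(cfg.shock_duration):
            if 0 <= i0 + d < T:
                shock[i0 + d] = cfg.shock_magnitude
    offsets = np.array(cfg.region_offsets)[region_idx]
    # persistent unit effects, truncated at 2 sd to respect the (0,1) scale
    a_unit = np.clip(
        rng.normal(0, cfg.unit_effect_sd, n),
        -2 * cfg.unit_effect_sd, 2 * cfg.unit_effect_sd,
    )
    a_unit -= a_unit.mean()
    g = _dispersion(cfg)

    A_inv = np.linalg.inv(np.eye(n) - cfg.rho * wm.w)
    cov_mean = {name: float(cov[name].mean()) for name in COVARIATES}
    latent = np.empty((T, n))
    for t in range(T):
        xb = np.zeros(n)
        for name in COVARIATES:
            xc = cov[name][t] - cov_mean[name]
            xb += beta[name] * xc + theta[name] * (wm.w @ xc)
        eps = rng.normal(0, cfg.noise_sd, n)
        # cross-sectional deviations: regional offsets, persistent unit
        # effects, and the spatial-Durbin response to covariates and noise
        dev = offsets + a_unit + A_inv @ (xb + eps)
        # the dispersion path g(t) contracts/expands the whole deviation,
        # emulating regional gaps that narrow and then re-widen; in
        # recovery configurations g is identically 1 and the latent index
        # follows the spatial-Durbin structural equation exactly
        latent[t] = trend[t] + shock[t] + dev.mean() + g[t] * (dev - dev.mean())

    lo, hi = latent.min(), latent.max()
    if lo > 0.01 and hi < 0.99:
        scale, offset = 1.0, 0.0
    else:
        scale = 0.96 / (hi - lo)
        offset = 0.02 - scale * lo
    index = latent * scale + offset

    # back-generate raw indicator fields: each indicator a noisy monotone
    # transform of the index
    records = []
    fa = np.full(n, 100.0)      # fixed assets path
    tr = np.full(n, 100.0)      # total revenue path
    for t in range(T):
        q = index[t]
        eta = lambda s=cfg.indicator_noise_sd: rng.normal(0, s, n)
        if t > 0:
            fa = fa * (1 + 0.04 + 0.09 * q + eta())
            tr = tr * (1 + 0.06 + 0.12 * q + eta())
        total_assets = np.full(n, 100.0)
        row = {
            "total_assets": total_assets,
            "total_liabilities": total_assets * np.clip(0.55 - 0.30 * q + eta(), 0.05, 0.95),
            "current_liabilities": np.full(n, 50.0),
            "current_assets": 50.0 * np.clip(1.2 + 1.8 * q + eta(0.05), 0.2, None),
            "cash": 50.0 * np.clip(0.3 + 0.9 * q + eta(0.03), 0.02, None),
            "medical_revenue": 0.9 * tr,
            "total_revenue": tr,
            "net_income": tr * (0.02 + 0.08 * q + eta(0.005)),
            "discharges": 100.0 * (20 + 20 * q + eta(0.5)),
            "beds": np.full(n, 100.0),
            "outpatient_visits": 100.0 * (3000 + 2000 * q + eta(50.0)),
            "staff": np.full(n, 100.0),
            "fixed_assets": fa.copy(),
            "new_equipment_investment": 100.0 * (0.05 + 0.10 * q + eta(0.005)),
            "total_equipment_value": np.full(n, 100.0),
        }
        row["medical_expenditure"] = row["medical_revenue"] * (
            1 - np.clip(0.02 + 0.12 * q + eta(0.005), -0.5, 0.9)
        )
        row["patient_days"] = row["discharges"] * np.clip(12 - 5 * q + eta(0.2), 2.0, None)
        for i in range(n):
            rec = {"unit": units[i], "region": regions[i], "year": years[t]}
            for k, v in row.items():
                rec[k] = float(v[i])
            for name in COVARIATES:
                rec[name] = float(cov[name][t][i])
            records.append(rec)
    panel = PanelDataset(pd.DataFrame.from_records(records))

    idx_df = pd.DataFrame(index.T, index=units, columns=years)
    truth = {
        "config": asdict(cfg),
        "units": units,
        "regions": regions,
        "years": years,
        "beta": beta,
        "theta": theta,
        "rho": cfg.rho,
        "trend": trend.tolist(),
        "shock": shock.tolist(),
        "region_offsets": offsets.tolist(),
        "unit_effects": a_unit.tolist(),
        "dispersion": g.tolist(),
        "affine": {"scale": float(scale), "offset": float(offset)},
        "index": idx_df,
        "weights": wm,
    }
    return panel, truth


def truth_scores(truth: dict) -> pd.Series:
    """Latent index as a (unit, year)-indexed series, like pipeline scores."""
    idx: pd.DataFrame = truth["index"]
    s = idx.stack()
    s.index.names = ["unit", "year"]
    return s.rename("fsi")


def recovery_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Configuration for parameter-recovery experiments.

    Regional offsets, persistent unit effects and the dispersion path are
    switched off so the spatial Durbin process is the only cross-sectional
    structure and the pooled estimator with year dummies is correctly
    specified; trend and shock remain (absorbed exactly by the year
    dummies).
    """
    base = dict(
        seed=seed,
        unit_effect_sd=0.0,
        region_offsets=(0.0, 0.0, 0.0),
        dispersion_path=((0, 1.0), (12, 1.0)),
    )
    base.update(overrides)
    return SyntheticConfig(**base)


# ---------------------------------------------------- focused DGP helpers --

def ar1_scores(
    n_units: int = 31,
    n_years: int = 13,
    phi: float = 0.95,
    alpha: float | None = None,
    sigma: float = 0.02,
    start_year: int = 2010,
    seed: int = 0,
    mean_log: float = np.log(0.5),
) -> pd.Series:
    """Log-AR(1) index paths: ln y_{t+1} = alpha + phi ln y_t + eps.

    The implied catch-up (beta-convergence) coefficient of growth on
    lagged log level is phi - 1.  ``alpha`` defaults to the value keeping
    the stationary mean at ``mean_log``.
    """
    if alpha is None:
        alpha = (1 - phi) * mean_log
    rng = np.random.default_rng(seed)
    logy = np.empty((n_years, n_units))
    stat_sd = sigma / np.sqrt(max(1 - phi**2, 1e-8)) if abs(phi) < 1 else 0.15
    logy[0] = mean_log + rng.normal(0, min(stat_sd, 0.5), n_units)
    for t in range(1, n_years):
        logy[t] = alpha + phi * logy[t - 1] + rng.normal(0, sigma, n_units)
    units = [f"u{i:02d}" for i in range(n_units)]
    years = range(start_year, start_year + n_years)
    df = pd.DataFrame(np.exp(logy), index=list(years), columns=units)
    s = df.T.stack()
    s.index.names = ["unit", "year"]
    return s.rename("fsi")


def club_scores(
    club_targets: Sequence[float] = (0.712, 0.443),
    club_sizes: Sequence[int] = (15, 16),
    n_years: int = 13,
    decay: float = 0.35,
    spread: float = 0.25,
    noise: float = 0.003,
    n_divergent: int = 0,
    start_year: int = 2010,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Panels converging to distinct club targets.

    y_it = target_c * (1 + a_i exp(-decay * t)) + noise, a_i ~ U(-spread,
    spread).  Optional divergent units follow an exploding relative path.
    Returns (scores, true club labels: 1-based, -1 for divergent).
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], {}
    uid = 0
    for ci, (target, size) in enumerate(zip(club_targets, club_sizes), start=1):
        for _ in range(size):
            u = f"u{uid:02d}"
            uid += 1
            a = rng.uniform(-spread, spread)
            path = target * (1 + a * np.exp(-decay * np.arange(n_years)))
            path = path + rng.normal(0, noise, n_years)
            rows.append((u, path))
            labels[u] = ci
    for _ in range(n_divergent):
        u = f"u{uid:02d}"
        uid += 1
        path = 0.5 * np.exp(0.12 * np.arange(n_years)) + rng.normal(0, noise, n_years)
        rows.append((u, path))
        labels[u] = -1
    years = list(range(start_year, start_year + n_years))
    df = pd.DataFrame({u: p for u, p in rows}, index=years)
    s = df.T.stack()
    s.index.names = ["unit", "year"]
    return s.rename("fsi"), pd.Series(labels)


def markov_scores(
    wm: WeightMatrix,
    k: int = 3,
    p_up: Mapping[int, float] = None,
    p_down: float = 0.25,
    n_years: int = 200,
    start_year: int = 0,
    seed: int = 0,
) -> tuple[pd.Series, np.ndarray]:
    """Class dynamics with neighbor-dependent upward mobility.

    Units hold one of k classes encoded as values (c + 0.5)/k.  Each
    period a unit below the top class moves up with probability
    p_up[neighbor-lag class]; a unit above the bottom moves down with
    probability p_down.  Returns (scores, cutpoints) where the cutpoints
    reproduce the class encoding exactly.
    """
    if p_up is None:
        p_up = {0: 0.15, 1: 0.25, 2: 0.40}
    rng = np.random.default_rng(seed)
    n = wm.n
    cut = np.arange(1, k) / k
    classes = rng.integers(0, k, n)
    vals = np.empty((n_years, n))
    for t in range(n_years):
        v = (classes + 0.5) / k
        vals[t] = v
        lag = wm.w @ v
        lag_class = np.searchsorted(cut, lag, side="right")
        up = rng.random(n) < np.array([p_up[int(c)] for c in lag_class])
        down = rng.random(n) < p_down
        nxt = classes.copy()
        nxt[up & (classes < k - 1)] += 1
        move_down = down & (classes > 0) & ~(up & (classes < k - 1))
        nxt[move_down] -= 1
        classes = nxt
    years = list(range(start_year, start_year + n_years))
    df = pd.DataFrame(vals, index=years, columns=list(wm.units))
    s = df.T.stack()
    s.index.names = ["unit", "year"]
    return s.rename("fsi"), cut
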