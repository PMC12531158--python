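"""Temporal dynamics of the sustainability index.

Covers cross-sectional dispersion (sigma convergence), catch-up
regressions (beta convergence), Phillips-Sul log-t club clustering,
neighbor-conditioned spatial Markov chains, least-squares multiple
structural breaks selected by BIC, and event-window shock effects with a
placebo distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .index import CompositeIndexPanel
from .weights import WeightMatrix


# ---------------------------------------------------------------- sigma --

def sigma_convergence(scores: pd.Series | CompositeIndexPanel) -> pd.DataFrame:
    """Cross-sectional dispersion per year: sample SD and coefficient of
    variation.  A falling path is sigma convergence; a V shape is
    convergence followed by renewed divergence."""
    s = scores.scores if isinstance(scores, CompositeIndexPanel) else scores
    wide = s.unstack("year")
    if wide.shape[0] < 2:
        raise ValueError("sigma convergence needs at least 2 units per year")
    sd = wide.std(axis=0, ddof=1)
    cv = sd / wide.mean(axis=0)
    return pd.DataFrame({"sd": sd, "cv": cv})


# ----------------------------------------------------------------- beta --

@dataclass(frozen=True)
class BetaResult:
    beta: float
    se: float
    t_stat: float
    speed: float
    conditional: bool
    controls: tuple[str, ...] = ()
    n_obs: int = 0


def beta_convergence(
    scores: pd.Series | CompositeIndexPanel,
    controls: pd.DataFrame | None = None,
) -> BetaResult:
    """Pooled beta-convergence regression.

    Annual growth ln(y_{t+1}) - ln(y_t) is regressed on ln(y_t) (plus
    controls dated t when ``conditional``).  A negative coefficient means
    initially-low units grow faster; the implied annual catch-up speed is
    -ln(1 + beta).
    """
    s = scores.scores if isinstance(scores, CompositeIndexPanel) else scores
    if (s <= 0).any():
        raise ValueError("beta convergence requires positive index values")
    wide = s.unstack("year").sort_index(axis=1)
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 consecutive years")
    logy = np.log(wide)
    growth = logy.shift(-1, axis=1) - logy
    frames = []
    for year in wide.columns[:-1]:
        f = pd.DataFrame(
            {"growth": growth[year], "log_initial": logy[year]}, index=wide.index
        )
        if controls is not None:
            ctrl = controls.xs(year, level="year")
            f = f.join(ctrl)
        frames.append(f)
    df = pd.concat(frames).dropna()
    X = sm.add_constant(df.drop(columns="growth"))
    fit = sm.OLS(df["growth"], X).fit()
    beta = float(fit.params["log_initial"])
    se = float(fit.bse["log_initial"])
    return BetaResult(
        beta=beta,
        se=se,
        t_stat=float(fit.tvalues["log_initial"]),
        speed=float(-np.log1p(beta)),
        conditional=controls is not None,
        controls=tuple(controls.columns) if controls is not None else (),
        n_obs=int(fit.nobs),
    )


# ------------------------------------------------------- log-t clubs ----

@dataclass
class ClubAssignment:
    clubs: pd.Series            # unit -> club index (1-based); -1 = divergent
    club_targets: dict[int, float]
    log_t_stats: list[dict] = field(default_factory=list)

    @property
    def n_clubs(self) -> int:
        return int((pd.Series(list(self.club_targets)).astype(int) > 0).sum())


def log_t_regression(
    wide: pd.DataFrame, trim_fraction: float = 0.3
) -> tuple[float, float]:
    """Phillips-Sul log-t test on a units x years block.

    Relative transition h_it = y_it / cross-mean_t; cross-sectional
    variance H_t = mean_i (h_it - 1)^2.  Regress
    log(H_1/H_t) - 2 log(log(t+1)) on log(t) over the post-trim sample
    with HAC standard errors; returns (slope, t-statistic).  A t below
    -1.65 rejects convergence of the block.
    """
    y = wide.to_numpy(float)
    n, T = y.shape
    if T < 5:
        raise ValueError("log-t regression needs at least 5 periods")
    h = y / y.mean(axis=0, keepdims=True)
    H = ((h - 1.0) ** 2).mean(axis=0)
    start = int(np.floor(trim_fraction * T))
    t_idx = np.arange(start, T)
    t_ord = t_idx + 1  # 1-based period index
    H = np.maximum(H, 1e-30)
    dep = np.log(H[0] / H[t_idx]) - 2.0 * np.log(np.log(t_ord + 1.0))
    X = sm.add_constant(np.log(t_ord.astype(float)))
    maxlags = max(1, int(np.floor(4 * (len(t_ord) / 100) ** (2 / 9))))
    fit = sm.OLS(dep, X).fit(cov_type="HAC", cov_kwds={"maxlags": maxlags})
    return float(fit.params[1]), float(fit.tvalues[1])


def log_t_club_clustering(
    scores: pd.Series | CompositeIndexPanel,
    trim_fraction: float = 0.3,
    threshold: float = -1.65,
) -> ClubAssignment:
    """Phillips-Sul club-convergence clustering.

    Units are ordered by terminal value; a core group is grown from the
    top to maximize the log-t statistic, remaining units join while the
    club still passes the log-t test, and adjacent clubs are merged when
    they jointly pass.  Units supporting no passing club are 'divergent'
    (club -1).  Club targets are terminal-period club means.
    """
    s = scores.scores if isinstance(scores, CompositeIndexPanel) else scores
    wide = s.unstack("year").sort_index(axis=1)
    if wide.shape[0] < 3:
        raise ValueError("club clustering needs at least 3 units")
    # order by mean over the final half of the sample (robust terminal value)
    half = wide.iloc[:, wide.shape[1] // 2 :]
    order = half.mean(axis=1).sort_values(ascending=False).index.tolist()
    stats: list[dict] = []

    def tstat(members: list) -> float:
        return log_t_regression(wide.loc[members], trim_fraction)[1]

    remaining = list(order)
    clubs: list[list] = []
    strays: list = []
    while len(remaining) >= 2:
        # core group: first k from the top maximizing the log-t statistic
        # among passing sizes
        best_k, best_t = None, -np.inf
        for k in range(2, len(remaining) + 1):
            tk = tstat(remaining[:k])
            if k == 2 and tk < threshold:
                break
            if tk < threshold:
                break
            if tk > best_t:
                best_k, best_t = k, tk
        if best_k is None:
            # top unit forms no core with its successor; set it aside
            strays.append(remaining.pop(0))
            continue
        club = remaining[:best_k]
        rest = remaining[best_k:]
        # sieve: admit further units while the club keeps passing
        for u in list(rest):
            t_with = tstat(club + [u])
            if t_with >= threshold:
                club.append(u)
                rest.remove(u)
        stats.append({"club": len(clubs) + 1, "size": len(club), "t": tstat(club)})
        clubs.append(club)
        remaining = rest
    divergent = strays + list(remaining)
    # merge adjacent clubs that jointly pass
    merged = True
    while merged and len(clubs) > 1:
        merged = False
        for i in range(len(clubs) - 1):
            joint = clubs[i] + clubs[i + 1]
            tj = tstat(joint)
            if tj >= threshold:
                stats.append({"merge": (i + 1, i + 2), "t": tj})
                clubs[i : i + 2] = [joint]
                merged = True
                break
    assign = {}
    targets = {}
    final_year = wide.columns[-1]
    for ci, club in enumerate(clubs, start=1):
        for u in club:
            assign[u] = ci
        targets[ci] = float(wide.loc[club, final_year].mean())
    for u in divergent:
        assign[u] = -1
    if divergent:
        targets[-1] = float("nan")
    return ClubAssignment(
        clubs=pd.Series(assign).loc[wide.index], club_targets=targets, log_t_stats=stats
    )


# ------------------------------------------------------ spatial Markov --

@dataclass
class SpatialMarkovResult:
    cutpoints: np.ndarray
    pooled: np.ndarray                      # k x k row-stochastic
    conditional: dict[int, np.ndarray]      # neighbor class -> k x k
    upward_prob: dict[int, float]
    counts: dict[int, np.ndarray]


def spatial_markov(
    scores: pd.Series | CompositeIndexPanel,
    wm: WeightMatrix,
    k: int = 3,
    cutpoints: np.ndarray | None = None,
) -> SpatialMarkovResult:
    """Neighbor-conditioned discrete transition matrices.

    Classes come from pooled k-quantiles of the index (or supplied
    cutpoints).  Each year-to-year transition of a unit is tallied into
    the matrix for the class of the unit's spatial lag at the start year.
    ``upward_prob`` is, per neighbor class, the probability of moving to a
    strictly higher class averaged over starting classes below the top.
    """
    if k < 2:
        raise ValueError("need k >= 2 classes")
    s = scores.scores if isinstance(scores, CompositeIndexPanel) else scores
    wide = s.unstack("year").sort_index(axis=1).loc[list(wm.units)]
    vals = wide.to_numpy(float)
    if cutpoints is None:
        cutpoints = np.quantile(vals.ravel(), np.linspace(0, 1, k + 1)[1:-1])
    cutpoints = np.asarray(cutpoints, float)

    def classify(a: np.ndarray) -> np.ndarray:
        return np.searchsorted(cutpoints, a, side="right")

    classes = classify(vals)
    counts = {c: np.zeros((k, k)) for c in range(k)}
    for t in range(vals.shape[1] - 1):
        lag = wm.w @ vals[:, t]
        lag_class = classify(lag)
        for i in range(vals.shape[0]):
            counts[int(lag_class[i])][classes[i, t], classes[i, t + 1]] += 1

    def normalize(c: np.ndarray) -> np.ndarray:
        rs = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            m = np.where(rs > 0, c / rs, np.nan)
        return m

    conditional = {c: normalize(counts[c]) for c in range(k)}
    pooled = normalize(sum(counts.values()))
    upward = {}
    for c, mat in conditional.items():
        probs = []
        for row in range(k - 1):
            if np.isfinite(mat[row]).all():
                probs.append(mat[row, row + 1 :].sum())
        upward[c] = float(np.mean(probs)) if probs else float("nan")
    return SpatialMarkovResult(cutpoints, pooled, conditional, upward, counts)


# -------------------------------------------------- structural breaks ---

@dataclass(frozen=True)
class BreakResult:
    break_indices: tuple[int, ...]   # year labels where a new segment begins
    segment_means: tuple[float, ...]
    criterion_path: tuple[float, ...]  # BIC per candidate break count
    n_breaks: int


def _segment_costs(x: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-segment SSE of x[i..j] around its mean."""
    n = len(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x**2)])
    cost = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i, n):
            s = c1[j + 1] - c1[i]
            ss = c2[j + 1] - c2[i]
            cost[i, j] = ss - s * s / (j - i + 1)
    return cost


def bai_perron_breaks(
    series: pd.Series,
    max_breaks: int = 3,
    min_segment: int = 2,
) -> BreakResult:
    """Least-squares multiple mean-shift breaks by dynamic programming.

    The global SSE optimum is found for every break count m = 0..max and
    the count is selected by BIC with (m+1) segment means plus m break
    dates as parameters.  ``break_indices`` are the year labels starting
    each new segment.
    """
    x = series.to_numpy(float)
    years = list(series.index)
    n = len(x)
    if n < (max_breaks + 1) * min_segment:
        raise ValueError(
            f"series of length {n} too short for {max_breaks} breaks "
            f"with min segment {min_segment}"
        )
    cost = _segment_costs(x)
    # dp[m][j] = minimal SSE of x[0..j] split into m+1 segments
    dp = np.full((max_breaks + 1, n), np.inf)
    back = np.full((max_breaks + 1, n), -1, int)
    dp[0] = cost[0]
    for m in range(1, max_breaks + 1):
        for j in range((m + 1) * min_segment - 1, n):
            for split in range(m * min_segment - 1, j - min_segment + 1):
                val = dp[m - 1][split] + cost[split + 1, j]
                if val < dp[m][j]:
                    dp[m][j] = val
                    back[m][j] = split
    bics = []
    for m in range(max_breaks + 1):
        sse = dp[m][n - 1]
        p = 2 * m + 1
        sse = max(sse, 1e-300)
        bics.append(n * np.log(sse / n) + p * np.log(n))
    m_star = int(np.argmin(bics))
    # recover break positions
    splits = []
    j = n - 1
    for m in range(m_star, 0, -1):
        s = back[m][j]
        splits.append(s)
        j = s
    splits = sorted(splits)
    starts = [0] + [s + 1 for s in splits]
    ends = splits + [n - 1]
    means = tuple(float(x[a : b + 1].mean()) for a, b in zip(starts, ends))
    break_years = tuple(years[s + 1] for s in splits)
    return BreakResult(break_years, means, tuple(float(b) for b in bics), m_star)


def exhaustive_breaks(
    series: pd.Series, n_breaks: int, min_segment: int = 2
) -> tuple[tuple[int, ...], float]:
    """Brute-force minimum-SSE break placement (oracle for the DP)."""
    x = series.to_numpy(float)
    years = list(series.index)
    n = len(x)
    cost = _segment_costs(x)
    best: tuple[float, tuple[int, ...]] = (np.inf, ())
    for splits in combinations(range(n - 1), n_breaks):
        bounds = [-1, *splits, n - 1]
        if any(b - a < min_segment for a, b in zip(bounds, bounds[1:])):
            continue
        sse = sum(cost[a + 1, b] for a, b in zip(bounds, bounds[1:]))
        if sse < best[0]:
            best = (sse, splits)
    return tuple(years[s + 1] for s in best[1]), float(best[0])


# --------------------------------------------------------- event study --

@dataclass(frozen=True)
class EventStudyResult:
    effect: float
    pre_mean: float
    post_mean: float
    placebo_effects: tuple[float, ...]
    p_value: float


def event_study(
    scores: pd.Series | CompositeIndexPanel,
    event_year: int,
    window: int = 1,
) -> EventStudyResult:
    """Pre/post mean difference of the national mean around an event year.

    effect = mean(index, [event, event+window-1])
           - mean(index, [event-window, event-1]).
    The placebo distribution repeats the contrast at every admissible
    alternative event year; the p-value is the share of placebo effects
    at least as large in magnitude.
    """
    s = scores.scores if isinstance(scores, CompositeIndexPanel) else scores
    national = s.unstack("year").mean(axis=0).sort_index()
    years = list(national.index)
    if window < 1:
        raise ValueError("window must be >= 1")

    def contrast(ev: int) -> float:
        pre = [y for y in years if ev - window <= y <= ev - 1]
        post = [y for y in years if ev <= y <= ev + window - 1]
        if len(pre) < window or len(post) < window:
            raise ValueError(f"event window around {ev} exceeds the panel span")
        return float(national.loc[post].mean() - national.loc[pre].mean())

    effect = contrast(event_year)
    placebo = []
    for ev in years:
        if ev == event_year:
            continue
        try:
            placebo.append(contrast(ev))
        except ValueError:
            continue
    if not placebo:
        raise ValueError("no admissible placebo event years")
    p = float(np.mean([abs(pe) >= abs(effect) for pe in placebo]))
    pre_years = [y for y in years if event_year - window <= y <= event_year - 1]
    post_years = [y for y in years if event_year <= y <= event_year + window - 1]
    return EventStudyResult(
        effect=effect,
        pre_mean=float(national.loc[pre_years].mean()),
        post_mean=float(national.loc[post_years].mean()),
        placebo_effects=tuple(placebo),
        p_value=p,
    )
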