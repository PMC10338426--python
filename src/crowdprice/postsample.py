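"""Post-sampling: reweighting a convenience sample against a formal design.

Crowdsourced submissions are a non-probability (convenience) sample, so the
weekly state-level mean is estimated three ways: the unweighted mean (treating
the crowd as a simple random sample), and two reweighted means in which each
LGA's mean is weighted by the post-sampling ratio PS_l = m_l / n_l — the count
m_l a formal reference design of the same total size would require in LGA l,
over the count n_l actually observed there.  Reference designs: a stratified
random sample with probability proportional to population (pps), or the
spatially balanced Local Pivotal Method 2 (LPM2).  The Crowdsourcing
Reliability Index summarises how closely the observed spatial allocation
matches the design:

    CRI = 1 - sum_l (m_l - n_l)^2 / (sum_l n_l^2 - 2 N min_l n_l + N^2)

equal to 1 when the crowd and the design coincide exactly.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from sklearn.base import BaseEstimator, TransformerMixin

from .admin import AdminUnit, locate_points, units_at_level
from .geometry import deg_to_km

logger = logging.getLogger(__name__)


@dataclass
class ReferenceDesign:
    """Required counts per LGA under a formal sample design of total size N."""

    design_type: str  # "stratified_pps" | "lpm2"
    m: pd.Series  # index: LGA codes, values: nonnegative integers
    N: int

    def __post_init__(self):
        if int(self.m.sum()) != self.N:
            raise ValueError("design counts must sum exactly to N")


@dataclass
class PostSampleWeights:
    """Spatial post-sampling ratios PS_l = m_l / n_l."""

    ps: pd.Series
    n: pd.Series
    contributing: pd.Index


def count_by_lga(obs: pd.DataFrame, frame: Sequence[AdminUnit]) -> tuple[pd.Series, int]:
    """Observed counts n_l over every LGA of the frame (zeros included)."""
    codes = [u.code for u in units_at_level(frame, 2)]
    counts = obs["level2code"].value_counts()
    n = pd.Series([int(counts.get(c, 0)) for c in codes], index=pd.Index(codes, name="level2code"))
    return n, int(n.sum())


def lga_means(obs: pd.DataFrame) -> pd.Series:
    """Simple unweighted mean price per LGA (only LGAs with observations)."""
    return obs.groupby("level2code")["price_kg"].mean()


def apportion_stratified_pps(populations: pd.Series, N: int) -> ReferenceDesign:
    """Integer pps quotas by largest-remainder (Hamilton) apportionment.

    Quotas q_l = N * pop_l / sum(pop); floors first, then the remaining units
    to the largest fractional remainders, ties broken by LGA code order.
    """
    populations = populations.sort_index()
    total = float(populations.sum())
    if total <= 0:
        raise ValueError("total population must be positive")
    if N < 1:
        raise ValueError("design size N must be >= 1")
    quota = N * populations / total
    m = np.floor(quota).astype(int)
    remainder = quota - m
    short = N - int(m.sum())
    if short > 0:
        # stable sort: descending remainder, ties by code order
        order = sorted(populations.index, key=lambda c: (-remainder[c], c))
        for code in order[:short]:
            m[code] += 1
    return ReferenceDesign("stratified_pps", m, N)


def lpm2(
    pi: np.ndarray, coords: np.ndarray, rng: np.random.Generator, tol: float = 1e-9
) -> np.ndarray:
    """Local Pivotal Method 2: fixed-size spatially balanced 0/1 sample.

    Repeatedly picks a random undecided unit, finds its nearest undecided
    neighbour (Euclidean on ``coords``; ties by index), and lets the pair
    compete for probability mass until every unit is 0 or 1.  Preserves the
    total sum(pi), so an integer sum yields exactly that many selections.
    """
    pi = np.asarray(pi, dtype=float).copy()
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    coords = np.asarray(coords, dtype=float)
    n = len(pi)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)

    def undecided_mask():
        return (pi > tol) & (pi < 1 - tol)

    und = undecided_mask()
    while und.sum() > 1:
        cand = np.flatnonzero(und)
        i = int(rng.choice(cand))
        row = d2[i].copy()
        row[~und] = np.inf
        row[i] = np.inf
        j = int(np.argmin(row))
        a, b = pi[i], pi[j]
        s = a + b
        if s < 1.0:
            if rng.uniform() < b / s:
                pi[i], pi[j] = 0.0, s
            else:
                pi[i], pi[j] = s, 0.0
        else:
            if rng.uniform() < (1.0 - b) / (2.0 - s):
                pi[i], pi[j] = 1.0, s - 1.0
            else:
                pi[i], pi[j] = s - 1.0, 1.0
        und = undecided_mask()
    # a single leftover fractional unit (non-integer total mass) resolves by coin flip
    left = np.flatnonzero(und)
    for i in left:
        pi[i] = 1.0 if rng.uniform() < pi[i] else 0.0
    return pi > 0.5


def grid_frame(
    frame: Sequence[AdminUnit], grid_resolution: int = 20
) -> pd.DataFrame:
    """Candidate sampling frame: grid-cell centroids inside the state.

    Returns columns x_km, y_km, lon, lat, level2code, population (of the
    containing LGA).  Cells outside every LGA are dropped.
    """
    states = units_at_level(frame, 1)
    if not states:
        raise ValueError("frame carries no level-1 (state) unit")
    state = states[0]
    minx, miny, maxx, maxy = state.polygon.bounds
    xs = np.linspace(minx, maxx, grid_resolution, endpoint=False) + (maxx - minx) / (
        2 * grid_resolution
    )
    ys = np.linspace(miny, maxy, grid_resolution, endpoint=False) + (maxy - miny) / (
        2 * grid_resolution
    )
    lon, lat = np.meshgrid(xs, ys)
    lon, lat = lon.ravel(), lat.ravel()
    inside = shapely.intersects_xy(state.polygon, lon, lat)
    lon, lat = lon[inside], lat[inside]
    codes = locate_points(frame, lon, lat, level=2)
    keep = np.array([c is not None for c in codes])
    lon, lat, codes = lon[keep], lat[keep], codes[keep]
    pops = {u.code: u.population for u in units_at_level(frame, 2)}
    x_km, y_km = deg_to_km(lon, lat, minx, miny)
    return pd.DataFrame(
        {
            "x_km": x_km,
            "y_km": y_km,
            "lon": lon,
            "lat": lat,
            "level2code": codes.astype(str),
            "population": [pops[c] for c in codes],
        }
    )


def inclusion_probabilities(cells: pd.DataFrame, N: int) -> np.ndarray:
    """Cell-level inclusion probabilities, population-share pps, sum = N.

    Each LGA's population share of N is split evenly over its cells; any
    probability above 1 is capped and the excess redistributed iteratively.
    """
    if N > len(cells):
        raise ValueError(f"design size N={N} exceeds the candidate frame ({len(cells)} cells)")
    share = cells.groupby("level2code")["population"].transform("first")
    n_cells = cells.groupby("level2code")["population"].transform("size")
    total_pop = cells.drop_duplicates("level2code")["population"].sum()
    pi = (N * share / total_pop / n_cells).to_numpy(dtype=float)
    for _ in range(100):
        over = pi >= 1.0
        excess = float(pi[over].sum() - over.sum())
        if excess <= 1e-12:
            break
        pi[over] = 1.0
        free = ~over
        pi[free] += excess * pi[free] / pi[free].sum()
    return np.clip(pi, 0.0, 1.0)


def lpm2_design(
    frame: Sequence[AdminUnit],
    N: int,
    grid_resolution: int = 20,
    seed: int = 0,
) -> ReferenceDesign:
    """Spatially balanced reference design via LPM2 on a grid frame."""
    cells = grid_frame(frame, grid_resolution)
    pi = inclusion_probabilities(cells, N)
    rng = np.random.default_rng(seed)
    selected = lpm2(pi, cells[["x_km", "y_km"]].to_numpy(), rng)
    codes = [u.code for u in units_at_level(frame, 2)]
    chosen = cells.loc[selected, "level2code"].value_counts()
    m = pd.Series([int(chosen.get(c, 0)) for c in codes], index=pd.Index(codes, name="level2code"))
    return ReferenceDesign("lpm2", m, N)


def post_sampling_ratios(design: ReferenceDesign, n: pd.Series) -> PostSampleWeights:
    """PS_l = m_l / n_l; LGAs with n_l = 0 drop out, m_l = 0 gives weight 0."""
    m = design.m.reindex(n.index).fillna(0).astype(int)
    ps = pd.Series(0.0, index=n.index)
    observed = n > 0
    ps[observed] = m[observed] / n[observed]
    contributing = n.index[observed & (m > 0)]
    return PostSampleWeights(ps=ps, n=n, contributing=contributing)


def post_sampled_mean(weights: PostSampleWeights, means: pd.Series) -> float:
    """Eq-weighted mean: sum_l PS_l * Xbar_l / sum_l PS_l over contributors."""
    contrib = weights.contributing.intersection(means.index)
    if len(contrib) == 0:
        logger.warning("post_sampled_mean: no contributing LGA; estimate undefined")
        return float("nan")
    w = weights.ps[contrib]
    return float((w * means[contrib]).sum() / w.sum())


def cri(m: pd.Series, n: pd.Series) -> float:
    """Crowdsourcing Reliability Index over all sub-areas of the study area.

    Computed exactly as defined; a value outside [0, 1] is reported raw with
    a warning, never clipped.
    """
    m = np.asarray(m, dtype=float)
    n = np.asarray(n, dtype=float)
    if len(m) != len(n):
        raise ValueError("m and n must cover the same sub-areas")
    N = n.sum()
    denom = (n**2).sum() - 2.0 * N * n.min() + N**2
    if denom == 0:
        logger.warning("cri: zero denominator; index undefined")
        return float("nan")
    value = 1.0 - ((m - n) ** 2).sum() / denom
    if not 0.0 <= value <= 1.0:
        warnings.warn(f"CRI = {value:.6g} outside nominal [0, 1]", stacklevel=2)
    return float(value)


def _group_seed(base_seed: int, key: tuple) -> int:
    return (int(base_seed) * 1_000_003 + zlib.crc32(repr(key).encode())) % (2**31 - 1)


def _design_for(
    design_type: str,
    frame: Sequence[AdminUnit],
    populations: pd.Series,
    N: int,
    grid_resolution: int,
    seed: int,
) -> ReferenceDesign:
    if design_type in ("pps", "stratified_pps"):
        return apportion_stratified_pps(populations, N)
    if design_type == "lpm2":
        # refine the grid until it can host N points (frame must dominate N)
        res = grid_resolution
        while _frame_size(frame, res) < N:
            res *= 2
        return lpm2_design(frame, N, res, seed)
    raise ValueError(f"unknown design_type: {design_type!r}")


def _frame_size(frame, grid_resolution):
    return len(grid_frame(frame, grid_resolution))


def weekly_estimates(
    obs: pd.DataFrame,
    frame: Sequence[AdminUnit],
    design_type: str = "pps",
    grid_resolution: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Weekly (state, product, price type) estimates in the step3 layout.

    ``price.mean`` is the simple unweighted mean (crowd treated as a simple
    random sample), ``price.ps`` the post-sampled mean reweighted against the
    chosen reference design, and ``CRI`` the reliability index computed per
    state-week from the pooled counts over all products and price types of
    that state-week.  Rows sort by (state, week, product, price type); groups
    with no valid observation are omitted.
    """
    populations = pd.Series(
        {u.code: u.population for u in units_at_level(frame, 2)}
    ).sort_index()
    rows = []
    cri_cache: dict[tuple, float] = {}
    for (state, year, week), sw_group in obs.groupby(["level1", "iso_year", "iso_week"], sort=True):
        n_pool, N_pool = count_by_lga(sw_group, frame)
        if N_pool == 0:
            continue
        design_pool = _design_for(
            design_type, frame, populations, N_pool, grid_resolution,
            _group_seed(seed, (state, year, week, "pooled")),
        )
        cri_cache[(state, year, week)] = cri(design_pool.m, n_pool)
        for (product, price_type), g in sw_group.groupby(["product", "price_type"], sort=True):
            n_l, N = count_by_lga(g, frame)
            design = _design_for(
                design_type, frame, populations, N, grid_resolution,
                _group_seed(seed, (state, year, week, product, price_type)),
            )
            weights = post_sampling_ratios(design, n_l)
            rows.append(
                {
                    "level1": state,
                    "submission_week": int(week),
                    "submission_month": int(pd.Timestamp(g["week_start"].iloc[0]).month),
                    "submission_year": int(year),
                    "week_start": g["week_start"].iloc[0],
                    "product": product,
                    "price_type": price_type,
                    "price.mean": float(g["price_kg"].mean()),
                    "price.ps": post_sampled_mean(weights, lga_means(g)),
                    "CRI": cri_cache[(state, year, week)],
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["level1", "submission_week", "submission_month", "submission_year",
                 "week_start", "product", "price_type", "price.mean", "price.ps", "CRI"],
    )
    return out.sort_values(
        ["level1", "submission_year", "submission_week", "product", "price_type"]
    ).reset_index(drop=True)


class PostSampler(BaseEstimator, TransformerMixin):
    """sklearn-style estimator producing weekly post-sampled estimates.

    ``transform`` maps a table of validated observations to the weekly
    estimate table; the result is also stored as ``estimates_``.
    """

    def __init__(
        self,
        frame: Sequence[AdminUnit] = (),
        design_type: str = "pps",
        grid_resolution: int = 20,
        seed: int = 0,
    ):
        self.frame = frame
        self.design_type = design_type
        self.grid_resolution = grid_resolution
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        if self.design_type not in ("pps", "stratified_pps", "lpm2"):
            raise ValueError(f"unknown design_type: {self.design_type!r}")
        self.n_input_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.estimates_ = weekly_estimates(
            X, self.frame, self.design_type, self.grid_resolution, self.seed
        )
        return self.estimates_
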