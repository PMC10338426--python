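"""Real-time validation of crowdsourced price observations.

The pipeline standardises observed prices to Naira/kg, classifies the
marketing channel (retail / wholesale / farm gate), geolocates each point to
state and LGA, and then runs the three-step outlier procedure within each
(product, price type, state, ISO week) group:

1. spatio-temporal market definition by DBSCAN on great-circle distances,
   flagging low-density points as isolated;
2. a robust within-cluster screen, |P - median| > k * IQR;
3. a spatial screen against the local neighbourhood,
   P outside lag(P) ± r * sd(P), where lag(P) is the mean price of the
   neighbours within ``neighbour_radius`` and sd(P) their sample standard
   deviation;

followed by relocation of isolated points whose price is similar to a cluster
whose centroid lies within ``maxd``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import DBSCAN

from .admin import AdminUnit, locate_points, units_at_level
from .geometry import central_angle, pairwise_angle
from .synth import ConfigurationError

#: kg per packaging unit.  The volumetric measures (Mudu/Kwano, Kongo) have no
#: published conversion; these defaults are configuration, not data.
DEFAULT_CONVERSION_TABLE = {
    "1 kg": 1.0,
    "5 kg": 5.0,
    "10 kg": 10.0,
    "25 kg": 25.0,
    "50 kg": 50.0,
    "100 kg": 100.0,
    "Mudu/Kwano": 1.25,
    "Kongo": 3.0,
}

#: Outlet categories with special marketing-channel rules.
FARMGATE_OUTLET = "Directly from farmer"
BULK_OUTLET = "Bulk and discount stores"


@dataclass
class ClusteringParams:
    """Thresholds of the market-definition and outlier-screening steps.

    ``eps``, ``maxd`` and ``neighbour_radius`` are great-circle central
    angles in radians (0.0019 ≈ 12 km, 0.0078 ≈ 50 km on Earth).
    """

    eps: float = 0.0019
    min_pts: int = 5
    maxd: float = 0.0078
    k: float = 2.0
    r: float = 2.0
    neighbour_radius: Optional[float] = None

    def __post_init__(self):
        if self.eps <= 0:
            raise ConfigurationError(f"eps={self.eps} must be > 0")
        if self.maxd < self.eps:
            raise ConfigurationError("maxd must be >= eps")
        if self.min_pts < 2:
            raise ConfigurationError("min_pts must be >= 2")
        if self.k <= 0 or self.r <= 0:
            raise ConfigurationError("k and r must be > 0")
        if self.neighbour_radius is None:
            self.neighbour_radius = self.eps
        elif self.neighbour_radius <= 0:
            raise ConfigurationError("neighbour_radius must be > 0")


def convert_to_kg_price(
    obs: pd.DataFrame, conversion_table: Optional[dict] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Populate ``conversion`` and ``price_kg`` from the packaging unit.

    Returns (converted rows, rejected rows); rejections carry a ``reason``
    column naming the unknown packaging unit.
    """
    table = DEFAULT_CONVERSION_TABLE if conversion_table is None else conversion_table
    obs = obs.copy()
    conv = obs["packaging"].map(table)
    known = conv.notna()
    rejected = obs.loc[~known].copy()
    if len(rejected):
        rejected["reason"] = "unknown packaging unit: " + rejected["packaging"].astype(str)
    obs = obs.loc[known].copy()
    obs["conversion"] = conv[known].astype(float)
    obs["price_kg"] = obs["price_observed"].astype(float) / obs["conversion"]
    return obs, rejected


def classify_price_type(obs: pd.DataFrame, wholesale_kg_threshold: float = 50.0) -> pd.DataFrame:
    """Set the marketing channel from outlet type and package size.

    Farm-gate if bought directly from the farmer; wholesale if the package is
    at least ``wholesale_kg_threshold`` kg or the outlet is a bulk store;
    retail otherwise.
    """
    obs = obs.copy()
    farmgate = obs["market_type_cat"] == FARMGATE_OUTLET
    wholesale = (obs["conversion"].astype(float) >= wholesale_kg_threshold) | (
        obs["market_type_cat"] == BULK_OUTLET
    )
    obs["price_type"] = np.where(farmgate, "farmgate", np.where(wholesale, "wholesale", "retail"))
    return obs


def assign_admin_units(obs: pd.DataFrame, frame: Sequence[AdminUnit]) -> pd.DataFrame:
    """Point-in-polygon geolocation to country, state and LGA.

    Boundary-touching points go to the unit whose code sorts first.  Points
    outside every LGA are flagged ``unlocated`` and excluded downstream.
    """
    obs = obs.copy()
    lon = obs["lon"].to_numpy(dtype=float)
    lat = obs["lat"].to_numpy(dtype=float)
    for level, prefix in ((0, "level0"), (1, "level1"), (2, "level2")):
        units = units_at_level(frame, level)
        if not units:
            continue
        codes = locate_points(frame, lon, lat, level=level)
        by_code = {u.code: u for u in units}
        obs[prefix + "code"] = codes
        obs[prefix] = [by_code[c].name if c is not None else None for c in codes]
        if level == 2:
            obs["area"] = [by_code[c].area if c is not None else np.nan for c in codes]
            obs["population"] = [
                by_code[c].population if c is not None else np.nan for c in codes
            ]
    obs["density"] = obs["population"] / (obs["area"] / 1e6)
    obs["unlocated"] = obs["level2code"].isna()
    return obs


def cluster_markets(group: pd.DataFrame, params: ClusteringParams) -> np.ndarray:
    """DBSCAN spatio-temporal market labels for one group.

    Great-circle (haversine) distances, radius ``eps`` in radians; labels are
    positive integers in first-core-point-encountered order over the input
    ordering, 0 for points in no cluster (isolated).
    """
    if len(group) < params.min_pts:
        return np.zeros(len(group), dtype=int)
    coords = np.radians(group[["lat", "lon"]].to_numpy(dtype=float))
    labels = DBSCAN(
        eps=params.eps, min_samples=params.min_pts, metric="haversine", algorithm="ball_tree"
    ).fit_predict(coords)
    return np.where(labels < 0, 0, labels + 1)


def detect_robust_outliers(prices: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Flag prices with |P - median| > k * IQR (linear-interpolation quantiles)."""
    prices = np.asarray(prices, dtype=float)
    med = np.median(prices)
    q1, q3 = np.percentile(prices, [25.0, 75.0])
    return np.abs(prices - med) > k * (q3 - q1)


def detect_spatial_outliers(
    lat: np.ndarray,
    lon: np.ndarray,
    prices: np.ndarray,
    neighbour_radius: float,
    r: float = 2.0,
    already_out: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Flag prices outside lag(P) ± r * sd(P) over the local neighbourhood.

    Neighbours of j are the non-outlier members within ``neighbour_radius``
    (great-circle, radians), excluding j itself; lag is their mean price
    (row-standardised weights) and sd their sample standard deviation.
    Members with fewer than two neighbours are not evaluated.  All members
    are evaluated against the same survivor set (single simultaneous pass).
    """
    prices = np.asarray(prices, dtype=float)
    n = len(prices)
    out = np.zeros(n, dtype=bool) if already_out is None else np.asarray(already_out, bool).copy()
    angles = pairwise_angle(lat, lon)
    flags = np.zeros(n, dtype=bool)
    for j in range(n):
        if out[j]:
            continue
        nb = (angles[j] <= neighbour_radius) & ~out
        nb[j] = False
        if nb.sum() < 2:
            continue
        lag = prices[nb].mean()
        sd = prices[nb].std(ddof=1)
        flags[j] = (prices[j] > lag + r * sd) or (prices[j] < lag - r * sd)
    return flags


@dataclass
class MarketCluster:
    """Post-screening summary of one spatio-temporal market."""

    cluster_id: int
    group_key: tuple
    member_index: pd.Index
    centroid_lat: float
    centroid_lon: float
    price_median: float
    price_iqr: float
    price_mean: float
    price_sd: float
    n_members: int


def summarise_cluster(cluster_id, group_key, members: pd.DataFrame) -> MarketCluster:
    """Summary statistics over the non-outlier members of a cluster."""
    p = members["price_kg"].to_numpy(dtype=float)
    q1, q3 = np.percentile(p, [25.0, 75.0])
    return MarketCluster(
        cluster_id=int(cluster_id),
        group_key=group_key,
        member_index=members.index,
        centroid_lat=float(members["lat"].mean()),
        centroid_lon=float(members["lon"].mean()),
        price_median=float(np.median(p)),
        price_iqr=float(q3 - q1),
        price_mean=float(p.mean()),
        price_sd=float(p.std(ddof=1)) if len(p) > 1 else 0.0,
        n_members=len(p),
    )


def relocate_isolated_points(
    isolated: pd.DataFrame, clusters: Sequence[MarketCluster], params: ClusteringParams
) -> pd.Series:
    """Attach isolated points to a similar cluster within ``maxd``.

    Candidates are clusters whose centroid lies within ``maxd`` of the point;
    among those with |P - cluster mean| <= k * cluster IQR the nearest is
    chosen.  Returns the new cluster label per point (0 = stays isolated,
    hence discarded from estimation).
    """
    labels = pd.Series(0, index=isolated.index, dtype=int)
    if not clusters or isolated.empty:
        return labels
    c_lat = np.array([c.centroid_lat for c in clusters])
    c_lon = np.array([c.centroid_lon for c in clusters])
    c_mean = np.array([c.price_mean for c in clusters])
    c_iqr = np.array([c.price_iqr for c in clusters])
    c_id = np.array([c.cluster_id for c in clusters])
    for idx, row in isolated.iterrows():
        ang = central_angle(row["lat"], row["lon"], c_lat, c_lon)
        ok = (ang <= params.maxd) & (np.abs(row["price_kg"] - c_mean) <= params.k * c_iqr)
        if ok.any():
            labels.loc[idx] = int(c_id[np.flatnonzero(ok)[np.argmin(ang[ok])]])
    return labels


GROUP_COLS = ["product", "price_type", "level1code", "iso_year", "iso_week"]


def _add_week(obs: pd.DataFrame) -> pd.DataFrame:
    t = pd.to_datetime(obs["submission_time"], utc=True, format="ISO8601")
    iso = t.dt.isocalendar()
    obs = obs.copy()
    obs["iso_year"] = iso["year"].astype(int)
    obs["iso_week"] = iso["week"].astype(int)
    obs["week_start"] = (t - pd.to_timedelta(t.dt.dayofweek, unit="D")).dt.strftime("%Y-%m-%d")
    obs["submission_month"] = t.dt.month.astype(int)
    return obs


def screen_group(group: pd.DataFrame, params: ClusteringParams):
    """Cluster one group and run both screens plus relocation.

    Returns (cluster labels, outlier flags, relocation flags) aligned to the
    group index, and the post-screening cluster summaries.
    """
    labels = pd.Series(cluster_markets(group, params), index=group.index)
    outlier = pd.Series(False, index=group.index)
    relocation = pd.Series(False, index=group.index)
    group_key = tuple(group.iloc[0][c] for c in GROUP_COLS) if len(group) else ()

    clusters: list[MarketCluster] = []
    for cid in sorted(set(labels) - {0}):
        members = group[labels == cid]
        p = members["price_kg"].to_numpy(dtype=float)
        rob = detect_robust_outliers(p, params.k) if len(members) >= 2 else np.zeros(len(members), bool)
        spa = detect_spatial_outliers(
            members["lat"].to_numpy(float),
            members["lon"].to_numpy(float),
            p,
            params.neighbour_radius,
            params.r,
            already_out=rob,
        )
        flagged = rob | spa
        outlier.loc[members.index[flagged]] = True
        survivors = members[~flagged]
        if len(survivors):
            clusters.append(summarise_cluster(cid, group_key, survivors))

    isolated = group[labels == 0]
    new_labels = relocate_isolated_points(isolated, clusters, params)
    moved = new_labels[new_labels > 0]
    labels.loc[moved.index] = moved
    relocation.loc[moved.index] = True
    return labels, outlier, relocation, clusters


def run_preprocessing(
    raw: pd.DataFrame,
    frame: Sequence[AdminUnit],
    params: Optional[ClusteringParams] = None,
    conversion_table: Optional[dict] = None,
    wholesale_kg_threshold: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full validation pipeline.

    Returns (flagged observations, run report, rejected rows with reasons).

    Every input row ends in exactly one category: ``rejected`` (unknown
    packaging), ``unlocated``, ``outlier``, ``isolated`` (discarded),
    ``relocated`` or ``valid``; the report tabulates the counts per state and
    product plus an overall row.
    """
    params = params or ClusteringParams()
    if raw.empty:
        empty_report = pd.DataFrame(
            columns=["level1", "product", "n_input", "n_rejected", "n_unlocated",
                     "n_outlier", "n_isolated", "n_relocated", "n_valid"]
        )
        return raw.copy(), empty_report, raw.copy()
    obs, rejected = convert_to_kg_price(raw, conversion_table)
    obs = classify_price_type(obs, wholesale_kg_threshold)
    obs = assign_admin_units(obs, frame)
    obs = _add_week(obs)

    obs["outlier"] = False
    obs["cluster"] = 0
    obs["relocation"] = False
    located = obs[~obs["unlocated"]]
    for _key, group in located.groupby(GROUP_COLS, sort=True):
        labels, outlier, relocation, _clusters = screen_group(group, params)
        obs.loc[group.index, "cluster"] = labels
        obs.loc[group.index, "outlier"] = outlier
        obs.loc[group.index, "relocation"] = relocation

    obs["status"] = np.select(
        [
            obs["unlocated"],
            obs["outlier"],
            obs["relocation"],
            obs["cluster"] > 0,
        ],
        ["unlocated", "outlier", "relocated", "valid"],
        default="isolated",
    )
    report = _build_report(obs, n_rejected_total=len(rejected))
    if len(rejected):
        rejected = rejected.copy()
        rejected["status"] = "rejected"
    return obs, report, rejected


def _build_report(obs: pd.DataFrame, n_rejected_total: int = 0) -> pd.DataFrame:
    rows = []
    for (state, product), g in obs.groupby(["level1", "product"], dropna=False, sort=True):
        counts = g["status"].value_counts()
        rows.append(
            {
                "level1": state,
                "product": product,
                "n_input": len(g),
                "n_rejected": 0,
                "n_unlocated": int(counts.get("unlocated", 0)),
                "n_outlier": int(counts.get("outlier", 0)),
                "n_isolated": int(counts.get("isolated", 0)),
                "n_relocated": int(counts.get("relocated", 0)),
                "n_valid": int(counts.get("valid", 0)) + int(counts.get("relocated", 0)),
            }
        )
    report = pd.DataFrame(rows)
    total = {
        "level1": "ALL",
        "product": "ALL",
        "n_input": int(report["n_input"].sum()) + n_rejected_total,
        "n_rejected": n_rejected_total,
        "n_unlocated": int(report["n_unlocated"].sum()),
        "n_outlier": int(report["n_outlier"].sum()),
        "n_isolated": int(report["n_isolated"].sum()),
        "n_relocated": int(report["n_relocated"].sum()),
        "n_valid": int(report["n_valid"].sum()),
    }
    report = pd.concat([report, pd.DataFrame([total])], ignore_index=True)
    for col in ("n_outlier", "n_isolated", "n_valid"):
        report["frac" + col[1:]] = report[col] / report["n_input"].where(report["n_input"] > 0)
    return report


class PricePreprocessor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`run_preprocessing`.

    Parameters mirror :class:`ClusteringParams` plus the packaging conversion
    table and the wholesale package-size threshold.  ``transform`` maps a raw
    observation table to the flagged table; the per-run report is stored as
    ``report_`` and the flagged table as ``observations_``.
    """

    def __init__(
        self,
        frame: Sequence[AdminUnit] = (),
        eps: float = 0.0019,
        min_pts: int = 5,
        maxd: float = 0.0078,
        k: float = 2.0,
        r: float = 2.0,
        neighbour_radius: Optional[float] = None,
        conversion_table: Optional[dict] = None,
        wholesale_kg_threshold: float = 50.0,
    ):
        self.frame = frame
        self.eps = eps
        self.min_pts = min_pts
        self.maxd = maxd
        self.k = k
        self.r = r
        self.neighbour_radius = neighbour_radius
        self.conversion_table = conversion_table
        self.wholesale_kg_threshold = wholesale_kg_threshold

    def _params(self) -> ClusteringParams:
        return ClusteringParams(
            eps=self.eps, min_pts=self.min_pts, maxd=self.maxd,
            k=self.k, r=self.r, neighbour_radius=self.neighbour_radius,
        )

    def fit(self, X: pd.DataFrame, y=None):
        self._params()  # validates thresholds
        self.n_input_ = len(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        obs, report, rejected = run_preprocessing(
            X, self.frame, self._params(), self.conversion_table, self.wholesale_kg_threshold
        )
        self.observations_ = obs
        self.report_ = report
        self.rejected_ = rejected
        return obs


def valid_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Rows usable for estimation: in a cluster (directly or relocated)."""
    return obs[obs["status"].isin(["valid", "relocated"])]
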