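"""Synthetic administrative frames and crowdsourced price observations.

The generator emulates a single-state crowdsourcing campaign with known ground
truth: a rectangular state tiled into rectangular LGAs, Matérn-style market
cluster centres inside each LGA, volunteer submissions scattered around the
markets, a smooth west-to-east price trend, Gaussian reporting noise,
multiplicative gross-error contamination, remote ("isolated") submissions far
from any market, and convenience-sampling participation tilted toward
high-population LGAs.  Every run is fully reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import box

from .admin import AdminUnit
from .geometry import km_to_deg, km_per_degree_lat, km_per_degree_lon


class ConfigurationError(ValueError):
    """A scenario or run configuration violates its invariants."""


def _default_populations() -> tuple[float, ...]:
    # urbanisation gradient: population grows along the (west->east) trend axis
    return tuple(100_000.0 * (c + 1) for _r in range(3) for c in range(3))


@dataclass
class SyntheticScenario:
    """Configuration of one synthetic campaign.

    Parameters
    ----------
    n_lgas, lga_grid_shape, lga_size_km
        The state is a ``rows x cols`` tiling of identical rectangular LGAs of
        side ``lga_size_km`` (km), so the default 3x3 grid of 200 km tiles is
        a 600 km square state.
    populations
        Population per LGA, in row-major tile order; the default grows
        linearly along the west->east axis, correlating population with the
        price trend so that convenience sampling produces a genuine bias.
    n_markets_per_lga, market_dispersion_km
        Fixed number of market cluster centres drawn uniformly inside each
        LGA, and the isotropic Gaussian scatter (km) of submissions around
        their market.
    participation_bias
        Volunteer submissions land in an LGA with probability proportional to
        ``population**participation_bias``; 0 is uniform, 1 matches a
        population-proportional design, 2 (default) is a convenience crowd.
    price_base, spatial_trend_slope, noise_sd
        Clean price surface in Naira/kg: ``base[product] + slope * x_km``
        plus N(0, noise_sd) reporting noise, where ``x_km`` is the west->east
        coordinate.
    contamination_rate, contamination_factor
        Fraction of submissions whose price is multiplied or divided (50/50)
        by the factor, emulating unit mistakes and fraudulent entries.
    isolated_rate, isolation_km
        Fraction of submissions placed uniformly at least ``isolation_km``
        (default ~2x the 50 km relocation radius) from every market centre.
    n_weeks, start
        Submission timestamps are uniform over ``n_weeks`` ISO weeks starting
        at ``start`` (a Monday).
    """

    n_lgas: int = 9
    lga_grid_shape: tuple[int, int] = (3, 3)
    lga_size_km: float = 200.0
    populations: tuple[float, ...] = field(default_factory=_default_populations)
    n_markets_per_lga: int = 1
    market_dispersion_km: float = 3.0
    n_observations: int = 2000
    participation_bias: float = 2.0
    price_base: dict = field(default_factory=lambda: {"local_rice": 400.0})
    spatial_trend_slope: float = 0.15
    noise_sd: float = 30.0
    contamination_rate: float = 0.05
    contamination_factor: float = 5.0
    isolated_rate: float = 0.10
    isolation_km: float = 100.0
    n_weeks: int = 4
    start: str = "2021-04-05"
    origin_lon: float = 6.0
    origin_lat: float = 9.0
    state_code: str = "SIM001"
    state_name: str = "Kasuwa"
    country_code: str = "SIM"
    country_name: str = "Simuland"
    seed: int = 0

    def __post_init__(self):
        rows, cols = self.lga_grid_shape
        if rows * cols != self.n_lgas:
            raise ConfigurationError(
                f"lga_grid_shape {self.lga_grid_shape} inconsistent with n_lgas={self.n_lgas}"
            )
        if len(self.populations) != self.n_lgas:
            raise ConfigurationError("populations must have one entry per LGA")
        if min(self.populations) <= 0:
            raise ConfigurationError("populations must be strictly positive")
        for name in ("contamination_rate", "isolated_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.contamination_rate + self.isolated_rate >= 1.0:
            raise ConfigurationError("contamination_rate + isolated_rate must be < 1")
        if self.n_observations < 1 or self.n_markets_per_lga < 1 or self.n_weeks < 1:
            raise ConfigurationError("counts must be positive")
        if self.contamination_factor <= 1.0:
            raise ConfigurationError("contamination_factor must exceed 1")
        if not self.price_base:
            raise ConfigurationError("price_base must name at least one product")

    @property
    def state_size_km(self) -> tuple[float, float]:
        rows, cols = self.lga_grid_shape
        return cols * self.lga_size_km, rows * self.lga_size_km


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    #: (level1, iso_year, iso_week, product, price_type) -> spatial average of
    #: the noise-free price surface over the state, on a fine grid.
    true_means: pd.DataFrame
    #: per-observation label: "clean" | "contaminated" | "isolated"
    clean_flags: pd.Series
    #: market centre planar coordinates (km), columns x_km, y_km, level2code
    markets: pd.DataFrame


def _lga_box_km(scenario: SyntheticScenario, index: int):
    rows, cols = scenario.lga_grid_shape
    r, c = divmod(index, cols)
    s = scenario.lga_size_km
    return c * s, r * s  # lower-left corner (x, y) in km


def _tile_polygon(scenario: SyntheticScenario, x0: float, y0: float):
    s = scenario.lga_size_km
    kx = km_per_degree_lon(scenario.origin_lat)
    ky = km_per_degree_lat()
    return box(
        scenario.origin_lon + x0 / kx,
        scenario.origin_lat + y0 / ky,
        scenario.origin_lon + (x0 + s) / kx,
        scenario.origin_lat + (y0 + s) / ky,
    )


def generate_admin_frame(scenario: SyntheticScenario) -> list[AdminUnit]:
    """One state partitioned into ``n_lgas`` rectangular LGAs.

    LGA polygons tile the state exactly (mutually non-overlapping, union equal
    to the state rectangle); each carries its configured population and its
    planar area in m².
    """
    width_km, height_km = scenario.state_size_km
    area_m2 = scenario.lga_size_km**2 * 1e6
    units = [
        AdminUnit(
            code=scenario.country_code,
            name=scenario.country_name,
            level=0,
            polygon=_tile_polygon_full(scenario, width_km, height_km),
            population=float(sum(scenario.populations)),
            area=width_km * height_km * 1e6,
        ),
        AdminUnit(
            code=scenario.state_code,
            name=scenario.state_name,
            level=1,
            polygon=_tile_polygon_full(scenario, width_km, height_km),
            population=float(sum(scenario.populations)),
            area=width_km * height_km * 1e6,
        ),
    ]
    for i in range(scenario.n_lgas):
        x0, y0 = _lga_box_km(scenario, i)
        units.append(
            AdminUnit(
                code=f"{scenario.state_code}L{i + 1:02d}",
                name=f"{scenario.state_name} LGA {i + 1}",
                level=2,
                polygon=_tile_polygon(scenario, x0, y0),
                population=float(scenario.populations[i]),
                area=area_m2,
            )
        )
    return units


def _tile_polygon_full(scenario, width_km, height_km):
    kx = km_per_degree_lon(scenario.origin_lat)
    ky = km_per_degree_lat()
    return box(
        scenario.origin_lon,
        scenario.origin_lat,
        scenario.origin_lon + width_km / kx,
        scenario.origin_lat + height_km / ky,
    )


def _draw_markets(scenario: SyntheticScenario, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(scenario.n_lgas):
        x0, y0 = _lga_box_km(scenario, i)
        for _m in range(scenario.n_markets_per_lga):
            rows.append(
                {
                    "level2code": f"{scenario.state_code}L{i + 1:02d}",
                    "x_km": x0 + rng.uniform(0, scenario.lga_size_km),
                    "y_km": y0 + rng.uniform(0, scenario.lga_size_km),
                }
            )
    return pd.DataFrame(rows)


def _surface(scenario: SyntheticScenario, product: str, x_km) -> np.ndarray:
    return scenario.price_base[product] + scenario.spatial_trend_slope * np.asarray(x_km)


def true_spatial_mean(scenario: SyntheticScenario, product: str, grid: int = 201) -> float:
    """Average of the noise-free surface over the state on a fine grid."""
    width_km, height_km = scenario.state_size_km
    xs = np.linspace(0.0, width_km, grid)
    ys = np.linspace(0.0, height_km, grid)
    xx, _yy = np.meshgrid(xs, ys)
    return float(_surface(scenario, product, xx).mean())


def _draw_isolated(
    scenario: SyntheticScenario, markets: pd.DataFrame, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform points at least ``isolation_km`` from every market centre."""
    width_km, height_km = scenario.state_size_km
    xs = np.empty(n)
    ys = np.empty(n)
    mx = markets["x_km"].to_numpy()
    my = markets["y_km"].to_numpy()
    got = 0
    for _attempt in range(2000):
        if got == n:
            break
        m = max(4 * (n - got), 64)
        cx = rng.uniform(0, width_km, m)
        cy = rng.uniform(0, height_km, m)
        d2 = (cx[:, None] - mx[None, :]) ** 2 + (cy[:, None] - my[None, :]) ** 2
        ok = d2.min(axis=1) >= scenario.isolation_km**2
        take = min(int(ok.sum()), n - got)
        xs[got : got + take] = cx[ok][:take]
        ys[got : got + take] = cy[ok][:take]
        got += take
    if got < n:
        raise ConfigurationError(
            "cannot place isolated points: isolation_km too large for the state geometry"
        )
    return xs, ys


def generate_observations(
    scenario: SyntheticScenario, frame: list[AdminUnit]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one campaign of submissions plus its ground truth.

    Returns a raw observation table in the step2 column layout (pipeline
    output fields left unset) and a :class:`GroundTruth`.  Identical scenarios
    produce byte-identical tables.
    """
    if not frame:
        raise ConfigurationError("empty administrative frame")
    rng = np.random.default_rng(scenario.seed)
    markets = _draw_markets(scenario, rng)
    n = scenario.n_observations

    # flag assignment: contaminated / isolated / clean, mutually exclusive
    u = rng.uniform(size=n)
    flags = np.where(
        u < scenario.contamination_rate,
        "contaminated",
        np.where(u < scenario.contamination_rate + scenario.isolated_rate, "isolated", "clean"),
    )

    # convenience participation: LGA choice ~ population^bias
    pops = np.asarray(scenario.populations, dtype=float)
    p_lga = pops**scenario.participation_bias
    p_lga = p_lga / p_lga.sum()
    lga_idx = rng.choice(scenario.n_lgas, size=n, p=p_lga)

    # market-based positions for clean + contaminated submissions
    x = np.empty(n)
    y = np.empty(n)
    at_market = flags != "isolated"
    mx = markets["x_km"].to_numpy()
    my = markets["y_km"].to_numpy()
    market_lga = markets["level2code"].to_numpy()
    for i in range(scenario.n_lgas):
        code = f"{scenario.state_code}L{i + 1:02d}"
        sel = np.flatnonzero(at_market & (lga_idx == i))
        if not len(sel):
            continue
        cands = np.flatnonzero(market_lga == code)
        pick = cands[rng.integers(0, len(cands), size=len(sel))]
        x[sel] = mx[pick] + rng.normal(0, scenario.market_dispersion_km, len(sel))
        y[sel] = my[pick] + rng.normal(0, scenario.market_dispersion_km, len(sel))
    n_iso = int((~at_market).sum())
    if n_iso:
        xi, yi = _draw_isolated(scenario, markets, n_iso, rng)
        x[~at_market] = xi
        y[~at_market] = yi
    width_km, height_km = scenario.state_size_km
    x = np.clip(x, 0.0, width_km)
    y = np.clip(y, 0.0, height_km)

    products = np.array(sorted(scenario.price_base))
    product = products[rng.integers(0, len(products), size=n)]

    price_kg = np.empty(n)
    for prod in products:
        sel = product == prod
        price_kg[sel] = _surface(scenario, prod, x[sel]) + rng.normal(
            0, scenario.noise_sd, int(sel.sum())
        )
    price_kg = np.maximum(price_kg, 1.0)
    contaminated = flags == "contaminated"
    updown = rng.uniform(size=n) < 0.5
    price_kg[contaminated & updown] *= scenario.contamination_factor
    price_kg[contaminated & ~updown] /= scenario.contamination_factor

    lon, lat = km_to_deg(x, y, scenario.origin_lon, scenario.origin_lat)
    start = pd.Timestamp(scenario.start, tz="UTC")
    offsets = rng.uniform(0, scenario.n_weeks * 7 * 24 * 3600, size=n)
    submission_time = start + pd.to_timedelta(np.sort(offsets), unit="s")

    mudu_kg = 1.25  # observed prices are quoted per Mudu/Kwano measure
    obs = pd.DataFrame(
        {
            "id_form": np.arange(1, n + 1) // 5 + 1,
            "id": np.arange(1, n + 1),
            "deviceid": 1000 + rng.integers(0, 150, size=n),
            "volunteer_id": 1 + rng.integers(0, 150, size=n),
            "product": product,
            "type": "1",
            "price_type": pd.NA,
            "market_type_cat": "Open-air markets",
            "lat": np.round(lat, 6),
            "lon": np.round(lon, 6),
            "alt": np.round(rng.uniform(200, 600, size=n), 1),
            "pre": np.round(rng.uniform(3, 15, size=n), 1),
            "time_start": (submission_time - pd.Timedelta(minutes=4)).strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "submission_time": submission_time.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "packaging": "Mudu/Kwano",
            "conversion": np.nan,
            "price_observed": np.round(price_kg * mudu_kg, 2),
            "price_kg": np.nan,
            "buying_purpose": "only price observer",
            "market_distance": np.round(rng.uniform(0.2, 10.0, size=n), 1),
        }
    )

    weeks = submission_time.isocalendar()
    true_rows = []
    for prod in products:
        tm = true_spatial_mean(scenario, prod)
        for (yr, wk), _g in pd.DataFrame({"y": weeks.year, "w": weeks.week}).groupby(["y", "w"]):
            true_rows.append(
                {
                    "level1": scenario.state_name,
                    "iso_year": int(yr),
                    "iso_week": int(wk),
                    "product": prod,
                    "price_type": "retail",
                    "true_mean": tm,
                }
            )
    truth = GroundTruth(
        true_means=pd.DataFrame(true_rows),
        clean_flags=pd.Series(flags, index=obs.index, name="clean_flag"),
        markets=markets,
    )
    return obs, truth


def generate_campaign(
    scenario: Optional[SyntheticScenario] = None,
) -> tuple[pd.DataFrame, list[AdminUnit], GroundTruth]:
    """Convenience wrapper: frame + observations for one scenario."""
    scenario = scenario or SyntheticScenario()
    frame = generate_admin_frame(scenario)
    obs, truth = generate_observations(scenario, frame)
    return obs, frame, truth
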