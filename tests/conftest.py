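import numpy as np
import pytest

from crowdprice import SyntheticScenario, generate_admin_frame, generate_campaign
from crowdprice.preprocess import run_preprocessing


@pytest.fixture(scope="session")
def scenario():
    return SyntheticScenario(seed=42)


@pytest.fixture(scope="session")
def campaign(scenario):
    """(observations, frame, ground truth) for the default scenario."""
    return generate_campaign(scenario)


@pytest.fixture(scope="session")
def frame(campaign):
    return campaign[1]


@pytest.fixture(scope="session")
def preprocessed(campaign):
    obs, frame, _truth = campaign
    return run_preprocessing(obs, frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def haversine_oracle(lat1, lon1, lat2, lon2):
    """Independent great-circle angle via the spherical law of cosines."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2) - np.radians(lon1)
    c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return np.arccos(np.clip(c, -1.0, 1.0))


def angle_matrix_oracle(lat, lon):
    n = len(lat)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = haversine_oracle(lat[i], lon[i], lat[j], lon[j])
    return d


def dbscan_oracle(lat, lon, eps, min_pts):
    """Textbook sequential DBSCAN on the epsilon-neighbourhood graph.

    Core points have at least ``min_pts`` members (self included) within
    ``eps``; clusters are grown from cores in input order, so border points
    belong to the earliest-started cluster that reaches them.  Labels are
    positive integers, 0 is noise.
    """
    d = angle_matrix_oracle(lat, lon)
    n = len(lat)
    neighbourhoods = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbourhoods])
    labels = np.zeros(n, dtype=int)
    current = 0
    for i in range(n):
        if labels[i] != 0 or not core[i]:
            continue
        current += 1
        stack = [i]
        while stack:
            j = stack.pop()
            if labels[j] == 0:
                labels[j] = current
                if core[j]:
                    stack.extend(v for v in neighbourhoods[j] if labels[v] == 0)
    return labels


def spatial_outlier_oracle(lat, lon, prices, radius, r, already_out):
    """O(n^2) literal evaluation of the spatial-lag outlier rule."""
    n = len(prices)
    flags = np.zeros(n, dtype=bool)
    for j in range(n):
        if already_out[j]:
            continue
        nb = []
        for i in range(n):
            if i == j or already_out[i]:
                continue
            if haversine_oracle(lat[j], lon[j], lat[i], lon[i]) <= radius:
                nb.append(prices[i])
        if len(nb) < 2:
            continue
        nb = np.asarray(nb, dtype=float)
        lag = nb.mean()
        sd = nb.std(ddof=1)
        flags[j] = prices[j] > lag + r * sd or prices[j] < lag - r * sd
    return flags
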