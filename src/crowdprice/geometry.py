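"""Great-circle and local planar distance helpers.

All clustering radii in this package (``eps``, ``maxd``, ``neighbour_radius``)
are great-circle central angles in radians on the unit sphere, the convention
under which an ``eps`` of 0.0019 corresponds to roughly 12 km on Earth.
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius in kilometres used to convert central angles to distances.
EARTH_RADIUS_KM = 6371.0


def central_angle(lat1, lon1, lat2, lon2):
    """Great-circle central angle (radians) between WGS84 points in degrees.

    Uses the haversine formula; fully vectorised over numpy broadcastable
    inputs.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # guard against rounding pushing the argument a hair above 1
    return 2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in kilometres between WGS84 points in degrees."""
    return EARTH_RADIUS_KM * central_angle(lat1, lon1, lat2, lon2)


def pairwise_angle(lat, lon):
    """Dense matrix of great-circle central angles (radians) between points."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    return central_angle(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


def km_per_degree_lat() -> float:
    """Kilometres spanned by one degree of latitude (spherical Earth)."""
    return EARTH_RADIUS_KM * np.pi / 180.0


def km_per_degree_lon(reference_lat: float) -> float:
    """Kilometres spanned by one degree of longitude at a reference latitude."""
    return EARTH_RADIUS_KM * np.pi / 180.0 * np.cos(np.radians(reference_lat))


def km_to_deg(x_km, y_km, origin_lon: float, origin_lat: float):
    """Map local planar km offsets from an origin to (lon, lat) degrees.

    A local equirectangular projection centred on ``origin_lat``; planar and
    great-circle distances agree to well under 1% at the ~100 km scale for the
    low latitudes this package targets.
    """
    lon = origin_lon + np.asarray(x_km, dtype=float) / km_per_degree_lon(origin_lat)
    lat = origin_lat + np.asarray(y_km, dtype=float) / km_per_degree_lat()
    return lon, lat


def deg_to_km(lon, lat, origin_lon: float, origin_lat: float):
    """Inverse of :func:`km_to_deg`: (lon, lat) degrees to planar km offsets."""
    x_km = (np.asarray(lon, dtype=float) - origin_lon) * km_per_degree_lon(origin_lat)
    y_km = (np.asarray(lat, dtype=float) - origin_lat) * km_per_degree_lat()
    return x_km, y_km
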