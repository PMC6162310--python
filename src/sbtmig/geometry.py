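"""Great-circle geometry and the distance-to-GAB observable.

The behavioural model watches a single scalar per fish per day: the
great-circle distance from the fish's position to a fixed reference point
in the Great Australian Bight (32°S, 130°E), written ``d_GAB``.  Its daily
first difference ``d_t = d_GAB(t) - d_GAB(t-1)`` is the signed step
displacement (km/day, positive = moving away from the GAB) that the hidden
Markov model treats as its observation.

All distances use a spherical Earth (haversine, R = 6371 km); at the basin
scales of tuna migration the difference to an ellipsoidal geodesic is well
below the geolocation error of archival tags.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "GabReference",
    "great_circle_km",
    "initial_bearing_deg",
    "destination_point",
    "distance_to_gab",
    "step_observations",
    "cumulative_path_length",
]


@dataclass(frozen=True)
class GabReference:
    """Reference locus in the Great Australian Bight.

    ``radius_km`` is the residency threshold: positions closer than this to
    the reference point count as "within the GAB".
    """

    lat: float = -32.0
    lon: float = 130.0
    radius_km: float = 500.0

    def __post_init__(self) -> None:
        if not (self.radius_km > 0):
            raise ValueError("GAB radius must be positive")
        _check_coords(np.asarray(self.lat), np.asarray(self.lon))


def _check_coords(lat: np.ndarray, lon: np.ndarray) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def great_circle_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Haversine great-circle distance in km (broadcasts over arrays)."""
    _check_coords(np.asarray(lat1), np.asarray(lon1))
    _check_coords(np.asarray(lat2), np.asarray(lon2))
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def initial_bearing_deg(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Initial azimuth (degrees clockwise from north) from point 1 to point 2."""
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlam = l2 - l1
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def destination_point(lat: float, lon: float, bearing_deg: float, distance_km: float) -> tuple[float, float]:
    """Point reached travelling ``distance_km`` along a great circle.

    Spherical direct problem; returns (lat, lon) with lon in [-180, 180].
    """
    phi1 = np.radians(lat)
    lam1 = np.radians(lon)
    theta = np.radians(bearing_deg)
    delta = distance_km / EARTH_RADIUS_KM
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    lon2 = (np.degrees(lam2) + 180.0) % 360.0 - 180.0
    return float(np.degrees(phi2)), float(lon2)


def distance_to_gab(track, ref: GabReference | None = None) -> np.ndarray:
    """Per-day distance (km) from each track position to the GAB reference."""
    if ref is None:
        ref = GabReference()
    return np.asarray(great_circle_km(track.lat, track.lon, ref.lat, ref.lon), dtype=float)


def step_observations(dseries: np.ndarray, plausibility_cap_km: float = 250.0):
    """Signed daily displacement d_t = d_GAB(t) - d_GAB(t-1).

    Returns ``(d_t, flagged)`` where ``flagged`` marks steps whose magnitude
    exceeds the plausibility cap (default 250 km/day, far beyond sustained
    tuna swimming speed); flagged steps are returned unchanged, the caller
    decides what to do with them.
    """
    d = np.asarray(dseries, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("distance series must be 1-D with at least 2 entries")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance series contains non-finite values")
    dt = np.diff(d)
    flagged = np.abs(dt) > plausibility_cap_km
    return dt, flagged


def cumulative_path_length(track) -> float:
    """Total along-track great-circle distance travelled (km)."""
    lat = np.asarray(track.lat, dtype=float)
    lon = np.asarray(track.lon, dtype=float)
    if lat.size < 2:
        return 0.0
    steps = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return float(np.sum(steps))
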