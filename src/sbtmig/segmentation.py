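"""Rule-based division of tracks into GAB residence and migration trips.

A position is "within the GAB" when its distance to the reference locus is
strictly below 500 km.  A trip departs on the first day of a consecutive
run of at least 120 positions with d_GAB beyond the threshold, and returns
on the first subsequent day back inside it; an excursion still open when
the tag record ends is kept as a censored trip with no return date.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import GabReference, distance_to_gab

__all__ = ["Trip", "classify_gab_residence", "detect_trips", "detect_trips_for_trackset",
           "trips_to_frame", "trip_summaries"]

DEFAULT_RADIUS_KM = 500.0
DEFAULT_MIN_RUN = 120          # positions =~ 4 months at one per day
DIRECTION_WINDOW_DAYS = 30     # net longitude change window deciding direction


@dataclass
class Trip:
    """One departure -> return excursion beyond the GAB threshold."""

    fish_id: str
    departure_date: np.datetime64
    return_date: np.datetime64 | None   # None when censored (tag ended away)
    duration_days: int | None
    max_d_gab_km: float
    direction: str                      # "westward" or "eastward"

    @property
    def censored(self) -> bool:
        return self.return_date is None


def classify_gab_residence(dseries: np.ndarray, radius_km: float = DEFAULT_RADIUS_KM) -> np.ndarray:
    """Boolean in-GAB flags; the boundary d == radius counts as outside."""
    d = np.asarray(dseries, dtype=float)
    return d < radius_km


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs, stop exclusive."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_trips(dseries: np.ndarray, dates: np.ndarray, *, fish_id: str = "",
                 lon: np.ndarray | None = None,
                 radius_km: float = DEFAULT_RADIUS_KM, min_run: int = DEFAULT_MIN_RUN) -> list[Trip]:
    """Apply the excursion rule to one fish's daily distance series.

    Runs shorter than ``min_run`` are ignored; the return date is the first
    day back inside the radius after a qualifying run; an excursion that
    never re-enters before the record ends is censored.
    """
    d = np.asarray(dseries, dtype=float)
    dates = np.asarray(dates, dtype="datetime64[D]")
    if len(d) != len(dates):
        raise ValueError("distance series and dates must align")
    out_mask = ~classify_gab_residence(d, radius_km)
    trips: list[Trip] = []
    for start, stop in _runs(out_mask):
        if stop - start < min_run:
            continue
        departure = dates[start]
        if stop < len(d):
            ret = dates[stop]           # first day with d < radius
            duration = int((ret - departure) / np.timedelta64(1, "D"))
        else:
            ret, duration = None, None
        if lon is not None:
            w = lon[start:min(start + DIRECTION_WINDOW_DAYS, stop)]
            dlon = (w[-1] - w[0] + 180.0) % 360.0 - 180.0
            direction = "westward" if dlon < 0 else "eastward"
        else:
            direction = "unknown"
        trips.append(Trip(fish_id, departure, ret, duration,
                          float(np.max(d[start:stop])), direction))
    return trips


def detect_trips_for_trackset(trackset, gab: GabReference | None = None,
                              min_run: int = DEFAULT_MIN_RUN) -> list[Trip]:
    gab = gab or GabReference()
    trips: list[Trip] = []
    for tr in trackset:
        d = distance_to_gab(tr, gab)
        trips.extend(detect_trips(d, tr.dates, fish_id=tr.fish_id, lon=tr.lon,
                                  radius_km=gab.radius_km, min_run=min_run))
    return trips


def trips_to_frame(trips: list[Trip]) -> pd.DataFrame:
    return pd.DataFrame({
        "fish_id": [t.fish_id for t in trips],
        "departure_date": [t.departure_date for t in trips],
        "return_date": [t.return_date for t in trips],
        "duration_days": [t.duration_days for t in trips],
        "max_d_gab_km": [t.max_d_gab_km for t in trips],
        "direction": [t.direction for t in trips],
        "censored": [t.censored for t in trips],
    })


def trip_summaries(trips: list[Trip]) -> dict:
    """Descriptive statistics over detected trips.

    Duration statistics use complete (uncensored) trips only; maximum-
    distance statistics include censored trips, whose recorded maximum is a
    lower bound on the true excursion extent.
    """
    if not trips:
        return {"n_trips": 0, "n_complete": 0, "n_censored": 0}
    complete = [t for t in trips if not t.censored]
    durations = np.array([t.duration_days for t in complete], dtype=float)
    maxd = np.array([t.max_d_gab_km for t in trips], dtype=float)
    directions = [t.direction for t in trips if t.direction != "unknown"]
    summary = {
        "n_trips": len(trips),
        "n_complete": len(complete),
        "n_censored": len(trips) - len(complete),
        "max_distance_mean_km": float(maxd.mean()),
        "max_distance_sd_km": float(maxd.std(ddof=1)) if len(maxd) > 1 else 0.0,
        "max_distance_max_km": float(maxd.max()),
    }
    if len(complete):
        summary.update({
            "duration_mean_days": float(durations.mean()),
            "duration_sd_days": float(durations.std(ddof=1)) if len(durations) > 1 else 0.0,
            "duration_min_days": float(durations.min()),
            "duration_max_days": float(durations.max()),
            "duration_n1_flag": len(durations) == 1,
        })
    if directions:
        summary["westward_fraction"] = directions.count("westward") / len(directions)
    return summary
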