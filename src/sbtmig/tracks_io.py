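"""Reading, writing and regularizing daily tag-track tables.

Tracks arrive as delimited text with one estimated position per fish per
day (``fish_id,date,lat,lon[,age_at_tagging]``).  Downstream statistics
assume exactly one position per calendar day, so :func:`regularize_track`
fills short gaps by great-circle interpolation and splits a track at gaps
longer than a configurable limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Track", "TrackSet", "read_tracks", "write_tracks", "regularize_track", "regularize_trackset"]

DAY = np.timedelta64(1, "D")


@dataclass
class Track:
    """Ordered daily positions for one fish."""

    fish_id: str
    dates: np.ndarray  # datetime64[D], strictly increasing
    lat: np.ndarray
    lon: np.ndarray
    age_at_tagging: int | None = None

    def __post_init__(self) -> None:
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if not (len(self.dates) == len(self.lat) == len(self.lon)):
            raise ValueError("dates, lat and lon must have equal length")
        if len(self.dates) > 1 and not np.all(np.diff(self.dates) > np.timedelta64(0, "D")):
            raise ValueError(f"track {self.fish_id}: dates must be strictly increasing")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError(f"track {self.fish_id}: coordinate out of range")
        if not (np.all(np.isfinite(self.lat)) and np.all(np.isfinite(self.lon))):
            raise ValueError(f"track {self.fish_id}: non-finite coordinate")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def release_date(self) -> np.datetime64:
        return self.dates[0]

    @property
    def end_date(self) -> np.datetime64:
        return self.dates[-1]

    def is_daily(self) -> bool:
        return len(self) < 2 or bool(np.all(np.diff(self.dates) == DAY))


@dataclass
class TrackSet:
    """Collection of tracks keyed by fish id, with provenance metadata."""

    tracks: dict[str, Track] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def add(self, track: Track) -> None:
        if track.fish_id in self.tracks:
            raise ValueError(f"duplicate fish_id {track.fish_id!r}")
        self.tracks[track.fish_id] = track

    def __iter__(self):
        return iter(self.tracks.values())

    def __len__(self) -> int:
        return len(self.tracks)

    def __getitem__(self, fish_id: str) -> Track:
        return self.tracks[fish_id]


_DEFAULT_DIALECT = {"fish_id": "fish_id", "date": "date", "lat": "lat", "lon": "lon",
                    "age_at_tagging": "age_at_tagging"}


def read_tracks(path, dialect: dict | None = None) -> TrackSet:
    """Read a delimited track table into a :class:`TrackSet`.

    ``dialect`` maps canonical field names to column names in the file.
    Rows with unparseable coordinates or dates are dropped with a logged
    count; a missing mandatory column or an empty file is a hard error.
    """
    cols = dict(_DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no track rows")
    for key in ("fish_id", "date", "lat", "lon"):
        if cols[key] not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {cols[key]!r}")

    n_raw = len(df)
    df = df.rename(columns={v: k for k, v in cols.items() if v in df.columns})
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["date"] = pd.to_datetime(df["date"], errors="coerce")
    bad = df[["lat", "lon", "date"]].isna().any(axis=1)
    if bad.any():
        logger.warning("%s: dropped %d unparseable row(s)", path, int(bad.sum()))
    df = df[~bad]
    if df.empty:
        raise ValueError(f"{path}: no parseable track rows")

    ts = TrackSet(provenance={"source": str(path), "n_rows": n_raw, "n_dropped": int(bad.sum())})
    for fish_id, grp in df.groupby("fish_id", sort=True):
        grp = grp.sort_values("date")
        age = None
        if "age_at_tagging" in grp.columns:
            a = pd.to_numeric(grp["age_at_tagging"], errors="coerce").dropna()
            if len(a):
                age = int(a.iloc[0])
        ts.add(Track(
            fish_id=str(fish_id),
            dates=grp["date"].to_numpy(dtype="datetime64[D]"),
            lat=grp["lat"].to_numpy(),
            lon=grp["lon"].to_numpy(),
            age_at_tagging=age,
        ))
    return ts


def write_tracks(trackset: TrackSet, path) -> None:
    """Write a TrackSet back to CSV (inverse of :func:`read_tracks`)."""
    frames = []
    for tr in trackset:
        frame = pd.DataFrame({
            "fish_id": tr.fish_id,
            "date": pd.to_datetime(tr.dates).strftime("%Y-%m-%d"),
            "lat": tr.lat,
            "lon": tr.lon,
        })
        if tr.age_at_tagging is not None:
            frame["age_at_tagging"] = tr.age_at_tagging
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _slerp(lat1, lon1, lat2, lon2, fracs):
    """Great-circle interpolation via 3-D vector slerp.

    Works across the dateline because interpolation happens on the unit
    sphere, always along the shorter arc.
    """
    def to_vec(lat, lon):
        phi, lam = np.radians(lat), np.radians(lon)
        return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])

    v1, v2 = to_vec(lat1, lon1), to_vec(lat2, lon2)
    omega = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    out = []
    for f in fracs:
        if omega < 1e-12:
            v = v1
        else:
            v = (np.sin((1 - f) * omega) * v1 + np.sin(f * omega) * v2) / np.sin(omega)
        v = v / np.linalg.norm(v)
        lat = np.degrees(np.arcsin(np.clip(v[2], -1, 1)))
        lon = np.degrees(np.arctan2(v[1], v[0]))
        out.append((lat, lon))
    return out


def regularize_track(track: Track, max_gap_days: int = 5) -> list[Track]:
    """Resample a track to exactly one position per calendar day.

    Interior gaps of at most ``max_gap_days`` missing days are filled by
    great-circle interpolation; longer gaps split the track into separate
    segments whose fish_id gains a ``_segN`` suffix.  Idempotent on already
    daily tracks.
    """
    if len(track) < 2:
        raise ValueError(f"track {track.fish_id} too short to regularize")
    if track.is_daily():
        return [track]

    gaps = (np.diff(track.dates) / DAY).astype(int)
    # split points where the gap exceeds the interpolation limit
    split_idx = np.flatnonzero(gaps > max_gap_days + 1)
    bounds = [0, *list(split_idx + 1), len(track)]
    segments: list[Track] = []
    multi = len(bounds) > 2
    for seg_no, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        if b - a < 2:
            continue  # an isolated single position carries no step information
        dates, lat, lon = track.dates[a:b], track.lat[a:b], track.lon[a:b]
        out_dates = np.arange(dates[0], dates[-1] + DAY, DAY)
        out_lat = np.empty(len(out_dates))
        out_lon = np.empty(len(out_dates))
        pos = 0
        for i in range(len(dates) - 1):
            ndays = int((dates[i + 1] - dates[i]) / DAY)
            out_lat[pos], out_lon[pos] = lat[i], lon[i]
            if ndays > 1:
                fracs = np.arange(1, ndays) / ndays
                for k, (la, lo) in enumerate(_slerp(lat[i], lon[i], lat[i + 1], lon[i + 1], fracs)):
                    out_lat[pos + 1 + k], out_lon[pos + 1 + k] = la, lo
            pos += ndays
        out_lat[-1], out_lon[-1] = lat[-1], lon[-1]
        fid = f"{track.fish_id}_seg{seg_no}" if multi else track.fish_id
        segments.append(Track(fid, out_dates, out_lat, out_lon, track.age_at_tagging))
    if not segments:
        raise ValueError(f"track {track.fish_id}: no segment with >=2 positions after splitting")
    return segments


def regularize_trackset(trackset: TrackSet, max_gap_days: int = 5) -> TrackSet:
    out = TrackSet(provenance={**trackset.provenance, "regularized": True,
                               "max_gap_days": max_gap_days})
    for tr in trackset:
        for seg in regularize_track(tr, max_gap_days=max_gap_days):
            out.add(seg)
    return out
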