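"""Spatial kernel density mapping of resident-classified locations.

Positions whose decoded behavioural state is "resident" are pooled across
fish and smoothed with a planar Gaussian KDE on a regular lon/lat grid.
Cell densities are expressed per km^2 using the cos-latitude area of each
cell, so integrated mass is 1 over the map.  Contiguous cells above a
density quantile form candidate residency regions — the synthetic
analogue of the core residence areas mapped from the real tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import EARTH_RADIUS_KM
from .hmm import RESIDENT

__all__ = ["DensityGrid", "ResidencyRegion", "resident_points", "kde2d", "extract_regions"]

KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


def resident_points(trackset, decodings) -> np.ndarray:
    """(n, 2) array of (lat, lon) for every Viterbi-resident position.

    The decoded state for step t is attributed to the position at day t
    (the end of the displacement), so the first day of each track carries
    no state and is excluded.
    """
    tracks = list(trackset)
    if len(tracks) != len(decodings):
        raise ValueError("one decoding per track required")
    pts = []
    for tr, dec in zip(tracks, decodings):
        m = dec.states == RESIDENT
        if m.any():
            pts.append(np.column_stack([tr.lat[1:][m], tr.lon[1:][m]]))
    if not pts:
        raise ValueError("no positions classified as resident")
    return np.vstack(pts)


@dataclass
class DensityGrid:
    lat_edges: np.ndarray     # (nlat+1,)
    lon_edges: np.ndarray     # (nlon+1,)
    density: np.ndarray       # (nlat, nlon), per km^2
    cell_area_km2: np.ndarray  # (nlat, nlon)

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def total_mass(self) -> float:
        return float(np.sum(self.density * self.cell_area_km2))


def _silverman(x: np.ndarray) -> float:
    n = len(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    s = min(np.std(x, ddof=1), iqr / 1.349) if iqr > 0 else np.std(x, ddof=1)
    return 0.9 * s * n ** (-0.2)


def kde2d(points: np.ndarray, bandwidth_deg: tuple[float, float] | None = None,
          cell_deg: float = 0.5, pad_bandwidths: float = 4.0) -> DensityGrid:
    """Separable Gaussian KDE of (lat, lon) points on a regular grid.

    Per-axis bandwidths default to Silverman's rule.  The grid covers the
    data plus ``pad_bandwidths`` bandwidths so that essentially all kernel
    mass lands on the map; densities are converted to per-km^2 with the
    cos-latitude cell area, making the map integrate to one.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 2:
        raise ValueError("need an (n, 2) array of (lat, lon) with n >= 2")
    lat, lon = points[:, 0], points[:, 1]
    if bandwidth_deg is None:
        h_lat, h_lon = _silverman(lat), _silverman(lon)
    else:
        h_lat, h_lon = bandwidth_deg
    if min(h_lat, h_lon) < cell_deg / 10.0:
        raise ValueError("degenerate point cloud: bandwidth collapsed; pass a larger bandwidth_deg")

    def edges(x, h):
        lo = np.floor((x.min() - pad_bandwidths * h) / cell_deg) * cell_deg
        hi = np.ceil((x.max() + pad_bandwidths * h) / cell_deg) * cell_deg
        return np.arange(lo, hi + cell_deg / 2, cell_deg)

    lat_edges, lon_edges = edges(lat, h_lat), edges(lon, h_lon)
    lat_c = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    lon_c = 0.5 * (lon_edges[:-1] + lon_edges[1:])

    # separable Gaussian products, averaged over points -> density per deg^2
    klat = np.exp(-0.5 * ((lat_c[:, None] - lat[None, :]) / h_lat) ** 2) / (h_lat * np.sqrt(2 * np.pi))
    klon = np.exp(-0.5 * ((lon_c[:, None] - lon[None, :]) / h_lon) ** 2) / (h_lon * np.sqrt(2 * np.pi))
    dens_deg2 = (klat @ klon.T) / len(points)

    dlat_km = cell_deg * KM_PER_DEG
    dlon_km = cell_deg * KM_PER_DEG * np.cos(np.radians(lat_c))
    cell_area = np.outer(dlat_km * dlon_km, np.ones(len(lon_c)))
    density_km2 = dens_deg2 * cell_deg ** 2 / cell_area
    return DensityGrid(lat_edges, lon_edges, density_km2, cell_area)


@dataclass
class ResidencyRegion:
    label: int
    cells: np.ndarray          # (k, 2) integer (row, col) indices
    mass: float                # integrated density within the region
    centroid: tuple[float, float]   # (lat, lon), mass-weighted
    area_km2: float


def extract_regions(grid: DensityGrid, quantile: float = 0.75) -> list[ResidencyRegion]:
    """Connected components of cells above a density quantile.

    8-neighbour connectivity; regions ranked by contained probability
    mass.  The quantile is taken over cells with non-negligible density so
    the vast empty ocean does not drag the threshold to zero.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    d = grid.density
    occupied = d > d.max() * 1e-6
    thresh = np.quantile(d[occupied], quantile)
    mask = d >= thresh
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    regions = []
    lat_c, lon_c = grid.lat_centers, grid.lon_centers
    for lab in range(1, n + 1):
        cells = np.argwhere(labels == lab)
        w = d[cells[:, 0], cells[:, 1]] * grid.cell_area_km2[cells[:, 0], cells[:, 1]]
        mass = float(w.sum())
        centroid = (float(np.average(lat_c[cells[:, 0]], weights=w)),
                    float(np.average(lon_c[cells[:, 1]], weights=w)))
        area = float(grid.cell_area_km2[cells[:, 0], cells[:, 1]].sum())
        regions.append(ResidencyRegion(lab, cells, mass, centroid, area))
    regions.sort(key=lambda r: r.mass, reverse=True)
    for k, r in enumerate(regions, start=1):
        r.label = k
    return regions
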