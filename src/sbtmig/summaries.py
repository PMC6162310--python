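"""Descriptive statistics over decoded tracks and detected trips.

These reproduce the headline population summaries of the analysis: the
proportion of time in each behavioural state (pooled and median-across-
fish with IQR), run-length distributions, the relation between time spent
migrating and maximum excursion distance, the per-age westward extent,
and the percentage by which outward displacement exceeds inward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .geometry import GabReference, distance_to_gab

logger = logging.getLogger(__name__)

__all__ = ["StateOccupancySummary", "state_occupancy", "run_lengths",
           "migration_time_vs_max_distance", "westward_extent_by_age",
           "outward_inward_ratio"]


@dataclass
class StateOccupancySummary:
    labels: tuple[str, ...]
    pooled: np.ndarray          # step-weighted proportions, sums to 1
    median: np.ndarray          # median of per-fish proportions
    iqr: np.ndarray             # interquartile range of per-fish proportions
    per_fish: pd.DataFrame      # one row per fish


def state_occupancy(decodings, use_posterior: bool = False) -> StateOccupancySummary:
    """Proportion of time in each state.

    Viterbi-path proportions by default; ``use_posterior`` swaps in mean
    posterior probabilities.  Pooled proportions weight every decoded step
    equally (so long tracks count more); medians and IQRs are across fish.
    """
    if not decodings:
        raise ValueError("need at least one decoding")
    S = len(decodings[0].state_labels)
    rows = []
    for dec in decodings:
        if use_posterior:
            p = dec.posteriors.mean(axis=0)
        else:
            p = np.bincount(dec.states, minlength=S) / len(dec.states)
        rows.append(p)
    per_fish = pd.DataFrame(rows, columns=list(decodings[0].state_labels))
    weights = np.array([len(d.states) for d in decodings], dtype=float)
    pooled = (per_fish.to_numpy() * weights[:, None]).sum(axis=0) / weights.sum()
    q25, q50, q75 = np.percentile(per_fish.to_numpy(), [25, 50, 75], axis=0)
    return StateOccupancySummary(decodings[0].state_labels, pooled, q50, q75 - q25, per_fish)


def run_lengths(decodings) -> dict[int, np.ndarray]:
    """Lengths of maximal same-state runs, per state.

    Runs truncated by track ends are counted at their observed length.
    The total run mass per state (sum of its run lengths) equals that
    state's total step count.
    """
    S = len(decodings[0].state_labels) if decodings else 0
    out: dict[int, list[int]] = {s: [] for s in range(S)}
    for dec in decodings:
        path = dec.states
        change = np.flatnonzero(np.diff(path) != 0)
        starts = np.concatenate([[0], change + 1])
        stops = np.concatenate([change + 1, [len(path)]])
        for a, b in zip(starts, stops):
            out[int(path[a])].append(int(b - a))
    return {s: np.array(v, dtype=int) for s, v in out.items()}


def migration_time_vs_max_distance(trackset, decodings, gab: GabReference | None = None,
                                   spline_cv_grid: int = 8):
    """Per-fish days in migratory states vs maximum distance from the GAB.

    Returns ``(table, fit)`` where ``table`` has one row per fish and
    ``fit`` carries the least-squares slope (with p-value) and a smoothing
    spline whose penalty is picked by K-fold cross-validation.
    """
    gab = gab or GabReference()
    tracks = list(trackset)
    if len(tracks) != len(decodings):
        raise ValueError("one decoding per track required")
    rows = []
    for tr, dec in zip(tracks, decodings):
        d = distance_to_gab(tr, gab)
        rows.append({"fish_id": tr.fish_id,
                     "migration_days": int(np.sum(dec.states != 0)),
                     "max_d_gab_km": float(d.max())})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("need at least 3 fish for a trend fit")
    x = table["max_d_gab_km"].to_numpy()
    y = table["migration_days"].to_numpy(dtype=float)
    lin = stats.linregress(x, y)
    spline = _cv_spline(x, y, n_penalties=spline_cv_grid)
    fit = {"slope": float(lin.slope), "intercept": float(lin.intercept),
           "r": float(lin.rvalue), "pvalue": float(lin.pvalue),
           "stderr": float(lin.stderr), "spline": spline}
    return table, fit


def _cv_spline(x, y, n_penalties: int = 8, k_folds: int = 5, seed: int = 0):
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # collapse duplicate x for spline fitting
    xu, inv = np.unique(xs, return_inverse=True)
    yu = np.bincount(inv, weights=ys) / np.bincount(inv)
    if len(xu) < 5:
        return UnivariateSpline(xu, yu, k=min(3, len(xu) - 1), s=0)
    n = len(xu)
    base = n * np.var(yu)
    grid = base * np.logspace(-3, 1, n_penalties)
    rng = np.random.default_rng(seed)
    folds = rng.integers(0, k_folds, size=n)
    best_s, best_err = None, np.inf
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # fitpack maxit chatter
        for s in grid:
            err = 0.0
            for f in range(k_folds):
                tr = folds != f
                if tr.sum() < 5 or (~tr).sum() == 0:
                    continue
                spl = UnivariateSpline(xu[tr], yu[tr], s=s * tr.sum() / n, k=3)
                err += float(np.sum((spl(xu[~tr]) - yu[~tr]) ** 2))
            if err < best_err:
                best_err, best_s = err, s
        return UnivariateSpline(xu, yu, s=best_s, k=3)


def westward_extent_by_age(trackset) -> pd.DataFrame:
    """Mean per-fish-year minimum longitude, by age.

    Age in each track-year is age at tagging plus elapsed whole calendar
    years (ages advance at Jan 1, the turn of the austral summer).  Fish
    without a recorded tagging age are skipped with a warning.
    """
    rows = []
    skipped = 0
    for tr in trackset:
        if tr.age_at_tagging is None:
            skipped += 1
            continue
        years = pd.to_datetime(tr.dates).year.to_numpy()
        release_year = years[0]
        for yr in np.unique(years):
            sel = years == yr
            rows.append({"fish_id": tr.fish_id,
                         "age": int(tr.age_at_tagging + (yr - release_year)),
                         "min_lon": float(tr.lon[sel].min())})
    if skipped:
        logger.warning("westward_extent_by_age: %d track(s) without age skipped", skipped)
    if not rows:
        return pd.DataFrame(columns=["age", "mean_min_lon", "n"])
    df = pd.DataFrame(rows)
    out = df.groupby("age").agg(mean_min_lon=("min_lon", "mean"), n=("min_lon", "size"))
    return out.reset_index()


def outward_inward_ratio(means: np.ndarray) -> float:
    """Percent by which outward displacement exceeds inward, from emissions.

    100 * (mu_outward - |mu_inward|) / |mu_inward| on a fitted 3-state
    model (signed convention: inward mean is negative).
    """
    means = np.asarray(means, dtype=float)
    if means.shape != (3,):
        raise ValueError("expected 3-state emission means (resident, outward, inward)")
    mu_out, mu_in = means[1], abs(means[2])
    if mu_in < 1e-6:
        raise ValueError("inward mean magnitude too small for a ratio")
    return float(100.0 * (mu_out - mu_in) / mu_in)
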