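"""Remaining behavioural summaries: run lengths, time-in-migration trend,
and westward extent by age.

Writes results/runlengths.csv, results/migration_vs_distance.csv and
results/westward_extent_by_age.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sbtmig import geometry, hmm, summaries, tracks_io
from sbtmig.config import AnalysisConfig

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = AnalysisConfig()
    trackset = tracks_io.regularize_trackset(tracks_io.read_tracks(OUT / "tracks.csv"))
    params = hmm.load_params(OUT / "fitted_model.yaml")
    obs = [geometry.step_observations(geometry.distance_to_gab(tr, cfg.gab))[0]
           for tr in trackset]
    decs = hmm.decode_tracks(obs, params)

    rl = summaries.run_lengths(decs)
    labels = decs[0].state_labels
    pd.DataFrame([{"state": labels[s], "run_length": int(L)}
                  for s, runs in rl.items() for L in runs]
                 ).to_csv(OUT / "runlengths.csv", index=False)
    for s, runs in rl.items():
        print(f"{labels[s]}: {len(runs)} runs, mean length {runs.mean():.1f} steps, "
              f"max {runs.max()}")

    table, fit = summaries.migration_time_vs_max_distance(trackset, decs, cfg.gab)
    table.to_csv(OUT / "migration_vs_distance.csv", index=False)
    print(f"time-in-migration vs max distance: slope {fit['slope'] * 1000:.1f} "
          f"days per 1000 km (r={fit['r']:.2f}, p={fit['pvalue']:.2g})")

    extent = summaries.westward_extent_by_age(trackset)
    extent.to_csv(OUT / "westward_extent_by_age.csv", index=False)
    print(extent.to_string(index=False))

    longest = max(trackset, key=len)
    km = geometry.cumulative_path_length(longest)
    print(f"longest deployment {longest.fish_id}: {len(longest) / 365.25:.2f} years, "
          f"{km:,.0f} km travelled")


if __name__ == "__main__":
    main()
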