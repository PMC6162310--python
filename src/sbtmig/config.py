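"""Analysis configuration: one YAML file holds every tunable threshold."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .geometry import GabReference

__all__ = ["AnalysisConfig", "load_config", "save_config"]


@dataclass
class AnalysisConfig:
    gab_lat: float = -32.0
    gab_lon: float = 130.0
    gab_radius_km: float = 500.0
    trip_min_run: int = 120            # positions required out of the GAB
    max_gap_days: int = 5              # interpolate gaps up to this, split beyond
    step_cap_km: float = 250.0         # plausibility cap on daily displacement
    em_tol: float = 1e-8
    em_max_iter: int = 500
    em_restarts: int = 5
    sigma_floor: float = 0.1
    kde_cell_deg: float = 0.5
    kde_region_quantile: float = 0.75
    extra: dict = field(default_factory=dict)

    @property
    def gab(self) -> GabReference:
        return GabReference(self.gab_lat, self.gab_lon, self.gab_radius_km)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in raw.items() if k in known}
    extra = {k: v for k, v in raw.items() if k not in known}
    return AnalysisConfig(**kwargs, extra=extra)


def save_config(cfg: AnalysisConfig, path) -> None:
    d = asdict(cfg)
    d.update(d.pop("extra"))
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)
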