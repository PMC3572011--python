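"""YAML/JSON configuration: site boundaries, grouping overrides, scoring,
kinetic Monte Carlo rates.

Everything the analysis treats as a convention — where the site boundaries
sit, which states belong to which mechanistic group, how paths are scored —
can be overridden from one config file, so the defaults stay defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cycles import Scoring, StateCodeMap
from .kmc import KMCParams
from .states import RESTING_STATE
from .trajectory import SiteMap


@dataclass
class AnalysisConfig:
    site_boundaries: tuple[float, ...] | None = None
    group_overrides: dict[str, str] = field(default_factory=dict)
    state_codes: dict[str, str] | None = None
    resting_state: str = RESTING_STATE
    min_dwell_frames: int = 1
    bin_width: float = 0.5
    scoring: Scoring = field(default_factory=Scoring)
    kmc: KMCParams = field(default_factory=KMCParams)

    def site_map(self) -> SiteMap:
        if self.site_boundaries is None:
            return SiteMap()
        return SiteMap(tuple(self.site_boundaries))

    def code_map(self) -> StateCodeMap:
        return StateCodeMap(self.state_codes)


def load_config(path) -> AnalysisConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
    data = data or {}
    kwargs = {}
    if "site_boundaries" in data:
        kwargs["site_boundaries"] = tuple(data["site_boundaries"])
    for key in ("group_overrides", "state_codes", "resting_state",
                "min_dwell_frames", "bin_width"):
        if key in data:
            kwargs[key] = data[key]
    if "scoring" in data:
        kwargs["scoring"] = Scoring(**data["scoring"])
    if "kmc" in data:
        kmc = dict(data["kmc"])
        if "initial_sites" in kmc:
            kmc["initial_sites"] = tuple(kmc["initial_sites"])
        kwargs["kmc"] = KMCParams(**kmc)
    return AnalysisConfig(**kwargs)


def save_config(cfg: AnalysisConfig, path) -> None:
    data = {
        "site_boundaries": list(cfg.site_boundaries) if cfg.site_boundaries else None,
        "group_overrides": cfg.group_overrides,
        "state_codes": cfg.state_codes,
        "resting_state": cfg.resting_state,
        "min_dwell_frames": cfg.min_dwell_frames,
        "bin_width": cfg.bin_width,
        "scoring": asdict(cfg.scoring),
        "kmc": {**asdict(cfg.kmc), "initial_sites": list(cfg.kmc.initial_sites)},
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
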