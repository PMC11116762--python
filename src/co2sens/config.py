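"""Pipeline configuration: structured text (YAML) mirrored by CLI flags."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from co2sens.synthetic import ScenarioConfig

MODES = ("historical", "future")


@dataclass
class PipelineConfig:
    """End-to-end run description.

    Either ``inputs`` maps logical variable names (gpp, tas, rh/avp, tmax,
    precip, et, ndep, pdep/soil_n, co2) to file paths, or ``simulate`` holds
    a :class:`ScenarioConfig` and the pipeline generates its own inputs.
    ``var_map`` translates dataset-dialect variable names inside each file to
    the logical names (e.g. ``{"tas": "t2m"}``).
    """

    output_dir: str = "co2sens_out"
    inputs: dict[str, str] = field(default_factory=dict)
    simulate: ScenarioConfig | None = None
    var_map: dict[str, str] = field(default_factory=dict)
    humidity_kind: str = "rh"  # "rh" or "avp"
    window_len: int = 15
    stride: int = 1
    lat_threshold: float = 30.0
    alpha: float = 0.05
    mode: str = "historical"
    seed: int = 0

    def validate(self) -> None:
        if self.window_len < 3:
            raise ValueError("window_len must be >= 3")
        if not 0 < self.alpha < 1:
            raise ValueError("significance level must lie in (0, 1)")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.humidity_kind not in ("rh", "avp"):
            raise ValueError("humidity_kind must be 'rh' or 'avp'")
        if self.simulate is None and not self.inputs:
            raise ValueError("either 'inputs' paths or a 'simulate' block is required")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            sim = d["simulate"]
            sim["lat_range"] = list(sim["lat_range"])
            sim["lon_range"] = list(sim["lon_range"])
        return d

    def hash(self) -> str:
        """Stable digest of the configuration (first 16 hex chars).

        The output directory is excluded: where results are written does not
        change what they are, and reruns into different directories must
        remain comparable.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    return pipeline_config_from_dict(d)


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    sim = d.pop("simulate", None)
    cfg = PipelineConfig(**d)
    if sim is not None:
        for key in ("lat_range", "lon_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        cfg.simulate = ScenarioConfig(**sim)
    cfg.validate()
    return cfg


def save_pipeline_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
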