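"""Run configuration: every threshold that affects a result, in one place.

Defaults are the pipeline's canonical constants: 600 nm z window, 15/25 nm
lateral/axial precision bounds, 65/35 nm initial ellipse axes, 75.12 nm
elongation threshold, 150 nm anchoring radius, four gonad zones. Configs are
loadable from YAML (unknown keys rejected), hashable for run logs, and
validated with the offending key named.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "CONFIG_SCHEMA_VERSION"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION
    # SMLM filtering / fitting
    z_window_nm: float = 600.0  # full window; half-window passed to the filter
    max_precision_xy_nm: float = 15.0
    max_precision_z_nm: float = 25.0
    init_full_major_axis_nm: float = 65.0
    init_full_minor_axis_nm: float = 35.0
    # focus categorization
    sigma_threshold_nm: float = 75.12
    anchor_radius_nm: float = 150.0
    n_zones: int = 4
    # paths
    out_dir: str = "meioquant_out"

    _POSITIVE = (
        "z_window_nm",
        "max_precision_xy_nm",
        "max_precision_z_nm",
        "init_full_major_axis_nm",
        "init_full_minor_axis_nm",
        "sigma_threshold_nm",
        "anchor_radius_nm",
        "n_zones",
    )

    def validate(self) -> "RunConfig":
        for key in self._POSITIVE:
            if getattr(self, key) <= 0:
                raise ValueError(f"config key {key!r} must be positive, got {getattr(self, key)}")
        if int(self.seed) != self.seed:
            raise ValueError("config key 'seed' must be an integer")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if not f.name.startswith("_")
        }

    def config_hash(self) -> str:
        """Hash of the result-affecting settings (paths excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
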