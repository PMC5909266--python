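"""Run configuration: grids, conventions and simulator settings.

Defaults follow the study grids: modeling periods T_M in {5, 10, 15, 25,
35} s, correction periods T_C in {5, 10, 15} s with T_C <= T_M enforced
cell-wise, dt = 0.2 s over 70 s.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import InvalidInputError

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    dt_s: float = 0.2
    duration_s: float = 70.0
    t_m_set: list[float] = field(default_factory=lambda: [5.0, 10.0, 15.0, 25.0, 35.0])
    t_c_set: list[float] = field(default_factory=lambda: [5.0, 10.0, 15.0])
    model_kinds: list[str] = field(default_factory=lambda: ["quadratic"])
    anchor: str = "scan_a"
    invert_breathing_sign: bool = False
    per_marker_target_drift: bool = False
    min_prominence_mm: float | None = None  # None -> 20% of trace IQR
    min_separation_s: float = 1.0
    smooth_window_s: float = 0.0
    n_patients: int = 20
    event_probability: float = 0.2
    param_ranges: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> "RunConfig":
        if not self.t_m_set or not self.t_c_set:
            raise InvalidInputError("t_m_set and t_c_set must be non-empty")
        if max(self.t_c_set) > max(self.t_m_set):
            raise InvalidInputError(
                "every correction period must be usable: max(T_C) <= max(T_M)"
            )
        for name, values in (("t_m_set", self.t_m_set), ("t_c_set", self.t_c_set)):
            for T in values:
                if T <= 0:
                    raise InvalidInputError(f"{name} entries must be positive")
                ratio = T / self.dt_s
                if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
                    raise InvalidInputError(
                        f"{name} entry {T} s is not a multiple of dt {self.dt_s} s"
                    )
        if self.anchor not in ("scan_a", "scan_b"):
            raise InvalidInputError("anchor must be 'scan_a' or 'scan_b'")
        for kind in self.model_kinds:
            if kind not in ("quadratic", "phase_linear"):
                raise InvalidInputError(f"unknown model kind {kind!r}")
        return self


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a validated config from YAML, applying explicit overrides."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise InvalidInputError(f"config {path} must be a YAML mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data).validate()


def dump_config(cfg: RunConfig, path) -> Path:
    """Echo the effective configuration (for reproducibility) to YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
    return path
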