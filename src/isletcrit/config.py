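"""Run configuration: YAML round-trip with documented defaults.

Every stochastic run records its seed and the package version in its output
artifacts, so any recorded artifact can be reproduced from its config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "DEFAULTS"]

COMMANDS = (
    "boolean-sweep",
    "boolean-fit",
    "conductance-fit",
    "islet-simulate",
    "islet-scan",
    "classify",
    "synth-obs",
)


@dataclass
class RunConfig:
    """Flat configuration shared by all CLI commands (unused keys are
    ignored by commands that do not need them)."""

    command: str = "boolean-sweep"
    seed: int = 0
    out: str = "."
    verbosity: int = 1
    # Boolean engine
    L: int = 11
    reps: int = 500
    sp: float = 0.15
    p: float = 0.30
    grid_step: float = 0.01
    p_grid_min: float = 0.0
    p_grid_max: float = 1.0
    sp_grid_min: float = 0.05
    sp_grid_max: float = 0.30
    sp_grid_step: float = 0.01
    p_exc: float = 0.7
    # fitting / synthetic observations
    obs_path: str = ""
    noise_sd: float = 0.0
    p_true: float = 0.30
    sp_true: float = 0.15
    control_kind: str = "P_exc"
    control_points: list = field(default_factory=list)
    # dynamical engine
    n_cells: int = 500
    mean_g: float = 120.0
    coupling_cv: float = 0.70
    cv_general: float = 0.10
    cv_gkatp: float = 0.25
    heterogeneity_mode: str = "all"
    glucose_mM: float = 11.0
    dt_ms: float = 0.1
    sample_ms: float = 100.0
    duration_ms: float = 60000.0
    transient_s: float = 10.0
    scan_kind: str = "mutant_fraction"
    scan_values: list = field(default_factory=list)
    mean_g_list: list = field(default_factory=lambda: [120.0])
    architecture: str = "sphere"
    # classification
    traces_path: str = ""
    reference_cell: int = -1

    def validate(self) -> None:
        if self.command not in COMMANDS:
            raise ValueError(
                f"unknown command {self.command!r}; expected one of {COMMANDS}"
            )


DEFAULTS = RunConfig()
_KNOWN = {f.name for f in fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load a YAML config; unspecified fields take the documented defaults,
    unknown keys warn and are ignored, and an empty file yields the
    all-defaults config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(raw) - _KNOWN
    for key in sorted(unknown):
        warnings.warn(f"ignoring unknown config key {key!r}", stacklevel=2)
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in _KNOWN})
    cfg.validate()
    return cfg


def save_config(config: RunConfig, path) -> None:
    config.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(
            {f.name: getattr(config, f.name) for f in fields(config)},
            fh,
            sort_keys=False,
        )
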