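"""File interfaces: tidy CSVs, YAML configuration blocks, JSON results."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .dynamics import DoseEvent, ModelParameters, Trajectory
from .measurement import ObservationModel
from .mpc import MPCConfig
from .pdpk import PDPKConfig
from .protocols import ProtocolConfig

__all__ = [
    "trajectory_to_csv",
    "doses_to_csv",
    "doses_from_csv",
    "load_config",
    "dump_config",
    "model_parameters_from_config",
    "save_json",
]


def trajectory_to_csv(traj: Trajectory, path) -> None:
    """Tidy trajectory CSV: day, x1_mm3, x2_mm3, total_mm3, x3_mgkg."""
    traj.to_frame().to_csv(path, index=False)


def doses_to_csv(doses, path) -> None:
    pd.DataFrame(
        {"day": [d.time for d in doses], "dose_mgkg": [d.dose for d in doses]}
    ).to_csv(path, index=False)


def doses_from_csv(path) -> list[DoseEvent]:
    df = pd.read_csv(path)
    return [
        DoseEvent(float(r.day), float(r.dose_mgkg))
        for r in df.sort_values("day").itertuples()
    ]


_CONFIG_SECTIONS = {
    "model": ModelParameters,
    "pdpk": PDPKConfig,
    "mpc": MPCConfig,
    "protocol": ProtocolConfig,
    "observation": ObservationModel,
}


def load_config(path) -> dict:
    """Parse a YAML config with optional model/pdpk/mpc/protocol/observation
    blocks into the corresponding configuration objects.

    Unknown top-level keys are passed through untouched (trial settings,
    seeds, ...)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    for key, value in raw.items():
        cls = _CONFIG_SECTIONS.get(key)
        if cls is not None and isinstance(value, dict):
            if key == "mpc" and "injection_offsets" in value:
                value = dict(value)
                value["injection_offsets"] = tuple(value["injection_offsets"])
            out[key] = cls(**value)
        else:
            out[key] = value
    return out


def dump_config(sections: dict, path) -> None:
    """Write configuration objects back to YAML (inverse of load_config)."""
    raw = {}
    for key, value in sections.items():
        if key == "model" and isinstance(value, ModelParameters):
            raw[key] = value.to_dict()
        elif hasattr(value, "__dataclass_fields__"):
            raw[key] = {
                f: _plain(getattr(value, f)) for f in value.__dataclass_fields__
            }
        else:
            raw[key] = value
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    if hasattr(v, "__dataclass_fields__"):
        return {f: _plain(getattr(v, f)) for f in v.__dataclass_fields__}
    return v


def model_parameters_from_config(path) -> ModelParameters:
    cfg = load_config(path)
    if "model" not in cfg:
        raise KeyError(f"no 'model:' block in {path}")
    return cfg["model"]


def save_json(obj, path) -> None:
    """JSON dump with dataclass/ndarray-aware fallback."""

    def default(o):
        if hasattr(o, "to_dict"):
            return o.to_dict()
        if hasattr(o, "tolist"):
            return o.tolist()
        if hasattr(o, "__dataclass_fields__"):
            return {f: getattr(o, f) for f in o.__dataclass_fields__}
        return str(o)

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
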