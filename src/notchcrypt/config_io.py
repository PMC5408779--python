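"""Configuration files, deterministic output writing, and run manifests.

Parameter sets and crypt configurations are flat key--value mappings; YAML
and JSON are accepted on input, canonical JSON (sorted keys) is used for
hashing so that manifests are stable across dialects.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from .circuits import CircuitParams, ModelForm
from .crypt import CryptConfig

__all__ = [
    "params_to_dict",
    "params_from_dict",
    "load_config",
    "dump_config",
    "canonical_hash",
    "RunManifest",
    "write_dataframe",
]

_PARAM_FIELDS = {f.name for f in dataclasses.fields(CircuitParams)}


def params_to_dict(params: CircuitParams) -> dict:
    d = dataclasses.asdict(params)
    d["model_form"] = params.model_form.name
    return {k: v for k, v in d.items() if v is not None}


def params_from_dict(d: dict) -> CircuitParams:
    d = dict(d)
    unknown = set(d) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown circuit parameter keys: {sorted(unknown)}")
    form = d.pop("model_form", "MODEL3")
    if isinstance(form, str):
        form = ModelForm[form]
    return CircuitParams(model_form=form, **d)


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config file; an empty file means all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def dump_config(data: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def canonical_hash(data: dict) -> str:
    """SHA-256 of the canonical (sorted-key JSON) serialization."""

    def default(o: Any):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    blob = json.dumps(data, sort_keys=True, separators=(",", ":"), default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record written next to every CLI stage output."""

    stage: str
    seed: Optional[int]
    config: dict
    outputs: list[str]
    version: str = __version__

    @property
    def config_hash(self) -> str:
        return canonical_hash(self.config)

    def write(self, path: str | Path) -> None:
        payload = {
            "stage": self.stage,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "config": self.config,
            "outputs": self.outputs,
            "version": self.version,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def write_dataframe(df, path: str | Path) -> None:
    """Deterministic CSV output (fixed float format, no index)."""
    df.to_csv(path, index=False, float_format="%.12g")
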