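"""Delimited-table formats, YAML configuration and the run manifest.

The cell-table dialect mirrors spot exports from commercial imaging
software: one row per segmented cell with header
``id,cell_type,x_um,y_um,z_um,radius_um,confetti``.  Vessel networks use a
long-form vertex table ``segment_id,vclass,radius_um,point_index,x_um,y_um,
z_um``.  Ground-truth annotations travel as a JSON sidecar.  Every pipeline
run records a manifest (config snapshot, seeds, artifact digests, test
results) so each reported number is traceable to a written table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import CONFETTI_COLOURS, KNOWN_TYPES
from .errors import SchemaError
from .geometry import CELL_COLUMNS, VesselNetwork
from .synthetic import (
    BSiteParams,
    ConfettiParams,
    ErythroidSiteParams,
    GeneratorConfig,
    HspcParams,
    MyeloidSiteParams,
    PreCfuEParams,
    PRESETS,
    SizeDistribution,
    VesselParams,
)

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_vessel_table",
    "write_vessel_table",
    "read_truth",
    "write_truth",
    "load_config",
    "config_to_dict",
    "RunManifest",
]

VESSEL_COLUMNS = ["segment_id", "vclass", "radius_um", "point_index",
                  "x_um", "y_um", "z_um"]
_VALID_COLOURS = set(CONFETTI_COLOURS) | {"none"}


def read_cell_table(path) -> pd.DataFrame:
    """Load and validate a delimited cell table (units asserted µm).

    Schema violations (missing columns, non-numeric coordinates, duplicate
    ids, unknown cell types or colours) raise :class:`SchemaError` naming
    the offending rows (1-based data line numbers).
    """
    table = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in ("x_um", "y_um", "z_um", "radius_um"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[numeric.isna() & table[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col} at rows {[int(i) + 1 for i in bad]}"
            )
        table[col] = numeric
    dup = table["id"][table["id"].duplicated()]
    if len(dup):
        raise SchemaError(f"{path}: duplicate ids {sorted(set(dup))[:10]}")
    unknown = table.index[~table["cell_type"].isin(KNOWN_TYPES)]
    if len(unknown):
        types = sorted(set(table.loc[unknown, "cell_type"]))
        raise SchemaError(
            f"{path}: unknown cell types {types} at rows "
            f"{[int(i) + 1 for i in unknown[:10]]}"
        )
    table["confetti"] = table["confetti"].fillna("none")
    bad_colour = table.index[~table["confetti"].isin(_VALID_COLOURS)]
    if len(bad_colour):
        raise SchemaError(
            f"{path}: invalid confetti values at rows "
            f"{[int(i) + 1 for i in bad_colour[:10]]}"
        )
    return table[CELL_COLUMNS]


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells[CELL_COLUMNS].to_csv(path, index=False)


def read_vessel_table(path) -> VesselNetwork:
    table = pd.read_csv(path)
    missing = [c for c in VESSEL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return VesselNetwork.from_frame(table)


def write_vessel_table(network: VesselNetwork, path) -> None:
    network.to_frame().to_csv(path, index=False)


def write_truth(truth: dict, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(truth, default=_default, indent=1))


def read_truth(path) -> dict:
    truth = json.loads(Path(path).read_text())
    for key in ("clone_of", "pre_cfu_e_contact"):
        if key in truth:
            truth[key] = {int(k): v for k, v in truth[key].items()}
    return truth


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_NESTED = {
    "vessel_params": VesselParams,
    "hspc": HspcParams,
    "erythroid": ErythroidSiteParams,
    "b_site": BSiteParams,
    "myeloid": MyeloidSiteParams,
    "pre_cfu_e": PreCfuEParams,
    "confetti": ConfettiParams,
}


def _apply(obj, updates: dict):
    for key, value in updates.items():
        if not hasattr(obj, key):
            raise SchemaError(f"unknown config field {key!r} on {type(obj).__name__}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            if isinstance(current, SizeDistribution):
                setattr(obj, key, SizeDistribution(**value))
            else:
                _apply(current, value)
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            setattr(obj, key, tuple(value))
        else:
            setattr(obj, key, value)


def load_config(source=None, preset: str | None = None) -> GeneratorConfig:
    """Build a generator config from a preset and/or a YAML file or dict.

    Overrides from the YAML are applied on top of the preset (default:
    ``steady_state``); unknown keys are schema errors.
    """
    if preset is not None and preset not in PRESETS:
        raise SchemaError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
        )
    config = PRESETS[preset or "steady_state"]()
    if source is None:
        updates: dict = {}
    elif isinstance(source, dict):
        updates = source
    else:
        updates = yaml.safe_load(Path(source).read_text()) or {}
    _apply(config, updates)
    config.validate()
    return config


def config_to_dict(config: GeneratorConfig) -> dict:
    return dataclasses.asdict(config)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class RunManifest:
    """Record of one pipeline run: config, seeds, artifact digests, tests."""

    def __init__(self, config: GeneratorConfig | None = None,
                 seed: int | None = None):
        from . import __version__

        self.data = {
            "version": __version__,
            "seed": seed,
            "config": config_to_dict(config) if config is not None else None,
            "stages": [],
            "artifacts": {},
            "tests": [],
        }

    def add_stage(self, name: str, **info) -> None:
        self.data["stages"].append({"stage": name, **info})

    def add_artifact(self, name: str, path) -> None:
        self.data["artifacts"][name] = {
            "path": str(path), "sha256": _digest(path)
        }

    def add_test(self, label: str, result) -> None:
        entry = {"label": label}
        if dataclasses.is_dataclass(result):
            entry.update(dataclasses.asdict(result))
        else:
            entry.update(result)
        self.data["tests"].append(entry)

    def save(self, path) -> None:
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        Path(path).write_text(
            json.dumps(self.data, default=_default, indent=1)
        )
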