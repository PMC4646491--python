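"""CSV / JSON / YAML input-output and run provenance.

The contract formats are plain text: event tables and per-well count
tables as CSV, ground truth and QC as JSON, run configuration as YAML.
Every file the pipeline writes is accompanied by provenance (config
hash, master seed, package version) so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .channels import CHANNELS, EVENT_COLUMNS

WELL_COUNT_COLUMNS = (
    "plate_id",
    "well_id",
    "role",
    "compound_id",
    "n_enucleated",
    "n_nucleated",
    "n_live",
    "n_total",
)

PLATE_MAP_COLUMNS = ("well_id", "role", "compound_id", "concentration")

ROLES = ("compound", "neg_control", "pos_control")


class SchemaError(ValueError):
    """An input file does not match its contract schema."""


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table with the canonical column layout."""
    out = events.copy()
    if "truth_label" not in out.columns:
        out["truth_label"] = ""
    out[list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path)
    missing = [c for c in ("event_id", *CHANNELS) if c not in events.columns]
    if missing:
        raise SchemaError(f"{path}: event CSV missing columns {missing}")
    if "truth_label" not in events.columns:
        events["truth_label"] = ""
    events["truth_label"] = events["truth_label"].fillna("")
    return events


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Plate map CSV: well -> role / compound / concentration."""
    pm = pd.read_csv(path)
    if pm.empty:
        raise SchemaError(f"{path}: plate map is empty")
    missing = [c for c in PLATE_MAP_COLUMNS if c not in pm.columns]
    if missing:
        raise SchemaError(f"{path}: plate map missing columns {missing}")
    bad_roles = set(pm["role"]) - set(ROLES)
    if bad_roles:
        raise SchemaError(f"{path}: unknown roles {sorted(bad_roles)}")
    if pm["well_id"].duplicated().any() and "plate_id" not in pm.columns:
        raise SchemaError(f"{path}: duplicate well_id entries")
    return pm


def read_well_counts(path: str | Path) -> pd.DataFrame:
    wc = pd.read_csv(path)
    missing = [c for c in WELL_COUNT_COLUMNS if c not in wc.columns]
    if missing:
        raise SchemaError(f"{path}: well-count CSV missing columns {missing}")
    return wc


def read_validation_table(path: str | Path) -> pd.DataFrame:
    """Tidy follow-up table: compound_id, experiment_id, arm,
    timepoint_h (optional), enucleation_pct."""
    tab = pd.read_csv(path)
    required = ("compound_id", "experiment_id", "arm", "enucleation_pct")
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise SchemaError(f"{path}: validation table missing columns {missing}")
    bad_arms = set(tab["arm"]) - {"treated", "control"}
    if bad_arms:
        raise SchemaError(f"{path}: unknown arms {sorted(bad_arms)}")
    return tab


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_provenance(out_dir: str | Path, cfg: dict, seed: int) -> Path:
    """Write the provenance block every pipeline run carries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = {
        "package": "erythroscreen",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config_hash(cfg),
        "config": cfg,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(prov, indent=2, default=str) + "\n")
    return path


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
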