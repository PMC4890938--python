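"""Readers, writers, configuration and run logging.

One CSV dialect throughout: UTF-8, comma-separated, mandatory header,
ISO-8601 timestamps, long format with columns

    site_id, cassette_id, slot, timestamp, substance,
    concentration_ng_ml, below_lod

Truth files carry ``visitor_id, true_use, true_conc_ng_ml`` alongside the
sample key. Simulation configs are flat YAML with a per-substance table.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from .panel import ConfigurationError, SubstancePanel, SubstanceSpec
from .simulate import (
    CarryoverModel,
    DATASET_COLUMNS,
    SimulationConfig,
    TRUTH_COLUMNS,
)

__all__ = [
    "ValidationError",
    "read_samples",
    "write_samples",
    "write_truth",
    "read_config",
    "write_run_log",
]


class ValidationError(ValueError):
    """Malformed input data; message names the column/row at fault."""


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format sample CSV.

    Checks the header, slot range, non-negative concentrations, the
    below-LOD flag domain, and that no (cassette, slot, substance) cell is
    duplicated. Errors name the offending rows (1-based, excluding header).
    """
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df = df[DATASET_COLUMNS]

    bad = df.index[df["slot"] < 1]
    if len(bad):
        raise ValidationError(
            f"{path}: slot must be >= 1 at rows {_rows(bad)}"
        )
    bad = df.index[df["concentration_ng_ml"] < 0]
    if len(bad):
        raise ValidationError(
            f"{path}: negative concentration at rows {_rows(bad)}"
        )
    bad = df.index[~df["below_lod"].isin([0, 1])]
    if len(bad):
        raise ValidationError(
            f"{path}: below_lod must be 0 or 1 at rows {_rows(bad)}"
        )
    key = ["site_id", "cassette_id", "slot", "substance"]
    dup = df.index[df.duplicated(key, keep=False)]
    if len(dup):
        raise ValidationError(
            f"{path}: duplicate (cassette, slot, substance) at rows {_rows(dup)}"
        )
    return df


def _rows(idx) -> list[int]:
    return [int(i) + 2 for i in list(idx)[:10]]  # +2: header + 1-based


def write_samples(dataset: pd.DataFrame, path: str | Path) -> None:
    dataset[DATASET_COLUMNS].to_csv(path, index=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth[TRUTH_COLUMNS].to_csv(path, index=False)


def read_config(path: str | Path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file.

    Schema: ``seed`` (mandatory), ``sites`` (site id → cassette count),
    optional ``slots_per_cassette``, ``events_per_cassette`` (int, list, or
    ``{poisson: mean}``), ``revisit_mean``, ``carryover`` (mapping of
    :class:`CarryoverModel` fields), ``metabolite_links`` (list of
    [primary, metabolite]) and ``panel`` (list of substance mappings).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    if "seed" not in raw:
        raise ConfigurationError(f"{path}: 'seed' is mandatory")
    if "panel" not in raw or not raw["panel"]:
        raise ConfigurationError(f"{path}: 'panel' must list >= 1 substance")
    try:
        substances = tuple(SubstanceSpec(**row) for row in raw["panel"])
    except TypeError as exc:
        raise ConfigurationError(f"{path}: bad panel row ({exc})") from exc
    links = tuple(tuple(pair) for pair in raw.get("metabolite_links", []))
    panel = SubstancePanel(substances=substances, metabolite_links=links)
    carry = CarryoverModel(**raw.get("carryover", {}))
    events = raw.get("events_per_cassette", 24)
    if isinstance(events, dict):
        events = ("poisson", float(events["poisson"]))
    kwargs = {}
    for key in ("slots_per_cassette", "revisit_mean", "start_date"):
        if key in raw:
            kwargs[key] = raw[key]
    return SimulationConfig(
        panel=panel,
        sites=dict(raw["sites"]),
        seed=int(raw["seed"]),
        events_per_cassette=events,
        carryover=carry,
        **kwargs,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_log(
    out_dir: str | Path,
    stage: str,
    parameters: dict,
    inputs: list[str | Path] = (),
) -> Path:
    """Write a machine-readable provenance log next to a stage's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = {
        "stage": stage,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "parameters": parameters,
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()
        },
        "versions": {
            "anonprev": __version__,
            "python": platform.python_version(),
            "pandas": pd.__version__,
        },
    }
    path = out_dir / f"{stage}_run_log.json"
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return path
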