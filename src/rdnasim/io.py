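"""Configuration parsing and TSV serialization.

All outputs are plain TSV; configuration is YAML with keys mirroring
:class:`~rdnasim.core.ModelParams` fields.  Readers and writers are exact
inverses on their own output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from rdnasim.core import ModelParams, ParameterError, Trajectory

__all__ = [
    "params_from_config",
    "params_from_mapping",
    "write_trajectory",
    "read_trajectory",
    "write_table",
]

_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(ModelParams)}
_INT_FIELDS = {"c_start", "c_max", "n0", "reseed_interval", "aging_cap", "max_generations"}


def params_from_mapping(mapping: dict | None, **overrides) -> ModelParams:
    """Build validated :class:`ModelParams` from a dict plus overrides.

    Unknown keys are rejected with a message naming them; an empty mapping
    yields the default parameterization.
    """
    merged: dict = {}
    for source in (mapping or {}), overrides:
        for key, value in source.items():
            if value is None:
                continue
            if key not in _PARAM_FIELDS:
                raise ParameterError(
                    f"unknown parameter {key!r}; valid keys: "
                    f"{sorted(_PARAM_FIELDS)}"
                )
            if key in _INT_FIELDS:
                if float(value) != int(value):
                    raise ParameterError(f"{key} must be an integer, got {value}")
                value = int(value)
            else:
                value = float(value)
            merged[key] = value
    return ModelParams(**merged)


def params_from_config(path: str | Path | None, **overrides) -> ModelParams:
    """Load parameters from a YAML file (optional) with flag overrides."""
    mapping: dict | None = None
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config {path} must be a mapping")
        mapping = loaded
    return params_from_mapping(mapping, **overrides)


def write_trajectory(
    traj: Trajectory,
    destination: str | Path,
    snapshot_interval: int | None = None,
) -> None:
    """Write a trajectory as TSV.

    Default long format has columns (generation, time_s, mean_copies,
    frac_at_cap).  With ``snapshot_interval`` set, a wide per-state format
    is written instead, with one row per recorded multiple of the interval
    and one column per copy-number state (requires snapshots to have been
    recorded at those generations).
    """
    if snapshot_interval is None:
        traj.to_frame().to_csv(destination, sep="\t", index=False)
        return
    if snapshot_interval < 1:
        raise ParameterError("snapshot_interval must be >= 1")
    rows = []
    for g in sorted(traj.snapshots):
        if g % snapshot_interval != 0:
            continue
        snap = traj.snapshots[g]
        row = {"generation": g}
        row.update(
            {str(c): w for c, w in zip(snap.support, snap.weights)}
        )
        rows.append(row)
    if not rows:
        raise ParameterError(
            "no snapshots at multiples of the requested interval; "
            "record snapshots when running the model"
        )
    pd.DataFrame(rows).to_csv(destination, sep="\t", index=False)


def read_trajectory(source: str | Path) -> Trajectory:
    """Read back a long-format trajectory TSV."""
    df = pd.read_csv(source, sep="\t")
    expected = ["generation", "time_s", "mean_copies", "frac_at_cap"]
    if list(df.columns) != expected:
        raise ParameterError(
            f"unexpected trajectory columns {list(df.columns)}; expected {expected}"
        )
    traj = Trajectory()
    for row in df.itertuples(index=False):
        traj.append(
            int(row.generation),
            float(row.time_s),
            float(row.mean_copies),
            float(row.frac_at_cap),
        )
    return traj


def write_table(df: pd.DataFrame, destination: str | Path) -> None:
    """Write any result table (scenario summaries, delta scans) as TSV."""
    df.to_csv(destination, sep="\t", index=False)
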