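"""File I/O for the package's tabular and parameter schemas.

Every numeric CSV column carries a unit suffix (``flux_LMH``, ``glc_mM``) to
prevent silent unit errors.  ``write`` followed by ``read`` is the identity
on valid files; missing required columns raise errors naming the column;
unknown extra columns produce a warning and are preserved on write.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from evtwin.cultivation import KineticParams, PhaseSchedule
from evtwin.streams import StreamState
from evtwin.ufdf import UFDFConfig

TRAJECTORY_COLUMNS = ["time_h", "phase", "vcd_e6_per_ml", "glc_mM", "lac_mM",
                      "product_mM", "particles_per_ml"]
FLUX_COLUMNS = ["v_Lm2", "flux_LMH"]
CHROMATOGRAM_COLUMNS = ["time_min", "flow_ml_min", "modifier_mM"]
FRACTION_COLUMNS = ["fraction", "start_min", "end_min", "volume_ml"]
STEP_TABLE_COLUMNS = ["step", "recovery", "protein_removal", "dna_removal"]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _check_columns(df: pd.DataFrame, required: list[str], path,
                   optional: tuple[str, ...] = (),
                   free_extras: bool = False) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if free_extras:
        return
    extra = [c for c in df.columns if c not in required and c not in optional]
    if extra:
        warnings.warn(f"{path}: unknown column(s) {extra} preserved",
                      stacklevel=3)


def _read_csv(path, required: list[str], optional: tuple[str, ...] = (),
              free_extras: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, required, path, optional, free_extras)
    numeric = [c for c in required if c not in ("phase", "step")]
    for c in numeric:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: non-numeric values in {c!r}: {exc}")
    return df


_TRAJ_OPT = ("replicate",)
_FLUX_OPT = ("time_h", "tmp_bar", "replicate")
_STEP_OPT = ("cumulative_recovery",)


def read_trajectory(path) -> pd.DataFrame:
    return _read_csv(path, TRAJECTORY_COLUMNS, _TRAJ_OPT)


def write_trajectory(df: pd.DataFrame, path) -> None:
    _check_columns(df, TRAJECTORY_COLUMNS, path, _TRAJ_OPT)
    df.to_csv(path, index=False)


def read_flux_series(path) -> pd.DataFrame:
    return _read_csv(path, FLUX_COLUMNS, _FLUX_OPT)


def write_flux_series(df: pd.DataFrame, path) -> None:
    _check_columns(df, FLUX_COLUMNS, path, _FLUX_OPT)
    df.to_csv(path, index=False)


def read_chromatogram(path) -> pd.DataFrame:
    # extra columns are per-component outlet traces: accepted freely
    return _read_csv(path, CHROMATOGRAM_COLUMNS, free_extras=True)


def write_chromatogram(df: pd.DataFrame, path) -> None:
    _check_columns(df, CHROMATOGRAM_COLUMNS, path, free_extras=True)
    df.to_csv(path, index=False)


def read_fraction_table(path) -> pd.DataFrame:
    # extra columns are per-component assay values: accepted freely
    return _read_csv(path, FRACTION_COLUMNS, free_extras=True)


def write_fraction_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, FRACTION_COLUMNS, path, free_extras=True)
    df.to_csv(path, index=False)


def read_step_table(path) -> pd.DataFrame:
    return _read_csv(path, STEP_TABLE_COLUMNS, _STEP_OPT)


def write_step_table(df: pd.DataFrame, path) -> None:
    _check_columns(df, STEP_TABLE_COLUMNS, path, _STEP_OPT)
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Parameter files (YAML/JSON)
# --------------------------------------------------------------------------

def write_kinetic_params(params: Mapping[str, KineticParams], path) -> None:
    """Phase-keyed kinetic parameter file (YAML or JSON by extension)."""
    data = {}
    for phase, p in params.items():
        d = {k: v for k, v in vars(p).items() if v is not None}
        data[phase] = d
    _dump(data, path)


def read_kinetic_params(path) -> dict[str, KineticParams]:
    data = _load(path)
    out = {}
    for phase, d in data.items():
        try:
            out[phase] = KineticParams(**d)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: invalid parameters for {phase!r}: {exc}")
    return out


def write_ufdf_config(cfg: UFDFConfig, path) -> None:
    _dump(vars(cfg), path)


def read_ufdf_config(path) -> UFDFConfig:
    data = _load(path)
    try:
        return UFDFConfig(**data)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: invalid UFDF config: {exc}")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, StreamState):
        return vars(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump(data: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yml", ".yaml"):
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
    else:
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, default=_json_default)


def _load(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yml", ".yaml"):
            return yaml.safe_load(fh)
        return json.load(fh)


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

_CONFIG_SECTIONS = {"cultivation", "ufdf", "mmsec", "aex", "ledger",
                    "optimization", "synthetic"}
_CONFIG_GLOBALS = {"seed", "output_dir", "log_level"}


def validate_run_config(config: dict) -> dict:
    """Validate a pipeline run configuration before any computation.

    Unknown top-level keys are rejected; ``seed`` must be a non-negative
    integer.  Returns the config with defaults filled in.
    """
    if not isinstance(config, dict):
        raise SchemaError("run config must be a mapping")
    unknown = set(config) - _CONFIG_SECTIONS - _CONFIG_GLOBALS
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    out = dict(config)
    seed = out.setdefault("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        raise SchemaError("seed must be a non-negative integer")
    out.setdefault("output_dir", "results")
    out.setdefault("log_level", "INFO")
    for section in _CONFIG_SECTIONS:
        sec = out.setdefault(section, {})
        if not isinstance(sec, dict):
            raise SchemaError(f"config section {section!r} must be a mapping")
    ufdf_sec = out["ufdf"]
    for key in ("vcf1", "vcf2"):
        if key in ufdf_sec and ufdf_sec[key] < 1:
            raise SchemaError(f"ufdf.{key} must be >= 1")
    if "dv" in ufdf_sec and ufdf_sec["dv"] < 0:
        raise SchemaError("ufdf.dv must be non-negative")
    return out
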