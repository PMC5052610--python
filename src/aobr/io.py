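"""CSV readers/writers and configuration handling.

All tabular interchange is comma-separated UTF-8 with a mandatory header
row; times are hours, concentrations mg/L, percentages on the 0-100 scale.
Malformed rows are reported with their file line number (header = line 1).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diversity import BandTable
from .errors import ConfigError, ParseError
from .performance import stage_for_day
from .reactor import CCurve, CODScenario, ReactorConfig, TracerExperiment

__all__ = [
    "read_tracer_csv", "write_tracer_csv",
    "read_band_csv", "write_band_csv",
    "read_cod_csv", "write_cod_csv",
    "load_config", "build_reactor_config", "build_tracer_experiment",
    "build_cod_scenario", "config_hash", "write_run_log",
]

TRACER_COLUMNS = ["time_h", "conc_mg_L"]
COD_COLUMNS = ["day", "stage", "reactor_id", "compartment", "cod_mg_L"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _line(df_index: int) -> int:
    # header occupies line 1
    return int(df_index) + 2


def read_tracer_csv(path, c0: float, nominal_hrt: float) -> CCurve:
    """Read a tracer curve (columns ``time_h``, ``conc_mg_L``)."""
    df = _read_csv(path, TRACER_COLUMNS)
    for col in TRACER_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        numeric = pd.to_numeric(df[col], errors="coerce")
        nonnum = numeric.isna()
        if nonnum.any():
            raise ParseError(f"non-numeric value in column {col!r}",
                             line=_line(df.index[nonnum][0]))
        df[col] = numeric
        del bad
    neg = df["conc_mg_L"] < 0
    if neg.any():
        raise ParseError("negative concentration", line=_line(df.index[neg][0]))
    times = df["time_h"].to_numpy()
    if np.any(np.diff(times) <= 0):
        i = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
        raise ParseError("times not strictly increasing", line=_line(df.index[i]))
    return CCurve(times=times, concentrations=df["conc_mg_L"].to_numpy(),
                  c0=c0, nominal_hrt=nominal_hrt)


def write_tracer_csv(curve: CCurve, path) -> None:
    pd.DataFrame({"time_h": curve.times,
                  "conc_mg_L": curve.concentrations}).to_csv(path, index=False)


def read_band_csv(path) -> BandTable:
    """Read a band-intensity table: first column lane id, rest band intensities."""
    df = _read_csv(path, [])
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a lane-id column plus >= 1 band column")
    lane_col = df.columns[0]
    band_cols = list(df.columns[1:])
    for col in band_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            raise ParseError(f"non-numeric intensity in column {col!r}",
                             line=_line(df.index[numeric.isna()][0]))
        neg = numeric < 0
        if neg.any():
            raise ParseError(f"negative intensity in column {col!r}",
                             line=_line(df.index[neg][0]))
        df[col] = numeric
    return BandTable(lane_ids=[str(x) for x in df[lane_col]],
                     band_ids=[str(c) for c in band_cols],
                     intensities=df[band_cols].to_numpy(dtype=float))


def write_band_csv(table: BandTable, path) -> None:
    table.to_frame().to_csv(path)


def read_cod_csv(path, validate_stages: bool = True) -> pd.DataFrame:
    """Read long-format COD records (day, stage, reactor_id, compartment, cod_mg_L)."""
    df = _read_csv(path, COD_COLUMNS)
    numeric = pd.to_numeric(df["cod_mg_L"], errors="coerce")
    if numeric.isna().any():
        raise ParseError("non-numeric COD value",
                         line=_line(df.index[numeric.isna()][0]))
    df["cod_mg_L"] = numeric
    neg = df["cod_mg_L"] < 0
    if neg.any():
        raise ParseError("negative COD value", line=_line(df.index[neg][0]))
    days = pd.to_numeric(df["day"], errors="coerce")
    if days.isna().any():
        raise ParseError("non-numeric day", line=_line(df.index[days.isna()][0]))
    df["day"] = days.astype(int)
    if validate_stages:
        for idx, row in df.iterrows():
            expected = stage_for_day(int(row["day"]))
            if str(row["stage"]) != expected:
                raise ParseError(
                    f"day {row['day']} belongs to stage {expected}, "
                    f"not {row['stage']!r}", line=_line(idx))
    df["compartment"] = df["compartment"].astype(str)
    return df


def write_cod_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML key-value configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a key-value mapping")
    return data


def build_reactor_config(cfg: dict) -> ReactorConfig:
    kw = {}
    for key in ("n_compartments", "total_volume", "total_flow",
                "compartment_volumes", "feed_split"):
        if key in cfg:
            kw[key] = cfg[key]
    return ReactorConfig(**kw)


def build_tracer_experiment(cfg: dict) -> TracerExperiment:
    kw = {}
    for key in ("injected_mass", "injection_compartment", "sampling_interval",
                "duration_multiple", "noise_cv", "rng_seed", "pulse_duration"):
        if key in cfg:
            kw[key] = cfg[key]
    return TracerExperiment(**kw)


def build_cod_scenario(cfg: dict, n_compartments: int) -> CODScenario:
    if "feed_cod" not in cfg:
        raise ConfigError("cod scenario requires 'feed_cod'")
    rates = cfg.get("rates", [0.0] * n_compartments)
    return CODScenario(feed_cod=cfg["feed_cod"], rates=tuple(rates))


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping, for provenance logs."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(path, config: dict, seed: int | None, outputs: list[str]) -> None:
    """Append a provenance record (config hash, seed, outputs) as JSON lines."""
    record = {"config_hash": config_hash(config), "seed": seed,
              "outputs": [str(o) for o in outputs]}
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(record) + "\n")
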