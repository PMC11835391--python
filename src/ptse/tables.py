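"""Tabular file formats (TSV) with declared schemas and YAML sidecars.

Every table is tab-separated with a header row; structured metadata
(spec parameters, seeds, provenance) travels in a ``<file>.meta.yaml``
sidecar.  Reading validates the declared schema and rejects malformed
or non-finite rows with their line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .committor import CommittorEstimate, ShotRecord
from .fep import FreeEnergyProfile, WorkProfile
from .kinetics import RateMeasurement
from .umbrella import UmbrellaWindow

__all__ = [
    "FormatError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_metadata",
    "write_work_profiles",
    "read_work_profiles",
    "write_fep",
    "read_fep",
    "write_windows",
    "read_windows",
    "write_shot_log",
    "read_shot_log",
    "write_committor_curve",
    "write_rate_table",
    "read_rate_table",
]


class FormatError(ValueError):
    pass


#: column name -> (kind, required finite) for each table family
SCHEMAS: Dict[str, Dict[str, str]] = {
    "work_profile": {"replicate_id": "int", "lambda": "float", "xi": "float", "work": "float"},
    "fep": {"rc": "float", "G": "float", "stderr": "float_or_inf"},
    "umbrella_window": {"time": "float", "rc": "float"},
    "shot_log": {"config_id": "int", "grid_rc": "float", "launch_rc": "float",
                 "seed": "int", "outcome": "str", "steps": "int"},
    "committor_curve": {"rc": "float", "n_shots": "int", "n_product": "int",
                        "p": "float", "ci_low": "float", "ci_high": "float"},
    "rate_table": {"temperature_K": "float", "pH": "float_nullable", "condition": "str",
                   "k_obs": "float", "se": "float"},
    "time_course": {"time_min": "float", "product_conc": "float"},
}


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_table(path, df: pd.DataFrame, schema: str, metadata: Optional[dict] = None) -> None:
    cols = list(SCHEMAS[schema])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"dataframe missing columns {missing} for schema {schema!r}")
    df[cols].to_csv(path, sep="\t", index=False)
    if metadata is not None:
        _sidecar(path).write_text(yaml.safe_dump(metadata, sort_keys=True))


def read_metadata(path) -> Optional[dict]:
    sc = _sidecar(path)
    return yaml.safe_load(sc.read_text()) if sc.exists() else None


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema.

    Malformed rows (wrong type, NaN/inf in finite columns) raise
    :class:`FormatError` naming the offending line; an empty file yields
    an empty frame.
    """
    spec = SCHEMAS[schema]
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame({c: [] for c in spec})
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({c: [] for c in spec})
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = {}
    for col, kind in spec.items():
        raw = df[col]
        if kind == "str":
            out[col] = raw.astype(str)
            continue
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() & (raw.astype(str).str.len() > 0)
        if kind in ("float", "int"):
            bad |= ~np.isfinite(vals.fillna(np.nan)) | vals.isna()
        elif kind == "float_or_inf":
            bad |= vals.isna()
        # float_nullable: empty/NaN entries are allowed
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: malformed value in column {col!r} at line {line}")
        out[col] = vals.astype(int) if kind == "int" else vals.astype(float)
    return pd.DataFrame(out)


# -- work profiles ----------------------------------------------------

def write_work_profiles(path, profiles: Sequence[WorkProfile], metadata: Optional[dict] = None) -> None:
    rows = []
    for p in profiles:
        rows.append(pd.DataFrame({
            "replicate_id": p.replicate_id,
            "lambda": p.lambda_grid,
            "xi": p.xi_trace,
            "work": p.work,
        }))
    meta = dict(metadata or {})
    meta.setdefault("direction", profiles[0].direction if profiles else "forward")
    meta.setdefault("seeds", [int(p.seed) for p in profiles])
    write_table(path, pd.concat(rows, ignore_index=True), "work_profile", meta)


def read_work_profiles(path) -> List[WorkProfile]:
    df = read_table(path, "work_profile")
    meta = read_metadata(path) or {}
    direction = meta.get("direction", "forward")
    seeds = meta.get("seeds", [])
    out = []
    for i, (rid, grp) in enumerate(df.groupby("replicate_id", sort=True)):
        out.append(WorkProfile(
            replicate_id=int(rid),
            lambda_grid=grp["lambda"].to_numpy(),
            xi_trace=grp["xi"].to_numpy(),
            work=grp["work"].to_numpy(),
            direction=direction,
            seed=int(seeds[i]) if i < len(seeds) else 0,
        ))
    return out


# -- free-energy profiles ---------------------------------------------

def write_fep(path, profile: FreeEnergyProfile, metadata: Optional[dict] = None) -> None:
    df = pd.DataFrame({"rc": profile.rc_grid, "G": profile.G, "stderr": profile.stderr})
    meta = dict(metadata or {})
    meta.update({
        "estimator": profile.estimator,
        "n_replicates": int(profile.n_replicates),
        "temperature": float(profile.temperature),
        "units_mode": profile.units_mode,
        "info": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in profile.info.items()},
    })
    write_table(path, df, "fep", meta)


def read_fep(path) -> FreeEnergyProfile:
    df = read_table(path, "fep")
    meta = read_metadata(path) or {}
    return FreeEnergyProfile(
        rc_grid=df["rc"].to_numpy(),
        G=df["G"].to_numpy(),
        stderr=df["stderr"].to_numpy(),
        estimator=meta.get("estimator", ""),
        n_replicates=int(meta.get("n_replicates", 0)),
        temperature=float(meta.get("temperature", 1.0)),
        units_mode=meta.get("units_mode", "reduced"),
        info=meta.get("info", {}),
    )


# -- umbrella windows -------------------------------------------------

def write_windows(directory, windows: Sequence[UmbrellaWindow]) -> List[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, w in enumerate(windows):
        p = directory / f"window_{i:03d}.tsv"
        t = w.sample_interval * np.arange(len(w.rc_samples))
        write_table(p, pd.DataFrame({"time": t, "rc": w.rc_samples}), "umbrella_window", {
            "center": float(w.center),
            "force_constant": float(w.force_constant),
            "equil_time": float(w.equil_time),
            "prod_time": float(w.prod_time),
            "sample_interval": float(w.sample_interval),
            "temperature": float(w.temperature),
            "seed": int(w.seed),
            "flags": list(w.flags),
        })
        paths.append(p)
    return paths


def read_windows(directory) -> List[UmbrellaWindow]:
    out = []
    for p in sorted(Path(directory).glob("window_*.tsv")):
        df = read_table(p, "umbrella_window")
        meta = read_metadata(p) or {}
        out.append(UmbrellaWindow(
            center=float(meta["center"]),
            force_constant=float(meta["force_constant"]),
            rc_samples=df["rc"].to_numpy(),
            equil_time=float(meta.get("equil_time", 0.0)),
            prod_time=float(meta.get("prod_time", 0.0)),
            sample_interval=float(meta.get("sample_interval", 1.0)),
            seed=int(meta.get("seed", 0)),
            temperature=float(meta.get("temperature", 1.0)),
            flags=list(meta.get("flags", [])),
        ))
    return out


# -- shot logs and committor curves -----------------------------------

def write_shot_log(path, records: Sequence[ShotRecord], metadata: Optional[dict] = None) -> None:
    df = pd.DataFrame({
        "config_id": [r.config_id for r in records],
        "grid_rc": [r.grid_rc if r.grid_rc is not None else r.launch_rc for r in records],
        "launch_rc": [r.launch_rc for r in records],
        "seed": [r.seed for r in records],
        "outcome": [r.outcome for r in records],
        "steps": [r.steps_to_absorption for r in records],
    })
    write_table(path, df, "shot_log", metadata)


def read_shot_log(path) -> List[ShotRecord]:
    df = read_table(path, "shot_log")
    return [
        ShotRecord(
            config_id=int(r.config_id),
            launch_rc=float(r.launch_rc),
            seed=int(r.seed),
            outcome=str(r.outcome),
            steps_to_absorption=int(r.steps),
            grid_rc=float(r.grid_rc),
        )
        for r in df.itertuples()
    ]


def write_committor_curve(path, estimates: Sequence[CommittorEstimate],
                          metadata: Optional[dict] = None) -> None:
    df = pd.DataFrame({
        "rc": [e.grid_rc for e in estimates],
        "n_shots": [e.n_shots for e in estimates],
        "n_product": [e.n_product for e in estimates],
        "p": [e.p_B for e in estimates],
        "ci_low": [e.ci_low for e in estimates],
        "ci_high": [e.ci_high for e in estimates],
    })
    write_table(path, df, "committor_curve", metadata)


# -- kinetics ---------------------------------------------------------

def write_rate_table(path, measurements: Sequence[RateMeasurement],
                     metadata: Optional[dict] = None) -> None:
    df = pd.DataFrame({
        "temperature_K": [m.temperature for m in measurements],
        "pH": [m.pH if m.pH is not None else np.nan for m in measurements],
        "condition": [m.condition for m in measurements],
        "k_obs": [m.k_obs for m in measurements],
        "se": [m.se for m in measurements],
    })
    write_table(path, df, "rate_table", metadata)


def read_rate_table(path) -> List[RateMeasurement]:
    df = read_table(path, "rate_table")
    return [
        RateMeasurement(
            temperature=float(r.temperature_K),
            k_obs=float(r.k_obs),
            se=float(r.se),
            pH=None if np.isnan(r.pH) else float(r.pH),
            condition=str(r.condition),
        )
        for r in df.itertuples()
    ]
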