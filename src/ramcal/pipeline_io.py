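"""Dataset CSV dialect, run configuration and provenance.

The dataset file mirrors a merged spectrometer/bioreactor export: metadata
columns first (record id, vessel, batch, sampling time, batch age, sample
kind, spike annotation, reference concentrations), then one column per
wavenumber (cm^-1, strictly ascending). One row per sub-spectrum;
``record_id`` groups the replicates of one averaged sample.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiment_design import ANALYTES
from .synthetic_data import SampleRecord

RUN_START = _dt.datetime(2022, 3, 1, 8, 0, 0)

META_COLUMNS = (
    ["record_id", "vessel_id", "batch_id", "sample_id", "sampling_time",
     "batch_age_days", "kind", "analyte_spiked", "replicate"]
    + [f"reference_{a}" for a in ANALYTES]
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "results",
    "design": {"n_doe": 16, "n_control": 8},
    "schedule": {"n_days": 14, "spike_days": list(range(6, 14))},
    "spike": {
        "v_sample_ul": 140.0, "v_min_ul": 20.0, "v_max_ul": 60.0,
        "stocks": {a: {"low_g_per_l": lo, "high_g_per_l": hi}
                   for a, (lo, hi) in
                   {"glucose": (16.0, 32.0), "lactate": (12.0, 24.0),
                    "glutamine": (8.0, 16.0), "glutamate": (8.0, 16.0),
                    "titer": (10.0, 20.0)}.items()},
    },
    "acquisition": {"sub_spectrum_s": 60.0, "replicates": 5},
    "noise": {"detector_sd": 0.05, "gain_jitter_sd": 0.05,
              "reference_cv": 0.02, "mixing_bias": 1.0,
              "fluor_amplitude_day0": 4.0, "fluor_growth_per_day": 0.30},
    "preprocess": {"asls_lambda": 1.0e5, "asls_p": 0.001,
                   "asls_iterations": 10, "water_statistic": "area",
                   "water_half_width": 50.0,
                   "min_total_intensity": 1000.0,
                   "min_water_band_ratio": 1.05},
    "outliers": {"alpha": 0.05, "dmodx_confirm": 2.0, "dmodx_crit": 3.0,
                 "t2_extreme_factor": 5.0},
    "model": {"max_ortho": 6, "overfit_gap": 0.3},
    "cv": {"k": 4},
}


class ConfigError(ValueError):
    pass


def _validate(cfg: dict, defaults: dict, path: str = "") -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    out = {}
    for key, default in defaults.items():
        here = f"{path}.{key}" if path else key
        if key in cfg and isinstance(default, dict) and not path.endswith("stocks"):
            if not isinstance(cfg[key], dict):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _validate(cfg[key], default, here)
        else:
            out[key] = cfg.get(key, default)
    unknown = set(cfg) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys at {path or 'top level'}: "
                          f"{sorted(unknown)}")
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML run configuration, materializing every default."""
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
    if overrides:
        cfg = {**cfg, **overrides}
    return _validate(cfg, DEFAULT_CONFIG)


def write_dataset(records: list[SampleRecord], path: str | Path) -> Path:
    """Write SampleRecords in the dataset dialect (one row per sub-spectrum,
    deterministic column order, UTF-8, RFC-4180 quoting via pandas)."""
    path = Path(path)
    if len(records) == 0:
        pd.DataFrame(columns=META_COLUMNS).to_csv(path, index=False)
        return path
    axis = records[0].axis
    spec_cols = [f"{w:g}" for w in axis]
    rows = []
    for rec in records:
        stamp = (RUN_START + _dt.timedelta(days=rec.day)).isoformat()
        for k, intensity in enumerate(rec.replicates):
            meta = {
                "record_id": rec.record_id,
                "vessel_id": rec.vessel_id,
                "batch_id": f"B{rec.vessel_id:02d}",
                "sample_id": f"{rec.record_id}R{k}",
                "sampling_time": stamp,
                "batch_age_days": float(rec.day),
                "kind": rec.kind,
                "analyte_spiked": rec.analyte_spiked or "",
                "replicate": k,
            }
            for a in ANALYTES:
                meta[f"reference_{a}"] = rec.reference.get(a, np.nan)
            rows.append(meta | dict(zip(spec_cols, intensity)))
    frame = pd.DataFrame(rows, columns=META_COLUMNS + spec_cols)
    frame.to_csv(path, index=False)
    return path


def read_dataset(path: str | Path) -> list[SampleRecord]:
    """Read a dataset dialect file back into SampleRecords.

    Validates the mandatory metadata columns and the strict ascent of the
    wavenumber header; malformed rows are reported with their line numbers.
    """
    frame = pd.read_csv(path, low_memory=False)
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    spec_cols = [c for c in frame.columns if c not in META_COLUMNS]
    if len(frame) == 0:
        return []
    axis = np.array([float(c) for c in spec_cols])
    if np.any(np.diff(axis) <= 0):
        raise ValueError("wavenumber columns are not strictly ascending")

    bad = frame.index[frame[spec_cols].isna().any(axis=1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]  # header is line 1
        raise ValueError(f"malformed rows (missing intensities) at lines {lines}")

    records = []
    for rid, group in frame.groupby("record_id", sort=False):
        group = group.sort_values("replicate")
        first = group.iloc[0]
        reference = {a: float(first[f"reference_{a}"]) for a in ANALYTES}
        records.append(SampleRecord(
            record_id=str(rid),
            vessel_id=int(first["vessel_id"]),
            day=int(first["batch_age_days"]),
            kind=str(first["kind"]),
            axis=axis,
            replicates=group[spec_cols].to_numpy(dtype=float),
            truth={},
            reference=reference,
            analyte_spiked=(str(first["analyte_spiked"])
                            if isinstance(first["analyte_spiked"], str)
                            and first["analyte_spiked"] else None),
        ))
    return records


def write_truth(records: list[SampleRecord], path: str | Path) -> Path:
    """Noise-free concentrations per record, for parameter-recovery tests."""
    rows = [{"record_id": r.record_id,
             **{f"truth_{a}": r.truth.get(a, np.nan) for a in ANALYTES}}
            for r in records]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def attach_truth(records: list[SampleRecord], path: str | Path) -> None:
    truth = pd.read_csv(path).set_index("record_id")
    for rec in records:
        rec.truth = {a: float(truth.loc[rec.record_id, f"truth_{a}"])
                     for a in ANALYTES}


def write_matrix(X: np.ndarray, meta: pd.DataFrame, axis: np.ndarray,
                 path: str | Path) -> Path:
    """Preprocessed sample x channel matrix with aligned metadata."""
    spec_cols = [f"{w:g}" for w in axis]
    frame = pd.concat([meta.reset_index(drop=True),
                       pd.DataFrame(X, columns=spec_cols)], axis=1)
    frame.to_csv(Path(path), index=False)
    return Path(path)


def read_matrix(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    frame = pd.read_csv(path, low_memory=False)
    spec_cols = [c for c in frame.columns if _is_number(c)]
    meta = frame[[c for c in frame.columns if c not in spec_cols]]
    axis = np.array([float(c) for c in spec_cols])
    return frame[spec_cols].to_numpy(dtype=float), meta, axis


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(out_dir: str | Path, command: str, config: dict,
                     inputs: list[str | Path] = ()) -> Path:
    """Append a provenance record (config echo, seed, version, input hashes)."""
    from importlib.metadata import version as _pkg_version
    try:
        pkg_version = _pkg_version("ramcal")
    except Exception:
        pkg_version = "unknown"
    record = {
        "command": command,
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        "package_version": pkg_version,
        "seed": config.get("seed"),
        "config": config,
        "input_hashes": {str(p): file_sha256(p) for p in inputs},
    }
    out = Path(out_dir) / "run.log"
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "a") as fh:
        fh.write(json.dumps(record) + "\n")
    return out
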