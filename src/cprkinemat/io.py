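"""Readers and writers for the interchange formats, plus the end-to-end run.

Interchange is plain text with "." decimals and "," field separators:
kinematic stream CSV ``time_s,sensor_id,x_mm,y_mm,z_mm``, manikin stream CSV
``time_s,depth_mm``, feature table TSV, YAML metadata sidecars and JSON
result blobs.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import DriftConfig, PosturePose, RunConfig, TrialConfig
from .errors import ValidationError
from .pipeline import FEATURE_COLUMNS, build_feature_table, synchronize
from .rescuer_sim import generate_trial, reference_posture
from .stats import analyze_features
from .streams import KNOWN_SENSORS, KinematicStream, ManikinStream

logger = logging.getLogger(__name__)

KINEMATIC_COLUMNS = ("time_s", "sensor_id", "x_mm", "y_mm", "z_mm")
MANIKIN_COLUMNS = ("time_s", "depth_mm")


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")


def _coerce_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header line
            raise ValidationError(
                f"{path}: non-numeric value in column {col!r} at line {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise ValidationError(f"{path}: empty cell in column {col!r} at line {row}")
        df[col] = coerced
    return df


def read_kinematic_stream(path, sample_hz: float | None = None) -> KinematicStream:
    """Read a long-form kinematic CSV; timestamps must be non-decreasing per
    sensor; unknown sensor ids are preserved but warned about."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sensor_id": str})
    _check_columns(df, KINEMATIC_COLUMNS, path)
    df = _coerce_numeric(df, ("time_s", "x_mm", "y_mm", "z_mm"), path)
    unknown = sorted(set(df["sensor_id"]) - set(KNOWN_SENSORS))
    if unknown:
        warnings.warn(f"{path}: unknown sensor ids {unknown}", stacklevel=2)
    for sensor, sub in df.groupby("sensor_id"):
        t = sub["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValidationError(
                f"{path}: timestamps decrease for sensor {sensor!r}"
            )
    return KinematicStream.from_frame(df, sample_hz=sample_hz)


def write_kinematic_stream(stream: KinematicStream, path) -> None:
    stream.to_frame().to_csv(path, index=False, float_format="%.9f")


def read_manikin_stream(path) -> ManikinStream:
    """Read a manikin depth CSV; negative depths are rejected with the
    offending line number; an all-zero signal is flagged."""
    path = Path(path)
    df = pd.read_csv(path)
    _check_columns(df, MANIKIN_COLUMNS, path)
    df = _coerce_numeric(df, MANIKIN_COLUMNS, path)
    neg = df["depth_mm"] < 0
    if neg.any():
        row = int(neg.idxmax()) + 2
        raise ValidationError(f"{path}: negative depth_mm at line {row}")
    if not (df["depth_mm"] > 0).any():
        warnings.warn(f"{path}: no compressions (all-zero depth)", stacklevel=2)
    return ManikinStream(
        time_s=df["time_s"].to_numpy(), depth_mm=df["depth_mm"].to_numpy()
    )


def write_manikin_stream(man: ManikinStream, path) -> None:
    man.to_frame().to_csv(path, index=False, float_format="%.9f")


def write_feature_table(table: pd.DataFrame, path) -> None:
    table[list(FEATURE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, [c for c in FEATURE_COLUMNS if c != "group"], path)
    return df


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(results: dict, path) -> None:
    Path(path).write_text(json.dumps(results, indent=2, default=_json_default) + "\n")


def write_metadata(meta: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_run_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def trial_config_from_run(cfg: RunConfig) -> TrialConfig:
    return TrialConfig(
        pose=reference_posture(cfg.preset),
        rate_cpm=cfg.rate_cpm,
        depth_mm=cfg.depth_mm,
        duration_s=cfg.duration_s,
        sample_hz=cfg.sample_hz,
        noise_sd_mm=cfg.noise_sd_mm,
        clock_offset_s=cfg.clock_offset_s,
        seed=cfg.seed,
        drift=DriftConfig(),
    )


def run_pipeline(cfg: RunConfig) -> Path:
    """simulate -> synchronize -> features -> analyze; returns the report path.

    Writes kinematic/manikin CSVs, the feature TSV, a JSON report and a YAML
    metadata sidecar into ``cfg.out_dir``.  Deterministic for a fixed seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial = trial_config_from_run(cfg)

    logger.info("stage simulate: preset=%s seed=%d", cfg.preset, cfg.seed)
    kin, man = generate_trial(trial)
    write_kinematic_stream(kin, out / "kinematic.csv")
    write_manikin_stream(man, out / "manikin.csv")

    logger.info("stage synchronize")
    lag = synchronize(kin, man)

    logger.info("stage features: threshold=%.1f mm", cfg.threshold_mm)
    table = build_feature_table(
        kin,
        man,
        lag_s=lag,
        threshold_mm=cfg.threshold_mm,
        smooth_window=cfg.smooth_window,
        ellipse_method=cfg.ellipse_method,
    )
    write_feature_table(table, out / "features.tsv")

    logger.info("stage analyze")
    analysis = analyze_features(table)
    report = {
        "config": asdict(cfg),
        "lag_s": lag,
        "n_rows": int(table.shape[0]),
        "group_sizes": table["group"].value_counts().to_dict(),
        **analysis,
    }
    report_path = out / "report.json"
    write_results(report, report_path)
    write_metadata(
        {
            "sample_hz": cfg.sample_hz,
            "resistance_n_per_cm2": 9.0,
            "seed": cfg.seed,
            "config": asdict(cfg),
            "pose": asdict(trial.pose),
        },
        out / "meta.yaml",
    )
    logger.info("report written to %s", report_path)
    return report_path
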