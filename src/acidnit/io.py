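"""Tabular input/output: CSV schemas, validation, and run manifests.

Each analysis module reads and writes small long-format CSV tables.  Parsing
is strict: missing columns, non-numeric cells, and invariant violations
(e.g. an atom fraction outside [0, 1]) raise :class:`~acidnit.errors.SchemaError`
naming the offending column and row — bad values are rejected at parse time,
never clamped.  Numbers are written at full ``repr`` precision so a
write -> read round trip is lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import SchemaError
from .response import DoseResponsePoint
from .tracer_rates import RateResult, TracerPool
from .synthetic_data import IncubationSeries

INCUBATION_COLUMNS = (
    "vessel_id",
    "treatment",
    "time_h",
    "nox_umol_L",
    "r15_nox",
    "n2o45_pmol",
    "n2o46_pmol",
)

RESPONSE_COLUMNS = ("site_id", "replicate", "delta_ph", "percent_change")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _check_numeric(df: pd.DataFrame, column: str, path: str) -> pd.Series:
    series = pd.to_numeric(df[column], errors="coerce")
    bad = series.index[series.isna() & df[column].notna()]
    if len(bad):
        raise SchemaError(
            f"{path}: column {column!r} has non-numeric value at row {bad[0]}"
        )
    nan_rows = series.index[series.isna()]
    if len(nan_rows):
        raise SchemaError(f"{path}: column {column!r} is empty at row {nan_rows[0]}")
    return series


def read_incubation_csv(path: str | Path) -> list[IncubationSeries]:
    """Read incubation observations, one :class:`IncubationSeries` per vessel.

    Expected columns: ``vessel_id, treatment, time_h, nox_umol_L, r15_nox,
    n2o45_pmol, n2o46_pmol``.  Atom fractions outside [0, 1] and negative
    concentrations or amounts are rejected with the offending row named.
    Tracer context (F, volume) travels in a JSON sidecar or is attached by
    the caller; here the series carries a unit placeholder tracer.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty input file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    _require_columns(df, INCUBATION_COLUMNS, str(path))
    for col in INCUBATION_COLUMNS[2:]:
        df[col] = _check_numeric(df, col, str(path))

    bad_r15 = df.index[(df["r15_nox"] < 0) | (df["r15_nox"] > 1)]
    if len(bad_r15):
        raise SchemaError(
            f"{path}: column 'r15_nox' outside [0, 1] at row {bad_r15[0]}"
        )
    for col in ("time_h", "nox_umol_L", "n2o45_pmol", "n2o46_pmol"):
        neg = df.index[df[col] < 0]
        if len(neg):
            raise SchemaError(f"{path}: column {col!r} negative at row {neg[0]}")

    series = []
    for (vessel, treatment), group in df.groupby(["vessel_id", "treatment"], sort=True):
        data = (
            group[list(INCUBATION_COLUMNS[2:])]
            .sort_values("time_h")
            .reset_index(drop=True)
        )
        series.append(
            IncubationSeries(
                vessel_id=str(vessel),
                treatment=str(treatment),
                tracer=TracerPool(0.0, 1.0),  # placeholder F=1; caller overrides
                volume=1.0,
                data=data,
                truth={},
            )
        )
    return series


def write_incubation_csv(series: Sequence[IncubationSeries], path: str | Path) -> None:
    """Write incubation series to the canonical CSV schema (repr precision)."""
    frames = []
    for s in series:
        frame = s.data.copy()
        frame.insert(0, "vessel_id", s.vessel_id)
        frame.insert(1, "treatment", s.treatment)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def write_rates_csv(rates: Sequence[tuple[str, RateResult]], path: str | Path) -> None:
    """Write labelled rate results: vessel_id, estimator_id, t0, t1, value, negative."""
    df = pd.DataFrame(
        {
            "vessel_id": [v for v, _ in rates],
            "estimator_id": [r.estimator_id for _, r in rates],
            "t0_h": [r.interval[0] for _, r in rates],
            "t1_h": [r.interval[1] for _, r in rates],
            "value": [r.value for _, r in rates],
            "negative": [r.negative for _, r in rates],
        }
    )
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_response_csv(path: str | Path) -> list[DoseResponsePoint]:
    """Read precomputed dose-response points (long format)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty input file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    _require_columns(df, RESPONSE_COLUMNS, str(path))
    for col in ("delta_ph", "percent_change"):
        df[col] = _check_numeric(df, col, str(path))
    neg = df.index[df["delta_ph"] < 0]
    if len(neg):
        raise SchemaError(f"{path}: column 'delta_ph' negative at row {neg[0]}")
    return [
        DoseResponsePoint(
            site_id=str(r.site_id),
            replicate=int(r.replicate),
            delta_ph=float(r.delta_ph),
            percent_change=float(r.percent_change),
        )
        for r in df.itertuples()
    ]


def write_response_csv(points: Sequence[DoseResponsePoint], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "site_id": [p.site_id for p in points],
            "replicate": [p.replicate for p in points],
            "delta_ph": [p.delta_ph for p in points],
            "percent_change": [p.percent_change for p in points],
        }
    )
    df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path: str | Path, *, seed: int | None, config: dict) -> dict:
    """Write a run manifest (tool version, config hash, seed) next to outputs."""
    from . import __version__

    manifest = {
        "tool": "acidnit",
        "version": __version__,
        "seed": seed,
        "config_sha256": config_hash(config),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
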