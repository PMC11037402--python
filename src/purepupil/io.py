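"""CSV dialects and JSON model serialization.

Recording CSV (long format): ``recording_id,subject_id,t_s,diameter_mm``.
Metadata CSV: ``recording_id,subject_id,illuminance_lux,exposure,
drug_state,eye,flash_onset_s,flash_duration_s``. Parameter tables are one
row per recording. Numeric output uses 9 significant digits, UTF-8, with a
mandatory header row. Models are serialized as JSON and validated on load
(unknown fields rejected in strict mode; truncated files never yield a
partial model).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lighting import CorrectionModel
from .score import PuReModel
from .waveform import Pupillogram

__all__ = [
    "ParseError",
    "FLOAT_FORMAT",
    "read_recordings",
    "write_recordings",
    "read_metadata",
    "write_table",
    "read_table",
    "save_correction_models",
    "load_correction_models",
    "save_pure_model",
    "load_pure_model",
]

FLOAT_FORMAT = "%.9g"

_RECORDING_COLS = ("recording_id", "subject_id", "t_s", "diameter_mm")
_METADATA_COLS = (
    "recording_id", "subject_id", "illuminance_lux", "exposure",
    "drug_state", "eye", "flash_onset_s", "flash_duration_s",
)


class ParseError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols, path):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, _METADATA_COLS, path)
    return df


def read_recordings(recordings_path, metadata_path) -> tuple[list[Pupillogram], pd.DataFrame]:
    """Parse recordings + metadata CSVs into validated Pupillograms.

    Rows are grouped by ``recording_id`` and sorted by time. Malformed
    values raise :class:`ParseError` naming the offending file row (1-based,
    header included).
    """
    df = pd.read_csv(recordings_path, dtype={"recording_id": str, "subject_id": str})
    _require_columns(df, _RECORDING_COLS, recordings_path)
    for col in ("t_s", "diameter_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy()))[0]
        if bad.size:
            raise ParseError(
                f"{recordings_path}: malformed {col} "
                f"{df[col].iloc[bad[0]]!r} at row {bad[0] + 2}"
            )
        df[col] = vals
    if (df["diameter_mm"] <= 0).any():
        row = int(np.nonzero((df["diameter_mm"] <= 0).to_numpy())[0][0])
        raise ParseError(f"{recordings_path}: non-positive diameter at row {row + 2}")

    meta = read_metadata(metadata_path)
    meta_by_id = meta.set_index("recording_id")
    recs = []
    for rid, g in df.groupby("recording_id", sort=True):
        g = g.sort_values("t_s")
        if g["t_s"].duplicated().any():
            raise ParseError(f"{recordings_path}: duplicate time in recording {rid}")
        if rid not in meta_by_id.index:
            raise ParseError(f"{metadata_path}: no metadata for recording {rid}")
        m = meta_by_id.loc[rid]
        recs.append(Pupillogram(
            recording_id=str(rid),
            t=g["t_s"].to_numpy(),
            d=g["diameter_mm"].to_numpy(),
            flash_onset=float(m["flash_onset_s"]),
            flash_duration=float(m["flash_duration_s"]),
        ))
    return recs, meta


def write_recordings(recordings, metadata: pd.DataFrame, recordings_path, metadata_path):
    sid = metadata.set_index("recording_id")["subject_id"]
    frames = [
        pd.DataFrame({
            "recording_id": rec.recording_id,
            "subject_id": sid.get(rec.recording_id, ""),
            "t_s": rec.t,
            "diameter_mm": rec.d,
        })
        for rec in recordings
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        recordings_path, index=False, float_format=FLOAT_FORMAT
    )
    metadata.to_csv(metadata_path, index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path):
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# model JSON


def _load_json(path) -> dict:
    try:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid or truncated JSON ({exc})") from exc


def save_correction_models(models: dict[str, CorrectionModel], path):
    payload = {"correction_models": {p: m.to_dict() for p, m in models.items()}}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def load_correction_models(path, strict: bool = True) -> dict[str, CorrectionModel]:
    payload = _load_json(path)
    if "correction_models" not in payload:
        raise ParseError(f"{path}: not a correction-model file")
    return {
        p: CorrectionModel.from_dict(d, strict=strict)
        for p, d in payload["correction_models"].items()
    }


def save_pure_model(model: PuReModel, path):
    Path(path).write_text(model.to_json(), encoding="utf-8")


def load_pure_model(path, strict: bool = True) -> PuReModel:
    return PuReModel.from_dict(_load_json(path), strict=strict)
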