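"""End-to-end helpers tying the modules into one analysis chain:

simulate -> fit waveforms & extract parameters -> train / apply lighting
corrections -> score -> calibrate and apply the 0-5 scaler.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import lighting, score as score_mod, waveform

log = logging.getLogger("purepupil")

__all__ = ["extract_table", "score_table", "calibrate_scaler_on_cohort"]


def extract_table(recordings, metadata: pd.DataFrame) -> pd.DataFrame:
    """Fit every recording and extract its PLR parameters.

    Returns one row per recording: identifiers and lighting metadata, the
    eight parameters (INIT doubling as the ``baseline`` predictor), flags
    and fit diagnostics. Recordings whose fit fails are skipped with a log
    entry.
    """
    meta = metadata.set_index("recording_id")
    rows = []
    for rec in recordings:
        m = meta.loc[rec.recording_id]
        try:
            fit = waveform.fit_canonical(rec)
        except (waveform.FitFailureError, waveform.InputError) as exc:
            log.warning("skipping %s: %s", rec.recording_id, exc)
            continue
        p = waveform.extract_parameters(rec, fit)
        rows.append({
            "recording_id": rec.recording_id,
            "subject_id": m["subject_id"],
            "illumination": m["illuminance_lux"],
            "baseline": p.init,
            "exposure": m["exposure"],
            "drug_state": m.get("drug_state", "none"),
            "eye": m.get("eye", "L"),
            "init": p.init, "end": p.end, "fin": p.fin, "camp": p.camp,
            "mcv": p.mcv, "pdv": p.pdv, "lat": p.lat, "t75": p.t75,
            "t75_unreached": p.t75_unreached,
            "non_constricting": p.non_constricting,
            "fit_rmse": fit.rmse,
        })
    return pd.DataFrame(rows)


def score_table(df: pd.DataFrame, model: score_mod.PuReModel) -> pd.DataFrame:
    """Raw (and, when the model carries a scaler, scaled) PuRe scores.

    Stored MCV is signed (minimum of the diameter derivative, <= 0); the
    score formula consumes the constriction *speed*, so the ``mcv_c``
    input is negated here. Because the correction chain is equivariant
    under a sign flip of the response, ``-mcv_c`` is exactly the corrected
    speed.
    """
    out = df.copy()
    raw = []
    for _, row in df.iterrows():
        corrected = {
            k: (-row[k] if k == "mcv_c" else row[k])
            for k in model.coefficients if k != "init"
        }
        raw.append(score_mod.pure_linear_score(model, row["init"], corrected))
    out["raw_score"] = raw
    if model.scaler is not None:
        out["pure_score"] = score_mod.apply_scaler(model.scaler, np.asarray(raw))
        out["class"] = score_mod.classify(out["pure_score"].to_numpy())
    return out


def calibrate_scaler_on_cohort(scored: pd.DataFrame) -> score_mod.PiecewiseScaler:
    """Fit the 0-5 scaler from a scored pre/post cohort table."""
    pre = scored.loc[scored["drug_state"] == "pre", "raw_score"].to_numpy()
    post = scored.loc[scored["drug_state"] == "post", "raw_score"].to_numpy()
    return score_mod.fit_piecewise_scaler(pre, post)
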