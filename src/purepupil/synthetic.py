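"""Synthetic pupillogram cohorts with known ground truth.

The generator reproduces the statistical structure the analysis chain
assumes, so every module can be exercised end-to-end without measured data:

* a per-subject pupil-luminance curve (Hill-type sigmoid in illuminance)
  drives the baseline diameter down as ambient light increases;
* the flash response is a canonical double-sigmoid waveform whose
  constriction amplitude scales with the light-dependent baseline, and
  whose latency and time scales drift with log-illuminance so that every
  extracted parameter carries a light dependence for the correction stage
  to remove;
* camera exposure is a monotone-decreasing function of illuminance with a
  small multiplicative jitter, mimicking a firmware auto-exposure value;
* a mydriatic ("post-drug") state shrinks the response amplitude by a
  multiplier (default 0.02) and pins the baseline near the dark-adapted
  diameter, emulating a fixed dilated, unreactive pupil;
* i.i.d. Gaussian measurement noise is added per frame.

Two study layouts mirror the intended use: a laboratory lighting study
(9 subjects x 8 illuminance levels spanning ~5-10,000 lx x 5 repeats) and a
pre/post-mydriatic clinic cohort (15 patients, both eyes, 12-120 lx). All
randomness flows from one master seed through named substreams, so a given
configuration always produces the identical dataset.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .waveform import Pupillogram, WaveformFit

__all__ = [
    "SubjectProfile",
    "CohortConfig",
    "SimulatedStudy",
    "DEFAULT_LIGHT_LEVELS",
    "baseline_diameter",
    "exposure_from_lux",
    "sample_profile",
    "simulate_recording",
    "simulate_lighting_study",
    "simulate_mydriasis_study",
]

#: default laboratory illuminance levels (lx), log-spaced over the studied
#: range and including the three commonly reported conditions 5/112/1343 lx
DEFAULT_LIGHT_LEVELS = (5.0, 16.0, 43.0, 112.0, 380.0, 1343.0, 3900.0, 10000.0)

# light-dependence slopes applied through z = log10(1 + lux)/4 in [0, 1]:
# latency lengthens and both sigmoid time scales stretch under bright light
_LAT_SLOPE = 0.10   # s, added to the constriction midpoint
_S1_SLOPE = 0.20    # relative stretch of the constriction time scale
_S2_SLOPE = 0.25    # relative stretch of the re-dilation time scale
_REDILATION_DELAY = 1.3   # s between the two sigmoid midpoints
_A2_FRACTION = 0.8        # re-dilation amplitude as a fraction of a1
_MYDRIATIC_BASELINE = 0.95  # dilated baseline position within (d_min, d_max)


def _rng(seed: int, *key) -> np.random.Generator:
    """Named substream of the master seed (stable across processes)."""
    ent = [int(seed)] + [
        k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode())
        for k in key
    ]
    return np.random.default_rng(np.random.SeedSequence([int(e) for e in ent]))


@dataclass(frozen=True)
class SubjectProfile:
    """Physiological parameters of one simulated subject."""

    d_max: float = 7.0          # dark-adapted diameter (mm)
    d_min: float = 2.5          # bright-light floor (mm)
    L_half: float = 100.0       # half-constriction illuminance (lx)
    h: float = 0.8              # luminance sensitivity exponent
    amp_gain: float = 0.75      # flash-response gain (0-1)
    s1: float = 0.07            # constriction time scale (s)
    s2: float = 0.30            # re-dilation time scale (s)
    latency_offset: float = 0.55  # flash onset -> constriction midpoint (s)
    noise_sd: float = 0.05      # per-frame measurement noise (mm)

    def __post_init__(self):
        if not (self.d_max > self.d_min > 0):
            raise ValueError("require d_max > d_min > 0")
        if self.L_half <= 0 or self.h <= 0:
            raise ValueError("L_half and h must be positive")
        if not (0 < self.amp_gain <= 1):
            raise ValueError("amp_gain must be in (0, 1]")


def sample_profile(rng: np.random.Generator, noise_sd: float = 0.05) -> SubjectProfile:
    """Draw one subject's profile from the population spread."""
    return SubjectProfile(
        d_max=rng.uniform(6.0, 8.0),
        d_min=rng.uniform(2.0, 3.0),
        L_half=rng.uniform(60.0, 200.0),
        h=rng.uniform(0.6, 1.0),
        amp_gain=rng.uniform(0.6, 0.9),
        s1=rng.uniform(0.060, 0.085),
        s2=rng.uniform(0.22, 0.35),
        latency_offset=rng.uniform(0.50, 0.62),
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration; defaults are the laboratory conditions."""

    n_subjects: int = 9
    levels: tuple = DEFAULT_LIGHT_LEVELS
    repeats: int = 5
    drug_delta: float = 0.02      # mydriatic amplitude multiplier
    pre_s: float = 1.0            # recording before the flash (s)
    flash_s: float = 1.0          # flash duration (s)
    post_s: float = 3.0           # recording after the flash (s)
    sample_rate: float = 60.0     # Hz
    noise_sd: float = 0.05        # mm
    dropout: float = 0.0          # per-recording drop probability
    seed: int = 0

    def __post_init__(self):
        if any(lv <= 0 for lv in self.levels):
            raise ValueError("illuminance levels must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (0 <= self.drug_delta <= 1):
            raise ValueError("drug_delta must be in [0, 1]")


@dataclass
class SimulatedStudy:
    """Recordings plus per-recording metadata and generating ground truth."""

    recordings: list
    metadata: pd.DataFrame
    truth: pd.DataFrame


def baseline_diameter(profile: SubjectProfile, lux: float) -> float:
    """Steady-state pupil diameter (mm) at an ambient illuminance.

    Hill-type sigmoid: d_min + (d_max - d_min) / (1 + (lux/L_half)^h);
    strictly decreasing in lux, d_max in darkness, d_min in bright light.
    """
    if lux < 0:
        raise ValueError("lux must be >= 0")
    x = (lux / profile.L_half) ** profile.h if lux > 0 else 0.0
    return profile.d_min + (profile.d_max - profile.d_min) / (1.0 + x)


def exposure_from_lux(
    lux: float,
    e_max: float = 1000.0,
    l_e: float = 50.0,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Firmware-style auto-exposure value: E_max / (1 + lux/L_E), with
    optional multiplicative log-normal jitter (strictly decreasing in
    expectation)."""
    if lux < 0:
        raise ValueError("lux must be >= 0")
    e = e_max / (1.0 + lux / l_e)
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("jitter requires an rng")
        e *= float(np.exp(rng.normal(0.0, jitter_sd)))
    return float(e)


def _light_z(lux: float) -> float:
    return min(np.log10(1.0 + lux) / 4.0, 1.0)


def simulate_recording(
    profile: SubjectProfile,
    lux: float,
    drug: str = "none",
    seed: int = 0,
    recording_id: str = "rec",
    config: CohortConfig | None = None,
) -> tuple[Pupillogram, WaveformFit]:
    """One flash recording plus its generating waveform (the oracle).

    ``drug='mydriatic'`` multiplies the response amplitude by the
    configured delta and pins the baseline near the dark-adapted diameter
    (a fixed dilated pupil). The same (profile, lux, drug, seed) always
    yields the identical trace.
    """
    cfg = config or CohortConfig()
    if drug not in ("none", "mydriatic"):
        raise ValueError(f"unknown drug state: {drug!r}")
    z = _light_z(lux)
    if drug == "mydriatic":
        b = profile.d_min + _MYDRIATIC_BASELINE * (profile.d_max - profile.d_min)
        delta = cfg.drug_delta
    else:
        b = baseline_diameter(profile, lux)
        delta = 1.0
    a1 = profile.amp_gain * (b - profile.d_min) * delta
    a2 = _A2_FRACTION * a1
    flash_onset = cfg.pre_s
    s1 = profile.s1 * (1.0 + _S1_SLOPE * z)
    s2 = profile.s2 * (1.0 + _S2_SLOPE * z)
    t1 = flash_onset + profile.latency_offset + _LAT_SLOPE * z
    truth = WaveformFit(b=b, a1=a1, t1=t1, s1=s1, a2=a2,
                        t2=t1 + _REDILATION_DELAY, s2=s2)

    n = int(round((cfg.pre_s + cfg.flash_s + cfg.post_s) * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    from .waveform import eval_canonical  # local to avoid cycle at import

    d = eval_canonical(truth, t)
    if profile.noise_sd > 0:
        rng = _rng(seed, "trace")
        d = d + rng.normal(0.0, profile.noise_sd, size=n)
    d = np.maximum(d, 0.05)  # diameters must stay positive
    rec = Pupillogram(
        recording_id=recording_id, t=t, d=d,
        flash_onset=flash_onset, flash_duration=cfg.flash_s,
        sample_rate_nominal=cfg.sample_rate,
    )
    return rec, truth


def _truth_row(rid, sid, lux, exposure, drug, eye, fit: WaveformFit) -> dict:
    return {
        "recording_id": rid, "subject_id": sid, "illuminance_lux": lux,
        "exposure": exposure, "drug_state": drug, "eye": eye,
        "true_b": fit.b, "true_a1": fit.a1, "true_t1": fit.t1,
        "true_s1": fit.s1, "true_a2": fit.a2, "true_t2": fit.t2,
        "true_s2": fit.s2,
    }


def simulate_lighting_study(config: CohortConfig | None = None) -> SimulatedStudy:
    """Laboratory lighting study: n_subjects x levels x repeats recordings."""
    cfg = config or CohortConfig()
    recs, meta, truth = [], [], []
    for si in range(cfg.n_subjects):
        sid = f"S{si + 1:02d}"
        profile = sample_profile(_rng(cfg.seed, "profile", si), cfg.noise_sd)
        for li, lux in enumerate(cfg.levels):
            for rep in range(cfg.repeats):
                if cfg.dropout > 0 and _rng(
                    cfg.seed, "dropout", si, li, rep
                ).random() < cfg.dropout:
                    continue
                rid = f"{sid}_L{li}_R{rep}"
                rec_seed = _rng(cfg.seed, "rec", si, li, rep).integers(2**31)
                rec, fit = simulate_recording(
                    profile, lux, "none", seed=int(rec_seed),
                    recording_id=rid, config=cfg,
                )
                exposure = exposure_from_lux(
                    lux, jitter_sd=0.03, rng=_rng(cfg.seed, "exposure", si, li, rep)
                )
                recs.append(rec)
                meta.append({
                    "recording_id": rid, "subject_id": sid,
                    "illuminance_lux": lux, "exposure": exposure,
                    "drug_state": "none", "eye": "L",
                    "flash_onset_s": cfg.pre_s, "flash_duration_s": cfg.flash_s,
                })
                truth.append(_truth_row(rid, sid, lux, exposure, "none", "L", fit))
    return SimulatedStudy(recs, pd.DataFrame(meta), pd.DataFrame(truth))


def simulate_mydriasis_study(config: CohortConfig | None = None) -> SimulatedStudy:
    """Pre/post-mydriatic clinic cohort: 15 patients x 2 eyes x 2 states
    under clinic lighting (uniform 12-120 lx per recording)."""
    cfg = config if config is not None else CohortConfig(n_subjects=15)
    recs, meta, truth = [], [], []
    for si in range(cfg.n_subjects):
        sid = f"P{si + 1:02d}"
        profile = sample_profile(_rng(cfg.seed, "clinic-profile", si), cfg.noise_sd)
        for ei, eye in enumerate(("L", "R")):
            for state_i, drug in enumerate(("pre", "post")):
                lux = float(_rng(cfg.seed, "clinic-lux", si, ei, state_i).uniform(12.0, 120.0))
                rid = f"{sid}_{eye}_{drug}"
                rec_seed = _rng(cfg.seed, "clinic-rec", si, ei, state_i).integers(2**31)
                rec, fit = simulate_recording(
                    profile, lux, "mydriatic" if drug == "post" else "none",
                    seed=int(rec_seed), recording_id=rid, config=cfg,
                )
                exposure = exposure_from_lux(
                    lux, jitter_sd=0.03,
                    rng=_rng(cfg.seed, "clinic-exposure", si, ei, state_i),
                )
                recs.append(rec)
                meta.append({
                    "recording_id": rid, "subject_id": sid,
                    "illuminance_lux": lux, "exposure": exposure,
                    "drug_state": drug, "eye": eye,
                    "flash_onset_s": cfg.pre_s, "flash_duration_s": cfg.flash_s,
                })
                truth.append(_truth_row(rid, sid, lux, exposure, drug, eye, fit))
    return SimulatedStudy(recs, pd.DataFrame(meta), pd.DataFrame(truth))
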