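"""Canonical pupillary-light-reflex waveform model, fitting and parameters.

The pupil response to a light flash is modelled as a baseline diameter minus
a constriction sigmoid plus a re-dilation sigmoid::

    D(t) = b - a1 * sigma((t - t1) / s1) + a2 * sigma((t - t2) / s2)

with ``sigma(x) = 1 / (1 + exp(-x))``. ``b`` is the pre-flash asymptote,
``a1``/``a2`` the constriction and re-dilation amplitudes (mm), ``t1 < t2``
the sigmoid midpoints (s) and ``s1``/``s2`` the time scales (s). The
physiological constraints are ``0 <= a2 <= a1 < b`` (the pupil constricts,
then recovers at most back to baseline) and positive time scales.

From a fitted model plus the raw trace, the eight standard PLR parameters
are extracted: INIT (baseline diameter, mean over the first 250 ms), END
(minimum diameter, median of a 130 ms window around the post-flash trough,
searched within 1.5 s of flash onset), FIN (asymptotic final size), CAMP
(constriction amplitude, INIT - END), MCV / PDV (extreme diameter
velocities, from the model's analytic derivative), LAT (latency from flash
onset to the commencement of constriction) and T75 (time from the trough to
recover 75 % of CAMP).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import expit

__all__ = [
    "Pupillogram",
    "WaveformFit",
    "PLRParameters",
    "InvalidModelError",
    "FitFailureError",
    "InputError",
    "eval_canonical",
    "canonical_derivative",
    "fit_canonical",
    "extract_parameters",
]

#: latency threshold: constriction "commences" when the constriction sigmoid
#: has delivered this fraction of a1 (logit(0.01) = -ln 99).
LATENCY_FRACTION = 0.01


class InvalidModelError(ValueError):
    """Waveform parameters violate the model invariants."""


class FitFailureError(RuntimeError):
    """Constrained least squares did not produce an acceptable fit."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InputError(ValueError):
    """Recording does not satisfy the preconditions for fitting."""


@dataclass(frozen=True)
class Pupillogram:
    """A single pupil-diameter trace around one flash stimulus.

    Times are seconds, diameters millimetres. The default acquisition
    emulated throughout the package is a 5 s recording at a nominal 60 Hz
    with a 1 s flash starting 1 s in.
    """

    recording_id: str
    t: np.ndarray
    d: np.ndarray
    flash_onset: float
    flash_duration: float = 1.0
    sample_rate_nominal: float = 60.0

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "d", d)
        if t.ndim != 1 or d.ndim != 1 or len(t) != len(d):
            raise InputError("t and d must be 1-D sequences of equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise InputError("time points must be strictly increasing")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise InputError("diameters must be finite and positive")
        if len(t) and not (t[0] <= self.flash_onset <= t[-1]):
            raise InputError("flash_onset must lie within the recording")


@dataclass(frozen=True)
class WaveformFit:
    """Parameters of the canonical double-sigmoid model (see module docs)."""

    b: float
    a1: float
    t1: float
    s1: float
    a2: float
    t2: float
    s2: float
    rmse: float = 0.0

    def validate(self) -> "WaveformFit":
        f = dataclasses.astuple(self)
        if not np.all(np.isfinite(f)):
            raise InvalidModelError("non-finite waveform parameter")
        if self.s1 <= 0 or self.s2 <= 0:
            raise InvalidModelError("time scales must be positive")
        if self.t2 <= self.t1:
            raise InvalidModelError("re-dilation midpoint must follow constriction")
        if not (0 <= self.a2 <= self.a1):
            raise InvalidModelError("require 0 <= a2 <= a1")
        if self.b <= 0 or self.b - self.a1 <= 0:
            raise InvalidModelError("baseline and trough asymptote must be positive")
        return self

    @property
    def fin(self) -> float:
        """Asymptotic final diameter, D(+inf) = b - a1 + a2."""
        return self.b - self.a1 + self.a2


def eval_canonical(fit: WaveformFit, times) -> np.ndarray:
    """Evaluate the canonical model D(t) at the given times (mm)."""
    fit.validate()
    t = np.asarray(times, dtype=float)
    return (
        fit.b
        - fit.a1 * expit((t - fit.t1) / fit.s1)
        + fit.a2 * expit((t - fit.t2) / fit.s2)
    )


def canonical_derivative(fit: WaveformFit, times) -> np.ndarray:
    """Analytic dD/dt of the canonical model (mm/s).

    sigma'(x) = sigma(x) (1 - sigma(x)), so each sigmoid contributes a bump
    of height amplitude/(4 * scale) centred at its midpoint.
    """
    fit.validate()
    t = np.asarray(times, dtype=float)
    u1 = expit((t - fit.t1) / fit.s1)
    u2 = expit((t - fit.t2) / fit.s2)
    return -fit.a1 / fit.s1 * u1 * (1 - u1) + fit.a2 / fit.s2 * u2 * (1 - u2)


# ---------------------------------------------------------------------------
# fitting

# internal parameterisation theta = (b, u, r, t1, dt, s1, s2) with
# a1 = u*b (u in [0, 0.95] keeps the trough asymptote positive) and
# a2 = r*a1 (r in [0, 1] enforces 0 <= a2 <= a1); t2 = t1 + dt, dt > 0.
_U_MAX = 0.95
_S_MIN = 0.02


def _theta_to_fit(theta, rmse=0.0) -> WaveformFit:
    b, u, r, t1, dt, s1, s2 = theta
    a1 = u * b
    return WaveformFit(b=b, a1=a1, t1=t1, s1=s1, a2=r * a1, t2=t1 + dt, s2=s2, rmse=rmse)


def _residuals(theta, t, d):
    b, u, r, t1, dt, s1, s2 = theta
    a1 = u * b
    return (b - a1 * expit((t - t1) / s1) + r * a1 * expit((t - t1 - dt) / s2)) - d


def fit_canonical(rec: Pupillogram, max_nfev: int = 2000) -> WaveformFit:
    """Fit the canonical model to a recording by constrained least squares.

    Initial values are derived from the trace (pre-flash mean, trough depth
    and timing) and refined from a small fixed multistart grid over the
    constriction time scale, so repeated fits of the same input are
    bit-identical. Raises :class:`InputError` for traces that are too short
    and :class:`FitFailureError` (with diagnostics) on non-convergence.
    """
    t, d = rec.t, rec.d
    if len(t) < 30:
        raise InputError(f"need >= 30 samples, got {len(t)}")
    if t[0] > rec.flash_onset - 1e-9 or t[-1] < rec.flash_onset + 2.0 - 1e-9:
        raise InputError("recording must span pre-flash data and >= 2 s post-flash")

    pre = d[t <= rec.flash_onset]
    b0 = float(np.mean(pre)) if len(pre) else float(d[0])
    post = (t > rec.flash_onset) & (t <= rec.flash_onset + 1.5)
    i_trough = int(np.argmin(np.where(post, d, np.inf)))
    depth = max(b0 - d[i_trough], 0.0)
    u0 = min(depth / b0, _U_MAX) if b0 > 0 else 0.0
    t1_0 = 0.5 * (rec.flash_onset + t[i_trough])

    span = t[-1] - t[0]
    lo = [1e-3, 0.0, 0.0, t[0], 1e-3, _S_MIN, _S_MIN]
    hi = [20.0, _U_MAX, 1.0, t[-1], max(2 * span, 1.0), 2.0, 5.0]

    best = None
    for s1_0 in (0.05, 0.1, 0.2):
        for dt_0 in (0.7, 1.2):
            x0 = np.clip(
                [b0, max(u0, 1e-3), 0.8, t1_0, dt_0, s1_0, 0.4], lo, hi
            )
            res = least_squares(
                _residuals, x0, bounds=(lo, hi), args=(t, d), max_nfev=max_nfev
            )
            if best is None or res.cost < best.cost - 1e-12:
                best = res
    if best is None or not best.success:
        raise FitFailureError(
            "canonical fit did not converge",
            diagnostics={
                "status": getattr(best, "status", None),
                "cost": getattr(best, "cost", None),
                "recording_id": rec.recording_id,
            },
        )
    rmse = float(np.sqrt(np.mean(best.fun**2)))
    return _theta_to_fit(best.x, rmse=rmse).validate()


# ---------------------------------------------------------------------------
# parameter extraction

#: the fitted trough asymptote never exactly reaches the 75 %-recovery
#: threshold; search this far past the trough before declaring T75 unreached.
_T75_HORIZON = 60.0


@dataclass(frozen=True)
class PLRParameters:
    """The eight standard PLR parameters for one recording.

    ``mcv`` is stored signed (<= 0); ``pdv`` is >= 0. ``t75`` is NaN when
    flagged ``t75_unreached``; a recording whose trace never drops below
    baseline is flagged ``non_constricting`` and reports END = INIT,
    CAMP = 0.
    """

    init: float
    end: float
    fin: float
    camp: float
    mcv: float
    pdv: float
    lat: float
    t75: float
    t75_unreached: bool = False
    non_constricting: bool = False

    @property
    def mcv_abs(self) -> float:
        return abs(self.mcv)

    @property
    def pdv_abs(self) -> float:
        return abs(self.pdv)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def extract_parameters(
    rec: Pupillogram,
    fit: WaveformFit,
    latency_fraction: float = LATENCY_FRACTION,
    end_window: float = 0.130,
    end_search: float = 1.5,
    raw_velocities: bool = False,
) -> PLRParameters:
    """Extract the eight PLR parameters from a trace and its fitted model.

    INIT, END and CAMP come from the raw samples (per their quantitative
    definitions); FIN, MCV, PDV, LAT and T75 come from the fitted model,
    whose analytic derivative is robust to frame-to-frame noise. With
    ``raw_velocities=True`` MCV/PDV use finite differences of the samples
    instead (noise-sensitive; for comparison studies).
    """
    fit.validate()
    t, d = rec.t, rec.d
    t0 = t[0]

    init = float(np.mean(d[t <= t0 + 0.25]))

    post = (t > rec.flash_onset) & (t <= rec.flash_onset + end_search)
    if not np.any(post):
        raise InputError("no samples in the post-flash search window")
    i_trough = int(np.argmin(np.where(post, d, np.inf)))
    t_trough = float(t[i_trough])
    in_win = np.abs(t - t_trough) <= end_window / 2
    end = float(np.median(d[in_win]))

    camp = init - end
    non_constricting = camp <= 0
    if non_constricting:
        end, camp = init, 0.0

    fin = fit.fin

    # velocities split at the trough: MCV on the constriction phase, PDV on
    # the recovery phase (analytic model derivative by default)
    if raw_velocities:
        grid = t
        dgrid = np.gradient(d, t)
    else:
        grid = np.linspace(t0, t[-1], 2001)
        dgrid = canonical_derivative(fit, grid)
    neg = dgrid[(grid <= t_trough) & (dgrid < 0)]
    mcv = float(neg.min()) if neg.size else 0.0
    pos = dgrid[(grid >= t_trough) & (dgrid > 0)]
    pdv = float(pos.max()) if pos.size else 0.0

    lat = float(fit.t1 + fit.s1 * np.log(latency_fraction / (1 - latency_fraction)) - rec.flash_onset)
    if fit.a1 == 0:
        lat = float("nan")

    t75, unreached = _recovery_time(fit, t_trough, end, camp)
    if non_constricting:
        t75, unreached = float("nan"), True

    return PLRParameters(
        init=init, end=end, fin=fin, camp=camp, mcv=mcv, pdv=pdv,
        lat=lat, t75=t75, t75_unreached=unreached,
        non_constricting=non_constricting,
    )


def _recovery_time(fit: WaveformFit, t_trough: float, end: float, camp: float):
    """First time after the trough at which D(t) >= END + 0.75*CAMP,
    relative to the trough; (nan, True) if the model never gets there."""
    threshold = end + 0.75 * camp
    if eval_canonical(fit, t_trough) >= threshold:
        return 0.0, False
    grid = np.linspace(t_trough, t_trough + _T75_HORIZON, 4001)
    vals = eval_canonical(fit, grid)
    above = np.nonzero(vals >= threshold)[0]
    if above.size == 0:
        return float("nan"), True
    i = int(above[0])
    t_cross = brentq(
        lambda x: eval_canonical(fit, x) - threshold, grid[i - 1], grid[i]
    )
    return float(t_cross - t_trough), False
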