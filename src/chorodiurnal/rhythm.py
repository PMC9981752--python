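"""Per-subject Fourier rhythmometry of 24-hour measurement series.

Each subject contributes, per index and region, 7 timed values over 24 h
(hours since the 9 AM study start).  A truncated Fourier series

    y(t) = a0 + sum_k [ a_k cos(2 pi k t / 24) + b_k sin(2 pi k t / 24) ]

is fitted by least squares (default two harmonics).  The diurnal amplitude
is the fitted curve's maximum minus minimum (peak-to-trough) and the
acrophase is the time of the fitted maximum, both read off a 1-minute grid.
The daily mean is the arithmetic mean of the recorded session values (the
repeated 9 AM phase at t=0 and t=24 is intentionally not deduplicated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiurnalSeries",
    "RhythmFit",
    "VitalSigns",
    "fit_diurnal_rhythm",
    "daily_mean",
    "amplitude_percent",
    "derive_vitals",
    "hours_to_clock",
    "DEFAULT_SESSION_TIMES_H",
]

HOURS_PER_DAY = 24.0
#: 7 sessions every 4 h over 24 h, hours since the 9 AM study start.
DEFAULT_SESSION_TIMES_H = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
#: Clock hour (24-h) of the study start.
STUDY_START_CLOCK_H = 9.0


@dataclass(frozen=True)
class DiurnalSeries:
    """Timed measurements of one index, region and subject over 24 h."""

    subject_id: str
    index: str
    region: str
    times_h: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_h) != len(self.values):
            raise ValueError("times and values must have equal length")
        t = np.asarray(self.times_h, dtype=float)
        if t.size and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class RhythmFit:
    """Fitted diurnal rhythm for one series.

    ``acrophase_h`` is hours since the 9 AM study start and is None (with a
    ``flat_fit`` flag) when the fitted curve is constant.  The clock time of
    the peak is 9 AM + acrophase_h (mod 24).
    """

    a0: float
    cos_coeffs: tuple[float, ...]
    sin_coeffs: tuple[float, ...]
    amplitude: float
    acrophase_h: float | None
    daily_mean: float
    residual_rms: float
    n_harmonics: int
    flags: tuple[str, ...] = ()

    @property
    def acrophase_clock(self) -> str | None:
        if self.acrophase_h is None:
            return None
        return hours_to_clock(self.acrophase_h)

    def evaluate(self, times_h: np.ndarray) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        out = np.full(t.shape, self.a0, dtype=float)
        for k in range(1, self.n_harmonics + 1):
            w = 2.0 * np.pi * k / HOURS_PER_DAY
            out += self.cos_coeffs[k - 1] * np.cos(w * t)
            out += self.sin_coeffs[k - 1] * np.sin(w * t)
        return out


@dataclass(frozen=True)
class VitalSigns:
    """Blood-pressure-derived quantities (mmHg)."""

    sbp: float
    dbp: float
    map: float
    pulse_pressure: float
    iop: float | None = None


def _design_matrix(times_h: np.ndarray, n_harmonics: int) -> np.ndarray:
    cols = [np.ones_like(times_h)]
    for k in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * k / HOURS_PER_DAY
        cols.append(np.cos(w * times_h))
        cols.append(np.sin(w * times_h))
    return np.column_stack(cols)


def _refine_extremum(
    beta: np.ndarray, n_harmonics: int, t0: float, step: float, sign: int
) -> tuple[float, float]:
    """Polish a grid extremum of the fitted curve within one grid step."""
    from scipy.optimize import minimize_scalar

    def objective(t: float) -> float:
        value = beta[0]
        for k in range(1, n_harmonics + 1):
            w = 2.0 * np.pi * k / HOURS_PER_DAY
            value += beta[1 + 2 * (k - 1)] * math.cos(w * t)
            value += beta[2 + 2 * (k - 1)] * math.sin(w * t)
        return -sign * float(value)

    res = minimize_scalar(
        objective, bounds=(t0 - step, t0 + step), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(-res.fun) if sign > 0 else float(res.fun)


def fit_diurnal_rhythm(
    series: DiurnalSeries,
    n_harmonics: int = 2,
    grid_minutes: float = 1.0,
    flat_tol: float = 1e-9,
) -> RhythmFit:
    """Least-squares Fourier fit; amplitude and acrophase from a dense grid.

    Requires at least ``2 * n_harmonics + 1`` points.  Duplicate-phase
    samples (t=0 and t=24 h) both enter the fit.  Amplitude is the fitted
    curve's max − min over one cycle evaluated every ``grid_minutes``;
    acrophase is the grid time of the maximum (earliest time on ties).  A
    constant series (or a fit with amplitude below ``flat_tol``) reports
    amplitude 0 and an undefined acrophase, flagged ``flat_fit``.
    """
    t = np.asarray(series.times_h, dtype=float)
    y = np.asarray(series.values, dtype=float)
    n_params = 2 * n_harmonics + 1
    if t.size < n_params:
        raise ValueError(
            f"need >= {n_params} points for {n_harmonics} harmonics, got {t.size}"
        )
    X = _design_matrix(t, n_harmonics)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rms = float(np.sqrt(np.mean(resid**2)))
    a0 = float(beta[0])
    cos_c = tuple(float(beta[1 + 2 * i]) for i in range(n_harmonics))
    sin_c = tuple(float(beta[2 + 2 * i]) for i in range(n_harmonics))

    grid = np.arange(0.0, HOURS_PER_DAY, grid_minutes / 60.0)
    Xg = _design_matrix(grid, n_harmonics)
    curve = Xg @ beta
    step = grid_minutes / 60.0
    # the grid locates the global extrema (first index on ties); a bounded
    # local refinement then removes the grid-quantization error
    t_max, y_max = _refine_extremum(beta, n_harmonics, grid[int(np.argmax(curve))], step, +1)
    _, y_min = _refine_extremum(beta, n_harmonics, grid[int(np.argmin(curve))], step, -1)
    amplitude = float(y_max - y_min)
    flags: tuple[str, ...] = ()
    if amplitude <= flat_tol:
        amplitude = 0.0
        acrophase: float | None = None
        flags = ("flat_fit",)
    else:
        acrophase = float(t_max % HOURS_PER_DAY)
    return RhythmFit(
        a0=a0,
        cos_coeffs=cos_c,
        sin_coeffs=sin_c,
        amplitude=amplitude,
        acrophase_h=acrophase,
        daily_mean=float(y.mean()),
        residual_rms=rms,
        n_harmonics=n_harmonics,
        flags=flags,
    )


def daily_mean(series: DiurnalSeries) -> float:
    """Arithmetic mean of all recorded session values."""
    if not series.values:
        raise ValueError("cannot take the mean of an empty series")
    return float(np.mean(series.values))


def amplitude_percent(amplitude: float, daily_mean_value: float) -> float:
    """Diurnal amplitude expressed as a percentage of the daily mean.

    Reported to two decimals, matching the summary-table convention.
    """
    if daily_mean_value <= 0:
        raise ValueError("daily mean must be positive to express amplitude as %")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    return round(100.0 * amplitude / daily_mean_value, 2)


def derive_vitals(sbp: float, dbp: float, iop: float | None = None) -> VitalSigns:
    """Pulse pressure and mean arterial pressure from SBP/DBP.

    PP = SBP − DBP;  MAP = (SBP − DBP)/3 + DBP.
    """
    if dbp <= 0:
        raise ValueError("DBP must be positive")
    if sbp < dbp:
        raise ValueError("SBP must be >= DBP")
    pp = sbp - dbp
    map_ = (sbp - dbp) / 3.0 + dbp
    return VitalSigns(sbp=sbp, dbp=dbp, map=map_, pulse_pressure=pp, iop=iop)


def hours_to_clock(hours_since_start: float, start_clock_h: float = STUDY_START_CLOCK_H) -> str:
    """Format hours since the study start (9 AM) as a 12-hour clock time.

    >>> hours_to_clock(16.0 + 31.0 / 60.0)
    '1:31 AM'
    """
    clock = (start_clock_h + hours_since_start) % HOURS_PER_DAY
    total_min = int(round(clock * 60.0)) % (24 * 60)
    hh, mm = divmod(total_min, 60)
    suffix = "AM" if hh < 12 else "PM"
    hh12 = hh % 12
    if hh12 == 0:
        hh12 = 12
    return f"{hh12}:{mm:02d} {suffix}"
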