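"""Circular statistics for acrophases and group comparisons.

Acrophases live on a 24-hour circle; hours convert to radians at 2π/24.
This module provides the mean resultant vector, the Rayleigh uniformity
test, circular deviation in hours, Watson's two-sample U² with a seeded
permutation null, the Fisher–Lee circular–circular correlation, the
in-phase/antiphase classification rule, and the linear group tests used
alongside them (Mann–Whitney U, Spearman's rho).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

__all__ = [
    "AngleSample",
    "RayleighResult",
    "WatsonResult",
    "PhaseRelation",
    "PhaseRelationKind",
    "hours_to_radians",
    "radians_to_hours",
    "mean_resultant",
    "rayleigh_p",
    "rayleigh_test",
    "circular_deviation",
    "watson_u2_statistic",
    "watson_u2_two_sample",
    "fisher_lee_correlation",
    "phase_relation",
    "mann_whitney_u",
    "spearman_rho",
]

TWO_PI = 2.0 * math.pi
HOURS_PER_DAY = 24.0


def hours_to_radians(hours: np.ndarray | float) -> np.ndarray | float:
    return (np.asarray(hours, dtype=float) % HOURS_PER_DAY) * TWO_PI / HOURS_PER_DAY


def radians_to_hours(angles: np.ndarray | float) -> np.ndarray | float:
    return (np.asarray(angles, dtype=float) % TWO_PI) * HOURS_PER_DAY / TWO_PI


@dataclass(frozen=True)
class AngleSample:
    """A sample of angles wrapped to [0, 2π)."""

    angles: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.angles) < 1:
            raise ValueError("an angle sample needs at least one angle")
        wrapped = tuple(float(a) % TWO_PI for a in self.angles)
        object.__setattr__(self, "angles", wrapped)

    @classmethod
    def from_hours(cls, hours, label: str = "") -> "AngleSample":
        return cls(tuple(float(h) % HOURS_PER_DAY * TWO_PI / HOURS_PER_DAY for h in hours), label)

    @property
    def n(self) -> int:
        return len(self.angles)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.angles, dtype=float)


@dataclass(frozen=True)
class RayleighResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class WatsonResult:
    u2: float
    p: float
    n_a: int
    n_b: int
    n_perm: int


class PhaseRelationKind(str, Enum):
    IN_PHASE = "in_phase"
    ANTIPHASE = "antiphase"
    NEITHER = "neither"


@dataclass(frozen=True)
class PhaseRelation:
    kind: PhaseRelationKind
    separation_h: float


def mean_resultant(sample: AngleSample, floor: float = 1e-12) -> tuple[float, float | None]:
    """Mean resultant length r = |Σ e^{iθ}| / n and mean angle in [0, 2π).

    The mean angle is undefined (None) when r falls below ``floor`` — e.g.
    antipodal pairs whose resultant cancels.
    """
    a = sample.as_array()
    z = np.exp(1j * a).sum() / sample.n
    r = float(abs(z))
    if r < floor:
        return r, None
    return r, float(np.angle(z) % TWO_PI)


def rayleigh_p(n: int, r: float) -> float:
    """Closed-form approximation to the Rayleigh uniformity p-value.

    With R = n·r,  p = exp( sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n) );
    accurate for n ≥ 4.
    """
    R = n * r
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - R * R)) - (1.0 + 2.0 * n))
    return min(p, 1.0)


def rayleigh_test(sample: AngleSample) -> RayleighResult:
    """Rayleigh test for clustering of acrophases.

    r ranges from 1 (all acrophases identical) to 0 (spread uniformly around
    the 24 h); a small p rejects uniformity.  The closed-form approximation
    requires n ≥ 4.
    """
    if sample.n < 4:
        raise ValueError("the Rayleigh p approximation requires n >= 4")
    r, _ = mean_resultant(sample)
    return RayleighResult(r=r, p=rayleigh_p(sample.n, r), n=sample.n)


def circular_deviation(sample: AngleSample, method: str = "angular") -> float:
    """Dispersion of a circular sample, in hours.

    ``"angular"`` (default): angular deviation sqrt(2(1−r)).
    ``"circular_sd"``: sqrt(−2 ln r).  Both convert radians → hours at 24/2π.
    """
    if sample.n < 2:
        raise ValueError("circular deviation needs n >= 2")
    r, _ = mean_resultant(sample)
    if method == "angular":
        rad = math.sqrt(max(0.0, 2.0 * (1.0 - r)))
    elif method == "circular_sd":
        rad = math.sqrt(-2.0 * math.log(r)) if r > 0 else math.inf
    else:
        raise ValueError(f"unknown method {method!r}")
    return rad * HOURS_PER_DAY / TWO_PI


def watson_u2_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Watson's two-sample U² statistic on angle arrays (radians)."""
    a = np.asarray(a, dtype=float) % TWO_PI
    b = np.asarray(b, dtype=float) % TWO_PI
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    is_b = np.concatenate([np.zeros(na, dtype=bool), np.ones(nb, dtype=bool)])[order]
    ca = np.cumsum(~is_b) / na
    cb = np.cumsum(is_b) / nb
    d = ca - cb
    return float(na * nb / n**2 * np.sum((d - d.mean()) ** 2))


def _watson_u2_perm(
    pooled: np.ndarray, na: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """U² for ``n_perm`` random relabelings of a pooled sample (vectorized)."""
    n = pooled.size
    nb = n - na
    order = np.argsort(pooled, kind="stable")
    # random label matrices: each row a permutation of [True]*na + [False]*nb
    labels = np.tile(np.concatenate([np.zeros(na, bool), np.ones(nb, bool)]), (n_perm, 1))
    labels = rng.permuted(labels, axis=1)
    labels = labels[:, order]
    ca = np.cumsum(~labels, axis=1) / na
    cb = np.cumsum(labels, axis=1) / nb
    d = ca - cb
    d -= d.mean(axis=1, keepdims=True)
    return na * nb / n**2 * np.sum(d**2, axis=1)


def watson_u2_two_sample(
    a: AngleSample,
    b: AngleSample,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> WatsonResult:
    """Watson's two-sample U² test with a seeded permutation null.

    p = (1 + #{U²_perm ≥ U²_obs}) / (1 + n_perm).  Degenerate pooled samples
    (all angles identical) return p = 1.
    """
    if a.n < 4 or b.n < 4:
        raise ValueError("Watson's U2 requires at least 4 angles per sample")
    arr_a, arr_b = a.as_array(), b.as_array()
    pooled = np.concatenate([arr_a, arr_b])
    if np.ptp(pooled) == 0:
        return WatsonResult(u2=0.0, p=1.0, n_a=a.n, n_b=b.n, n_perm=n_perm)
    obs = watson_u2_statistic(arr_a, arr_b)
    rng = np.random.default_rng(seed)
    perm = _watson_u2_perm(pooled, a.n, n_perm, rng)
    p = (1.0 + np.count_nonzero(perm >= obs - 1e-12)) / (1.0 + n_perm)
    return WatsonResult(u2=obs, p=float(p), n_a=a.n, n_b=b.n, n_perm=n_perm)


def fisher_lee_correlation(
    x: AngleSample,
    y: AngleSample,
    n_perm: int = 9999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Fisher–Lee circular–circular correlation with permutation p-value.

    T = Σ_{i<j} sin(x_i−x_j) sin(y_i−y_j)
        / sqrt( Σ_{i<j} sin²(x_i−x_j) · Σ_{i<j} sin²(y_i−y_j) ).

    Invariant to rotations of either sample; +1 when y = x + const, −1 when
    y = −x + const.  Raises for a degenerate (single-angle) sample.  p is a
    two-sided permutation p over random re-pairings of y against x.
    """
    if x.n != y.n:
        raise ValueError("samples must be paired (equal n)")
    if x.n < 5:
        raise ValueError("circular correlation requires n >= 5")
    ax, ay = x.as_array(), y.as_array()
    sx = np.sin(ax[:, None] - ax[None, :])
    sy = np.sin(ay[:, None] - ay[None, :])
    iu = np.triu_indices(x.n, k=1)
    denom_x = float(np.sum(sx[iu] ** 2))
    denom_y = float(np.sum(sy[iu] ** 2))
    if denom_x <= 0 or denom_y <= 0:
        raise ValueError("degenerate sample: all angles identical in x or y")
    denom = math.sqrt(denom_x * denom_y)
    obs = float(np.sum(sx[iu] * sy[iu])) / denom
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(x.n)
        sy_p = sy[np.ix_(perm, perm)]
        t = float(np.sum(sx[iu] * sy_p[iu])) / denom
        if abs(t) >= abs(obs) - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return obs, float(p)


def phase_relation(
    acro_a_h: float, acro_b_h: float, tolerance_h: float = 2.0
) -> PhaseRelation:
    """Classify two acrophases as in phase, antiphase, or neither.

    In phase when the circular separation is within ±``tolerance_h`` of 0;
    antiphase when within ±``tolerance_h`` of 12 h.
    """
    for h in (acro_a_h, acro_b_h):
        if not 0.0 <= h < HOURS_PER_DAY:
            raise ValueError("acrophase hours must lie in [0, 24)")
    delta = abs(acro_a_h - acro_b_h)
    sep = min(delta, HOURS_PER_DAY - delta)
    if sep <= tolerance_h:
        kind = PhaseRelationKind.IN_PHASE
    elif abs(sep - 12.0) <= tolerance_h:
        kind = PhaseRelationKind.ANTIPHASE
    else:
        kind = PhaseRelationKind.NEITHER
    return PhaseRelation(kind=kind, separation_h=sep)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test on linear values (e.g. amplitudes).

    Exact null enumeration when both groups have ≤ 8 untied observations;
    otherwise the normal approximation with tie correction.  Identical
    pooled constants give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (ties handled by ranks).

    Constant input yields an undefined correlation, returned as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 5:
        raise ValueError("Spearman correlation requires n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
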