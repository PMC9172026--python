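"""Multi-harmonic cosinor regression and acrophase extraction.

Replicate expression time courses are regressed onto sine/cosine pairs of a
fixed 24 h period,

    level(t) = a0 + sum_{j=1..k} [ a_j sin(2*pi*j*t/24) + b_j cos(2*pi*j*t/24) ],

with the number of harmonics ``k`` chosen by forward selection: starting
from the fundamental, harmonic ``k+1`` is added only while its incremental
F-test is significant. The overall rhythmicity p-value is the F-test of the
selected model against the flat mean. Peak times (acrophases) are read off
the fitted waveform on a dense circular grid; secondary local maxima above a
prominence threshold capture bimodal profiles.

Replicates enter the regression as independent observations, preserving the
within-time-point variance the F-tests rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .timeframes import ClockTime, PeakRecord, PhotoperiodScheme, circular_diff

__all__ = [
    "ExpressionSeries",
    "CosinorFit",
    "AcrophaseSet",
    "NoAcrophaseError",
    "fit_cosinor",
    "extract_acrophases",
    "label_peaks",
]

logger = logging.getLogger(__name__)

_PERIOD = 24.0


class NoAcrophaseError(ValueError):
    """The fitted waveform is flat, so no peak time is defined."""


@dataclass
class ExpressionSeries:
    """Replicate relative-expression values on a 24 h grid for one
    gene × condition.

    ``time`` holds sampling times in hours (typically ZT1–ZT23 every 2 h),
    ``replicate`` integer replicate indices, ``level`` nonnegative relative
    expression; the three arrays are parallel.
    """

    gene: str
    condition: str
    time: np.ndarray
    replicate: np.ndarray
    level: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float) % _PERIOD
        self.replicate = np.asarray(self.replicate, dtype=int)
        self.level = np.asarray(self.level, dtype=float)
        if not (len(self.time) == len(self.replicate) == len(self.level)):
            raise ValueError("time, replicate and level must be equal length")
        if np.any(self.level < 0):
            raise ValueError("expression levels must be nonnegative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, gene: str | None = None,
                   condition: str | None = None) -> "ExpressionSeries":
        """Build from a long-format frame with columns zt, replicate, level."""
        if gene is None:
            (gene,) = df["gene"].unique()
        if condition is None:
            (condition,) = df["condition"].unique()
        return cls(
            gene=gene,
            condition=condition,
            time=df["zt"].to_numpy(),
            replicate=df["replicate"].to_numpy(),
            level=df["level"].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene,
                "condition": self.condition,
                "zt": self.time,
                "replicate": self.replicate,
                "level": self.level,
            }
        )

    @property
    def n_timepoints(self) -> int:
        return len(np.unique(self.time))


def _design(t: np.ndarray, k: int, period: float = _PERIOD) -> np.ndarray:
    cols = [np.ones_like(t)]
    for j in range(1, k + 1):
        w = 2.0 * np.pi * j * t / period
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


@dataclass
class CosinorFit:
    """A fitted 24 h-periodic waveform.

    ``coefficients`` holds the (sin, cos) pair for each harmonic
    ``j = 1..n_harmonics``; ``mesor`` is the intercept. ``p_value`` is the
    rhythmicity F-test of the selected model against the flat mean
    (``1.0`` for a flat, non-rhythmic fit with ``n_harmonics == 0``).
    """

    gene: str
    condition: str
    mesor: float
    coefficients: list[tuple[float, float]]
    p_value: float
    r_squared: float
    n_obs: int
    period: float = _PERIOD
    alpha: float = 0.05

    @property
    def n_harmonics(self) -> int:
        return len(self.coefficients)

    @property
    def rhythmic(self) -> bool:
        return self.n_harmonics >= 1 and self.p_value < self.alpha

    @property
    def harmonics(self) -> list[tuple[int, float, float]]:
        """(j, amplitude, peak time in hours of harmonic j) per harmonic."""
        out = []
        for j, (a, b) in enumerate(self.coefficients, start=1):
            amp = float(np.hypot(a, b))
            phase = float(np.arctan2(a, b) * self.period / (2.0 * np.pi * j))
            out.append((j, amp, phase % (self.period / j)))
        return out

    @property
    def fundamental_acrophase(self) -> float:
        """Closed-form peak time of the first harmonic, in hours."""
        if not self.coefficients:
            raise NoAcrophaseError("flat fit has no acrophase")
        a, b = self.coefficients[0]
        return float(np.arctan2(a, b) * self.period / (2.0 * np.pi)) % self.period

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        beta = np.concatenate(
            [[self.mesor]] + [list(ab) for ab in self.coefficients] or [[]]
        )
        y = _design(np.atleast_1d(t_arr), self.n_harmonics, self.period) @ beta
        return y if t_arr.ndim else float(y[0])


def fit_cosinor(
    series: ExpressionSeries,
    max_harmonics: int = 3,
    alpha: float = 0.05,
) -> CosinorFit:
    """Fit a 24 h cosinor with forward harmonic selection.

    Degenerate inputs (fewer than two distinct time points, or zero
    variance) return an explicit flat, non-rhythmic fit (``n_harmonics=0``,
    ``p_value=1``) rather than raising, so batch runs complete. The number
    of harmonics is capped so that at least ``2k+2`` distinct time points
    and one residual degree of freedom remain.
    """
    t, y = series.time, series.level
    n = len(y)
    mean = float(np.mean(y)) if n else 0.0
    tss = float(np.sum((y - mean) ** 2)) if n else 0.0

    def flat() -> CosinorFit:
        return CosinorFit(series.gene, series.condition, mesor=mean,
                          coefficients=[], p_value=1.0, r_squared=0.0,
                          n_obs=n, alpha=alpha)

    m = series.n_timepoints
    # k harmonics need 2k+2 distinct times and >= 1 residual dof.
    cap = min(max_harmonics, m // 2 - 1, (n - 2) // 2)
    if m < 2 or tss <= 1e-12 * max(1.0, mean**2) or cap < 1:
        return flat()

    def lsq(k: int) -> tuple[np.ndarray, float]:
        X = _design(t, k)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        return beta, rss

    k = 1
    beta, rss = lsq(1)
    while k < cap:
        if rss <= 1e-12 * tss:  # already a perfect fit
            break
        beta_next, rss_next = lsq(k + 1)
        df_next = n - (2 * (k + 1) + 1)
        num = max(rss - rss_next, 0.0) / 2.0
        den = rss_next / df_next
        if den <= 1e-12 * tss / n:
            p_inc = 0.0 if num > 0 else 1.0
        else:
            p_inc = float(stats.f.sf(num / den, 2, df_next))
        if p_inc < alpha:
            k, beta, rss = k + 1, beta_next, rss_next
        else:
            break

    df_res = n - (2 * k + 1)
    if rss <= 1e-12 * tss:
        p_value, r2 = 0.0, 1.0
    else:
        f_stat = ((tss - rss) / (2 * k)) / (rss / df_res)
        p_value = float(stats.f.sf(f_stat, 2 * k, df_res))
        r2 = 1.0 - rss / tss
    coeffs = [(float(beta[2 * j - 1]), float(beta[2 * j])) for j in range(1, k + 1)]
    return CosinorFit(series.gene, series.condition, mesor=float(beta[0]),
                      coefficients=coeffs, p_value=p_value, r_squared=r2,
                      n_obs=n, alpha=alpha)


@dataclass
class AcrophaseSet:
    """Peak times of a fitted waveform, in hours on the 24 h cycle.

    ``primary`` is the global maximum; ``secondary`` lists the other local
    maxima as (hours, relative prominence), sorted by decreasing prominence.
    """

    primary: float
    secondary: list[tuple[float, float]] = field(default_factory=list)

    @property
    def times(self) -> list[float]:
        return [self.primary] + [t for t, _ in self.secondary]


def extract_acrophases(
    fit: CosinorFit,
    grid_step: float = 0.01,
    min_prominence: float = 0.1,
) -> AcrophaseSet:
    """Locate peaks of the fitted waveform on a dense circular grid.

    The global maximum is the primary acrophase. Every other local maximum
    whose prominence — peak height minus the higher of its two adjacent
    troughs, divided by the fitted peak-to-trough range — exceeds
    ``min_prominence`` is returned as a secondary peak.
    """
    if fit.n_harmonics < 1:
        raise NoAcrophaseError(
            f"{fit.gene}/{fit.condition}: flat fit has no acrophase"
        )
    grid = np.arange(0.0, fit.period, grid_step)
    v = np.asarray(fit.predict(grid))
    vmax, vmin = float(v.max()), float(v.min())
    if vmax - vmin <= 1e-12 * max(1.0, abs(vmax)):
        raise NoAcrophaseError(
            f"{fit.gene}/{fit.condition}: fitted waveform is flat"
        )

    left, right = np.roll(v, 1), np.roll(v, -1)
    is_max = (v > left) & (v >= right)
    is_min = (v < left) & (v <= right)
    max_idx = np.flatnonzero(is_max)
    min_idx = np.flatnonzero(is_min)

    global_i = max_idx[np.argmax(v[max_idx])]
    secondary: list[tuple[float, float]] = []
    for i in max_idx:
        if i == global_i:
            continue
        # adjacent troughs on the circle
        later = min_idx[min_idx > i]
        earlier = min_idx[min_idx < i]
        next_trough = later[0] if len(later) else min_idx[0]
        prev_trough = earlier[-1] if len(earlier) else min_idx[-1]
        higher_trough = max(v[next_trough], v[prev_trough])
        prom = (v[i] - higher_trough) / (vmax - vmin)
        if prom > min_prominence:
            secondary.append((float(grid[i]), float(prom)))
    secondary.sort(key=lambda p: -p[1])
    return AcrophaseSet(primary=float(grid[global_i]), secondary=secondary)


def label_peaks(
    acro: AcrophaseSet,
    scheme: PhotoperiodScheme,
    gene: str,
    *,
    partner_unimodal: bool = False,
) -> list[PeakRecord]:
    """Assign peak labels for downstream cross-condition comparison.

    A single peak is labeled ``primary``. For two peaks, the one nearer
    (projected) sunrise is the morning peak ``M`` and the other the evening
    peak ``E`` — unless the same gene is unimodal in the partner condition,
    in which case the global maximum stays ``primary`` and the extra peak is
    labeled ``second``. More than two peaks is logged as a likely overfit;
    all are returned, extras labeled ``second``, ``second3``, ...
    """
    frame = scheme.frame("ZT")
    times = acro.times

    def rec(hours: float, label: str) -> PeakRecord:
        return PeakRecord(gene, scheme.label, ClockTime(hours, frame), label)

    if len(times) == 1:
        return [rec(times[0], "primary")]
    if len(times) == 2 and not partner_unimodal:
        t0, t1 = times
        if circular_diff(t0, scheme.sunrise) <= circular_diff(t1, scheme.sunrise):
            return [rec(t0, "M"), rec(t1, "E")]
        return [rec(t1, "M"), rec(t0, "E")]
    if len(times) > 3:
        logger.warning(
            "%s/%s: %d local maxima in fitted waveform, possible overfit",
            gene, scheme.label, len(times),
        )
    out = [rec(acro.primary, "primary")]
    for i, (hours, _prom) in enumerate(acro.secondary):
        out.append(rec(hours, "second" if i == 0 else f"second{i + 1}"))
    return out
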