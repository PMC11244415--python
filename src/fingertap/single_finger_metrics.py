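"""Per-finger metrics: inter-tap times, fatigue slope, windowed excursion.

The central fatigue statistic is the *angular coefficient*: the slope of
the ordinary-least-squares line of inter-tap time against elapsed
execution time.  A positive slope means the participant's taps spread out
as the 30 s trial progresses (fatigue); a negative slope means they speed
up (a training effect).

The amplitude side of the analysis divides the record into consecutive
5 s windows and averages, per window, the per-tap acceleration
*excursion*: crest value minus the signal minimum in a neighbourhood of
half the local inter-tap interval around the crest.  This definition is
invariant to a constant baseline offset (e.g. the gravity component on
the motion axis); the raw crest value is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np
from scipy import stats

from .errors import (
    DataError,
    DegenerateSignalError,
    DomainError,
    InsufficientEventsError,
)
from .tap_detection import TapSeries

__all__ = [
    "SingleFingerMetrics",
    "FatigueFit",
    "inter_tap_times",
    "fit_fatigue_line",
    "windowed_excursion",
    "excursion_percent_difference",
    "compute_single_finger_metrics",
]


class FatigueFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool


@dataclass
class SingleFingerMetrics:
    """Derived quantities for one finger of one trial."""

    n_taps: int
    event_times: np.ndarray
    inter_times: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    degenerate_fit: bool
    window_excursions: np.ndarray
    excursion_mean: float
    excursion_std: Optional[float]
    n_windows: int


def inter_tap_times(taps: TapSeries) -> Tuple[np.ndarray, np.ndarray]:
    """Consecutive time differences of one finger's taps.

    Returns ``(event_times, inter_times)`` where ``inter_times[i] =
    t[i+1] - t[i]`` is attributed to ``event_times[i] = t[i+1]``, the time
    the interval completes.  Length is ``n_taps - 1``.
    """
    if taps.n_taps < 2:
        raise InsufficientEventsError(
            f"need at least 2 taps for inter-tap times, got {taps.n_taps}"
        )
    t = taps.peak_times
    return t[1:], np.diff(t)


def fit_fatigue_line(
    event_times: np.ndarray, inter_times: np.ndarray
) -> FatigueFit:
    """OLS fit of inter-tap time on elapsed execution time.

    Returns slope (s per s), intercept (s) and R^2 = 1 - SS_res/SS_tot.
    Exactly constant inter-times (SS_tot = 0) cannot reject the fit, so
    that case reports slope 0, R^2 1 and ``degenerate=True`` rather than
    a NaN, keeping downstream aggregation stable.
    """
    x = np.asarray(event_times, dtype=float)
    y = np.asarray(inter_times, dtype=float)
    if x.size != y.size:
        raise DataError("event_times and inter_times must have equal length")
    if x.size < 3:
        raise InsufficientEventsError(
            f"need at least 3 points for a fatigue fit, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateSignalError("event_times have zero variance; cannot fit")
    if np.ptp(y) == 0:
        return FatigueFit(0.0, float(y[0]), 1.0, True)
    res = stats.linregress(x, y)
    return FatigueFit(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue) ** 2,
        False,
    )


def _local_halfwidths(peak_times: np.ndarray, span: float) -> np.ndarray:
    """Half of the local inter-tap interval per tap.

    Interior taps use the smaller of their two adjacent intervals (so
    neighbourhoods never swallow the next tap); edge taps use their single
    adjacent interval; a lone tap uses the whole record span.
    """
    n = peak_times.size
    if n == 1:
        return np.array([span])
    gaps = np.diff(peak_times)
    local = np.empty(n)
    local[0] = gaps[0]
    local[-1] = gaps[-1]
    if n > 2:
        local[1:-1] = np.minimum(gaps[:-1], gaps[1:])
    return local / 2.0


def windowed_excursion(
    timestamps: np.ndarray,
    signal: np.ndarray,
    taps: TapSeries,
    window: float = 5.0,
    *,
    use_raw_crest: bool = False,
) -> Tuple[np.ndarray, float, Optional[float], int]:
    """Average per-tap acceleration excursion in consecutive time windows.

    The record span ``[t0, t0 + duration)`` is partitioned into
    consecutive windows of ``window`` seconds (the last may be shorter).
    Per tap, the excursion is the crest amplitude minus the minimum signal
    value within +/- half the local inter-tap interval of the crest
    (``use_raw_crest=True`` reports the bare crest value instead).  Each
    window's value is the mean excursion of the taps falling in it; empty
    windows are omitted rather than zero-filled.

    Returns ``(window_excursions, excursion_mean, excursion_std,
    n_windows)`` where the mean/std are taken over the non-empty windows
    (sample standard deviation; ``None`` when fewer than two windows).
    """
    if window <= 0:
        raise DomainError(f"window must be > 0, got {window}")
    if taps.n_taps < 1:
        raise InsufficientEventsError("need at least 1 tap for excursion analysis")
    timestamps = np.asarray(timestamps, dtype=float)
    signal = np.asarray(signal, dtype=float)
    t0 = timestamps[0]
    span = float(timestamps[-1] - t0)
    n_windows = int(np.ceil(span / window)) if span > 0 else 1

    halfwidths = _local_halfwidths(taps.peak_times, span)
    excursions = np.empty(taps.n_taps)
    for i, (tc, amp, hw) in enumerate(
        zip(taps.peak_times, taps.peak_amplitudes, halfwidths)
    ):
        if use_raw_crest:
            excursions[i] = amp
            continue
        mask = (timestamps >= tc - hw) & (timestamps <= tc + hw)
        excursions[i] = amp - float(np.min(signal[mask]))

    win_idx = np.floor((taps.peak_times - t0) / window).astype(int)
    # a tap exactly at the last sample falls on the partition edge
    win_idx = np.clip(win_idx, 0, n_windows - 1)
    values = [
        float(np.mean(excursions[win_idx == w]))
        for w in range(n_windows)
        if np.any(win_idx == w)
    ]
    values = np.asarray(values)
    mean = float(np.mean(values))
    std = float(np.std(values, ddof=1)) if values.size >= 2 else None
    return values, mean, std, n_windows


def excursion_percent_difference(reference_mean: float, other_mean: float) -> float:
    """Percent amplitude loss of ``other`` relative to a reference test.

    ``100 * (reference - other) / reference``: positive values mean the
    other condition reaches smaller excursions than the reference.
    """
    if not reference_mean > 0:
        raise DomainError(
            f"reference excursion must be > 0, got {reference_mean}"
        )
    return 100.0 * (reference_mean - other_mean) / reference_mean


def compute_single_finger_metrics(
    timestamps: np.ndarray,
    oriented_signal: np.ndarray,
    taps: TapSeries,
    window: float = 5.0,
) -> SingleFingerMetrics:
    """Bundle inter-time, fatigue-fit and excursion metrics for one finger."""
    event_times, inter = inter_tap_times(taps)
    fit = fit_fatigue_line(event_times, inter)
    values, exc_mean, exc_std, n_windows = windowed_excursion(
        timestamps, oriented_signal, taps, window
    )
    return SingleFingerMetrics(
        n_taps=taps.n_taps,
        event_times=event_times,
        inter_times=inter,
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        degenerate_fit=fit.degenerate,
        window_excursions=values,
        excursion_mean=exc_mean,
        excursion_std=exc_std,
        n_windows=n_windows,
    )
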