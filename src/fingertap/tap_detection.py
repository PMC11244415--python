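"""Motion-axis selection and tap-event detection.

A tap produces a short, high-amplitude acceleration transient on the axis
normal to the tapping surface (nominally the sensor z axis for the
mounting used here).  The detector works in three steps:

1. pick the motion axis as the one with the largest robust excursion
   (99th minus 1st percentile), with ties broken z > y > x;
2. orient the signal so tap transients point upward (mount-dependent:
   the impact deceleration may register as a negative spike);
3. find local maxima whose topographic prominence exceeds a threshold,
   then enforce a minimum time separation, keeping the more prominent
   of any conflicting pair.

Prominence-based selection is what makes the detector robust to broadband
sensor noise: noise wiggles riding on a tap pulse have small prominence
even when their absolute amplitude is large.  The threshold defaults are
conservative for a +/-8 g, 120 Hz recording of vigorous tapping
(prominence >= 0.5 g, separation >= 0.08 s, i.e. below the period of the
fastest plausible tapping); an optional moving-average smoothing pass
(``smoothing_halfwidth`` samples on each side) helps at poor SNR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .data_model_io import AccelTrace, FingerLabel
from .errors import ConfigError, DataError, DegenerateSignalError

__all__ = [
    "DetectionParams",
    "TapSeries",
    "select_motion_axis",
    "orient_signal",
    "detect_taps",
    "detect_taps_from_trace",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tap-detector settings.

    min_prominence : g
        Minimum topographic prominence of a retained peak.
    min_separation : s
        Minimum time between retained peaks; of two conflicting candidates
        the higher-prominence one survives (earlier one on an exact tie).
    smoothing_halfwidth : samples
        Half-width of a centred moving-average applied before peak
        finding; 0 disables smoothing.  Peak times/amplitudes are always
        reported on the unsmoothed signal grid.
    polarity : {'positive', 'negative', 'auto'}
        Whether taps are upward or downward transients; 'auto' chooses the
        side on which the signal deviates more from its median.
    """

    min_prominence: float = 0.5
    min_separation: float = 0.08
    smoothing_halfwidth: int = 0
    polarity: str = "auto"

    def __post_init__(self) -> None:
        if not self.min_prominence > 0:
            raise ConfigError(f"min_prominence must be > 0, got {self.min_prominence}")
        if self.min_separation < 0:
            raise ConfigError(f"min_separation must be >= 0, got {self.min_separation}")
        if self.smoothing_halfwidth < 0 or int(self.smoothing_halfwidth) != self.smoothing_halfwidth:
            raise ConfigError("smoothing_halfwidth must be a non-negative integer")
        if self.polarity not in ("positive", "negative", "auto"):
            raise ConfigError(f"unknown polarity {self.polarity!r}")


@dataclass
class TapSeries:
    """Detected tap events for one trace."""

    source_finger: Optional[FingerLabel]
    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    detection_params: Optional[DetectionParams] = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.peak_times.shape != self.peak_amplitudes.shape:
            raise DataError("peak_times and peak_amplitudes must have equal length")
        if self.peak_times.size and np.any(np.diff(self.peak_times) <= 0):
            raise DataError("peak_times must be strictly increasing")
        if self.peak_amplitudes.size and not np.all(np.isfinite(self.peak_amplitudes)):
            raise DataError("peak_amplitudes must be finite")

    @property
    def n_taps(self) -> int:
        return self.peak_times.size

    def __len__(self) -> int:
        return self.n_taps


def _robust_excursion(signal: np.ndarray) -> float:
    hi, lo = np.percentile(signal, [99, 1])
    return float(hi - lo)


def select_motion_axis(trace: AccelTrace) -> Tuple[str, np.ndarray]:
    """Pick the axis with the greatest robust acceleration excursion.

    Excursion is the spread between the 99th and 1st percentiles, which
    ignores isolated glitch samples.  Ties are broken in the fixed order
    z > y > x (z is the expected motion axis for the standard mounting).

    Returns ``(axis_label, signal)``.  Raises
    :class:`DegenerateSignalError` when no axis carries any excursion.
    """
    best_label, best_signal, best_exc = None, None, -np.inf
    for label in ("z", "y", "x"):  # tie-break order: first strictly-greater wins
        sig = trace.axis(label)
        exc = _robust_excursion(sig)
        if exc > best_exc:
            best_label, best_signal, best_exc = label, sig, exc
    if best_exc <= 0.0:
        raise DegenerateSignalError(
            "all axes are constant; no motion axis can be selected"
        )
    return best_label, best_signal


def orient_signal(signal: np.ndarray, polarity: str = "auto") -> Tuple[np.ndarray, int]:
    """Orient a signal so tap transients are positive.

    Returns ``(oriented_signal, sign)`` with ``sign`` in {+1, -1}.  In
    'auto' mode the side with the larger deviation of the 99th/1st
    percentile from the median wins (positive on a tie).
    """
    signal = np.asarray(signal, dtype=float)
    if polarity == "positive":
        sign = 1
    elif polarity == "negative":
        sign = -1
    elif polarity == "auto":
        hi, med, lo = np.percentile(signal, [99, 50, 1])
        sign = 1 if (hi - med) >= (med - lo) else -1
    else:
        raise ConfigError(f"unknown polarity {polarity!r}")
    return sign * signal, sign


def _enforce_separation(
    times: np.ndarray, prominences: np.ndarray, min_separation: float
) -> np.ndarray:
    """Greedy selection: accept candidates by decreasing prominence
    (earlier first on ties), rejecting any within min_separation of an
    accepted peak.  Returns indices into `times`, sorted by time."""
    order = np.lexsort((times, -prominences))
    accepted_times: list[float] = []
    accepted_idx: list[int] = []
    for i in order:
        t = times[i]
        if all(abs(t - ta) >= min_separation for ta in accepted_times):
            accepted_times.append(t)
            accepted_idx.append(i)
    out = np.array(sorted(accepted_idx, key=lambda i: times[i]), dtype=int)
    return out


def detect_taps(
    timestamps: np.ndarray,
    signal: np.ndarray,
    params: Optional[DetectionParams] = None,
    *,
    source_finger: Optional[FingerLabel] = None,
) -> TapSeries:
    """Detect tap events on a 1-D acceleration signal.

    Local maxima of the (optionally smoothed, polarity-oriented) signal
    with topographic prominence >= ``min_prominence`` are candidate taps;
    candidates closer than ``min_separation`` are thinned keeping the
    higher-prominence one.  Reported times are the timestamps of the
    retained samples; amplitudes are the oriented *unsmoothed* signal
    values there.
    """
    if params is None:
        params = DetectionParams()
    timestamps = np.asarray(timestamps, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if timestamps.size != signal.size:
        raise DataError("timestamps and signal must have equal length")
    if signal.size < 3:
        raise DataError(f"signal too short for peak finding: {signal.size} samples")

    oriented, _sign = orient_signal(signal, params.polarity)
    work = oriented
    h = int(params.smoothing_halfwidth)
    if h > 0:
        kernel = np.ones(2 * h + 1) / (2 * h + 1)
        work = np.convolve(oriented, kernel, mode="same")

    idx, props = find_peaks(work, prominence=params.min_prominence)
    if idx.size and params.min_separation > 0:
        keep = _enforce_separation(
            timestamps[idx], props["prominences"], params.min_separation
        )
        idx = idx[keep]
    if h > 0 and idx.size:
        # refine: smoothing flattens the crest, so snap each peak to the
        # raw-signal argmax within +/- halfwidth samples
        refined = np.empty_like(idx)
        for k, i in enumerate(idx):
            lo, hi = max(0, i - h), min(oriented.size, i + h + 1)
            refined[k] = lo + int(np.argmax(oriented[lo:hi]))
        idx = np.unique(refined)
    return TapSeries(
        source_finger=source_finger,
        peak_times=timestamps[idx],
        peak_amplitudes=oriented[idx],
        detection_params=params,
    )


def detect_taps_from_trace(
    trace: AccelTrace, params: Optional[DetectionParams] = None
) -> Tuple[TapSeries, str, np.ndarray]:
    """Full per-trace front end: axis selection, orientation, detection.

    Returns ``(taps, axis_label, oriented_signal)``; the oriented signal
    is what downstream amplitude metrics (excursions) should consume.
    """
    if params is None:
        params = DetectionParams()
    axis_label, raw = select_motion_axis(trace)
    oriented, _sign = orient_signal(raw, params.polarity)
    taps = detect_taps(
        trace.timestamps,
        raw,
        params,
        source_finger=trace.finger_label,
    )
    return taps, axis_label, oriented
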