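"""Two-finger coordination metrics.

The coordination statistic is SATime: the absolute time difference
between paired taps of the two instrumented fingers.  In the simultaneous
tests both fingers should strike together, so SATime should approach
zero; a trial passes when the mean SATime stays strictly under a 0.1 s
threshold (an experimental bound on what the cohort achieves in the
easiest, uni-manual simultaneous condition).  In the alternating tests
the fingers should interleave, so SATime should approach half the tap
period; a trial passes when the mean SATime *exceeds* the criterion —
either the same fixed 0.1 s threshold, or adaptively the upper limit
(mean + std) of the same participant's simultaneous test under the same
manual condition.

Pairing the two tap trains is under-determined when the detectors return
different counts.  The default ``index_aligned`` mode truncates both
trains to the shorter length and pairs i-th with i-th, which is the
pseudocode-faithful reading; ``nearest`` mode instead computes the
minimum-total-|dt| assignment between the trains, which is robust to a
missed detection shifting all subsequent indices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ConfigError, DomainError, InsufficientEventsError
from .tap_detection import TapSeries

__all__ = [
    "Classification",
    "DualFingerMetrics",
    "pair_taps",
    "sa_time_metrics",
    "classify_simultaneity",
    "classify_alternation",
    "classify_trial",
    "cohort_task_failure_rate",
]


class Classification(str, enum.Enum):
    SIMULTANEOUS_PASS = "simultaneous_pass"
    SIMULTANEOUS_FAIL = "simultaneous_fail"
    ALTERNATE_PASS = "alternate_pass"
    ALTERNATE_FAIL = "alternate_fail"

    @property
    def passed(self) -> bool:
        return self in (
            Classification.SIMULTANEOUS_PASS,
            Classification.ALTERNATE_PASS,
        )


@dataclass
class DualFingerMetrics:
    """SATime statistics and task classification for one trial."""

    sa_times: np.ndarray
    sa_mean: float
    sa_std: Optional[float]
    n_pairs: int
    classification: Optional[Classification] = None
    threshold_used: Optional[float] = None


def pair_taps(
    taps1: TapSeries,
    taps2: TapSeries,
    mode: str = "index_aligned",
) -> np.ndarray:
    """Pair the tap events of two fingers.

    ``index_aligned`` truncates both trains to ``n = min(n1, n2)`` events
    and pairs i-th with i-th.  ``nearest`` pairs each train-1 tap with a
    distinct train-2 tap so that the total |t2 - t1| over the ``n`` pairs
    is minimal (optimal assignment).  Pairs are returned as an ``(n, 2)``
    array sorted by t1.
    """
    if taps1.n_taps == 0 or taps2.n_taps == 0:
        raise InsufficientEventsError("both tap series must be non-empty to pair")
    t1, t2 = taps1.peak_times, taps2.peak_times
    n = min(t1.size, t2.size)
    if mode == "index_aligned":
        pairs = np.column_stack([t1[:n], t2[:n]])
    elif mode == "nearest":
        cost = np.abs(t1[:, None] - t2[None, :])
        rows, cols = linear_sum_assignment(cost)
        pairs = np.column_stack([t1[rows], t2[cols]])
        pairs = pairs[np.argsort(pairs[:, 0], kind="stable")]
    else:
        raise ConfigError(f"unknown pairing mode {mode!r}")
    return pairs


def sa_time_metrics(pairs: np.ndarray) -> DualFingerMetrics:
    """SATime statistics over paired events.

    ``sa_times[i] = |t2_i - t1_i|``; the mean requires at least one pair
    and the sample standard deviation at least two (a single pair reports
    ``sa_std=None`` rather than 0).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.size == 0:
        raise InsufficientEventsError("no pairs; cannot compute SATime metrics")
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise DomainError(f"pairs must be an (n, 2) array, got shape {pairs.shape}")
    sa = np.abs(pairs[:, 1] - pairs[:, 0])
    std = float(np.std(sa, ddof=1)) if sa.size >= 2 else None
    return DualFingerMetrics(
        sa_times=sa,
        sa_mean=float(np.mean(sa)),
        sa_std=std,
        n_pairs=sa.size,
    )


def classify_simultaneity(sa_mean: float, threshold: float = 0.1) -> bool:
    """A simultaneous trial passes iff mean SATime < threshold (strict).

    The boundary value itself fails; callers keep the raw sa_mean so the
    trial can be re-thresholded.
    """
    if sa_mean < 0:
        raise DomainError(f"sa_mean must be >= 0, got {sa_mean}")
    if not threshold > 0:
        raise DomainError(f"threshold must be > 0, got {threshold}")
    return sa_mean < threshold


def classify_alternation(
    sa_mean: float,
    *,
    mode: str = "fixed",
    threshold: float = 0.1,
    sim_reference: Optional[Tuple[float, float]] = None,
) -> bool:
    """An alternating trial passes iff mean SATime exceeds the criterion.

    ``mode='fixed'``: criterion is ``threshold`` (default 0.1 s).
    ``mode='adaptive'``: criterion is ``sim_mean + sim_std`` from the same
    participant's simultaneous test of the same manual condition, passed
    as ``sim_reference=(sim_mean, sim_std)``.
    """
    if sa_mean < 0:
        raise DomainError(f"sa_mean must be >= 0, got {sa_mean}")
    if mode == "fixed":
        return sa_mean > threshold
    if mode == "adaptive":
        if sim_reference is None:
            raise ConfigError(
                "adaptive alternation criterion needs sim_reference=(mean, std)"
            )
        sim_mean, sim_std = sim_reference
        return sa_mean > sim_mean + sim_std
    raise ConfigError(f"unknown alternation mode {mode!r}")


def classify_trial(
    metrics: DualFingerMetrics,
    is_alternate: bool,
    *,
    threshold: float = 0.1,
    mode: str = "fixed",
    sim_reference: Optional[Tuple[float, float]] = None,
) -> DualFingerMetrics:
    """Attach the pass/fail classification appropriate to the test type."""
    if is_alternate:
        ok = classify_alternation(
            metrics.sa_mean, mode=mode, threshold=threshold, sim_reference=sim_reference
        )
        cls = Classification.ALTERNATE_PASS if ok else Classification.ALTERNATE_FAIL
    else:
        ok = classify_simultaneity(metrics.sa_mean, threshold)
        cls = (
            Classification.SIMULTANEOUS_PASS if ok else Classification.SIMULTANEOUS_FAIL
        )
    metrics.classification = cls
    metrics.threshold_used = threshold
    return metrics


def cohort_task_failure_rate(
    classifications: Sequence[Union[Classification, bool]],
) -> float:
    """Percent of trials classified as failures, unrounded.

    Accepts :class:`Classification` values or plain booleans
    (``True`` = pass).
    """
    if len(classifications) == 0:
        raise DomainError("cannot compute a failure rate over an empty cohort")
    failures = 0
    for c in classifications:
        passed = c.passed if isinstance(c, Classification) else bool(c)
        failures += not passed
    return 100.0 * failures / len(classifications)
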