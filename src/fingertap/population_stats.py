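"""Cohort-level statistics.

Three statistics summarise a cohort of tapping-test trials:

* the **coefficient of variation** of tap counts across repeated runs of
  the same sensor placement, ``Cv = 100 * std(NTap) / mean(NTap)`` — the
  repeatability figure used to choose where on the finger to mount the
  IMU (lower is better);
* a **Gaussian model of the fatigue slopes**: per test and finger, the
  per-participant angular coefficients are summarised by their sample
  mean and standard deviation, defining a normal random variable X;
* the **Sample Fatigue Percentage (SFP)**: P(X > 0), i.e. the
  complementary normal CDF of the fitted slope distribution evaluated at
  zero — the estimated fraction of the population whose taps slow down
  over the trial.  SFP > 0.5 flags a test that on balance fatigues,
  SFP < 0.5 one that on balance trains.

All standard deviations are sample (n-1) estimates, and rounding happens
only at presentation (2 decimals for table-style output, decimal
half-up).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import norm

from .data_model_io import FingerLabel, TestType
from .dual_finger_metrics import Classification, cohort_task_failure_rate
from .errors import DomainError, InsufficientDataError
from .single_finger_metrics import excursion_percent_difference

__all__ = [
    "SlopeDistribution",
    "CohortSummary",
    "coefficient_of_variation",
    "mean_cv",
    "fit_slope_distribution",
    "sample_fatigue_percentage",
    "empirical_fatigue_fraction",
    "summarize_cohort",
    "round_to_printed",
]


def round_to_printed(x: float, ndigits: int = 2) -> float:
    """Presentation rounding: decimal half-up at ``ndigits`` decimals.

    Binary floats are first snapped at 9 decimals so that a value that is
    exactly representable in decimal (e.g. a mean of printed 2-d.p.
    numbers) rounds the way it would by hand.
    """
    snapped = Decimal(float(x)).quantize(Decimal("1e-9"), rounding=ROUND_HALF_EVEN)
    return float(snapped.quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def coefficient_of_variation(n_taps_per_repeat: Sequence[float]) -> float:
    """Repeatability of a sensor placement: 100 * sample std / mean of the
    tap counts across repeated runs."""
    counts = np.asarray(n_taps_per_repeat, dtype=float)
    if counts.size < 2:
        raise InsufficientDataError(
            f"need at least 2 repeats for a CV, got {counts.size}"
        )
    mean = float(np.mean(counts))
    if mean == 0:
        raise DomainError("mean tap count is zero; CV undefined")
    return 100.0 * float(np.std(counts, ddof=1)) / mean


def mean_cv(cv_per_participant: Sequence[float]) -> float:
    """Cohort average of per-participant CVs (percent)."""
    values = np.asarray(cv_per_participant, dtype=float)
    if values.size == 0:
        raise DomainError("cannot average an empty list of CVs")
    return float(np.mean(values))


@dataclass
class SlopeDistribution:
    """Gaussian summary of per-participant fatigue slopes for one cell."""

    mu: float
    sigma: float
    n: int
    test_type: Optional[TestType] = None
    finger_label: Optional[FingerLabel] = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DomainError(f"sigma must be >= 0, got {self.sigma}")
        if self.n < 2:
            raise InsufficientDataError(f"need n >= 2 participants, got {self.n}")

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0


def fit_slope_distribution(
    slopes: Sequence[float],
    test_type: Optional[TestType] = None,
    finger_label: Optional[FingerLabel] = None,
) -> SlopeDistribution:
    """Sample mean / sample std of per-participant fatigue slopes."""
    arr = np.asarray(slopes, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(
            f"need at least 2 slopes to fit a distribution, got {arr.size}"
        )
    return SlopeDistribution(
        mu=float(np.mean(arr)),
        sigma=float(np.std(arr, ddof=1)),
        n=arr.size,
        test_type=test_type,
        finger_label=finger_label,
    )


def sample_fatigue_percentage(
    dist: Union[SlopeDistribution, Tuple[float, float]],
) -> float:
    """P(X > 0) for X ~ Normal(mu, sigma): the complementary normal CDF
    at zero, i.e. the estimated fraction of the cohort that fatigues.

    Accepts a :class:`SlopeDistribution` or a bare ``(mu, sigma)`` pair.
    A degenerate sigma = 0 distribution is a point mass: SFP is 0 for
    mu < 0 and 1 for mu > 0; mu = 0 sits exactly on the boundary and is
    rejected as undefined.
    """
    if isinstance(dist, SlopeDistribution):
        mu, sigma = dist.mu, dist.sigma
    else:
        mu, sigma = float(dist[0]), float(dist[1])
    if sigma < 0:
        raise DomainError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        if mu < 0:
            return 0.0
        if mu > 0:
            return 1.0
        raise DomainError("SFP undefined for a point mass exactly at zero")
    return float(norm.sf(0.0, loc=mu, scale=sigma))


def empirical_fatigue_fraction(slopes: Sequence[float]) -> float:
    """Model-free variant: the observed fraction of positive slopes."""
    arr = np.asarray(slopes, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no slopes")
    return float(np.mean(arr > 0))


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Aggregates over a cohort of analysed trials.

    Cells with fewer than 2 contributing participants are absent from the
    mappings (never zero-filled).  Excursion percent differences are
    computed for the index finger against the UniSIM reference test
    (dominant index for the uni-manual tests, right index for the
    bi-manual ones).
    """

    slope_distributions: Dict[Tuple[TestType, FingerLabel], SlopeDistribution] = field(
        default_factory=dict
    )
    sfp: Dict[Tuple[TestType, FingerLabel], float] = field(default_factory=dict)
    sa_aggregate: Dict[TestType, Tuple[float, float, int]] = field(
        default_factory=dict
    )
    excursion_pct_difference: Dict[TestType, float] = field(default_factory=dict)
    failure_rate: Dict[TestType, float] = field(default_factory=dict)
    placement_cv: Optional[Dict[str, float]] = None
    n_trials: int = 0

    def to_json_dict(self) -> dict:
        """Plain-JSON view with string keys and 2-d.p. presentation of SFP."""
        return {
            "n_trials": self.n_trials,
            "slope_distributions": {
                f"{t.value}/{f.value}": {
                    "mu": d.mu,
                    "sigma": d.sigma,
                    "n": d.n,
                }
                for (t, f), d in self.slope_distributions.items()
            },
            "sfp": {
                f"{t.value}/{f.value}": round_to_printed(v)
                for (t, f), v in self.sfp.items()
            },
            "sa_aggregate": {
                t.value: {"mean": m, "std": s, "n": n}
                for t, (m, s, n) in self.sa_aggregate.items()
            },
            "excursion_pct_difference": {
                t.value: v for t, v in self.excursion_pct_difference.items()
            },
            "failure_rate": {t.value: v for t, v in self.failure_rate.items()},
            "placement_cv": self.placement_cv,
        }


def _index_finger_for(test_type: TestType) -> FingerLabel:
    return (
        FingerLabel.INDEX_RIGHT if test_type.is_bimanual else FingerLabel.INDEX_DOM
    )


def summarize_cohort(trial_metrics: Iterable) -> CohortSummary:
    """Aggregate per-trial metrics into a :class:`CohortSummary`.

    ``trial_metrics`` is an iterable of :class:`fingertap.pipeline.TrialMetrics`
    (anything exposing ``test_type``, ``finger_metrics`` — a mapping
    finger label -> SingleFingerMetrics — and ``dual``).
    """
    trials: List = list(trial_metrics)
    summary = CohortSummary(n_trials=len(trials))
    if not trials:
        return summary

    # --- slope distributions and SFP, per (test, finger) cell
    slopes: Dict[Tuple[TestType, FingerLabel], List[float]] = {}
    for tm in trials:
        for finger, sfm in tm.finger_metrics.items():
            slopes.setdefault((tm.test_type, FingerLabel(finger)), []).append(
                sfm.slope
            )
    for cell, values in slopes.items():
        if len(values) < 2:
            continue  # cell marked absent
        dist = fit_slope_distribution(values, cell[0], cell[1])
        summary.slope_distributions[cell] = dist
        if not (dist.degenerate and dist.mu == 0):
            summary.sfp[cell] = sample_fatigue_percentage(dist)

    # --- SATime aggregates and failure rates, per test
    by_test: Dict[TestType, List] = {}
    for tm in trials:
        by_test.setdefault(tm.test_type, []).append(tm)
    for test, group in by_test.items():
        sa_means = [tm.dual.sa_mean for tm in group if tm.dual is not None]
        if len(sa_means) >= 2:
            summary.sa_aggregate[test] = (
                float(np.mean(sa_means)),
                float(np.std(sa_means, ddof=1)),
                len(sa_means),
            )
        classifications = [
            tm.dual.classification
            for tm in group
            if tm.dual is not None and tm.dual.classification is not None
        ]
        if classifications:
            summary.failure_rate[test] = cohort_task_failure_rate(classifications)

    # --- index-finger excursion differences vs the UniSIM reference
    def cohort_excursion(test: TestType) -> Optional[float]:
        finger = _index_finger_for(test)
        vals = [
            tm.finger_metrics[finger].excursion_mean
            for tm in by_test.get(test, [])
            if finger in tm.finger_metrics
        ]
        return float(np.mean(vals)) if len(vals) >= 2 else None

    ref = cohort_excursion(TestType.UNISIM)
    if ref is not None and ref > 0:
        for test in (TestType.UNIALT, TestType.BIMSIM, TestType.BIMALT):
            other = cohort_excursion(test)
            if other is not None:
                summary.excursion_pct_difference[test] = (
                    excursion_percent_difference(ref, other)
                )
    return summary
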