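"""End-to-end analysis of a trial: detection -> per-finger and dual metrics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .data_model_io import FingerLabel, SessionConfig, TestType, TrialRecord
from .dual_finger_metrics import (
    DualFingerMetrics,
    classify_trial,
    pair_taps,
    sa_time_metrics,
)
from .single_finger_metrics import SingleFingerMetrics, compute_single_finger_metrics
from .tap_detection import TapSeries, detect_taps_from_trace

__all__ = ["TrialMetrics", "analyze_trial", "trial_metrics_rows"]


@dataclass
class TrialMetrics:
    """All derived quantities for one analysed trial."""

    participant_id: str
    test_type: TestType
    finger_metrics: Dict[FingerLabel, SingleFingerMetrics]
    dual: Optional[DualFingerMetrics]
    taps: Dict[FingerLabel, TapSeries] = field(default_factory=dict)


def analyze_trial(
    trial: TrialRecord,
    config: Optional[SessionConfig] = None,
    *,
    pairing_mode: str = "index_aligned",
    alternation_mode: str = "fixed",
    sim_reference: Optional[Tuple[float, float]] = None,
) -> TrialMetrics:
    """Run the full measurement chain on one trial.

    Axis selection and tap detection run per trace; per-finger metrics
    (inter-times, fatigue fit, 5 s windowed excursions) and the
    dual-finger SATime statistics plus pass/fail classification follow.
    """
    if config is None:
        config = SessionConfig()
    params = config.detection_params()

    finger_metrics: Dict[FingerLabel, SingleFingerMetrics] = {}
    taps_by_finger: Dict[FingerLabel, TapSeries] = {}
    series = []
    for trace in (trial.trace_1, trial.trace_2):
        taps, _axis, oriented = detect_taps_from_trace(trace, params)
        taps_by_finger[trace.finger_label] = taps
        series.append(taps)
        if taps.n_taps >= 2:
            finger_metrics[trace.finger_label] = compute_single_finger_metrics(
                trace.timestamps, oriented, taps, config.excursion_window
            )

    dual: Optional[DualFingerMetrics] = None
    if all(s.n_taps > 0 for s in series):
        pairs = pair_taps(series[0], series[1], mode=pairing_mode)
        dual = sa_time_metrics(pairs)
        dual = classify_trial(
            dual,
            trial.test_type.is_alternate,
            threshold=config.simultaneity_threshold,
            mode=alternation_mode,
            sim_reference=sim_reference,
        )
    return TrialMetrics(
        participant_id=trial.participant_id,
        test_type=trial.test_type,
        finger_metrics=finger_metrics,
        dual=dual,
        taps=taps_by_finger,
    )


def trial_metrics_rows(tm: TrialMetrics) -> List[dict]:
    """Flatten a TrialMetrics into tidy per-finger rows plus one pair row."""
    rows: List[dict] = []
    for finger, m in tm.finger_metrics.items():
        rows.append(
            {
                "participant_id": tm.participant_id,
                "test_type": tm.test_type.value,
                "finger": finger.value,
                "n_taps": m.n_taps,
                "slope": m.slope,
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "excursion_mean": m.excursion_mean,
                "excursion_std": m.excursion_std,
                "n_windows": m.n_windows,
                "sa_mean": None,
                "sa_std": None,
                "n_pairs": None,
                "classification": None,
            }
        )
    if tm.dual is not None:
        rows.append(
            {
                "participant_id": tm.participant_id,
                "test_type": tm.test_type.value,
                "finger": "pair",
                "n_taps": None,
                "slope": None,
                "intercept": None,
                "r_squared": None,
                "excursion_mean": None,
                "excursion_std": None,
                "n_windows": None,
                "sa_mean": tm.dual.sa_mean,
                "sa_std": tm.dual.sa_std,
                "n_pairs": tm.dual.n_pairs,
                "classification": (
                    tm.dual.classification.value if tm.dual.classification else None
                ),
            }
        )
    return rows
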