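"""Ground-truthed synthetic tapping trials.

Real recordings come from IMUs worn on two fingers; none are
redistributable, so every pipeline stage is exercised against this
generator instead.  It emulates the salient structure of a tapping
trace:

* quasi-periodic tap events with base interval ``T0``, a linear timing
  drift ``m`` (the ground-truth fatigue slope: intervals grow by ``m``
  seconds per second of elapsed time), and Gaussian per-event jitter;
* a biphasic raised-cosine pulse per tap on the z axis — a positive
  crest of amplitude ``A`` immediately followed by a trough of ``-A/2``
  over ``pulse_width`` seconds — which is a modelling convenience, not a
  claim about real tap waveforms: any sharp unimodal crest suits a
  prominence-based detector;
* optional geometric amplitude decay over the trial;
* a second finger shifted by a per-event inter-finger offset: around a
  constant ``offset`` for simultaneous trials, around half the local tap
  interval for alternating ones, both with Gaussian offset jitter;
* white sensor noise on all three axes (taps only on z).

A single seed fans out into independent substreams (event timing,
inter-finger offsets, per-finger noise), so each trace is reproducible
on its own.  Defaults describe a 30 s trial at 120 Hz with a 0.3 s base
interval at 2 g — brisk tapping whose alternation half-period (~0.15 s)
sits in the range healthy adults produce when asked to tap as fast as
possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .data_model_io import AccelTrace, FingerLabel, TestType, TrialRecord
from .errors import ConfigError, DataError

__all__ = [
    "SynthParams",
    "GroundTruth",
    "generate_tap_times",
    "render_trace",
    "generate_trial",
    "generate_cohort",
]


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; see the module docstring for the model."""

    duration: float = 30.0
    sampling_rate: float = 120.0
    base_interval: float = 0.3
    drift: float = 0.0
    timing_jitter: float = 0.01
    pulse_amplitude: float = 2.0
    amplitude_decay: float = 0.0
    pulse_width: float = 0.08
    inter_finger_mode: str = "simultaneous"
    offset: float = 0.0
    offset_jitter: float = 0.01
    noise: float = 0.05
    full_scale: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ConfigError("duration must be > 0")
        if not self.sampling_rate > 0:
            raise ConfigError("sampling_rate must be > 0")
        if not self.base_interval > 0:
            raise ConfigError("base_interval must be > 0")
        if self.timing_jitter < 0 or self.offset_jitter < 0 or self.noise < 0:
            raise ConfigError("jitter and noise amplitudes must be >= 0")
        if not self.pulse_amplitude > 0:
            raise ConfigError("pulse_amplitude must be > 0")
        if not 0 <= self.amplitude_decay < 1:
            raise ConfigError("amplitude_decay must be in [0, 1)")
        if not 0 < self.pulse_width < self.base_interval:
            raise ConfigError("pulse_width must satisfy 0 < width < base_interval")
        if self.inter_finger_mode not in ("simultaneous", "alternate"):
            raise ConfigError(
                f"unknown inter_finger_mode {self.inter_finger_mode!r}"
            )


@dataclass
class GroundTruth:
    """What the generator actually drew, for recovery checks."""

    tap_times_1: np.ndarray
    tap_times_2: np.ndarray
    drift: float
    offsets: np.ndarray
    params: SynthParams


#: Decay is expressed per 5 s analysis window.
DECAY_WINDOW = 5.0


def _streams(params: SynthParams):
    children = np.random.SeedSequence(params.seed).spawn(4)
    return tuple(np.random.default_rng(s) for s in children)


def _tap_times_finger1(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """First-finger event times: t0 = T0, then
    ``t_{i+1} = t_i + max(eps, T0 + m*t_i + jitter_i)`` with
    eps = 2 * pulse_width, truncated to [0, duration)."""
    eps = 2.0 * params.pulse_width
    times = []
    t = params.base_interval
    # a tap's pulse must fit inside the record, so no events are
    # scheduled in the final pulse_width of the trial
    while t < params.duration - params.pulse_width:
        times.append(t)
        jitter = rng.normal(0.0, params.timing_jitter) if params.timing_jitter else 0.0
        t = t + max(eps, params.base_interval + params.drift * t + jitter)
    return np.asarray(times)


def _offsets_for(
    params: SynthParams, t1: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    jitter = (
        rng.normal(0.0, params.offset_jitter, size=t1.size)
        if params.offset_jitter
        else np.zeros(t1.size)
    )
    if params.inter_finger_mode == "simultaneous":
        return params.offset + jitter
    # alternate: half the realized gap to the next first-finger tap, so
    # the second finger strikes midway between consecutive taps even when
    # drift pushes the nominal interval against the physical floor
    if t1.size >= 2:
        gaps = np.diff(t1)
        local = np.append(gaps, gaps[-1])
    else:
        local = np.full(t1.size, params.base_interval)
    return params.offset + local / 2.0 + jitter


def generate_tap_times(
    params: SynthParams, finger_index: int = 1
) -> np.ndarray:
    """Ground-truth tap times for finger 1 or 2 (deterministic in seed)."""
    if finger_index not in (1, 2):
        raise ConfigError(f"finger_index must be 1 or 2, got {finger_index}")
    timing_rng, offset_rng, _, _ = _streams(params)
    t1 = _tap_times_finger1(params, timing_rng)
    if finger_index == 1:
        return t1
    t2 = t1 + _offsets_for(params, t1, offset_rng)
    keep = (t2 >= 0) & (t2 < params.duration - params.pulse_width)
    return np.sort(t2[keep])


def _pulse_into(z: np.ndarray, fs: float, tc: float, amp: float, width: float) -> None:
    """Add one biphasic pulse: raised-cosine crest ``+amp`` at ``tc``
    (lobe width width/2) followed by a trough ``-amp/2`` at
    ``tc + width/2``."""
    n = z.size

    def lobe(center: float, height: float, lobe_width: float) -> None:
        i0 = max(0, int(np.ceil((center - lobe_width / 2) * fs)))
        i1 = min(n - 1, int(np.floor((center + lobe_width / 2) * fs)))
        if i1 < i0:
            return
        t = np.arange(i0, i1 + 1) / fs
        z[i0 : i1 + 1] += height * 0.5 * (
            1.0 + np.cos(2.0 * np.pi * (t - center) / lobe_width)
        )

    lobe(tc, amp, width / 2.0)
    lobe(tc + width / 2.0, -amp / 2.0, width / 2.0)


def render_trace(
    tap_times: np.ndarray,
    params: SynthParams,
    finger_label: FingerLabel = FingerLabel.INDEX_DOM,
    *,
    noise_rng: Optional[np.random.Generator] = None,
    sensor_id: str = "synthetic",
) -> AccelTrace:
    """Render tap times into a tri-axial AccelTrace.

    The z axis carries the tap pulses plus white noise; x and y are noise
    only.  The pulse crest coincides with the tap time to within half a
    sample.  Amplitudes decay geometrically by ``amplitude_decay`` per
    5 s of elapsed time.
    """
    tap_times = np.asarray(tap_times, dtype=float)
    if tap_times.size and (
        np.min(tap_times) < 0 or np.max(tap_times) >= params.duration
    ):
        raise DataError("tap times must lie within [0, duration)")
    if noise_rng is None:
        noise_rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(4)[2])
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    z = np.zeros(n)
    for tc in tap_times:
        amp = params.pulse_amplitude * (1.0 - params.amplitude_decay) ** (
            tc / DECAY_WINDOW
        )
        _pulse_into(z, fs, tc, amp, params.pulse_width)
    sigma = params.noise
    ax = noise_rng.normal(0.0, sigma, n) if sigma else np.zeros(n)
    ay = noise_rng.normal(0.0, sigma, n) if sigma else np.zeros(n)
    az = z + (noise_rng.normal(0.0, sigma, n) if sigma else 0.0)
    return AccelTrace(
        sensor_id=sensor_id,
        finger_label=finger_label,
        sampling_rate=fs,
        timestamps=t,
        ax=ax,
        ay=ay,
        az=az,
        full_scale=params.full_scale,
    )


_TRIAL_FINGERS = {
    TestType.UNISIM: (FingerLabel.INDEX_DOM, FingerLabel.MIDDLE_DOM),
    TestType.UNIALT: (FingerLabel.INDEX_DOM, FingerLabel.MIDDLE_DOM),
    TestType.BIMSIM: (FingerLabel.INDEX_RIGHT, FingerLabel.INDEX_LEFT),
    TestType.BIMALT: (FingerLabel.INDEX_RIGHT, FingerLabel.INDEX_LEFT),
}


def generate_trial(
    test_type: TestType,
    params: SynthParams,
    participant_id: Optional[str] = None,
) -> Tuple[TrialRecord, GroundTruth]:
    """Generate one complete trial of the given test type.

    The inter-finger mode is implied by the test type (``*SIM`` →
    simultaneous, ``*ALT`` → alternate) and overrides ``params``.
    """
    test_type = TestType(test_type)
    mode = "alternate" if test_type.is_alternate else "simultaneous"
    params = dataclasses.replace(params, inter_finger_mode=mode)

    timing_rng, offset_rng, noise1, noise2 = _streams(params)
    t1 = _tap_times_finger1(params, timing_rng)
    offsets = _offsets_for(params, t1, offset_rng)
    t2 = t1 + offsets
    keep = (t2 >= 0) & (t2 < params.duration - params.pulse_width)
    t2 = np.sort(t2[keep])

    f1, f2 = _TRIAL_FINGERS[test_type]
    trace_1 = render_trace(
        t1, params, f1, noise_rng=noise1, sensor_id=f"synth-{f1.value}"
    )
    trace_2 = render_trace(
        t2, params, f2, noise_rng=noise2, sensor_id=f"synth-{f2.value}"
    )
    trial = TrialRecord(
        participant_id=participant_id or f"synth-{params.seed}",
        test_type=test_type,
        trace_1=trace_1,
        trace_2=trace_2,
        duration=params.duration,
    )
    truth = GroundTruth(
        tap_times_1=t1,
        tap_times_2=t2,
        drift=params.drift,
        offsets=offsets,
        params=params,
    )
    return trial, truth


def generate_cohort(
    n_participants: int,
    test_type: TestType,
    params: SynthParams,
    *,
    slope_mean: float = 0.0,
    slope_sd: float = 0.0,
    seed: Optional[int] = None,
) -> list[Tuple[TrialRecord, GroundTruth]]:
    """A cohort of trials whose true drifts are drawn from
    Normal(slope_mean, slope_sd); each participant gets an independent
    seed derived from ``seed`` (defaults to ``params.seed``)."""
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    drift_rng = np.random.default_rng(root.spawn(1)[0])
    out = []
    for i in range(n_participants):
        m = (
            float(drift_rng.normal(slope_mean, slope_sd))
            if slope_sd
            else slope_mean
        )
        p = dataclasses.replace(
            params, drift=m, seed=int((root.generate_state(1)[0] + i) % (2**31))
        )
        out.append(generate_trial(test_type, p, participant_id=f"P{i:03d}"))
    return out
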