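"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from fingertap import AccelTrace, FingerLabel


def make_trace(
    z,
    sampling_rate=120.0,
    finger=FingerLabel.INDEX_DOM,
    x=None,
    y=None,
    full_scale=8.0,
):
    """Build a valid AccelTrace around a given z-axis signal."""
    z = np.asarray(z, dtype=float)
    n = z.size
    t = np.arange(n) / sampling_rate
    zeros = np.zeros(n)
    return AccelTrace(
        sensor_id="test",
        finger_label=finger,
        sampling_rate=sampling_rate,
        timestamps=t,
        ax=zeros if x is None else np.asarray(x, float),
        ay=zeros if y is None else np.asarray(y, float),
        az=z,
        full_scale=full_scale,
    )


def brute_force_prominent_peaks(signal, min_prominence):
    """Definition-level peak finder: strict local maxima with topographic
    prominence >= min_prominence.

    The prominence of a peak is its height minus the higher of its two
    bases; each base is the lowest sample between the peak and the
    nearest strictly higher sample on that side (or the signal border).
    Independent of scipy; quadratic time, for short signals only.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    out = []
    for i in range(1, n - 1):
        if not (signal[i] > signal[i - 1] and signal[i] > signal[i + 1]):
            continue
        h = signal[i]
        j = i - 1
        while j >= 0 and signal[j] <= h:
            j -= 1
        left_base = np.min(signal[j + 1 : i])  # segment contains i-1
        k = i + 1
        while k < n and signal[k] <= h:
            k += 1
        right_base = np.min(signal[i + 1 : k])
        prom = h - max(left_base, right_base)
        if prom >= min_prominence:
            out.append(i)
    return np.asarray(out, dtype=int)


def ols_closed_form(x, y):
    """Two-parameter OLS by the textbook formulas, as the fit oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    sxy = np.sum((x - xbar) * (y - ybar))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = np.sum(resid**2)
    ss_tot = np.sum((y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    return slope, intercept, r2


def brute_force_min_cost_pairs(t1, t2):
    """Exhaustive minimum-total-|dt| bipartite matching over
    min(n1, n2)-subsets; factorial time, for tiny instances only."""
    import itertools

    t1 = np.asarray(t1, float)
    t2 = np.asarray(t2, float)
    n = min(t1.size, t2.size)
    best_cost, best = np.inf, None
    short, long_ = (t1, t2) if t1.size <= t2.size else (t2, t1)
    for subset in itertools.permutations(range(long_.size), n):
        cost = float(np.sum(np.abs(short - long_[list(subset)])))
        if cost < best_cost - 1e-15:
            best_cost = cost
            best = subset
    if t1.size <= t2.size:
        pairs = np.column_stack([t1, t2[list(best)]])
    else:
        pairs = np.column_stack([t1[list(best)], t2])
    return best_cost, pairs[np.argsort(pairs[:, 0])]


@pytest.fixture
def rng():
    return np.random.default_rng(20240613)
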