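"""Covariance-based detection of single actomyosin attachment events.

The detector follows the classic three-bead-assay scheme: a running
covariance between the two bead positions is computed over a sliding window
(8 ms default), its histogram is fit by a double Gaussian (high-covariance
component = unbound actin, low = attached), and events are selected by a
hysteresis trigger — the covariance must drop below the high peak, then
below the low peak (confirmation), then rise back above the high peak
(closure).  Events shorter than the instrument dead time (16 ms default)
are excluded, as are partial events at the trace edges.

Boundary convention: each covariance sample is computed over the trailing
window ``[i, i + w)`` and is stamped at the window center; reported event
boundaries subtract half a window, which lands them at the window-start
index ``i / fs``.  For well-separated covariance states this places the
detected start/stop within about a window of the true attachment and
detachment times, with the confirming (low-peak) crossing essentially
unbiased — a property the substep extraction downstream relies on.
"""

from __future__ import annotations

import numpy as np
from sklearn.mixture import GaussianMixture

from .datatypes import CovarianceSeries, CovThresholds, Event, EventSet, TrapTrace

__all__ = [
    "StatesNotSeparableError",
    "running_covariance",
    "fit_cov_double_gaussian",
    "detect_events",
    "extract_gap_times",
]


class StatesNotSeparableError(RuntimeError):
    """The covariance histogram has no resolvable two-state structure."""


def running_covariance(trace: TrapTrace, window: float = 0.008) -> CovarianceSeries:
    """Sliding-window sample covariance of the two position channels.

    ``values[i]`` is the covariance over samples ``[i, i + w)`` (valid mode,
    length ``n - w + 1``).  Implemented with cumulative sums, so it is exact
    and O(n).
    """
    w = int(round(window * trace.sampling_rate))
    if w < 8:
        raise ValueError("covariance window must span at least 8 samples")
    n = trace.n_samples
    if n < w:
        raise ValueError("trace shorter than covariance window")
    x = trace.motor_pos
    y = trace.transducer_pos
    # windowed sums via cumulative sums; subtract channel means first for
    # numerical stability (covariance is offset-invariant)
    x = x - x.mean()
    y = y - y.mean()

    def _winsum(a: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(a)))
        return c[w:] - c[:-w]

    sx, sy, sxy = _winsum(x), _winsum(y), _winsum(x * y)
    values = (sxy - sx * sy / w) / (w - 1)
    return CovarianceSeries(values=values, window=window, sampling_rate=trace.sampling_rate)


def fit_cov_double_gaussian(
    cov: CovarianceSeries,
    seed: int = 0,
    max_samples: int = 200_000,
) -> CovThresholds:
    """Two-component Gaussian mixture fit of the covariance histogram.

    EM with k-means initialization and three random restarts (seeded); the
    best-likelihood solution is kept and components are labeled by mean.
    Raises :class:`StatesNotSeparableError` for a single-state trace with
    no detectable events, flagged when any of these hold: a one-component
    fit has the better BIC (a pure unimodal histogram gets split into two
    overlapping components), the means are closer than twice the narrower
    SD, or closer than half the wider SD.
    """
    values = np.asarray(cov.values, dtype=float)
    if values.size < 100:
        raise ValueError("need at least 100 covariance samples")
    if values.size > max_samples:
        # the mixture is over a 1-D histogram; a deterministic stride
        # subsample preserves it and bounds the EM cost
        stride = int(np.ceil(values.size / max_samples))
        values = values[::stride]
    X = values.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=3,
        init_params="kmeans",
        random_state=seed,
    ).fit(X)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(X)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    hi, lo = (0, 1) if means[0] > means[1] else (1, 0)
    sep = abs(means[hi] - means[lo])
    if gm1.bic(X) <= gm.bic(X) or sep < 2 * min(sds) or sep < max(sds) / 2:
        raise StatesNotSeparableError("states not separable")
    return CovThresholds(
        mu_high=float(means[hi]),
        mu_low=float(means[lo]),
        sd_high=float(sds[hi]),
        sd_low=float(sds[lo]),
        weight_high=float(weights[hi]),
    )


def detect_events(
    cov: CovarianceSeries,
    thr: CovThresholds,
    dead_time: float = 0.016,
    refine: bool = True,
) -> EventSet:
    """Hysteresis event trigger on the covariance series.

    A candidate opens when the covariance crosses below ``mu_high``, is
    confirmed when it crosses below ``mu_low`` and closes when it rises back
    above ``mu_high``.  Events shorter than ``dead_time`` and partial events
    at the trace edges are discarded.

    Boundary placement: the confirm/close crossings sit at the centers of
    the bound/free covariance distributions, so their latency relative to
    the true transition is stochastic with a heavy tail (the covariance
    hovers around each threshold between transitions).  With
    ``refine=True`` (default) the reported boundaries are instead taken
    from the midpoint-threshold crossing of the covariance ramp — the last
    down-crossing of ``(mu_high + mu_low)/2`` before confirmation and the
    last up-crossing before closure — plus half a window, which places
    each boundary at the window whose center straddles the transition.
    The ramp crossing is steep, so this estimator has millisecond-scale
    jitter and no tail; ``refine=False`` reports the raw confirm/close
    crossings (at the window-start index, i.e. window-center time minus
    half a window).
    """
    v = cov.values
    fs = cov.sampling_rate
    w = cov.window_samples
    mid = 0.5 * (thr.mu_high + thr.mu_low)
    above = v >= thr.mu_high
    falls = np.flatnonzero(above[:-1] & ~above[1:]) + 1  # first sample < mu_high
    rises = np.flatnonzero(~above[:-1] & above[1:]) + 1  # first sample >= mu_high
    events: list[Event] = []
    j = 0
    for f in falls:
        while j < rises.size and rises[j] <= f:
            j += 1
        if j >= rises.size:
            break  # unterminated run at trace end -> partial, discarded
        r = rises[j]
        seg = v[f:r]
        below_low = np.flatnonzero(seg < thr.mu_low)
        if below_low.size == 0:
            continue  # never confirmed
        confirm_i = f + below_low[0]
        if refine:
            # last down-crossing of the midpoint before confirmation
            down = np.flatnonzero((v[f:confirm_i] >= mid) & (v[f + 1 : confirm_i + 1] < mid))
            start_i = (f + down[-1] + 1 if down.size else confirm_i) + w // 2
            # last up-crossing of the midpoint before closure
            up = np.flatnonzero((v[confirm_i:r] < mid) & (v[confirm_i + 1 : r + 1] >= mid))
            stop_i = (confirm_i + up[-1] + 1 if up.size else r) + w // 2
        else:
            start_i, stop_i = confirm_i, r
        duration = (stop_i - start_i) / fs
        if duration < dead_time:
            continue
        events.append(Event(start=start_i / fs, stop=stop_i / fs))
    return EventSet(
        events=events,
        dead_time=dead_time,
        source={"window": cov.window, "mu_high": thr.mu_high, "mu_low": thr.mu_low},
    )


def extract_gap_times(events: EventSet) -> list[float]:
    """Stop-to-next-start intervals (reattachment times), in order.

    Returns an empty list for fewer than two events.
    """
    return events.gaps
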