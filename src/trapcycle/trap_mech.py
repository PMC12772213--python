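"""Working-stroke mechanics and load-dependent detachment from trap events.

Covers three analyses that consume detected events:

* three-window substep extraction from unloaded low-ATP events
  (1 ms position averages at fixed offsets from the attachment and
  detachment transitions);
* time-forward / time-reversed ensemble averages with terminal-window
  padding and single-exponential rate fits (forward rise = substep 1 -> 2
  transition, i.e. ADP release; reverse rise = ATP-induced detachment);
* per-event clamp forces and the unbinned maximum-likelihood Bell-equation
  fit with dead-time truncation and event-level bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import Event, EventSet, TrapTrace
from .synthkin import KT_20C

__all__ = [
    "EnsembleAverage",
    "BellFit",
    "NonIdentifiableError",
    "compute_substeps",
    "ensemble_average",
    "event_mean_force",
    "fit_bell",
    "bin_detachment_vs_force",
]


class NonIdentifiableError(RuntimeError):
    """The requested fit has no identifiable solution for this design."""


# 1 ms averaging window used for the three substep anchor points
_SUBSTEP_AVG = 1e-3
# offsets per the three-point scheme: window ending 4 ms before attachment,
# window starting 2 ms after attachment, window ending 4 ms before detachment
_PRE_END = 4e-3
_POST_START = 2e-3
_MIN_EVENT = 8e-3  # below this the three windows would overlap


def _window_mean(pos: np.ndarray, fs: float, t0: float, t1: float) -> float:
    i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
    if i0 < 0 or i1 > pos.size or i1 <= i0:
        return float("nan")
    return float(pos[i0:i1].mean())


def compute_substeps(
    trace: TrapTrace, event: Event, channel: str = "transducer"
) -> tuple[float, float, float]:
    """Three-window substep extraction for one unloaded event.

    Averages 1 ms of the bead position at three anchor points: (1) ending
    4 ms before attachment, (2) starting 2 ms after attachment, (3) ending
    4 ms before detachment.  Substep 1 = p2 - p1, substep 2 = p3 - p2,
    total = p3 - p1.  Events shorter than 8 ms (or whose windows fall off
    the trace) return NaNs — they are flagged missing but still count for
    duration statistics.
    """
    pos = trace.transducer_pos if channel == "transducer" else trace.motor_pos
    fs = trace.sampling_rate
    if event.duration < _MIN_EVENT:
        return (float("nan"),) * 3
    p1 = _window_mean(pos, fs, event.start - _PRE_END - _SUBSTEP_AVG, event.start - _PRE_END)
    p2 = _window_mean(pos, fs, event.start + _POST_START, event.start + _POST_START + _SUBSTEP_AVG)
    p3 = _window_mean(pos, fs, event.stop - _PRE_END - _SUBSTEP_AVG, event.stop - _PRE_END)
    return (p2 - p1, p3 - p2, p3 - p1)


def annotate_substeps(
    trace: TrapTrace, events: EventSet, channel: str = "transducer"
) -> EventSet:
    """Fill the substep fields of each event in place; returns the set."""
    for ev in events:
        s1, s2, tot = compute_substeps(trace, ev, channel=channel)
        ev.substep1, ev.substep2, ev.total_step = s1, s2, tot
    return events


@dataclass
class EnsembleAverage:
    """Event-aligned mean bead displacement with its exponential-rate fit."""

    direction: str  # "forward" | "reverse"
    time: np.ndarray  # s; 0 at the alignment transition
    mean_position: np.ndarray  # nm, baseline-subtracted
    n_events: int
    fitted_rate: float  # 1/s
    rate_ci: tuple[float, float]  # 95% CI
    initial_level: float  # nm (forward: ~substep 1)
    plateau_level: float  # nm (forward: ~substep 1 + substep 2)


# padding per the ensemble scheme: a 4 ms window of in-event data ending
# 1 ms before the event's own terminal transition
_PAD_WIN = 4e-3
_PAD_GAP = 1e-3


def _event_slice(pos: np.ndarray, fs: float, t0: float, t1: float) -> np.ndarray:
    return pos[int(round(t0 * fs)) : int(round(t1 * fs))]


def ensemble_average(
    data: Sequence[tuple[TrapTrace, Event]],
    direction: str = "forward",
    channel: str = "transducer",
) -> EnsembleAverage:
    """Equal-weight ensemble average of events aligned at start or stop.

    Forward averages align events at attachment; shorter events are extended
    to the longest event's duration with the mean of 4 ms of their own data
    ending 1 ms before detachment.  Reverse averages align at detachment and
    extend events backward with the mean of 4 ms of data starting 1 ms after
    attachment.  Each event's pre-attachment (forward) or post-detachment
    (reverse) 4 ms baseline is subtracted, so the forward initial level
    estimates substep 1 and the plateau estimates the total step.

    The rise is fit by nonlinear least squares to the three-parameter model
    ``offset + amplitude * (1 - exp(-rate * t))``; the forward rate
    estimates the substep 1 -> 2 (ADP release) transition and the reverse
    rate ATP-induced detachment.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if len(data) < 10:
        raise ValueError("need at least 10 events for an ensemble average")
    fs = data[0][0].sampling_rate
    tmax = max(ev.duration for _, ev in data)
    m = int(round(tmax * fs))
    rows = np.empty((len(data), m))
    kept = 0
    for trace, ev in data:
        pos = trace.transducer_pos if channel == "transducer" else trace.motor_pos
        seg = _event_slice(pos, fs, ev.start, ev.stop)
        if direction == "forward":
            pad_src = _event_slice(pos, fs, ev.stop - _PAD_GAP - _PAD_WIN, ev.stop - _PAD_GAP)
            base_src = _event_slice(pos, fs, ev.start - _PAD_GAP - _PAD_WIN, ev.start - _PAD_GAP)
        else:
            pad_src = _event_slice(pos, fs, ev.start + _PAD_GAP, ev.start + _PAD_GAP + _PAD_WIN)
            base_src = _event_slice(pos, fs, ev.stop + _PAD_GAP, ev.stop + _PAD_GAP + _PAD_WIN)
        if seg.size == 0 or pad_src.size == 0 or base_src.size == 0:
            continue
        pad = pad_src.mean()
        row = np.full(m, pad)
        if direction == "forward":
            row[: seg.size] = seg[:m]
        else:
            row[m - seg.size :] = seg[-m:]
        rows[kept] = row - base_src.mean()
        kept += 1
    if kept < 10:
        raise ValueError("need at least 10 events with usable position data")
    mean_pos = rows[:kept].mean(axis=0)
    if direction == "forward":
        t = np.arange(m) / fs
        y = mean_pos
    else:
        t = np.arange(m) / fs  # time before detachment, reversed so rise is forward
        y = mean_pos[::-1]

    def model(tt, off, amp, rate):
        return off + amp * (1.0 - np.exp(-rate * tt))

    span = y[-1] - y[0] if abs(y[-1] - y[0]) > 0 else 1.0
    p0 = (float(y[0]), float(span), 1.0 / max(t[-1] / 5.0, 1e-4))
    # rate bounded away from 0 to exclude the degenerate linear-ramp solution
    bounds = ([-np.inf, -np.inf, 0.2 / max(t[-1], 1e-6)], [np.inf, np.inf, np.inf])
    popt, pcov = optimize.curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=20000)
    rate = float(popt[2])
    se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    ci = (rate - 1.96 * se, rate + 1.96 * se)
    return EnsembleAverage(
        direction=direction,
        time=t,
        mean_position=y,
        n_events=kept,
        fitted_rate=rate,
        rate_ci=ci,
        initial_level=float(popt[0]),
        plateau_level=float(popt[0] + popt[1]),
    )


# force averaging scheme: event mean from 2 ms after attachment to 2 ms
# before detachment; baseline = 1 ms mean centered 4 ms after detachment
_FORCE_MARGIN = 2e-3
_BASE_CENTER = 4e-3


def event_mean_force(trace: TrapTrace, event: Event) -> float:
    """Baseline-subtracted mean clamp force for one isometric event.

    Averages the motor-bead force from 2 ms after detected attachment to
    2 ms before detachment, then subtracts the post-detachment baseline
    (1 ms mean centered 4 ms after detachment).
    """
    if trace.force is None:
        raise ValueError("trace has no force channel")
    if trace.mode != "isometric":
        raise ValueError("event forces require isometric mode")
    fs = trace.sampling_rate
    if event.duration <= 2 * _FORCE_MARGIN:
        return float("nan")
    f = _window_mean(trace.force, fs, event.start + _FORCE_MARGIN, event.stop - _FORCE_MARGIN)
    base = _window_mean(
        trace.force,
        fs,
        event.stop + _BASE_CENTER - _SUBSTEP_AVG / 2,
        event.stop + _BASE_CENTER + _SUBSTEP_AVG / 2,
    )
    return f - base


@dataclass
class BellFit:
    """Maximum-likelihood Bell-equation fit of force-lifetime pairs."""

    k0: float  # 1/s
    d_bell: float  # nm
    k0_ci: tuple[float, float]
    d_ci: tuple[float, float]
    kT: float  # pN*nm
    n_events: int
    exclusion_threshold: float  # pN
    dead_time: float  # s
    log_likelihood: float


def _bell_nll(theta: np.ndarray, f: np.ndarray, t: np.ndarray, kT: float, t0: float) -> float:
    log_k0, d = theta
    log_rate = log_k0 - f * d / kT
    return float(np.sum(np.exp(log_rate) * (t - t0) - log_rate))


def _bell_mle(
    f: np.ndarray,
    t: np.ndarray,
    kT: float,
    t0: float,
    fix_d: float | None = None,
) -> tuple[float, float, float]:
    k_init = 1.0 / max(np.mean(t) - t0, 1e-9)
    d_bounds = (0.0, 20.0) if fix_d is None else (fix_d, fix_d)
    d_starts = (0.1, 0.5, 1.5) if fix_d is None else (fix_d,)
    best = None
    for d0 in d_starts:
        res = optimize.minimize(
            _bell_nll,
            x0=np.array([np.log(k_init), d0]),
            args=(f, t, kT, t0),
            method="L-BFGS-B",
            bounds=[(-15.0, 15.0), d_bounds],
        )
        if best is None or res.fun < best.fun:
            best = res
    k0 = float(np.exp(best.x[0]))
    return k0, float(best.x[1]), -float(best.fun)


def fit_bell(
    pairs: np.ndarray,
    kT: float = KT_20C,
    exclude_above: float = 10.0,
    dead_time: float = 0.016,
    n_boot: int = 1000,
    seed: int = 0,
    fix_d: float | None = None,
) -> BellFit:
    """Unbinned MLE of the Bell equation ``k(F) = k0 exp(-F d / kT)``.

    Each lifetime is modeled as a dead-time-truncated exponential at the
    event's force-dependent rate.  Events with force above
    ``exclude_above`` (possible second-head interactions beyond the clamp's
    subsaturating range) are removed first.  95% CIs are percentile
    intervals over ``n_boot`` event-level bootstrap resamples (seeded);
    pass ``n_boot=0`` to skip the bootstrap.  ``d`` is constrained to be
    non-negative; a fit pinned at 0 reports a CI lower bound of 0.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (force, lifetime)")
    if kT <= 0:
        raise ValueError("kT must be > 0")
    keep = pairs[:, 0] <= exclude_above
    f, t = pairs[keep, 0], pairs[keep, 1]
    if f.size == 0:
        raise ValueError("all events excluded by the force threshold")
    if f.size < 50:
        raise ValueError("need at least 50 surviving force-lifetime pairs")
    if np.any(t < dead_time):
        raise ValueError("dead-time violation: lifetime below dead time")
    if fix_d is None and np.ptp(f) < 1e-9:
        raise NonIdentifiableError(
            "k0 and d are not jointly identifiable when all forces are equal"
        )
    k0, d, ll = _bell_mle(f, t, kT, dead_time, fix_d=fix_d)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        k0s = np.empty(n_boot)
        ds = np.empty(n_boot)
        n = f.size
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            k0s[b], ds[b], _ = _bell_mle(f[idx], t[idx], kT, dead_time, fix_d=fix_d)
        k0_ci = tuple(np.percentile(k0s, [2.5, 97.5]))
        d_ci = tuple(np.percentile(ds, [2.5, 97.5]))
    else:
        k0_ci = (float("nan"), float("nan"))
        d_ci = (float("nan"), float("nan"))
    return BellFit(
        k0=k0,
        d_bell=d,
        k0_ci=k0_ci,
        d_ci=d_ci,
        kT=kT,
        n_events=int(f.size),
        exclusion_threshold=exclude_above,
        dead_time=dead_time,
        log_likelihood=ll,
    )


def bin_detachment_vs_force(pairs: np.ndarray, bin_size: int = 25) -> pd.DataFrame:
    """Display binning of detachment rate vs force (never used for fitting).

    Pairs are sorted by force and grouped into consecutive ``bin_size``-event
    bins (the final partial bin is dropped); each bin reports its mean force
    and the reciprocal of its mean lifetime.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.shape[0] < bin_size:
        raise ValueError("need at least one full bin of pairs")
    order = np.argsort(pairs[:, 0], kind="stable")
    f, t = pairs[order, 0], pairs[order, 1]
    n_bins = f.size // bin_size
    rows = []
    for i in range(n_bins):
        sl = slice(i * bin_size, (i + 1) * bin_size)
        rows.append({"mean_force_pN": f[sl].mean(), "rate_per_s": 1.0 / t[sl].mean()})
    return pd.DataFrame(rows)
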