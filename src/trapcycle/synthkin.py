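"""Synthetic-data generators with known ground truth.

Every downstream stage of the package (covariance event detection, substep
and ensemble analysis, dwell-time MLE, Bell fitting, transient fitting,
Michaelis-Menten and mixed-motor gliding analysis) is exercised against data
produced here, so each generator records the exact ground truth it drew.

The trapped-bead model is a discrete-time AR(1) (Ornstein-Uhlenbeck) process
per bead with a shared innovation component that sets the inter-bead
correlation.  Actomyosin attachment stiffens the bead-actin-bead dumbbell,
which lowers both the position variance and the inter-bead correlation; the
covariance drop between the two beads is what the detector keys on.  Only
this second-moment structure matters for detection, so no hydrodynamic
coupling is simulated.

Attachment kinetics are sequential, following the actomyosin cycle at low
ATP: binding produces substep 1 immediately (Pi release), substep 2 (ADP
release) follows after an exponential wait with rate ``substep2_rate``, and
detachment (ATP binding to the rigor head) follows substep 2 after an
exponential wait with rate ``detachment_rate``.  At saturating ATP one sets
``detachment_rate`` large so that the attachment duration is dominated by the
ADP-release wait, or equivalently ``substep2_rate`` large so durations are
exponential at ``detachment_rate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .datatypes import Event, EventSet, TrapTrace, Transient

__all__ = [
    "TrapSimParams",
    "ForceEventSimParams",
    "TransientSimParams",
    "simulate_unloaded_trace",
    "simulate_isometric_trace",
    "simulate_isometric_events",
    "simulate_transient",
    "simulate_atpase_progress",
    "simulate_gliding_velocities",
    "simulate_exponential_mixture",
    "KT_20C",
]

log = logging.getLogger(__name__)

#: kT at the 20 degC trap temperature, pN*nm.
KT_20C = 4.05

# NADH extinction coefficient, 1/(M*cm), and assumed 1 cm path length.
NADH_EXTINCTION = 6220.0


@dataclass
class TrapSimParams:
    """Generative parameters for a two-bead trap recording.

    Noise defaults give free/bound covariance levels well separated relative
    to the 8 ms windowed-covariance sampling noise, comparable to the
    detection contrast of real recordings; they are not measured quantities
    and are fully configurable.
    """

    sampling_rate: float = 25_000.0  # Hz
    duration: float = 15.0  # s, one recording
    trap_stiffness: tuple[float, float] = (0.08, 0.08)  # pN/nm
    bead_noise_sd_free: float = 7.0  # nm, stationary SD per bead, detached
    bead_noise_sd_bound: float = 2.0  # nm, attached
    correlation_free: float = 0.9  # inter-bead correlation, detached
    correlation_bound: float = 0.2  # attached; must be < correlation_free
    attachment_rate: float = 1.0  # 1/s
    detachment_rate: float = 5.5  # 1/s, post-substep-2 (ATP binding) exit
    substep1: float = 3.88  # nm
    substep2: float = 0.94  # nm
    substep2_rate: float = 62.0  # 1/s (ADP release)
    relaxation_rate: float = 25_000.0  # 1/s, AR(1) corner of the trapped bead
    atp: float = 1.0  # µM, metadata only
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.bead_noise_sd_free <= 0 or self.bead_noise_sd_bound <= 0:
            raise ValueError("bead noise SDs must be > 0")
        for r, name in [
            (self.attachment_rate, "attachment_rate"),
            (self.detachment_rate, "detachment_rate"),
            (self.substep2_rate, "substep2_rate"),
        ]:
            if r < 0:
                raise ValueError(f"{name} must be >= 0")
        for c in (self.correlation_free, self.correlation_bound):
            if not 0.0 <= c <= 1.0:
                raise ValueError("correlations must lie in [0, 1]")
        if not self.correlation_bound < self.correlation_free:
            raise ValueError(
                "bound-state correlation must be below free-state correlation"
            )
        if self.relaxation_rate <= 0:
            raise ValueError("relaxation_rate must be > 0")


@dataclass
class ForceEventSimParams:
    """Generative twin of the Bell relation for isometric-clamp events.

    Forces are drawn from a truncated normal emulating the Brownian spread of
    attachment positions under the clamp; lifetimes are exponential at
    ``k0 * exp(-F * d_bell / kT)``.  Lifetimes below ``dead_time`` are
    censored (regenerated), as in the instrument.
    """

    k0: float = 32.9  # 1/s
    d_bell: float = 0.80  # nm
    kT: float = KT_20C  # pN*nm
    force_mean: float = 3.0  # pN
    force_sd: float = 2.0  # pN
    force_bounds: tuple[float, float] = (0.2, 10.0)  # pN
    n_events: int = 1000
    dead_time: float = 0.016  # s
    seed: int = 0

    def validate(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0")
        if self.kT <= 0:
            raise ValueError("kT must be > 0")
        if self.d_bell < 0:
            raise ValueError("d_bell must be >= 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.force_sd <= 0:
            raise ValueError("force_sd must be > 0")
        lo, hi = self.force_bounds
        if not lo < hi:
            raise ValueError("force_bounds must be increasing")


@dataclass
class TransientSimParams:
    """Generative parameters for a stopped-flow style transient."""

    kind: str = "pyrene"  # pyrene | mant_turnover | pi_release | nadh
    rates: Sequence[float] = (69.0,)  # 1/s
    fractional_amplitudes: Sequence[float] = (1.0,)  # sum to 1
    total_amplitude: float = 1.0  # AU
    bleach_fraction: float = 0.0  # of total_amplitude
    bleach_rate: float = 0.002  # 1/s
    noise_sd: float = 0.01  # AU
    duration: float = 1.0  # s
    n_points: int = 1000
    split_timebase: Optional[Sequence[int]] = None  # points per segment
    split_durations: Optional[Sequence[float]] = None  # s per segment
    seed: int = 0

    def validate(self) -> None:
        amps = np.asarray(self.fractional_amplitudes, dtype=float)
        if abs(amps.sum() - 1.0) > 1e-9:
            raise ValueError("fractional_amplitudes must sum to 1")
        if len(self.rates) != amps.size:
            raise ValueError("rates and fractional_amplitudes must align")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be > 0")
        if not 0.0 <= self.bleach_fraction < 1.0:
            raise ValueError("bleach_fraction must lie in [0, 1)")
        if self.duration <= 0 or self.n_points < 2:
            raise ValueError("duration and n_points must be positive")


# ---------------------------------------------------------------------------
# trap traces


def _draw_events(
    params: TrapSimParams, rng: np.random.Generator, edge_margin: float = 0.02
) -> list[Event]:
    """Alternate exponential gaps and sequential-kinetics durations.

    Events are kept only if they fit entirely inside the recording with an
    ``edge_margin`` buffer on both sides (partial events never appear in the
    ground truth, mirroring their exclusion during detection).
    """
    events: list[Event] = []
    if params.attachment_rate == 0:
        return events
    t = edge_margin
    while True:
        gap = rng.exponential(1.0 / params.attachment_rate)
        start = t + gap
        w = (
            rng.exponential(1.0 / params.substep2_rate)
            if params.substep2_rate > 0
            else np.inf
        )
        u = (
            rng.exponential(1.0 / params.detachment_rate)
            if params.detachment_rate > 0
            else np.inf
        )
        stop = start + w + u
        if not np.isfinite(stop) or stop > params.duration - edge_margin:
            break
        events.append(
            Event(
                start=start,
                stop=stop,
                substep1=params.substep1,
                substep2=params.substep2,
                total_step=params.substep1 + params.substep2,
                substep2_time=start + w,
            )
        )
        t = stop
    return events


def _ar1_channels(
    params: TrapSimParams, bound: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated AR(1) noise for the two beads with state-dependent moments."""
    n = bound.size
    phi = np.exp(-params.relaxation_rate / params.sampling_rate)
    sd = np.where(bound, params.bead_noise_sd_bound, params.bead_noise_sd_free)
    rho = np.where(bound, params.correlation_bound, params.correlation_free)
    sigma_inn = sd * np.sqrt(1.0 - phi**2)
    common = rng.standard_normal(n)
    chans = []
    for _ in range(2):
        eigen = rng.standard_normal(n)
        inn = sigma_inn * (np.sqrt(rho) * common + np.sqrt(1.0 - rho) * eigen)
        x = _signal.lfilter([1.0], [1.0, -phi], inn)
        chans.append(x)
    return chans[0], chans[1]


def _mean_displacement(params: TrapSimParams, events: list[Event], n: int) -> np.ndarray:
    """Deterministic dumbbell displacement implied by the event ground truth."""
    fs = params.sampling_rate
    mean = np.zeros(n)
    for ev in events:
        i0, i1 = int(round(ev.start * fs)), int(round(ev.stop * fs))
        i2 = int(round(ev.substep2_time * fs))
        mean[i0:i1] += ev.substep1
        mean[min(i2, i1) : i1] += ev.substep2
    return mean


def simulate_unloaded_trace(
    params: TrapSimParams, cov_window: float = 0.008
) -> tuple[TrapTrace, EventSet]:
    """Simulate an unloaded two-bead recording plus its ground-truth events.

    Returns a trace in which attachment intervals carry reduced inter-bead
    covariance and the two-substep displacement, and an :class:`EventSet`
    with exact boundaries and substep-2 times.  Identical seed and parameters
    give bit-identical output.
    """
    params.validate()
    if params.duration < 2 * cov_window:
        raise ValueError("trace too short")
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.sampling_rate))
    events = _draw_events(params, rng)
    bound = np.zeros(n, dtype=bool)
    fs = params.sampling_rate
    for ev in events:
        bound[int(round(ev.start * fs)) : int(round(ev.stop * fs))] = True
    x1, x2 = _ar1_channels(params, bound, rng)
    mean = _mean_displacement(params, events, n)
    trace = TrapTrace(
        motor_pos=x1 + mean,
        transducer_pos=x2 + mean,
        sampling_rate=fs,
        atp=params.atp,
        mode="unloaded",
        stiffness=params.trap_stiffness,
    )
    truth = EventSet(events=events, dead_time=0.0, source={"generator": "simulate_unloaded_trace", "seed": params.seed})
    return trace, truth


def simulate_isometric_trace(
    params: TrapSimParams,
    force_params: ForceEventSimParams | None = None,
    force_noise_sd: float = 0.3,
    cov_window: float = 0.008,
) -> tuple[TrapTrace, EventSet]:
    """Simulate an isometric-clamp recording with a force channel.

    Position-channel statistics (free/bound covariance structure) follow
    :func:`simulate_unloaded_trace`, but the clamp holds the filament, so
    no working-stroke displacement appears on the position channels; the
    event's clamp force (drawn from the truncated normal in
    ``force_params``) is held on the force channel, plus white measurement
    noise, with a zero baseline between events.

    Lifetimes follow the Bell relation: each event's post-stroke dwell is
    exponential at ``force_params.k0 * exp(-F * d_bell / kT)`` (the
    substep-2 wait from ``params.substep2_rate`` still precedes it, so set
    it fast to emulate saturating ATP); ``params.detachment_rate`` is
    ignored in this mode.
    """
    params.validate()
    if force_params is None:
        force_params = ForceEventSimParams()
    force_params.validate()
    if params.duration < 2 * cov_window:
        raise ValueError("trace too short")
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    lo, hi = force_params.force_bounds
    a = (lo - force_params.force_mean) / force_params.force_sd
    b = (hi - force_params.force_mean) / force_params.force_sd
    events: list[Event] = []
    t = 0.02
    while params.attachment_rate > 0:
        start = t + rng.exponential(1.0 / params.attachment_rate)
        f = float(
            _stats.truncnorm.rvs(
                a, b, loc=force_params.force_mean, scale=force_params.force_sd,
                random_state=rng,
            )
        )
        w = (
            rng.exponential(1.0 / params.substep2_rate)
            if params.substep2_rate > 0
            else np.inf
        )
        rate = force_params.k0 * np.exp(-f * force_params.d_bell / force_params.kT)
        stop = start + w + rng.exponential(1.0 / rate)
        if not np.isfinite(stop) or stop > params.duration - 0.02:
            break
        events.append(
            Event(
                start=start, stop=stop, substep1=params.substep1,
                substep2=params.substep2, total_step=params.substep1 + params.substep2,
                mean_force=f, substep2_time=start + w,
            )
        )
        t = stop
    bound = np.zeros(n, dtype=bool)
    force = np.empty(n)
    for ev in events:
        bound[int(round(ev.start * fs)) : int(round(ev.stop * fs))] = True
    x1, x2 = _ar1_channels(params, bound, rng)
    force = rng.normal(0.0, force_noise_sd, n)
    for ev in events:
        force[int(round(ev.start * fs)) : int(round(ev.stop * fs))] += ev.mean_force
    trace = TrapTrace(
        motor_pos=x1,
        transducer_pos=x2,
        sampling_rate=fs,
        force=force,
        atp=params.atp,
        mode="isometric",
        stiffness=params.trap_stiffness,
    )
    truth = EventSet(
        events=events,
        dead_time=0.0,
        source={"generator": "simulate_isometric_trace", "seed": params.seed},
    )
    return trace, truth


# ---------------------------------------------------------------------------
# isometric force-lifetime pairs


def simulate_isometric_events(params: ForceEventSimParams) -> np.ndarray:
    """Draw (force, lifetime) pairs from the Bell detachment model.

    Each event draws a force F from the truncated normal, then a lifetime
    from an exponential with rate ``k0 * exp(-F * d_bell / kT)``.  Lifetimes
    below ``dead_time`` are discarded and regeneration continues until
    ``n_events`` survive.  Returns an (n_events, 2) array of (F pN, t s).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.force_bounds
    a = (lo - params.force_mean) / params.force_sd
    b = (hi - params.force_mean) / params.force_sd
    out = np.empty((params.n_events, 2))
    filled = 0
    while filled < params.n_events:
        m = max(params.n_events - filled, 64)
        f = _stats.truncnorm.rvs(
            a, b, loc=params.force_mean, scale=params.force_sd, size=m, random_state=rng
        )
        rate = params.k0 * np.exp(-f * params.d_bell / params.kT)
        t = rng.exponential(1.0 / rate)
        keep = t >= params.dead_time
        k = min(int(keep.sum()), params.n_events - filled)
        out[filled : filled + k, 0] = f[keep][:k]
        out[filled : filled + k, 1] = t[keep][:k]
        filled += k
    return out


def simulate_exponential_mixture(
    rates: Sequence[float],
    weights: Sequence[float],
    n: int,
    seed: int = 0,
    dead_time: float = 0.0,
) -> np.ndarray:
    """Draw dwell times from a finite exponential mixture.

    Values below ``dead_time`` are censored and regenerated, as in detection.
    Used to emulate attachment durations and reattachment gap times.
    """
    rates = np.asarray(rates, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be > 0")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(n - filled, 64)
        comp = rng.choice(rates.size, size=m, p=weights)
        t = rng.exponential(1.0 / rates[comp])
        t = t[t >= dead_time]
        k = min(t.size, n - filled)
        out[filled : filled + k] = t[:k]
        filled += k
    return out


# ---------------------------------------------------------------------------
# transients


def _transient_timebase(params: TransientSimParams) -> np.ndarray:
    if params.split_timebase is not None:
        segs = list(params.split_timebase)
        durs = list(params.split_durations or [])
        if len(durs) != len(segs):
            raise ValueError("split_durations must accompany split_timebase")
        t = []
        t0 = 0.0
        for npts, d in zip(segs, durs):
            t.append(t0 + (np.arange(npts) + 1) * (d / npts))
            t0 += d
        return np.concatenate(t)
    return np.linspace(0.0, params.duration, params.n_points)


def simulate_transient(
    params: TransientSimParams,
) -> Transient | tuple[Transient, Transient]:
    """Simulate a multi-exponential transient with optional photobleaching.

    The signal is ``total_amplitude * sum_i a_i exp(-k_i t)`` plus an
    additive bleaching exponential of amplitude
    ``bleach_fraction * total_amplitude`` at ``bleach_rate``, plus iid
    Gaussian noise.  For ``kind='mant_turnover'`` a paired blank trace
    containing only the bleach component (with independent noise) is also
    returned, for blank subtraction downstream.
    """
    params.validate()
    if params.duration * min(params.rates) < 1.0:
        log.warning("decay poorly sampled")
    rng = np.random.default_rng(params.seed)
    t = _transient_timebase(params)
    amps = np.asarray(params.fractional_amplitudes, dtype=float)
    decay = params.total_amplitude * sum(
        a * np.exp(-k * t) for a, k in zip(amps, params.rates)
    )
    bleach = (
        params.bleach_fraction
        * params.total_amplitude
        * np.exp(-params.bleach_rate * t)
    )
    sample = Transient(
        time=t,
        signal=decay + bleach + rng.normal(0.0, params.noise_sd, t.size),
        kind=params.kind,
        split_timebase=params.split_timebase,
        meta={"ground_truth_rates": tuple(params.rates), "seed": params.seed},
    )
    if params.kind == "mant_turnover":
        blank = Transient(
            time=t.copy(),
            signal=bleach + rng.normal(0.0, params.noise_sd, t.size),
            kind=params.kind,
            split_timebase=params.split_timebase,
            meta={"blank": True, "seed": params.seed},
        )
        return sample, blank
    return sample


def simulate_atpase_progress(
    vmax: float,
    km: float,
    tf_concs: Sequence[float],
    heads: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration: float = 110.0,
    n_points: int = 111,
    a0: float = 1.0,
) -> list[Transient]:
    """Linear NADH-absorbance progress curves obeying Michaelis-Menten kinetics.

    One curve per thin-filament concentration (µM).  The absorbance slope is
    ``-rate * heads * 6220e-6`` AU/s (1 cm path, heads in µM) with
    ``rate = vmax * [TF] / (km + [TF])`` per head, plus iid Gaussian noise.
    """
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be > 0")
    if heads <= 0:
        raise ValueError("heads must be > 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    out = []
    for conc in tf_concs:
        rate = vmax * conc / (km + conc)
        slope = -rate * heads * 1e-6 * NADH_EXTINCTION
        sig = a0 + slope * t
        if noise_sd > 0:
            sig = sig + rng.normal(0.0, noise_sd, t.size)
        out.append(
            Transient(
                time=t,
                signal=sig,
                kind="nadh",
                meta={"tf_uM": float(conc), "heads_uM": float(heads), "true_rate": rate},
            )
        )
    return out


def simulate_gliding_velocities(
    fractions: Sequence[float],
    model,
    n_per_fraction: int = 30,
    noise_sd: float = 0.15,
    seed: int = 0,
    frames_range: tuple[int, int] = (10, 100),
):
    """Per-filament gliding velocities for two-species myosin mixtures.

    ``model`` is a :class:`trapcycle.cycle_model.MixtureModel`.  Velocities
    are Normal(v(x), noise_sd) truncated at 0; each filament also carries a
    trajectory length in frames (uniform in ``frames_range``), used by the
    weighted Gaussian summary downstream.  Returns a DataFrame with columns
    filament_id, frames, velocity_um_s, fraction_slow.
    """
    import pandas as pd

    from .cycle_model import mixture_velocity

    rng = np.random.default_rng(seed)
    rows = []
    fid = 0
    for x in fractions:
        v = mixture_velocity(x, model)
        for _ in range(n_per_fraction):
            vel = v if noise_sd == 0 else max(rng.normal(v, noise_sd), 0.0)
            rows.append(
                {
                    "filament_id": fid,
                    "frames": int(rng.integers(*frames_range)),
                    "velocity_um_s": vel,
                    "fraction_slow": float(x),
                }
            )
            fid += 1
    return pd.DataFrame(rows)
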