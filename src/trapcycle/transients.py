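"""Stopped-flow and plate-style transient fitting.

Single/double exponential decays by nonlinear least squares (with residual
-resampling bootstrap CIs), photobleach blank subtraction, linear NADH
slopes with unit conversion to per-head ATPase rates, Michaelis-Menten
fits, and the low-substrate second-order binding line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .datatypes import Transient
from .synthkin import NADH_EXTINCTION

__all__ = [
    "DecayFit",
    "MMFit",
    "FitError",
    "fit_exp_decay",
    "correct_photobleach",
    "nadh_slope_to_rate",
    "fit_michaelis_menten",
    "second_order_binding",
]


class FitError(RuntimeError):
    """A transient fit failed to converge or is unidentifiable."""


@dataclass
class DecayFit:
    """Multi-exponential decay fit ``offset + sum_i A_i exp(-k_i t)``."""

    n_phases: int
    rates: tuple[float, ...]  # 1/s, ordered fast -> slow
    amplitudes: tuple[float, ...]  # AU, absolute
    fractional_amplitudes: tuple[float, ...]  # A_i / sum A
    offset: float
    rate_cis: tuple[tuple[float, float], ...]
    n_points: int


def _noise_sd(signal: np.ndarray) -> float:
    """High-frequency noise estimate from first differences."""
    if signal.size < 3:
        return 0.0
    return float(np.std(np.diff(signal)) / np.sqrt(2.0))


def _decay_model(n_phases: int):
    if n_phases == 1:

        def f(t, off, a1, k1):
            return off + a1 * np.exp(-k1 * t)

    else:

        def f(t, off, a1, k1, a2, k2):
            return off + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)

    return f


def _decay_p0(t: np.ndarray, y: np.ndarray, n_phases: int) -> list[np.ndarray]:
    span = y[0] - y[-1]
    k_guess = 1.0 / max((t[-1] - t[0]) / 5.0, 1e-12)
    if n_phases == 1:
        base = np.array([y[-1], span, k_guess])
        scales = [1.0, 5.0, 0.2, 25.0, 0.04]
        return [base * np.array([1.0, 1.0, s]) for s in scales]
    base = np.array([y[-1], 0.5 * span, k_guess * 5.0, 0.5 * span, k_guess / 5.0])
    out = []
    for s in (1.0, 10.0, 0.1, 100.0):
        p = base.copy()
        p[2] *= s
        out.append(p)
    return out


def fit_exp_decay(
    tr: Transient,
    n_phases: int = 1,
    n_boot: int = 0,
    seed: int = 0,
) -> DecayFit:
    """Nonlinear least-squares fit of a 1- or 2-exponential decay.

    Requires at least 20 points and a signal span exceeding three times the
    estimated noise SD (otherwise the amplitude/rate are unidentifiable and
    :class:`FitError` is raised).  Bootstrap CIs (optional) resample
    residuals on the fixed time design.  Rates are reported fast -> slow
    with absolute and fractional amplitudes.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = tr.time, tr.signal
    if t.size < 20:
        raise ValueError("need at least 20 points")
    noise = _noise_sd(y)
    if np.ptp(y) <= 3.0 * noise or np.ptp(y) == 0.0:
        raise FitError("signal span below 3x noise SD: decay unidentifiable")
    model = _decay_model(n_phases)

    def _fit(yy: np.ndarray) -> np.ndarray:
        last_err: Exception | None = None
        for p0 in _decay_p0(t, yy, n_phases):
            try:
                popt, _ = optimize.curve_fit(model, t, yy, p0=p0, maxfev=20000)
                if np.all(np.isfinite(popt)) and np.all(popt[2::2] > 0):
                    return popt
            except Exception as err:  # pragma: no cover - diagnostic path
                last_err = err
        raise FitError(f"decay fit did not converge: {last_err}")

    popt = _fit(y)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        resid = y - model(t, *popt)
        boots = []
        for _ in range(n_boot):
            yb = model(t, *popt) + rng.choice(resid, resid.size, replace=True)
            try:
                boots.append(_fit(yb))
            except FitError:
                continue
        boots = np.array(boots)
    else:
        boots = None

    def _order(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        amps, rates = p[1::2], p[2::2]
        o = np.argsort(-rates)  # fast first
        return amps[o], rates[o]

    amps, rates = _order(popt)
    if boots is not None and boots.size:
        brates = np.array([_order(b)[1] for b in boots])
        rate_cis = tuple(
            tuple(np.percentile(brates[:, i], [2.5, 97.5])) for i in range(n_phases)
        )
    else:
        rate_cis = tuple((float("nan"), float("nan")) for _ in range(n_phases))
    total = float(np.sum(amps))
    return DecayFit(
        n_phases=n_phases,
        rates=tuple(float(k) for k in rates),
        amplitudes=tuple(float(a) for a in amps),
        fractional_amplitudes=tuple(float(a / total) for a in amps),
        offset=float(popt[0]),
        rate_cis=rate_cis,
        n_points=int(t.size),
    )


def correct_photobleach(sample: Transient, blank: Transient) -> Transient:
    """Pointwise blank subtraction to remove the photobleaching component.

    The blank (fluorophore alone) is interpolated onto the sample's time
    base when the bases differ; disjoint time ranges are an error.  The
    subtraction is unscaled, matching the measured-blank procedure.
    """
    if blank.time[-1] < sample.time[0] or blank.time[0] > sample.time[-1]:
        raise ValueError("sample and blank time ranges are disjoint")
    if blank.time.shape == sample.time.shape and np.allclose(blank.time, sample.time):
        b = blank.signal
    else:
        b = np.interp(sample.time, blank.time, blank.signal)
    meta = dict(sample.meta)
    meta["bleach_corrected"] = True
    return Transient(
        time=sample.time.copy(),
        signal=sample.signal - b,
        kind=sample.kind,
        split_timebase=sample.split_timebase,
        meta=meta,
    )


def nadh_slope_to_rate(
    tr: Transient,
    heads: float,
    extinction: float = NADH_EXTINCTION,
    path: float = 1.0,
) -> float:
    """Per-head ATPase rate from a linear NADH-absorbance progress curve.

    Fits a least-squares line to the absorbance; the ATP-hydrolysis rate is
    ``|slope| / (extinction * path * heads)`` with heads in µM (so the µM ->
    M factor 1e-6 is applied internally).  A slope that is positive beyond
    its standard error draws a warning (NADH should be consumed).
    """
    if heads <= 0:
        raise ValueError("heads must be > 0")
    if tr.n_points < 10:
        raise ValueError("need at least 10 points")
    res = stats.linregress(tr.time, tr.signal)
    if res.slope > 0 and res.stderr and res.slope > 2.0 * res.stderr:
        warnings.warn("NADH increasing", UserWarning)
    return float(-res.slope / (extinction * path * heads * 1e-6))


@dataclass
class MMFit:
    """Michaelis-Menten fit ``v = Vmax * x / (Km + x)``."""

    vmax: float  # 1/s
    km: float  # µM
    vmax_ci: tuple[float, float]
    km_ci: tuple[float, float]
    n_points: int
    flags: tuple[str, ...] = ()


def _mm(x, vmax, km):
    return vmax * x / (km + x)


def fit_michaelis_menten(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> MMFit:
    """Nonlinear least-squares Michaelis-Menten fit with pair bootstrap CIs.

    Requires at least four distinct concentrations.  Data with no curvature
    leave Km unbounded and raise :class:`FitError`; saturated data (y at
    Vmax everywhere) pin Km at the zero boundary, which is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct concentrations")

    def _fit(xx, yy):
        km0 = float(np.median(xx[xx > 0])) if np.any(xx > 0) else 1.0
        best, best_sse = None, np.inf
        for km_start in (km0, km0 / 20.0, 20.0 * km0):
            try:
                popt, _ = optimize.curve_fit(
                    _mm, xx, yy, p0=(float(np.max(yy)), km_start),
                    bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
                )
            except Exception:
                continue
            sse = float(np.sum((_mm(xx, *popt) - yy) ** 2))
            if sse < best_sse:
                best, best_sse = popt, sse
        if best is None:
            raise FitError("Michaelis-Menten fit failed to converge")
        return best

    try:
        vmax, km = _fit(x, y)
    except Exception as err:
        raise FitError(f"Michaelis-Menten fit failed: {err}") from err
    flags = []
    if km > 50.0 * np.max(x):
        raise FitError("Km unbounded: data show no curvature")
    if km < 1e-6 * max(np.max(x), 1.0):
        flags.append("km_at_zero_boundary")
    if vmax <= 0 or km < 0:
        raise FitError("non-physical Michaelis-Menten optimum")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = x.size
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            if np.unique(x[idx]).size < 3:
                continue
            try:
                boots.append(_fit(x[idx], y[idx]))
            except Exception:
                continue
        boots = np.array(boots)
        vmax_ci = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        km_ci = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
    else:
        vmax_ci = (float("nan"), float("nan"))
        km_ci = (float("nan"), float("nan"))
    return MMFit(
        vmax=float(vmax),
        km=float(km),
        vmax_ci=vmax_ci,
        km_ci=km_ci,
        n_points=int(x.size),
        flags=tuple(flags),
    )


@dataclass
class LineFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    n_points: int


def second_order_binding(x: Sequence[float], kobs: Sequence[float]) -> LineFit:
    """Second-order binding constant from the low-substrate kobs line.

    Least-squares line through (concentration, kobs); the slope (µM^-1 s^-1)
    is the apparent second-order rate constant, valid only in the
    low-substrate linear range of the hyperbola.  The 95% CI uses the
    t distribution on the slope standard error.
    """
    x = np.asarray(x, dtype=float)
    kobs = np.asarray(kobs, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    res = stats.linregress(x, kobs)
    tcrit = stats.t.ppf(0.975, x.size - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return LineFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(float(ci[0]), float(ci[1])),
        n_points=int(x.size),
    )
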