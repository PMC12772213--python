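"""Mechanochemical cycle arithmetic for two-headed cardiac myosin fragments.

Implements the quantitative relations that tie the measured rates together:

* the SRX/DRX rapid-equilibrium relation ``k_obs = k_DRX * K_EQ`` from
  mantATP single-turnover rates, with the DRX head fraction
  ``K_EQ / (1 + K_EQ)``;
* the unloaded duty ratio ``DR = (1/k_ADP) / (1/Vmax) = Vmax / k_ADP``
  (the AM.ADP dwell as a fraction of the whole-population cycle time) and
  its single-headed (S1) rescaling by the DRX fraction;
* the Bell relation ``k(F) = k0 exp(-F d / kT)`` and force-dependent power
  ``P(F) = F * d_step * k_ADP(F)``, with and without the duty-ratio
  correction (the corrected curve collapses to ``F * d_step * Vmax`` —
  the Bell factor cancels exactly);
* a two-species mixed-motor gliding model in which a slow, high-duty
  species drags the filament driven by the fast species.

Note the two distinct distance symbols: ``d_bell`` (Bell distance
parameter, the mechanochemical compliance of detachment) and ``step_size``
(the working-stroke displacement entering the power relation).  They are
stored as separate fields and never interchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .synthkin import KT_20C
from .trap_mech import BellFit

__all__ = [
    "TurnoverResult",
    "CycleParams",
    "MixtureModel",
    "compute_keq",
    "duty_ratio",
    "s1_duty_ratio",
    "bell_rate",
    "power_curve",
    "mixture_velocity",
    "fit_mixture",
    "summarize_gliding",
]


@dataclass
class TurnoverResult:
    """SRX/DRX partition inferred from single-turnover rates."""

    k_obs_hmm: float  # 1/s, intact-tail (HMM) single-turnover rate
    k_drx: float  # 1/s, S1 / papain-digested elementary release rate
    K_eq: float  # [DRX]/[SRX]
    frac_drx: float  # K / (1 + K)


@dataclass
class CycleParams:
    """Per-construct mechanochemical summary feeding the cycle arithmetic."""

    k_adp: float  # 1/s, ADP release at zero load
    vmax: float  # 1/s, per-head steady-state ATPase
    duty_ratio: float
    step_size: float  # nm, working-stroke displacement (power relation d)
    bell: Optional[BellFit] = None  # k0 and d_bell (Bell relation d)
    frac_drx: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_ratio <= 1.0:
            raise ValueError("duty_ratio must lie in (0, 1]")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")


def compute_keq(k_obs_hmm: float, k_drx: float) -> TurnoverResult:
    """SRX/DRX equilibrium constant from the rapid-equilibrium relation.

    With interconversion fast relative to turnover, the observed HMM
    single-turnover rate is ``k_obs = k_DRX * K_EQ`` with
    ``K_EQ = [DRX]/[SRX]``, so ``K_EQ = k_obs / k_DRX``; the DRX head
    fraction is ``K_EQ / (1 + K_EQ)``.
    """
    if k_obs_hmm <= 0 or k_drx <= 0:
        raise ValueError("rates must be positive")
    if k_obs_hmm > k_drx:
        raise ValueError("HMM turnover exceeds S1 rate")
    K = k_obs_hmm / k_drx
    return TurnoverResult(
        k_obs_hmm=k_obs_hmm, k_drx=k_drx, K_eq=K, frac_drx=K / (1.0 + K)
    )


def duty_ratio(k_adp: float, vmax: float) -> float:
    """Unloaded duty ratio: strong-binding dwell over whole-cycle time.

    ``DR = (1/k_ADP) / (1/Vmax) = Vmax / k_ADP``, taking 1/Vmax as the
    cycle time of the whole head population (SRX dwell included) and the
    AM.ADP lifetime 1/k_ADP as the strong-binding time.
    """
    if k_adp <= 0 or vmax <= 0:
        raise ValueError("rates must be positive")
    if vmax >= k_adp:
        raise ValueError("strong-state time exceeds cycle time")
    return vmax / k_adp


def s1_duty_ratio(dr_hmm: float, frac_drx: float) -> float:
    """Duty ratio of the available (DRX) heads only.

    S1 cannot populate the folded-back state, so its duty ratio is the HMM
    value rescaled by the DRX fraction: ``DR_S1 = DR_HMM / frac_drx``.
    """
    if not 0.0 < dr_hmm < 1.0 or not 0.0 < frac_drx <= 1.0:
        raise ValueError("dr_hmm and frac_drx must lie in (0, 1)")
    out = dr_hmm / frac_drx
    if out > 1.0:
        raise ValueError("implied S1 duty ratio exceeds 1")
    return out


def bell_rate(F, k0: float, d_bell: float, kT: float = KT_20C):
    """Force-dependent detachment rate ``k0 * exp(-F * d_bell / kT)``."""
    if kT <= 0:
        raise ValueError("kT must be > 0")
    return k0 * np.exp(-np.asarray(F, dtype=float) * d_bell / kT)


def power_curve(
    F_grid: Sequence[float], params: CycleParams, dr_corrected: bool = False
) -> np.ndarray:
    """Force-dependent power ``P(F) = F * d_step * k_ADP(F)`` in pN*nm/s.

    ``k_ADP(F)`` is the Bell rate from ``params.bell``.  With the
    duty-ratio correction the curve is multiplied by
    ``DR(F) = Vmax / k_ADP(F)``, so the Bell factor cancels and the
    corrected power is exactly ``F * d_step * Vmax`` (linear in F).
    """
    F = np.asarray(F_grid, dtype=float)
    if dr_corrected:
        return F * params.step_size * params.vmax
    if params.bell is None:
        raise ValueError("uncorrected power needs Bell parameters")
    kf = bell_rate(F, params.bell.k0, params.bell.d_bell, params.bell.kT)
    return F * params.step_size * kf


@dataclass
class MixtureModel:
    """Two-species gliding force balance with one drag-shape parameter.

    ``drag_weight`` is the relative attachment-flux x force weight of the
    slow species; larger values make small mole fractions of the slow
    species dominate the filament velocity.
    """

    v_fast: float = 1.6  # µm/s
    v_slow: float = 0.46  # µm/s
    drag_weight: float = 1.0  # >= 0

    def __post_init__(self) -> None:
        if not self.v_fast > self.v_slow > 0:
            raise ValueError("require v_fast > v_slow > 0")
        if self.drag_weight < 0:
            raise ValueError("drag_weight must be >= 0")


def mixture_velocity(x, model: MixtureModel):
    """Steady gliding velocity of a filament over a two-species motor mix.

    Solves the force balance in which the fast species (mole fraction
    ``1 - x``) drives with force ``(1 - v/v_fast)`` per unit flux while the
    slow species resists with weight ``w`` and an attachment flux
    proportional to v (its on-time per encounter scales as 1/v):

        ``(1 - x)(1 - v/v_fast) + x w (v/v_slow)(1 - v/v_slow) = 0``

    which is quadratic in v; the root in ``[v_slow, v_fast]`` is returned.
    Endpoints are exact: ``v(0) = v_fast``, ``v(1) = v_slow``.
    """
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any((xs < 0) | (xs > 1)):
        raise ValueError("mole fraction must lie in [0, 1]")
    vf, vs, w = model.v_fast, model.v_slow, model.drag_weight
    out = np.empty_like(xs)
    tol = 1e-9 * vf
    for i, xi in enumerate(xs):
        if xi == 0.0:
            out[i] = vf
            continue
        if xi == 1.0:
            out[i] = vs
            continue
        a = -xi * w / vs**2
        b = -(1.0 - xi) / vf + xi * w / vs
        c = 1.0 - xi
        if a == 0.0:  # w == 0: weightless slow species
            out[i] = -c / b if b != 0 else vf
            continue
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("no real root in the force balance")
        roots = ((-b + np.sqrt(disc)) / (2 * a), (-b - np.sqrt(disc)) / (2 * a))
        sel = [r for r in roots if vs - tol <= r <= vf + tol]
        if not sel:
            raise ValueError("no root in [v_slow, v_fast]")
        out[i] = min(max(sel[0], vs), vf)
    return out[0] if np.isscalar(x) or np.ndim(x) == 0 else out


def fit_mixture(
    data: Sequence[tuple[float, float]],
    v_fast: Optional[float] = None,
    v_slow: Optional[float] = None,
) -> MixtureModel:
    """Least-squares fit of the mixed-motor model to (x, velocity) pairs.

    ``drag_weight`` is always fitted (over its log); the pure-species
    endpoint velocities are fitted too unless given, in which case they are
    held fixed.
    """
    arr = np.asarray(data, dtype=float)
    x, v = arr[:, 0], arr[:, 1]
    fit_ends = v_fast is None or v_slow is None
    vf0 = v_fast if v_fast is not None else float(np.max(v))
    vs0 = v_slow if v_slow is not None else float(max(np.min(v), 1e-3))

    def unpack(theta):
        if fit_ends:
            lw, lvf, lvs = theta
            return MixtureModel(
                v_fast=float(np.exp(lvf)),
                v_slow=float(np.exp(lvs)),
                drag_weight=float(np.exp(lw)),
            )
        return MixtureModel(v_fast=vf0, v_slow=vs0, drag_weight=float(np.exp(theta[0])))

    def resid(theta):
        try:
            m = unpack(theta)
        except ValueError:
            return np.full(v.size, 1e6)
        return mixture_velocity(x, m) - v

    theta0 = [0.0] + ([np.log(vf0), np.log(vs0)] if fit_ends else [])
    sol = optimize.least_squares(resid, theta0, method="lm" if not fit_ends else "trf")
    return unpack(sol.x)


def summarize_gliding(table, weighted: bool = True):
    """Gaussian summary of per-filament velocities for each mole fraction.

    The velocity distribution at each ``fraction_slow`` is summarized by a
    (trajectory-length-weighted, by default) Gaussian mean and SD, the
    standard reduction of tracked-filament data.  Returns a DataFrame with
    columns fraction_slow, mean_velocity_um_s, sd_velocity_um_s, n.
    """
    import pandas as pd

    rows = []
    for frac, grp in table.groupby("fraction_slow"):
        v = grp["velocity_um_s"].to_numpy(dtype=float)
        wts = (
            grp["frames"].to_numpy(dtype=float)
            if weighted and "frames" in grp
            else np.ones_like(v)
        )
        mean = np.average(v, weights=wts)
        sd = np.sqrt(np.average((v - mean) ** 2, weights=wts))
        rows.append(
            {
                "fraction_slow": float(frac),
                "mean_velocity_um_s": float(mean),
                "sd_velocity_um_s": float(sd),
                "n": int(v.size),
            }
        )
    return pd.DataFrame(rows).sort_values("fraction_slow", ignore_index=True)
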