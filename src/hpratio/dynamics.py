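"""Numerical integration of the producer-herbivore dynamics.

Two variants of the two-species system are integrated:

``lv`` (Lotka-Volterra)
    Constant specific production ``g`` and linear (type I) grazing ``f``:

        dP/dt = (g - x) P - f P H
        dH/dt = k f P H - m H

    Neutrally stable cycles around the fixed point
    ``P* = m / (k f)``, ``H* = (g - x) / f``.  The temporal mean of each
    state variable over a whole number of cycles equals its equilibrium
    value, which is what justifies using time-averaged field biomasses in
    the equilibrium framework.

``rm`` (Rosenzweig-MacArthur)
    Logistic production ``g(P) = g (1 - P/K)`` and Holling type II grazing
    written as ``f(P) P = f_max P / (h_s + P)`` with ``f_max = f * h_s`` so
    that the low-density per-capita grazing rate matches the LV coefficient
    ``f``.  Beyond the Hopf bifurcation this produces sustained limit
    cycles.

Biomasses are in gC m^-2 and time in days throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .core import CommunityParams

__all__ = [
    "SimConfig",
    "Trajectory",
    "SimulationError",
    "simulate",
    "lv_equilibrium",
    "temporal_mean",
    "windowed_mean",
]

#: Biomass below which a run is considered to have left the biologically
#: meaningful region; integration stops and reports the failing time.
EXTINCTION_FLOOR = 1e-12


class SimulationError(RuntimeError):
    """Integration failure or biomass underflow, carrying the failing time."""

    def __init__(self, message: str, time: Optional[float] = None):
        super().__init__(message)
        self.time = time


@dataclass
class SimConfig:
    """Configuration of one simulation run.

    ``carrying_capacity`` (K, gC m^-2) and ``half_saturation`` (h_s, gC m^-2)
    are required for the ``rm`` variant and ignored for ``lv``.
    """

    variant: Literal["lv", "rm"]
    params: CommunityParams
    p0: float
    h0: float
    t_end: float
    output_step: float = 0.1
    carrying_capacity: Optional[float] = None
    half_saturation: Optional[float] = None
    rtol: float = 1e-6
    atol: float = 1e-12

    def __post_init__(self) -> None:
        if self.variant not in ("lv", "rm"):
            raise ValueError(f"variant must be 'lv' or 'rm', got {self.variant!r}")
        if not (self.p0 > 0 and self.h0 > 0):
            raise ValueError("initial biomasses must be positive")
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if not self.output_step > 0:
            raise ValueError("output_step must be positive")
        if self.variant == "rm":
            if self.carrying_capacity is None or self.half_saturation is None:
                raise ValueError(
                    "rm variant requires carrying_capacity and half_saturation"
                )
            if self.carrying_capacity <= 0 or self.half_saturation <= 0:
                raise ValueError("K and h_s must be positive")
        else:
            if self.carrying_capacity is not None or self.half_saturation is not None:
                raise ValueError("lv variant takes no K or h_s")


@dataclass
class Trajectory:
    """Simulated time series of producer and herbivore biomass."""

    times: np.ndarray
    p_series: np.ndarray
    h_series: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_series = np.asarray(self.p_series, dtype=float)
        self.h_series = np.asarray(self.h_series, dtype=float)
        if not (len(self.times) == len(self.p_series) == len(self.h_series)):
            raise ValueError("times, p_series, h_series must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.p_series < 0) or np.any(self.h_series < 0):
            raise ValueError("biomasses must be nonnegative")


def lv_equilibrium(params: CommunityParams) -> tuple[float, float]:
    """LV coexistence fixed point (P*, H*) = (m/(k f), (g - x)/f)."""
    if params.g <= params.x:
        raise ValueError("g <= x: no positive equilibrium")
    return params.m / (params.k * params.f), (params.g - params.x) / params.f


def _rhs(variant: str, cfg: SimConfig):
    p = cfg.params
    if variant == "lv":

        def rhs(t, y):
            P, H = y
            return [(p.g - p.x) * P - p.f * P * H, p.k * p.f * P * H - p.m * H]

    else:
        K = cfg.carrying_capacity
        hs = cfg.half_saturation
        fmax = p.f * hs  # matches LV grazing slope as P -> 0

        def rhs(t, y):
            P, H = y
            graze = fmax * P / (hs + P)
            return [
                p.g * (1.0 - P / K) * P - p.x * P - graze * H,
                p.k * graze * H - p.m * H,
            ]

    return rhs


def simulate(config: SimConfig) -> Trajectory:
    """Integrate the configured system with adaptive Runge-Kutta.

    Raises :class:`SimulationError` (with the failing time) if either
    biomass crosses the extinction floor or the integrator fails.
    """
    times = np.arange(0.0, config.t_end + 0.5 * config.output_step, config.output_step)
    times = times[times <= config.t_end]

    def extinct(t, y):
        return min(y) - EXTINCTION_FLOOR

    extinct.terminal = True
    extinct.direction = -1

    sol = solve_ivp(
        _rhs(config.variant, config),
        (0.0, config.t_end),
        [config.p0, config.h0],
        t_eval=times,
        rtol=config.rtol,
        atol=config.atol,
        method="RK45",
        events=extinct,
        dense_output=False,
    )
    if sol.status == 1:  # event: extinction floor crossed
        t_fail = float(sol.t_events[0][0])
        raise SimulationError(
            f"biomass fell below extinction floor {EXTINCTION_FLOOR:g} "
            f"at t = {t_fail:.4g} d",
            time=t_fail,
        )
    if not sol.success:
        t_fail = float(sol.t[-1]) if len(sol.t) else 0.0
        raise SimulationError(
            f"integration failed at t = {t_fail:.4g} d: {sol.message}", time=t_fail
        )
    P = np.clip(sol.y[0], 0.0, None)
    H = np.clip(sol.y[1], 0.0, None)
    return Trajectory(times=sol.t, p_series=P, h_series=H)


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Quadratic refinement of a discrete peak at index i."""
    if i == 0 or i == len(y) - 1:
        return float(t[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom == 0:
        return float(t1)
    # equal-spacing vertex formula
    dt = 0.5 * (t2 - t0) / 2.0
    offset = 0.5 * (y0 - y2) / denom
    return float(t1 + offset * 2 * dt)


def _find_peaks(t: np.ndarray, y: np.ndarray, t_start: float) -> list[float]:
    """Times of local maxima of y after t_start (sign change of dy/dt)."""
    mask = t >= t_start
    ti, yi = t[mask], y[mask]
    if len(yi) < 3:
        return []
    d = np.diff(yi)
    peaks = []
    span = float(np.max(yi) - np.min(yi))
    for i in range(1, len(yi) - 1):
        if d[i - 1] > 0 and d[i] <= 0:
            # ignore flat-noise peaks on an essentially constant series
            if span > 0 and (yi[i] - np.min(yi)) > 1e-9 * max(span, 1e-30):
                peaks.append(_refine_peak(ti, yi, i))
    return peaks


def _mean_between(t: np.ndarray, y: np.ndarray, t0: float, t1: float) -> float:
    """Time-average of a sampled series over [t0, t1] by the trapezoid rule."""
    if t1 <= t0:
        raise ValueError("empty averaging window")
    inner = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inner], [t1]))
    yy = np.concatenate(
        ([np.interp(t0, t, y)], y[inner], [np.interp(t1, t, y)])
    )
    return float(np.trapezoid(yy, tt) / (t1 - t0))


def temporal_mean(
    traj: Trajectory, t_start: float = 0.0, n_cycles: int = 1
) -> tuple[float, float, float]:
    """Mean (P-bar, H-bar, H-bar/P-bar) over whole oscillation cycles.

    Cycles are delimited peak-to-peak on the producer series (peaks located
    by sign change of the discrete derivative and refined quadratically).
    For an essentially constant trajectory (relative range < 1e-6) plain
    whole-window means are returned instead.

    Raises ``ValueError`` naming the number of cycles found when the
    trajectory contains fewer than ``n_cycles`` complete cycles after
    ``t_start``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    t, P, H = traj.times, traj.p_series, traj.h_series
    scale = max(float(np.max(P)), 1e-300)
    if (np.max(P) - np.min(P)) / scale < 1e-6:
        # constant (equilibrium) trajectory: cycles are degenerate
        mask = t >= t_start
        pbar = float(np.mean(P[mask]))
        hbar = float(np.mean(H[mask]))
        return pbar, hbar, hbar / pbar
    peaks = _find_peaks(t, P, t_start)
    if len(peaks) < n_cycles + 1:
        found = max(len(peaks) - 1, 0)
        raise ValueError(
            f"requested {n_cycles} complete cycle(s) after t={t_start}, "
            f"found {found}"
        )
    t0, t1 = peaks[0], peaks[n_cycles]
    pbar = _mean_between(t, P, t0, t1)
    hbar = _mean_between(t, H, t0, t1)
    return pbar, hbar, hbar / pbar


def windowed_mean(
    traj: Trajectory, t_start: float, interval: float, n_samples: int
) -> tuple[float, float, float]:
    """Plain mean of point samples taken every ``interval`` days.

    Emulates a discrete field-sampling design (e.g. biweekly sampling,
    ``interval=14, n_samples=7``) rather than averaging over exact cycles.
    """
    if n_samples < 1 or interval <= 0:
        raise ValueError("need n_samples >= 1 and interval > 0")
    t_samples = t_start + interval * np.arange(n_samples)
    if t_samples[-1] > traj.times[-1] + 1e-9:
        raise ValueError(
            f"sampling design extends to t={t_samples[-1]:g} beyond the "
            f"trajectory end t={traj.times[-1]:g}"
        )
    P = np.interp(t_samples, traj.times, traj.p_series)
    H = np.interp(t_samples, traj.times, traj.h_series)
    pbar, hbar = float(np.mean(P)), float(np.mean(H))
    return pbar, hbar, hbar / pbar
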