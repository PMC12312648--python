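"""Stiff integration of compiled networks and circuit metrics.

Default solver tolerances are rtol=1e-9, atol=1e-12; gene-expression models
are stiff (per-step elongation rates of thousands per minute against protein
half-lives of minutes), so the default method is LSODA which switches to BDF
automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import null_space
from scipy.optimize import root
from scipy.signal import find_peaks

from .errors import NoLimitCycleError, NoSteadyStateError, SolverError, StateError
from .network import NetworkSpec

#: sentinel returned by switching_time when the threshold is never held
NOT_SWITCHED = math.inf

DEFAULT_RTOL = 1e-9
DEFAULT_ATOL = 1e-12


@dataclass
class Timecourse:
    """Simulation output: a time grid with one state row per output time."""

    times: np.ndarray
    states: np.ndarray
    species: List[str]
    fluxes: Optional[np.ndarray] = None
    dissipation: Optional[np.ndarray] = None

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise StateError("timecourse times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise StateError("timecourse states must be finite")

    def trace(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class CircuitMetrics:
    """Derived circuit quantities (units: molecules and minutes)."""

    steady_state: Optional[dict] = None
    switching_time: Optional[float] = None
    bistability_index: Optional[float] = None
    amplitude: Optional[float] = None
    period: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def integrate(
    net: NetworkSpec,
    x0: Optional[np.ndarray] = None,
    t_span: Tuple[float, float] = (0.0, 100.0),
    t_eval: Optional[np.ndarray] = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    record_fluxes: bool = False,
    record_dissipation: bool = False,
) -> Timecourse:
    """Integrate the compiled rate field over ``t_span``.

    Dynamic amounts that undershoot zero by less than 1e-9 are clipped;
    larger undershoot raises :class:`SolverError`, as does solver failure
    (with the last valid state attached).
    """
    if x0 is None:
        x0 = net.initial_state()
    x0 = np.asarray(x0, dtype=float)
    rhs = net.rate_field()
    f0 = rhs(t_span[0], x0)
    if not np.all(np.isfinite(f0)):
        raise StateError("non-finite derivative at the initial state")
    sol = solve_ivp(
        rhs, t_span, x0, method=method, t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise SolverError(
            f"solver failed: {sol.message}",
            last_time=sol.t[-1] if sol.t.size else t_span[0],
            last_state=sol.y[:, -1] if sol.t.size else x0,
        )
    states = sol.y.T
    if states.min() < -1e-9:
        raise SolverError(
            f"state went negative (min {states.min():.3e})",
            last_time=sol.t[-1],
            last_state=states[-1],
        )
    states = np.maximum(states, 0.0)
    # clamped-potential species keep their placeholder amount; restore x0
    tc = Timecourse(sol.t, states, net.species_names)
    if record_fluxes:
        tc.fluxes = np.array([net.fluxes(s) for s in states])
    if record_dissipation:
        tc.dissipation = np.array([net.power_dissipation(s) for s in states])
    return tc


def _steady_criterion(net: NetworkSpec, x: np.ndarray, atol: float) -> float:
    """Scale-free residual max |dx_i/dt| / (|x_i| + atol) over dynamic species."""
    f = net.rate_field()(0.0, x)
    dyn = np.array([s.is_dynamic for s in net.species])
    return float(np.max(np.abs(f[dyn]) / (np.abs(x[dyn]) + atol)))


def find_steady_state(
    net: NetworkSpec,
    x0: Optional[np.ndarray] = None,
    t_init: float = 100.0,
    max_doublings: int = 12,
    criterion: float = 1e-9,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Steady state by integrate-then-polish.

    Integrates over doubling horizons until the scale-free derivative
    criterion is met or a Newton polish (restricted to the moiety-consistent
    manifold, so conserved totals are preserved exactly) converges from the
    integration endpoint.  Oscillatory or divergent dynamics raise
    :class:`NoSteadyStateError`.
    """
    if x0 is None:
        x0 = net.initial_state()
    x = np.asarray(x0, dtype=float)
    dyn = np.array([s.is_dynamic for s in net.species])
    rhs = net.rate_field()

    # basis of admissible directions: dynamic subspace orthogonal to moieties
    moieties = net.conserved_moieties()
    E = np.eye(len(x))[:, dyn]
    if moieties:
        G = np.array(moieties)  # rows g, zero at chemostats
        Z = E @ null_space(G @ E)
    else:
        Z = E

    def polish(x_start: np.ndarray) -> Optional[np.ndarray]:
        if Z.shape[1] == 0:
            return x_start
        fun = lambda y: Z.T @ rhs(0.0, x_start + Z @ y)
        sol = root(fun, np.zeros(Z.shape[1]), method="hybr", tol=1e-13)
        if not sol.success:
            return None
        cand = x_start + Z @ sol.x
        if np.any(cand[dyn] < -1e-9):
            return None
        # the polish refines a converged endpoint; a large correction means
        # the root finder jumped to a different (possibly unstable) fixed
        # point, e.g. the symmetric saddle of an oscillating circuit
        rel_move = np.abs(cand[dyn] - x_start[dyn]) / (np.abs(x_start[dyn]) + atol + 1.0)
        if np.max(rel_move) > 1e-2:
            return None
        return np.maximum(cand, 0.0)

    horizon = t_init
    prev_end = None
    for _ in range(max_doublings):
        tc = integrate(net, x, t_span=(0.0, horizon), rtol=rtol, atol=atol)
        x = tc.states[-1]
        if _steady_criterion(net, x, atol) < criterion:
            return x
        cand = polish(x)
        if cand is not None and _steady_criterion(net, cand, atol) < criterion:
            return cand
        if prev_end is not None:
            # no contraction between successive horizons: likely oscillatory
            scale = np.abs(x[dyn]) + np.abs(prev_end[dyn]) + atol
            change = np.max(np.abs(x[dyn] - prev_end[dyn]) / scale)
            if change > 1e-3 and horizon > 100 * t_init:
                break
        prev_end = x
        horizon *= 2.0
    raise NoSteadyStateError(
        "trajectory did not converge to a steady state "
        f"(residual {_steady_criterion(net, x, atol):.2e}); "
        "oscillatory dynamics should use limit_cycle_metrics"
    )


def steady_state_distance(
    P1: np.ndarray, P2: np.ndarray, P1_star: float, P2_star: float
) -> np.ndarray:
    """Normalized distance d = sqrt(((P1-P1*)/P1*)^2 + ((P2-P2*)/P2*)^2)."""
    return np.sqrt(((P1 - P1_star) / P1_star) ** 2 + ((P2 - P2_star) / P2_star) ** 2)


def switching_time(
    tc: Timecourse,
    P1_star: float,
    P2_star: float,
    p1: str = "g1_P",
    p2: str = "g2_P",
    threshold: float = 0.01,
) -> float:
    """First time the distance d drops below the threshold and stays there.

    Arrival is required, not a first touch: the distance is monitored to the
    end of the trajectory.  Returns :data:`NOT_SWITCHED` (inf) if the
    threshold is never held.
    """
    if P1_star <= 0 or P2_star <= 0:
        raise StateError("steady-state targets must be positive")
    d = steady_state_distance(tc.trace(p1), tc.trace(p2), P1_star, P2_star)
    below = d < threshold
    # last index where d >= threshold; switched one sample later
    above = np.flatnonzero(~below)
    if above.size == 0:
        return float(tc.times[0])
    if above[-1] == len(d) - 1:
        return NOT_SWITCHED
    return float(tc.times[above[-1] + 1])


def bistability_index(
    net: NetworkSpec,
    ic_active: np.ndarray,
    ic_inactive: np.ndarray,
    species: str = "g1_P",
    **ss_kwargs,
) -> float:
    """Steady-state amount of the readout protein, active over inactive branch.

    Both initial conditions are relaxed to steady state; a monostable system
    returns 1 (both branches coincide).
    """
    i = net.species_index(species)
    x_active = find_steady_state(net, ic_active, **ss_kwargs)
    x_inactive = find_steady_state(net, ic_inactive, **ss_kwargs)
    return float(x_active[i] / x_inactive[i])


def limit_cycle_metrics(
    tc: Timecourse,
    species: str,
    peak_convergence: float = 1e-3,
    min_peaks: int = 4,
) -> Tuple[float, float]:
    """Amplitude (max - min) and period of the converged oscillation.

    The transient is discarded until consecutive peak heights differ by less
    than ``peak_convergence`` (0.1%); at least ``min_peaks`` converged peaks
    are required.  Amplitude is max - min over the converged cycles, period
    the mean peak-to-peak interval.
    """
    y = tc.trace(species)
    span = y.max() - y.min()
    if span <= 0:
        raise NoLimitCycleError(f"trace of {species!r} is constant")
    peaks, _ = find_peaks(y, prominence=0.01 * span)
    if peaks.size < min_peaks + 1:
        raise NoLimitCycleError(
            f"only {peaks.size} peaks found in {species!r}; trajectory too short"
        )
    heights = y[peaks]
    rel = np.abs(np.diff(heights)) / np.maximum(np.abs(heights[:-1]), 1e-30)
    converged_from = None
    for i in range(rel.size):
        if np.all(rel[i:] < peak_convergence):
            converged_from = i
            break
    if converged_from is None or peaks.size - converged_from < min_peaks:
        raise NoLimitCycleError(
            f"oscillation of {species!r} did not converge to a limit cycle"
        )
    sel = peaks[converged_from:]
    seg = y[sel[0] : sel[-1] + 1]
    amplitude = float(seg.max() - seg.min())
    period = float(np.mean(np.diff(tc.times[sel])))
    return amplitude, period
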