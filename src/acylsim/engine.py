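"""Steady-state search, feeding-step perturbation and time-course
integration for the fatty-acid / phospholipid model.

The feeding experiments are simulated exactly as in the study design:
integrate the network to its pre-feeding steady state, clamp the fed
acyl-CoA species to a fixed concentration in a stepwise fashion (a large
external fatty-acid reservoir keeps intracellular acyl-CoA effectively
constant), and follow the response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelSpec, StateVector

__all__ = [
    "FeedingProtocol",
    "Trajectory",
    "SteadyStateError",
    "FATTY_ACID_TO_COA",
    "find_steady_state",
    "apply_feeding_step",
    "simulate_timecourse",
    "run_feeding_experiment",
]

#: common-name fatty acids mapped to the acyl-CoA species their uptake and
#: FadD activation produce
FATTY_ACID_TO_COA = {
    "palmitate": "C16:0-CoA",
    "palmitoleate": "C16:1-CoA",
    "cis-vaccenate": "C18:1-CoA",
}

#: default intracellular acyl-CoA clamp (µM) reached after feeding the
#: fatty acid to 0.8 mM externally; a modelling choice, configurable
DEFAULT_CLAMP_UM = 30.0

#: default time of the stepwise acyl-CoA increase (s)
DEFAULT_T_STEP = 8000.0

_RTOL = 1e-8
_ATOL = 1e-12


class SteadyStateError(RuntimeError):
    """Raised when the residual criterion is not met by t_max."""

    def __init__(self, residual: float, tol: float, t_max: float):
        self.residual = residual
        super().__init__(
            f"steady state not reached by t={t_max} s: "
            f"residual {residual:.3e} > tol {tol:.3e}"
        )


@dataclass(frozen=True)
class FeedingProtocol:
    """Clamp ``fed_species`` to ``clamp_value`` µM from ``t_step`` s on."""

    fed_species: str
    clamp_value: float = DEFAULT_CLAMP_UM
    t_step: float = DEFAULT_T_STEP

    def __post_init__(self) -> None:
        if self.clamp_value < 0:
            raise ValueError("clamp_value must be >= 0")
        if self.fed_species not in FATTY_ACID_TO_COA.values():
            raise ValueError(
                f"fed_species must be one of {sorted(FATTY_ACID_TO_COA.values())}, "
                f"got {self.fed_species!r}"
            )

    @classmethod
    def for_fatty_acid(cls, name: str, clamp_value: float = DEFAULT_CLAMP_UM,
                       t_step: float = DEFAULT_T_STEP) -> "FeedingProtocol":
        if name not in FATTY_ACID_TO_COA:
            raise ValueError(
                f"unknown fatty acid {name!r}; choose from "
                f"{sorted(FATTY_ACID_TO_COA)}"
            )
        return cls(FATTY_ACID_TO_COA[name], clamp_value, t_step)


@dataclass
class Trajectory:
    """Time grid (s) by species concentration matrix (µM)."""

    model: ModelSpec
    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    protocol: FeedingProtocol | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.times), len(self.model.species)):
            raise ValueError("values shape does not match times x species")
        if self.protocol is not None and len(self.times) and \
                self.times[0] > self.protocol.t_step:
            raise ValueError("trajectory must start at or before t_step")

    def state_at(self, t: float) -> StateVector:
        i = int(np.argmin(np.abs(self.times - t)))
        return StateVector(self.model, self.values[i])

    def series(self, species: str) -> np.ndarray:
        return self.values[:, self.model.index[species]]

    def window_mean(self, species: str, t_lo: float, t_hi: float) -> float:
        mask = (self.times >= t_lo) & (self.times <= t_hi)
        if not mask.any():
            raise ValueError(f"no sample times in window [{t_lo}, {t_hi}]")
        return float(self.series(species)[mask].mean())


def _integrate(model: ModelSpec, y0: np.ndarray, t_span: tuple[float, float],
               t_eval: np.ndarray | None = None,
               rtol: float = _RTOL, atol: float = _ATOL):
    sol = solve_ivp(
        lambda t, y: model.rhs(y),
        t_span,
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed on [{t_span[0]}, {t_span[1]}] s: {sol.message}"
        )
    return sol


def _residual(model: ModelSpec, c: np.ndarray, atol: float = 1e-6) -> float:
    """max over non-clamped species of |dx/dt| / (|x| + atol), in 1/s."""
    dc = model.rhs(c)
    free = np.ones(len(model.species), dtype=bool)
    for s in model.clamped:
        free[model.index[s]] = False
    return float(np.max(np.abs(dc[free]) / (np.abs(c[free]) + atol)))


def find_steady_state(
    model: ModelSpec,
    state0: StateVector | None = None,
    t_max: float = 2e5,
    tol: float = 1e-8,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> StateVector:
    """Integrate until the relative rate residual falls below ``tol``.

    The residual is max over non-clamped species of |dx/dt|/(|x|+1e-6).
    Long integration (rather than algebraic root finding) is robust for
    this stiff network with its ACP and enzyme conservation constraints.
    """
    if state0 is None:
        state0 = model.initial_state()
    y = state0.values.copy()
    t, chunk = 0.0, 5000.0
    while t < t_max:
        t_next = min(t + chunk, t_max)
        sol = _integrate(model, y, (t, t_next), rtol=rtol, atol=atol)
        y = sol.y[:, -1]
        t = t_next
        if _residual(model, y) < tol:
            return StateVector(model, np.maximum(y, 0.0))
        chunk = min(chunk * 2, 5e4)
    res = _residual(model, y)
    if res < tol:
        return StateVector(model, np.maximum(y, 0.0))
    raise SteadyStateError(res, tol, t_max)


def apply_feeding_step(model: ModelSpec, state: StateVector,
                       protocol: FeedingProtocol) -> StateVector:
    """Set the fed acyl-CoA clamp; all other species stay continuous."""
    if protocol.fed_species not in model.clamped:
        raise ValueError(f"{protocol.fed_species} is not clampable in this model")
    stepped = state.copy()
    stepped[protocol.fed_species] = protocol.clamp_value
    return stepped


def default_time_grid(t_step: float = DEFAULT_T_STEP,
                      post_window: float = 3600.0) -> np.ndarray:
    """Reporting grid: sparse pre-step samples, then 10 s resolution for
    the first 10 min after the step (resolving the ~1 min response) and
    60 s afterwards."""
    pre = np.linspace(0.0, t_step, 41)
    fine = t_step + np.arange(10.0, 600.0 + 1e-9, 10.0)
    coarse = t_step + np.arange(660.0, post_window + 1e-9, 60.0)
    return np.unique(np.concatenate([pre, fine, coarse]))


def simulate_timecourse(
    model: ModelSpec,
    state0: StateVector,
    t_grid: Sequence[float],
    protocol: FeedingProtocol | None = None,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trajectory:
    """Integrate over ``t_grid``, restarting exactly at the feeding step."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly ascending")

    out = np.empty((len(t_grid), len(model.species)))
    y = state0.values.copy()
    t0 = t_grid[0]
    out_rows_done = 0

    def run_segment(t_start: float, t_end: float, eval_times: np.ndarray,
                    y_start: np.ndarray) -> np.ndarray:
        nonlocal out_rows_done
        if len(eval_times) and eval_times[0] == t_start:
            out[out_rows_done] = y_start
            out_rows_done += 1
            eval_times = eval_times[1:]
        if t_end > t_start:
            sol = _integrate(model, y_start, (t_start, t_end),
                             t_eval=eval_times if len(eval_times) else None,
                             rtol=rtol, atol=atol)
            if len(eval_times):
                out[out_rows_done:out_rows_done + len(eval_times)] = sol.y.T
                out_rows_done += len(eval_times)
            return sol.y[:, -1]
        return y_start

    if protocol is None or protocol.t_step >= t_grid[-1]:
        y = run_segment(t0, t_grid[-1], t_grid, y)
    else:
        t_step = protocol.t_step
        pre_mask = t_grid <= t_step
        y = run_segment(t0, t_step, t_grid[pre_mask], y)
        state_at_step = StateVector(model, np.maximum(y, 0.0))
        y = apply_feeding_step(model, state_at_step, protocol).values
        y = run_segment(t_step, t_grid[-1], t_grid[~pre_mask], y)

    return Trajectory(model, t_grid, np.maximum(out, 0.0), protocol)


@dataclass
class FeedingExperiment:
    """Bundle of pre-step steady state and stepped trajectory."""

    fatty_acid: str
    protocol: FeedingProtocol
    baseline: StateVector
    trajectory: Trajectory

    @property
    def t_step(self) -> float:
        return self.protocol.t_step


def run_feeding_experiment(
    model: ModelSpec,
    fatty_acid: str,
    clamp_value: float = DEFAULT_CLAMP_UM,
    t_step: float = DEFAULT_T_STEP,
    post_window: float = 3600.0,
    baseline: StateVector | None = None,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> FeedingExperiment:
    """Simulate one exogenous-fatty-acid feeding experiment.

    Finds the pre-feeding steady state (unless ``baseline`` is supplied),
    applies the acyl-CoA step at ``t_step`` and integrates a post-step
    window (default 60 min).
    """
    protocol = FeedingProtocol.for_fatty_acid(fatty_acid, clamp_value, t_step)
    if baseline is None:
        baseline = find_steady_state(model, rtol=rtol, atol=atol)
    grid = default_time_grid(t_step, post_window)
    traj = simulate_timecourse(model, baseline, grid, protocol,
                               rtol=rtol, atol=atol)
    return FeedingExperiment(fatty_acid, protocol, baseline, traj)
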