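"""Deterministic trajectory integration for both glucose-homeostasis models.

The growth-hormone clearance rate (w ~ 2000 /min) is three to four orders of
magnitude faster than the glucose and insulin dynamics, making the systems
stiff; LSODA, which switches to a BDF method on stiff intervals, is the
default integrator with tight tolerances (rtol = atol = 1e-8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
from scipy.integrate import ODEintWarning, odeint

from .models import (
    AnyParameters,
    Model1Parameters,
    Model2Parameters,
    StateVector,
    _coerce_state,
    _rhs1,
    _rhs2,
    _rhs_args,
    state_names,
)

__all__ = ["Trajectory", "IntegrationError", "simulate", "gh_closed_form"]

#: trajectories dipping below this are treated as integration failures
NEGATIVE_TOLERANCE = -1e-6


class IntegrationError(RuntimeError):
    """The ODE solver failed (step-size collapse, non-finite or materially
    negative state).  Distinct from :class:`~glucodyn.models.DomainError` so
    that calibration can map it onto an infinite cost."""


@dataclass(frozen=True)
class Trajectory:
    """A solved trajectory: ``states[j]`` is the state at ``times[j]``."""

    times: np.ndarray  # minutes, strictly increasing
    states: np.ndarray  # shape (len(times), state dimension)
    model_id: int

    @property
    def columns(self) -> tuple[str, ...]:
        return state_names(self.model_id)

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def glucose(self) -> np.ndarray:
        return self.column("GL")

    def to_frame(self, clip_negative: bool = True) -> pd.DataFrame:
        """Tabular view; tiny negative solver excursions are clipped to 0
        for reporting (never inside the integrator)."""
        states = np.clip(self.states, 0.0, None) if clip_negative else self.states
        frame = pd.DataFrame(states, columns=list(self.columns))
        frame.insert(0, "time_min", self.times)
        return frame

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _validate_times(times: Iterable[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a non-empty 1-d sequence")
    if t[0] < 0:
        raise ValueError("times must start at or after 0")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


def simulate(model_id: int,
             params: AnyParameters,
             init: Union[StateVector, Iterable[float]],
             times: Iterable[float],
             *,
             rtol: float = 1e-8,
             atol: float = 1e-8) -> Trajectory:
    """Integrate a model from ``t = 0`` and return the state at ``times``.

    ``init`` is the state at time 0.  ``times`` must be strictly increasing
    and non-negative; they need not coincide with solver steps (LSODA's
    internal interpolant supplies intermediate values), and if
    ``times[0] == 0`` the first returned state equals ``init`` exactly.

    Raises
    ------
    IntegrationError
        If the solver reports failure, or the solution becomes non-finite
        or materially negative (below ``NEGATIVE_TOLERANCE``).
    """
    if model_id == 1:
        if not isinstance(params, Model1Parameters):
            raise TypeError("model_id 1 requires Model1Parameters")
        rhs = _rhs1
    elif model_id == 2:
        if not isinstance(params, Model2Parameters):
            raise TypeError("model_id 2 requires Model2Parameters")
        rhs = _rhs2
    else:
        raise ValueError(f"unknown model_id {model_id!r}")

    t = _validate_times(times)
    y0 = _coerce_state(init, model_id)

    # odeint integrates from t_grid[0]; prepend 0 when absent.
    prepend = t[0] > 0
    t_grid = np.concatenate(([0.0], t)) if prepend else t
    if t_grid.size == 1:  # single observation at t=0
        states = y0[None, :].copy()
    else:
        with warnings.catch_warnings():
            # failures are detected via full_output and raised below
            warnings.simplefilter("ignore", ODEintWarning)
            states, info = odeint(
                rhs, y0, t_grid, args=_rhs_args(params),
                rtol=rtol, atol=atol, tfirst=True, full_output=True,
                mxstep=10000, printmessg=False,
            )
        if info["message"] != "Integration successful.":
            raise IntegrationError(f"ODE solver failed: {info['message']}")
        if prepend:
            states = states[1:]
    if not np.all(np.isfinite(states)):
        raise IntegrationError("ODE solution contains non-finite values")
    if states.min() < NEGATIVE_TOLERANCE:
        raise IntegrationError(
            f"ODE solution materially negative (min {states.min():.3e})"
        )
    if t[0] == 0.0:
        states[0] = y0  # exact initial condition
    return Trajectory(times=t, states=states, model_id=model_id)


def gh_closed_form(t: Union[float, np.ndarray], rho: float, w: float,
                   GH0: float) -> Union[float, np.ndarray]:
    """Exact solution ``rho/w + (GH0 - rho/w) * exp(-w*t)`` of the linear
    growth-hormone equation; used as an independent oracle for the solver."""
    if w <= 0:
        raise ValueError("w must be > 0")
    t = np.asarray(t, dtype=float)
    equilibrium = rho / w
    out = equilibrium + (GH0 - equilibrium) * np.exp(-w * t)
    return float(out) if out.ndim == 0 else out
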