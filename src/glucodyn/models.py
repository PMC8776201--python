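"""Candidate ODE models of the glucose homeostasis system.

Two minimal-model-style formulations of whole-body glucose dynamics in a
type 1 diabetic are provided:

* **Model 1** (no β-cells): insulin enters only through a constant
  subcutaneous bolus ``I0`` absorbed at rate ``psi``; state is
  ``(I, GL, GH)`` — insulin, glucose and growth hormone concentration.
* **Model 2** (with β-cells): insulin is secreted by a β-cell compartment
  with a sigmoidal glucose dependence; state is ``(beta, I, GL, GH)``.

Both share the glucose balance ``dGL/dt = a - (b + c*I)*GL + c*GH`` and a
linear growth-hormone equation ``dGH/dt = rho - w*GH``.  Units follow the
conventional mouse parameterisation: time in minutes, glucose in mg/dL,
insulin and growth hormone in mIU/mL, β-cell mass in mg.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, fields
from typing import Iterable, Mapping, TextIO, Union

import numpy as np
import yaml

__all__ = [
    "DomainError",
    "Model1Parameters",
    "Model2Parameters",
    "StateVector",
    "MODEL1_STATE_NAMES",
    "MODEL2_STATE_NAMES",
    "state_names",
    "model1_rhs",
    "model2_rhs",
    "model1_steady_state",
]

MODEL1_STATE_NAMES: tuple[str, ...] = ("I", "GL", "GH")
MODEL2_STATE_NAMES: tuple[str, ...] = ("beta", "I", "GL", "GH")


class DomainError(ValueError):
    """A state or parameter value lies outside the model's domain."""


def state_names(model_id: int) -> tuple[str, ...]:
    """Ordered state-variable names for a model (1 or 2)."""
    if model_id == 1:
        return MODEL1_STATE_NAMES
    if model_id == 2:
        return MODEL2_STATE_NAMES
    raise ValueError(f"unknown model_id {model_id!r}; expected 1 or 2")


# Units for every parameter symbol, used when serialising to config files.
_PARAM_UNITS: dict[str, str] = {
    "psi": "mIU/mL/min",
    "delta": "1/min",
    "I0": "mIU/mL",
    "a": "mg/dL/min",
    "b": "1/min",
    "c": "mL/mIU/min",
    "rho": "mIU/mL/min",
    "w": "1/min",
    "h": "dL/mg/min",
    "i": "dL^2/mg^2/min",
    "g": "1/min",
    "d": "mIU/mL/min/mg",
    "e": "mg^2/dL^2",
    "f": "1/min",
}


class _ParameterBase:
    """Shared validation and flat key-value (de)serialisation."""

    def _validate(self) -> None:
        for fld in fields(self):  # type: ignore[arg-type]
            value = getattr(self, fld.name)
            if not np.isfinite(value):
                raise DomainError(f"parameter {fld.name} must be finite, got {value!r}")
            if value < 0:
                raise DomainError(f"parameter {fld.name} must be >= 0, got {value!r}")

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}  # type: ignore[arg-type]

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]):
        return cls(**{str(k): float(v) for k, v in mapping.items()})

    def replace(self, **changes: float):
        return dataclasses.replace(self, **changes)  # type: ignore[type-var]

    def to_config(self, stream: Union[TextIO, None] = None) -> str:
        """Write a flat ``key: value`` config, one symbol per line, units in comments."""
        buf = io.StringIO()
        for name, value in self.to_dict().items():
            unit = _PARAM_UNITS.get(name, "dimensionless")
            buf.write(f"{name}: {value!r}  # {unit}\n")
        text = buf.getvalue()
        if stream is not None:
            stream.write(text)
        return text

    @classmethod
    def from_config(cls, source: Union[str, TextIO]):
        text = source if isinstance(source, str) else source.read()
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class Model1Parameters(_ParameterBase):
    """Rate constants of the β-cell-free model.

    ``psi``, ``delta``, ``a`` and ``b`` are the quantities typically fitted
    to data and therefore carry no defaults; the remaining constants default
    to their literature baselines.
    """

    psi: float  # insulin absorption rate, mIU/mL/min
    delta: float  # insulin clearance rate, 1/min
    a: float  # liver glucose production rate, mg/dL/min
    b: float  # insulin-independent glucose clearance rate, 1/min
    I0: float = 5.0  # insulin bolus, mIU/mL
    c: float = 0.85  # insulin-induced glucose uptake rate, mL/mIU/min
    rho: float = 15.06  # growth-hormone production rate, mIU/mL/min
    w: float = 1958.40  # growth-hormone clearance rate, 1/min

    def __post_init__(self) -> None:
        self._validate()
        if self.w <= 0:
            raise DomainError("w (growth-hormone clearance rate) must be > 0")


@dataclass(frozen=True)
class Model2Parameters(_ParameterBase):
    """Rate constants of the β-cell model.

    ``a``, ``b``, ``f`` and ``i`` are the usual fitted quantities and carry
    no defaults.
    """

    a: float  # liver glucose production rate, mg/dL/min
    b: float  # insulin-independent glucose clearance rate, 1/min
    f: float  # whole-body insulin clearance rate, 1/min
    i: float  # β-cell glucose tolerance factor (quadratic), dL^2/mg^2/min
    h: float = 0.5727e-3  # β-cell glucose tolerance factor (linear), dL/mg/min
    g: float = 0.03  # β-cell natural death rate, 1/min
    d: float = 43.2  # β-cell maximum insulin secretory rate, mIU/mL/min/mg
    e: float = 20000.0  # sigmoidal inflection point, mg^2/dL^2
    c: float = 0.85  # insulin-induced glucose uptake rate, mL/mIU/min
    rho: float = 15.06  # growth-hormone production rate, mIU/mL/min
    w: float = 1958.40  # growth-hormone clearance rate, 1/min

    def __post_init__(self) -> None:
        self._validate()
        if self.e <= 0:
            raise DomainError("e (sigmoidal inflection point) must be > 0")
        if self.w <= 0:
            raise DomainError("w (growth-hormone clearance rate) must be > 0")


AnyParameters = Union[Model1Parameters, Model2Parameters]


@dataclass(frozen=True)
class StateVector:
    """Instantaneous physiological state.

    ``beta`` is the β-cell mass (mg) and is ignored by Model 1.  Defaults
    are the conventional initial conditions β=800 mg, I=20 mIU/mL,
    GL=80 mg/dL, GH=30 mIU/mL.
    """

    I: float = 20.0
    GL: float = 80.0
    GH: float = 30.0
    beta: float = 800.0

    def __post_init__(self) -> None:
        for name in ("I", "GL", "GH", "beta"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise DomainError(f"state component {name} must be finite")
            if value < 0:
                raise DomainError(f"state component {name} must be >= 0, got {value!r}")

    def as_array(self, model_id: int) -> np.ndarray:
        return np.array([getattr(self, n) for n in state_names(model_id)], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float], model_id: int) -> "StateVector":
        values = list(values)
        names = state_names(model_id)
        if len(values) != len(names):
            raise ValueError(f"expected {len(names)} components for model {model_id}")
        kwargs = dict(zip(names, (float(v) for v in values)))
        return cls(**kwargs)


def _coerce_state(state: Union[StateVector, Iterable[float]], model_id: int) -> np.ndarray:
    if isinstance(state, StateVector):
        arr = state.as_array(model_id)
    else:
        arr = np.asarray(list(state), dtype=float)
        if arr.shape != (len(state_names(model_id)),):
            raise ValueError(
                f"state must have {len(state_names(model_id))} components for model {model_id}"
            )
    if not np.all(np.isfinite(arr)):
        raise DomainError("state components must be finite")
    if np.any(arr < 0):
        raise DomainError("state components must be >= 0")
    return arr


# Raw right-hand sides used inside the integrator: no validation, scalar math.

def _rhs1(t, y, psi, delta, I0, a, b, c, rho, w):
    I, GL, GH = y
    return (
        psi * I0 * I / (1.0 + I) - delta * I,
        a - (b + c * I) * GL + c * GH,
        rho - w * GH,
    )


def _rhs2(t, y, a, b, f, i, h, g, d, e, c, rho, w):
    beta, I, GL, GH = y
    GL2 = GL * GL
    return (
        (h * GL - i * GL2 - g) * beta,
        beta * d * GL2 / (e + GL2) - f * I,
        a - (b + c * I) * GL + c * GH,
        rho - w * GH,
    )


def _rhs_args(params: AnyParameters) -> tuple:
    if isinstance(params, Model1Parameters):
        return (params.psi, params.delta, params.I0, params.a, params.b,
                params.c, params.rho, params.w)
    return (params.a, params.b, params.f, params.i, params.h, params.g,
            params.d, params.e, params.c, params.rho, params.w)


def model1_rhs(state: Union[StateVector, Iterable[float]],
               params: Model1Parameters) -> np.ndarray:
    """Time derivative ``(dI/dt, dGL/dt, dGH/dt)`` of the β-cell-free model.

    The insulin equation balances bolus absorption ``psi*I0*I/(1+I)``
    against clearance ``delta*I``; glucose balances hepatic production
    ``a`` against insulin-dependent uptake ``(b + c*I)*GL`` plus the
    growth-hormone input ``c*GH``; growth hormone is linear,
    ``rho - w*GH``.
    """
    y = _coerce_state(state, model_id=1)
    return np.array(_rhs1(0.0, y, *_rhs_args(params)), dtype=float)


def model2_rhs(state: Union[StateVector, Iterable[float]],
               params: Model2Parameters) -> np.ndarray:
    """Time derivative ``(dβ/dt, dI/dt, dGL/dt, dGH/dt)`` of the β-cell model.

    β-cell mass grows or shrinks according to the glucose tolerance window
    ``h*GL - i*GL^2 - g``; insulin is secreted sigmoidally in glucose,
    ``beta*d*GL^2/(e + GL^2)``, and cleared at rate ``f``.
    """
    y = _coerce_state(state, model_id=2)
    return np.array(_rhs2(0.0, y, *_rhs_args(params)), dtype=float)


def model1_steady_state(params: Model1Parameters) -> StateVector:
    """Closed-form fixed point of the β-cell-free model.

    The insulin equation has the nontrivial root ``I* = psi*I0/delta - 1``
    (clamped at zero when the bolus cannot sustain positive insulin),
    growth hormone settles at ``GH* = rho/w`` and glucose at
    ``GL* = (a + c*GH*)/(b + c*I*)``.
    """
    if params.delta <= 0:
        raise DomainError("steady state undefined for delta <= 0")
    if params.w <= 0:
        raise DomainError("steady state undefined for w <= 0")
    I_star = max(0.0, params.psi * params.I0 / params.delta - 1.0)
    GH_star = params.rho / params.w
    denom = params.b + params.c * I_star
    if denom <= 0:
        raise DomainError("glucose steady state undefined: b + c*I* must be > 0")
    GL_star = (params.a + params.c * GH_star) / denom
    return StateVector(I=I_star, GL=GL_star, GH=GH_star, beta=0.0)
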