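"""Fitting a glucose model to observed data.

The likelihood assumes i.i.d. additive Gaussian measurement noise on the
glucose channel, so the data enter only through the sum of squares
``SS(theta) = sum_j (y_j - GL(t_j; theta))^2``.  A uniform prior is placed
on each varied parameter over a bound box, and the error precision carries
a conjugate Gamma prior, sampled exactly at every MCMC step.

This module holds the fit specification, the cost function, posterior
summaries and convergence diagnostics; the sampling workflow itself lives
in :class:`glucodyn.estimators.GlucoseModelCalibrator`, for which
:func:`least_squares_fit` and :func:`run_mcmc` are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import arviz as az
import numpy as np
import pandas as pd

from .datasets import GlucoseDataset
from .models import AnyParameters, Model1Parameters, Model2Parameters, StateVector
from .sampler import sample_error_precision  # re-exported: part of the fitting API
from .simulate import IntegrationError, simulate

__all__ = [
    "DEFAULT_VARIED",
    "DEFAULT_BOUNDS",
    "FitSpecification",
    "PosteriorSample",
    "sum_of_squares",
    "least_squares_fit",
    "run_mcmc",
    "summarize",
    "convergence_diagnostics",
    "sample_error_precision",
]

#: default varied-parameter sets: insulin clearance and absorption for the
#: β-cell-free model; glucose production/clearance, insulin clearance and
#: the quadratic tolerance factor for the β-cell model
DEFAULT_VARIED: dict[int, tuple[str, ...]] = {
    1: ("delta", "psi"),
    2: ("a", "b", "f", "i"),
}

#: default uniform-prior boxes, bracketing literature-scale estimates by
#: roughly a factor of ten on each side
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "delta": (1e-3, 1.0),
    "psi": (1e-2, 1e2),
    "a": (1.0, 1e3),
    "b": (1e-3, 5.0),
    "f": (1e-2, 1e3),
    "i": (1e-8, 1e-4),
}


@dataclass(frozen=True)
class FitSpecification:
    """Everything needed to fit one model to one dataset."""

    model_id: int
    fixed: AnyParameters  # full parameter set; varied entries are overwritten
    varied: tuple[str, ...] = ()
    bounds: dict = field(default_factory=dict)  # name -> (lower, upper)
    init: StateVector = StateVector()
    chain_length: int = 100_000
    seed: Optional[int] = None
    dr_stages: int = 1
    dr_scale: float = 0.2
    n0: float = 1.0
    s0: Optional[float] = None  # default: least-squares variance estimate SS/n
    adapt_start: int = 1000
    adapt_interval: int = 100
    burn_in_fraction: float = 0.5

    def __post_init__(self) -> None:
        expected = Model1Parameters if self.model_id == 1 else Model2Parameters
        if self.model_id not in (1, 2):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if not isinstance(self.fixed, expected):
            raise TypeError(f"fixed must be {expected.__name__} for model {self.model_id}")
        varied = tuple(self.varied) or DEFAULT_VARIED[self.model_id]
        object.__setattr__(self, "varied", varied)
        bounds = dict(self.bounds)
        for name in varied:
            if not hasattr(self.fixed, name):
                raise ValueError(f"unknown varied parameter {name!r}")
            bounds.setdefault(name, DEFAULT_BOUNDS[name])
            lo, hi = bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite with lower < upper")
        object.__setattr__(self, "bounds", bounds)
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.dr_stages not in (0, 1):
            raise ValueError("dr_stages must be 0 or 1")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in self.varied])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in self.varied])

    def build_params(self, theta: Sequence[float]) -> AnyParameters:
        """Full parameter object with the varied subset set to ``theta``."""
        return self.fixed.replace(**dict(zip(self.varied, map(float, theta))))


@dataclass(frozen=True)
class PosteriorSample:
    """MCMC output for one fit."""

    names: tuple[str, ...]
    chain: np.ndarray  # (chain_length, n_varied)
    sigma2_chain: np.ndarray
    ss_chain: np.ndarray
    acceptance_rate: float
    seed: Optional[int] = None
    ss_min: Optional[float] = None  # best SS seen incl. the least-squares fit

    def __post_init__(self) -> None:
        if self.chain.ndim != 2 or self.chain.shape[1] != len(self.names):
            raise ValueError("chain must be (length, n_parameters)")
        if np.any(self.ss_chain < 0):
            raise ValueError("SS values must be >= 0")
        if np.any(self.sigma2_chain <= 0):
            raise ValueError("sigma2 values must be > 0")

    def __len__(self) -> int:
        return self.chain.shape[0]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.chain, columns=list(self.names))
        frame["sigma2"] = self.sigma2_chain
        frame["ss"] = self.ss_chain
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def sum_of_squares(theta: Sequence[float],
                   spec: FitSpecification,
                   data: GlucoseDataset) -> float:
    """``SS(theta)``: squared glucose residuals at the data's times.

    Returns ``inf`` when ``theta`` leaves the prior box or the ODE solver
    fails, so that callers can treat both as zero posterior mass.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < spec.lower) or np.any(theta > spec.upper):
        return math.inf
    try:
        params = spec.build_params(theta)
        trajectory = simulate(spec.model_id, params, spec.init, data.times)
    except (IntegrationError, ValueError):
        return math.inf
    residuals = data.glucose - trajectory.glucose
    return float(residuals @ residuals)


def least_squares_fit(spec: FitSpecification,
                      data: GlucoseDataset) -> tuple[np.ndarray, float]:
    """Bound-constrained least-squares fit of the varied parameters.

    Thin wrapper over
    :meth:`glucodyn.estimators.GlucoseModelCalibrator.least_squares`.
    """
    from .estimators import GlucoseModelCalibrator

    est = GlucoseModelCalibrator.from_spec(spec)
    return est.least_squares(data.times, data.glucose)


def run_mcmc(spec: FitSpecification, data: GlucoseDataset) -> PosteriorSample:
    """Full calibration: least-squares initialisation then a DRAM chain.

    Thin wrapper over :class:`glucodyn.estimators.GlucoseModelCalibrator`.
    """
    from .estimators import GlucoseModelCalibrator

    est = GlucoseModelCalibrator.from_spec(spec)
    est.fit(data.times, data.glucose)
    return est.posterior_


def _as_chain(sample: Union[PosteriorSample, np.ndarray]) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(sample, PosteriorSample):
        return sample.chain, sample.names
    chain = np.asarray(sample, dtype=float)
    if chain.ndim == 1:
        chain = chain[:, None]
    names = tuple(f"theta{j}" for j in range(chain.shape[1]))
    return chain, names


def summarize(sample: Union[PosteriorSample, np.ndarray],
              burn_in_fraction: float = 0.5) -> pd.DataFrame:
    """Posterior medians and 95% credible intervals (2.5%/97.5% quantiles)
    of the post-burn-in chain, one row per varied parameter."""
    chain, names = _as_chain(sample)
    start = int(burn_in_fraction * chain.shape[0])
    kept = chain[start:]
    if kept.shape[0] == 0:
        raise ValueError("burn-in leaves an empty chain")
    lower, median, upper = np.quantile(kept, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {"median": median, "lower": lower, "upper": upper}, index=list(names)
    )


def effective_sample_size(values: np.ndarray) -> float:
    """Autocorrelation-adjusted effective sample size of a 1-d chain."""
    values = np.asarray(values, dtype=float)
    if np.allclose(values, values[0]):
        return 1.0
    return float(az.ess(values[None, :]))


def convergence_diagnostics(sample: Union[PosteriorSample, np.ndarray]) -> pd.DataFrame:
    """Quantitative convergence report, one row per parameter.

    Columns: ``ess`` (effective sample size), ``z`` (a stationarity score
    comparing the means of the first 10% and last 50% of the chain,
    standardised by ESS-adjusted standard errors) and ``needs_extension``
    (True when ESS < 200 or |z| > 2, recommending an extended run).
    """
    chain, names = _as_chain(sample)
    n = chain.shape[0]
    if n < 10:
        raise ValueError("chain too short for diagnostics")
    rows = []
    for j, name in enumerate(names):
        values = chain[:, j]
        ess = effective_sample_size(values)
        head = values[: max(2, n // 10)]
        tail = values[-(n // 2):]
        ess_head = effective_sample_size(head)
        ess_tail = effective_sample_size(tail)
        se2 = head.var(ddof=1) / ess_head + tail.var(ddof=1) / ess_tail
        z = (head.mean() - tail.mean()) / math.sqrt(se2) if se2 > 0 else math.inf
        rows.append({"ess": ess, "z": z,
                     "needs_extension": bool(ess < 200 or abs(z) > 2)})
    return pd.DataFrame(rows, index=list(names))
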