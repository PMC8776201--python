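"""Scikit-learn style calibrator for the glucose-homeostasis models.

:class:`GlucoseModelCalibrator` is a regressor over time: ``fit(X, y)``
takes observation times (minutes) and glucose concentrations (mg/dL),
initialises the varied parameters by bound-constrained least squares, then
runs a DRAM chain with conjugate error-variance sampling.  ``predict(X)``
returns the posterior-median glucose trajectory and
:meth:`predict_interval` a pointwise posterior(-predictive) band.

The class composes with scikit-learn tooling (``get_params``/``set_params``,
``clone``); fitted attributes carry a trailing underscore.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .calibration import (
    FitSpecification,
    PosteriorSample,
    convergence_diagnostics,
    summarize,
    sum_of_squares,
)
from .datasets import GlucoseDataset
from .models import AnyParameters, StateVector
from .sampler import dram_chain
from .simulate import IntegrationError, simulate

__all__ = ["GlucoseModelCalibrator"]

#: residual magnitude substituted when the ODE cannot be integrated,
#: steering the optimizer away without raising
_FAILED_RESIDUAL = 1e6


class GlucoseModelCalibrator(RegressorMixin, BaseEstimator):
    """Bayesian calibrator for one glucose model on one glucose time series.

    Parameters
    ----------
    model_id : {1, 2}
        1 for the β-cell-free model, 2 for the β-cell model.
    fixed_params : Model1Parameters or Model2Parameters
        Full parameter set; entries named in ``varied`` are overwritten
        during fitting and act only as placeholders.
    varied : tuple of str, optional
        Parameters to fit.  Defaults to ``(delta, psi)`` for model 1 and
        ``(a, b, f, i)`` for model 2.
    bounds : dict, optional
        ``name -> (lower, upper)`` uniform-prior boxes; unlisted varied
        parameters take the package defaults.
    init_state : StateVector
        Initial physiological state at t = 0.
    chain_length : int
        MCMC iterations (default 100,000).
    n0, s0 : float
        Gamma-prior hyperparameters for the error precision; ``s0=None``
        uses the least-squares variance estimate ``SS/n``.
    dr_scale : float or None
        Delayed-rejection proposal shrinkage; ``None`` disables the stage.
    adapt_start, adapt_interval : int
        Adaptive-Metropolis schedule; ``adapt_start=None`` disables
        adaptation.
    n_restarts : int
        Extra random starting points for the least-squares initialisation.
    random_state : int, Generator or None
        Seed for the least-squares restarts and the chain.

    Attributes
    ----------
    theta_ls_ : ndarray
        Least-squares estimate of the varied parameters.
    ss_ls_ : float
        Sum of squares at ``theta_ls_``.
    posterior_ : PosteriorSample
        The MCMC chain with per-iteration error variance and SS.
    summary_ : DataFrame
        Posterior medians and 95% credible intervals.
    diagnostics_ : DataFrame
        ESS and stationarity scores per parameter.
    ss_min_ : float
        Best SS across the least-squares fit and the chain (the value used
        by information criteria).
    """

    def __init__(self,
                 model_id: int = 1,
                 fixed_params: Optional[AnyParameters] = None,
                 varied: Optional[Sequence[str]] = None,
                 bounds: Optional[dict] = None,
                 init_state: StateVector = StateVector(),
                 chain_length: int = 100_000,
                 burn_in_fraction: float = 0.5,
                 n0: float = 1.0,
                 s0: Optional[float] = None,
                 dr_scale: Optional[float] = 0.2,
                 adapt_start: Optional[int] = 1000,
                 adapt_interval: int = 100,
                 n_restarts: int = 2,
                 random_state=None):
        self.model_id = model_id
        self.fixed_params = fixed_params
        self.varied = varied
        self.bounds = bounds
        self.init_state = init_state
        self.chain_length = chain_length
        self.burn_in_fraction = burn_in_fraction
        self.n0 = n0
        self.s0 = s0
        self.dr_scale = dr_scale
        self.adapt_start = adapt_start
        self.adapt_interval = adapt_interval
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_spec(cls, spec: FitSpecification) -> "GlucoseModelCalibrator":
        return cls(
            model_id=spec.model_id,
            fixed_params=spec.fixed,
            varied=spec.varied,
            bounds=spec.bounds,
            init_state=spec.init,
            chain_length=spec.chain_length,
            burn_in_fraction=spec.burn_in_fraction,
            n0=spec.n0,
            s0=spec.s0,
            dr_scale=spec.dr_scale if spec.dr_stages else None,
            adapt_start=spec.adapt_start,
            adapt_interval=spec.adapt_interval,
            random_state=spec.seed,
        )

    def _spec(self) -> FitSpecification:
        if self.fixed_params is None:
            raise ValueError("fixed_params must be supplied")
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None
        return FitSpecification(
            model_id=self.model_id,
            fixed=self.fixed_params,
            varied=tuple(self.varied) if self.varied else (),
            bounds=dict(self.bounds) if self.bounds else {},
            init=self.init_state,
            chain_length=self.chain_length,
            seed=seed,
            dr_stages=0 if self.dr_scale is None else 1,
            dr_scale=self.dr_scale if self.dr_scale is not None else 0.2,
            n0=self.n0,
            s0=self.s0,
            adapt_start=self.adapt_start if self.adapt_start is not None else 10 ** 9,
            adapt_interval=self.adapt_interval,
            burn_in_fraction=self.burn_in_fraction,
        )

    @staticmethod
    def _validate_times_glucose(X, y=None):
        times = np.asarray(X, dtype=float)
        if times.ndim == 2 and times.shape[1] == 1:
            times = times[:, 0]
        if times.ndim != 1:
            raise ValueError("X must be a 1-d array of times (or a single column)")
        if y is None:
            return times
        glucose = np.asarray(y, dtype=float)
        if glucose.shape != times.shape:
            raise ValueError("y must match the length of X")
        return times, glucose

    # -- least-squares initialisation -----------------------------------------

    def least_squares(self, X, y) -> tuple[np.ndarray, float]:
        """Bound-constrained least-squares estimate of the varied parameters.

        The box is first probed at log-uniform points ranked by SS (the cost
        surface has narrow basins surrounded by flat plateaus), then
        trust-region-reflective solves run from the best-ranked starts;
        returns ``(theta_hat, ss_min)``.
        """
        times, glucose = self._validate_times_glucose(X, y)
        spec = self._spec()
        data = GlucoseDataset(times=times, glucose=glucose)
        rng = np.random.default_rng(self.random_state)
        lo, hi = spec.lower, spec.upper

        def residuals(theta: np.ndarray) -> np.ndarray:
            try:
                params = spec.build_params(theta)
                traj = simulate(spec.model_id, params, spec.init, data.times)
            except (IntegrationError, ValueError):
                return np.full(times.shape, _FAILED_RESIDUAL)
            return glucose - traj.glucose

        # Coarse log-uniform probe of the box: the cost surface has narrow
        # basins surrounded by flat plateaus, so local solves need ranked
        # starting points rather than a single midpoint.
        probes = [np.sqrt(lo * hi)]
        n_probes = max(8, 16 * lo.size)
        u = rng.uniform(size=(n_probes, lo.size))
        probes.extend(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
        scored = sorted(
            (float(np.sum(residuals(p) ** 2)), tuple(p)) for p in probes
        )
        starts = [np.asarray(p) for _, p in scored[: 1 + max(0, int(self.n_restarts))]]

        best_theta, best_ss, best_result = None, math.inf, None
        for x0 in starts:
            try:
                result = least_squares(residuals, x0, bounds=(lo, hi),
                                       method="trf", x_scale="jac")
            except Exception:
                continue
            ss = float(2.0 * result.cost)
            if ss < best_ss:
                best_theta, best_ss, best_result = result.x.copy(), ss, result
        if best_theta is None:
            raise RuntimeError("least-squares initialisation failed from every start")
        self._ls_result = best_result
        return best_theta, best_ss

    def _proposal_covariance(self, spec: FitSpecification, ss_ls: float,
                             n: int) -> np.ndarray:
        """Initial proposal covariance from the local Gauss-Newton curvature
        of the least-squares solution, with a bound-scaled fallback."""
        d = len(spec.varied)
        fallback = np.diag(((spec.upper - spec.lower) / 50.0) ** 2)
        result = getattr(self, "_ls_result", None)
        if result is None or result.jac is None:
            return fallback
        jac = np.asarray(result.jac)
        hessian = jac.T @ jac
        sigma2_hat = max(ss_ls / max(n - d, 1), 1e-12)
        try:
            cov = sigma2_hat * np.linalg.inv(
                hessian + 1e-10 * np.eye(d) * max(np.trace(hessian) / d, 1e-300)
            )
        except np.linalg.LinAlgError:
            return fallback
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            return fallback
        # cap each marginal at the box scale so a flat (non-identified)
        # direction cannot blow the initial proposal up
        sd = np.sqrt(np.diag(cov))
        capped_sd = np.minimum(sd, np.sqrt(np.diag(fallback)))
        corr = cov / np.outer(sd, sd)
        return corr * np.outer(capped_sd, capped_sd)

    # -- full calibration -----------------------------------------------------

    def fit(self, X, y) -> "GlucoseModelCalibrator":
        """Least-squares initialisation followed by a DRAM chain."""
        times, glucose = self._validate_times_glucose(X, y)
        spec = self._spec()
        data = GlucoseDataset(times=times, glucose=glucose)
        n = len(data)

        theta_ls, ss_ls = self.least_squares(times, glucose)
        s0 = self.s0 if self.s0 is not None else max(ss_ls / n, 1e-12)
        cov0 = self._proposal_covariance(spec, ss_ls, n)

        seed = spec.seed
        rng = np.random.default_rng(self.random_state)
        result = dram_chain(
            lambda theta: sum_of_squares(theta, spec, data),
            theta_ls, spec.lower, spec.upper, cov0,
            n_iter=spec.chain_length, rng=rng, n_obs=n,
            n0=spec.n0, s0=s0,
            dr_scale=self.dr_scale,
            adapt_start=self.adapt_start,
            adapt_interval=spec.adapt_interval,
        )

        self.spec_ = spec
        self.data_ = data
        self.theta_ls_ = np.asarray(theta_ls)
        self.ss_ls_ = ss_ls
        self.s0_ = s0
        self.posterior_ = PosteriorSample(
            names=spec.varied,
            chain=result.chain,
            sigma2_chain=result.sigma2_chain,
            ss_chain=result.ss_chain,
            acceptance_rate=result.acceptance_rate,
            seed=seed,
            ss_min=float(min(ss_ls, result.ss_chain.min())),
        )
        self.acceptance_rate_ = result.acceptance_rate
        self.ss_min_ = self.posterior_.ss_min
        self.summary_ = summarize(self.posterior_, spec.burn_in_fraction)
        self.diagnostics_ = convergence_diagnostics(self.posterior_)
        self.n_obs_ = n
        return self

    # -- prediction -----------------------------------------------------------

    def _simulate_glucose(self, theta: np.ndarray, times: np.ndarray) -> np.ndarray:
        order = np.argsort(times)
        sorted_times = times[order]
        traj = simulate(self.spec_.model_id, self.spec_.build_params(theta),
                        self.spec_.init, sorted_times)
        out = np.empty_like(sorted_times)
        out[order] = np.clip(traj.glucose, 0.0, None)
        return out

    def predict(self, X) -> np.ndarray:
        """Glucose trajectory at the posterior-median parameters."""
        check_is_fitted(self, "posterior_")
        times = self._validate_times_glucose(X)
        theta = self.summary_["median"].to_numpy()
        return self._simulate_glucose(theta, times)

    def predict_interval(self, X, n_draws: int = 500,
                         include_noise: bool = False,
                         seed: Optional[int] = None) -> dict[str, np.ndarray]:
        """Pointwise posterior(-predictive) band at the requested times.

        Thins the post-burn-in chain to ``n_draws`` parameter draws,
        simulates glucose for each, optionally adds observation noise drawn
        from the sampled error variances, and returns the 2.5%, 50% and
        97.5% pointwise quantiles as ``{"lower", "median", "upper"}``.
        """
        check_is_fitted(self, "posterior_")
        times = self._validate_times_glucose(X)
        start = int(self.spec_.burn_in_fraction * len(self.posterior_))
        kept = self.posterior_.chain[start:]
        kept_sigma2 = self.posterior_.sigma2_chain[start:]
        idx = np.unique(np.linspace(0, kept.shape[0] - 1,
                                    min(n_draws, kept.shape[0])).astype(int))
        rng = np.random.default_rng(self.posterior_.seed if seed is None else seed)
        curves = np.empty((idx.size, times.size))
        for row, j in enumerate(idx):
            curves[row] = self._simulate_glucose(kept[j], times)
            if include_noise:
                curves[row] += rng.normal(0.0, math.sqrt(kept_sigma2[j]),
                                          size=times.size)
        lower, median, upper = np.quantile(curves, [0.025, 0.5, 0.975], axis=0)
        return {"lower": lower, "median": median, "upper": upper}
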