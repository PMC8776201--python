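"""Delayed-rejection adaptive Metropolis (DRAM) core.

The sampler targets a posterior built from the Gaussian likelihood kernel

    p(theta | y, sigma^2)  ∝  exp(-0.5 * SS(theta) / sigma^2) * 1[theta in box]

where ``SS`` is a sum-of-squares discrepancy and the prior is uniform on a
bound box.  The error variance ``sigma^2`` is either held fixed (the
acceptance ratio then uses the kernel above directly) or treated as
unknown with a conjugate Gamma(n0/2, n0*S0/2) prior on the precision
``sigma^-2``.  In the unknown-variance case theta moves are accepted under
the sigma^2-marginalised likelihood

    p(theta | y)  ∝  (n0*S0 + SS(theta))^(-(n0 + n)/2) * 1[theta in box]

and sigma^2 is drawn each iteration from its full conditional
Gamma((n0 + n)/2, (n0*S0 + SS(theta))/2) for recording and for posterior-
predictive use.  Accepting under the conditional kernel instead is a valid
scheme but mixes pathologically on flexible models at small n: sigma^2
inflates to accommodate any badly fitting state, flattening the acceptance
ratio, so excursions onto high-SS plateaus become near-absorbing.
Marginalisation removes that ratchet while leaving the joint target
unchanged.

The proposal is Gaussian.  Adaptation follows the adaptive-Metropolis
recipe (empirical chain covariance scaled by 2.4^2/d, refreshed on a fixed
cadence after a warm-up); delayed rejection retries a rejected move once
with the proposal shrunk by a fixed factor, using the two-stage acceptance
probability that preserves detailed balance.

The module is deliberately generic over ``ss_fn`` so that the same code
path can be validated against analytically tractable targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["ChainResult", "ProposalRecord", "SamplerDivergence",
           "sample_error_precision", "dram_chain"]


class SamplerDivergence(RuntimeError):
    """Raised when most proposals fail to evaluate (pervasive integration
    failure), indicating the sampler cannot explore the posterior."""


def sample_error_precision(ss: float, n: int, n0: float, s0: float,
                           rng: np.random.Generator) -> float:
    """Draw the error variance ``sigma^2`` from its conjugate posterior.

    The precision ``sigma^-2`` is drawn from
    ``Gamma(shape=(n0 + n)/2, rate=(n0*s0 + ss)/2)`` and inverted.
    """
    if ss < 0:
        raise ValueError("ss must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    if n0 < 0 or s0 < 0:
        raise ValueError("n0 and s0 must be >= 0")
    rate = 0.5 * (n0 * s0 + ss)
    if rate <= 0:
        raise ValueError("degenerate posterior: n0*s0 + ss must be > 0")
    shape = 0.5 * (n0 + n)
    precision = rng.gamma(shape, 1.0 / rate)
    return 1.0 / precision


@dataclass(frozen=True)
class ProposalRecord:
    """One logged first-stage proposal (for acceptance-rule audits)."""

    theta_current: np.ndarray
    ss_current: float
    theta_proposed: np.ndarray
    ss_proposed: float
    sigma2: float
    log_alpha: float
    uniform: float
    accepted: bool


@dataclass
class ChainResult:
    """Output of :func:`dram_chain`."""

    chain: np.ndarray  # (n_iter, d) states after each iteration
    ss_chain: np.ndarray  # (n_iter,)
    sigma2_chain: np.ndarray  # (n_iter,)
    acceptance_rate: float
    n_evaluations: int
    n_failures: int  # in-bounds proposals whose SS was non-finite
    proposals: list = field(default_factory=list)  # ProposalRecord if tracked


def _chol(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    jitter = 1e-12 * max(np.trace(cov) / d, 1e-300)
    for _ in range(6):
        try:
            return np.linalg.cholesky(cov + jitter * np.eye(d))
        except np.linalg.LinAlgError:
            jitter *= 100.0
    raise np.linalg.LinAlgError("proposal covariance not positive definite")


def dram_chain(ss_fn: Callable[[np.ndarray], float],
               theta0: Sequence[float],
               lower: Sequence[float],
               upper: Sequence[float],
               cov0: np.ndarray,
               n_iter: int,
               rng: np.random.Generator,
               n_obs: int,
               *,
               n0: float = 1.0,
               s0: Optional[float] = None,
               sigma2: Optional[float] = None,
               dr_scale: Optional[float] = 0.2,
               adapt_start: Optional[int] = 1000,
               adapt_interval: int = 100,
               track_proposals: bool = False,
               failure_patience: int = 200) -> ChainResult:
    """Run a DRAM chain of ``n_iter`` iterations.

    Parameters
    ----------
    ss_fn
        Maps a parameter vector to its sum of squares; may return ``inf``
        for infeasible points (e.g. integration failure).
    theta0
        In-bounds starting point with finite ``ss_fn(theta0)``.
    cov0
        Initial proposal covariance (d x d).
    sigma2
        If given, the error variance is held fixed; otherwise it is sampled
        each iteration from the conjugate Gamma posterior (requires ``s0``
        unless ``n0 == 0``).
    dr_scale
        Scale factor for the single delayed-rejection stage; ``None``
        disables delayed rejection.
    adapt_start
        Iteration after which the proposal covariance is re-estimated from
        the chain history every ``adapt_interval`` iterations; ``None``
        disables adaptation.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    d = theta.size
    if np.any(theta < lower) or np.any(theta > upper):
        raise ValueError("theta0 must lie inside the bound box")
    sample_sigma2 = sigma2 is None
    if sample_sigma2 and s0 is None:
        raise ValueError("s0 is required when sigma2 is sampled")

    ss_cur = float(ss_fn(theta))
    if not math.isfinite(ss_cur):
        raise ValueError("ss_fn(theta0) must be finite")
    n_eval = 1
    n_fail = 0
    sig2 = float(sigma2) if not sample_sigma2 else None

    chol = _chol(np.asarray(cov0, dtype=float))
    sd = 2.4 ** 2 / d  # adaptive-Metropolis scaling

    chain = np.empty((n_iter, d))
    ss_chain = np.empty(n_iter)
    sigma2_chain = np.empty(n_iter)
    n_accept = 0
    proposals: list[ProposalRecord] = []

    def evaluate(point: np.ndarray) -> float:
        nonlocal n_eval, n_fail
        if np.any(point < lower) or np.any(point > upper):
            return math.inf  # outside the uniform prior's support
        n_eval += 1
        value = float(ss_fn(point))
        if not math.isfinite(value):
            n_fail += 1
            value = math.inf
        if n_eval >= failure_patience and n_fail > 0.5 * n_eval:
            raise SamplerDivergence(
                f"{n_fail}/{n_eval} proposal evaluations failed; the model "
                "cannot be integrated over most of the parameter box"
            )
        return value

    if sample_sigma2:
        # sigma^2-marginalised log-likelihood (theta acceptance)
        half_dof = 0.5 * (n0 + n_obs)
        prior_mass = n0 * s0

        def log_posterior(ss: float, s2: float) -> float:
            if not math.isfinite(ss):
                return -math.inf
            return -half_dof * math.log(max(prior_mass + ss, 1e-300))
    else:
        def log_posterior(ss: float, s2: float) -> float:
            return -0.5 * ss / s2 if math.isfinite(ss) else -math.inf

    for k in range(n_iter):
        if sample_sigma2:
            sig2 = sample_error_precision(ss_cur, n_obs, n0, s0, rng)

        y1 = theta + chol @ rng.standard_normal(d)
        ss1 = evaluate(y1)
        log_a1 = min(0.0, log_posterior(ss1, sig2) - log_posterior(ss_cur, sig2))
        u = rng.uniform()
        accept = math.log(u) < log_a1
        if track_proposals:
            proposals.append(ProposalRecord(theta.copy(), ss_cur, y1.copy(),
                                            ss1, sig2, log_a1, u, accept))
        if accept:
            theta, ss_cur = y1, ss1
            n_accept += 1
        elif dr_scale is not None:
            # one delayed-rejection stage at a shrunken proposal
            y2 = theta + (dr_scale * chol) @ rng.standard_normal(d)
            ss2 = evaluate(y2)
            if math.isfinite(ss2):
                # alpha1 evaluated from y2 toward y1
                log_a1_rev = min(0.0, log_posterior(ss1, sig2)
                                 - log_posterior(ss2, sig2))
                if log_a1_rev < 0.0 and log_a1 < 0.0:
                    # q1 density ratio: N(y1; y2, cov) / N(y1; x, cov)
                    z2 = np.linalg.solve(chol, y1 - y2)
                    z1 = np.linalg.solve(chol, y1 - theta)
                    log_q_ratio = -0.5 * (z2 @ z2 - z1 @ z1)
                    log_a2 = (log_posterior(ss2, sig2)
                              - log_posterior(ss_cur, sig2)
                              + log_q_ratio
                              + math.log1p(-math.exp(log_a1_rev))
                              - math.log1p(-math.exp(log_a1)))
                    if math.log(rng.uniform()) < min(0.0, log_a2):
                        theta, ss_cur = y2, ss2
                        n_accept += 1

        chain[k] = theta
        ss_chain[k] = ss_cur
        sigma2_chain[k] = sig2

        if (adapt_start is not None and k + 1 >= adapt_start
                and (k + 1 - adapt_start) % adapt_interval == 0):
            history = chain[: k + 1]
            cov = sd * np.cov(history, rowvar=False).reshape(d, d)
            cov += sd * 1e-10 * np.eye(d)
            try:
                chol = _chol(cov)
            except np.linalg.LinAlgError:
                pass  # keep the previous proposal if history is degenerate

    return ChainResult(chain=chain, ss_chain=ss_chain,
                       sigma2_chain=sigma2_chain,
                       acceptance_rate=n_accept / n_iter,
                       n_evaluations=n_eval, n_failures=n_fail,
                       proposals=proposals)
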