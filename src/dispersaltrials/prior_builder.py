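"""Informative prior on the population growth rate via error propagation.

The growth rate entering the hierarchical model as ``r ~ Normal(m, sigma)``
is predicted from a previously fitted nonlinear temperature-growth model at
the incubation temperature.  Because the fitted parameters carry estimation
uncertainty, the prediction's mean and standard deviation are obtained by
propagating the parameter covariance through the (generally nonlinear)
prediction function, two ways:

* a second-order Taylor expansion around the parameter estimates, giving

      mean = g(theta_hat) + 1/2 * tr(H Sigma)
      var  = grad' Sigma grad + 1/2 * tr((H Sigma)^2)

  with gradient and Hessian of g taken in theta at theta_hat; and

* Monte Carlo simulation: draw theta* ~ MVN(theta_hat, Sigma), evaluate
  g(theta*), and report the sample mean and SD.

For a linear g the Taylor result is exact; for nonlinear g the two serve as
mutual cross-checks, and the default policy keeps the Monte-Carlo moments
while warning when the Taylor mean disagrees beyond sampling error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "FittedGrowthModel",
    "GrowthPrior",
    "PropagationResult",
    "taylor_propagate",
    "mc_propagate",
    "make_growth_prior",
]

_SYM_TOL = 1e-10
_PSD_TOL = 1e-8


@dataclass(frozen=True)
class GrowthPrior:
    """Normal prior on the population growth rate: mean ``m`` and SD ``sigma``."""

    m: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.m):
            raise ValueError(f"prior mean must be finite, got {self.m}")
        if not (self.sigma > 0 and np.isfinite(self.sigma)):
            raise ValueError(f"prior sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class PropagationResult:
    """Mean/SD of a propagated prediction; ``n_draws`` set for Monte Carlo."""

    mean: float
    sd: float
    n_draws: Optional[int] = None

    @property
    def se_mean(self) -> Optional[float]:
        """Monte-Carlo standard error of the mean (None for Taylor results)."""
        if self.n_draws is None:
            return None
        return self.sd / np.sqrt(self.n_draws)


class FittedGrowthModel:
    """A fitted prediction model: g(theta, x), estimates and their covariance.

    Parameters
    ----------
    predict
        Callable ``predict(theta, x) -> float`` mapping a parameter vector
        and a covariate value (e.g. temperature in °C) to a prediction.
        Must be twice differentiable in ``theta`` near ``theta_hat``.
    theta_hat
        Parameter estimates, length-k vector.
    covariance
        k x k symmetric positive-semidefinite covariance of the estimates.
    """

    def __init__(
        self,
        predict: Callable[[np.ndarray, float], float],
        theta_hat: Sequence[float],
        covariance: Sequence[Sequence[float]],
    ) -> None:
        self.predict = predict
        self.theta_hat = np.atleast_1d(np.asarray(theta_hat, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
        k = self.theta_hat.shape[0]
        if self.covariance.shape != (k, k):
            raise ValueError(
                f"covariance shape {self.covariance.shape} does not match "
                f"{k} parameters"
            )
        if not np.allclose(self.covariance, self.covariance.T, atol=_SYM_TOL):
            raise ValueError("covariance matrix is not symmetric")
        eigvals = np.linalg.eigvalsh(self.covariance)
        scale = max(1.0, float(np.max(np.abs(eigvals), initial=0.0)))
        if np.min(eigvals, initial=0.0) < -_PSD_TOL * scale:
            raise ValueError(
                f"covariance matrix is not positive semidefinite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )


def _gradient_and_hessian(model: FittedGrowthModel, x) -> tuple:
    """Central-difference gradient and Hessian of g in theta at theta_hat."""
    theta = model.theta_hat
    k = theta.shape[0]
    # Central differences with per-coordinate scaled steps: ~eps^(1/3) for
    # first derivatives, ~eps^(1/4) for second, balancing truncation
    # against round-off at each order.
    scale = np.maximum(np.abs(theta), 1.0)
    hg = np.cbrt(np.finfo(float).eps) * scale
    hh = np.finfo(float).eps ** 0.25 * scale

    def g(t: np.ndarray) -> float:
        return float(model.predict(t, x))

    g0 = g(theta)
    grad = np.empty(k)
    hess = np.empty((k, k))
    for j in range(k):
        e = np.zeros(k)
        e[j] = hg[j]
        grad[j] = (g(theta + e) - g(theta - e)) / (2.0 * hg[j])
        e[j] = hh[j]
        hess[j, j] = (g(theta + e) - 2.0 * g0 + g(theta - e)) / hh[j] ** 2
    for j in range(k):
        for l in range(j + 1, k):
            ej = np.zeros(k)
            el = np.zeros(k)
            ej[j] = hh[j]
            el[l] = hh[l]
            gpp = g(theta + ej + el)
            gpm = g(theta + ej - el)
            gmp = g(theta - ej + el)
            gmm = g(theta - ej - el)
            hess[j, l] = hess[l, j] = (gpp - gpm - gmp + gmm) / (4.0 * hh[j] * hh[l])
    return g0, grad, hess


def taylor_propagate(model: FittedGrowthModel, x) -> PropagationResult:
    """Second-order Taylor propagation of parameter uncertainty.

    Returns the second-order mean ``g + tr(H Sigma)/2`` and the SD from
    ``var = grad' Sigma grad + tr((H Sigma)^2)/2``.  Exact when ``predict``
    is linear in theta and theta_hat is multivariate normal.
    """
    g0, grad, hess = _gradient_and_hessian(model, x)
    sigma = model.covariance
    hs = hess @ sigma
    mean = g0 + 0.5 * np.trace(hs)
    var = float(grad @ sigma @ grad) + 0.5 * float(np.trace(hs @ hs))
    if var < 0:
        if var > -1e-12 * max(1.0, abs(mean)):
            var = 0.0
        else:
            raise ArithmeticError(
                f"propagated variance is negative ({var:.3g}); the Hessian "
                "estimate is likely unstable at this step size"
            )
    return PropagationResult(mean=float(mean), sd=float(np.sqrt(var)))


def mc_propagate(
    model: FittedGrowthModel, x, n_draws: int = 100_000, seed: int = 0
) -> PropagationResult:
    """Monte-Carlo propagation: sample theta* ~ MVN(theta_hat, Sigma).

    The prediction is evaluated at each draw and the sample mean/SD are
    returned; reproducible for a fixed seed.
    """
    if n_draws < 1000:
        raise ValueError(f"n_draws must be >= 1000 for a stable SD, got {n_draws}")
    rng = np.random.default_rng(seed)
    thetas = rng.multivariate_normal(
        model.theta_hat, model.covariance, size=n_draws, method="svd"
    )
    values = np.array([float(model.predict(t, x)) for t in thetas])
    return PropagationResult(
        mean=float(values.mean()), sd=float(values.std(ddof=1)), n_draws=n_draws
    )


def make_growth_prior(
    taylor_result: PropagationResult,
    mc_result: PropagationResult,
    policy: str = "mc",
) -> GrowthPrior:
    """Combine the two propagation results into the Normal prior on r.

    policy "mc" (default) keeps the Monte-Carlo mean and SD and uses the
    Taylor mean as a cross-check: a warning is emitted when the two means
    differ by more than twice the Monte-Carlo standard error of the mean.
    policy "taylor" keeps the Taylor moments instead.
    """
    if policy not in ("mc", "taylor"):
        raise ValueError(f"unknown policy {policy!r}")
    se = mc_result.se_mean
    if se is not None:
        gap = abs(taylor_result.mean - mc_result.mean)
        if gap > 2.0 * max(se, 1e-300):
            warnings.warn(
                f"Taylor and Monte-Carlo means disagree by {gap:.4g} "
                f"(> 2 MC standard errors, {2 * se:.4g}); keeping the "
                f"{policy} values — check the prediction function",
                stacklevel=2,
            )
    chosen = mc_result if policy == "mc" else taylor_result
    if chosen.sd <= 0:
        raise ValueError(
            "propagated SD is not positive; a degenerate prior on the growth "
            "rate is not usable"
        )
    return GrowthPrior(m=chosen.mean, sigma=chosen.sd)
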