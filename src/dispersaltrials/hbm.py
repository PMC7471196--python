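"""Hierarchical Bayesian model of multi-stage passive dispersal.

Each tunnel trial i observes the source population N_i, the disperser
count D_i (by subtraction) and, after incubation, the colonizer count C_i
on the target patch.  The founder count F_i — the dispersers that actually
settled — is unobservable.  The generative hierarchy is

    D_i ~ Binomial(N_i, q)                 departure
    F_i ~ Binomial(D_i, p_i)               settlement (latent)
    logit(p_i) = eta_i,  eta_i ~ Normal(mu, sigma_p)   overdispersion
    C_i ~ Poisson(lambda_i),  lambda_i = F_i * (2**r - 1)   growth

with an informative prior r ~ Normal(m, sigma) supplied by the
prior-propagation step, and weakly informative hyperpriors
q ~ Beta(a, b), mu ~ Normal(m0, s0), sigma_p ~ Uniform(0, U).

The dispersal rate q is shared across the trials of a treatment.  During
sampling the latent F_i is marginalized exactly by the finite sum
F = 0..D_i (the F = 0 term contributes a point mass at C = 0); after
sampling, F_i is re-imputed per retained draw from its exact discrete
conditional.  Sampling is by adaptive random-walk Metropolis-within-Gibbs
on the unconstrained parameters (logit q, mu, log sigma_p, r, eta_i), with
the eta block updated jointly (trials are conditionally independent).

Derived quantities reported per draw: population-expected effectiveness
p = logit^{-1}(mu) and colonization potential k = p * (2**r - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, gammaln, log_expit, logsumexp

from .metrics import TrialRecord
from .prior_builder import GrowthPrior

__all__ = [
    "HBMData",
    "PriorSpec",
    "HBMParams",
    "PosteriorDraws",
    "PosteriorSummary",
    "trial_loglik_marginal",
    "log_posterior",
    "fit",
    "summarize",
    "posterior_predictive",
]

RHAT_WARN = 1.05

#: Table-style labels for the reported parameters.
PARAMETER_MEANINGS = {
    "q": "Dispersal rate",
    "p": "Dispersal effectiveness",
    "r": "Population growth rate",
    "k": "Colonization potential",
    "sigma_p": "Standard deviation of the random intercept",
    "mu": "Expected effectiveness on the logit scale",
}


@dataclass(frozen=True)
class HBMData:
    """Trial records feeding the model; dispersers are derived per record."""

    trials: tuple

    def __post_init__(self) -> None:
        trials = tuple(self.trials)
        if len(trials) == 0:
            raise ValueError("at least one trial is required")
        for t in trials:
            if not isinstance(t, TrialRecord):
                raise TypeError(f"expected TrialRecord, got {type(t).__name__}")
        object.__setattr__(self, "trials", trials)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_source(self) -> np.ndarray:
        return np.array([t.n_source for t in self.trials], dtype=np.int64)

    @property
    def dispersers(self) -> np.ndarray:
        return np.array([t.dispersers for t in self.trials], dtype=np.int64)

    @property
    def colonizers(self) -> np.ndarray:
        return np.array([t.n_colonizers for t in self.trials], dtype=np.int64)


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the hierarchy.

    growth        Normal prior (m, sigma) on the population growth rate r,
                  typically built by propagating a temperature-growth model.
    mu_prior      (mean, sd) of the Normal prior on mu (logit scale).
    sigma_p_upper Upper bound of the Uniform(0, U) prior on sigma_p.
    q_prior       (a, b) of the Beta prior on the dispersal rate q.
    """

    growth: GrowthPrior
    mu_prior: tuple = (0.0, 1.5)
    sigma_p_upper: float = 10.0
    q_prior: tuple = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.mu_prior[1] <= 0:
            raise ValueError("mu prior sd must be positive")
        if self.sigma_p_upper <= 0:
            raise ValueError("sigma_p upper bound must be positive")
        if self.q_prior[0] <= 0 or self.q_prior[1] <= 0:
            raise ValueError("Beta prior shapes for q must be positive")


@dataclass(frozen=True)
class HBMParams:
    """One point in parameter space: (q, mu, sigma_p, r, eta_1..eta_n)."""

    q: float
    mu: float
    sigma_p: float
    r: float
    eta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "eta", np.atleast_1d(np.asarray(self.eta, dtype=float)))


# --------------------------------------------------------------------------
# Likelihood with the founder count marginalized
# --------------------------------------------------------------------------


def _log_colonization(D: int, C: int, log_p: float, log_1mp: float, r: float) -> float:
    """log sum_{F=0..D} Binom(F | D, p) * Poisson(C | F * (2**r - 1)).

    The F = 0 term is a point mass at C = 0; terms with a non-positive
    Poisson rate (r <= 0) likewise degenerate to a point mass (rate 0) or
    an impossible event (rate < 0).
    """
    g = 2.0**r - 1.0
    F = np.arange(D + 1)
    lb = (
        gammaln(D + 1)
        - gammaln(F + 1)
        - gammaln(D - F + 1)
        + F * log_p
        + (D - F) * log_1mp
    )
    lpois = np.full(D + 1, -np.inf)
    lpois[0] = 0.0 if C == 0 else -np.inf
    if D >= 1:
        if g > 0:
            lam = F[1:] * g
            lpois[1:] = C * np.log(lam) - lam - gammaln(C + 1)
        elif g == 0 and C == 0:
            lpois[1:] = 0.0
    return float(logsumexp(lb + lpois))


def trial_loglik_marginal(
    N: int, D: int, C: int, q: float, p_i: float, r: float
) -> float:
    """Marginal log-likelihood of one trial's counts (founders summed out).

    Returns log[ Binom(D|N,q) * sum_F Binom(F|D,p_i) * Poisson(C|F(2**r-1)) ].
    An impossible configuration (C > 0 with D = 0) yields -inf, not an
    exception.
    """
    for name, v in (("N", N), ("D", D), ("C", C)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    N, D, C = int(N), int(D), int(C)
    if D > N:
        raise ValueError(f"D ({D}) cannot exceed N ({N})")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie in (0, 1), got {q}")
    if not (0.0 < p_i < 1.0):
        raise ValueError(f"p_i must lie in (0, 1), got {p_i}")
    if not np.isfinite(r):
        raise ValueError(f"r must be finite, got {r}")
    ll_D = (
        gammaln(N + 1)
        - gammaln(D + 1)
        - gammaln(N - D + 1)
        + D * np.log(q)
        + (N - D) * np.log1p(-q)
    )
    return float(ll_D) + _log_colonization(D, C, np.log(p_i), np.log1p(-p_i), r)


def log_posterior(
    data: HBMData,
    params: HBMParams,
    prior: PriorSpec,
    departure_only: bool = False,
) -> float:
    """Unnormalized log posterior density at ``params``.

    Sum of the marginal trial log-likelihoods, the random-effect densities
    eta_i | (mu, sigma_p), the informative prior on r and the hyperpriors
    on q, mu and sigma_p.  Returns -inf outside the support instead of
    raising, so samplers can probe freely.
    """
    q, mu, sp, r = params.q, params.mu, params.sigma_p, params.r
    eta = params.eta
    if eta.shape[0] != data.n_trials:
        raise ValueError(
            f"eta has length {eta.shape[0]} but there are {data.n_trials} trials"
        )
    if not (0.0 < q < 1.0) or not (0.0 < sp < prior.sigma_p_upper):
        return -np.inf
    if not (np.isfinite(mu) and np.isfinite(r) and np.all(np.isfinite(eta))):
        return -np.inf

    N, D, C = data.n_source, data.dispersers, data.colonizers
    total = 0.0
    for i in range(data.n_trials):
        ll_D = (
            gammaln(N[i] + 1)
            - gammaln(D[i] + 1)
            - gammaln(N[i] - D[i] + 1)
            + D[i] * np.log(q)
            + (N[i] - D[i]) * np.log1p(-q)
        )
        total += float(ll_D)
        if not departure_only:
            total += _log_colonization(
                int(D[i]), int(C[i]), float(log_expit(eta[i])), float(log_expit(-eta[i])), r
            )
    total += float(np.sum(stats.norm.logpdf(eta, loc=mu, scale=sp)))
    total += float(stats.norm.logpdf(r, loc=prior.growth.m, scale=prior.growth.sigma))
    total += float(stats.beta.logpdf(q, prior.q_prior[0], prior.q_prior[1]))
    total += float(stats.norm.logpdf(mu, loc=prior.mu_prior[0], scale=prior.mu_prior[1]))
    total += -np.log(prior.sigma_p_upper)
    if not np.isfinite(total):
        return -np.inf
    return total


# --------------------------------------------------------------------------
# Sampler
# --------------------------------------------------------------------------


class _TrialTables:
    """Padded per-trial tables for vectorized marginal-likelihood evaluation."""

    def __init__(self, data: HBMData) -> None:
        self.N = data.n_source
        self.D = data.dispersers
        self.C = data.colonizers
        if np.any((self.D == 0) & (self.C > 0)):
            bad = int(np.nonzero((self.D == 0) & (self.C > 0))[0][0])
            raise ValueError(
                f"trial {data.trials[bad].trial_id!r} has colonizers but no "
                "dispersers; its likelihood is zero under the model"
            )
        n = len(self.D)
        dmax = int(self.D.max())
        F = np.arange(dmax + 1)[None, :]
        self.F = F
        self.valid = F <= self.D[:, None]
        DmF = np.clip(self.D[:, None] - F, 0, None)
        self.DmF = DmF
        lchoose = (
            gammaln(self.D + 1)[:, None] - gammaln(F + 1) - gammaln(DmF + 1)
        )
        self.lchoose = np.where(self.valid, lchoose, -np.inf)
        self.lgC1 = gammaln(self.C + 1)
        self.czero = self.C == 0
        self.n = n
        self.dmax = dmax

    def col_loglik(self, eta: np.ndarray, r: float) -> np.ndarray:
        """Per-trial marginal colonization log-likelihood, vector over trials."""
        g = 2.0**r - 1.0
        logp = log_expit(eta)[:, None]
        log1mp = log_expit(-eta)[:, None]
        lb = self.lchoose + self.F * logp + self.DmF * log1mp
        lpois = np.full((self.n, self.dmax + 1), -np.inf)
        lpois[:, 0] = np.where(self.czero, 0.0, -np.inf)
        if self.dmax >= 1:
            if g > 0:
                lam = self.F[0, 1:] * g
                lpois[:, 1:] = (
                    self.C[:, None] * np.log(lam)[None, :]
                    - lam[None, :]
                    - self.lgC1[:, None]
                )
            elif g == 0:
                lpois[:, 1:] = np.where(self.czero, 0.0, -np.inf)[:, None]
        return logsumexp(lb + lpois, axis=1)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shape (n_chains, n_draws) per scalar parameter.

    Per-trial quantities (eta_i, p_i, founders F_i) have a trailing trial
    axis.  ``founders`` is None for a departure-only fit.  Derived per-draw
    quantities p = logit^{-1}(mu) and k = p * (2**r - 1) are exposed as
    properties.
    """

    q: np.ndarray
    mu: np.ndarray
    sigma_p: np.ndarray
    r: np.ndarray
    eta: np.ndarray
    founders: Optional[np.ndarray]
    seed: int
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.q.shape[0]

    @property
    def n_draws(self) -> int:
        return self.q.shape[1]

    @property
    def n_trials(self) -> int:
        return self.eta.shape[2]

    @property
    def p(self) -> np.ndarray:
        """Population-expected dispersal effectiveness, logit^{-1}(mu)."""
        return expit(self.mu)

    @property
    def k(self) -> np.ndarray:
        """Colonization potential, p * (2**r - 1), per draw."""
        return self.p * (2.0**self.r - 1.0)

    @property
    def p_trial(self) -> np.ndarray:
        """Per-trial effectiveness logit^{-1}(eta_i), per draw."""
        return expit(self.eta)

    def flat(self, name: str) -> np.ndarray:
        """Draws of a scalar parameter pooled across chains."""
        return np.asarray(getattr(self, name)).reshape(-1)

    def to_frame(self):
        """One row per (chain, draw) with scalar, derived and per-trial columns."""
        import pandas as pd

        nc, nd, nt = self.n_chains, self.n_draws, self.n_trials
        chain = np.repeat(np.arange(nc), nd)
        draw = np.tile(np.arange(nd), nc)
        cols = {
            "chain": chain,
            "draw": draw,
            "q": self.flat("q"),
            "mu": self.flat("mu"),
            "sigma_p": self.flat("sigma_p"),
            "r": self.flat("r"),
            "p": self.flat("p"),
            "k": self.flat("k"),
        }
        eta = self.eta.reshape(nc * nd, nt)
        for i in range(nt):
            cols[f"eta_{i + 1}"] = eta[:, i]
        if self.founders is not None:
            fo = self.founders.reshape(nc * nd, nt)
            for i in range(nt):
                cols[f"F_{i + 1}"] = fo[:, i]
        return pd.DataFrame(cols)


def _run_chain(
    tables: _TrialTables,
    prior: PriorSpec,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    departure_only: bool,
) -> dict:
    n = tables.n
    a_q, b_q = prior.q_prior
    m0, s0 = prior.mu_prior
    m_r, s_r = prior.growth.m, prior.growth.sigma
    sumD = float(tables.D.sum())
    sumNmD = float((tables.N - tables.D).sum())

    # Target density of logit(q): Beta(a,b) prior + binomial likelihood +
    # the logit Jacobian q(1-q), which merges into the exponents.
    def lp_zq(zq: float) -> float:
        return (sumD + a_q) * float(log_expit(zq)) + (sumNmD + b_q) * float(
            log_expit(-zq)
        )

    def lp_r(r: float) -> float:
        return -0.5 * ((r - m_r) / s_r) ** 2

    def lp_mu(mu: float) -> float:
        return -0.5 * ((mu - m0) / s0) ** 2

    def eta_prior_sum(eta: np.ndarray, mu: float, sig: float) -> float:
        return -n * np.log(sig) - 0.5 * float(np.sum(((eta - mu) / sig) ** 2))

    # Initial state: q near its empirical proportion, the rest near the
    # prior center, all jittered so chains start overdispersed.
    q0 = (sumD + 1.0) / (sumD + sumNmD + 2.0)
    zq = float(np.log(q0 / (1.0 - q0)) + 0.5 * rng.standard_normal())
    mu = float(m0 + s0 * 0.5 * rng.standard_normal())
    lsig = float(np.log(rng.uniform(0.3, 1.5)))
    r = float(m_r + 0.5 * s_r * rng.standard_normal())
    eta = mu + np.exp(lsig) * rng.standard_normal(n)

    col = (
        np.zeros(n) if departure_only else tables.col_loglik(eta, r)
    )

    scales = {"zq": 0.5, "mu": 0.5, "lsig": 0.5, "r": 0.3 * s_r, "joint": 0.5 * s_r}
    s_eta = np.full(n, 0.8)
    target_acc = 0.30

    out = {
        "q": np.empty(n_draws),
        "mu": np.empty(n_draws),
        "sigma_p": np.empty(n_draws),
        "r": np.empty(n_draws),
        "eta": np.empty((n_draws, n)),
    }

    cur_zq_lp = lp_zq(zq)
    total_iter = n_warmup + n_draws
    # Pre-drawn innovations: 5 scalar moves + the eta block per iteration.
    z_norm = rng.standard_normal((total_iter, 5))
    z_unif = rng.uniform(size=(total_iter, 5))
    e_norm = rng.standard_normal((total_iter, n))
    e_unif = rng.uniform(size=(total_iter, n))

    for t in range(total_iter):
        warm = t < n_warmup
        gamma = (t + 10.0) ** -0.6 if warm else 0.0

        # --- logit(q)
        prop = zq + scales["zq"] * z_norm[t, 0]
        lp_prop = lp_zq(prop)
        alpha = min(1.0, np.exp(min(0.0, lp_prop - cur_zq_lp)))
        if z_unif[t, 0] < alpha:
            zq, cur_zq_lp = prop, lp_prop
        if warm:
            scales["zq"] *= np.exp(gamma * (alpha - target_acc))

        sig = np.exp(lsig)

        # --- mu (only the random-effect layer and its own prior depend on it)
        prop = mu + scales["mu"] * z_norm[t, 1]
        delta = (
            eta_prior_sum(eta, prop, sig)
            + lp_mu(prop)
            - eta_prior_sum(eta, mu, sig)
            - lp_mu(mu)
        )
        alpha = min(1.0, np.exp(min(0.0, delta)))
        if z_unif[t, 1] < alpha:
            mu = prop
        if warm:
            scales["mu"] *= np.exp(gamma * (alpha - target_acc))

        # --- log(sigma_p); Uniform(0, U) prior, log Jacobian = lsig
        prop = lsig + scales["lsig"] * z_norm[t, 2]
        if np.exp(prop) >= prior.sigma_p_upper:
            alpha = 0.0
        else:
            delta = (
                eta_prior_sum(eta, mu, np.exp(prop))
                + prop
                - eta_prior_sum(eta, mu, sig)
                - lsig
            )
            alpha = min(1.0, np.exp(min(0.0, delta)))
            if z_unif[t, 2] < alpha:
                lsig = prop
                sig = np.exp(lsig)
        if warm:
            scales["lsig"] *= np.exp(gamma * (alpha - target_acc))

        # --- r (informative prior + all colonization terms)
        if not departure_only:
            prop = r + scales["r"] * z_norm[t, 3]
            col_prop = tables.col_loglik(eta, prop)
            delta = float(col_prop.sum()) + lp_r(prop) - float(col.sum()) - lp_r(r)
            alpha = min(1.0, np.exp(min(0.0, delta)))
            if z_unif[t, 3] < alpha:
                r, col = prop, col_prop
            if warm:
                scales["r"] *= np.exp(gamma * (alpha - target_acc))

            # --- joint (r, mu, eta) ridge move: faster growth needs fewer
            # founders, so translate mu and every eta to keep
            # p * (2**r - 1) roughly constant.  Shifting mu with the etas
            # leaves the random-effect layer invariant; the map is a
            # translation (unit Jacobian).
            r_prop = r + scales["joint"] * z_norm[t, 4]
            g_cur, g_prop = 2.0**r - 1.0, 2.0**r_prop - 1.0
            if g_prop > 0 and g_cur > 0:
                shift = np.log(g_prop) - np.log(g_cur)
                eta_prop = eta - shift
                mu_prop = mu - shift
                col_prop = tables.col_loglik(eta_prop, r_prop)
                delta = (
                    float(col_prop.sum())
                    + lp_r(r_prop)
                    + lp_mu(mu_prop)
                    - float(col.sum())
                    - lp_r(r)
                    - lp_mu(mu)
                )
                alpha = min(1.0, np.exp(min(0.0, delta)))
                if z_unif[t, 4] < alpha:
                    r, eta, mu, col = r_prop, eta_prop, mu_prop, col_prop
            else:
                alpha = 0.0
            if warm:
                scales["joint"] *= np.exp(gamma * (alpha - target_acc))

        # --- eta block: conditionally independent given (mu, sigma_p, r),
        # so propose jointly and accept per trial.
        prop = eta + s_eta * e_norm[t]
        if departure_only:
            col_prop = col
            delta_i = -0.5 * ((prop - mu) / sig) ** 2 + 0.5 * ((eta - mu) / sig) ** 2
        else:
            col_prop = tables.col_loglik(prop, r)
            delta_i = (
                col_prop
                - col
                - 0.5 * ((prop - mu) / sig) ** 2
                + 0.5 * ((eta - mu) / sig) ** 2
            )
        alpha_i = np.minimum(1.0, np.exp(np.minimum(0.0, delta_i)))
        accept = e_unif[t] < alpha_i
        eta = np.where(accept, prop, eta)
        col = np.where(accept, col_prop, col)
        if warm:
            s_eta *= np.exp(gamma * (alpha_i - target_acc))

        if not warm:
            j = t - n_warmup
            out["q"][j] = expit(zq)
            out["mu"][j] = mu
            out["sigma_p"][j] = sig
            out["r"][j] = r
            out["eta"][j] = eta
    return out


def _impute_founders(
    tables: _TrialTables,
    eta: np.ndarray,
    r: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample F_i | (D_i, p_i, r, C_i) from its exact discrete conditional.

    eta and r are flattened draw arrays; returns founders with the same
    leading shape and a trailing trial axis.  Uses the Gumbel-max trick on
    the conditional log-weights.
    """
    M = r.shape[0]
    n = tables.n
    founders = np.zeros((M, n), dtype=np.int64)
    g = 2.0**r - 1.0
    for i in range(n):
        D, C = int(tables.D[i]), int(tables.C[i])
        if D == 0:
            continue
        F = np.arange(D + 1)
        lch = (
            gammaln(D + 1) - gammaln(F + 1) - gammaln(D - F + 1)
        )
        e = eta[:, i]
        lb = lch[None, :] + F[None, :] * log_expit(e)[:, None] + (D - F)[
            None, :
        ] * log_expit(-e)[:, None]
        lpois = np.full((M, D + 1), -np.inf)
        lpois[:, 0] = 0.0 if C == 0 else -np.inf
        pos = g > 0
        if np.any(pos):
            lam = g[pos, None] * F[None, 1:]
            lpois[pos, 1:] = C * np.log(lam) - lam - gammaln(C + 1)
        if C == 0:
            zero = g == 0
            lpois[zero, 1:] = 0.0
        lw = lb + lpois
        gum = rng.gumbel(size=lw.shape)
        founders[:, i] = np.argmax(lw + gum, axis=1)
    return founders


def fit(
    data: HBMData,
    prior: PriorSpec,
    n_chains: int = 4,
    n_warmup: int = 2000,
    n_draws: int = 4000,
    seed: int = 0,
    departure_only: bool = False,
) -> PosteriorDraws:
    """Sample the posterior of the dispersal hierarchy by adaptive MCMC.

    The latent founder counts are marginalized exactly during sampling and
    re-imputed afterwards from their discrete conditionals.  Split-Rhat and
    effective sample sizes are attached as diagnostics; any split-Rhat
    above 1.05 produces a warning (recorded on the output, never silent).

    With ``departure_only=True`` the colonization stage is dropped and the
    likelihood reduces to the binomial departure counts D_i | (N_i, q);
    the remaining parameters then follow their priors.
    """
    if n_chains < 2:
        raise ValueError("at least 2 chains are required for split-Rhat")
    if n_warmup < 1 or n_draws < 1:
        raise ValueError("n_warmup and n_draws must be positive")
    tables = _TrialTables(data)
    seed = int(seed)
    children = np.random.SeedSequence(seed).spawn(n_chains + 1)
    chains = [
        _run_chain(
            tables,
            prior,
            n_warmup,
            n_draws,
            np.random.default_rng(children[c]),
            departure_only,
        )
        for c in range(n_chains)
    ]

    q = np.stack([c["q"] for c in chains])
    mu = np.stack([c["mu"] for c in chains])
    sigma_p = np.stack([c["sigma_p"] for c in chains])
    r = np.stack([c["r"] for c in chains])
    eta = np.stack([c["eta"] for c in chains])

    founders = None
    if not departure_only:
        rng_f = np.random.default_rng(children[n_chains])
        founders = _impute_founders(
            tables, eta.reshape(-1, tables.n), r.reshape(-1), rng_f
        ).reshape(n_chains, n_draws, tables.n)

    draws = PosteriorDraws(
        q=q, mu=mu, sigma_p=sigma_p, r=r, eta=eta, founders=founders, seed=seed
    )
    draws.diagnostics = _diagnostics(draws)
    bad = {
        k: v["rhat"]
        for k, v in draws.diagnostics.items()
        if np.isfinite(v["rhat"]) and v["rhat"] > RHAT_WARN
    }
    if bad:
        msg = (
            "possible non-convergence: split-Rhat above "
            f"{RHAT_WARN} for " + ", ".join(f"{k}={v:.3f}" for k, v in bad.items())
        )
        draws.warnings.append(msg)
        warnings.warn(msg, stacklevel=2)
    return draws


def _diagnostics(draws: PosteriorDraws) -> dict:
    """Split-Rhat and bulk ESS per scalar parameter (via arviz)."""
    import arviz as az

    data = {
        "q": draws.q,
        "mu": draws.mu,
        "sigma_p": draws.sigma_p,
        "r": draws.r,
        "p": draws.p,
        "k": draws.k,
    }
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.convert_to_dataset(data))
        ess = az.ess(az.convert_to_dataset(data))
    for name in data:
        out[name] = {
            "rhat": float(rhat[name].values),
            "ess": float(ess[name].values),
        }
    return out


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior means and central 95% credible intervals per parameter."""

    table: "object"  # pandas.DataFrame: parameter, meaning, mean, q2.5, q97.5, rhat, ess

    def row(self, parameter: str) -> dict:
        df = self.table
        match = df[df["parameter"] == parameter]
        if len(match) == 0:
            raise KeyError(parameter)
        return match.iloc[0].to_dict()


def summarize(draws: PosteriorDraws, parameters: Sequence[str] = None) -> PosteriorSummary:
    """Posterior mean and 2.5%/97.5% quantiles per reported parameter.

    Derived quantities (p, k) are computed per draw before summarizing, so
    e.g. the summary of k is the summary of p * (2**r - 1) draw by draw,
    not a function of the summaries of p and r.
    """
    import pandas as pd

    total = draws.n_chains * draws.n_draws
    if total < 100:
        raise ValueError(f"need at least 100 retained draws, got {total}")
    if parameters is None:
        parameters = ["q", "p", "r", "k", "sigma_p", "mu"]
    rows = []
    for name in parameters:
        if name not in PARAMETER_MEANINGS:
            raise KeyError(f"unknown parameter {name!r}")
        x = draws.flat(name)
        diag = draws.diagnostics.get(name, {})
        rows.append(
            {
                "parameter": name,
                "meaning": PARAMETER_MEANINGS[name],
                "mean": float(np.mean(x)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
                "rhat": float(diag.get("rhat", np.nan)),
                "ess": float(diag.get("ess", np.nan)),
            }
        )
    return PosteriorSummary(table=pd.DataFrame(rows))


def posterior_predictive(
    draws: PosteriorDraws, data: HBMData, seed: int = 0
) -> dict:
    """Replicate (D*, F*, C*) per trial for each retained draw.

    Simulates the full generative chain — departure, a fresh random effect
    eta* ~ Normal(mu, sigma_p), settlement, growth — for model checking
    against the observed colonizer counts.  Returns arrays of shape
    (n_chains * n_draws, n_trials).
    """
    rng = np.random.default_rng(int(seed))
    N = data.n_source
    q = draws.flat("q")[:, None]
    mu = draws.flat("mu")[:, None]
    sp = draws.flat("sigma_p")[:, None]
    r = draws.flat("r")[:, None]
    M, n = q.shape[0], len(N)
    D = rng.binomial(N[None, :], q)
    eta = mu + sp * rng.standard_normal((M, n))
    F = rng.binomial(D, expit(eta))
    lam = F * np.clip(2.0**r - 1.0, 0.0, None)
    C = rng.poisson(lam)
    return {"D": D, "F": F, "C": C}
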