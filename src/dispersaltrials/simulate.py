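"""Forward generative simulator of dispersal-tunnel experiments.

Draws synthetic trial tables from exactly the hierarchy the inference
module fits — binomial departure, logit-normal trial effects, binomial
founding, Poisson colonization — and returns the latent truth alongside,
for parameter-recovery and coverage experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .hbm import HBMData
from .metrics import TrialRecord

__all__ = ["SimConfig", "simulate_trials", "simulate_comparison"]


@dataclass(frozen=True)
class SimConfig:
    """Generative truth for a simulated tunnel experiment.

    source_sizes may be a single fixed N, an explicit per-trial sequence,
    or ``("poisson", mean)`` for Poisson-distributed sizes (zero-truncated,
    since a trial needs at least one individual on the source patch).
    """

    n_trials: int
    source_sizes: Union[int, Sequence[int], tuple]
    q_true: float
    mu_true: float
    sigma_p_true: float
    r_true: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 <= self.q_true <= 1.0):
            raise ValueError(f"q_true must lie in [0, 1], got {self.q_true}")
        if self.sigma_p_true < 0:
            raise ValueError("sigma_p_true must be non-negative")
        if not np.isfinite(self.mu_true):
            raise ValueError("mu_true must be finite")
        if self.r_true <= 0:
            raise ValueError("r_true must be positive")


def _resolve_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.source_sizes
    if isinstance(spec, (int, np.integer)):
        sizes = np.full(config.n_trials, int(spec), dtype=np.int64)
    elif isinstance(spec, tuple) and len(spec) == 2 and spec[0] == "poisson":
        mean = float(spec[1])
        if mean <= 0:
            raise ValueError("Poisson source-size mean must be positive")
        sizes = rng.poisson(mean, size=config.n_trials).astype(np.int64)
        sizes = np.maximum(sizes, 1)
    else:
        sizes = np.asarray(list(spec), dtype=np.int64)
        if sizes.shape[0] != config.n_trials:
            raise ValueError(
                f"got {sizes.shape[0]} source sizes for {config.n_trials} trials"
            )
    if np.any(sizes < 1):
        raise ValueError("all source sizes must be >= 1")
    return sizes


def simulate_trials(config: SimConfig) -> tuple:
    """Draw (D_i, eta_i, F_i, C_i) per trial through the generative chain.

    Returns ``(data, latent)``: an :class:`HBMData` of trial records (with
    ``n_remaining = N - D``) and a DataFrame of the latent truth
    (D_i, eta_i, p_i, F_i) per trial.

    One master seed spawns a deterministic substream per trial, so adding
    trials never perturbs earlier ones.
    """
    master = np.random.SeedSequence(int(config.seed))
    size_ss, *trial_ss = master.spawn(config.n_trials + 1)
    sizes = _resolve_sizes(config, np.random.default_rng(size_ss))

    growth = 2.0**config.r_true - 1.0
    records, latent_rows = [], []
    for i in range(config.n_trials):
        rng = np.random.default_rng(trial_ss[i])
        N = int(sizes[i])
        D = int(rng.binomial(N, config.q_true))
        eta = float(config.mu_true + config.sigma_p_true * rng.standard_normal())
        p = float(expit(eta))
        F = int(rng.binomial(D, p))
        C = int(rng.poisson(F * growth)) if F > 0 else 0
        trial_id = f"sim_{i + 1:03d}"
        records.append(TrialRecord.from_dispersers(trial_id, N, D, C))
        latent_rows.append(
            {"trial_id": trial_id, "n_source": N, "D": D, "eta": eta, "p": p, "F": F, "C": C}
        )
    return HBMData(tuple(records)), pd.DataFrame(latent_rows)


def simulate_comparison(
    group_sizes: dict,
    totals_per_replicate: dict,
    p_per_group: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-replicate binomial departure counts for two-group tests.

    Parameters are dicts keyed by group label: number of replicates,
    individuals per replicate (a scalar or a per-replicate sequence), and
    the true departure probability.  Returns a table with columns
    replicate_id, dispersers, total, group.
    """
    if set(group_sizes) != set(totals_per_replicate) or set(group_sizes) != set(
        p_per_group
    ):
        raise ValueError("group labels must agree across the three arguments")
    rng = np.random.default_rng(int(seed))
    rows = []
    for group in sorted(group_sizes):
        p = float(p_per_group[group])
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability for group {group!r} must lie in [0, 1]")
        n_rep = int(group_sizes[group])
        totals = totals_per_replicate[group]
        if isinstance(totals, (int, np.integer)):
            totals = [int(totals)] * n_rep
        totals = [int(t) for t in totals]
        if len(totals) != n_rep:
            raise ValueError(
                f"group {group!r}: {len(totals)} totals for {n_rep} replicates"
            )
        if any(t < 1 for t in totals):
            raise ValueError("replicate totals must be >= 1")
        for j, total in enumerate(totals):
            rows.append(
                {
                    "replicate_id": f"{group}_{j + 1:03d}",
                    "dispersers": int(rng.binomial(total, p)),
                    "total": total,
                    "group": group,
                }
            )
    return pd.DataFrame(rows)
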