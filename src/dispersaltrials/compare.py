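"""Two-group comparison of dispersal rates.

Departure counts per replicate are aggregated per group and modeled with a
binomial GLM with logit link (via statsmodels).  Rates are reported with
95% Wald confidence intervals built on the logit scale and back-transformed
(hence asymmetric around the estimate), and the two groups are compared
with a likelihood-ratio test against the pooled single-rate null
(chi-square reference distribution, 1 degree of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["GroupCounts", "RateModelResult", "fit_rate_model", "lr_test"]

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class GroupCounts:
    """Per-replicate (dispersers, total, group) counts.

    The binomial likelihood depends only on per-group sums, so replicate
    structure is collapsed before fitting.
    """

    replicates: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.replicates
        for col in ("dispersers", "total", "group"):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r}")
        if len(df) == 0:
            raise ValueError("no replicates")
        if (df["total"] < 1).any():
            raise ValueError("every replicate total must be >= 1")
        if ((df["dispersers"] < 0) | (df["dispersers"] > df["total"])).any():
            raise ValueError("dispersers must satisfy 0 <= dispersers <= total")

    @classmethod
    def from_replicates(cls, rows) -> "GroupCounts":
        """Build from an iterable of (dispersers, total, group) triples."""
        return cls(pd.DataFrame(rows, columns=["dispersers", "total", "group"]))

    def group_sums(self) -> pd.DataFrame:
        return (
            self.replicates.groupby("group", sort=True)[["dispersers", "total"]]
            .sum()
            .reset_index()
        )


@dataclass(frozen=True)
class RateModelResult:
    """Fitted binomial-GLM rates: per-group estimates, CIs, log-likelihood."""

    rates: dict
    coef: dict  # logit-scale estimate per group (or "pooled")
    se: dict
    ci95: dict  # per group: (lo, hi) on the probability scale
    log_likelihood: float


def fit_rate_model(counts: GroupCounts, pooled: bool = False) -> RateModelResult:
    """Maximum-likelihood dispersal rates via a binomial GLM with logit link.

    With ``pooled=False`` each group gets its own rate (the saturated-by-
    group model); with ``pooled=True`` a single common rate is fitted (the
    null of the likelihood-ratio test).  95% CIs are Wald intervals on the
    logit scale, back-transformed.
    """
    sums = counts.group_sums()
    # Both models are fit on the same per-group rows so that the binomial
    # normalizing constants cancel in the likelihood-ratio statistic.
    endog = np.column_stack([sums["dispersers"], sums["total"] - sums["dispersers"]])
    if not pooled:
        degenerate = sums[
            (sums["dispersers"] == 0) | (sums["dispersers"] == sums["total"])
        ]
        if len(degenerate) > 0:
            bad = ", ".join(repr(g) for g in degenerate["group"])
            raise ValueError(
                f"complete separation: group(s) {bad} have all-zero or "
                "all-disperser counts; the logit-scale estimate is unbounded"
            )
        exog = pd.get_dummies(sums["group"], dtype=float).to_numpy()
        labels = list(sums["group"])
    else:
        s, t = int(sums["dispersers"].sum()), int(sums["total"].sum())
        if s == 0 or s == t:
            raise ValueError(
                "complete separation: the pooled counts are all zeros or all "
                "dispersers; the logit-scale estimate is unbounded"
            )
        exog = np.ones((len(sums), 1))
        labels = ["pooled"]

    with warnings.catch_warnings():
        # the by-group model is saturated by design: statsmodels flags the
        # perfect fit and the zero residual dof, neither is a problem here
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    coef = dict(zip(labels, res.params))
    se = dict(zip(labels, res.bse))
    rates, ci95 = {}, {}
    for lab in labels:
        lo = coef[lab] - _Z975 * se[lab]
        hi = coef[lab] + _Z975 * se[lab]
        rates[lab] = float(stats.logistic.cdf(coef[lab]))
        ci95[lab] = (float(stats.logistic.cdf(lo)), float(stats.logistic.cdf(hi)))
    return RateModelResult(
        rates=rates,
        coef={k: float(v) for k, v in coef.items()},
        se={k: float(v) for k, v in se.items()},
        ci95=ci95,
        log_likelihood=float(res.llf),
    )


def lr_test(counts: GroupCounts) -> dict:
    """Likelihood-ratio test for equal dispersal rates between two groups.

    chi2 = 2 * (loglik of the per-group model - loglik of the pooled
    model); the p-value is the chi-square upper tail with 1 df.
    """
    sums = counts.group_sums()
    if len(sums) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(sums)}")
    full = fit_rate_model(counts, pooled=False)
    null = fit_rate_model(counts, pooled=True)
    chi2 = max(0.0, 2.0 * (full.log_likelihood - null.log_likelihood))
    return {
        "chi2": float(chi2),
        "df": 1,
        "p_value": float(stats.chi2.sf(chi2, df=1)),
    }
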