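"""Choosing the number of clusters by the deviance information criterion.

DIC = D_bar + pD with pD = D_bar - D_hat, equivalently 2*D_bar - D_hat,
where D_bar averages the deviance -2*loglik over posterior draws and D_hat
evaluates the deviance at the posterior means of the parameters.  D_hat uses
*per-subject* posterior means of the assigned intercept and slope (and the
posterior mean of gamma), which makes it invariant under cluster
relabelling without any post-hoc label alignment.

Two selection rules are provided: the +1 SE rule (smallest K whose mean DIC
over repeated runs is within one Monte-Carlo SE of the minimising K's mean)
and the single-run +1 rule (smallest K with DIC within 1 of the minimum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mcmc import CaseControlData, PosteriorSamples, _sigmoid_loglik

__all__ = ["DicSummary", "compute_dic", "select_k_one_se", "select_k_plus_one"]


@dataclass
class DicSummary:
    """DIC decomposition for one fitted model."""

    K: int
    d_bar: float
    d_hat: float
    dic: float
    p_d: float

    def __post_init__(self):
        if self.p_d < 0:
            warnings.warn(
                f"negative effective number of parameters pD={self.p_d:.3f} at K={self.K}"
            )


def compute_dic(samples: PosteriorSamples, data: CaseControlData) -> DicSummary:
    """DIC from stored draws; label-switching-proof by construction."""
    if samples.n_draws == 0:
        raise ValueError("empty posterior sample")
    d_bar = float(np.mean(-2.0 * samples.loglik_draws))

    a_i = samples.subject_posterior_mean(data, "alpha")
    b_i = samples.subject_posterior_mean(data, "beta")
    gamma_mean = (
        samples.gamma_draws.mean(axis=0) if samples.gamma_draws.shape[1] else np.zeros(0)
    )
    eta = a_i + b_i * data.E
    if data.n_covariates:
        eta = eta + data.X @ gamma_mean
    d_hat = -2.0 * _sigmoid_loglik(data.D, eta)
    dic = 2.0 * d_bar - d_hat
    return DicSummary(
        K=samples.config.K, d_bar=d_bar, d_hat=d_hat, dic=dic, p_d=d_bar - d_hat
    )


def select_k_one_se(dic_runs: dict) -> int:
    """The +1 SE rule over repeated runs per K.

    ``dic_runs`` maps K -> sequence of DIC values from independent chains.
    Returns the smallest K whose mean DIC is no greater than the minimising
    K's mean plus the Monte-Carlo SE of that mean (SD over runs divided by
    sqrt(#runs), computed at the minimiser).
    """
    if not dic_runs:
        raise ValueError("empty DIC table")
    ks = sorted(dic_runs)
    means = {k: float(np.mean(dic_runs[k])) for k in ks}
    k_min = min(ks, key=lambda k: means[k])
    runs = np.asarray(dic_runs[k_min], dtype=float)
    if runs.size < 2:
        raise ValueError(
            "need >= 2 runs per K to estimate an SE; use select_k_plus_one for single runs"
        )
    se = float(runs.std(ddof=1) / np.sqrt(runs.size))
    threshold = means[k_min] + se
    for k in ks:
        if means[k] <= threshold:
            return k
    return k_min


def select_k_plus_one(dic_by_k: dict) -> int:
    """The +1 rule: smallest K with DIC within 1 of the minimum."""
    if not dic_by_k:
        raise ValueError("empty DIC table")
    ks = sorted(dic_by_k)
    values = {k: float(dic_by_k[k]) for k in ks}
    threshold = min(values.values()) + 1.0
    for k in ks:
        if values[k] <= threshold:
            return k
    raise AssertionError("unreachable")
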