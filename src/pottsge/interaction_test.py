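"""Parametric-bootstrap likelihood-ratio test for G-E interaction.

The nominal test compares, by MLE, the logistic model with the consensual
latent profile L (categorical), exposure E, covariates X and the L x E
interaction against the same model without the interaction; with K* profile
levels the LRT has K* - 1 df.  Because L is itself estimated from the data,
the nominal p-value p_obs overstates significance; it is therefore treated
as the *test statistic* and calibrated by a parametric bootstrap:

1. fit the no-interaction Bayesian model, select K0* by the +1 rule, build
   the consensual assignment L0;
2. fit, by MLE, the null logistic model with L0, E, X;
3. regenerate every subject's outcome from the fitted null probabilities to
   form B bootstrap datasets (genotypes, exposure and covariates copied);
4. rerun the full interaction pipeline on each replicate to obtain T_b;
5. p = (1 + #{T_b <= p_obs}) / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import chi2

from .consensus import ConsensusPartition, consensus_partition
from .mcmc import INTERACTION, NO_INTERACTION, CaseControlData, ChainConfig, run_chain
from .model_selection import compute_dic, select_k_plus_one

__all__ = [
    "InteractionTestResult",
    "lrt_interaction",
    "fit_null_logistic",
    "bootstrap_null_dataset",
    "resampling_test",
    "fit_select_consensus",
]


@dataclass
class InteractionTestResult:
    """Observed statistic, bootstrap replicates and calibrated p-value."""

    p_obs: float
    statistic: float
    df: int
    k1_star: int
    k0_star: int
    bootstrap_stats: np.ndarray
    p_value: float
    B: int
    n_failed: int = 0


def _design(labels, E, X, interaction: bool):
    """Design matrix: intercept, L dummies (ref = level 0), E, X [, L x E]."""
    labels = np.asarray(labels)
    levels = np.unique(labels)
    n = labels.shape[0]
    cols = [np.ones(n)]
    for lv in levels[1:]:
        cols.append((labels == lv).astype(float))
    cols.append(np.asarray(E, dtype=float))
    for j in range(X.shape[1]):
        cols.append(X[:, j])
    if interaction:
        for lv in levels[1:]:
            cols.append((labels == lv).astype(float) * E)
    return np.column_stack(cols), len(levels)


def _fit_logit(y, design):
    """GLM-Binomial fit; returns (loglik, fitted probabilities, converged)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
    converged = bool(getattr(res, "converged", True)) and np.isfinite(res.llf)
    return float(res.llf), np.asarray(res.fittedvalues), converged, res


def lrt_interaction(data: CaseControlData, labels) -> tuple:
    """Likelihood-ratio test of the L x E interaction at the consensus labels.

    Returns (statistic, df, p).  With quasi-separated data the statistic is
    still reported but flagged through a RuntimeWarning.
    """
    labels = np.asarray(labels)
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise ValueError("interaction LRT needs >= 2 cluster levels")
    if counts.min() == 0:
        raise ValueError("empty cluster level")
    Xf, k = _design(labels, data.E, data.X, interaction=True)
    Xr, _ = _design(labels, data.E, data.X, interaction=False)
    ll_full, _, conv_f, _ = _fit_logit(data.D, Xf)
    ll_red, _, conv_r, _ = _fit_logit(data.D, Xr)
    if not (conv_f and conv_r):
        warnings.warn("logistic fit did not fully converge (possible quasi-separation)",
                      RuntimeWarning)
    stat = max(0.0, 2.0 * (ll_full - ll_red))
    df = k - 1
    return stat, df, float(chi2.sf(stat, df))


def fit_null_logistic(data: CaseControlData, labels0):
    """MLE fit of the no-interaction null model (L0 main effect, E, X).

    Returns (fitted probabilities, statsmodels results object).
    """
    labels0 = np.asarray(labels0)
    X0, _ = _design(labels0, data.E, data.X, interaction=False)
    _, probs, converged, res = _fit_logit(data.D, X0)
    if not converged:
        warnings.warn("null logistic fit did not fully converge", RuntimeWarning)
    return probs, res


def bootstrap_null_dataset(null_probs, data: CaseControlData, rng) -> CaseControlData:
    """A copy of the data with outcomes redrawn as Bernoulli(fitted prob)."""
    D_new = (rng.random(data.n) < np.asarray(null_probs)).astype(np.int64)
    return CaseControlData(
        D=D_new,
        E=data.E,
        X=data.X,
        genotype_id=data.genotype_id,
        table=data.table,
        graph=data.graph,
    )


def fit_select_consensus(
    data: CaseControlData,
    k_grid: Sequence[int],
    config: ChainConfig,
    model_form: str,
    seed: int,
) -> tuple:
    """Fit the Bayesian model over a K grid, select K* by the +1 rule and
    build the consensual partition.

    Returns (k_star, ConsensusPartition, dic_by_k).  For K = 1 grids the
    partition is the trivial single cluster.
    """
    dic_by_k = {}
    samples_by_k = {}
    for i, k in enumerate(sorted(set(k_grid))):
        cfg = replace(config, K=k, model_form=model_form, seed=(seed + 7919 * i) % 2**31)
        samples = run_chain(data, cfg)
        samples_by_k[k] = samples
        dic_by_k[k] = compute_dic(samples, data).dic
    k_star = select_k_plus_one(dic_by_k)
    part = consensus_partition(samples_by_k[k_star], k_star, data=data)
    return k_star, part, dic_by_k


def resampling_test(
    data: CaseControlData,
    k_grid: Sequence[int],
    chain_config: ChainConfig,
    B: int,
    rng=None,
    null_k_grid: Optional[Sequence[int]] = None,
) -> InteractionTestResult:
    """The full parametric-bootstrap G-E interaction test.

    ``k_grid`` is the interaction-model grid and must start at K >= 2 (the
    test is undefined at K = 1); replicates re-select K within the same grid
    by the +1 rule, mirroring the observed-data procedure.  ``null_k_grid``
    defaults to {1} union ``k_grid`` for the no-interaction fit.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    k_grid = sorted(set(int(k) for k in k_grid))
    if min(k_grid) < 2:
        raise ValueError("interaction fits require K >= 2; k_grid must start at 2")
    rng = np.random.default_rng(rng)
    null_grid = sorted(set([1] + k_grid)) if null_k_grid is None else sorted(set(null_k_grid))

    seed0 = int(rng.integers(2**31))
    k1_star, part1, _ = fit_select_consensus(
        data, k_grid, chain_config, INTERACTION, seed0
    )
    stat, df, p_obs = lrt_interaction(data, part1.subject_labels)

    k0_star, part0, _ = fit_select_consensus(
        data, null_grid, chain_config, NO_INTERACTION, seed0 + 1
    )
    if k0_star == 1:
        null_probs, _ = fit_null_logistic(
            data, np.zeros(data.n, dtype=np.int64)
        )
    else:
        null_probs, _ = fit_null_logistic(data, part0.subject_labels)

    stats = np.full(B, np.nan)
    n_failed = 0
    for b in range(B):
        boot = bootstrap_null_dataset(null_probs, data, rng)
        try:
            kb, partb, _ = fit_select_consensus(
                boot, k_grid, chain_config, INTERACTION, int(rng.integers(2**31))
            )
            _, _, stats[b] = lrt_interaction(boot, partb.subject_labels)
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(f"bootstrap replicate {b} failed: {exc}", RuntimeWarning)
            n_failed += 1
    good = stats[np.isfinite(stats)]
    eff_B = good.size
    if eff_B == 0:
        raise RuntimeError("all bootstrap replicates failed")
    p_value = (1.0 + np.sum(good <= p_obs)) / (eff_B + 1.0)
    return InteractionTestResult(
        p_obs=p_obs,
        statistic=stat,
        df=df,
        k1_star=k1_star,
        k0_star=k0_star,
        bootstrap_stats=stats,
        p_value=float(p_value),
        B=eff_B,
        n_failed=n_failed,
    )
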