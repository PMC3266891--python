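"""Benchmark region-level interaction tests: minP-SNP and minP-PC.

minP-SNP takes the minimum nominal p-value over per-SNP likelihood-ratio
tests of SNP x E interaction, each SNP coded as a three-level categorical
(2 df when all three genotypes are observed).  minP-PC does the same over
principal components of the centred genotype matrix, each PC x E test being
1 df.  Because the minimum over correlated tests is anti-conservative, the
minimum is calibrated by a parametric bootstrap under a fitted
main-effects-only logistic null (G main effects + E + X), the same
resampling construction used by the primary test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .interaction_test import _fit_logit
from .mcmc import CaseControlData

__all__ = ["ComparatorResult", "minp_snp_test", "minp_pc_test"]


@dataclass
class ComparatorResult:
    """Per-unit nominal p-values and the calibrated minimum."""

    unit_p_values: np.ndarray
    min_p: float
    p_value: float
    B: int
    which: str
    best_unit: int = -1


def _lrt_pair(y, X_full, X_red, df):
    ll_f, _, _, _ = _fit_logit(y, X_full)
    ll_r, _, _, _ = _fit_logit(y, X_red)
    stat = max(0.0, 2.0 * (ll_f - ll_r))
    return float(chi2.sf(stat, df))


def _snp_design(G, E, X, j, interaction):
    """Design with SNP j categorical (levels observed in the data)."""
    n = G.shape[0]
    levels = np.unique(G[:, j])
    cols = [np.ones(n)]
    dummies = [(G[:, j] == lv).astype(float) for lv in levels[1:]]
    cols.extend(dummies)
    cols.append(E)
    for c in range(X.shape[1]):
        cols.append(X[:, c])
    if interaction:
        cols.extend(d * E for d in dummies)
    return np.column_stack(cols), len(levels) - 1


def _snp_min_p(G, y, E, X):
    J = G.shape[1]
    ps = np.full(J, np.nan)
    for j in range(J):
        if np.unique(G[:, j]).size < 2:
            continue  # monomorphic in this sample
        Xf, df = _snp_design(G, E, X, j, True)
        Xr, _ = _snp_design(G, E, X, j, False)
        ps[j] = _lrt_pair(y, Xf, Xr, df)
    return ps


def _pc_scores(G, n_components=None):
    """Principal component scores of the centred 0/1/2 code matrix.

    Codes are centred but not scaled; each loading vector's sign is fixed so
    its largest-absolute entry is positive.
    """
    Gc = G - G.mean(axis=0)
    if np.allclose(Gc, 0):
        raise ValueError("zero-variance genotype matrix")
    U, s, Vt = np.linalg.svd(Gc, full_matrices=False)
    keep = s > 1e-10 * s[0]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    scores = (U * s) * signs
    if n_components is not None:
        scores = scores[:, :n_components]
    return scores


def _pc_min_p(scores, y, E, X):
    n = scores.shape[0]
    ps = np.empty(scores.shape[1])
    base = [np.ones(n), E] + [X[:, c] for c in range(X.shape[1])]
    for j in range(scores.shape[1]):
        pc = scores[:, j]
        Xr = np.column_stack(base + [pc])
        Xf = np.column_stack(base + [pc, pc * E])
        ps[j] = _lrt_pair(y, Xf, Xr, 1)
    return ps


def _null_probs(G, y, E, X):
    """Fitted probabilities of the G-main-effects + E + X logistic null."""
    n = G.shape[0]
    cols = [np.ones(n)]
    for j in range(G.shape[1]):
        levels = np.unique(G[:, j])
        cols.extend((G[:, j] == lv).astype(float) for lv in levels[1:])
    cols.append(E)
    for c in range(X.shape[1]):
        cols.append(X[:, c])
    _, probs, converged, _ = _fit_logit(y, np.column_stack(cols))
    if not converged:
        warnings.warn("comparator null fit did not fully converge", RuntimeWarning)
    return probs


def _calibrate(min_p_obs, unit_fn, probs, B, rng):
    count = 0
    for _ in range(B):
        yb = (rng.random(probs.shape[0]) < probs).astype(float)
        ps = unit_fn(yb)
        mb = np.nanmin(ps)
        if mb <= min_p_obs:
            count += 1
    return (1.0 + count) / (B + 1.0)


def minp_snp_test(data: CaseControlData, B: int = 199, rng=None) -> ComparatorResult:
    """minP over per-SNP categorical SNP x E interaction LRTs, calibrated."""
    rng = np.random.default_rng(rng)
    G = data.table.codes[data.genotype_id]
    ps = _snp_min_p(G, data.D, data.E, data.X)
    if np.all(np.isnan(ps)):
        raise ValueError("no polymorphic SNPs available")
    min_p = float(np.nanmin(ps))
    probs = _null_probs(G, data.D, data.E, data.X)
    p_cal = _calibrate(
        min_p, lambda yb: _snp_min_p(G, yb, data.E, data.X), probs, B, rng
    )
    return ComparatorResult(
        unit_p_values=ps,
        min_p=min_p,
        p_value=float(p_cal),
        B=B,
        which="minP-SNP",
        best_unit=int(np.nanargmin(ps)),
    )


def minp_pc_test(
    data: CaseControlData, B: int = 199, rng=None, n_components=None
) -> ComparatorResult:
    """minP over per-PC continuous PC x E interaction LRTs, calibrated.

    PC scores depend only on genotypes, which the bootstrap leaves
    unchanged, so they are computed once.
    """
    rng = np.random.default_rng(rng)
    G = data.table.codes[data.genotype_id].astype(float)
    scores = _pc_scores(G, n_components)
    ps = _pc_min_p(scores, data.D, data.E, data.X)
    min_p = float(np.min(ps))
    probs = _null_probs(G.astype(np.int64), data.D, data.E, data.X)
    p_cal = _calibrate(
        min_p, lambda yb: _pc_min_p(scores, yb, data.E, data.X), probs, B, rng
    )
    return ComparatorResult(
        unit_p_values=ps,
        min_p=min_p,
        p_value=float(p_cal),
        B=B,
        which="minP-PC",
        best_unit=int(np.argmin(ps)),
    )
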