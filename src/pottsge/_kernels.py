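"""Compiled inner loops for the discrete samplers.

Single-site Gibbs and Metropolized-Gibbs sweeps over the allocation vector
are inherently sequential, so they are JIT-compiled with numba.  All
randomness enters through pre-generated uniform arrays, keeping the kernels
bit-reproducible under a seeded numpy Generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _site_conditional(scores, u):
    """Sample an index from probabilities proportional to exp(scores)."""
    K = scores.shape[0]
    m = scores[0]
    for k in range(1, K):
        if scores[k] > m:
            m = scores[k]
    total = 0.0
    for k in range(K):
        total += np.exp(scores[k] - m)
    target = u * total
    acc = 0.0
    for k in range(K):
        acc += np.exp(scores[k] - m)
        if acc >= target:
            return k
    return K - 1


@njit(cache=True)
def gibbs_sweeps(z, indptr, indices, weights, psi, K, uniforms):
    """In-place single-site Gibbs sweeps from the prior Potts conditional.

    ``uniforms`` has shape (n_sweeps, H); one uniform per site update.
    """
    n_sweeps = uniforms.shape[0]
    H = z.shape[0]
    scores = np.empty(K)
    for s in range(n_sweeps):
        for h in range(H):
            for k in range(K):
                scores[k] = 0.0
            for idx in range(indptr[h], indptr[h + 1]):
                scores[z[indices[idx]]] += weights[idx]
            for k in range(K):
                scores[k] *= psi
            z[h] = _site_conditional(scores, uniforms[s, h])


@njit(cache=True)
def potts_suff_stat_edges(z, edge_i, edge_j, edge_w):
    """U(z) = sum over edges of w * 1{z_i == z_j}."""
    total = 0.0
    for e in range(edge_i.shape[0]):
        if z[edge_i[e]] == z[edge_j[e]]:
            total += edge_w[e]
    return total


@njit(cache=True)
def sample_potts_u_batch(indptr, indices, weights, psi, K, H, init_states, uniforms):
    """Draw fresh-start Potts samples; return only the sufficient statistics.

    Used by the MCMH update of the regulating parameter, which needs U(z_i)
    for m auxiliary draws.  ``init_states`` is (m, H) integer starts;
    ``uniforms`` is (m, n_sweeps, H).
    """
    m = init_states.shape[0]
    out = np.empty(m)
    z = np.empty(H, dtype=np.int64)
    for i in range(m):
        for h in range(H):
            z[h] = init_states[i, h]
        gibbs_sweeps(z, indptr, indices, weights, psi, K, uniforms[i])
        # U(z) over the symmetric CSR: each edge counted twice, halve
        total = 0.0
        for h in range(H):
            for idx in range(indptr[h], indptr[h + 1]):
                if z[indices[idx]] == z[h]:
                    total += weights[idx]
        out[i] = 0.5 * total
    return out


@njit(cache=True)
def metropolized_gibbs_sweep(
    z, indptr, indices, weights, psi, loglik_hk, u_prop, u_acc
):
    """One Metropolized-Gibbs sweep over all sites, in place.

    The full conditional for site h is proportional to
    exp(psi * u_hk + loglik_hk[h, k]) where u_hk is the summed neighbour
    weight into cluster k under the current z.  The Metropolized variant
    proposes from the conditional restricted to clusters other than the
    current one and accepts with the ratio (1 - p_cur) / (1 - p_prop),
    which dominates plain Gibbs on discrete spaces.

    Returns the number of accepted moves (sites whose label changed).
    """
    H = z.shape[0]
    K = loglik_hk.shape[1]
    scores = np.empty(K)
    probs = np.empty(K)
    accepted = 0
    if K == 1:
        return 0
    for h in range(H):
        for k in range(K):
            scores[k] = loglik_hk[h, k]
        for idx in range(indptr[h], indptr[h + 1]):
            scores[z[indices[idx]]] += psi * weights[idx]
        m = scores[0]
        for k in range(1, K):
            if scores[k] > m:
                m = scores[k]
        total = 0.0
        for k in range(K):
            probs[k] = np.exp(scores[k] - m)
            total += probs[k]
        for k in range(K):
            probs[k] /= total
        cur = z[h]
        p_cur = probs[cur]
        rest = 1.0 - p_cur
        if rest <= 1e-300:
            continue  # conditional is degenerate at the current label
        # propose j != cur with probability probs[j] / rest
        target = u_prop[h] * rest
        acc = 0.0
        prop = -1
        for k in range(K):
            if k == cur:
                continue
            acc += probs[k]
            if acc >= target:
                prop = k
                break
        if prop < 0:
            for k in range(K - 1, -1, -1):
                if k != cur:
                    prop = k
                    break
        denom = 1.0 - probs[prop]
        # p_prop ~ 1 makes the Liu ratio diverge: certain acceptance
        ratio = rest / denom if denom > 1e-300 else 2.0
        if ratio >= 1.0 or u_acc[h] < ratio:
            z[h] = prop
            accepted += 1
    return accepted
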