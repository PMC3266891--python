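"""Ensemble-averaged consensus clustering of the posterior allocations.

Individual MCMC draws of the allocation vector are subject to label
switching and Monte-Carlo noise; the consensus summary sidesteps both.  The
co-assignment matrix pi_hh' records the proportion of stored draws in which
genotypes h and h' share a cluster (invariant under any within-draw label
permutation), and PAM (partitioning around medoids, BUILD + SWAP) on the
dissimilarity 1 - pi yields the consensual K*-cluster partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mcmc import CaseControlData, PosteriorSamples

__all__ = ["ConsensusPartition", "coassignment_matrix", "pam", "consensus_partition"]


@dataclass
class ConsensusPartition:
    """Co-assignment proportions and the consensual partition.

    ``labels`` are 0-based genotype-level cluster labels; ``subject_labels``
    propagate them to subjects through their genotype ids.
    """

    coassign: np.ndarray
    labels: np.ndarray
    subject_labels: np.ndarray
    medoids: np.ndarray

    @property
    def k(self) -> int:
        return len(self.medoids)


def coassignment_matrix(samples: PosteriorSamples) -> np.ndarray:
    """pi_hh' = fraction of stored draws with z_h = z_h'."""
    Z = samples.z_draws
    if Z.shape[0] == 0:
        raise ValueError("empty posterior sample")
    T, H = Z.shape
    pi = np.zeros((H, H))
    # accumulate one-hot outer products per cluster; O(T*K*H^2) bitwise
    K = int(Z.max()) + 1
    for t in range(0, T, 256):
        block = Z[t : t + 256]
        for k in range(K):
            M = (block == k).astype(np.float64)
            pi += M.T @ M
    pi /= T
    np.fill_diagonal(pi, 1.0)
    return pi


def _pam_objective(D: np.ndarray, medoids) -> float:
    return float(D[:, list(medoids)].min(axis=1).sum())


def _swap_to_local_opt(D, medoids, max_iter):
    """Best-improvement SWAP: perform the best (medoid, candidate) exchange
    per pass until none lowers the objective."""
    H = D.shape[0]
    medoids = sorted(medoids)
    best_obj = _pam_objective(D, medoids)
    for _ in range(max_iter):
        best_swap = None
        swap_obj = best_obj
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            partial = D[:, others].min(axis=1) if others else np.full(H, np.inf)
            for c in range(H):
                if c in medoids:
                    continue
                obj = float(np.minimum(partial, D[:, c]).sum())
                if obj < swap_obj - 1e-12:
                    swap_obj = obj
                    best_swap = (mi, c)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids.sort()
        best_obj = swap_obj
    return medoids, best_obj


def pam(dissimilarity, k: int, seed: int = 0, max_iter: int = 100, n_restarts: int = 4):
    """k-medoids by BUILD + SWAP on a precomputed dissimilarity matrix.

    The greedy BUILD seeding is followed by best-improvement SWAP passes; to
    escape the occasional deep local optimum the search is repeated from
    ``n_restarts`` seeded random medoid sets and the best local optimum is
    kept.  Deterministic given ``seed``; exact ties are broken toward the
    lowest medoid ids (candidates are scanned in ascending order).

    Returns (labels, medoids), labels 0-based.
    """
    D = np.asarray(dissimilarity, dtype=float)
    H = D.shape[0]
    if D.shape != (H, H):
        raise ValueError("dissimilarity must be square")
    if k <= 0 or k >= H:
        raise ValueError(f"need 1 <= k < H, got k={k}, H={H}")
    if np.any(D < 0):
        raise ValueError("dissimilarity must be nonnegative")

    # BUILD: greedy seeding
    build = [int(np.argmin(D.sum(axis=1)))]
    while len(build) < k:
        current = D[:, build].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0.0).sum(axis=1)
        gains[build] = -np.inf
        build.append(int(np.argmax(gains)))

    rng = np.random.default_rng(seed)
    starts = [build] + [
        list(rng.choice(H, size=k, replace=False)) for _ in range(n_restarts)
    ]
    best_medoids, best_obj = None, np.inf
    for start in starts:
        medoids, obj = _swap_to_local_opt(D, [int(m) for m in start], max_iter)
        if obj < best_obj - 1e-12:
            best_obj = obj
            best_medoids = medoids

    medoids = np.asarray(sorted(best_medoids), dtype=np.int64)
    labels = np.argmin(D[:, medoids], axis=1).astype(np.int64)
    labels[medoids] = np.arange(len(medoids))  # a medoid belongs to itself
    return labels, medoids


def consensus_partition(
    samples: PosteriorSamples,
    k_star: int,
    data: CaseControlData = None,
    seed: int = 0,
) -> ConsensusPartition:
    """PAM on 1 - pi; labels propagated to subjects via genotype ids."""
    if k_star < 1:
        raise ValueError("k_star must be >= 1")
    pi = coassignment_matrix(samples)
    H = pi.shape[0]
    if k_star == 1:
        labels = np.zeros(H, dtype=np.int64)
        medoids = np.asarray([int(np.argmin((1 - pi).sum(axis=1)))])
    else:
        diss = 1.0 - pi
        np.fill_diagonal(diss, 0.0)
        labels, medoids = pam(diss, k_star, seed=seed)
    subject_labels = (
        labels[data.genotype_id] if data is not None else np.empty(0, dtype=np.int64)
    )
    return ConsensusPartition(
        coassign=pi, labels=labels, subject_labels=subject_labels, medoids=medoids
    )
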