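"""Discrete genotype space and its neighbourhood structure.

A *multilocus genotype* is the joint vector of minor-allele counts (0/1/2)
over the J SNPs of a candidate region.  The latent-profile model operates on
the H *distinct* multilocus genotypes observed in the sample, treating each
as an "area" whose spatial contiguity is defined through a
variance-standardised squared Euclidean distance and a k-nearest-neighbour
graph: two genotypes that are each in the other's k-NN set are strong
neighbours (weight 2), a one-way k-NN relation gives weight 1, anything else
weight 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "GenotypeTable",
    "NeighborGraph",
    "MonomorphicSNPError",
    "InvalidGenotypeCodeError",
    "build_genotype_table",
    "genotype_distance",
    "build_neighbor_graph",
    "regroup_genotypes",
    "impute_missing",
]


class MonomorphicSNPError(ValueError):
    """Raised when a SNP has zero variance over the sample."""


class InvalidGenotypeCodeError(ValueError):
    """Raised when genotype codes fall outside {0, 1, 2}."""


@dataclass(frozen=True)
class GenotypeTable:
    """The distinct multilocus genotypes observed in a sample.

    Attributes
    ----------
    codes : (H, J) int array
        One row per distinct multilocus genotype, entries in {0, 1, 2}.
    subject_index : (n,) int array
        Maps each subject to its genotype row (0-based).
    counts : (H,) int array
        Number of subjects carrying each distinct genotype.
    snp_variance : (J,) float array
        Population (divide-by-n) variance of each SNP's code over all n
        subjects; strictly positive for every retained SNP.
    """

    codes: np.ndarray
    subject_index: np.ndarray
    counts: np.ndarray
    snp_variance: np.ndarray

    @property
    def n_genotypes(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.subject_index.shape[0]


@dataclass(frozen=True)
class NeighborGraph:
    """Symmetric similarity weights between distinct genotypes.

    ``weights`` is a sparse H×H matrix with entries in {0, 1, 2} (2 for
    mutual k-NN pairs, 1 for one-way pairs) and zero diagonal.  The CSR
    arrays and the upper-triangular edge list are cached for the samplers.
    """

    weights: sp.csr_matrix
    n_neighbors: int = 4
    # upper-triangular edge list (h < h'), derived
    edge_i: np.ndarray = field(default=None, repr=False)
    edge_j: np.ndarray = field(default=None, repr=False)
    edge_w: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        coo = sp.triu(self.weights, k=1).tocoo()
        object.__setattr__(self, "edge_i", coo.row.astype(np.int64))
        object.__setattr__(self, "edge_j", coo.col.astype(np.int64))
        object.__setattr__(self, "edge_w", coo.data.astype(np.float64))
        csr = self.weights.tocsr()
        object.__setattr__(
            self,
            "_csr",
            (
                csr.indptr.astype(np.int64),
                csr.indices.astype(np.int64),
                csr.data.astype(np.float64),
            ),
        )

    @property
    def n_genotypes(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.edge_w.sum())

    def csr_arrays(self):
        """(indptr, indices, data) of the full symmetric weight matrix."""
        return self._csr


def build_genotype_table(genotype_matrix, snp_names=None) -> GenotypeTable:
    """Deduplicate an n×J matrix of 0/1/2 codes into a :class:`GenotypeTable`.

    Parameters
    ----------
    genotype_matrix : array-like, shape (n, J)
        Complete genotype codes; missing values are rejected (impute
        upstream, e.g. with :func:`impute_missing`).
    snp_names : sequence of str, optional
        Used only to name offending SNPs in error messages.

    Raises
    ------
    InvalidGenotypeCodeError
        If any code is missing or outside {0, 1, 2}.
    MonomorphicSNPError
        If a SNP has zero sample variance.
    """
    G = np.asarray(genotype_matrix)
    if G.ndim != 2:
        raise ValueError("genotype matrix must be 2-dimensional")
    n, J = G.shape
    if n < 2 or J < 1:
        raise ValueError(f"need n >= 2 subjects and J >= 1 SNPs, got {n}x{J}")
    if not np.isfinite(G.astype(float)).all():
        raise InvalidGenotypeCodeError("missing or non-finite genotype codes")
    Gi = G.astype(np.int64)
    if np.any(Gi.astype(float) != G.astype(float)) or Gi.min() < 0 or Gi.max() > 2:
        bad = np.argwhere((G.astype(float) < 0) | (G.astype(float) > 2))
        raise InvalidGenotypeCodeError(
            f"genotype codes outside {{0,1,2}} (first offender at row "
            f"{bad[0][0] if len(bad) else '?'})"
        )

    var = Gi.var(axis=0)  # population variance, divide-by-n
    if np.any(var <= 0):
        j = int(np.argmin(var))
        name = snp_names[j] if snp_names is not None else f"column {j}"
        raise MonomorphicSNPError(f"SNP {name} is monomorphic (variance 0)")

    codes, inverse, counts = np.unique(
        Gi, axis=0, return_inverse=True, return_counts=True
    )
    return GenotypeTable(
        codes=codes,
        subject_index=inverse.ravel().astype(np.int64),
        counts=counts.astype(np.int64),
        snp_variance=var.astype(np.float64),
    )


def impute_missing(genotype_matrix, missing=-9):
    """Replace missing codes by the per-SNP rounded mean of observed codes."""
    G = np.array(genotype_matrix, dtype=float)
    G[G == missing] = np.nan
    filled = G.copy()
    for j in range(G.shape[1]):
        col = G[:, j]
        mask = np.isnan(col)
        if mask.any():
            if mask.all():
                raise ValueError(f"SNP column {j} entirely missing")
            filled[mask, j] = np.clip(np.round(np.nanmean(col)), 0, 2)
    return filled.astype(np.int64)


def genotype_distance(table: GenotypeTable) -> np.ndarray:
    """Variance-standardised squared Euclidean distance between genotypes.

    d(h, h') = sum_j (g_hj - g_h'j)^2 / s_j^2, with s_j^2 the sample variance
    of SNP j's code over all subjects.  A valid semimetric on genotype rows:
    nonnegative, symmetric, and zero iff the rows are identical.
    """
    X = table.codes.astype(np.float64) / np.sqrt(table.snp_variance)
    diff = X[:, None, :] - X[None, :, :]
    d = np.einsum("hij,hij->hi", diff, diff)
    np.fill_diagonal(d, 0.0)
    return d


def build_neighbor_graph(distance, n_neighbors: int = 4) -> NeighborGraph:
    """Mutual / one-way k-nearest-neighbour weights from a distance matrix.

    w = 2 when each genotype is among the other's ``n_neighbors`` closest
    distinct genotypes, w = 1 when the relation holds one way only.  Ties at
    the k-th nearest distance are broken by ascending genotype id, so the
    graph is deterministic.  When ``n_neighbors >= H - 1`` every pair is a
    mutual neighbour and the graph is complete with all weights 2.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    D = np.asarray(distance, dtype=float)
    H = D.shape[0]
    if D.shape != (H, H):
        raise ValueError("distance must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance must be symmetric")

    k = min(n_neighbors, H - 1)
    is_nn = np.zeros((H, H), dtype=bool)
    ids = np.arange(H)
    for h in range(H):
        others = ids[ids != h]
        # sort by (distance, id): deterministic tie-break
        order = others[np.lexsort((others, D[h, others]))]
        is_nn[h, order[:k]] = True

    # mutual k-NN -> 2, one-way -> 1, else 0
    W = is_nn.astype(np.int8) + is_nn.T.astype(np.int8)
    np.fill_diagonal(W, 0)
    return NeighborGraph(weights=sp.csr_matrix(W.astype(np.float64)), n_neighbors=n_neighbors)


def regroup_genotypes(table: GenotypeTable, target_groups: int, seed: int = 0):
    """Coarsen a large genotype space into ``target_groups`` pseudo-genotypes.

    For regions where H runs into the thousands, the genotype space can first
    be divided into a few hundred subgroups by k-medoids (PAM) on the
    genotype distance, each pseudo-genotype represented by its medoid's
    codes.  Returns a new :class:`GenotypeTable` with remapped subjects.
    """
    import warnings

    from .consensus import pam

    H = table.n_genotypes
    if target_groups >= H:
        if target_groups > H:
            warnings.warn(
                f"target_groups={target_groups} >= H={H}; returning table unchanged"
            )
        return table

    D = genotype_distance(table)
    labels, medoids = pam(D, target_groups, seed=seed)
    new_codes = table.codes[medoids]
    # subjects -> old genotype -> group label
    subj_groups = labels[table.subject_index]
    counts = np.bincount(subj_groups, minlength=target_groups)
    return GenotypeTable(
        codes=new_codes,
        subject_index=subj_groups.astype(np.int64),
        counts=counts.astype(np.int64),
        snp_variance=table.snp_variance,
    )
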