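"""Synthetic case-control data with cluster-structured G-E risk models.

The generator emulates the study design used throughout the simulation
experiments: multilocus genotypes at 15 tagging SNPs in a candidate region,
a binary environmental exposure whose distribution depends on the genotype's
risk region, and retrospective case-control sampling under a logistic risk
model whose intercept and exposure effect vary across latent clusters of the
genotype space.

Genotypes are formed from two independent haplotypes (Hardy-Weinberg at the
haplotype level) drawn either from an explicit haplotype pool, from
independent per-SNP minor-allele frequencies, or from a Gaussian-copula
block-LD model.  The default MAF vector is the 15-SNP reference panel used
in the region-level analyses (0.32, 0.22, ..., 0.24).

Because case-control sampling conditions on the outcome, the baseline
intercept is not identified; the generator uses a working baseline chosen
for a ~10% marginal prevalence, which only affects rejection-sampling
efficiency, never the identified odds-ratio contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit

from .genotype_space import build_genotype_table, build_neighbor_graph, genotype_distance
from .mcmc import CaseControlData

__all__ = [
    "REFERENCE_MAFS",
    "PopulationModel",
    "RiskModelSpec",
    "risk_allele_regions",
    "simulate_genotypes",
    "assign_true_clusters",
    "simulate_exposure",
    "simulate_case_control",
    "build_case_control_data",
]

#: Minor-allele frequencies of the 15-SNP reference panel (region 15q25.1
#: tagging SNPs, estimated in population controls).
REFERENCE_MAFS = np.array(
    [0.32, 0.22, 0.38, 0.23, 0.39, 0.17, 0.12, 0.24, 0.36, 0.37, 0.29, 0.41, 0.30, 0.35, 0.24]
)

#: Functional SNP indices (0-based) of the default three-region partition:
#: the 2nd, 6th and 10th SNPs of the reference panel.
DEFAULT_FUNCTIONAL_SNPS = (1, 5, 9)


@dataclass
class PopulationModel:
    """Haplotype-level population model for a set of J SNPs.

    Exactly one source is active:

    * ``haplotypes``/``hap_freqs``: an explicit pool; haplotypes are drawn
      i.i.d. with the given frequencies.
    * ``mafs`` alone: independent SNPs, allele ~ Bernoulli(maf).
    * ``mafs`` + ``ld_blocks``/``rho``: Gaussian-copula haplotypes with
      exchangeable within-block correlation ``rho`` and independence across
      blocks.
    """

    mafs: Optional[np.ndarray] = None
    ld_blocks: Optional[Sequence[Sequence[int]]] = None
    rho: float = 0.0
    haplotypes: Optional[np.ndarray] = None
    hap_freqs: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int64)
            self.hap_freqs = np.asarray(self.hap_freqs, dtype=float)
            if not np.isclose(self.hap_freqs.sum(), 1.0):
                raise ValueError("haplotype frequencies must sum to 1")
            if self.haplotypes.min() < 0 or self.haplotypes.max() > 1:
                raise ValueError("haplotypes must be 0/1 allele vectors")
        else:
            if self.mafs is None:
                self.mafs = REFERENCE_MAFS.copy()
            self.mafs = np.asarray(self.mafs, dtype=float)
            if np.any(self.mafs <= 0) or np.any(self.mafs > 0.5):
                raise ValueError("MAFs must lie in (0, 0.5]")
            if self.ld_blocks is not None and not (0 <= self.rho < 1):
                raise ValueError("within-block correlation must be in [0, 1)")

    @classmethod
    def reference(cls) -> "PopulationModel":
        """Independent SNPs at the 15 reference MAFs."""
        return cls(mafs=REFERENCE_MAFS.copy())

    @property
    def n_snps(self) -> int:
        if self.haplotypes is not None:
            return self.haplotypes.shape[1]
        return self.mafs.shape[0]

    def draw_haplotypes(self, n: int, rng) -> np.ndarray:
        """(n, J) matrix of 0/1 alleles."""
        if self.haplotypes is not None:
            idx = rng.choice(len(self.haplotypes), size=n, p=self.hap_freqs)
            return self.haplotypes[idx]
        J = self.n_snps
        if self.ld_blocks is None or self.rho == 0.0:
            return (rng.random((n, J)) < self.mafs).astype(np.int64)
        from scipy.stats import norm

        out = np.empty((n, J), dtype=np.int64)
        thresholds = norm.ppf(self.mafs)
        for block in self.ld_blocks:
            block = list(block)
            # exchangeable correlation: shared factor + idiosyncratic noise
            shared = rng.standard_normal((n, 1))
            noise = rng.standard_normal((n, len(block)))
            latent = np.sqrt(self.rho) * shared + np.sqrt(1 - self.rho) * noise
            out[:, block] = (latent < thresholds[block]).astype(np.int64)
        covered = sorted(j for b in self.ld_blocks for j in b)
        if covered != list(range(J)):
            rest = [j for j in range(J) if j not in set(covered)]
            out[:, rest] = (rng.random((n, len(rest))) < self.mafs[rest]).astype(np.int64)
        return out


def simulate_genotypes(pop: PopulationModel, n: int, seed=None) -> np.ndarray:
    """(n, J) genotype codes as the sum of two independent haplotypes."""
    rng = np.random.default_rng(seed)
    return pop.draw_haplotypes(n, rng) + pop.draw_haplotypes(n, rng)


def risk_allele_regions(
    functional_snps: Sequence[int] = DEFAULT_FUNCTIONAL_SNPS,
    cuts: Sequence[int] = (1, 2),
) -> Callable[[np.ndarray], np.ndarray]:
    """Three-region partition by total risk alleles at the functional SNPs.

    With the default cuts: region 0 (I) has <= 1 risk allele, region 1 (II)
    exactly 2, region 2 (III) more than 2.  The minor allele is taken as the
    risk allele.
    """
    lo, hi = cuts

    def rule(G: np.ndarray) -> np.ndarray:
        G = np.asarray(G)
        if max(functional_snps) >= G.shape[1]:
            raise IndexError(
                f"functional SNP index {max(functional_snps)} out of range for J={G.shape[1]}"
            )
        total = G[:, list(functional_snps)].sum(axis=1)
        return np.where(total <= lo, 0, np.where(total <= hi, 1, 2)).astype(np.int64)

    return rule


def dominant_snp_rule(snp: int) -> Callable[[np.ndarray], np.ndarray]:
    """Two clusters: carriers of the minor allele at one SNP vs non-carriers."""

    def rule(G: np.ndarray) -> np.ndarray:
        G = np.asarray(G)
        if snp >= G.shape[1]:
            raise IndexError(f"SNP index {snp} out of range")
        return (G[:, snp] > 0).astype(np.int64)

    return rule


def assign_true_clusters(genotypes, rule) -> np.ndarray:
    """Apply a deterministic partition rule to an (n, J) genotype matrix."""
    labels = np.asarray(rule(np.asarray(genotypes)), dtype=np.int64)
    if labels.min() < 0:
        raise ValueError("partition rule produced negative labels")
    return labels


@dataclass
class RiskModelSpec:
    """A cluster-structured logistic risk model for the simulator.

    ``rule`` maps genotype rows to cluster ids; ``alpha`` and ``beta`` give
    per-cluster intercept contrasts (relative to cluster 0) and exposure log
    odds ratios; ``exposure_prob`` gives P(E = 1 | cluster).  The defaults
    for ``exposure_prob`` encode the G-dependent exposure of the study
    design: P(E=1) = 0.3 in region I and 0.6 elsewhere.
    """

    rule: Callable[[np.ndarray], np.ndarray]
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    exposure_prob: Optional[np.ndarray] = None

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float)) if np.size(self.gamma) else np.zeros(0)
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have one entry per cluster")
        if self.exposure_prob is None:
            k = self.alpha.shape[0]
            self.exposure_prob = np.array([0.3] + [0.6] * (k - 1))
        self.exposure_prob = np.asarray(self.exposure_prob, dtype=float)
        if np.any((self.exposure_prob < 0) | (self.exposure_prob > 1)):
            raise ValueError("exposure probabilities must lie in [0, 1]")

    @property
    def n_clusters(self) -> int:
        return self.alpha.shape[0]


def simulate_exposure(cluster_labels, exposure_prob, seed=None) -> np.ndarray:
    """Binary exposure drawn independently per subject given the cluster."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(cluster_labels, dtype=np.int64)
    p = np.asarray(exposure_prob, dtype=float)
    if labels.max(initial=0) >= p.shape[0]:
        raise ValueError("exposure model does not cover all clusters")
    return (rng.random(labels.shape[0]) < p[labels]).astype(np.int64)


def _working_baseline(pop, risk: RiskModelSpec, rng, target_prev=0.10, pilot=20000):
    """Intercept offset giving ~``target_prev`` marginal prevalence.

    Not identified under case-control sampling; only rejection efficiency
    depends on it.
    """
    G = pop.draw_haplotypes(pilot, rng) + pop.draw_haplotypes(pilot, rng)
    labels = assign_true_clusters(G, risk.rule)
    E = simulate_exposure(labels, risk.exposure_prob, seed=rng)
    eta = risk.alpha[labels] + risk.beta[labels] * E
    lo, hi = -30.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expit(mid + eta).mean() > target_prev:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def simulate_case_control(
    pop: PopulationModel,
    risk: RiskModelSpec,
    n_cases: int,
    n_controls: int,
    seed=None,
    n_neighbors: int = 4,
    covariate_sampler=None,
    max_batches: int = 10_000,
) -> "SimulatedStudy":
    """Retrospective sampling: draw (G, E, D) and keep until quotas fill.

    Subjects are drawn from the population risk model with a working
    baseline intercept (~10% prevalence) and retained as cases or controls
    until exactly ``n_cases`` and ``n_controls`` are collected.  Returns a
    :class:`SimulatedStudy` holding the dataset plus the generating truth.
    """
    rng = np.random.default_rng(seed)
    base = _working_baseline(pop, risk, rng)
    batch = max(2 * (n_cases + n_controls), 1000)

    Gs, Es, Ds, Xs = [], [], [], []
    got_cases = got_controls = 0
    for _ in range(max_batches):
        G = pop.draw_haplotypes(batch, rng) + pop.draw_haplotypes(batch, rng)
        labels = assign_true_clusters(G, risk.rule)
        E = simulate_exposure(labels, risk.exposure_prob, seed=rng)
        eta = base + risk.alpha[labels] + risk.beta[labels] * E
        X = None
        if covariate_sampler is not None:
            X = np.atleast_2d(covariate_sampler(batch, rng))
            if X.shape[0] != batch:
                X = X.T
            eta = eta + X @ risk.gamma
        p = expit(eta)
        if np.all((p < 1e-12) | (p > 1 - 1e-12)):
            raise RuntimeError("degenerate risk model: probabilities are all ~0 or ~1")
        D = (rng.random(batch) < p).astype(np.int64)
        keep_case = np.flatnonzero(D == 1)[: n_cases - got_cases]
        keep_ctrl = np.flatnonzero(D == 0)[: n_controls - got_controls]
        keep = np.concatenate([keep_case, keep_ctrl])
        got_cases += len(keep_case)
        got_controls += len(keep_ctrl)
        Gs.append(G[keep])
        Es.append(E[keep])
        Ds.append(D[keep])
        if X is not None:
            Xs.append(X[keep])
        if got_cases >= n_cases and got_controls >= n_controls:
            break
    else:
        raise RuntimeError(
            f"case-control quota unreachable after {max_batches} batches "
            f"(have {got_cases} cases / {got_controls} controls)"
        )

    G = np.concatenate(Gs)
    E = np.concatenate(Es)
    D = np.concatenate(Ds)
    X = np.concatenate(Xs) if Xs else np.zeros((len(D), 0))
    # shuffle so cases/controls are interleaved
    order = rng.permutation(len(D))
    G, E, D, X = G[order], E[order], D[order], X[order]
    true_labels = assign_true_clusters(G, risk.rule)

    data = build_case_control_data(G, D, E, X, n_neighbors=n_neighbors)
    return SimulatedStudy(data=data, genotypes=G, true_labels=true_labels, risk=risk)


def build_case_control_data(G, D, E, X=None, n_neighbors: int = 4) -> CaseControlData:
    """Assemble a :class:`CaseControlData` from raw arrays."""
    table = build_genotype_table(G)
    graph = build_neighbor_graph(genotype_distance(table), n_neighbors=n_neighbors)
    X = np.zeros((len(D), 0)) if X is None else np.asarray(X, dtype=float)
    return CaseControlData(
        D=np.asarray(D),
        E=np.asarray(E),
        X=X,
        genotype_id=table.subject_index,
        table=table,
        graph=graph,
    )


@dataclass
class SimulatedStudy:
    """A simulated case-control study plus its generating truth."""

    data: CaseControlData
    genotypes: np.ndarray
    true_labels: np.ndarray
    risk: RiskModelSpec
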