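"""Joint posterior sampler for the cluster-structured logistic risk model.

Disease risk for subject i with multilocus genotype c_i allocated to cluster
k = z(c_i) follows a logistic model

    logit P(D_i = 1) = alpha_k + beta_k * E_i + gamma' X_i     (interaction)
    logit P(D_i = 1) = alpha_k + beta   * E_i + gamma' X_i     (no interaction)

with the prospective likelihood applied to retrospectively sampled
case-control data (valid for odds-ratio inference; intercept levels are not
identified, only their contrasts).  The allocation vector z carries the Potts
prior of :mod:`pottsge.potts`.  One sweep of the sampler updates, in order:

* the coefficients, by Gaussian random-walk Metropolis-Hastings on each
  scalar, against likelihood x prior (normal mean 0 variance 4 by default);
* the allocations, by a Metropolized-Gibbs pass over all genotypes;
* the regulating parameter psi, by Monte Carlo Metropolis-Hastings (MCMH):
  the intractable normalizing-constant ratio Z(psi)/Z(psi') is replaced by
  an importance-sampling estimate from m auxiliary Potts draws at the
  current psi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .genotype_space import GenotypeTable, NeighborGraph, genotype_distance
from .potts import PSI_MAX_DEFAULT, _sample_potts_suff_stats, potts_suff_stat

__all__ = [
    "CaseControlData",
    "CoefficientSet",
    "ChainConfig",
    "ChainState",
    "PosteriorSamples",
    "log_likelihood",
    "update_coefficients",
    "update_allocation",
    "update_psi",
    "run_chain",
]

INTERACTION = "interaction"
NO_INTERACTION = "no_interaction"


@dataclass
class CaseControlData:
    """Per-subject outcome, exposure, covariates and genotype id.

    D in {0,1} (1 = case), E binary or continuous exposure, X an (n, p)
    covariate matrix (p may be 0), genotype_id the 0-based index into the
    linked :class:`GenotypeTable`.
    """

    D: np.ndarray
    E: np.ndarray
    X: np.ndarray
    genotype_id: np.ndarray
    table: GenotypeTable
    graph: NeighborGraph

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=np.float64)
        self.E = np.asarray(self.E, dtype=np.float64)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.size == 0:
            self.X = np.zeros((self.n, 0))
        elif self.X.shape[0] != self.n:
            self.X = self.X.T
        self.genotype_id = np.asarray(self.genotype_id, dtype=np.int64)
        if not set(np.unique(self.D)) <= {0.0, 1.0}:
            raise ValueError("disease status must be 0/1")
        if self.n == 0:
            raise ValueError("empty dataset")
        for name, arr in (("E", self.E), ("X", self.X)):
            if not np.isfinite(arr).all():
                raise ValueError(f"missing values in {name}")

    @property
    def n(self) -> int:
        return self.D.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.D.sum())

    @property
    def n_controls(self) -> int:
        return self.n - self.n_cases

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


@dataclass
class CoefficientSet:
    """Cluster intercepts, exposure log odds ratios, covariate coefficients.

    ``beta`` has length K in the interaction model and length 1 (shared
    across clusters) in the no-interaction model.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=np.float64))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=np.float64))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=np.float64)) if np.size(self.gamma) else np.zeros(0)
        for arr in (self.alpha, self.beta, self.gamma):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite coefficient")

    def copy(self) -> "CoefficientSet":
        return CoefficientSet(self.alpha.copy(), self.beta.copy(), self.gamma.copy())


@dataclass
class ChainConfig:
    """Sampler settings.

    Defaults mirror a full-scale analysis (200,000 iterations, half burn-in,
    thinning 10, m = 50 auxiliary draws); the class methods provide reduced
    presets for bootstrap replicates and quick exploratory fits.
    """

    K: int = 2
    model_form: str = INTERACTION
    iterations: int = 200_000
    burn_in: int = 100_000
    thinning: int = 10
    m_auxiliary: int = 50
    aux_sweeps: int = 20
    alpha_scale: float = 0.1
    beta_scale: float = 0.1
    gamma_scale: float = 0.1
    psi_scale: float = 0.05
    prior: str = "normal"  # or "uniform"
    prior_variance: float = 4.0
    uniform_bound: float = 10.0
    psi_max: float = PSI_MAX_DEFAULT
    psi_update_every: int = 1
    psi_warmup_frac: float = 0.25
    adapt: bool = True
    init: str = "risk_profile"  # or "pam" / "random"
    swap_every: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.m_auxiliary < 1:
            raise ValueError("m_auxiliary must be >= 1")
        if self.model_form not in (INTERACTION, NO_INTERACTION):
            raise ValueError(f"unknown model_form {self.model_form!r}")

    @classmethod
    def bootstrap_preset(cls, **kw) -> "ChainConfig":
        """Shorter chains for bootstrap replicates (300k/200k full scale)."""
        kw.setdefault("iterations", 300_000)
        kw.setdefault("burn_in", 200_000)
        return cls(**kw)

    @classmethod
    def desk_preset(cls, **kw) -> "ChainConfig":
        """A reduced preset for small synthetic studies and test benches."""
        kw.setdefault("iterations", 2_000)
        kw.setdefault("burn_in", 1_000)
        kw.setdefault("thinning", 5)
        kw.setdefault("m_auxiliary", 15)
        kw.setdefault("aux_sweeps", 5)
        kw.setdefault("psi_update_every", 5)
        return cls(**kw)

    def with_seed(self, seed: int) -> "ChainConfig":
        return replace(self, seed=seed)

    @property
    def n_beta(self) -> int:
        return self.K if self.model_form == INTERACTION else 1


@dataclass
class ChainState:
    """Mutable sampler state: allocations, psi, coefficients."""

    z: np.ndarray
    psi: float
    coeffs: CoefficientSet


@dataclass
class PosteriorSamples:
    """Thinned posterior draws and acceptance diagnostics.

    ``z_draws`` is (T, H); coefficient draws are (T, K)/(T, n_beta)/(T, p);
    ``loglik_draws`` holds the data log-likelihood of each stored draw.
    """

    z_draws: np.ndarray
    alpha_draws: np.ndarray
    beta_draws: np.ndarray
    gamma_draws: np.ndarray
    psi_draws: np.ndarray
    loglik_draws: np.ndarray
    acceptance: dict
    config: ChainConfig
    shared_beta: bool = field(init=False)

    def __post_init__(self):
        self.shared_beta = self.beta_draws.shape[1] == 1

    @property
    def n_draws(self) -> int:
        return self.z_draws.shape[0]

    def genotype_coefficient_draws(self, which: str = "beta") -> np.ndarray:
        """(T, H) draws of the coefficient assigned to each genotype."""
        T = self.n_draws
        rows = np.arange(T)[:, None]
        if which == "alpha":
            return self.alpha_draws[rows, self.z_draws]
        if which == "beta":
            if self.shared_beta:
                return np.repeat(self.beta_draws, self.z_draws.shape[1], axis=1)
            return self.beta_draws[rows, self.z_draws]
        raise ValueError(which)

    def subject_posterior_median(self, data: CaseControlData, which: str) -> np.ndarray:
        """Per-subject posterior median of the assigned alpha or beta."""
        g = np.median(self.genotype_coefficient_draws(which), axis=0)
        return g[data.genotype_id]

    def subject_posterior_mean(self, data: CaseControlData, which: str) -> np.ndarray:
        g = self.genotype_coefficient_draws(which).mean(axis=0)
        return g[data.genotype_id]


def _sigmoid_loglik(D, eta):
    # D*eta - log(1 + e^eta), stable at extreme linear predictors
    return float(np.sum(D * eta - np.logaddexp(0.0, eta)))


def _linear_predictor(data: CaseControlData, z, coeffs: CoefficientSet, model_form):
    zc = np.asarray(z)[data.genotype_id]
    eta = coeffs.alpha[zc].copy()
    if model_form == INTERACTION:
        eta += coeffs.beta[zc] * data.E
    else:
        eta += coeffs.beta[0] * data.E
    if data.n_covariates:
        eta += data.X @ coeffs.gamma
    return eta


def log_likelihood(data: CaseControlData, z, coeffs: CoefficientSet, model_form=INTERACTION) -> float:
    """Prospective Bernoulli log-likelihood of the cluster-structured model."""
    z = np.asarray(z, dtype=np.int64)
    if z.shape[0] != data.table.n_genotypes:
        raise ValueError("allocation vector length does not match genotype table")
    K = coeffs.alpha.shape[0]
    if model_form == INTERACTION and coeffs.beta.shape[0] != K:
        raise ValueError("interaction model needs one beta per cluster")
    if data.n_covariates != coeffs.gamma.shape[0]:
        raise ValueError("gamma length does not match covariates")
    return _sigmoid_loglik(data.D, _linear_predictor(data, z, coeffs, model_form))


def _log_prior(x: float, config: ChainConfig) -> float:
    if config.prior == "normal":
        return -0.5 * x * x / config.prior_variance
    b = config.uniform_bound
    return 0.0 if -b <= x <= b else -np.inf


def update_coefficients(
    state: ChainState, data: CaseControlData, config: ChainConfig, rng
) -> dict:
    """Random-walk MH on each scalar coefficient; returns per-block accepts.

    Each proposal changes one coefficient, so only the affected subjects'
    likelihood terms are recomputed.
    """
    coeffs = state.coeffs
    zc = state.z[data.genotype_id]
    eta = _linear_predictor(data, state.z, coeffs, config.model_form)
    D = data.D
    accepts = {"alpha": 0, "beta": 0, "gamma": 0}
    proposals = {"alpha": 0, "beta": 0, "gamma": 0}

    def try_move(block, cur, scale, idx, direction):
        """direction: per-subject multiplier of the coefficient in eta."""
        nonlocal eta
        prop = cur + scale * rng.standard_normal()
        lp = _log_prior(prop, config) - _log_prior(cur, config)
        proposals[block] += 1
        if not np.isfinite(lp):
            return cur
        eta_new = eta[idx] + (prop - cur) * direction
        delta = np.sum(
            D[idx] * (eta_new - eta[idx])
            - np.logaddexp(0.0, eta_new)
            + np.logaddexp(0.0, eta[idx])
        )
        if np.log(rng.random()) < delta + lp:
            eta[idx] = eta_new
            accepts[block] += 1
            return prop
        return cur

    for k in range(config.K):
        idx = np.flatnonzero(zc == k)
        coeffs.alpha[k] = try_move(
            "alpha", coeffs.alpha[k], config.alpha_scale, idx, 1.0
        )
    if config.model_form == INTERACTION:
        for k in range(config.K):
            idx = np.flatnonzero(zc == k)
            coeffs.beta[k] = try_move(
                "beta", coeffs.beta[k], config.beta_scale, idx, data.E[idx]
            )
    else:
        all_idx = slice(None)
        coeffs.beta[0] = try_move(
            "beta", coeffs.beta[0], config.beta_scale, all_idx, data.E
        )
    for j in range(data.n_covariates):
        coeffs.gamma[j] = try_move(
            "gamma", coeffs.gamma[j], config.gamma_scale, slice(None), data.X[:, j]
        )
    return {"accepts": accepts, "proposals": proposals}


def _cluster_loglik_by_genotype(data: CaseControlData, coeffs: CoefficientSet, config: ChainConfig):
    """(H, K) matrix: log-likelihood contribution of each genotype's
    subjects were that genotype assigned to cluster k."""
    H = data.table.n_genotypes
    K = config.K
    base = data.X @ coeffs.gamma if data.n_covariates else 0.0
    out = np.empty((H, K))
    for k in range(K):
        b = coeffs.beta[k] if config.model_form == INTERACTION else coeffs.beta[0]
        eta = coeffs.alpha[k] + b * data.E + base
        ll = data.D * eta - np.logaddexp(0.0, eta)
        out[:, k] = np.bincount(data.genotype_id, weights=ll, minlength=H)
    return out


def update_allocation(
    state: ChainState, data: CaseControlData, config: ChainConfig, rng
) -> int:
    """One Metropolized-Gibbs sweep over all genotypes' cluster labels.

    The full conditional for genotype h is proportional to
    exp(psi * u_hk) times the likelihood of h's subjects under cluster k,
    where u_hk sums the neighbour weights from h into cluster k.  A genotype
    carried by no subject and psi = 0 has a uniform conditional.
    """
    if config.K == 1:
        return 0
    loglik_hk = _cluster_loglik_by_genotype(data, state.coeffs, config)
    indptr, indices, weights = data.graph.csr_arrays()
    H = data.table.n_genotypes
    return int(
        _kernels.metropolized_gibbs_sweep(
            state.z,
            indptr,
            indices,
            weights,
            state.psi,
            loglik_hk,
            rng.random(H),
            rng.random(H),
        )
    )


def update_psi(
    state: ChainState, graph: NeighborGraph, config: ChainConfig, rng
) -> bool:
    """MCMH update of the Potts regulating parameter.

    Proposes psi' by a random walk reflected into [0, psi_max].  The exact
    acceptance ratio involves Z(psi)/Z(psi'), which is intractable; it is
    replaced by the importance-sampling estimate
    (1/m) sum_i exp{(psi' - psi) U(z_i)} with z_i drawn fresh from
    Potts(psi).  The uniform prior and the symmetric reflected proposal
    cancel.  Returns True if the proposal was accepted.
    """
    psi = state.psi
    prop = psi + config.psi_scale * rng.standard_normal()
    # reflect into [0, psi_max]
    width = config.psi_max
    prop = abs(prop) % (2 * width)
    if prop > width:
        prop = 2 * width - prop
    u_obs = potts_suff_stat(state.z, graph)
    u_aux = _sample_potts_suff_stats(
        psi, graph, config.K, config.m_auxiliary, config.aux_sweeps, rng
    )
    terms = (prop - psi) * u_aux
    mx = terms.max()
    log_est = mx + np.log(np.exp(terms - mx).mean())
    log_ratio = (prop - psi) * u_obs - log_est
    if np.log(rng.random()) < log_ratio:
        state.psi = prop
        return True
    return False


def swap_coefficients(state: ChainState, data: CaseControlData, config: ChainConfig, rng) -> bool:
    """MH move exchanging two clusters' (alpha, beta) pairs, z unchanged.

    Single-site allocation updates mix poorly between "patchwork" modes in
    which two clusters' roles are locally interchanged; this global move
    jumps between them.  The proposal is symmetric and the coefficient prior
    is exchangeable, so the acceptance ratio is the likelihood ratio.
    """
    K = config.K
    if K < 2:
        return False
    j, k = rng.choice(K, size=2, replace=False)
    coeffs = state.coeffs
    prop = coeffs.copy()
    prop.alpha[[j, k]] = prop.alpha[[k, j]]
    if config.model_form == INTERACTION:
        prop.beta[[j, k]] = prop.beta[[k, j]]
    ll_cur = log_likelihood(data, state.z, coeffs, config.model_form)
    ll_prop = log_likelihood(data, state.z, prop, config.model_form)
    if np.log(rng.random()) < ll_prop - ll_cur:
        state.coeffs = prop
        return True
    return False


def _risk_profile_init(data: CaseControlData, K: int, rng) -> np.ndarray:
    """Cluster genotypes on their empirical (smoothed) risk profiles.

    Each genotype is summarised by the logit of its shrunken case rate among
    unexposed and exposed subjects; k-means on these two coordinates seeds
    the allocation near likelihood-relevant structure.  With a continuous
    exposure the split is at the median.
    """
    from scipy.cluster.vq import kmeans2
    from scipy.special import logit

    H = data.table.n_genotypes
    e_split = np.median(data.E)
    feats = []
    for mask in (data.E <= e_split, data.E > e_split):
        if not mask.any():
            continue
        num = np.bincount(data.genotype_id[mask], weights=data.D[mask], minlength=H)
        den = np.bincount(data.genotype_id[mask], minlength=H)
        p0 = data.D[mask].mean()
        feats.append(logit((num + 4.0 * p0) / (den + 4.0)))
    F = np.column_stack(feats)
    _, labels = kmeans2(F, K, minit="++", seed=int(rng.integers(2**31)))
    # guard: k-means can return empty clusters; remap to a dense label set
    uniq = np.unique(labels)
    if uniq.size < K:
        remap = {u: i for i, u in enumerate(uniq)}
        labels = np.array([remap[v] for v in labels])
        # scatter a few random sites into the missing clusters
        for k in range(uniq.size, K):
            labels[rng.integers(0, H)] = k
    return labels.astype(np.int64)


def _moment_init_coefficients(
    coeffs: CoefficientSet, data: CaseControlData, z0, config: ChainConfig
) -> None:
    """Crude per-cluster intercept/slope starts from empirical case rates.

    Starting every coefficient at 0 leaves the early allocation sweeps with
    no likelihood gradient, which lets clusters evaporate before the
    sampler organises; instead alpha_k and beta_k start at the logit case
    rate of cluster k's low-exposure subjects and the corresponding crude
    log odds ratio.  Clipped to modest magnitudes — this is a starting
    point, not an estimate.
    """
    zc = np.asarray(z0)[data.genotype_id]
    e_split = np.median(data.E)
    lo, hi = data.E <= e_split, data.E > e_split

    def crude_logit(mask):
        n_k = mask.sum()
        return np.log((data.D[mask].sum() + 1.0) / (n_k - data.D[mask].sum() + 1.0))

    overall = crude_logit(np.ones(data.n, dtype=bool))
    for k in range(config.K):
        in_k = zc == k
        a = crude_logit(in_k & lo) if (in_k & lo).any() else overall
        b = (crude_logit(in_k & hi) - a) if (in_k & hi).any() else 0.0
        coeffs.alpha[k] = float(np.clip(a, -3.0, 3.0))
        if config.model_form == INTERACTION:
            coeffs.beta[k] = float(np.clip(b, -3.0, 3.0))
    if config.model_form == NO_INTERACTION:
        a_all = crude_logit(lo) if lo.any() else overall
        b_all = (crude_logit(hi) - a_all) if hi.any() else 0.0
        coeffs.beta[0] = float(np.clip(b_all, -3.0, 3.0))


def _initial_allocation(data: CaseControlData, config: ChainConfig, rng) -> np.ndarray:
    H = data.table.n_genotypes
    if config.K == 1:
        return np.zeros(H, dtype=np.int64)
    if config.init == "random":
        return rng.integers(0, config.K, size=H)
    if config.init == "risk_profile":
        return _risk_profile_init(data, config.K, rng)
    from .consensus import pam

    labels, _ = pam(genotype_distance(data.table), config.K, seed=int(rng.integers(2**31)))
    return labels.astype(np.int64)


def _tune(scale: float, rate: float) -> float:
    if rate < 0.20:
        return scale * 0.8
    if rate > 0.45:
        return scale * 1.25
    return scale


def run_chain(data: CaseControlData, config: ChainConfig) -> PosteriorSamples:
    """Run the full sampler and return thinned posterior draws.

    One iteration sweeps coefficients, then allocations, then psi (every
    ``psi_update_every`` iterations).  Proposal scales are optionally
    adapted during burn-in toward a 20-45% acceptance rate and frozen
    afterwards.  Fully reproducible given ``config.seed``.
    """
    from dataclasses import replace as _replace

    config = _replace(config)  # private copy; adaptation mutates scales
    rng = np.random.default_rng(config.seed)
    K = config.K
    coeffs = CoefficientSet(
        alpha=np.zeros(K), beta=np.zeros(config.n_beta), gamma=np.zeros(data.n_covariates)
    )
    # psi is held at 0 for the first psi_warmup_frac of burn-in so the
    # allocations first organise around the likelihood, then the spatial
    # coupling is released and psi explores [0, psi_max] by MCMH.
    psi_warmup = int(config.psi_warmup_frac * config.burn_in)
    z0 = _initial_allocation(data, config, rng)
    _moment_init_coefficients(coeffs, data, z0, config)
    state = ChainState(z=z0, psi=0.0, coeffs=coeffs)
    ll0 = log_likelihood(data, state.z, state.coeffs, config.model_form)
    if not np.isfinite(ll0):
        raise ValueError(f"non-finite log-likelihood at initialization ({ll0})")

    T = (config.iterations - config.burn_in) // config.thinning
    H = data.table.n_genotypes
    z_draws = np.empty((T, H), dtype=np.int16)
    alpha_draws = np.empty((T, K))
    beta_draws = np.empty((T, config.n_beta))
    gamma_draws = np.empty((T, data.n_covariates))
    psi_draws = np.empty(T)
    loglik_draws = np.empty(T)

    totals = {"alpha": [0, 0], "beta": [0, 0], "gamma": [0, 0], "z": [0, 0], "psi": [0, 0]}
    window = {"alpha": [0, 0], "beta": [0, 0], "gamma": [0, 0], "psi": [0, 0]}
    stored = 0
    for it in range(config.iterations):
        res = update_coefficients(state, data, config, rng)
        for block in ("alpha", "beta", "gamma"):
            totals[block][0] += res["accepts"][block]
            totals[block][1] += res["proposals"][block]
            window[block][0] += res["accepts"][block]
            window[block][1] += res["proposals"][block]
        acc_z = update_allocation(state, data, config, rng)
        totals["z"][0] += acc_z
        totals["z"][1] += H if K > 1 else 0
        if K > 1 and config.swap_every and it % config.swap_every == 0:
            swap_coefficients(state, data, config, rng)
        if (
            it >= psi_warmup
            and config.psi_update_every
            and it % config.psi_update_every == 0
        ):
            acc_psi = update_psi(state, data.graph, config, rng)
            totals["psi"][0] += int(acc_psi)
            totals["psi"][1] += 1
            window["psi"][0] += int(acc_psi)
            window["psi"][1] += 1

        if config.adapt and it < config.burn_in and (it + 1) % 100 == 0:
            for block, attr in (
                ("alpha", "alpha_scale"),
                ("beta", "beta_scale"),
                ("gamma", "gamma_scale"),
                ("psi", "psi_scale"),
            ):
                acc, prop = window[block]
                if prop:
                    setattr(config, attr, _tune(getattr(config, attr), acc / prop))
                window[block] = [0, 0]

        if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0 and stored < T:
            z_draws[stored] = state.z
            alpha_draws[stored] = state.coeffs.alpha
            beta_draws[stored] = state.coeffs.beta
            gamma_draws[stored] = state.coeffs.gamma
            psi_draws[stored] = state.psi
            loglik_draws[stored] = log_likelihood(
                data, state.z, state.coeffs, config.model_form
            )
            stored += 1

    acceptance = {
        block: (vals[0] / vals[1] if vals[1] else float("nan"))
        for block, vals in totals.items()
    }
    return PosteriorSamples(
        z_draws=z_draws[:stored].astype(np.int64),
        alpha_draws=alpha_draws[:stored],
        beta_draws=beta_draws[:stored],
        gamma_draws=gamma_draws[:stored],
        psi_draws=psi_draws[:stored],
        loglik_draws=loglik_draws[:stored],
        acceptance=acceptance,
        config=config,
    )
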