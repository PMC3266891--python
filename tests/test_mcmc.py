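"""Sampler correctness: likelihood, block updates vs exact oracles, chains."""

import itertools

import numpy as np
import pytest

from pottsge import log_likelihood, potts_log_norm_exact, potts_suff_stat
from pottsge.mcmc import (
    INTERACTION,
    CaseControlData,
    ChainConfig,
    ChainState,
    CoefficientSet,
    run_chain,
    update_allocation,
    update_coefficients,
    update_psi,
)

from conftest import make_tiny_data


class TestLogLikelihood:
    def test_all_zero_coefficients(self):
        data = make_tiny_data(seed=1, n=30)
        coeffs = CoefficientSet(np.zeros(2), np.zeros(2), np.zeros(0))
        z = np.zeros(data.table.n_genotypes, dtype=int)
        assert log_likelihood(data, z, coeffs) == pytest.approx(30 * np.log(0.5))

    def test_k1_collapses_to_plain_logistic(self):
        data = make_tiny_data(seed=2, n=50)
        a, b = 0.3, -0.8
        coeffs = CoefficientSet(np.array([a]), np.array([b]), np.zeros(0))
        z = np.zeros(data.table.n_genotypes, dtype=int)
        eta = a + b * data.E
        expected = np.sum(data.D * eta - np.log1p(np.exp(eta)))
        assert log_likelihood(data, z, coeffs) == pytest.approx(expected)

    def test_matches_naive_subject_loop(self):
        rng = np.random.default_rng(3)
        data = make_tiny_data(seed=3, n=40)
        K = 3
        coeffs = CoefficientSet(
            rng.normal(size=K), rng.normal(size=K), np.zeros(0)
        )
        z = rng.integers(0, K, size=data.table.n_genotypes)
        expected = 0.0
        for i in range(data.n):
            k = z[data.genotype_id[i]]
            eta = coeffs.alpha[k] + coeffs.beta[k] * data.E[i]
            p = 1.0 / (1.0 + np.exp(-eta))
            expected += data.D[i] * np.log(p) + (1 - data.D[i]) * np.log(1 - p)
        assert log_likelihood(data, z, coeffs) == pytest.approx(expected)

    def test_stable_at_extreme_linear_predictors(self):
        data = make_tiny_data(seed=4, n=20)
        coeffs = CoefficientSet(np.array([500.0]), np.array([-900.0]), np.zeros(0))
        z = np.zeros(data.table.n_genotypes, dtype=int)
        ll = log_likelihood(data, z, coeffs)
        assert np.isfinite(ll) or ll == -np.inf  # no NaN ever
        assert not np.isnan(ll)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        data = make_tiny_data(seed=5, n=40)
        K = 3
        coeffs = CoefficientSet(rng.normal(size=K), rng.normal(size=K), np.zeros(0))
        z = rng.integers(0, K, size=data.table.n_genotypes)
        perm = np.array([1, 2, 0])
        permuted = CoefficientSet(
            coeffs.alpha[np.argsort(perm)], coeffs.beta[np.argsort(perm)], np.zeros(0)
        )
        assert log_likelihood(data, z, coeffs) == pytest.approx(
            log_likelihood(data, perm[z], permuted)
        )

    def test_dimension_mismatch_rejected(self):
        data = make_tiny_data(seed=6)
        coeffs = CoefficientSet(np.zeros(2), np.zeros(1), np.zeros(0))
        with pytest.raises(ValueError):
            log_likelihood(data, np.zeros(data.table.n_genotypes, dtype=int), coeffs,
                           INTERACTION)


class TestUpdateCoefficients:
    def test_zero_proposal_scale_never_moves(self):
        data = make_tiny_data(seed=7, n=30)
        config = ChainConfig(K=2, iterations=10, burn_in=5, alpha_scale=0.0,
                             beta_scale=0.0, adapt=False)
        rng = np.random.default_rng(0)
        coeffs = CoefficientSet(np.array([0.5, -0.5]), np.array([0.2, 0.1]), np.zeros(0))
        state = ChainState(z=np.zeros(data.table.n_genotypes, dtype=int), psi=0.0,
                           coeffs=coeffs)
        before = (coeffs.alpha.copy(), coeffs.beta.copy())
        for _ in range(20):
            update_coefficients(state, data, config, rng)
        assert np.array_equal(state.coeffs.alpha, before[0])
        assert np.array_equal(state.coeffs.beta, before[1])

    def test_k1_posterior_matches_mle_oracle(self):
        # large simulated plain-logistic data: posterior mean within 2 SD of MLE
        rng = np.random.default_rng(11)
        n = 2000
        E = rng.integers(0, 2, size=n).astype(float)
        eta = -0.4 + 0.9 * E
        D = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        # genotype structure irrelevant at K = 1
        from pottsge import build_genotype_table, build_neighbor_graph, genotype_distance

        G = rng.integers(0, 3, size=(n, 3))
        table = build_genotype_table(G)
        graph = build_neighbor_graph(genotype_distance(table))
        data = CaseControlData(D=D, E=E, X=np.zeros((n, 0)),
                               genotype_id=table.subject_index, table=table, graph=graph)
        cfg = ChainConfig(K=1, iterations=4000, burn_in=1000, thinning=2,
                          m_auxiliary=5, aux_sweeps=2, psi_update_every=0, seed=1)
        samples = run_chain(data, cfg)

        import statsmodels.api as sm

        res = sm.GLM(D, np.column_stack([np.ones(n), E]),
                     family=sm.families.Binomial()).fit()
        a_mle, b_mle = res.params
        a_sd = samples.alpha_draws[:, 0].std()
        b_sd = samples.beta_draws[:, 0].std()
        assert abs(samples.alpha_draws[:, 0].mean() - a_mle) < 2 * a_sd
        assert abs(samples.beta_draws[:, 0].mean() - b_mle) < 2 * b_sd


class TestUpdateAllocation:
    def test_uniform_conditional_for_unobserved_genotype_at_zero_psi(self):
        # genotype carried by no subject, psi = 0: labels ~ uniform over sweeps
        data = make_tiny_data(seed=8, n=25)
        # find or force an unobserved genotype by restricting subjects
        H = data.table.n_genotypes
        config = ChainConfig(K=2, iterations=10, burn_in=5, adapt=False)
        rng = np.random.default_rng(1)
        coeffs = CoefficientSet(np.zeros(2), np.zeros(2), np.zeros(0))
        state = ChainState(z=np.zeros(H, dtype=int), psi=0.0, coeffs=coeffs)
        # with all coefficients 0 and psi 0 every site's conditional is uniform
        counts = np.zeros((H, 2))
        for _ in range(600):
            update_allocation(state, data, config, rng)
            for h in range(H):
                counts[h, state.z[h]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        assert np.all(np.abs(freqs - 0.5) < 0.08)

    def test_dominant_likelihood_forces_assignment(self):
        data = make_tiny_data(seed=9, n=30)
        H = data.table.n_genotypes
        config = ChainConfig(K=2, iterations=10, burn_in=5, adapt=False)
        rng = np.random.default_rng(2)
        # cluster 0 fits the data vastly better than cluster 1 for cases
        coeffs = CoefficientSet(np.array([0.0, -50.0]), np.zeros(2), np.zeros(0))
        state = ChainState(z=np.ones(H, dtype=int), psi=0.0, coeffs=coeffs)
        # genotypes whose subjects include a case must end in cluster 0
        has_case = np.zeros(H, dtype=bool)
        for h in range(H):
            has_case[h] = data.D[data.genotype_id == h].any()
        for _ in range(10):
            update_allocation(state, data, config, rng)
        assert np.all(state.z[has_case] == 0)

    def test_stationary_distribution_matches_enumeration(self):
        """Frozen-coefficient z-chain on H=4, K=2 vs exact 16-state posterior."""
        data = make_tiny_data(seed=10, n=20)
        H = data.table.n_genotypes
        assert H == 4
        K, psi = 2, 0.5
        coeffs = CoefficientSet(np.array([0.8, -0.8]), np.array([-0.5, 0.7]), np.zeros(0))
        config = ChainConfig(K=K, iterations=10, burn_in=5, adapt=False)

        target = {}
        for z in itertools.product(range(K), repeat=H):
            za = np.array(z)
            target[z] = psi * potts_suff_stat(za, data.graph) + log_likelihood(
                data, za, coeffs, INTERACTION
            )
        mx = max(target.values())
        total = sum(np.exp(v - mx) for v in target.values())
        target = {z: np.exp(v - mx) / total for z, v in target.items()}

        rng = np.random.default_rng(3)
        state = ChainState(z=np.zeros(H, dtype=int), psi=psi, coeffs=coeffs)
        counts = {}
        n_sweeps = 30000
        for _ in range(n_sweeps):
            update_allocation(state, data, config, rng)
            key = tuple(state.z)
            counts[key] = counts.get(key, 0) + 1
        for z, p in target.items():
            if p < 0.01:
                continue
            emp = counts.get(z, 0) / n_sweeps
            # autocorrelated draws: generous Monte-Carlo tolerance
            assert emp == pytest.approx(p, abs=max(0.25 * p, 0.015)), z


class TestUpdatePsi:
    def _fixed_state(self, graph, K=2, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.integers(0, K, size=graph.n_genotypes)
        coeffs = CoefficientSet(np.zeros(K), np.zeros(K), np.zeros(0))
        return ChainState(z=z, psi=0.4, coeffs=coeffs)

    def test_identical_proposal_would_be_accepted(self, tiny_graph):
        # with proposal scale 0 the move is psi' = psi and is always accepted
        config = ChainConfig(K=2, iterations=10, burn_in=5, psi_scale=0.0,
                             m_auxiliary=10, aux_sweeps=3, adapt=False)
        state = self._fixed_state(tiny_graph)
        rng = np.random.default_rng(1)
        before = state.psi
        assert update_psi(state, tiny_graph, config, rng)
        assert state.psi == before

    def test_ratio_estimate_converges_to_enumerated_ratio(self, tiny_graph):
        from pottsge.potts import _sample_potts_suff_stats

        K, psi, prop = 2, 0.4, 0.6
        exact = np.exp(
            potts_log_norm_exact(prop, tiny_graph, K)
            - potts_log_norm_exact(psi, tiny_graph, K)
        )
        rng = np.random.default_rng(2)
        u = _sample_potts_suff_stats(psi, tiny_graph, K, 4000, 40, rng)
        est = np.exp((prop - psi) * u).mean()
        se = np.exp((prop - psi) * u).std() / np.sqrt(len(u))
        assert abs(est - exact) < 4 * se

    def test_mcmh_posterior_matches_exact_normalizer_mh(self, tiny_graph):
        """Posterior of psi given fixed z: MCMH vs MH with enumerated Z(psi)."""
        K = 2
        state = self._fixed_state(tiny_graph, K=K, seed=4)
        z = state.z.copy()
        u_obs = potts_suff_stat(z, tiny_graph)
        psi_max = 1.2
        config = ChainConfig(K=K, iterations=10, burn_in=5, psi_scale=0.15,
                             m_auxiliary=40, aux_sweeps=25, psi_max=psi_max,
                             adapt=False)

        rng = np.random.default_rng(5)
        n_iter = 3000
        mcmh = np.empty(n_iter)
        for t in range(n_iter):
            update_psi(state, tiny_graph, config, rng)
            mcmh[t] = state.psi

        # exact-normalizer random-walk MH on the same posterior
        rng2 = np.random.default_rng(6)
        logz = {}

        def log_post(p):
            if p not in logz:
                logz[p] = potts_log_norm_exact(p, tiny_graph, K)
            return p * u_obs - logz[p]

        cur = 0.4
        exact = np.empty(n_iter)
        for t in range(n_iter):
            prop = cur + 0.15 * rng2.standard_normal()
            prop = abs(prop) % (2 * psi_max)
            if prop > psi_max:
                prop = 2 * psi_max - prop
            if np.log(rng2.random()) < log_post(prop) - log_post(cur):
                cur = prop
            exact[t] = cur

        burn = 500
        m1, m2 = mcmh[burn:].mean(), exact[burn:].mean()
        # 3 x MC SE of the mean, inflated for autocorrelation
        se = 3 * np.sqrt(
            mcmh[burn:].var() / (n_iter - burn) + exact[burn:].var() / (n_iter - burn)
        ) * 4
        assert abs(m1 - m2) < max(se, 0.05), (m1, m2)


class TestRunChain:
    def test_single_stored_draw(self):
        data = make_tiny_data(seed=12, n=30)
        cfg = ChainConfig(K=2, iterations=6, burn_in=5, thinning=1,
                          m_auxiliary=3, aux_sweeps=2, seed=0)
        s = run_chain(data, cfg)
        assert s.n_draws == 1

    def test_same_seed_identical_paths(self):
        data = make_tiny_data(seed=13, n=40)
        cfg = ChainConfig(K=2, iterations=200, burn_in=100, thinning=2,
                          m_auxiliary=5, aux_sweeps=3, seed=42)
        s1 = run_chain(data, cfg)
        s2 = run_chain(data, cfg)
        assert np.array_equal(s1.z_draws, s2.z_draws)
        assert np.array_equal(s1.alpha_draws, s2.alpha_draws)
        assert np.array_equal(s1.psi_draws, s2.psi_draws)

    def test_draw_count_contract(self):
        data = make_tiny_data(seed=14, n=30)
        cfg = ChainConfig(K=2, iterations=350, burn_in=150, thinning=10,
                          m_auxiliary=3, aux_sweeps=2, seed=1)
        s = run_chain(data, cfg)
        assert s.n_draws == (350 - 150) // 10

    def test_acceptance_rates_reported(self):
        data = make_tiny_data(seed=15, n=40)
        cfg = ChainConfig(K=2, iterations=300, burn_in=100, thinning=5,
                          m_auxiliary=5, aux_sweeps=3, seed=2)
        s = run_chain(data, cfg)
        for block in ("alpha", "beta", "z", "psi"):
            assert 0.0 <= s.acceptance[block] <= 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ChainConfig(model_form="nonsense")
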