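"""Genotype table construction, distance, and neighbour graph."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pottsge import (
    build_genotype_table,
    build_neighbor_graph,
    genotype_distance,
    regroup_genotypes,
)
from pottsge.genotype_space import (
    InvalidGenotypeCodeError,
    MonomorphicSNPError,
    impute_missing,
)


class TestBuildGenotypeTable:
    def test_deduplicates_repeated_rows(self):
        G = np.array([[0, 1], [0, 1], [2, 0], [0, 1]])
        t = build_genotype_table(G)
        assert t.n_genotypes == 2
        assert sorted(t.counts.tolist()) == [1, 3]
        assert t.counts.sum() == 4
        # every subject maps back to its own row
        assert np.array_equal(t.codes[t.subject_index], G)

    def test_single_distinct_genotype_rejected_as_monomorphic(self):
        # all subjects identical means every SNP is monomorphic
        with pytest.raises(MonomorphicSNPError):
            build_genotype_table(np.tile([1, 2], (5, 1)))

    def test_h_matches_brute_force_row_scan(self):
        rng = np.random.default_rng(42)
        G = rng.integers(0, 3, size=(50, 5))
        t = build_genotype_table(G)
        seen = {tuple(row) for row in G}
        assert t.n_genotypes == len(seen)
        # per-SNP variance over subjects, not over distinct rows
        assert np.allclose(t.snp_variance, G.var(axis=0))

    def test_rejects_bad_codes_and_missing(self):
        with pytest.raises(InvalidGenotypeCodeError):
            build_genotype_table(np.array([[0, 3], [1, 0]]))
        with pytest.raises(InvalidGenotypeCodeError):
            build_genotype_table(np.array([[0.0, np.nan], [1.0, 0.0]]))

    def test_monomorphic_snp_named_in_error(self):
        G = np.array([[0, 1], [1, 1], [2, 1]])
        with pytest.raises(MonomorphicSNPError, match="rs99"):
            build_genotype_table(G, snp_names=["rs1", "rs99"])

    def test_impute_missing_uses_rounded_snp_mean(self):
        G = np.array([[0, 2], [2, -9], [1, 2], [-9, 2]])
        filled = impute_missing(G)
        assert filled[3, 0] == 1  # mean of 0,2,1 = 1
        assert filled[1, 1] == 2


class TestGenotypeDistance:
    def test_semimetric_properties(self, random_table):
        D = genotype_distance(random_table)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)
        off = D[~np.eye(len(D), dtype=bool)]
        assert np.all(off > 0)  # distinct rows strictly positive

    def test_single_snp_difference_scaled_by_variance(self):
        # two genotypes differing by one code unit at a SNP with s^2 = 0.5
        G = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        t = build_genotype_table(G)
        assert np.allclose(t.snp_variance, [0.25, 0.25])
        D = genotype_distance(t)
        i = int(np.flatnonzero((t.codes == [0, 0]).all(axis=1))[0])
        j = int(np.flatnonzero((t.codes == [0, 1]).all(axis=1))[0])
        assert D[i, j] == pytest.approx(1 / 0.25)

    def test_matches_naive_double_loop(self, random_table):
        D = genotype_distance(random_table)
        codes, s2 = random_table.codes, random_table.snp_variance
        H = len(codes)
        expected = np.zeros((H, H))
        for a in range(H):
            for b in range(H):
                expected[a, b] = sum(
                    (codes[a, j] - codes[b, j]) ** 2 / s2[j] for j in range(codes.shape[1])
                )
        assert np.allclose(D, expected)

    def test_invariant_to_subject_permutation(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 3, size=(40, 4))
        t1 = build_genotype_table(G)
        t2 = build_genotype_table(G[rng.permutation(40)])
        assert np.array_equal(t1.codes, t2.codes)
        assert np.allclose(genotype_distance(t1), genotype_distance(t2))


class TestNeighborGraph:
    def test_small_h_gives_complete_graph_of_mutual_pairs(self):
        G = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2]])
        t = build_genotype_table(G)
        g = build_neighbor_graph(genotype_distance(t), n_neighbors=4)
        W = g.weights.toarray()
        assert np.all(np.diag(W) == 0)
        off = W[~np.eye(3, dtype=bool)]
        assert np.all(off == 2)  # k >= H-1: everyone mutual

    def test_one_way_neighbor_gets_weight_one(self):
        # a chain where the far end point is in the hub's k-NN one way only
        D = np.array(
            [
                [0, 1, 2, 3, 10],
                [1, 0, 1, 2, 10],
                [2, 1, 0, 1, 10],
                [3, 2, 1, 0, 10],
                [10, 10, 10, 10, 0],
            ],
            dtype=float,
        )
        g = build_neighbor_graph(D, n_neighbors=2)
        W = g.weights.toarray()
        # genotype 4's 2 nearest are (0,1) but 4 is in nobody's 2-NN
        assert W[4, 0] == 1 and W[4, 1] == 1
        assert W[0, 4] == 1  # symmetry
        assert W[4, 2] == 0 and W[4, 3] == 0

    def test_matches_brute_force_knn(self):
        rng = np.random.default_rng(7)
        G = rng.integers(0, 3, size=(80, 5))
        t = build_genotype_table(G)
        D = genotype_distance(t)
        g = build_neighbor_graph(D, n_neighbors=4)
        H = len(D)
        nn = []
        for h in range(H):
            order = sorted((D[h, o], o) for o in range(H) if o != h)
            nn.append({o for _, o in order[:4]})
        W = g.weights.toarray()
        for a in range(H):
            for b in range(H):
                if a == b:
                    continue
                expected = int(b in nn[a]) + int(a in nn[b])
                assert W[a, b] == expected

    def test_rejects_bad_k(self, random_table):
        D = genotype_distance(random_table)
        with pytest.raises(ValueError):
            build_neighbor_graph(D, n_neighbors=0)

    def test_each_row_has_at_least_k_neighbors(self, random_graph, random_table):
        W = random_graph.weights.toarray()
        assert np.all((W > 0).sum(axis=1) >= 4)


class TestRegroup:
    def test_equal_target_is_identity(self, random_table):
        out = regroup_genotypes(random_table, random_table.n_genotypes)
        assert out is random_table

    def test_duplicate_blocks_recovered(self):
        # two well-separated blocks of genotypes
        block1 = np.array([[0, 0, 0], [0, 0, 1]])
        block2 = np.array([[2, 2, 2], [2, 2, 1]])
        G = np.vstack([np.repeat(block1, 5, axis=0), np.repeat(block2, 5, axis=0)])
        t = build_genotype_table(G)
        out = regroup_genotypes(t, 2)
        assert out.n_genotypes == 2
        # subjects from the same original block share a pseudo-genotype
        labels = out.subject_index
        first, second = labels[:10], labels[10:]
        assert len(set(first.tolist())) == 1
        assert len(set(second.tolist())) == 1
        assert first[0] != second[0]

    def test_matches_exhaustive_medoid_search(self):
        from itertools import combinations

        rng = np.random.default_rng(9)
        base = np.array(
            [[0, 0, 1], [0, 1, 2], [1, 0, 0], [1, 2, 1], [2, 1, 0], [2, 2, 2], [0, 2, 0]]
        )
        G = base[rng.integers(0, len(base), size=30)]
        t = build_genotype_table(G)
        assert t.n_genotypes <= 8
        D = genotype_distance(t)
        H = t.n_genotypes
        k = 2
        best = min(
            (D[:, list(m)].min(axis=1).sum() for m in combinations(range(H), k))
        )
        out = regroup_genotypes(t, k)
        # recompute the PAM objective achieved by the grouping's medoids
        medoid_rows = [
            int(np.flatnonzero((t.codes == row).all(axis=1))[0]) for row in out.codes
        ]
        achieved = D[:, medoid_rows].min(axis=1).sum()
        assert achieved == pytest.approx(best)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_distance_zero_iff_identical(seed):
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 3, size=(20, 4))
    try:
        t = build_genotype_table(G)
    except MonomorphicSNPError:
        return
    D = genotype_distance(t)
    H = t.n_genotypes
    for a in range(H):
        for b in range(H):
            if a == b:
                assert D[a, b] == 0
            else:
                assert D[a, b] > 0
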