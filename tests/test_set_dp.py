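"""Held-Karp, Hamiltonian-path tables and Boltzmann ensemble posteriors."""

import itertools
import math

import numpy as np
import pytest
from scipy.special import logsumexp

from conftest import random_symmetric_matrix
from gadp.set_dp import (
    DistanceMatrix,
    EnsembleParams,
    adjacency_conditional,
    enumerate_hamiltonian_paths,
    held_karp,
    is_robinson,
    path_ensemble,
    shortest_hamiltonian_path,
    shp_inside,
    shp_outside,
)


def ensemble_oracle(dm, params):
    """Posterior summaries from exhaustive path enumeration."""
    paths = enumerate_hamiltonian_paths(dm)
    n = dm.n
    w = np.array([math.exp(-params.alpha * l) for _, l in paths])
    Z = w.sum()
    endpoint = np.zeros(n)
    pair = np.zeros((n, n))
    adj = np.zeros((n, n))
    for (p, _), wi in zip(paths, w):
        endpoint[p[0]] += wi
        endpoint[p[-1]] += wi
        pair[min(p[0], p[-1]), max(p[0], p[-1])] += wi
        for k in range(n - 1):
            adj[p[k], p[k + 1]] += wi
            adj[p[k + 1], p[k]] += wi
    return Z, endpoint / Z, pair / Z, adj / Z


def robinson_matrix(steps):
    t = np.concatenate([[0.0], np.cumsum(steps)])
    return DistanceMatrix(np.abs(t[:, None] - t[None, :]))


class TestDistanceMatrix:
    def test_rejects_nonsquare_negative_and_diagonal(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, -1.0], [-1.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_asymmetry_detection_names_offenders(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        dm = DistanceMatrix(d, ["a", "b"])
        with pytest.raises(ValueError, match="a"):
            dm.require_symmetric()


class TestHeldKarp:
    def test_two_cities(self):
        d = np.array([[0.0, 3.0], [4.0, 0.0]])
        order, length = held_karp(DistanceMatrix(d))
        assert order == [0, 1]
        assert length == 7.0

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_matches_bruteforce_minimum(self, n, seed):
        rng = np.random.default_rng(seed)
        dm = DistanceMatrix(random_symmetric_matrix(rng, n))
        _, length = held_karp(dm)
        best = min(
            sum(dm.d[p[k], p[k + 1]] for k in range(n - 1)) + dm.d[p[-1], p[0]]
            for p in ((0,) + q for q in itertools.permutations(range(1, n)))
        )
        assert length == pytest.approx(best, rel=1e-12)

    def test_asymmetric_matrices_accepted(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(1, 5, (5, 5))
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d)
        _, length = held_karp(dm)
        best = min(
            sum(d[p[k], p[k + 1]] for k in range(4)) + d[p[-1], p[0]]
            for p in ((0,) + q for q in itertools.permutations(range(1, 5)))
        )
        assert length == pytest.approx(best)

    def test_uniform_distances(self):
        n, c = 6, 2.5
        d = np.full((n, n), c)
        np.fill_diagonal(d, 0.0)
        order, length = held_karp(DistanceMatrix(d))
        assert length == pytest.approx(n * c)
        assert order[0] == 0  # anchored, canonical tie-break

    def test_cap_enforced(self):
        dm = DistanceMatrix(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            held_karp(dm, cap=3)


class TestInsideTables:
    def test_count_algebra_complete_graph(self):
        """(n-2)! directed paths per endpoint pair; n!/2 undirected total."""
        n = 4
        dm = DistanceMatrix(random_symmetric_matrix(np.random.default_rng(0), n))
        t = shp_inside(dm, algebra="count")
        full = t.full_mask()
        for p in range(n):
            for q in range(n):
                if p != q:
                    assert t.table[full, p, q] == math.factorial(n - 2)
        total_directed = t.table[full].sum()
        assert total_directed / 2 == math.factorial(n) / 2
        assert len(enumerate_hamiltonian_paths(dm)) == math.factorial(n) // 2

    def test_three_vertices_forced_middle(self):
        d = np.full((3, 3), 4.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d)
        params = EnsembleParams.for_matrix(dm, 1.0)
        t = shp_inside(dm, params)
        # single path p - r - q per endpoint pair
        expect = -params.alpha * 8.0
        assert t.table[0b111, 0, 2] == pytest.approx(expect)

    def test_min_algebra_on_robinson_matrix(self):
        dm = robinson_matrix([2.0, 3.5, 1.0, 4.0, 2.2])
        assert is_robinson(dm)
        order, length = shortest_hamiltonian_path(dm)
        assert order in ([0, 1, 2, 3, 4, 5], [5, 4, 3, 2, 1, 0])
        assert length == pytest.approx(dm.d[0, -1])  # line metric: span

    def test_min_matches_enumeration(self, rng):
        dm = DistanceMatrix(random_symmetric_matrix(rng, 7))
        _, length = shortest_hamiltonian_path(dm)
        oracle = min(l for _, l in enumerate_hamiltonian_paths(dm))
        assert length == pytest.approx(oracle, rel=1e-12)

    def test_asymmetric_rejected_for_ensembles(self):
        d = np.array([[0.0, 1.0, 2.0], [2.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        dm = DistanceMatrix(d)
        with pytest.raises(ValueError, match="symmetric"):
            shp_inside(dm, EnsembleParams(1.0, 1.0))

    def test_cap_enforced(self):
        dm = DistanceMatrix(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            shp_inside(dm, EnsembleParams(1.0, 1.0), cap=4)


class TestOutsideTables:
    def test_pair_base_case_is_single_edge(self, rng):
        dm = DistanceMatrix(random_symmetric_matrix(rng, 5))
        params = EnsembleParams.for_matrix(dm, 0.7)
        inside = shp_inside(dm, params)
        outside = shp_outside(dm, params, inside)
        mask = (1 << 1) | (1 << 3)
        assert outside.table[mask, 1, 3] == pytest.approx(
            -params.alpha * dm.d[1, 3]
        )

    def test_outside_equals_inside_on_complements(self, rng):
        """Path reversal: completing [j, A*, q] is a path from j to q."""
        dm = DistanceMatrix(random_symmetric_matrix(rng, 6))
        params = EnsembleParams.for_matrix(dm, 0.5)
        inside = shp_inside(dm, params)
        outside = shp_outside(dm, params, inside)
        np.testing.assert_allclose(inside.table, outside.table, atol=1e-12)

    def test_split_consistency_reproduces_z_pq(self, rng):
        """Summing inside x outside over all complementary splits sharing a
        fixed overlap vertex recovers the endpoint-pair partition function."""
        n = 6
        dm = DistanceMatrix(random_symmetric_matrix(rng, n))
        params = EnsembleParams.for_matrix(dm, 0.3)
        inside = shp_inside(dm, params)
        outside = shp_outside(dm, params, inside)
        full = inside.full_mask()
        p, q, j = 0, 4, 2
        terms = []
        for mask in range(1, full + 1):
            if not (mask >> p & 1) or not (mask >> j & 1) or (mask >> q & 1):
                continue
            comp = (full ^ mask) | (1 << j)
            terms.append(inside.table[mask, p, j]
                         + outside.table[comp, j, q])
        assert logsumexp(terms) == pytest.approx(
            inside.table[full, p, q], rel=1e-12
        )

    def test_count_consistency_at_fixed_vertex(self):
        """Inside x outside counts across splits at a fixed overlap vertex
        add up to the (n-2)! paths of every endpoint pair."""
        n = 5
        dm = DistanceMatrix(
            random_symmetric_matrix(np.random.default_rng(5), n)
        )
        params = EnsembleParams.for_matrix(dm, 1e9)  # weights ~ 1: counts
        inside = shp_inside(dm, params)
        outside = shp_outside(dm, params, inside)
        full = inside.full_mask()
        p, q, j = 0, 3, 1
        total = sum(
            math.exp(inside.table[mask, p, j]
                     + outside.table[(full ^ mask) | (1 << j), j, q])
            for mask in range(1, full + 1)
            if (mask >> p & 1) and (mask >> j & 1) and not (mask >> q & 1)
        )
        assert total == pytest.approx(math.factorial(n - 2), rel=1e-6)


class TestEnsemblePosteriors:
    @pytest.mark.parametrize("n,T,seed", [(5, 0.05, 0), (6, 0.3, 1),
                                          (6, 1.0, 2), (7, 2.0, 3)])
    def test_posteriors_match_enumeration(self, n, T, seed):
        rng = np.random.default_rng(seed)
        dm = DistanceMatrix(random_symmetric_matrix(rng, n))
        params = EnsembleParams.for_matrix(dm, T)
        res = path_ensemble(dm, params)
        Z, endpoint, pair, adj = ensemble_oracle(dm, params)
        assert res.Z_total == pytest.approx(Z, rel=1e-9)
        np.testing.assert_allclose(res.endpoint, endpoint, atol=1e-9)
        np.testing.assert_allclose(res.endpoint_pair, pair, atol=1e-9)
        np.testing.assert_allclose(res.adjacency, adj, atol=1e-9)

    def test_normalizations(self, rng):
        dm = DistanceMatrix(random_symmetric_matrix(rng, 7))
        params = EnsembleParams.for_matrix(dm, 0.2)
        res = path_ensemble(dm, params)
        assert res.endpoint.sum() == pytest.approx(2.0, abs=1e-9)
        assert res.endpoint_pair.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.triu(res.adjacency, 1).sum() == pytest.approx(
            dm.n - 1, abs=1e-9
        )

    def test_uniform_distances_give_uniform_posteriors(self):
        n = 5
        d = np.full((n, n), 3.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d)
        res = path_ensemble(dm, EnsembleParams.for_matrix(dm, 0.8))
        np.testing.assert_allclose(res.endpoint, 2.0 / n, atol=1e-12)
        offdiag = res.adjacency[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(offdiag, 2.0 / n, atol=1e-12)

    def test_three_vertex_conditional_is_deterministic(self):
        dm = DistanceMatrix(
            random_symmetric_matrix(np.random.default_rng(11), 3)
        )
        params = EnsembleParams.for_matrix(dm, 0.5)
        cond = adjacency_conditional(dm, params, 0, 2)
        # the middle vertex 1 is forced adjacent to both endpoints
        assert cond[0, 1] == pytest.approx(1.0)
        assert cond[1, 2] == pytest.approx(1.0)
        assert cond[0, 2] == pytest.approx(0.0)

    def test_conditional_matches_enumeration(self, rng):
        dm = DistanceMatrix(random_symmetric_matrix(rng, 6))
        params = EnsembleParams.for_matrix(dm, 0.4)
        p, q = 1, 4
        cond = adjacency_conditional(dm, params, p, q)
        paths = enumerate_hamiltonian_paths(dm)
        num = np.zeros((6, 6))
        Zpq = 0.0
        for path, l in paths:
            if {path[0], path[-1]} != {p, q}:
                continue
            w = math.exp(-params.alpha * l)
            Zpq += w
            for k in range(5):
                num[path[k], path[k + 1]] += w
                num[path[k + 1], path[k]] += w
        np.testing.assert_allclose(cond, num / Zpq, atol=1e-9)

    def test_high_temperature_limit_is_uniform(self, rng):
        """T -> infinity: every adjacency approaches 2/n."""
        n = 6
        dm = DistanceMatrix(random_symmetric_matrix(rng, n))
        res = path_ensemble(dm, EnsembleParams.for_matrix(dm, 1e6))
        offdiag = res.adjacency[~np.eye(n, dtype=bool)]
        np.testing.assert_allclose(offdiag, 2.0 / n, atol=1e-4)

    def test_low_temperature_concentrates_on_optimal_path(self):
        """T -> 0 with a unique optimum: adjacency mass sits on its edges
        and the endpoint mass on its termini."""
        dm = robinson_matrix([3.0, 5.0, 2.0, 4.0, 6.0, 1.5])
        n = dm.n
        res = path_ensemble(dm, EnsembleParams.for_matrix(dm, 1e-4))
        for k in range(n - 1):
            assert res.adjacency[k, k + 1] > 0.999
        assert res.endpoint[0] > 0.999 and res.endpoint[-1] > 0.999
        assert res.endpoint[1:-1].max() < 1e-3


class TestPathOracle:
    def test_small_counts(self):
        dm3 = DistanceMatrix(np.ones((3, 3)) - np.eye(3))
        dm4 = DistanceMatrix(np.ones((4, 4)) - np.eye(4))
        assert len(enumerate_hamiltonian_paths(dm3)) == 3
        assert len(enumerate_hamiltonian_paths(dm4)) == 12

    def test_paths_are_unique_and_undirected(self, rng):
        dm = DistanceMatrix(random_symmetric_matrix(rng, 5))
        paths = [p for p, _ in enumerate_hamiltonian_paths(dm)]
        assert len(paths) == len(set(paths)) == math.factorial(5) // 2
        assert all(p[0] < p[-1] for p in paths)

    def test_size_guard(self):
        dm = DistanceMatrix(np.zeros((10, 10)))
        with pytest.raises(ValueError):
            enumerate_hamiltonian_paths(dm)
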