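"""Dynamic programming over vertex sets: exact TSP/shortest-Hamiltonian-path
solvers and Boltzmann ensembles of Hamiltonian paths.

The index type is the *punctuated set* ``[i, A, j]``: an unordered vertex
subset ``A`` with one or two distinguished boundary vertices (the endpoints
of the partial paths it stands for).  The single decomposition rule —
split one boundary vertex off the set — yields the classic O(n^2 2^n)
subset recursion; evaluated under min/plus it solves the shortest
Hamiltonian path, under sum/product with edge weights
``exp(-d_ij / (R T))`` it computes partition functions over the path
ensemble, and combining a punctuated set with its complement (they share
one boundary vertex) gives posterior probabilities of adjacencies and path
endpoints.

The fictitious temperature ``T`` interpolates between the optimal path
(``T -> 0``) and the uniform ensemble (``T -> infinity``); the scale
``R = (n-1) * mean(d)`` makes ``T`` unitless against the typical path
length.  Partition-function tables are kept in log space throughout, so
very small temperatures stay numerically exact.

Endpoints of a path are not distinguished from each other (paths are
undirected); the internal tables use a directed convention and halve the
totals where appropriate.  Ensemble routines require a symmetric distance
matrix; the Held-Karp tour solver also accepts asymmetric ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "DistanceMatrix",
    "EnsembleParams",
    "PathEnsembleResult",
    "ShpTables",
    "held_karp",
    "shp_inside",
    "shp_outside",
    "shortest_hamiltonian_path",
    "path_ensemble",
    "adjacency_posterior",
    "endpoint_posterior",
    "adjacency_conditional",
    "enumerate_hamiltonian_paths",
    "is_robinson",
]

HELD_KARP_CAP = 24
ENSEMBLE_CAP = 16
ORACLE_CAP = 9


@dataclass
class DistanceMatrix:
    """A labelled nonnegative dissimilarity matrix."""

    d: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if (np.diag(self.d) != 0).any():
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")
        if self.labels is None:
            self.labels = [str(i + 1) for i in range(self.n)]
        if len(self.labels) != self.n:
            raise ValueError("label count does not match matrix size")

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.d, self.d.T, atol=tol))

    def require_symmetric(self) -> None:
        if not self.is_symmetric():
            i, j = np.unravel_index(
                np.abs(self.d - self.d.T).argmax(), self.d.shape
            )
            raise ValueError(
                f"ensemble routines need a symmetric matrix; "
                f"d[{self.labels[i]},{self.labels[j]}] != "
                f"d[{self.labels[j]},{self.labels[i]}]"
            )

    @property
    def mean_offdiag(self) -> float:
        """Mean over distinct unordered off-diagonal pairs."""
        iu = np.triu_indices(self.n, k=1)
        return float(self.d[iu].mean())


@dataclass
class EnsembleParams:
    """Fictitious temperature T and normalisation R; alpha = 1/(R T).

    ``R`` defaults to ``(n-1) * mean(d)`` (the scale of a typical path
    length) when built through :meth:`for_matrix`.
    """

    T: float
    R: float

    def __post_init__(self) -> None:
        if self.T <= 0 or self.R <= 0:
            raise ValueError("T and R must be positive")

    @property
    def alpha(self) -> float:
        return 1.0 / (self.R * self.T)

    @classmethod
    def for_matrix(cls, d: DistanceMatrix, T: float,
                   R: float | None = None) -> "EnsembleParams":
        if R is None:
            R = (d.n - 1) * d.mean_offdiag
        return cls(T, R)


# ---------------------------------------------------------------------------
# Held-Karp TSP
# ---------------------------------------------------------------------------

def held_karp(dm: DistanceMatrix, cap: int = HELD_KARP_CAP):
    """Exact TSP by subset DP: returns (tour vertex order, tour length).

    ``f([A, i])`` is the shortest path starting at vertex 0, visiting all of
    ``A`` and ending in ``i``; the optimal tour closes the cheapest such
    path back to the anchor.  Accepts asymmetric matrices.  Ties break
    deterministically towards the smallest vertex index.
    """
    n = dm.n
    if n < 2:
        raise ValueError("need at least two vertices")
    if n > cap:
        raise ValueError(f"n={n} exceeds the configured cap {cap}")
    d = dm.d
    full = (1 << n) - 1
    f = np.full((1 << n, n), np.inf)
    parent = np.full((1 << n, n), -1, dtype=np.int8)
    f[1, 0] = 0.0
    for mask in range(1, 1 << n):
        if not mask & 1:
            continue  # all paths are anchored at vertex 0
        for j in range(1, n):
            bit = 1 << j
            if not mask & bit:
                continue
            prev = f[mask ^ bit] + d[:, j]
            prev[j] = np.inf
            k = int(np.argmin(prev))
            f[mask, j] = prev[k]
            parent[mask, j] = k
    closing = f[full] + d[:, 0]
    closing[0] = np.inf if n > 1 else closing[0]
    last = int(np.argmin(closing))
    length = float(closing[last])
    order = [last]
    mask = full
    while order[-1] != 0:
        k = int(parent[mask, order[-1]])
        mask ^= 1 << order[-1]
        order.append(k)
    order.reverse()
    return order, length


# ---------------------------------------------------------------------------
# Hamiltonian-path tables
# ---------------------------------------------------------------------------

@dataclass
class ShpTables:
    """Tables over punctuated-set states ``[i, A, j]``.

    ``table[mask, i, j]`` evaluates all Hamiltonian paths on the vertex set
    ``mask`` running from ``i`` to ``j`` (directed convention): the log
    partition function (``partition``), the path count (``count``), or the
    minimum length (``min``, with parent pointers for backtracing).
    """

    dm: DistanceMatrix
    algebra: str
    params: EnsembleParams | None
    table: np.ndarray
    parent: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.dm.n

    def full_mask(self) -> int:
        return (1 << self.n) - 1

    def log_Z_pq(self) -> np.ndarray:
        if self.algebra != "partition":
            raise ValueError("log_Z_pq requires the partition algebra")
        return self.table[self.full_mask()]


def _mask_members(mask: int, n: int) -> list[int]:
    return [v for v in range(n) if mask >> v & 1]


def shp_inside(dm: DistanceMatrix, params: EnsembleParams | None = None,
               algebra: str = "partition",
               cap: int = ENSEMBLE_CAP) -> ShpTables:
    """Fill the punctuated-set table bottom-up by splitting off an endpoint.

    The single rule: a path on ``A`` from ``i`` to ``j`` is a path on
    ``A \\ {j}`` from ``i`` to some ``k`` plus the edge (k, j).  Base case:
    the singleton set holds the neutral value.
    """
    n = dm.n
    if n > cap:
        raise ValueError(f"n={n} exceeds the configured cap {cap}")
    if algebra not in ("partition", "count", "min"):
        raise ValueError("algebra must be partition, count or min")
    if algebra == "partition":
        if params is None:
            raise ValueError("partition algebra needs EnsembleParams")
        dm.require_symmetric()
        lw = -params.alpha * dm.d
        table = np.full((1 << n, n, n), -np.inf)
        for v in range(n):
            table[1 << v, v, v] = 0.0
        parent = None
        for mask in range(1, 1 << n):
            members = _mask_members(mask, n)
            if len(members) < 2:
                continue
            for j in members:
                prev = table[mask ^ (1 << j)]  # (i, k)
                table[mask, :, j] = logsumexp(
                    prev + lw[:, j][None, :], axis=1
                )
    elif algebra == "count":
        dm.require_symmetric()
        table = np.zeros((1 << n, n, n))
        for v in range(n):
            table[1 << v, v, v] = 1.0
        parent = None
        for mask in range(1, 1 << n):
            members = _mask_members(mask, n)
            if len(members) < 2:
                continue
            for j in members:
                table[mask, :, j] = table[mask ^ (1 << j)].sum(axis=1)
    else:  # min
        dm.require_symmetric()
        table = np.full((1 << n, n, n), np.inf)
        parent = np.full((1 << n, n, n), -1, dtype=np.int8)
        for v in range(n):
            table[1 << v, v, v] = 0.0
        for mask in range(1, 1 << n):
            members = _mask_members(mask, n)
            if len(members) < 2:
                continue
            for j in members:
                cand = table[mask ^ (1 << j)] + dm.d[:, j][None, :]
                k = np.argmin(cand, axis=1)
                table[mask, :, j] = cand[np.arange(n), k]
                parent[mask, :, j] = k
    return ShpTables(dm, algebra, params, table, parent)


def shp_outside(dm: DistanceMatrix, params: EnsembleParams | None,
                inside: ShpTables) -> ShpTables:
    """Outside tables for punctuated complements ``[j, A*, q]``.

    ``outside[mask, j, q]`` evaluates the completions of a partial path: the
    complement set ``mask`` (sharing the boundary vertex ``j`` with the
    inside part) traversed from ``j`` to the far endpoint ``q``.  The
    recursion is the derived rule A* -> A*v — the *inner* boundary vertex is
    split off — seeded with the singleton {q}.  For a symmetric matrix the
    resulting table coincides with the inside table (path reversal), which
    the test suite exploits as a consistency check.
    """
    if inside.algebra != "partition":
        raise ValueError("outside tables are defined for the partition algebra")
    n = dm.n
    lw = -params.alpha * dm.d
    table = np.full((1 << n, n, n), -np.inf)
    for q in range(n):
        table[1 << q, q, q] = 0.0
    for mask in range(1, 1 << n):
        members = _mask_members(mask, n)
        if len(members) < 2:
            continue
        for j in members:
            # split off the inner boundary j: step to some v, then complete
            prev = table[mask ^ (1 << j)]  # (v, q)
            table[mask, j, :] = logsumexp(
                prev + lw[j, :][:, None], axis=0
            )
    return ShpTables(dm, "partition", params, table)


def shortest_hamiltonian_path(dm: DistanceMatrix):
    """Optimal (minimum-length) Hamiltonian path: (vertex order, length).

    Ties break deterministically (smallest endpoint pair, then smallest
    predecessor index).
    """
    t = shp_inside(dm, algebra="min")
    full = t.full_mask()
    n = dm.n
    best = (math.inf, None)
    for p in range(n):
        for q in range(p + 1, n):
            v = t.table[full, p, q]
            if v < best[0] - 1e-15:
                best = (v, (p, q))
    length, (p, q) = best
    order = [q]
    mask = full
    while order[-1] != p:
        k = int(t.parent[mask, p, order[-1]])
        mask ^= 1 << order[-1]
        order.append(k)
    order.reverse()
    return order, float(length)


# ---------------------------------------------------------------------------
# Ensemble posteriors
# ---------------------------------------------------------------------------

@dataclass
class PathEnsembleResult:
    """Posterior summaries of the Boltzmann ensemble of Hamiltonian paths.

    ``endpoint_pair[p, q]`` (upper triangle) is P(path ends are {p, q});
    ``endpoint[p] = sum_q endpoint_pair`` sums to 2 over p (two ends per
    path); ``adjacency[i, j]`` is the unconditional P(i ~ j), summing to
    n - 1 over unordered pairs.
    """

    dm: DistanceMatrix
    params: EnsembleParams
    log_Z_total: float
    log_Z_pq: np.ndarray
    endpoint: np.ndarray
    endpoint_pair: np.ndarray
    adjacency: np.ndarray

    @property
    def Z_total(self) -> float:
        return float(np.exp(self.log_Z_total))

    @property
    def Z_pq(self) -> np.ndarray:
        return np.exp(self.log_Z_pq)

    @property
    def labels(self) -> list[str]:
        return self.dm.labels


def path_ensemble(dm: DistanceMatrix, params: EnsembleParams,
                  inside: ShpTables | None = None) -> PathEnsembleResult:
    """Compute endpoint and adjacency posteriors from the inside tables.

    The adjacency marginal P(i ~ j) sums, over all complementary splits, the
    weight of paths that cross the edge {i, j}: inside part ending at i,
    the edge, and the completion starting at j.
    """
    if inside is None:
        inside = shp_inside(dm, params, "partition")
    n = dm.n
    full = inside.full_mask()
    LZ = inside.table
    lw = -params.alpha * dm.d
    # directed totals: W[mask, i] = weight of directed paths on mask ending i
    with np.errstate(divide="ignore"):
        W = logsumexp(LZ, axis=1)
    log_Z_dir = float(logsumexp(W[full]))
    log_Z_total = log_Z_dir - math.log(2.0)

    endpoint = 2.0 * np.exp(W[full] - log_Z_dir)
    log_Z_pq = LZ[full].copy()
    np.fill_diagonal(log_Z_pq, -np.inf)
    endpoint_pair = np.triu(2.0 * np.exp(log_Z_pq - log_Z_dir), k=1)

    acc = np.zeros((n, n))
    for mask in range(1, full):
        members = np.array(_mask_members(mask, n))
        comp = np.array(_mask_members(full ^ mask, n))
        term = (W[mask, members][:, None]
                + lw[np.ix_(members, comp)]
                + W[full ^ mask, comp][None, :])
        acc[np.ix_(members, comp)] += np.exp(term - log_Z_dir)
    adjacency = acc + acc.T
    return PathEnsembleResult(dm, params, log_Z_total, log_Z_pq,
                              endpoint, endpoint_pair, adjacency)


def adjacency_posterior(dm: DistanceMatrix,
                        params: EnsembleParams) -> PathEnsembleResult:
    """Unconditional adjacency probabilities P(i ~ j) (full result object)."""
    return path_ensemble(dm, params)


def endpoint_posterior(dm: DistanceMatrix,
                       params: EnsembleParams) -> PathEnsembleResult:
    """Endpoint and endpoint-pair probabilities (full result object)."""
    return path_ensemble(dm, params)


def adjacency_conditional(dm: DistanceMatrix, params: EnsembleParams,
                          p: int, q: int,
                          inside: ShpTables | None = None) -> np.ndarray:
    """P(i ~ j | path ends are p and q), as a symmetric matrix.

    Exact split sum: inside part [p, A, i], the edge (i, j), and the
    complement [j, S \\ A, q]; both traversal orientations of the edge are
    accumulated.  Requires i, p in A and j, q outside A.
    """
    if p == q:
        raise ValueError("endpoints must differ")
    if inside is None:
        inside = shp_inside(dm, params, "partition")
    n = dm.n
    full = inside.full_mask()
    LZ = inside.table
    lw = -params.alpha * dm.d
    log_Z_pq = LZ[full, p, q]
    acc = np.zeros((n, n))
    for mask in range(1, full):
        if not (mask >> p & 1) or (mask >> q & 1):
            continue
        members = np.array(_mask_members(mask, n))
        comp = np.array(_mask_members(full ^ mask, n))
        term = (LZ[mask, p, members][:, None]
                + lw[np.ix_(members, comp)]
                + LZ[full ^ mask, comp, q][None, :])
        acc[np.ix_(members, comp)] += np.exp(term - log_Z_pq)
    return acc + acc.T


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_hamiltonian_paths(dm: DistanceMatrix, cap: int = ORACLE_CAP):
    """All unordered Hamiltonian paths with exact lengths (test oracle).

    Each undirected path appears exactly once (orientation with the smaller
    first endpoint).  Exhaustive; limited to small n.
    """
    n = dm.n
    if n > cap:
        raise ValueError(f"oracle limited to n <= {cap}")
    d = dm.d
    out = []
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:
            continue
        length = float(sum(d[perm[k], perm[k + 1]] for k in range(n - 1)))
        out.append((perm, length))
    return out


def is_robinson(dm: DistanceMatrix, tol: float = 1e-12) -> bool:
    """Does d satisfy d[i,k] >= max(d[i,j], d[j,k]) for all i < j < k?"""
    d = dm.d
    n = dm.n
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if d[i, k] < max(d[i, j], d[j, k]) - tol:
                    return False
    return True
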