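"""Pairwise alignment inside/outside engines: Needleman-Wunsch and Gotoh.

Inside tables are indexed by prefix lengths: ``M[i][j]`` (Gotoh) evaluates
all alignments of ``x[1..i]`` with ``y[1..j]`` whose last column is a
(mis)match, ``D``/``I`` those ending in a gap in ``y`` resp. ``x``.  Outside
tables evaluate the complementary suffix alignments: ``M*[i][j]`` covers the
"hole" ``x[i+1..n], y[j+1..m]`` reached *after* a match column, which turns
the usual gap-opening recursion into its mirror image that scores gap
*closing*.  In partition mode the product ``M[i][j] * M*[i][j] / Z`` is the
posterior probability that ``x_i`` is aligned to ``y_j``.

All engines are written over a small semiring (choice, combination), so one
set of recursions serves optimisation, alignment counting and Boltzmann
partition functions.

The empty alignment is pinned to the match class (``D`` and ``I`` start at
the semiring zero), which gives every alignment exactly one parse: the first
column of every gap run is always scored as an opening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

__all__ = [
    "ScoringScheme",
    "AlignmentTables",
    "nw_inside_outside",
    "gotoh_inside",
    "gotoh_outside",
    "match_posterior",
    "nw_match_posterior",
    "enumerate_alignments",
    "alignment_weight",
    "GOTOH_OUTSIDE_RULES_IMPLEMENTED",
]

MODES = ("optimize", "count", "partition")


@dataclass
class ScoringScheme:
    """Scores/weights for alignment columns.

    Scores are on an additive scale; in ``partition`` mode each column
    contributes the Boltzmann weight ``exp(score / RT)``, in ``count`` mode
    every column weighs 1, and in ``optimize`` mode scores are combined
    additively and chosen by ``objective`` (max by default; min turns the
    scheme into a cost such as unit edit distance).
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    mode: str = "partition"
    RT: float = 1.0
    objective: str = "max"
    substitution: Callable[[str, str], float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.objective not in ("max", "min"):
            raise ValueError("objective must be 'max' or 'min'")
        if self.mode == "partition" and self.RT <= 0:
            raise ValueError("RT must be positive in partition mode")

    def sub_score(self, u: str, v: str) -> float:
        if self.substitution is not None:
            return self.substitution(u, v)
        return self.match if u == v else self.mismatch

    # semiring interface -----------------------------------------------
    def weight(self, score: float) -> float:
        if self.mode == "optimize":
            return score
        if self.mode == "count":
            return 1.0
        return math.exp(score / self.RT)

    @property
    def zero(self) -> float:
        if self.mode == "optimize":
            return -math.inf if self.objective == "max" else math.inf
        return 0.0

    @property
    def one(self) -> float:
        return 0.0 if self.mode == "optimize" else 1.0

    def choice(self, *vals: float) -> float:
        if self.mode == "optimize":
            return max(vals) if self.objective == "max" else min(vals)
        return sum(vals)

    def combine(self, a: float, b: float) -> float:
        return a + b if self.mode == "optimize" else a * b


@dataclass
class AlignmentTables:
    """DP tables of one engine run; shapes are (n+1, m+1)."""

    x: str
    y: str
    scheme: ScoringScheme
    A: np.ndarray | None = None
    A_star: np.ndarray | None = None
    M: np.ndarray | None = None
    D: np.ndarray | None = None
    I: np.ndarray | None = None
    M_star: np.ndarray | None = None
    D_star: np.ndarray | None = None
    I_star: np.ndarray | None = None
    Z: float = 0.0


def _checked(x: str, y: str) -> tuple[str, str]:
    return str(x), str(y)


def nw_inside_outside(x: str, y: str, s: ScoringScheme) -> AlignmentTables:
    """Linear-gap alignment: inside table A and outside (suffix) table A*.

    ``A[i][j]`` evaluates alignments of the prefixes ``x[1..i], y[1..j]``;
    ``A*[i][j]`` evaluates the complementary suffix alignments of
    ``x[i+1..n], y[j+1..m]``.  Gaps are scored with ``gap_open`` only.
    """
    x, y = _checked(x, y)
    n, m = len(x), len(y)
    A = np.full((n + 1, m + 1), s.zero)
    A[0, 0] = s.one
    wg = s.weight(s.gap_open)
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            cands = []
            if i > 0 and j > 0:
                cands.append(
                    s.combine(A[i - 1, j - 1],
                              s.weight(s.sub_score(x[i - 1], y[j - 1])))
                )
            if i > 0:
                cands.append(s.combine(A[i - 1, j], wg))
            if j > 0:
                cands.append(s.combine(A[i, j - 1], wg))
            A[i, j] = s.choice(*cands)
    A_star = np.full((n + 1, m + 1), s.zero)
    A_star[n, m] = s.one
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            cands = []
            if i < n and j < m:
                cands.append(
                    s.combine(A_star[i + 1, j + 1],
                              s.weight(s.sub_score(x[i], y[j])))
                )
            if i < n:
                cands.append(s.combine(A_star[i + 1, j], wg))
            if j < m:
                cands.append(s.combine(A_star[i, j + 1], wg))
            A_star[i, j] = s.choice(*cands)
    return AlignmentTables(x, y, s, A=A, A_star=A_star, Z=float(A[n, m]))


def gotoh_inside(x: str, y: str, s: ScoringScheme) -> AlignmentTables:
    """Affine-gap inside recursion over last-column classes M, D, I."""
    x, y = _checked(x, y)
    n, m = len(x), len(y)
    M = np.full((n + 1, m + 1), s.zero)
    D = np.full((n + 1, m + 1), s.zero)
    I = np.full((n + 1, m + 1), s.zero)
    M[0, 0] = s.one  # empty alignment; D/I stay at zero (unique parses)
    wo, we = s.weight(s.gap_open), s.weight(s.gap_extend)
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                wm = s.weight(s.sub_score(x[i - 1], y[j - 1]))
                M[i, j] = s.choice(
                    s.combine(M[i - 1, j - 1], wm),
                    s.combine(D[i - 1, j - 1], wm),
                    s.combine(I[i - 1, j - 1], wm),
                )
            if i > 0:
                D[i, j] = s.choice(
                    s.combine(M[i - 1, j], wo),
                    s.combine(D[i - 1, j], we),
                    s.combine(I[i - 1, j], wo),
                )
            if j > 0:
                I[i, j] = s.choice(
                    s.combine(M[i, j - 1], wo),
                    s.combine(D[i, j - 1], wo),
                    s.combine(I[i, j - 1], we),
                )
    Z = s.choice(M[n, m], D[n, m], I[n, m])
    return AlignmentTables(x, y, s, M=M, D=D, I=I, Z=float(Z))


def gotoh_outside(x: str, y: str, s: ScoringScheme,
                  inside: AlignmentTables) -> AlignmentTables:
    """Affine-gap outside recursion (the gap-closing variant).

    Derived mechanically from the inside grammar: the weight of the inside
    rule "open a deletion after a match" attaches to the outside rule that
    extends ``M*`` by the same gap column, and the start rules S -> M|D|I
    become the terminations ``M*,D*,I* -> (σσ)*`` seeding the (n, m) corner.
    """
    x, y = _checked(x, y)
    if inside.M is None or inside.M.shape != (len(x) + 1, len(y) + 1):
        raise ValueError("inside tables missing or shaped for different input")
    n, m = len(x), len(y)
    Ms = np.full((n + 1, m + 1), s.zero)
    Ds = np.full((n + 1, m + 1), s.zero)
    Is = np.full((n + 1, m + 1), s.zero)
    Ms[n, m] = Ds[n, m] = Is[n, m] = s.one
    wo, we = s.weight(s.gap_open), s.weight(s.gap_extend)
    for i in range(n, -1, -1):
        for j in range(m, -1, -1):
            if i == n and j == m:
                continue
            wm = (s.weight(s.sub_score(x[i], y[j]))
                  if i < n and j < m else None)
            zm = s.combine(Ms[i + 1, j + 1], wm) if wm is not None else s.zero
            zd = Ds[i + 1, j] if i < n else None
            zi = Is[i, j + 1] if j < m else None
            Ms[i, j] = s.choice(
                zm,
                s.combine(zd, wo) if zd is not None else s.zero,
                s.combine(zi, wo) if zi is not None else s.zero,
            )
            Ds[i, j] = s.choice(
                zm,
                s.combine(zd, we) if zd is not None else s.zero,
                s.combine(zi, wo) if zi is not None else s.zero,
            )
            Is[i, j] = s.choice(
                zm,
                s.combine(zd, wo) if zd is not None else s.zero,
                s.combine(zi, we) if zi is not None else s.zero,
            )
    out = AlignmentTables(x, y, s, M_star=Ms, D_star=Ds, I_star=Is,
                          Z=inside.Z)
    return out


# outside rules the loops above implement, as (lhs, rhs) pairs; tested to be
# exactly the mechanical outside derivation of the engine's inside grammar.
GOTOH_OUTSIDE_RULES_IMPLEMENTED = frozenset(
    [
        ("M*", ("M*", "(uv)")),
        ("D*", ("M*", "(uv)")),
        ("I*", ("M*", "(uv)")),
        ("M*", ("D*", "(u-)")),
        ("D*", ("D*", "(u·)")),
        ("I*", ("D*", "(u-)")),
        ("M*", ("I*", "(-v)")),
        ("D*", ("I*", "(-v)")),
        ("I*", ("I*", "(·v)")),
        ("M*", ("S*",)),
        ("D*", ("S*",)),
        ("I*", ("S*",)),
        ("(εε)*", ("M*",)),
    ]
)


def match_posterior(inside: AlignmentTables,
                    outside: AlignmentTables) -> np.ndarray:
    """Posterior match probabilities P(i, j) = M[i][j] M*[i][j] / Z.

    Requires partition-mode tables; entry ``[i-1, j-1]`` of the returned
    array is the probability that ``x_i`` is aligned to ``y_j`` in the
    Boltzmann ensemble of global alignments.
    """
    if inside.scheme.mode != "partition":
        raise ValueError("match posteriors require partition-mode tables")
    if inside.M is None or outside.M_star is None:
        raise ValueError("need Gotoh inside and outside tables")
    if inside.M.shape != outside.M_star.shape:
        raise ValueError("inside/outside shape mismatch")
    P = inside.M[1:, 1:] * outside.M_star[1:, 1:] / inside.Z
    return P


def nw_match_posterior(t: AlignmentTables) -> np.ndarray:
    """Match posteriors for the linear-gap engine via A[i-1][j-1] w A*[i][j]."""
    if t.scheme.mode != "partition":
        raise ValueError("match posteriors require partition-mode tables")
    n, m = len(t.x), len(t.y)
    P = np.zeros((n, m))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            w = t.scheme.weight(t.scheme.sub_score(t.x[i - 1], t.y[j - 1]))
            P[i - 1, j - 1] = t.A[i - 1, j - 1] * w * t.A_star[i, j] / t.Z
    return P


def split_probability(inside: AlignmentTables,
                      outside: AlignmentTables) -> np.ndarray:
    """P(some column boundary of the alignment falls exactly at (i, j)).

    Computed as (M M* + D D* + I I*) / Z; equals 1 at the two corners and,
    summed over any antichain of cut points each alignment crosses once,
    reproduces 1.
    """
    num = (inside.M * outside.M_star + inside.D * outside.D_star
           + inside.I * outside.I_star)
    return num / inside.Z


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_alignments(x: str, y: str) -> Iterator[list[tuple]]:
    """Yield every global alignment as a list of columns.

    Columns are ``("M", i, j)``, ``("D", i, None)`` (x_i over a gap) and
    ``("I", None, j)``; indices are 1-based.  Independent of the DP engines.
    """
    n, m = len(x), len(y)

    def rec(i: int, j: int):
        if i == n and j == m:
            yield []
            return
        if i < n and j < m:
            for rest in rec(i + 1, j + 1):
                yield [("M", i + 1, j + 1)] + rest
        if i < n:
            for rest in rec(i + 1, j):
                yield [("D", i + 1, None)] + rest
        if j < m:
            for rest in rec(i, j + 1):
                yield [("I", None, j + 1)] + rest

    yield from rec(0, 0)


def alignment_score(x: str, y: str, cols: list[tuple],
                    s: ScoringScheme) -> float:
    """Additive score of one alignment, affine gaps scored run-wise."""
    score = 0.0
    prev = None
    for kind, i, j in cols:
        if kind == "M":
            score += s.sub_score(x[i - 1], y[j - 1])
        else:
            score += s.gap_extend if prev == kind else s.gap_open
        prev = kind
    return score


def alignment_weight(x: str, y: str, cols: list[tuple],
                     s: ScoringScheme) -> float:
    """Boltzmann weight (partition), 1 (count) or score (optimize)."""
    sc = alignment_score(x, y, cols, s)
    if s.mode == "optimize":
        return sc
    if s.mode == "count":
        return 1.0
    return math.exp(sc / s.RT)
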