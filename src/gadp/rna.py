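"""Toy RNA secondary-structure DP: counting, maximum pairing, partition
function, outside recursions and base-pair probabilities.

The decomposition is the classic unambiguous left-to-right one: an interval
either starts with an unpaired base (``U -> cU``), or with a helix closed by
a canonical pair anchored at its left end (``U -> BU``, ``B -> cUc'``), or is
empty.  ``B[i][j]`` carries the closing pair (i, j) as a boundary: the pair
is shared between the enclosed structure and its outside context, so its
Boltzmann factor is assigned to the inside ``B`` rule only and is therefore
counted exactly once in ``B[i][j] * B*[i][j]``.

Energies are the toy model: ``E_pair`` per base pair (default 1) and
``E_unpaired`` per unpaired base (default 0); partition weights are
``exp(-E/RT)``.  The nearest-neighbour loop model is out of scope here.

All tables are 1-based on sequence positions: ``U[i][j]`` covers
``seq[i..j]`` inclusive, with ``i = j + 1`` denoting the empty interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grammars import CANONICAL_PAIRS

__all__ = [
    "RnaInput",
    "RnaTables",
    "rna_inside",
    "rna_outside",
    "basepair_probabilities",
    "unpaired_probabilities",
    "enumerate_structures",
    "structure_energy",
    "RNA_OUTSIDE_RULES_IMPLEMENTED",
]

MODES = ("count", "maxpair", "partition")

RNA_ALPHABET = set("ACGU")


@dataclass
class RnaInput:
    """An RNA sequence with its pairing rules.

    ``min_hairpin`` is the minimum number of positions strictly enclosed by
    a pair; 0 matches the bare grammar, 3 is the physically realistic value.
    """

    seq: str
    pairs: frozenset = CANONICAL_PAIRS
    min_hairpin: int = 0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("T", "U")
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"invalid nucleotide(s) {sorted(bad)}")
        self.pairs = frozenset(self.pairs)

    @property
    def n(self) -> int:
        return len(self.seq)

    def pairable(self, i: int, j: int) -> bool:
        """Can positions i < j (1-based) close a pair?"""
        if j - i - 1 < self.min_hairpin:
            return False
        return (self.seq[i - 1], self.seq[j - 1]) in self.pairs


@dataclass
class RnaTables:
    """Inside (U, B) and outside (U*, B*) tables plus the total Z.

    Arrays are (n+2) x (n+2); entry [i][j] is the 1-based interval [i..j],
    with j = i - 1 the empty interval.
    """

    inp: RnaInput
    mode: str
    RT: float
    E_pair: float
    E_unpaired: float
    U: np.ndarray | None = None
    B: np.ndarray | None = None
    U_star: np.ndarray | None = None
    B_star: np.ndarray | None = None
    Z: float = 0.0

    # semiring helpers shared by inside and outside fills ----------------
    @property
    def zero(self) -> float:
        return -math.inf if self.mode == "maxpair" else 0.0

    @property
    def one(self) -> float:
        return 0.0 if self.mode == "maxpair" else 1.0

    def choice(self, a: float, b: float) -> float:
        return max(a, b) if self.mode == "maxpair" else a + b

    def combine(self, a: float, b: float) -> float:
        return a + b if self.mode == "maxpair" else a * b

    @property
    def w_pair(self) -> float:
        if self.mode == "count":
            return 1.0
        if self.mode == "maxpair":
            return self.E_pair  # additive gain per pair
        return math.exp(-self.E_pair / self.RT)

    @property
    def w_unpaired(self) -> float:
        if self.mode == "count":
            return 1.0
        if self.mode == "maxpair":
            return 0.0
        return math.exp(-self.E_unpaired / self.RT)


def rna_inside(inp: RnaInput, mode: str = "partition", RT: float = 1.0,
               E_pair: float = 1.0, E_unpaired: float = 0.0) -> RnaTables:
    """Fill U and B bottom-up; Z = U[1][n]."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    t = RnaTables(inp, mode, RT, E_pair, E_unpaired)
    n = inp.n
    U = np.full((n + 2, n + 2), t.zero)
    B = np.full((n + 2, n + 2), t.zero)
    for i in range(1, n + 2):
        U[i, i - 1] = t.one  # empty parse
    for span in range(1, n + 1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            # B[i, j]: closing pair (i, j) around U[i+1, j-1]
            if inp.pairable(i, j):
                B[i, j] = t.combine(U[i + 1, j - 1], t.w_pair)
            # U[i, j]: leftmost position unpaired, or paired to some k
            acc = t.combine(U[i + 1, j], t.w_unpaired)
            for k in range(i + 1, j + 1):
                if inp.pairable(i, k):
                    acc = t.choice(acc, t.combine(B[i, k], U[k + 1, j]))
            U[i, j] = acc
    t.U, t.B = U, B
    t.Z = float(U[1, n]) if n else t.one
    return t


def rna_outside(inp: RnaInput, inside: RnaTables) -> RnaTables:
    """Fill the outside tables U*, B* top-down.

    The five rules are the mechanical outside derivation of the inside
    grammar: left-unpaired extension, enclosing-pair extension, helix split
    (using inside B values), the split rule B*[i][j] = sum_k U*[i][k]
    U[j+1][k], and the initialisation U*[1][n] = 1 from the start rule.
    """
    if inside.U is None:
        raise ValueError("inside tables not filled")
    if inside.inp.seq != inp.seq:
        raise ValueError("inside tables belong to a different input")
    t = inside
    n = inp.n
    Us = np.full((n + 2, n + 2), t.zero)
    Bs = np.full((n + 2, n + 2), t.zero)
    if n == 0:
        out = RnaTables(inp, t.mode, t.RT, t.E_pair, t.E_unpaired,
                        U=t.U, B=t.B, U_star=Us, B_star=Bs, Z=t.Z)
        return out
    Us[1, n] = t.one
    # decreasing span; within a span, U* cells first (B* of the same span
    # reads U* at equal span), B* cells after.
    for span in range(n, -1, -1):
        for i in range(1, n - span + 2):
            j = i + span - 1
            if j > n or j < 0:
                continue
            acc = Us[i, j] if (i == 1 and j == n) else t.zero
            if i >= 2:
                # from U -> cU: context gains the unpaired base i-1
                acc = t.choice(acc, t.combine(Us[i - 1, j], t.w_unpaired))
                # from B -> cUc': enclosing pair (i-1, j+1)
                if j + 1 <= n and inp.pairable(i - 1, j + 1):
                    acc = t.choice(acc,
                                   t.combine(Bs[i - 1, j + 1], t.w_pair))
            # from U -> BU: a helix B[k, i-1] sits left of this interval
            for k in range(1, i):
                if inp.pairable(k, i - 1):
                    acc = t.choice(acc, t.combine(t.B[k, i - 1], Us[k, j]))
            Us[i, j] = acc
        for i in range(1, n - span + 2):
            j = i + span - 1
            if j > n or j < 1 or not inp.pairable(i, j):
                continue
            acc = t.zero
            for k in range(j, n + 1):
                acc = t.choice(acc, t.combine(Us[i, k], t.U[j + 1, k]))
            Bs[i, j] = acc
    return RnaTables(inp, t.mode, t.RT, t.E_pair, t.E_unpaired,
                     U=t.U, B=t.B, U_star=Us, B_star=Bs, Z=t.Z)


# outside rules implemented by the loops above, as (lhs, rhs) pairs;
# tested to equal the mechanical outside derivation of the inside grammar.
RNA_OUTSIDE_RULES_IMPLEMENTED = frozenset(
    [
        ("ε*", ("U*",)),
        ("U*", ("c", "U*")),
        ("U*", ("B", "U*")),
        ("U*", ("c", "B*", "c'")),
        ("U*", ("S*",)),
        ("B*", ("U*", "U")),
    ]
)


def basepair_probabilities(inp: RnaInput, RT: float = 1.0,
                           E_pair: float = 1.0, E_unpaired: float = 0.0,
                           tables: RnaTables | None = None) -> np.ndarray:
    """Symmetric matrix of Boltzmann pair probabilities P(i, j).

    ``P[i-1, j-1] = B[i][j] B*[i][j] / Z``: the pair factor lives on the
    inside B rule only, so the product counts it exactly once.
    """
    if tables is None:
        inside = rna_inside(inp, "partition", RT, E_pair, E_unpaired)
        tables = rna_outside(inp, inside)
    if tables.mode != "partition":
        raise ValueError("base-pair probabilities require partition mode")
    n = inp.n
    P = np.zeros((n, n))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if inp.pairable(i, j):
                p = tables.B[i, j] * tables.B_star[i, j] / tables.Z
                P[i - 1, j - 1] = P[j - 1, i - 1] = p
    return P


def unpaired_probabilities(inp: RnaInput, tables: RnaTables) -> np.ndarray:
    """P(position i is unpaired), from the U -> cU rule applications."""
    if tables.mode != "partition" or tables.U_star is None:
        raise ValueError("requires partition-mode inside+outside tables")
    n = inp.n
    out = np.zeros(n)
    for i in range(1, n + 1):
        acc = 0.0
        for j in range(i - 1, n + 1):
            acc += tables.U_star[i, j] * tables.w_unpaired * tables.U[i + 1, j]
        out[i - 1] = acc / tables.Z
    return out


def max_pairing_structure(tables: RnaTables) -> str:
    """Backtrace one optimal structure from maxpair tables (dot-bracket).

    Ties break towards leaving the leftmost position unpaired, then towards
    the smallest pairing partner.
    """
    if tables.mode != "maxpair" or tables.U is None:
        raise ValueError("requires filled maxpair tables")
    inp, U, B = tables.inp, tables.U, tables.B
    out = ["."] * inp.n

    def rec(i: int, j: int) -> None:
        while i <= j:
            if U[i, j] == U[i + 1, j]:
                i += 1
                continue
            for k in range(i + 1, j + 1):
                if inp.pairable(i, k) and U[i, j] == B[i, k] + U[k + 1, j]:
                    out[i - 1], out[k - 1] = "(", ")"
                    rec(i + 1, k - 1)
                    i = k + 1
                    break
            else:  # pragma: no cover - tables are self-consistent
                raise AssertionError("inconsistent maxpair tables")

    rec(1, inp.n)
    return "".join(out)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_structures(inp: RnaInput, max_len: int = 20) -> list[str]:
    """All non-crossing structures over the allowed pairs, as dot-bracket.

    Exhaustive recursion independent of the DP tables; each structure is
    produced exactly once (leftmost decomposition).
    """
    n = inp.n
    if n > max_len:
        raise ValueError(f"oracle limited to length {max_len}")
    memo: dict[tuple[int, int], list[list[tuple[int, int]]]] = {}

    def rec(i: int, j: int) -> list[list[tuple[int, int]]]:
        if i > j:
            return [[]]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [rest for rest in rec(i + 1, j)]
        for k in range(i + 1, j + 1):
            if inp.pairable(i, k):
                for inner in rec(i + 1, k - 1):
                    for rest in rec(k + 1, j):
                        out.append([(i, k)] + inner + rest)
        memo[key] = out
        return out

    structures = []
    for pairing in rec(1, n):
        db = ["."] * n
        for i, j in pairing:
            db[i - 1] = "("
            db[j - 1] = ")"
        structures.append("".join(db))
    return structures


def structure_energy(db: str, E_pair: float = 1.0,
                     E_unpaired: float = 0.0) -> float:
    """Toy energy of a dot-bracket structure."""
    return E_pair * db.count("(") + E_unpaired * db.count(".")
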