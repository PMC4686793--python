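"""Two-state CpG-island HMM: forward/backward recursions and state posteriors.

The model emits a DNA sequence from two hidden states, ``+`` (inside a CpG
island) and ``-`` (background).  Each state carries its own first-order
dinucleotide model ``a[prev, next]`` (the probability that ``next`` follows
``prev``), and the chain switches out of ``+`` with probability ``q_pm`` and
out of ``-`` with probability ``q_mp`` per step.  A step from origin state
``s`` to destination ``s'`` at position ``i`` therefore weighs

    (stay/switch factor of s -> s') * a_s[x[i-1], x[i]]

with the origin state's dinucleotide table.  The first position has no
predecessor; it is scored with a per-state initial emission weight
(by default the column marginal of ``a_s``), and the chain may start in
either state with configurable start weights, matching the initialisation
``f+[0] = f-[0] = 1``.

The forward table is the inside quantity over prefixes, the backward table
the outside quantity over suffixes; their per-position product, normalised
by the sequence likelihood, is the posterior probability of the ``+`` state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HmmParams", "HmmTables", "forward", "backward", "state_posterior",
           "enumerate_state_paths"]

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}

# columns of the factor tensor: origin/destination state order is (+, -)
PLUS, MINUS = 0, 1

_SCALE_THRESHOLD = 64  # switch to scaled arithmetic beyond this length


def _row_stochastic(a: np.ndarray, what: str, tol: float = 1e-9) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (4, 4):
        raise ValueError(f"{what} must be 4x4 (ACGT x ACGT)")
    if (a < 0).any() or (a > 1).any():
        raise ValueError(f"{what} entries must lie in [0, 1]")
    if not np.allclose(a.sum(axis=1), 1.0, atol=tol):
        raise ValueError(f"rows of {what} must sum to 1")
    return a


@dataclass
class HmmParams:
    """Parameters of the two-state dinucleotide HMM.

    a_plus, a_minus : (4, 4) arrays, ``a[prev, next]``, rows sum to 1.
    q_pm, q_mp      : probability of leaving ``+`` resp. ``-`` per step.
    init_plus/minus : length-4 initial emission weights for position 1;
                      default is the column marginal of the state's ``a``.
    start_weights   : weights of starting in (+, -); (1, 1) allows both.
    """

    a_plus: np.ndarray
    a_minus: np.ndarray
    q_pm: float
    q_mp: float
    init_plus: np.ndarray | None = None
    init_minus: np.ndarray | None = None
    start_weights: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.a_plus = _row_stochastic(self.a_plus, "a_plus")
        self.a_minus = _row_stochastic(self.a_minus, "a_minus")
        for q, nm in ((self.q_pm, "q_pm"), (self.q_mp, "q_mp")):
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"{nm} must lie in [0, 1]")
        if self.init_plus is None:
            self.init_plus = self.a_plus.mean(axis=0)
        if self.init_minus is None:
            self.init_minus = self.a_minus.mean(axis=0)
        self.init_plus = np.asarray(self.init_plus, dtype=float)
        self.init_minus = np.asarray(self.init_minus, dtype=float)

    @classmethod
    def uniform(cls, q: float = 0.5) -> "HmmParams":
        """All dinucleotide probabilities 0.25, switch probability ``q``."""
        a = np.full((4, 4), 0.25)
        return cls(a, a.copy(), q, q)

    @classmethod
    def random(cls, rng: np.random.Generator) -> "HmmParams":
        """Random row-stochastic tables and switch probabilities (tests)."""
        def table() -> np.ndarray:
            a = rng.uniform(0.05, 1.0, size=(4, 4))
            return a / a.sum(axis=1, keepdims=True)

        return cls(table(), table(), rng.uniform(0.0, 1.0),
                   rng.uniform(0.0, 1.0))

    def step_factors(self, seq: str) -> np.ndarray:
        """Tensor ``T[i, origin, dest]`` of transition weights, i = 1..n.

        Entry ``T[i]`` weighs the step from the state at position i-1 to the
        state at position i; position 1 uses the initial emission weights in
        place of the (nonexistent) dinucleotide x0 -> x1.
        """
        idx = encode(seq)
        n = len(idx)
        T = np.empty((n + 1, 2, 2))
        T[0] = np.nan  # there is no step into position 0
        switch = np.array(
            [[1.0 - self.q_pm, self.q_pm],   # origin +: stay, leave
             [self.q_mp, 1.0 - self.q_mp]]   # origin -: leave, stay
        )
        emis1 = np.array([self.init_plus[idx[0]], self.init_minus[idx[0]]])
        T[1] = switch * emis1[:, None]
        for i in range(2, n + 1):
            emis = np.array(
                [self.a_plus[idx[i - 2], idx[i - 1]],
                 self.a_minus[idx[i - 2], idx[i - 1]]]
            )
            T[i] = switch * emis[:, None]
        return T


def encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    try:
        return np.array([_IDX[b] for b in seq], dtype=int)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc.args[0]!r} in input") from exc


@dataclass
class HmmTables:
    """Forward and/or backward tables for one (params, sequence) pair.

    The stored arrays are scaled by ``exp(log_scale[i])`` per position when
    the sequence is long enough for underflow to matter; the ``f_plus`` etc.
    properties return linear-scale values.
    """

    seq: str
    _f: np.ndarray | None = None       # shape (n+1, 2), scaled
    _b: np.ndarray | None = None
    _f_scale: np.ndarray | None = None  # cumulative log scale per position
    _b_scale: np.ndarray | None = None
    log_total: float | None = None

    @property
    def n(self) -> int:
        return len(self.seq)

    def _linear(self, arr, scale, col):
        if arr is None:
            raise ValueError("table not computed")
        if scale is None:
            return arr[:, col].copy()
        return arr[:, col] * np.exp(scale)

    @property
    def f_plus(self) -> np.ndarray:
        return self._linear(self._f, self._f_scale, PLUS)

    @property
    def f_minus(self) -> np.ndarray:
        return self._linear(self._f, self._f_scale, MINUS)

    @property
    def b_plus(self) -> np.ndarray:
        return self._linear(self._b, self._b_scale, PLUS)

    @property
    def b_minus(self) -> np.ndarray:
        return self._linear(self._b, self._b_scale, MINUS)

    @property
    def total(self) -> float:
        """Sequence likelihood (forward or backward total)."""
        return float(np.exp(self.log_total))


def forward(params: HmmParams, seq: str) -> HmmTables:
    """Fill the forward (inside) tables left to right; total = f+[n] + f-[n]."""
    if not seq:
        raise ValueError("sequence must be nonempty")
    T = params.step_factors(seq)
    n = len(seq)
    scale = n > _SCALE_THRESHOLD
    f = np.empty((n + 1, 2))
    logs = np.zeros(n + 1)
    f[0] = params.start_weights
    for i in range(1, n + 1):
        f[i] = T[i].T @ f[i - 1]
        logs[i] = logs[i - 1]
        if scale:
            s = f[i].sum()
            f[i] /= s
            logs[i] += np.log(s)
    log_total = float(np.log(f[n].sum()) + logs[n])
    return HmmTables(seq, _f=f, _f_scale=logs if scale else None,
                     log_total=log_total)


def backward(params: HmmParams, seq: str) -> HmmTables:
    """Fill the backward (outside) tables right to left; b±[n] = 1."""
    if not seq:
        raise ValueError("sequence must be nonempty")
    T = params.step_factors(seq)
    n = len(seq)
    scale = n > _SCALE_THRESHOLD
    b = np.empty((n + 1, 2))
    logs = np.zeros(n + 1)
    b[n] = (1.0, 1.0)
    for i in range(n - 1, -1, -1):
        b[i] = T[i + 1] @ b[i + 1]
        logs[i] = logs[i + 1]
        if scale:
            s = b[i].sum()
            b[i] /= s
            logs[i] += np.log(s)
    w = np.asarray(params.start_weights)
    log_total = float(np.log(float(w @ b[0])) + logs[0])
    return HmmTables(seq, _b=b, _b_scale=logs if scale else None,
                     log_total=log_total)


def merge(fwd: HmmTables, bwd: HmmTables) -> HmmTables:
    """Combine a forward and a backward table object for the same sequence."""
    if fwd.seq != bwd.seq:
        raise ValueError("tables computed on different sequences")
    return HmmTables(fwd.seq, _f=fwd._f, _b=bwd._b, _f_scale=fwd._f_scale,
                     _b_scale=bwd._b_scale, log_total=fwd.log_total)


def unnormalized_posterior_product(fwd: HmmTables, bwd: HmmTables) -> np.ndarray:
    """The raw per-position products f±[i] * b±[i] (shape (n+1, 2))."""
    _check_pair(fwd, bwd)
    out = np.stack([fwd.f_plus * bwd.b_plus, fwd.f_minus * bwd.b_minus],
                   axis=1)
    return out


def _check_pair(fwd: HmmTables, bwd: HmmTables) -> None:
    if fwd.seq != bwd.seq:
        raise ValueError("forward/backward tables have mismatched sequences")
    if fwd._f is None or bwd._b is None:
        raise ValueError("need a forward table and a backward table")


def state_posterior(fwd: HmmTables, bwd: HmmTables) -> np.ndarray:
    """Posterior probability of the ``+`` state at positions 1..n.

    Normalised per position by f+b+ + f-b- (which equals the sequence
    likelihood at every position), so that P(+) + P(-) = 1.
    """
    _check_pair(fwd, bwd)
    # scales cancel inside the ratio, so use the scaled arrays directly
    fp, fm = fwd._f[:, PLUS], fwd._f[:, MINUS]
    bp, bm = bwd._b[:, PLUS], bwd._b[:, MINUS]
    plus = fp * bp
    minus = fm * bm
    post = plus / (plus + minus)
    return post[1:]


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_state_paths(params: HmmParams, seq: str):
    """Exhaustive enumeration over all 2^(n+1) state sequences.

    Returns (paths, weights): each path is a tuple of states over positions
    0..n (position 0 is the fictitious pre-sequence state), its weight the
    product of step factors and start weight.  Independent of the DP code;
    used as the test oracle for totals and posteriors.
    """
    from itertools import product

    T = params.step_factors(seq)
    n = len(seq)
    paths, weights = [], []
    for states in product((PLUS, MINUS), repeat=n + 1):
        w = params.start_weights[states[0]]
        for i in range(1, n + 1):
            w *= T[i][states[i - 1], states[i]]
        paths.append(states)
        weights.append(w)
    return paths, np.array(weights)
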