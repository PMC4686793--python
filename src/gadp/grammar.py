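"""Symbolic decomposition grammars and the mechanical inside -> outside transform.

A :class:`Grammar` describes how a dynamic-programming state space decomposes:
nonterminals name classes of sub-objects (prefixes, intervals, punctuated
sets), terminals name the atomic pieces consumed from the input, and each
production records one way of decomposing the left-hand object into the parts
on the right.  Every object class carries a *boundary kind* saying what part
of an object is shared with its complement (nothing, an interval endpoint
pair, a base pair, a set of path endpoints).

The outside counterpart of an inside grammar is obtained purely mechanically:
a production ``A -> alpha B beta`` contributes ``B* -> alpha A* beta`` for
every nonterminal ``B`` on its right-hand side, start rules ``S -> A`` become
termination rules ``A* -> S*``, and stop rules ``A -> eps`` become the outside
start rules ``eps* -> A*``.  The attribute (scoring-function slot) of each
derived rule is inherited from the inside rule that generated it, so inside
and outside grammars share one evaluation algebra.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

__all__ = [
    "Symbol",
    "Production",
    "Grammar",
    "GrammarError",
    "OracleTooLarge",
    "check_normalized",
    "normalize",
    "derive_outside",
    "enumerate_parses",
    "attribute_signature",
    "grammar_to_json",
    "grammar_from_json",
]

ROLES = ("terminal", "nonterminal", "start", "stop", "outside_nonterminal")
BOUNDARY_KINDS = ("empty", "left-right-points", "point-pair", "endpoint-set")


class GrammarError(ValueError):
    """Structural problem with a grammar (missing start/stop, bad rule, ...)."""


class OracleTooLarge(RuntimeError):
    """Raised when exhaustive parse enumeration would exceed its limit."""


@dataclass(frozen=True)
class Symbol:
    """A terminal, nonterminal, start, stop or outside-nonterminal symbol.

    ``consumes`` gives, for terminals, how many characters the symbol reads
    from each input tape (e.g. an alignment match column reads one character
    from both tapes, a gap column reads from only one).  ``inside_ref`` links
    an outside nonterminal ``X*`` back to its inside nonterminal ``X``.
    """

    name: str
    role: str = "nonterminal"
    boundary_kind: str = "empty"
    consumes: tuple[int, ...] | None = None
    inside_ref: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise GrammarError(f"unknown symbol role {self.role!r}")
        if self.boundary_kind not in BOUNDARY_KINDS:
            raise GrammarError(f"unknown boundary kind {self.boundary_kind!r}")

    @property
    def is_syntactic(self) -> bool:
        """True for symbols that can be expanded (inside or outside NTs)."""
        return self.role in ("nonterminal", "outside_nonterminal", "start")


@dataclass(frozen=True)
class Production:
    """One decomposition rule ``lhs -> rhs``.

    ``ordered`` distinguishes ordered right-hand sides (string tapes) from
    multiset ones (set tapes).  ``attribute`` names the scoring-function slot
    of the evaluation algebra attached to this rule.  ``constraint``, when
    given, is a predicate over the matched parts (used e.g. to restrict an
    RNA closing pair to the canonical base pairs); it is engine plumbing and
    is not serialised.
    """

    lhs: str
    rhs: tuple[str, ...]
    attribute: str = ""
    ordered: bool = True
    constraint: Callable | None = field(default=None, compare=False)

    def __str__(self) -> str:
        return f"{self.lhs} -> {' '.join(self.rhs) if self.rhs else 'ε'}"


@dataclass
class Grammar:
    """A decomposition scheme: symbols, productions, start/stop, tape count."""

    symbols: dict[str, Symbol]
    productions: list[Production]
    start: str
    stop: str
    tapes: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.start not in self.symbols:
            raise GrammarError(f"start symbol {self.start!r} not declared")
        if self.stop not in self.symbols:
            raise GrammarError(f"stop symbol {self.stop!r} not declared")
        if self.symbols[self.start].role != "start":
            raise GrammarError(f"{self.start!r} must have role 'start'")
        if self.symbols[self.stop].role != "stop":
            raise GrammarError(f"{self.stop!r} must have role 'stop'")
        for p in self.productions:
            if p.lhs not in self.symbols:
                raise GrammarError(f"unknown lhs {p.lhs!r} in {p}")
            lhs_role = self.symbols[p.lhs].role
            if lhs_role not in ("nonterminal", "start", "outside_nonterminal"):
                raise GrammarError(f"lhs of {p} has role {lhs_role!r}")
            for s in p.rhs:
                if s not in self.symbols:
                    raise GrammarError(f"unknown rhs symbol {s!r} in {p}")

    # -- convenience -------------------------------------------------------
    def sym(self, name: str) -> Symbol:
        return self.symbols[name]

    def rules_for(self, lhs: str) -> list[Production]:
        return [p for p in self.productions if p.lhs == lhs]

    def nonterminals(self) -> list[str]:
        return [
            s.name
            for s in self.symbols.values()
            if s.role in ("nonterminal", "outside_nonterminal")
        ]

    def canonical_productions(self) -> list[Production]:
        """Productions in a deterministic lexicographic order."""
        return sorted(self.productions, key=lambda p: (p.lhs, p.rhs))

    def same_rules(self, other: "Grammar") -> bool:
        """Rule-set equality up to production order (attributes ignored)."""
        mine = Counter((p.lhs, p.rhs) for p in self.productions)
        theirs = Counter((p.lhs, p.rhs) for p in other.productions)
        return mine == theirs

    def validate(self) -> None:
        """Sanity check: every nonterminal is reachable and productive."""
        reach = {self.start}
        frontier = [self.start]
        while frontier:
            cur = frontier.pop()
            for p in self.rules_for(cur):
                for s in p.rhs:
                    if self.symbols[s].is_syntactic and s not in reach:
                        reach.add(s)
                        frontier.append(s)
        productive: set[str] = set()
        changed = True
        while changed:
            changed = False
            for p in self.productions:
                if p.lhs in productive:
                    continue
                if all(
                    (not self.symbols[s].is_syntactic) or s in productive
                    for s in p.rhs
                ):
                    productive.add(p.lhs)
                    changed = True
        bad = [
            n
            for n in self.nonterminals()
            if n not in reach or n not in productive
        ]
        if bad:
            raise GrammarError(f"unreachable or unproductive symbols: {bad}")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def check_normalized(g: Grammar) -> tuple[bool, list[Production]]:
    """Check the two normalization conditions; return (ok, violations).

    A grammar is normalized when (1) every rule with the start symbol on the
    left has a single nonterminal right-hand side, and (2) every rule whose
    right-hand side consists of terminals only is exactly ``lhs -> stop``.
    Multi-tape stop symbols such as the paired empty column of an alignment
    grammar count as the stop symbol, not as plain terminals.
    """
    violations: list[Production] = []
    for p in g.productions:
        if p.lhs == g.start:
            if len(p.rhs) != 1 or not g.symbols[p.rhs[0]].is_syntactic:
                violations.append(p)
        elif all(not g.symbols[s].is_syntactic for s in p.rhs):
            if p.rhs != (g.stop,):
                violations.append(p)
    return (not violations, violations)


def normalize(g: Grammar) -> Grammar:
    """Return a normalized equivalent of ``g`` (fresh rules where needed).

    Start rules with a compound right-hand side are routed through a fresh
    nonterminal; terminal-only rules other than ``lhs -> stop`` get the stop
    symbol appended through a fresh epsilon-deriving nonterminal.
    """
    ok, violations = check_normalized(g)
    if ok:
        return g
    symbols = dict(g.symbols)
    productions: list[Production] = []
    fresh_eps: str | None = None

    def fresh_name(base: str) -> str:
        i = 1
        while f"{base}{i}" in symbols:
            i += 1
        return f"{base}{i}"

    for p in g.productions:
        if p not in violations:
            productions.append(p)
            continue
        if p.lhs == g.start:
            aux = fresh_name(g.start)
            symbols[aux] = Symbol(aux, "nonterminal")
            productions.append(Production(g.start, (aux,), f"start_{aux}"))
            productions.append(replace(p, lhs=aux))
        else:
            nonlocal_eps = fresh_eps
            if nonlocal_eps is None:
                nonlocal_eps = fresh_name("E")
                symbols[nonlocal_eps] = Symbol(nonlocal_eps, "nonterminal")
                productions.append(
                    Production(nonlocal_eps, (g.stop,), f"stop_{nonlocal_eps}")
                )
                fresh_eps = nonlocal_eps
            productions.append(replace(p, rhs=p.rhs + (nonlocal_eps,)))
    return Grammar(symbols, productions, g.start, g.stop, g.tapes, g.name)


# ---------------------------------------------------------------------------
# Outside derivation
# ---------------------------------------------------------------------------

def star(name: str) -> str:
    return name + "*"


def derive_outside(g: Grammar, auto_normalize: bool = False) -> Grammar:
    """Mechanically derive the outside grammar ``g*`` of a normalized ``g``.

    For every inside production ``A -> alpha B beta`` and every nonterminal
    ``B`` on its right-hand side the outside grammar receives
    ``B* -> alpha A* beta``; start rules ``S -> A`` become the termination
    rules ``A* -> S*`` and stop rules ``A -> eps`` become the outside start
    rules ``eps* -> A*``.  Each derived rule inherits the attribute slot of
    the inside rule that generated it (signature isomorphism), so evaluation
    algebras are shared between the two grammars.

    Raises :class:`GrammarError` for non-normalized input unless
    ``auto_normalize`` is set, in which case a normalized copy is derived.
    """
    ok, violations = check_normalized(g)
    if not ok:
        if not auto_normalize:
            listing = "; ".join(str(p) for p in violations)
            raise GrammarError(
                f"grammar is not normalized; violating rules: {listing}"
            )
        g = normalize(g)

    o_start = star(g.stop)   # eps*  -- outside start: nothing parsed yet
    o_stop = star(g.start)   # S*    -- outside stop: whole input is the hole
    symbols: dict[str, Symbol] = {
        o_start: Symbol(o_start, "start", g.symbols[g.stop].boundary_kind),
        o_stop: Symbol(o_stop, "stop", g.symbols[g.start].boundary_kind),
    }
    # inside terminals and nonterminals keep their identity; from the outside
    # grammar's viewpoint inside nonterminals behave as syntactic terminals,
    # but they remain expandable by the inside grammar in a combined run.
    for s in g.symbols.values():
        if s.role in ("terminal", "nonterminal"):
            symbols[s.name] = s
        if s.role == "nonterminal":
            symbols[star(s.name)] = Symbol(
                star(s.name),
                "outside_nonterminal",
                s.boundary_kind,
                inside_ref=s.name,
            )

    productions: list[Production] = []
    for p in g.productions:
        if p.lhs == g.start:
            # S -> A  ~~>  A* -> S*
            productions.append(
                Production(star(p.rhs[0]), (o_stop,), p.attribute, p.ordered)
            )
        elif p.rhs == (g.stop,):
            # A -> eps  ~~>  eps* -> A*
            productions.append(
                Production(o_start, (star(p.lhs),), p.attribute, p.ordered)
            )
        else:
            for idx, b in enumerate(p.rhs):
                if not g.symbols[b].is_syntactic:
                    continue
                rhs = p.rhs[:idx] + (star(p.lhs),) + p.rhs[idx + 1 :]
                productions.append(
                    Production(star(b), rhs, p.attribute, p.ordered,
                               p.constraint)
                )

    out = Grammar(
        symbols,
        productions,
        start=o_start,
        stop=o_stop,
        tapes=g.tapes,
        name=(g.name + "*") if g.name else "",
    )
    for p in out.productions:
        # the outside stop symbol S* counts as an outside variable here:
        # termination rules A* -> S* carry it in place of a starred NT.
        n_outside = sum(
            1 for s in p.rhs
            if out.symbols[s].role == "outside_nonterminal" or s == o_stop
        )
        if n_outside != 1:
            raise AssertionError(
                f"outside rule {p} has {n_outside} outside nonterminals"
            )
    return out


def attribute_signature(g: Grammar) -> dict[str, tuple[int, int]]:
    """Map attribute slot -> (syntactic arity, terminal arity).

    The inside grammar and its derived outside grammar have identical
    signatures: every attribute slot appears in both with the same argument
    types, which is what lets one algebra evaluate both.
    Start/stop plumbing rules (unit-valued) are excluded.
    """
    sig: dict[str, tuple[int, int]] = {}
    for p in g.productions:
        if p.lhs == g.start or p.rhs == (g.stop,):
            continue
        nt = sum(1 for s in p.rhs if g.symbols[s].is_syntactic)
        t = sum(1 for s in p.rhs if g.symbols[s].role == "terminal")
        prev = sig.setdefault(p.attribute, (nt, t))
        if prev != (nt, t):
            raise GrammarError(
                f"attribute {p.attribute!r} used with conflicting types"
            )
    return sig


# ---------------------------------------------------------------------------
# Exhaustive parse enumeration (the brute-force oracle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParseNode:
    """A node of an explicit parse tree.

    Terminal leaves store the consumed text per tape; syntactic nodes store
    the production applied and the child nodes.
    """

    symbol: str
    spans: tuple[tuple[int, int], ...]
    production: Production | None = None
    children: tuple["ParseNode", ...] = ()
    text: tuple[str, ...] | None = None

    def leaves(self) -> list["ParseNode"]:
        if self.production is None:
            return [self]
        out: list[ParseNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def _consumption(sym: Symbol, tapes: int) -> tuple[int, ...]:
    if sym.consumes is not None:
        return sym.consumes
    if sym.role == "stop":
        return (0,) * tapes
    return (1,) * tapes


def enumerate_parses(
    g: Grammar,
    tapes: Sequence[str] | str,
    limit: int = 100_000,
) -> list[ParseNode]:
    """Exhaustively enumerate all derivations of the input from the start.

    This is the brute-force oracle every DP engine is checked against: it
    recurses over all productions and all ways of splitting the input
    interval(s) among the right-hand-side symbols, left to right on every
    tape.  Only ordered (string) tapes are supported here; set-structured
    inputs have their own dedicated enumeration oracle in :mod:`gadp.set_dp`.

    Raises :class:`OracleTooLarge` when more than ``limit`` parses exist.
    """
    if isinstance(tapes, str):
        tapes = (tapes,)
    if len(tapes) != g.tapes:
        raise GrammarError(f"grammar expects {g.tapes} tapes, got {len(tapes)}")
    if any(not p.ordered for p in g.productions):
        raise NotImplementedError(
            "parse enumeration is only implemented for ordered (string) tapes"
        )
    # memoised recursion; a symbol re-entered on the same spans while still
    # being expanded can only arise from a non-consuming cycle, which has no
    # finite parse, so in-progress entries contribute nothing.
    IN_PROGRESS = object()
    memo: dict[tuple[str, tuple], object] = {}

    def derive(sym_name: str, spans: tuple[tuple[int, int], ...]):
        sym = g.symbols[sym_name]
        if not sym.is_syntactic:
            widths = _consumption(sym, g.tapes)
            if all(hi - lo == w for (lo, hi), w in zip(spans, widths)):
                text = tuple(t[lo:hi] for t, (lo, hi) in zip(tapes, spans))
                return [ParseNode(sym_name, spans, text=text)]
            return []
        key = (sym_name, spans)
        cached = memo.get(key)
        if cached is IN_PROGRESS:
            return []
        if cached is not None:
            return cached
        memo[key] = IN_PROGRESS
        out: list[ParseNode] = []
        for p in g.rules_for(sym_name):
            for children in assign(p, 0, spans):
                node = ParseNode(sym_name, spans, p, tuple(children))
                if p.constraint is not None and not p.constraint(node.children):
                    continue
                out.append(node)
                if len(out) > limit:
                    raise OracleTooLarge(f"more than {limit} parses")
        memo[key] = out
        return out

    def assign(p: Production, idx: int, spans) -> list[list[ParseNode]]:
        if idx == len(p.rhs):
            return [[]] if all(lo == hi for lo, hi in spans) else []
        sym = g.symbols[p.rhs[idx]]
        out: list[list[ParseNode]] = []
        if not sym.is_syntactic:
            widths = _consumption(sym, g.tapes)
            head, new_spans = [], []
            for (lo, hi), w in zip(spans, widths):
                if hi - lo < w:
                    return []
                head.append((lo, lo + w))
                new_spans.append((lo + w, hi))
            for leaf in derive(p.rhs[idx], tuple(head)):
                for rest in assign(p, idx + 1, tuple(new_spans)):
                    out.append([leaf] + rest)
            return out
        # syntactic symbol: try every split point on every tape
        def splits(tape_idx: int, chosen) -> list[tuple]:
            if tape_idx == g.tapes:
                return [tuple(chosen)]
            lo, hi = spans[tape_idx]
            acc = []
            for k in range(lo, hi + 1):
                acc.extend(splits(tape_idx + 1, chosen + [(lo, k)]))
            return acc

        for head in splits(0, []):
            rest_spans = tuple((h[1], s[1]) for h, s in zip(head, spans))
            children = derive(p.rhs[idx], head)
            if not children:
                continue
            rests = assign(p, idx + 1, rest_spans)
            for child in children:
                for rest in rests:
                    out.append([child] + rest)
        return out

    full = tuple((0, len(t)) for t in tapes)
    results = list(derive(g.start, full))
    if len(results) > limit:
        raise OracleTooLarge(f"more than {limit} parses")
    return results


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def grammar_to_json(g: Grammar) -> str:
    """Serialise the symbolic content of a grammar as JSON.

    Engine-level constraints attached to productions are deliberately not
    part of the on-disk dialect; they are re-attached by the engine builders.
    """
    doc = {
        "name": g.name,
        "tapes": g.tapes,
        "start": g.start,
        "stop": g.stop,
        "symbols": [
            {
                "name": s.name,
                "role": s.role,
                "boundary_kind": s.boundary_kind,
                **({"consumes": list(s.consumes)} if s.consumes else {}),
                **({"inside_ref": s.inside_ref} if s.inside_ref else {}),
            }
            for s in g.symbols.values()
        ],
        "productions": [
            {
                "lhs": p.lhs,
                "rhs": list(p.rhs),
                "attribute": p.attribute,
                "ordered": p.ordered,
            }
            for p in g.productions
        ],
    }
    return json.dumps(doc, indent=2, ensure_ascii=False)


def grammar_from_json(text: str) -> Grammar:
    doc = json.loads(text)
    symbols = {
        d["name"]: Symbol(
            d["name"],
            d.get("role", "nonterminal"),
            d.get("boundary_kind", "empty"),
            tuple(d["consumes"]) if "consumes" in d else None,
            d.get("inside_ref"),
        )
        for d in doc["symbols"]
    }
    productions = [
        Production(
            d["lhs"], tuple(d["rhs"]), d.get("attribute", ""),
            d.get("ordered", True),
        )
        for d in doc["productions"]
    ]
    return Grammar(
        symbols,
        productions,
        start=doc["start"],
        stop=doc["stop"],
        tapes=doc.get("tapes", 1),
        name=doc.get("name", ""),
    )
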