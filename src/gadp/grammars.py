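"""Concrete decomposition grammars used by the DP engines.

Each builder returns the inside grammar of one engine:

* :func:`hmm_grammar` — two-state prefix grammar of the CpG-island HMM,
  whose outside derivation is the backward recursion;
* :func:`nw_grammar` — Needleman-Wunsch global alignment (linear gaps);
* :func:`gotoh_grammar` — affine-gap alignment with last-column state,
  whose outside derivation scores gap *closing* instead of opening;
* :func:`rna_grammar` — the toy RNA secondary-structure grammar, whose
  outside derivation yields base-pair probability recursions;
* :func:`shp_grammar` — the linear set grammar of Hamiltonian-path DP.
"""

from __future__ import annotations

from .grammar import Grammar, Production, Symbol

CANONICAL_PAIRS = frozenset(
    [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]
)


def hmm_grammar() -> Grammar:
    """Two-state HMM prefix grammar: S -> P|M; P,M -> Pc|Mc|eps.

    ``P`` (resp. ``M``) stands for a prefix whose last position is in the
    CpG-island "+" (resp. background "-") state; the terminal ``c`` is a
    transition between adjacent positions, so prefix objects carry their
    last position as a boundary shared with the complementary suffix.
    """
    symbols = {
        "S": Symbol("S", "start"),
        "ε": Symbol("ε", "stop"),
        "P": Symbol("P", "nonterminal", "left-right-points"),
        "M": Symbol("M", "nonterminal", "left-right-points"),
        "c": Symbol("c", "terminal", consumes=(1,)),
    }
    productions = [
        Production("S", ("P",), "top_plus"),
        Production("S", ("M",), "top_minus"),
        Production("P", ("P", "c"), "stay_plus"),
        Production("P", ("M", "c"), "switch_to_plus"),
        Production("P", ("ε",), "init_plus"),
        Production("M", ("P", "c"), "switch_to_minus"),
        Production("M", ("M", "c"), "stay_minus"),
        Production("M", ("ε",), "init_minus"),
    ]
    return Grammar(symbols, productions, "S", "ε", tapes=1, name="hmm")


def nw_grammar() -> Grammar:
    """Needleman-Wunsch: S -> A; A -> A(uv) | A(u-) | A(-v) | (εε)."""
    symbols = {
        "S": Symbol("S", "start"),
        "(εε)": Symbol("(εε)", "stop", consumes=(0, 0)),
        "A": Symbol("A", "nonterminal"),
        "(uv)": Symbol("(uv)", "terminal", consumes=(1, 1)),
        "(u-)": Symbol("(u-)", "terminal", consumes=(1, 0)),
        "(-v)": Symbol("(-v)", "terminal", consumes=(0, 1)),
    }
    productions = [
        Production("S", ("A",), "total"),
        Production("A", ("A", "(uv)"), "match"),
        Production("A", ("A", "(u-)"), "delete"),
        Production("A", ("A", "(-v)"), "insert"),
        Production("A", ("(εε)",), "empty"),
    ]
    return Grammar(symbols, productions, "S", "(εε)", tapes=2, name="nw")


def gotoh_grammar(stop_convention: str = "all") -> Grammar:
    """Affine-gap alignment grammar with last-column state M/D/I.

    ``(u-)``/``(-v)`` open a gap (entered from a different state), while
    ``(u·)``/``(·v)`` extend one.  ``stop_convention`` selects which states
    may derive the empty alignment: ``"all"`` is the symmetric textbook rule
    set; ``"match"`` keeps the stop rule on ``M`` only, which makes every
    alignment have a unique parse (the convention the numeric engine uses —
    it pins the empty prefix to the match class so the first gap column is
    always scored as an opening).
    """
    if stop_convention not in ("all", "match"):
        raise ValueError("stop_convention must be 'all' or 'match'")
    symbols = {
        "S": Symbol("S", "start"),
        "(εε)": Symbol("(εε)", "stop", consumes=(0, 0)),
        "M": Symbol("M", "nonterminal"),
        "D": Symbol("D", "nonterminal"),
        "I": Symbol("I", "nonterminal"),
        "(uv)": Symbol("(uv)", "terminal", consumes=(1, 1)),
        "(u-)": Symbol("(u-)", "terminal", consumes=(1, 0)),
        "(u·)": Symbol("(u·)", "terminal", consumes=(1, 0)),
        "(-v)": Symbol("(-v)", "terminal", consumes=(0, 1)),
        "(·v)": Symbol("(·v)", "terminal", consumes=(0, 1)),
    }
    productions = [
        Production("S", ("M",), "top_m"),
        Production("S", ("D",), "top_d"),
        Production("S", ("I",), "top_i"),
        Production("M", ("M", "(uv)"), "match_after_match"),
        Production("M", ("D", "(uv)"), "match_after_delete"),
        Production("M", ("I", "(uv)"), "match_after_insert"),
        Production("M", ("(εε)",), "empty_m"),
        Production("D", ("M", "(u-)"), "open_del_after_match"),
        Production("D", ("D", "(u·)"), "extend_del"),
        Production("D", ("I", "(u-)"), "open_del_after_insert"),
        Production("I", ("M", "(-v)"), "open_ins_after_match"),
        Production("I", ("D", "(-v)"), "open_ins_after_delete"),
        Production("I", ("I", "(·v)"), "extend_ins"),
    ]
    if stop_convention == "all":
        productions.insert(8, Production("D", ("(εε)",), "empty_d"))
        productions.append(Production("I", ("(εε)",), "empty_i"))
    return Grammar(symbols, productions, "S", "(εε)", tapes=2, name="gotoh")


def rna_grammar(pairs=CANONICAL_PAIRS, min_hairpin: int = 0) -> Grammar:
    """Toy RNA folding grammar: S -> U; U -> cU | BU | eps; B -> cUc'.

    ``B`` carries its closing base pair as a boundary (the pair is shared
    between the helix interior and its outside context).  The production
    constraint restricts ``B -> cUc'`` to the allowed pair set and to an
    enclosed span of at least ``min_hairpin`` positions; it is used by the
    exhaustive parse oracle, while the engines apply the same restriction
    inside their recursions.
    """
    pairs = frozenset(pairs)

    def pair_ok(children) -> bool:
        left, inner, right = children
        if (left.text[0], right.text[0]) not in pairs:
            return False
        lo, hi = inner.spans[0]
        return hi - lo >= min_hairpin

    symbols = {
        "S": Symbol("S", "start"),
        "ε": Symbol("ε", "stop"),
        "U": Symbol("U", "nonterminal"),
        "B": Symbol("B", "nonterminal", "point-pair"),
        "c": Symbol("c", "terminal", consumes=(1,)),
        "c'": Symbol("c'", "terminal", consumes=(1,)),
    }
    productions = [
        Production("S", ("U",), "total"),
        Production("U", ("c", "U"), "unpaired"),
        Production("U", ("B", "U"), "split"),
        Production("U", ("ε",), "empty"),
        Production("B", ("c", "U", "c'"), "pair", constraint=pair_ok),
    ]
    return Grammar(symbols, productions, "S", "ε", tapes=1, name="rna")


def shp_grammar() -> Grammar:
    """Linear set grammar of Hamiltonian-path DP: S -> A; A -> Av | eps.

    ``A`` is a punctuated set — an unordered vertex set with distinguished
    path endpoints — and the terminal ``v`` is the edge connecting the old
    endpoint to the newly split-off one.  The right-hand sides are multisets
    (``ordered=False``): a set tape has no intrinsic order, so ``A -> Av``
    stands for all |A| ways of splitting off a boundary vertex.
    """
    symbols = {
        "S": Symbol("S", "start"),
        "ε": Symbol("ε", "stop", boundary_kind="empty"),
        "A": Symbol("A", "nonterminal", "endpoint-set"),
        "v": Symbol("v", "terminal", consumes=(1,)),
    }
    productions = [
        Production("S", ("A",), "seed", ordered=False),
        Production("A", ("A", "v"), "extend", ordered=False),
        Production("A", ("ε",), "base", ordered=False),
    ]
    return Grammar(symbols, productions, "S", "ε", tapes=1, name="shp")
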