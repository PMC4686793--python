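"""Hand-transcribed outside rule sets used as golden references.

Each entry lists the outside grammar's productions as (lhs, rhs) pairs, in
no particular order; tests compare them as multisets against the mechanical
derivation from the corresponding inside grammar.
"""

# backward grammar of the two-state HMM:
# ε* -> P* | M* ;  P* -> P*c | M*c | S* ;  M* -> P*c | M*c | S*
HMM_OUTSIDE = [
    ("ε*", ("P*",)),
    ("ε*", ("M*",)),
    ("P*", ("P*", "c")),
    ("P*", ("M*", "c")),
    ("P*", ("S*",)),
    ("M*", ("P*", "c")),
    ("M*", ("M*", "c")),
    ("M*", ("S*",)),
]

# suffix variant of Needleman-Wunsch:
# (εε)* -> A* ;  A* -> A*(uv) | A*(u-) | A*(-v) | S*
NW_OUTSIDE = [
    ("(εε)*", ("A*",)),
    ("A*", ("A*", "(uv)")),
    ("A*", ("A*", "(u-)")),
    ("A*", ("A*", "(-v)")),
    ("A*", ("S*",)),
]

# gap-closing variant of the affine-gap grammar:
# E* -> M* | D* | I*
# M* -> M*(uv) | D*(u-) | I*(-v) | (σσ)*
# D* -> M*(uv) | D*(u·) | I*(-v) | (σσ)*
# I* -> M*(uv) | D*(u-) | I*(·v) | (σσ)*
GOTOH_OUTSIDE = [
    ("(εε)*", ("M*",)),
    ("(εε)*", ("D*",)),
    ("(εε)*", ("I*",)),
    ("M*", ("M*", "(uv)")),
    ("M*", ("D*", "(u-)")),
    ("M*", ("I*", "(-v)")),
    ("M*", ("S*",)),
    ("D*", ("M*", "(uv)")),
    ("D*", ("D*", "(u·)")),
    ("D*", ("I*", "(-v)")),
    ("D*", ("S*",)),
    ("I*", ("M*", "(uv)")),
    ("I*", ("D*", "(u-)")),
    ("I*", ("I*", "(·v)")),
    ("I*", ("S*",)),
]

# outside variant of the toy RNA folding grammar:
# ε* -> U* ;  U* -> cU* | BU* | cB*c' | S* ;  B* -> U*U
RNA_OUTSIDE = [
    ("ε*", ("U*",)),
    ("U*", ("c", "U*")),
    ("U*", ("B", "U*")),
    ("U*", ("c", "B*", "c'")),
    ("U*", ("S*",)),
    ("B*", ("U*", "U")),
]

# outside variant of the Hamiltonian-path set grammar:
# ε* -> A* ;  A* -> A*v | S*
SHP_OUTSIDE = [
    ("ε*", ("A*",)),
    ("A*", ("A*", "v")),
    ("A*", ("S*",)),
]
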