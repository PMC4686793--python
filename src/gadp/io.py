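"""Readers and writers for the plain-text formats the toolkit consumes.

FASTA goes through Biopython; the square distance-matrix format is the
PHYLIP-style dialect (first line the vertex count, then one row per vertex:
label followed by the full row of values).  All coordinates written to TSV
outputs are 1-based inclusive; internal arrays are 0-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .set_dp import DistanceMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_tsv_matrix",
    "write_tsv_vector",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Ordered (label, sequence) pairs; input order is preserved.

    Fails fast on empty files and duplicate labels (genomic order and
    identity matter downstream).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    labels = [r.id for r in records]
    dup = {l for l in labels if labels.count(l) > 1}
    if dup:
        raise ValueError(f"duplicate labels in {path}: {sorted(dup)}")
    return [(r.id, str(r.seq)) for r in records]


def write_fasta(path, pairs: list[tuple[str, str]]) -> None:
    records = [
        SeqRecord(Seq(seq), id=label, description="") for label, seq in pairs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_distance_matrix(path, require_symmetric: bool = False,
                         tol: float = 1e-6) -> DistanceMatrix:
    """Read a PHYLIP-style square distance matrix with labels."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty distance-matrix file {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"first line of {path} must be the matrix size")
    if len(lines) != n + 1:
        raise ValueError(f"expected {n} matrix rows in {path}, "
                         f"got {len(lines) - 1}")
    labels, rows = [], []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(
                f"row {parts[0] if parts else '?'} must have a label "
                f"and {n} values"
            )
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1:]])
    d = np.array(rows)
    dm = DistanceMatrix(d, labels)
    if require_symmetric and not dm.is_symmetric(tol):
        i, j = np.unravel_index(np.abs(d - d.T).argmax(), d.shape)
        raise ValueError(
            f"matrix in {path} is asymmetric at ({labels[i]}, {labels[j]}): "
            f"{d[i, j]!r} vs {d[j, i]!r}"
        )
    return dm


def write_distance_matrix(path, dm: DistanceMatrix) -> None:
    with open(path, "w") as fh:
        fh.write(f"{dm.n}\n")
        for label, row in zip(dm.labels, dm.d):
            vals = " ".join(f"{v:.6g}" for v in row)
            fh.write(f"{label} {vals}\n")


def write_tsv_matrix(path, matrix: np.ndarray, row_labels, col_labels) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(map(str, col_labels)) + "\n")
        for label, row in zip(row_labels, np.asarray(matrix)):
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{label}\t{vals}\n")


def write_tsv_vector(path, header: tuple[str, str], values: dict) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for key, v in values.items():
            fh.write(f"{key}\t{v:.6g}\n")
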