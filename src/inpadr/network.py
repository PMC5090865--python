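"""Loading, validation and assembly of the integrated protein--ADR network.

The integrated network couples three layers:

* a weighted, undirected protein--protein interaction (PPI) network with
  adjacency ``A`` (n x n, confidence scores in ``(0, 1]``),
* a binary bipartite protein--ADR relation network ``B`` (n x m), and
* a weighted, undirected ADR--ADR similarity network ``C`` (m x m, Jaccard
  scores in ``(0, 1]``).

Joined through the bipartite links, these form the block adjacency matrix
``W = [[A, B], [B^T, C]]`` on which the random walk operates.  Proteins are
indexed first (rows/columns ``0..n-1``), ADRs second (``n..n+m-1``); every
vector and matrix in the package follows that convention.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LabelIndex",
    "HeteroNetwork",
    "load_ppi",
    "load_relations",
    "read_pairs",
    "assemble",
    "write_ppi",
    "build_network",
]

#: words recognised as column headers in two-column relation/drug tables
_HEADER_WORDS = {
    "protein", "protein_a", "protein_b", "adr", "drug", "cui",
    "source", "target", "weight", "similarity", "score", "id",
}


class LabelIndex(Sequence[str]):
    """Ordered, unique identifier list with O(1) label -> position lookup.

    Used for both the protein and the ADR vertex sets; positions are
    contiguous ``0..len-1`` and define matrix rows/columns.
    """

    __slots__ = ("_labels", "_pos")

    def __init__(self, labels: Iterable[str]):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("identifiers must be unique")
        self._labels = tuple(labels)
        self._pos = {lab: i for i, lab in enumerate(self._labels)}

    @classmethod
    def from_labels(cls, labels: Iterable[str], sort: bool = True) -> "LabelIndex":
        labs = set(labels)
        return cls(sorted(labs) if sort else labs)

    def position(self, label: str) -> int:
        return self._pos[label]

    def __contains__(self, label: object) -> bool:
        return label in self._pos

    def __getitem__(self, i):
        return self._labels[i]

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelIndex) and self._labels == other._labels

    def __hash__(self) -> int:
        return hash(self._labels)

    def __repr__(self) -> str:
        return f"LabelIndex({len(self)} labels)"


@dataclass(frozen=True)
class HeteroNetwork:
    """The integrated protein--ADR network.

    Attributes
    ----------
    A : scipy.sparse.csr_matrix
        Symmetric nonnegative PPI confidence weights, zero diagonal.
    B : scipy.sparse.csr_matrix
        Binary protein--ADR relations (gold standard), shape (n, m).
    C : scipy.sparse.csr_matrix
        Symmetric ADR Jaccard similarities, zero diagonal.
    protein_index, adr_index : LabelIndex
        Row/column labelling of the blocks.
    """

    A: sp.csr_matrix
    B: sp.csr_matrix
    C: sp.csr_matrix
    protein_index: LabelIndex
    adr_index: LabelIndex

    @property
    def n_proteins(self) -> int:
        return len(self.protein_index)

    @property
    def n_adrs(self) -> int:
        return len(self.adr_index)

    def known_proteins(self, adr: str) -> frozenset[str]:
        """Proteins with a gold-standard relation to ``adr``."""
        j = self.adr_index.position(adr)
        rows = self.B.getcol(j).tocoo().row
        return frozenset(self.protein_index[i] for i in rows)

    def relation_pairs(self) -> list[tuple[str, str]]:
        """All (protein, adr) gold-standard pairs, deterministically ordered."""
        coo = self.B.tocoo()
        pairs = [
            (self.protein_index[i], self.adr_index[j])
            for i, j in zip(coo.row, coo.col)
        ]
        return sorted(pairs)

    def without_relation(self, protein: str, adr: str) -> "HeteroNetwork":
        """Copy of the network with one bipartite edge removed (LOOCV hold-out)."""
        i = self.protein_index.position(protein)
        j = self.adr_index.position(adr)
        if self.B[i, j] == 0:
            raise ValueError(f"relation ({protein}, {adr}) not present")
        B = self.B.tolil(copy=True)
        B[i, j] = 0
        B = B.tocsr()
        B.eliminate_zeros()
        return replace(self, B=B)


# ---------------------------------------------------------------------------
# readers

def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _rows(path) -> Iterator[list[str]]:
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def load_ppi(
    path,
    weight_scale: str = "raw01",
    extra_nodes: Iterable[str] | None = None,
) -> tuple[LabelIndex, sp.csr_matrix]:
    """Read a weighted PPI edge list and build the symmetric matrix ``A``.

    Parameters
    ----------
    path : str or Path
        TSV with columns ``protein_a<TAB>protein_b<TAB>weight``; a header
        line is detected by a non-numeric weight field; ``#`` lines are
        skipped; ``.gz`` files are decompressed transparently.
    weight_scale : {"raw01", "string_0_999"}
        ``raw01`` expects weights already in (0, 1]; ``string_0_999``
        accepts the STRING-style integer scale and divides by 1000.
    extra_nodes : iterable of str, optional
        Additional protein identifiers to index even if they carry no edge
        (isolated nodes; their transition rows are handled downstream).

    Returns
    -------
    (LabelIndex, csr_matrix)
        Sorted protein index and the symmetric weight matrix.
    """
    if weight_scale not in ("raw01", "string_0_999"):
        raise ValueError(f"unknown weight_scale {weight_scale!r}")
    divisor = 1000.0 if weight_scale == "string_0_999" else 1.0

    edges: dict[tuple[str, str], float] = {}
    nodes: set[str] = set(extra_nodes or ())
    first = True
    n_records = 0
    for fields in _rows(path):
        if len(fields) < 3:
            raise ValueError(f"PPI record needs 3 columns, got {fields!r}")
        a, b, wtxt = fields[0].strip(), fields[1].strip(), fields[2].strip()
        try:
            w = float(wtxt)
        except ValueError:
            if first:
                first = False
                continue  # header line
            raise ValueError(f"non-numeric weight {wtxt!r} for edge ({a}, {b})")
        first = False
        n_records += 1
        if w < 0:
            raise ValueError(f"negative weight {w} for edge ({a}, {b})")
        w /= divisor
        if w > 1.0:
            raise ValueError(
                f"weight {w} out of range (0, 1] for edge ({a}, {b}); "
                f"check weight_scale"
            )
        if a == b:
            warnings.warn(f"self-loop on {a!r} dropped")
            nodes.add(a)
            continue
        if w == 0:
            warnings.warn(f"zero-weight edge ({a}, {b}) dropped")
            nodes.update((a, b))
            continue
        nodes.update((a, b))
        key = (a, b) if a < b else (b, a)
        prev = edges.get(key)
        if prev is None or w > prev:  # duplicates collapse to max confidence
            edges[key] = w
    if n_records == 0:
        raise ValueError(f"no PPI records found in {path}")

    index = LabelIndex.from_labels(nodes)
    n = len(index)
    if edges:
        ii = np.fromiter((index.position(a) for a, _ in edges), dtype=np.int64)
        jj = np.fromiter((index.position(b) for _, b in edges), dtype=np.int64)
        ww = np.fromiter(edges.values(), dtype=float)
        A = sp.coo_matrix(
            (np.concatenate([ww, ww]),
             (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
            shape=(n, n),
        ).tocsr()
    else:
        A = sp.csr_matrix((n, n))
    return index, A


def read_pairs(path) -> list[tuple[str, str]]:
    """Read a two-column TSV of identifier pairs, skipping a header if present."""
    pairs: list[tuple[str, str]] = []
    first = True
    for fields in _rows(path):
        if len(fields) < 2:
            raise ValueError(f"record needs 2 columns, got {fields!r}")
        a, b = fields[0].strip(), fields[1].strip()
        if first and {a.lower(), b.lower()} <= _HEADER_WORDS:
            first = False
            continue
        first = False
        pairs.append((a, b))
    return pairs


def load_relations(
    source,
    protein_index: LabelIndex,
    adr_index: LabelIndex,
    on_unknown: str = "drop",
) -> sp.csr_matrix:
    """Build the binary bipartite matrix ``B`` from (protein, adr) records.

    ``source`` may be a path to a two-column TSV or an iterable of pairs.
    Records naming a protein (or ADR) absent from the corresponding index
    are dropped with a warning by default (``on_unknown="drop"``) — only
    networked proteins can be ranked — or rejected (``on_unknown="error"``).
    Duplicate records collapse to a single relation.
    """
    if on_unknown not in ("drop", "error"):
        raise ValueError(f"unknown policy {on_unknown!r}")
    pairs = source if isinstance(source, (list, tuple, set)) else read_pairs(source)

    rows, cols = [], []
    seen: set[tuple[int, int]] = set()
    for p, a in pairs:
        if p not in protein_index or a not in adr_index:
            msg = f"relation ({p}, {a}) references an unindexed identifier"
            if on_unknown == "error":
                raise ValueError(msg)
            warnings.warn(msg + "; dropped")
            continue
        ij = (protein_index.position(p), adr_index.position(a))
        if ij in seen:
            continue
        seen.add(ij)
        rows.append(ij[0])
        cols.append(ij[1])
    return sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(protein_index), len(adr_index)),
    ).tocsr()


def load_similarity(path, adr_index: LabelIndex) -> sp.csr_matrix:
    """Read a precomputed ADR--ADR similarity edge list aligned to ``adr_index``."""
    rows, cols, vals = [], [], []
    first = True
    for fields in _rows(path):
        if len(fields) < 3:
            raise ValueError(f"similarity record needs 3 columns, got {fields!r}")
        a, b, stxt = fields[0].strip(), fields[1].strip(), fields[2].strip()
        try:
            s = float(stxt)
        except ValueError:
            if first:
                first = False
                continue
            raise
        first = False
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"similarity {s} out of [0, 1] for ({a}, {b})")
        if a == b or s == 0.0:
            continue
        if a not in adr_index or b not in adr_index:
            warnings.warn(f"similarity edge ({a}, {b}) references an unindexed ADR; dropped")
            continue
        i, j = adr_index.position(a), adr_index.position(b)
        rows += [i, j]
        cols += [j, i]
        vals += [s, s]
    C = sp.coo_matrix((vals, (rows, cols)), shape=(len(adr_index),) * 2)
    # duplicate undirected records collapse to the maximum
    C = C.tocsr()
    C.sum_duplicates()
    coo = C.tocoo()
    dedup: dict[tuple[int, int], float] = {}
    for i, j, v in zip(coo.row, coo.col, coo.data):
        dedup[(i, j)] = max(dedup.get((i, j), 0.0), v)
    if dedup:
        ii, jj = zip(*dedup)
        C = sp.coo_matrix((list(dedup.values()), (ii, jj)), shape=C.shape).tocsr()
    return C


# ---------------------------------------------------------------------------
# assembly and output

def _symmetrize_max(X: sp.spmatrix, name: str) -> sp.csr_matrix:
    X = sp.csr_matrix(X)
    diff = (X - X.T)
    if diff.nnz and np.abs(diff.data).max() > 0:
        warnings.warn(f"{name} is asymmetric; symmetrized by elementwise max")
        X = X.maximum(X.T)
    return X


def assemble(
    A: sp.spmatrix,
    B: sp.spmatrix,
    C: sp.spmatrix,
    protein_index: LabelIndex,
    adr_index: LabelIndex,
) -> HeteroNetwork:
    """Validate the three blocks and return a :class:`HeteroNetwork`.

    Enforces dimension agreement, symmetry of ``A`` and ``C`` (symmetrizing
    by elementwise max with a warning if violated), zero diagonals, weight
    range [0, 1], and binary ``B``.
    """
    n, m = len(protein_index), len(adr_index)
    A, B, C = sp.csr_matrix(A), sp.csr_matrix(B), sp.csr_matrix(C)
    if A.shape != (n, n) or B.shape != (n, m) or C.shape != (m, m):
        raise ValueError(
            f"dimension mismatch: A{A.shape}, B{B.shape}, C{C.shape} "
            f"vs n={n}, m={m}"
        )
    A = _symmetrize_max(A, "A")
    C = _symmetrize_max(C, "C")
    for X, name in ((A, "A"), (C, "C")):
        if X.diagonal().any():
            warnings.warn(f"nonzero diagonal of {name} zeroed")
            X.setdiag(0)
            X.eliminate_zeros()
        if X.nnz and (X.data.min() < 0 or X.data.max() > 1):
            raise ValueError(f"{name} entries must lie in [0, 1]")
    if B.nnz and not np.isin(B.data, (0.0, 1.0)).all():
        raise ValueError("B entries must be binary")
    B.eliminate_zeros()
    return HeteroNetwork(A=A, B=B, C=C,
                         protein_index=protein_index, adr_index=adr_index)


def write_ppi(index: LabelIndex, A: sp.spmatrix, path) -> None:
    """Write the upper triangle of ``A`` as a 3-column edge-list TSV."""
    coo = sp.coo_matrix(sp.triu(A, k=1))
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tweight\n")
        for k in order:
            fh.write(f"{index[coo.row[k]]}\t{index[coo.col[k]]}\t{coo.data[k]:.10g}\n")


def build_network(
    ppi_path,
    relations_path,
    drug_adr_path=None,
    adr_sim_path=None,
    weight_scale: str = "raw01",
    on_unknown: str = "drop",
) -> HeteroNetwork:
    """End-to-end construction of the integrated network from TSV inputs.

    The ADR similarity layer comes either from a drug--ADR table (Jaccard
    over drug sets) or from a precomputed similarity edge list; at least one
    of the two must be given.  The ADR index is the sorted union of ADRs in
    the drug table (if any) and in the gold-standard relations.
    """
    from . import similarity  # local import avoids a module cycle

    protein_index, A = load_ppi(ppi_path, weight_scale=weight_scale)
    rel_pairs = read_pairs(relations_path)
    adr_labels = {a for _, a in rel_pairs}
    table = None
    if drug_adr_path is not None:
        table = similarity.DrugAdrTable.from_tsv(drug_adr_path)
        adr_labels |= set(table.adrs)
    elif adr_sim_path is None:
        raise ValueError("need a drug-ADR table or a precomputed ADR similarity file")
    adr_index = LabelIndex.from_labels(adr_labels)

    if table is not None:
        C = similarity.build_adr_similarity(table, adr_index)
    else:
        C = load_similarity(adr_sim_path, adr_index)
    B = load_relations(rel_pairs, protein_index, adr_index, on_unknown=on_unknown)
    return assemble(A, B, C, protein_index, adr_index)
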