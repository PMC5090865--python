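"""ADR--ADR similarity from drug co-occurrence.

Two adverse reactions are considered similar when they are elicited by
overlapping sets of drugs.  For ADRs *i* and *j* with drug sets ``D_i`` and
``D_j`` the similarity is the Jaccard index

    J(i, j) = |D_i ∩ D_j| / |D_i ∪ D_j|

and the ADR similarity network links *i* and *j* whenever J(i, j) > 0, with
the score as edge weight.  Self-similarity is never an edge (zero diagonal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

from .network import LabelIndex, read_pairs

__all__ = ["DrugAdrTable", "jaccard", "build_adr_similarity", "write_similarity"]


@dataclass(frozen=True)
class DrugAdrTable:
    """Deduplicated (drug, adr) pairs with the induced map adr -> drug set.

    Every ADR present in the table has at least one causing drug; ADRs with
    empty drug sets cannot occur by construction.
    """

    pairs: tuple[tuple[str, str], ...]
    adr_to_drugs: Mapping[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DrugAdrTable":
        uniq = sorted(set((d, a) for d, a in pairs))
        if not uniq:
            raise ValueError("drug-ADR table is empty")
        by_adr: dict[str, set[str]] = {}
        for d, a in uniq:
            by_adr.setdefault(a, set()).add(d)
        return cls(
            pairs=tuple(uniq),
            adr_to_drugs={a: frozenset(s) for a, s in by_adr.items()},
        )

    @classmethod
    def from_tsv(cls, path) -> "DrugAdrTable":
        """Read a 2-column ``drug<TAB>adr`` TSV (optional header, gzip ok)."""
        return cls.from_pairs(read_pairs(path))

    @property
    def adrs(self) -> tuple[str, ...]:
        return tuple(sorted(self.adr_to_drugs))

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted({d for d, _ in self.pairs}))


def jaccard(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b| of two drug sets.

    Undefined (raises) when both sets are empty.
    """
    if not set_a and not set_b:
        raise ValueError("Jaccard similarity of two empty sets is undefined")
    inter = len(set_a & set_b)
    if inter == 0:
        return 0.0
    return inter / len(set_a | set_b)


def build_adr_similarity(table: DrugAdrTable, adr_index: LabelIndex) -> sp.csr_matrix:
    """Pairwise Jaccard matrix ``C`` over the indexed ADRs.

    ``C[i, j] = J(D_i, D_j)`` for i != j when positive, else 0; the diagonal
    is zero.  An indexed ADR absent from the drug table becomes an isolated
    node (zero row) with a warning — this keeps the ranking universe aligned
    with the gold standard even when the drug table does not cover it.
    """
    m = len(adr_index)
    missing = [a for a in adr_index if a not in table.adr_to_drugs]
    if missing:
        warnings.warn(
            f"{len(missing)} ADR(s) absent from the drug table are isolated "
            f"in the similarity network: {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    covered = [a for a in adr_index if a in table.adr_to_drugs]
    if not covered:
        return sp.csr_matrix((m, m))

    drug_pos = {d: k for k, d in enumerate(sorted({d for a in covered
                                                   for d in table.adr_to_drugs[a]}))}
    X = sp.lil_matrix((m, len(drug_pos)), dtype=np.float64)
    for a in covered:
        i = adr_index.position(a)
        for d in table.adr_to_drugs[a]:
            X[i, drug_pos[d]] = 1.0
    X = X.tocsr()

    inter = (X @ X.T).toarray()
    sizes = np.asarray(X.sum(axis=1)).ravel()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(C, 0.0)
    return sp.csr_matrix(C)


def write_similarity(adr_index: LabelIndex, C: sp.spmatrix, path) -> None:
    """Write the upper triangle of ``C`` as a 3-column edge-list TSV."""
    coo = sp.coo_matrix(sp.triu(C, k=1))
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write("adr_a\tadr_b\tsimilarity\n")
        for k in order:
            fh.write(f"{adr_index[coo.row[k]]}\t{adr_index[coo.col[k]]}\t{coo.data[k]:.10g}\n")
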