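"""Row-stochastic block transition matrix of the heterogeneous walk.

The walker's one-step kernel is the block matrix

    M = [[M_PP, M_PA],
         [M_AP, M_AA]]

with proteins indexed first.  At a protein that has both PPI neighbours and
ADR links, the walker crosses to a linked ADR with the jumping probability
``lambda`` and stays in the PPI layer with ``1 - lambda``; within each
choice the destination is drawn proportionally to edge weight.  A protein
with no ADR links moves only in the PPI layer (its row is the normalized
PPI row regardless of ``lambda``); a protein whose only edges are bipartite
gives its full mass to the ADR layer, except at ``lambda = 0`` where the
bipartite links are severed and the row is left dangling.  ADR rows are
built symmetrically from the similarity matrix ``C`` and ``B^T``.

Rows of fully isolated nodes are all-zero ("dangling"); the walk module
redistributes their mass to the restart distribution, which preserves total
probability without inventing edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network import HeteroNetwork

__all__ = [
    "TransitionModel",
    "build_transition",
    "build_ppi_transition",
    "validate_stochastic",
    "write_transition",
    "StochasticReport",
]


@dataclass(frozen=True)
class TransitionModel:
    """Sparse row-stochastic transition matrix with block layout metadata."""

    M: sp.csr_matrix
    lam: float
    n_proteins: int
    n_adrs: int

    @property
    def size(self) -> int:
        return self.n_proteins + self.n_adrs

    @property
    def dangling(self) -> np.ndarray:
        """Boolean mask of all-zero rows (isolated nodes)."""
        return np.asarray(np.abs(self.M).sum(axis=1)).ravel() == 0


def _row_scaled(X: sp.spmatrix, scale_over_sum: np.ndarray) -> sp.csr_matrix:
    """Rows of X multiplied elementwise by scale_over_sum (already /rowsum)."""
    return sp.diags(scale_over_sum) @ sp.csr_matrix(X)


def build_transition(net: HeteroNetwork, lam: float = 0.5) -> TransitionModel:
    """Assemble the transition matrix for jumping probability ``lam``.

    For a protein row *i* with PPI weight sum ``a_i`` and bipartite degree
    ``b_i``::

        a_i > 0, b_i > 0:  M_PP[i,:] = (1-lam) A[i,:]/a_i,  M_PA[i,:] = lam B[i,:]/b_i
        a_i > 0, b_i = 0:  M_PP[i,:] = A[i,:]/a_i
        a_i = 0, b_i > 0:  M_PA[i,:] = B[i,:]/b_i   (dangling if lam == 0)
        a_i = 0, b_i = 0:  zero row (dangling)

    and symmetrically for ADR rows with ``C`` and ``B^T``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"jumping probability {lam} outside [0, 1]")
    A, B, C = net.A, net.B, net.C
    a = np.asarray(A.sum(axis=1)).ravel()
    b = np.asarray(B.sum(axis=1)).ravel()
    c = np.asarray(C.sum(axis=1)).ravel()
    bt = np.asarray(B.sum(axis=0)).ravel()

    def scales(intra_sum, cross_sum):
        has_i = intra_sum > 0
        has_c = cross_sum > 0
        intra = np.where(has_i & has_c, 1.0 - lam, np.where(has_i, 1.0, 0.0))
        cross = np.where(has_i & has_c, lam,
                         np.where(has_c, 1.0 if lam > 0 else 0.0, 0.0))
        safe_i = np.where(has_i, intra_sum, 1.0)
        safe_c = np.where(has_c, cross_sum, 1.0)
        return intra / safe_i, cross / safe_c

    pp, pa = scales(a, b)
    aa, ap = scales(c, bt)

    M = sp.bmat(
        [[_row_scaled(A, pp), _row_scaled(B, pa)],
         [_row_scaled(B.T, ap), _row_scaled(C, aa)]],
        format="csr",
    )
    return TransitionModel(M=M, lam=lam,
                           n_proteins=net.n_proteins, n_adrs=net.n_adrs)


def build_ppi_transition(net: HeteroNetwork) -> TransitionModel:
    """Row-normalized walk on the PPI layer alone (the single-network baseline)."""
    a = np.asarray(net.A.sum(axis=1)).ravel()
    scale = np.where(a > 0, 1.0 / np.where(a > 0, a, 1.0), 0.0)
    M = _row_scaled(net.A, scale)
    return TransitionModel(M=M, lam=0.0, n_proteins=net.n_proteins, n_adrs=0)


@dataclass(frozen=True)
class StochasticReport:
    """Row-sum audit of a transition matrix."""

    deviant_rows: tuple[tuple[int, float], ...]  # (row, row sum) pairs
    dangling_rows: tuple[int, ...]
    tol: float = 1e-9

    @property
    def ok(self) -> bool:
        return not self.deviant_rows


def validate_stochastic(model: TransitionModel, tol: float = 1e-9) -> StochasticReport:
    """List rows whose sum deviates from 1 by more than ``tol`` and zero rows."""
    sums = np.asarray(model.M.sum(axis=1)).ravel()
    dangling = np.flatnonzero(sums == 0)
    nonzero = np.setdiff1d(np.flatnonzero(np.abs(sums - 1.0) > tol), dangling)
    return StochasticReport(
        deviant_rows=tuple((int(i), float(sums[i])) for i in nonzero),
        dangling_rows=tuple(int(i) for i in dangling),
        tol=tol,
    )


def write_transition(model: TransitionModel, path) -> None:
    """Dump M as coordinate triplets ``row<TAB>col<TAB>prob`` for inspection."""
    coo = model.M.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write("row\tcol\tprob\n")
        for k in order:
            fh.write(f"{coo.row[k]}\t{coo.col[k]}\t{coo.data[k]:.12g}\n")
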