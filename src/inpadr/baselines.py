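"""Comparison methods: hypergeometric enrichment and PPI-only restart walk.

Both baselines rank the same candidate universe as the integrated-network
walk, so their LOOCV reports are directly comparable.

The enrichment baseline scores a candidate protein by the over-representation
of the focus ADR's known proteins among the candidate's PPI neighbours
(upper-tail hypergeometric test).  The construction of the contingency table
from the network — neighbourhood x known-protein-set overlap against the
population of networked proteins — is this package's concrete reading of a
network-based enrichment baseline; other constructions are possible.

The PPI-only walk seeds the remaining known proteins uniformly and walks on
the row-normalized PPI layer alone; it requires at least one remaining seed
protein, hence ADRs with fewer than two known relations cannot be evaluated
with it under leave-one-out.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import hypergeom, rankdata

from .network import HeteroNetwork
from .rwr import (
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    RankResult,
    rank_candidates,
    walk,
)
from .transition import build_ppi_transition

__all__ = [
    "hypergeom_pvalue",
    "rank_by_enrichment",
    "rwr_ppi",
    "filter_gold_for_rwr",
]


def hypergeom_pvalue(k: int, K: int, s: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeom(N, K, s).

    ``N`` networked proteins of which ``K`` are related to the ADR; a
    neighbourhood of size ``s`` containing ``k`` of them.
    """
    if not (0 <= K <= N and 0 <= s <= N):
        raise ValueError(f"invalid configuration K={K}, s={s}, N={N}")
    if not 0 <= k <= min(K, s):
        raise ValueError(f"impossible overlap k={k} for K={K}, s={s}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, s))


def rank_by_enrichment(
    net: HeteroNetwork,
    focus_adr: str,
    known: frozenset[str] | set[str] | None = None,
    exclude: frozenset[str] | set[str] | None = None,
) -> RankResult:
    """Rank candidates by ascending hypergeometric p-value.

    For each candidate: k = |PPI neighbours ∩ known proteins of the ADR|,
    s = |PPI neighbours|, K = |known proteins|, N = number of indexed
    proteins.  Ties (identical p-values) get average ranks.  ``known``
    defaults to the ADR's proteins in ``net``; ``exclude`` defaults to
    ``known``.
    """
    if known is None:
        known = net.known_proteins(focus_adr)
    known = frozenset(known)
    exclude = frozenset(known if exclude is None else exclude)
    K = len(known)
    N = net.n_proteins
    if K == 0:
        warnings.warn(f"ADR {focus_adr!r} has no known proteins; "
                      f"enrichment ranking is degenerate")
    known_pos = np.zeros(N, dtype=bool)
    for p in known:
        known_pos[net.protein_index.position(p)] = True

    A = net.A.tocsr()
    cand = [p for p in net.protein_index if p not in exclude]
    if not cand:
        warnings.warn(f"no candidate proteins left for ADR {focus_adr!r}")
        return RankResult(focus_adr=focus_adr, proteins=(),
                          scores=np.empty(0), ranks=np.empty(0), exclude=exclude)
    ks = np.empty(len(cand), dtype=int)
    ss = np.empty(len(cand), dtype=int)
    for idx, p in enumerate(cand):
        i = net.protein_index.position(p)
        nbrs = A.indices[A.indptr[i]:A.indptr[i + 1]]
        ss[idx] = len(nbrs)
        ks[idx] = int(known_pos[nbrs].sum())
    pvals = hypergeom.sf(ks - 1, N, K, ss)
    ranks = rankdata(pvals, method="average")
    with np.errstate(divide="ignore"):
        scores = -np.log10(pvals)
    order = np.lexsort((np.array(cand), ranks))
    return RankResult(
        focus_adr=focus_adr,
        proteins=tuple(cand[i] for i in order),
        scores=scores[order],
        ranks=ranks[order],
        exclude=exclude,
    )


def rwr_ppi(
    net: HeteroNetwork,
    focus_adr: str,
    seed_proteins: frozenset[str] | set[str] | None = None,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    exclude: frozenset[str] | set[str] | None = None,
) -> RankResult:
    """Restart walk on the PPI layer alone, seeded at the known proteins.

    The initial distribution is uniform over ``seed_proteins`` (defaulting
    to the ADR's known proteins); at least one seed is required.
    """
    if seed_proteins is None:
        seed_proteins = net.known_proteins(focus_adr)
    seed_proteins = frozenset(seed_proteins)
    if not seed_proteins:
        raise ValueError(
            f"PPI-only walk needs at least one seed protein for {focus_adr!r}"
        )
    model = build_ppi_transition(net)
    p0 = np.zeros(net.n_proteins)
    for p in seed_proteins:
        p0[net.protein_index.position(p)] = 1.0 / len(seed_proteins)
    res = walk(model, p0, r=r, tol=tol, max_iter=max_iter)
    # pad with an (unused) zero ADR block so the shared ranker applies
    stable = np.concatenate([res.p, np.zeros(net.n_adrs)])
    return rank_candidates(stable, net, focus_adr,
                           exclude=seed_proteins if exclude is None else exclude)


def filter_gold_for_rwr(pairs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Keep relations whose ADR has at least two related proteins.

    Under leave-one-out, the PPI-only walk needs a remaining seed protein,
    so single-relation ADRs cannot be evaluated with it.
    """
    counts: dict[str, int] = {}
    for _, a in pairs:
        counts[a] = counts.get(a, 0) + 1
    return [(p, a) for p, a in pairs if counts[a] >= 2]
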