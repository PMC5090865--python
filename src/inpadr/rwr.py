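"""Random walk with restart on the integrated network, and candidate ranking.

The walk iterates

    p_{t+1} = (1 - r) M^T p_t + r p_0

until the L1 change falls below a tolerance.  ``p_0`` places mass ``eta`` on
the query ADR node and ``1 - eta`` spread uniformly over its known (seed)
proteins; ``r`` is the per-step restart probability.  The converged ("stable")
probability over protein nodes scores each candidate's proximity to the
query, and candidates are ranked by descending score.

Defaults r = 0.7, lambda = 0.5, eta = 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .network import HeteroNetwork
from .transition import TransitionModel, build_transition

__all__ = [
    "SeedSpec",
    "WalkResult",
    "RankResult",
    "initial_probability",
    "walk",
    "rank_candidates",
    "top_k",
    "rank_adr",
    "DEFAULT_RESTART",
    "DEFAULT_LAMBDA",
    "DEFAULT_ETA",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
    "DEFAULT_TOP_K",
]

logger = logging.getLogger(__name__)

DEFAULT_RESTART = 0.7
DEFAULT_LAMBDA = 0.5
DEFAULT_ETA = 0.5
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000
DEFAULT_TOP_K = 50


@dataclass(frozen=True)
class SeedSpec:
    """A query: one focus ADR, its known proteins, and the mass split ``eta``."""

    focus_adr: str
    seed_proteins: frozenset[str] = frozenset()
    eta: float = DEFAULT_ETA
    restart: float = DEFAULT_RESTART

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta {self.eta} outside [0, 1]")
        if not 0.0 < self.restart <= 1.0:
            raise ValueError(f"restart {self.restart} outside (0, 1]")


@dataclass(frozen=True)
class WalkResult:
    p: np.ndarray
    iterations: int
    converged: bool
    residual: float


@dataclass(frozen=True)
class RankResult:
    """Stable-probability scores over the candidate proteins of one ADR.

    Candidates are stored in rank order (best first); ``ranks`` uses average
    (mid-) ranks for ties, so tied scores share a fractional rank.
    """

    focus_adr: str
    proteins: tuple[str, ...]
    scores: np.ndarray
    ranks: np.ndarray
    exclude: frozenset[str] = frozenset()
    _pos: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "_pos",
                           {p: i for i, p in enumerate(self.proteins)})

    def __len__(self) -> int:
        return len(self.proteins)

    def rank_of(self, protein: str) -> float:
        return float(self.ranks[self._pos[protein]])

    def score_of(self, protein: str) -> float:
        return float(self.scores[self._pos[protein]])


def initial_probability(spec: SeedSpec, net: HeteroNetwork) -> np.ndarray:
    """The restart distribution ``p_0`` of length n + m (proteins first).

    The protein block carries ``1 - eta`` uniformly over the seed proteins;
    the ADR block carries ``eta`` on the focus ADR.  When the query has no
    seed proteins (e.g. a single-relation ADR under hold-out) all mass goes
    to the ADR node with a warning — this is precisely the situation where
    the integrated network still yields a ranking while a PPI-only walk
    cannot.
    """
    if spec.focus_adr not in net.adr_index:
        raise ValueError(f"unknown focus ADR {spec.focus_adr!r}")
    unknown = [p for p in spec.seed_proteins if p not in net.protein_index]
    if unknown:
        raise ValueError(f"seed proteins not indexed: {unknown[:5]}")
    n, m = net.n_proteins, net.n_adrs
    p0 = np.zeros(n + m)
    j = net.adr_index.position(spec.focus_adr)
    if spec.seed_proteins:
        w = (1.0 - spec.eta) / len(spec.seed_proteins)
        for p in spec.seed_proteins:
            p0[net.protein_index.position(p)] = w
        p0[n + j] = spec.eta
    else:
        warnings.warn(
            f"no seed proteins for ADR {spec.focus_adr!r}; "
            f"all initial mass placed on the ADR node"
        )
        p0[n + j] = 1.0
    if spec.seed_proteins and spec.eta == 0.0 and p0.sum() == 0.0:
        raise ValueError("initial probability has zero mass")
    return p0


def walk(
    model: TransitionModel,
    p0: np.ndarray,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> WalkResult:
    """Iterate the restart walk to its stable probability.

    Mass sitting on dangling (all-zero) rows of ``M`` would leak out of the
    propagation step; it is redistributed proportionally to ``p_0`` before
    the restart term, so every iterate sums to 1 exactly.  Non-convergence
    within ``max_iter`` returns ``converged=False`` with a warning rather
    than raising.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"restart probability {r} outside (0, 1]")
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"p0 sums to {p0.sum()}, expected 1")
    MT = model.M.T.tocsr()
    dang = model.dangling
    any_dang = bool(dang.any())

    p = p0.copy()
    residual = np.inf
    for t in range(1, max_iter + 1):
        q = MT @ p
        if any_dang:
            q = q + p[dang].sum() * p0
        p_next = (1.0 - r) * q + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            logger.info("walk converged in %d iterations (residual %.3g)", t, residual)
            return WalkResult(p=p, iterations=t, converged=True, residual=residual)
    warnings.warn(f"walk did not converge in {max_iter} iterations "
                  f"(residual {residual:.3g})")
    return WalkResult(p=p, iterations=max_iter, converged=False, residual=residual)


def rank_candidates(
    stable: np.ndarray,
    net: HeteroNetwork,
    focus_adr: str,
    exclude: frozenset[str] | set[str] | None = None,
) -> RankResult:
    """Rank candidate proteins of ``focus_adr`` by stable probability.

    Candidates are all indexed proteins minus ``exclude`` (defaulting to the
    ADR's known proteins, i.e. the seeds).  Ties receive average ranks, the
    Mann-Whitney-consistent convention.
    """
    if exclude is None:
        exclude = net.known_proteins(focus_adr)
    exclude = frozenset(exclude)
    cand = [p for p in net.protein_index if p not in exclude]
    if not cand:
        warnings.warn(f"no candidate proteins left for ADR {focus_adr!r}")
        return RankResult(focus_adr=focus_adr, proteins=(),
                          scores=np.empty(0), ranks=np.empty(0),
                          exclude=exclude)
    scores = np.array([stable[net.protein_index.position(p)] for p in cand])
    ranks = rankdata(-scores, method="average")
    order = np.lexsort((np.array(cand), ranks))  # rank, then id for determinism
    return RankResult(
        focus_adr=focus_adr,
        proteins=tuple(cand[i] for i in order),
        scores=scores[order],
        ranks=ranks[order],
        exclude=exclude,
    )


def top_k(result: RankResult, k: int = DEFAULT_TOP_K) -> list[str]:
    """The first ``min(k, |candidates|)`` proteins by rank (best first)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return list(result.proteins[:k])


def rank_adr(
    net: HeteroNetwork,
    focus_adr: str,
    seed_proteins: frozenset[str] | set[str] | None = None,
    *,
    r: float = DEFAULT_RESTART,
    lam: float = DEFAULT_LAMBDA,
    eta: float = DEFAULT_ETA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    exclude: frozenset[str] | set[str] | None = None,
    model: TransitionModel | None = None,
) -> RankResult:
    """One-call query: build M, seed, walk, and rank candidates for one ADR.

    ``seed_proteins`` defaults to the ADR's known proteins in ``net``;
    ``exclude`` defaults to the seed set.  A prebuilt ``model`` may be passed
    when the same network is queried repeatedly.
    """
    if seed_proteins is None:
        seed_proteins = net.known_proteins(focus_adr)
    seed_proteins = frozenset(seed_proteins)
    spec = SeedSpec(focus_adr=focus_adr, seed_proteins=seed_proteins,
                    eta=eta, restart=r)
    if model is None:
        model = build_transition(net, lam=lam)
    p0 = initial_probability(spec, net)
    res = walk(model, p0, r=r, tol=tol, max_iter=max_iter)
    return rank_candidates(res.p, net, focus_adr,
                           exclude=seed_proteins if exclude is None else exclude)
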