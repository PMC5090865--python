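"""Leave-one-out cross-validation, ROC curves, and AUC.

Each gold-standard relation (protein, ADR) is removed from the bipartite
layer, the focus ADR and its remaining known proteins become the seeds, and
the held-out protein is ranked among all candidates (every indexed protein
without a remaining known relation to that ADR — so the test protein is
always a candidate).

Folds from ADRs with different candidate-set sizes are pooled on the
normalized rank

    u = (rank - 1) / (n_candidates - 1)  in [0, 1],

the fraction of candidates ranked strictly above the test protein (with
half-weight for ties, via average ranks).  The ROC is the exact threshold
sweep over distinct normalized ranks: sensitivity(theta) is the fraction of
held-out relations recovered at threshold theta, and 1 - specificity(theta)
is the fraction of candidate proteins above the threshold, which under this
pooling is theta itself.  The trapezoidal area then coincides exactly with
the Mann-Whitney statistic ``1 - mean(u)``, i.e. the average probability
that the test protein outranks a random candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import baselines
from .network import HeteroNetwork
from .rwr import (
    DEFAULT_ETA,
    DEFAULT_LAMBDA,
    DEFAULT_MAX_ITER,
    DEFAULT_RESTART,
    DEFAULT_TOL,
    RankResult,
    rank_adr,
)

__all__ = [
    "CVFold",
    "CVReport",
    "FoldSkipped",
    "loocv",
    "roc_auc",
    "normalized_rank",
    "parameter_sweep",
    "permute_relations",
    "inpadr_ranker",
    "enrichment_ranker",
    "rwr_ppi_ranker",
    "METHODS",
]


class FoldSkipped(Exception):
    """Raised by a ranking method that cannot evaluate a fold."""


@dataclass(frozen=True)
class CVFold:
    """One hold-out: the removed relation and the rank of its protein."""

    protein: str
    adr: str
    n_seed_proteins: int
    n_candidates: int
    rank: float
    normalized_rank: float
    status: str = "ok"  # ok | skipped | failed
    note: str = ""


@dataclass(frozen=True)
class CVReport:
    method: str
    params: dict = field(compare=False)
    folds: tuple[CVFold, ...] = ()
    roc: np.ndarray = field(default_factory=lambda: np.empty((0, 2)), compare=False)
    auc: float = float("nan")

    @property
    def ok_folds(self) -> tuple[CVFold, ...]:
        return tuple(f for f in self.folds if f.status == "ok")

    @property
    def n_failed(self) -> int:
        return sum(f.status != "ok" for f in self.folds)

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(f) for f in self.folds])


def normalized_rank(rank: float, n_candidates: int) -> float:
    """Fraction of candidates ranked strictly above (ties half-weighted)."""
    if n_candidates < 1 or not 1 <= rank <= n_candidates:
        raise ValueError(f"rank {rank} invalid for {n_candidates} candidates")
    if n_candidates == 1:
        return 0.0
    return (rank - 1.0) / (n_candidates - 1.0)


# ---------------------------------------------------------------------------
# ranking-method adapters: (net-without-edge, adr, seeds, **params) -> RankResult

def inpadr_ranker(net, focus_adr, seed_proteins, *, r=DEFAULT_RESTART,
                  lam=DEFAULT_LAMBDA, eta=DEFAULT_ETA, tol=DEFAULT_TOL,
                  max_iter=DEFAULT_MAX_ITER) -> RankResult:
    """The integrated-network walk (the method under study)."""
    return rank_adr(net, focus_adr, seed_proteins, r=r, lam=lam, eta=eta,
                    tol=tol, max_iter=max_iter, exclude=seed_proteins)


def enrichment_ranker(net, focus_adr, seed_proteins, **_params) -> RankResult:
    """Hypergeometric enrichment baseline."""
    return baselines.rank_by_enrichment(net, focus_adr, known=seed_proteins,
                                        exclude=seed_proteins)


def rwr_ppi_ranker(net, focus_adr, seed_proteins, *, r=DEFAULT_RESTART,
                   tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER,
                   **_params) -> RankResult:
    """PPI-only restart walk; skips folds without a remaining seed protein."""
    if not seed_proteins:
        raise FoldSkipped("no remaining seed protein for the PPI-only walk")
    return baselines.rwr_ppi(net, focus_adr, seed_proteins, r=r, tol=tol,
                             max_iter=max_iter, exclude=seed_proteins)


METHODS = {
    "inpadr": inpadr_ranker,
    "hyper": enrichment_ranker,
    "rwr-ppi": rwr_ppi_ranker,
}


# ---------------------------------------------------------------------------

def loocv(
    net: HeteroNetwork,
    method=inpadr_ranker,
    params: dict | None = None,
    pairs: list[tuple[str, str]] | None = None,
    method_label: str | None = None,
) -> CVReport:
    """Leave-one-out cross-validation over the gold-standard relations.

    Parameters
    ----------
    method : callable
        ``method(net_without_edge, focus_adr, seed_proteins, **params)``
        returning a :class:`~inpadr.rwr.RankResult`; one of the adapters in
        :data:`METHODS` or any compatible callable.
    pairs : list of (protein, adr), optional
        Restrict the folds to a subset of relations (e.g. the >= 2-protein
        subset used to compare against the PPI-only walk); the full network
        is still used for seeding.
    """
    params = dict(params or {})
    if pairs is None:
        pairs = net.relation_pairs()
    if not pairs:
        raise ValueError("no gold-standard relations to cross-validate")

    folds: list[CVFold] = []
    for protein, adr in pairs:
        held = net.without_relation(protein, adr)
        seeds = held.known_proteins(adr)
        assert protein not in seeds, "held-out protein must not remain a seed"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = method(held, adr, seeds, **params)
            rank = result.rank_of(protein)
        except FoldSkipped as exc:
            folds.append(CVFold(protein, adr, len(seeds), 0, np.nan, np.nan,
                                status="skipped", note=str(exc)))
            continue
        except Exception as exc:  # fold-level failure is reported, not fatal
            warnings.warn(f"fold ({protein}, {adr}) failed: {exc}")
            folds.append(CVFold(protein, adr, len(seeds), 0, np.nan, np.nan,
                                status="failed", note=str(exc)))
            continue
        ncand = len(result)
        folds.append(CVFold(protein, adr, len(seeds), ncand, rank,
                            normalized_rank(rank, ncand)))

    label = method_label or getattr(method, "__name__", "method")
    ok = [f for f in folds if f.status == "ok"]
    if ok:
        roc, auc = roc_auc(ok)
    else:
        warnings.warn(f"no successful folds for method {label!r}")
        roc, auc = np.empty((0, 2)), float("nan")
    return CVReport(method=label, params=params, folds=tuple(folds),
                    roc=roc, auc=auc)


def roc_auc(folds) -> tuple[np.ndarray, float]:
    """Exact ROC over the pooled normalized ranks and its trapezoidal AUC.

    ``folds`` is a sequence of :class:`CVFold` (or anything exposing
    ``normalized_rank``).  The curve starts at (0, 0), steps up at every
    distinct normalized rank, and ends at (1, 1); the returned AUC equals
    ``1 - mean(normalized rank)``.
    """
    u = np.array([f.normalized_rank for f in folds], dtype=float)
    if u.size == 0:
        raise ValueError("no successful folds")
    if np.isnan(u).any() or u.min() < 0 or u.max() > 1:
        raise ValueError("normalized ranks must lie in [0, 1]")

    values, counts = np.unique(u, return_counts=True)
    ecdf = np.cumsum(counts) / u.size
    xs: list[float] = [0.0]
    ys: list[float] = [0.0]
    prev = 0.0
    for v, y in zip(values, ecdf):
        xs += [float(v), float(v)]
        ys += [prev, float(y)]
        prev = float(y)
    xs.append(1.0)
    ys.append(1.0)
    points = np.column_stack([xs, ys])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc


def parameter_sweep(
    net: HeteroNetwork,
    param_name: str,
    values,
    method=inpadr_ranker,
    base_params: dict | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """One full LOOCV per parameter value, other parameters at defaults."""
    if param_name not in ("lam", "eta", "r"):
        raise ValueError(f"unknown parameter {param_name!r}")
    rows = []
    for v in values:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{param_name}={v} outside [0, 1]")
        params = dict(base_params or {})
        params[param_name] = v
        report = loocv(net, method, params=params, pairs=pairs)
        rows.append({param_name: v, "auc": report.auc,
                     "n_folds": len(report.ok_folds)})
    return pd.DataFrame(rows)


def permute_relations(net: HeteroNetwork, seed: int) -> HeteroNetwork:
    """Null network: reassign each ADR's related proteins uniformly at random.

    Preserves the number of relations per ADR but destroys the planted
    protein-module signal; LOOCV on the result estimates chance performance.
    """
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    n, m = net.n_proteins, net.n_adrs
    rows, cols = [], []
    counts = np.asarray(net.B.sum(axis=0)).ravel().astype(int)
    for j in range(m):
        if counts[j] == 0:
            continue
        chosen = rng.choice(n, size=counts[j], replace=False)
        rows.extend(int(i) for i in chosen)
        cols.extend([j] * counts[j])
    B = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, m)).tocsr()
    return replace(net, B=B)
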