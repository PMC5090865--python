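"""Synthetic tripartite drug--ADR--protein fixtures with planted signal.

The generator emulates the structure of the real inputs — a sparse weighted
PPI network, a drug--ADR bipartite layer inducing Jaccard similarities
between ADRs, and a sparse protein--ADR gold standard — at desk scale, with
a controllable planted signal: proteins fall into modules (planted-partition
topology), each ADR is assigned a module, ADRs of a module draw their drugs
from a shared pool (so within-module Jaccard similarity is high), and each
gold relation's protein is drawn from the ADR's module with probability
``signal`` (else uniformly).  At ``signal = 0`` the gold standard carries no
network information and rank-based evaluation should sit at chance.

A preferential-attachment ("scale_free") topology is available as a
secondary option for the PPI layer, echoing the heavy-tailed degree
distributions of real interactomes; modules are then label-only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .network import HeteroNetwork, LabelIndex, assemble, load_relations
from .similarity import DrugAdrTable, build_adr_similarity

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "summarize",
           "network_from_truth"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic fixture.

    Defaults give a desk-scale analogue of the real data: 200 proteins in 5
    modules, 40 ADRs, 120 drugs, ~3 relations per ADR (about 120 gold
    relations) and ~6 drugs per ADR, with a strong (0.9) planted
    protein-module signal.
    """

    n_proteins: int = 200
    n_adrs: int = 40
    n_drugs: int = 120
    n_modules: int = 5
    p_intra: float = 0.5      # edge probability within a protein module
    p_inter: float = 0.01     # edge probability between modules
    w_min: float = 0.4        # PPI weights ~ Uniform[w_min, 1]
    relations_per_adr: float = 3.0   # mean of 1 + Poisson(mean - 1)
    drugs_per_adr: float = 6.0       # mean of 1 + Poisson(mean - 1)
    signal: float = 0.9       # P(relation protein drawn from the ADR's module)
    drug_fidelity: float = 0.9  # P(drug drawn from the module's pool)
    topology: str = "planted"   # "planted" | "scale_free"
    seed: int = 0

    def __post_init__(self):
        for name in ("p_intra", "p_inter", "signal", "drug_fidelity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.w_min < 1.0:
            raise ValueError("w_min must lie in [0, 1)")
        for name in ("n_proteins", "n_adrs", "n_drugs", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.relations_per_adr < 1 or self.drugs_per_adr < 1:
            raise ValueError("per-ADR means must be >= 1")
        if self.n_modules > self.n_proteins or self.n_modules > self.n_drugs:
            raise ValueError("more modules than proteins or drugs")
        if self.topology not in ("planted", "scale_free"):
            raise ValueError(f"unknown topology {self.topology!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generated data plus the hidden module assignments."""

    config: SyntheticConfig
    ppi_edges: tuple[tuple[str, str, float], ...]
    drug_adr: tuple[tuple[str, str], ...]
    relations: tuple[tuple[str, str], ...]
    protein_modules: dict = field(compare=False)
    adr_modules: dict = field(compare=False)

    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(sorted({x for e in self.ppi_edges for x in e[:2]}))


def _pid(i: int) -> str:
    return f"P{i:04d}"


def _aid(j: int) -> str:
    return f"ADR{j:03d}"


def _did(k: int) -> str:
    return f"D{k:03d}"


def generate(config: SyntheticConfig, out_dir=None) -> SyntheticTruth:
    """Sample one fixture; optionally write the three TSVs plus a sidecar.

    With ``out_dir`` set, writes ``ppi.tsv``, ``drug_adr.tsv``,
    ``relations.tsv`` and ``truth.json`` (config and module assignments).
    Output is deterministic in ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_proteins, config.n_adrs
    nmod = config.n_modules
    prot_mod = np.array([i * nmod // n for i in range(n)])
    adr_mod = np.array([j % nmod for j in range(m)])
    drug_mod = np.array([k % nmod for k in range(config.n_drugs)])

    # --- PPI layer
    edges: list[tuple[str, str, float]] = []
    if config.topology == "planted":
        iu, ju = np.triu_indices(n, k=1)
        p = np.where(prot_mod[iu] == prot_mod[ju], config.p_intra, config.p_inter)
        keep = rng.random(p.size) < p
        w = rng.uniform(config.w_min, 1.0, size=int(keep.sum()))
        for i, j, wij in zip(iu[keep], ju[keep], w):
            edges.append((_pid(i), _pid(j), round(float(wij), 6)))
    else:
        import networkx as nx

        g = nx.barabasi_albert_graph(n, m=3, seed=int(rng.integers(2**31)))
        for i, j in sorted(g.edges()):
            wij = rng.uniform(config.w_min, 1.0)
            edges.append((_pid(min(i, j)), _pid(max(i, j)), round(float(wij), 6)))

    degree = np.zeros(n, dtype=int)
    pos = {_pid(i): i for i in range(n)}
    for a, b, _ in edges:
        degree[pos[a]] += 1
        degree[pos[b]] += 1

    # --- drug-ADR layer: ADRs of a module sample from the module's drug pool
    pools = [np.flatnonzero(drug_mod == q) for q in range(nmod)]
    all_drugs = np.arange(config.n_drugs)
    drug_pairs: set[tuple[str, str]] = set()
    for j in range(m):
        nd = 1 + rng.poisson(config.drugs_per_adr - 1.0)
        chosen: set[int] = set()
        guard = 0
        while len(chosen) < nd and guard < 50 * nd:
            guard += 1
            pool = pools[adr_mod[j]] if rng.random() < config.drug_fidelity else all_drugs
            chosen.add(int(rng.choice(pool)))
        for k in sorted(chosen):
            drug_pairs.add((_did(k), _aid(j)))

    # --- gold standard: relation proteins cluster in the ADR's module
    eligible = np.flatnonzero(degree > 0)  # every gold protein is networked
    rel_pairs: set[tuple[str, str]] = set()
    for j in range(m):
        nr = 1 + rng.poisson(config.relations_per_adr - 1.0)
        module_prot = eligible[prot_mod[eligible] == adr_mod[j]]
        chosen = set()
        guard = 0
        while len(chosen) < nr and guard < 50 * nr:
            guard += 1
            if module_prot.size and rng.random() < config.signal:
                chosen.add(int(rng.choice(module_prot)))
            else:
                chosen.add(int(rng.choice(eligible)))
        for i in sorted(chosen):
            rel_pairs.add((_pid(i), _aid(j)))

    truth = SyntheticTruth(
        config=config,
        ppi_edges=tuple(sorted(edges)),
        drug_adr=tuple(sorted(drug_pairs)),
        relations=tuple(sorted(rel_pairs)),
        protein_modules={_pid(i): int(prot_mod[i]) for i in range(n)},
        adr_modules={_aid(j): int(adr_mod[j]) for j in range(m)},
    )
    if out_dir is not None:
        _write(truth, Path(out_dir))
    return truth


def _write(truth: SyntheticTruth, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "ppi.tsv", "w") as fh:
        fh.write("protein_a\tprotein_b\tweight\n")
        for a, b, w in truth.ppi_edges:
            fh.write(f"{a}\t{b}\t{w:.6f}\n")
    with open(out_dir / "drug_adr.tsv", "w") as fh:
        fh.write("drug\tadr\n")
        for d, a in truth.drug_adr:
            fh.write(f"{d}\t{a}\n")
    with open(out_dir / "relations.tsv", "w") as fh:
        fh.write("protein\tadr\n")
        for p, a in truth.relations:
            fh.write(f"{p}\t{a}\n")
    sidecar = {
        "config": asdict(truth.config),
        "protein_modules": truth.protein_modules,
        "adr_modules": truth.adr_modules,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")


def network_from_truth(truth: SyntheticTruth) -> HeteroNetwork:
    """Assemble the in-memory :class:`HeteroNetwork` without touching disk."""
    import scipy.sparse as sp

    proteins = truth.proteins
    protein_index = LabelIndex.from_labels(proteins)
    n = len(protein_index)
    rows, cols, vals = [], [], []
    for a, b, w in truth.ppi_edges:
        i, j = protein_index.position(a), protein_index.position(b)
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    table = DrugAdrTable.from_pairs(truth.drug_adr)
    adr_labels = set(table.adrs) | {a for _, a in truth.relations}
    adr_index = LabelIndex.from_labels(adr_labels)
    C = build_adr_similarity(table, adr_index)
    B = load_relations(list(truth.relations), protein_index, adr_index)
    return assemble(A, B, C, protein_index, adr_index)


def summarize(truth: SyntheticTruth) -> dict:
    """Exact counts and simple degree statistics of a generated fixture."""
    proteins = truth.proteins
    if not truth.relations:
        raise ValueError("fixture has no gold relations")
    adrs_rel = {a for _, a in truth.relations}
    adrs_drug = {a for _, a in truth.drug_adr}
    deg: dict[str, int] = {}
    for a, b, _ in truth.ppi_edges:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    degrees = np.array(sorted(deg.values()))
    rel_per_adr = len(truth.relations) / len(adrs_rel)
    drugs_per_adr = len(truth.drug_adr) / len(adrs_drug)
    return {
        "n_proteins": len(proteins),
        "n_ppi_edges": len(truth.ppi_edges),
        "n_adrs": len(adrs_drug | adrs_rel),
        "n_drugs": len({d for d, _ in truth.drug_adr}),
        "n_relations": len(truth.relations),
        "mean_relations_per_adr": rel_per_adr,
        "mean_drugs_per_adr": drugs_per_adr,
        "degree_mean": float(degrees.mean()),
        "degree_p90": float(np.quantile(degrees, 0.9)),
        "degree_max": int(degrees.max()),
    }
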