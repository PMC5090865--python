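# Methods

## The integrated network

Three layers are assembled into one heterogeneous graph with proteins
indexed first and ADRs second:

* **PPI layer** `A` (n × n): undirected, weighted by interaction confidence
  in (0, 1]. Readers accept raw [0, 1] scores or the STRING-style 0–999
  integer scale (`weight_scale="string_0_999"`, divided by 1000); both
  dialects exist in the wild and the choice is explicit rather than
  guessed. Self-loops are dropped (with a warning; the node stays indexed),
  duplicate undirected records collapse to the maximum confidence, and
  zero-weight records are dropped — only positive-confidence pairs are
  edges.
* **ADR similarity layer** `C` (m × m): the Jaccard index of the drug sets
  causing each pair of reactions, linking two ADRs whenever it is positive.
  The diagonal is forced to zero — a node's self-similarity is never an
  edge. An ADR that appears in the gold standard but not in the drug table
  becomes an isolated node with a warning, keeping the ranking universe
  aligned with the gold standard.
* **Bipartite layer** `B` (n × m): binary known protein–ADR relations.
  Relations naming proteins outside the PPI index are dropped with a
  warning by default (only networked proteins can be ranked); a strict
  error policy is available.

`assemble` validates symmetry (symmetrizing by elementwise max with a
warning on violation), zero diagonals, weight ranges and binarity, so every
downstream computation can assume a clean `W = [[A, B], [Bᵀ, C]]`.

## Transition matrix

Intra-layer moves are weighted by edge weight (confidence / Jaccard), not
uniform. For protein row *i* with PPI weight sum `a_i` and bipartite degree
`b_i`, with jumping probability λ:

| row type            | PPI block                  | bipartite block      |
|---------------------|----------------------------|----------------------|
| `a_i>0, b_i>0`      | `(1−λ) · A[i,:]/a_i`       | `λ · B[i,:]/b_i`     |
| `a_i>0, b_i=0`      | `A[i,:]/a_i`               | 0                    |
| `a_i=0, b_i>0`      | 0                          | `B[i,:]/b_i` (λ > 0) |
| isolated            | 0                          | 0                    |

ADR rows are built symmetrically from `C` and `Bᵀ`. Two corner cases are
worth spelling out. A node whose only edges are bipartite gives its full
mass to the other layer when λ > 0 (each row with an outgoing edge must be
stochastic); at λ = 0 the bipartite links are severed entirely and such a
row is left dangling, which makes the λ = 0, η = 0 configuration collapse
*exactly* (to 1e-10 and beyond) onto the PPI-only walk. A node with only
intra-layer edges keeps its normalized intra-layer row at every λ,
including λ = 1; such nodes receive no mass at λ = 1 anyway, because all
incoming intra-layer probability is scaled by 1−λ.

Rows of isolated nodes are all-zero rather than self-looped: the walk
redistributes their mass to the restart distribution (below), which keeps
total probability at 1 without inventing topology.

Row-normalization makes the matrix invariant to a global rescaling of the
weights in a layer; only relative confidences matter.

## Restart walk

`p_{t+1} = (1−r) (Mᵀ p_t + m_t p_0) + r p_0`, where `m_t` is the mass
currently sitting on dangling rows. Iteration stops when the L1 change
drops below `tol` (default 1e-10, reached in ~20 iterations at r = 0.7
since the propagated mass contracts by 1−r per step) or after `max_iter`
(default 1000) with a warning, never an exception. The fixed point
satisfies the closed form `p = r (I − (1−r) M_effᵀ)⁻¹ p_0` with the
dangling redistribution folded into `M_eff`; the test suite checks the
iterate against this dense solve on batches of random networks.

The initial distribution splits as (1−η) uniformly over the seed proteins
and η on the focus ADR. η > 0.5 biases the walker toward the ADR-similarity
layer; the (1−η, η) convention makes η = 0.5 weigh the two layers equally.
When a query has no seed proteins (single-relation ADRs under hold-out) the
entire unit mass goes to the ADR node with a warning — the integrated
network still produces a ranking there, which is precisely its advantage
over the PPI-only walk.

Ranking: candidates are all indexed proteins minus the exclusion set
(defaulting to the ADR's known/seed proteins, so the held-out protein is
always a candidate in cross-validation), sorted by stable probability with
average (mid-) ranks for ties — the Mann–Whitney-consistent convention,
which matters because tied ranks feed the AUC. Identical inputs give
bitwise-identical rankings; there is no randomness in the walk.

## Cross-validation and AUC

One fold per gold relation: the edge is removed from `B` *before* seeding
(asserted), the remaining proteins of the ADR plus the ADR node seed the
walk, and the held-out protein's rank among the candidates is recorded.
Folds a method cannot evaluate (e.g. the PPI-only walk on an ADR left with
no seed) are recorded as skipped, never silently dropped.

Folds from ADRs with different candidate-set sizes are pooled on the
normalized rank `u = (rank − 1)/(n_candidates − 1)` — the fraction of
candidates ranked strictly above the test protein, with ties
half-weighted. The ROC is the exact sweep over all distinct normalized
ranks: sensitivity(θ) is the fraction of held-out relations recovered at
threshold θ, and the false-positive rate is the fraction of candidate
proteins above the threshold, which under this pooling equals θ. The
trapezoidal area of that curve equals `1 − mean(u)`, i.e. exactly the mean
per-fold Mann–Whitney statistic of the test protein against the other
candidates; a perfect ranking yields AUC = 1 and uniform ranks yield 0.5.
(The alternative normalization `rank/n` was rejected because it caps the
AUC of a perfect ranking below 1 and breaks the exact Mann–Whitney
identity.) Candidate sets differ across ADRs only through the excluded
seed count, so the normalization is what makes thresholds comparable; the
pooling is one consistent reading of a sensitivity/specificity sweep over
rank thresholds and is documented as such.

`parameter_sweep` reruns the full LOOCV per value of λ, η or r with the
others at their defaults.

## Baselines

**Hypergeometric enrichment.** A candidate protein with `s` PPI neighbours
of which `k` are among the ADR's `K` known proteins, in a population of `N`
networked proteins, is scored by the exact upper tail P(X ≥ k) of
Hypergeom(N, K, s); candidates are ranked by ascending p-value (ties get
average ranks). This neighbourhood-overlap construction of the contingency
table from the network is this package's concrete reconstruction of a
network-based enrichment baseline — drug-level tables are not retained in
the integrated network, so a drug-based variant is out of scope — and it is
used for ranking only (no multiple-testing correction). The score reported
alongside is −log10 p.

**PPI-only restart walk.** Uniform seed mass over the ADR's remaining known
proteins, walk on row-normalized `A`, same ranking rules. It needs at least
one remaining seed protein, so under leave-one-out only ADRs with ≥ 2 known
proteins are evaluable; `filter_gold_for_rwr` extracts that subset so the
comparison runs on identical folds.

## Synthetic study conditions

The generator emulates the *structure* of the real inputs (a confidence-
weighted interactome, a drug–ADR table inducing Jaccard similarities, and a
sparse gold standard whose proteins cluster in the interactome) without
fitting any real database's marginals. Defaults, chosen once as a
desk-scale analogue of the real data and used by the tests and the
acceptance script:

| parameter | default | rationale |
|---|---|---|
| proteins / ADRs / drugs | 200 / 40 / 120 | ~6× reduction of the real gold-standard scale, LOOCV in seconds |
| modules | 5 | planted-partition topology; co-localized targets are the method's core assumption |
| p(edge) intra / inter | 0.5 / 0.01 | strong but not clique-like modules, sparse background |
| PPI weight | Uniform[0.4, 1] | medium-to-high confidence scores |
| relations per ADR | 1 + Poisson(2), mean 3 | matches the few-proteins-per-ADR regime of curated data |
| drugs per ADR | 1 + Poisson(5), mean 6 | small drug sets, so Jaccard similarities are informative |
| signal | 0.9 | P(gold protein drawn from the ADR's module); 0 gives a label-free null |
| drug fidelity | 0.9 | P(drug drawn from the module's shared pool); drives within-module similarity |

Each ADR belongs to a module; its drugs come mostly from that module's
shared drug pool (so within-module ADR pairs have high Jaccard similarity)
and its gold proteins come mostly from the module's proteins. Gold proteins
are drawn only from networked (degree ≥ 1) proteins so fixtures reload
through the standard loaders without warnings. A preferential-attachment
(`topology="scale_free"`) PPI layer is available to echo the heavy-tailed
degree distributions of real interactomes; modules are then labels only and
the planted-partition topology remains the primary fixture.

What passing on this fixture shows: the pipeline recovers a modular
protein–ADR signal well above chance (LOOCV AUC ≳ 0.85 at the defaults),
collapses to chance when labels are permuted, and orders the methods as the
real-data analysis does (integrated walk ≥ enrichment ≥ nothing). What it
does **not** show: performance on real interactomes (hub structure,
ascertainment bias, weight calibration), on identifier-mapping noise, or at
the real data's scale — the generator makes no attempt to match SIDER or
STRING marginals.

## Numerical choices and degenerate inputs

* Convergence: L1 tolerance 1e-10, max 1000 iterations; both exposed.
* Ties: average ranks everywhere (walk scores and p-values alike).
* Deterministic candidate ordering: by rank, then identifier.
* An ADR with no known proteins: enrichment ranking degenerates to a
  uniform tie with a warning; the walk runs seeded on the ADR node alone.
* An isolated seed protein keeps its restart mass (dangling redistribution
  returns it to `p_0`); the walk still conserves probability to 1e-9.
* Exhaustive-enumeration and dense-linear-algebra oracles back the
  hypergeometric tail and the walk, respectively, in the test suite; the
  AUC is cross-checked against scipy's Mann–Whitney U and scikit-learn's
  pooled `roc_auc_score` on equal-sized folds.

## Problem sizes

The test suite and the acceptance script run entirely on the desk-scale
fixture above (full LOOCV ≈ 130 folds in well under a second per method)
plus batches of ≤ 60-node random networks for the oracle checks; the whole
suite completes in well under a minute.

## Known limitations

* One ADR per query; batch prediction loops single queries.
* The enrichment baseline is a reconstruction (see above), not a validated
  replica of any published drug-level Fisher construction.
* The exact ROC pooling across ADRs of different candidate-set sizes is one
  consistent convention; per-ADR micro-averaging would weight folds
  differently.
* No identifier mapping, no database clients, no ontology-based ADR
  similarity — inputs must already share an identifier universe.
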