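# inpadr

Prioritization of proteins behind adverse drug reactions (ADRs) by a random
walk with restart on an integrated heterogeneous network.

Adverse drug reactions often arise from drugs hitting off-target proteins,
and experimentally screening thousands of candidate targets per reaction is
infeasible. `inpadr` ranks candidate proteins for a given ADR by propagating
probability over a network that joins three layers:

* a weighted protein–protein interaction (PPI) network `A` (confidence
  scores as edge weights),
* an ADR–ADR similarity network `C`, where the similarity of two reactions
  is the Jaccard index of the drug sets that cause them,
  `J(i,j) = |D_i ∩ D_j| / |D_i ∪ D_j|`,
* the known protein–ADR relations `B` (a binary bipartite layer), which
  stitch the two together into the block adjacency `W = [[A, B], [Bᵀ, C]]`.

The package is aimed at computational biologists who want to reproduce or
extend this style of network-propagation analysis, and ships the predictor,
its leave-one-out evaluation, two baseline methods, and a synthetic data
generator so the whole pipeline runs without any external databases.

## The model

A row-stochastic transition matrix `M = [[M_PP, M_PA], [M_AP, M_AA]]` is
built from `W`: at a protein with both PPI neighbours and ADR links the
walker jumps to a linked ADR with probability λ and stays in the PPI layer
with 1−λ (destinations weighted by edge weight); nodes with only one edge
type move within it. A query for ADR *i* seeds the walk with

* mass η on the ADR node *i*, and
* mass 1−η spread uniformly over the proteins already known for *i*,

and iterates the restart walk

```
p_{t+1} = (1 − r) Mᵀ p_t + r p_0
```

to its stable probability `p_∞`; candidate proteins (all proteins without a
known relation to the ADR) are ranked by their stable probability. Defaults
are r = 0.7, λ = 0.5, η = 0.5, with a top-k cutoff of k = 50 for prediction
lists. Because the seed can be the ADR node alone, the method still ranks
candidates for single-relation ADRs, where a PPI-only walk has no seed left
after hold-out.

Evaluation is leave-one-out cross-validation: each known relation is
removed, re-predicted, and the held-out protein's rank among the candidates
is pooled into an exact ROC curve whose area equals the Mann–Whitney
statistic of the test proteins against the other candidates. Baselines:
a hypergeometric enrichment test (over-representation of the ADR's proteins
in a candidate's PPI neighbourhood) and the restart walk on the PPI layer
alone.

## Worked example

Generate a synthetic fixture (200 proteins in 5 modules, 40 ADRs, 120
drugs, ~130 gold relations with a 0.9 planted module signal), evaluate, and
query one ADR:

```
$ inpadr simulate --seed 0 -o demo
n_proteins      200
n_ppi_edges     2110
n_adrs  40
n_relations     132
...

$ inpadr loocv --ppi demo/ppi.tsv --relations demo/relations.tsv \
               --drug-adr demo/drug_adr.tsv --method inpadr -o demo/cv_inpadr
inpadr: AUC = 0.8848 over 132 folds (0 skipped/failed)

$ inpadr loocv --ppi demo/ppi.tsv --relations demo/relations.tsv \
               --drug-adr demo/drug_adr.tsv --method hyper -o demo/cv_hyper
hyper: AUC = 0.7880 over 132 folds (0 skipped/failed)

$ inpadr rank --ppi demo/ppi.tsv --relations demo/relations.tsv \
              --drug-adr demo/drug_adr.tsv --adr ADR000 --k 5 -o demo/adr000.tsv
wrote top 5 of 198 candidates to demo/adr000.tsv
$ cat demo/adr000.tsv
rank    protein score
1       P0036   0.005806532
2       P0032   0.0050680932
3       P0004   0.0049306885
4       P0012   0.0041690683
5       P0014   0.0034292283
```

The LOOCV AUC of 0.88 means a held-out causal protein outranks a random
candidate 88% of the time; the integrated walk clearly beats the enrichment
baseline (0.79) on the same folds, and label-permuted relations drop the
AUC to chance (≈0.5). The same operations are available as library calls
(`inpadr.loocv`, `inpadr.rank_adr`, …); see `docs/methods.md` for the full
model description and design choices.

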