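# mdmf

Prediction of miRNA–disease associations by **weighted matrix factorization
with a disease-similarity constraint**.

Experimentally confirmed miRNA–disease associations are sparse: a zero in
the association matrix usually means *untested*, not *unrelated*. `mdmf`
treats the problem as implicit-feedback link prediction. It learns latent
vectors `m_i` (miRNA) and `d_j` (disease) by minimizing

```
L = 1/2 [ Σ_ij w_ij (r_ij − d_jᵀ m_i)²
          + α Σ_{j<k} (S_jk − cos(d_j, d_k))²
          + λ₁‖M‖_F² + λ₂‖D‖_F² ]
```

where

* `r_ij ∈ {0,1}` is the known association matrix,
* `w_ij` is a per-entry confidence weight — 1 on known associations,
  min–max-normalized miRNA expression on unobserved entries (high expression
  under a disease condition ⇒ more confidence in the implicit zero),
* `S` is an integrated disease-similarity matrix: Wang-style semantic
  similarity over the disease DAG (e.g. MeSH tree numbers) where both
  diseases are covered, Gaussian interaction-profile (GIP) kernel similarity
  on association profiles otherwise,
* the `α` term constrains the *geometry* of the disease latent space: the
  cosine between disease latent vectors is pulled toward the integrated
  similarity.

Association scores are the inner products `m_i · d_j`. Evaluation follows
global and local leave-one-out cross-validation (LOOCV): each known pair is
removed, the model retrained, and the pair ranked against all unknown pairs
(global) or the unknown pairs of its disease (local), yielding AUC, AUPR,
F1, ACC and MCC. A seeded synthetic-data module (planted low-rank
associations, expression-derived weights, random layered DAGs) makes the
whole pipeline testable without any database download; the real input
formats (association pair lists, expression tables, MeSH-style tree-number
files) are supported as plain TSV.

Audience: computational biologists prioritizing candidate disease miRNAs,
and method developers who need a transparent, fully deterministic
similarity-regularized factorization baseline.

## Worked example

Generate a synthetic dataset (100 miRNAs × 40 diseases, planted rank 5, 5 %
association density), cross-validate, and rank candidates for one disease:

```sh
mdmf synth --seed 7 --outdir data
mdmf loocv --associations data/associations.tsv --expression data/expression.tsv \
    --dag data/dag_edges.tsv --k 5 --epochs 300 --seed 7 \
    --protocol global --max-folds 30 --outdir cv
```

```
global LOOCV over 30 folds: AUC=0.8257 AUPR=0.0430 F1=0.0645 ACC=0.9984 MCC=0.1824
```

AUC 0.83 means a held-out true association outranks a random unknown pair
83 % of the time (0.5 would be chance). AUPR is low in absolute terms
because each fold ranks one positive against ~600 candidate pairs — the
class imbalance the precision-recall view is meant to expose. `cv/folds.tsv`
lists the rank of every held-out pair among its candidates:

```
miRNA	disease	rank	candidates	score
miR-0093	D0032	401	616	0.002283827555
miR-0016	D0033	55	616	0.3890059337
```

Candidate prioritization for a disease (known associations are excluded;
ties break by miRNA id):

```sh
mdmf rank --associations data/associations.tsv --expression data/expression.tsv \
    --dag data/dag_edges.tsv --k 5 --epochs 300 --seed 7 --disease D0006 --top 5
```

```
1	miR-0049	0.487696
2	miR-0030	0.456355
3	miR-0058	0.214671
4	miR-0013	0.20314
5	miR-0069	0.180562
```

The same operations are available as library functions
(`mdmf.train`, `mdmf.global_loocv`, `mdmf.rank_candidates`, …); see
`docs/methods.md` for the model details and design choices.

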