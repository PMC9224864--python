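# Methods

## Model

`mdmf` factorizes the binary miRNA–disease association matrix
`R ∈ {0,1}^{p×q}` into latent matrices `M ∈ R^{k×p}` and `D ∈ R^{k×q}`
under the objective

```
L(M, D) = 1/2 [ Σ_ij w_ij (r_ij − d_jᵀ m_i)²
               + α Σ_{j<k} (S_jk − cos(d_j, d_k))²
               + λ₁‖M‖_F² + λ₂‖D‖_F² ]
```

Three modelling assumptions:

1. **Implicit feedback.** Unobserved entries are trained toward 0, but with
   confidence weight `w_ij < 1` derived from miRNA expression, so an
   unexplored but plausibly related pair contributes little loss when the
   model scores it high. Observed entries carry full weight 1.
2. **Similarity-consistent disease geometry.** The cosine between disease
   latent vectors is pulled toward an integrated disease-similarity matrix
   `S`. This injects DAG-derived knowledge about diseases into the latent
   space and regularizes diseases with few associations.
3. **Linearity.** Scores are inner products `m_i · d_j`; the model captures
   only linear interactions in the shared latent space.

The constraint appears squared in the objective. Its gradient in `d_j`
sums over all partners `k ≠ j` — each unordered pair of the `j<k` sum
contributes to both members — with

```
∂cos(d_j, d_k)/∂d_j = d_k/(‖d_j‖‖d_k‖) − cos(d_j, d_k) · d_j/‖d_j‖².
```

Both analytic gradients are validated against central finite differences
of the implemented objective in the test suite, which pins the
objective/gradient pair to a single consistent form.

## Disease similarity

**Semantic (Wang) similarity.** For disease `D` with ancestor closure
`T(D)`, contributions decay along the hierarchy:
`DD_D(D) = 1`, and for a strict ancestor `d`,
`DD_D(d) = max{Δ · DD_D(d′)}` over children `d′` of `d` inside `T(D)`.
Equivalently `DD_D(t) = max over paths t→…→D of Δ^len(path)`, which is the
independent brute-force oracle the tests enumerate with `networkx`
simple-path search. Then `DV(D) = Σ_t DD_D(t)` and

```
SS(i, j) = Σ_{t ∈ T(i)∩T(j)} (DD_i(t) + DD_j(t)) / (DV(i) + DV(j)).
```

Δ is the semantic contribution factor, default **0.5** (the standard
choice for this measure), configurable in `(0, 1]`.

**GIP kernel.** `GS(i, j) = exp(−r ‖IP(d_i) − IP(d_j)‖²)` on binary
association profiles, with bandwidth `r = r′ / mean_i ‖IP(d_i)‖²` and
`r′ = 1` by default.

**Integration.** `S_jk = SS(j,k)` when the pair has semantic similarity,
else `GS(j,k)`. "Has semantic similarity" defaults to *both diseases
present in the DAG* — a disease absent from the hierarchy has no defined
SS at all; a `coverage="positive"` switch additionally requires `SS > 0`,
sending shared-ancestor-free pairs to the GIP fallback. Similarities are
clamped to `[0, 1]` after computation to absorb rounding.

## Optimization

Full-batch gradient descent, both matrices updated simultaneously each
epoch: `m_i ← m_i − η ∂L/∂m_i`, `d_j ← d_j − η ∂L/∂d_j`. Full-batch (not
stochastic) keeps runs bit-deterministic for a fixed seed, which the
evaluation protocol relies on. Initialization is i.i.d. uniform on
`(0, init_scale]` — strictly positive, so no disease column starts at zero
and every cosine is defined. During training a column norm below `1e-12`
is guarded by adding `1e-12` to the denominator (with a warning) rather
than aborting; outside training, a zero column is an error. Training stops
at `max_epochs` or when the relative objective decrease falls below `tol`;
a non-finite objective aborts with advice to lower `η`. Monotone descent
is guaranteed only for sufficiently small `η`; the default step can
overshoot on the first epochs of some instances, which is why the CLI
records the per-epoch objective log.

Defaults: `k = 40`, `α = 0.7` (the constraint weight at which performance
peaks before the similarity term starts to dominate), `λ₁ = λ₂ = 0.01`,
`η = 0.01`, `max_epochs = 500`, `tol = 1e-6`, `init_scale = 0.1`. Only α
has a principled externally-motivated value; the rest are conventional
magnitudes for problems of a few hundred by a few dozen entities and are
all configurable.

## Data handling

* Association pair lists collapse duplicates; ids are deduplicated and
  sorted lexicographically, so index order is deterministic across runs.
  Id matching is case-sensitive and exact — synonym curation against a
  vocabulary is out of scope.
* Expression is min–max normalized **globally** over the whole table (a
  single normalization step), not per disease. Both a per-miRNA dialect
  (value broadcast across diseases) and a per-(miRNA, condition) dialect
  are accepted. miRNAs missing from the table raise an error unless a
  default unobserved-entry weight (typically 0: no confidence) is
  configured, in which case a warning is logged.
* All-identical expression values make min–max normalization undefined and
  raise (`degenerate normalization`).
* Disease DAG input: parent→child edge list, or MeSH-style tree-number
  pairs where each tree-number prefix links to its one-level extension.
  Cycles are rejected with the offending cycle listed.

## Evaluation protocol

Each known pair is held out: its entry set to 0, its loss weight reverted
to the unobserved weight (the `WeightMatrix` retains the pre-override
expression weights for exactly this purpose), and the model retrained from
the same seeded initialization — folds are independent and reproducible,
never warm-started. Candidates are the zero entries of the fold's
training matrix, across all diseases (global) or within the held-out
disease's column (local); a local fold with no candidate negatives is
skipped with a warning. Ranks use midrank tie handling.

Held-out scores and candidate scores pool across folds into one ranking
universe. AUC is the Mann–Whitney statistic (ties ½). AUPR is step-wise
average precision. No classification threshold is prescribed a priori:
all distinct pooled scores are swept and F1/ACC/MCC are reported at the
F1-maximizing threshold, recorded as `threshold_used`. MCC returns 0 by
convention when a confusion-table margin is zero. For large datasets
`max_folds` subsamples folds reproducibly.

## Synthetic data

The generator emulates the statistical structure the model assumes:

* nonnegative uniform true factors (`k = 5` by default), matching the
  nonnegative-factor framing of the method;
* `y` marks the top `⌈density·p·q⌉` entries of `true_Mᵀtrue_D` plus
  Gaussian score noise — deterministic top-entry thresholding keeps planted
  counts exact, so count-based tests are tight;
* `S` is the exact cosine matrix of the true disease factors — the ideal
  case for the constraint;
* expression is `signal·(scaled truth) + (1−signal)·uniform` with
  `signal = 0.7`, giving weights informatively correlated with the truth;
* a random layered DAG (3 layers, ≤ 2 parents per node) accompanies each
  dataset for exercising the DAG input path.

The study conditions for the end-to-end experiments are `p = 100`,
`q = 40`, `k = 5`, `density = 0.05`, `noise = 0.1`, evaluated on 50
sampled LOOCV folds (20 per run for the five-seed ablation), with the
training dimension matched to the planted rank and a 300-epoch budget —
ample for this problem size. Under these conditions sampled-fold global
LOOCV reaches AUC ≈ 0.9–0.97 depending on seed, the shuffled-label control
stays near 0.5, and the constraint (α = 0.7 vs α = 0) adds a strictly
positive mean-AUC gain when `S` carries the true geometry.

What the generator does **not** emulate: real MeSH topology, expression
measurement units and batch structure, the long-tailed degree
distributions of curated association databases, and disease-name
curation noise. Passing the synthetic benchmarks therefore demonstrates
correctness of the machinery and the qualitative value of the similarity
constraint, not performance on any curated database.

## Numerical choices and edge cases

* Cosine guard `1e-12`; similarity clamping to `[0, 1]`; symmetric
  matrices are symmetrized (`(A + Aᵀ)/2`) before validation.
* Candidate ranking breaks score ties by miRNA id ascending.
* Gradient checks use central differences with step `1e-6` and relative
  tolerance `1e-5`; semantic-similarity oracle agreement is required to
  `1e-12`.
* The association container accepts only `{0,1}`; the training loss itself
  is defined for arbitrary real targets (used in planted-recovery tests).

## Known limitations

* LOOCV retrains per fold: O(#folds) full trainings. Fold subsampling is
  the intended mitigation at scale.
* Full-batch descent with a fixed step has no convergence guarantee for
  aggressive `η`; there is no line search or adaptive optimizer by design
  (determinism and transparency are prioritized).
* The constraint sum is dense in disease pairs, O(q²k) per epoch, fine for
  hundreds of diseases but a bottleneck beyond that.
* Only linear interactions are representable; nonlinear extensions are out
  of scope.
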