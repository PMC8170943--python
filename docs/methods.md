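# Methods

`repogru` predicts unobserved drug–disease associations from three inputs: a
drug–drug chemical similarity matrix `S_D` (m×m), a disease–disease
phenotype similarity matrix `S_d` (n×n) and a binary interaction matrix `I`
(m×n) whose 1-entries are the known associations. The working hypothesis is
the standard repositioning premise: similar drugs treat similar diseases,
and entities with similar interaction profiles behave similarly towards new
partners. This note records the model, the defaults and the design choices
made where the design was genuinely open.

## Feature construction

**Logistic similarity adjustment.** Raw chemical similarity is remapped
elementwise by `L(x) = 1/(1+e^(a·x+b))` with `a = −15`, `b = ln 9999`
(configurable). With a negative slope the map is strictly increasing, so
ranking is preserved, while the non-discriminative low/mid range collapses:
`L(0) = 10⁻⁴` exactly and `L(1) ≈ 0.997`. These defaults are the
calibration used by the similarity-adjustment lineage in the repositioning
literature; the library exposes both parameters.

**Cohesiveness clustering and boosting.** Drugs are clustered by greedy
cohesiveness maximisation on a weighted graph: a vertex set `M` scores
`f(M) = C_in/(C_in + C_bound + P(M))` with internal weight `C_in`, boundary
weight `C_bound` and penalty `P(M) = penalty_per_node·|M|` (default 2.0,
which damps spuriously cohesive small sets). Growth starts from the
highest-degree uncovered vertex, accepts the single best add/remove step
only on a strict score increase, filters by minimum size (3) and internal
weighted density (0.25), and merges cluster pairs whose overlap
`ω = |A∩B|²/(|A||B|)` reaches 0.8. The procedure is deterministic (ties
break on the lowest vertex index); exact parity with the reference
implementation of this clustering scheme is not a goal.

Which graph to cluster was an open choice: the clustering is meant to be
driven by the known associations, not by chemistry alone. The pipeline
clusters the **shared-disease cosine graph** — cosine similarity between
drug interaction profiles, the standard shared-partner similarity of a
bipartite network — computed from the training interactions. (The
distance-based GIP kernel was considered and rejected for this role: on
block-structured data its within/between contrast is weak, ~0.48 vs ~0.39,
whereas profile cosine separates at ~0.25 vs ~0.03, so cohesiveness
boundaries actually exist.) Co-clustered drug pairs then have their raw
chemical similarity restored (elementwise max with the adjusted value).
The boost never lowers an entry below the adjusted value and never exceeds
the elementwise max of raw and adjusted; it can be disabled
(`use_cluster_boost=False`).

**GIP kernels.** For diseases with interaction profiles `y_i` (columns of
`I`), `K(i,j) = exp(−α‖y_i − y_j‖²)` with `α = α′ / ((1/n)Σ‖y_i‖²)` and
`α′ = 0.5`. Normalising by the mean squared profile norm makes the
bandwidth adapt to interaction density. The same construction is available
on the drug axis (`use_drug_gip`, off by default: the drug side is
represented by similarity, the disease side by GIP).

**Representations and fusion.** Disease rows are the convex blend
`w·K_GIP + (1−w)·S_d` with `w = 0.5` by default — the two disease
information sources are averaged since no principled weighting is known a
priori. Drug rows are the boosted similarity rows. A pair `(i,j)` is the
concatenation of drug row i and disease row j.

**Truncated SVD.** The assembled pair-feature matrix is reduced to
`tsvd_dim = 64` columns via a deterministic LAPACK SVD with an explicit
sign convention (largest-magnitude component of each right singular vector
made positive), so results are bit-reproducible. Reducing the assembled
pairs (rather than each representation separately) is the default; the
other order is available (`tsvd_stage="representations"`). In
cross-validation the basis is fitted on training rows only and test rows
are projected onto it.

## Classifier

A single-layer gated recurrent unit (GRU) followed by a dense sigmoid head:

    z_t = σ(W_z i_t + U_z h_{t−1} + b_z)
    r_t = σ(W_r i_t + U_r h_{t−1} + b_r)
    c_t = tanh(W_h i_t + U_h (r_t ⊙ h_{t−1}) + b_h)
    h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ c_t
    p   = σ(w·h_T + b)

implemented in NumPy with full backpropagation through time and the Adam
optimizer. Biases enter with `+b`; a formulation with `−b` is the same
model up to the sign of the bias vector. The flat per-pair feature vector
is presented as `timesteps` equal chunks; the default is a single step over
the whole vector, which is the natural reading when per-pair features have
no intrinsic sequence order (chunking into T > 1 steps is supported).

Defaults: 128 hidden units; dropout 0.25 applied (inverted) to the final
hidden state before the dense head; binary cross-entropy loss (standard
form, probabilities clipped at 1e−7); Adam at learning rate 1e−3; 50
epochs; batch size 64. Initialisation is Glorot-uniform for input matrices,
orthogonal for recurrent matrices, zeros for biases. Training is bitwise
reproducible for a given seed: fixed initialisation, fixed shuffling, fixed
dropout masks.

## Evaluation protocol

Known pairs are positives; an equal number (`negative_ratio = 1`) of
uniformly drawn zero cells are presumed negatives. Negative sampling
happens once per run; positives and negatives are shuffled together into 10
near-equal folds (sizes differ by ≤1, disjoint, covering all samples).

**Leakage control.** The GIP kernels and the cluster boosting are functions
of `I`, so computing them from the full matrix would leak held-out labels
into the features. Per fold, the test-fold positive cells are zeroed out of
the interaction matrix before any feature is computed, and the SVD basis
and classifier are refitted on the training fold. The naive variant
(features from the full `I`) is available via `refit_per_fold=False` /
`--no-fold-refit` for comparison only.

Threshold metrics (Acc, TPR, TNR, PPV, MCC) are computed at probability
0.5 (configurable); a zero denominator yields 0 with an explicit degenerate
flag rather than an exception. AUC is the Mann–Whitney statistic; the
report carries the mean and the population standard deviation over the 10
folds (a pooled-scores AUC is available via `pooled_auc=True`). Ranking
mode scores every candidate on the opposite axis of a query entity, sorts
descending with ties broken by candidate id, and flags — without removing —
known interactions, so confirmed indications can be read off the top ranks.

## Synthetic data: what it emulates and what it does not

The generator plants `k` matched drug/disease blocks: near-uniform block
assignment; `I[i,j] ~ Bernoulli(p_in)` when blocks match, else
`Bernoulli(p_out)`; similarities `sim_in`/`sim_out` plus symmetric Gaussian
noise, clipped to [0,1]. Defaults — m=200, n=150, k=5, p_in=0.3,
p_out=0.02, sim_in=0.8, sim_out=0.2, sim_noise=0.05 — are the study
conditions used across the tests and the acceptance script: the scale keeps
a full tenfold cross-validation within minutes on one CPU, the interaction
rates give ≈2300 positives (density ≈0.078, comparable to a few percent to
one order denser than real deposits), and the similarity means straddle the
logistic map's discrimination band (`L(0.8) ≈ 0.94`, `L(0.2) ≈ 0.002`).

This instantiates exactly the assumption the method exploits, which is the
point: recovery (cross-validated AUC well above chance) demonstrates that
the pipeline uses the similarity/profile signal, and the label-permutation
null (`permute_labels`, which shuffles the entries of `I` uniformly while
preserving their count) verifies it finds nothing when there is nothing.
What the synthetic data does **not** emulate: real marginal degree
distributions (hub drugs, rare diseases), block overlap, similarity
measurement error correlated with interaction noise, or annotation biases
in curated databases. Passing on planted blocks is therefore evidence of
correctness of the machinery, not a performance claim on any real
benchmark.

## Numerical and interface choices

- Similarity matrices are validated symmetric to 1e−10 with unit diagonal;
  out-of-[0,1] entries are clipped with a logged warning (real deposits
  contain rounding artifacts), then symmetrised exactly.
- The GIP bandwidth is undefined on an all-zero interaction matrix; this is
  an error, not a silent default.
- Degenerate metric denominators return 0 with a flag (see above); the
  top-N count clamps N to the candidate count with a warning.
- One global seed fans out to per-stage seeds via SHA-256 of
  `"{seed}:{stage}"` reduced mod 2³¹, so any stage is independently
  re-runnable.
- The optional SMILES path computes Tanimoto similarity over hashed Morgan
  (circular, radius 2, 2048-bit) fingerprints; it approximates, and does
  not reproduce bit-for-bit, similarities computed with other fingerprint
  toolkits. Precomputed similarity matrices remain the primary input.

## Known limitations

- The GRU sees each pair as a length-1 sequence by default; the recurrence
  then acts as a gated dense layer. This follows the flat-feature
  formulation; chunked timesteps are available but untuned.
- Negative "samples" are unlabelled cells, not verified non-interactions;
  reported TNR/PPV inherit this standard caveat of the field.
- The clustering is a faithful but independent implementation of the greedy
  cohesiveness scheme; cluster-level agreement with the reference Java tool
  is not guaranteed.
- Hyperparameters are fixed defaults; no search is performed.
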