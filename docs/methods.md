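# Methods

## Problem setting

Given a set of drugs D = {d_1, …, d_n}, a symmetric binary matrix R holds
the interactions known at time t (r_ij = r_ji ∈ {0, 1}, zero diagonal), and
each drug carries a fixed text embedding L_i ∈ ℝ^e derived from biomedical
literature. The task is retrospective link prediction: rank all unordered
drug pairs absent from R by their probability of appearing in a later
release R′. An absent edge is treated as *unknown* (implicit feedback), not
as a verified negative; training negatives are sampled from the non-edge
pool, a fresh uniform draw without replacement each epoch, at a
negatives-per-positive ratio of 1 by default.

All pairs are canonicalized as (i, j) with i < j, and drug catalogs are
ordered lexicographically, so matrix indices and samples are reproducible.

## AMFP component

Factorizes R with one latent vector per drug, U_i ∈ ℝ^k, shared between the
row and column roles. Before scoring, factors are blended once with their
training neighborhood mean:

    U′_i = (1 − α) U_i + α · mean_{j ∈ N(i)} U_j,

with N(i) the training partners of i and isolated drugs left unchanged;
α = 0 recovers plain adjacency matrix factorization (AMF), bitwise (the
propagation step is genuinely skipped, not multiplied by zero). The pair
score is

    r̂_ij = σ( wᵀ (U′_i ⊙ U′_j) + b_i + b_j + b_0 ),

a weighted element-wise product plus per-drug and global biases, symmetric
in (i, j) by construction (the two per-drug biases are summed before the
other terms so symmetry holds to the last bit). Propagation sits inside
every forward pass, so gradients flow through the blending operator
(implemented as a sparse matrix P with U′ = PU, backpropagated as PᵀG);
the alternative of propagating once after convergence would make the
propagation invisible to the optimizer. The neighborhood *mean* (rather
than sum) keeps U′_i in the coordinate-wise convex hull of the drug and its
neighbors, so the update is bounded and the α = 0 limit is exact.

Training: Adam on binary cross-entropy over per-epoch resampled batches;
Glorot-normal initialization for U and w, zero biases.

## Bio-text component

A feed-forward network over the frozen pre-trained vectors. Input features
per pair, by variant:

| variant | a^(0) | width |
|---|---|---|
| concat | [L_i, L_j] | 2e |
| multiply | [L_i ⊙ L_j, 1] | e + 1 |
| concat, feature combination | [L_i, L_j, E_i ⊙ E_j] | 2e + k |
| multiply, feature combination | [L_i ⊙ L_j, E_i ⊙ E_j] | e + k |

E is a per-drug ID embedding trained jointly inside the same network
(gradients reach it through the element-wise product); the text vectors
stay frozen. Hidden layers are ReLU with inverted dropout (training only),
the output unit is a sigmoid, and the loss is standard binary cross-entropy
−[y log p + (1 − y) log(1 − p)] with predictions clipped at 1e−7.

The concat features are order-dependent; since a DDI is undirected, the
per-pair score at inference is the average of both orderings. Multiply
variants are exactly symmetric.

Drugs resolve to embedding rows through an explicit ID→token mapping
(concept mode) or by their own identifier (word mode); unresolved drugs
default to the column-wise mean of resolved rows — a neutral prior that
keeps every drug scoreable — with `zero` and `error` policies available.

## Stacking and switching

The two components are trained separately; a 2-input MLP (one hidden layer
of 8 ReLU units, sigmoid output) is then fit on their probabilities for the
validation pairs. Two deliberate choices here:

* **Validation scores, not training scores.** Component scores on their own
  training pairs are optimistic; stacking on them would teach the combiner
  to over-trust the more overfit component.
* **Balanced stacker batches.** The stacker trains on all validation
  positives plus an equal-size uniform draw of validation negatives — the
  same one-negative-per-positive protocol the components train under. This
  keeps all three branch outputs on one prior scale, which matters because
  the switching rule splices raw scores from two branches into a single
  ranking: with mismatched priors (e.g. a stacker fit at the natural ~2%
  positive rate against components fit at 50%), the spliced ranking
  degrades and the tuned threshold collapses to M = 0 regardless of any
  cold-start structure.

The switching threshold M is chosen by scanning 0–10 and maximizing
validation AUPR, ties resolving to the smallest M (broader use of the
better-calibrated stacking branch). Switching counts I_i are taken from the
sub-training matrix the components were actually fitted on, so routing
reflects exactly the interactions the factorization saw. The text branch of
the assembled model returns the bio-text probability verbatim (bit-equal),
so the hybrid restricted to cold pairs *is* the text model.

## Evaluation protocol

Evaluation pairs are all unordered pairs not positive in the training
matrix, labelled by presence in the later release. Metrics: AUROC (the
tie-corrected Mann–Whitney statistic), AUPR by the step-wise
average-precision sum Σ (R_k − R_{k−1}) P_k (trapezoidal PR interpolation
is optimistically biased, so it is not used), and precision@K / recall@K
with a deterministic tie-break (score descending, index ascending). AUROC
and AUPR are computed via scikit-learn, whose estimators are exactly these
definitions; the test suite cross-checks them against a brute-force
pairwise-counting oracle and a hand-walked ranked-threshold sum.

The rare (cold-start) stratum pools pairs with min(I_i, I_j) < 3; the
threshold matches the tuned M region and the requirement is on the *rarer*
drug of the pair, since one uninformative latent vector already degrades a
factorization score. Reports include pooled per-stratum metrics, per-drug
averaged top-K metrics over rare drugs, and the cumulative distribution of
drugs and of test positives by training-count bin — both pooled and
per-drug views are emitted because they answer different questions (overall
ranking quality vs. the experience of a typical new drug).

## Synthetic studies

The generator emulates the ingredients of a release-to-release study with a
planted-partition (stochastic block model) design: drugs are assigned
uniformly to `n_clusters` communities; an edge is Bernoulli(p_within)
inside a community, Bernoulli(p_between) across; embeddings are scaled
orthogonal community centroids plus isotropic Gaussian noise. Community
co-membership therefore drives interactions and embeddings simultaneously —
the premise that literature-derived vectors carry interaction signal. A
uniform `holdout_frac` of drawn edges becomes the future release, and a
`cold_frac` of drugs is forced cold, each keeping a training-edge budget
drawn uniformly from {0, …, cold_max_links}: the cold population mixes
genuinely new drugs (no known interactions at time t) with barely-known
ones, as in a real release gap.

Defaults: n = 300 drugs, 6 clusters, e = 100 (the dimension of the
pre-trained tables the package consumes), p_within = 0.25,
p_between = 0.01, embedding noise σ = 0.3 (nearest-centroid recovery of
community labels ≈ 95%, so the text channel carries signal without being
trivial), holdout 0.5, cold fraction 0.15, cold budget ≤ 2 (inside the
rare stratum). At these settings a study has roughly 2,000 interactions,
a ~2% positive rate on evaluation pairs, and trains in seconds on one CPU —
the problem size used throughout the tests and the acceptance script.

What the generator does **not** emulate: degree heterogeneity beyond the
cold mechanism (real DDI matrices are heavy-tailed), interaction mechanisms
shared across communities, embedding anisotropy of real language models,
and partial embedding coverage (real concept mapping resolves ~70% of
drugs; the resolver and its fallbacks are tested separately). Passing the
synthetic study therefore shows the pipeline recovers plantable structure
and that the cold-start switching logic behaves as designed — not that the
published real-data accuracy would be reproduced.

## Default hyperparameters

Selected once by grid search on validation AUPR (20% of training pairs,
existing and non-existing alike, removed from the fit) over the stated
search ranges, at the default study conditions, then frozen:

| parameter | default | notes |
|---|---|---|
| AMFP factors k | 16 | grid 8–64; larger k memorizes the sparse matrix |
| propagation α | 0.5 | grid 0.1–0.5 |
| bio-text hidden widths | (128, 64) | |
| dropout | 0.5 | main defense against pair memorization |
| learning rate | 0.01 | Adam, both components |
| epochs | 40 (AMFP) / 50 (text) | |
| negative ratio | 1 | one negative per positive, all models |
| batch size | 256 | |
| stacker | (8,), lr 0.01, 300 epochs | |
| M candidates | 0–10 | validation AUPR, ties → smallest |

## Numerical notes

* Same-seed runs are bit-identical end to end; all child seeds derive from
  one `SeedSequence`, and per-epoch negative draws are seeded by
  (seed, epoch).
* Sigmoid outputs are clipped only inside the loss; predictions are exact
  sigmoids in (0, 1).
* Pair scores are bitwise-symmetric: element-wise products are commutative
  per IEEE-754, and bias pairs are summed before other terms to avoid
  associativity drift.
* Degenerate inputs: empty negative pools, single-class metric calls,
  K beyond the scored-pair count, self-pairs, and unresolved drugs under
  the `error` policy all raise with explicit messages; an empty rare
  stratum is reported as absent rather than raising.

## Known limitations

* The concat variant under-exploits multiplicative structure (a plain MLP
  learns products of concatenated halves slowly); on the synthetic geometry
  the multiply variant converges closer to the informed ceiling, while the
  published real-data ordering favors concat. Both are provided.
* Splicing raw probabilities from two branches into one ranking (the
  switching rule) can cost pooled AUROC relative to the best single branch
  even when each branch is better on its own stratum; the balanced-stacker
  protocol mitigates but does not remove this.
* Validation-tuned M is noisy when validation pairs involving cold drugs
  are scarce — by construction cold drugs contribute few positives.
* Training materializes the full non-edge pool per epoch; fine to a few
  thousand drugs, beyond that a rejection sampler would be needed.
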