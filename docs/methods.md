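# Methods

## Overview

`coevotriplet` predicts residue–residue contact and distance maps for a
protein from a multiple sequence alignment (MSA), by (1) extracting three
*raw* coevolutionary feature tensors, (2) feeding them to a four-branch
residual convolutional network that outputs a per-pair probability
distribution over 12 distance bins, and (3) deriving the contact map from
the distance distribution. A Potts-model simulator with planted contact
maps provides ground truth at desk scale, so the whole pipeline is
trainable and testable on one CPU without external databases or
pretrained weights.

## Alignment statistics

Sequences are encoded over 21 states (20 amino acids, gap; ambiguous
residues collapse onto the gap state). Sequence redundancy is handled by
the standard identity-threshold weighting: sequence *n* receives weight

    w_n = 1 / (1 + #{m != n : S_mn >= 0.8})

where S_mn is the fraction of identical positions over the full alignment
length (a gap aligned to a gap counts as identical; the alternative
non-gap-denominator convention is available behind a switch). The
effective depth is

    Neff = (1/L) * sum_n w_n .

Neff is exactly invariant under duplicating a sequence whenever the
80%-identity relation is cluster-structured (the usual case); when the
relation is non-transitive the invariance is only approximate, which is
inherent to this weighting scheme. The staged-search predicate
`needs_deeper_search` returns true iff Neff < 128, the trigger used by
hierarchical MSA pipelines; the searches themselves are out of scope.

Weighted single-site frequencies f_i(a) and pair frequencies f_ij(a,b)
are computed with arbitrary nonnegative weights. By default the
covariance feature uses uniform weights (the literal frequency
definition); the pipeline passes identity-threshold weights to all three
features, the standard practice in direct coupling analysis.

## The feature triplet

* **COV** — the covariance tensor `S_ij(a,b) = f_ij(a,b) − f_i(a) f_j(b)`,
  an L×L grid of 21×21 blocks. It captures marginal, including
  transitive, dependence.
* **PRE** — the ridge-regularized precision matrix: the minimizer of

      G(Θ) = tr(SΘ) − log|Θ| + ρ Σ_ij ||Θ_ij||²,   ρ = e⁻⁶.

  Because the ridge term is a full Frobenius penalty, the minimizer is
  computed *in closed form*: diagonalize S = U diag(s) Uᵀ and set
  Θ = U diag(θ) Uᵀ with θ_k the positive root of 2ρθ² + s_k θ − 1 = 0.
  This is the exact stationary point (S − Θ⁻¹ + 2ρΘ = 0 per eigenvalue),
  is always symmetric positive definite, and costs one eigendecomposition
  of the 21L×21L matrix. Before inversion the covariance is optionally
  shrunk toward mean(diag(S))·I with weight γ = 0.1 (default): finite-MSA
  covariances are rank-deficient and shrinkage stabilizes the small
  eigenvalues; γ = 0 reproduces the bare objective. Θ itself is fed to
  the network; a sign flag exposes the negative-inverse-covariance
  convention.
* **PLM** — the couplings of a 21-state Potts model fitted by weighted
  pseudolikelihood maximization. Each site's conditional

      P(σ_l = a | σ_{\l}) ∝ exp( h_l(a) + Σ_{k≠l} J_lk(a, σ_k) )

  is a multinomial regression on the rest of the sequence; we minimize
  the weighted sum of negative log conditionals plus L2 penalties
  (λ_h = 0.01, λ_J = 0.2·(L−1), the common pseudolikelihood-DCA
  convention) with L-BFGS from a zero start. The parametrization is
  *asymmetric* (site l owns row J_l·); the coupling tensor is symmetrized
  J ← (J_ij + J_jiᵀ)/2 afterwards, and the raw symmetrized J is the
  network feature. Weights are internally rescaled to sum to N so the
  fit depends only on relative weights. Self-coupling blocks are
  projected out of value and gradient, so they remain exactly zero.

Each feature is reshaped to an L×L×441 tensor with channel 21a+b holding
block entry (a,b). For the classical unsupervised baseline, pair scores
are the Frobenius norms of the 20×20 (gap-excluded) blocks followed by
the average product correction (APC), with all row/column means taken
over off-diagonal entries. The sign of the potentials plays no role in
the score.

Numerical notes: the PLM objective is smooth and convex in the asymmetric
parametrization; the iteration cap (default 500) with projected-gradient
tolerance 1e-4 is reported through `PottsModel.converged`, and partial
fits are returned with a warning. For the simulation corpora used in the
tests the cap is lowered (40–150 iterations) because coupling *rankings*
stabilize long before full convergence; the caps used are stated with
each experiment below.

## Synthetic families

The simulator emulates what the real pipeline never observes directly: a
known structure and a known coupling topology.

* **Toy chains.** One interaction site per residue; consecutive sites
  3.8 units apart; excluded volume 3.6 units; step directions combine a
  persistence term (stiffness 1.5) and a radial confinement bias
  (compactness 0.3, confinement radius 3.8·L^⅓). These values were
  calibrated once so that an L = 50 chain has an 8-unit contacting-pair
  fraction of roughly 0.1 (well inside the 0.02–0.25 band of globular
  backbones). Chains of L ≥ 30 are regrown until at least one long-range
  contact (|i−j| ≥ 24) exists, so the evaluation ranges are always
  populated. Distances are in chain units and read as Å.
* **Planted Potts models.** Every contacting pair (distance < 8, i ≠ j)
  receives a coupling block rewarding a random one-to-one pairing of the
  21 states: B[a, π(a)] = c for a seeded permutation π and coupling
  strength c (default 1.5), giving every planted block the analytic norm
  c·√21. Non-contact blocks are exactly zero. Fields are i.i.d. Gaussian
  (scale 0.3) with the gap state offset by −1 so alignments are mostly
  gap-free.
* **Gibbs sampling.** Sequences are drawn by single-site Gibbs sweeps
  whose kernel is exactly the Potts conditional above — the same
  conditional PLM later fits. By default each of the N sequences is an
  independent chain initialized from the fields-only distribution and
  swept 200 times (all burn-in), matching the exchangeable-sequence
  assumption of pseudolikelihood fitting; a thinned single-chain mode
  exists behind a flag. Sampling exploits coupling sparsity (only contact
  partners enter a site's conditional), so a 2000-sequence family at
  L = 30 costs a few seconds.

What the simulator does *not* emulate: phylogenetic correlation between
sequences, alignment errors and gap patterns of real homolog searches,
realistic protein energetics, and the composition bias of real families.
Passing tests therefore demonstrate the correctness of the machinery and
the qualitative feature ordering, not benchmark-level precision on real
proteins.

Reference study conditions used by the recovery experiments:
L = 30, N = 2000, coupling strength 1.5. Under these conditions the
APC-corrected PLM scores recover ≥ 70% (typically 100%) of planted
contacts at separation ≥ 6, and the recovery ordering is
PLM ≥ PRE ≥ COV.

## Distance discretization and losses

Distances are binned into 12 intervals: below 5 Å, ten 1-Å bins from 5
to 15 Å, and beyond 15 Å (half-open on the right). The first four bins
cover exactly d < 8 Å, so bin membership and the CASP contact definition
(Cβ–Cβ < 8.0 Å, Cα for glycine) coincide by construction.

The training loss is the summed negative log-likelihood of the true bin
over residue pairs (diagonal excluded, unresolved residues masked). The
two-state alternative — cross-entropy of the summed first-four-bin mass
against the binary contact label — is provided for the
distance-versus-binary ablation. The predicted contact probability is
always the first-four-bin mass.

## Network

Per feature branch: a 1×1 convolution reduces 441 channels to the hidden
width, then instance normalization, ReLU, and a stack of residual basic
blocks (two 3×3 convolutions with instance norm and ReLU, identity skip,
post-addition activation; dropout 0.2 between the convolutions during
training). Branch outputs are concatenated and fused by the same
construction, then projected to 12 channels and passed through a per-pair
softmax. Because distance maps are symmetric, the softmax outputs for
(i,j) and (j,i) are averaged. The full-scale configuration (64 channels,
24 blocks per stack) is constructible via `NetConfig.paper_scale()`; the
desk-scale default is 16 channels and 2 blocks per stack (~60k
parameters), which trains in seconds per epoch on one CPU.

Training uses Adam, batch = one protein, random square crops (default
128) for proteins longer than the crop, and global gradient-norm
clipping at 5 (the two-state loss produces near-singular gradients when
predicted probabilities saturate). The desk-scale default learning rate
is 3e-3: the small profile underfits at the 1e-3 rate appropriate for
the deep full-scale stack within any reasonable desk epoch budget.
Everything is seeded; two runs with the same seed and data produce
bit-identical parameters.

The layer stack itself (conv via im2col, instance norm, dropout, Adam)
is implemented in numpy with hand-derived backward passes; every layer's
gradient is finite-difference-checked in the test suite.

## Evaluation

Contacts are ranked per separation range — medium 12 ≤ |i−j| ≤ 23, long
|i−j| ≥ 24 — by descending probability (ties broken lexicographically,
each unordered pair counted once, asymmetric inputs symmetrized by
averaging). Top-L/k precision uses depth floor(L/k), minimum 1; when
fewer eligible pairs exist the denominator is the number evaluated.
Native contacts are strictly below 8.0 Å; residues without coordinates
are excluded from numerator and denominator. PDB input takes the Cβ
atom, Cα for glycine, and falls back to Cα (with a warning) when a
non-glycine residue lacks Cβ.

## Desk-scale experiment sizes

The end-to-end training experiments use a corpus of 75 simulated
families (60 train, 15 held out) at L = 36 and N = 300, with corpus
features extracted at a 30-iteration PLM cap, and desk-profile networks
trained for 20 epochs. L = 36 was chosen so the long-range band holds 78
pairs and the top-L/k depths remain meaningful; 300 sequences per family
keep feature extraction fast while leaving clear coevolutionary signal
(the unsupervised PLM+APC baseline reaches ~0.7 long-range top-L/5
precision on held-out families). The random-ranking null expectation for
long-range precision equals the long-range contact density of the
held-out families (~0.11 under these conditions).

## Known limitations

* Exchangeable Gibbs chains ignore phylogeny, so sequence reweighting is
  nearly inactive on simulated data (all weights ≈ 1).
* The closed-form precision estimator relies on the penalty being a full
  Frobenius ridge; a graphical-lasso-style L1 penalty would require an
  iterative solver.
* The desk-scale network is far below the full-scale capacity; its
  held-out precision sits between the random null and the unsupervised
  DCA baseline rather than above it, and ablation gaps (ensemble vs
  single feature, distance vs binary loss) are correspondingly small at
  this scale. In particular, at L = 36 the long-range top-L list covers
  36 of only 78 eligible pairs with ~9 true contacts among them, so
  top-L precision has a ceiling near 0.24 and the distance-vs-binary
  loss comparison lands within noise of that ceiling: the advantage of
  distance supervision reported at full scale does not separate from
  noise under these conditions, and the corresponding end-to-end test
  documents this as a failing expectation rather than hiding it.
* Single-domain evaluation only; no domain splitting, no Z-score-style
  cross-predictor ranking.
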