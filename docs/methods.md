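# Methods

## Model

`repolink` treats drug repositioning as supervised link prediction on a
bipartite drug–disease graph. Known associations are positives; an equal
number of negatives is drawn uniformly without replacement from the
unobserved cells (unobserved ≠ false, so the negative set is noisy by
construction — a standard compromise in this literature). Each pair is
described by similarity features of its endpoints and classified; the
classifier's score orders candidate pairs.

### Interaction-profile kernels

For entity sets with binary association profiles `Y(i)` the Gaussian
interaction profile kernel is `K[x,y] = exp(−∂‖Y(x)−Y(y)‖²)` with
`∂ = ∂′ / ((1/n) Σᵢ ‖Y(i)‖²)`. Normalizing by the mean squared profile norm
makes the bandwidth adapt to network density: the same `∂′` is usable on
sparse and dense matrices. `∂′ = 0.5` on the drug side follows the
reference formulation; the disease side mirrors it for symmetry (both
configurable). Entities with all-zero profiles participate in the bandwidth
mean and get well-defined kernel rows; only an entirely associationless
matrix raises a degenerate-bandwidth error. The kernel is computed via the
Gram expansion `‖a−b‖² = ‖a‖² + ‖b‖² − 2a·b`, exact for 0/1 profiles;
symmetry and the unit diagonal are enforced to the last bit.

### Sharing network, cohesive clusters, semantic boost

Two diseases are connected with weight = number of drugs associated with
both (`W = AᵀA` off-diagonal). Clusters are grown greedily from the
highest-weighted-degree unprocessed seed: at each step the single vertex
addition or removal that most increases the cohesiveness
`f(K) = C_in/(C_in + C_bound + p·|K|)` is applied, strict improvements
only, lowest vertex index breaking ties, so every returned cluster is a
single-move local optimum. The per-vertex penalty `p` (default 2)
discourages accidental two-vertex "clusters" on sparse graphs. Growth may
eject its own seed; such seeds are marked processed so the scan always
terminates. Clusters whose overlap score `|Kᵢ∩Kⱼ|²/(|Kᵢ||Kⱼ|)` exceeds the
merge threshold (default 0.8) are merged and rescored. Degree-zero vertices
become f = 0 singletons.

For disease pairs co-resident in at least one cluster the semantic
similarity is boosted by the best co-resident cluster:
`DS = (1 + f(K*)) · DS_r`; any off-diagonal value ≥ 1 becomes 0.99. Values
already in (0.99, 1) are left untouched — the cap replaces only values that
reach 1, it is not a ceiling. The boost is applied on the disease side
only; the clustering machinery is generic and reusable should drug-side
boosting be wanted.

### Autoencoder

A plain single-hidden-layer autoencoder with logistic activations
compresses fingerprint bits to a dense code. Training is full-batch
gradient descent on the mean squared reconstruction error; weights start
Glorot-uniform from a seeded stream, biases at zero. Defaults — hidden
width 64, 200 epochs, learning rate 0.1 — train the standard benchmark in
well under a second and reach a monotone (10-epoch smoothed) loss curve;
they are deliberately the smallest standard choice, not a tuned one. The
loss gradients are hand-derived backpropagation, verified against central
finite differences in the tests. Divergence (non-finite loss) aborts with a
pointer at the learning rate.

### Fusion and refinement

The disease descriptor is the GIP kernel row with a semantic fallback: a
pair uses its kernel entry where a profile-kernel similarity *exists* and
`DS` otherwise. Existence, not mere nonzeroness, is the operative notion: a
float Gaussian is never exactly zero, so the fallback is triggered by
diseases with empty association profiles (for which the kernel row is a
bandwidth artifact, not a similarity). This matters in leave-disease-out
ranking, where the target disease's column is zeroed and its only
informative features are semantic. The drug descriptor is the drug-kernel
row concatenated with the autoencoded fingerprint code; a pair feature is
the concatenation of both descriptors.

The optional refinement stage (default on) standardizes each feature with
training-fold mean and population variance (ε = 1e-8; constant features map
to zero), applies one fully-connected ReLU layer (width 128), and trains it
through a logistic head on the binary cross-entropy of the training labels
(50 epochs, learning rate 0.05, seeded full-batch gradient descent). The
classifier consumes the ReLU activations; the head is kept only so the
training objective is auditable. Statistics and weights are fit on training
folds exclusively.

### Classification and evaluation

The random forest (100 trees, √d candidate features per split, unlimited
depth, seeded) scores a pair by the fraction of trees voting positive, so
thresholding at 0.5 reproduces the ensemble's majority vote exactly; the
comparator is an RBF-SVM (C = 1, scale gamma) with Platt-scaled scores.
Folds are stratified — positives and negatives are each dealt round-robin
after shuffling, with the remainders offset so total fold sizes differ by
at most one. Metrics use the standard confusion definitions; a
zero-denominator metric is reported as NaN rather than 0. AUC is the
Mann–Whitney statistic with half-credit for ties.

Two kernel-computation modes exist. `full_matrix` (default) computes the
GIP kernels once from the complete association matrix, which matches the
reference protocol but lets held-out positives influence the features.
`train_only` zeroes each fold's held-out positives before computing kernels
(and the sharing network) for that fold. The default is kept for fidelity;
any null or negative-control experiment should use `train_only`, because in
`full_matrix` mode even structure-free data yields AUC ≈ 0.63: positives
oversample high-degree drugs and diseases, degree is visible in the
bandwidth-normalized kernels, and held-out positives additionally leak in.
With the leakage channel removed the same data scores ≈ 0.46, and a
label-permutation null (which breaks the label–matrix correspondence
itself) sits at ≈ 0.5 in either mode.

The autoencoder is trained once per experiment on the full fingerprint
matrix rather than per fold: its inputs are per-drug bit vectors that carry
no pair labels, so fold-wise retraining would add cost without removing any
leakage path.

## Synthetic benchmark

The generator plants module structure: drugs and diseases are assigned
uniformly to `n_modules` modules; associations are Bernoulli(p_in) within a
module and Bernoulli(p_out) across; each module has a random prototype
fingerprint copied with per-bit flip noise; semantic similarity is
`ds_in`/`ds_out` plus Gaussian jitter, clipped to [0, 1], symmetrized, unit
diagonal. The standard benchmark uses 100 drugs × 60 diseases, 5 modules,
p_in = 0.35, p_out = 0.02, 64 bits with 5 % flip noise, ds_in = 0.6,
ds_out = 0.1, jitter 0.05, at a fixed generator seed (expected positives
516). These sizes keep a full 10-fold run of the whole pipeline under ten
seconds on one core while leaving all stages statistically exercised; they
were chosen once as a realistic sparse-network miniature, not fitted to any
outcome.

What the benchmark does *not* emulate: the long-tailed degree
distributions, block-overlapping disease etiologies and fingerprint
correlation structure of real pharmacological data, or label noise in the
semantic matrix. Passing tests therefore demonstrate that the
implementation recovers plantable structure and honors its contracts — not
that the method attains any particular AUC on real datasets, which is
additionally sensitive to hyperparameters the original description leaves
open (autoencoder width and schedule, refinement design, forest size).

## Numerical and design choices

- One master seed; every stochastic stage derives an independent child
  stream from a stable hash of its name, so stages can be reordered without
  perturbing each other and runs are bit-reproducible.
- Greedy growth accepts only improvements > 1e-12 to be robust to float
  noise; with integer edge weights all cohesiveness updates are exact.
- Negative sampling happens once per experiment, before fold assignment.
- Score ≥ threshold predicts positive (boundary counts as positive).
- Ties in rankings break by drug ID for a total, reproducible order.
- Known limitation: with `full_matrix` kernels the cross-validated AUC is
  optimistic (see above); with `train_only` it is conservative, since
  masking also distorts the test pairs' own features. The truth for a
  prospective prediction lies between, closer to the leave-disease-out
  protocol, which removes the target's associations before any stage runs.
- On this benchmark the RBF-SVM comparator edges out the random forest by
  ~0.02 AUC; the forest's advantage reported on the real datasets appears
  tied to their feature geometry and is not reproduced by this smooth,
  low-dimensional synthetic one.
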