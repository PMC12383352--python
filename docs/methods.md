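# Methods

`connstage` asks whether the topology of structural brain connectomes
orders subjects along a low-dimensional axis of cognitive decline, and
provides every stage of that analysis — encoder, manifold, cohort
statistics, controls, ablations and regional divergence maps — as
seeded, reproducible code.  Because the clinical cohorts this kind of
study uses cannot be redistributed, the package ships a synthetic
cohort generator that plants a known progression signal; all shipped
evaluations run on it.

## Graph model and input encoding

A connectome is a weighted, undirected, loop-free graph: `N` cortical
parcels, symmetric nonnegative weights `A[i,j]`, zero diagonal.  The
encoder deliberately consumes *binarized* topology: an edge is present
iff its weight exceeds a threshold (default 0, i.e. the presence of any
reconstructed fibers).  Node features are one-hot parcel indices
(`X = I_N`), so all information reaching the model is which parcel
pairs are connected.  This makes the learned representation a function
of network topology alone, not of streamline-count magnitudes, which
vary strongly with acquisition details.

## Encoder

The baseline encoder is a three-stage composition:

1. **GIN layer** — node update `φ((1+ε)·x_v + Σ_{u∈N(v)} x_u)`, sum
   aggregation with a `(1+ε)` self-weight.  `φ` is a two-layer
   perceptron (width 128) whose output is batch-normalized and
   rectified, the conventional GIN stack ordering.  `ε` is fixed at 0
   and not trained; it is exposed for experimentation.
2. **GAT layer** — single-head attention, 64-dimensional output.
   `z_u = W x_u`; the logit for the pair (u, v) is
   `LeakyReLU₀.₂(a·(z_u ‖ z_v))`, softmax-normalized over the closed
   neighborhood `N(v) ∪ {v}`, and the update is the α-weighted sum of
   `z_u` over that set.  The self-loop is included in both the softmax
   set and the aggregation; non-neighbors get exactly zero attention.
   The output is batch-normalized and passed to the readout with no
   further nonlinearity.
3. **Attention readout** — `x_G = Σ_v softmax_v(φ_gate(x_v)) ⊙ x_v`
   with `φ_gate` a single affine map to a scalar; a learned convex
   weighting of nodes rather than a fixed pooling.

Ablation variants swap one stage at a time: sum pooling for the
readout, a symmetric-normalized GCN (`D̃^{-1/2}(A+I)D̃^{-1/2} X W`,
batch-normalized, rectified) for the GIN, or drop the GIN/GAT stage
entirely.  Embedding dimension D is 64 whenever a GAT is last, 128 for
the GIN-only variant.

**Why the batch normalization matters.**  Training couples the encoder
to a small MLP head (hidden 32, softmax over 2 classes) and minimizes
cross-entropy with full-batch Adam (learning rate and weight decay
0.001, 100 epochs).  With 88 or fewer graphs this regime memorizes any
two-class labeling, and without per-feature normalization that has a
degenerate side effect: the gradient inflates embedding variance along
the single logit-relevant direction while weight decay erases every
other direction, so the embedding spectrum collapses to rank ≈ 1 for
*any* task — including random graphs with arbitrary labels.  That
collapse would make the dimensionality comparison between real-like
and random inputs (the package's central control) meaningless.
Normalizing each graph layer's output keeps every feature at unit
scale, so the spectrum reflects directional structure in the data:
cohorts with a genuine 1-D progression signal compress into ~2
components, random graphs do not.  Normalization statistics are taken
from the training batch (which is the full training set under
full-batch training) and reused at inference, so held-out projections
are deterministic.

All layers, backpropagation and the Adam optimizer are implemented in
NumPy (float64) inside `_nn.py`; gradients are verified against finite
differences in the test suite, and initialization is uniform fan-in
scaling drawn in fixed order from a seeded generator, so a seed fully
determines a trained model.

## Manifold

After training, the head is discarded and the encoder embeds each
graph; PCA (sample covariance, 1/(n−1)) fit on the two-extreme-group
embeddings defines a fixed 2-D manifold.  Held-out subjects are
projected without refitting.  Sign conventions make outputs
reproducible: PC1 is oriented so the most advanced group's mean
coordinate is positive, later components so their largest-magnitude
loading is positive.  Intrinsic dimensionality is the smallest k whose
cumulative explained-variance ratio reaches a threshold (default 0.99,
configurable; the threshold is interpreted as `ratio ≥ 0.99`, not a
rounded value).

## Cohort statistics

Univariate Gaussians (sample mean/SD) fit to each diagnostic group's
PC1 define μ±σ *manifold cohorts*; interval membership is reported
as-is, so a subject may belong to several cohorts or none.  Staging of
the held-out group is maximum-density Naive Bayes on PC1 with equal
priors (the held-out group's size should not bias its staging) and
density ties broken toward the earlier stage.  Manifold separability is
tested by permutation: the statistic is the in-sample macro
one-vs-rest ROC-AUC of an L2-regularized multinomial logistic model fit
on the 2-D coordinates (an in-package L-BFGS fit, light enough to be
refit thousands of times); the null refits the identical procedure on
label-shuffled data, and the plus-one estimator
`p = (1 + #{null ≥ obs})/(1 + B)` never returns zero.  Under random
labels the p-value is uniform; the test suite checks this over 200
replicates.

## Divergence mapping

The subjects inside the earliest-stage manifold interval form the
normative reference.  Per edge, the reference cohort's sample mean and
SD (floored at 1e-6 × the global mean positive weight, so
zero-variance edges cannot dominate) define a Gaussian; a comparison
subject's edge is scored by the two-sided tail probability
`p_e = 2(1 − Φ(|w_e − μ_e|/σ_e))`, clipped below at 1e-12.  Regional
evidence accumulates Fisher-style, `S_r = −Σ_{e∋r} ln p_e` over all
incident edges (unfiltered; each edge counts toward both endpoints).
Raw weighted connectomes, not binarized ones, are compared here.
Alternatives (significance-filtered or degree-normalized accumulation)
were considered and left out to keep the score monotone in every
edge's deviation; the monotonicity, nonnegativity and scale-invariance
properties are asserted in the tests.

## Synthetic cohort generator

The generator emulates the structure the analysis depends on and
nothing more.  One population skeleton (Erdős–Rényi at density 0.30
over 148 nodes) with log-normal edge weights (meanlog 0, sdlog 0.5,
heavy-tailed like streamline counts) is shared by all subjects.  The
first 12 node indices form a *vulnerable set* — an echo of the
parietal/precuneus hubs implicated early in dementia, without any claim
of anatomical fidelity.  Each subject draws a progression score
`t ~ N(group mean, 0.15)` clipped to [0,1] (group means 0.0/0.5/1.0
for G0/G1/G2; per-subject draws make the middle group straddle the
axis, emulating its clinical heterogeneity).  Edges touching the
vulnerable set are attenuated by `1 − 0.6·t`; all edges receive
multiplicative noise (CV 0.2); weights below a dropout cutoff are
zeroed.

The cutoff is 0.30 × the base-weight median.  This value is what makes
the planted effect *topological*: under the log-normal weight model it
yields vulnerable-edge dropout rates of roughly 1%, 5% and 30% for the
three stages, while non-vulnerable edges drop at a stage-independent
~1.5%.  A much smaller cutoff would leave the binarized topology
essentially identical across stages (the attenuation alone almost
never pushes a log-normal weight near zero), and a binary-input
encoder could then not see the progression at all.

What the generator does **not** emulate: realistic regional degree
profiles, hemispheric symmetry, community structure, distance-dependent
connectivity, scanner/site effects, or streamline-count magnitudes.
Passing tests therefore demonstrate that the pipeline recovers a
planted low-dimensional progression from binarized topology under
realistic noise — not that it would achieve any particular performance
on clinical data.

## Evaluation protocol and problem sizes

Classification quality is measured by pooled leave-one-out
cross-validation: per run, every sample is held out once, the model is
retrained from scratch on the remainder, and one ROC-AUC pools all
held-out positive-class probabilities (per-fold AUC is undefined with
a single test sample).  Runs differ only by seed (base+0 … base+r−1)
and results are reported mean ± SD across runs.

Problem sizes used by the shipped tests: single-model analyses
(manifold compactness, random-network control, held-out intermediacy,
divergence recovery) run at the full default scale, 148 nodes and
24/46/18 subjects.  Cross-validation protocols (task ordering,
ablation) retrain the encoder hundreds of times, so they run on a
scaled profile — 50 nodes, 8/12/6 subjects per group — with every
other generator setting (density, vulnerable-region count, attenuation,
noise, progression means) unchanged; 3 runs for the task ordering, 2
for the ablation.

## Numerical choices

- float64 throughout; symmetry tolerance 1e-8 on input, exact
  symmetrization after validation.
- Masked softmax subtracts the per-group maximum; every softmax group
  contains at least the self-loop, so it is always well defined.  An
  edgeless graph is processed through self-loops alone.
- Adam: β = (0.9, 0.999), eps 1e-8, L2-coupled weight decay added to
  the raw gradient; BatchNorm eps 1e-5.
- Gaussian fits reject groups with fewer than two values or zero
  variance; PCA requires n ≥ 2 and k ≤ min(n−1, D); eigenvalue ties
  are broken by the decomposition's stable ordering.
- Written adjacency files use `%.17g`, so an I/O round trip is exact
  to < 1e-12.

## Limitations

The encoder's supervision is a two-group task, so the manifold axis is
defined by the extremes and everything about the intermediate group is
read off a projection it never influenced — by design, but it means
the intermediacy result is only as meaningful as the extremes model.
The permutation test evaluates in-sample separability (train =
evaluate), which is valid as a permutation test but is not a
generalization estimate.  LOOCV retrains the full encoder per fold and
dominates runtime; the scaled profile trades statistical resolution
for tractability.  Divergence scores accumulate unfiltered log
tail-probabilities, so mild diffuse deviations and a single extreme
deviation can produce similar scores; no multiple-testing correction
is applied.
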