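# Methods

## Model and quantities

For `R` simultaneously recorded channels `X^(1)..X^(R)` (continuous
voltages or binary binned spike trains on a uniform grid), the pairwise
**directed information** from channel `j` to channel `k` with memory `M` is

    DI(j -> k) = I( X^(j)_{i-M..i-1} ; X^(k)_i | X^(k)_{i-M..i-1} ),

the mutual information between the source's recent past and the target's
present, conditioned on the target's own past.  **Graphical directed
information** (GDI) additionally conditions on the pasts of other
channels, so that an edge expresses conditional (direct) dependence and
influence routed through intermediate nodes is suppressed:

    GDI(j -> k) = I( X^(j)_past ; X^(k)_i | X^(k)_past, X^(r)_past for r in Z ),

with `Z` either all remaining channels or, for sample-starved spike data,
only those with appreciable incoming normalized DI to the target.
Both quantities are conditional MIs and are computed as a difference of
two plain MI terms sharing the same source-past block, `I(A; B, Z) -
I(A; Z)`.  All information values are in nats.

Edges are signed by the **time-lagged partial correlation** (TLPC): the
Pearson correlation between `x^(j)_i` and `x^(k)_{i-tau}` after both are
residualized on the conditioning channels at lag 0, maximized in absolute
value over negative lags; the coefficient's sign at the peak labels the
edge excitatory (+1) or inhibitory (-1).  With no conditioning this is
the plain time-lagged correlation (TLC).  The residual-regression
implementation is canonical; a one-variable-at-a-time recursion is kept
as a numerical cross-check (agreement ~1e-8).

## MI estimation

Each MI term is estimated by the Donsker–Varadhan (likelihood-ratio)
route.  Non-overlapping windows of length `M+1` provide samples of a
joint distribution p; permuting the rows of the source-past block yields
an independence surrogate q with identical marginals.  A probabilistic
binary classifier separating p from q yields the pointwise ratio
`L(x) = P(l=1|x)/(1-P(l=1|x))`, and

    KL(p||q)  ~=  mean_p log L  -  log mean_q L

evaluated on held-out rows estimates the MI.  Per bootstrap iteration the
rows are split 2/3 train / 1/3 test with a fresh permutation; the
estimate is the mean over iterations.

The classifier is a 2x64 ReLU multilayer perceptron over standardized
inputs with three stabilizing components, each of which measurably
matters at the sample sizes used here:

* **Gaussian discriminant feature.**  The closed-form log-ratio
  `log N(x; S) - log N(x_A; S_A) - log N(x_B; S_B)` computed from
  ridge-regularized training covariances enters the logit with a
  learnable scale.  For jointly Gaussian data this is the exact answer up
  to calibration, and the network only learns the non-Gaussian residual.
  The A block is augmented with its element-wise squares so that
  quadratic source-to-target interactions (as in the squared-interaction
  benchmark) are visible to this linear term.  Ridge default 1e-2 x
  (mean eigenvalue); smaller values destabilize channels with tiny noise
  floors, larger ones bias strong edges.
* **Platt recalibration.**  The logit is rescaled by a two-parameter
  logistic fit on the early-stopping slice (Newton with backtracking and
  smoothed targets, so separable slices cannot diverge).  A calibrated
  classifier makes the plug-in consistent; an over- or under-trained one
  otherwise inflates or deflates the KL estimate.
* **Pooled q-side evaluation.**  The `log mean_q L` term is evaluated
  over 8 independent permutations of the held-out rows, cutting the
  variance of the heavy-tailed mean.

Probabilities are clipped to `[1e-3, 1-1e-3]` (logit cap ~6.9 nats —
far above any value arising in these analyses; with much looser clipping
single outliers dominate the q-side mean).  Training is minibatch Adam
(batch 256, lr 2e-3), at most 60 epochs, early-stopped on a held-out 15%
slice with patience 6.  Everything is float32 numpy and fully seeded.

The two MI terms of a conditional MI share their bootstrap splits,
permutations, and initialization streams, so the sizeable common bias of
the two large MI values cancels in the difference; off-edges come out at
|GDI| < ~0.02 nats even when both terms exceed 1 nat.  For a full graph
under all-others conditioning the reduced term `I(A_j; other pasts)`
does not depend on the target and is estimated once per source channel.

## Normalization and spike analyses

For binary data, raw values are divided by the plug-in conditional
entropy of the target, `H(Y_i | Y_{i-M..i-1})` (empirical frequencies
over sliding windows).  This is the target's own new information per
sample and bounds DI from above, giving a 0..1 scale; values below the
threshold 0.01 are set to zero.  In the thresholded conditioning policy
an edge `j -> k` conditions only on channels `r` with normalized
DI(r -> k) >= 0.01, keeping dimensionality low when samples are scarce.
Among the possible "target information" denominators, the conditional
entropy of the target is the natural choice: it is the exact upper bound
of DI for a binary target.  Continuous
analyses report nats and are never normalized.

Spike analyses may sweep several bin widths (e.g. 15-40 ms in 5 ms
steps with M = 3, covering 45-120 ms of history); magnitudes are
averaged across widths and the final sign is the sign of the mean of the
per-width signs over widths with non-zero estimates, ties reported as
undetermined.  Averaging acts on normalized values, consistent with the
per-width thresholding.

## Synthetic benchmarks

* **Gaussian pair** `(X_{i-1}, Y_i) ~ N(0, [[1, rho], [rho, 1]])` with
  DI = -1/2 ln(1-rho^2); **binary symmetric channel** `Y_i = X_{i-1}`
  flipped with probability p, X ~ Bernoulli(0.3), with the exact DI from
  enumeration.  Both are laid out so that M=1 windows recover the pairs.
* **11-node linear-Gaussian network**
  `x^(k)_i = sum_j beta_jk x^(j)_{i-1} + alpha_k z^(k)_i`, with
  per-target `sum_j |beta_jk| + alpha_k = 1`.  Topology: extended path
  6→1→4→11, sink {6,8,9}→2, multipath 6→{3,5}→10, node 7 isolated;
  edges 6→1 and 5→10 inhibitory.  Closed forms: for any true edge
  GDI = 1/2 ln(1 + beta^2 sigma_j^2 / alpha_k^2) with sigma_j^2 = 1 for
  source nodes and alpha_j^2 otherwise; pairwise DI into multi-input
  nodes adds the other couplings to the noise term.  Shipped weights:
  |beta| = 0.65 on the extended path, 0.45 on fan-out/multipath, 0.25 on
  sink edges.  The stronger path coupling is deliberate: with uniform
  0.45 weights the third-hop edge of the squared-interaction variant has
  a true GDI of ~0.016 nats (squaring values below 1 twice attenuates
  brutally), which no estimator can separate from zero at realistic
  sample sizes; 0.65 lifts it to ~0.03 nats while keeping the linear
  dynamics comfortably stationary.  0.8 was evaluated and rejected — the
  near-deterministic chain makes the conditioning covariance
  ill-conditioned and degrades the Gaussian-network estimates.
* **Nonlinear variant**: same topology/weights with
  `x^(k)_i = sum_j beta_jk (x^(j)_{i-1})^2 + alpha_k z^(k)_i`, sources
  and the isolated node Uniform(0,1), target noise variance 0.25.
* **Three-node masking demos**: W excites Y, X inhibits Y, both delayed
  0.125 s, with X co-active with W so that plain correlation calls X
  excitatory.  Continuous: 1 Hz sinusoids at 400 Hz sampling, X carrying
  a narrow dip on each peak, `Y(t) = W(t-0.125) - X(t-0.125)`, 1% drive
  noise.  Spikes: 25 ms bins, synchronous periodic bursts, X dropping
  out every fourth cycle, Y spiking via a logistic drive.  Without the
  dip/dropout the inhibition would be unidentifiable in principle.
* **Spiking surrogate**: discrete-time logistic-Bernoulli dynamics —
  spike probability `sigmoid(-1.8 + 6 * sum_j beta_jk s_j(i-1))` per
  35 ms bin (~5.6 Hz baseline).  The baseline is deliberately not lower:
  suppressing an almost-silent unit is invisible in binary counts, so
  inhibitory edges need a few Hz of background rate to be detectable.
  This surrogate reproduces binned-spike statistics only; it contains no
  membrane or conductance dynamics, no refractoriness, and no bursting,
  so conclusions about real conductance-based networks rest on the
  binary-statistics analogy alone.

What passing these benchmarks does *not* show: performance on real
recordings (non-stationarity, common input from unobserved units,
measurement noise), behaviour of pattern-generating circuits where
conditioning can suppress true edges, and data-driven edge significance
(the 0.01 threshold is a convention, not a test).

## Numerical and design choices

* Windows anchor at sample 0; a trailing remainder is discarded.
  (Anchoring is a free choice; maximizing window count instead changes
  nothing material.)
* A fresh permutation per bootstrap iteration, not one global
  permutation, avoids permutation-specific bias.
* Bins are half-open `[left, right)`; simultaneous spikes in a bin code 1.
* Negative MI estimates are reported as-is at the estimator layer;
  graph assembly floors magnitudes at zero by default (DI is
  non-negative; negativity is estimator noise).
* The conditioning threshold compares *incoming* DI to the target
  (r -> k), since incoming influence is what can confound an edge into k.
* TLPC conditioning enters at lag 0 on both residualizations; argmax
  ties break toward the lag closest to zero; default search range is
  `-5M..-1` samples.
* Sign inference on binary series uses the same Pearson machinery on
  0/1 values.
* Per-edge estimator seeds are derived from the master seed with
  order-independent substreams, so results do not depend on evaluation
  order and edges can be evaluated in parallel.
* Problem sizes in the test suite (N = 2500 for the scalar benchmarks,
  N = 2e4 with 20 bootstrap iterations for the 11-node networks, 300 s
  of surrogate spiking) are the package's default desk-scale settings;
  estimates tighten with more data and iterations.

## Known limitations

* The estimator's residual bias is downward for large MI terms; at the
  default scales on-edge GDI values are accurate to ~10% on the Gaussian
  network, but very small true values (< ~0.01 nats) are not separable
  from zero.
* TLPC is a linear surrogate for sign inference: with purely quadratic
  interactions the sign of a weakly skewed source can be misassigned
  (observed on the inhibitory multipath edge of the nonlinear network),
  and this is inherent to the method, not a defect of the implementation.
* The Gaussian discriminant feature assumes a well-conditioned
  covariance; deterministic channel copies are handled by the ridge and
  calibration safeguards but sit at the edge of the estimator's design
  envelope.
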