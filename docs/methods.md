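# Methods

## Model and procedure

`dfcstates` detects recurring states of dynamic whole-brain functional
connectivity (dWFC). The unit of analysis is one window's normalized edge
vector: within each non-overlapping window of length `L` timepoints, the
Pearson correlation of every unordered region pair is Fisher r-z
transformed, and the M(M−1)/2 values are standardized to mean 0 / sd 1
*within the window*. The per-window normalization removes the window's
overall connectivity level, so downstream similarity reflects the
*pattern* of connectivity, not its magnitude. μ(s) and σ(s) are computed
per window per session independently (the normalization indexes only the
window), with σ in the population (divide-by-n) convention — the target
sd = 1 holds exactly under either convention; the choice is fixed for
reproducibility. The mean-0/sd-1 contract is enforced at container
construction with tolerance 1e-10.

Two normalized edge vectors are compared by Pearson correlation, which
for mean-0/sd-1 vectors of dimension m equals a scaled Euclidean
distance: 1 − corr(x, y) = ‖x − y‖²/(2m). The sample-by-sample
correlation matrix is a signed graph (diagonal set to 0; a self-edge of 1
would inflate within-community weight uniformly) and states are the
communities that maximize signed Q-modularity:

    Q = (1/m) Σ_ij (A_ij − p⁺_ij + p⁻_ij) δ(σ_i, σ_j)
    p±_ij = k±_i k±_j / (2w±)

where A⁺/A⁻ split the adjacency by sign (A⁻ kept as magnitudes), k± are
layer degree sequences, 2w± the layer totals over ordered pairs, and
m = 2w⁺ + 2w⁻ the sum of absolute values of all elements of A. This is
the Gómez et al. signed convention: each sign gets its own configuration
null model, and a pure-sign graph reduces exactly to standard weighted
Newman modularity (cross-checked against networkx in the tests). The
1/m prefactor is a convention; it rescales Q but never changes the argmax
partition. Reported Q values use this convention.

### Optimizer

Signed Q is maximized by a greedy multi-level schedule: seeded random
sweeps of single-node moves (each node moves to the community with the
largest positive Q gain; ties go to the lowest community index), then
aggregation of communities into super-nodes carrying separate positive
and negative layers (sign cancellation inside blocks would corrupt the
null terms), repeated until a level yields no gain, followed by one
refinement sweep at single-node resolution. A full pass improving Q by
less than 1e-10 terminates a sweep.

Because the greedy schedule is order-dependent and single-node moves can
stall in local optima on dense signed graphs, the optimizer runs
`n_restarts` (default 10) independent seeded starts, each followed by an
iterated-local-search phase (default 15 iterations): a random 30% of
nodes are reassigned to random communities and the sweep re-run, keeping
the perturbation only when Q improves. The best partition over all
restarts is returned, and is floored at the trivial one-community
partition. Everything is deterministic given the seed. On random signed
graphs with n ≤ 8 this schedule attains the exhaustive-enumeration
optimum (the brute-force oracle iterates all Bell(n) set partitions and
is exposed as `best_partition_exact`, guarded to n ≤ 12).

### Two-step clustering

For large cohorts the samples are first split into groups, each subject
contributing exactly `S` windows per group; subjects must share one
window count T, and the number of groups is T/S. Chronological mode cuts
consecutive blocks of each subject's time-ordered windows; random mode
shuffles each subject's windows first (seeded). Sessions are concatenated
at the window level — windows never span a session boundary. Each group
is clustered independently and reduced to its community centroids (plain
means of member edge vectors, deliberately left un-normalized: the
second-step similarity is correlation-based and therefore location/scale
invariant, so re-normalizing would be inert). Singleton group communities
are carried into step 2 as centroids; pruning them would be an
undocumented filter. The pooled centroids are clustered once more; each
second-step community is a global state, every sample inherits its state
through its group community, and the published state centroids (WFC-C_i)
are means over all original member samples, re-normalized for symmetry
with the input samples.

On data small enough for one group, the two-step result agrees with
direct one-step clustering (adjusted Rand ≥ 0.9 under strong planted
separation; enforced in the tests).

### State dynamics

The feature score of a sample against state i is its Pearson correlation
with WFC-C_i; the argmax predicts the state (ties to the lowest id).
Dynamics are summarized as: occurrence (fraction of a subject's windows
per state; rows sum to 1), transition rates (off-diagonal transition
counts pooled over sequences, normalized by the total transition count —
raw counts are also emitted, so a time-normalized rate can be derived),
and mean lifetime (mean run length of consecutive same-state windows ×
L·TR seconds, pooled per state). Runs never span a session boundary; runs
truncated by a session end are included, which biases lifetimes slightly
downward. A two-sample t-test between state-occurrence distributions is
provided as a standard convenience wrapper.

### Evaluation

The Davies–Bouldin index is implemented directly (mean over clusters of
the worst (s_i + s_j)/d_ij ratio) because its default metric here is
correlation distance, consistent with the clustering similarity;
Euclidean is selectable and cross-checked against scikit-learn.
Coincident centroids raise rather than returning infinity. The k-means
baseline is classical Lloyd k-means (scikit-learn) on the normalized edge
vectors with Euclidean distance, K swept over a range (default 1..6) with
seeded multi-restart (default 100), best restart by inertia; DBI is
reported for K ≥ 2. Cross-run state agreement maximizes confusion-matrix
overlap over label bijections (Hungarian assignment, rectangular when
state counts differ) and reports an empirical p-value against a
permutation null.

## Synthetic data

The generator emulates the single property the pipeline exploits:
region-by-region covariance that switches among a few recurring patterns.
Each planted state is a block-modular correlation matrix — regions are
randomly reassigned to `n_modules` modules per state, correlation
`within_module_corr` inside a module and 0 between (block-diagonal, hence
positive semi-definite by construction). Layouts are resampled until all
pairwise normalized edge-vector correlations are below 0.5 (separation
guarantee). Within a window the signal is zero-mean Gaussian with the
active state's correlation plus isotropic noise of variance `noise_sd²`;
the state sequence has geometric dwell times (stay probability
1 − 1/mean_dwell) and is aligned to window boundaries by default so every
window has an unambiguous ground-truth label. A misaligned mode shifts
switch points off the window grid for robustness checks.

Defaults (the reference synthetic cohort used throughout the tests):
3 states, M = 20 regions in 4 modules, within-module correlation 0.6,
noise_sd 0.5 (noise variance one quarter of the unit signal variance),
20 subjects × 1 session × 1200 timepoints at TR = 0.72 s, L = 20
(60 windows/subject, 1200 samples), mean dwell 1.75 windows ≈ 25 s — the
scale of empirically reported state lifetimes. Group size S = 5 gives 12
groups of 100 samples. These sizes keep a full pipeline run at a few
seconds on one CPU while leaving every stage non-trivial.

What the generator does *not* model: hemodynamic response, 1/f noise,
head motion, physiological artifact, spatial autocorrelation of real
parcellations, or within-window covariance drift. Passing tests therefore
demonstrate the correctness of the machinery (windowing, normalization,
signed clustering, state assignment, metrics) and recoverability under a
Gaussian covariance-switching regime — not performance on real scans.
Real-data quantities (specific DBI magnitudes, lifetimes, cross-atlas
matching rates) depend on the dataset and are deliberately not asserted.

## Numerical choices

- Fisher z rejects |r| ≥ 1 between distinct regions (a degenerate window
  signals pathological input; clipping would silently distort the
  normalization). Zero-variance regions within a window are errors naming
  the region and window.
- Adjacency symmetry tolerance 1e-12; similarity matrices are clipped to
  [−1, 1] and symmetrized before use.
- Community labels are canonicalized to contiguous 1..c by first
  appearance; modularity is invariant to relabeling (property-tested).
- Local-move convergence threshold 1e-10 on the Q gain of a full pass.
- k-means empty-cluster restarts are handled by scikit-learn's internal
  re-initialization.
- The dwell distribution's `mean_dwell_windows = inf` degenerates to one
  state per session, exercised in tests.

## Known limitations

- Dense similarity matrices: memory is O(n²) per clustered group, which
  is exactly why the two-step procedure exists; step 2 scales with the
  total number of group communities, not samples.
- Lifetime estimates are biased downward by session-truncated runs
  (documented above; both raw counts and rates are emitted so users can
  re-normalize transitions differently).
- The optimizer is stochastic-restart greedy: global optimality is
  verified only at oracle scale (n ≤ 8 exhaustively); on larger graphs
  quality is established through planted-structure recovery.
- No overlapping/tapered windows, no multi-resolution (γ-parameterized)
  modularity, no hierarchical sub-state discovery.
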