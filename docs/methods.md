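# Methods

## Model and statistic

For a graph `G` on `n` nodes with a fixed partition `σ` into `k` communities
of sizes `Ω` (the *a-priori* functional networks), the package infers the
stochastic-block-model parameters in closed form, treating both `G` and `σ`
as observed:

- `p_i = Ω_i / n`, `P = diag(p)`;
- block statistics `C` over unordered node pairs `u < v`: edge counts in
  binary mode, sums of `|w_uv|` in weighted mode (only the magnitude of a
  functional coupling contributes to block connectivity — signs are
  neurophysiologically contentious and would cancel);
- capacities `C_max`: `Ω_i Ω_j` off the diagonal and `Ω_i (Ω_i − 1)/2` on it
  (unordered pairs, no self-pairs — connectome diagonals are identically
  zero). The literal outer-product convention `Ω_i²` on the diagonal is
  available as `cmax_convention="literal"` for sensitivity checks; it scales
  the within-block densities by `(Ω_i − 1)/(2 Ω_i) ≈ 1/2` and therefore
  shifts, but does not reorder, SNR profiles.
- `W = C ⊘ C_max` (0/0 → 0 for singleton-community diagonals), `Q = nW`
  (constant-degree regime, scale factor `s_t = 1`), and the community
  profile matrix `PQ = nPW`, whose `(i, j)` entry is the expected number of
  community-`j` neighbors of a community-`i` node.

The prominence statistic is `SNR = λ₂²/λ₁` of `PQ` with eigenvalues sorted
by descending magnitude; `SNR > 1` is the Kesten–Stigum weak-recovery
condition. `PQ` is similar to the symmetric matrix `P^{1/2}(nW)P^{1/2}`, so
its spectrum is real; the implementation verifies this (imaginary parts
below 1e-8) rather than assuming it, as a guard against corrupted inputs.

Numerical conventions for the spectrum:

- `PQ` is entrywise nonnegative, so its spectral radius is itself an
  eigenvalue (Perron). When the two largest magnitudes tie — e.g.,
  bipartite-like block structure with spectrum `±r`, which shuffled
  partitions do produce — `λ₁` is the positive root of the tie.
- `SNR` is defined as exactly 0 when `k = 1`, when `λ₁ ≤ 1e-12` (empty
  graph) or when `|λ₂| ≤ 1e-12·λ₁` (rank-one `PQ`: complete or structureless
  graphs). "No mesoscopic signal" is a value, not a NaN.
- With equal blocks and uniform contrast the sub-leading eigenvalue is
  `(k−1)`-fold degenerate; sampling noise splits the cluster, and taking the
  second-largest magnitude selects the top of the split. Empirical SNR on
  sampled graphs therefore sits a few percent *above* the analytic value on
  average (≈ +7% at `n = 400`, `k = 4`, within/between 0.30/0.05). This is a
  property of the estimator at degenerate spectra, not a bug; consistency
  tests compare against the analytic value with a 10% band.

## Threshold pipeline

Thresholding keeps pairs with `|w_uv| > τ` (strict, so `τ = 0` keeps exactly
the nonzero support); `positive_only=True` switches to `w_uv > τ`. The
four-step cohort routine: (1) entrywise mean of signed weights (no Fisher-z;
sign cancellation before thresholding is intended), binarized per `τ` on the
grid (default step 0.05); (2) weak-recoverability interval `[a_w, b_w]` =
smallest/largest grid `τ` with binary group-average SNR > 1, with a warning
flag if the super-threshold set is non-contiguous; (3) weighted SNR profiles
for the group average and each subject — by default subjects are thresholded
on their own entries; `mask="group_average"` instead restricts each subject
to the support of the thresholded group average, since either reading of the
"masked" group representation is defensible; (4) per-source `argmax` over
the grid (ties break toward the smaller `τ`; an all-zero profile is flagged
degenerate and reported at the smallest grid point) and membership checks
against the single interval from step 2.

Vetting is deliberately computed once, from the binarized group average,
even when optimizing individual thresholds: the interval is a property of
the cohort-level graph sequence, and per-subject optima are checked against
it rather than against per-subject intervals.

Topology profiles (density = retained pairs / all pairs; connected
components via `scipy.sparse.csgraph`) accompany the SNR profiles because
fragmentation — the component count leaving 1 — is the topological
counterpart of the SNR decline at high `τ`.

## Null models

The null destroys only the alignment between communities and topology:
uniformly random permutations of the label vector, which preserve the size
multiset `Ω` (hence `P`) and the graph exactly. Re-drawing labels i.i.d.
would perturb `P` and conflate two effects. Default 100 shuffles, explicit
seed recorded in every summary. Binary mode is the default for comparison
against the hard threshold `SNR = 1`. On planted cohorts the null maximum
stays below 1 across the grid while the true partition exceeds it over a
broad interval; pointwise dominance of the true profile is guaranteed only
over the weak-recoverability range — in the fragmented high-`τ` tail both
profiles are near zero and their order is noise.

## Forward back-test

Two detector families solve the forward problem on each thresholded graph:

- **Modularity maximization**: `Q = (1/2m) Σ_{u,v} (A_uv − α k_u k_v / 2m)
  δ(σ_u, σ_v)` over ordered pairs (`α = 1` default), maximized by the seeded
  Louvain implementation in networkx. The `Q` of the found partition and its
  AMI against the a-priori partition are recorded per `τ`.
- **Poisson weighted SBM**: non-degree-corrected, `k` fixed to the a-priori
  `k`. Edge data become integer counts (binary adjacency directly; `|w|`
  scaled by 100 and rounded — configurable). Block rates are the empirical
  means; labels are optimized by greedy single-node moves in seeded random
  order with 5 random restarts, rejecting moves that would empty a block.
  The log-likelihood trace is non-decreasing across accepted moves.

Agreement uses adjusted mutual information (chance-corrected; arithmetic
mean normalization by default, `max`/`sqrt` switchable, plain NMI behind
`variant="nmi"`), via scikit-learn. Edgeless high-`τ` graphs are recorded
with AMI = Q = 0 and a degeneracy flag rather than an error.

On planted cohorts the AMI-vs-`τ` curves of both detectors peak within one
grid step of the weighted SNR peak, while raw `Q` keeps climbing into the
sparse regime and plateaus high after agreement with the planted partition
has collapsed — which is precisely why raw modularity is a poor threshold
guide for a fixed a-priori partition and chance-corrected agreement (or the
blinded SNR) is not.

## Synthetic cohorts

The generator emulates the statistical shape of Pearson FC cohorts, not BOLD
physiology. Per subject, each community has a latent factor signal over `T`
time points; factor correlations are set so node-level between-community
couplings target `rho_between`; node `u` mixes its community factor
(loading `√ρ_u`) with private noise; the connectome is the sample
correlation matrix with zeroed diagonal.

Heterogeneity enters at three levels, and the split matters:

- **Population-shared** (identical for all subjects, survives group
  averaging): node loadings drawn once with spread `rho_within_sd`, and
  community-pair coupling levels drawn once with spread `rho_between_sd`
  (different functional-network pairs couple at different strengths). This
  gives the group-average FC broad within/between coupling distributions, so
  thresholding is a genuine trade-off with an interior optimum rather than a
  cliff. Heterogeneous coupling targets can leave the factor-correlation
  matrix slightly outside the elliptope; it is repaired by spectral flooring
  with the unit diagonal restored.
- **Subject-specific** ("fingerprints", damped by group averaging): a jitter
  `fingerprint_sd` on the node loadings, plus a subject-unique latent factor
  carried by a random `fingerprint_fraction` of nodes with variance share
  `fingerprint_var` and random sign. The latter produces reproducible
  high-magnitude couplings that cut across the planted communities — the
  mechanism that makes individual FCs fragment later, peak later and peak
  lower than the group average.
- **Sampling noise**, controlled by `T` (standard error ≈ `1/√T` per
  coupling).

Default study conditions (chosen once): `n = 112` nodes in `k = 7`
equal communities (a mid-resolution cortical parcellation carrying seven
functional networks), `T = 166` (a short task-scan length), `Γ = 20`
subjects, `rho_within = 0.40` (sd 0.10), `rho_between = 0.10` (sd 0.10),
`fingerprint_sd = 0.05`, `fingerprint_var = 0.06`, fraction 0.3. Under these
conditions the pipeline reproduces, at fixed seed: non-monotone SNR profiles
with interior maxima; every optimum inside `[a_w, b_w]`; group average
peaking higher and no later than the median individual; mean individualized
optimum within one grid step of the group optimum; and SNR growth under
2× parcellation refinement (children inherit their parent's community,
loading and fingerprint but draw independent private noise, so cohorts at
different granularities share their latent structure at fixed seed).

What passing these tests does *not* show about real data: the generator has
no spatial embedding, no hemodynamics or temporal autocorrelation (its `T`
points are i.i.d., so `T` understates the effective sample size of a real
scan), Gaussian rather than heavy-tailed couplings, equal community sizes by
default, and fingerprints that are random rather than spatially organized.
Scan-length effects on the *group average* are secondary once `Γ` is large
(averaging removes most sampling noise); the documented growth of peak group
SNR with `T` is asserted in the small-cohort regime (`Γ = 5`) where noise
dominates.

## Problem sizes

Test and acceptance computations run at desk scale by design: cohorts of 20
subjects at `n = 112` (and 224 after refinement), planted graphs at
`n = 200–400`, 100-shuffle nulls, and 100-case randomized oracle suites with
brute-force double-loop references at `n ≤ 30`. These sizes put every
qualitative regime (sub- and super-threshold, fragmented and dense) within a
few seconds' reach while keeping binomial standard errors small enough for
the quantitative bands used.

## Known limitations

- Weighted-mode "inference" is a prominence extension, not maximum
  likelihood for a generative weighted SBM; the Poisson back-test fitter is
  the generative counterpart and is intentionally separate.
- Exact recovery (and the Chernoff–Hellinger distance that governs it) is
  out of scope; the package speaks only to weak recovery.
- The Louvain and greedy-move optimizers are heuristics: seeded and
  deterministic, but not guaranteed global maximizers at realistic sizes.
- Partitions are taken as given and complete; nothing maps nodes to
  communities for you.
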