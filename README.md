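# connsnr

**SBM-theoretic prominence of a-priori functional sub-circuits, and
SNR-guided thresholding of weighted functional connectomes.**

Functional connectomes (FCs) — symmetric matrices of pairwise Pearson-like
couplings between brain regions — are routinely thresholded to suppress
spurious couplings, and routinely analyzed against an *a-priori* partition of
regions into functional networks (e.g., seven resting-state networks). Both
steps beg the same question: *how well does that fixed partition actually fit
the network, and at which threshold does it fit best?*

`connsnr` answers it with the weak-recovery theory of stochastic block models
(SBMs). For a graph `G` on `n` nodes and a fixed partition `σ` into `k`
communities of sizes `Ω`, the block model parameters are inferred in closed
form:

```
p = Ω/n,   P = diag(p),   W = C ⊘ C_max,   Q = nW,   PQ = nPW
```

where `C` counts edges (binary graphs) or sums absolute couplings `|w_uv|`
(weighted graphs) within/between communities and `C_max` is the pair
capacity. The **prominence** of the partition is the signal-to-noise ratio

```
SNR = λ₂² / λ₁
```

over the eigenvalues of the community profile matrix `PQ`, sorted by
descending magnitude. `SNR > 1` is the Kesten–Stigum condition: weak recovery
of the planted communities (beating a constant guess) is efficiently
solvable. `SNR` is zero for both empty graphs (no signal) and complete graphs
(no contrast) — exactly the failure modes naive thresholding can produce.

The cohort-level pipeline turns this statistic into a threshold-selection
device, in four steps:

1. **Group-average** the cohort's FCs entrywise and binarize at each
   threshold `τ` on a grid (default step 0.05 on [0, 1], keeping `|w| > τ`).
2. **Vet**: compute the binary SNR profile of the group average and extract
   the *weak-recoverability interval* `[a_w, b_w]` where `SNR > 1`.
3. **Score prominence**: compute the weighted SNR profile (mean-`|w|` blocks)
   for the group average and for every subject.
4. **Optimize**: take `τ_opt = argmax SNR` per source and check membership in
   `[a_w, b_w]`.

Around the core sit partition-shuffle null models (size-preserving label
permutations; null SNR should stay below 1), a forward community-detection
back-test (seeded Louvain modularity maximization and a fixed-`k` Poisson
weighted-SBM fit, compared to the a-priori partition via adjusted mutual
information), and a synthetic-cohort generator with planted assortative
structure, subject fingerprints, scan-length control and parcellation
refinement — so every stage is exercisable without any restricted data.

## Worked example

Score a single graph against a fixed two-community partition:

```python
import numpy as np
import connsnr as cs

adj = np.zeros((4, 4))
for u, v in [(0, 1), (0, 2), (2, 3)]:
    adj[u, v] = adj[v, u] = 1
graph = cs.BinaryConnectome(adjacency=adj)
partition = cs.make_planted_partition(4, 2)   # nodes (1,2) vs (3,4)

print(cs.PartitionedSBM(graph, partition).fit().summary())
```

```
Partitioned SBM fit
===================
nodes: 4    communities: 2    mode: binary
community sizes: [2, 2]
lambda1 = 2.5    lambda2 = 1.5
SNR = lambda2^2/lambda1 = 0.9  (<= 1)

block connectivity W (rows/cols = communities):
[[1.   0.25]
 [0.25 1.  ]]
```

Both within-community pairs are wired (`W` diagonal 1) and one of four
between-community pairs is (`W` off-diagonal 0.25), but at `n = 4` the
contrast yields `SNR = 0.9 < 1`: this partition is not weakly recoverable
from this graph.

Run the full threshold search on a simulated 20-subject cohort with seven
planted functional networks (112 nodes, 166 time points per scan):

```python
model = cs.ConnectomeThreshold.from_simulation(cs.SimConfig(seed=0))
results = model.fit()
print(results.summary())
```

```
SNR-guided connectome threshold search
======================================
subjects: 20    nodes: 112    communities: 7
grid: [0.00, 1.00] step 0.05
weak-recoverability interval [a_w, b_w] = [0.05, 0.45]
tau_opt (group average, weighted SNR) = 0.25  [inside interval]
individual tau_opt: mean 0.263, median 0.25, range [0.20, 0.35]
individual optima inside [a_w, b_w]: 20/20
```

Reading this: thresholds between 0.05 and 0.45 keep the binarized
group-average FC above the weak-recovery phase transition; the weighted
prominence of the planted partition peaks at `τ_opt = 0.25` for the group
average; each subject's individualized optimum (spread 0.20–0.35, a
fingerprint effect) also lands inside the vetted interval. `results`
additionally exposes the profiles as a tidy DataFrame
(`results.profiles_frame()`), the reconstructed FC at the optimum
(`results.reconstructed()`), a profile plot (`results.plot_profiles()`), and
the shuffle null (`model.null_distribution()`).

The same workflows are scriptable from a shell:

```sh
connsnr simulate --n 112 --k 7 --gamma 20 --seed 0 --out cohort/
connsnr fit cohort/manifest.json cohort/partition.tsv --out fit/
connsnr null cohort/sub-1.csv cohort/partition.tsv --n-shuffles 100 --out null/
connsnr validate cohort/sub-1.csv cohort/partition.tsv --out curves/
```

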