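# Methods

## Problem setting

Two LC/MS runs of comparable samples yield feature lists whose peaks must
be put in one-to-one correspondence. m/z is reproducible to high precision;
retention time drifts between runs, often nonlinearly, so a peak can have
several plausible partners. groupalign is a *direct matching* method: it
scores candidate cross-run pairs and solves a bipartite matching, without
fitting an RT correction function first. Its distinguishing ingredient is
within-run related-peak structure: all peaks caused by one compound
(isotopologues, adducts, fragments) coelute, and a pair of peaks whose
groups mutually support each other across runs is more likely a true
correspondence.

## Similarity score

Peaks are vectors [m/z, RT]. With a diagonal covariance of squared
tolerances (σ_m², σ_t²) the Mahalanobis distance reduces to
D = √((Δm/σ_m)² + (Δt/σ_t)²). We use the proper (square-root) distance;
since scores are normalized by the maximum computed distance the choice
only rescales the score distribution, not its ordering. Distances are
computed only for pairs with |Δm/z| ≤ σ_m and |Δrt| ≤ σ_t — the windows are
hard thresholds that define the solution space, and the thresholding is on
the raw coordinate differences, not the scaled components (so every stored
distance is ≤ √2). The score is W = 1 − D/D_max with D_max the maximum
*stored* distance of the run pair.

Degenerate normalizations: if only one in-window pair exists, or all stored
distances are zero, all stored pairs score 1. Otherwise the single worst
pair would score exactly 0 and become unmatchable despite being inside the
user's tolerance windows.

ppm mode: σ_m in ppm is converted per pair as σ_abs = σ_m · mz_A · 10⁻⁶,
anchored at the run-A peak. The induced asymmetry is below σ_m ppm of
itself and keeps the computation deterministic.

## Related-peak grouping

Both groupers emit an N×N co-membership matrix C with zero diagonal (the
diagonal would double-count the pair itself when blending).

**Greedy RT clustering.** Seeds are chosen in strictly decreasing intensity
among unclustered peaks (ties broken by ascending peak id); every
unclustered peak within g_tol seconds of the *seed's* RT joins. When shape
traces are available and a Pearson threshold c is set, a candidate joins
only if the correlation of its trace with the seed's strictly exceeds c;
peaks lacking traces fail the filter. Traces are compared after linear
interpolation onto the union of their scan times restricted to the
overlapping RT range; fewer than 3 overlapping samples or a zero-variance
signal make the correlation undefined (NaN), which fails any threshold.
Because seeding depends only on intensity and id, the partition is
invariant to input row order.

**DP Gaussian mixture on RT.** Assignments follow a Chinese-restaurant
process with concentration α_DP; cluster means have prior
Normal(μ₀, s₀²) with μ₀ the empirical RT mean; observations are
Normal(mean, cluster_rt_sd²) with *fixed* within-cluster variance. Means
are integrated out, giving standard collapsed Gibbs conditionals
(posterior-predictive Normals per existing cluster, the prior predictive
for a new one). C_ij is the fraction of kept sweeps in which i and j share
a cluster. Fixed variance keeps every conditional analytic; inferring the
cluster variance is a known extension we deliberately omit, exposing
cluster_rt_sd instead as the user's statement of coelution width.

Defaults: cluster_rt_sd = 2 s (typical coelution spread on UHPLC
gradients), prior_mean_sd = span of observed RTs (a flat, data-scaled
location prior), concentration = 1, burn-in 500 sweeps, 1000 kept samples,
seeded. Identical inputs and seed give a bit-identical matrix.

## Blending and matching

L = C_A · W · C_B sums similarity mass between the two candidate peaks'
groups. Because it is a sum, L grows with group size and is not
commensurable with W ∈ [0, 1]; we rescale L by its maximum entry before
blending (toggleable, `normalize_L`). The final score
S = αW + (1 − α)L̂ is kept only on W's sparsity pattern: grouping evidence
must never create a match outside the hard tolerance windows. α defaults
to 0.3, inside the 0.2–0.4 band that balances the two evidence sources;
α = 1 reproduces plain similarity matching exactly.

Matching drops zero-weight scores (the worst in-window pair) from the
graph by default — matching on zero evidence only inflates false
positives — then greedily accepts edges in non-increasing weight order
(ties: ascending (i, j)), which is a maximal matching with total weight
≥ ½ of optimal, at the cost of one edge-list sort. The exact solver
(scipy's assignment algorithm) is gated to small instances and used
throughout the tests as a cross-check, itself validated against
brute-force enumeration over all matchings.

## Evaluation protocol

A predicted pair is *considered* only if both its peaks occur somewhere in
the ground truth; considered pairs in the truth are TP, considered pairs
not in the truth are FP, truth pairs not predicted are FN. Precision,
recall and F1 = 2PR/(P+R) follow, with degenerate ratios defined as 0 so
parameter sweeps never crash. Peak-level filtering is the only reading
under which FPs are assessable when the truth covers a subset of peaks;
note that with a one-to-one prediction and a fully one-to-one truth, an
incorrect considered pair necessarily displaces two truth pairs, so FP
counts move in steps tied to FN counts.

## Synthetic paired runs

The simulator is the package's test bed. Per compound it plants an isotope
ladder (spacing 1.003 Th, geometric intensity decay 0.6 per step, group
sizes uniform on [2, 4]) at a shared RT with jitter (sd 0.3 s). Run B is
derived from run A by:

* a smooth strictly monotonic warp t' = t + A·sin(πt/t_max), default
  A = 20 s (validated: A < t_max/π guarantees monotonicity, preserving
  elution order);
* a compound-level RT shift (sd 2 s) — related peaks drift *together*,
  which is what makes within-run grouping informative; purely independent
  per-peak RT noise would destroy run-B group compactness;
* independent per-peak noise: m/z sd 0.002 Th, RT sd 0.3 s, a mild
  log-normal intensity factor;
* independent dropout of run-B peaks (default 10%).

Ground truth lists exactly the surviving cross-run pairs; the planted
partitions are returned as membership matrices for both runs. Confusable
instances additionally plant pairs of compounds sharing a base m/z and
eluting 4 s apart — within matching tolerances, so raw similarity is
ambiguous — with satellites at distinct spacings (1.003 vs 0.335 Th,
i.e. singly charged vs highly charged ladders) that match only their true
counterparts.

What the simulator does **not** emulate: raw profile signals and peak
picking errors, intensity response differences between runs beyond a
scalar factor, correlated m/z error, many-to-one correspondences,
chimeric/overlapping features, or real adduct chemistry (adducts are
approximated by the fixed-offset ladder members). Perfect scores on
synthetic data therefore demonstrate the machinery is correct under the
stated generative assumptions, not field performance on instrument data.

## Numerical and design choices

* RT is seconds everywhere internally; minute-valued inputs are converted
  at read time.
* Sparse score matrices store explicit (row, col, value) triplets in
  canonical order, so matrices compare deterministically and explicit
  zeros (the D_max pair) survive.
* Greedy grouping ties on intensity break by ascending id; matching ties
  on weight break by ascending (i, j); both purely for determinism.
* Ground truth is restricted to one-to-one pairs; many-to-many inputs are
  rejected rather than silently resolved.
* Problem sizes: the test suite and the acceptance script use runs of
  ~60–130 peaks (20–40 compounds), 1000 random bipartite instances up to
  8×8 with enumeration cross-checks up to 5×5, and a 5-peak run against
  the exhaustive set-partition posterior (203 partitions) with 20 000 kept
  Gibbs samples — sizes at which every oracle is exact and the whole suite
  runs in well under a minute.

## Limitations

* Pair-wise only: multi-run alignment via hierarchical merging is out of
  scope.
* No RT warping correction; systematic drifts larger than σ_t are not
  recoverable by design.
* The ½-approximation is a worst-case bound; on realistic score matrices
  the greedy matching is near-optimal, but adversarial weight structures
  can approach the bound.
* Grouping helps only when related peaks exist and group structure is
  preserved across runs; singleton features gain nothing (and with α < 1
  their scores are strictly downweighted relative to grouped pairs).
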