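# groupalign

Direct-matching peak alignment for LC/MS feature lists that exploits
**related-peak grouping**: the isotopologues, adducts and fragments a single
compound produces within one run coelute, and the same group structure
should be preserved across runs. groupalign folds that structure into the
pair-wise similarity score before solving the correspondence problem as a
maximum-weight bipartite matching.

It is aimed at proteomics / metabolomics / glycomics pipelines that already
have extracted feature tables (id, m/z, RT, intensity) from two runs and
need the cross-run peak correspondence — no raw-signal parsing, no RT
warping step.

## Method

For runs A (N_A peaks) and B (N_B peaks), each peak is the vector
p = [m, t]ᵀ of its m/z and RT. With tolerances σ_m and σ_t,

* **Similarity.** D(p_i, p_j) = √((Δm/σ_m)² + (Δt/σ_t)²), computed only for
  pairs within both tolerance windows (hard thresholds), and
  W(p_i, p_j) = 1 − D(p_i, p_j)/D_max, where D_max is the largest in-window
  distance for the run pair — so W ∈ [0, 1].
* **Grouping.** Each run gets a square co-membership matrix C (zero
  diagonal): binary from greedy intensity-seeded RT clustering within a
  window g_tol (optionally gated by the Pearson correlation of
  chromatographic peak shapes), or probabilistic from a Dirichlet-process
  Gaussian mixture on RT sampled with collapsed Gibbs.
* **Blending.** L = C_A · W · C_B accumulates similarity between the groups
  of each candidate pair; the final score is S = αW + (1 − α)L̂ with
  α ∈ [0, 1] (L̂ is L rescaled to [0, 1]; α = 1 ignores grouping entirely).
* **Matching.** A greedy approximation to maximum-weight bipartite matching
  (repeatedly take the heaviest remaining edge) guarantees at least ½ of
  the optimal total weight in O(m log n); an exact assignment-problem
  solver is available for small instances.
* **Evaluation.** Against a one-to-one ground truth, precision, recall and
  F1 are computed over predicted pairs whose peaks both occur in the truth.

The three method variants are MW (α = 1, no grouping), MWG (greedy
grouping) and MWM (mixture-model grouping).

## Worked example

Simulate a paired run with planted confusable near-isobaric compounds, then
align with and without grouping information:

```sh
$ groupalign simulate -o demo --seed 7 --confusable
wrote 124+114 peaks, 114 truth pairs to demo

$ groupalign align demo/run_a.tsv demo/run_b.tsv -o demo/matching_mw.tsv \
    --mz-tol 0.01 --rt-tol 30 --ground-truth demo/ground_truth.tsv
matched 113 pairs, total score 58.7280
tp      fp      fn      precision       recall  f1
98      13      16      0.8829  0.8596  0.8711

$ groupalign align demo/run_a.tsv demo/run_b.tsv -o demo/matching.tsv \
    --mz-tol 0.01 --rt-tol 30 --grouping greedy --g-tol 1.5 --alpha 0.3 \
    --ground-truth demo/ground_truth.tsv
matched 114 pairs, total score 48.9798
tp      fp      fn      precision       recall  f1
114     0       0       1.0000  1.0000  1.0000
```

Raw similarity matching (first call) confuses 13 of the planted isobaric
base peaks; blending in greedy RT grouping at α = 0.3 (second call)
resolves all of them because each confusable compound carries satellite
peaks that only match their true counterparts. The same pipeline is
available from Python:

```python
from groupalign import AlignmentConfig, Tolerances, align, read_peaklist

run_a = read_peaklist("demo/run_a.tsv")
run_b = read_peaklist("demo/run_b.tsv")
config = AlignmentConfig(tolerances=Tolerances(0.01, 30.0),
                         grouping="greedy", alpha=0.3)
matching = align(run_a, run_b, config)
```

`groupalign sweep` evaluates a full-factorial parameter grid (tolerances,
α, g_tol, grouping method) against a ground truth, for train/test parameter
transfer studies.

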