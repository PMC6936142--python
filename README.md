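# manialign

Manifold alignment and simultaneous clustering of gene co-expression
networks across conditions, states or species.

## The problem

Comparing two gene expression datasets — the same organism under two
conditions (say, light vs dark periods of a diurnal time course), or two
species during development — usually means clustering each dataset
separately and matching clusters afterwards. That loses exactly the
information of interest: which groups of genes behave the same way in both
settings, which are private to one, and which *different* gene sets are
linked across settings through a handful of common genes.

`manialign` instead embeds both gene sets onto one low-dimensional manifold
and clusters them **together**, so every module is a cross-network object
whose composition can be read off directly.

## The method

Given expression matrices X (m_X genes × d_X samples) and Y (m_Y × d_Y),
and a correspondence matrix W ∈ R^{m_X×m_Y} (shared gene ids, ortholog
pairs, or a warp path learned by dynamic time warping when both datasets
are ordered time courses):

1. **Manifold approximation.** Build a k-nearest-neighbor graph over each
   dataset's genes (affinities W_X, W_Y; unnormalized Laplacians
   L = D − W).
2. **Alignment.** Minimize, over embeddings f of X and g of Y into R^d,

       (1−μ) Σ_{ij} ‖f_i − g_j‖² W^{ij}  +  μ fᵀL_X f  +  μ gᵀL_Y g

   subject to the scale constraint PᵀDP = I for the stacked coordinates
   P = [f; g]. Assembling the blocks into one joint graph turns this into
   the generalized eigenproblem L p = λ D p (nonparametric variant) or
   ZᵀLZ p = λ ZᵀDZ p with Z = blockdiag(X, Y) (linear variant with explicit
   projection maps). The bottom d nontrivial eigenvectors are the shared
   coordinates. μ (default ½) trades correspondence fidelity against each
   dataset's own geometry.
3. **Simultaneous clustering.** k-medoids on the concatenated embedded
   coordinates yields n cross-network modules.
4. **Module typing.** Each module C_i is scored by intra-module Jaccard
   similarity J = |X′∩Y′| / |X′∪Y′| (co-clustered corresponded pairs over
   the gene union), condition number κ = ratio of dataset-specific counts,
   and the functional linkage score

       S(C_i) = 1 − (|1−κ_i|/max κ + J_i/max J) / max_i(|1−κ_i|/max κ + J_i/max J).

   High J ⇒ **conserved**; one-sided κ ⇒ **condition-specific**; low J with
   κ ≈ 1 (high S) ⇒ **functional linkage** — different gene sets from the
   two networks bound together by few shared genes. Thresholds are set
   data-dependently by 1-D k-means rather than fixed cutoffs.

A linear CCA alignment and a no-alignment baseline are included for
comparison; alignment quality is the summed Chebyshev distance between
corresponded pairs, and clusterings are compared by the adjusted Rand
index.

## Worked example

```bash
python examples/01_align_and_type_modules.py
```

generates a synthetic pair of datasets (one planted module per type on a
shared S-curve manifold), aligns and clusters them, and prints:

```
        count_x_specific  count_y_specific  count_shared  size  jaccard  condition_number  linkage_score         module_type
module
0                      0                31             0    31    0.000               inf           0.50          Y_specific
1                     19                28            11    69    0.190             1.474           0.72  functional_linkage
2                      8                 0            31    70    0.795               inf           0.00           conserved
3                     32                 0             0    32    0.000               inf           0.50          X_specific

planted types recovered: 4/4
```

Module 2 is mostly co-clustered gene pairs (high Jaccard ⇒ conserved);
modules 0 and 3 are one-sided (condition-specific); module 1 mixes both
datasets nearly evenly with few shared genes (κ close to 1, low J, high
linkage score ⇒ functional linkage). All four planted types are recovered.

The other examples demonstrate correspondence learning by manifold warping
(`02_manifold_warping.py`) and the alignment-quality comparison across
methods (`03_compare_alignment_methods.py`).

## Command line

```bash
manialign simulate --seed 1 --outdir sim/
manialign run --x sim/X.tsv --y sim/Y.tsv --pairs sim/pairs.tsv \
    --method alignment_nonparametric --k 3 --d 3 --n 4 --seed 7 --outdir out/
manialign eval --modules-a out/modules.tsv --modules-b other/modules.tsv
```

`run` writes `embedding.tsv`, `modules.tsv`, `module_stats.tsv`,
`evaluation.json` and `summary.json` (the full resolved configuration,
stage timings and warnings).

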