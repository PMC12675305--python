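# Methods

This note documents the model implemented by `pgdas`, the choices made where
the design was genuinely open, the synthetic cohorts the package validates
itself on, and the known limitations of both.

## Problem setting

Cohorts of individuals with a heterogeneous neuropsychiatric condition (the
motivating case is autism spectrum disorder measured with resting-state
fMRI) are widely believed to mix several *biotypes*: subgroups with distinct
neurobiology that clinical labels do not separate. The package identifies
such subgroups from functional connectivity (FC) with a deep-clustering
model that treats the cohort as a graph, and then characterizes the
subgroups with standard inferential statistics.

## Connectivity features

Each subject contributes an N×N FC matrix: Pearson correlations between ROI
time series, Fisher-transformed, z = atanh(r). Correlations are clamped to
|r| ≤ 1 − 10⁻⁷ before the transform so duplicated or perfectly
anti-correlated ROIs stay finite; the diagonal is stored as 0 because
self-connections are excluded from every downstream statistic. A scrubbing
utility removes volumes with framewise displacement > 0.5 mm together with
1 preceding and 2 following volumes (windows clipped at the series bounds);
it applies when inputs are raw ROI time series and is bypassed when
precomputed FC matrices are supplied. The node feature vector is the
row-major upper triangle of the FC matrix, of length N(N−1)/2.

## Population graph

Subjects are nodes; the edge weight between subjects u and v is

    w_uv = exp(−d_uv² / 2σ²) · ( 1[site_u = site_v] + 1[|age_u − age_v| ≤ τ] )

with d_uv the correlation distance between feature vectors, σ the median of
all pairwise distances (median heuristic) unless set, and τ = 2 years
(inclusive). The multiplicative form lets the phenotype gate imaging
similarity; a subject whose affinity is zero against the whole cohort is
re-attached to its nearest feature neighbour (logged) so that no node is
isolated. Each node keeps its k = 10 strongest edges and the matrix is
symmetrized by elementwise maximum. Graph propagation uses the normalized
operator Â = D^(−1/2)(W + I)D^(−1/2), whose spectrum lies in [−1, 1].

The exact functional form of the edge weight, the top-k density rule, and
the bandwidth default are design choices of this package: the requirement
they implement is only that edges combine imaging similarity with age and
site affinity and that the propagation operator is sparse.

## Dual autoencoders, fusion, attention

* **AE.** Three encoder layers F→512→256→d and a mirrored decoder,
  LeakyReLU (slope 0.01) after all but the final layer of each stack,
  dropout p = 0.2 in the hidden layers during training. Hidden widths are
  shrunk to ≤ F when the feature dimension is small (logged).
* **GAE.** Three propagation layers H ← act(Â H Θ) with the same widths,
  linear last layer; the decoder reconstructs the adjacency as
  Ŵ = sigmoid(Z_GAE Z_GAEᵀ).
* **Fusion.** Zi = g ⊙ Z_GAE + (1 − g) ⊙ Z_AE with g = sigmoid of a
  learnable per-dimension vector initialized at 0 (so fusion starts as the
  plain average). A per-dimension gate is the smallest architecture that
  realizes adaptive fusion while keeping the zero-initialization behaviour
  exactly testable.
* **Attention.** Single-head sample-level self-attention with a residual:
  Z̃ = Zi + A (Zi V), A = row-softmax((Zi Q_w)(Zi K_w)ᵀ/√d). V is
  initialized at zero, making the module exactly the identity at the start
  of training.

## Deep clustering

Soft assignments use the Student-t kernel with α = 1 degree of freedom,

    q_ij ∝ (1 + ‖z̃_i − μ_j‖²/α)^(−(α+1)/2),

and the self-supervised target sharpens them with squared, cluster-frequency
normalized responsibilities,

    p_ij ∝ q_ij² / f_j,   f_j = Σ_i q_ij,

renormalized per row. This is the canonical target-distribution
self-supervision for deep embedded clustering; the match between Q and P is
penalized with KL(P‖Q). The joint loss is

    L = MSE(X, X̂) + β · BCE(1[W > 0], Ŵ) + γ · KL(P‖Q)

with β = 1, γ = 0.1 by default. The BCE uses the binarized sparsified
adjacency as its target with positive-class weight (#zeros/#ones) to offset
the sparsity imbalance, and probabilities clipped to (10⁻⁷, 1 − 10⁻⁷) for
numerical safety.

Training: (1) pretrain both autoencoders on the reconstruction terms for 50
epochs; (2) initialize centroids with k-means++ followed by Lloyd iterations
on Z̃ (the initial hard labels are this Lloyd partition, so with γ = 0 and
fusion/attention disabled the pipeline reduces exactly to k-means++ on the
AE embedding); (3) alternate gradient steps on L with refreshes of P every
5 epochs, stopping early when < 0.1% of hard labels change between
refreshes or at 200 epochs. The optimizer is Adam with decoupled L2 weight
decay λ = 10⁻⁴ (applied to weight matrices, not biases, gates or
centroids), learning rate 10⁻³. A cluster that empties at a refresh has its
centroid re-seeded at the point with the lowest maximum responsibility
(logged). All randomness — initialization, dropout masks, k-means++ — flows
from one integer seed, and runs are bit-reproducible given (config, seed).

K is selected in 2..6 by the silhouette coefficient computed on Z̃ with
Euclidean distance and the hard labels; ties break toward the smaller K. A
fit that ends with fewer than K non-empty clusters is degenerate for that K
and scores −1: a collapsed K=3 run whose labels form two clusters is
evidence *for* K=2, and scoring its (sharper, lower-K) partition as a K=3
candidate would bias the selection toward whichever K happens to collapse
onto the true structure. The silhouette is computed on the refined
embedding because that is the space the clustering itself operates in.

## Internal validation

* **Cross-parcellation agreement.** Refit the whole pipeline per
  parcellation (same training configuration) and report the percentage of
  subjects co-assigned after optimal label alignment (maximum-weight
  matching on the contingency table, padded when cluster counts differ).
* **Bootstrap stability.** B = 500 replicates by default; each draws 50% of
  subjects with replacement, collapses duplicates (a subject graph cannot
  contain duplicate nodes; the report records completed/skipped counts),
  rebuilds the graph on the sample and reruns the K selection. The modal K
  and its frequency summarize cluster-number stability. The *stability
  index* of a replicate is its matched label agreement with the full-sample
  solution restricted to the sampled subjects at the modal K — a
  definition chosen here because a per-K mean ± SD summary requires one,
  and matched agreement is the natural choice.

## Biotype characterization

* **Group comparisons.** Welch two-sample t-tests (biotype sizes are
  typically unbalanced) per ROI (node strength: mean z-FC of the ROI to all
  others) and per network block, with Benjamini–Hochberg FDR at q = 0.05
  across units. Zero-variance units with equal means are reported as
  t = 0, p = 1 rather than NaN.
* **Connectivity–symptom correlation.** For M = 6 networks there are
  M(M+1)/2 = 21 unique blocks, ordered within-network first then
  between-network pairs. A within-network Frobenius norm sums squares over
  unique ROI pairs i < j (each edge once); a between-network block uses the
  full rectangular submatrix. Norms are z-scored across subjects within the
  analysis group before Spearman correlation with the clinical score;
  significance is raw p < α/21 (Bonferroni). Missing scores are dropped
  pairwise-complete.
* **Prediction.** Linear ε-SVR (C = 1, ε = 0.1) predicting a clinical score
  from the 21 block norms under leave-one-out cross-validation. Inside each
  training fold the features are standardized and rescaled by their
  *contribution rates* — |Spearman ρ| with the training-fold target,
  normalized to sum to 1 — so no information from the held-out subject
  leaks into the weighting. Subjects with a missing target are excluded.
  Significance comes from a permutation test (default 1000 target
  shuffles, each rerunning the full LOOCV); the p-value is the raw
  proportion of permuted correlations exceeding the observed one, with the
  smoothed variant (k+1)/(n+1) also reported. The 95% CI for Spearman ρ
  uses the Fisher-z approximation tanh(atanh ρ ± 1.96/√(n−3)).

  The LOOCV machinery precomputes fold standardization and feature ranks
  (which depend only on the features) and fits the SVR through the libsvm
  backend directly, with a public-estimator fallback; the test suite
  asserts exact equality of the two routes.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes in a
multi-site FC cohort. Each subject's z-FC matrix is

    Z_s = base + biotype_offset(label_s) + site_offset(site_s) + noise_s

with a block base pattern (within-network z = 0.4, between-network z = 0.1,
typical Fisher-z magnitudes for resting-state FC), a +0.3 offset on every
between-network block involving CON or SMN for the majority biotype,
per-site scalar offsets ~ N(0, 0.05), and symmetric subject noise with
entrywise SD 0.1. Biotype proportions default to 0.25/0.75, stressing the
unbalanced minority/majority split this kind of cohort shows; sites (4) are
assigned uniformly and ages uniformly in 8–35 years. Clinical scores couple
to connectivity through the z-scored Frobenius norms of the offset blocks
(weight 1.0) plus a per-biotype intercept shift (−0.5/+0.5 around a base of
12) and N(0, 0.5) noise, so the majority biotype scores higher on average.
A time-series mode draws multivariate-normal volumes from tanh(Z) projected
to the nearest positive-definite correlation matrix, for testing the FC
construction end to end. Generation refuses offsets that push |z| beyond 6
(implausible connectivity).

The frozen default (`paperlike_default()`: 200 subjects, 40 ROIs, 6
networks, 4 sites, seed 42) is the cohort the acceptance checks run on.

What the generator does **not** emulate: hemodynamics and autocorrelated
BOLD noise, head motion, atlas geometry and ROI size heterogeneity,
scanner-specific covariance structure, non-Gaussian score distributions, or
any age dependence of connectivity. Tests passing on these cohorts show the
pipeline recovers structure of the planted kind at realistic effect sizes;
they do not certify performance on real multi-site data.

## Problem sizes used in the checks

Repeated-fitting checks (multi-seed recovery, bootstrap stability) use
reduced network widths and epoch counts (hidden 128/64 or 64/32, embedding
16, pretraining 15–25 epochs, at most 50–100 training epochs) and a
100-replicate bootstrap; these sizes were chosen so the whole validation
suite runs comfortably on one CPU while leaving the planted structure
clearly recoverable. The calibration of the permutation-SVR pipeline uses
200 null repetitions with 199 permutations at n = 30, and the Bonferroni
screen 200 repetitions at n = 100.

## Known limitations

* The exact architectures of the fusion gate, attention module and target
  distribution are reconstructed minimal designs satisfying the published
  description of the framework; other parametrizations are plausible.
* The graph edge formula is a standard population-graph recipe, not a
  published specification; results can be sensitive to σ and k.
* Silhouette-based K selection on the learned embedding can prefer small K
  when the embedding collapses; the bootstrap check is the guard.
* With very small cohorts (S ≲ 15) the default k = 10 sparsification makes
  the graph nearly complete and the GAE adds little beyond the AE.
* The permutation test reruns the full LOOCV per shuffle and is O(n_perm ·
  n²) SVR fits; for large groups reduce `n_perm` or expect minutes.
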