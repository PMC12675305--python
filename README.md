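# pgdas

Deep clustering of functional-connectivity cohorts into *biotypes* —
data-driven subgroups with shared brain-network patterns — using a
population-graph dual autoencoder, together with the internal validation
and biotype-characterization statistics that belong to such an analysis.

The package is aimed at researchers working with resting-state fMRI
connectomes of heterogeneous clinical populations (the motivating use case
is autism spectrum disorder) who want to go beyond one-shot k-means on raw
connectivity: it couples representation learning to the clustering
objective and folds non-imaging phenotypes (age, acquisition site) into a
subject-level graph.

## The model

Each subject s contributes a Fisher-z FC matrix; its upper triangle
x_s ∈ R^{N(N−1)/2} is a node feature in a population graph whose edges are

    w_uv = exp(−d_uv²/2σ²) · ( 1[site_u = site_v] + 1[|age_u − age_v| ≤ τ] ),

d_uv the correlation distance between feature vectors, sparsified to the 10
strongest neighbours per node. Two encoders learn complementary embeddings:
a dense autoencoder Z_AE compressing x_s, and a graph autoencoder Z_GAE
propagating features with Â = D^(−1/2)(W+I)D^(−1/2) and reconstructing the
adjacency via sigmoid(Z Zᵀ). They are fused through a learnable
per-dimension gate, refined by residual self-attention over subjects, and
clustered by k-means++ with Student-t soft assignments

    q_ij ∝ (1 + ‖z̃_i − μ_j‖²)⁻¹,   p_ij ∝ q_ij² / Σ_i q_ij ,

training end to end on

    L = MSE(X, X̂) + β·BCE(1[W>0], Ŵ) + γ·KL(P‖Q),

with periodic refreshes of the sharpened target P and early stopping when
the hard labels stabilize. The cluster number K is chosen in 2..6 by the
silhouette coefficient on the refined embedding. Downstream, biotypes are
characterized by Welch t-tests with BH-FDR on node strengths and network
blocks, Bonferroni-corrected Spearman correlations between the 21
network-block Frobenius norms and clinical scores, and permutation-tested
linear SVR prediction of scores under leave-one-out cross-validation.

See `docs/methods.md` for the full specification of every component and
the design decisions behind it.

## Worked example

The package ships a synthetic-cohort generator (multi-site FC cohorts with
planted biotypes and connectivity-coupled clinical scores), so the whole
pipeline runs without any data download:

```bash
pgdas simulate --out run/cohort --seed 7 --subjects 100
pgdas build-graph --fc-dir run/cohort/fc \
    --phenotypes run/cohort/phenotypes.csv --out run/graph
pgdas select-k --graph run/graph --seed 11 --out run/selk \
    --k-min 2 --k-max 6
```

which prints

```
wrote cohort of 100 subjects to run/cohort
graph with 100 nodes written to run/graph
best K = 2; silhouettes: K=2: 0.857, K=3: 0.687, K=4: 0.566, K=5: 0.412, K=6: 0.503
```

The silhouette peaks at K = 2 — the generator planted two biotypes in a
25/75 split, the minority one with weaker CON/SMN internetwork
connectivity — and `run/selk/labels.csv` holds the recovered assignment
(here matching the planted labels exactly: clusters of 25 and 75
subjects). Biotype characterization then runs on the labels:

```bash
pgdas stats compare --fc-dir run/cohort/fc \
    --parcellation run/cohort/parcellation.tsv \
    --labels run/selk/labels.csv --out run/stats
```

```
40 ROIs and 9 blocks significant at q=0.05 (groups 0 vs 1)
```

i.e. the planted between-network differences survive FDR correction (all
40 ROI strengths differ because the offsets touch most between-network
blocks; 9 of the 21 network blocks differ). `pgdas validate` bootstraps the K selection and `pgdas stats
predict` runs the permutation-tested SVR prediction of a clinical score;
`pgdas --help` lists all subcommands. Every output directory contains a
`manifest.json` (inputs hashed, config echoed, seed) sufficient to
reproduce it.

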