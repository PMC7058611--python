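# gradmap

Macroscale gradient mapping for connectivity-like data: build affinity
matrices from seed × feature matrices, extract low-dimensional
*gradients* with linear and non-linear spectral embeddings, align
gradient sets across datasets and subjects, and test gradient–map
associations against spatial-autocorrelation-preserving null models.

The package is aimed at connectomics and systems-neuroscience workflows
(functional or structural connectivity, microstructural covariance),
but every operation is a generic graph/manifold method and works on any
similarity-structured data.

## The method

Given an input matrix X ∈ ℝⁿˣᵖ whose rows are the feature profiles of n
seed regions, the pipeline is:

1. **Sparsification** — per row, keep only the top fraction of entries
   (e.g. the strongest 10% of connections), zeroing the rest.
2. **Affinity** — a kernel over seed rows yields a non-negative
   symmetric A ∈ ℝⁿˣⁿ. Kernels: Gaussian
   `A(i,j) = exp(−γ‖xᵢ−xⱼ‖²)`, cosine similarity, normalized angle
   `1 − cos⁻¹(cossim)/π`, Pearson and Spearman correlation (negative
   similarities clamped to zero by default), or a precomputed affinity.
3. **Embedding** — one of
   * PCA: scores U·S of the column-demeaned X_d = USVᵀ,
   * Laplacian eigenmaps (LE): eigenvectors of L g = λ D g with
     L = D − A, smallest non-trivial eigenvalues first,
   * diffusion maps (DM): top non-stationary eigenvectors of
     P_α = D_α⁻¹ W_α with W_α = D^{−α} A D^{−α}, each scaled by λᵗ
     (or λ/(1−λ) at t = 0). α = 0.5 — the field's default —
     approximates Fokker–Planck diffusion.

   The columns of the result 𝒢 ∈ ℝⁿˣᵐ are the gradients: smooth axes
   ordering seeds by feature similarity.
4. **Alignment** — orthogonal Procrustes (pairwise or generalized, with
   optional out-of-sample template) or joint embedding of the block
   affinity matrix 𝒥 whose off-diagonal blocks are cross-dataset
   affinities.
5. **Inference** — spin permutations (uniform SO(3) rotations of a
   spherical registration, nearest-neighbor re-sampling) or Moran
   spectral randomization (loading randomization on the eigenvectors of
   the doubly-centered spatial weight matrix; the singleton procedure
   preserves Moran's I exactly), with empirical p-values.

A seedable synthetic-data module generates planted-manifold
connectomes, icospheres, spatially autocorrelated fields and two-group
cohorts, so the whole toolbox runs and is tested without any external
data.

## Worked example

```python
import gradmap as gm
from scipy.stats import spearmanr

# connectome with a known 1-d latent axis
X, theta = gm.planted_gradient_connectome(n_seeds=100, noise_sd=0.05, seed=7)

res = gm.fit_gradients(X, gm.KernelSpec("cosine"), method="dm",
                       m=5, keep_fraction=0.1)
rho = spearmanr(res.gradients[:, 0], theta[:, 0]).statistic
print(res.lambdas[:3], abs(rho))
```

prints

```
[0.99312108 0.97447366 0.93930715] 0.9992919291929192
```

— the first diffusion-map gradient orders the 100 seeds along the
planted latent axis with |Spearman ρ| ≈ 0.999.

The same pipeline from the shell:

```sh
gradmap synth connectome --n-seeds 100 --seed 7 --out X.csv
gradmap fit --input X.csv --kernel cosine --approach dm \
        --n-components 5 --keep-fraction 0.1 --output gradients.csv
```

Each output gets a `.prov.json` sidecar with the package version, the
full parameter set and input checksums. `examples/` contains narrative
scripts for each capability (fitting, alignment, joint embedding, spin
tests, Moran randomization).

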