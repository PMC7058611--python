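# Methods

This note records the models implemented, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions that make results reproducible.

## Input model and affinities

The unit of analysis is a matrix X ∈ ℝⁿˣᵖ: one row per seed region, one
column per feature (typically connectivity with p target regions; when
seeds and targets coincide, X is square and, for non-directional
measures, symmetric). Row-wise sparsification keeps, per row, the
k = ⌈keep_fraction · p⌉ largest entries and zeroes the rest; ties keep
the lowest column index so the operation is deterministic. The
parameter is named `keep_fraction` (fraction *retained*) because the
word "sparsity" is used in the literature for both the kept and the
discarded fraction; `sparsity = 1 − keep_fraction` is accepted as an
alias. The diagonal of a square matrix is treated like any other entry
during thresholding. Sparsification precedes the kernel, matching the
standard workflow (threshold the connectivity profile, then measure
profile similarity).

Five kernels map row pairs to affinities; cosine-family kernels
(cosine, normalized angle, Pearson, Spearman) are exact algebraic
transforms of each other (Pearson = cosine of demeaned rows, Spearman =
Pearson of average ranks), which the test suite exploits as an
invariant. Negative similarities are clamped to zero by default — the
standard mitigation, and a requirement for the spectral embeddings,
which assume a non-negative affinity. The affinity diagonal is set to
exactly 1 for these kernels (self-similarity is exact by definition;
computing it numerically and then taking arccos loses ~1e-8 near 1).

The Gaussian γ defaults to `1 / (2 · median ‖xᵢ−xⱼ‖²)` over at most
1000 pairs subsampled with a fixed internal seed: the median heuristic
is scale-free and the fixed seed keeps the default deterministic.

## Embeddings

**PCA** factorizes the column-demeaned X and returns scores U·S with
variance fractions s²/Σs².

**Laplacian eigenmaps** solves L g = λ D g through the symmetric
conjugate L_S = D^{−1/2} L D^{−1/2} (same spectrum; g = D^{−1/2} y),
discarding the trivial λ = 0 constant eigenvector. Gradient columns are
normalized to unit Euclidean norm, which makes the embedding invariant
to positive rescaling of A — the D-norm convention (gᵀDg = 1) would
not be. `normalized=True` returns the eigenvectors of L_S itself.

**Diffusion maps** use the Coifman–Lafon density normalization
W_α = D^{−α} A D^{−α} and the row-stochastic operator P_α = D_α^{−1} W_α.
α interpolates between maximal influence of sampling density (α = 0,
the random-walk / normalized-Laplacian case) and none (α = 1,
Laplace–Beltrami); the default α = 0.5 (Fokker–Planck) is the
near-universal choice in the gradient literature. Eigenvectors are
computed via the symmetric conjugate and unit-normalized; the
stationary λ = 1 vector is dropped; coordinates are scaled by λᵗ.
`diffusion_time = 0` selects λ/(1−λ), the multi-scale convention that
integrates the diffusion over all times — the time parameter has no
canonical default, and this choice keeps λᵗ available for t > 0.

Determinism: every eigenvector is flipped so its largest-magnitude
entry is positive (ties at the lowest index). A disconnected affinity
graph raises an error naming the component count rather than silently
embedding per component; zero-degree rows are rejected separately.
Dense solvers are used up to n = 1000, iterative (Lanczos with a
seed-derived start vector, tolerance 1e-10) beyond.

## Alignment

Orthogonal Procrustes allows reflections: sign flips of individual
eigenvectors are precisely the degeneracy alignment exists to repair,
so restricting to proper rotations would be self-defeating. Centering
and isotropic scaling are off by default (spectral gradients are
already commensurate); when enabled, both sets are centered/normalized
before the rotation is estimated and the aligned output is returned in
the target's frame. Generalized Procrustes aligns all sets to a
reference and replaces it by the mean of the aligned sets, seeding the
reference with the first set or a user-supplied out-of-sample template;
it stops after `n_iter` (default 10) iterations or when the total
disparity changes by < 1e-10 relative. The reference is not re-centered
between iterations. The disparity sequence is non-increasing and is
asserted as such in the tests.

Joint embedding builds the block affinity 𝒥 by applying the kernel to
the row-concatenation of the (sparsified) inputs — for pairwise row
kernels this *is* the block matrix of within- and between-dataset
affinities — then embeds with LE or DM and slices the rows back per
dataset. No per-block normalization is applied beyond the kernel. The
λᵗ scaling of joint DM uses the joint spectrum. Inputs must share
feature columns; PCA has no joint form here.

## Null models

**Spin permutations** draw Haar-uniform rotations of SO(3) by the
quaternion method (four standard normals, normalized; always det +1,
re-orthonormalized to push round-off below 1e-12), rotate the sphere's
vertex coordinates, and re-sample each rotated vertex from its nearest
neighbor on the original sphere. Surrogate values are therefore always
a re-indexing of the observed values, and the identity rotation is a
fixed point. Masked source vertices (e.g. a medial wall) propagate
their masked status through the nearest-neighbor map. Bilateral data
are not treated specially: each hemisphere's sphere is spun with its
own call; mirrored-rotation schemes for contralateral hemispheres exist
but are not implemented.

**Moran spectral randomization** builds the spatial weight matrix on
the mesh's 1-ring adjacency with inverse-distance (default) or binary
weights, doubly centers it, and eigendecomposes; eigenvectors with
numerically zero eigenvalue (|λ| < 1e-10 · max|λ|) are dropped, leaving
the orthonormal Moran eigenvector maps M. The map's loadings
r_k = Mₖ·(u−ū)/‖u−ū‖ (Pearson correlations, which for centered
unit-norm columns reduce to scaled projections) reconstruct the map
exactly as u = ū + σ_u √(l−1) M r when u lies in the span of M — this
identity pins the normalization, with σ_u the sample standard deviation
(ddof = 1). The singleton procedure flips each loading's sign
independently, preserving mean, sd, and Moran's I exactly (Moran's I of
a centered map is Σλₖaₖ²/Σaₖ², invariant under sign flips); its
capacity of 2^(l−1) unique draws is enforced. The pair procedure
rotates loadings two at a time by a uniform phase, pairing eigenvectors
*adjacent in the eigenvalue ordering*: the rotation redistributes
qᵢⱼ² = vᵢ² + vⱼ² within the pair, so pairing near-equal eigenvalues is
what keeps Moran's I approximately preserved (measured: within 0.1–8%
relative depending on smoothness). Pairing arbitrary eigenvectors would
instead shrink the expected I toward the spectrum mean (≈ I/2 for
smooth maps) and was rejected for that reason. An odd last element
falls back to a singleton flip. Masked vertices are deleted from the
weight matrix before double-centering and excluded from all Moran
statistics; masked positions in MSR surrogates carry the original
values and stay flagged.

Empirical p-values use the (1 + k)/(1 + n) estimator (the observed
statistic counts as a member of its own null), so p is never exactly 0;
two-tailed p is 2·min(left, right) capped at 1.

## Synthetic data

`planted_gradient_connectome` samples latent positions θᵢ uniformly on
[0,1]^d (d = 1 or 2) and sets X = exp(−‖θᵢ−θⱼ‖/τ) plus symmetric
Gaussian noise, unit diagonal. The exponential (rather than Gaussian)
similarity decay has heavier tails, which yields a single dominant,
cleanly recoverable gradient. Defaults (n = 100, τ = 0.2, noise sd
0.05) give a problem comparable in difficulty to a well-behaved
group-average connectome: the canonical pipeline (top-10% rows, cosine
kernel, DM or LE) recovers θ with |Spearman ρ| > 0.99.
`smooth_field` iterates 1-ring neighbor averaging on white noise and
re-standardizes; `make_icosphere` provides spheres of 10·4ˢ+2 vertices;
`two_group_gradients` shares one latent manifold across subjects with
independent noise and an optional contraction of group B's latent range.

What these generators do **not** emulate: realistic fMRI noise spectra
and motion artifacts, hemispheric structure and a medial wall,
inter-subject registration error, or the heavy-tailed degree
distributions of empirical connectomes. Passing tests demonstrate the
correctness and calibration of the algorithms under controlled spatial
structure, not end-to-end performance on real scans.

## Problem sizes used in the checks

The acceptance checks run at desk scale: kernel oracles on 6×5
matrices, embeddings on graphs of 3–100 nodes, null models on 642-vertex
icospheres, and the spin-test calibration as 200 repetitions of a
250-permutation test (nominal α = 0.05; the empirical rejection rate is
required to fall inside the exact 99% binomial interval). These sizes
were chosen so the whole suite runs in minutes on one CPU while keeping
every statistical check adequately powered.

## Known limitations

- No out-of-sample extension (Nyström) for embedding new seeds into an
  existing gradient space; no t-SNE/UMAP-style embeddings.
- Spin permutations require a genuinely spherical registration; MSR is
  the fallback for arbitrary meshes.
- The MSR triplet procedure and Gaussian spatial-weighting scheme are
  not implemented.
- FreeSurfer binary surfaces, CIFTI and volumetric NIfTI are out of
  scope; supported formats are delimited text, MatrixMarket, ASCII PLY
  and GIFTI.
- Generalized Procrustes convergence is declared by disparity change;
  no global optimality guarantee exists (the problem is non-convex),
  though in practice rotated copies of a common configuration converge
  to machine precision.
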