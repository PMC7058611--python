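"""Fit connectivity gradients from a planted-manifold connectome.

Builds a synthetic connectome whose seeds lie on a known 1-d latent
axis, runs the standard pipeline (top-10% row sparsification, cosine
affinity, diffusion-map embedding), and scores how well the first
gradient recovers the planted axis.
"""

import numpy as np
from scipy.stats import spearmanr

import gradmap as gm

X, theta = gm.planted_gradient_connectome(n_seeds=100, noise_sd=0.05, seed=7)
print(f"connectome: {X.n_seeds} seeds x {X.n_features} features")

res = gm.fit_gradients(
    X, gm.KernelSpec("cosine"), method="dm", m=5, keep_fraction=0.1
)
print(f"gradients: {res.gradients.shape}, eigenvalues: {np.round(res.lambdas, 4)}")

rho = spearmanr(res.gradients[:, 0], theta[:, 0]).statistic
print(f"|Spearman rho| between gradient 1 and the planted latent: {abs(rho):.4f}")
# ~0.999: the first diffusion-map gradient orders seeds almost exactly
# along the latent axis the connectome was built from.
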