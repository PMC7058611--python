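"""Gradient extraction: PCA, Laplacian eigenmaps, and diffusion maps.

Each method maps n seeds into an m-dimensional space (m << p) whose
columns — the *gradients* — are smooth axes of variation ordering seeds
by feature similarity.

* PCA factorizes the column-demeaned input X_d = U S V^T and returns the
  scores U S (a linear embedding).
* Laplacian eigenmaps (LE) solves the generalized eigenproblem
  L g = lambda D g with L = D - A, keeping the eigenvectors of the m
  smallest non-trivial eigenvalues.
* Diffusion maps (DM) embeds the anisotropic diffusion operator
  P_alpha = D_alpha^{-1} W_alpha with W_alpha = D^{-alpha} A D^{-alpha},
  keeping the top non-stationary eigenvectors scaled by lambda^t (or by
  lambda/(1-lambda) when t = 0, the automatic-scaling convention).

The alpha-normalization uses the standard Coifman–Lafon exponent
D^{-alpha} A D^{-alpha}: alpha = 0 reduces to the random-walk
(normalized-Laplacian) operator, alpha = 1 approximates the
Laplace–Beltrami operator, and alpha = 0.5 — the default throughout the
gradient literature — approximates Fokker–Planck diffusion.

Eigenvector sign is canonicalized (largest-magnitude entry positive) so
results are deterministic; disconnected affinity graphs are an error
rather than a silent per-component embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
from scipy.sparse.csgraph import connected_components

from . import errors
from .affinity import KernelSpec, compute_affinity, sparsify_rows
from .io import AffinityMatrix, FeatureMatrix

__all__ = [
    "GradientResult",
    "pca_embedding",
    "laplacian_eigenmaps",
    "diffusion_maps",
    "fit_gradients",
    "canonical_sign",
]

# above this size the dense eigensolver is replaced by an iterative one
_DENSE_LIMIT = 1000


@dataclass
class GradientResult:
    """Low-dimensional embedding of n seeds.

    Attributes
    ----------
    gradients
        n x m matrix; column k is gradient k.
    lambdas
        Eigen/singular values in the producing method's own order
        (PCA/DM: non-increasing relevance; LE: ascending eigenvalues).
    method
        ``"pca"``, ``"le"`` or ``"dm"``.
    params
        Method parameters used.
    variance_explained
        Fraction of variance per component (PCA only).
    """

    gradients: np.ndarray
    lambdas: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    variance_explained: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if not np.all(np.isfinite(self.gradients)):
            raise errors.NonFiniteError("gradients contain NaN or Inf")

    @property
    def n_seeds(self) -> int:
        return self.gradients.shape[0]

    @property
    def n_components(self) -> int:
        return self.gradients.shape[1]


def canonical_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive.

    Ties resolve to the lowest row index (argmax returns the first
    maximum), making the convention deterministic.
    """
    vectors = np.array(vectors, dtype=float)
    for k in range(vectors.shape[1]):
        col = vectors[:, k]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            vectors[:, k] = -col
    return vectors


def _as_affinity_values(A) -> np.ndarray:
    if isinstance(A, AffinityMatrix):
        return A.values
    arr = np.asarray(A, dtype=float)
    AffinityMatrix(arr)  # validate symmetry / non-negativity / finiteness
    return arr


def _check_connected(A: np.ndarray) -> np.ndarray:
    """Return the degree vector; raise on zero-degree nodes or disconnection."""
    deg = A.sum(axis=1)
    zero = np.flatnonzero(deg == 0)
    if zero.size:
        raise errors.ZeroDegreeError(f"node {zero[0]} has zero degree")
    n_comp, _ = connected_components(
        scipy.sparse.csr_matrix(A != 0), directed=False
    )
    if n_comp > 1:
        raise errors.DisconnectedGraphError(
            f"affinity graph has {n_comp} connected components; expected 1"
        )
    return deg


def _eigh_smallest(S, k: int, seed: int = 0):
    """k algebraically smallest eigenpairs of dense/sparse symmetric S."""
    n = S.shape[0]
    if n <= _DENSE_LIMIT:
        S = S.toarray() if scipy.sparse.issparse(S) else S
        w, v = scipy.linalg.eigh(S)
        return w[:k], v[:, :k]
    v0 = np.random.default_rng(seed).standard_normal(n)
    w, v = scipy.sparse.linalg.eigsh(S, k=k, sigma=0, which="LM", v0=v0, tol=1e-10)
    order = np.argsort(w)
    return w[order], v[:, order]


def _eigh_largest(S, k: int, seed: int = 0):
    """k algebraically largest eigenpairs, descending."""
    n = S.shape[0]
    if n <= _DENSE_LIMIT:
        S = S.toarray() if scipy.sparse.issparse(S) else S
        w, v = scipy.linalg.eigh(S)
        return w[::-1][:k], v[:, ::-1][:, :k]
    v0 = np.random.default_rng(seed).standard_normal(n)
    w, v = scipy.sparse.linalg.eigsh(S, k=k, which="LA", v0=v0, tol=1e-10)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


def pca_embedding(X, m: int) -> GradientResult:
    """Principal component scores of the column-demeaned input.

    Gradients are the first m columns of U S from the SVD X_d = U S V^T;
    ``variance_explained[k] = s_k^2 / sum(s^2)``.
    """
    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    n, p = values.shape
    if not (1 <= m <= min(n - 1, p)):
        raise errors.ComponentCountError(
            f"m must satisfy 1 <= m <= min(n-1, p) = {min(n - 1, p)}, got {m}"
        )
    Xd = values - values.mean(axis=0, keepdims=True)
    U, s, _ = scipy.linalg.svd(Xd, full_matrices=False)
    if s[0] <= 1e-12 * max(n, p):
        raise errors.ConstantInputError("input matrix is constant; PCA undefined")
    scores = canonical_sign(U[:, :m]) * s[:m]
    total = float(np.sum(s**2))
    return GradientResult(
        gradients=scores,
        lambdas=s[:m],
        method="pca",
        params={"m": m},
        variance_explained=s[:m] ** 2 / total,
    )


def laplacian_eigenmaps(
    A, m: int, normalized: bool = False, seed: int = 0
) -> GradientResult:
    """Laplacian-eigenmaps embedding of an affinity matrix.

    Solves L g = lambda D g (L = D - A) and returns the eigenvectors of
    the m smallest eigenvalues after discarding the trivial constant
    eigenvector at lambda = 0; ``lambdas`` are ascending. With
    ``normalized=True`` the eigenvectors of the symmetric normalized
    Laplacian L_S = D^{-1/2} L D^{-1/2} are returned instead (same
    spectrum, vectors not divided by sqrt-degree).
    """
    Av = _as_affinity_values(A)
    n = Av.shape[0]
    if not (1 <= m <= n - 1):
        raise errors.ComponentCountError(
            f"m must satisfy 1 <= m <= n-1 = {n - 1}, got {m}"
        )
    deg = _check_connected(Av)
    # generalized problem via the symmetric conjugate:
    #   L_S y = lambda y,  g = D^{-1/2} y
    d_isqrt = 1.0 / np.sqrt(deg)
    Ls = -(Av * d_isqrt[:, None]) * d_isqrt[None, :]
    np.fill_diagonal(Ls, Ls.diagonal() + 1.0)
    Ls = 0.5 * (Ls + Ls.T)
    w, y = _eigh_smallest(Ls, m + 1, seed=seed)
    w = np.maximum(w, 0.0)  # clip tiny negative round-off at lambda=0
    vecs = y if normalized else y * d_isqrt[:, None]
    # unit-norm columns: makes the embedding invariant to scaling of A
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    grads = canonical_sign(vecs[:, 1 : m + 1])
    return GradientResult(
        gradients=grads,
        lambdas=w[1 : m + 1],
        method="le",
        params={"m": m, "normalized": normalized},
    )


def diffusion_maps(
    A, m: int, alpha: float = 0.5, diffusion_time: float = 0.0, seed: int = 0
) -> GradientResult:
    """Diffusion-map embedding of an affinity matrix.

    Density-normalizes the affinity, W_alpha = D^{-alpha} A D^{-alpha},
    forms the row-stochastic operator P_alpha = D_alpha^{-1} W_alpha,
    and embeds with its top eigenvectors (stationary lambda = 1 vector
    omitted), each scaled by lambda^t. ``diffusion_time`` t = 0 selects
    the automatic scaling lambda / (1 - lambda), which integrates over
    all diffusion scales.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if diffusion_time < 0:
        raise ValueError(f"diffusion_time must be >= 0, got {diffusion_time}")
    Av = _as_affinity_values(A)
    n = Av.shape[0]
    if not (1 <= m <= n - 1):
        raise errors.ComponentCountError(
            f"m must satisfy 1 <= m <= n-1 = {n - 1}, got {m}"
        )
    deg = _check_connected(Av)
    if alpha > 0:
        d_alpha = deg**-alpha
        W = (Av * d_alpha[:, None]) * d_alpha[None, :]
    else:
        W = Av.copy()
    deg_w = W.sum(axis=1)
    # P = D_w^{-1} W shares its spectrum with the symmetric conjugate
    # S = D_w^{-1/2} W D_w^{-1/2}; eigvec(P) = D_w^{-1/2} eigvec(S).
    dw_isqrt = 1.0 / np.sqrt(deg_w)
    S = (W * dw_isqrt[:, None]) * dw_isqrt[None, :]
    S = 0.5 * (S + S.T)
    w, y = _eigh_largest(S, m + 1, seed=seed)
    vecs = y * dw_isqrt[:, None]
    # unit-norm eigenvectors before sign fixing and spectral scaling
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    lam = np.clip(w[1 : m + 1], -1.0, 1.0 - 1e-15)
    grads = canonical_sign(vecs[:, 1 : m + 1])
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    return GradientResult(
        gradients=grads * scale,
        lambdas=lam,
        method="dm",
        params={"m": m, "alpha": alpha, "diffusion_time": diffusion_time},
    )


def fit_gradients(
    X,
    spec: KernelSpec = None,
    method: str = "dm",
    m: int = 10,
    keep_fraction: float = None,
    sparsity: float = None,
    **method_params,
) -> GradientResult:
    """End-to-end gradient fit: sparsify rows, build the affinity, embed.

    The PCA branch operates on the (sparsified) feature matrix itself —
    its gradients are scores of X_d, not of the affinity — while LE and
    DM embed the kernel affinity.
    """
    if method not in ("pca", "le", "dm"):
        raise ValueError(f"method must be pca, le or dm, got {method!r}")
    if spec is None:
        spec = KernelSpec()
    Xs = sparsify_rows(X, keep_fraction=keep_fraction, sparsity=sparsity)
    if method == "pca":
        return pca_embedding(Xs, m)
    A = compute_affinity(Xs, spec)
    if method == "le":
        return laplacian_eigenmaps(A, m, **method_params)
    return diffusion_maps(A, m, **method_params)
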