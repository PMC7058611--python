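"""Aligning gradient sets across datasets or subjects.

Gradients computed independently for two datasets are not directly
comparable: eigenvalue multiplicity can reorder components and the
eigenvector sign is arbitrary. Two remedies are provided.

*Procrustes analysis* finds the orthogonal transform (rotation, with
reflections allowed — sign flips are exactly the pathology to fix) that
best superimposes a source gradient set onto a target; the generalized
form iteratively aligns N sets to an evolving mean reference, optionally
seeded by an out-of-sample template.

*Joint embedding* instead embeds all datasets simultaneously through the
block affinity matrix J whose diagonal blocks are within-dataset
affinities and off-diagonal blocks cross-dataset affinities (all built
with the same kernel, which requires identical feature columns across
inputs). Slicing the joint gradients row-wise gives per-dataset
embeddings that live in a shared space by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import scipy.linalg

from . import errors
from .affinity import KernelSpec, compute_affinity, sparsify_rows
from .embedding import GradientResult, diffusion_maps, laplacian_eigenmaps
from .io import FeatureMatrix

__all__ = [
    "ProcrustesTransform",
    "procrustes_align",
    "generalized_procrustes",
    "joint_embedding",
]


@dataclass
class ProcrustesTransform:
    """Orthogonal map (plus optional scale/translation) aligning a source
    gradient set onto a target: aligned = scale * (source - center) @ rotation
    + translation."""

    rotation: np.ndarray
    scale: float = 1.0
    translation: Optional[np.ndarray] = None
    center: Optional[np.ndarray] = None

    def apply(self, G: np.ndarray) -> np.ndarray:
        out = np.asarray(G, dtype=float)
        if self.center is not None:
            out = out - self.center
        out = self.scale * (out @ self.rotation)
        if self.translation is not None:
            out = out + self.translation
        return out


def _gradients_of(G) -> np.ndarray:
    return G.gradients if isinstance(G, GradientResult) else np.asarray(G, dtype=float)


def _wrap_like(template, gradients: np.ndarray) -> GradientResult:
    if isinstance(template, GradientResult):
        return GradientResult(
            gradients=gradients,
            lambdas=template.lambdas.copy(),
            method=template.method,
            params=dict(template.params, aligned=True),
            variance_explained=template.variance_explained,
        )
    return GradientResult(
        gradients=gradients,
        lambdas=np.full(gradients.shape[1], np.nan),
        method="procrustes",
        params={"aligned": True},
    )


def procrustes_align(
    source, target, center: bool = False, scale: bool = False
):
    """Orthogonal Procrustes superimposition of ``source`` onto ``target``.

    Finds the orthogonal matrix (reflections permitted) minimizing the
    Frobenius distance ``||source @ R - target||_F``; with ``center``
    and/or ``scale``, both sets are first centered / normalized and the
    output is mapped into the target's frame. Returns the aligned
    gradients and the fitted :class:`ProcrustesTransform`.
    """
    Gs = _gradients_of(source)
    Gt = _gradients_of(target)
    if Gs.shape != Gt.shape:
        raise errors.ShapeMismatchError(
            f"source {Gs.shape} and target {Gt.shape} must have identical shape"
        )
    mu_s = Gs.mean(axis=0) if center else None
    mu_t = Gt.mean(axis=0) if center else None
    As = Gs - mu_s if center else Gs
    At = Gt - mu_t if center else Gt
    if scale:
        ns, nt = np.linalg.norm(As), np.linalg.norm(At)
        if ns == 0 or nt == 0:
            raise errors.ConstantInputError("cannot scale a zero gradient set")
        As, At = As / ns, At / nt

    M = As.T @ At
    if center and scale and np.linalg.matrix_rank(M) < M.shape[0]:
        warnings.warn(
            "rank-deficient cross-covariance; Procrustes rotation is not unique",
            RuntimeWarning,
            stacklevel=2,
        )
    U, _, Vt = scipy.linalg.svd(M)
    R = U @ Vt

    s = (nt / ns) if scale else 1.0
    transform = ProcrustesTransform(
        rotation=R, scale=s, translation=mu_t, center=mu_s
    )
    aligned = transform.apply(Gs)
    return _wrap_like(source, aligned), transform


def generalized_procrustes(
    gradient_sets: Sequence,
    n_iter: int = 10,
    reference=None,
    center: bool = False,
    scale: bool = False,
    tol: float = 1e-10,
) -> List[GradientResult]:
    """Iterative alignment of N gradient sets to a common mean reference.

    Each iteration aligns every set to the current reference, then
    replaces the reference by the mean of the aligned sets. The first
    reference is ``reference`` if given (template mode — e.g. a
    group-level gradient from a hold-out sample), otherwise the first
    set. Iteration stops at ``n_iter`` or when the total disparity
    ``sum_k ||aligned_k - ref||_F^2`` changes by less than ``tol``
    relative.
    """
    if len(gradient_sets) == 0:
        raise errors.ShapeMismatchError("need at least one gradient set")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    mats = [_gradients_of(g) for g in gradient_sets]
    shape = mats[0].shape
    for k, Gk in enumerate(mats):
        if Gk.shape != shape:
            raise errors.ShapeMismatchError(
                f"gradient set {k} has shape {Gk.shape}, expected {shape}"
            )
    ref = _gradients_of(reference) if reference is not None else mats[0]
    if ref.shape != shape:
        raise errors.ShapeMismatchError(
            f"reference has shape {ref.shape}, expected {shape}"
        )

    aligned = mats
    prev_disparity = np.inf
    for _ in range(n_iter):
        aligned = [
            procrustes_align(Gk, ref, center=center, scale=scale)[0].gradients
            for Gk in mats
        ]
        ref = np.mean(aligned, axis=0)
        disparity = float(sum(np.sum((Ak - ref) ** 2) for Ak in aligned))
        if prev_disparity - disparity <= tol * max(prev_disparity, 1e-30):
            break
        prev_disparity = disparity

    return [_wrap_like(g, Ak) for g, Ak in zip(gradient_sets, aligned)]


def joint_embedding(
    datasets: Sequence,
    spec: KernelSpec = None,
    method: str = "dm",
    m: int = 10,
    keep_fraction: float = None,
    sparsity: float = None,
    **method_params,
) -> List[GradientResult]:
    """Simultaneous spectral embedding of several datasets.

    Assembles the joint affinity J over the row-concatenation of all
    (optionally row-sparsified) inputs — its diagonal blocks are the
    within-dataset affinities and its off-diagonal blocks the
    cross-dataset affinities under the same kernel — embeds J with LE or
    DM, and slices the joint gradients back into per-dataset results.
    All inputs must share the same feature columns.
    """
    if method not in ("le", "dm"):
        raise ValueError("joint embedding supports only le and dm")
    if len(datasets) == 0:
        raise errors.ShapeMismatchError("need at least one dataset")
    if spec is None:
        spec = KernelSpec()
    mats = [X.values if hasattr(X, "values") else np.asarray(X, float) for X in datasets]
    p = mats[0].shape[1]
    for k, Xk in enumerate(mats):
        if Xk.shape[1] != p:
            raise errors.FeatureMismatchError(
                f"dataset {k} has {Xk.shape[1]} features, expected {p}: joint "
                "embedding can only be used if the input matrices share features"
            )
    sizes = [Xk.shape[0] for Xk in mats]
    sparse_mats = [
        sparsify_rows(
            FeatureMatrix(Xk), keep_fraction=keep_fraction, sparsity=sparsity
        ).values
        for Xk in mats
    ]
    joint = compute_affinity(np.vstack(sparse_mats), spec)
    if method == "le":
        res = laplacian_eigenmaps(joint, m, **method_params)
    else:
        res = diffusion_maps(joint, m, **method_params)

    out = []
    offset = 0
    for k, nk in enumerate(sizes):
        out.append(
            GradientResult(
                gradients=res.gradients[offset : offset + nk],
                lambdas=res.lambdas.copy(),
                method=res.method,
                params=dict(res.params, joint=True, dataset=k),
            )
        )
        offset += nk
    return out
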