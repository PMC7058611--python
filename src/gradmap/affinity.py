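"""Affinity construction: row sparsification and similarity kernels.

A seed-by-feature matrix X is turned into a square symmetric non-negative
affinity matrix A in two steps: optional row-wise sparsification (keep
only each seed's strongest feature weights) followed by a pairwise
similarity kernel over seed rows. Five kernels are provided — Gaussian,
cosine similarity, normalized angle similarity, Pearson correlation and
Spearman rank correlation — plus a pass-through for matrices that are
already affinities.

Kernels that can produce negative similarities (cosine, Pearson,
Spearman) are clamped at zero by default, the standard mitigation in
the gradient literature; normalized angle avoids negatives by mapping
the angle between feature vectors into [0, 1].

On sparsity terminology: ``keep_fraction`` is the fraction of entries
retained per row (keep_fraction=0.1 keeps the top 10%). The equivalent
``sparsity`` parameter (fraction zeroed) is accepted as an alias, with
``sparsity = 1 - keep_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from . import errors
from .io import AffinityMatrix, FeatureMatrix

__all__ = ["KernelSpec", "KERNELS", "sparsify_rows", "compute_affinity"]

KERNELS = (
    "gaussian",
    "cosine",
    "normalized_angle",
    "pearson",
    "spearman",
    "precomputed",
)


@dataclass
class KernelSpec:
    """Kernel choice and parameters for affinity construction.

    Parameters
    ----------
    kernel
        One of ``gaussian``, ``cosine``, ``normalized_angle``,
        ``pearson``, ``spearman``, ``precomputed``.
    gamma
        Inverse width of the Gaussian kernel, A(i,j) = exp(-gamma *
        ||x_i - x_j||^2). Only used by ``gaussian``. When None, defaults
        to 1 / (2 * median squared pairwise distance), estimated over at
        most 1000 seed pairs (deterministically subsampled): a
        scale-free heuristic.
    clamp_negative
        Set negative similarities to zero (default True).
    """

    kernel: str = "normalized_angle"
    gamma: Optional[float] = None
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {KERNELS}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _resolve_keep_fraction(keep_fraction=None, sparsity=None) -> float:
    if keep_fraction is not None and sparsity is not None:
        raise errors.SparsityError("give either keep_fraction or sparsity, not both")
    if sparsity is not None:
        if not (0 <= sparsity < 1):
            raise errors.SparsityError(f"sparsity must be in [0, 1), got {sparsity}")
        return 1.0 - sparsity
    if keep_fraction is None:
        return 1.0
    if not (0 < keep_fraction <= 1):
        raise errors.SparsityError(
            f"keep_fraction must be in (0, 1], got {keep_fraction}"
        )
    return float(keep_fraction)


def sparsify_rows(
    X: FeatureMatrix, keep_fraction: float = None, sparsity: float = None
) -> FeatureMatrix:
    """Zero all but each row's top entries by value.

    Per row, exactly ``k = ceil(keep_fraction * p)`` entries keep their
    value (the k largest); ties are broken by keeping the lowest column
    index. The input is not modified. For a square connectivity matrix
    the diagonal is treated like any other entry.
    """
    frac = _resolve_keep_fraction(keep_fraction, sparsity)
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, p = values.shape
    k = ceil(frac * p)
    if k >= p:
        return FeatureMatrix(values.copy(),
                             getattr(X, "row_ids", None), getattr(X, "col_ids", None))
    out = np.zeros_like(values)
    # stable argsort on negated values: among ties the lowest column wins
    order = np.argsort(-values, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    out[rows, cols] = values[rows, cols]
    return FeatureMatrix(out, getattr(X, "row_ids", None), getattr(X, "col_ids", None))


def _default_gamma(values: np.ndarray) -> float:
    """Median heuristic: gamma = 1 / (2 * median ||x_i - x_j||^2)."""
    n = values.shape[0]
    pairs_i, pairs_j = np.triu_indices(n, k=1)
    if pairs_i.size > 1000:
        # deterministic subsample so the default is reproducible
        rng = np.random.default_rng(0)
        sel = rng.choice(pairs_i.size, 1000, replace=False)
        pairs_i, pairs_j = pairs_i[sel], pairs_j[sel]
    sq = np.sum((values[pairs_i] - values[pairs_j]) ** 2, axis=1)
    med = np.median(sq)
    if med <= 0:
        raise errors.ConstantInputError(
            "median pairwise distance is zero; cannot set default gamma"
        )
    return 1.0 / (2.0 * med)


def _cosine_matrix(values: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(values, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise errors.ZeroNormRowError(
            f"row {bad[0]} has zero norm; angle-based kernel undefined"
        )
    unit = values / norms[:, None]
    C = unit @ unit.T
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)  # self-similarity is exact; arccos is touchy near 1
    return C


def _demean_rows(values: np.ndarray, kernel: str) -> np.ndarray:
    centered = values - values.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(centered, axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise errors.ZeroVarianceRowError(
            f"row {bad[0]} is constant; {kernel} correlation undefined"
        )
    return centered


def compute_affinity(X, spec: KernelSpec = None, **spec_kwargs) -> AffinityMatrix:
    """Build the seed-by-seed affinity matrix from feature rows.

    With ``kernel="precomputed"`` the input must already be square and
    symmetric and is passed through unchanged (aside from optional
    clamping of negative entries).
    """
    if spec is None:
        spec = KernelSpec(**spec_kwargs)
    values = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
    kernel = spec.kernel
    params = {"kernel": kernel, "clamp_negative": spec.clamp_negative}

    if kernel == "precomputed":
        if values.shape[0] != values.shape[1]:
            raise errors.PrecomputedAffinityError(
                f"precomputed affinity must be square, got {values.shape}"
            )
        if not np.allclose(values, values.T, rtol=0, atol=1e-10 * max(1.0, np.abs(values).max())):
            raise errors.PrecomputedAffinityError("precomputed affinity is not symmetric")
        A = values.copy()
    elif kernel == "gaussian":
        gamma = spec.gamma if spec.gamma is not None else _default_gamma(values)
        params["gamma"] = gamma
        sq = np.sum(values**2, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (values @ values.T)
        np.maximum(d2, 0.0, out=d2)
        A = np.exp(-gamma * d2)
    elif kernel == "cosine":
        A = _cosine_matrix(values)
    elif kernel == "normalized_angle":
        A = 1.0 - np.arccos(_cosine_matrix(values)) / np.pi
    elif kernel == "pearson":
        A = _cosine_matrix(_demean_rows(values, "pearson"))
    elif kernel == "spearman":
        ranks = np.apply_along_axis(rankdata, 1, values)  # average ranks for ties
        A = _cosine_matrix(_demean_rows(ranks, "spearman"))
    else:  # pragma: no cover - guarded by KernelSpec
        raise ValueError(kernel)

    A = 0.5 * (A + A.T)  # remove floating-point asymmetry
    if spec.clamp_negative:
        np.maximum(A, 0.0, out=A)
    return AffinityMatrix(A, kernel_name=kernel, params=params)
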