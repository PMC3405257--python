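"""Standardized marker distances and the Gaussian kernels used for averaging.

The squared distance between lines i and i' is

    d2[i, i'] = sum_j (x_ij - x_i'j)^2 / V_j

with V_j the sample (n-1) variance of marker j, and the kernels are

    K_k = exp(-(h_k / q05) * d2),    h in (5, 1, 1/5) by default,

where q05 is the 5th percentile of the off-diagonal d2 values.  h = 5 gives
extremely local basis functions, h = 1/5 a much wider span.  For test-set
prediction the rectangular blocks K(test, train) reuse V_j and q05 computed
on the training lines only, so no test information leaks into the kernel
geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DegenerateInputError

__all__ = [
    "DistanceMatrix",
    "KernelSet",
    "DEFAULT_BANDWIDTHS",
    "distance_matrix",
    "cross_distance",
    "build_kernels",
    "cross_kernels",
]

DEFAULT_BANDWIDTHS = (5.0, 1.0, 0.2)


@dataclass
class DistanceMatrix:
    """Pairwise standardized squared Euclidean distances between lines."""

    d2: np.ndarray
    marker_variances: np.ndarray  # V_j for the markers actually used
    used_columns: np.ndarray  # indices of markers with V_j > 0
    q05: float

    @property
    def n(self) -> int:
        return self.d2.shape[0]


@dataclass
class KernelSet:
    """Gaussian kernels sharing one distance matrix and one q05 scale."""

    bandwidths: tuple
    matrices: list  # one n x n array per bandwidth
    q05: float
    distance: DistanceMatrix | None = None

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n(self) -> int:
        return self.matrices[0].shape[0]

    def to_frames(self, line_ids) -> list:
        """Square DataFrames with line-id headers, for CSV export."""
        return [
            pd.DataFrame(K, index=line_ids, columns=line_ids) for K in self.matrices
        ]


def _standardize_columns(X: np.ndarray, variances: np.ndarray | None = None):
    """Scale columns by 1/sqrt(V_j); drop monomorphic markers (V_j = 0)."""
    X = np.asarray(X, dtype=float)
    if variances is None:
        V = X.var(axis=0, ddof=1)
        used = np.flatnonzero(V > 0)
        if used.size == 0:
            raise DegenerateInputError("all markers are monomorphic; no distances defined")
        if used.size < X.shape[1]:
            warnings.warn(
                f"dropping {X.shape[1] - used.size} monomorphic markers "
                "before distance computation",
                stacklevel=3,
            )
        V = V[used]
    else:
        V = np.asarray(variances, dtype=float)
        used = np.arange(X.shape[1])
    return X[:, used] / np.sqrt(V), V, used


def _pairwise_sq(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    sq_a = np.einsum("ij,ij->i", A, A)
    sq_b = np.einsum("ij,ij->i", B, B)
    d2 = sq_a[:, None] + sq_b[None, :] - 2.0 * (A @ B.T)
    np.maximum(d2, 0.0, out=d2)
    return d2


def distance_matrix(genotypes) -> DistanceMatrix:
    """Standardized squared Euclidean distances between all pairs of lines.

    Accepts a GenotypeMatrix/CovariateMatrix or a plain 2-D array.
    """
    X = genotypes.values if hasattr(genotypes, "values") else np.asarray(genotypes)
    Xs, V, used = _standardize_columns(X)
    d2 = _pairwise_sq(Xs, Xs)
    np.fill_diagonal(d2, 0.0)
    d2 = 0.5 * (d2 + d2.T)
    iu = np.triu_indices(d2.shape[0], k=1)
    q05 = float(np.percentile(d2[iu], 5.0))
    return DistanceMatrix(d2=d2, marker_variances=V, used_columns=used, q05=q05)


def cross_distance(new, train, dist: DistanceMatrix) -> np.ndarray:
    """Rectangular d2(new, train) using the training V_j (leakage-safe)."""
    Xn = new.values if hasattr(new, "values") else np.asarray(new)
    Xt = train.values if hasattr(train, "values") else np.asarray(train)
    scale = np.sqrt(dist.marker_variances)
    A = np.asarray(Xn, dtype=float)[:, dist.used_columns] / scale
    B = np.asarray(Xt, dtype=float)[:, dist.used_columns] / scale
    return _pairwise_sq(A, B)


def build_kernels(dist: DistanceMatrix, bandwidths=DEFAULT_BANDWIDTHS) -> KernelSet:
    """Gaussian kernels exp(-(h/q05) d2) for each bandwidth h.

    With the default decreasing bandwidths the kernels are ordered entrywise
    K1 <= K2 <= K3; every kernel has unit diagonal and is PSD up to
    numerical tolerance.
    """
    hs = tuple(float(h) for h in bandwidths)
    if not hs or any(h <= 0 for h in hs):
        raise ValueError("bandwidths must be a non-empty list of positive scalars")
    if dist.q05 <= 0:
        raise DegenerateInputError(
            "q05 of the pairwise distances is 0 (too many duplicate lines); "
            "deduplicate the genotype matrix"
        )
    mats = [np.exp(-(h / dist.q05) * dist.d2) for h in hs]
    return KernelSet(bandwidths=hs, matrices=mats, q05=dist.q05, distance=dist)


def cross_kernels(d2_new_train: np.ndarray, kernels: KernelSet) -> list:
    """Rectangular kernel blocks K(new, train) on the training q05 scale."""
    return [np.exp(-(h / kernels.q05) * d2_new_train) for h in kernels.bandwidths]
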