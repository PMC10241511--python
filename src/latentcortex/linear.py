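"""Linear latent spaces: spatial-ICA bases and parcellation averaging.

These are the comparison methods for the nonlinear encoder.  A linear basis
is a V x k matrix A (independent-component spatial maps, or parcel
indicators); encoding is the pseudoinverse projection Y = A+ X and
reconstruction is X~ = A Y, the orthogonal projection of X onto the column
space of A.  Typical comparison ranks are 50, 100, 200, 300, and 256.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA

__all__ = ["LinearBasis", "fit_linear_basis", "linear_encode", "linear_reconstruct",
           "COMPARISON_RANKS"]

#: Component counts used when comparing linear bases against the VAE.
COMPARISON_RANKS = (50, 100, 200, 300, 256)


@dataclass
class LinearBasis:
    """V x k basis with a cached pseudoinverse."""

    A: np.ndarray
    method: str  # 'spatial_ica' | 'parcellation' | 'pca'
    k: int
    seed: int | None = None
    pinv: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2 or self.A.shape[1] != self.k:
            raise ValueError(f"A must be (V, {self.k}), got {self.A.shape}")
        if np.any(np.linalg.norm(self.A, axis=0) == 0):
            raise ValueError("basis columns must be non-zero")
        if self.pinv is None:
            self.pinv = np.linalg.pinv(self.A)


def _concat_frames(training_ts) -> np.ndarray:
    """Stack scans into one V x (sum T) matrix."""
    mats = [ts.values if hasattr(ts, "values") else np.asarray(ts)
            for ts in training_ts]
    return np.concatenate(mats, axis=1)


def fit_linear_basis(training_ts, method: str = "spatial_ica", k: int = 256,
                     seed: int = 0, labels=None) -> LinearBasis:
    """Fit a linear basis on training scans.

    ``spatial_ica``: PCA-whitening of the concatenated frames to k dimensions
    followed by FastICA (deflation, tanh contrast) over the spatial axis, so
    the recovered columns are spatially independent maps, scaled to unit
    norm.  ``parcellation``: indicator columns built from the provided
    integer ``labels`` (one parcel id per vertex); the pseudoinverse then
    averages within parcels.  ``pca``: variance-ordered principal-component
    basis (useful for nested-rank comparisons).
    """
    if method == "parcellation":
        if labels is None:
            raise ValueError("parcellation requires per-vertex labels")
        labels = np.asarray(labels)
        ids = np.unique(labels)
        A = np.stack([(labels == i).astype(np.float64) for i in ids], axis=1)
        return LinearBasis(A=A, method=method, k=A.shape[1], seed=None)

    X = _concat_frames(training_ts)  # (V, T_total)
    if X.shape[1] < k:
        raise ValueError(f"need at least k={k} concatenated frames, got {X.shape[1]}")
    rank = min(X.shape)
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank bound {rank}")
    if method == "spatial_ica":
        # samples = vertices, features = time points -> spatially independent
        # component maps in the "sources" matrix
        ica = FastICA(n_components=k, algorithm="deflation", fun="logcosh",
                      whiten="unit-variance", random_state=seed, max_iter=500)
        S = ica.fit_transform(X)  # (V, k)
        A = S / np.linalg.norm(S, axis=0, keepdims=True)
    elif method == "pca":
        Xc = X - X.mean(axis=1, keepdims=True)
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        A = U[:, :k]
    else:
        raise ValueError(f"unknown method {method!r}")
    return LinearBasis(A=A, method=method, k=k, seed=seed)


def linear_encode(X: np.ndarray, basis: LinearBasis) -> np.ndarray:
    """Y = A+ X, the least-squares coefficients of X in the basis."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != basis.A.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} vertices, basis has {basis.A.shape[0]}")
    return basis.pinv @ X


def linear_reconstruct(Y: np.ndarray, basis: LinearBasis) -> np.ndarray:
    """X~ = A Y; composed with :func:`linear_encode` this is the orthogonal
    projection onto span(A), hence idempotent with residuals orthogonal to
    every basis column."""
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] != basis.k:
        raise ValueError(f"Y has {Y.shape[0]} rows, basis has k={basis.k}")
    return basis.A @ Y
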