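"""Non-negative matrix factorization of the region-lesion matrix.

The patients x 129 count matrix X is factorized as X ~ W H with W, H >= 0
and k = 10 patterns, by multiplicative updates under the Frobenius loss
with NNDSVDa initialization.  Basis rows are rescaled to a maximum loading
of 1 (inverse scale absorbed into W), which makes the 0.05
region-affiliation threshold interpretable as "at least 5% of the
pattern's peak loading".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

_EPS = 1e-12


def _nndsvda(X: np.ndarray, k: int) -> tuple:
    """NNDSVD initialization with zeros filled by the matrix mean."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((X.shape[0], k))
    H = np.zeros((k, X.shape[1]))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(S[0]) * np.abs(Vt[0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            norm = n_up * n_vp
            wj, hj = up / max(n_up, _EPS), vp / max(n_vp, _EPS)
        else:
            norm = n_un * n_vn
            wj, hj = un / max(n_un, _EPS), vn / max(n_vn, _EPS)
        W[:, j] = np.sqrt(S[j] * norm) * wj
        H[j] = np.sqrt(S[j] * norm) * hj
    mean = X.mean()
    W[W == 0] = mean
    H[H == 0] = mean
    return W, H


@dataclass
class PatternBasis:
    """Normalized k x n_regions loading matrix with fit metadata."""

    H: np.ndarray
    region_names: Sequence[str]
    scales: np.ndarray                    # row maxima absorbed into W
    n_iter: int
    reconstruction_error: float           # Frobenius norm of the residual
    relative_error: float
    seed: int

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if (self.H < 0).any():
            raise ValueError("basis loadings must be non-negative")
        norms = np.linalg.norm(self.H, axis=1)
        if (norms == 0).any():
            raise ValueError("basis contains an all-zero pattern row")

    @property
    def k(self) -> int:
        return self.H.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.H, columns=list(self.region_names),
            index=[f"pattern_{j + 1}" for j in range(self.k)])

    def hemisphere_of(self, region_hemis: Sequence[str]) -> list:
        """Dominant hemisphere per pattern (ties -> 'bilateral')."""
        hemis = np.asarray(list(region_hemis))
        out = []
        for row in self.H:
            left = row[hemis == "L"].sum()
            right = row[hemis == "R"].sum()
            if np.isclose(left, right):
                out.append("bilateral")
            else:
                out.append("left" if left > right else "right")
        return out


def _frobenius(X, W, H) -> float:
    return float(np.linalg.norm(X - W @ H))


def fit_nmf(X, k: int = 10, seed: int = 0, max_iter: int = 2000,
            tol: float = 1e-6) -> tuple:
    """Factorize a non-negative matrix into k patterns.

    Returns ``(expressions, basis)`` where ``expressions`` is a patients x k
    DataFrame (if X is a DataFrame) and ``basis`` a :class:`PatternBasis`
    with rows normalized to max loading 1.  Multiplicative updates
    guarantee a non-increasing objective; this is asserted every iteration.
    Iteration stops once the relative improvement of the Frobenius error
    drops below ``tol`` or after ``max_iter`` iterations.
    """
    index = None
    region_names = None
    if isinstance(X, pd.DataFrame):
        index = X.index
        region_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("input matrix has negative entries")
    n, r = X.shape
    if k > min(n, r):
        raise ValueError(f"k={k} exceeds the rank bound min{(n, r)}")
    if region_names is None:
        region_names = [f"r{i}" for i in range(r)]

    # fit on a max-normalized copy: makes the solve (and the additive
    # update guard below) exactly invariant to the input's scale
    scale = float(X.max())
    if scale == 0:
        raise ValueError("input matrix is identically zero")
    Xs = X / scale
    W, H = _nndsvda(Xs, k)
    err = _frobenius(Xs, W, H)
    err0 = err if err > 0 else 1.0
    checkpoint = err
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        H *= (W.T @ Xs) / (W.T @ W @ H + _EPS)
        W *= (Xs @ H.T) / (W @ (H @ H.T) + _EPS)
        new_err = _frobenius(Xs, W, H)
        # non-increase up to float round-off on the problem's scale
        if new_err > err * (1 + 1e-9) + 1e-10:
            raise AssertionError(
                f"NMF objective increased at iteration {n_iter}: "
                f"{err} -> {new_err}")
        err = new_err
        if n_iter % 10 == 0:
            if (checkpoint - err) / err0 < tol:
                break
            checkpoint = err
    W *= scale
    err *= scale

    scales = H.max(axis=1)
    scales[scales == 0] = 1.0
    H_norm = H / scales[:, None]
    W_scaled = W * scales[None, :]
    x_norm = float(np.linalg.norm(X))
    basis = PatternBasis(
        H=H_norm, region_names=region_names, scales=scales, n_iter=n_iter,
        reconstruction_error=err,
        relative_error=err / x_norm if x_norm > 0 else 0.0, seed=seed)
    cols = [f"pattern_{j + 1}" for j in range(k)]
    if index is not None:
        expressions = pd.DataFrame(W_scaled, index=index, columns=cols)
    else:
        expressions = pd.DataFrame(W_scaled, columns=cols)
    return expressions, basis


def transform(X_new, basis: PatternBasis):
    """Project new lesion rows onto a fixed basis by row-wise NNLS."""
    index = None
    if isinstance(X_new, pd.DataFrame):
        index = X_new.index
        X_new = X_new.to_numpy(dtype=float)
    else:
        X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if (X_new < 0).any():
        raise ValueError("input matrix has negative entries")
    if X_new.shape[1] != basis.H.shape[1]:
        raise ValueError(
            f"column mismatch: input has {X_new.shape[1]} regions, basis "
            f"has {basis.H.shape[1]}")
    A = basis.H.T  # regions x k
    W = np.vstack([nnls(A, row)[0] for row in X_new])
    cols = [f"pattern_{j + 1}" for j in range(basis.k)]
    if index is not None:
        return pd.DataFrame(W, index=index, columns=cols)
    return pd.DataFrame(W, columns=cols)


def affiliated_regions(basis: PatternBasis, pattern_id: int,
                       threshold: float = 0.05) -> list:
    """Region names whose normalized loading exceeds ``threshold``.

    ``pattern_id`` is 1-based; the result is ordered by descending loading.
    """
    if not 1 <= pattern_id <= basis.k:
        raise ValueError(f"pattern_id must be in 1..{basis.k}")
    row = basis.H[pattern_id - 1]
    sel = np.flatnonzero(row > threshold)
    if sel.size == 0:
        raise ValueError(
            f"no region of pattern {pattern_id} exceeds loading "
            f"{threshold}; lower the threshold")
    order = sel[np.argsort(row[sel])[::-1]]
    return [basis.region_names[i] for i in order]
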