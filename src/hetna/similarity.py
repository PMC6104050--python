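"""Cross-network node similarity from graphlet signature matrices.

The two networks' signature rows are stacked, optionally reduced with
PCA (keeping the smallest r >= 2 components explaining at least the
target variance fraction), and every cross-network pair is scored by
cosine similarity mapped affinely onto [0, 1] via (cos + 1) / 2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .netmodel import SimilarityMatrix

__all__ = ["build_similarity", "select_n_components"]


def select_n_components(explained_variance_ratio: np.ndarray,
                        variance_target: float) -> int:
    """Smallest r >= 2 whose leading components reach the variance target."""
    cum = np.cumsum(explained_variance_ratio)
    r = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    r = max(2, r)
    return min(r, len(explained_variance_ratio))


def build_similarity(sig_g: pd.DataFrame, sig_h: pd.DataFrame,
                     reduction: str = "pca",
                     variance_target: float = 0.9) -> SimilarityMatrix:
    """Pairwise node similarity between two networks' signature matrices.

    Parameters
    ----------
    sig_g, sig_h:
        Signature matrices with identical column layouts (same catalog
        and same ordered color set), one row per node.
    reduction:
        ``"pca"`` (default) or ``"none"`` (the NoPCA variant).
    variance_target:
        Fraction of variance the retained components must explain.
    """
    if sig_g.shape[0] == 0 or sig_h.shape[0] == 0:
        raise ValueError("empty signature matrix")
    if list(sig_g.columns) != list(sig_h.columns):
        raise ValueError("signature matrices have mismatched column layouts")
    if reduction not in ("pca", "none"):
        raise ValueError(f"unknown reduction {reduction!r}")

    X = np.vstack([sig_g.to_numpy(dtype=float), sig_h.to_numpy(dtype=float)])
    if reduction == "pca":
        n_comp = min(X.shape)
        pca = PCA(n_components=n_comp, svd_solver="full")
        Z = pca.fit_transform(X)  # mean-centered projection
        r = select_n_components(pca.explained_variance_ratio_, variance_target)
        Z = Z[:, :r]
    else:
        Z = X

    n_g = sig_g.shape[0]
    A, B = Z[:n_g], Z[n_g:]
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (A @ B.T) / denom
    cos[denom == 0] = 0.0  # zero vectors: cosine defined as 0 -> similarity 0.5
    np.clip(cos, -1.0, 1.0, out=cos)
    sim = (cos + 1.0) / 2.0
    return SimilarityMatrix(list(sig_g.index), list(sig_h.index), sim)
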