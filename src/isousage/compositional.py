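"""Aitchison-geometry toolkit for isoform-usage compositions.

A gene's isoform usage is a composition: a vector of K non-negative
relative abundances summing to one.  Statistical work on compositions is
done on the open simplex under Aitchison geometry, mapped isometrically
to ordinary Euclidean space R^(K-1) by the isometric log-ratio (ilr)
transform.  This module provides closure, zero handling, the clr/ilr
transforms and their inverses, the Aitchison distance, and the fixed
orthonormal (Helmert-type) contrast basis used throughout the package.

All functions accept array-likes and return ``numpy`` arrays; 2-D inputs
are interpreted as one composition per row.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "close",
    "replace_zeros",
    "drop_all_zero_isoforms",
    "helmert_basis",
    "clr",
    "ilr",
    "ilr_inverse",
    "aitchison_distance",
    "perturb",
    "compositional_mean",
]

#: Parts at or below this threshold are treated as "estimated as zero"
#: by :func:`replace_zeros` and :func:`drop_all_zero_isoforms`.  EM
#: iterates approach zero geometrically and only reach exact 0.0 when an
#: isoform has no compatible reads, so a small tolerance is needed to
#: recognise numerically-zero estimates.
ZERO_TOL = 1e-8


def close(v) -> np.ndarray:
    """Normalise a non-negative vector (or rows of a matrix) to sum 1.

    Raises ``ValueError`` on an all-zero or negative input.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("composition parts must be non-negative")
    s = v.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("cannot close an all-zero vector")
    return v / s


def replace_zeros(c, eps: float = 1e-4, zero_tol: float = ZERO_TOL) -> np.ndarray:
    """Replace zero parts by a small positive value ``eps`` and re-close.

    Parts at or below ``zero_tol`` are considered estimated zeros.
    Non-zero parts are perturbed only through the final re-closure.
    ``eps`` defaults to 1e-4; raising it (e.g. to 0.01) damps the
    influence of near-zero usage values on log-ratio distances.
    """
    c = np.asarray(c, dtype=float)
    if np.all(c <= zero_tol):
        raise ValueError("composition has no positive part")
    out = np.where(c <= zero_tol, eps, c)
    return close(out)


def drop_all_zero_isoforms(group0, group1, zero_tol: float = ZERO_TOL):
    """Remove isoforms whose usage is zero in every sample of both groups.

    Parameters
    ----------
    group0, group1 : (J_i, K) array-likes
        Per-sample usage compositions for the two groups.

    Returns
    -------
    (reduced0, reduced1, kept, dropped)
        Row-closed reduced matrices, plus the kept and dropped column
        indices.  If fewer than two isoforms survive, the caller should
        flag the gene untestable.
    """
    g0 = np.atleast_2d(np.asarray(group0, dtype=float))
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    if g0.shape[1] != g1.shape[1]:
        raise ValueError("groups must share the isoform dimension")
    nonzero = (g0 > zero_tol).any(axis=0) | (g1 > zero_tol).any(axis=0)
    kept = np.flatnonzero(nonzero)
    dropped = np.flatnonzero(~nonzero)
    return close(g0[:, kept]), close(g1[:, kept]), kept, dropped


def helmert_basis(K: int) -> np.ndarray:
    """Orthonormal (K-1) x K contrast matrix defining the canonical ilr basis.

    Row i (1-based) contrasts the first i parts against part i+1:
    ``(1/sqrt(i(i+1))) * (1,...,1, -i, 0,...,0)``.  Rows are orthonormal
    and orthogonal to the all-ones vector.
    """
    if K < 2:
        raise ValueError("a contrast basis requires K >= 2")
    V = np.zeros((K - 1, K))
    for i in range(1, K):
        V[i - 1, :i] = 1.0 / np.sqrt(i * (i + 1))
        V[i - 1, i] = -i / np.sqrt(i * (i + 1))
    return V


def clr(c) -> np.ndarray:
    """Centred log-ratio: log parts minus their mean log (rowwise)."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError(
            "clr/ilr require strictly positive parts; apply replace_zeros first"
        )
    lg = np.log(c)
    return lg - lg.mean(axis=-1, keepdims=True)


def ilr(c, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates ``V @ clr(c)`` in R^(K-1).

    ``basis`` is a (K-1, K) orthonormal contrast matrix; defaults to
    :func:`helmert_basis`.
    """
    c = np.asarray(c, dtype=float)
    K = c.shape[-1]
    V = helmert_basis(K) if basis is None else np.asarray(basis, dtype=float)
    return clr(c) @ V.T


def ilr_inverse(z, basis: np.ndarray | None = None) -> np.ndarray:
    """Map ilr coordinates back to the open simplex."""
    z = np.asarray(z, dtype=float)
    d = z.shape[-1]
    V = helmert_basis(d + 1) if basis is None else np.asarray(basis, dtype=float)
    return close(np.exp(z @ V))


def aitchison_distance(x, y) -> float:
    """Aitchison distance: Euclidean norm of clr(x) - clr(y).

    Equals the Euclidean distance between ilr images under any
    orthonormal basis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("compositions must have the same number of parts")
    return float(np.linalg.norm(clr(x) - clr(y), axis=-1))


def perturb(p, x) -> np.ndarray:
    """Aitchison perturbation (the simplex's addition): close(p * x)."""
    return close(np.asarray(p, dtype=float) * np.asarray(x, dtype=float))


def compositional_mean(samples, basis: np.ndarray | None = None) -> np.ndarray:
    """Mean composition in Aitchison geometry.

    The ilr-inverse of the arithmetic mean of ilr coordinates, which
    equals the closed component-wise geometric mean of the samples.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    return ilr_inverse(ilr(X, basis).mean(axis=0), basis)
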