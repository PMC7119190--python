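"""Genomic relationship matrix (VanRaden method I) and structure diagnostics.

``K = W W' / s`` with ``W`` the column-centred dosage matrix and ``s`` the
expected variance sum: ``2 * sum_j p_j (1 - p_j)`` for biallelic 0/1/2
dosages and ``sum_j p_j (1 - p_j)`` for dominant 0/1 scores (one Bernoulli
draw per line instead of two). Population structure is summarised by the
eigendecomposition ``K = U D U'``: plotted coordinates are eigenvectors
scaled by their eigenvalues, and the variance explained by component i is
``D_ii / tr(D)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import Coding, MarkerMatrix, allele_freqs

#: eigenvalues above this (negative) floor are treated as numerical zeros
PSD_TOL = 1e-8


@dataclass(frozen=True)
class GenomicRelationship:
    """Symmetric additive relationship matrix with its line ordering."""

    line_ids: tuple
    K: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "K", K)
        n = len(self.line_ids)
        if K.shape != (n, n):
            raise ValueError(f"K is {K.shape} for {n} lines")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("K is not symmetric (tolerance 1e-10)")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.K)[0])

    def subset(self, line_ids) -> "GenomicRelationship":
        idx = {l: i for i, l in enumerate(self.line_ids)}
        rows = np.array([idx[l] for l in line_ids])
        return GenomicRelationship(tuple(line_ids), self.K[np.ix_(rows, rows)])


@dataclass(frozen=True)
class PCProjection:
    """Principal-component summary of a relationship matrix.

    ``scores[:, i]`` are the coordinates of each line on component i
    (eigenvector times eigenvalue by default); ``eigenvalues`` is the full
    nonincreasing spectrum and ``prop_var`` the per-component share of
    ``tr(D)``.
    """

    line_ids: tuple
    scores: np.ndarray
    eigenvalues: np.ndarray
    prop_var: np.ndarray


def compute_K(m: MarkerMatrix) -> GenomicRelationship:
    """VanRaden method-I additive relationship matrix from imputed markers.

    Parameters
    ----------
    m : MarkerMatrix
        Must contain no missing calls (see
        :func:`gxegblup.markers.impute_missing`) and at least one
        polymorphic marker.
    """
    if m.missing_mask.any():
        raise ValueError("markers contain missing calls; impute first")
    p = allele_freqs(m)
    pq = p * (1.0 - p)
    s = (2.0 if m.coding is Coding.BIALLELIC_012 else 1.0) * pq.sum()
    if s <= 0.0:
        raise ValueError("all markers monomorphic: scaling constant is zero")
    W = m.dosages - m.dosages.mean(axis=0, keepdims=True)
    K = (W @ W.T) / s
    K = 0.5 * (K + K.T)
    return GenomicRelationship(m.line_ids, K)


def pca_K(g: GenomicRelationship, n_components: int | None = None,
          scale: str = "eigenvalue") -> PCProjection:
    """Eigendecomposition of K with scaled component scores.

    Parameters
    ----------
    g : GenomicRelationship
    n_components : int, optional
        Number of score columns to return (default: all).
    scale : {"eigenvalue", "sqrt"}
        ``"eigenvalue"`` multiplies each eigenvector by its eigenvalue
        (the plotting convention used with K = UDU' structure plots);
        ``"sqrt"`` uses the conventional sqrt-eigenvalue PC scores.

    Negative eigenvalues within ``-1e-8`` of zero are clamped to 0 before
    proportions of variance are formed.
    """
    n = g.n_lines
    if n_components is None:
        n_components = n
    if not 1 <= n_components <= n:
        raise ValueError(f"n_components must be in [1, {n}]")
    if scale not in ("eigenvalue", "sqrt"):
        raise ValueError(f"unknown scale {scale!r}")
    evals, evecs = np.linalg.eigh(g.K)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals[-1] < -PSD_TOL * max(1.0, abs(evals[0])):
        raise ValueError(f"K has eigenvalue {evals[-1]:.3e}: not PSD")
    evals = np.clip(evals, 0.0, None)
    tr = evals.sum()
    prop_var = evals / tr if tr > 0 else np.full(n, 1.0 / n)
    mult = evals if scale == "eigenvalue" else np.sqrt(evals)
    scores = evecs[:, :n_components] * mult[:n_components][None, :]
    return PCProjection(g.line_ids, scores, evals, prop_var)
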