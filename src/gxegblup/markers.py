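"""Marker-matrix handling for genomic selection.

A :class:`MarkerMatrix` holds a lines x markers dosage matrix in one of two
codings: biallelic additive dosages (0/1/2 copies of the reference allele) or
dominant presence/absence scores (0/1), with an explicit missing-call mask.
Quality control (minor-allele-frequency and missingness filtering) and
marker-mean imputation operate on this container; the genomic relationship
matrix is built from it in :mod:`gxegblup.kinship`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Coding(Enum):
    """Marker coding convention."""

    BIALLELIC_012 = "biallelic_012"
    DOMINANT_01 = "dominant_01"


class NoMarkersError(ValueError):
    """Raised when a filter removes every marker."""


@dataclass(frozen=True)
class MarkerMatrix:
    """Lines x markers dosage matrix with coding metadata.

    Parameters
    ----------
    line_ids : sequence of str
        Unique line identifiers, one per row.
    marker_ids : sequence of str
        Unique marker identifiers, one per column.
    dosages : ndarray, shape (n_lines, n_markers)
        Float matrix of dosage calls. Entries at masked positions are
        ignored (conventionally ``nan``).
    coding : Coding
        ``BIALLELIC_012`` restricts non-missing calls to {0, 1, 2};
        ``DOMINANT_01`` to {0, 1}.
    missing_mask : ndarray of bool, optional
        True where the call is missing. Defaults to ``isnan(dosages)``.
    """

    line_ids: tuple
    marker_ids: tuple
    dosages: np.ndarray
    coding: Coding = Coding.BIALLELIC_012
    missing_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "line_ids", tuple(self.line_ids))
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        mask = self.missing_mask
        if mask is None:
            mask = np.isnan(d)
        mask = np.asarray(mask, dtype=bool) | np.isnan(d)
        object.__setattr__(self, "missing_mask", mask)
        self._validate()

    def _validate(self):
        n, m = self.dosages.shape
        if len(self.line_ids) != n:
            raise ValueError(f"{len(self.line_ids)} line ids for {n} rows")
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        if self.missing_mask.shape != self.dosages.shape:
            raise ValueError("missing_mask shape mismatch")
        obs = self.dosages[~self.missing_mask]
        allowed = {Coding.BIALLELIC_012: (0.0, 1.0, 2.0),
                   Coding.DOMINANT_01: (0.0, 1.0)}[self.coding]
        if obs.size and not np.isin(obs, allowed).all():
            bad = obs[~np.isin(obs, allowed)]
            raise ValueError(
                f"dosage values {sorted(set(bad.tolist()))[:5]} invalid for {self.coding.name}"
            )

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def select_markers(self, keep: np.ndarray) -> "MarkerMatrix":
        """Return a copy restricted to the markers flagged in ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MarkerMatrix(
            self.line_ids,
            tuple(self.marker_ids[j] for j in keep),
            self.dosages[:, keep],
            self.coding,
            self.missing_mask[:, keep],
        )

    def select_lines(self, line_ids) -> "MarkerMatrix":
        """Return a copy restricted to ``line_ids`` (in the given order)."""
        idx = {l: i for i, l in enumerate(self.line_ids)}
        rows = [idx[l] for l in line_ids]
        return MarkerMatrix(
            tuple(line_ids), self.marker_ids,
            self.dosages[rows], self.coding, self.missing_mask[rows],
        )


def allele_freqs(m: MarkerMatrix) -> np.ndarray:
    """Per-marker reference-allele frequency.

    For biallelic 0/1/2 dosages ``p_j = mean(dosage_j) / 2`` over non-missing
    calls; for dominant 0/1 scores ``p_j = mean(dosage_j)``.

    Raises
    ------
    ValueError
        If a marker has no non-missing calls (the marker is named).
    """
    obs = ~m.missing_mask
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"marker {m.marker_ids[j]!r} has no non-missing calls")
    d = np.where(obs, m.dosages, 0.0)
    means = d.sum(axis=0) / n_obs
    if m.coding is Coding.BIALLELIC_012:
        return means / 2.0
    return means


def minor_allele_freqs(m: MarkerMatrix) -> np.ndarray:
    """Per-marker minor-allele frequency, ``min(p, 1 - p)``."""
    p = allele_freqs(m)
    return np.minimum(p, 1.0 - p)


def filter_markers(m: MarkerMatrix, maf_min: float = 0.05,
                   max_missing: float = 0.10) -> MarkerMatrix:
    """Keep markers with MAF strictly above ``maf_min`` and missing-call
    fraction strictly below ``max_missing``.

    Both comparisons are strict, so e.g. a marker missing in exactly 10% of
    lines is removed at ``max_missing=0.10``. The line set and the relative
    marker order are preserved, and the filter is idempotent.

    Raises
    ------
    NoMarkersError
        If no marker survives.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    miss_frac = m.missing_mask.mean(axis=0)
    # markers that are entirely missing cannot have a MAF; they always fail
    # the missingness test unless max_missing is 1, so guard the freq call
    maf = np.zeros(m.n_markers)
    has_calls = miss_frac < 1.0
    if has_calls.any():
        maf[has_calls] = minor_allele_freqs(m.select_markers(has_calls))
    keep = (maf > maf_min) & (miss_frac < max_missing)
    if not keep.any():
        raise NoMarkersError(
            f"no markers survive maf > {maf_min} and missing < {max_missing}"
        )
    return m.select_markers(keep)


def impute_missing(m: MarkerMatrix) -> MarkerMatrix:
    """Replace missing calls by the marker's mean dosage over observed calls.

    Non-missing cells are untouched; the imputed value is generally a
    non-integer, which downstream kinship computation accepts. Returns a
    matrix whose ``missing_mask`` is all False.
    """
    if not m.missing_mask.any():
        return m
    obs = ~m.missing_mask
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        raise ValueError(f"marker {m.marker_ids[j]!r} has no non-missing calls")
    col_means = np.where(obs, m.dosages, 0.0).sum(axis=0) / n_obs
    filled = np.where(m.missing_mask, col_means[None, :], m.dosages)
    out = MarkerMatrix.__new__(MarkerMatrix)
    # bypass the coding check: imputed cells are fractional by design
    object.__setattr__(out, "line_ids", m.line_ids)
    object.__setattr__(out, "marker_ids", m.marker_ids)
    object.__setattr__(out, "dosages", filled)
    object.__setattr__(out, "coding", m.coding)
    object.__setattr__(out, "missing_mask", np.zeros_like(m.missing_mask))
    return out
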