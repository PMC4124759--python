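"""Correlation-weighted re-encoding of binary IPR profiles.

The core transform of the package.  Binary presence/absence columns are
first correlated pairwise (Pearson on 0/1 columns, i.e. the phi
coefficient).  Each protein's profile is then re-expressed feature by
feature: the features it carries form one group, the features it lacks
another, and within each group a feature's raw weight is the sum of its
correlations with the other members.  A total mass of 0.5 is allocated
to each group in proportion to these weights:

    weightsum(i) = 0.5 * weight(i) / sum_{k in group(i)} weight(k)

A feature alone in its group receives 0.5 outright.  The denominator may
legitimately be negative (mutually anti-correlated groups); the ratio is
taken as-is, so group weights always total 0.5.  If a group of two or
more members has a numerically zero denominator, mass is split equally
and the event recorded in ``degenerate_groups``.

Correlations are used at full floating precision throughout; rounding,
if wanted for display, is applied to the final weights only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import AnnotationMatrix

__all__ = [
    "CorrelationMatrix",
    "WeightedMatrix",
    "phi_correlation_matrix",
    "weighted_transform",
    "group_weights",
    "GROUP_MASS",
]

GROUP_MASS = 0.5
_ZERO_DENOM_TOL = 1e-12


@dataclass
class CorrelationMatrix:
    """Symmetric feature x feature phi-coefficient matrix."""

    feature_ids: list[str]
    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class WeightedMatrix:
    """Continuous weighted-IPR matrix; same shape as the binary input.

    ``degenerate_groups`` lists (row index, group value) pairs where the
    equal-shares fallback was applied.
    """

    protein_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    group_mass: float = GROUP_MASS
    degenerate_groups: list[tuple[int, int]] = field(default_factory=list)


def _as_array(X: AnnotationMatrix | np.ndarray) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, AnnotationMatrix):
        return X.values.astype(float), list(X.protein_ids), list(X.feature_ids)
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    return X, [f"row{i}" for i in range(n)], [f"col{j}" for j in range(m)]


def phi_correlation_matrix(X: AnnotationMatrix | np.ndarray) -> CorrelationMatrix:
    """Pairwise Pearson (phi) correlations of the binary columns.

    Zero-variance columns (all-0 or all-1) correlate 0 with every other
    column and 1 with themselves, so they contribute nothing downstream.

    Raises
    ------
    ValueError
        If the matrix has fewer than 2 rows (correlation undefined).
    """
    values, _, feature_ids = _as_array(X)
    if values.shape[0] < 2:
        raise ValueError("phi correlation requires at least 2 proteins (rows)")
    centered = values - values.mean(axis=0)
    cov = centered.T @ centered
    sd = np.sqrt(np.diag(cov))
    degenerate = sd < _ZERO_DENOM_TOL
    denom = np.outer(sd, sd)
    denom[denom < _ZERO_DENOM_TOL] = 1.0  # avoided below
    corr = cov / denom
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return CorrelationMatrix(feature_ids=feature_ids, values=corr)


def group_weights(
    row: np.ndarray, corr: np.ndarray, value: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Raw weights of one same-value feature group of one protein.

    Returns (member column indices, per-member weight = sum of
    correlations with the other members, total weight).  Exposed because
    the intermediate weights and their total are meaningful diagnostics
    in their own right.
    """
    members = np.flatnonzero(np.asarray(row) == value)
    if len(members) == 0:
        return members, np.array([]), 0.0
    sub = corr[np.ix_(members, members)]
    w = sub.sum(axis=1) - np.diag(sub)
    return members, w, float(w.sum())


def weighted_transform(
    X: AnnotationMatrix | np.ndarray, C: CorrelationMatrix
) -> WeightedMatrix:
    """Apply the 0.5-mass group-normalized weighting to every protein.

    ``C`` must cover the same feature universe as ``X`` (typically
    computed from the training rows; new proteins can then be transformed
    with the training correlations).
    """
    values, protein_ids, feature_ids = _as_array(X)
    corr = C.values
    if corr.shape != (values.shape[1], values.shape[1]):
        raise ValueError(
            f"correlation matrix shape {corr.shape} does not match "
            f"{values.shape[1]} feature columns"
        )
    out = np.zeros_like(values, dtype=float)
    degenerate: list[tuple[int, int]] = []
    for p in range(values.shape[0]):
        for value in (0, 1):
            members, w, total = group_weights(values[p], corr, value)
            if len(members) == 0:
                continue
            if len(members) == 1:
                out[p, members[0]] = GROUP_MASS
            elif abs(total) < _ZERO_DENOM_TOL:
                out[p, members] = GROUP_MASS / len(members)
                degenerate.append((p, value))
            else:
                out[p, members] = GROUP_MASS * w / total
    return WeightedMatrix(
        protein_ids=protein_ids,
        feature_ids=feature_ids,
        values=out,
        degenerate_groups=degenerate,
    )
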