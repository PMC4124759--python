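"""Conditional-probability feature selection for IPR columns.

Each IPR column, crossed with one GO term's label vector, yields a 2x2
contingency (present/absent x has-term/lacks-term).  Normalizing by the
number of proteins that carry, respectively lack, the IPR gives four
conditional probabilities; their sum is 2 for any column observed in both
states and drops below 2 only for degenerate columns.  In a balanced
per-term subset the bulk of the signature universe is all-zero —
jointly absent with the term — and carries no signal; the retained
("informative-area") columns are those that co-occur with at least
``min_cooccur`` positive proteins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FourStateCounts",
    "ConditionalProfile",
    "FeatureSelection",
    "four_state_counts",
    "conditional_profile",
    "select_features",
]


@dataclass(frozen=True)
class FourStateCounts:
    """2x2 contingency of one IPR column against one GO label vector."""

    n_gpos_ipos: int  # IPR present, GO present
    n_gneg_ipos: int  # IPR present, GO absent
    n_gpos_ineg: int  # IPR absent,  GO present
    n_gneg_ineg: int  # IPR absent,  GO absent

    @property
    def n_ipos(self) -> int:
        return self.n_gpos_ipos + self.n_gneg_ipos

    @property
    def n_ineg(self) -> int:
        return self.n_gpos_ineg + self.n_gneg_ineg

    @property
    def total(self) -> int:
        return self.n_ipos + self.n_ineg


@dataclass(frozen=True)
class ConditionalProfile:
    """The four conditionals P(GO state | IPR state) and their sum.

    Zero denominators yield probability 0 by convention, so scores are
    totally ordered: non-degenerate columns score exactly 2, degenerate
    ones less.
    """

    p_gpos_given_ipos: float
    p_gneg_given_ipos: float
    p_gpos_given_ineg: float
    p_gneg_given_ineg: float

    @property
    def score(self) -> float:
        return (
            self.p_gpos_given_ipos
            + self.p_gneg_given_ipos
            + self.p_gpos_given_ineg
            + self.p_gneg_given_ineg
        )


@dataclass
class FeatureSelection:
    """Selected column indices (original order) plus an empty-selection flag."""

    indices: np.ndarray
    empty: bool

    def __len__(self) -> int:
        return len(self.indices)


def four_state_counts(ipr_column: np.ndarray, go_labels: np.ndarray) -> FourStateCounts:
    """Count the four (IPR, GO) presence states over proteins."""
    x = np.asarray(ipr_column).astype(bool)
    y = np.asarray(go_labels).astype(bool)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("ipr_column and go_labels must be equal-length 1-D vectors")
    return FourStateCounts(
        n_gpos_ipos=int(np.sum(x & y)),
        n_gneg_ipos=int(np.sum(x & ~y)),
        n_gpos_ineg=int(np.sum(~x & y)),
        n_gneg_ineg=int(np.sum(~x & ~y)),
    )


def conditional_profile(counts: FourStateCounts, condition_on: str = "ipr") -> ConditionalProfile:
    """Turn four-state counts into conditional probabilities.

    ``condition_on="ipr"`` (default) divides each joint count by the
    number of proteins in the matching IPR state, giving
    P(GO state | IPR state).  ``condition_on="go"`` is the alternative
    normalization by GO-state totals, exposed for comparison.
    """
    if condition_on == "ipr":
        d_pos, d_neg = counts.n_ipos, counts.n_ineg
        pairs = (
            (counts.n_gpos_ipos, d_pos),
            (counts.n_gneg_ipos, d_pos),
            (counts.n_gpos_ineg, d_neg),
            (counts.n_gneg_ineg, d_neg),
        )
    elif condition_on == "go":
        d_pos = counts.n_gpos_ipos + counts.n_gpos_ineg
        d_neg = counts.n_gneg_ipos + counts.n_gneg_ineg
        pairs = (
            (counts.n_gpos_ipos, d_pos),
            (counts.n_gneg_ipos, d_neg),
            (counts.n_gpos_ineg, d_pos),
            (counts.n_gneg_ineg, d_neg),
        )
    else:
        raise ValueError("condition_on must be 'ipr' or 'go'")
    probs = [n / d if d > 0 else 0.0 for n, d in pairs]
    return ConditionalProfile(*probs)


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    min_cooccur: int = 1,
    score_min: float | None = None,
) -> FeatureSelection:
    """Select the informative IPR columns of a balanced training set.

    A column is kept iff it is non-zero within the set and co-occurs with
    at least ``min_cooccur`` positive proteins; columns failing this are
    the joint-absence bulk that dominates the signature universe.
    ``score_min``, when given, additionally requires the conditional-
    probability sum to reach that value (degenerate columns score < 2).

    If nothing survives, ``empty`` is flagged and callers may fall back to
    all non-zero columns.
    """
    if min_cooccur < 1:
        raise ValueError("min_cooccur must be >= 1")
    X = np.asarray(X)
    y = np.asarray(y).astype(bool)
    nonzero = X.sum(axis=0) >= 1
    cooccur = X[y].sum(axis=0) >= min_cooccur
    keep = nonzero & cooccur
    if score_min is not None:
        scores = np.array(
            [conditional_profile(four_state_counts(X[:, j], y)).score for j in range(X.shape[1])]
        )
        keep &= scores >= score_min
    idx = np.flatnonzero(keep)
    return FeatureSelection(indices=idx, empty=len(idx) == 0)
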