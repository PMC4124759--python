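"""Class-balanced training sets by undersampling negative proteins.

Viewed from any single GO term, almost every protein is a negative: a
classifier trained on the raw data learns to answer "does not have it".
The remedy used here keeps every positive protein and draws, uniformly
without replacement, exactly as many negatives, so each per-term training
set is 50/50.  Oversampling the minority class is deliberately not
offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_io import AnnotationMatrix

__all__ = ["BalancedDataset", "undersample", "InsufficientNegativesError", "NoPositivesError"]


class NoPositivesError(ValueError):
    """The GO label vector contains no positive protein."""


class InsufficientNegativesError(ValueError):
    """Fewer negatives than positives; undersampling cannot balance."""


@dataclass
class BalancedDataset:
    """Per-GO-term balanced training set.

    ``X`` is the IPR sub-matrix restricted to the kept proteins (positives
    first, in original row order, then the sampled negatives in original
    row order); ``y`` the matching 0/1 label vector.  ``seed`` records the
    PRNG seed used for the negative draw.
    """

    go_term: str
    protein_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    seed: int

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    def __len__(self) -> int:
        return len(self.protein_ids)


def undersample(
    ipr_matrix: AnnotationMatrix,
    go_labels: np.ndarray,
    seed: int,
    go_term: str = "",
) -> BalancedDataset:
    """Balance one GO term's training set by undersampling negatives.

    All positive proteins are retained; ``n_positive`` negatives are drawn
    uniformly without replacement with ``numpy.random.default_rng(seed)``.

    Raises
    ------
    NoPositivesError
        If no protein carries the term.
    InsufficientNegativesError
        If negatives are scarcer than positives (the opposite skew from
        the one this sampler addresses).
    """
    y = np.asarray(go_labels).astype(int)
    if y.shape != (len(ipr_matrix.protein_ids),):
        raise ValueError("go_labels length must match the number of proteins")
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0:
        raise NoPositivesError(f"no positive proteins for {go_term or 'this term'}")
    if len(neg) < len(pos):
        raise InsufficientNegativesError(
            f"{len(neg)} negatives < {len(pos)} positives; oversampling is not implemented"
        )
    rng = np.random.default_rng(seed)
    sampled = np.sort(rng.choice(neg, size=len(pos), replace=False))
    keep = np.concatenate([pos, sampled])
    return BalancedDataset(
        go_term=go_term,
        protein_ids=[ipr_matrix.protein_ids[i] for i in keep],
        X=ipr_matrix.values[keep].astype(np.int8),
        y=np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(pos), dtype=int)]),
        seed=seed,
    )
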