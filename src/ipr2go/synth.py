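"""Synthetic sparse annotation matrices with planted IPR-GO associations.

Real domain-signature data is sparse and skewed: most IPR columns are
near-all-zero and, per GO term, positives are a small minority.  The
generator reproduces that shape at a scale convenient for testing.  Every
IPR column fires at a low background rate; for each GO term, a small set
of "informative" columns fires at a much higher rate on that term's
positive proteins.  The planted truth map is returned so that
feature-selection recovery can be measured directly.

Defaults emulate a yeast-scale extraction (thousands of proteins, a
signature universe where most columns are nearly empty, ~5% positives
per term) scaled down about 2x for speed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation_io import AnnotationMatrix

__all__ = ["SynthConfig", "generate"]


@dataclass
class SynthConfig:
    """Generator settings.

    background_density is the Bernoulli rate of uninformative entries;
    assoc_strength the rate of informative entries on positive proteins
    (must exceed 0.5 to constitute signal); positive_fraction the share
    of proteins annotated with each GO term.
    """

    n_proteins: int = 2000
    n_iprs: int = 500
    n_go: int = 5
    background_density: float = 0.01
    n_informative_per_go: int = 10
    assoc_strength: float = 0.8
    positive_fraction: float = 0.05
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.background_density < 1:
            raise ValueError("background_density must be in (0, 1)")
        if not 0.5 < self.assoc_strength <= 1:
            raise ValueError("assoc_strength must be in (0.5, 1]")
        if not 0 < self.positive_fraction <= 0.5:
            raise ValueError("positive_fraction must be in (0, 0.5]")
        if self.n_informative_per_go > self.n_iprs:
            raise ValueError("n_informative_per_go cannot exceed n_iprs")


def generate(
    config: SynthConfig,
) -> tuple[AnnotationMatrix, AnnotationMatrix, dict[str, list[str]]]:
    """Draw one synthetic (IPR matrix, GO matrix, truth map) triple.

    Per GO term, ``round(positive_fraction * n_proteins)`` proteins are
    positive (exactly); each of that term's ``n_informative_per_go``
    informative columns is 1 with probability ``assoc_strength`` on
    positives and ``background_density`` elsewhere; all remaining entries
    are background.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, m, g = config.n_proteins, config.n_iprs, config.n_go

    protein_ids = [f"P{i + 1:05d}" for i in range(n)]
    ipr_ids = [f"IPR{j + 1:06d}" for j in range(m)]
    go_ids = [f"GO:{k + 1:07d}" for k in range(g)]

    ipr = rng.random((n, m)) < config.background_density
    go = np.zeros((n, g), dtype=np.int8)
    n_pos = round(config.positive_fraction * n)
    truth: dict[str, list[str]] = {}
    for k, term in enumerate(go_ids):
        positives = rng.choice(n, size=n_pos, replace=False)
        informative = rng.choice(m, size=config.n_informative_per_go, replace=False)
        go[positives, k] = 1
        ipr[np.ix_(positives, informative)] = (
            rng.random((n_pos, config.n_informative_per_go)) < config.assoc_strength
        )
        truth[term] = sorted(ipr_ids[j] for j in informative)

    return (
        AnnotationMatrix(protein_ids=protein_ids, feature_ids=ipr_ids, values=ipr.astype(np.int8)),
        AnnotationMatrix(protein_ids=protein_ids, feature_ids=go_ids, values=go),
        truth,
    )
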