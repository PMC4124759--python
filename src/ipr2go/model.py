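"""Model/results interface over the per-term evaluation pipeline.

``ProteinFunctionModel`` holds an IPR matrix and a GO matrix for the same
proteins; ``fit`` runs the balanced, cross-validated method grid for the
trainable GO terms and returns ``GridResults``, which carries the error
estimates, their spread across resamples, and a ``summary()`` table, in
the style of a fitted-model results object.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation_io import (
    AnnotationMatrix,
    build_matrix,
    read_annotations,
    trainable_go_terms,
)
from .grid import MethodConfig, MethodGridReport, full_grid, run_grid

__all__ = ["ProteinFunctionModel", "GridResults"]


class ProteinFunctionModel:
    """Per-GO-term protein function annotation from IPR signature profiles.

    Parameters
    ----------
    ipr_matrix, go_matrix
        Binary incidence matrices over the same protein set (row ids must
        agree after sorting; both builders sort rows, so matrices built by
        :func:`build_matrix` line up).
    min_positive
        Minimum positive proteins for a GO term to be considered
        trainable (default 20 keeps >= 2 positives per fold of 10).
    """

    def __init__(
        self,
        ipr_matrix: AnnotationMatrix,
        go_matrix: AnnotationMatrix,
        min_positive: int = 20,
    ) -> None:
        if ipr_matrix.protein_ids != go_matrix.protein_ids:
            raise ValueError("IPR and GO matrices must cover the same proteins in the same order")
        self.ipr = ipr_matrix
        self.go = go_matrix
        self.min_positive = min_positive

    @classmethod
    def from_files(
        cls,
        ipr_path: str | Path,
        go_path: str | Path,
        min_positive: int = 20,
        go_dialect: str = "tsv",
    ) -> "ProteinFunctionModel":
        """Build the model from two annotation files.

        The protein universe is the union of both tables' proteins: a
        protein missing from the GO table is negative for every term, and
        one missing from the IPR table has an all-zero signature profile.
        """
        ipr_table = read_annotations(ipr_path, "IPR")
        go_table = read_annotations(go_path, "GO", dialect=go_dialect)
        universe = sorted(set(ipr_table.protein_ids) | set(go_table.protein_ids))
        return cls(
            build_matrix(ipr_table, protein_universe=universe),
            build_matrix(go_table, protein_universe=universe),
            min_positive=min_positive,
        )

    @property
    def trainable_terms(self) -> list[str]:
        """GO terms with enough positives, most-supported first."""
        return trainable_go_terms(self.go, self.min_positive)

    def fit(
        self,
        go_terms: list[str] | None = None,
        grid: list[MethodConfig] | None = None,
        seed: int = 0,
        n_splits: int = 10,
        min_cooccur: int = 1,
        n_resamples: int = 1,
        pooled: bool = False,
        leakage: str = "none",
    ) -> "GridResults":
        """Run the method grid; returns a :class:`GridResults`.

        ``go_terms`` defaults to all trainable terms and ``grid`` to the
        full 12-cell grid.
        """
        if go_terms is None:
            go_terms = self.trainable_terms
        missing = [t for t in go_terms if t not in self.go.feature_ids]
        if missing:
            raise ValueError(f"unknown GO terms: {', '.join(missing)}")
        report = run_grid(
            self.ipr, self.go, go_terms,
            grid=grid if grid is not None else full_grid(seed),
            seed=seed, n_splits=n_splits, min_cooccur=min_cooccur,
            n_resamples=n_resamples, pooled=pooled, leakage=leakage,
        )
        return GridResults(self, report, seed=seed)


class GridResults:
    """Cross-validated error rates for every (GO term, method) cell."""

    def __init__(self, model: ProteinFunctionModel, report: MethodGridReport, seed: int) -> None:
        self.model = model
        self.report = report
        self.seed = seed

    @property
    def frame(self) -> pd.DataFrame:
        return self.report.frame

    def error_rate(self, go_term: str, learner: str,
                   feature_selection: bool = False, weighted: bool = False) -> float:
        f = self.frame
        row = f[
            (f.go_term == go_term) & (f.learner == learner)
            & (f.feature_selection == feature_selection) & (f.weighted == weighted)
        ]
        if row.empty:
            raise KeyError(f"no grid cell ({go_term}, {learner}, fs={feature_selection}, "
                           f"weighted={weighted})")
        return float(row.error_rate.iloc[0])

    def pivot(self) -> pd.DataFrame:
        """Terms x method-cells table of error rates."""
        f = self.frame[self.frame.status == "ok"]
        return f.pivot_table(
            index="go_term",
            columns=["learner", "feature_selection", "weighted"],
            values="error_rate",
        )

    def summary(self) -> str:
        """Human-readable report: per-cell errors and per-learner means."""
        ok = self.frame[self.frame.status == "ok"]
        lines = [
            "Protein function annotation — method grid (10-fold CV error rates)",
            f"terms evaluated: {ok.go_term.nunique()}   seed: {self.seed}",
            "",
            self.pivot().round(4).to_string(),
            "",
            "mean error by method cell:",
        ]
        means = ok.groupby(["learner", "feature_selection", "weighted"]).error_rate.mean()
        lines.append(means.round(4).to_string())
        skipped = self.frame[self.frame.status != "ok"]
        if not skipped.empty:
            lines += ["", f"skipped rows: {len(skipped)}"]
            for _, r in skipped.drop_duplicates("go_term").iterrows():
                lines.append(f"  {r.go_term}: {r.status}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.report.to_tsv(path)

    def plot(self, ax=None):
        """Grouped bar chart of error rates per term and grid cell."""
        import matplotlib.pyplot as plt

        piv = self.pivot()
        if ax is None:
            _, ax = plt.subplots(figsize=(1.5 + 0.9 * len(piv.columns), 4))
        piv.plot.bar(ax=ax, legend=True)
        ax.set_ylabel("10-fold CV error rate")
        ax.set_xlabel("GO term")
        ax.legend(
            [f"{lr} {'W' if fs else 'W/O'} FS, {'weighted' if w else 'original'}"
             for lr, fs, w in piv.columns],
            fontsize=7,
        )
        return ax
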