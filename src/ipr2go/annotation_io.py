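"""Annotation tables and binary incidence matrices.

Protein function data arrives as long-format (protein, term) pairs: one
table mapping proteins to InterPro (IPR) signatures, another mapping
proteins to Gene Ontology (GO) terms.  Both are turned into binary
protein x feature matrices, the in-memory currency of the rest of the
package.  GO columns with too few positive proteins cannot support
cross-validated training and are filtered out here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "AnnotationTable",
    "AnnotationMatrix",
    "AnnotationParseError",
    "ValidationError",
    "read_annotations",
    "build_matrix",
    "trainable_go_terms",
    "save_matrix_mtx",
    "load_matrix_mtx",
]

_PREFIX = {"IPR": "IPR", "GO": "GO:"}


class AnnotationParseError(ValueError):
    """A line of an annotation file could not be parsed."""


class ValidationError(ValueError):
    """Input violated a structural contract (term prefix, universe, shape)."""


@dataclass
class AnnotationTable:
    """Deduplicated long-format (protein_id, term_id) records.

    ``namespace`` is ``"IPR"`` or ``"GO"`` and fixes the accepted term-id
    prefix (``IPR...`` / ``GO:...``).
    """

    records: list[tuple[str, str]]
    namespace: str

    def __post_init__(self) -> None:
        if self.namespace not in _PREFIX:
            raise ValidationError(f"namespace must be IPR or GO, got {self.namespace!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def protein_ids(self) -> list[str]:
        """Unique protein ids in first-occurrence order."""
        return list(dict.fromkeys(p for p, _ in self.records))

    @property
    def term_ids(self) -> list[str]:
        """Unique term ids in first-occurrence order."""
        return list(dict.fromkeys(t for _, t in self.records))


@dataclass
class AnnotationMatrix:
    """Binary protein x feature incidence matrix with identifier lists.

    Rows are proteins, columns are features (IPR signatures or GO terms);
    entry (p, f) is 1 iff protein p carries feature f.
    """

    protein_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, m = self.values.shape
        if n != len(self.protein_ids) or m != len(self.feature_ids):
            raise ValidationError("identifier lists do not match matrix dimensions")
        if len(set(self.protein_ids)) != n or len(set(self.feature_ids)) != m:
            raise ValidationError("row/column identifiers must be unique")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("matrix entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.feature_ids.index(feature_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.protein_ids, columns=self.feature_ids)

    def to_pairs(self) -> list[tuple[str, str]]:
        """The (protein, feature) pairs of the 1-entries (row-major order)."""
        rows, cols = np.nonzero(self.values)
        return [(self.protein_ids[r], self.feature_ids[c]) for r, c in zip(rows, cols)]


def _detect_header(first: Sequence[str], namespace: str) -> bool:
    # header row: second column carries no known term prefix at all
    # (a wrong-namespace prefix is an error, not a header)
    return len(first) == 2 and not any(first[1].startswith(p) for p in _PREFIX.values())


def read_annotations(path: str | Path, namespace: str, dialect: str = "tsv") -> AnnotationTable:
    """Read a protein-term annotation file into an :class:`AnnotationTable`.

    Parameters
    ----------
    path
        Input file. ``dialect="tsv"``: two tab-separated columns
        (protein_id, term_id), UTF-8, optional header (auto-detected by the
        prefix of the second column).  ``dialect="gaf"``: GAF 2.x gene
        association format; columns 2 (object id) and 5 (GO id) are used and
        ``!``-prefixed comment lines are skipped (GO namespace only).
    namespace
        ``"IPR"`` or ``"GO"``; every term id must carry the matching prefix.

    Returns
    -------
    AnnotationTable with duplicate pairs removed, keeping first-occurrence
    order.
    """
    if namespace not in _PREFIX:
        raise ValidationError(f"namespace must be IPR or GO, got {namespace!r}")
    if dialect not in ("tsv", "gaf"):
        raise ValidationError(f"unknown dialect {dialect!r}")
    if dialect == "gaf" and namespace != "GO":
        raise ValidationError("GAF dialect only carries GO annotations")

    prefix = _PREFIX[namespace]
    pairs: dict[tuple[str, str], None] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if dialect == "gaf":
                if line.startswith("!"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise AnnotationParseError(
                        f"{path}: line {lineno}: expected >= 5 tab-separated GAF columns, "
                        f"got {len(fields)}"
                    )
                protein, term = fields[1], fields[4]
            else:
                fields = line.split("\t")
                if len(fields) != 2:
                    raise AnnotationParseError(
                        f"{path}: line {lineno}: expected 2 tab-separated columns, "
                        f"got {len(fields)}"
                    )
                protein, term = fields
                if lineno == 1 and _detect_header(fields, namespace):
                    continue
            if not term.startswith(prefix):
                raise ValidationError(
                    f"{path}: line {lineno}: term {term!r} does not match namespace "
                    f"{namespace} (expected prefix {prefix!r})"
                )
            pairs.setdefault((protein, term))
    return AnnotationTable(records=list(pairs), namespace=namespace)


def build_matrix(
    table: AnnotationTable,
    feature_universe: Sequence[str] | None = None,
    protein_universe: Sequence[str] | None = None,
) -> AnnotationMatrix:
    """Build the binary incidence matrix of an annotation table.

    Rows are sorted protein ids; columns follow ``feature_universe`` when
    given (every term in the table must belong to it), otherwise sorted
    term ids.  Universe features (or proteins) never seen in the table
    yield all-zero columns (rows) — a protein with no annotation line is
    a genuine negative for every term, not missing data.
    """
    if protein_universe is not None:
        proteins = list(protein_universe)
        missing_p = sorted(set(p for p, _ in table.records) - set(proteins))
        if missing_p:
            raise ValidationError(
                f"proteins outside protein universe: {', '.join(missing_p)}"
            )
    else:
        proteins = sorted(set(p for p, _ in table.records))
    if feature_universe is not None:
        features = list(feature_universe)
        missing = sorted(set(t for _, t in table.records) - set(features))
        if missing:
            raise ValidationError(f"terms outside feature universe: {', '.join(missing)}")
    else:
        features = sorted(set(t for _, t in table.records))
    p_index = {p: i for i, p in enumerate(proteins)}
    f_index = {f: j for j, f in enumerate(features)}
    values = np.zeros((len(proteins), len(features)), dtype=np.int8)
    for protein, term in table.records:
        values[p_index[protein], f_index[term]] = 1
    return AnnotationMatrix(protein_ids=proteins, feature_ids=features, values=values)


def trainable_go_terms(go_matrix: AnnotationMatrix, min_positive: int = 20) -> list[str]:
    """GO terms with at least ``min_positive`` annotated proteins.

    A term annotated to very few proteins cannot populate every fold of a
    10-fold cross-validation with positives; the default of 20 keeps >= 2
    positives per fold.  Returned in descending support order, ties broken
    by term id.

    Parameters
    ----------
    min_positive
        Minimum column sum; must be >= 2.
    """
    if min_positive < 2:
        raise ValidationError("min_positive must be >= 2")
    sums = go_matrix.column_sums()
    keep = [(int(s), t) for t, s in zip(go_matrix.feature_ids, sums) if s >= min_positive]
    keep.sort(key=lambda st: (-st[0], st[1]))
    return [t for _, t in keep]


def save_matrix_mtx(matrix: AnnotationMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` (Matrix Market) plus ``<prefix>.rows.txt`` /
    ``<prefix>.cols.txt`` sidecar identifier lists."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.coo_matrix(matrix.values))
    Path(str(prefix) + ".rows.txt").write_text("\n".join(matrix.protein_ids) + "\n")
    Path(str(prefix) + ".cols.txt").write_text("\n".join(matrix.feature_ids) + "\n")


def load_matrix_mtx(prefix: str | Path) -> AnnotationMatrix:
    """Inverse of :func:`save_matrix_mtx`."""
    prefix = Path(prefix)
    values = scipy.io.mmread(str(prefix) + ".mtx").toarray()
    rows = Path(str(prefix) + ".rows.txt").read_text().splitlines()
    cols = Path(str(prefix) + ".cols.txt").read_text().splitlines()
    return AnnotationMatrix(protein_ids=rows, feature_ids=cols, values=values)
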