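"""Bundled example data."""

from __future__ import annotations

from importlib import resources

from .annotation_io import AnnotationMatrix, AnnotationTable, build_matrix, read_annotations

__all__ = ["load_demo_table", "load_demo_matrix"]


def _demo_path():
    return resources.files("ipr2go.data") / "demo_ipr.tsv"


def load_demo_table() -> AnnotationTable:
    """The 5-protein, 6-signature worked-example annotation table (13 pairs)."""
    with resources.as_file(_demo_path()) as path:
        return read_annotations(path, "IPR")


def load_demo_matrix() -> AnnotationMatrix:
    """The 5x6 binary worked-example matrix used throughout the docs.

    Small enough to follow the correlation and weighting arithmetic by
    hand; see the README's worked example.
    """
    return build_matrix(load_demo_table())
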