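"""Readers and writers for delimited expression tables.

Matrices travel as plain TSV/CSV: first column gene (or tag) id, header row
of sample ids matching the dilution design.  The delimiter is auto-detected
with tab preferred.  Purity designs travel as a two-column table
(sample_id, purity_percent); percent is converted to a fraction at this
boundary and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, DilutionDesign, ExpressionMatrix, TagAnnotation

__all__ = [
    "read_design",
    "write_design",
    "read_matrix",
    "write_matrix",
    "read_tag_annotation",
    "summarize_tags_to_genes",
    "library_stats",
    "percent_annotated",
]

logger = logging.getLogger(__name__)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_design(path) -> DilutionDesign:
    """Read a (sample_id, purity_percent) table as a :class:`DilutionDesign`."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = {"sample_id", "purity_percent"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    return DilutionDesign(
        purities=(df["purity_percent"] / 100.0).tolist(),
        sample_ids=df["sample_id"].astype(str).tolist(),
    )


def write_design(design: DilutionDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def read_matrix(path, kind: str, design: DilutionDesign):
    """Read a delimited gene x sample table as a typed matrix.

    Parameters
    ----------
    path
        TSV or CSV file; first column gene id, remaining columns one per
        sample in the order of ``design``.
    kind
        ``"intensity"`` for an :class:`ExpressionMatrix` of continuous
        linear-scale values, ``"count"`` for a :class:`CountMatrix` of
        integers (non-integral entries are an error, not rounded).
    design
        The purity design the columns must match.
    """
    if kind not in ("intensity", "count"):
        raise ValueError(f"kind must be 'intensity' or 'count', got {kind!r}")
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sniff_delimiter(path), index_col=0, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if kind == "count":
        return CountMatrix(df, design)
    return ExpressionMatrix(df, design)


def write_matrix(mat, path) -> None:
    """Write a typed matrix as TSV (lossless round-trip for counts)."""
    df = mat.counts if isinstance(mat, CountMatrix) else mat.values
    # default float formatting is the shortest round-tripping repr
    df.to_csv(path, sep="\t", index_label="gene")


def read_tag_annotation(path) -> TagAnnotation:
    """Read a two-column (tag_id, gene) table; blank genes mean unannotated."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str).fillna("")
    tag_col, gene_col = df.columns[:2]
    if df[tag_col].duplicated().any():
        raise ValueError("a tag maps to more than one gene")
    mapping = {
        t: g for t, g in zip(df[tag_col], df[gene_col]) if g
    }
    return TagAnnotation(mapping)


def summarize_tags_to_genes(
    tag_counts: CountMatrix, ann: TagAnnotation
) -> CountMatrix:
    """Collapse tag-level counts to gene level by summing a gene's tags.

    Unannotated tags are dropped; their per-sample totals are reported via
    logging.  The total annotated count per sample is conserved exactly.
    """
    tags = tag_counts.genes
    annotated = ann.is_annotated(tags)
    dropped = tag_counts.counts.loc[~annotated].sum(axis=0)
    if dropped.sum() > 0:
        logger.info(
            "dropping %d unannotated tags carrying %s counts per sample",
            int((~annotated).sum()),
            dropped.to_dict(),
        )
    kept = tag_counts.counts.loc[annotated]
    genes = pd.Index([ann.gene_of(t) for t in kept.index], name="gene")
    summed = kept.groupby(genes, sort=True).sum()
    return CountMatrix(summed, tag_counts.design)


def percent_annotated(annotated: int, total: int) -> float:
    """Annotation percentage, rounded to one decimal (the reporting unit)."""
    if total <= 0:
        raise ValueError("zero library size")
    return round(100.0 * annotated / total, 1)


def library_stats(tag_counts: CountMatrix, annotated_mask) -> pd.DataFrame:
    """Per-sample library size, annotated count and annotation percent.

    Operates on tag-level counts before gene summarisation.  Also appends a
    ``unique`` row counting distinct tag species (rows with any count)
    versus annotated tag species, matching how library tables report the
    unique-read annotation rate.
    """
    mask = np.asarray(annotated_mask, dtype=bool)
    if mask.shape[0] != tag_counts.n_genes:
        raise ValueError("annotated_mask length must equal number of tags")
    lib = tag_counts.lib_sizes
    ann = tag_counts.counts.loc[mask].sum(axis=0)
    rows = {
        sid: {
            "lib_size": int(lib[sid]),
            "annotated": int(ann[sid]),
            "percent": percent_annotated(int(ann[sid]), int(lib[sid])),
        }
        for sid in tag_counts.counts.columns
    }
    present = tag_counts.counts.sum(axis=1) > 0
    n_unique = int(present.sum())
    n_unique_ann = int((present & mask).sum())
    rows["unique"] = {
        "lib_size": n_unique,
        "annotated": n_unique_ann,
        "percent": percent_annotated(n_unique_ann, n_unique) if n_unique else 0.0,
    }
    return pd.DataFrame(rows).T
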