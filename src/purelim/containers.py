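"""Typed containers for dilution-series expression data.

A dilution series mixes a target cell population (e.g. malignant B-cells)
into a background population at known fractions ("purities").  The same
genes are measured across all mixtures, either as continuous hybridisation
intensities (microarray-like) or as non-negative integer tag counts
(tag-seq-like).  These containers pair the measurement matrix with the
purity design and validate the invariants every downstream stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DilutionDesign",
    "ExpressionMatrix",
    "CountMatrix",
    "TagAnnotation",
]


@dataclass(frozen=True)
class DilutionDesign:
    """Ordered purity fractions, one per sample.

    Parameters
    ----------
    purities
        Fractions in [0, 1] (0 = pure background, 1 = pure target).
        Duplicates are allowed; at least two distinct values are required
        so dilution regressions are identifiable.
    sample_ids
        Unique sample labels, same length as ``purities``.
    """

    purities: tuple[float, ...]
    sample_ids: tuple[str, ...]

    #: The eight-point mixing grid of the reference dilution experiment
    #: (percent target cells: 0, 0.5, 1, 5, 10, 20, 30, 100).
    DEFAULT_GRID = (0.0, 0.005, 0.01, 0.05, 0.10, 0.20, 0.30, 1.0)

    def __init__(self, purities, sample_ids=None):
        purities = tuple(float(p) for p in purities)
        if sample_ids is None:
            names, seen = [], {}
            for p in purities:
                base = f"p{100 * p:g}"
                seen[base] = seen.get(base, 0) + 1
                names.append(base if seen[base] == 1 else f"{base}_{seen[base]}")
            sample_ids = tuple(names)
        else:
            sample_ids = tuple(str(s) for s in sample_ids)
        object.__setattr__(self, "purities", purities)
        object.__setattr__(self, "sample_ids", sample_ids)
        self._validate()

    def _validate(self) -> None:
        if len(self.sample_ids) != len(self.purities):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {len(self.purities)} purities"
            )
        for p in self.purities:
            if not (0.0 <= p <= 1.0) or not np.isfinite(p):
                raise ValueError(f"purity {p} outside [0, 1]")
        if len(set(self.purities)) < 2:
            raise ValueError("need at least 2 distinct purities")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")

    @classmethod
    def default(cls) -> "DilutionDesign":
        return cls(cls.DEFAULT_GRID)

    def __len__(self) -> int:
        return len(self.purities)

    @property
    def x(self) -> np.ndarray:
        """Purities as a float array (regression covariate)."""
        return np.asarray(self.purities, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Two-column table (sample_id, purity_percent) for I/O."""
        return pd.DataFrame(
            {
                "sample_id": list(self.sample_ids),
                "purity_percent": [100.0 * p for p in self.purities],
            }
        )


def _check_values(
    values: pd.DataFrame, design: DilutionDesign, allow_negative: bool
) -> pd.DataFrame:
    if values.isna().any().any():
        raise ValueError("missing values are not supported")
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    if values.shape[1] != len(design):
        raise ValueError(
            f"matrix has {values.shape[1]} columns but design has {len(design)} samples"
        )
    if list(values.columns) != list(design.sample_ids):
        raise ValueError("matrix columns must match design sample ids in order")
    if not allow_negative and (values.to_numpy() < 0).any():
        raise ValueError("negative values not allowed")
    return values


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of linear-scale intensities.

    Intensities are nominally non-negative, but background-corrected
    measurements (and the untruncated Gaussian measurement model) can dip
    below zero, so negative entries are tolerated.
    """

    values: pd.DataFrame
    design: DilutionDesign

    def __post_init__(self) -> None:
        self.values = _check_values(
            self.values.astype(float, copy=False), self.design, allow_negative=True
        )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, genes) -> "ExpressionMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.design)

    def log2(self, pseudo: float = 0.0) -> pd.DataFrame:
        """log2-transformed view (used by DE and clustering stages)."""
        return np.log2(self.values + pseudo)


@dataclass
class CountMatrix:
    """Gene (or tag) x sample matrix of non-negative integer counts.

    ``lib_sizes`` always equal the column sums; they are recomputed on
    construction so the invariant cannot drift.
    """

    counts: pd.DataFrame
    design: DilutionDesign
    lib_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        self.counts = _check_values(self.counts, self.design, allow_negative=False)
        sums = self.counts.sum(axis=0)
        if self.lib_sizes is not None and not (
            np.asarray(self.lib_sizes) == sums.to_numpy()
        ).all():
            raise ValueError("lib_sizes must equal column sums")
        self.lib_sizes = sums

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset(self, genes) -> "CountMatrix":
        missing = set(genes) - set(self.counts.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        return CountMatrix(self.counts.loc[list(genes)], self.design)

    def log2(self, pseudo: float = 0.5) -> pd.DataFrame:
        """log2(count + pseudo) view for clustering/visualisation."""
        return np.log2(self.counts + pseudo)


@dataclass(frozen=True)
class TagAnnotation:
    """Mapping from sequence tag id to gene symbol.

    Each tag maps to at most one gene; tags absent from the mapping are
    "unannotated" and are dropped (with accounting) at gene summarisation.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("empty annotation")
        for tag, gene in self.mapping.items():
            if not gene:
                raise ValueError(f"tag {tag!r} maps to an empty gene symbol")

    def gene_of(self, tag: str) -> str | None:
        return self.mapping.get(tag)

    def is_annotated(self, tags) -> np.ndarray:
        return np.asarray([t in self.mapping for t in tags], dtype=bool)
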