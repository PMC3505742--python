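"""Count normalisation, low-count filtering and gene-presence calling.

Three standard steps sit between raw matrices and the dilution analyses:

* library equalisation by random subsampling without replacement down to
  the smallest library (rarefaction), so platform counts are comparable
  across samples of very different sequencing depth;
* removal of tags/genes never observed above a minimum count in any
  sample (default: a count must exceed 15 somewhere to keep the row);
* the detection-above-background (DABG) presence rule for exon arrays: an
  exon is "present" in a sample when its background p-value is below
  0.005, and a gene is present when at least half of its exons are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

__all__ = [
    "ExonPValueTable",
    "subsample_to_min_library",
    "filter_min_count",
    "dabg_gene_presence",
    "presence_vs_purity_curve",
]


@dataclass
class ExonPValueTable:
    """Long-format per-exon background p-values.

    ``table`` needs columns (gene, exon, sample, p); each exon belongs to
    exactly one gene.  Computing the p-values themselves (against
    antigenomic background probes) happens upstream; this container only
    consumes them.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "exon", "sample", "p"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"ExonPValueTable needs columns {sorted(required)}")
        p = self.table["p"].to_numpy()
        if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        owners = self.table.groupby("exon")["gene"].nunique()
        if (owners > 1).any():
            bad = owners[owners > 1].index.tolist()
            raise ValueError(f"exons assigned to multiple genes: {bad[:5]}")


def subsample_to_min_library(counts: CountMatrix, seed: int = 0) -> CountMatrix:
    """Rarefy every sample to the smallest library size.

    Each column is subsampled without replacement over its tag instances
    (a multivariate hypergeometric draw over the genes), so column sums
    equal the original minimum exactly and no gene can gain counts.
    """
    if counts.n_genes == 0:
        raise ValueError("empty matrix")
    rng = np.random.default_rng(seed)
    target = int(counts.lib_sizes.min())
    if target <= 0:
        raise ValueError("all library sizes must be positive")
    out = {}
    for sid in counts.counts.columns:
        col = counts.counts[sid].to_numpy()
        if col.sum() == target:
            out[sid] = col
        else:
            out[sid] = rng.multivariate_hypergeometric(col, target, method="marginals")
    df = pd.DataFrame(out, index=counts.counts.index)
    return CountMatrix(df, counts.design)


def filter_min_count(counts: CountMatrix, threshold: int = 15) -> CountMatrix:
    """Keep a gene only if its count exceeds ``threshold`` in some sample.

    The inequality is strict: a gene whose largest count equals the
    threshold is removed ("not above" the threshold anywhere).
    """
    keep = (counts.counts > threshold).any(axis=1)
    return CountMatrix(counts.counts.loc[keep], counts.design)


def dabg_gene_presence(tbl: ExonPValueTable, alpha: float = 0.005) -> pd.DataFrame:
    """Gene x sample presence calls from exon-level background p-values.

    An exon is present when p < ``alpha`` (strict); a gene is present when
    the number of present exons is at least half the number of its exons
    (ties go to present).  Returns a boolean DataFrame.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    df = tbl.table.copy()
    df["present"] = df["p"].to_numpy() < alpha
    grouped = df.groupby(["gene", "sample"])["present"].agg(["sum", "count"])
    if (grouped["count"] == 0).any():
        raise ValueError("gene with zero exons")
    calls = grouped["sum"] >= grouped["count"] / 2.0
    mat = calls.unstack("sample")
    if mat.isna().any().any():
        raise ValueError("every gene needs exon p-values in every sample")
    return mat.astype(bool)


def presence_vs_purity_curve(
    presence: pd.DataFrame, signature_genes, purities=None
) -> pd.DataFrame:
    """Fraction of signature genes called present, per sample.

    Monotonicity in purity is expected for real signatures but is only
    reported, never enforced.  ``purities`` (optional, one per column)
    is carried through into the output for plotting.
    """
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise ValueError("empty signature set")
    missing = set(signature_genes) - set(presence.index)
    if missing:
        raise KeyError(f"signature genes not in presence matrix: {sorted(missing)[:5]}")
    frac = presence.loc[signature_genes].mean(axis=0)
    out = pd.DataFrame({"proportion_present": frac})
    if purities is not None:
        out.insert(0, "purity", np.asarray(purities, dtype=float))
    return out
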