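"""Cross-platform agreement of gene lists and expression profiles.

Two platforms measuring the same dilution series should nominate
overlapping differentially expressed genes, cluster the samples the same
way, and rank per-gene expression consistently.  This module provides:

* an exact hypergeometric upper-tail test for the overlap of two gene
  lists drawn from a common universe (the universe size is an explicit,
  required argument — it is never inferred);
* correspondence curves: overlap of the top-d genes of two significance
  rankings against d (y = x under perfect concordance, ~d^2/N under
  independence) with exact hypergeometric acceptance regions;
* complete-linkage hierarchical clustering of samples (Euclidean
  distance) with a deterministic lexicographic tie-break;
* Spearman rank correlation (mid-ranks for ties);
* the delta-delta-Cq method for qPCR relative quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln, logsumexp
from scipy.stats import spearmanr

__all__ = [
    "RankedGeneList",
    "CqTable",
    "overlap_hypergeometric_test",
    "correspondence_curve",
    "acceptance_region",
    "HClustResult",
    "hclust_samples",
    "spearman",
    "delta_delta_cq",
]


@dataclass(frozen=True)
class RankedGeneList:
    """Gene ids ordered by increasing p-value (most significant first)."""

    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


def _log_hypergeom_pmf(k, N, K, n):
    """log P(X = k) for overlap of a size-n draw with K marked among N."""
    return (
        gammaln(K + 1)
        - gammaln(k + 1)
        - gammaln(K - k + 1)
        + gammaln(N - K + 1)
        - gammaln(n - k + 1)
        - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def overlap_hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for the overlap of two gene lists.

    ``K`` and ``n`` are the two list sizes, ``N`` the universe both were
    drawn from.  Computed by log-space summation of the hypergeometric pmf.
    """
    if not (0 <= k <= min(K, n) <= N) or max(K, n) > N:
        raise ValueError(f"inconsistent sizes: k={k}, K={K}, n={n}, N={N}")
    if k <= max(0, K + n - N):
        return 1.0
    ks = np.arange(k, min(K, n) + 1)
    return float(np.exp(logsumexp(_log_hypergeom_pmf(ks, N, K, n))))


def correspondence_curve(a, b, depth: int | None = None) -> pd.DataFrame:
    """Overlap of the top-d genes of two rankings, for d = 1..depth.

    Returns a DataFrame with columns ``d`` and ``overlap``; overlap is
    non-decreasing in d and never exceeds d.
    """
    ga = tuple(a.genes) if isinstance(a, RankedGeneList) else tuple(a)
    gb = tuple(b.genes) if isinstance(b, RankedGeneList) else tuple(b)
    for name, g in (("first", ga), ("second", gb)):
        if len(set(g)) != len(g):
            raise ValueError(f"duplicate genes in {name} ranking")
    if depth is None:
        depth = min(len(ga), len(gb))
    if depth > min(len(ga), len(gb)):
        raise ValueError("depth exceeds the shorter ranking")
    seen_a: set = set()
    seen_b: set = set()
    overlap = 0
    out = np.empty(depth, dtype=int)
    for d in range(depth):
        xa, xb = ga[d], gb[d]
        if xa == xb:
            overlap += 1
        else:
            if xa in seen_b:
                overlap += 1
            if xb in seen_a:
                overlap += 1
        seen_a.add(xa)
        seen_b.add(xb)
        out[d] = overlap
    return pd.DataFrame({"d": np.arange(1, depth + 1), "overlap": out})


def acceptance_region(d: int, N: int, level: float = 0.05) -> tuple[int, int]:
    """Smallest two-sided acceptance interval for a random overlap at depth d.

    Under the null that both top-d lists are uniform random size-d subsets
    of an N-gene universe, their overlap is hypergeometric.  Outcomes are
    accumulated in decreasing probability until at least 1 - level mass is
    covered; observed overlaps outside the returned (lower, upper) bounds
    reject random sampling.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    if d > N or d < 0:
        raise ValueError("need 0 <= d <= N")
    lo_support = max(0, 2 * d - N)
    ks = np.arange(lo_support, d + 1)
    pmf = np.exp(_log_hypergeom_pmf(ks, N, d, d))
    order = np.argsort(pmf)[::-1]
    cum = np.cumsum(pmf[order])
    m = int(np.searchsorted(cum, 1.0 - level) + 1)
    chosen = ks[order[:m]]
    return int(chosen.min()), int(chosen.max())


@dataclass
class HClustResult:
    """Complete-linkage dendrogram over samples.

    ``merges`` lists, in order, (height, members_left, members_right) with
    members as sorted tuples of sample ids.  Merge heights are
    non-decreasing (complete linkage is monotone).
    """

    sample_ids: tuple[str, ...]
    merges: list[tuple[float, tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=list
    )

    @property
    def heights(self) -> list[float]:
        return [m[0] for m in self.merges]

    def labels(self, k: int) -> pd.Series:
        """Cluster labels (0..k-1) after cutting the dendrogram at k groups."""
        n = len(self.sample_ids)
        if not (1 <= k <= n):
            raise ValueError(f"k must be in [1, {n}]")
        clusters = [(s,) for s in self.sample_ids]
        for height, left, right in self.merges[: n - k]:
            clusters = [c for c in clusters if c not in (left, right)]
            clusters.append(tuple(sorted(left + right)))
        clusters.sort()
        lab = {}
        for i, members in enumerate(clusters):
            for s in members:
                lab[s] = i
        return pd.Series([lab[s] for s in self.sample_ids], index=list(self.sample_ids))

    def to_newick(self) -> str:
        """Ultrametric Newick string (leaf depth = merge height / 2)."""
        node = {(s,): (f"{s}", 0.0) for s in self.sample_ids}
        for height, left, right in self.merges:
            sl, hl = node.pop(left)
            sr, hr = node.pop(right)
            h = height / 2.0
            s = f"({sl}:{h - hl:g},{sr}:{h - hr:g})"
            node[tuple(sorted(left + right))] = (s, h)
        (tree, _), = node.values()
        return tree + ";"


def hclust_samples(mat: pd.DataFrame) -> HClustResult:
    """Complete-linkage clustering of sample columns (Euclidean distance).

    When two candidate merges share the minimal height the pair with the
    lexicographically smallest member labels is merged first, so the
    dendrogram is fully deterministic.  Input scale is the caller's choice
    (log2 intensities / log2(count+0.5) by convention).
    """
    samples = list(map(str, mat.columns))
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    D = squareform(pdist(mat.to_numpy(dtype=float).T, metric="euclidean"))
    dist = {
        frozenset((samples[i], samples[j])): D[i, j]
        for i in range(len(samples))
        for j in range(i + 1, len(samples))
    }
    active: list[tuple[str, ...]] = [(s,) for s in sorted(samples)]

    def linkage(ca, cb):
        return max(dist[frozenset((a, b))] for a in ca for b in cb)

    result = HClustResult(sample_ids=tuple(samples))
    while len(active) > 1:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                ca, cb = sorted((active[i], active[j]))
                cand = (linkage(ca, cb), ca, cb)
                if best is None or cand < best:
                    best = cand
        height, ca, cb = best
        active = [c for c in active if c not in (ca, cb)]
        active.append(tuple(sorted(ca + cb)))
        active.sort()
        result.merges.append((float(height), ca, cb))
    return result


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    return float(spearmanr(x, y).statistic)


@dataclass
class CqTable:
    """qPCR quantification cycles per (sample, gene, replicate).

    ``table`` needs columns (sample, gene, cq); replicate rows are simply
    repeated (sample, gene) entries and are averaged before differencing.
    """

    table: pd.DataFrame
    reference_gene: str
    reference_sample: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "cq"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"CqTable needs columns {sorted(required)}")
        samples = set(self.table["sample"])
        has_ref = set(
            self.table.loc[self.table["gene"] == self.reference_gene, "sample"]
        )
        if has_ref != samples:
            raise ValueError("reference gene must be measured in every sample")
        if self.reference_sample not in samples:
            raise ValueError("reference sample missing from table")


def delta_delta_cq(tbl: CqTable, target_gene: str) -> pd.Series:
    """Relative expression of ``target_gene`` per sample by delta-delta-Cq.

    Replicate Cq values are averaged; dCq = Cq(target) - Cq(reference
    gene) per sample; ddCq subtracts dCq of the reference sample; the fold
    change is 2^(-ddCq) (1.0 at the reference sample by construction).
    """
    means = tbl.table.groupby(["sample", "gene"])["cq"].mean().unstack("gene")
    for g in (target_gene, tbl.reference_gene):
        if g not in means.columns or means[g].isna().any():
            raise ValueError(f"missing Cq measurements for gene {g!r}")
    dcq = means[target_gene] - means[tbl.reference_gene]
    ddcq = dcq - dcq.loc[tbl.reference_sample]
    return (2.0 ** (-ddcq)).rename(f"fold_change_{target_gene}")
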