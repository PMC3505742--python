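"""Differential expression between two samples without replicates.

With one sample per condition, gene-level variance cannot be estimated per
gene.  Two routes are provided:

* intensities — a pooled-scale z-test: assuming Y_gi ~ Normal(mu_gi,
  sigma^2) with a common sigma across genes, the difference Y_g1 - Y_g2 is
  Normal(0, 2 sigma^2) under the null, and the pooled scale
  s^2 = (1/(G-1)) * sum_g (Y_g1 - Y_g2)^2 (no mean-centering) turns each
  difference into a z-score z_g = (Y_g1 - Y_g2)/s;
* counts — an exact conditional test under a quadratic mean-variance
  negative binomial (NB2) with a common dispersion phi shared by all
  genes: condition on the per-gene total and sum the probabilities of all
  splits no more likely than the observed one.

Raw p-values are Benjamini-Hochberg adjusted; 0.05 is the conventional FDR
level downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import norm
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, ExpressionMatrix

__all__ = [
    "DEResult",
    "bh_adjust",
    "zscore_de_test",
    "estimate_common_dispersion",
    "nb_exact_test",
    "log2_fold_change_counts",
]


@dataclass
class DEResult:
    """Per-gene effect sizes and (adjusted) p-values.

    ``table`` is indexed by gene with columns ``log2_fc``, ``p_raw``,
    ``p_adj`` and ``direction`` ("up" = higher in the first sample).
    """

    table: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        cols = {"log2_fc", "p_raw", "p_adj", "direction"}
        if not cols.issubset(self.table.columns):
            raise ValueError(f"DEResult table needs columns {sorted(cols)}")
        if (self.table["p_adj"] + 1e-12 < self.table["p_raw"]).any():
            raise ValueError("adjusted p-values cannot be below raw p-values")

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < fdr].sort_values("p_adj")

    def ranked_genes(self) -> list[str]:
        """Genes ordered by increasing raw p (significance ranking)."""
        order = self.table.sort_values(["p_raw", "p_adj"], kind="mergesort")
        return list(order.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def zscore_de_test(pair: ExpressionMatrix) -> DEResult:
    """Pooled-scale z-test between exactly two samples.

    The matrix is used on the scale provided; when it holds log2
    intensities, the reported effect (first minus second column) is a log2
    fold change.  The pooled scale s is computed over all genes, including
    any truly changed ones, exactly as defined; no robustification.
    """
    if pair.n_samples != 2:
        raise ValueError("zscore_de_test needs exactly two samples")
    if pair.n_genes < 2:
        raise ValueError("need at least two genes to pool a scale")
    y = pair.values.to_numpy(dtype=float)
    d = y[:, 0] - y[:, 1]
    s2 = (d**2).sum() / (len(d) - 1)
    if s2 == 0.0:
        raise ValueError("degenerate input: the two samples are identical (s = 0)")
    s = np.sqrt(s2)
    z = d / s
    p = 2.0 * norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "log2_fc": d,
            "z": z,
            "p_raw": p,
            "p_adj": bh_adjust(p),
            "direction": np.where(d >= 0, "up", "down"),
        },
        index=pair.values.index,
    )
    return DEResult(table, method="zscore")


# ---------------------------------------------------------------------------
# NB2 conditional machinery: for Y1, Y2 i.i.d. NB2 with common mean and
# dispersion phi (shape r = 1/phi), the split Y1 | Y1+Y2 = n follows
#   P(y | n) = C(y+r-1, y) C(n-y+r-1, n-y) / C(n+2r-1, n),
# free of the mean — the basis of both the exact test and the conditional
# maximum-likelihood dispersion estimate.
# ---------------------------------------------------------------------------


def _cond_logpmf(n: int, phi: float) -> np.ndarray:
    """log P(Y1 = y | Y1+Y2 = n) for y = 0..n under equal-mean NB2(phi)."""
    y = np.arange(n + 1)
    if phi <= 0:
        # Poisson limit: Binomial(n, 1/2)
        return (
            gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1) - n * np.log(2.0)
        )
    r = 1.0 / phi
    lp = (
        gammaln(y + r)
        - gammaln(y + 1)
        + gammaln(n - y + r)
        - gammaln(n - y + 1)
        - 2 * gammaln(r)
        - (gammaln(n + 2 * r) - gammaln(n + 1) - gammaln(2 * r))
    )
    return lp - logsumexp(lp)  # guard cumulative rounding


def estimate_common_dispersion(
    pair: CountMatrix, phi: float | None = None, max_phi: float = 100.0
) -> float:
    """Common NB2 dispersion for a two-sample pair.

    With one sample per group, dispersion is not identifiable from
    between-group variation; the estimate instead maximises the exact
    conditional likelihood of the per-gene splits given their totals,
    treating the two samples as replicates of one group (most genes
    assumed non-DE).  With equal library sizes this conditional likelihood
    is the small-sample quantity the Cox-Reid adjusted profile likelihood
    approximates.  Pass ``phi`` to skip estimation entirely.
    """
    if phi is not None:
        if phi < 0:
            raise ValueError("phi must be >= 0")
        return float(phi)
    if pair.n_samples != 2:
        raise ValueError("dispersion estimation needs exactly two samples")
    y1 = pair.counts.iloc[:, 0].to_numpy()
    y2 = pair.counts.iloc[:, 1].to_numpy()
    totals = y1 + y2
    keep = totals > 0
    if not keep.any():
        raise ValueError("all genes have zero total count")
    y1, totals = y1[keep], totals[keep]

    def negloglik(log_phi: float) -> float:
        ph = np.exp(log_phi)
        ll = 0.0
        for yy, nn in zip(y1, totals):
            ll += _cond_logpmf(int(nn), ph)[int(yy)]
        return -ll

    res = minimize_scalar(
        negloglik,
        bounds=(np.log(1e-6), np.log(max_phi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(
            f"dispersion estimation did not converge in [1e-6, {max_phi}]: {res}"
        )
    phi_hat = float(np.exp(res.x))
    # Poisson boundary: if phi -> 0 fits at least as well, report 0
    if negloglik(np.log(1e-6)) <= res.fun + 1e-9 or phi_hat <= 2e-6:
        return 0.0
    return phi_hat


def log2_fold_change_counts(y1: float, y2: float, pseudocount: float = 0.5) -> float:
    """log2((y1+c)/(y2+c)) on library-size-equalised counts."""
    if y1 < 0 or y2 < 0:
        raise ValueError("counts must be non-negative")
    return float(np.log2((y1 + pseudocount) / (y2 + pseudocount)))


def nb_exact_test(
    pair: CountMatrix,
    phi: float,
    pseudocount: float = 0.5,
    sidedness: str = "doubletail",
) -> DEResult:
    """Exact two-sample NB2 test conditioning on per-gene totals.

    Requires equal effective library sizes (subsample first).  Two-sided
    p-values default to doubling the smaller conditional tail (clipped at
    1), the rule of the standard count exact test; it keeps a balanced
    split at p = 1 for every dispersion.  ``sidedness="minlik"`` instead
    sums the probabilities of all splits no more likely than the observed
    one — equivalent for phi <= 1, but for phi > 1 the conditional split
    distribution is U-shaped and minlik then treats balanced splits as
    extreme.  Genes with total 0 get p = 1 by convention.
    """
    if pair.n_samples != 2:
        raise ValueError("nb_exact_test needs exactly two samples")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if sidedness not in ("doubletail", "minlik"):
        raise ValueError("sidedness must be 'doubletail' or 'minlik'")
    if pair.lib_sizes.iloc[0] != pair.lib_sizes.iloc[1]:
        import warnings

        warnings.warn(
            "library sizes differ; the exact test assumes equalised libraries "
            "(run subsample_to_min_library first)",
            stacklevel=2,
        )
    y1 = pair.counts.iloc[:, 0].to_numpy()
    y2 = pair.counts.iloc[:, 1].to_numpy()
    pvals = np.ones(len(y1))
    cache: dict[int, np.ndarray] = {}
    for g, (a, n) in enumerate(zip(y1, y1 + y2)):
        n = int(n)
        if n == 0:
            continue
        lp = cache.get(n)
        if lp is None:
            lp = _cond_logpmf(n, phi)
            if len(cache) < 4096:
                cache[n] = lp
        a = int(a)
        if sidedness == "minlik":
            mask = lp <= lp[a] + 1e-12  # tolerate float ties
            pvals[g] = min(1.0, float(np.exp(logsumexp(lp[mask]))))
        else:
            lower = logsumexp(lp[: a + 1])
            upper = logsumexp(lp[a:])
            pvals[g] = min(1.0, 2.0 * float(np.exp(min(lower, upper))))
    lfc = np.log2((y1 + pseudocount) / (y2 + pseudocount))
    table = pd.DataFrame(
        {
            "log2_fc": lfc,
            "p_raw": pvals,
            "p_adj": bh_adjust(pvals),
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=pair.counts.index,
    )
    return DEResult(table, method="nbexact")
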