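"""Synthetic dilution-series generators.

The generators produce data with exactly the statistical structure the
downstream fits assume, so every stage of the pipeline is testable without
external data:

* intensities:  y_ki = t_k * p_i + b + eps,  eps ~ Normal(0, sigma^2) — a
  shared additive background b with gene-individual slopes t_k (the
  abundance in the pure target sample);
* counts:  y_ki ~ NBx(t_k * p_i * M_i / M_ref, theta), x in {1, 2}, with
  zero background (a transcript absent from the mixture yields count 0
  with probability 1) and a common dispersion theta.

NB1 denotes the linear mean-variance parameterisation (var = mu + theta*mu),
NB2 the quadratic one (var = mu + theta*mu^2); both reduce to Poisson as
theta -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CountMatrix, DilutionDesign, ExpressionMatrix

__all__ = [
    "SimConfig",
    "sample_nb",
    "simulate_exon_dilution",
    "simulate_tag_dilution",
    "simulate_two_group",
]


def _log_uniform(rng: np.random.Generator, low: float, high: float, n: int):
    return np.exp(rng.uniform(np.log(low), np.log(high), size=n))


@dataclass
class SimConfig:
    """Parameters of a simulated dilution experiment.

    Attributes
    ----------
    n_genes
        Number of genes simulated.
    design
        Purity grid; defaults to the eight-point mixing series
        (0, 0.5, 1, 5, 10, 20, 30, 100 percent target cells).
    background
        Shared additive background ``b`` for intensities (counts assume 0).
    sigma
        Residual SD of the intensity noise.
    theta
        Common NB dispersion for counts (0 = Poisson).
    abundances
        Per-gene pure-sample abundances t_k.  If None, signature genes draw
        t_k log-uniformly from ``abundance_range`` (no canonical abundance
        law exists for real transcriptomes, so the sampling law is
        configurable rather than fixed).
    abundance_range
        (low, high) of the log-uniform abundance law.
    fraction_signature
        Share of genes with t_k > 0 (purity-responsive); the rest are
        background-only (t_k = 0).
    lib_sizes
        Per-sample library sizes M_i for counts; mean scales by M_i/M_ref
        with M_ref the smallest library (None = all equal).
    truncate_at_zero
        Clip negative intensities at 0.  Off by default: the linear model
        fitted downstream is untruncated.
    seed
        Seed for the internal generator.
    """

    n_genes: int
    design: DilutionDesign = field(default_factory=DilutionDesign.default)
    background: float = 100.0
    sigma: float = 224.0
    theta: float = 2.0
    abundances: np.ndarray | None = None
    abundance_range: tuple[float, float] = (500.0, 50_000.0)
    fraction_signature: float = 1.0
    lib_sizes: np.ndarray | None = None
    truncate_at_zero: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.sigma < 0 or self.theta < 0:
            raise ValueError("sigma and theta must be non-negative")
        if not (0.0 <= self.fraction_signature <= 1.0):
            raise ValueError("fraction_signature must be in [0, 1]")
        if self.abundances is not None:
            self.abundances = np.asarray(self.abundances, dtype=float)
            if self.abundances.shape != (self.n_genes,):
                raise ValueError("abundances must have length n_genes")
            if (self.abundances < 0).any():
                raise ValueError("abundances must be non-negative")
        if self.lib_sizes is not None:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
            if self.lib_sizes.shape != (len(self.design),):
                raise ValueError("lib_sizes must have one entry per sample")
            if (self.lib_sizes <= 0).any():
                raise ValueError("lib_sizes must be positive")

    def draw_abundances(self, rng: np.random.Generator) -> np.ndarray:
        if self.abundances is not None:
            return self.abundances.copy()
        t = np.zeros(self.n_genes)
        n_sig = int(round(self.fraction_signature * self.n_genes))
        t[:n_sig] = _log_uniform(rng, *self.abundance_range, n_sig)
        return t


def sample_nb(
    rng: np.random.Generator,
    mu,
    theta: float,
    model: str,
    size=None,
):
    """Draw NB1 or NB2 variates via the Poisson-Gamma mixture.

    NB1(mu, theta): Gamma(shape=mu/theta, scale=theta) mixing mean, giving
    var = mu + theta*mu.  NB2(mu, theta): Gamma(shape=1/theta,
    scale=mu*theta), giving var = mu + theta*mu^2.  theta=0 falls back to
    Poisson; mu=0 yields 0 with probability 1.
    """
    if model not in ("NB1", "NB2"):
        raise ValueError(f"model must be 'NB1' or 'NB2', got {model!r}")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size or np.shape(mu)).copy()
    if (mu < 0).any():
        raise ValueError("mean must be >= 0")
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if theta == 0:
        out[pos] = rng.poisson(mu[pos])
        return out
    if model == "NB1":
        lam = rng.gamma(shape=mu[pos] / theta, scale=theta)
    else:
        lam = rng.gamma(shape=1.0 / theta, scale=mu[pos] * theta)
    out[pos] = rng.poisson(lam)
    return out


def _frame(values: np.ndarray, design: DilutionDesign) -> pd.DataFrame:
    genes = [f"g{k:04d}" for k in range(values.shape[0])]
    return pd.DataFrame(values, index=genes, columns=list(design.sample_ids))


def simulate_exon_dilution(cfg: SimConfig):
    """Simulate intensity measurements over the dilution grid.

    Returns
    -------
    (ExpressionMatrix, truth)
        ``truth`` is a dict with keys ``background``, ``sigma`` and
        ``abundances`` (a per-gene Series of the true slopes t_k).
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.draw_abundances(rng)
    x = cfg.design.x
    mean = np.outer(t, x) + cfg.background
    y = mean + rng.normal(0.0, cfg.sigma, size=mean.shape)
    if cfg.truncate_at_zero:
        y = np.clip(y, 0.0, None)
    mat = ExpressionMatrix(_frame(y, cfg.design), cfg.design)
    truth = {
        "background": cfg.background,
        "sigma": cfg.sigma,
        "abundances": pd.Series(t, index=mat.values.index, name="t_k"),
    }
    return mat, truth


def simulate_tag_dilution(cfg: SimConfig, model: str = "NB1"):
    """Simulate tag counts over the dilution grid under NB1 or NB2.

    Mean of gene k in sample i is t_k * p_i * (M_i / M_ref) with M_ref the
    smallest library; background is zero, so counts at purity 0 are zero
    with probability 1.

    Returns
    -------
    (CountMatrix, truth)
        ``truth`` carries ``theta``, ``model`` and the per-gene ``abundances``.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.draw_abundances(rng)
    x = cfg.design.x
    mean = np.outer(t, x)
    if cfg.lib_sizes is not None:
        mean = mean * (cfg.lib_sizes / cfg.lib_sizes.min())
    counts = sample_nb(rng, mean, cfg.theta, model)
    mat = CountMatrix(_frame(counts, cfg.design), cfg.design)
    truth = {
        "theta": cfg.theta,
        "model": model,
        "abundances": pd.Series(t, index=mat.counts.index, name="t_k"),
    }
    return mat, truth


def simulate_two_group(
    n_genes: int,
    n_de: int,
    effect: float,
    model: str = "gaussian",
    theta: float = 0.2,
    base_mean: float = 100.0,
    sigma: float = 1.0,
    seed: int = 0,
):
    """Two single-sample groups with a known set of perturbed genes.

    The first ``n_de`` genes carry a log2 fold change of ``effect`` between
    the two samples (alternating sign); the rest are null.  For
    ``model="gaussian"`` the matrix holds log2-scale intensities with noise
    SD ``sigma``; for ``model="NB2"`` it holds counts with dispersion
    ``theta`` around a mean of ``base_mean``.

    Returns
    -------
    (matrix, truth)
        ``truth`` is a boolean Series marking the truly perturbed genes.
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    design = DilutionDesign((1.0, 0.0), ("s1", "s2"))
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    if model == "gaussian":
        base = rng.uniform(5.0, 12.0, size=n_genes)
        y = np.column_stack([base, base.copy()])
        y[:n_de, 0] += signs * effect / 2.0
        y[:n_de, 1] -= signs * effect / 2.0
        y += rng.normal(0.0, sigma, size=y.shape)
        y -= y.min() if y.min() < 0 else 0.0
        mat = ExpressionMatrix(_frame(y, design), design)
    elif model == "NB2":
        mu = np.full((n_genes, 2), base_mean, dtype=float)
        fc = 2.0 ** (signs * effect / 2.0)
        mu[:n_de, 0] *= fc
        mu[:n_de, 1] /= fc
        counts = sample_nb(rng, mu, theta, "NB2")
        mat = CountMatrix(_frame(counts, design), design)
    else:
        raise ValueError(f"model must be 'gaussian' or 'NB2', got {model!r}")
    truth = pd.Series(
        np.arange(n_genes) < n_de, index=mat.values.index if model == "gaussian" else mat.counts.index,
        name="is_de",
    )
    return mat, truth
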