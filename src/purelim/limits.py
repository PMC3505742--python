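"""Instrument and method detection limits from dilution regressions.

The instrument detection limit (IDL) is the smallest true signal whose
measurement is distinguishable from the blank with a stated confidence
(default 95%), a concept borrowed from analytical chemistry.  For the
three measurement models supported here the IDL has a closed form:

* Gaussian intensities, Y(t) = t + b + eps with eps ~ N(0, sigma^2):
  IDL = z * sigma with z the one-sided normal factor (1.64 at 95%);
* NB1 counts (variance mu + theta*mu):  P(Y=0) = (1+theta)^(-mu/theta),
  so IDL = theta * ln(1/alpha) / ln(1+theta) with alpha = 1 - confidence;
* NB2 counts (variance mu + theta*mu^2):  P(Y=0) = (1+mu*theta)^(-1/theta),
  so IDL = ((1/alpha)^theta - 1) / theta.

Both NB limits tend to -ln(alpha) (= ln 20 at 95%) as theta -> 0, the
Poisson limit.  The method detection limit at sample purity p is simply
MDL(p) = IDL / p: a transcript must be IDL/p abundant in the pure target
population to be seen in a mixture containing a fraction p of it.
Equivalently, a gene with pure-sample abundance t_k needs purity of at
least IDL / t_k to be detectable.

Model parameters (b, sigma, t_k; theta, t_k) are estimated from dilution
series: intensities by least squares with a common intercept and
gene-individual slopes, counts by joint maximum likelihood with a common
dispersion and per-gene log-abundances a_k = log t_k, mean t_k * p_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, shapiro

from .containers import CountMatrix, ExpressionMatrix

__all__ = [
    "GaussianDilutionFit",
    "NBDilutionFit",
    "MDLCurve",
    "nb_logpmf",
    "nb_pmf",
    "nb_cdf",
    "gaussian_idl",
    "nb_idl",
    "fit_gaussian_dilution",
    "fit_nb_dilution",
    "mdl_curve",
    "required_purity",
    "model_diagnostics",
]

#: One-sided 95% normal factor as conventionally rounded in detection-limit
#: work; pass ``z_factor=scipy.stats.norm.ppf(0.95)`` for full precision.
DEFAULT_Z = 1.64


# ---------------------------------------------------------------------------
# Negative binomial pmf/cdf in both parameterisations
# ---------------------------------------------------------------------------


def _check_nb_args(model: str, theta: float) -> None:
    if model not in ("NB1", "NB2"):
        raise ValueError(f"model must be 'NB1' or 'NB2', got {model!r}")
    if theta < 0:
        raise ValueError("theta must be >= 0")


def nb_logpmf(k, mu, theta: float, model: str):
    """Log pmf of NB1 or NB2 at counts ``k`` and mean ``mu`` (vectorised).

    theta = 0 is the Poisson limit; mu = 0 puts all mass on k = 0.
    """
    _check_nb_args(model, theta)
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if (k < 0).any() or not np.all(k == np.floor(k)):
        raise ValueError("k must be non-negative integers")
    if (mu < 0).any():
        raise ValueError("mu must be >= 0")
    k, mu = np.broadcast_arrays(k, mu)
    out = np.full(k.shape, -np.inf)
    zero_mu = mu == 0
    out[zero_mu & (k == 0)] = 0.0
    m = ~zero_mu
    if m.any():
        kk, mm = k[m], mu[m]
        if theta == 0:
            out[m] = kk * np.log(mm) - mm - gammaln(kk + 1)
        elif model == "NB1":
            r = mm / theta
            out[m] = (
                gammaln(kk + r)
                - gammaln(r)
                - gammaln(kk + 1)
                + kk * np.log(theta / (1.0 + theta))
                - r * np.log1p(theta)
            )
        else:
            r = 1.0 / theta
            out[m] = (
                gammaln(kk + r)
                - gammaln(r)
                - gammaln(kk + 1)
                + kk * (np.log(mm * theta) - np.log1p(mm * theta))
                - r * np.log1p(mm * theta)
            )
    return out if out.shape else float(out)


def nb_pmf(k, mu, theta: float, model: str):
    """Pmf of NB1 or NB2 (exp of :func:`nb_logpmf`)."""
    return np.exp(nb_logpmf(k, mu, theta, model))


def nb_cdf(k, mu, theta: float, model: str):
    """CDF of NB1 or NB2 via scipy's negative binomial / Poisson."""
    from scipy.stats import nbinom, poisson

    _check_nb_args(model, theta)
    k = np.asarray(k, dtype=float)
    mu = np.asarray(mu, dtype=float)
    k, mu = np.broadcast_arrays(k, mu)
    out = np.where(k >= 0, 1.0, 0.0)
    m = mu > 0
    if m.any():
        if theta == 0:
            out = np.where(m, poisson.cdf(k, mu), out)
        elif model == "NB1":
            out = np.where(m, nbinom.cdf(k, mu / theta, 1.0 / (1.0 + theta)), out)
        else:
            out = np.where(
                m, nbinom.cdf(k, 1.0 / theta, 1.0 / (1.0 + mu * theta)), out
            )
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Closed-form detection limits
# ---------------------------------------------------------------------------


def gaussian_idl(sigma: float, z_factor: float = DEFAULT_Z) -> float:
    """IDL of the Gaussian intensity model: ``z_factor * sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return z_factor * sigma


def nb_idl(theta: float, model: str, confidence: float = 0.95) -> float:
    """Closed-form IDL of the NB1 or NB2 count model.

    The smallest mean at which a zero count has probability at most
    1 - confidence.  The classical "20" in the 95% formulas is derived as
    1/(1-confidence), never hard-coded.
    """
    _check_nb_args(model, theta)
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    log_inv_alpha = -np.log1p(-confidence)  # ln(1/(1-conf))
    if theta == 0:
        return float(log_inv_alpha)
    if model == "NB1":
        return float(theta * log_inv_alpha / np.log1p(theta))
    return float(np.expm1(theta * log_inv_alpha) / theta)


# ---------------------------------------------------------------------------
# Gaussian dilution regression
# ---------------------------------------------------------------------------


@dataclass
class GaussianDilutionFit:
    """Least-squares fit of y_ki = t_k * p_i + b + eps, common sigma.

    ``idl`` always equals ``z_factor * sigma_hat``; ``df`` equals
    n_obs - n_genes - 1 (one slope per gene plus the shared intercept).
    """

    background: float
    sigma_hat: float
    abundances: pd.Series  # per-gene slopes t_k
    z_factor: float
    df: int
    fitted: pd.DataFrame
    std_residuals: pd.DataFrame
    outlier_threshold: float = 3.0

    @property
    def idl(self) -> float:
        return gaussian_idl(self.sigma_hat, self.z_factor)

    @property
    def outliers(self) -> pd.DataFrame:
        """Long-format (gene, sample, std_residual) rows with |r| > 3."""
        long = self.std_residuals.stack()
        flagged = long[long.abs() > self.outlier_threshold]
        return (
            flagged.rename("std_residual")
            .rename_axis(["gene", "sample"])
            .reset_index()
        )


def fit_gaussian_dilution(
    mat: ExpressionMatrix, genes=None, z_factor: float = DEFAULT_Z
) -> GaussianDilutionFit:
    """Fit the shared-background, gene-individual-slope dilution regression.

    Linear-scale intensities are required (an IDL on a log scale is not
    meaningful).  Outlying observations (|standardised residual| > 3) are
    reported but retained in the fit.
    """
    if genes is not None:
        mat = mat.subset(genes)
    x = mat.design.x
    if len(np.unique(x)) < 2:
        raise ValueError("all purities equal: slopes are not identifiable")
    y = mat.values.to_numpy(dtype=float)
    K, n = y.shape
    if K < 1:
        raise ValueError("need at least one gene")
    # design: one slope column per gene (x in that gene's rows) + intercept
    N = K * n
    X = np.zeros((N, K + 1))
    for k in range(K):
        X[k * n : (k + 1) * n, k] = x
    X[:, K] = 1.0
    yy = y.reshape(N)
    beta, _, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
    if rank < K + 1:
        raise ValueError("rank-deficient dilution design")
    resid = yy - X @ beta
    df = N - K - 1
    if df <= 0:
        raise ValueError("not enough observations for a residual SD")
    sigma_hat = float(np.sqrt((resid**2).sum() / df))
    # a residual SD at float-noise level means an exact (degenerate) fit
    scale = max(1.0, float(np.abs(yy).max()))
    if sigma_hat <= 1e-10 * scale:
        sigma_hat = 0.0
    # internally studentised residuals need the leverages
    Q, _ = np.linalg.qr(X)
    h = (Q**2).sum(axis=1)
    if sigma_hat == 0:
        std = np.zeros(N)
    else:
        std = resid / (sigma_hat * np.sqrt(np.clip(1.0 - h, 1e-12, None)))
    cols = list(mat.values.columns)
    idx = mat.values.index
    return GaussianDilutionFit(
        background=float(beta[K]),
        sigma_hat=sigma_hat,
        abundances=pd.Series(beta[:K], index=idx, name="t_k"),
        z_factor=z_factor,
        df=df,
        fitted=pd.DataFrame((X @ beta).reshape(K, n), index=idx, columns=cols),
        std_residuals=pd.DataFrame(std.reshape(K, n), index=idx, columns=cols),
    )


# ---------------------------------------------------------------------------
# Negative binomial dilution regression
# ---------------------------------------------------------------------------


@dataclass
class NBDilutionFit:
    """Joint ML fit of counts ~ NBx(t_k * p_i, theta), common dispersion."""

    model: str
    theta_hat: float
    log_abundances: pd.Series  # a_k = log t_k
    confidence: float
    loglik: float
    deviance: float
    design_x: np.ndarray = field(repr=False)
    counts: pd.DataFrame = field(repr=False, default=None)
    background_eps: float = 0.0

    @property
    def abundances(self) -> pd.Series:
        return np.exp(self.log_abundances).rename("t_k")

    @property
    def idl(self) -> float:
        return nb_idl(self.theta_hat, self.model, self.confidence)

    @property
    def fitted(self) -> pd.DataFrame:
        mu = np.outer(np.exp(self.log_abundances.to_numpy()), self.design_x)
        if self.background_eps > 0:
            mu[:, self.design_x == 0] = self.background_eps
        return pd.DataFrame(
            mu, index=self.log_abundances.index, columns=self.counts.columns
        )

    def quantile_residuals(self, seed: int = 0) -> pd.DataFrame:
        """Randomised quantile residuals (N(0,1) under a correct model).

        For each count y the fitted CDF interval (F(y-1), F(y)) is sampled
        uniformly and mapped through the standard normal quantile; the
        randomisation is seeded for reproducibility.
        """
        rng = np.random.default_rng(seed)
        y = self.counts.to_numpy(dtype=float)
        mu = self.fitted.to_numpy()
        lo = nb_cdf(y - 1, mu, self.theta_hat, self.model)
        hi = nb_cdf(y, mu, self.theta_hat, self.model)
        u = rng.uniform(lo, np.clip(hi, lo + 1e-300, None))
        q = norm.ppf(np.clip(u, 1e-12, 1.0 - 1e-12))
        return pd.DataFrame(q, index=self.counts.index, columns=self.counts.columns)


def _nb_loglik_matrix(y, mu, theta, model):
    return nb_logpmf(y, mu, theta, model).sum()


def _cr_penalty(y, x, theta, model, a):
    """Cox-Reid adjustment: 0.5 * sum_k log I_k(a_k) over nuisance slopes.

    I_k is the per-gene observed information in a_k at the profile
    maximum, from a central finite difference (h = 1e-3 on the log scale).
    """
    pos = x > 0
    xp, yp = x[pos], y[:, pos]
    h = 1e-3

    def per_gene(av):
        mu = np.exp(av)[:, None] * xp[None, :]
        return nb_logpmf(yp, mu, theta, model).sum(axis=1)

    l0, lp, lm = per_gene(a), per_gene(a + h), per_gene(a - h)
    info = -(lp - 2 * l0 + lm) / h**2
    return 0.5 * np.sum(np.log(np.clip(info, 1e-12, None)))


def _profile_abundances(y, x, theta, model, a_init, rounds=(4.0, 0.5, 0.0625, 0.008)):
    """Maximise the log-likelihood over per-gene a_k at fixed theta.

    Vectorised grid refinement: each round evaluates 33 candidate offsets
    around the incumbent per gene and zooms in; robust for theta spanning
    orders of magnitude, no derivatives needed.
    """
    pos = x > 0
    xp = x[pos]
    yp = y[:, pos]
    a = a_init.copy()
    for w in rounds:
        offs = np.linspace(-w, w, 33)
        best_ll = np.full(a.shape, -np.inf)
        best_a = a.copy()
        for o in offs:
            cand = a + o
            mu = np.exp(cand)[:, None] * xp[None, :]
            ll = nb_logpmf(yp, mu, theta, model).sum(axis=1)
            better = ll > best_ll
            best_ll[better] = ll[better]
            best_a[better] = cand[better]
        a = best_a
    return a, best_ll.sum()


def fit_nb_dilution(
    mat: CountMatrix,
    genes=None,
    model: str = "NB1",
    confidence: float = 0.95,
    background_eps: float = 0.0,
    theta_grid=None,
    dispersion_adjust: str = "cox-reid",
    qres_seed: int = 0,
) -> NBDilutionFit:
    """Joint ML dilution fit of counts with a common dispersion.

    Library sizes should be equalised beforehand (subsampling).  Genes
    with all-zero rows are dropped with a warning, as are genes with
    non-zero counts in zero-purity samples (impossible under a zero
    background; set ``background_eps`` > 0 to keep them with a small fixed
    mean at purity 0 instead).

    theta is profiled on a log grid and polished by a bounded golden
    search; per-gene log-abundances are maximised by vectorised grid
    refinement at each candidate theta.  With one dispersion shared by
    many genes and one free slope per gene, the plain profile likelihood
    underestimates theta (incidental-parameter bias), so the profile is
    Cox-Reid adjusted by default; pass ``dispersion_adjust="none"`` for
    the unadjusted joint ML.
    """
    if dispersion_adjust not in ("cox-reid", "none"):
        raise ValueError("dispersion_adjust must be 'cox-reid' or 'none'")
    _check_nb_args(model, 0.0)
    if genes is not None:
        mat = mat.subset(genes)
    x = mat.design.x
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct purities")
    counts = mat.counts
    y = counts.to_numpy(dtype=float)

    zero_rows = (y == 0).all(axis=1)
    if zero_rows.any():
        warnings.warn(
            f"dropping {int(zero_rows.sum())} all-zero gene rows from the NB fit",
            stacklevel=2,
        )
    leak = (y[:, x == 0] > 0).any(axis=1) if (x == 0).any() else np.zeros(len(y), bool)
    if leak.any() and background_eps == 0.0:
        warnings.warn(
            f"dropping {int(leak.sum())} genes with non-zero counts at purity 0 "
            "(zero-background model; pass background_eps to keep them)",
            stacklevel=2,
        )
        keep = ~zero_rows & ~leak
    else:
        keep = ~zero_rows
    counts = counts.loc[keep]
    y = y[keep]
    if y.shape[0] == 0:
        raise ValueError("no usable genes left for the NB fit")

    pos = x > 0
    a0 = np.log(np.clip(y[:, pos].sum(axis=1) / x[pos].sum(), 1e-8, None))

    # constant likelihood contribution of purity-0 columns
    if (x == 0).any():
        mu0 = np.full((y.shape[0], int((~pos).sum())), background_eps)
    else:
        mu0 = None

    def profile(theta):
        a, ll = _profile_abundances(y, x, theta, model, a0)
        if mu0 is not None:
            ll += _nb_loglik_matrix(y[:, ~pos], mu0, theta, model)
        obj = ll
        if dispersion_adjust == "cox-reid":
            obj = ll - _cr_penalty(y, x, theta, model, a)
        return a, ll, obj

    if theta_grid is None:
        theta_grid = np.concatenate([[0.0], np.logspace(-3, 2, 26)])
        if dispersion_adjust == "cox-reid":
            theta_grid = theta_grid[theta_grid > 0]  # penalty needs theta > 0
    objs = np.array([profile(th)[2] for th in theta_grid])
    best = int(np.argmax(objs))

    # polish around the best grid point on the log-theta scale
    if 0 < best < len(theta_grid) - 1 and theta_grid[best] > 0:
        from scipy.optimize import minimize_scalar

        lo = max(theta_grid[best - 1], 1e-8)
        hi = theta_grid[best + 1]
        res = minimize_scalar(
            lambda lt: -profile(np.exp(lt))[2],
            bounds=(np.log(lo), np.log(hi)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        theta_hat = float(np.exp(res.x))
        if -res.fun < objs[best]:  # keep grid optimum if polish failed
            theta_hat = float(theta_grid[best])
    else:
        theta_hat = float(theta_grid[best])

    a_hat, ll_hat, _ = profile(theta_hat)
    mu_hat = np.exp(a_hat)[:, None] * x[None, :]
    if mu0 is not None:
        mu_hat[:, ~pos] = background_eps
    ll_sat = _nb_loglik_matrix(y, y, theta_hat, model)
    fit = NBDilutionFit(
        model=model,
        theta_hat=theta_hat,
        log_abundances=pd.Series(a_hat, index=counts.index, name="a_k"),
        confidence=confidence,
        loglik=float(ll_hat),
        deviance=float(2.0 * (ll_sat - ll_hat)),
        design_x=x,
        counts=counts,
        background_eps=background_eps,
    )
    return fit


# ---------------------------------------------------------------------------
# Method detection limit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MDLCurve:
    """MDL(p) = IDL / p over a purity grid."""

    idl: float
    purities: tuple[float, ...]
    mdl: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"purity": self.purities, "mdl": self.mdl})


def mdl_curve(idl: float, purities) -> MDLCurve:
    """Method detection limit as a function of purity (inverse proportional)."""
    if idl < 0:
        raise ValueError("idl must be >= 0")
    p = np.asarray(purities, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("purities must lie in (0, 1]; MDL is undefined at p = 0")
    return MDLCurve(idl=float(idl), purities=tuple(p), mdl=tuple(idl / p))


def required_purity(t_k, idl: float):
    """Smallest purity at which a gene of pure-sample abundance t_k is detectable.

    min(idl / t_k, 1) for t_k > 0; NaN for genes not elevated in the pure
    target sample (t_k <= 0), mirroring how detection-limit tables mark
    down-regulated genes NA.
    """
    if idl < 0:
        raise ValueError("idl must be >= 0")
    t = np.asarray(t_k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rp = np.where(t > 0, np.minimum(idl / t, 1.0), np.nan)
    return rp if rp.shape else float(rp)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def model_diagnostics(fit, seed: int = 0) -> dict:
    """Residual diagnostics as plain tables (rendering is optional).

    Gaussian fits yield standardised residuals vs fitted values, their
    normal-probability ordinates, the outlier list (|r| > 3) and a
    Shapiro-Wilk statistic; NB fits yield randomised quantile residuals
    (seeded) vs fitted values and the deviance.  A degenerate fit with all
    residuals zero is flagged instead of tested.
    """
    if isinstance(fit, GaussianDilutionFit):
        r = fit.std_residuals.stack().to_numpy()
        table = pd.DataFrame(
            {
                "fitted": fit.fitted.stack().to_numpy(),
                "std_residual": r,
            }
        )
        out = {
            "kind": "gaussian",
            "residual_table": table,
            "outliers": fit.outliers,
            "degenerate": bool(np.allclose(r, 0.0)),
        }
        if not out["degenerate"]:
            order = np.sort(r)
            nn = len(order)
            theo = norm.ppf((np.arange(1, nn + 1) - 0.375) / (nn + 0.25))
            out["normal_probability"] = pd.DataFrame(
                {"theoretical": theo, "observed": order}
            )
            sub = order if nn <= 5000 else np.random.default_rng(seed).choice(
                order, 5000, replace=False
            )
            out["shapiro_stat"], out["shapiro_p"] = map(float, shapiro(sub))
        return out
    if isinstance(fit, NBDilutionFit):
        q = fit.quantile_residuals(seed=seed)
        table = pd.DataFrame(
            {
                "fitted": fit.fitted.stack().to_numpy(),
                "quantile_residual": q.stack().to_numpy(),
            }
        )
        return {
            "kind": fit.model,
            "residual_table": table,
            "deviance": fit.deviance,
            "degenerate": bool(np.allclose(q.to_numpy(), 0.0)),
        }
    raise TypeError(f"unsupported fit type: {type(fit).__name__}")
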