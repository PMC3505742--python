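# Methods

## Measurement models and detection limits

The package treats "can this transcript be detected?" as a detection-limit
problem. The blank level is what the platform reports when the transcript
is absent; the instrument detection limit (IDL) is the smallest true
signal `t` for which `P(Y(t) > blank) ≥ confidence`, with confidence 0.95
throughout (a parameter everywhere; the `20` appearing in the count
formulas is `1/(1 − confidence)`).

**Intensities.** `Y(t) = t + b + ε`, `ε ~ N(0, σ²)`. The blank is `b`, so
`IDL = z·σ` with `z` the one-sided normal factor. The default `z = 1.64`
is the conventional rounding used in detection-limit work; the
full-precision quantile (1.6449…) can be passed explicitly. The dilution
regression `y_ki = t_k·x_i + b + ε_ki` is fitted by least squares with a
single shared intercept and one slope per gene; the residual SD uses
`df = N_obs − K − 1`. Intensities must be on a linear scale — an IDL on a
log scale is meaningless; `ExpressionMatrix.log2()` exists only for the
DE/clustering stages, which conventionally work on log2 values.
Standardised (internally studentised) residuals above 3 in magnitude are
reported as outliers but never removed. Negative intensities are
tolerated in the containers: background-corrected measurements and the
untruncated Gaussian model both produce them.

**Counts.** Zero background: a transcript absent from the mixture gives
count 0 with probability 1. Two negative binomial parameterisations are
supported, NB1 with variance `μ + θμ` and NB2 with `μ + θμ²`, both
Poisson at `θ = 0`. Setting `P(Y = 0 | μ) ≤ 1 − confidence` gives the
closed forms `θ·ln20/ln(1+θ)` (NB1) and `(20^θ − 1)/θ` (NB2). These are
verified in the test suite against a bisection root of the implemented
pmf — the central internal oracle. Note the practical asymmetry: at the
same θ the NB2 limit explodes (θ = 2 gives ~200 counts) while NB1 grows
slowly (~5.5), so the choice of mean-variance law dominates any
conclusion about count-platform sensitivity; the deviance comparison in
`fit_nb_dilution` is there to make that choice data-driven.

**MDL.** At purity `p` the measurement model becomes `Y = p·t + b + ε`
(or mean `p·t` for counts), so `MDL(p) = IDL/p` exactly — an identity,
not an approximation, and tested as such. `required_purity` inverts it
per gene: `min(IDL/t_k, 1)` for genes elevated in the pure target sample,
NA otherwise (a gene *lower* in the target population has no meaningful
required purity).

## Fitting the count dilution model

`fit_nb_dilution` maximises the joint likelihood over `(θ, a_1..a_K)`
with mean `exp(a_k)·x_i`. Per-gene log-abundances are maximised at fixed
θ by a vectorised grid-refinement search (33 candidates per round, four
zoom rounds, final precision ~5·10⁻⁴ on the log scale) — no derivatives,
robust for θ spanning orders of magnitude. θ is profiled on a log grid
(10⁻³…10²) and polished by bounded golden search (xatol 10⁻⁶).

The plain profile likelihood underestimates θ: each gene contributes only
n = 8 observations to its own slope, a classic incidental-parameter
situation (simulations at the default design show ~20% downward bias at
θ = 2). The θ profile is therefore Cox–Reid adjusted — subtracting half
the log observed information of each nuisance slope — which removes the
bias in the same simulations. `dispersion_adjust="none"` restores the
unadjusted joint ML.

Zero-purity columns carry likelihood only through zero counts. Genes with
non-zero counts at purity 0 are impossible under the zero-background
model and are dropped from the fit with a warning by default; a
`background_eps` option instead assigns a small fixed mean at purity 0
for data with genuine background leakage. Deviance is reported against
the saturated model (`μ = y` per observation) at the fitted θ; model
control uses randomised quantile residuals (seeded uniform draw on the
fitted CDF interval of each count, mapped through the normal quantile),
which are N(0,1) under a correct model even for low counts.

## No-replicate differential expression

With one sample per condition nothing gene-specific is estimable, so both
tests borrow strength across genes.

*Intensities*: assuming `Y_gi ~ N(μ_gi, σ²)` with common σ, the null
difference is `N(0, 2σ²)`; the pooled scale is
`s² = Σ_g (Y_g1 − Y_g2)²/(G−1)` — no mean-centering, computed over all
genes including truly changed ones, exactly as defined. Truly changed
genes therefore inflate `s` and make the test conservative; no
robustification is applied by default.

*Counts*: `Y_gi ~ NB2` with a dispersion φ shared by all genes. For two
i.i.d. NB2 samples the split of a gene's total is free of the mean
(`P(y|n) = C(y+r−1,y)·C(n−y+r−1,n−y)/C(n+2r−1,n)`, `r = 1/φ`), which
yields both the dispersion estimate — conditional maximum likelihood over
all genes' splits, the exact small-sample quantity that the Cox–Reid
adjusted profile likelihood approximates, with the two samples treated as
replicates of one group — and the exact test. Two-sidedness defaults to
doubling the smaller conditional tail (clipped at 1), the rule of the
standard count exact test: it keeps balanced splits at p = 1 for every φ.
The minimum-likelihood rule is available (`sidedness="minlik"`) and
agrees for φ ≤ 1; for φ > 1 the conditional split distribution is
U-shaped and minlik would call balanced splits extreme, which is why it
is not the default. Totals of 0 get p = 1 by convention. Count fold
changes are `log2((y1+c)/(y2+c))` with pseudocount c = 0.5 on
library-equalised counts.

BH adjustment is the standard step-up procedure (via statsmodels),
property-tested against a brute-force implementation of the definition.

## Preprocessing rules

Boundary semantics are deliberately strict and fixed: an exon is present
when its background p-value is *below* 0.005; a gene is present when at
least half its exons are (ties present); the low-count filter removes a
gene whose count is *not above* 15 in every sample (so a max of exactly
15 is removed). Library equalisation is an exact multivariate
hypergeometric draw per sample (sampling tag instances without
replacement down to the smallest library), seeded; column sums equal the
minimum library size exactly and no count can grow. Computing the
exon-level background p-values themselves is upstream of this package;
`ExonPValueTable` consumes them.

## Concordance

The hypergeometric overlap test requires the universe size N explicitly —
with gene lists there is no safe default universe, and the p-value is
extremely sensitive to it. Correspondence curves report `|top-d ∩ top-d|`
against d; under identical rankings this is exactly d, under independent
rankings its mean is d²/N, and the acceptance region accumulates
hypergeometric outcomes in decreasing probability until the target mass
is covered (smallest such interval). Sample clustering is complete
linkage on Euclidean distances with an explicit merge loop so that ties
break lexicographically on member labels — fully deterministic, at the
cost of O(n³) in the number of samples, which is trivial here (n ≤
dozens). Input scale follows the DE convention: log2 intensities,
log2(count + 0.5). ΔΔCq averages replicate Cq values per (sample, gene)
before differencing against the reference gene and reference sample;
fold change is `2^(−ΔΔCq)`.

## The synthetic generator and what passing tests mean

`SimConfig` defaults mirror the reference dilution experiment: the
8-point purity grid (0, 0.5, 1, 5, 10, 20, 30, 100%), intensity noise
σ = 224 with background b = 100, count dispersion θ = 2, and ~60–80
signature genes. No canonical law exists for true abundances `t_k`, so
the generator exposes a sampling law (default log-uniform on
[500, 50000]) rather than fixing one. NB counts are drawn by the
Poisson–Gamma mixture matching each pmf (NB1: shape μ/θ, scale θ; NB2:
shape 1/θ, scale μθ). Library-size variation enters as a multiplicative
mean factor `M_i/M_ref` against the smallest library, mirroring
downstream subsample-to-minimum normalisation. Fixed seeds give
bit-identical output.

The generator reproduces the *assumed* statistical structure, not real
data: no probe-sequence effects, no mean-variance trends beyond the
chosen NB law, no gene-gene correlation, no below-IDL flattening of the
intensity response. Passing recovery tests therefore demonstrates
internal consistency of estimator and model — not that real platforms
follow these models, which is what residual diagnostics are for on real
data. The piecewise ("hockey-stick") regression that would model the
below-IDL flattening is explicitly out of scope.

## Problem sizes and numerical choices

Simulation-backed tests use the reference design (8 purities, 60–79
genes) with 5–20 seeded replicates, 10³–10⁴ genes for type-I checks, 2·10³
draws for coverage checks and 10⁶ draws for the detection-probability
Monte-Carlo — sizes chosen so the full suite runs in well under a minute
of compute per module while keeping Monte-Carlo error far below the
asserted tolerances. Statistical assertions use 3-standard-error bands
around their targets. pmf and likelihood computations are in log space
throughout; the IDL oracle bisects on log μ for 200+ iterations (relative
error ≪ 10⁻⁸); a residual SD below 10⁻¹⁰ of the data scale is treated as
an exact fit (degenerate, flagged in diagnostics rather than tested for
normality).

## Known limitations

- One dispersion θ (or φ) for all genes; tagwise/trended dispersion is a
  non-goal.
- The no-replicate tests lean on strong exchangeability assumptions
  (common σ, common φ, most genes null); with replicates you should use
  a replicated-design tool instead.
- `required_purity` clamps at 1: a gene whose pure-sample abundance is
  below the IDL is undetectable at any purity, reported as 100%.
- The Gaussian model ignores truncation at zero and below-IDL
  flattening; fits dominated by near-blank observations will show the
  systematic residual patterns the diagnostics are designed to expose.
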