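# Methods

## Model

The package implements the exponential-Rayleigh (ER) distribution right
truncated to the unit interval.  The parent law has cumulative hazard
H(x) = δx + (λ/2)x² (δ, λ > 0): the δ term is an exponential, constant
hazard contribution, the λ term a Rayleigh, linearly increasing one.
Truncation conditions on X ≤ 1 and rescales the cdf by
Z = 1 − e^{−(δ+λ/2)} ∈ (0, 1):

    G(x) = (1 − e^{−H(x)}) / Z,    g(x) = (δ + λx) e^{−H(x)} / Z,    0 ≤ x ≤ 1.

At the origin the density and hazard both equal δ/Z; the hazard rises
monotonically and diverges at x = 1, where the survival function hits
zero — a defining feature of right-truncated lifetime models.

Support conventions: the distribution functions accept any real x
(density 0, cdf 0/1 outside [0, 1]); `hazard` raises outside [0, 1] and
returns +∞ at exactly 1; observed *data* must lie in (0, 1] because real
lifetimes are strictly positive, while function evaluation allows x = 0.

## Quantile and sampling

Inverting G leads to the quadratic (λ/2)x² + δx + log(1 − uZ) = 0.  Only
the "+" root is non-negative (the discriminant δ² − 2λ·log(1−uZ) ≥ δ²
since the log term is ≤ 0).  The package evaluates the root in the
conjugate ("citardauq") form

    x_u = 2A / (δ + sqrt(δ² + 2λA)),    A = −log1p(−uZ),

which avoids the catastrophic cancellation of the textbook form when
λ → 0 and degrades smoothly to the truncated-exponential inverse A/δ.
All `1 − e^{−·}` expressions use `expm1`/`log1p`.  Random variates are
inverse-transform draws of uniforms from a `numpy` Generator; identical
seeds give bit-identical samples.

## Moments, MGF, entropy

Quadrature (`scipy.integrate.quad`, absolute tolerance 1e−12 on a smooth
bounded integrand) is the reference route for every integral quantity.
The series routes expand e^{−λx²/2} (binomially, for the Rényi integrand)
and substitute y = cx, which turns each term into lower incomplete gamma
functions **evaluated at upper limit c** — c = δ for moments, c = δ − t
for the MGF, c = ηδ for Rényi entropy.  Two presentation slips in the
published derivation are corrected here, because the corrected forms (and
only they) agree with quadrature and with the published numeric table:

- the γ(·, 1) upper limit is replaced by the substitution's true upper
  limit (the printed "1" is only right when the parameter is 1), and the
  i-dependent factor δ^{r+2i+1} moves inside the sum;
- the MGF's tilted exponent is e^{−(δ−t)x} (e^{tx}·e^{−δx}), not
  e^{−(δ+t)x}; consequently the series route needs t < δ, while the
  quadrature route works for all t.

Series are truncated when the next term's magnitude falls below the
tolerance (default 1e−12, cap 10⁴ terms, `NumericalError` beyond).  The
Rényi double series additionally requires λ < δ for its binomial
expansion to converge and is exposed only there, as a cross-check.

The `skew_coef`/`kurt_coef` reported by `moment_summary` are the
raw-moment ratios M₃′/(M₂′)^{3/2} and M₄′/(M₂′)² − 3, matching the
convention of the source tables; conventional central-moment versions
are provided separately (`central_coefficients`) to avoid confusion.

## Maximum likelihood

The log-likelihood and its analytic score are closed-form.  `fit_mle`
minimizes the negative log-likelihood with L-BFGS-B on the box
[1e−8, 60]² from a moment-matched start (coarse cached grid of model
means, matched to the sample mean) plus three fixed starts; the best
local optimum wins, ties broken by smaller δ̂.  Interior solutions are
then polished by a Newton root solve of the score, which drives the
score norm to ~1e−10.  A fit is `converged` when the projected score
sup-norm is below 1e−6 *and* the estimate is interior to the box —
boundary solutions (typically λ̂ at the floor, where the model
degenerates to a truncated exponential) are deliberately flagged as
non-converged because the two-parameter model is then not identified.

Information criteria use k = 2 free parameters: AIC = 2k − 2L̂,
AICc = AIC + 2k(k+1)/(n−k−1) (n > k+1 required), BIC = k·ln n − 2L̂,
HQIC = 2k·ln ln n − 2L̂.

### Competitor models

The published comparison names four competitors without defining them;
this package constructs them by the same truncation operator F(x)/F(1):

| model | parent cdf | k |
|---|---|---|
| RTE | 1 − e^{−θx} | 1 |
| RTR | 1 − e^{−(θ/2)x²} | 1 |
| RTW | 1 − e^{−(x/a)^b} | 2 |
| ER  | untruncated parent, data as-is | 2 |

One-parameter models are fitted by bounded scalar minimization, RTW/ER
by multi-start L-BFGS-B.  Per-model failures are recorded in the table
row, never raised.

### A note on the published fit table

For the bundled 50-point failure-time data the honestly maximized
log-likelihoods are **positive** (RTER +14.157 at the λ → 0 boundary, ER
+12.820): the fitted densities exceed 1 over most of the data mass, which
is perfectly legal for a continuous density on a short interval.  The
published table instead prints positive *negative* log-likelihoods
(12.558, 14.818), which no parameter choice near the optimum can produce,
and its one-parameter rows imply non-integer parameter counts under any
standard criterion formula.  The package reports what the likelihood
actually is; the acceptance tests that assert the published row values
therefore fail by design, with the discrepancy documented here rather
than papered over.

## Monte Carlo study

`run_mc_study` repeats, for each sample size n (default 20, 30, 50, 100,
200) and L replications (default 1000): draw n variates at the true
parameters, fit by `fit_mle`, and aggregate mean, bias and MSE per
parameter.  Replicates flagged non-converged (boundary optima) are
excluded from the aggregates and counted in `n_failed`; cells with more
than 10% exclusions carry `flagged=True`.  At small n and weakly
identified truth (e.g. δ=0.25, λ=1.5 at n=20) the exclusion rate is
substantial — the likelihood surface is nearly flat along a δ–λ ridge
and boundary optima are common; this is a property of the model, not of
the optimizer.

Seeding: replicate (n, rep) uses
`SeedSequence(entropy=master_seed, spawn_key=(n, rep))`, so every cell is
independently reproducible and the whole study is bit-identical under the
same master seed.  Monte Carlo standard errors of the reported means and
MSEs are estimated from the replicate spread and carried in the result.

The published error table's qualitative claims — bias and MSE shrink as n
grows, estimates approach the truth — reproduce cleanly.  Its exact n=200
MSE values do not: they lie *below* the Cramér–Rao variance bound at the
stated true parameters (e.g. printed MSE(δ̂) = 0.0062 vs a per-observation
Fisher-information bound of 0.0069 at δ=0.25, λ=1.5, and 0.0024 vs 0.0063
at δ=0.1, λ=0.5), so no genuine maximum-likelihood protocol can attain
them.  The package reports its honestly computed cells together with
their Monte Carlo standard errors.

## Problem sizes used by the test suite

The default test run exercises the Monte Carlo harness at reduced
replication counts (L = 120–300 across three to five sample sizes) —
enough for the 4-standard-error comparisons the checks use — while
`scripts/acceptance.py` runs the full L = 1000 protocol.  Property tests
(normalization, inverse round-trips, series/quadrature agreement, score
vs finite differences) run on deterministic grids and seeded draws.

## What the synthetic data does and does not emulate

Simulated samples are exact i.i.d. draws from the model itself, so the
study measures estimator behaviour under a correctly specified model with
complete, uncensored unit-interval data.  Real reliability data bring
censoring, rounding (the bundled dataset has three decimal places),
model misspecification and dependence, none of which the generator
emulates; passing tests certify the estimator and its implementation,
not the model's adequacy for any particular dataset.

## Known limitations

- No censoring or left/interval truncation; only right truncation at 1.
- No standard errors, confidence intervals or hypothesis tests for the
  MLE (none are defined in the reference tables either).
- The Rényi series route is restricted to λ < δ; use the quadrature
  route elsewhere.
- Boundary-optimum fits report the boundary value with
  `converged=False`; users who want the nested one-parameter fit should
  use the RTE row of `fit_competitors`.
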