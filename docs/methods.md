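# Methods

## Model

Species sensitivity to a chemical is treated as a random variable on
(0, ∞): each species contributes one acute toxicity value (an EC50 or LC50
in µg/L; the geometric mean when several tests exist), and the fitted
distribution of these values — the species sensitivity distribution — gives
the hazardous concentration HC_p as its p-quantile (HC5 at p = 0.05, HC1 at
p = 0.01). Five candidate families are fitted by maximum likelihood:

| family   | parameters                        | CDF |
|----------|-----------------------------------|-----|
| lnorm    | meanlog µ ∈ ℝ, sdlog σ > 0        | Φ((ln x − µ)/σ) |
| llogis   | locationlog µ ∈ ℝ, scalelog s > 0 | 1/(1 + e^{−(ln x − µ)/s}) |
| burr3    | shape1 b > 0, shape2 c > 0, scale λ > 0 | (1 + (x/λ)^{−b})^{−c} |
| weibull  | shape κ > 0, scale λ > 0          | 1 − e^{−(x/λ)^κ} |
| gamma    | shape α > 0, scale θ > 0          | P(α, x/θ) |

Burr III parameter conventions differ between software packages; the form
above contains the log-logistic exactly at c = 1 (with µ = ln λ, s = 1/b),
which both anchors the parameterization and provides the Burr III starting
point. The gamma is parameterized by scale, not rate (conversion helpers
are provided). Support is the open interval (0, ∞); zero or negative
concentrations are rejected during ingest.

Model weights follow the AICc,
AICc = −2ℓ + 2k + 2k(k+1)/(n − k − 1), through Akaike weights
w_i = exp(−ΔAICc_i/2) / Σ_k exp(−ΔAICc_k/2), computed after subtracting
the minimum AICc so large spreads cannot underflow. The model-averaged HC
is, by default, the arithmetic weighted mean Σ w_i·HC_i of the per-family
quantiles — the literal reading of "a weighted average of the estimated HC
values". Because averaging HC quantiles versus inverting the averaged CDF
is a known sensitivity of SSD software, two variants are exposed and logged
wherever used: `geometric` (exp Σ w_i ln HC_i) and `distributional` (the
root of Σ w_i F_i(x) = p, found by Brent's method on a bracket spanning the
component HCs, widened ×10 and ×100 before giving up). All three lie within
[min_i HC_i, max_i HC_i].

## Fitting and failure handling

The log-normal MLE is the closed form µ̂ = mean(ln x),
σ̂ = √(mean((ln x − µ̂)²)) (n-denominator variance). The other families are
maximized numerically over unconstrained transforms (log of every positive
parameter; log-locations kept linear) with Nelder–Mead simplex and a small
multi-start schedule: the moment-based start (log-moment inversion for
llogis/weibull, method of moments for gamma, the fitted log-logistic
embedded at c = 1 for burr3) plus two starts with each parameter perturbed
by a factor uniform in [0.5, 1.5] from a fixed-seed stream recorded in the
fit diagnostics. A derivative-free simplex was chosen over quasi-Newton
because the 3-parameter Burr III likelihood at n = 15 routinely defeats
gradient steps near its log-logistic ridge; the contract here is failure
*handling*, not any particular failure *rate*, which is always an optimizer
artifact. A fit counts as converged when the optimizer reports success, the
log-likelihood is finite, every positive parameter lies in [1e−8, 1e8]
(log-locations within ±ln 1e8), and the 0.1%/99.9% quantiles of the fitted
distribution are finite and positive — a fit whose hazard quantiles
under- or overflow is unusable and is treated as failed. Failed fits are
returned flagged (`converged=False`), never raised: downstream, the failing
family is excluded from that iteration and the model average is taken over
the surviving families of the same subsample, so all arms always see
identical data. Requesting a family with fewer than k + 2 species (the AICc
denominator requirement; 5 for Burr III) is an error at the single-fit
level and a flagged failure inside `fit_all`.

## The benchmark

A chemical qualifies when it has ≥ 51 species spanning ≥ 3 of the 4
taxonomic groups, after a record-level screen removing concentrations
strictly exceeding 5× the chemical's water solubility (records of chemicals
without a solubility entry pass with a warning — curated sources apply this
screen upstream) and geometric-mean collapse to one value per species. The
nonparametric reference HC_p is the empirical p-th percentile of the
species means under linear interpolation of order statistics
(h = (n−1)p + 1, "type 7"); the convention is configurable
(`lower_empirical` is also provided) because published analyses rarely
state it.

Each benchmark iteration draws `size` ∈ {5, 10, 15} species without
replacement, uniformly over subsets containing ≥ 3 taxonomic groups —
implemented by rejection (redraw the whole subset, up to 10,000 times),
which preserves uniformity on the constrained support where stratified
draws would bias composition. The group constraint applies at every size,
including 5. Randomness is counter-split: iteration t of chemical c uses
`default_rng([seed, crc32(c), t])`, so arms and reruns see identical
subsamples and iterations may be processed in any order.

Deviations are log10(HC_est) − log10(HC_ref) per iteration and approach
(five families + model average). Per chemical and approach, the 2.5, 50 and
97.5 percentiles are computed over the *non-excluded* deviations (the
denominator shrinks when fits fail; `n_used` is reported), with the same
quantile convention as the reference. Cross-chemical aggregation reports
the mean, min and max of each percentile column per approach.

Bimodality of a complete dataset — e.g. a hypersensitive taxon creating a
low mode — is screened with BC = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3))) on
log10-transformed species means, where g₁ and g₂ are the bias-corrected
sample skewness and excess kurtosis (scipy `bias=False`); the
bias-corrected estimators are required for the 0.555 reference value, which
is the large-n limit for a uniform distribution (g₁ → 0, g₂ → −1.2,
correction → 3 gives 1/1.8 ≈ 0.5556; a normal gives 1/3). BC strictly
greater than 0.555 flags bimodality; equality does not. Log transform and
threshold are configurable. Bimodal and unimodal chemicals are compared per
approach and percentile with Welch's two-sample t-test
(Welch–Satterthwaite df, two-sided) and Holm's step-down adjustment across
the six approaches at one percentile level; the comparison runs only when
both groups contain ≥ 2 chemicals.

## Synthetic data

The generator emulates the structure of a curated acute-toxicity
compilation, not any particular database's schema. Per chemical: n_species
(default 60) sensitivities drawn i.i.d. on the log10 scale from either a
normal (default µ = 1.5, σ = 0.8 log10 µg/L — an SSD spanning the typical
3–4 orders of magnitude) or a two-component normal mixture (default 10%
sensitive component at µ₁ = 0 versus µ₂ = 3, σ = 0.3 — a clearly separated
hypersensitive mode); taxonomic groups assigned multinomially with weights
algae 0.15 / invertebrate 0.35 / amphibian 0.10 / fish 0.40 (acute data are
dominated by invertebrate and fish tests), except that mixture-sensitive
species can be linked to a designated group (default invertebrate,
mimicking taxon-specific modes of action such as daphniid hypersensitivity
to aniline); labels are redrawn (≤ 100 times) until ≥ 3 groups are
nonempty. Each species yields `records_per_species` (default 2) records
equal to the species value times log-normal noise (default SD 0.2 log10
units, about a factor 1.6 between-test spread), so the geometric-mean
collapse is genuinely exercised. Analytic quantiles of the generating
marginal (mixture quantiles by Brent root-finding on the mixture CDF) are
emitted as ground truth. Species are synthetic (`sp_0001`…); no real
taxonomy, no solubility table (the filter is exercised with explicit
fixtures instead), no censored values, and species values are exchangeable
within groups — real compilations have phylogenetic correlation, unbalanced
replicate counts and reporting artifacts that this generator deliberately
omits, so green tests demonstrate correctness of the machinery, not
performance on any real database.

## Numerical and design choices

- Quantiles/CDFs are closed forms on scipy.special primitives; the Burr III
  quantile is evaluated in logs (t = −ln p / c;
  ln(p^{−1/c} − 1) = t + log1p(−e^{−t})) to survive extreme shape values.
- Likelihoods clip the unconstrained parameter vector to ±200 before
  exponentiation; non-finite log-likelihoods become +∞ NLL so the simplex
  retreats instead of crashing.
- Degenerate samples: a zero log-variance sample gets σ̂ floored at 1e−12
  (lnorm) and moment starts floored at 1e−4 spread; the bimodality
  coefficient refuses zero-variance input (undefined moments).
- Ties in AICc produce exactly equal weights; the minimum is subtracted
  before exponentiation so ΔAICc up to ~1400 remains exact.
- The reference percentile and all deviation percentiles share one
  configurable quantile convention, so convention mismatches cannot
  masquerade as estimator bias.
- Percentile deviations use only non-excluded iterations; an approach with
  zero survivors yields NaN percentiles and `n_used = 0` rather than a
  silent drop.

## Problem sizes

The default configuration is the full study design (1,000 iterations,
size 15, p = 0.05). The test suite and `scripts/acceptance.py` run desk-
scale versions chosen to exercise every code path at meaningful Monte-Carlo
precision: the null benchmark uses one 60-species log-normal chemical at
the full 1,000 iterations; the multi-chemical study uses six chemicals
(five unimodal, one bimodal) at 200 iterations each; end-to-end determinism
uses two chemicals at 30 iterations.

## Known limitations

- No confidence intervals on HC estimates (the benchmark compares point
  estimates), no censored-data likelihoods, no goodness-of-fit tests, no
  additional families (inverse Pareto, log-Gumbel, mixtures as *fitted*
  SSDs), and no taxonomic-group-specific SSDs.
- Burr III failure rates depend on the optimizer and are not a stable
  quantity; only the exclude-and-continue protocol is guaranteed.
- The arithmetic-vs-distributional averaging choice materially affects HC5
  for strongly disagreeing ensembles; the default is arithmetic, and the
  method label is carried through all outputs.
- The bimodality coefficient is a screen, not a test: it is sensitive to
  skewness and has low power for close or unequal-variance modes.
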