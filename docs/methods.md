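# Methods

## The dispersal hierarchy

A tunnel trial `i` starts with `N_i` individuals on a source patch.
Dispersers are counted by subtraction, `D_i = N_i − remaining_i`, because
individuals that leave the source cannot be followed in flight. Founders
`F_i` — dispersers that settle on the target patch — cannot be counted
either without destroying the target habitat, so the target is incubated
for a fixed period (about two generations for the mite systems this
design comes from) and the colonizer population `C_i` is counted instead.
The model links the layers generatively:

    D_i ~ Binomial(N_i, q)
    F_i ~ Binomial(D_i, p_i),   logit(p_i) = η_i,   η_i ~ Normal(μ, σ_p)
    C_i ~ Poisson(λ_i),         λ_i = F_i · (2^r − 1)
    r   ~ Normal(m, σ)

`q` is shared across the trials of a treatment: the trial index on the
departure probability is read as indexing data, not parameters, which
matches the single narrow-interval rate reported per treatment in this
experimental tradition. The logit-normal random effect absorbs
between-trial overdispersion in effectiveness. The Poisson mean
`F(2^r − 1)` is the expected colony size after incubation when growth is
measured as `r = log₂(C/F + 1)`; with that convention `r = 1` means an
unchanged population and `r = 0` extinction, and the colonization
potential obeys the exact identity `k = C/D = p(2^r − 1)`.

Model assumptions worth keeping in mind: a single shared growth rate `r`
across trials (no per-trial growth variation beyond Poisson noise), no
immigration into the target patch, and independence between trials.

## Priors

* `r ~ Normal(m, σ)` — informative, built by the propagation step below
  or supplied directly (`r_mean`/`r_sd` in a prior file). There is no
  default: the growth prior encodes system-specific evidence and must be
  given explicitly.
* `q ~ Beta(1, 1)` — flat on the departure probability.
* `μ ~ Normal(0, 1.5)` — weakly informative on the logit scale; keeps
  `logit⁻¹(μ)` roughly uniform over (0.05, 0.95).
* `σ_p ~ Uniform(0, 10)` — an upper bound far above any plausible
  between-trial spread on the logit scale.

All four are overridable through `PriorSpec` (or the `--priors` YAML).

## Building the growth prior by error propagation

The growth rate at the incubation temperature is predicted from a
previously fitted nonlinear temperature–growth model, supplied as a
triple (prediction function `g(θ, x)`, estimates `θ̂`, covariance `Σ`).
Two propagation routes are implemented:

* **Second-order Taylor**: mean `g(θ̂) + ½ tr(HΣ)` and variance
  `∇gᵀΣ∇g + ½ tr((HΣ)²)`, with gradient and Hessian from central
  differences. Step sizes are per-coordinate scaled, `eps^(1/3)` for first
  derivatives and `eps^(1/4)` for second — the order-matched choice that
  keeps the linear case exact to ≈ 1e−9 relative error rather than the
  ≈ 1e−7 noise a cube-root Hessian step would leave.
* **Monte Carlo**: draw `θ* ~ MVN(θ̂, Σ)` (SVD factorization, so a
  singular Σ is fine), evaluate `g`, report sample mean/SD.

The default combination policy keeps the Monte-Carlo moments and uses the
Taylor mean as a cross-check, warning when the two disagree by more than
twice the Monte-Carlo standard error of the mean. For a linear `g` the
Taylor result is exact, which makes it the oracle for the sampler in the
tests. A degenerate (zero-SD) prior is rejected.

## Sampling

The latent founder counts are **marginalized exactly** during sampling:
`Σ_{F=0}^{D} Binom(F|D,p) Pois(C|F(2^r−1))` is a finite sum (computed in
log space with `logsumexp` over a padded trial × F table), so the
continuous-parameter sampler never sees a discrete variable. The `F = 0`
term contributes a point mass at `C = 0`; a non-positive growth factor
(`r ≤ 0`) likewise degenerates to extinction-only mass, and a trial with
`C > 0, D = 0` has likelihood zero (reported as −∞, and rejected with a
clear message at fitting time since no parameter value can explain it).

The sampler is adaptive random-walk Metropolis-within-Gibbs on
`(logit q, μ, log σ_p, r, η_1..η_n)`:

* `logit q` sees only the binomial departure terms (and its Beta prior
  with the logit Jacobian folded into the exponents).
* `μ` and `log σ_p` see only the random-effect layer and their priors.
* `r` sees the informative prior plus all colonization sums.
* the `η` block is proposed jointly and accepted per trial — the trials
  are conditionally independent given `(μ, σ_p, r)`.
* one extra **ridge move** translates `(r, μ, η_1..η_n)` together: a
  faster growth rate requires fewer founders, so the posterior has a
  ridge along which `p(2^r − 1)` is constant. The move shifts every `η`
  (and `μ`, leaving the random-effect layer invariant) by
  `−Δ log(2^r − 1)`; it is a translation (unit Jacobian) and roughly
  triples the effective sample size of `r`.

Scales adapt by Robbins–Monro toward 0.30 acceptance during warmup only
(step `(t+10)^{−0.6}`), then freeze. Chains start overdispersed (jittered
around the empirical departure proportion and the prior centers). Each
chain draws its RNG from a `SeedSequence` child of the master seed, so a
fit is bit-reproducible for a given seed. After sampling, `F_i` is
re-imputed per retained draw from its exact discrete conditional with the
Gumbel-max trick.

Convergence is summarized by split-R̂ and bulk ESS (via arviz); any
split-R̂ above 1.05 attaches a warning to the returned draws. Reported
summaries are posterior means and central 2.5%/97.5% quantiles. The
effectiveness reported as `p` is the population-expected value
`logit⁻¹(μ)` (per-trial `p_i` draws remain available), and `k` is
computed per draw as `p(2^r − 1)` before summarizing — the plug-in of
posterior means would be biased by the Jensen gap.

## The simulator

`simulate_trials` draws `(D, η, F, C)` per trial through exactly the
hierarchy above. One master seed spawns a deterministic substream per
trial, so extending an experiment never perturbs earlier trials. Source
sizes can be fixed, listed per trial, or Poisson-distributed (truncated
at 1), reflecting designs where each replicate uses one infested plant
whose census varies. The recovery experiments in the test suite use 10
trials of `N = 300` at truth `q = 0.37`, `μ = logit(0.29)`, `σ_p = 1.8`,
`r = 4.0` — population sizes and parameter magnitudes typical of a
wind-tunnel study on a strongly growing mite colony — with the growth
prior `Normal(4.0, 0.5)` standing in for an accurate external growth
model, as the design intends.

What the simulator deliberately does not emulate: wind-speed or regime
effects on `q` (trials are pooled over the schedule), mortality between
settlement and census other than what the net growth rate absorbs,
counting error in `N` and `C`, and any spatial structure of the target
patch. Passing recovery tests therefore show the inference is correct
for the stated hierarchy, not that the hierarchy captures every feature
of a real tunnel experiment.

## Two-group comparison

Departure-only experiments are analysed on per-group sums (the binomial
likelihood is sufficient in them) with a binomial GLM with logit link via
statsmodels: the by-group model uses one indicator per group, the null a
single intercept, both fit on the same rows so the combinatorial
constants cancel in `χ² = 2(ℓ_full − ℓ_null)`, referred to a chi-square
with 1 df. Confidence intervals are Wald intervals on the logit scale,
back-transformed — hence asymmetric around the estimate and always
strictly inside (0, 1). Complete separation (a group with all zeros or
all dispersers) is reported as an error naming the group rather than
returning an unbounded estimate. p-values are reported at full precision.

## Numerical and design notes

* All likelihood sums are in log space; `log_expit` keeps `log p` and
  `log(1−p)` accurate for extreme `η`.
* `log_posterior` returns −∞ outside the support (σ_p ≤ 0, q ∉ (0,1),
  non-finite parameters) instead of raising, so samplers can probe
  freely; constructors of data objects, by contrast, validate eagerly.
* The wind-regime parser accepts `on/off` tokens and a bare trailing
  `on` token (a final blowing phase with no still segment, stored as
  `off = 0`).
* Dispersers are stored as derived (`N − remaining`) because that is how
  they are measured; `TrialRecord.from_dispersers` exists for simulator
  output.
* Test problem sizes (50 coverage replicates with 2 chains × 1500/2000
  iterations; 1000 calibration replications) were chosen as the smallest
  runs whose Monte-Carlo error is comfortably below the tolerances being
  checked.

## Known limitations

* With `F` latent, `p` and `r` are only jointly identified through the
  colonizer counts; an informative growth prior is essential, and the
  posterior of `p` stays wide at realistic trial counts.
* `σ_p` is weakly identified below ~10 trials; its posterior mean can sit
  well above the truth while the credible interval remains calibrated.
* The random-walk sampler mixes slowly along the `(r, η)` ridge compared
  with gradient-based samplers; the ridge move mitigates but long chains
  are still advisable for publication-grade ESS.
* No model comparison (WAIC/LOO), no covariates on `q` or `μ`, no
  zero-inflation, and no more-than-two-group omnibus tests.
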