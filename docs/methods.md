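# Methods

`bwskit` implements the analysis pipeline for object-case best-worst
scaling (BWS / maxdiff) choice experiments of the kind used to study
intrahousehold food-allocation decisions: a respondent sees a series of
choice cards, each showing `k` of `v` candidate options, and marks the
option they would most likely adopt (best) and the option they would least
likely adopt (worst). The package covers card design, counting scores,
three likelihood-based estimators, model selection, the share-of-preference
transform, and a synthetic-respondent generator used to validate every
stage.

## Choice-card design

Cards are blocks of a (near-)balanced incomplete block design (BIBD):
`v` items in `b` blocks of size `k`, equal replication `r = bk/v`, and
pairwise co-occurrence counts `λ_ij` as even as possible. A perfect BIBD
needs integral `λ = r(k-1)/(v-1)`; for the reference configuration
(v=9, b=9, k=4) `λ = 1.5`, so the best achievable design mixes counts of 1
and 2 ("nearly" balanced).

`generate_design` uses randomized greedy construction followed by pairwise
item-exchange hill climbing on the variance of the off-diagonal concurrence
counts (equivalently the sum of squared `λ_ij`, whose total is fixed at
`bk(k-1)/2`), with restarts; it stops early when the integer lower bound on
the objective is reached. At (9, 9, 4) the search reliably attains
`λ_ij ∈ {1, 2}` for every seed we have tried. Infeasible requests
(`bk` not divisible by `v`) are rejected rather than approximated.

Balance diagnostics:

* **average pairwise frequency** — mean off-diagonal concurrence, equal to
  `bk(k-1)/(v(v-1))` for any design (1.5 at (9, 9, 4));
* **D-efficiency** — with intra-block information matrix
  `C = diag(r) − N N'/k`, efficiency is the geometric mean of the `v−1`
  nonzero eigenvalues of `C` relative to the perfect-BIBD bound `vλ̄/k`,
  `λ̄ = r(k−1)/(v−1)`, times 100. It equals 100 exactly for a perfect BIBD.
  Several definitions of block-design efficiency circulate among software
  packages; this eigenvalue (D-) criterion is the one documented and tested
  here, and generated (9, 9, 4) designs score ≈ 99.4 % under it.

Presentation order within a card is not modelled.

## Counting scores

With per-option best and worst totals `B(o)`, `W(o)` over a complete panel
of `N` respondents in which option `o` appears on `r_o` cards:

* standardized best-worst score `(B − W)/(r_o N)`, in [−1, 1], zero-sum
  across options;
* square-root ratio scale `√(B/W)`, a positive ratio-scale transform;
* standardized ratio scale `100·√(B/W)/max`, anchored at 100;
* relative importance `100·√(B/W)/Σ`, summing to 100 %;
* the two weighting factors `100/max √(B/W)` and `100/Σ √(B/W)`;
* per-respondent scores `(B_n − W_n)/r_o` whose population (ddof = 0)
  standard deviation measures response heterogeneity. The population
  convention is a package choice; the sample convention differs by
  `√(N/(N−1))` ≈ 0.25 % at N = 200.

`W = 0` makes the ratio scale undefined; the package substitutes
`W = 0.5` (a continuity correction), flags the option, and warns. This can
only arise on small panels.

Display convention: `ScoreTable.display()` rounds half away from zero
(publication style) and recomputes the relative-importance column and its
weighting factor from the 2-dp-rounded square-root ratios. Published
best-worst score tables are internally consistent under exactly this
convention (an option with `√(B/W)` = 0.156 shows 0.16 and a relative
importance of 0.9 %, not the full-precision 0.8 %); full precision is always
available in `ScoreTable.table`.

## The maxdiff likelihood

A card with shown set `S` (|S| = J) is modelled as a single choice among
the `J(J−1)` ordered (best, worst) pairs:

    P(i, j) = exp(β_i − β_j) / Σ_{k≠l} exp(β_k − β_l),   i ≠ j ∈ S.

This is the *simultaneous* (maxdiff) form; the sequential best-then-worst
form is out of scope. One option's utility is pinned at zero (the
reference); probabilities are invariant to adding a constant to all β.

Numerics: the normalizer factorizes as
`Σ_{k≠l} e^{u_k−u_l} = (Σ_k e^{u_k})(Σ_l e^{−u_l}) − J`, which is
shift-invariant; after centering the utilities at their midrange the
package evaluates it in log space (`log S+ + log S− + log1p(−J e^{−…})`),
so no J×J pair array is ever built and utilities with spreads of several
hundred remain finite. Gradients use the same factorization
(`∂ log D/∂u_j` = row minus column margins of the implicit pair matrix).

### Pooled (conditional logit) estimator

`MaxDiffModel.fit()` maximizes the card-sum log-likelihood by BFGS with
analytic gradients (default gradient tolerance 1e-6 on the sup-norm).
The likelihood is concave, so multi-start runs agree to optimizer
precision. Standard errors come from the inverse observed information,
computed by central differences of the analytic score (step 1e-5).
Complete separation (an option always best, or always worst, wherever
shown) is detected up front and produces a warning: such utilities diverge
and have no finite standard errors.

### Shares of preference

`S_i = e^{β_i} / Σ_m e^{β_m}` — the softmax of the utilities. Shares sum
to one and are ratio-scaled: `S_i/S_j = e^{β_i−β_j}`, so "twice the share"
means "twice as likely to be picked as best".

### Mixed logit (maximum simulated likelihood)

Respondent utilities are `β_n = μ + σ ∘ z_n`, `z_n ~ N(0, I)` over the
non-reference options — independent normals, i.e. a diagonal mixing
covariance, matching the one-mean-one-SD-per-option reporting convention
of applied best-worst studies. The panel structure enters through the
per-respondent product over cards inside the draw average:

    L_n = (1/R) Σ_r Π_c P(best_c, worst_c | μ + σ z_nr).

Draws are scrambled Halton sequences (scipy's `qmc.Halton`, one dimension
per random coefficient, a contiguous block of R points per respondent,
normal-quantile transformed), reproducible by seed; R defaults to 500.
The likelihood depends on σ only through |σ|, so the sign is not
identified; raw estimates are reported alongside magnitudes and published
negative SDs are read as magnitudes.

Estimation is L-BFGS-B with analytic gradients propagated through the draw
average. The |σ| kink at zero can trap a component in a spurious local
mode at σ = 0; after convergence any component with |σ| < 0.05 is
restarted at 0.5 and the refit kept only if it improves the likelihood.
For hard problems a two-stage fit (small R, then warm-started large R) is
effective and is what the test suite uses. Standard errors come from the
central-difference Hessian of the simulated log-likelihood.

Finite R biases the simulated likelihood (Jensen) and attenuates
estimates toward the pooled model; the effect shrinks as R grows but is
visible at study-like parameter scales. Re-evaluating the simulated LL at
the estimates with 2R draws moves it by a few hundredths of a unit per
respondent at R = 1000 — the stability check the package exposes through
`MixedMaxDiffResults.loglike_at`.

`population_shares` summarizes heterogeneity on the share scale: draw
`β ~ N(μ, diag(σ²))`, apply the softmax per draw, report the per-option
mean (sums to one) and standard deviation. Because the softmax is
nonlinear, mean population shares differ from the plug-in softmax of μ
whenever σ > 0; published share columns produced by unspecified simulation
conventions are therefore reproduced in ordering but not claimed digit by
digit.

### Latent-class estimator (EM)

A C-component finite mixture: class utilities `β_c` (reference pinned per
class) and shares `π_c`. The E-step computes posterior memberships from
per-respondent panel likelihoods; the M-step refits each class's pooled
model with posteriors as card weights (warm-started BFGS) and sets `π_c`
to mean posteriors. The log-likelihood is asserted non-decreasing at every
iteration; convergence is ΔLL < 1e-7 with a 500-iteration cap. Class
shares are kept on the simplex by construction (mean posteriors). The
likelihood is multimodal, so the best of `n_starts` (default 20) jittered
pooled-fit initializations is returned; a start that collapses a class
(π < 1e-6) is discarded and retried. Classes are canonically ordered by
descending share, which makes seeded fits reproducible and comparable.
C = 1 reduces exactly to the pooled estimator.

Free parameters: `k = C(v−1) + (C−1)`. Model selection uses
`AIC = −2LL + 2k`, `BIC = −2LL + k ln n`, `CAIC = −2LL + k(ln n + 1)` with
`n` = number of respondents — the independent sampling units of the panel
likelihood, not the number of cards; at v = 9 the published criterion
table reproduces arithmetically only under this convention (k = 26 at
C = 3, k = 17 at C = 2). `class_sweep` adds the percent-improvement
columns `Δ_IC(C) = 100·(IC(C−1) − IC(C))/IC(C−1)` and leaves the choice of
C to the analyst (the Δ columns leveling off is the usual signal).

Per-class standard errors are taken from the posterior-weighted observed
information at convergence, ignoring the uncertainty in the weights and
shares — the usual approximation; significance stars in report tables are
plain Wald z-tests without multiplicity correction. Posterior profiling
(`profile_classes`) cross-tabulates modal assignments against categorical
covariates as column percentages per covariate block, excluding missing
values pairwise.

## Synthetic panels

`simulate_panel` draws each respondent's latent state once (a class, or a
normal coefficient vector), then samples one (best, worst) pair per card
from the exact maxdiff probabilities. The random stream is hierarchical
(`SeedSequence` spawned per respondent), so enlarging a panel never
changes earlier respondents' data. The truth record (classes or
coefficient draws) is returned for recovery testing.

The packaged fixture emulates the study conditions the estimators target:
200 respondents on a (9, 9, 4) near-BIBD, a 3-class preference structure
with shares (0.65, 0.21, 0.14) taken from the published latent-class
solution, and class-conditional categorical covariates (income tier, head
gender, age band, education) drawn at the published composition rates. The
fixture seed was chosen once, at fixture creation, so that the O2/O4 pair
tops the relative-importance ranking (a high-probability property of this
DGP at N = 200) and then frozen; regeneration is byte-identical.

What the generator does *not* emulate: response styles (lexicographic or
attention-limited responding), card-order and position effects, scale
heterogeneity across respondents, and item non-response. Passing recovery
tests therefore demonstrate correctness of the estimators under the
model's own assumptions, not robustness to real-world violations of them.

## Test problem sizes and tolerances

Parameter-recovery checks run at sizes where the estimators' sampling
error is comfortably below the asserted tolerances, chosen as the
package's own test budget: pooled N = 2000 (tolerance ±0.1 on utilities),
mixed logit N = 1000 with a 64-draw pilot stage and an R = 1000 final
stage (±0.3 on means, ±0.4 on SD magnitudes), latent class N = 2000 with
3 starts (±0.05 on class shares, ±0.4 on the smaller classes' utilities).
Goodness-of-fit of the generator is checked at N = 20000 respondents by
per-card chi-square tests against the enumerated pair probabilities at
α = 0.01, and small-sample uniformity at N = 5000 within 4σ binomial
bounds.

## Known limitations

* The mixed-logit mixing distribution is limited to independent normals;
  correlated, lognormal, or triangular mixing is not implemented.
* Simulated-likelihood attenuation at moderate R biases small σ components
  toward zero; the zero-restart polish mitigates the local-mode trap but
  not the attenuation itself.
* Latent-class standard errors ignore share-estimation uncertainty.
* Incomplete panels are handled card-wise only; there is no imputation or
  weighting for missing cards.
* The design search is heuristic; it is not guaranteed optimal for large
  (v, b, k), though it attains the balance lower bound in the
  configurations used here.
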