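# Methods

## The model

A community of `p` taxa with abundances `f_j(t)` evolves by generalized
Lotka-Volterra (gLV) dynamics

    f_j'(t) = alpha_j f_j(t) + sum_k beta_jk f_j(t) f_k(t),

where `alpha_j` (1/time) is the intrinsic per-capita growth rate and
`beta_jk` (1/(abundance x time)) the per-capita effect of taxon `k` on taxon
`j`; `beta_jj < 0` encodes self-limitation. The model assumes absolute
abundances, parameters shared across subjects of a population, and purely
pairwise interactions. For invertible `beta` the algebraic steady state is
`f* = -beta^{-1} alpha`; it is reported even when some components are
negative (flagged `feasible=False`), and a condition number above 1e12
marks the system singular rather than raising.

Counts observed at discrete, irregular times are modeled as negative
binomial, `Y ~ NB(mu, phi)` with `mu = f(t)` and `Var = mu + mu^2/phi`
(NB2): larger `phi` means less overdispersion, and `phi -> inf` recovers
Poisson noise.

## Denoising: NB penalized B-splines

Each (subject, taxon) series is fit independently: a cubic B-spline linear
predictor `eta(t)` with log link (`fhat = exp(eta)`, hence positive
everywhere), `min(10, m-1)` basis functions with knots at quantiles of the
observed times, and a difference penalty on the coefficients. Estimation
is penalized IRLS on the NB working response (convergence at relative
deviance change < 1e-8 or 100 iterations, `eta` clipped to +/-30); the
smoothing parameter is chosen per series from a 13-point log-spaced grid
(1e-4..1e8) by deviance GCV, `m * dev / (m - 1.4 * edf)^2`. The 1.4
degrees-of-freedom inflation is the standard guard against GCV's tendency
to undersmooth; without it, flat noisy series were interpolated outright.

The penalty is **first-order** coefficient differences by default. Its null
space is the constant curve, so a series with no temporal signal collapses
to the NB mean; a second-order penalty (available as `penalty_order=2`)
leaves linear trends unpenalized and, on trendless noisy series, carried
spurious noise-fitted slopes (measured max relative error 0.21-0.32 vs
0.05-0.12 for first order, with equal or better per-capita-rate recovery
on exponential test curves and equal end-to-end parameter recovery).

Derivatives are analytic: `fhat'(t) = fhat(t) * eta'(t)` with `eta'` the
exact B-spline derivative, so the chain-rule identity holds to machine
precision. Evaluation outside the fitted time range is refused rather than
clamped. All-zero series cannot inform a positive curve; they return a
degenerate flat fit at floor 0.5 with zero derivative, flagged for
downstream exclusion. Zeros within otherwise informative series are
handled by the NB likelihood directly — no pseudo-counts are added during
smoothing.

### Dispersion

The observation model indexes dispersion by species. Each `phi_j` is
estimated *before* smoothing from trend-corrected pseudo-residuals: at
every interior time point the count is compared with the linear
interpolation of its two neighbours, which annihilates locally linear
trends and leaves a known multiple of observation noise. The standardized
squared pseudo-residual is approximately chi-squared(1) under the NB
model, and `phi_j` is solved by matching the *median* of the statistic
over all of the species' interior points (pooled across subjects) to the
chi-squared(1) median; the median makes the estimate robust to the
minority of points straddling genuinely fast dynamics. Estimates are
bounded to [0.01, 1e8]: below 0.01 the NB likelihood is nearly
information-free and penalized fits become unstable. Fit-based Pearson
alternatives were rejected because they are bistable — an overfit smooth
hides overdispersion (`phi -> inf`) while smoother lack-of-fit masquerades
as overdispersion (`phi -> 0`) — and both failure modes were observed on
simulated data.

## Estimation: regularized gradient matching

Dividing the gLV equation by the abundance linearizes it in the
parameters:

    f_j'(t) / f_j(t) = alpha_j + sum_k beta_jk f_k(t).

With `fhat` and `fhat'` in place of the latent quantities, evaluated at
each subject's observed time points and pooled across subjects, each taxon
gives one penalized least-squares problem: unpenalized intercept
`alpha_j`, penalized slopes `beta_j.`, predictors standardized internally
and coefficients returned on the original scale. Ridge (default), lasso,
and elastic net (mixing 0.5) are supported; the penalty strength is chosen
per taxon by subject-grouped k-fold cross-validation (default 5 folds,
whole subjects per fold to respect serial dependence; lambda at minimum CV
error).

Rows where a taxon's fitted abundance is below 1 (roughly one organism) or
outside the span of its positive observations are excluded from that
taxon's own regression: the per-capita rate is a 0/0 degeneracy where the
taxon is absent, and the fitted curve is an unsupported extrapolation
outside its positive span. Without this mask, extinct-taxon series
occasionally produced unbounded responses that destroyed whole fits. The
masked rows remain as predictors for other taxa. Growth-rate estimates for
taxa that crash and vanish within the observation window reflect their
observed net decline rather than an intrinsic growth rate; they are not
separately flagged.

A difference-based baseline is provided for comparison: response
`(ln(Y_{s+1}+1) - ln(Y_s+1)) / (t_{s+1} - t_s)` per within-subject
interval, predictors the arithmetic mean of the two raw count vectors.

## Driver scores

Taxon `j` is scored by manipulating the interaction matrix and comparing
algebraic steady states, `D = ||f2* - f1*||_2^2`:

* **D1 (removal)** zeroes the off-diagonal entries of row and column `j`;
* **D2 (do-operator)** zeroes the off-diagonal row (j influences, is not
  influenced);
* **D3 (anti-do)** zeroes the off-diagonal column (j is influenced, does
  not influence).

Growth rates and the self-interaction `beta_jj` are preserved under every
manipulation: zeroing the full row or column including the diagonal makes
the perturbed matrix exactly singular, so preserving the diagonal is the
minimal reading under which the steady-state formula stays defined. Under
D1 the removed taxon therefore equilibrates at its isolated abundance
`-alpha_j / beta_jj` inside `f2*`; `removed_as_zero=True` instead pins its
component to 0 and solves the remaining (p-1)-taxon subsystem. Scores are
computed regardless of steady-state feasibility (infeasibility is
flagged); a singular perturbed system yields a NaN score and no rank.
Ranks are descending by score with ties broken by taxon label. D3 — total
outgoing influence — is the recommended driver index: a pure sink scores
exactly zero however strongly it is itself regulated, which neither D1 nor
D2 guarantees. The three-node fork/collider/chain motifs (growth rate 0.1,
self-limitation -0.001, edge magnitude 0.0005 x strength) reproduce this
qualitatively and are part of the test suite.

## Synthetic data

The generator reproduces a standard simulation protocol: `alpha_j ~
U(0, 0.2)`; off-diagonal `beta_jk` nonzero with probability `pi` drawn
from `U(-0.0005, 0.0005)`, `beta_jj = -0.001`; one shared truth model per
dataset; per-subject initial abundances `~ U(100, 10000)`; per-subject
time grids starting at 0 with integer gaps `~ U{1..5}`; latent
trajectories integrated with LSODA (rtol 1e-6, atol 1e-8, negative
excursions clipped to 0); NB noise with a single scenario-level `phi`
(the species-indexed dispersion of the observation model collapses to one
value per scenario). Initial abundances are redrawn up to 10 times if a
trajectory blows up. Datasets are bit-reproducible under their seed, and
ground truth (model and latents) is retained.

What the generator does *not* emulate: compositional (relative-abundance)
noise, zero inflation beyond what NB sampling produces, per-subject
parameter variation, and measurement-time uncertainty. Passing recovery
tests therefore speak to the estimator under the stated noise model, not
to sequencing-specific artifacts.

A property of this protocol worth knowing: initial abundances reach ~50x
the carrying capacities implied by the parameter ranges, so trajectories
crash onto a shared attractor within roughly one sampling interval and
most samples sit near one fixed point. Relative RMSE of the interaction
matrix then saturates near 1 for *every* gradient-matching variant (the
estimator is exact when fed latent trajectories), and small orderings
between pipelines are dominated by comparator implementation details. In
an informative regime — initial states scattered 0.3-3x around a feasible
steady state — the spline pipeline recovers a substantial part of the
interaction matrix (relative RMSE ~0.5 at m=50, low noise) and clearly
outperforms the difference baseline (~0.9); under the crash-dominated
protocol its advantage shows in trajectory prediction error instead.

## Evaluation

Relative RMSE is the Frobenius-norm ratio `||estimate - truth|| /
||truth||`. Trajectory prediction error simulates each subject forward
from its first reference state (latent for synthetic data, smoothed
otherwise) on its own grid under the fitted model and returns the pooled
relative RMSE; integration failure is penalized with an infinite error.
The benchmark harness regenerates datasets per condition x replicate
(seeded deterministically), runs the requested design x method pipelines,
and records both metrics plus wall time; per-replicate failures are logged
and skipped. Default problem sizes are n=10 subjects, p=10 taxa, 10
replicates per condition — the scenario's standard size with a reduced
replicate count — and are configurable.

## Known limitations

* Driver scores are context-dependent (they inherit the fitted community)
  and steady-state-based; they say nothing about transient influence.
* Growth rates of taxa absent for most of the window are weakly
  identified; their interaction rows rely on few masked-in rows.
* The smoother fits each (subject, taxon) series separately; pooling
  subjects within one smooth (subject-specific curves in a joint fit) is a
  reasonable alternative not implemented here.
* No zero-inflated observation model; heavily zero-inflated real data will
  push dispersion estimates down and oversmooth low-abundance taxa.
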