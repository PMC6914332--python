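# Methods

## Model

The gaze-weighted linear accumulator model (GLAM) describes a single
multi-alternative choice as a race of independent linear stochastic
accumulators.  Gaze enters only through the fraction of trial time
*g<sub>i</sub>* each item was fixated: the value signal of item *i* is
*r<sub>i</sub>* while fixated and *γ r<sub>i</sub>* while not, so its
trial-average signal is *Ā<sub>i</sub> = g<sub>i</sub> r<sub>i</sub> +
(1 − g<sub>i</sub>) γ r<sub>i</sub>*.  Abstracting over the fixation
sequence is the model's central simplification: drifts are constant within a
trial, the first-passage time of each accumulator is inverse-Gaussian
(mean *b/(v R<sub>i</sub>)*, shape *b²/σ²*, boundary *b = 1*), and the joint
choice/RT density has the closed form
*p<sub>i</sub>(t) = f<sub>i</sub>(t) ∏<sub>j≠i</sub>(1 − F<sub>j</sub>(t))*.
The relative-signal transform
*R<sub>i</sub> = logistic(τ(Ā<sub>i</sub> − max<sub>j≠i</sub>Ā<sub>j</sub>))*
assumes an adaptive representation most sensitive to differences near zero.
A fixed-rate uniform contaminant (rate ε, support = the subject's observed
RT range × the N items) absorbs lapses; ε is user-settable (default 0.05)
and never estimated.  The uniform density is zero outside the observed RT
range, so the mixture remains a proper density.

Assumptions worth keeping in mind: gaze is treated as exogenous (no model of
the fixation process), drifts are stationary within a trial, racers are
independent, and the boundary is fixed at 1 for identifiability.

## Parameters

| parameter | meaning | support | typical range |
|---|---|---|---|
| v | drift scaling (1/s) — smaller v, longer RTs | (0, 4) | 0.3–1.5 |
| γ | gaze bias — 1 = none, < 0 = unattended evidence lost | (−2, 1] | −0.8–1 |
| σ | accumulator noise s.d. (1/√s) | (0, 4) | 0.1–0.5 |
| τ | logistic sensitivity of the relative signal (per value unit) | [0, 10) | 0.2–3 |

Item values are expected on a common scale (a 1–10 rating scale is the
recommended convention) so that τ and v are comparable across studies.

## Priors

Individual and pooled fits use uniform priors over the supports above.
Hierarchical fits draw each subject's parameter from a truncated normal
(truncated to the same supports) whose mean and s.d. carry truncated-normal
hyperpriors; hyperprior locations and base scales are the across-dataset
distribution of published group-level estimates (e.g. group mean of v:
N(0.63, f·0.26) on [0, 2]), widened by a vagueness factor *f* (default 10).
Location and scale are pre-truncation moments.  `PriorConfig` exposes all of
these.

## Estimation

**MCMC (default).**  A custom adaptive Metropolis-within-Gibbs sampler
exploits the model's conditional independence structure: one sweep proposes
a new value of each free-parameter column for *all* subjects at once
(the per-trial likelihood is evaluated vectorized over the entire table) and
accepts per subject; hierarchical group means/s.d.s are then updated by
scalar Metropolis steps against their cheap truncated-normal conditionals.
Proposal scales adapt per (subject, parameter) toward a 0.44 acceptance rate
in windows of 25 iterations during tuning only, and are frozen afterwards,
so retained draws come from a fixed reversible kernel.  Chains start from
prior draws (individual/pooled) or jittered hyperprior locations
(hierarchical); a non-finite initial density triggers redraws.  A
Metropolis-adjusted Langevin step (`step="mala"`, finite-difference
gradients) is available where random-walk mixing is poor.  Convergence
should always be checked: `Posterior.diagnostics()` reports split-R̂ and
bulk/tail effective sample sizes (via arviz); the CLI refuses (exit ≠ 0)
fits with R̂ above a threshold (default 1.05).

**Variational (`fit_vi`).**  A diagonal Gaussian over scaled-logit-
transformed parameters, optimized with Adam on a one-sample
reparameterized ELBO estimate; likelihood gradients use column-wise central
finite differences (again one vectorized table evaluation per column),
prior/hyperprior gradients are analytic.  VI is fast but approximate —
posteriors are typically narrowed and estimates occasionally off; results
are flagged `approximate` and MCMC is recommended for final analyses.

**Point estimates.**  MAP = mode of a Gaussian-KDE fit to the marginal
samples on a 512-point grid (a degenerate all-equal marginal returns that
value); intervals are shortest-contiguous 95% HPDs over sorted samples
(unimodality assumed).  At least 100 samples are required.

## Model comparison and contrasts

WAIC and PSIS-LOO are computed (arviz) from per-trial pointwise
log-likelihood draws stored with every fit — the pointwise unit is one
(choice, RT) pair, since the likelihood factorizes by trial — and reported
on the deviance scale (−2·elpd, lower is better) with plain pseudo-BMA
(Akaike) weights; `waic_from_pointwise` is an independent lppd − p_waic
implementation kept for cross-checking (it matches arviz's population-
variance convention).  For individually fitted models the comparison is per
subject on that subject's trials.  `compare_parameters` contrasts
group-level mean posteriors (hierarchical) or per-subject condition
posteriors (individual): mean difference, fraction of the posterior above
zero, and the 95% HPD of the difference.

## Behavioural measures

`aggregate_subject_level_data` reports per subject the mean RT, the
probability of choosing the highest-valued item (ties: any tied-maximal item
counts as best), and a model-free gaze-influence score.  The score is
computed from item-trial observations: a per-subject logistic regression of
the choice indicator on the item's relative value (value minus the best
other value) gives the value-predicted choice probability; the score is the
mean of (observed − predicted) over item-trials whose relative gaze is
positive.  This operationalizes "the increase in choice probability from
longer gaze after correcting for value"; the underlying literature describes
the measure only verbally, so this concrete form is a package choice — its
null behaviour (≈ 0 when γ = 1 and gaze is value-independent) is verified in
the tests.  Binned behavioural curves (RT by difficulty, choice probability
by relative value / relative gaze, and the value-corrected curve) use
equal-width bins over the observed range (default 8); empty bins report
count 0 and an undefined mean.  Gaze fractions are used exactly as given —
they are fractions of total trial time and are deliberately not renormalized
to sum to one.

## Simulation

`simulate_trial`/`simulate_group` sample the race *exactly*: one Wald
variate per accumulator (numpy's generator) and an argmin — no time
discretization.  An Euler discretization of the accumulation process exists
only as a test oracle, where it converges to the exact sampler as the step
shrinks.  Study-design defaults (all overridable) emulate a value-based
choice task: item values i.i.d. uniform integers 1–10 (the rating-scale
convention), gaze vectors symmetric Dirichlet(1) and independent of values,
ε = 0.05.  Default per-subject parameters are drawn from truncated normals
centred on published across-dataset locations (v 0.63, γ 0.12, σ 0.27,
τ 1.03) with the across-dataset spreads (0.26, 0.35, 0.05, 0.62) as
heterogeneity; hierarchical generation uses user-supplied group means with
within-group s.d. defaults (v 0.2, γ 0.2, σ 0.05, τ 0.3) chosen to match the
clearly separated groups of the motivating designs.  Because simulated
cohorts have no empirical RTs yet, the contaminant support of a simulated
subject is the 1st–99th percentile range of that subject's exactly-sampled
race RTs (a self-consistent analogue of the observed-RT rule; percentiles of
exact samples estimate the same quantity as a quadrature of the race
density without a per-trial quadrature pass).  `predict` replays each
observed trial `n_repeats` times through the exact sampler at the subject's
MAP estimates, using the observed per-subject RT range for the contaminant.

What the generator does **not** emulate: fixation sequences, gaze that
depends on value (empirically, gaze does correlate with value), item-value
correlations, or session effects.  Passing tests therefore certify the
estimation machinery under the model's own assumptions, not robustness of
the model to real data.

## Numerical choices

- Densities are evaluated in log space.  The inverse-Gaussian survival
  function uses `logΦ` differencing and is floored at 1e−300 before logs.
  The published form of the first-passage CDF omits square roots and has an
  ambiguous exponent; the standard inverse-Gaussian CDF (exp(2λ/μ),
  √(λ/t) arguments) is implemented and validated against quadrature of the
  density and against scipy.
- Ā is computed as r·(γ + g(1 − γ)) — algebraically identical to the
  defining form but *exactly* equal to r at γ = 1, so the no-gaze-influence
  invariance holds bitwise, not just to rounding.
- Exact ties in the max-of-others reduction are kept (R* = 0 → R = 0.5), no
  perturbation is added.
- RTs are never censored during fitting; simulation offers no RT cap by
  default (degenerate drifts near zero can produce long RTs).

## Problem sizes

The test-suite and acceptance-script study sizes are desk-scale versions of
the standard designs: parameter recovery uses 10 subjects × 300 trials with
2 chains of 2000 tune + 2000 draws; model recovery 6 subjects (2 without
gaze bias) × 300 trials; the hierarchical contrast three groups of 5/10/15
subjects × 50 trials with 2500 + 2500 draws.  Published analyses of this
model family typically use 4–5k draws and 4 chains at the same data sizes;
nothing in the implementation depends on the reduced sizes.

## Known limitations

- Random-walk Metropolis mixes slowly through the v–τ posterior ridge;
  hierarchical group-s.d. parameters have high autocorrelation.  Increase
  draws/tune (or use `step="mala"`) when R̂ or ESS are unsatisfactory.
- The hierarchical likelihood treats subjects as exchangeable within a
  group; within-subject condition dependencies are supported, but crossed
  random effects are not.
- ε is fixed, not estimated; a grossly wrong ε biases σ and v.
- VI is mean-field: posterior correlations (notably v–τ) are ignored.
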