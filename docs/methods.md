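# Methods

This note records the models, approximations and design choices behind
`pkmoo`, in the order a reader would meet them: the search space and its
sampler, the mixed-effects evaluator, the two search algorithms, the
synthetic-data generator, and the VPC machinery.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Search space and genome coding

A candidate model is a choice of one option from each *token set*.  A token
set with `k` options occupies `ceil(log2 k)` bits of the genome (0 bits when
`k = 1`); bit groups are read as plain unsigned binary and out-of-range
values wrap by `v mod k`.  Plain binary plus modulo was chosen over Gray
coding or rejection because it makes decoding total on all `2^n` genomes (no
invalid bit strings anywhere in the operators) and trivially checkable
against a table-driven reference decoder.  The cost is that some options own
more bit patterns than others in non-power-of-two sets; the sampler corrects
for this by sampling at the option level and then choosing uniformly among
that option's bit patterns, so option frequencies — not pattern frequencies —
are uniform.

Each option carries `n_effects` (units of added complexity, one per
additional estimated parameter tied to a covariate or feature) and
`n_extra_params`.  Token-set order in the genome is declaration order of the
definition file, for reproducibility.

### Effect-limit sampling

With an effect limit `L`, the generator weights option `o` of each set by
`exp(−λ·n_effects(o))` and calibrates `λ` by bisection so that
`P(total effects ≤ L) = 0.80` for a raw draw.  The probability is computed
exactly by dynamic-programming convolution of the per-set effect
distributions, so the calibration needs no simulation.  `λ` is
sign-unrestricted: when the untilted sampler already lands more than 80%
within the limit, a negative `λ` (favouring effects) brings the fraction
down to the target; `P` is monotone in `λ`, so bisection always converges.
When *every* option combination satisfies the limit there is nothing to
calibrate and `λ = 0`; when none does, the configuration is rejected.

The 80% figure is a property of the raw generator only.  Draws exceeding the
limit are discarded and replaced before evaluation — in the searches this
applies to the initial population, to GA offspring, and to downhill
neighbors, so no model over the limit is ever fitted.

## The mixed-effects evaluator

### Structural models

1–3 disposition compartments, IV bolus or first-order oral absorption with
optional lag.  Predictions solve the linear compartment system by
eigendecomposition of the rate matrix with dose superposition (half-open
intervals: a dose at time `t` contributes for times `≥ t`, plus the lag for
oral input).  The 1-compartment cases use the equivalent analytic solutions
directly; the generic eigen path covers 2–3 compartments and is verified
against hand-coded mono- and bi-exponential closed forms.  Near-degenerate
spectra (e.g. `KA` numerically equal to an elimination rate) fall back to
scipy's `expm`.

Covariate effects are multiplicative on the typical value: power
`(x/ref)^b`, linear `1 + b(x − ref)`, exponential `exp(b(x − ref))`, and a
proportional shift `1 + b·x` for discrete covariates.  Continuous covariates
are referenced at the dataset median (standard practice; the reference is
recorded so estimates are interpretable).  BSV and BOV are log-normal:
`p_i = p_pop · exp(η_i)` with diagonal Ω; BOV adds one occasion-indexed
deviate per flagged parameter with a single shared variance, occasions read
from an `OCC` column.  With BOV the profile is computed piecewise — each
occasion's observations use that occasion's parameter set over the full dose
history — an approximation that avoids time-varying-coefficient ODEs and is
the usual implementation for diagonal BOV.

### Likelihood

The objective function value is the FOCE-I approximation

    OFV = Σ_i [ log|V_i| + r_i' V_i⁻¹ r_i ],
    V_i = G_i Ω G_i' + H_i,   r_i = y_i − f_i(η̂_i) + G_i η̂_i,

with `G_i = ∂f_i/∂η` at the empirical-Bayes mode `η̂_i` and `H_i` the
diagonal residual variance evaluated at the *individual* prediction (the
interaction).  The additive `n·log 2π` constant is omitted — the convention
of standard popPK estimation software — because only OFV differences drive
model selection.  `method="fo"` linearizes about `η = 0` instead.  The
approximation is exact when `f` is linear in `η` with constant residual
variance, which the tests exploit as a closed-form linear-mixed-model
oracle.

The mode `η̂_i` is found by a damped Newton-type iteration: exact gradient of
the conditional objective (including the `∂v/∂f` interaction terms) with a
Gauss-Newton Hessian, step-halving line search, warm starts across outer
iterations, and a zero start competing with the warm start so a stale warm
point can never trap the mode.  This converges in a handful of prediction
evaluations per subject, which is what makes thousands of model fits per
search affordable.

### Estimation and diagnostics

`fit` minimizes the OFV over (θ, ω², σ²) with L-BFGS-B on log-transformed
positivity-constrained parameters (covariate coefficients stay linear);
non-convergence triggers up to two jittered restarts, and optimizer failure
is always reported as `converged=False` with the best value found, never an
exception.  Because a quasi-Newton final point can sit a hair above the best
point visited, the reported estimate is the best point ever evaluated — this
keeps nested-model OFV comparisons clean.  Default initial values are crude
data-driven guesses (dose/Cmax for volume, terminal slope for elimination).

The covariance step takes a central finite-difference Hessian of the OFV in
the optimizer's transformed coordinates with absolute step `1e-3` and a
tightened inner-mode tolerance, then maps the covariance to the natural
scale by the delta method.  (Relative steps on the natural scale were tried
first and discarded: for small-magnitude parameters such as σ² ≈ 0.01 they
shrink below the numerical noise of the inner optimization and produce
garbage curvature.)  From the covariance come the estimation correlation
matrix, its eigenvalue ratio as the condition number (the correlation rather
than covariance matrix, making the threshold scale-free), per-parameter
RSE%, and `covariance_ok` (all Hessian eigenvalues > 1e-10).  The four
diagnostic thresholds — convergence, covariance success, max |off-diagonal
correlation| > 0.95 (strict), condition number > 1000 (strict) — feed the
composite fitness at 100 penalty points each, alongside 10 points per
estimated θ, ω and σ.

## Search algorithms

Shared hyperparameters and defaults (single-objective / multi-objective):
population 80/100, generations 20/30, crossover 0.95, mutation 0.95,
elitists 4, niches 2, niche radius 2 bits, downhill every 5 generations.
Crossover is single-point with a uniform cut; mutation flips exactly one
uniformly chosen bit with per-candidate probability 0.95 (a per-bit rate of
0.95 would randomize the genome).  Every tie anywhere breaks by (fitness,
NEP, lexicographic bit string), and all randomness flows through one seeded
generator, so runs are pure functions of their seed.  `num_parallel` only
splits model evaluations across workers; results are identical for any
worker count.

**SOHGA.**  Binary tournament on composite fitness; elitist slots filled
round-robin across niche heads then by global fitness, where niche heads are
found greedily (scan by ascending fitness, found a niche when more than
`niche_radius` bits from every existing head).  Downhill seeds are the best
record of each niche.  The downhill loop evaluates all one-bit neighbors,
moves to the single best improvement and repeats; on a stall with two-bit
search enabled it evaluates all two-bit neighbors once, and an improvement
there resumes the one-bit loop — so the returned model is a one-bit (and
two-bit, when enabled) local minimum.  The search result is the
lowest-fitness record ever evaluated.

**NSGA-II.**  Canonical generational form: crowded binary tournament (rank,
then crowding, then the deterministic tie-break), environmental selection
over the combined parent+offspring pool by rank with crowding-distance
truncation of the partially fitting front.  `elitist_num` is accepted in the
config but ignored on this path — environmental selection already preserves
every rank-1 member that fits, subsuming elitism — and the niche settings
likewise play no role in the multi-objective search; both are noted in the
run log.  A crowding denominator of zero (an objective constant across the
front) contributes nothing for interior points.  The MOO downhill accepts a
neighbor whenever the current archive does not dominate it — the weakest
rule that can only improve the front — and its discoveries are folded back
into the population.  The reported archive is the non-dominated set over
*all* evaluated models (merging at evaluation time is exact because
domination is transitive), deduplicated on equal (OFV, NEP) by keeping the
lexicographically smallest bit string; the final generation's front is also
tagged in the history.

Evaluations are cached by exact bit string (both algorithms re-encounter
genomes constantly through elitism and downhill) and can be persisted keyed
by a dataset hash.  A genome whose decoded model cannot be evaluated at all
(e.g. a covariate token naming a column absent from the data) gets `+inf`
fitness, a logged reason, and is excluded from Pareto archives.  Tokens
referencing structural parameters absent from the decoded structure (BSV on
Q2 under a 1-compartment choice) are dropped rather than invalidating the
model, mirroring how token-substitution search tools behave in practice.

## Synthetic data

The generator emulates the two study shapes popPK searches are typically run
on: a *rich* design (16 nominal times per subject over the observation
window, dense early for absorption) and a *sparse* therapeutic-drug-
monitoring design (multiple doses to steady state, 1–3 samples drawn
uniformly in the final dosing interval).  Canonical scenarios: rich — 50
subjects, single 100 mg dose, CL 5 L/h, V 50 L, KA 1.2 h⁻¹, 15% BSV on CL
and V, 10% proportional error, weight (log-normal, median 70 kg) acting on
CL with power 0.75, age and sex as decoy covariates; sparse — 100 subjects,
ten q12h doses with log-uniform amounts, 30% BSV, combined error.  Sizes are
desk-scale choices that keep a full search affordable while leaving enough
information to recover parameters.

Residual noise is added at the individual prediction with the true error
model; additive-error draws are deliberately *not* truncated at zero, since
truncation would bias the residual distribution (a real assay-error model
does produce the occasional negative value).  With all ω and σ at zero the
DV column equals the model prediction bit-for-bit.  A YAML truth sidecar
(model, parameters, covariate references, seed) accompanies every dataset so
recovery is checkable.

What the generator does **not** emulate: real assay quantification limits
(no BLQ censoring), dropout/compliance patterns, time-varying covariates,
correlated random effects (Ω is diagonal), and model misspecification — the
data always come from a model inside the search space.  Passing tests
therefore demonstrate the machinery (search correctness, estimation
consistency, VPC calibration) under the stated designs, not robustness to
the messiness of clinical datasets.

Benchmark spaces: `tiny` is a 10-bit, 1024-genome space used wherever an
exhaustive oracle is wanted; `table3_like` mirrors a typical compound search
(compartment counts, covariate/parameter pairings with per-option effect
counts, BSV/BOV subsets, three residual models, absorption options).  The
synthetic benchmark objective used by the search oracles decomposes the OFV
into additive per-option contributions plus mild pairwise interactions —
the structure model-selection landscapes actually have — with NEP taken from
the decoded parameter count.

## pcVPC

Population predictions (η = 0) are computed per observation row; rows with
non-positive PRED cannot be prediction-corrected and are excluded with a
logged count.  Bins are quantile-based on observation time (8 by default) so
each holds roughly equal numbers of observations — equal-count bins
stabilize percentiles on sparse designs; duplicate quantile edges collapse.
Observations and simulated values are corrected by `pcY = Y ·
median(PRED in bin) / PRED`; the observed 5th/50th/95th percentiles per bin
are compared with the across-replicate 90% interval (5th–95th percentile
over 1000 replicate datasets) of each simulated percentile.  All percentiles
use linear interpolation, so tables are bit-reproducible under a fixed seed.
BLQ-aware correction is not implemented.

## Known limitations

- Estimation is FOCE-I-style only; no SAEM or importance sampling, no Ω
  block matrices, no nonlinear (saturable) kinetics.
- The inner mode search uses a Gauss-Newton Hessian; for violently
  nonlinear subjects the mode can be slightly off the exact conditional
  optimum (the line search guarantees it is never worse than the zero/warm
  start).
- The covariance step is finite-difference based; very flat or boundary
  solutions report `covariance_ok=False` rather than attempting repair.
- BOV uses piecewise occasion parameters (see above) rather than solving a
  time-varying system.
- The CLI is a thin convenience layer; long campaigns drive the library
  directly.
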