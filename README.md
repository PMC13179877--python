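# pkmoo

Machine-learning model selection for population pharmacokinetics (popPK):
single-objective hybrid genetic-algorithm search and multi-objective NSGA-II
search over a token-set space of candidate model structures, with a built-in
FOCE-I-style nonlinear mixed-effects evaluator, estimation diagnostics, and
prediction-corrected visual predictive checks.

## The problem

Building a popPK model means choosing, jointly: the number of disposition
compartments; the absorption model (IV bolus vs. first-order oral, with or
without lag); which covariates act on which parameters and through which
functional form (power, linear, exponential, proportional shift); which
parameters carry between-subject (BSV) and between-occasion (BOV) log-normal
variability; and the residual-error model (additive, proportional, combined).
The classical forward-addition/backward-elimination search tests one feature
at a time and is easily trapped by feature interactions. `pkmoo` instead
encodes every candidate model as a fixed-length bit string — one bit group
per *token set* of mutually exclusive options — and searches the resulting
space globally.

Two search drivers are provided:

- **SOHGA** (single-objective hybrid GA) minimizes a composite penalized
  fitness

  `fitness = OFV + 10·(#θ + #ω + #σ) + 100·[no convergence] + 100·[covariance
  step failed] + 100·[max |off-diagonal correlation| > 0.95] + 100·[condition
  number > 1000]`

  where `OFV = −2 log L(θ)` is the approximate marginal likelihood
  objective.  The GA (binary tournament, single-point crossover, one-bit
  mutation, elitism across Hamming-distance niches) alternates with a
  steepest-descent *downhill* search: every `downhill_period` generations,
  all `n` one-bit flips of the incumbent — and, on a stall, all `n(n−1)/2`
  two-bit flips — are evaluated and the best improvement is taken, until no
  neighbor improves.

- **NSGA-II** searches two objectives simultaneously — OFV and NEP (the
  number of estimated parameters θ + ω + σ) — using fast non-dominated
  sorting (domination counts `n_p` and dominated-sets `S_p`, peeled front by
  front) and crowding-distance diversity
  (`d_i += (f_m(i+1) − f_m(i−1)) / (f_m^max − f_m^min)`, boundary solutions
  at +∞).  The output is the Pareto front: the set of models for which
  neither fit nor parsimony can improve without worsening the other.
  Diagnostics (convergence, covariance step, correlations, condition number)
  are attached to every front member but never enter the objectives.  An
  *effect limit* caps candidate complexity: per-option sampling
  probabilities are exponentially tilted so that 80% of raw candidates fall
  at or under the limit, and the remainder are discarded and replaced before
  any model is run.

Model evaluation never shells out to external estimation software: a compact
engine computes analytic 1–3-compartment predictions (eigendecomposition of
the linear rate matrix with dose superposition), and the marginal likelihood
by first-order conditional estimation with interaction (linearization about
each subject's empirical-Bayes random-effect mode, residual variance at the
individual prediction).

## Worked example

Simulate a richly sampled oral study from a known model, then ask NSGA-II for
the fit/parsimony front over a small 4-bit space (BSV on CL yes/no, weight
effect on CL yes/no, residual model ∈ {proportional, additive, combined}):

```python
import pkmoo
from pkmoo.search_space import SearchSpace
from pkmoo.synthetic_data import _bsv_set, _cov_set, _ruv_set
from pkmoo.sohga import GAConfig

scenario = pkmoo.rich_oral_scenario(n_subjects=12, rng_seed=1)
dataset, truth = pkmoo.generate_dataset(scenario)

space = SearchSpace((_bsv_set("CL"), _cov_set("CL", "WT", ("power",)), _ruv_set()))
search = pkmoo.NSGA2Search(
    space,
    config=GAConfig(population_size=10, num_generations=3, elitist_num=2,
                    downhill_period=2, rng_seed=0),
    method="fo", route="oral_first_order",
).fit(dataset)

print(pkmoo.pareto_report(search.archive_)[["bits", "nep", "ofv", "model"]]
      .to_string(index=False))
```

Output:

```
bits  nep         ofv                                                       model
0000    4 -414.596513                      1cpt oral_first_order RUV:proportional
1000    5 -588.653303              1cpt oral_first_order BSV(CL) RUV:proportional
1100    6 -590.122956 1cpt oral_first_order power:WT->CL BSV(CL) RUV:proportional
```

Read the staircase bottom-up: adding BSV on clearance (5 estimated
parameters) improves the OFV by ~174 points over the no-variability model;
adding the weight-on-clearance power relationship (the generating model) buys
a further 1.5 points.  Along a Pareto front NEP strictly increases while OFV
strictly decreases — every listed model is a defensible trade-off, and the
modeler picks among them with diagnostics, plausibility and pcVPCs
(`pkmoo.pcvpc`).

The same workflows are scriptable from the shell:

```bash
pkmoo simulate --config scenario.yaml --out sim/
pkmoo search --config search.yaml --algorithm nsga2 --out run/
pkmoo exhaustive --config search.yaml --out oracle/     # tiny spaces only
pkmoo vpc --config vpc.yaml --out vpc/
pkmoo report --front run/front.csv --passing-only --out report/
```

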