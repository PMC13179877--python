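"""Turning genomes into evaluated model records.

An :class:`EvalRecord` bundles a genome with its decoded model, the fit
outcome, the two search objectives (OFV and NEP — the number of estimated
parameters), the diagnostic flags, and the composite penalized fitness that
drives the single-objective search:

    fitness = OFV
            + theta_penalty * #theta + omega_penalty * #omega + sigma_penalty * #sigma
            + convergence_penalty   * [did not converge]
            + covariance_penalty    * [covariance step failed]
            + correlation_penalty   * [some |off-diagonal correlation| > 0.95]
            + condition_number_penalty * [condition number > 1000]

The diagnostic flags are attached to every record but never enter the
multi-objective (OFV, NEP) comparison; they are reported alongside the Pareto
front for the modeler's own judgement.

Evaluations are cached by exact bit string, since elitism and the downhill
passes revisit genomes constantly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed

from .errors import ConfigurationError, NumericalError
from . import pk_engine
from .pk_engine import (
    CovariateEffect,
    FitResult,
    ModelSpec,
    ParameterVector,
    PKDataset,
)
from .search_space import Genome, Phenotype, SearchSpace, decode

__all__ = [
    "PenaltyConfig",
    "EvalRecord",
    "composite_fitness",
    "build_model_spec",
    "ModelEvaluator",
    "FunctionEvaluator",
    "benchmark_objectives",
]


@dataclass(frozen=True)
class PenaltyConfig:
    """Penalty points added to the OFV to form the composite fitness.

    Defaults are the standard single-objective settings: 10 points per
    estimated parameter (theta, omega and sigma alike) and 100 points for each
    failed diagnostic (non-convergence, covariance-step failure, an absolute
    estimation correlation above 0.95, condition number above 1000).
    """

    theta_penalty: float = 10.0
    omega_penalty: float = 10.0
    sigma_penalty: float = 10.0
    convergence_penalty: float = 100.0
    covariance_penalty: float = 100.0
    correlation_penalty: float = 100.0
    condition_number_penalty: float = 100.0
    condition_threshold: float = 1000.0
    correlation_threshold: float = 0.95

    def __post_init__(self) -> None:
        for f in (
            self.theta_penalty,
            self.omega_penalty,
            self.sigma_penalty,
            self.convergence_penalty,
            self.covariance_penalty,
            self.correlation_penalty,
            self.condition_number_penalty,
        ):
            if f < 0:
                raise ConfigurationError("penalties must be >= 0")
        if self.condition_threshold <= 0 or self.correlation_threshold <= 0:
            raise ConfigurationError("thresholds must be > 0")

    @staticmethod
    def from_dict(d: Mapping[str, Any]) -> "PenaltyConfig":
        return PenaltyConfig(**{k: float(v) for k, v in d.items()})


def composite_fitness(
    fit: FitResult, spec: ModelSpec, penalties: PenaltyConfig = PenaltyConfig()
) -> float:
    """Penalized single-objective fitness of a fitted model (lower is better)."""
    f = fit.ofv
    f += penalties.theta_penalty * spec.n_theta
    f += penalties.omega_penalty * spec.n_omega
    f += penalties.sigma_penalty * spec.n_sigma
    if not fit.converged:
        f += penalties.convergence_penalty
    if not fit.covariance_ok:
        f += penalties.covariance_penalty
    if fit.correlation_exceeds(penalties.correlation_threshold):
        f += penalties.correlation_penalty
    if fit.condition_number > penalties.condition_threshold:
        f += penalties.condition_number_penalty
    return float(f)


@dataclass(frozen=True, eq=False)
class EvalRecord:
    """One evaluated candidate: genome, decoded model, fit, objectives, fitness.

    Records compare by identity; ordering for selection uses :attr:`sort_key`.
    """

    genome: Genome
    spec: ModelSpec | None
    fit: FitResult | None
    nep: int
    ofv: float
    fitness: float
    flags: dict[str, bool] = field(default_factory=dict)
    reason: str = ""

    @property
    def objectives(self) -> tuple[float, int]:
        """The multi-objective vector (OFV, NEP); penalties never enter here."""
        return (self.ofv, self.nep)

    @property
    def feasible(self) -> bool:
        return np.isfinite(self.fitness)

    @property
    def sort_key(self) -> tuple[float, int, Genome]:
        """Total order for deterministic tie-breaking: fitness, NEP, bits."""
        return (self.fitness, self.nep, self.genome)

    @property
    def bits(self) -> str:
        return "".join(map(str, self.genome))


# ---------------------------------------------------------------------------
# Phenotype -> ModelSpec


def build_model_spec(
    space: SearchSpace, phenotype: Phenotype, route: str = "iv_bolus"
) -> ModelSpec:
    """Merge the chosen options' feature payloads into a ModelSpec.

    Payload keys understood: ``n_compartments``, ``route``, ``lag``,
    ``covariate`` (a mapping with parameter/covariate/form), ``bsv`` and
    ``bov`` (parameter-name lists, unioned across sets), ``ruv``.  Later
    token sets override scalar keys; list keys accumulate.

    Tokens that reference a structural parameter absent from the decoded
    structure (e.g. BSV on Q2 while the 1-compartment option is chosen) are
    dropped silently: the option combination decodes to the model without
    that term rather than to an invalid model.
    """
    merged: dict[str, Any] = {
        "n_compartments": 1,
        "route": route,
        "lag": False,
        "ruv": "proportional",
    }
    covs: list[CovariateEffect] = []
    bsv: list[str] = []
    bov: list[str] = []
    for opt in phenotype.options(space):
        pl = opt.payload
        for key in ("n_compartments", "route", "ruv"):
            if key in pl:
                merged[key] = pl[key]
        if "lag" in pl:
            merged["lag"] = bool(pl["lag"])
        if pl.get("covariate"):
            c = pl["covariate"]
            covs.append(
                CovariateEffect(
                    parameter=c["parameter"],
                    covariate=c["covariate"],
                    form=c.get("form", "power"),
                )
            )
        for name in pl.get("bsv", ()):  # lists union across token sets
            if name not in bsv:
                bsv.append(name)
        for name in pl.get("bov", ()):
            if name not in bov:
                bov.append(name)
    structural = ModelSpec(
        n_compartments=int(merged["n_compartments"]),
        route=str(merged["route"]),
        lag=bool(merged["lag"]) and merged["route"] == "oral_first_order",
        ruv=str(merged["ruv"]),
    ).structural_params
    return ModelSpec(
        n_compartments=int(merged["n_compartments"]),
        route=str(merged["route"]),
        lag=bool(merged["lag"]) and merged["route"] == "oral_first_order",
        covariate_effects=tuple(c for c in covs if c.parameter in structural),
        bsv_on=tuple(p for p in bsv if p in structural),
        bov_on=tuple(p for p in bov if p in structural),
        ruv=str(merged["ruv"]),
    )


# ---------------------------------------------------------------------------
# Evaluators


def _flags_from_fit(fit: FitResult, penalties: PenaltyConfig) -> dict[str, bool]:
    return {
        "converged": bool(fit.converged),
        "covariance_ok": bool(fit.covariance_ok),
        "correlation_ok": not fit.correlation_exceeds(penalties.correlation_threshold),
        "condition_ok": not (fit.condition_number > penalties.condition_threshold),
    }


class ModelEvaluator:
    """Genome -> EvalRecord against a PK dataset, with a bit-string cache.

    A genome whose decoded model cannot be fitted to the dataset at all (for
    example an oral-absorption token against IV-only data) yields an
    infeasible record with ``fitness = +inf`` and a logged reason; the search
    loops treat those as arbitrarily bad and Pareto archives exclude them.
    """

    def __init__(
        self,
        space: SearchSpace,
        dataset: PKDataset,
        penalties: PenaltyConfig = PenaltyConfig(),
        method: str = "foce_i",
        route: str = "iv_bolus",
        fit_seed: int = 0,
    ):
        self.space = space
        self.dataset = dataset
        self.penalties = penalties
        self.method = method
        self.route = route
        self.fit_seed = fit_seed
        self.cache: dict[Genome, EvalRecord] = {}
        self.log: list[dict[str, Any]] = []
        self.generation: int | None = None
        self.n_fit_calls = 0

    # -- core ------------------------------------------------------------
    def _evaluate_uncached(self, genome: Genome) -> EvalRecord:
        phen = decode(self.space, genome)
        try:
            spec = build_model_spec(self.space, phen, route=self.route)
        except ConfigurationError as exc:
            return EvalRecord(
                genome=tuple(genome), spec=None, fit=None, nep=0,
                ofv=float("inf"), fitness=float("inf"),
                flags={}, reason=f"infeasible spec: {exc}",
            )
        try:
            self.n_fit_calls += 1
            fr = pk_engine.fit(
                spec, self.dataset, method=self.method, rng_seed=self.fit_seed
            )
        except (ConfigurationError, NumericalError, ValueError) as exc:
            return EvalRecord(
                genome=tuple(genome), spec=spec, fit=None, nep=spec.nep,
                ofv=float("inf"), fitness=float("inf"),
                flags={}, reason=f"unfittable: {exc}",
            )
        return EvalRecord(
            genome=tuple(genome),
            spec=spec,
            fit=fr,
            nep=spec.nep,
            ofv=fr.ofv,
            fitness=composite_fitness(fr, spec, self.penalties),
            flags=_flags_from_fit(fr, self.penalties),
        )

    def evaluate(self, genome: Sequence[int]) -> EvalRecord:
        key = tuple(int(b) for b in genome)
        if key in self.cache:
            return self.cache[key]
        rec = self._evaluate_uncached(key)
        self._store(rec)
        return rec

    def _store(self, rec: EvalRecord) -> None:
        self.cache[rec.genome] = rec
        self.log.append(
            {
                "generation": self.generation,
                "bits": rec.bits,
                "ofv": rec.ofv,
                "nep": rec.nep,
                "fitness": rec.fitness,
                **{k: int(v) for k, v in rec.flags.items()},
                "reason": rec.reason,
            }
        )

    def evaluate_many(
        self, genomes: Sequence[Sequence[int]], n_jobs: int = 1
    ) -> list[EvalRecord]:
        """Evaluate a batch; results are independent of the worker count
        because each evaluation is a pure deterministic function of the
        genome (workers only split the uncached computations)."""
        keys = [tuple(int(b) for b in g) for g in genomes]
        todo = sorted({k for k in keys if k not in self.cache})
        if n_jobs > 1 and len(todo) > 1:
            recs = Parallel(n_jobs=n_jobs, backend="threading")(
                delayed(self._evaluate_uncached)(k) for k in todo
            )
            self.n_fit_calls += 0  # counted inside _evaluate_uncached (threaded)
        else:
            recs = [self._evaluate_uncached(k) for k in todo]
        for rec in recs:
            self._store(rec)
        return [self.cache[k] for k in keys]

    # -- persistence -----------------------------------------------------
    def dataset_hash(self) -> str:
        raw = self.dataset.df.to_csv(index=False).encode()
        return hashlib.sha256(raw).hexdigest()[:16]

    def save_cache(self, path: str) -> None:
        payload = {
            "dataset_hash": self.dataset_hash(),
            "records": [
                {
                    "bits": r.bits,
                    "ofv": r.ofv,
                    "nep": r.nep,
                    "fitness": r.fitness,
                    "flags": r.flags,
                    "reason": r.reason,
                }
                for r in self.cache.values()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=str)

    def load_cache(self, path: str) -> int:
        """Preload records from a previous run of the same dataset; returns
        the number of records loaded (0 on a dataset-hash mismatch)."""
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("dataset_hash") != self.dataset_hash():
            return 0
        n = 0
        for r in payload["records"]:
            key = tuple(int(b) for b in r["bits"])
            if key in self.cache:
                continue
            self.cache[key] = EvalRecord(
                genome=key, spec=None, fit=None,
                nep=int(r["nep"]),
                ofv=float(r["ofv"]), fitness=float(r["fitness"]),
                flags={k: bool(v) for k, v in r["flags"].items()},
                reason=r.get("reason", ""),
            )
            n += 1
        return n


class FunctionEvaluator:
    """Evaluator over a deterministic objective function, no PK fitting.

    Used for benchmarking the search operators on enumerable spaces where the
    exact optimum / Pareto front is known: ``objective(genome)`` must return
    ``(ofv, nep)``.  The composite fitness applies only the per-parameter
    penalty (``nep`` estimated parameters, split reported as thetas); all
    diagnostic flags pass.
    """

    def __init__(
        self,
        space: SearchSpace,
        objective: Callable[[Genome], tuple[float, int]],
        penalties: PenaltyConfig = PenaltyConfig(),
    ):
        self.space = space
        self.objective = objective
        self.penalties = penalties
        self.cache: dict[Genome, EvalRecord] = {}
        self.log: list[dict[str, Any]] = []
        self.generation: int | None = None
        self.n_objective_calls = 0

    def evaluate(self, genome: Sequence[int]) -> EvalRecord:
        key = tuple(int(b) for b in genome)
        if key in self.cache:
            return self.cache[key]
        self.n_objective_calls += 1
        ofv, nep = self.objective(key)
        rec = EvalRecord(
            genome=key,
            spec=None,
            fit=None,
            nep=int(nep),
            ofv=float(ofv),
            fitness=float(ofv) + self.penalties.theta_penalty * int(nep),
            flags={
                "converged": True,
                "covariance_ok": True,
                "correlation_ok": True,
                "condition_ok": True,
            },
        )
        self.cache[key] = rec
        self.log.append(
            {
                "generation": self.generation,
                "bits": rec.bits,
                "ofv": rec.ofv,
                "nep": rec.nep,
                "fitness": rec.fitness,
            }
        )
        return rec

    def evaluate_many(
        self, genomes: Sequence[Sequence[int]], n_jobs: int = 1
    ) -> list[EvalRecord]:
        return [self.evaluate(g) for g in genomes]


def benchmark_objectives(
    space: SearchSpace, rng_seed: int = 0, interaction_scale: float = 2.0
) -> Callable[[Genome], tuple[float, int]]:
    """A deterministic synthetic (OFV, NEP) landscape over a search space.

    Emulates the structure of model-selection objectives: the OFV decomposes
    into additive per-option contributions (choosing a richer feature lowers
    the OFV by a random amount) plus mild pairwise interactions between token
    sets; the NEP is the decoded model's total extra-parameter count plus a
    base. Deterministic given the seed, so enumerable spaces have an exactly
    known minimum and Pareto front.
    """
    rng = np.random.default_rng(rng_seed)
    per_option = [
        rng.uniform(0, 50, ts.k) - 25.0 * np.array([o.n_extra_params for o in ts.options])
        for ts in space.token_sets
    ]
    n_sets = len(space.token_sets)
    inter = {}
    for i in range(n_sets):
        for j in range(i + 1, n_sets):
            inter[(i, j)] = rng.normal(
                0, interaction_scale, (space.token_sets[i].k, space.token_sets[j].k)
            )
    base_ofv = 1000.0

    def objective(genome: Genome) -> tuple[float, int]:
        phen = decode(space, genome)
        ofv = base_ofv + sum(per_option[i][c] for i, c in enumerate(phen.choices))
        for (i, j), m in inter.items():
            ofv += m[phen.choices[i], phen.choices[j]]
        return float(ofv), int(3 + phen.total_extra_params)

    return objective
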