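"""Synthetic PK datasets with the statistical shape of real popPK studies.

Two canonical study designs are emulated: *rich* sampling (>= 15 nominal
observation times per subject, typical of an intensively sampled trial) and
*sparse* therapeutic-drug-monitoring sampling (1-3 random draws per subject,
taken in the last dosing interval at steady state — the shape of the
antipsychotic concentration datasets popPK searches are usually run on).
Datasets are generated from a known true model: covariates are drawn from
declared distributions, log-normal between-subject (and per-occasion
between-occasion) deviates perturb the individual parameters, the
compartmental engine produces the individual predictions, and residual noise
is added per the true error model.  Additive-error draws are *not* truncated
at zero: a handful of negative concentrations is what a real assay-error
model produces, and truncating would bias the residual distribution.

The companion truth sidecar (YAML) records the generating model, parameters,
covariate reference values and seed so that recovery is checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .pk_engine import (
    CovariateEffect,
    ModelSpec,
    ParameterVector,
    PKDataset,
    predict,
)
from .search_space import SearchSpace, TokenOption, TokenSet

__all__ = [
    "DoseSchedule",
    "Scenario",
    "generate_dataset",
    "write_dataset",
    "rich_oral_scenario",
    "sparse_oral_scenario",
    "make_benchmark_space",
    "model_spec_from_dict",
    "parameter_vector_from_dict",
    "scenario_from_dict",
]


def model_spec_from_dict(d: Mapping[str, Any]) -> ModelSpec:
    """ModelSpec from a truth-sidecar / config mapping."""
    return ModelSpec(
        n_compartments=int(d.get("n_compartments", 1)),
        route=str(d.get("route", "iv_bolus")),
        lag=bool(d.get("lag", False)),
        covariate_effects=tuple(
            CovariateEffect(c["parameter"], c["covariate"], c.get("form", "power"))
            for c in d.get("covariate_effects", [])
        ),
        bsv_on=tuple(d.get("bsv_on", ())),
        bov_on=tuple(d.get("bov_on", ())),
        ruv=str(d.get("ruv", "proportional")),
    )


def parameter_vector_from_dict(d: Mapping[str, Any]) -> ParameterVector:
    return ParameterVector(
        theta={k: float(v) for k, v in d.get("theta", {}).items()},
        omega={k: float(v) for k, v in d.get("omega", {}).items()},
        sigma={k: float(v) for k, v in d.get("sigma", {}).items()},
    )


def scenario_from_dict(d: Mapping[str, Any]) -> Scenario:
    """Scenario from a parsed YAML config (see the truth-sidecar layout)."""
    dosing = d.get("dosing", {})
    amount = dosing.get("amount", 100.0)
    if isinstance(amount, (list, tuple)):
        amount = (float(amount[0]), float(amount[1]))
    cov_model = {
        name: tuple(v) if not isinstance(v[1], (list, tuple)) else
        (v[0], tuple(v[1]), tuple(v[2]))
        for name, v in d.get("covariate_model", {}).items()
    }
    return Scenario(
        truth_spec=model_spec_from_dict(d["spec"]),
        truth_params=parameter_vector_from_dict(d["parameters"]),
        n_subjects=int(d.get("n_subjects", 50)),
        dosing=DoseSchedule(
            amount=amount,
            n_doses=int(dosing.get("n_doses", 1)),
            interval=float(dosing.get("interval", 12.0)),
        ),
        sampling_design=str(d.get("sampling_design", "rich")),
        rich_times=tuple(d.get("rich_times", ())),
        sparse_max_samples=int(d.get("sparse_max_samples", 3)),
        observation_window=float(d.get("observation_window", 24.0)),
        covariate_model=cov_model,
        covariate_refs={
            k: float(v) for k, v in d.get("covariate_refs", {}).items()
        },
        occasions=int(d.get("occasions", 1)),
        rng_seed=int(d.get("rng_seed", 0)),
    )


@dataclass(frozen=True)
class DoseSchedule:
    """Dose amount (a fixed value or a log-uniform (low, high) range drawn
    once per subject) given ``n_doses`` times every ``interval`` hours."""

    amount: float | tuple[float, float] = 100.0
    n_doses: int = 1
    interval: float = 12.0

    def draw_amount(self, rng: np.random.Generator) -> float:
        if isinstance(self.amount, tuple):
            lo, hi = self.amount
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return float(self.amount)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_doses) * self.interval


@dataclass(frozen=True)
class Scenario:
    """Complete description of one simulated study.

    ``covariate_model`` maps a column name to a distribution spec:
    ``("lognormal", median, sdlog)``, ``("uniform", lo, hi)``,
    ``("bernoulli", p)`` or ``("choice", (values...), (probs...))``.
    ``covariate_refs`` are the reference values the true covariate effects
    are centered at (defaults to the distribution median).  ``occasions``
    partitions the dosing intervals into that many equal blocks for BOV.
    """

    truth_spec: ModelSpec
    truth_params: ParameterVector
    n_subjects: int = 50
    dosing: DoseSchedule = DoseSchedule()
    sampling_design: str = "rich"  # rich | sparse
    rich_times: tuple[float, ...] = ()
    sparse_max_samples: int = 3
    observation_window: float = 24.0
    covariate_model: Mapping[str, tuple] = field(default_factory=dict)
    covariate_refs: Mapping[str, float] = field(default_factory=dict)
    occasions: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.sampling_design not in ("rich", "sparse"):
            raise ConfigurationError("sampling_design must be 'rich' or 'sparse'")
        if self.occasions < 1:
            raise ConfigurationError("occasions must be >= 1")
        if self.truth_spec.bov_on and self.occasions < 2:
            raise ConfigurationError("BOV in the truth model needs >= 2 occasions")
        if self.occasions > max(self.dosing.n_doses, 1):
            raise ConfigurationError("more occasions than dosing intervals")

    def nominal_rich_times(self) -> np.ndarray:
        if self.rich_times:
            return np.asarray(self.rich_times, float)
        # 16 nominal times: dense early (absorption), spread late (elimination)
        t_end = self.observation_window
        offs = np.array(
            [0.25, 0.5, 0.75, 1, 1.5, 2, 3, 4, 6, 8, 10, 12, 16, 20, 22, 24]
        ) * (t_end / 24.0)
        return self.dosing.times[-1] + offs


def _draw_covariate(spec: tuple, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "lognormal":
        _, median, sdlog = spec
        return float(median * np.exp(rng.normal(0.0, sdlog)))
    if kind == "uniform":
        _, lo, hi = spec
        return float(rng.uniform(lo, hi))
    if kind == "bernoulli":
        return float(rng.random() < spec[1])
    if kind == "choice":
        _, values, probs = spec
        return float(rng.choice(values, p=np.asarray(probs)))
    raise ConfigurationError(f"unknown covariate distribution {kind!r}")


def _covariate_median(spec: tuple) -> float:
    kind = spec[0]
    if kind == "lognormal":
        return float(spec[1])
    if kind == "uniform":
        return float((spec[1] + spec[2]) / 2)
    if kind == "bernoulli":
        return 0.0
    if kind == "choice":
        return float(spec[1][0])
    raise ConfigurationError(f"unknown covariate distribution {kind!r}")


def generate_dataset(scenario: Scenario) -> tuple[PKDataset, dict[str, Any]]:
    """Simulate one dataset; returns (dataset, truth record).

    Per subject: draw covariates, BSV deviates and per-occasion BOV deviates,
    compute the individual profile with the true model, add residual noise
    per the true error model.  With all omega and sigma at zero the DV column
    equals the model prediction exactly.  Deterministic given the seed.
    """
    spec, params = scenario.truth_spec, scenario.truth_params
    params.validate(spec)
    rng = np.random.default_rng(scenario.rng_seed)
    refs = dict(scenario.covariate_refs)
    for name, dist in scenario.covariate_model.items():
        refs.setdefault(name, _covariate_median(dist))

    sig_add = params.sigma.get("SIG_ADD", 0.0) if spec.ruv in ("additive", "combined") else 0.0
    sig_prop = params.sigma.get("SIG_PROP", 0.0) if spec.ruv in ("proportional", "combined") else 0.0

    dose_times = scenario.dosing.times
    occ_of_time = lambda t: min(
        int(t // (scenario.dosing.interval * max(scenario.dosing.n_doses, 1) / scenario.occasions)),
        scenario.occasions - 1,
    ) if scenario.occasions > 1 else 0

    rows: list[dict[str, Any]] = []
    for sid in range(1, scenario.n_subjects + 1):
        covs = {
            name: _draw_covariate(dist, rng)
            for name, dist in scenario.covariate_model.items()
        }
        amount = scenario.dosing.draw_amount(rng)
        eta = {p: rng.normal(0.0, np.sqrt(params.omega[p])) for p in spec.bsv_on}
        bov = {
            p: rng.normal(0.0, np.sqrt(params.omega[f"BOV({p})"]), scenario.occasions)
            for p in spec.bov_on
        }
        if scenario.sampling_design == "rich":
            times = scenario.nominal_rich_times()
        else:
            last = dose_times[-1]
            k = int(rng.integers(1, scenario.sparse_max_samples + 1))
            times = np.sort(
                rng.uniform(last, last + scenario.dosing.interval, size=k)
            )
        occ = np.array([occ_of_time(t) for t in times])
        pred = np.empty(len(times))
        doses = [(float(t), amount) for t in dose_times]
        for o in np.unique(occ):
            emap = dict(eta)
            for p in spec.bov_on:
                emap[f"BOV({p})"] = float(bov[p][o])
            mask = occ == o
            pred[mask] = predict(
                spec, params, covs, doses, times[mask],
                covariate_refs=refs, eta=emap,
            )
        # residual noise at the individual prediction; exact zero when
        # sigma = 0 so noise-free scenarios reproduce predictions bit-for-bit
        eps = rng.standard_normal(len(times))
        dv = pred + eps * np.sqrt(sig_add + sig_prop * pred**2)

        for t in dose_times:
            rows.append(
                {"ID": sid, "TIME": float(t), "AMT": amount, "EVID": 1,
                 "MDV": 1, "DV": np.nan, **covs,
                 **({"OCC": occ_of_time(t)} if scenario.occasions > 1 else {})}
            )
        for t, y, o in zip(times, dv, occ):
            rows.append(
                {"ID": sid, "TIME": float(t), "AMT": 0.0, "EVID": 0,
                 "MDV": 0, "DV": float(y), **covs,
                 **({"OCC": int(o)} if scenario.occasions > 1 else {})}
            )
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID"], kind="stable")
    df = df.reset_index(drop=True)
    truth = {
        "spec": {
            "n_compartments": spec.n_compartments,
            "route": spec.route,
            "lag": spec.lag,
            "covariate_effects": [
                {"parameter": c.parameter, "covariate": c.covariate, "form": c.form}
                for c in spec.covariate_effects
            ],
            "bsv_on": list(spec.bsv_on),
            "bov_on": list(spec.bov_on),
            "ruv": spec.ruv,
        },
        "parameters": {
            "theta": dict(params.theta),
            "omega": dict(params.omega),
            "sigma": dict(params.sigma),
        },
        "covariate_refs": refs,
        "rng_seed": scenario.rng_seed,
    }
    return PKDataset(df), truth


def write_dataset(
    dataset: PKDataset, truth: dict[str, Any], csv_path: str, truth_path: str
) -> None:
    """NONMEM-style CSV plus the YAML truth sidecar."""
    dataset.to_csv(csv_path)
    with open(truth_path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Canonical scenarios


def rich_oral_scenario(
    n_subjects: int = 50, rng_seed: int = 0, with_covariates: bool = True
) -> Scenario:
    """Richly sampled single-dose oral study: 16 samples/subject over 24 h,
    15% BSV on CL and V, 10% proportional residual error."""
    spec = ModelSpec(
        n_compartments=1,
        route="oral_first_order",
        covariate_effects=(
            (CovariateEffect("CL", "WT", "power"),) if with_covariates else ()
        ),
        bsv_on=("CL", "V"),
        ruv="proportional",
    )
    theta = {"CL": 5.0, "V": 50.0, "KA": 1.2}
    if with_covariates:
        theta["B_CL_WT_power"] = 0.75
    params = ParameterVector(
        theta=theta,
        omega={"CL": 0.0225, "V": 0.0225},  # 15% CV
        sigma={"SIG_PROP": 0.01},  # 10% CV
    )
    return Scenario(
        truth_spec=spec,
        truth_params=params,
        n_subjects=n_subjects,
        dosing=DoseSchedule(amount=100.0, n_doses=1),
        sampling_design="rich",
        observation_window=24.0,
        covariate_model=(
            {
                "WT": ("lognormal", 70.0, 0.2),
                "AGE": ("uniform", 20.0, 60.0),
                "SEX": ("bernoulli", 0.5),
            }
            if with_covariates
            else {}
        ),
        covariate_refs={"WT": 70.0} if with_covariates else {},
        rng_seed=rng_seed,
    )


def sparse_oral_scenario(n_subjects: int = 100, rng_seed: int = 0) -> Scenario:
    """Sparse TDM-style study: multiple oral doses to steady state, 1-3
    samples drawn in the final dosing interval."""
    spec = ModelSpec(
        n_compartments=1,
        route="oral_first_order",
        covariate_effects=(CovariateEffect("CL", "WT", "power"),),
        bsv_on=("CL", "V"),
        ruv="combined",
    )
    params = ParameterVector(
        theta={"CL": 20.0, "V": 300.0, "KA": 0.8, "B_CL_WT_power": 0.75},
        omega={"CL": 0.09, "V": 0.09},  # 30% CV
        sigma={"SIG_ADD": 1.0, "SIG_PROP": 0.04},
    )
    return Scenario(
        truth_spec=spec,
        truth_params=params,
        n_subjects=n_subjects,
        dosing=DoseSchedule(amount=(100.0, 600.0), n_doses=10, interval=12.0),
        sampling_design="sparse",
        covariate_model={
            "WT": ("lognormal", 75.0, 0.25),
            "AGE": ("uniform", 18.0, 65.0),
            "SEX": ("bernoulli", 0.5),
        },
        covariate_refs={"WT": 75.0},
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Benchmark search spaces


def _cov_option(parameter: str, covariate: str, form: str) -> TokenOption:
    return TokenOption(
        label=f"{form}_{covariate}_{parameter}",
        payload={
            "covariate": {"parameter": parameter, "covariate": covariate, "form": form}
        },
        n_effects=1,
        n_extra_params=1,
    )


def _none_option(label: str = "none") -> TokenOption:
    return TokenOption(label=label, payload={})


def _cov_set(parameter: str, covariate: str, forms: tuple[str, ...]) -> TokenSet:
    return TokenSet(
        name=f"{covariate}_on_{parameter}",
        options=(_none_option(),) + tuple(_cov_option(parameter, covariate, f) for f in forms),
    )


def _bsv_set(parameter: str) -> TokenSet:
    return TokenSet(
        name=f"bsv_{parameter}",
        options=(
            _none_option(),
            TokenOption(
                label=f"bsv_{parameter}",
                payload={"bsv": [parameter]},
                n_effects=0,
                n_extra_params=1,
            ),
        ),
    )


def _bov_set(parameter: str) -> TokenSet:
    return TokenSet(
        name=f"bov_{parameter}",
        options=(
            _none_option(),
            TokenOption(
                label=f"bov_{parameter}",
                payload={"bov": [parameter]},
                n_effects=1,
                n_extra_params=1,
            ),
        ),
    )


def _ruv_set() -> TokenSet:
    return TokenSet(
        name="ruv",
        options=(
            TokenOption("prop", {"ruv": "proportional"}, 0, 1),
            TokenOption("add", {"ruv": "additive"}, 0, 1),
            TokenOption("comb", {"ruv": "combined"}, 0, 2),
        ),
    )


def _compartment_set(counts: tuple[int, ...]) -> TokenSet:
    return TokenSet(
        name="compartments",
        options=tuple(
            TokenOption(
                label=f"{c}cpt",
                payload={"n_compartments": c},
                n_effects=0,
                n_extra_params=2 * (c - counts[0]),
            )
            for c in counts
        ),
    )


def _lag_set() -> TokenSet:
    return TokenSet(
        name="absorption_lag",
        options=(
            _none_option("no_lag"),
            TokenOption("lag", {"lag": True}, 1, 1),
        ),
    )


_TABLE_TEMPLATES = {
    # covariate pairings follow each compound's searched covariate list;
    # continuous covariates get a power form, discrete ones a proportional
    # shift, each mapped onto a plausible disposition parameter
    "ziprasidone": dict(
        compartments=(1, 2),
        covs=[("CL", "AGE", ("power",)), ("V", "WT", ("power",)),
              ("CL", "SEX", ("proportional_shift",)),
              ("CL", "RACE", ("proportional_shift",)),
              ("CL", "COMED", ("proportional_shift",))],
        bsv=("CL", "V", "Q2", "V2", "KA"),
        bov=(),
        lag=True,
        route="oral_first_order",
    ),
    "clozapine": dict(
        compartments=(1, 2),
        covs=[("CL", "AGE", ("power",)), ("V", "WT", ("power",)),
              ("CL", "HT", ("power",)), ("CL", "SEX", ("proportional_shift",)),
              ("KA", "FORM", ("proportional_shift",))],
        bsv=("CL", "V", "Q2", "V2"),
        bov=(),
        lag=False,
        route="oral_first_order",
    ),
    "dmag": dict(
        compartments=(1, 2, 3),
        covs=[("CL", "AGE", ("power",)), ("V", "WT", ("power",)),
              ("CL", "CRCL", ("power",)), ("CL", "SEX", ("proportional_shift",))],
        bsv=("CL", "V", "Q2", "V2", "Q3", "V3"),
        bov=("V", "CL", "Q2"),
        lag=False,
        route="iv_bolus",
    ),
    "quetiapine": dict(
        compartments=(1, 2, 3),
        covs=[("CL", "AGE", ("power",)), ("V", "WT", ("power",)),
              ("CL", "SEX", ("proportional_shift",)),
              ("CL", "SMOK", ("proportional_shift",))],
        bsv=("CL", "V", "Q2", "V2"),
        bov=(),
        lag=True,
        route="oral_first_order",
    ),
}


def make_benchmark_space(
    kind: str = "tiny",
    compound_template: str = "quetiapine",
    effect_limit: int | None = None,
) -> SearchSpace:
    """Benchmark search spaces.

    ``tiny`` is a 10-bit, fully enumerable (1024-genome) space for oracle
    tests; ``compound_like`` mirrors one compound's search-space row
    (compartment options, covariate forms, BSV/BOV subsets, residual models,
    absorption options) with per-option effect counts.
    """
    if kind == "tiny":
        sets = (
            _compartment_set((1, 2)),
            _cov_set("CL", "WT", ("power",)),
            TokenSet(
                name="AGE_on_CL",
                options=(
                    _none_option(),
                    _cov_option("CL", "AGE", "power"),
                    _cov_option("CL", "AGE", "linear"),
                ),
            ),
            _cov_set("V", "SEX", ("proportional_shift",)),
            _bsv_set("CL"),
            _bsv_set("V"),
            _ruv_set(),
            _lag_set(),
        )
        space = SearchSpace(token_sets=sets, effect_limit=effect_limit)
        assert space.n_total_bits <= 12
        return space
    if kind == "compound_like":
        try:
            tpl = _TABLE_TEMPLATES[compound_template]
        except KeyError:
            raise ConfigurationError(
                f"unknown compound template {compound_template!r}"
            ) from None
        sets: list[TokenSet] = [_compartment_set(tpl["compartments"])]
        sets += [_cov_set(p, c, forms) for p, c, forms in tpl["covs"]]
        sets += [_bsv_set(p) for p in tpl["bsv"]]
        sets += [_bov_set(p) for p in tpl["bov"]]
        sets.append(_ruv_set())
        if tpl["lag"]:
            sets.append(_lag_set())
        return SearchSpace(token_sets=tuple(sets), effect_limit=effect_limit)
    raise ConfigurationError(f"unknown benchmark space kind {kind!r}")
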