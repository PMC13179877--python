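"""Lightweight nonlinear mixed-effects engine for linear compartmental PK.

Evaluates one candidate model (1–3 disposition compartments, IV bolus or
first-order oral absorption with optional lag, multiplicative covariate
effects, log-normal between-subject and between-occasion variability, and an
additive / proportional / combined residual-error model) against a
NONMEM-style longitudinal dataset.

Predictions come from the linear compartment system: the rate matrix is
diagonalized once per parameter set and doses are superposed, which is the
matrix exponential of the system evaluated at the observation times.  The
marginal likelihood uses the first-order conditional approximation with
interaction (FOCE-I): linearization of the subject prediction about the
empirical-Bayes mode of the random effects, with the residual variance
evaluated at the individual prediction.  The objective function value is

    OFV = -2 log L = sum_i [ log|V_i| + r_i' V_i^-1 r_i ]

with ``V_i = G_i Omega G_i' + H_i`` and ``r_i = y_i - f_i(eta_hat) + G_i
eta_hat``; the additive ``n log 2 pi`` constant is omitted, mirroring the
convention of standard popPK estimation software (only OFV differences drive
the model search).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, NumericalError

__all__ = [
    "CovariateEffect",
    "ModelSpec",
    "PKDataset",
    "ParameterVector",
    "FitResult",
    "predict",
    "neg2loglik",
    "marginal_neg2loglik",
    "fit",
    "condition_number",
    "correlation_flag",
    "CompartmentModel",
]

#: canonical ordering of structural fixed effects
PARAM_ORDER = ("CL", "V", "Q2", "V2", "Q3", "V3", "KA", "ALAG")

COVARIATE_FORMS = ("power", "linear", "exponential", "proportional_shift")
RUV_MODELS = ("additive", "proportional", "combined")

_VAR_FLOOR = 1e-12
_PARAM_FLOOR = 1e-8


@dataclass(frozen=True)
class CovariateEffect:
    """A multiplicative covariate relationship on one structural parameter.

    Forms (``x`` the covariate value, ``ref`` its reference, ``b`` the
    estimated coefficient): power ``(x/ref)**b``; linear ``1 + b*(x-ref)``;
    exponential ``exp(b*(x-ref))``; proportional_shift ``1 + b*x`` for a 0/1
    (or small-integer) discrete covariate.
    """

    parameter: str
    covariate: str
    form: str = "power"

    def __post_init__(self) -> None:
        if self.form not in COVARIATE_FORMS:
            raise ConfigurationError(f"unknown covariate form {self.form!r}")

    @property
    def theta_name(self) -> str:
        return f"B_{self.parameter}_{self.covariate}_{self.form}"


@dataclass(frozen=True)
class ModelSpec:
    """Decoded phenotype of one candidate population-PK model."""

    n_compartments: int = 1
    route: str = "iv_bolus"
    lag: bool = False
    covariate_effects: tuple[CovariateEffect, ...] = ()
    bsv_on: tuple[str, ...] = ()
    bov_on: tuple[str, ...] = ()
    ruv: str = "proportional"

    def __post_init__(self) -> None:
        if self.n_compartments not in (1, 2, 3):
            raise ConfigurationError("n_compartments must be 1, 2 or 3")
        if self.route not in ("iv_bolus", "oral_first_order"):
            raise ConfigurationError(f"unknown route {self.route!r}")
        if self.ruv not in RUV_MODELS:
            raise ConfigurationError(f"unknown residual model {self.ruv!r}")
        if self.lag and self.route != "oral_first_order":
            raise ConfigurationError("absorption lag requires oral dosing")
        sp = set(self.structural_params)
        for p in (*self.bsv_on, *self.bov_on):
            if p not in sp:
                raise ConfigurationError(
                    f"random effect on {p!r} but {p!r} is not a structural parameter"
                )
        for ce in self.covariate_effects:
            if ce.parameter not in sp:
                raise ConfigurationError(
                    f"covariate effect on {ce.parameter!r} not in structural set"
                )

    @property
    def structural_params(self) -> tuple[str, ...]:
        names = ["CL", "V"]
        if self.n_compartments >= 2:
            names += ["Q2", "V2"]
        if self.n_compartments == 3:
            names += ["Q3", "V3"]
        if self.route == "oral_first_order":
            names.append("KA")
            if self.lag:
                names.append("ALAG")
        return tuple(names)

    @property
    def theta_names(self) -> tuple[str, ...]:
        return self.structural_params + tuple(
            ce.theta_name for ce in self.covariate_effects
        )

    @property
    def omega_names(self) -> tuple[str, ...]:
        return tuple(self.bsv_on) + tuple(f"BOV({p})" for p in self.bov_on)

    @property
    def sigma_names(self) -> tuple[str, ...]:
        if self.ruv == "additive":
            return ("SIG_ADD",)
        if self.ruv == "proportional":
            return ("SIG_PROP",)
        return ("SIG_ADD", "SIG_PROP")

    @property
    def n_theta(self) -> int:
        return len(self.theta_names)

    @property
    def n_omega(self) -> int:
        return len(self.omega_names)

    @property
    def n_sigma(self) -> int:
        return len(self.sigma_names)

    @property
    def nep(self) -> int:
        """Number of estimated parameters: #theta + #omega + #sigma."""
        return self.n_theta + self.n_omega + self.n_sigma


@dataclass
class ParameterVector:
    """Population parameter values: fixed effects, random-effect variances
    (diagonal), and residual variance components."""

    theta: dict[str, float]
    omega: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)

    def validate(self, spec: ModelSpec) -> None:
        for name in spec.structural_params:
            if name not in self.theta:
                raise ConfigurationError(f"missing structural parameter {name}")
            if name != "ALAG" and self.theta[name] <= 0:
                raise ValueError(f"structural parameter {name} must be positive")
        for name in spec.omega_names:
            if self.omega.get(name, 0.0) < 0:
                raise ValueError(f"omega[{name}] must be >= 0")
        for name in spec.sigma_names:
            if self.sigma.get(name, 0.0) < 0:
                raise ValueError(f"sigma[{name}] must be >= 0")

    def as_array(self, spec: ModelSpec) -> np.ndarray:
        return np.array(
            [self.theta[n] for n in spec.theta_names]
            + [self.omega[n] for n in spec.omega_names]
            + [self.sigma[n] for n in spec.sigma_names]
        )

    @staticmethod
    def from_array(spec: ModelSpec, x: Sequence[float]) -> "ParameterVector":
        x = list(x)
        nt, no = spec.n_theta, spec.n_omega
        return ParameterVector(
            theta=dict(zip(spec.theta_names, x[:nt])),
            omega=dict(zip(spec.omega_names, x[nt : nt + no])),
            sigma=dict(zip(spec.sigma_names, x[nt + no :])),
        )


# ---------------------------------------------------------------------------
# Dataset


class PKDataset:
    """NONMEM-style longitudinal PK data (ID, TIME, AMT, EVID, MDV, DV, covariates).

    Dose rows have EVID=1/MDV=1; observation rows EVID=0.  '.' in DV is read
    as missing.  An optional OCC column indexes occasions for BOV models.
    Covariates are taken as constant within subject (first row per subject).
    """

    REQUIRED = ("ID", "TIME", "AMT", "EVID", "MDV", "DV")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ConfigurationError(f"dataset missing required column {col}")
        df["DV"] = pd.to_numeric(df["DV"], errors="coerce")
        for col in ("TIME", "AMT"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        for col in ("ID", "EVID", "MDV"):
            df[col] = df[col].astype(int)
        for sid, sub in df.groupby("ID", sort=False):
            if not sub["TIME"].is_monotonic_increasing:
                raise ConfigurationError(f"TIME not non-decreasing for subject {sid}")
        bad = df[(df["EVID"] == 1) & (df["MDV"] != 1)]
        if len(bad):
            raise ConfigurationError("dose rows must have MDV=1")
        self.df = df
        self.covariate_columns = tuple(
            c
            for c in df.columns
            if c not in self.REQUIRED and c not in ("OCC",)
        )

    @classmethod
    def from_csv(cls, path: str, column_map: Mapping[str, str] | None = None):
        df = pd.read_csv(path, na_values=["."])
        if column_map:
            df = df.rename(columns=dict(column_map))
        return cls(df)

    def to_csv(self, path: str) -> None:
        out = self.df.copy()
        out["DV"] = out["DV"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
        out.to_csv(path, index=False)

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        obs = self.df[(self.df["EVID"] == 0) & self.df["DV"].notna()]
        return len(obs)

    def covariate_references(self) -> dict[str, float]:
        """Per-covariate reference value: the median of subject-level values."""
        firsts = self.df.groupby("ID", sort=False).first()
        return {c: float(firsts[c].median()) for c in self.covariate_columns}

    def subjects(self) -> list["_Subject"]:
        out = []
        has_occ = "OCC" in self.df.columns
        for sid, sub in self.df.groupby("ID", sort=False):
            doses = sub[sub["EVID"] == 1]
            obs = sub[(sub["EVID"] == 0) & sub["DV"].notna()]
            covs = {c: float(sub.iloc[0][c]) for c in self.covariate_columns}
            occ = (
                obs["OCC"].astype(int).to_numpy()
                if has_occ
                else np.zeros(len(obs), dtype=int)
            )
            out.append(
                _Subject(
                    id=int(sid),
                    dose_times=doses["TIME"].to_numpy(float),
                    dose_amts=doses["AMT"].to_numpy(float),
                    obs_times=obs["TIME"].to_numpy(float),
                    y=obs["DV"].to_numpy(float),
                    occ=occ,
                    covariates=covs,
                )
            )
        return out


@dataclass
class _Subject:
    id: int
    dose_times: np.ndarray
    dose_amts: np.ndarray
    obs_times: np.ndarray
    y: np.ndarray
    occ: np.ndarray
    covariates: dict[str, float]

    @property
    def occasions(self) -> np.ndarray:
        return np.unique(self.occ)


# ---------------------------------------------------------------------------
# Structural predictions


def _rate_matrix(p: Mapping[str, float], n_cpt: int, oral: bool) -> np.ndarray:
    """Linear transfer-rate matrix; compartment 0 is the depot when oral."""
    cl, v = p["CL"], p["V"]
    if cl <= 0 or v <= 0:
        raise ValueError("CL and V must be positive")
    k10 = cl / v
    off = 1 if oral else 0
    n = n_cpt + off
    A = np.zeros((n, n))
    c = off  # index of the central compartment
    A[c, c] -= k10
    if n_cpt >= 2:
        k12, k21 = p["Q2"] / v, p["Q2"] / p["V2"]
        A[c, c] -= k12
        A[c + 1, c] += k12
        A[c + 1, c + 1] -= k21
        A[c, c + 1] += k21
    if n_cpt == 3:
        k13, k31 = p["Q3"] / v, p["Q3"] / p["V3"]
        A[c, c] -= k13
        A[c + 2, c] += k13
        A[c + 2, c + 2] -= k31
        A[c, c + 2] += k31
    if oral:
        ka = p["KA"]
        if ka <= 0:
            raise ValueError("KA must be positive")
        A[0, 0] -= ka
        A[c, 0] += ka
    return A


def _disposition(
    p: Mapping[str, float],
    n_cpt: int,
    oral: bool,
    dose_times: np.ndarray,
    dose_amts: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    """Central-compartment concentration at ``times`` by dose superposition.

    Diagonalizes the rate matrix once; each dose contributes
    ``P exp(w dt) P^-1 d0`` for ``dt >= 0`` (half-open intervals: a dose at
    time t contributes for times >= t).  Eigenvalues of these matrices are
    real-negative and generically distinct; near-degenerate spectra (e.g. KA
    numerically equal to the elimination rate) fall back to scipy's expm.
    """
    if n_cpt == 1:  # analytic solution of the same linear system
        return _disposition_1cpt(p, oral, dose_times, dose_amts, times)
    return _disposition_eig(p, n_cpt, oral, dose_times, dose_amts, times)


def _disposition_1cpt(
    p: Mapping[str, float],
    oral: bool,
    dose_times: np.ndarray,
    dose_amts: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    cl, v = p["CL"], p["V"]
    if cl <= 0 or v <= 0:
        raise ValueError("CL and V must be positive")
    k = cl / v
    out = np.zeros(len(times))
    if oral:
        ka = p["KA"]
        if ka <= 0:
            raise ValueError("KA must be positive")
        if abs(ka - k) < 1e-9 * max(ka, k):  # keep the two exponents distinct
            ka *= 1.0 + 1e-7
        alag = float(p.get("ALAG", 0.0))
        coef = ka / (v * (ka - k))
        for td, amt in zip(dose_times, dose_amts):
            dt = times - td - alag
            m = dt >= 0
            out[m] += amt * coef * (np.exp(-k * dt[m]) - np.exp(-ka * dt[m]))
    else:
        for td, amt in zip(dose_times, dose_amts):
            dt = times - td
            m = dt >= 0
            out[m] += amt / v * np.exp(-k * dt[m])
    return np.maximum(out, 0.0)


def _disposition_eig(
    p: Mapping[str, float],
    n_cpt: int,
    oral: bool,
    dose_times: np.ndarray,
    dose_amts: np.ndarray,
    times: np.ndarray,
) -> np.ndarray:
    A = _rate_matrix(p, n_cpt, oral)
    n = A.shape[0]
    central = 1 if oral else 0
    alag = float(p.get("ALAG", 0.0)) if oral else 0.0
    d0 = np.zeros(n)
    d0[0] = 1.0  # unit dose into depot (oral) or central (IV)

    w, P = np.linalg.eig(A)
    scale = max(np.max(np.abs(w)), 1e-12)
    degenerate = np.min(
        np.abs(w[:, None] - w[None, :]) + np.eye(n) * scale
    ) < 1e-9 * scale

    out = np.zeros(len(times))
    if not degenerate:
        coef = np.linalg.solve(P, d0)  # P^-1 d0
        row = P[central]  # central-compartment row of P
        for td, amt in zip(dose_times, dose_amts):
            dt = times - td - alag
            mask = dt >= 0
            if not mask.any():
                continue
            e = np.exp(np.outer(dt[mask], w))
            out[mask] += amt * np.real(e @ (row * coef))
    else:  # repeated eigenvalues: exact matrix exponential per time point
        for td, amt in zip(dose_times, dose_amts):
            dt = times - td - alag
            for i, d in enumerate(dt):
                if d >= 0:
                    out[i] += amt * (linalg.expm(A * d) @ d0)[central]
    return np.maximum(out, 0.0) / p["V"]


def _covariate_factor(
    ce: CovariateEffect, beta: float, x: float, ref: float
) -> float:
    if ce.form == "power":
        if x <= 0 or ref <= 0:
            raise ValueError(
                f"power covariate {ce.covariate} needs positive values"
            )
        return (x / ref) ** beta
    if ce.form == "linear":
        return 1.0 + beta * (x - ref)
    if ce.form == "exponential":
        return math.exp(beta * (x - ref))
    return 1.0 + beta * x  # proportional_shift on a discrete indicator


def individual_parameters(
    spec: ModelSpec,
    params: ParameterVector,
    covariates: Mapping[str, float],
    covariate_refs: Mapping[str, float] | None = None,
    eta: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Apply covariate effects and random-effect deviates to the typical values.

    ``eta`` keys follow :attr:`ModelSpec.omega_names` (``"CL"`` for BSV,
    ``"BOV(CL)"`` for the current occasion's BOV deviate).  Multiplicative
    factors are floored at a small positive value so that predictions stay in
    the model's domain even for extreme linear-covariate draws.
    """
    refs = covariate_refs or {}
    p = {name: float(params.theta[name]) for name in spec.structural_params}
    for ce in spec.covariate_effects:
        if ce.covariate not in covariates:
            raise ConfigurationError(f"covariate {ce.covariate!r} missing from data")
        beta = float(params.theta[ce.theta_name])
        fac = _covariate_factor(
            ce, beta, float(covariates[ce.covariate]), float(refs.get(ce.covariate, 1.0))
        )
        p[ce.parameter] *= max(fac, _PARAM_FLOOR)
    if eta:
        for pname in spec.bsv_on:
            p[pname] *= math.exp(eta.get(pname, 0.0))
        for pname in spec.bov_on:
            p[pname] *= math.exp(eta.get(f"BOV({pname})", 0.0))
    return p


def predict(
    spec: ModelSpec,
    params: ParameterVector,
    subject_covariates: Mapping[str, float],
    dose_history: Sequence[tuple[float, float]],
    times: Sequence[float],
    covariate_refs: Mapping[str, float] | None = None,
    eta: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Concentration-time prediction for one subject.

    ``dose_history`` is a sequence of ``(time, amount)`` pairs; ``eta`` maps
    random-effect names to deviates (empty/None for the typical subject).
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be >= 0")
    params.validate(spec)
    p = individual_parameters(spec, params, subject_covariates, covariate_refs, eta)
    dt = np.array([d[0] for d in dose_history], dtype=float)
    da = np.array([d[1] for d in dose_history], dtype=float)
    return _disposition(
        p, spec.n_compartments, spec.route == "oral_first_order", dt, da, times
    )


def residual_variance(
    spec: ModelSpec, params: ParameterVector, pred: np.ndarray
) -> np.ndarray:
    """Residual-error variance at the (individual) prediction."""
    v = np.zeros_like(pred)
    if spec.ruv in ("additive", "combined"):
        v = v + params.sigma["SIG_ADD"]
    if spec.ruv in ("proportional", "combined"):
        v = v + params.sigma["SIG_PROP"] * pred**2
    return np.maximum(v, _VAR_FLOOR)


# ---------------------------------------------------------------------------
# Marginal likelihood (FOCE-I / FO)


def _fd_jacobian(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray, h: float = 1e-5):
    """Central-difference Jacobian of a vector function."""
    cols = []
    for j in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        cols.append((f(xp) - f(xm)) / (2 * h))
    return np.column_stack(cols) if cols else np.zeros((0, 0))


def _fwd_jacobian(
    f: Callable[[np.ndarray], np.ndarray], x: np.ndarray, f0: np.ndarray,
    h: float = 1e-6,
):
    """Forward-difference Jacobian reusing f(x); used inside the mode search."""
    cols = []
    for j in range(len(x)):
        xp = x.copy()
        xp[j] += h
        cols.append((f(xp) - f0) / h)
    return np.column_stack(cols) if cols else np.zeros((len(f0), 0))


def _ebe_mode(
    y: np.ndarray,
    f_func: Callable[[np.ndarray], np.ndarray],
    omega_diag: np.ndarray,
    resvar_func: Callable[[np.ndarray], np.ndarray],
    eta0: np.ndarray | None,
    max_iter: int = 40,
    tol: float = 1e-9,
) -> np.ndarray:
    """Empirical-Bayes mode of the random effects for one subject.

    Minimizes the conditional objective
    ``sum[log v(f) + (y - f)^2 / v(f)] + sum eta^2 / omega`` by a damped
    Newton-type iteration: the exact objective gradient (including the
    residual-variance dependence on the prediction, i.e. the interaction
    term) with a Gauss-Newton Hessian approximation, and step halving
    against the full objective.  Converges in one step for predictions
    linear in eta with constant residual variance.  A zero start competes
    with the warm start so a stale warm point can never trap the mode.
    """
    k = len(omega_diag)

    def cond_obj(e: np.ndarray) -> float:
        f = f_func(e)
        v = resvar_func(f)
        return float(np.sum(np.log(v) + (y - f) ** 2 / v) + np.sum(e**2 / omega_diag))

    eta = np.zeros(k)
    obj = cond_obj(eta)
    if eta0 is not None and np.any(eta0 != 0):
        o_w = cond_obj(eta0)
        if o_w < obj:
            eta, obj = np.asarray(eta0, float).copy(), o_w
    inv_om = 1.0 / omega_diag
    for _ in range(max_iter):
        f = f_func(eta)
        G = _fwd_jacobian(f_func, eta, f)
        v = resvar_func(f)
        h = 1e-6 * (1.0 + np.abs(f))
        dv_df = (resvar_func(f + h) - resvar_func(f - h)) / (2 * h)
        w = 1.0 / v
        r = y - f
        A = (G.T * w) @ G + np.diag(inv_om)
        # -(1/2) gradient of the conditional objective w.r.t. eta
        g = G.T @ (w * r + 0.5 * dv_df * w * (w * r**2 - 1.0)) - inv_om * eta
        try:
            d = np.linalg.solve(A, g)
        except np.linalg.LinAlgError:
            break
        step, trial, o_t = 1.0, None, obj
        for _ in range(12):
            cand = eta + step * d
            o_c = cond_obj(cand)
            if o_c < obj:
                trial, o_t = cand, o_c
                break
            step *= 0.5
        if trial is None:
            break
        gain = obj - o_t
        eta, obj = trial, o_t
        if np.max(np.abs(step * d)) < 1e-8 or gain < tol * (1.0 + abs(obj)):
            break
    return eta


def marginal_neg2loglik(
    y: np.ndarray,
    f_func: Callable[[np.ndarray], np.ndarray],
    omega_diag: np.ndarray,
    resvar_func: Callable[[np.ndarray], np.ndarray],
    method: str = "foce_i",
    eta0: np.ndarray | None = None,
    inner_tol: float = 1e-9,
) -> tuple[float, np.ndarray]:
    """One subject's -2 log marginal likelihood under FOCE(-I) or FO.

    ``f_func(eta)`` maps the random-effect vector to the prediction vector;
    ``resvar_func(pred)`` gives the residual variance at a prediction
    (evaluated at the individual prediction — the "interaction" part).
    Returns ``(value, eta_hat)``; the ``n log 2 pi`` constant is omitted.
    Exact for predictions linear in ``eta`` (the linear-mixed-model case).
    """
    y = np.asarray(y, float)
    omega_diag = np.asarray(omega_diag, float)
    k = len(omega_diag)
    if k == 0:
        f = f_func(np.zeros(0))
        v = resvar_func(f)
        val = float(np.sum(np.log(v) + (y - f) ** 2 / v))
        return val, np.zeros(0)
    if (omega_diag <= 0).any():
        raise ValueError("omega variances must be positive for included effects")

    if method == "fo":
        eta_hat = np.zeros(k)
    elif method == "foce_i":
        eta_hat = _ebe_mode(y, f_func, omega_diag, resvar_func, eta0, tol=inner_tol)
    else:
        raise ValueError(f"unknown method {method!r}")

    f_hat = f_func(eta_hat)
    G = _fd_jacobian(f_func, eta_hat)
    H = np.diag(resvar_func(f_hat))
    V = G @ np.diag(omega_diag) @ G.T + H
    r = y - f_hat + G @ eta_hat
    sign, logdet = np.linalg.slogdet(V)
    if sign <= 0:
        raise NumericalError("non-positive-definite marginal covariance")
    try:
        sol = np.linalg.solve(V, r)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - singular V
        raise NumericalError("singular marginal covariance") from exc
    return float(logdet + r @ sol), eta_hat


class _LikelihoodProblem:
    """Dataset-bound likelihood evaluator with per-subject warm starts."""

    def __init__(
        self,
        spec: ModelSpec,
        dataset: PKDataset,
        method: str = "foce_i",
        inner_tol: float = 1e-9,
    ):
        if method not in ("foce_i", "fo"):
            raise ValueError(f"unknown estimation method {method!r}")
        self.spec = spec
        self.method = method
        self.inner_tol = inner_tol
        self.subjects = dataset.subjects()
        if not self.subjects:
            raise ConfigurationError("dataset has no subjects")
        for s in self.subjects:
            if len(s.y) == 0:
                raise ConfigurationError(f"subject {s.id} has no observations")
        self.refs = dataset.covariate_references()
        for ce in spec.covariate_effects:
            if ce.covariate not in dataset.covariate_columns:
                raise ConfigurationError(
                    f"covariate {ce.covariate!r} not in dataset"
                )
        if spec.route == "oral_first_order":
            if any((s.dose_times < 0).any() for s in self.subjects):
                raise ConfigurationError("negative dose times")
        if spec.bov_on:
            n_occ = {len(s.occasions) for s in self.subjects}
            if n_occ == {1}:
                raise ConfigurationError(
                    "BOV requested but the dataset has a single occasion"
                )
        self._warm: dict[int, np.ndarray] = {}
        # eta layout per subject: BSV entries then, per BOV parameter, one
        # entry per occasion present in that subject's data
        self._layout = {
            s.id: list(spec.bsv_on)
            + [f"BOV({p})@{o}" for p in spec.bov_on for o in s.occasions]
            for s in self.subjects
        }

    def _omega_diag(self, params: ParameterVector, s: _Subject) -> np.ndarray:
        out = [params.omega[p] for p in self.spec.bsv_on]
        for p in self.spec.bov_on:
            out.extend([params.omega[f"BOV({p})"]] * len(s.occasions))
        return np.array(out)

    def _f_func(self, params: ParameterVector, s: _Subject):
        spec, refs = self.spec, self.refs
        nb = len(spec.bsv_on)
        occs = list(s.occasions)

        def f(eta: np.ndarray) -> np.ndarray:
            pred = np.empty(len(s.obs_times))
            for io, occ in enumerate(occs):
                emap = {p: eta[i] for i, p in enumerate(spec.bsv_on)}
                for ip, p in enumerate(spec.bov_on):
                    emap[f"BOV({p})"] = eta[nb + ip * len(occs) + io]
                pind = individual_parameters(spec, params, s.covariates, refs, emap)
                mask = s.occ == occ
                pred[mask] = _disposition(
                    pind,
                    spec.n_compartments,
                    spec.route == "oral_first_order",
                    s.dose_times,
                    s.dose_amts,
                    s.obs_times[mask],
                )
            return pred

        return f

    def __call__(self, params: ParameterVector) -> float:
        total = 0.0
        for s in self.subjects:
            odiag = self._omega_diag(params, s)
            # variances fixed to 0 (e.g. during profiling) drop those effects
            keep = odiag > 0
            f_full = self._f_func(params, s)
            if keep.all():
                f_func = f_full
                od = odiag
            else:
                idx = np.where(keep)[0]
                od = odiag[keep]

                def f_func(eta, _idx=idx, _n=len(odiag), _f=f_full):
                    full = np.zeros(_n)
                    full[_idx] = eta
                    return _f(full)

            val, eta_hat = marginal_neg2loglik(
                s.y,
                f_func,
                od,
                lambda pred: residual_variance(self.spec, params, pred),
                method=self.method,
                eta0=self._warm.get(s.id),
                inner_tol=self.inner_tol,
            )
            if self.method == "foce_i" and keep.all():
                self._warm[s.id] = eta_hat
            total += val
        return total


def neg2loglik(
    spec: ModelSpec,
    params: ParameterVector,
    dataset: PKDataset,
    method: str = "foce_i",
) -> float:
    """-2 log marginal likelihood of the dataset (OFV, constant omitted)."""
    params.validate(spec)
    return _LikelihoodProblem(spec, dataset, method)(params)


# ---------------------------------------------------------------------------
# Fitting and diagnostics


def condition_number(correlation_matrix: np.ndarray) -> float:
    """Ratio of the largest to smallest eigenvalue of a correlation matrix."""
    C = np.asarray(correlation_matrix, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    w = np.linalg.eigvalsh(C)
    if w[-1] <= 0 or w[0] <= 0:
        return float("inf")
    return float(w[-1] / w[0])


def correlation_flag(correlation_matrix: np.ndarray, threshold: float = 0.95) -> bool:
    """True iff some off-diagonal |correlation| strictly exceeds the threshold."""
    C = np.asarray(correlation_matrix, float)
    off = C - np.diag(np.diag(C))
    return bool(np.any(np.abs(off) > threshold))


@dataclass
class FitResult:
    """Outcome of one model estimation."""

    estimates: ParameterVector
    ofv: float
    converged: bool
    covariance_ok: bool
    correlation_matrix: np.ndarray | None
    condition_number: float
    rse: dict[str, float]
    param_names: tuple[str, ...] = ()
    n_function_evals: int = 0
    message: str = ""

    def correlation_exceeds(self, threshold: float = 0.95) -> bool:
        if self.correlation_matrix is None:
            return False
        return correlation_flag(self.correlation_matrix, threshold)


def _default_starts(spec: ModelSpec, dataset: PKDataset) -> ParameterVector:
    """Crude data-driven initial estimates (dose scale and terminal slope)."""
    subs = dataset.subjects()
    cmax = np.median([s.y.max() for s in subs if len(s.y)])
    dose = np.median(np.concatenate([s.dose_amts for s in subs if len(s.dose_amts)]))
    v0 = float(np.clip(dose / max(cmax, 1e-9), 1e-2, 1e5))
    slopes = []
    for s in subs:
        if len(s.y) >= 2 and s.y[0] > 0 and s.y[-1] > 0:
            dt = s.obs_times[-1] - s.obs_times[0]
            if dt > 0 and s.y[-1] < s.y[0]:
                slopes.append(math.log(s.y[0] / s.y[-1]) / dt)
    k0 = float(np.clip(np.median(slopes) if slopes else 0.1, 1e-3, 5.0))
    theta: dict[str, float] = {}
    defaults = {
        "CL": k0 * v0,
        "V": v0,
        "Q2": 0.5 * k0 * v0,
        "V2": 2.0 * v0,
        "Q3": 0.25 * k0 * v0,
        "V3": 4.0 * v0,
        "KA": 1.0,
        "ALAG": 0.25,
    }
    for name in spec.structural_params:
        theta[name] = defaults[name]
    for ce in spec.covariate_effects:
        theta[ce.theta_name] = 0.1
    omega = {name: 0.1 for name in spec.omega_names}
    sigma = {}
    if "SIG_ADD" in spec.sigma_names:
        sigma["SIG_ADD"] = float(max((0.1 * cmax) ** 2, 1e-6))
    if "SIG_PROP" in spec.sigma_names:
        sigma["SIG_PROP"] = 0.04
    return ParameterVector(theta, omega, sigma)


class _Transform:
    """Pack/unpack between the optimizer vector and a ParameterVector.

    Positivity-constrained entries (structural thetas, omegas, sigmas) live on
    the log scale; covariate coefficients are unconstrained.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        struct = set(spec.structural_params)
        # omega entries get an OM_ prefix so report keys never collide with theta
        self.names = (
            list(spec.theta_names)
            + [f"OM_{n}" for n in spec.omega_names]
            + list(spec.sigma_names)
        )
        self.is_log = (
            [n in struct for n in spec.theta_names]  # covariate betas stay linear
            + [True] * spec.n_omega
            + [True] * spec.n_sigma
        )

    def pack(self, pv: ParameterVector) -> np.ndarray:
        vals = pv.as_array(self.spec)
        return np.array(
            [math.log(max(v, 1e-12)) if lg else v for v, lg in zip(vals, self.is_log)]
        )

    def unpack(self, x: np.ndarray) -> ParameterVector:
        vals = [math.exp(min(xi, 50.0)) if lg else xi for xi, lg in zip(x, self.is_log)]
        return ParameterVector.from_array(self.spec, vals)


def fit(
    spec: ModelSpec,
    dataset: PKDataset,
    method: str = "foce_i",
    start_values: ParameterVector | None = None,
    rng_seed: int = 0,
    max_restarts: int = 2,
) -> FitResult:
    """Estimate a model by minimizing the approximate -2 log-likelihood.

    Optimization runs on log-transformed positive parameters with L-BFGS-B;
    non-convergence triggers up to ``max_restarts`` jittered restarts.  The
    covariance of the estimates comes from the inverse finite-difference
    Hessian on the natural scale; the estimation correlation matrix, its
    eigenvalue condition number and per-parameter RSE (%) feed the search
    diagnostics.  Optimizer failure never raises: the result carries
    ``converged=False`` and the best OFV found.
    """
    problem = _LikelihoodProblem(spec, dataset, method)
    tf = _Transform(spec)
    pv0 = start_values or _default_starts(spec, dataset)
    pv0.validate(spec)
    rng = np.random.default_rng(rng_seed)
    n_eval = 0
    seen_best: list = [np.inf, None]  # lowest OFV point ever evaluated

    def obj(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            v = problem(tf.unpack(x))
        except (NumericalError, ValueError, OverflowError, np.linalg.LinAlgError):
            return 1e12
        v = v if np.isfinite(v) else 1e12
        if v < seen_best[0]:
            seen_best[0], seen_best[1] = v, x.copy()
        return v

    x0 = tf.pack(pv0)
    converged = False
    message = ""
    for attempt in range(max_restarts + 1):
        xs = x0 if attempt == 0 else x0 + rng.normal(0, 0.3, len(x0))
        res = optimize.minimize(
            obj,
            xs,
            method="L-BFGS-B",
            options={"maxiter": 200, "ftol": 1e-9, "gtol": 1e-5, "eps": 1e-5},
        )
        message = str(res.message)
        if res.success and res.fun < 1e11:
            converged = True
            break

    # the optimizer's final point can sit a hair above the best point it
    # visited; report the best visited point so OFV comparisons are clean
    best_x = seen_best[1] if seen_best[1] is not None else x0
    est = tf.unpack(best_x)
    ofv = float(seen_best[0])

    # covariance step: finite-difference Hessian of the OFV in the optimizer's
    # transformed coordinates (absolute steps are well scaled there), then
    # delta-method transform of the covariance back to the natural scale
    names = tf.names
    x_nat = est.as_array(spec)
    cov_ok = False
    corr = None
    cond = float("inf")
    rse: dict[str, float] = {}
    if converged and np.isfinite(ofv):
        hess_problem = _LikelihoodProblem(spec, dataset, method, inner_tol=1e-13)

        def ofv_t(x: np.ndarray) -> float:
            try:
                v = hess_problem(tf.unpack(x))
            except (NumericalError, ValueError, OverflowError, np.linalg.LinAlgError):
                return 1e12
            return v if np.isfinite(v) else 1e12

        ofv_t(best_x)  # prime the warm starts at the optimum
        H = _ofv_hessian(ofv_t, best_x, h_abs=1e-3)
        Hs = (H + H.T) / 2
        w = np.linalg.eigvalsh(Hs)
        if np.all(w > 1e-10):
            cov_t = 2.0 * np.linalg.inv(Hs)
            # jacobian of natural w.r.t. transformed coords: exp for log-scale
            J = np.diag([v if lg else 1.0 for v, lg in zip(x_nat, tf.is_log)])
            cov = J @ cov_t @ J
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
            denom = np.outer(se, se)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.where(denom > 0, cov / denom, 0.0)
            np.fill_diagonal(corr, 1.0)
            cond = condition_number(corr)
            rse = {
                n: float(100.0 * s / abs(v)) if v != 0 else float("inf")
                for n, s, v in zip(names, se, x_nat)
            }
            cov_ok = True
    return FitResult(
        estimates=est,
        ofv=ofv,
        converged=converged,
        covariance_ok=cov_ok,
        correlation_matrix=corr,
        condition_number=cond,
        rse=rse,
        param_names=tuple(names),
        n_function_evals=n_eval,
        message=message,
    )


def _ofv_hessian(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    rel: float = 1e-4,
    h_abs: float | None = None,
):
    """Central finite-difference Hessian (relative steps, or absolute when
    ``h_abs`` is given — appropriate in log-transformed coordinates)."""
    n = len(x)
    h = np.full(n, h_abs) if h_abs else rel * np.maximum(np.abs(x), 1e-4)
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp, xm = x.copy(), x.copy()
                xp[i] += h[i]
                xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                xpp[i] += h[i]; xpp[j] += h[j]
                xpm[i] += h[i]; xpm[j] -= h[j]
                xmp[i] -= h[i]; xmp[j] += h[j]
                xmm[i] -= h[i]; xmm[j] -= h[j]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (
                    4 * h[i] * h[j]
                )
    return H


# ---------------------------------------------------------------------------
# sklearn-style facade


class CompartmentModel(BaseEstimator):
    """Estimator facade over :func:`fit`/:func:`predict`.

    Follows the scikit-learn estimator protocol (``get_params``/``set_params``
    from :class:`~sklearn.base.BaseEstimator`, fitted attributes with trailing
    underscores) so model evaluation can be scripted with familiar tooling.
    ``fit`` takes a :class:`PKDataset` (or a NONMEM-style DataFrame);
    ``predict`` returns the population prediction (all random effects at zero)
    for each observation row.
    """

    def __init__(
        self,
        spec: ModelSpec = ModelSpec(),
        method: str = "foce_i",
        start_values: ParameterVector | None = None,
        rng_seed: int = 0,
    ):
        self.spec = spec
        self.method = method
        self.start_values = start_values
        self.rng_seed = rng_seed

    @staticmethod
    def _as_dataset(X: "PKDataset | pd.DataFrame") -> PKDataset:
        return X if isinstance(X, PKDataset) else PKDataset(X)

    def fit(self, X: "PKDataset | pd.DataFrame", y: Any = None) -> "CompartmentModel":
        ds = self._as_dataset(X)
        self.result_ = fit(
            self.spec, ds, self.method, self.start_values, self.rng_seed
        )
        self.params_ = self.result_.estimates
        self.ofv_ = self.result_.ofv
        return self

    def predict(self, X: "PKDataset | pd.DataFrame") -> np.ndarray:
        if not hasattr(self, "result_"):
            raise RuntimeError("call fit before predict")
        ds = self._as_dataset(X)
        refs = ds.covariate_references()
        out = []
        for s in ds.subjects():
            out.append(
                predict(
                    self.spec,
                    self.params_,
                    s.covariates,
                    list(zip(s.dose_times, s.dose_amts)),
                    s.obs_times,
                    covariate_refs=refs,
                )
            )
        return np.concatenate(out) if out else np.zeros(0)
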