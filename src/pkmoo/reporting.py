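"""Subjective model comparison: prediction-corrected VPC and front reports.

A pcVPC normalizes observations and simulations by the bin-median population
prediction (pcY = Y * median(PRED in bin) / PRED), removing dose- and
covariate-driven trends so that sparse heterogeneous designs can be binned
together.  Observed 5th/50th/95th percentiles per time bin are compared with
the across-replicate 90% confidence interval of the same percentiles from
full-dataset simulations under the fitted model.

Percentiles use linear interpolation throughout (numpy's default), so tables
are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .nsga2 import ParetoArchive
from .pk_engine import (
    ModelSpec,
    ParameterVector,
    PKDataset,
    predict,
    residual_variance,
)

logger = logging.getLogger(__name__)

__all__ = ["VPCTable", "pcvpc", "pareto_report", "spec_summary"]

_PCTS = (5.0, 50.0, 95.0)


@dataclass
class VPCTable:
    """Binned pcVPC summaries.

    ``table`` has one row per time bin: the bin edges and midpoint, the
    observation count, observed prediction-corrected 5th/50th/95th
    percentiles, and for each percentile the median and 90% interval
    (5th-95th across replicates) of the simulated value.
    """

    table: pd.DataFrame
    n_replicates: int
    n_excluded: int

    def coverage(self, percentile: int = 50) -> float:
        """Fraction of bins whose observed percentile falls inside the
        simulated 90% interval for that percentile."""
        t = self.table
        lo, hi = t[f"sim_p{percentile}_lo"], t[f"sim_p{percentile}_hi"]
        obs = t[f"obs_p{percentile}"]
        return float(((obs >= lo) & (obs <= hi)).mean())


def _quantile_bins(times: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin index per observation; covers every observation once."""
    edges = np.quantile(times, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)  # ties on sparse designs collapse bins
    idx = np.searchsorted(edges, times, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def _simulate_once(
    spec: ModelSpec,
    params: ParameterVector,
    subjects,
    refs: Mapping[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One replicate of the whole dataset's DV vector under the model."""
    out = []
    for s in subjects:
        eta = {p: rng.normal(0.0, np.sqrt(params.omega[p])) for p in spec.bsv_on}
        bov = {
            p: rng.normal(0.0, np.sqrt(params.omega[f"BOV({p})"]), len(s.occasions))
            for p in spec.bov_on
        }
        pred = np.empty(len(s.obs_times))
        for io, occ in enumerate(s.occasions):
            emap = dict(eta)
            for p in spec.bov_on:
                emap[f"BOV({p})"] = float(bov[p][io])
            mask = s.occ == occ
            pred[mask] = predict(
                spec, params, s.covariates,
                list(zip(s.dose_times, s.dose_amts)),
                s.obs_times[mask], covariate_refs=refs, eta=emap,
            )
        eps = rng.standard_normal(len(pred))
        out.append(pred + eps * np.sqrt(residual_variance(spec, params, pred)))
    return np.concatenate(out)


def pcvpc(
    dataset: PKDataset,
    spec: ModelSpec,
    fitted_params: ParameterVector,
    n_replicates: int = 1000,
    n_bins: int = 8,
    rng_seed: int = 0,
) -> VPCTable:
    """Prediction-corrected visual predictive check of one fitted model.

    Rows with a non-positive population prediction cannot be
    prediction-corrected and are excluded (their count is logged and
    reported).  Bins are quantile-based on observation time, so each holds
    roughly the same number of observations.
    """
    fitted_params.validate(spec)
    subjects = dataset.subjects()
    if not any(len(s.y) for s in subjects):
        raise ConfigurationError("dataset has no observations")
    refs = dataset.covariate_references()
    rng = np.random.default_rng(rng_seed)

    times = np.concatenate([s.obs_times for s in subjects])
    y = np.concatenate([s.y for s in subjects])
    pred = np.concatenate(
        [
            predict(
                spec, fitted_params, s.covariates,
                list(zip(s.dose_times, s.dose_amts)),
                s.obs_times, covariate_refs=refs,
            )
            for s in subjects
        ]
    )
    keep = pred > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("pcVPC: excluded %d rows with PRED <= 0", n_excluded)
    if not keep.any():
        raise ConfigurationError("no rows with positive population prediction")

    bins = np.full(len(times), -1)
    bins[keep] = _quantile_bins(times[keep], n_bins)
    used_bins = np.unique(bins[keep])
    med_pred = {b: float(np.median(pred[bins == b])) for b in used_bins}
    corr = np.ones(len(times))
    for b in used_bins:
        m = bins == b
        corr[m] = med_pred[b] / pred[m]

    def bin_percentiles(values: np.ndarray) -> np.ndarray:
        return np.array(
            [np.percentile(values[(bins == b) & keep] * corr[(bins == b) & keep], _PCTS)
             for b in used_bins]
        )

    obs_p = bin_percentiles(y)

    sim_p = np.empty((n_replicates, len(used_bins), len(_PCTS)))
    for r in range(n_replicates):
        sim_p[r] = bin_percentiles(_simulate_once(spec, fitted_params, subjects, refs, rng))

    rows = []
    for bi, b in enumerate(used_bins):
        m = (bins == b) & keep
        row: dict[str, Any] = {
            "bin": int(b),
            "t_lo": float(times[m].min()),
            "t_hi": float(times[m].max()),
            "t_mid": float(np.median(times[m])),
            "n_obs": int(m.sum()),
        }
        for pi, pct in enumerate((5, 50, 95)):
            row[f"obs_p{pct}"] = float(obs_p[bi, pi])
            row[f"sim_p{pct}_med"] = float(np.percentile(sim_p[:, bi, pi], 50.0))
            row[f"sim_p{pct}_lo"] = float(np.percentile(sim_p[:, bi, pi], 5.0))
            row[f"sim_p{pct}_hi"] = float(np.percentile(sim_p[:, bi, pi], 95.0))
        rows.append(row)
    return VPCTable(
        table=pd.DataFrame(rows), n_replicates=n_replicates, n_excluded=n_excluded
    )


# ---------------------------------------------------------------------------
# Pareto-front reporting


def spec_summary(spec: ModelSpec | None) -> str:
    if spec is None:
        return "<infeasible>"
    parts = [f"{spec.n_compartments}cpt", spec.route]
    if spec.lag:
        parts.append("lag")
    for c in spec.covariate_effects:
        parts.append(f"{c.form}:{c.covariate}->{c.parameter}")
    if spec.bsv_on:
        parts.append("BSV(" + ",".join(spec.bsv_on) + ")")
    if spec.bov_on:
        parts.append("BOV(" + ",".join(spec.bov_on) + ")")
    parts.append(f"RUV:{spec.ruv}")
    return " ".join(parts)


def pareto_report(
    archive: ParetoArchive, flags_filter: bool = False
) -> pd.DataFrame:
    """Tabulate a Pareto archive: ascending NEP, with OFV, model summary,
    the four diagnostic flags and downhill provenance.

    With ``flags_filter`` only models passing every diagnostic are listed
    (the "passed basic diagnostics" view).  The (NEP, OFV) columns double as
    the front-staircase plot data.
    """
    if len(archive) == 0:
        raise ValueError("archive is empty")
    rows = []
    for rec in archive.sorted():
        if flags_filter and not all(rec.flags.values()):
            continue
        prov = archive.provenance.get(rec.genome, {})
        rows.append(
            {
                "bits": rec.bits,
                "nep": rec.nep,
                "ofv": rec.ofv,
                "model": spec_summary(rec.spec),
                **{k: bool(v) for k, v in rec.flags.items()},
                "generation": prov.get("generation"),
                "via_downhill": bool(prov.get("downhill", False)),
            }
        )
    return pd.DataFrame(rows)


def merge_archives(*archives: ParetoArchive) -> ParetoArchive:
    """Non-dominated union of several run archives; the merged front is never
    dominated by any input front."""
    out = ParetoArchive()
    for a in archives:
        for rec in a.sorted():
            prov = a.provenance.get(rec.genome, {})
            out.add(rec, prov.get("generation"), bool(prov.get("downhill", False)))
    return out
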