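"""Aggregated half-lives derived from fitted kinetic parameters.

The cascade rates are *transitional*: each describes one step of the mRNA
life cycle.  For comparison with classic whole-cell or transcription-
inhibition experiments, aggregated (residence) half-lives are derived by
generating model pulse-chase curves (share of old mRNA = 1 - share of new
mRNA), mixing compartments by their abundance-scaled steady-state amounts
for the whole-cell signal, and fitting a single exponential decay.
Transcription-shutoff expression series are handled the same way after
library normalization on long-lived genes and scaling to the t = 0 point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .model import (
    FOUR_STEP,
    KineticParams,
    exit_rates,
    half_life,
    hypoexponential_share,
    steady_state_amounts,
)

__all__ = [
    "DecayFitResult",
    "ExponentialDecayFitter",
    "model_derived_pulse_chase",
    "fit_exponential_decay",
    "flavopiridol_halflives",
    "summarize_cohort",
]

_RATE_BOUNDS = (1e-5, 10.0)  # 1/min; half-lives ~ 4 s .. 48 d


@dataclass
class DecayFitResult:
    half_life_min: float
    rate: float
    fit_residual: float
    compartment: str = "whole"
    flagged: bool = False


def model_derived_pulse_chase(
    params: KineticParams,
    factors,
    times: Sequence[float],
) -> pd.DataFrame:
    """Share-old curves per compartment and their whole-cell mixture.

    ``share_old_c(t) = 1 - share_new_c(t)`` from the closed-form cascade;
    the whole-cell curve mixes the compartments with weights proportional
    to the abundance-scaled steady-state amounts (nuclear pools pre- and
    mature mRNA).  ``factors`` is accepted for interface symmetry with
    expression-weighted callers; per-gene steady-state amounts already
    carry the compartment proportions implied by the fitted rates.
    """
    times = np.asarray(times, dtype=float)
    rates = exit_rates(params)
    shares = hypoexponential_share(rates, times)
    amounts = steady_state_amounts(params)
    has_pre = params.k1 is not None
    idx = 0
    comp_new = {}
    weights = {}
    if has_pre:
        pre = shares[idx]
        idx += 1
    nucmat = shares[idx]
    cyto = shares[idx + 1]
    if has_pre:
        w_pre = amounts["x1_pre"]
        w_mat = amounts["x2_nucmat"]
        comp_new["nuc"] = (w_pre * pre + w_mat * nucmat) / (w_pre + w_mat)
        weights["nuc"] = w_pre + w_mat
    else:
        comp_new["nuc"] = nucmat
        weights["nuc"] = amounts["x2_nucmat"]
    comp_new["cyto"] = cyto
    weights["cyto"] = amounts["x3_cyto"]
    if params.variant == FOUR_STEP:
        comp_new["mem"] = shares[idx + 2]
        weights["mem"] = amounts["x4_mem"]
    wtot = sum(weights.values())
    whole = sum(weights[c] * comp_new[c] for c in comp_new) / wtot
    records = []
    for comp, new in list(comp_new.items()) + [("whole", whole)]:
        for t, s in zip(times, new):
            records.append(
                {"compartment": comp, "time_min": t, "share_old": 1.0 - s}
            )
    return pd.DataFrame.from_records(records)


class ExponentialDecayFitter(BaseEstimator):
    """Single-rate exponential fit ``y = exp(-rate * t)`` (or its complement).

    ``mode="share_old"`` fits a decaying exponential, ``mode="share_new"``
    fits ``1 - exp(-rate t)``.  The rate is optimized in log space from a
    log-linear initial guess; non-monotone or badly fitting input is
    returned with its residual and a flag instead of raising.
    """

    def __init__(self, mode="share_old", rate_bounds=_RATE_BOUNDS):
        self.mode = mode
        self.rate_bounds = rate_bounds

    def fit(self, t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(t) < 3:
            raise ValueError("need at least 3 points for a decay fit")
        if np.any((y < -1e-9) | (y > 1 + 1e-9)):
            raise ValueError("decay fit expects shares in [0, 1]")
        decay = y if self.mode == "share_old" else 1.0 - y
        lo, hi = self.rate_bounds

        # log-linear initial guess on the strictly positive part
        pos = decay > 1e-12
        if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
            slope = -np.polyfit(t[pos], np.log(decay[pos]), 1)[0]
            lam0 = float(np.clip(slope, lo, hi))
        else:
            lam0 = float(np.sqrt(lo * hi))

        def resid(logl):
            return np.exp(-np.exp(logl[0]) * t) - decay

        res = least_squares(
            resid,
            np.array([np.log(lam0)]),
            bounds=(np.log(lo), np.log(hi)),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-12,
        )
        rate = float(np.exp(res.x[0]))
        residual = float(np.sqrt(2.0 * res.cost / len(t)))
        self.rate_ = rate
        self.half_life_ = half_life(rate)
        self.fit_residual_ = residual
        self.flagged_ = bool(residual > 0.2)
        return self

    def result_(self, compartment="whole") -> DecayFitResult:
        return DecayFitResult(
            half_life_min=self.half_life_,
            rate=self.rate_,
            fit_residual=self.fit_residual_,
            compartment=compartment,
            flagged=self.flagged_,
        )


def fit_exponential_decay(t, y, mode="share_old", compartment="whole") -> DecayFitResult:
    """Functional wrapper around :class:`ExponentialDecayFitter`."""
    return ExponentialDecayFitter(mode=mode).fit(t, y).result_(compartment)


def flavopiridol_halflives(
    expr_timeseries: pd.DataFrame,
    stable_gene_ids: Sequence[str],
    compartments: Sequence[str] = ("nuc", "cyto", "mem", "whole"),
) -> pd.DataFrame:
    """Aggregated subcellular half-lives from a transcription-shutoff series.

    ``expr_timeseries`` has columns gene_id, time_min and one expression
    column per compartment.  Library sizes are normalized per sample by
    the median ratio of long-lived (stable) genes to their cross-sample
    mean; each gene's series is then scaled to its t = 0 value and fit
    with a single exponential per compartment.  Genes without a t = 0
    sample are skipped.
    """
    if len(stable_gene_ids) == 0:
        raise ValueError("need at least one stable gene for normalization")
    df = expr_timeseries.copy()
    stable = df[df.gene_id.isin(stable_gene_ids)]
    records = []
    for comp in compartments:
        if comp not in df.columns:
            continue
        ref = stable.groupby("gene_id")[comp].mean()
        # per-sample (time) scale factor from stable genes
        scale = {}
        for t, sub in stable.groupby("time_min"):
            ratios = sub.set_index("gene_id")[comp] / ref
            scale[t] = float(np.median(ratios.dropna()))
        for gid, sub in df.groupby("gene_id"):
            sub = sub.sort_values("time_min")
            t = sub["time_min"].to_numpy(dtype=float)
            if 0.0 not in t:
                continue
            y = sub[comp].to_numpy(dtype=float) / np.array(
                [scale.get(ti, 1.0) for ti in t]
            )
            y0 = y[t == 0.0][0]
            if y0 <= 0:
                continue
            y = np.clip(y / y0, 0.0, 1.0)
            fit = fit_exponential_decay(t, y, mode="share_old", compartment=comp)
            records.append(
                {
                    "gene_id": gid,
                    "compartment": comp,
                    "half_life_min": fit.half_life_min,
                    "rate": fit.rate,
                    "fit_residual": fit.fit_residual,
                    "flagged": fit.flagged,
                }
            )
    return pd.DataFrame.from_records(records)


def summarize_cohort(results: pd.DataFrame) -> pd.DataFrame:
    """Cohort medians and 10th/90th percentiles of the four half-lives.

    Operates on QC-passing genes; also counts genes per localization class
    and per chosen decay model.  An empty input yields an empty table.
    """
    if len(results) == 0:
        return pd.DataFrame(
            columns=["quantity", "median", "p10", "p90", "n"]
        )
    ok = results[results.get("qc_pass", True) == True]  # noqa: E712
    rows = []
    for name, col in [
        ("pre_mrna_processing_halflife_min", "halflife_processing"),
        ("nuclear_retention_halflife_min", "halflife_nuclear"),
        ("cytosolic_halflife_min", "halflife_cytosolic"),
        ("membrane_halflife_min", "halflife_membrane"),
    ]:
        if col not in ok.columns:
            continue
        vals = ok[col].dropna()
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        rows.append(
            {
                "quantity": name,
                "median": float(vals.median()),
                "p10": float(vals.quantile(0.10)),
                "p90": float(vals.quantile(0.90)),
                "n": int(len(vals)),
            }
        )
    if "localization" in ok.columns:
        for loc, n in ok["localization"].value_counts().items():
            rows.append({"quantity": f"n_{loc}", "median": float("nan"),
                         "p10": float("nan"), "p90": float("nan"), "n": int(n)})
    if "includes_nuclear_decay" in ok.columns:
        n_decay = int(ok["includes_nuclear_decay"].fillna(False).sum())
        rows.append({"quantity": "n_nuclear_decay", "median": float("nan"),
                     "p10": float("nan"), "p90": float("nan"), "n": n_decay})
    return pd.DataFrame.from_records(rows)
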