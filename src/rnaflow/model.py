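"""Compartmental kinetics of the mRNA life cycle.

The life of an mRNA molecule is modeled as a linear first-order cascade
through subcellular compartments: nuclear pre-mRNA (processed with rate
``k1``), nuclear mature mRNA (leaving the nucleus by export ``k2`` and,
optionally, nuclear decay ``gamma2``), cytosolic mRNA (degraded with
``gamma3`` in the 3-step model, or transported to the ER/membrane with
``k3`` in the 4-step model) and membrane-bound mRNA (degraded with
``gamma4``).  In absolute amounts::

    dx1/dt = p        - k1*x1
    dx2/dt = k1*x1    - (k2 + gamma2)*x2
    dx3/dt = k2*x2    - r3*x3          (r3 = gamma3 or k3)
    dx4/dt = k3*x3    - gamma4*x4

Dividing each compartment by its steady state removes the production rate
``p`` and turns the system into a pure relaxation cascade for the share of
new (metabolically labeled) mRNA ``x~_i``::

    dx~_i/dt = r_i * (x~_{i-1} - x~_i),   x~_0 = 1,  x~_i(0) = 0

with exit rates ``r = (k1, k2+gamma2, r3, gamma4)``.  The solution of stage
``i`` is the CDF of a hypoexponential distribution (a sum of independent
exponential waiting times with rates ``r_1..r_i``), which this module
evaluates in closed form.

Sequences far from the 3' end of a transcript are labeled late: a region at
distance ``d`` (kb) from the 3' end of a gene transcribed with elongation
rate ``v`` (kb/min) only starts accumulating label after ``d/v`` minutes,
plus a global experimental delay ``delta`` (5 min by default).  Predicted
curves are therefore evaluated at the delayed time
``t~ = max(0, t - d/v - delta)``.

Units are minutes and kilobases throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "THREE_STEP",
    "FOUR_STEP",
    "RATE_MIN",
    "RATE_MAX",
    "GAMMA2_MIN",
    "V_MIN",
    "V_MAX",
    "DEFAULT_DELTA",
    "INTRON_DISTANCE_FACTOR",
    "GeneModel",
    "KineticParams",
    "CompartmentShares",
    "exit_rates",
    "share_new_analytic",
    "hypoexponential_share",
    "delayed_time",
    "predict_gene_curves",
    "steady_state_amounts",
    "steady_state_ratios",
    "half_life",
]

THREE_STEP = "three_step"
FOUR_STEP = "four_step"

#: fitting bounds for all kinetic rates (1/min)
RATE_MIN, RATE_MAX = 1e-3, 2.0
#: lower bound of the nuclear decay rate when it is allowed to vary
GAMMA2_MIN = 1e-6
#: elongation-rate bounds (kb/min)
V_MIN, V_MAX = 0.1, 10.0
#: global delay until any labeling is observed (min)
DEFAULT_DELTA = 5.0
#: pseudo-distance of the pooled intronic region: this fraction of the gene
#: length approximates the expression-weighted mean relative exon distance
INTRON_DISTANCE_FACTOR = 0.1

# relative gap below which two exit rates are treated as degenerate and the
# partial-fraction form is replaced by the matrix-exponential evaluation;
# at a 1e-4 gap the cancellation error of the partial fractions is ~1e-12
_DEGENERATE_RTOL = 1e-4


@dataclass(frozen=True)
class GeneModel:
    """Static structure of a gene as the kinetic model sees it.

    ``exon_distances_kb`` holds the mean distance of each quantified exon to
    the 3' end.  Intron-containing genes additionally contribute a pooled
    intronic region at pseudo-distance ``0.1 * gene_length_kb``.
    """

    gene_id: str
    gene_length_kb: float
    exon_distances_kb: tuple[float, ...]
    has_introns: bool
    localization: str = "cytosol"  # cytosol | undefined | membrane

    def __post_init__(self):
        if self.gene_length_kb <= 0:
            raise ValueError(f"{self.gene_id}: gene length must be positive")
        if len(self.exon_distances_kb) == 0:
            raise ValueError(f"{self.gene_id}: need at least one exon")
        if any(d < 0 or d > self.gene_length_kb for d in self.exon_distances_kb):
            raise ValueError(
                f"{self.gene_id}: exon distances must lie in [0, gene length]"
            )
        if self.localization not in ("cytosol", "undefined", "membrane"):
            raise ValueError(f"unknown localization {self.localization!r}")

    @property
    def intron_distance_kb(self) -> float:
        return INTRON_DISTANCE_FACTOR * self.gene_length_kb

    @property
    def reduced_model(self) -> bool:
        """True when pre-mRNA/elongation stages cannot be informed.

        Intron-less genes have no intronic signal, and genes with a single
        usable exon cannot constrain the elongation rate; both are fit with
        the cascade shortened by one stage, no ``k1``/``v``, and
        ``t~ = t - delta``.
        """
        return (not self.has_introns) or len(self.exon_distances_kb) == 1


@dataclass
class KineticParams:
    """Rate vector of one gene's kinetic model.

    Exactly one of ``gamma3`` (3-step) or ``k3``/``gamma4`` (4-step) is set,
    depending on ``variant``.  ``v`` and ``k1`` are ``None`` for genes fit
    with the reduced (intron-less / single-exon) model.  The production rate
    drops out of the rescaled system and is not represented.
    """

    k2: float
    k1: float | None = None
    gamma2: float = 0.0
    gamma3: float | None = None
    k3: float | None = None
    gamma4: float | None = None
    v: float | None = None
    delta: float = DEFAULT_DELTA
    variant: str = THREE_STEP

    def __post_init__(self):
        if self.variant not in (THREE_STEP, FOUR_STEP):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == THREE_STEP:
            if self.gamma3 is None:
                raise ValueError("three_step model requires gamma3")
            if self.k3 is not None or self.gamma4 is not None:
                raise ValueError("three_step model must not set k3/gamma4")
        else:
            if self.k3 is None or self.gamma4 is None:
                raise ValueError("four_step model requires k3 and gamma4")
            if self.gamma3 is not None:
                raise ValueError("four_step model must not set gamma3")
        if self.gamma2 < 0:
            raise ValueError("gamma2 must be >= 0")

    @property
    def r2(self) -> float:
        """Total nuclear exit rate (export plus decay)."""
        return self.k2 + self.gamma2

    @property
    def r3(self) -> float:
        return self.gamma3 if self.variant == THREE_STEP else self.k3

    def with_gamma2(self, gamma2: float) -> "KineticParams":
        return replace(self, gamma2=gamma2)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "k1": self.k1,
            "k2": self.k2,
            "gamma2": self.gamma2,
            "gamma3": self.gamma3,
            "k3": self.k3,
            "gamma4": self.gamma4,
            "v": self.v,
            "delta": self.delta,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParams":
        """Rebuild from a flat record (e.g. a fits-table row); NaN -> None."""

        def opt(key):
            val = d.get(key)
            if val is None:
                return None
            val = float(val)
            return None if np.isnan(val) else val

        return cls(
            k2=float(d["k2"]),
            k1=opt("k1"),
            gamma2=opt("gamma2") or 0.0,
            gamma3=opt("gamma3"),
            k3=opt("k3"),
            gamma4=opt("gamma4"),
            v=opt("v"),
            delta=float(d.get("delta", DEFAULT_DELTA) or DEFAULT_DELTA),
            variant=str(d.get("variant", THREE_STEP)),
        )


@dataclass(frozen=True)
class CompartmentShares:
    """Share of new mRNA per compartment at one time point."""

    x1_pre: float | None
    x2_nucmat: float
    x3_cyto: float
    x4_mem: float | None


def exit_rates(params: KineticParams, include_stage1: bool = True) -> np.ndarray:
    """Ordered exit rates of the relaxation cascade.

    ``(k1, k2+gamma2, gamma3)`` for the 3-step model and
    ``(k1, k2+gamma2, k3, gamma4)`` for the 4-step model; the first entry is
    dropped for the reduced model (``include_stage1=False`` or ``k1`` unset).
    """
    rates = [params.r2, params.r3]
    if params.variant == FOUR_STEP:
        rates.append(params.gamma4)
    if include_stage1 and params.k1 is not None:
        rates.insert(0, params.k1)
    r = np.asarray(rates, dtype=float)
    if np.any(r <= 0):
        raise ValueError("all exit rates must be positive")
    return r


def _partial_fraction_coeffs(rates: np.ndarray) -> np.ndarray:
    """Coefficient matrix C with share_i(t) = 1 - sum_j C[i, j] exp(-r_j t).

    C[i, j] = prod_{m <= i, m != j} r_m / (r_m - r_j); rows are cumulative
    stages.  Only valid for pairwise-distinct rates.
    """
    n = len(rates)
    C = np.zeros((n, n))
    for i in range(n):
        r = rates[: i + 1]
        for j in range(i + 1):
            others = np.delete(r, j)
            C[i, j] = np.prod(others / (others - r[j]))
    return C


def _is_degenerate(rates: np.ndarray) -> bool:
    for a, b in itertools.combinations(rates, 2):
        if abs(a - b) / max(a, b) < _DEGENERATE_RTOL:
            return True
    return False


def _shares_expm(rates: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact shares via the matrix exponential of the cascade generator.

    The survival vector y = 1 - x~ obeys dy/dt = A y with lower-bidiagonal
    A (A[i,i] = -r_i, A[i,i-1] = r_i) and y(0) = 1; this handles repeated
    rates without special casing.
    """
    n = len(rates)
    A = -np.diag(rates)
    for i in range(1, n):
        A[i, i - 1] = rates[i]
    ones = np.ones(n)
    out = np.empty((n, t.size))
    for idx, ti in enumerate(np.ravel(t)):
        out[:, idx] = 1.0 - expm(A * ti) @ ones
    return out


def hypoexponential_share(rates, t) -> np.ndarray:
    """Share of new mRNA for every cascade stage, shape ``(n_stages, n_t)``.

    Stage ``i`` is the hypoexponential CDF with rates ``r_1..r_i``: the
    probability that a molecule produced since labeling start has reached
    (passed through) stage ``i``.  Values are clipped to ``[0, 1]`` to guard
    against roundoff at large ``t``.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be nonnegative; delays are applied upstream")
    if np.any(rates <= 0):
        raise ValueError("rates must be positive")
    if _is_degenerate(rates):
        shares = _shares_expm(rates, t)
    else:
        C = _partial_fraction_coeffs(rates)
        E = np.exp(-np.outer(rates, t))  # (n, n_t)
        shares = 1.0 - C @ E
    return np.clip(shares, 0.0, 1.0)


def share_new_analytic(rates: Sequence[float], t: float) -> CompartmentShares:
    """Closed-form compartment shares at a single (already delayed) time."""
    rates = np.asarray(rates, dtype=float)
    s = hypoexponential_share(rates, t)[:, 0]
    if len(rates) == 4:
        return CompartmentShares(s[0], s[1], s[2], s[3])
    if len(rates) == 3:
        return CompartmentShares(s[0], s[1], s[2], None)
    if len(rates) == 2:
        return CompartmentShares(None, s[0], s[1], None)
    raise ValueError("expected 2, 3 or 4 cascade stages")


def delayed_time(t, d_kb=0.0, v=None, delta=DEFAULT_DELTA):
    """Elongation-delayed time ``max(0, t - d/v - delta)`` (vectorized)."""
    t = np.asarray(t, dtype=float)
    if d_kb is None or np.all(np.asarray(d_kb) == 0):
        shift = delta
    else:
        if v is None or v <= 0:
            raise ValueError("positive elongation rate v required when d > 0")
        shift = np.asarray(d_kb, dtype=float) / v + delta
    return np.maximum(0.0, t - shift)


# stage index of each observable per model layout --------------------------

def _stage_map(variant: str, reduced: bool) -> dict[tuple[str, str], int]:
    """(region kind, compartment) -> 0-based cascade stage index."""
    if reduced:
        m = {("exon", "nuc"): 0, ("exon", "cyto"): 1}
        if variant == FOUR_STEP:
            m[("exon", "mem")] = 2
    else:
        m = {("intron", "nuc"): 0, ("exon", "nuc"): 1, ("exon", "cyto"): 2}
        if variant == FOUR_STEP:
            m[("exon", "mem")] = 3
    return m


def predict_gene_curves(
    gene: GeneModel,
    params: KineticParams,
    times: Sequence[float],
) -> pd.DataFrame:
    """Predicted share-new curves for every region x compartment of a gene.

    Intron-containing, multi-exon genes: the pooled intronic region follows
    stage 1 at pseudo-distance ``0.1 * L``; each exon follows stages 2..4 at
    its own elongation delay.  Reduced-model genes use the shortened cascade
    with ``t~ = t - delta`` for all regions.
    """
    times = np.asarray(times, dtype=float)
    reduced = gene.reduced_model
    if reduced:
        rates = exit_rates(params, include_stage1=False)
    else:
        if params.k1 is None or params.v is None:
            raise ValueError(
                f"{gene.gene_id}: full model requires k1 and v"
            )
        rates = exit_rates(params)
    smap = _stage_map(params.variant, reduced)

    records = []
    regions: list[tuple[str, str, float]] = []
    if not reduced:
        regions.append(("intronic", "intron", gene.intron_distance_kb))
    for i, d in enumerate(gene.exon_distances_kb):
        regions.append((f"exon_{i}", "exon", float(d)))

    for region_id, kind, d in regions:
        if reduced:
            tt = delayed_time(times, 0.0, None, params.delta)
        else:
            tt = delayed_time(times, d, params.v, params.delta)
        for (k, comp), stage in smap.items():
            if k != kind:
                continue
            shares = hypoexponential_share(rates[: stage + 1], tt)[stage]
            for ti, si in zip(times, shares):
                records.append(
                    {
                        "region": region_id,
                        "compartment": comp,
                        "d_kb": d,
                        "time_min": ti,
                        "share_new": si,
                    }
                )
    return pd.DataFrame.from_records(records)


def steady_state_amounts(params: KineticParams) -> dict[str, float]:
    """Steady-state amounts of each species for unit production rate.

    From the absolute system: ``x1 = 1/k1``, ``x2 = 1/(k2+gamma2)``,
    ``x3 = k2/((k2+gamma2) r3)`` and ``x4 = k2/((k2+gamma2) gamma4)``.
    The nuclear poly(A) pool is ``x1 + x2``.
    """
    r2 = params.r2
    amounts = {"x2_nucmat": 1.0 / r2}
    if params.k1 is not None:
        amounts["x1_pre"] = 1.0 / params.k1
    export_frac = params.k2 / r2
    amounts["x3_cyto"] = export_frac / params.r3
    if params.variant == FOUR_STEP:
        amounts["x4_mem"] = export_frac / params.gamma4
    return amounts


def steady_state_ratios(params: KineticParams) -> dict[str, float]:
    """Expression ratios between compartments implied by the steady state.

    ``mem_over_cyto`` reduces to ``k3/gamma4``; ``nucmat_over_cyto`` is
    ``r3/k2``; ``nuc_total_over_cyto`` additionally counts the pre-mRNA
    pool.  All ratios are independent of the production rate.
    """
    a = steady_state_amounts(params)
    cyto = a["x3_cyto"]
    out = {"nucmat_over_cyto": a["x2_nucmat"] / cyto}
    nuc_total = a["x2_nucmat"] + a.get("x1_pre", 0.0)
    out["nuc_total_over_cyto"] = nuc_total / cyto
    if params.variant == FOUR_STEP:
        out["mem_over_cyto"] = a["x4_mem"] / cyto
    return out


def half_life(rate: float) -> float:
    """Half-life ``ln 2 / rate`` in minutes; NaN for nonpositive rates."""
    if rate is None or not np.all(np.asarray(rate) > 0):
        return float("nan")
    return float(np.log(2) / rate) if np.isscalar(rate) else np.log(2) / np.asarray(rate)
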