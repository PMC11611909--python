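"""Per-gene kinetic parameter estimation.

Each gene's share-new time courses across compartments and exons are fit
simultaneously with the closed-form cascade solutions.  The procedure
mirrors a robust global-search protocol for small nonlinear problems:

* data points are weighted by the inverse of a *mixed* standard error
  (half the point's own replicate SE, half the time-averaged SE of its
  region x compartment series) with a floor of 0.06;
* the parameter space is constrained by measured steady-state expression
  ratios: the abundance-scaled membrane/cytosol and nuclear/cytosol TPM
  ratios, plus/minus five standard errors, bound the corresponding
  parameter ratios.  Constraints are imposed by reparameterization (the
  ratio is a bounded free variable, the dependent rate is derived);
* optimization runs in log10-parameter space from 200 random starts with
  a damped least-squares local optimizer; out of the ten lowest-chi2
  solutions the one farthest from the parameter boundaries (max-min
  log-distance) is selected;
* parameter standard errors come from the inverse Hessian (Gauss-Newton
  approximation) at the optimum;
* three quality-control filters flag bad fits: reduced chi2 > 4, relative
  standard deviation of any parameter across the ten-best pool > 0.05, or
  rates pinned at the upper bound (nuclear/cytosolic for cytosol-localized
  genes, nuclear/membrane for 4-step genes).  An elongation rate at its
  boundary is tracked as a separate flag;
* nuclear decay is a model-selection question: a gene is assigned the
  extended model (free ``gamma2``) only when its BIC improves on the null
  (``gamma2 = 0``) by more than 10 *and* the decay rate exceeds its own
  standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .abundance import AbundanceFactors, absolute_ratio
from .model import (
    FOUR_STEP,
    GAMMA2_MIN,
    RATE_MAX,
    RATE_MIN,
    THREE_STEP,
    V_MAX,
    V_MIN,
    GeneModel,
    KineticParams,
    half_life,
    hypoexponential_share,
)
from .synthetic import gene_seed

__all__ = [
    "FitConfig",
    "FitResult",
    "KineticModelFitter",
    "classify_localization",
    "compute_weights",
    "build_ratio_constraints",
    "multistart_fit",
    "quality_control",
    "compare_nuclear_decay_models",
    "compute_bic",
    "fit_cohort",
]

_BOUNDARY_RTOL = 1e-6


@dataclass
class FitConfig:
    """Tunable knobs of the per-gene fitting protocol."""

    n_starts: int = 200
    n_best_pool: int = 10
    rate_bounds: tuple[float, float] = (RATE_MIN, RATE_MAX)
    gamma2_min: float = GAMMA2_MIN
    v_bounds: tuple[float, float] = (V_MIN, V_MAX)
    se_floor: float = 0.06
    ratio_constraint_width: float = 5.0
    seed: int = 0
    delta: float = 5.0
    nuclear_constraint_mode: str = "total_nuclear"  # or "mature_only"
    #: iteration cap of the cheap (vectorized) screening stage; the ten
    #: best solutions are re-polished to tight tolerances afterwards
    n_screen_iterations: int = 25
    max_nfev_polish: int = 2000

    def __post_init__(self):
        if self.n_best_pool > self.n_starts:
            raise ValueError("n_best_pool must not exceed n_starts")
        lo, hi = self.rate_bounds
        if not (0 < lo < hi):
            raise ValueError("rate bounds must be positive and ordered")
        if self.nuclear_constraint_mode not in ("total_nuclear", "mature_only"):
            raise ValueError("unknown nuclear_constraint_mode")


@dataclass
class FitResult:
    gene_id: str
    params: KineticParams
    param_se: dict
    chi2: float
    reduced_chi2: float
    n_points: int
    n_params: int
    bic: float
    variant: str
    includes_nuclear_decay: bool
    localization: str
    qc: dict = field(default_factory=dict)
    boundary_score: float = float("nan")
    pool_params: list = field(default_factory=list)
    pool_chi2: list = field(default_factory=list)
    success: bool = True
    message: str = ""

    @property
    def qc_pass(self) -> bool:
        return self.success and not (
            self.qc.get("chi2_fail", False)
            or self.qc.get("instability_fail", False)
            or self.qc.get("boundary_fail", False)
        )


def classify_localization(tpm_mem: float, tpm_cyto: float) -> str:
    """Localization class from the membrane/cytosol TPM fold change.

    Enrichment < 1.5 -> cytosol-localized (3-step model); >= 3 -> membrane-
    localized; in between -> undefined.  Membrane and undefined transcripts
    are fit with the 4-step model.
    """
    if tpm_cyto is None or tpm_cyto <= 0 or not np.isfinite(tpm_cyto):
        return "missing"
    enrichment = tpm_mem / tpm_cyto
    if enrichment < 1.5:
        return "cytosol"
    if enrichment >= 3.0:
        return "membrane"
    return "undefined"


def compute_weights(obs: pd.DataFrame, se_floor: float = 0.06) -> np.ndarray:
    """Inverse mixed-standard-error weights for a gene's observations.

    ``mixed = 0.5 * se(point) + 0.5 * mean_over_time(se)`` within each
    region x compartment series, floored at ``se_floor``; the chi-square is
    then ``sum((weight * residual)^2)``.
    """
    if "share_se" not in obs.columns:
        raise ValueError("observations need a share_se column")
    se = obs["share_se"].to_numpy(dtype=float)
    mean_se = obs.groupby(["region", "compartment"])["share_se"].transform("mean")
    mixed = 0.5 * se + 0.5 * mean_se.to_numpy(dtype=float)
    se_used = np.maximum(mixed, se_floor)
    return 1.0 / se_used


def build_ratio_constraints(
    expression_row: Mapping[str, float],
    factors: AbundanceFactors,
    cfg: FitConfig,
    variant: str,
) -> dict[str, tuple[float, float]]:
    """Bounds on parameter ratios from abundance-scaled expression ratios.

    Returns ``{"nuc_over_cyto": (lo, hi)[, "mem_over_cyto": (lo, hi)]}``,
    each ratio plus/minus ``ratio_constraint_width`` standard errors; a
    nonpositive lower bound is clipped to a small positive floor, and a
    zero SE widens to a +/-1e-6 relative band.
    """
    a, b, c = factors.as_tuple()
    width = cfg.ratio_constraint_width

    def band(ratio, se):
        if not np.isfinite(ratio) or ratio <= 0:
            raise ValueError("nonpositive expression ratio")
        if not np.isfinite(se) or se == 0:
            se = 1e-6 * ratio / width
        lo = ratio - width * se
        hi = ratio + width * se
        if lo <= 0:
            lo = min(1e-6, 0.5 * ratio)
        return (lo, hi)

    out = {}
    r_nuc, se_nuc = absolute_ratio(
        expression_row["tpm_nuc"],
        expression_row["tpm_cyto"],
        a,
        b,
        expression_row.get("se_nuc"),
        expression_row.get("se_cyto"),
    )
    out["nuc_over_cyto"] = band(r_nuc, se_nuc)
    if variant == FOUR_STEP:
        r_mem, se_mem = absolute_ratio(
            expression_row["tpm_mem"],
            expression_row["tpm_cyto"],
            c,
            b,
            expression_row.get("se_mem"),
            expression_row.get("se_cyto"),
        )
        out["mem_over_cyto"] = band(r_mem, se_mem)
    return out


class _FitProblem:
    """Precompiled residual function of one gene's weighted fit."""

    def __init__(
        self,
        gene: GeneModel,
        obs: pd.DataFrame,
        constraints: Mapping[str, tuple[float, float]],
        cfg: FitConfig,
        variant: str,
        with_nuclear_decay: bool,
    ):
        self.gene = gene
        self.cfg = cfg
        self.variant = variant
        self.with_gamma2 = with_nuclear_decay
        self.reduced = gene.reduced_model
        self.mode = cfg.nuclear_constraint_mode

        comps = {"nuc", "cyto"} | ({"mem"} if variant == FOUR_STEP else set())
        sub = obs[obs.compartment.isin(comps)].copy()
        if self.reduced:
            sub = sub[sub.region != "intronic"]
        sub = sub.dropna(subset=["share_mean", "share_se"])
        if len(sub) == 0:
            raise ValueError(f"{gene.gene_id}: no usable observations")
        n_times = sub.groupby(["region", "compartment"])["time_min"].nunique()
        if (n_times < 2).any():
            raise ValueError(f"{gene.gene_id}: fewer than 2 time points in a series")

        self.y = sub["share_mean"].to_numpy(dtype=float)
        self.w = compute_weights(sub, cfg.se_floor)
        self.t = sub["time_min"].to_numpy(dtype=float)
        is_intron = (sub.region == "intronic").to_numpy()
        self.d = np.where(
            is_intron, gene.intron_distance_kb, sub["d_kb"].to_numpy(dtype=float)
        )
        # cascade stage per row
        if self.reduced:
            stage = np.where(sub.compartment == "nuc", 0, 1)
            if variant == FOUR_STEP:
                stage = np.where(sub.compartment == "mem", 2, stage)
        else:
            stage = np.where(sub.compartment == "nuc", 1, 2)
            stage[is_intron] = 0
            if variant == FOUR_STEP:
                stage = np.where(sub.compartment == "mem", 3, stage)
        self.stage = stage.astype(int)
        self.n_stages = int(self.stage.max()) + 1
        self.obs_used = sub

        # variable layout (all log10)
        lo_r, hi_r = cfg.rate_bounds
        names, lb, ub = [], [], []

        def add(name, lo, hi):
            names.append(name)
            lb.append(math.log10(lo))
            ub.append(math.log10(hi))

        if not self.reduced:
            add("k1", lo_r, hi_r)
        add("k2", lo_r, hi_r)
        if with_nuclear_decay:
            add("gamma2", cfg.gamma2_min, hi_r)
        add("r_nuc", *constraints["nuc_over_cyto"])
        if variant == FOUR_STEP:
            add("r_mem", *constraints["mem_over_cyto"])
        if not self.reduced:
            add("v", *cfg.v_bounds)
        self.var_names = names
        self.lb = np.asarray(lb)
        self.ub = np.asarray(ub)

    # -- parameter decoding -------------------------------------------------
    def decode(self, x: np.ndarray) -> dict[str, float]:
        """Natural-scale parameters (rates, ratios, v) from log10 variables."""
        v = {n: 10.0 ** xi for n, xi in zip(self.var_names, x)}
        k2 = v["k2"]
        gamma2 = v.get("gamma2", 0.0)
        r2 = k2 + gamma2
        rn = v["r_nuc"]
        if self.reduced or self.mode == "mature_only":
            r3 = rn * k2
        else:  # total nuclear pool (pre + mature) over cytosol
            r3 = rn * k2 / (1.0 + r2 / v["k1"])
        out = {"k2": k2, "gamma2": gamma2}
        if "k1" in v:
            out["k1"] = v["k1"]
        if "v" in v:
            out["v"] = v["v"]
        if self.variant == FOUR_STEP:
            out["k3"] = r3
            out["gamma4"] = r3 / v["r_mem"]
        else:
            out["gamma3"] = r3
        return out

    def rates_vector(self, p: dict[str, float]) -> np.ndarray:
        r = [p["k2"] + p["gamma2"], p.get("gamma3", p.get("k3"))]
        if self.variant == FOUR_STEP:
            r.append(p["gamma4"])
        if not self.reduced:
            r.insert(0, p["k1"])
        return np.asarray(r, dtype=float)

    def predict(self, x: np.ndarray) -> np.ndarray:
        p = self.decode(x)
        rates = self.rates_vector(p)
        if self.reduced:
            tt = np.maximum(0.0, self.t - self.cfg.delta)
        else:
            tt = np.maximum(0.0, self.t - self.d / p["v"] - self.cfg.delta)
        shares = hypoexponential_share(rates[: self.n_stages], tt)
        return shares[self.stage, np.arange(len(tt))]

    def residual(self, x: np.ndarray) -> np.ndarray:
        return self.w * (self.predict(x) - self.y)

    # -- vectorized evaluation over many starts -----------------------------
    def _decode_rates_batch(self, X: np.ndarray):
        """Cascade rates (S, n_stages) and elongation rates for S starts."""
        V = 10.0 ** X
        idx = {n: i for i, n in enumerate(self.var_names)}
        k2 = V[:, idx["k2"]]
        gamma2 = V[:, idx["gamma2"]] if "gamma2" in idx else 0.0
        r2 = k2 + gamma2
        rn = V[:, idx["r_nuc"]]
        if self.reduced or self.mode == "mature_only":
            r3 = rn * k2
        else:
            r3 = rn * k2 / (1.0 + r2 / V[:, idx["k1"]])
        cols = [r2, r3]
        if self.variant == FOUR_STEP:
            cols.append(r3 / V[:, idx["r_mem"]])
        if not self.reduced:
            cols.insert(0, V[:, idx["k1"]])
        R = np.column_stack(cols)[:, : self.n_stages]
        v = None if self.reduced else V[:, idx["v"]]
        return R, v

    def residual_batch(self, X: np.ndarray) -> np.ndarray:
        """Weighted residuals (S, N) for S parameter vectors at once.

        Used only by the screening stage: rates are separated by a fixed
        relative jitter of 1e-5 per stage so the partial-fraction form
        stays smooth through accidental rate degeneracies; the selected
        solutions are re-polished on the exact evaluation path.
        """
        R, v = self._decode_rates_batch(X)
        R = R * (1.0 + 1e-5 * np.arange(R.shape[1]))
        S, n = R.shape
        if self.reduced:
            tt = np.maximum(0.0, self.t - self.cfg.delta)
            TT = np.broadcast_to(tt, (S, tt.size))
        else:
            TT = np.maximum(
                0.0, self.t[None, :] - self.d[None, :] / v[:, None] - self.cfg.delta
            )
        diff = R[:, :, None] - R[:, None, :]  # [s, m, j] = r_m - r_j
        diag = np.arange(n)
        diff[:, diag, diag] = 1.0
        ratio = R[:, :, None] / diff
        ratio[:, diag, diag] = 1.0
        C = np.cumprod(ratio, axis=1)  # C[s, i, j] = prod_{m<=i, m!=j}
        C *= np.tril(np.ones((n, n)))[None]
        E = np.exp(-R[:, None, :] * TT[:, :, None])  # (S, N, n)
        Crow = C[:, self.stage, :]  # (S, N, n)
        pred = 1.0 - np.einsum("snj,snj->sn", Crow, E)
        np.clip(pred, 0.0, 1.0, out=pred)
        return self.w[None, :] * (pred - self.y[None, :])

    def to_params(self, p: dict[str, float]) -> KineticParams:
        kw = dict(
            k1=p.get("k1"),
            k2=p["k2"],
            gamma2=p["gamma2"],
            v=p.get("v"),
            delta=self.cfg.delta,
        )
        if self.variant == FOUR_STEP:
            return KineticParams(
                k3=p["k3"], gamma4=p["gamma4"], variant=FOUR_STEP, **kw
            )
        return KineticParams(gamma3=p["gamma3"], variant=THREE_STEP, **kw)


def _screen_starts(
    problem: _FitProblem, starts: np.ndarray, n_iter: int
) -> tuple[np.ndarray, np.ndarray]:
    """Damped least-squares (Levenberg-Marquardt) screening of all starts.

    Runs a fixed number of projected LM iterations on every start at once
    with vectorized residual/Jacobian evaluation; returns final costs
    (chi2) and positions.  This is the computationally inexpensive local
    stage; precise convergence is left to the per-solution polish.
    """
    X = starts.copy()
    S, P = X.shape
    lb, ub = problem.lb, problem.ub
    lam = np.full(S, 1e-2)
    eye = np.eye(P)

    def cost_and_resid(Xb):
        r = problem.residual_batch(Xb)
        return np.einsum("sn,sn->s", r, r), r

    cost, r = cost_and_resid(X)
    h = 1e-6
    for _ in range(n_iter):
        J = np.empty((S, r.shape[1], P))
        for p in range(P):
            Xp = X.copy()
            Xp[:, p] += h
            J[:, :, p] = (problem.residual_batch(Xp) - r) / h
        g = np.einsum("snp,sn->sp", J, r)
        H = np.einsum("snp,snq->spq", J, J)
        D = np.maximum(np.diagonal(H, axis1=1, axis2=2), 1e-12)
        A = H + lam[:, None, None] * (eye[None] * D[:, None, :]) + 1e-12 * eye[None]
        try:
            dx = -np.linalg.solve(A, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            dx = -np.stack([np.linalg.lstsq(a, gi, rcond=None)[0]
                            for a, gi in zip(A, g)])
        Xn = np.clip(X + dx, lb, ub)
        cost_n, r_n = cost_and_resid(Xn)
        better = cost_n < cost
        X[better] = Xn[better]
        r[better] = r_n[better]
        cost[better] = cost_n[better]
        lam = np.where(better, lam * 0.4, lam * 3.0)
        np.clip(lam, 1e-7, 1e7, out=lam)
    return cost, X


def compute_bic(chi2: float, n_points: int, n_params: int) -> float:
    """BIC for weighted least squares with known Gaussian errors.

    ``chi2`` equals -2 log L up to a model-independent constant, which
    cancels in BIC differences between models fit to the same data.
    """
    if n_points <= n_params:
        raise ValueError("need more data points than parameters")
    return float(chi2 + n_params * math.log(n_points))


def _param_standard_errors(problem: _FitProblem, x: np.ndarray, jac: np.ndarray):
    """Inverse-Hessian SEs in log10 space, delta-method to natural rates."""
    jtj = jac.T @ jac
    # pseudo-inverse: the ratio-band reparameterization can leave an exactly
    # flat direction (e.g. the export/decay split within the nuclear ratio
    # band); its zero curvature is dropped rather than inverted into
    # meaningless infinite errors
    cov_log = np.linalg.pinv(jtj, rcond=1e-10)
    base = problem.decode(x)
    keys = sorted(base)
    h = 1e-6
    G = np.zeros((len(keys), len(x)))
    for j in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        pp, pm = problem.decode(xp), problem.decode(xm)
        for i, k in enumerate(keys):
            G[i, j] = (pp[k] - pm[k]) / (2 * h)
    cov_nat = G @ cov_log @ G.T
    se = {k: float(np.sqrt(max(cov_nat[i, i], 0.0))) for i, k in enumerate(keys)}
    return se


def multistart_fit(
    gene: GeneModel,
    obs: pd.DataFrame,
    constraints: Mapping[str, tuple[float, float]],
    cfg: FitConfig,
    variant: str,
    with_nuclear_decay: bool = False,
    localization: str = "cytosol",
) -> FitResult:
    """200-start bounded least squares in log space, best-of-ten selection.

    Random starts are drawn log-uniform inside the variable bounds from a
    per-gene seed (stable under cohort composition).  Each start is
    minimized by a damped least-squares (trust-region) optimizer with a
    small evaluation cap; the ``n_best_pool`` lowest-chi2 solutions are
    re-polished to tight tolerances and the member with the largest
    minimal log10-distance of any variable to its nearer bound is selected.
    """
    problem = _FitProblem(gene, obs, constraints, cfg, variant, with_nuclear_decay)
    rng = np.random.default_rng(
        gene_seed(cfg.seed, gene.gene_id)
        + [1 if variant == FOUR_STEP else 0, int(with_nuclear_decay)]
    )
    lb, ub = problem.lb, problem.ub
    starts = rng.uniform(lb, ub, size=(cfg.n_starts, len(lb)))

    costs, X = _screen_starts(problem, starts, cfg.n_screen_iterations)
    order = np.argsort(costs)
    pool = []
    for x0 in X[order[: cfg.n_best_pool]]:
        res = least_squares(
            problem.residual,
            x0,
            bounds=(lb, ub),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-10,
            max_nfev=cfg.max_nfev_polish,
            x_scale="jac",
        )
        pool.append(res)
    pool.sort(key=lambda r: r.cost)

    def boundary_score(x):
        return float(np.min(np.minimum(x - lb, ub - x)))

    best = max(pool, key=lambda r: boundary_score(r.x))
    x = best.x
    chi2 = float(2.0 * best.cost)
    n_points = len(problem.y)
    n_params = len(lb)
    p = problem.decode(x)
    se = _param_standard_errors(problem, x, best.jac)
    pool_nat = [problem.decode(r.x) for r in pool]
    pool_chi2 = [float(2.0 * r.cost) for r in pool]
    result = FitResult(
        gene_id=gene.gene_id,
        params=problem.to_params(p),
        param_se=se,
        chi2=chi2,
        reduced_chi2=chi2 / max(n_points - n_params, 1),
        n_points=n_points,
        n_params=n_params,
        bic=compute_bic(chi2, n_points, n_params),
        variant=variant,
        includes_nuclear_decay=with_nuclear_decay,
        localization=localization,
        boundary_score=boundary_score(x),
        pool_params=pool_nat,
        pool_chi2=pool_chi2,
    )
    result.qc = quality_control(result, pool_nat, cfg)
    return result


def _failed_result(gene, variant, with_gamma2, localization, msg) -> FitResult:
    return FitResult(
        gene_id=gene.gene_id,
        params=None,
        param_se={},
        chi2=float("inf"),
        reduced_chi2=float("inf"),
        n_points=0,
        n_params=0,
        bic=float("inf"),
        variant=variant,
        includes_nuclear_decay=with_gamma2,
        localization=localization,
        qc={"chi2_fail": True, "instability_fail": False, "boundary_fail": False},
        success=False,
        message=msg,
    )


def quality_control(
    result: FitResult, pool_params: Sequence[Mapping[str, float]], cfg: FitConfig
) -> dict:
    """The three exclusion rules plus the elongation-boundary flag.

    (a) reduced chi2 > 4; (b) relative standard deviation of any kinetic
    parameter across the ten-best pool > 0.05; (c) the named rates of the
    localization class pinned within 1e-6 relative of the upper rate bound
    (nuclear k2 with the cytosolic rate for cytosol-localized genes,
    nuclear k2 with the membrane decay rate for 4-step genes).  An
    elongation rate at either of its bounds only flags the gene for
    elongation analyses.
    """
    flags = {
        "chi2_fail": bool(result.reduced_chi2 > 4.0),
        "instability_fail": False,
        "boundary_fail": False,
        "v_at_boundary": False,
    }
    rate_keys = [k for k in ("k1", "k2", "gamma2", "gamma3", "k3", "gamma4", "v")
                 if pool_params and k in pool_params[0]]
    for k in rate_keys:
        vals = np.array([p[k] for p in pool_params], dtype=float)
        mean = np.mean(vals)
        if mean != 0 and len(vals) > 1:
            if np.std(vals, ddof=1) / abs(mean) > 0.05:
                flags["instability_fail"] = True
                break
    p = result.params
    if p is not None:
        hi = cfg.rate_bounds[1]

        def at_upper(val):
            return val is not None and abs(val - hi) <= _BOUNDARY_RTOL * hi

        if p.variant == THREE_STEP:
            flags["boundary_fail"] = at_upper(p.k2) or at_upper(p.gamma3)
        else:
            flags["boundary_fail"] = at_upper(p.k2) or at_upper(p.gamma4)
        if p.v is not None:
            lo_v, hi_v = cfg.v_bounds
            flags["v_at_boundary"] = (
                abs(p.v - lo_v) <= _BOUNDARY_RTOL * lo_v
                or abs(p.v - hi_v) <= _BOUNDARY_RTOL * hi_v
            )
    return flags


def compare_nuclear_decay_models(
    fit_null: FitResult, fit_ext: FitResult, delta_bic_threshold: float = 10.0
):
    """Choose between the models without and with nuclear decay.

    The extended model wins only with very strong evidence: BIC(null) -
    BIC(extended) > 10 (Bayes factor above ~150) *and* the fitted decay
    rate exceeding its standard error.  A failed or QC-rejected extended
    fit retains the null.
    """
    record = {
        "gene_id": fit_null.gene_id,
        "delta_bic": fit_null.bic - fit_ext.bic if fit_ext.success else float("nan"),
        "gamma2": None,
        "se_gamma2": None,
        "chosen": "null_model",
    }
    if not fit_ext.success or not fit_ext.qc_pass:
        record["reason"] = "extended fit failed or rejected by QC"
        return fit_null, record
    g2 = fit_ext.params.gamma2
    se_g2 = fit_ext.param_se.get("gamma2", float("inf"))
    record["gamma2"] = g2
    record["se_gamma2"] = se_g2
    if record["delta_bic"] > delta_bic_threshold and se_g2 < g2:
        record["chosen"] = "extended"
        return fit_ext, record
    return fit_null, record


class KineticModelFitter(BaseEstimator):
    """Per-gene estimator: null and extended fits plus model selection.

    Configuration mirrors :class:`FitConfig`; after ``fit`` the chosen
    model is in ``result_`` with the competing fits in ``null_result_``
    and ``ext_result_`` and the decision in ``decision_``.
    """

    def __init__(self, n_starts=200, n_best_pool=10, se_floor=0.06,
                 ratio_constraint_width=5.0, seed=0, delta=5.0,
                 nuclear_constraint_mode="total_nuclear",
                 compare_decay=True, n_screen_iterations=25):
        self.n_starts = n_starts
        self.n_best_pool = n_best_pool
        self.se_floor = se_floor
        self.ratio_constraint_width = ratio_constraint_width
        self.seed = seed
        self.delta = delta
        self.nuclear_constraint_mode = nuclear_constraint_mode
        self.compare_decay = compare_decay
        self.n_screen_iterations = n_screen_iterations

    def _config(self) -> FitConfig:
        return FitConfig(
            n_starts=self.n_starts,
            n_best_pool=self.n_best_pool,
            se_floor=self.se_floor,
            ratio_constraint_width=self.ratio_constraint_width,
            seed=self.seed,
            delta=self.delta,
            nuclear_constraint_mode=self.nuclear_constraint_mode,
            n_screen_iterations=self.n_screen_iterations,
        )

    def fit(self, obs: pd.DataFrame, *, gene: GeneModel,
            expression_row: Mapping[str, float], factors: AbundanceFactors):
        cfg = self._config()
        loc = classify_localization(
            expression_row["tpm_mem"], expression_row["tpm_cyto"]
        )
        if loc == "missing":
            raise ValueError(f"{gene.gene_id}: missing cytosolic expression")
        variant = THREE_STEP if loc == "cytosol" else FOUR_STEP
        constraints = build_ratio_constraints(expression_row, factors, cfg, variant)
        self.null_result_ = multistart_fit(
            gene, obs, constraints, cfg, variant,
            with_nuclear_decay=False, localization=loc,
        )
        if self.compare_decay:
            self.ext_result_ = multistart_fit(
                gene, obs, constraints, cfg, variant,
                with_nuclear_decay=True, localization=loc,
            )
            self.result_, self.decision_ = compare_nuclear_decay_models(
                self.null_result_, self.ext_result_
            )
        else:
            self.ext_result_ = None
            self.result_ = self.null_result_
            self.decision_ = {"chosen": "null_model",
                              "reason": "comparison disabled"}
        return self


def _result_row(res: FitResult, decision: Mapping) -> dict:
    p = res.params
    row = {
        "gene_id": res.gene_id,
        "localization": res.localization,
        "variant": res.variant,
        "includes_nuclear_decay": res.includes_nuclear_decay
        and decision.get("chosen") == "extended",
        "chi2": res.chi2,
        "reduced_chi2": res.reduced_chi2,
        "n_points": res.n_points,
        "n_params": res.n_params,
        "bic": res.bic,
        "delta_bic": decision.get("delta_bic"),
        "qc_pass": res.qc_pass,
        "success": res.success,
        **{f"qc_{k}": v for k, v in res.qc.items()},
    }
    if p is not None:
        for k in ("k1", "k2", "gamma2", "gamma3", "k3", "gamma4", "v"):
            row[k] = getattr(p, k)
            row[f"se_{k}"] = res.param_se.get(k)
        row["halflife_processing"] = half_life(p.k1) if p.k1 else float("nan")
        row["halflife_nuclear"] = half_life(p.r2)
        row["halflife_cytosolic"] = half_life(p.r3)
        row["halflife_membrane"] = (
            half_life(p.gamma4) if p.variant == FOUR_STEP else float("nan")
        )
    return row


def _fit_one_gene(gene, obs, expr_row, factors, cfg, compare_decay):
    """One gene's fit; returns (result row, fitter or None)."""
    try:
        fitter = KineticModelFitter(
            n_starts=cfg.n_starts,
            n_best_pool=cfg.n_best_pool,
            se_floor=cfg.se_floor,
            ratio_constraint_width=cfg.ratio_constraint_width,
            seed=cfg.seed,
            delta=cfg.delta,
            nuclear_constraint_mode=cfg.nuclear_constraint_mode,
            compare_decay=compare_decay,
            n_screen_iterations=cfg.n_screen_iterations,
        ).fit(obs, gene=gene, expression_row=expr_row, factors=factors)
    except (ValueError, KeyError) as exc:
        return (
            {"gene_id": gene.gene_id, "success": False, "qc_pass": False,
             "message": str(exc)},
            None,
        )
    return _result_row(fitter.result_, fitter.decision_), fitter


def fit_cohort(
    genes: Sequence[GeneModel],
    labeling: pd.DataFrame,
    expression: pd.DataFrame,
    factors: AbundanceFactors,
    cfg: FitConfig | None = None,
    compare_decay: bool = True,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Fit every gene of a cohort; returns a result table and fitters.

    Genes failing preconditions (missing data, too few time points) are
    skipped with a log row rather than aborting the cohort.  Per-gene
    randomness is seeded from the gene id, so results are independent of
    cohort composition and of scheduling: ``n_jobs > 1`` (process-based
    via joblib) returns bit-identical output to the serial path.
    """
    cfg = cfg or FitConfig()
    expr_by_gene = expression.set_index("gene_id")

    tasks = []
    rows, detail = [], {}
    for gene in genes:
        gid = gene.gene_id
        if gid not in expr_by_gene.index:
            rows.append({"gene_id": gid, "success": False, "qc_pass": False,
                         "message": "no expression row"})
            continue
        tasks.append(
            (gene, labeling[labeling.gene_id == gid],
             expr_by_gene.loc[gid].to_dict())
        )
    if n_jobs != 1:
        from joblib import Parallel, delayed

        outputs = Parallel(n_jobs=n_jobs)(
            delayed(_fit_one_gene)(g, obs, er, factors, cfg, compare_decay)
            for g, obs, er in tasks
        )
    else:
        outputs = [_fit_one_gene(g, obs, er, factors, cfg, compare_decay)
                   for g, obs, er in tasks]
    for (gene, _, _), (row, fitter) in zip(tasks, outputs):
        rows.append(row)
        if fitter is not None:
            detail[gene.gene_id] = fitter
    return pd.DataFrame.from_records(rows), detail
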