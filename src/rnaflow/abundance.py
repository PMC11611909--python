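"""Relative mRNA abundance of subcellular compartments.

TPM is a within-sample unit, so nuclear, cytosolic and membrane TPM values
are not directly comparable: each fraction contains a different share of
the cell's mRNA.  Assuming the whole-cell expression vector is the
factor-weighted sum of the fraction vectors,

    a * TPM_nuc + b * TPM_cyto + c * TPM_mem = TPM_whole,   a + b + c = 1,

the factors (a, b, c) are estimated over highly expressed genes
(whole-cell TPM > 50) by errors-in-variables (orthogonal distance) total
least squares, weighting both the fraction TPMs and the whole-cell TPM by
their inverse squared standard errors.  The constraint is enforced by
parameterizing ``c = 1 - a - b``, so the returned factors sum to one
exactly.  Abundance-scaled TPMs (``factor * TPM``) are then on a common
absolute scale, and their ratios constrain the kinetic parameter space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import odr
from sklearn.base import BaseEstimator

__all__ = [
    "AbundanceFactors",
    "AbundanceFactorEstimator",
    "fit_relative_abundance",
    "absolute_ratio",
]


@dataclass(frozen=True)
class AbundanceFactors:
    """Fitted relative compartment abundances; sum to 1 by construction."""

    a_nuc: float
    b_cyto: float
    c_mem: float
    se_a: float
    se_b: float
    se_c: float

    def __post_init__(self):
        if abs(self.a_nuc + self.b_cyto + self.c_mem - 1.0) > 1e-9:
            raise ValueError("abundance factors must sum to 1")

    def as_tuple(self):
        return (self.a_nuc, self.b_cyto, self.c_mem)


class AbundanceFactorEstimator(BaseEstimator):
    """Constrained errors-in-variables fit of the compartment factors.

    Parameters
    ----------
    min_whole_tpm : float
        Expression filter: only genes with whole-cell TPM above this value
        enter the fit (highly expressed genes carry reliable SEs).

    Attributes (after ``fit``)
    --------------------------
    factors_ : AbundanceFactors
    n_genes_ : int
        Number of genes passing the filter.
    negative_factors_ : bool
        Flags a solution outside [0, 1] (reported, never silently clipped).
    """

    def __init__(self, min_whole_tpm: float = 50.0):
        self.min_whole_tpm = min_whole_tpm

    def fit(self, X, y, *, sx=None, sy=None):
        """Fit factors from fraction TPMs ``X`` (n_genes, 3) and whole ``y``.

        ``sx``/``sy`` are matching standard errors; omitted errors default
        to uniform weights.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_genes, 3): nuc, cyto, mem TPM")
        sx = np.ones_like(X) if sx is None else np.asarray(sx, dtype=float)
        sy = np.ones_like(y) if sy is None else np.asarray(sy, dtype=float)
        keep = y > self.min_whole_tpm
        if keep.sum() < 3:
            raise ValueError(
                f"fewer than 3 genes above whole-cell TPM {self.min_whole_tpm}"
            )
        X, y, sx, sy = X[keep], y[keep], sx[keep], sy[keep]
        sx = np.clip(sx, 1e-12, None)
        sy = np.clip(sy, 1e-12, None)

        def f(beta, x):
            a, b = beta
            return a * x[0] + b * x[1] + (1.0 - a - b) * x[2]

        data = odr.RealData(X.T, y, sx=sx.T, sy=sy)
        problem = odr.ODR(data, odr.Model(f), beta0=[1.0 / 3.0, 1.0 / 3.0])
        out = problem.run()
        a, b = (float(v) for v in out.beta)
        c = 1.0 - a - b
        cov = out.cov_beta * out.res_var
        se_a, se_b = (float(np.sqrt(cov[i, i])) for i in (0, 1))
        se_c = float(np.sqrt(cov[0, 0] + cov[1, 1] + 2.0 * cov[0, 1]))
        self.factors_ = AbundanceFactors(a, b, c, se_a, se_b, se_c)
        self.n_genes_ = int(keep.sum())
        self.negative_factors_ = bool(min(a, b, c) < 0 or max(a, b, c) > 1)
        return self


def fit_relative_abundance(
    tpm_nuc,
    tpm_cyto,
    tpm_mem,
    tpm_whole,
    se_nuc=None,
    se_cyto=None,
    se_mem=None,
    se_whole=None,
    min_whole_tpm: float = 50.0,
) -> AbundanceFactors:
    """Functional wrapper around :class:`AbundanceFactorEstimator`."""
    X = np.column_stack([tpm_nuc, tpm_cyto, tpm_mem])
    sx = None
    if se_nuc is not None:
        sx = np.column_stack([se_nuc, se_cyto, se_mem])
    est = AbundanceFactorEstimator(min_whole_tpm=min_whole_tpm).fit(
        X, np.asarray(tpm_whole, dtype=float), sx=sx, sy=se_whole
    )
    return est.factors_


def absolute_ratio(
    tpm_x, tpm_y, factor_x, factor_y, se_x=None, se_y=None
) -> tuple[float, float]:
    """Absolute steady-state expression ratio between two compartments.

    ``(factor_x * tpm_x) / (factor_y * tpm_y)`` with a first-order
    (delta-method) standard error propagated from the TPM standard errors;
    abundance-factor uncertainty is treated as fixed.  Returns
    ``(nan, nan)`` for a zero denominator.
    """
    denom = factor_y * tpm_y
    if denom == 0 or tpm_y == 0:
        return float("nan"), float("nan")
    ratio = (factor_x * tpm_x) / denom
    if se_x is None or se_y is None or tpm_x == 0:
        return float(ratio), float("nan")
    rel = np.sqrt((se_x / tpm_x) ** 2 + (se_y / tpm_y) ** 2)
    return float(ratio), float(abs(ratio) * rel)
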