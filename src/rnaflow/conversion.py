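"""T2C conversion-rate estimation and new/total mRNA ratios.

4sU labeling marks new transcripts by T-to-C conversions.  A read with
``n`` genomic T positions carries ``k ~ Binomial(n, p_conv)`` conversions
if it stems from a labeled (new) molecule and ``k ~ Binomial(n, p_e)``
conversions from sequencing errors otherwise.  Pooling reads gives a
mutation frequency table ``a_kn`` whose two-component binomial mixture

    P(k | n) = (1 - pi) Binom(k; n, p_e) + pi Binom(k; n, p_conv)

is fitted by expectation-maximization with the error rate ``p_e`` held
fixed (it is estimated separately from the control orientation, where no
labeling signal exists).  The new/total mRNA share of a region then
follows from its T2C/T ratio divided by the conversion rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

__all__ = [
    "MutationFrequencyTable",
    "ConversionEstimate",
    "ConversionRateEstimator",
    "estimate_error_rate",
    "em_fit_conversion_rate",
    "compute_new_total_ratio",
    "read_frequency_table",
    "write_frequency_table",
]


@dataclass(frozen=True)
class MutationFrequencyTable:
    """Counts ``a_kn`` of reads with ``k`` mutations among ``n`` Ts."""

    entries: dict  # (k, n) -> count
    orientation: str = "sense_T2C"  # or "antisense_A2G_control"

    def __post_init__(self):
        for (k, n), c in self.entries.items():
            if k < 0 or n < 0 or k > n:
                raise ValueError(f"invalid entry (k={k}, n={n})")
            if c < 0:
                raise ValueError("counts must be nonnegative")

    def arrays(self):
        items = sorted(self.entries.items())
        k = np.array([kk for (kk, _), _ in items], dtype=float)
        n = np.array([nn for (_, nn), _ in items], dtype=float)
        a = np.array([c for _, c in items], dtype=float)
        return k, n, a

    @property
    def total_reads(self) -> int:
        return int(sum(self.entries.values()))


@dataclass
class ConversionEstimate:
    p_conv: float
    p_e: float
    mixture_weight_new: float
    n_iterations: int
    converged: bool
    log_likelihood: float = float("nan")


def _as_table(table) -> MutationFrequencyTable:
    if isinstance(table, MutationFrequencyTable):
        return table
    return MutationFrequencyTable(entries=dict(table))


def estimate_error_rate(control_table) -> float:
    """Pooled mismatch rate ``sum(k a_kn) / sum(n a_kn)`` of the control.

    The control orientation (A2G on the primary read, T2C on the secondary)
    carries no labeling signal, so its pooled mismatch fraction estimates
    the sequencing error rate ``p_e``.
    """
    table = _as_table(control_table)
    k, n, a = table.arrays()
    total_t = float(np.sum(n * a))
    if len(a) == 0 or total_t <= 0:
        raise ValueError("control table is empty (no T positions)")
    return float(np.sum(k * a) / total_t)


def _log_binom_pmf(k, n, p):
    p = min(max(p, 1e-300), 1 - 1e-12)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * np.log(p)
        + (n - k) * np.log1p(-p)
    )


class ConversionRateEstimator(BaseEstimator):
    """EM fit of the binomial mixture of labeled and background reads.

    Parameters
    ----------
    p_e : float
        Sequencing error rate, held fixed during EM.
    p_conv_init : float, optional
        Starting conversion rate; defaults to ``10 * p_e`` (or 0.01 if the
        error rate is 0).
    pi_init : float
        Starting mixture weight of the labeled component.
    tol : float
        Convergence threshold on the log-likelihood increase.
    max_iter : int
        Iteration cap; exceeding it flags ``converged_ = False``.

    Attributes (after ``fit``)
    --------------------------
    p_conv_, weight_new_, n_iter_, converged_, log_likelihood_,
    log_likelihood_path_
    """

    def __init__(self, p_e=1e-3, p_conv_init=None, pi_init=0.5, tol=1e-8,
                 max_iter=500):
        self.p_e = p_e
        self.p_conv_init = p_conv_init
        self.pi_init = pi_init
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, table, y=None):
        table = _as_table(table)
        k, n, a = table.arrays()
        if len(a) == 0 or a.sum() <= 0:
            raise ValueError("mutation frequency table is empty")
        p_e = float(self.p_e)
        p_conv = self.p_conv_init
        if p_conv is None:
            p_conv = 10.0 * p_e if p_e > 0 else 0.01
        p_conv = max(p_conv, p_e + 1e-8)
        pi = float(self.pi_init)

        path = []
        ll_prev = -np.inf
        converged = False
        it = 0
        total = float(np.sum(a))
        degenerate = bool(np.all(k == 0))
        for it in range(1, self.max_iter + 1):
            lb = _log_binom_pmf(k, n, p_e)
            ln = _log_binom_pmf(k, n, p_conv)
            log_wn = np.log(max(pi, 1e-300)) + ln
            log_wb = np.log(max(1.0 - pi, 1e-300)) + lb
            m = np.maximum(log_wn, log_wb)
            log_mix = m + np.log(np.exp(log_wn - m) + np.exp(log_wb - m))
            ll = float(np.sum(a * log_mix))
            path.append(ll)
            # stop on the per-read likelihood gain, so the fit is invariant
            # to overall read depth
            if (ll - ll_prev) / total < self.tol and it > 1:
                converged = True
                break
            ll_prev = ll
            # E-step: posterior probability each read class is "new"
            w = np.exp(log_wn - log_mix)
            # M-step: weighted mixture weight and conversion rate
            aw = a * w
            pi = float(np.sum(aw) / total)
            denom = float(np.sum(aw * n))
            if denom > 0:
                p_conv = float(np.sum(aw * k) / denom)
            p_conv = max(p_conv, p_e + 1e-10)

        if degenerate:
            converged = False
            p_conv = p_e + 1e-10
        if p_conv <= p_e * 1.05 + 1e-6:
            # labeled component collapsed onto the background: the mixture
            # weight is unidentifiable, report an unlabeled sample
            pi = 0.0
        self.p_conv_ = float(p_conv)
        self.weight_new_ = float(pi)
        self.n_iter_ = it
        self.converged_ = converged
        self.log_likelihood_ = path[-1]
        self.log_likelihood_path_ = np.asarray(path)
        return self

    def estimate_(self) -> ConversionEstimate:
        return ConversionEstimate(
            p_conv=self.p_conv_,
            p_e=float(self.p_e),
            mixture_weight_new=self.weight_new_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            log_likelihood=self.log_likelihood_,
        )


def em_fit_conversion_rate(
    table, p_e, init=None, tol=1e-8, max_iter=500
) -> ConversionEstimate:
    """Functional wrapper around :class:`ConversionRateEstimator`."""
    est = ConversionRateEstimator(
        p_e=p_e, p_conv_init=init, tol=tol, max_iter=max_iter
    ).fit(table)
    return est.estimate_()


def compute_new_total_ratio(t2c, t, p_conv, p_e=0.0, mode="background_corrected"):
    """New/total mRNA share from a region's T2C and T counts.

    ``mode="paper"`` divides the raw T2C/T ratio by the conversion rate;
    ``mode="background_corrected"`` first subtracts the error rate from
    both numerator rate and conversion rate.  The result is clipped to
    [0, 1]; a region without T coverage yields NaN.
    """
    if t == 0:
        return float("nan")
    if p_conv <= 0:
        raise ValueError("p_conv must be positive")
    raw = t2c / t
    if mode == "paper":
        ratio = raw / p_conv
    elif mode == "background_corrected":
        if p_conv <= p_e:
            raise ValueError("p_conv must exceed p_e")
        ratio = (raw - p_e) / (p_conv - p_e)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.clip(ratio, 0.0, 1.0))


def write_frequency_table(table, path):
    t = _as_table(table)
    rows = [(k, n, c) for (k, n), c in sorted(t.entries.items())]
    pd.DataFrame(rows, columns=["k", "n", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_frequency_table(path, orientation="sense_T2C") -> MutationFrequencyTable:
    df = pd.read_csv(path, sep="\t")
    entries = {
        (int(r.k), int(r.n)): int(r["count"]) for _, r in df.iterrows()
    }
    return MutationFrequencyTable(entries=entries, orientation=orientation)
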