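# Methods

## The kinetic model

An mRNA molecule is tracked through up to four first-order stages:
nuclear pre-mRNA (`x1`), nuclear mature mRNA (`x2`), cytosolic mRNA
(`x3`) and membrane-bound mRNA (`x4`):

```
dx1/dt = p      - k1*x1
dx2/dt = k1*x1  - (k2 + g2)*x2
dx3/dt = k2*x2  - r3*x3        r3 = g3 (3-step) or k3 (4-step)
dx4/dt = k3*x3  - g4*x4
```

Cytosol-localized transcripts end at `x3` (decay `g3`); membrane-localized
and undefined transcripts are transported (`k3`, no cytosolic decay) and
degrade at the membrane (`g4`). Nuclear decay `g2` defaults to zero and
enters only through model selection (below). Rescaling each compartment by
its steady state yields a relaxation cascade for the share of new mRNA
`x~_i` with exit rates `r = (k1, k2+g2, r3, g4)` and solution equal to the
hypoexponential CDF of stages `1..i`. The production rate `p` cancels and
is never fitted.

Assumptions worth stating: first-order kinetics with time-constant rates
(steady state over the 3 h labeling window), no cell-division dilution
term (rates of interest are an order of magnitude faster than a ~14 h
cell cycle), no stochastic (single-molecule) effects, and irreversible
flow between compartments.

### Numerical evaluation

The partial-fraction form `x~_i(t) = 1 - sum_j [prod_{m!=j} r_m/(r_m-r_j)]
exp(-r_j t)` is used when all exit rates are pairwise separated by more
than 1e-4 relative; its cancellation error there stays near 1e-12. Below
that gap the shares are computed through the matrix exponential of the
bidiagonal cascade generator acting on the survival vector, which is exact
for any multiplicity pattern. The unit tests certify both branches against
endpoint ODE integration (DOP853, rtol 1e-12, atol 1e-14) to better than
1e-8 absolute, including rate pairs separated by only 1e-5.

### Elongation delay

Poly(A)-selected full-length sequencing observes label in a sequence at
distance `d` kb from the 3' end only once the polymerase has covered it:
every exon-level prediction is evaluated at `t~ = max(0, t - d/v - delta)`
with one shared elongation rate `v` (kb/min) per gene and a global delay
`delta = 5` min (poly(A) tailing and detection lag). The pooled intronic
region uses the pseudo-distance `0.1 * L` (gene length `L`), the
expression-weighted mean relative exon distance. Intron-less genes and
genes with a single usable exon are fit with the cascade shortened by one
stage, without `k1` and `v`, at `t~ = t - delta`.

## Compartment abundance factors

TPM is per-sample relative, so fraction TPMs are made comparable by
factors `(a, b, c)` solving `a*TPM_nuc + b*TPM_cyto + c*TPM_mem =
TPM_whole` with `a + b + c = 1`, fitted by orthogonal-distance (total)
least squares over genes with whole-cell TPM > 50, weighting all axes by
inverse squared standard errors. The constraint is enforced by
`c = 1 - a - b`, so the returned triple sums to one exactly; the SE of `c`
follows from the (a, b) covariance. Abundance-scaled TPM ratios
(`factor x TPM`) estimate absolute compartment ratios; their standard
errors use first-order propagation from the TPM SEs with the factors
treated as fixed (factor uncertainty is not propagated — an approximation,
since the reference analysis treats the factors as constants when building
constraints).

## Conversion rates and share-new values

A read with `n` T positions from a labeled molecule carries
`Binomial(n, p_conv)` T2C conversions; an unlabeled read
`Binomial(n, p_e)`. The error rate `p_e` is the pooled mismatch rate of
the control orientation (A2G on the primary read), and `p_conv` is fitted
by EM on the two-component binomial mixture with `p_e` held fixed
(start: `p_conv = 10 p_e`, mixture weight 0.5; stop when the per-read
log-likelihood gain falls below 1e-8 — a per-read criterion so the fit is
invariant to sequencing depth). If the labeled component collapses onto
the background the mixture weight is reported as zero (unlabeled sample).
The share of new mRNA of a region is its T2C/T ratio divided by `p_conv`
(optionally background-corrected: `(ratio - p_e)/(p_conv - p_e)`),
clipped to [0, 1].

## Per-gene fitting

* **Weights.** Each data point's SE is mixed half-and-half with the
  time-averaged SE of its region x compartment series and floored at 0.06
  (a variance-stabilization floor equal to the cohort's typical early-time
  SE); weights are inverse mixed SEs and chi2 is the weighted residual sum
  of squares.
* **Constraints.** The abundance-scaled nuclear/cytosol and (4-step)
  membrane/cytosol expression ratios, plus/minus five standard errors,
  bound the corresponding parameter ratios. They are imposed by
  reparameterization: the ratio is a bounded free variable, and the
  dependent rate is derived (`k3 = ratio_mem * g4`; the cytosolic rate
  from the nuclear ratio). The nuclear constraint defaults to the total
  nuclear pool (`(x1+x2)/x3`), since poly(A) nuclear expression includes
  pre-mRNA; a mature-only mode (`x2/x3`) is provided as configuration
  because the observable is not decisive between them.
* **Optimization.** Log10-parameter space, bounds 1e-3..2 /min for rates
  (1e-6 lower bound for `g2`), 0.1..10 kb/min for `v`. 200 random
  log-uniform starts (seeded per gene from a master seed plus a stable
  hash of the gene id, so results are independent of cohort composition)
  are screened by a vectorized projected Levenberg-Marquardt iteration
  (fixed 25-iteration budget, all starts advanced simultaneously; rates
  separated by a 1e-5 relative jitter to keep the screening smooth through
  accidental degeneracies). The ten lowest-chi2 solutions are re-polished
  with a bounded trust-region least-squares solver at tight tolerances on
  the exact evaluation path, and the member maximizing the minimal
  log10-distance of any variable to its nearer bound is selected — the
  most interior of the near-optimal solutions.
* **Errors.** Parameter SEs are square roots of the diagonal of the
  pseudo-inverse of the Gauss-Newton Hessian (J'J) at the optimum,
  transported to natural scale by the delta method. The pseudo-inverse
  (rcond 1e-10) matters: within the nuclear-ratio band the export/decay
  split `(k2, g2)` has an exactly flat chi2 direction, whose zero
  curvature must be dropped, not inverted. SEs therefore reflect the
  curved directions only and understate the flat-direction uncertainty,
  which is instead interval-bounded by the ratio band itself.
* **Quality control.** Genes are excluded when (a) reduced chi2 > 4,
  (b) the relative standard deviation of any parameter across the
  ten-best pool exceeds 0.05, or (c) the class-defining rates sit at the
  upper rate bound (nuclear and cytosolic rates for cytosol-localized
  genes; nuclear and membrane-decay rates for 4-step genes; "at bound"
  means within 1e-6 relative). An elongation rate at either of its bounds
  flags the gene for elongation analyses only.
* **Nuclear decay model selection.** Null (`g2 = 0`) and extended
  (`g2` free) fits are compared by `BIC = chi2 + k ln(n)` (valid for
  weighted least squares with known errors; the dropped likelihood
  constant cancels in differences). The extended model is chosen only if
  `BIC_null - BIC_ext > 10` and `SE(g2) < g2`; an extended fit that fails
  QC keeps the null. Because `g2` is identified only through the ratio
  band, detection power depends directly on expression-ratio precision:
  with wide bands the ten-best pool wanders along the flat direction and
  rule (b) rejects the extended fit. This is a property of the design,
  not of the optimizer — distinguishing export from decay requires
  precise steady-state ratios.

## Derived (aggregated) half-lives

Transitional rates describe single steps; for comparison with classical
experiments the package derives aggregated half-lives by generating
pulse-chase curves (share-old = 1 - share-new), mixing compartments by
their steady-state amounts for the whole-cell curve (the nuclear pool sums
pre- and mature mRNA), and fitting a single exponential
(`y = exp(-rate*t)`, rate bounded 1e-5..10 /min, log-rate optimization
from a log-linear initial guess, no plateau term). Transcription-shutoff
expression series are normalized per sample by the median ratio of
long-lived reference genes to their cross-sample mean, scaled to the t = 0
point, and fit the same way. These aggregated half-lives are residence
summaries and systematically differ from any single transitional rate.

## Synthetic data

The generator reproduces the study design: labeling at 15, 20, 30, 40,
60, 120 and 180 min with 2-4 replicates per time; nuclear, cytosolic,
membrane and whole-cell observations; replicate noise Gaussian on the
share scale, truncated to [0, 1], with a per-observable SD drawn lognormal
around the 0.06 floor (the SE distribution beyond the floor is not
specified by the reference analysis, so it is configuration, not
assertion); compartment abundances (0.3939, 0.1515, 0.4545) — the printed
0.39/0.15/0.45 normalized to sum exactly to one; ~19% membrane-localized
and ~5% undefined transcripts; 87% intron-containing genes with 2-8
quantified exons and lognormal lengths spanning under 12 kb to over 30 kb;
a ~6% subpopulation with nonzero nuclear decay. Ground-truth rates are
log-uniform over ranges whose implied half-lives match the observed
cohort medians (processing tens of minutes, nuclear retention up to
hours, cytosolic residence minutes for membrane-destined transcripts,
membrane stability tens of minutes); 4-step ratio draws respect the
enrichment class of the gene. Expression magnitudes are lognormal so both
the TPM >= 1.5 expressed-gene filter and the TPM > 50 abundance filter
are exercised.

Per-gene compartment TPMs are the model steady states scaled by the
expression magnitude and divided by the compartment's abundance factor (a
sequencing-depth convention making abundance-scaled ratios equal parameter
ratios exactly); whole-cell TPM is the factor-weighted mixture before
noise. Whole-cell labeling shares mix the mature compartments by
steady-state amounts; intronic whole-cell signal equals the pre-mRNA
share (pre-mRNA resides only in the nucleus). Read-level conversion
tables are simulated per read (`n ~ Poisson(40)` T positions, matching
75 bp paired-end reads) for EM validation. A linear labeling-efficiency
ramp is available but off by default; it mimics the known early-time
conversion-rate rise that the model otherwise ignores.

What passing synthetic tests does *not* show: the generator draws data
from the model family itself, so tests certify estimator correctness and
calibration — not robustness to misspecification (isoform mixtures,
compartment cross-contamination, position-dependent conversion rates,
UMI-less duplication noise) that real libraries carry.

## Problem sizes and numerical choices

The recovery and discrimination checks run on a 200-gene cohort with the
full 200-start protocol (about 0.5 s per gene for both decay variants);
the abundance Monte-Carlo uses 2,725 genes across 20 draws; the oracle
compares 100 random rate sets at 20 time points. Ties and degenerate
inputs: repeated exit rates route through the matrix-exponential branch;
a zero ratio SE widens the constraint to a 1e-6 relative band; a
nonpositive constraint lower bound is floored at a small positive value;
an all-zero mutation table pins `p_conv` at the background rate with the
fit flagged unconverged; exponential fits on non-monotone input return a
flagged result with its residual instead of raising.

## Known limitations

* Nuclear export vs decay is only interval-identified (see above); the
  reported `g2` SEs exclude the flat direction.
* Elongation rates for short genes are weakly identified by a 15-min
  first time point; boundary-limited estimates are flagged and excluded
  from elongation summaries.
* The cytosolic rate of membrane-localized transcripts is constrained
  mainly through the expression ratio, so its error is wider than for
  cytosol-localized genes.
* Aggregated inhibition-derived half-lives assume clean shutoff and no
  decay-machinery perturbation; the exponential fit carries no offset
  term.
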