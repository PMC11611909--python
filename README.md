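# rnaflow

Subcellular mRNA kinetics from metabolic-labeling (SLAM-seq) time series.

Bulk RNA half-lives hide where in the cell an mRNA spends its life. When
cells are labeled with 4-thiouridine and then fractionated into nuclear,
cytosolic and membrane (ER) compartments, the share of newly synthesized
mRNA in each compartment over labeling time traces the molecule's journey:
transcription, pre-mRNA processing, nuclear export (or decay), cytosolic
decay or transport to the membrane, and membrane decay. `rnaflow` turns
those share-new time courses into per-gene rate constants and derived
half-lives. It is written for computational biologists analyzing
subcellular metabolic-labeling experiments, and ships a synthetic-data
module that emulates the full experimental design so every stage can be
exercised and validated without sequencing data.

## Model

Each transcript follows a linear first-order cascade. In absolute amounts,

```
dx1/dt = p      - k1*x1                  nuclear pre-mRNA
dx2/dt = k1*x1  - (k2 + g2)*x2           nuclear mature mRNA
dx3/dt = k2*x2  - r3*x3                  cytosolic mRNA
dx4/dt = k3*x3  - g4*x4                  membrane-bound mRNA
```

with `r3 = g3` (cytosolic decay; 3-step model for cytosol-localized
transcripts) or `r3 = k3` (transport; 4-step model for membrane-localized
and undefined transcripts). Dividing by the steady states removes the
production rate `p` and leaves a relaxation cascade for the share of new
mRNA, whose stage-i solution is the hypoexponential CDF with exit rates
`(k1, k2+g2, r3, g4)` — evaluated in closed form by `rnaflow.model`.

Because sequencing covers full transcripts, sequences at distance `d` (kb)
from the 3' end are labeled only after `d/v` minutes (elongation rate `v`,
kb/min); every exon-level curve is evaluated at the delayed time
`t~ = max(0, t - d/v - delta)` with a global delay `delta = 5` min.

Fitting (per gene, `rnaflow.fitting`): weighted least squares in log10
parameter space from 200 random starts, with measured steady-state
expression ratios — TPMs made comparable across fractions by the
relative-abundance factors of `rnaflow.abundance` — constraining parameter
ratios such as `k3/g4` to plus/minus five standard errors. Out of the ten
lowest-chi2 solutions the one farthest from the parameter bounds is kept.
Nuclear decay `g2` is included only when it improves the BIC by more than
10 with `SE(g2) < g2`. Conversion of raw T2C counts into share-new values
(binomial-mixture EM) lives in `rnaflow.conversion`; aggregated pulse-chase
and transcription-inhibition half-lives in `rnaflow.halflives`.

## Worked example

```python
from rnaflow import (SimulationDesign, simulate_cohort, fit_relative_abundance,
                     FitConfig, fit_cohort)

bundle = simulate_cohort(20, seed=3)
e = bundle["expression"]
factors = fit_relative_abundance(
    e.tpm_nuc, e.tpm_cyto, e.tpm_mem, e.tpm_whole,
    e.se_nuc, e.se_cyto, e.se_mem, e.se_whole, min_whole_tpm=10)
print(f"abundance factors: nuc={factors.a_nuc:.3f} "
      f"cyto={factors.b_cyto:.3f} mem={factors.c_mem:.3f}")

fits, _ = fit_cohort(bundle["genes"], bundle["labeling"], bundle["expression"],
                     factors, cfg=FitConfig(seed=3), compare_decay=False)
row = fits.iloc[0]
print(f"{row.gene_id}: k2={row.k2:.4f}/min "
      f"nuclear half-life={row.halflife_nuclear:.1f} min "
      f"cytosolic half-life={row.halflife_cytosolic:.1f} min")
```

prints

```
abundance factors: nuc=0.386 cyto=0.186 mem=0.427
g00000: k2=0.0090/min nuclear half-life=76.8 min cytosolic half-life=28.7 min
```

The factors are the estimated shares of total cellular mRNA residing in
each fraction (the simulation's ground truth is 0.394/0.152/0.455, noisy
20-gene fit shown); `k2` is the gene's nuclear export rate, and the
half-lives are `ln 2` over the nuclear exit and cytosolic decay rates —
this gene's mRNA spends far longer in the nucleus than in the cytosol.

The same pipeline runs from the shell:

```
rnaflow run-all --seed 3 --outdir out --n-genes 50
rnaflow simulate --n-genes 100 --outdir sim   # tables for the fit command
```

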