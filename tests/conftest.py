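"""Shared fixtures: synthetic cohorts at the scales the checks need."""

import numpy as np
import pytest

from rnaflow.abundance import fit_relative_abundance
from rnaflow.fitting import FitConfig, fit_cohort
from rnaflow.synthetic import SimulationDesign, simulate_cohort


def _fit_factors(expression, min_whole_tpm=10.0):
    e = expression
    return fit_relative_abundance(
        e.tpm_nuc, e.tpm_cyto, e.tpm_mem, e.tpm_whole,
        e.se_nuc, e.se_cyto, e.se_mem, e.se_whole,
        min_whole_tpm=min_whole_tpm,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Ten genes with study-design noise; cheap enough for unit tests."""
    return simulate_cohort(10, seed=42)


@pytest.fixture(scope="session")
def small_cohort_factors(small_cohort):
    return _fit_factors(small_cohort["expression"])


@pytest.fixture(scope="session")
def recovery_cohort():
    """200 genes under the study design, fully fitted (null + extended).

    Shared by the parameter-recovery and decay-discrimination checks so the
    expensive multistart fits run once per session.
    """
    n_genes = 200
    seed = 7
    design = SimulationDesign(seed=seed)
    bundle = simulate_cohort(n_genes, seed, design)
    factors = _fit_factors(bundle["expression"])
    cfg = FitConfig(seed=seed, n_starts=200)
    fits, detail = fit_cohort(
        bundle["genes"], bundle["labeling"], bundle["expression"],
        factors, cfg=cfg, compare_decay=True,
    )
    return {"bundle": bundle, "factors": factors, "fits": fits,
            "detail": detail, "cfg": cfg}
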