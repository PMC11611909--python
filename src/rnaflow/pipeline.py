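"""End-to-end orchestration: tables in, per-gene rates and summaries out.

Stages run in a fixed order: expressed-gene filter (TPM >= 1.5 in at least
one fraction) -> abundance factors -> localization classes -> per-gene
multistart fits (null and extended) -> nuclear-decay model choice -> QC ->
derived half-lives -> cohort summary.  Every stage's output is written as
TSV next to a manifest recording the seed, package version and a config
hash, so a rerun with the same config is bit-identical.  Per-gene failures
are logged and skipped; they never abort the cohort.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import fit_relative_abundance
from .fitting import FitConfig, fit_cohort
from .halflives import fit_exponential_decay, model_derived_pulse_chase, summarize_cohort
from .model import GeneModel
from .synthetic import SimulationDesign, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "load_annotation"]

logger = logging.getLogger("rnaflow")

_LABELING_COLUMNS = {
    "gene_id", "region", "compartment", "d_kb", "time_min",
    "n_replicates", "share_mean", "share_se",
}
_EXPRESSION_COLUMNS = {
    "gene_id", "tpm_nuc", "se_nuc", "tpm_cyto", "se_cyto",
    "tpm_mem", "se_mem", "tpm_whole", "se_whole",
}
_ANNOTATION_COLUMNS = {
    "gene_id", "gene_length_kb", "exon_distances_kb", "has_introns",
}


@dataclass
class PipelineConfig:
    """Paths, thresholds and nested fit/simulation configuration."""

    outdir: str = "rnaflow_out"
    labeling_path: str | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    synthetic: bool = True
    n_genes: int = 50
    seed: int = 0
    expressed_gene_min_tpm: float = 1.5
    abundance_min_tpm: float = 50.0
    fit: FitConfig = field(default_factory=FitConfig)
    design: SimulationDesign = field(default_factory=SimulationDesign)
    compare_decay: bool = True
    n_jobs: int = 1
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit"] = asdict(self.fit)
        design = asdict(self.design)
        design["replicates_per_time"] = {
            str(k): v for k, v in design["replicates_per_time"].items()
        }
        d["design"] = design
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_inputs(
    labeling: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Schema and sanity report for the three input tables.

    Checks required columns, share values in [0, 1], nonnegative SEs and
    times, replicate counts >= 2, and distances within gene lengths.
    Returns ``{"ok": bool, "errors": [...], "warnings": [...]}`` with
    messages naming the offending column and rows.
    """
    errors, warnings = [], []

    def missing(df, required, name):
        miss = sorted(required - set(df.columns))
        for col in miss:
            errors.append(f"{name}: missing required column '{col}'")
        return bool(miss)

    if labeling is not None and not missing(labeling, _LABELING_COLUMNS, "labeling"):
        bad = labeling[(labeling.share_mean < 0) | (labeling.share_mean > 1)]
        if len(bad):
            errors.append(
                f"labeling: share_mean outside [0, 1] in rows {list(bad.index[:10])}"
            )
        if (labeling.share_se < 0).any():
            errors.append("labeling: negative share_se values")
        if (labeling.time_min <= 0).any():
            errors.append("labeling: nonpositive time_min values (units: minutes)")
        few = labeling[labeling.n_replicates < 2]
        if len(few):
            errors.append(
                f"labeling: n_replicates < 2 in rows {list(few.index[:10])}"
            )
        if labeling.time_min.max() > 1440:
            warnings.append("labeling: times exceed 24 h; are units minutes?")
    if expression is not None and not missing(
        expression, _EXPRESSION_COLUMNS, "expression"
    ):
        for col in ("tpm_nuc", "tpm_cyto", "tpm_mem", "tpm_whole"):
            if (expression[col] < 0).any():
                errors.append(f"expression: negative values in '{col}'")
    if annotation is not None and not missing(
        annotation, _ANNOTATION_COLUMNS, "annotation"
    ):
        if (annotation.gene_length_kb <= 0).any():
            errors.append("annotation: nonpositive gene_length_kb (units: kb)")
        if annotation.gene_length_kb.max() > 5000:
            warnings.append("annotation: gene lengths above 5000; are units kb?")
    return {"ok": not errors, "errors": errors, "warnings": warnings}


def load_annotation(annotation: pd.DataFrame) -> list[GeneModel]:
    """Gene models from the annotation table (distances as comma list)."""
    genes = []
    for _, row in annotation.iterrows():
        distances = tuple(
            float(x) for x in str(row.exon_distances_kb).split(",") if x != ""
        )
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                gene_length_kb=float(row.gene_length_kb),
                exon_distances_kb=distances,
                has_introns=bool(row.has_introns),
                localization=row.get("localization", "cytosol"),
            )
        )
    return genes


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    path = outdir / name
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    logger.info("wrote %s (%d rows)", path, len(df))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the result bundle also written to disk."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic:
        bundle = simulate_cohort(config.n_genes, config.seed, config.design)
        genes = bundle["genes"]
        labeling = bundle["labeling"]
        expression = bundle["expression"]
        annotation = bundle["annotation"]
        truth_rows = []
        for gid, p in bundle["truth"].items():
            truth_rows.append({"gene_id": gid, **p.to_dict()})
        truth = pd.DataFrame.from_records(truth_rows)
        _write(truth, outdir, "ground_truth.tsv")
    else:
        labeling = pd.read_csv(config.labeling_path, sep="\t")
        expression = pd.read_csv(config.expression_path, sep="\t")
        annotation = pd.read_csv(config.annotation_path, sep="\t")
        genes = load_annotation(annotation)
        truth = None

    report = validate_inputs(labeling, expression, annotation)
    if not report["ok"]:
        raise ValueError("input validation failed: " + "; ".join(report["errors"]))
    for w in report["warnings"]:
        logger.warning(w)

    # stage 1: expressed-gene filter
    tpm_cols = ["tpm_nuc", "tpm_cyto", "tpm_mem"]
    expressed = expression[
        (expression[tpm_cols] >= config.expressed_gene_min_tpm).any(axis=1)
    ]
    logger.info("expressed genes: %d / %d", len(expressed), len(expression))
    if len(expressed) == 0:
        logger.warning("no genes pass the expressed-gene TPM filter")
        empty = pd.DataFrame()
        _write(empty, outdir, "fits.tsv")
        _write(empty, outdir, "summary.tsv")
        manifest = {
            "version": __version__, "seed": config.seed,
            "config_hash": config.config_hash(), "n_genes": 0,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return {"fits": empty, "summary": empty, "manifest": manifest}

    # stage 2: abundance factors; small cohorts may not have 3 genes above
    # the high-expression cutoff, in which case all expressed genes are used
    abundance_min = config.abundance_min_tpm
    if (expressed.tpm_whole > abundance_min).sum() < 3:
        logger.warning(
            "fewer than 3 genes above whole-cell TPM %.3g; "
            "using all expressed genes for the abundance fit", abundance_min,
        )
        abundance_min = 0.0
    factors = fit_relative_abundance(
        expressed.tpm_nuc, expressed.tpm_cyto, expressed.tpm_mem,
        expressed.tpm_whole,
        expressed.se_nuc, expressed.se_cyto, expressed.se_mem,
        expressed.se_whole,
        min_whole_tpm=abundance_min,
    )
    _write(
        pd.DataFrame.from_records([{
            "a_nuc": factors.a_nuc, "b_cyto": factors.b_cyto,
            "c_mem": factors.c_mem, "se_a": factors.se_a,
            "se_b": factors.se_b, "se_c": factors.se_c,
        }]),
        outdir, "abundance_factors.tsv",
    )

    # stages 3-6: localization, fits, decay choice, QC
    keep_ids = set(expressed.gene_id)
    genes_kept = [g for g in genes if g.gene_id in keep_ids]
    fits, detail = fit_cohort(
        genes_kept, labeling, expressed, factors,
        cfg=config.fit, compare_decay=config.compare_decay,
        n_jobs=config.n_jobs,
    )
    _write(fits, outdir, "fits.tsv")

    # stage 7: derived whole-cell half-lives from the chosen models
    derived_rows = []
    chase_times = np.linspace(0.0, 600.0, 25)
    for gid, fitter in detail.items():
        res = fitter.result_
        if not res.qc_pass or res.params is None:
            continue
        curves = model_derived_pulse_chase(res.params, factors, chase_times)
        for comp, sub in curves.groupby("compartment"):
            fit = fit_exponential_decay(
                sub.time_min, sub.share_old, mode="share_old", compartment=comp
            )
            derived_rows.append({
                "gene_id": gid, "compartment": comp,
                "half_life_min": fit.half_life_min, "rate": fit.rate,
                "fit_residual": fit.fit_residual,
            })
    derived = pd.DataFrame.from_records(derived_rows)
    _write(derived, outdir, "derived_halflives.tsv")

    # stage 8: cohort summary
    summary = summarize_cohort(fits)
    _write(summary, outdir, "summary.tsv")

    # recovery report when ground truth is available
    recovery = None
    if truth is not None and len(fits) and "k2" in fits.columns:
        recovery = fits.merge(truth, on="gene_id", suffixes=("_fit", "_true"))
        _write(recovery, outdir, "recovery.tsv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_genes": int(len(genes_kept)),
        "n_qc_pass": int(fits.get("qc_pass", pd.Series(dtype=bool)).sum())
        if len(fits) else 0,
        "abundance_factors": [factors.a_nuc, factors.b_cyto, factors.c_mem],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "fits": fits, "detail": detail, "factors": factors,
        "derived": derived, "summary": summary, "manifest": manifest,
        "recovery": recovery,
    }
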