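"""End-to-end orchestration: simulate -> tile -> count -> QC -> filter ->
differential expression -> annotate -> reference screen -> qPCR ->
diagnostic models -> cross-validation.

Each stage writes plain-text outputs into the run directory and the run is
summarized by a JSON manifest (package/library versions, every parameter,
input digests, seed), so two runs with equal manifests produce equal
outputs. All randomness flows from one top-level seed, split per stage
deterministically by the generator config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import __version__
from .classify import ModelSpec, cross_validate, diagnostic_report
from .diffexpr import differential_expression, log_transform, pca
from .qc import apply_exclusion, sample_cv
from .qpcr import average_ct, log_predictor, relative_expression
from .refscreen import screen_reference_regions
from .regions import compute_tpm, count_matrix, filter_expressed, tile_genome
from .simulate import SimulationConfig, simulate_all

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_SCHEMA = {
    "seed": int,
    "outdir": str,
    "simulate": dict,
    "qc": dict,
    "filter": dict,
    "de": dict,
    "refscreen": dict,
    "classify": dict,
    "crossval": dict,
}
_SUBKEYS = {
    "qc": {"tile_size", "cv_threshold"},
    "filter": {"min_reads", "min_fraction"},
    "de": {"fdr"},
    "refscreen": {"run_length", "min_mean_percentile"},
    "classify": {"n_genes", "risk_factors", "threshold"},
    "crossval": {"folds", "repeats", "min_case", "min_control"},
}


class PipelineConfig(dict):
    """Validated pipeline configuration (YAML-loadable)."""

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        import yaml

        if not os.path.exists(path):
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.validate(raw)

    @classmethod
    def validate(cls, raw: dict) -> "PipelineConfig":
        for key, val in raw.items():
            if key not in _SCHEMA:
                raise ValueError(f"unknown config field: {key}")
            if not isinstance(val, _SCHEMA[key]):
                raise ValueError(
                    f"config field {key}: expected "
                    f"{_SCHEMA[key].__name__}, got {type(val).__name__}")
            if key in _SUBKEYS:
                bad = set(val) - _SUBKEYS[key]
                if bad:
                    raise ValueError(f"config field {key}.{sorted(bad)[0]}: "
                                     f"unknown")
        return cls(raw)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def run_pipeline(config, outdir=None, quiet: bool = False) -> dict:
    """Run every stage on a synthetic dataset; returns the result bundle.

    ``config`` is a PipelineConfig, a plain dict, or a path to a YAML
    file. Outputs (TSV/BED/JSON) land in ``outdir`` (or config's outdir,
    default ``uroev_run``); a manifest records seed, parameters and
    digests of the generated inputs.
    """
    if isinstance(config, (str, os.PathLike)):
        config = PipelineConfig.load(config)
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.validate(dict(config))
    if not quiet:
        logging.basicConfig(level=logging.INFO,
                            format="[uroev %(name)s] %(message)s")
    outdir = outdir or config.get("outdir", "uroev_run")
    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))

    # -- simulate ----------------------------------------------------------
    sim_cfg = SimulationConfig(**{"seed": seed, **config.get("simulate", {})})
    logger.info("simulate: cohort %d/%d, %d contigs x %d bp",
                sim_cfg.n_case, sim_cfg.n_control, sim_cfg.n_contigs,
                sim_cfg.contig_length)
    art = simulate_all(sim_cfg)
    sheet, grid, reads = art["sheet"], art["grid"], art["reads"]

    # -- count from read placements ---------------------------------------
    logger.info("count: %d regions x %d samples (start mode)",
                grid.n_regions, len(sheet))
    counts = count_matrix(grid, reads.values(), mode="start")

    # -- sample QC ---------------------------------------------------------
    qc_cfg = config.get("qc", {})
    tile_size = qc_cfg.get("tile_size") or sim_cfg.contig_length // 50
    cv_threshold = qc_cfg.get("cv_threshold", 0.5)
    cvs = {s: sample_cv(rs, grid.index, tile_size=tile_size).cv
           for s, rs in reads.items()}
    retained, excluded, qc_report = apply_exclusion(
        sheet, cvs, cv_threshold=cv_threshold)
    qc_report.to_csv(os.path.join(outdir, "qc_report.tsv"), sep="\t",
                     index=False)
    logger.info("qc: %d retained, %d excluded (CV < %g with DNA)",
                len(retained), len(excluded), cv_threshold)
    disc_sheet = sheet.subset(retained)
    disc_counts = counts.counts[retained]
    from .regions import RegionCountMatrix
    disc = RegionCountMatrix(regions=counts.regions, counts=disc_counts,
                             counting_mode=counts.counting_mode)

    # -- expression-evidence filter ---------------------------------------
    f_cfg = config.get("filter", {})
    filtered = filter_expressed(disc,
                                min_reads=f_cfg.get("min_reads", 5),
                                min_fraction=f_cfg.get("min_fraction", 0.20))
    logger.info("filter: %d of %d regions expressed", filtered.shape[0],
                disc.shape[0])

    # -- cohort structure (PCA on log2 TPM) --------------------------------
    tpm = compute_tpm(filtered)
    logtpm = log_transform(tpm)
    scores, _, var_exp = pca(logtpm, n_components=min(5, len(retained) - 1))
    scores.assign(group=disc_sheet.rows.set_index("sample_id")["group"],
                  gender=disc_sheet.rows.set_index("sample_id")["gender"]
                  ).to_csv(os.path.join(outdir, "pca_scores.tsv"), sep="\t")

    # -- differential region expression ------------------------------------
    de = differential_expression(filtered, disc_sheet,
                                 annotation=art["annotation"])
    fdr = config.get("de", {}).get("fdr", 0.05)
    de.result.to_csv(os.path.join(outdir, "de_results.tsv"), sep="\t")
    sig = de.result[de.result["p_adjusted"] < fdr]
    logger.info("de: %d regions significant at FDR < %g", len(sig), fdr)

    # -- reference-gene screen ---------------------------------------------
    r_cfg = config.get("refscreen", {})
    ref = screen_reference_regions(
        tpm, art["annotation"], run_length=r_cfg.get("run_length", 2),
        min_mean_percentile=r_cfg.get("min_mean_percentile", 90))
    ref.drop(columns=["region_keys"]).to_csv(
        os.path.join(outdir, "reference_candidates.tsv"), sep="\t",
        index=False)

    # -- qPCR quantification ------------------------------------------------
    mean_ct = average_ct(art["ct_table"])
    levels = relative_expression(mean_ct, art["refmap"])
    predictors = log_predictor(levels)
    predictors.to_csv(os.path.join(outdir, "qpcr_predictors.tsv"), sep="\t")

    # -- diagnostic models + CV (on the full cohort, as validation) --------
    c_cfg = config.get("classify", {})
    # rank marker assays by DE significance of their regions
    sig_regions = [k for k in sig.index
                   if k in set(art["truth"].marker_region_ids)]
    name_of = dict(zip(art["truth"].marker_region_ids,
                       art["truth"].marker_gene_names))
    ranked = []
    for k in sig_regions:
        g = name_of[k]
        if g not in ranked and g in predictors.columns:
            ranked.append(g)
    if not ranked:
        ranked = list(predictors.columns)
    n_genes = c_cfg.get("n_genes", 1)
    risk_factors = tuple(c_cfg.get("risk_factors",
                                   ["obesity", "hypertension"]))
    # try candidate panels in DE rank order; a separated fit is reported
    # and the next candidate panel is used
    report = None
    for start in range(max(len(ranked) - n_genes + 1, 1)):
        genes = tuple(ranked[start:start + n_genes]) or tuple(ranked[:1])
        spec = ModelSpec(gene_predictors=genes, risk_factors=risk_factors)
        try:
            report = diagnostic_report(spec, predictors, sheet,
                                       threshold=c_cfg.get("threshold", 0.5))
            break
        except ValueError as e:
            logger.warning("model %s skipped: %s", "+".join(genes), e)
    if report is None:
        raise RuntimeError("no candidate diagnostic model converged")
    pd.DataFrame([{
        "genes": "+".join(genes), "risk_factors": "+".join(spec.risk_factors),
        "sensitivity": report.sensitivity, "specificity": report.specificity,
        "accuracy": report.accuracy, "auc": report.auc,
        "p_model": report.p_model,
    }]).to_csv(os.path.join(outdir, "model_report.tsv"), sep="\t",
               index=False)
    report.or_iqr.to_csv(os.path.join(outdir, "odds_ratios.tsv"), sep="\t")
    report.roc_points.to_csv(os.path.join(outdir, "roc_points.tsv"),
                             sep="\t", index=False)
    logger.info("classify: %s -> accuracy %.3f, AUC %.3f", "+".join(genes),
                report.accuracy, report.auc)

    cv_cfg = config.get("crossval", {})
    n_folds = cv_cfg.get("folds", 5)
    cv = cross_validate(
        spec, predictors, sheet, n_folds=n_folds,
        n_repeats=cv_cfg.get("repeats", 100),
        min_per_fold={"case": cv_cfg.get("min_case", 10),
                      "control": cv_cfg.get("min_control", 4)},
        seed=seed)
    cv.summary.to_csv(os.path.join(outdir, "cv_summary.tsv"), sep="\t")
    logger.info("crossval: mean accuracy %.3f (sd %.3f) over %d repeats",
                cv.summary.loc["accuracy", "mean"],
                cv.summary.loc["accuracy", "sd"], cv.n_repeats)

    # -- manifest -----------------------------------------------------------
    manifest = {
        "uroev_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "parameters": {
            "simulate": asdict(sim_cfg),
            "qc": {"tile_size": tile_size, "cv_threshold": cv_threshold},
            "filter": {"min_reads": f_cfg.get("min_reads", 5),
                       "min_fraction": f_cfg.get("min_fraction", 0.20)},
            "de": {"fdr": fdr},
            "refscreen": dict(r_cfg),
            "classify": {"genes": list(genes),
                         "risk_factors": list(spec.risk_factors)},
            "crossval": {"folds": n_folds,
                         "repeats": cv_cfg.get("repeats", 100)},
        },
        "outputs": {},
    }
    for name in sorted(os.listdir(outdir)):
        path = os.path.join(outdir, name)
        if os.path.isfile(path) and name != "manifest.json":
            manifest["outputs"][name] = _digest(path)
    with open(os.path.join(outdir, "manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return {
        "sheet": sheet, "counts": counts, "qc_report": qc_report,
        "retained": retained, "excluded": excluded, "filtered": filtered,
        "tpm": tpm, "pca_scores": scores, "pca_var": var_exp, "de": de,
        "significant": sig, "reference_candidates": ref,
        "predictors": predictors, "model_report": report, "cv": cv,
        "truth": art["truth"], "manifest": manifest,
    }
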