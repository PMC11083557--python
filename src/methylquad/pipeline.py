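"""End-to-end orchestration: one config in, a manifest of outputs out.

Stage order: ROI annotation -> ams scoring + 0-1 scaling -> per-subtype
differential methylation -> context composition & subtype specificity
-> expression quadrant integration -> candidate screen -> composite-
risk survival stratification.  Every output file is recorded in a
manifest with a content checksum; rerunning with the same config and
seed reproduces the checksums bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, differential, integration, scoring, survival
from .errors import ConfigError, DataError
from .simulate import SimulationConfig, SimulatedCohort, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs (file paths or a simulation block) plus all thresholds."""

    outdir: str = "methylquad_out"
    simulation: SimulationConfig | None = None
    inputs: dict[str, str] | None = None  # counts, samples, expression, clinical,
    # genes, cgis, library_sizes
    delta_threshold: float = 0.2
    p_threshold: float = 0.05
    gate: str = "p"
    fc_threshold_log2: float = math.log2(1.2)
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    cgi_min_overlap: int = 1
    cpg_correction: bool = True
    cpg_pseudocount: float = 1.0
    target_subtype: str = "TNBC"
    meth_margin: float = 0.05
    expr_margin: float = 0.5
    quantile_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.inputs is None:
            raise ConfigError("config needs either a simulation block or input paths")
        if not 0 < self.delta_threshold < 1:
            raise ConfigError("delta_threshold must lie in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must lie in (0, 1)")
        if self.fc_threshold_log2 < 0:
            raise ConfigError("fc_threshold_log2 must be >= 0")
        lo, hi = self.quantile_range
        if not 0 <= lo < hi <= 1:
            raise ConfigError("quantile_range must satisfy 0 <= lo < hi <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "subtypes" in sim:
                sim["subtypes"] = tuple(sim["subtypes"])
            sim = SimulationConfig(**sim)
        if "quantile_range" in raw:
            raw["quantile_range"] = tuple(raw["quantile_range"])
        try:
            return cls(simulation=sim, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad pipeline config: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    paths = cfg.inputs
    required = ["counts", "samples", "expression", "clinical", "genes", "cgis",
                "library_sizes"]
    missing = [k for k in required if k not in paths]
    if missing:
        raise ConfigError(f"input paths missing: {missing}")
    samples = scoring.read_sample_metadata(paths["samples"])
    counts = pd.read_csv(paths["counts"], sep="\t", index_col=0)
    expression = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    clinical = survival.read_clinical_tsv(paths["clinical"])
    genes = annotation.read_gene_models(paths["genes"])
    cgis = annotation.read_cgi_bed(paths["cgis"])
    library_sizes = pd.read_csv(paths["library_sizes"], sep="\t", index_col=0).iloc[:, 0]
    return counts, samples, expression, clinical, genes, cgis, library_sizes


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; return the manifest (also written to disk)."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    stage_log: dict[str, dict] = {}

    def emit(name: str, path: Path) -> None:
        files[name] = path

    try:
        stage = "inputs"
        if cfg.simulation is not None:
            sim_cfg = cfg.simulation
            if sim_cfg.seed != cfg.seed:
                sim_cfg = SimulationConfig(**{**asdict(sim_cfg), "seed": cfg.seed})
            cohort = simulate_cohort(sim_cfg)
            sim_paths = write_cohort(cohort, outdir / "simulated")
            for k, p in sim_paths.items():
                emit(f"simulated_{k}", p)
            counts, samples = cohort.counts, cohort.samples
            expression, clinical = cohort.expression, cohort.clinical
            genes, cgis = cohort.genes, cohort.cgis
            library_sizes = cohort.library_sizes
        else:
            counts, samples, expression, clinical, genes, cgis, library_sizes = (
                _load_inputs(cfg)
            )

        stage = "roi_annotation"
        rois = annotation.build_rois(
            genes, cfg.promoter_upstream, cfg.promoter_downstream
        )
        rois = annotation.classify_cgi(rois, cgis, cfg.cgi_min_overlap)
        roi_info = annotation.rois_to_frame(rois)
        missing_counts = roi_info.index.difference(counts.index)
        if len(missing_counts):
            raise DataError(f"count matrix missing ROIs: {list(missing_counts[:5])}...")
        counts = counts.loc[roi_info.index]
        annotation.write_rois_bed(rois, outdir / "rois.bed")
        emit("rois", outdir / "rois.bed")
        if cfg.simulation is not None:
            roi_info = roi_info.assign(
                cpg_count=cohort.roi_info["cpg_count"].reindex(roi_info.index)
            )
        cpg_counts = _cpg_counts(cfg, roi_info, counts)
        logger.info("roi_annotation: %d genes, %d ROIs", len(genes), len(rois))
        stage_log["roi_annotation"] = {"n_genes": len(genes), "n_rois": len(rois)}

        stage = "methylome_scoring"
        ams = scoring.compute_ams(
            counts,
            roi_info["length"],
            library_sizes,
            samples,
            cpg_counts=cpg_counts,
            cpg_pseudocount=cfg.cpg_pseudocount,
            cpg_correction=cfg.cpg_correction,
        )
        scaled = scoring.scale_per_region_class(ams)
        scoring.write_matrix_tsv(scaled, outdir / "scaled_ams.tsv")
        emit("scaled_ams", outdir / "scaled_ams.tsv")

        stage = "differential_methylation"
        subtypes = list(dict.fromkeys(samples["subtype"]))
        dmr_tables: dict[str, pd.DataFrame] = {}
        gene_calls: dict[str, dict[str, set[str]]] = {}
        for s in subtypes:
            table = differential.call_dmrs(
                scaled, s, cfg.delta_threshold, cfg.p_threshold, cfg.gate
            )
            dmr_tables[s] = table
            gene_calls[s] = differential.gene_level_calls(table)
            path = outdir / f"dmr_{s}.tsv"
            table.rename_axis("roi").to_csv(path, sep="\t", float_format="%.6g")
            emit(f"dmr_{s}", path)
            stage_log[f"dmr_{s}"] = {
                "hyper": len(gene_calls[s][differential.HYPER]),
                "hypo": len(gene_calls[s][differential.HYPO]),
            }
            logger.info(
                "differential %s: %d hyper / %d hypo genes", s,
                len(gene_calls[s][differential.HYPER]),
                len(gene_calls[s][differential.HYPO]),
            )
        target = cfg.target_subtype
        if target not in dmr_tables:
            raise DataError(f"target subtype {target!r} absent from cohort")
        composition = differential.context_composition(dmr_tables[target], roi_info)
        with open(outdir / "context_composition.json", "w") as fh:
            json.dump(composition, fh, indent=1, sort_keys=True)
        emit("context_composition", outdir / "context_composition.json")

        stage = "integration"
        specificity = {
            d: integration.subtype_specific_sets({s: gene_calls[s][d] for s in subtypes})
            for d in (differential.HYPER, differential.HYPO)
        }
        with open(outdir / "specificity_sets.json", "w") as fh:
            json.dump({d: v.to_jsonable() for d, v in specificity.items()},
                      fh, indent=1, sort_keys=True)
        emit("specificity_sets", outdir / "specificity_sets.json")

        expr_diff = integration.expression_differential(expression, samples, target)
        quadrants = integration.assign_quadrants(
            gene_calls[target], expr_diff, cfg.fc_threshold_log2
        )
        quadrants.to_csv(outdir / "quadrants.tsv", sep="\t", index=False,
                         float_format="%.6g")
        emit("quadrants", outdir / "quadrants.tsv")
        stage_log["quadrants"] = (
            quadrants["quadrant"].value_counts().to_dict()
        )

        # restrict the screen to target-specific quadrant genes
        specific_union = (
            specificity[differential.HYPER].specific.get(target, set())
            | specificity[differential.HYPO].specific.get(target, set())
        )
        screen_input = quadrants[quadrants["gene_id"].isin(specific_union)]
        candidates = integration.candidate_screen(
            screen_input, scaled, expression, samples, target,
            cfg.meth_margin, cfg.expr_margin,
        )
        candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False,
                          float_format="%.6g")
        emit("candidates", outdir / "candidates.tsv")
        stage_log["candidates"] = {"n_pass": int(candidates["passes"].sum())}

        stage = "survival_analysis"
        survival_report = _survival_stage(
            cfg, outdir, candidates, scaled, expression, samples, clinical, emit
        )
        stage_log["survival"] = survival_report

    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs retained", stage)
        raise

    manifest = {
        "seed": cfg.seed,
        "stages": stage_log,
        "files": {
            name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for name, p in sorted(files.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _cpg_counts(cfg: PipelineConfig, roi_info: pd.DataFrame, counts: pd.DataFrame):
    if not cfg.cpg_correction:
        return None
    if "cpg_count" in roi_info.columns:
        return roi_info["cpg_count"]
    if cfg.inputs and "cpg_counts" in cfg.inputs:
        return pd.read_csv(cfg.inputs["cpg_counts"], sep="\t", index_col=0).iloc[:, 0]
    # without a CpG table the correction factor is flat (RPKM-like score)
    logger.warning("no CpG counts available; ams computed with a flat CpG factor")
    return pd.Series(0.0, index=counts.index)


def _survival_stage(cfg, outdir, candidates, scaled, expression, samples, clinical, emit):
    """Composite-risk stratification on the best candidate with survival data.

    Candidates are tried in rank order; a candidate is usable when the
    clinical table carries per-subject assay columns for it
    (``meth_<gene>``/``expr_<gene>``, validation-cohort mode) or when
    every clinical subject appears in the cohort matrices.
    """
    passing = candidates[candidates["passes"]]
    if passing.empty:
        logger.info("survival: no passing candidates; stage skipped")
        return {"skipped": "no passing candidates"}

    subjects = clinical.index
    gene = rule = meth_vals = expr_vals = None
    for top in passing.itertuples(index=False):
        meth_col, expr_col = f"meth_{top.gene_id}", f"expr_{top.gene_id}"
        if {meth_col, expr_col} <= set(clinical.columns):
            meth_vals, expr_vals = clinical[meth_col], clinical[expr_col]
        elif subjects.isin(scaled.values.columns).all():
            keys = [k for k in scaled.values.index if k.startswith(f"{top.gene_id}|")]
            # prefer the CDS region when both exist (gene-body marker convention)
            key = next((k for k in keys if k.endswith("|CDS")), keys[0])
            meth_vals = scaled.values.loc[key, subjects]
            expr_vals = expression.loc[top.gene_id, subjects]
        else:
            logger.info("survival: no assay data for candidate %s", top.gene_id)
            continue
        gene = top.gene_id
        meth_dir, expr_dir = top.quadrant.split("_")
        rule = survival.RiskRule(gene, meth_dir, "high" if expr_dir == "up" else "low")
        break
    if gene is None:
        logger.warning("survival: no candidate with usable survival data; skipped")
        return {"skipped": "no candidate with survival data"}
    meth_labels = survival.median_split(meth_vals)
    expr_labels = survival.median_split(expr_vals)
    risk = survival.composite_risk(meth_labels, expr_labels, rule)

    times = clinical["time"].to_numpy()
    events = clinical["event"].to_numpy()
    chi2, p = survival.logrank_test(times, events, risk.to_numpy())
    curves = {}
    for label in (survival.HIGH_RISK, survival.LOW_RISK):
        mask = (risk == label).to_numpy()
        curve = survival.km_estimate(times[mask], events[mask])
        path = outdir / f"km_{label}.tsv"
        curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
        emit(f"km_{label}", path)
        curves[label] = int(mask.sum())

    report = {
        "marker_gene": gene,
        "rule": asdict(rule),
        "n_high_risk": curves[survival.HIGH_RISK],
        "n_low_risk": curves[survival.LOW_RISK],
        "logrank_chi2": chi2,
        "logrank_p": p,
    }
    risk.rename("risk").rename_axis("subject").to_frame().to_csv(
        outdir / "risk_groups.tsv", sep="\t"
    )
    emit("risk_groups", outdir / "risk_groups.tsv")
    with open(outdir / "survival_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    emit("survival_report", outdir / "survival_report.json")
    return report
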