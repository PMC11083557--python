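"""Synthetic paired tumor/normal cohorts with planted methylation truth.

The generator emulates the statistical structure of an MBD-seq breast
cancer cohort: four intrinsic subtypes (LumA, LumB, HER2, TNBC), each
with matched tumor/normal pairs; over-dispersed ROI read counts whose
mean tracks a latent per-region methylation fraction; log2 expression
anti-/co-varying with methylation for a configurable subset of planted
genes; exponential survival whose hazard depends on a planted marker's
joint methylation/expression state; and two-peak -dF/dT melting curves
for the HRM calibration stage.

Planted truth (which genes are hyper/hypo in which subtype, which are
expression-coupled, which subjects are high risk) is returned alongside
the data so every downstream stage can be scored for recovery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    CDS,
    CGI,
    PROMOTER,
    GeneModel,
    ROIRecord,
    build_rois,
    classify_cgi,
    rois_to_frame,
    write_cgi_bed,
    write_gene_models,
    write_rois_bed,
)
from .errors import ConfigError, DataError
from .hrm import MeltingCurve
from .scoring import NORMAL, TUMOR
from .survival import HIGH, HIGH_RISK, LOW, LOW_RISK, RiskRule

logger = logging.getLogger(__name__)

DEFAULT_SUBTYPES = ("LumA", "LumB", "HER2", "TNBC")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Planted counts are per subtype; ``n_shared`` genes are additionally
    planted in every subtype (direction ``shared_direction``).
    ``effect_size`` is the shift of the latent methylation fraction in
    planted tumors relative to their matched normals, on the 0-1 scale.
    """

    n_genes: int = 500
    n_pairs_per_subtype: int = 10
    subtypes: tuple[str, ...] = DEFAULT_SUBTYPES
    n_planted_hyper: int = 15
    n_planted_hypo: int = 15
    n_shared: int = 5
    shared_direction: str = "hypo"
    effect_size: float = 0.3
    dispersion: float = 200.0  # negative-binomial size; variance = mu + mu^2/size.
    # Biological pair-to-pair variability lives in latent_sd; the NB size
    # captures residual technical overdispersion (~2-3x Poisson at typical depth).
    expr_effect: float = 1.0  # log2 shift for integrated planted genes
    integrated_fraction: float = 0.6  # fraction of planted genes coupled to expression
    marker_expr_boost: float = 1.5  # the designated marker carries the strongest
    # subtype-specific expression pattern (multiplies expr_effect for that gene)
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.05
    censoring_rate: float = 0.3
    n_clinical_subjects: int = 200  # survival validation cohort (distinct patients,
    # assayed for the marker only -- mirrors validating prognosis in a large
    # external cohort rather than in the small discovery cohort)
    seed: int = 0
    # nuisance parameters of the generative model
    planted_region: str = CDS
    base_depth: float = 120.0  # expected reads at latent fraction 1, reference length/CpG
    latent_sd: float = 0.05  # biological jitter of latent fractions
    expr_mean: float = 8.0
    expr_gene_sd: float = 1.5
    expr_noise_sd: float = 0.3
    depth_sd: float = 0.1  # log-scale per-sample depth variation
    cgi_promoter_rate: float = 0.35
    cgi_cds_rate: float = 0.15

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_pairs_per_subtype <= 0:
            raise ConfigError("n_genes and n_pairs_per_subtype must be positive")
        if len(self.subtypes) < 1:
            raise ConfigError("need at least one subtype")
        if min(self.n_planted_hyper, self.n_planted_hypo, self.n_shared) < 0:
            raise ConfigError("planted counts must be non-negative")
        total = len(self.subtypes) * (self.n_planted_hyper + self.n_planted_hypo) + self.n_shared
        if total > self.n_genes:
            raise ConfigError(
                f"planted genes ({total}) exceed n_genes ({self.n_genes}): "
                "violates n_planted_hyper + n_planted_hypo + n_shared <= n_genes"
            )
        if not 0.0 <= self.effect_size < 1.0:
            raise ConfigError("effect_size must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigError("censoring_rate must lie in [0, 1)")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.shared_direction not in ("hyper", "hypo"):
            raise ConfigError("shared_direction must be 'hyper' or 'hypo'")
        if self.planted_region not in (PROMOTER, CDS):
            raise ConfigError("planted_region must be 'promoter' or 'CDS'")


@dataclass
class PlantedTruth:
    """Ground truth of the simulation, for downstream scoring.

    ``hyper``/``hypo`` map subtype -> subtype-specific planted gene
    sets; ``shared`` genes are planted in all subtypes.  ``coupling``
    maps each planted gene to its expression direction ('up' for
    hypomethylated-and-upregulated, 'down', or 'none').  The latent
    fraction matrices are diagnostics for verifying the generator.
    """

    hyper: dict[str, set[str]]
    hypo: dict[str, set[str]]
    shared: set[str]
    shared_direction: str
    coupling: dict[str, str]
    marker_gene: str | None
    risk_rule: RiskRule | None
    high_risk_subjects: set[str]
    latent_normal: pd.DataFrame = field(repr=False, default=None)
    latent_tumor: pd.DataFrame = field(repr=False, default=None)

    def planted_direction(self, gene: str, subtype: str) -> str | None:
        """'hyper', 'hypo' or None for a gene in a given subtype."""
        if gene in self.shared:
            return self.shared_direction
        if gene in self.hyper.get(subtype, set()):
            return "hyper"
        if gene in self.hypo.get(subtype, set()):
            return "hypo"
        return None

    def to_jsonable(self) -> dict:
        return {
            "hyper": {s: sorted(g) for s, g in self.hyper.items()},
            "hypo": {s: sorted(g) for s, g in self.hypo.items()},
            "shared": sorted(self.shared),
            "shared_direction": self.shared_direction,
            "coupling": dict(sorted(self.coupling.items())),
            "marker_gene": self.marker_gene,
            "risk_rule": asdict(self.risk_rule) if self.risk_rule else None,
            "high_risk_subjects": sorted(self.high_risk_subjects),
        }


@dataclass
class SimulatedCohort:
    """Everything one pipeline run consumes, plus the planted truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    cgis: list[tuple[str, int, int]]
    rois: list[ROIRecord]
    roi_info: pd.DataFrame
    counts: pd.DataFrame
    library_sizes: pd.Series
    expression: pd.DataFrame
    samples: pd.DataFrame
    clinical: pd.DataFrame
    truth: PlantedTruth


def _make_annotation(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay genes on a synthetic chromosome and sprinkle CpG islands."""
    genes, cgis = [], []
    for i in range(cfg.n_genes):
        g0 = 10_000 + i * 10_000
        gene_id = f"G{i + 1:04d}"
        if i % 2 == 0:
            strand, tss = "+", g0 + 2000
            cds_start, cds_end = tss + 500, tss + 2500
        else:
            strand, tss = "-", g0 + 3000
            cds_start, cds_end = tss - 2500, tss - 500
        genes.append(GeneModel(gene_id, "chr1", strand, tss, cds_start, cds_end))
        sign = 1 if strand == "+" else -1
        if rng.random() < cfg.cgi_promoter_rate:
            a, b = tss - sign * 800, tss + sign * 200
            cgis.append(("chr1", min(a, b), max(a, b)))
        if rng.random() < cfg.cgi_cds_rate:
            mid = (cds_start + cds_end) // 2
            cgis.append(("chr1", mid - 400, mid + 400))
    return genes, sorted(cgis)


def _plant_genes(cfg: SimulationConfig, rng: np.random.Generator):
    """Disjoint subtype-specific and shared planted gene sets."""
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    order = rng.permutation(cfg.n_genes)
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        picked = [gene_ids[j] for j in order[cursor : cursor + n]]
        cursor += n
        return picked

    shared = take(cfg.n_shared)
    hyper = {s: take(cfg.n_planted_hyper) for s in cfg.subtypes}
    hypo = {s: take(cfg.n_planted_hypo) for s in cfg.subtypes}
    return shared, hyper, hypo


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate one paired cohort with planted truth.

    Counts are negative-binomial around a mean proportional to
    library depth x latent methylation fraction x ROI length x relative
    CpG density, so the ams/scaling stages recover the latent fraction
    up to a per-sample monotone transform.  Identical config (including
    seed) reproduces bitwise-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    genes, cgis = _make_annotation(cfg, rng)
    rois = classify_cgi(build_rois(genes), cgis)
    roi_info = rois_to_frame(rois)
    n_roi = len(rois)

    # CpG content per ROI, denser inside islands
    is_cgi = (roi_info["cgi_class"] == CGI).to_numpy()
    cpg = np.where(is_cgi, rng.poisson(60, n_roi) + 20, rng.poisson(8, n_roi) + 2)
    roi_info = roi_info.assign(cpg_count=cpg)

    shared, hyper, hypo = _plant_genes(cfg, rng)

    # baseline latent fractions; planted regions get headroom for the shift
    base = rng.beta(0.7, 0.7, n_roi) * 0.9 + 0.05
    gene_of = roi_info["gene_id"].to_numpy()
    region_of = roi_info["region_class"].to_numpy()
    key_index = roi_info.index

    def planted_rows(gene_set) -> np.ndarray:
        return np.isin(gene_of, list(gene_set)) & (region_of == cfg.planted_region)

    hypo_genes_all = set(shared if cfg.shared_direction == "hypo" else [])
    hyper_genes_all = set(shared if cfg.shared_direction == "hyper" else [])
    for s in cfg.subtypes:
        hypo_genes_all |= set(hypo[s])
        hyper_genes_all |= set(hyper[s])
    lo = min(cfg.effect_size + 0.25, 0.88)
    rows = planted_rows(hypo_genes_all)
    base[rows] = rng.uniform(lo, 0.9, rows.sum())
    hi = max(0.75 - cfg.effect_size, 0.12)
    rows = planted_rows(hyper_genes_all)
    base[rows] = rng.uniform(0.1, hi, rows.sum())

    # samples: one tumor + one matched normal per pair per subtype
    sample_rows = []
    for s in cfg.subtypes:
        for i in range(1, cfg.n_pairs_per_subtype + 1):
            pair = f"{s}_P{i:02d}"
            sample_rows.append((f"{s}_T{i:02d}", s, TUMOR, pair))
            sample_rows.append((f"{s}_N{i:02d}", s, NORMAL, pair))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "subtype", "tumor_normal", "pair_id"]
    ).set_index("sample")
    n_samples = len(samples)
    tumor_ids = samples.index[samples["tumor_normal"] == TUMOR]
    normal_ids = samples.index[samples["tumor_normal"] == NORMAL]

    # latent fractions: matched normals, tumors shifted where planted
    eps = rng.normal(0.0, cfg.latent_sd, (n_roi, n_samples))
    latent = np.clip(base[:, None] + eps, 0.02, 0.98)
    latent = pd.DataFrame(latent, index=key_index, columns=samples.index)
    for s in cfg.subtypes:
        t_cols = [f"{s}_T{i:02d}" for i in range(1, cfg.n_pairs_per_subtype + 1)]
        n_cols = [f"{s}_N{i:02d}" for i in range(1, cfg.n_pairs_per_subtype + 1)]
        for gene_set, sign in (
            (set(hypo[s]) | hypo_genes_all & set(shared), -1.0),
            (set(hyper[s]) | hyper_genes_all & set(shared), +1.0),
        ):
            rows = planted_rows(gene_set)
            if rows.any():
                shifted = latent.loc[rows, n_cols].to_numpy() + sign * cfg.effect_size
                latent.loc[rows, t_cols] = np.clip(shifted, 0.02, 0.98)

    # counts: NB around depth x latent x length x relative CpG density
    depth_factor = np.exp(rng.normal(0.0, cfg.depth_sd, n_samples))
    lengths = roi_info["length"].to_numpy(dtype=float)
    cpg_weight = (cpg + 1) / np.median(cpg + 1)
    mean = (
        cfg.base_depth
        * latent.to_numpy()
        * (lengths / 1000.0)[:, None]
        * cpg_weight[:, None]
        * depth_factor[None, :]
    )
    p_nb = cfg.dispersion / (cfg.dispersion + mean)
    counts = rng.negative_binomial(cfg.dispersion, p_nb)
    counts = pd.DataFrame(counts, index=key_index, columns=samples.index)
    # ROI counts are a slice of the library; scale column sums up to
    # genome-wide totals in the tens of millions of reads
    library_sizes = (counts.sum(axis=0) * 40).astype(int)
    library_sizes.name = "library_size"

    # expression: log2 intensities, coupled for integrated planted genes
    gene_ids = [g.gene_id for g in genes]
    gene_mean = rng.normal(cfg.expr_mean, cfg.expr_gene_sd, cfg.n_genes)
    expr = gene_mean[:, None] + rng.normal(0.0, cfg.expr_noise_sd, (cfg.n_genes, n_samples))
    expr = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=samples.index)

    def integrated(gene_list: list[str]) -> list[str]:
        k = int(np.ceil(cfg.integrated_fraction * len(gene_list)))
        return gene_list[:k]

    coupling: dict[str, str] = {}
    for s in cfg.subtypes:
        for g in hyper[s]:
            coupling.setdefault(g, "none")
        for g in hypo[s]:
            coupling.setdefault(g, "none")
    for g in shared:
        coupling.setdefault(g, "none")
    planted_by_dir = [(hypo, "up"), (hyper, "down")]
    for table, direction in planted_by_dir:
        for s in cfg.subtypes:
            for g in integrated(table[s]):
                coupling[g] = direction
    shared_dir = "up" if cfg.shared_direction == "hypo" else "down"
    for g in integrated(shared):
        coupling[g] = shared_dir

    for s in cfg.subtypes:
        t_cols = [f"{s}_T{i:02d}" for i in range(1, cfg.n_pairs_per_subtype + 1)]
        for table, direction, sign in ((hypo, "up", +1.0), (hyper, "down", -1.0)):
            planted_here = [g for g in table[s] if coupling.get(g) == direction]
            if cfg.shared_direction == ("hypo" if direction == "up" else "hyper"):
                planted_here += [g for g in shared if coupling.get(g) == direction]
            if planted_here:
                expr.loc[planted_here, t_cols] += sign * cfg.expr_effect

    # marker gene and survival
    marker = None
    for g in integrated(hypo.get("TNBC", [])):
        marker = g
        break
    if marker is not None and cfg.marker_expr_boost != 1.0:
        t_cols = [f"TNBC_T{i:02d}" for i in range(1, cfg.n_pairs_per_subtype + 1)]
        expr.loc[marker, t_cols] += (cfg.marker_expr_boost - 1.0) * cfg.expr_effect
    rule = RiskRule(marker, "hypo", "high") if marker else None
    if marker is not None:
        marker_row = np.flatnonzero(key_index == f"{marker}|{cfg.planted_region}")[0]
        marker_base = float(base[marker_row])
        marker_expr_mean = float(gene_mean[gene_ids.index(marker)])
    else:
        marker_base, marker_expr_mean = 0.5, cfg.expr_mean
    clinical, high_risk_subjects = _simulate_clinical(
        cfg, rng, marker, marker_base, marker_expr_mean
    )

    truth = PlantedTruth(
        hyper={s: set(hyper[s]) for s in cfg.subtypes},
        hypo={s: set(hypo[s]) for s in cfg.subtypes},
        shared=set(shared),
        shared_direction=cfg.shared_direction,
        coupling=coupling,
        marker_gene=marker,
        risk_rule=rule,
        high_risk_subjects=high_risk_subjects,
        latent_normal=latent[normal_ids],
        latent_tumor=latent[tumor_ids],
    )
    return SimulatedCohort(
        config=cfg,
        genes=genes,
        cgis=cgis,
        rois=rois,
        roi_info=roi_info,
        counts=counts,
        library_sizes=library_sizes,
        expression=expr,
        samples=samples,
        clinical=clinical,
        truth=truth,
    )


def _simulate_clinical(cfg, rng, marker, marker_base, marker_expr_mean):
    """Survival validation cohort: distinct tumor subjects assayed for the marker.

    Each subject carries a marker methylation fraction (beta-value-like,
    shifted down by effect_size for the marker's planted subtype) and a
    marker expression value (raised for that subtype when coupled).
    Subjects whose values satisfy the marker's risk rule (below-median
    methylation AND above-median expression) have their exponential
    hazard multiplied by hazard_ratio; censoring is independent with an
    expected censored fraction of censoring_rate.
    """
    n = cfg.n_clinical_subjects
    subjects = pd.Index([f"V{i + 1:04d}" for i in range(n)], name="subject")
    subtype = rng.choice(list(cfg.subtypes), size=n)
    in_target = subtype == "TNBC" if "TNBC" in cfg.subtypes else np.zeros(n, bool)
    meth = np.clip(
        marker_base
        - np.where(in_target, cfg.effect_size, 0.0)
        + rng.normal(0.0, cfg.latent_sd, n),
        0.02,
        0.98,
    )
    expr_shift = np.where(
        in_target, cfg.marker_expr_boost * cfg.expr_effect, 0.0
    )
    expr_vals = marker_expr_mean + expr_shift + rng.normal(0.0, cfg.expr_noise_sd, n)
    if marker is not None:
        high = (meth <= np.median(meth)) & (expr_vals > np.median(expr_vals))
    else:
        high = np.zeros(n, bool)
    hazard = cfg.baseline_hazard * np.where(high, cfg.hazard_ratio, 1.0)
    event_t = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        c_rate = hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        censor_t = rng.exponential(1.0 / c_rate)
    else:
        censor_t = np.full_like(event_t, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    clinical = pd.DataFrame(
        {"time": time, "event": event, "subtype": subtype}, index=subjects
    )
    if marker is not None:
        # per-subject marker assay values, named for the assayed gene
        clinical[f"meth_{marker}"] = meth
        clinical[f"expr_{marker}"] = expr_vals
    return clinical, set(subjects[high])


def simulate_survival(
    group_labels,
    hazard_ratio: float,
    baseline_hazard: float = 0.05,
    censoring_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group exponential survival with independent censoring.

    ``group_labels`` is a binary vector (0/1, bool, or the string pairs
    high/low, high_risk/low_risk); the "1"/high group's hazard is
    ``baseline_hazard * hazard_ratio``.  Censoring times are exponential
    with a rate chosen so the expected censored fraction equals
    ``censoring_rate``.
    """
    labels = np.asarray(group_labels)
    if labels.size == 0:
        raise DataError("empty group labels")
    if labels.dtype.kind in "biu":
        high = labels.astype(bool)
    else:
        mapping = {HIGH: True, LOW: False, HIGH_RISK: True, LOW_RISK: False}
        try:
            high = np.array([mapping[str(v)] for v in labels])
        except KeyError as exc:
            raise DataError(f"unrecognised group label {exc}") from exc
    if high.all() or (~high).all():
        raise DataError("both groups must be non-empty")
    if hazard_ratio <= 0 or baseline_hazard <= 0:
        raise ConfigError("hazards must be positive")
    if not 0.0 <= censoring_rate < 1.0:
        raise ConfigError("censoring_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    hazard = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    event_t = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        c_rate = hazard * censoring_rate / (1.0 - censoring_rate)
        censor_t = rng.exponential(1.0 / c_rate)
    else:
        censor_t = np.full_like(event_t, np.inf)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    return pd.DataFrame(
        {
            "subject": [f"S{i + 1:04d}" for i in range(labels.size)],
            "time": time,
            "event": event,
            "group": labels,
        }
    ).set_index("subject")


def simulate_melting_curve(
    true_fraction: float,
    noise_sd: float = 0.01,
    seed: int = 0,
    t_min: float = 70.0,
    t_max: float = 95.0,
    t_step: float = 0.1,
    unmeth_tm: float = 78.0,
    meth_tm: float = 85.0,
    peak_sd: float = 1.0,
    sample_id: str | None = None,
) -> MeltingCurve:
    """Two-Gaussian -dF/dT melting profile with mixture weight = fraction.

    The unmethylated-template peak sits at the lower melting temperature
    and carries weight (1 - true_fraction); the methylated peak at the
    higher temperature carries weight true_fraction.  Additive Gaussian
    noise with ``noise_sd`` is applied pointwise.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ConfigError("true_fraction must lie in [0, 1]")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_points = int(round((t_max - t_min) / t_step)) + 1
    t = np.linspace(t_min, t_max, n_points)
    signal = (1.0 - true_fraction) * stats.norm.pdf(t, unmeth_tm, peak_sd)
    signal = signal + true_fraction * stats.norm.pdf(t, meth_tm, peak_sd)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, t.size)
    return MeltingCurve(t, signal, sample_id=sample_id)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort in the pipeline's TSV/BED/JSON dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "genes": outdir / "genes.tsv",
        "cgis": outdir / "cgis.bed",
        "rois": outdir / "rois.bed",
        "library_sizes": outdir / "library_sizes.tsv",
        "cpg_counts": outdir / "cpg_counts.tsv",
        "truth": outdir / "truth.json",
    }
    cohort.counts.rename_axis("roi").to_csv(paths["counts"], sep="\t")
    cohort.samples.rename_axis("sample").to_csv(paths["samples"], sep="\t")
    cohort.expression.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", float_format="%.6g")
    write_gene_models(cohort.genes, paths["genes"])
    write_cgi_bed(cohort.cgis, paths["cgis"])
    write_rois_bed(cohort.rois, paths["rois"])
    cohort.library_sizes.rename_axis("sample").to_frame().to_csv(
        paths["library_sizes"], sep="\t"
    )
    cohort.roi_info["cpg_count"].rename_axis("roi").to_frame().to_csv(
        paths["cpg_counts"], sep="\t"
    )
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.to_jsonable(), fh, indent=1, sort_keys=True)
    return paths
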