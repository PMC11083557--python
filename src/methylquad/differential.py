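"""Differential methylation calling on paired tumor/normal cohorts.

A gene/region is hypermethylated in a subtype when the mean scaled ams
difference tumor - normal exceeds +0.2 with a paired-t p below 0.05,
hypomethylated when the difference is below -0.2 at the same p gate,
and unchanged (ns) otherwise.  Benjamini-Hochberg q-values are reported
alongside; a strict-FDR mode gates on q instead of raw p.

The statistical primitives (paired t, BH step-up, UPGMA clustering) are
implemented here with explicit degenerate-case conventions and
deterministic tie-breaks; established library implementations serve as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .annotation import CDS, CGI, NONCGI, PROMOTER
from .errors import ConfigError, DataError
from .scoring import NORMAL, TUMOR, MethylationMatrix

logger = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"
NS = "ns"


# ---------------------------------------------------------------------------
# primitives


def delta_mean(tumor, normal) -> float:
    """mean(tumor) - mean(normal); on scaled ams this is the "delta mean"."""
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.size == 0 or normal.size == 0:
        raise DataError("delta_mean: empty group")
    return float(tumor.mean() - normal.mean())


def paired_t_test(tumor, normal) -> tuple[float, float]:
    """Two-sided paired t-test on per-pair differences.

    t = mean(d) / (sd(d)/sqrt(n)) with n-1 degrees of freedom.  When all
    differences are identical (sd = 0) the convention is p = 0 if the
    common difference is non-zero, else p = 1, with a warning.
    """
    d = np.asarray(tumor, dtype=float) - np.asarray(normal, dtype=float)
    if d.size < 2:
        raise DataError("paired_t_test: need at least 2 pairs")
    m = d.mean()
    s = d.std(ddof=1)
    if s == 0.0:
        logger.warning("paired_t_test: zero variance of differences")
        if m == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, m), 0.0
    t = m / (s / math.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), d.size - 1)
    return float(t), float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending ordering, capped
    at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataError("bh_adjust expects a 1-D p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def paired_columns(meta: pd.DataFrame, subtype: str) -> tuple[list[str], list[str]]:
    """Align tumor and normal sample IDs of one subtype by pair ID."""
    sub = meta[meta["subtype"] == subtype]
    if sub.empty:
        raise DataError(f"no samples for subtype {subtype!r}")
    tumors = sub[sub["tumor_normal"] == TUMOR]
    normals = sub[sub["tumor_normal"] == NORMAL]
    t_by_pair = dict(zip(tumors["pair_id"], tumors.index))
    n_by_pair = dict(zip(normals["pair_id"], normals.index))
    orphans = sorted(set(t_by_pair) ^ set(n_by_pair))
    if orphans:
        raise DataError(f"unpaired samples for subtype {subtype!r}: pairs {orphans}")
    pairs = sorted(t_by_pair)
    if len(pairs) < 2:
        raise DataError(f"subtype {subtype!r}: need >= 2 tumor/normal pairs")
    return [t_by_pair[p] for p in pairs], [n_by_pair[p] for p in pairs]


def paired_t_matrix(tumor: np.ndarray, normal: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise paired t over aligned (rows x pairs) arrays.

    Returns (delta_mean, t, p) with the same zero-variance conventions
    as :func:`paired_t_test`.
    """
    d = tumor - normal
    n = d.shape[1]
    delta = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    zero_sd = sd == 0
    if zero_sd.any():
        logger.warning("%d rows with zero-variance differences", int(zero_sd.sum()))
        p[zero_sd & (delta != 0)] = 0.0
        p[zero_sd & (delta == 0)] = 1.0
        t[zero_sd & (delta == 0)] = 0.0
    return delta, t, p


def call_dmrs(
    matrix: MethylationMatrix,
    subtype: str,
    delta_threshold: float = 0.2,
    p_threshold: float = 0.05,
    gate: str = "p",
) -> pd.DataFrame:
    """Call hyper/hypo/ns per ROI for one subtype.

    Requires a 0-1 scaled matrix.  ``gate="p"`` reproduces the published
    criterion (raw p < threshold); ``gate="q"`` is the strict-FDR
    variant gating on the BH-adjusted value instead.  Returns a
    volcano-ready table indexed by ROI key with columns gene_id,
    region_class, subtype, delta_mean, t, p_value, q_value,
    neg_log10_p, call.
    """
    if not matrix.scaled:
        raise DataError("call_dmrs requires a 0-1 scaled matrix")
    if gate not in ("p", "q"):
        raise ConfigError("gate must be 'p' or 'q'")
    t_cols, n_cols = paired_columns(matrix.samples, subtype)
    tum = matrix.values[t_cols].to_numpy(dtype=float)
    nor = matrix.values[n_cols].to_numpy(dtype=float)
    delta, t, p = paired_t_matrix(tum, nor)
    q = bh_adjust(p)
    gate_values = p if gate == "p" else q
    call = np.where(
        (delta > delta_threshold) & (gate_values < p_threshold), HYPER,
        np.where((delta < -delta_threshold) & (gate_values < p_threshold), HYPO, NS),
    )
    index = matrix.values.index
    keys = index.to_series().str.split("|")
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(p)
    return pd.DataFrame(
        {
            "gene_id": keys.str[0].to_numpy(),
            "region_class": keys.str[-1].to_numpy(),
            "subtype": subtype,
            "delta_mean": delta,
            "t": t,
            "p_value": p,
            "q_value": q,
            "neg_log10_p": neg_log10_p,
            "call": call,
        },
        index=index,
    )


def gene_level_calls(dmr_table: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse ROI-level calls to gene-level hyper/hypo sets.

    A gene is hyper (hypo) when any of its regions is called so; genes
    with conflicting directions across regions are dropped with a
    warning.
    """
    hyper = set(dmr_table.loc[dmr_table["call"] == HYPER, "gene_id"])
    hypo = set(dmr_table.loc[dmr_table["call"] == HYPO, "gene_id"])
    conflicted = hyper & hypo
    if conflicted:
        logger.warning("genes with conflicting hyper/hypo regions dropped: %s",
                       sorted(conflicted))
    return {HYPER: hyper - conflicted, HYPO: hypo - conflicted}


def context_composition(calls: pd.DataFrame, rois: pd.DataFrame) -> dict:
    """2x2 context composition (CGI/nonCGI x promoter/CDS) per direction.

    ``calls`` is a call_dmrs table; ``rois`` a rois_to_frame table with
    a cgi_class column.  Fractions per direction sum to 1; a direction
    with no calls is absent from the result.
    """
    out: dict[str, dict[str, float]] = {}
    for direction in (HYPER, HYPO):
        hits = calls[calls["call"] == direction]
        if hits.empty:
            continue
        missing = [k for k in hits.index if k not in rois.index]
        if missing:
            raise DataError(f"called ROIs missing annotation: {missing}")
        ann = rois.loc[hits.index]
        if ann["cgi_class"].isna().any():
            raise DataError("cgi_class unset for some called ROIs")
        total = len(ann)
        cells = {}
        for cgi in (CGI, NONCGI):
            for region in (PROMOTER, CDS):
                n = int(((ann["cgi_class"] == cgi) & (ann["region_class"] == region)).sum())
                cells[f"{cgi}_{region}"] = n / total
        cells["n_calls"] = total
        out[direction] = cells
    return out


def select_top_variable(matrix: MethylationMatrix, k: int = 1000) -> list[str]:
    """Top-k most variable ROIs by SD/SD_max across all samples.

    SD/SD_max is rank-preserving, so the selection is by descending SD
    with ties broken by ROI key lexicographic order.
    """
    if k <= 0:
        raise ConfigError("k must be positive")
    if k > matrix.values.shape[0]:
        raise ConfigError("k exceeds number of ROIs")
    sd = matrix.values.std(axis=1, ddof=1)
    sd_max = sd.max()
    rel = sd / sd_max if sd_max > 0 else sd
    order = sorted(zip(-rel.to_numpy(), rel.index), key=lambda t: (t[0], t[1]))
    return [key for _, key in order[:k]]


# ---------------------------------------------------------------------------
# UPGMA clustering of samples


@dataclass(frozen=True)
class Merge:
    left: int
    right: int
    height: float
    size: int


def average_linkage_cluster(matrix: MethylationMatrix | pd.DataFrame) -> list[Merge]:
    """Agglomerative UPGMA clustering of sample columns (Euclidean).

    Leaves are numbered 0..n-1 in column order; the merge created at
    step s gets id n+s (scipy linkage convention).  Ties in the minimum
    inter-cluster distance are broken by the smallest (left, right) id
    pair, making the merge order deterministic.
    """
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    x = values.to_numpy(dtype=float).T
    if np.isnan(x).any():
        raise DataError("NaN in matrix")
    n = x.shape[0]
    if n < 2:
        raise DataError("need >= 2 samples to cluster")
    dist = squareform(pdist(x, metric="euclidean"))
    # active clusters: id -> (size, row index in dist workspace)
    ids = list(range(n))
    sizes = {i: 1 for i in ids}
    d = {frozenset((i, j)): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[Merge] = []
    next_id = n
    while len(ids) > 1:
        best = None
        for a_idx in range(len(ids)):
            for b_idx in range(a_idx + 1, len(ids)):
                a, b = ids[a_idx], ids[b_idx]
                key = (d[frozenset((a, b))], min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        h, a, b = best
        merges.append(Merge(a, b, h, sizes[a] + sizes[b]))
        ids = [i for i in ids if i not in (a, b)]
        for other in ids:
            d[frozenset((next_id, other))] = (
                sizes[a] * d[frozenset((a, other))] + sizes[b] * d[frozenset((b, other))]
            ) / (sizes[a] + sizes[b])
        sizes[next_id] = sizes[a] + sizes[b]
        ids.append(next_id)
        next_id += 1
    return merges


def merges_to_newick(merges: list[Merge], labels: list[str]) -> str:
    """Render a UPGMA merge list as a Newick string with branch lengths."""
    n = len(labels)
    height = {i: 0.0 for i in range(n)}
    node = {i: labels[i] for i in range(n)}
    for s, m in enumerate(merges):
        h = m.height / 2.0  # ultrametric: leaves at depth height/2
        left = f"{node[m.left]}:{h - height[m.left]:.6g}"
        right = f"{node[m.right]}:{h - height[m.right]:.6g}"
        node[n + s] = f"({left},{right})"
        height[n + s] = h
    return node[n + len(merges) - 1] + ";"
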