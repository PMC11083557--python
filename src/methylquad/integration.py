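"""Joint methylation/expression analysis: quadrants, specificity, screening.

Genes carrying both a methylation call and an expression change are
split into four quadrants (hyper_up, hyper_down, hypo_up, hypo_down).
Subtype specificity is exact set algebra over per-subtype call sets,
and the candidate screen scores how subtype-restricted a gene's joint
pattern is in an independent validation cohort.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import HYPER, HYPO, bh_adjust, paired_columns, paired_t_matrix
from .errors import ConfigError, DataError
from .scoring import TUMOR, MethylationMatrix

logger = logging.getLogger(__name__)

QUADRANTS = ("hyper_up", "hyper_down", "hypo_up", "hypo_down", "none")

DEFAULT_FC_THRESHOLD_LOG2 = math.log2(1.2)


def expression_differential(
    expr: pd.DataFrame, samples: pd.DataFrame, subtype: str
) -> pd.DataFrame:
    """Per-gene log2 fold change with paired-t p and BH q for one subtype.

    ``expr`` holds log2 intensities (genes x samples); pairing comes
    from the sample metadata.  log2FC = mean(tumor) - mean(normal) on
    the log2 scale.
    """
    t_cols, n_cols = paired_columns(samples, subtype)
    tum = expr[t_cols].to_numpy(dtype=float)
    nor = expr[n_cols].to_numpy(dtype=float)
    if not (np.isfinite(tum).all() and np.isfinite(nor).all()):
        raise DataError("expression matrix contains non-finite values")
    log2_fc, _t, p = paired_t_matrix(tum, nor)
    out = pd.DataFrame(
        {
            "gene_id": expr.index.to_numpy(),
            "log2_fold_change": log2_fc,
            "p_value": p,
            "q_value": bh_adjust(p),
        },
        index=expr.index,
    )
    if out["gene_id"].duplicated().any():
        raise DataError("duplicate gene records in expression matrix")
    return out


def assign_quadrants(
    meth_calls: dict[str, set[str]],
    expr: pd.DataFrame,
    fc_threshold_log2: float = DEFAULT_FC_THRESHOLD_LOG2,
) -> pd.DataFrame:
    """Assign each gene to one of the four quadrants or none.

    ``meth_calls`` maps "hyper"/"hypo" to gene-level call sets;
    ``expr`` is an expression_differential table.  A gene lands in a
    quadrant only when it carries a methylation call and |log2FC| >=
    ``fc_threshold_log2``.
    """
    if expr["gene_id"].duplicated().any():
        raise DataError("duplicate gene records in expression differential")
    fc = dict(zip(expr["gene_id"], expr["log2_fold_change"]))
    rows = []
    for gene, lfc in fc.items():
        direction = None
        if gene in meth_calls.get(HYPER, set()):
            direction = HYPER
        elif gene in meth_calls.get(HYPO, set()):
            direction = HYPO
        quad = "none"
        if direction is not None and abs(lfc) >= fc_threshold_log2:
            quad = f"{direction}_{'up' if lfc > 0 else 'down'}"
        rows.append((gene, lfc, quad))
    return pd.DataFrame(rows, columns=["gene_id", "log2_fold_change", "quadrant"])


@dataclass
class SpecificitySets:
    """Per-subtype specific call sets and the all-subtype shared set."""

    specific: dict[str, set[str]]
    shared: set[str]

    def to_jsonable(self) -> dict:
        return {
            "specific": {k: sorted(v) for k, v in self.specific.items()},
            "shared": sorted(self.shared),
        }


def subtype_specific_sets(call_sets: dict[str, set[str]]) -> SpecificitySets:
    """Exact set algebra over per-subtype call sets.

    specific(s) = calls(s) minus the union of all other subtypes;
    shared = intersection across every subtype.
    """
    if len(call_sets) < 2:
        raise ConfigError("need >= 2 subtypes for specificity analysis")
    subtypes = list(call_sets)
    specific = {}
    for s in subtypes:
        others = set().union(*(call_sets[o] for o in subtypes if o != s))
        specific[s] = set(call_sets[s]) - others
    shared = set.intersection(*(set(call_sets[s]) for s in subtypes))
    return SpecificitySets(specific=specific, shared=shared)


def candidate_screen(
    quadrants: pd.DataFrame,
    meth: MethylationMatrix,
    expr: pd.DataFrame,
    expr_samples: pd.DataFrame,
    target_subtype: str,
    meth_margin: float = 0.05,
    expr_margin: float = 0.5,
    region_class: str = "CDS",
) -> pd.DataFrame:
    """Score quadrant genes for subtype-restricted joint patterns.

    For each gene in a non-none quadrant the specificity score is the
    median difference between target-subtype tumors and all other
    tumors, computed separately for scaled methylation (sign must match
    the methylation call: hypo => negative) and expression (sign must
    match the quadrant arrow).  A candidate passes when both magnitudes
    exceed their margins; the ranking is by the product of the two
    magnitudes.
    """
    meta = meth.samples
    tumors = meta[meta["tumor_normal"] == TUMOR]
    if tumors["subtype"].nunique() < 2:
        raise DataError("validation matrix needs >= 2 subtypes")
    target_cols = tumors.index[tumors["subtype"] == target_subtype]
    other_cols = tumors.index[tumors["subtype"] != target_subtype]

    e_meta = expr_samples[expr_samples["tumor_normal"] == TUMOR]
    e_target = e_meta.index[e_meta["subtype"] == target_subtype]
    e_other = e_meta.index[e_meta["subtype"] != target_subtype]

    rows = []
    for rec in quadrants.itertuples(index=False):
        if rec.quadrant == "none":
            continue
        key = f"{rec.gene_id}|{region_class}"
        if key not in meth.values.index or rec.gene_id not in expr.index:
            logger.warning("candidate %s absent from validation tables; skipped", rec.gene_id)
            continue
        meth_diff = float(
            meth.values.loc[key, target_cols].median()
            - meth.values.loc[key, other_cols].median()
        )
        expr_diff = float(
            expr.loc[rec.gene_id, e_target].median() - expr.loc[rec.gene_id, e_other].median()
        )
        meth_dir, expr_dir = rec.quadrant.split("_")
        meth_sign_ok = meth_diff < 0 if meth_dir == HYPO else meth_diff > 0
        expr_sign_ok = expr_diff > 0 if expr_dir == "up" else expr_diff < 0
        passes = (
            meth_sign_ok
            and expr_sign_ok
            and abs(meth_diff) >= meth_margin
            and abs(expr_diff) >= expr_margin
        )
        rows.append(
            (
                rec.gene_id,
                rec.quadrant,
                meth_diff,
                expr_diff,
                bool(passes),
                abs(meth_diff) * abs(expr_diff) if passes else 0.0,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "quadrant", "meth_margin", "expr_margin", "passes", "score"],
    )
    return out.sort_values(
        ["passes", "score", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
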