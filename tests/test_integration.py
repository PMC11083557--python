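import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylquad import (
    assign_quadrants,
    call_dmrs,
    candidate_screen,
    expression_differential,
    gene_level_calls,
    subtype_specific_sets,
)
from methylquad.errors import ConfigError, DataError


def _expr_frame(genes, tumor, normal):
    """Build a tiny paired expression matrix plus metadata."""
    n_pairs = len(tumor[0])
    cols = [f"T{i}" for i in range(n_pairs)] + [f"N{i}" for i in range(n_pairs)]
    values = pd.DataFrame(
        np.hstack([np.asarray(tumor, float), np.asarray(normal, float)]),
        index=pd.Index(genes, name="gene_id"),
        columns=cols,
    )
    samples = pd.DataFrame(
        {
            "subtype": "TNBC",
            "tumor_normal": ["tumor"] * n_pairs + ["normal"] * n_pairs,
            "pair_id": [f"P{i}" for i in range(n_pairs)] * 2,
        },
        index=cols,
    )
    return values, samples


class TestExpressionDifferential:
    def test_identical_columns_give_zero_fold_change(self):
        values, samples = _expr_frame(["g1"], [[8, 8, 8]], [[8, 8, 8]])
        out = expression_differential(values, samples, "TNBC")
        assert out.loc["g1", "log2_fold_change"] == 0.0

    def test_unit_shift_gives_log2fc_one(self):
        values, samples = _expr_frame(["g1"], [[9.0, 9.1, 8.9]], [[8.0, 8.1, 7.9]])
        out = expression_differential(values, samples, "TNBC")
        assert out.loc["g1", "log2_fold_change"] == pytest.approx(1.0)

    def test_antisymmetric_under_group_swap(self):
        values, samples = _expr_frame(["g1"], [[9.0, 9.4, 8.9]], [[8.0, 8.1, 7.9]])
        swapped = samples.copy()
        swapped["tumor_normal"] = swapped["tumor_normal"].map(
            {"tumor": "normal", "normal": "tumor"}
        )
        a = expression_differential(values, samples, "TNBC")
        b = expression_differential(values, swapped, "TNBC")
        assert a.loc["g1", "log2_fold_change"] == pytest.approx(
            -b.loc["g1", "log2_fold_change"]
        )
        assert a.loc["g1", "p_value"] == pytest.approx(b.loc["g1", "p_value"])


class TestAssignQuadrants:
    def _expr(self, fc):
        return pd.DataFrame(
            {"gene_id": list(fc), "log2_fold_change": list(fc.values())}
        )

    def test_rule_application(self):
        calls = {"hyper": {"g1"}, "hypo": {"g2"}}
        expr = self._expr({"g1": -1.5, "g2": 1.5, "g3": 2.0})
        out = assign_quadrants(calls, expr).set_index("gene_id")
        assert out.loc["g1", "quadrant"] == "hyper_down"
        assert out.loc["g2", "quadrant"] == "hypo_up"
        assert out.loc["g3", "quadrant"] == "none"  # no methylation call

    def test_below_threshold_is_none(self):
        out = assign_quadrants({"hyper": {"g1"}, "hypo": set()},
                               self._expr({"g1": 0.1}))
        assert out.loc[0, "quadrant"] == "none"

    def test_threshold_boundary_inclusive(self):
        thr = math.log2(1.2)
        out = assign_quadrants({"hypo": {"g1"}, "hyper": set()},
                               self._expr({"g1": thr}))
        assert out.loc[0, "quadrant"] == "hypo_up"

    def test_duplicate_gene_rejected(self):
        expr = pd.DataFrame({"gene_id": ["g1", "g1"], "log2_fold_change": [1, 2]})
        with pytest.raises(DataError):
            assign_quadrants({"hyper": set(), "hypo": set()}, expr)

    def test_quadrants_partition_called_and_changed_genes(self, default_cohort,
                                                          default_scaled):
        c = default_cohort
        calls = gene_level_calls(call_dmrs(default_scaled, "TNBC"))
        expr = expression_differential(c.expression, c.samples, "TNBC")
        out = assign_quadrants(calls, expr)
        called = calls["hyper"] | calls["hypo"]
        thr = math.log2(1.2)
        both = {
            g
            for g, fc in zip(expr["gene_id"], expr["log2_fold_change"])
            if g in called and abs(fc) >= thr
        }
        in_quadrants = set(out.loc[out["quadrant"] != "none", "gene_id"])
        assert in_quadrants == both


class TestSpecificitySets:
    def test_basic_set_algebra(self):
        out = subtype_specific_sets({"A": {"g1", "g2"}, "B": {"g2", "g3"}})
        assert out.specific == {"A": {"g1"}, "B": {"g3"}}
        assert out.shared == {"g2"}

    def test_identical_sets(self):
        out = subtype_specific_sets({"A": {"g1"}, "B": {"g1"}, "C": {"g1"}})
        assert all(not s for s in out.specific.values())
        assert out.shared == {"g1"}

    def test_disjoint_sets(self):
        out = subtype_specific_sets({"A": {"g1"}, "B": {"g2"}})
        assert out.specific == {"A": {"g1"}, "B": {"g2"}}
        assert out.shared == set()

    def test_needs_two_subtypes(self):
        with pytest.raises(ConfigError):
            subtype_specific_sets({"A": {"g1"}})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_membership_count_oracle(self, data):
        n_subtypes = data.draw(st.integers(2, 5))
        universe = [f"g{i}" for i in range(data.draw(st.integers(1, 30)))]
        families = {
            f"S{k}": set(data.draw(st.lists(st.sampled_from(universe), max_size=30)))
            for k in range(n_subtypes)
        }
        out = subtype_specific_sets(families)
        for g in universe:
            count = sum(g in fam for fam in families.values())
            member_of = [s for s, fam in families.items() if g in fam]
            if count == 1:
                assert g in out.specific[member_of[0]]
            else:
                assert all(g not in spec for spec in out.specific.values())
            assert (g in out.shared) == (count == n_subtypes)


class TestCandidateScreen:
    def _validation(self, meth_target, meth_other, expr_target, expr_other):
        from methylquad import MethylationMatrix

        cols = [f"X{i}" for i in range(6)]
        samples = pd.DataFrame(
            {
                "subtype": ["TNBC"] * 3 + ["LumA"] * 3,
                "tumor_normal": "tumor",
                "pair_id": cols,
            },
            index=cols,
        )
        meth = pd.DataFrame(
            [[meth_target] * 3 + [meth_other] * 3], index=["g1|CDS"], columns=cols
        )
        expr = pd.DataFrame(
            [[expr_target] * 3 + [expr_other] * 3],
            index=pd.Index(["g1"], name="gene_id"),
            columns=cols,
        )
        return MethylationMatrix(meth, samples, scaled=True), expr, samples

    def _quadrants(self, quadrant):
        return pd.DataFrame(
            {"gene_id": ["g1"], "log2_fold_change": [1.0], "quadrant": [quadrant]}
        )

    def test_concordant_candidate_passes_and_ranks(self):
        meth, expr, samples = self._validation(0.2, 0.6, 9.5, 8.0)
        out = candidate_screen(self._quadrants("hypo_up"), meth, expr, samples, "TNBC")
        assert out.loc[0, "passes"]
        assert out.loc[0, "score"] > 0

    def test_zero_margin_fails(self):
        meth, expr, samples = self._validation(0.5, 0.5, 8.0, 8.0)
        out = candidate_screen(self._quadrants("hypo_up"), meth, expr, samples, "TNBC")
        assert not out.loc[0, "passes"]

    def test_sign_mismatch_fails_regardless_of_magnitude(self):
        # hypo call but methylation *higher* in the target subtype
        meth, expr, samples = self._validation(0.9, 0.2, 9.5, 8.0)
        out = candidate_screen(self._quadrants("hypo_up"), meth, expr, samples, "TNBC")
        assert not out.loc[0, "passes"]

    def test_absent_gene_skipped_with_warning(self, caplog):
        meth, expr, samples = self._validation(0.2, 0.6, 9.5, 8.0)
        quads = pd.DataFrame(
            {
                "gene_id": ["g1", "gMissing"],
                "log2_fold_change": [1.0, 1.0],
                "quadrant": ["hypo_up", "hypo_up"],
            }
        )
        with caplog.at_level("WARNING"):
            out = candidate_screen(quads, meth, expr, samples, "TNBC")
        assert list(out["gene_id"]) == ["g1"]
        assert any("gMissing" in r.message for r in caplog.records)

    def test_planted_specific_gene_recovered_first(self, default_cohort,
                                                   default_scaled):
        """A planted subtype-specific hypo+up gene tops its own screen."""
        c = default_cohort
        marker = c.truth.marker_gene
        quads = pd.DataFrame(
            {"gene_id": [marker], "log2_fold_change": [1.0], "quadrant": ["hypo_up"]}
        )
        out = candidate_screen(quads, default_scaled, c.expression, c.samples, "TNBC")
        assert out.loc[0, "gene_id"] == marker
        assert out.loc[0, "passes"]
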