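import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import pdist, squareform

from methylquad import (
    MethylationMatrix,
    average_linkage_cluster,
    bh_adjust,
    call_dmrs,
    context_composition,
    delta_mean,
    gene_level_calls,
    paired_t_test,
    select_top_variable,
)
from methylquad.differential import merges_to_newick
from methylquad.errors import DataError


class TestDeltaMean:
    def test_equal_groups_give_zero(self):
        assert delta_mean([0.2, 0.4], [0.2, 0.4]) == 0.0

    def test_arithmetic(self):
        assert delta_mean([0.8, 0.6], [0.3, 0.5]) == pytest.approx(0.3)

    def test_antisymmetry(self):
        a, b = [0.7, 0.9, 0.2], [0.1, 0.4, 0.3]
        assert delta_mean(a, b) == pytest.approx(-delta_mean(b, a))

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            delta_mean([], [0.5])


class TestPairedT:
    def test_closed_form_example(self):
        # differences [1, 2, 3]: t = 2 / (1/sqrt(3)) = 3.4641
        t, p = paired_t_test([2, 4, 6], [1, 2, 3])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-4)
        assert p == pytest.approx(0.0742, abs=1e-4)

    def test_no_effect_degenerate_case(self):
        t, p = paired_t_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_nonzero_difference_gives_p_zero(self):
        _, p = paired_t_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert p == 0.0

    def test_sign_symmetry(self):
        t1, p1 = paired_t_test([2, 4, 7], [1, 2, 3])
        t2, p2 = paired_t_test([1, 2, 3], [2, 4, 7])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestBHAdjust:
    def test_hand_executed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_identity(self):
        assert bh_adjust([0.5]).tolist() == [0.5]

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_at_least_p_and_rank_monotone(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-15).all()
        assert (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDmrs:
    def test_threshold_rules(self, toy_matrix):
        calls = call_dmrs(toy_matrix, "TNBC").set_index("gene_id")
        assert calls.loc["gA", "call"] == "hyper"
        assert calls.loc["gB", "call"] == "hypo"
        assert calls.loc["gC", "call"] == "ns"

    def test_p_gate_blocks_large_delta(self, toy_matrix):
        calls = call_dmrs(toy_matrix, "TNBC", p_threshold=1e-12)
        assert (calls["call"] == "ns").all()

    def test_requires_scaled_matrix(self, toy_matrix):
        toy_matrix.scaled = False
        with pytest.raises(DataError):
            call_dmrs(toy_matrix, "TNBC")

    def test_unpaired_samples_reported(self, toy_matrix):
        broken = toy_matrix.samples.copy()
        broken.loc["S1", "pair_id"] = "orphan"
        with pytest.raises(DataError, match="orphan|unpaired"):
            call_dmrs(MethylationMatrix(toy_matrix.values, broken, scaled=True), "TNBC")

    def test_hyper_hypo_sets_disjoint(self, default_scaled):
        calls = call_dmrs(default_scaled, "TNBC")
        gl = gene_level_calls(calls)
        assert not gl["hyper"] & gl["hypo"]


class TestContextComposition:
    @staticmethod
    def _rois(records):
        return pd.DataFrame.from_dict(records, orient="index").rename_axis("roi")

    def test_counting(self):
        calls = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(10)],
                "region_class": ["CDS"] * 10,
                "call": ["hypo"] * 10,
            },
            index=[f"g{i}|CDS" for i in range(10)],
        )
        rois = self._rois(
            {
                f"g{i}|CDS": {
                    "region_class": "CDS",
                    "cgi_class": "CGI" if i == 0 else "nonCGI",
                }
                for i in range(10)
            }
        )
        comp = context_composition(calls, rois)
        assert comp["hypo"]["nonCGI_CDS"] == pytest.approx(0.9)
        assert comp["hypo"]["CGI_CDS"] == pytest.approx(0.1)
        assert "hyper" not in comp

    def test_fractions_sum_to_one(self, default_scaled, default_cohort):
        calls = call_dmrs(default_scaled, "TNBC")
        comp = context_composition(calls, default_cohort.roi_info)
        for direction, cells in comp.items():
            total = sum(v for k, v in cells.items() if k != "n_calls")
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_missing_annotation_named(self):
        calls = pd.DataFrame(
            {"gene_id": ["gX"], "region_class": ["CDS"], "call": ["hyper"]},
            index=["gX|CDS"],
        )
        with pytest.raises(DataError, match="gX"):
            context_composition(calls, self._rois({}))


class TestSelectTopVariable:
    def _matrix(self, sds):
        rng = np.random.default_rng(0)
        cols = [f"S{i}" for i in range(40)]
        values = pd.DataFrame(
            {c: rng.normal(0, 1, len(sds)) for c in cols},
            index=[f"g{i}|CDS" for i in range(len(sds))],
        )
        values = values.sub(values.mean(axis=1), axis=0)
        values = values.div(values.std(axis=1, ddof=1), axis=0)
        values = values.mul(pd.Series(sds, index=values.index), axis=0) + 10
        samples = pd.DataFrame(
            {"subtype": "TNBC", "tumor_normal": "tumor", "pair_id": cols}, index=cols
        )
        return MethylationMatrix(values, samples)

    def test_ranking_by_sd(self):
        m = self._matrix([3.0, 1.0, 2.0])
        assert select_top_variable(m, k=2) == ["g0|CDS", "g2|CDS"]

    def test_k_equal_to_gene_count_orders_by_sd(self):
        m = self._matrix([3.0, 1.0, 2.0])
        assert select_top_variable(m, k=3) == ["g0|CDS", "g2|CDS", "g1|CDS"]

    def test_top_gene_relative_sd_is_one(self):
        m = self._matrix([3.0, 1.0, 2.0])
        sd = m.values.std(axis=1, ddof=1)
        assert (sd / sd.max()).loc[select_top_variable(m, k=1)[0]] == pytest.approx(1.0)


class TestUPGMA:
    @staticmethod
    def _matrix_from_points(points):
        cols = [f"S{i}" for i in range(len(points))]
        values = pd.DataFrame([points], index=["g0|CDS"], columns=cols, dtype=float)
        samples = pd.DataFrame(
            {"subtype": "x", "tumor_normal": "tumor", "pair_id": cols}, index=cols
        )
        return MethylationMatrix(values + 100, samples)

    def test_hand_executed_one_dimensional_case(self):
        merges = average_linkage_cluster(self._matrix_from_points([0.0, 1.0, 10.0]))
        assert (merges[0].left, merges[0].right) == (0, 1)
        assert merges[0].height == pytest.approx(1.0)
        assert merges[1].height == pytest.approx(9.5)

    def test_identical_samples_merge_first_at_zero(self):
        merges = average_linkage_cluster(self._matrix_from_points([5.0, 5.0, 1.0]))
        assert (merges[0].left, merges[0].right, merges[0].height) == (0, 1, 0.0)

    def test_merge_heights_non_decreasing(self, default_scaled):
        sub = default_scaled.subset_samples(default_scaled.sample_ids[:12])
        merges = average_linkage_cluster(sub)
        heights = [m.height for m in merges]
        assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_agrees_with_scipy_cophenetic_distances(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(0, 1, (4, 8))  # 8 samples, 4 features
            cols = [f"S{i}" for i in range(8)]
            values = pd.DataFrame(x + 10, columns=cols,
                                  index=[f"g{i}|CDS" for i in range(4)])
            samples = pd.DataFrame(
                {"subtype": "x", "tumor_normal": "tumor", "pair_id": cols}, index=cols
            )
            merges = average_linkage_cluster(MethylationMatrix(values, samples))
            z_mine = np.array(
                [[m.left, m.right, m.height, m.size] for m in merges], dtype=float
            )
            z_scipy = linkage(x.T, method="average", metric="euclidean")
            np.testing.assert_allclose(
                cophenet(z_mine), cophenet(z_scipy), atol=1e-10
            )

    def test_newick_rendering_contains_all_leaves(self):
        merges = average_linkage_cluster(self._matrix_from_points([0.0, 1.0, 10.0]))
        nwk = merges_to_newick(merges, ["a", "b", "c"])
        assert nwk.endswith(";")
        for leaf in ("a", "b", "c"):
            assert leaf in nwk

    def test_nan_rejected(self):
        m = self._matrix_from_points([0.0, 1.0, 10.0])
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(DataError):
            average_linkage_cluster(m)
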