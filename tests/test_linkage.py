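"""Segregation typing, two-point statistics, grouping, Haldane, ordering."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from grasspanel.linkage import (
    MISSING,
    MarkerSegregation,
    PairwiseLinkage,
    _g2,
    classify_segregation,
    distortion_test,
    group_markers,
    haldane_cM,
    haldane_rf,
    order_and_position,
    pairwise_linkage,
    read_loc,
    write_loc,
)


class TestClassification:
    def test_first_parent_het_is_lmxll(self):
        seg = classify_segregation("m", ("AB", "AA"), ["AB", "AA", "BB", "--"])
        assert seg.seg_type == "lmxll"
        assert seg.codes == ["lm", "ll", MISSING, MISSING]
        assert seg.n_impossible == 1

    def test_second_parent_het_is_nnxnp(self):
        seg = classify_segregation("m", ("AA", "AB"), ["AB", "AA"])
        assert seg.seg_type == "nnxnp"
        assert seg.codes == ["np", "nn"]

    def test_both_het_is_hkxhk(self):
        seg = classify_segregation("m", ("AB", "AB"), ["AA", "AB", "BB"])
        assert seg.seg_type == "hkxhk"
        assert seg.codes == ["hh", "hk", "kk"]

    def test_hom_by_hom_uninformative(self):
        seg = classify_segregation("m", ("AA", "BB"), ["AB", "AB"])
        assert seg.seg_type == "uninformative"

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError):
            classify_segregation("m", ("--", "AA"), ["AA"])


class TestDistortion:
    def test_balanced_1_1_has_zero_statistic(self):
        seg = MarkerSegregation("m", "lmxll", ["lm"] * 50 + ["ll"] * 50)
        chi2, df = distortion_test(seg)
        assert chi2 == pytest.approx(0.0)
        assert df == 1

    def test_60_40_imbalance(self):
        seg = MarkerSegregation("m", "lmxll", ["lm"] * 60 + ["ll"] * 40)
        chi2, df = distortion_test(seg)
        assert chi2 == pytest.approx(4.0)
        assert df == 1

    def test_mendelian_1_2_1(self):
        seg = MarkerSegregation("m", "hkxhk", ["hh"] * 25 + ["hk"] * 50 + ["kk"] * 25)
        chi2, df = distortion_test(seg)
        assert chi2 == pytest.approx(0.0)
        assert df == 2

    def test_all_missing_rejected(self):
        seg = MarkerSegregation("m", "lmxll", [MISSING] * 10)
        with pytest.raises(ValueError):
            distortion_test(seg)


class TestPairwise:
    def test_perfect_association_lod(self):
        a = MarkerSegregation("a", "lmxll", ["lm"] * 50 + ["ll"] * 50)
        b = MarkerSegregation("b", "lmxll", ["lm"] * 50 + ["ll"] * 50)
        link = pairwise_linkage(a, b)
        assert link.ind_lod == pytest.approx(200 * math.log(2) / (2 * math.log(10)), abs=0.01)
        assert link.ind_lod == pytest.approx(30.10, abs=0.01)
        assert link.rf == pytest.approx(0.0, abs=1e-3)

    def test_independent_markers_have_zero_ind_lod(self):
        a = MarkerSegregation("a", "lmxll", (["lm"] * 2 + ["ll"] * 2) * 25)
        b = MarkerSegregation("b", "lmxll", (["lm", "ll"]) * 50)
        link = pairwise_linkage(a, b)
        assert link.ind_lod == pytest.approx(0.0, abs=1e-9)

    def test_cross_parent_pair_is_uninformative(self):
        a = MarkerSegregation("a", "lmxll", ["lm", "ll"] * 20)
        b = MarkerSegregation("b", "nnxnp", ["np", "nn"] * 20)
        link = pairwise_linkage(a, b)
        assert link.rf == 0.5
        assert link.lod == 0.0
        assert link.phase is None

    def test_repulsion_phase_resolved(self):
        # b is a's complement: complete linkage in repulsion
        a = MarkerSegregation("a", "lmxll", ["lm"] * 50 + ["ll"] * 50)
        b = MarkerSegregation("b", "lmxll", ["ll"] * 50 + ["lm"] * 50)
        link = pairwise_linkage(a, b)
        assert link.rf == pytest.approx(0.0, abs=1e-3)
        assert link.phase is not None and link.phase[0] is True

    def test_too_few_shared_individuals_rejected(self):
        a = MarkerSegregation("a", "lmxll", ["lm"] * 10)
        b = MarkerSegregation("b", "lmxll", ["ll"] * 10)
        with pytest.raises(ValueError):
            pairwise_linkage(a, b)

    @given(st.data())
    def test_g2_matches_scipy_log_likelihood_ratio(self, data):
        rows = data.draw(st.integers(2, 3))
        cols = data.draw(st.integers(2, 3))
        cells = data.draw(
            st.lists(st.integers(1, 40), min_size=rows * cols, max_size=rows * cols)
        )
        table = np.array(cells, dtype=float).reshape(rows, cols)
        g2, _, _, _ = chi2_contingency(table, lambda_="log-likelihood", correction=False)
        assert _g2(table) == pytest.approx(g2, rel=1e-9)

    def test_planted_rf_recovered_within_three_se(self, rng):
        from grasspanel.simulate import SimConfig, simulate_cp_genotypes, MarkerTruth
        from grasspanel.linkage import classify_all

        d = -50 * math.log(1 - 2 * 0.2)  # distance whose Haldane rf is 0.2
        cfg = SimConfig(pop_size=10_000, n_groups=1, group_len_cM=d, seed=13,
                        missing_rate=0, geno_error_rate=0,
                        fail_fraction=0, monomorph_fraction=0)
        markers = [
            MarkerTruth("A", 0, 0.0, "p1het", "segregating"),
            MarkerTruth("B", 0, d, "p1het", "segregating"),
        ]
        geno = simulate_cp_genotypes(markers, cfg, rng)
        segs = classify_all(geno)
        link = pairwise_linkage(segs["A"], segs["B"])
        se = math.sqrt(0.2 * 0.8 / 10_000)
        assert abs(link.rf - 0.2) < 3 * se


class TestHaldane:
    @pytest.mark.parametrize(
        "rf,cm", [(0.0, 0.0), (0.2, 25.54), (0.25, 34.66)]
    )
    def test_known_distances(self, rf, cm):
        assert haldane_cM(rf) == pytest.approx(cm, abs=0.01)

    def test_unlinked_distance_is_infinite(self):
        assert haldane_cM(0.5) == math.inf

    def test_round_trip_identity_on_grid(self):
        for rf in np.linspace(0.0, 0.49, 200):
            assert abs(rf - haldane_rf(haldane_cM(rf))) < 1e-12


class TestGrouping:
    @staticmethod
    def _link(a, b, ind_lod, rf=0.1):
        return PairwiseLinkage(a, b, rf, ind_lod / 2, ind_lod, (False, False), 100)

    def test_two_clusters_separate(self):
        links = [
            self._link("a1", "a2", 30), self._link("a2", "a3", 30),
            self._link("b1", "b2", 30),
        ]
        groups, unmapped = group_markers(["a1", "a2", "a3", "b1", "b2"], links, 4.0)
        assert sorted(map(sorted, groups.values())) == [["a1", "a2", "a3"], ["b1", "b2"]]
        assert unmapped == []

    def test_sub_threshold_marker_unmapped(self):
        links = [self._link("a1", "a2", 30), self._link("a2", "x", 3.9)]
        groups, unmapped = group_markers(["a1", "a2", "x"], links, 4.0)
        assert unmapped == ["x"]

    def test_override_resplits_named_group(self):
        links = [
            self._link("a1", "a2", 30), self._link("b1", "b2", 30),
            self._link("a2", "b1", 6),  # pseudo-linkage bridge
        ]
        groups, _ = group_markers(["a1", "a2", "b1", "b2"], links, 4.0)
        assert len(groups) == 1
        groups, _ = group_markers(["a1", "a2", "b1", "b2"], links, 4.0,
                                  overrides={"LG1": 12.0})
        assert sorted(map(sorted, groups.values())) == [["a1", "a2"], ["b1", "b2"]]


class TestOrdering:
    @staticmethod
    def _links(rfs):
        out = []
        for (a, b), rf in rfs.items():
            out.append(PairwiseLinkage(a, b, rf, 10.0, 20.0, (False, False), 100))
        return out

    def test_three_markers_largest_rf_at_ends(self):
        links = self._links({("a", "b"): 0.1, ("b", "c"): 0.1, ("a", "c"): 0.18})
        order, pos = order_and_position(["a", "b", "c"], links)
        assert order[1] == "b"  # the 0.18 pair sits at the ends
        assert pos[0] == 0.0 and pos[1] > 0 and pos[2] > pos[1]

    def test_cosegregating_markers_tie_stably(self):
        links = self._links({("a", "b"): 0.0, ("a", "c"): 0.1, ("b", "c"): 0.1})
        order, pos = order_and_position(["a", "b", "c"], links)
        ia, ib = order.index("a"), order.index("b")
        assert pos[ia] == pos[ib]

    def test_relabelling_invariance_up_to_reversal(self):
        rfs = {("a", "b"): 0.05, ("b", "c"): 0.10, ("c", "d"): 0.05,
               ("a", "c"): 0.14, ("b", "d"): 0.14, ("a", "d"): 0.17}
        order1, _ = order_and_position(["a", "b", "c", "d"], self._links(rfs))
        relabel = {"a": "w", "b": "x", "c": "y", "d": "z"}
        rfs2 = {(relabel[x], relabel[y]): v for (x, y), v in rfs.items()}
        order2, _ = order_and_position(["w", "x", "y", "z"], self._links(rfs2))
        mapped = [relabel[m] for m in order1]
        assert mapped in (order2, order2[::-1])

    def test_singleton_group(self):
        assert order_and_position(["a"], []) == (["a"], [0.0])


def test_loc_round_trip(tmp_path):
    segs = {
        "m1": MarkerSegregation("m1", "lmxll", ["lm", "ll", MISSING, "lm"] * 25),
        "m2": MarkerSegregation("m2", "hkxhk", ["hh"] * 25 + ["hk"] * 50 + ["kk"] * 25),
        "m3": MarkerSegregation("m3", "uninformative", [MISSING] * 100),
    }
    path = tmp_path / "pop.loc"
    write_loc(segs, path)
    back = read_loc(path)
    assert set(back) == {"m1", "m2"}  # uninformative markers are not written
    assert back["m1"].codes == segs["m1"].codes
    assert back["m2"].seg_type == "hkxhk"
    assert back["m2"].chi2 == pytest.approx(0.0)
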