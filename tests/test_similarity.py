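from __future__ import annotations

import math

import pytest
from hypothesis import given, settings, strategies as st

from metnet.similarity import (
    ComparisonMode,
    compare_pair,
    reaction_union_size,
    sim_pathway,
    sim_structure,
)

from conftest import make_network

SET = ComparisonMode.SET
MULTISET = ComparisonMode.MULTISET


def _pair(plans_a, plans_b, universe=None):
    universe = universe or sorted(set(plans_a) | set(plans_b))
    return (
        make_network(plans_a, org_code="orga", universe=universe),
        make_network(plans_b, org_code="orgb", universe=universe),
    )


class TestSimPathwayCases:
    def test_case1_present_in_exactly_one(self):
        a, b = _pair({"00010": ({"R00001": 1}, set())}, {"00010": None})
        assert sim_pathway(a, b, "00010", SET) == (0.0, "1")
        assert sim_pathway(b, a, "00010", SET) == (0.0, "1")

    def test_case2_physical_in_both(self):
        a, b = _pair({"00010": ({}, set())}, {"00010": ({}, {"C00100"})})
        assert sim_pathway(a, b, "00010", SET) == (1.0, "2")

    def test_case3_set_jaccard(self):
        a, b = _pair(
            {"00010": ({"R00001": 1, "R00002": 1, "R00003": 1}, set())},
            {"00010": ({"R00002": 1, "R00003": 1, "R00004": 1}, set())},
        )
        value, case = sim_pathway(a, b, "00010", SET)
        assert case == "3"
        assert value == pytest.approx(2 / 4)

    def test_case3_multiset_min_max_counts(self):
        a, b = _pair(
            {"00010": ({"R00001": 2, "R00002": 1}, set())},
            {"00010": ({"R00001": 1, "R00002": 2}, set())},
        )
        value, case = sim_pathway(a, b, "00010", MULTISET)
        assert case == "3"
        assert value == pytest.approx((1 + 1) / (2 + 2))

    def test_identical_multiset_scores_one(self):
        a, b = _pair(
            {"00010": ({"R00001": 2, "R00002": 1}, set())},
            {"00010": ({"R00001": 2, "R00002": 1}, set())},
        )
        assert sim_pathway(a, b, "00010", MULTISET) == (1.0, "3")

    def test_mixed_physical_reaction_subcase(self):
        a, b = _pair(
            {"00010": ({}, set())}, {"00010": ({"R00001": 1}, set())}
        )
        assert sim_pathway(a, b, "00010", SET) == (0.0, "3*")
        assert sim_pathway(b, a, "00010", SET) == (0.0, "3*")

    def test_absent_in_both_is_domain_error(self):
        a, b = _pair(
            {"00010": ({}, set()), "00020": None},
            {"00010": ({}, set()), "00020": None},
        )
        with pytest.raises(ValueError, match="absent from both"):
            sim_pathway(a, b, "00020", SET)

    @settings(max_examples=50, deadline=None)
    @given(
        st.dictionaries(
            st.sampled_from([f"R0000{i}" for i in range(1, 8)]),
            st.just(1),
            max_size=6,
        ),
        st.dictionaries(
            st.sampled_from([f"R0000{i}" for i in range(1, 8)]),
            st.just(1),
            max_size=6,
        ),
    )
    def test_set_and_multiset_agree_at_unit_multiplicity(self, ra, rb):
        if not ra and not rb:
            return  # physical pathway: no Jaccard either way
        a, b = _pair({"00010": (ra, set())}, {"00010": (rb, set())})
        v_set, _ = sim_pathway(a, b, "00010", SET)
        v_multi, _ = sim_pathway(a, b, "00010", MULTISET)
        assert v_set == pytest.approx(v_multi, abs=1e-12)


class TestSimStructureCases:
    def test_case1_node_in_one_graph_only(self):
        a, b = _pair(
            {"00010": ({}, set()), "00020": None},
            {"00010": ({}, set()), "00020": ({}, set())},
        )
        assert sim_structure(a, b, "00020") == (0.0, "1")

    def test_case2_isolated_in_both(self):
        a, b = _pair(
            {"00010": ({}, {"C00100"}), "00020": ({}, {"C00200"})},
            {"00010": ({}, {"C00300"}), "00020": ({}, {"C00400"})},
        )
        assert sim_structure(a, b, "00010") == (1.0, "2")

    def test_case3_one_over_one_plus_degree(self):
        # isolated in a; three neighbours in b
        plans_b = {
            "00010": ({}, {"C00100", "C00200", "C00300"}),
            "00020": ({}, {"C00100"}),
            "00030": ({}, {"C00200"}),
            "00040": ({}, {"C00300"}),
        }
        plans_a = {p: ({}, {f"C0090{i}"}) for i, p in enumerate(plans_b)}
        a, b = _pair(plans_a, plans_b)
        assert sim_structure(a, b, "00010") == (pytest.approx(1 / 4), "3")

    def test_case4_edge_set_jaccard(self):
        # a: 00010 adjacent to {00020, 00030}; b: 00010 adjacent to {00030, 00040}
        plans_a = {
            "00010": ({}, {"C00100", "C00200"}),
            "00020": ({}, {"C00100"}),
            "00030": ({}, {"C00200"}),
            "00040": ({}, {"C00900"}),
        }
        plans_b = {
            "00010": ({}, {"C00200", "C00300"}),
            "00020": ({}, {"C00800"}),
            "00030": ({}, {"C00200"}),
            "00040": ({}, {"C00300"}),
        }
        a, b = _pair(plans_a, plans_b)
        value, case = sim_structure(a, b, "00010")
        assert case == "4"
        assert value == pytest.approx(1 / 3)


class TestComparePair:
    def test_identity_scores_one_everywhere(self, simple_pair):
        net_a, _ = simple_pair
        cmp = compare_pair(net_a, net_a, MULTISET)
        assert all(r.sim_p == 1.0 and r.sim_s == 1.0 for r in cmp.rows)
        assert cmp.psim == cmp.psim_w == cmp.ssim == cmp.csim == 1.0

    @pytest.mark.parametrize(
        "mode, expected",
        [
            (SET, {"psim": 7 / 12, "psim_w": 1 / 2, "ssim": 1 / 2, "csim": 1 / 3}),
            (MULTISET, {"psim": 9 / 16, "psim_w": 3 / 7, "ssim": 1 / 2, "csim": 5 / 16}),
        ],
    )
    def test_hand_computed_globals(self, simple_pair, mode, expected):
        """Frozen values hand-enumerated from the simple_pair plans."""
        cmp = compare_pair(*simple_pair, mode)
        for name, value in expected.items():
            assert cmp.globals_dict()[name] == pytest.approx(value, abs=1e-9), name

    def test_rows_cover_domain_sorted(self, simple_pair):
        cmp = compare_pair(*simple_pair, SET)
        assert [r.pathway_number for r in cmp.rows] == [
            "00010",
            "00020",
            "00030",
            "00040",
        ]
        assert cmp.n == 4

    def test_symmetry(self, simple_pair):
        net_a, net_b = simple_pair
        ab = compare_pair(net_a, net_b, MULTISET)
        ba = compare_pair(net_b, net_a, MULTISET)
        for row_ab, row_ba in zip(ab.rows, ba.rows):
            assert row_ab.sim_p == pytest.approx(row_ba.sim_p, abs=1e-12)
            assert row_ab.sim_s == pytest.approx(row_ba.sim_s, abs=1e-12)
        for name in ("psim", "psim_w", "ssim", "csim"):
            assert ab.globals_dict()[name] == pytest.approx(
                ba.globals_dict()[name], abs=1e-12
            )

    def test_weighted_mean_example(self):
        """SimP (1, 0.5) with union sizes (10, 2) -> PsimW = 11/12."""
        ra = {f"R000{i:02d}": 1 for i in range(10)}
        rb = dict(ra)  # identical: SimP = 1, union 10
        sa = {"R00090": 1, "R00091": 1}
        sb = {"R00090": 1}  # one common of union 2: SimP = 0.5
        a, b = _pair(
            {"00010": (ra, set()), "00020": (sa, set())},
            {"00010": (rb, set()), "00020": (sb, set())},
        )
        cmp = compare_pair(a, b, SET)
        assert cmp.psim == pytest.approx(0.75)
        assert cmp.psim_w == pytest.approx(11 / 12)

    def test_all_physical_makes_psimw_undefined(self, caplog):
        a, b = _pair({"00010": ({}, set())}, {"00010": ({}, set())})
        with caplog.at_level("WARNING"):
            cmp = compare_pair(a, b, SET)
        assert math.isnan(cmp.psim_w)
        assert cmp.psim == cmp.ssim == cmp.csim == 1.0
        assert any("PsimW" in m for m in caplog.messages)

    def test_universe_mismatch_rejected(self):
        a = make_network({"00010": ({}, set())})
        b = make_network({"00020": ({}, set())})
        with pytest.raises(ValueError, match="universe"):
            compare_pair(a, b)

    def test_empty_domain_rejected(self):
        a = make_network({"00010": None})
        b = make_network({"00010": None})
        with pytest.raises(ValueError, match="no pathway"):
            compare_pair(a, b)

    def test_absent_everywhere_pathway_excluded_from_denominator(self):
        plans = {"00010": ({"R00001": 1}, set()), "00020": None}
        a, b = _pair(plans, plans)
        cmp = compare_pair(a, b, SET)
        assert cmp.n == 1
        assert cmp.psim == 1.0

    def test_removing_a_shared_reaction_never_increases_simp(self):
        base = {"R00001": 1, "R00002": 1, "R00003": 1}
        for mode in (SET, MULTISET):
            reduced = {"R00001": 1, "R00002": 1}
            a1, b1 = _pair({"00010": (base, set())}, {"00010": (base, set())})
            a2, b2 = _pair({"00010": (reduced, set())}, {"00010": (base, set())})
            before, _ = sim_pathway(a1, b1, "00010", mode)
            after, _ = sim_pathway(a2, b2, "00010", mode)
            assert after <= before


def test_reaction_union_size_modes(simple_pair):
    net_a, net_b = simple_pair
    assert reaction_union_size(net_a, net_b, "00020", SET) == 3
    assert reaction_union_size(net_a, net_b, "00020", MULTISET) == 4
    assert reaction_union_size(net_a, net_b, "00030", SET) == 0
    assert reaction_union_size(net_a, net_b, "00040", SET) == 1
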