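"""Segment multiplication, link distribution and origin tracking."""

import random

import pytest

from gfakit import (
    GfaGraph,
    MultiplicationSpec,
    SegmentEnd,
    multiply,
    plan_distribution,
    select_distribution_end,
    toy_graph,
)
from gfakit.ends import links_of_end
from gfakit.errors import BadFactor, DistributionPreconditionViolated, UnknownSegment

from conftest import random_graph


class TestPlanDistribution:
    def test_three_links_two_copies(self):
        assert plan_distribution([1, 2, 3], 2) == {1: [1, 2], 2: [2, 3]}

    def test_equal_counts(self):
        assert plan_distribution([1, 2], 2) == {1: [1], 2: [2]}

    def test_more_copies_than_links(self):
        assert plan_distribution([1, 2], 3) == {1: [1], 2: [2], 3: []}

    def test_five_links_two_copies(self):
        assert plan_distribution(list(range(1, 6)), 2) == \
            {1: [1, 2, 3, 4], 2: [2, 3, 4, 5]}

    @pytest.mark.parametrize("n,m", [(3, 2), (5, 2), (5, 3), (6, 4), (4, 2)])
    def test_any_m_subset_of_links_remains_usable(self, n, m):
        """Any combination of m of the n links can be assigned to m
        distinct copies (checked by brute-force matching)."""
        from itertools import combinations, permutations

        plan = plan_distribution(list(range(1, n + 1)), m)
        for subset in combinations(range(1, n + 1), m):
            ok = any(all(link in plan[i + 1] for i, link in enumerate(perm))
                     for perm in permutations(subset))
            assert ok, f"subset {subset} not routable under plan {plan}"

    def test_union_covers_all_links_with_run_sizes(self):
        for n in range(1, 8):
            for m in range(2, 6):
                plan = plan_distribution(list(range(1, n + 1)), m)
                covered = set().union(*map(set, plan.values()))
                assert covered == set(range(1, n + 1))
                if n > m:
                    assert all(len(v) == n - m + 1 for v in plan.values())


class TestSelectDistributionEnd:
    def test_exact_match_preferred(self, branch):
        # lambda(B)=1, lambda(E)=3: only E eligible
        assert select_distribution_end(branch, "s", 3) == "E"

    def test_tie_on_exact_match_picks_e(self):
        g = GfaGraph.from_text(
            "S\ts\tACGT\nS\ta\tAC\nS\tb\tAC\nS\tc\tAC\nS\td\tAC\n"
            "L\ta\t+\ts\t+\t0M\nL\tb\t+\ts\t+\t0M\n"
            "L\ts\t+\tc\t+\t0M\nL\ts\t+\td\t+\t0M\n")
        assert select_distribution_end(g, "s", 2) == "E"

    def test_smaller_excess_wins(self):
        # lambda(B)=2, lambda(E)=5, m=2: B has excess 0... both exact? B=2=m
        g = GfaGraph()
        g.add_line("S\ts\tACGT")
        for i in range(2):
            g.add_line(f"S\tb{i}\tAC").add_line(f"L\tb{i}\t+\ts\t+\t0M")
        for i in range(5):
            g.add_line(f"S\te{i}\tAC").add_line(f"L\ts\t+\te{i}\t+\t0M")
        assert select_distribution_end(g, "s", 2) == "B"
        assert select_distribution_end(g, "s", 4) == "E"  # 5-4 < excess on B

    def test_no_eligible_end(self, chain):
        assert select_distribution_end(chain, "B", 2) is None

    def test_unknown_segment(self, chain):
        with pytest.raises(UnknownSegment):
            select_distribution_end(chain, "zz", 2)


class TestMultiply:
    def test_bad_factor(self):
        with pytest.raises(BadFactor):
            MultiplicationSpec(segment="s", factor=1)

    def test_default_duplication_copies_all_links_and_halves_counts(self, branch):
        copies = multiply(branch, MultiplicationSpec(segment="s", factor=2))
        assert copies == ["s_c1", "s_c2"]
        for name in copies:
            assert branch.segment(name).get_tag("RC") == 100
            assert len(branch.links_of_segment(name)) == 4
        assert "s" not in branch.segments

    def test_distribution_worked_example(self, branch):
        """n=3 links on the E end, m=2: S1 gets {L1,L2}, S2 gets {L2,L3}."""
        ordered = [l.to_name for l in sorted(
            branch.links_of_segment("s"),
            key=lambda l: (l.to_name, l.to_orient)) if l.from_name == "s"]
        assert ordered == ["a", "b", "c"]
        multiply(branch, MultiplicationSpec(segment="s", factor=2,
                                            distribution="E"))
        e1 = {l.to_name for l in links_of_end(branch, SegmentEnd("s_c1", "E"))}
        e2 = {l.to_name for l in links_of_end(branch, SegmentEnd("s_c2", "E"))}
        assert e1 == {"a", "b"}
        assert e2 == {"b", "c"}
        # links of the other (B) end are duplicated on each copy
        for name in ("s_c1", "s_c2"):
            assert len(links_of_end(branch, SegmentEnd(name, "B"))) == 1

    def test_last_copies_left_without_links(self):
        g = GfaGraph.from_text(
            "S\ts\tACGT\tcn:i:3\nS\ta\tAC\tcn:i:1\nS\tb\tAC\tcn:i:1\n"
            "L\ts\t+\ta\t+\t0M\nL\ts\t+\tb\t+\t0M\n")
        multiply(g, MultiplicationSpec(segment="s", factor=3, distribution="E"))
        degs = sorted(len(links_of_end(g, SegmentEnd(f"s_c{i}", "E")))
                      for i in (1, 2, 3))
        assert degs == [0, 1, 1]

    def test_auto_distribution_falls_back_to_duplication(self, chain):
        multiply(chain, MultiplicationSpec(segment="C", factor=2,
                                           distribution="auto"))
        for name in ("C_c1", "C_c2"):
            assert len(chain.links_of_segment(name)) == 2

    def test_precondition_requires_cn_tags(self, bubble):
        with pytest.raises(DistributionPreconditionViolated):
            multiply(bubble, MultiplicationSpec(segment="A", factor=2,
                                                distribution="E"))

    def test_precondition_rejects_multicopy_neighbours(self):
        g = GfaGraph.from_text(
            "S\ts\tACGT\tcn:i:2\nS\ta\tAC\tcn:i:3\nS\tb\tAC\tcn:i:1\n"
            "L\ts\t+\ta\t+\t0M\nL\ts\t+\tb\t+\t0M\n")
        with pytest.raises(DistributionPreconditionViolated, match="'a'"):
            multiply(g, MultiplicationSpec(segment="s", factor=2,
                                           distribution="E"))

    def test_origin_survives_two_multiplications(self, branch):
        multiply(branch, MultiplicationSpec(segment="s", factor=2))
        multiply(branch, MultiplicationSpec(segment="s_c1", factor=2))
        assert branch.segment("s_c1_c2").get_tag("or") == "s"

    def test_count_conservation_within_rounding_slack(self):
        rng = random.Random(11)
        for _ in range(25):
            g = random_graph(rng, n_segments=6)
            name = sorted(g.segments)[0]
            c = g.segment(name).get_tag("RC")
            m = rng.randint(2, 5)
            copies = multiply(g, MultiplicationSpec(segment=name, factor=m))
            total = sum(g.segment(cp).get_tag("RC") for cp in copies)
            assert c - m <= total <= c + m
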