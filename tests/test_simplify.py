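"""Mandatory links, invertible segments, coverage filter, p-bubbles."""

import itertools
import random

import pytest

from gfakit import (
    CoverageParams,
    GfaGraph,
    SegmentEnd,
    enforce_mandatory_links,
    filter_by_coverage,
    find_invertible_segments,
    randomly_orient_invertibles,
    remove_p_bubbles,
    toy_graph,
)
from gfakit.ends import link_ends, links_of_end
from gfakit.simplify import inversion_interval

from conftest import backbone_graph


class TestMandatoryLinks:
    def test_competitors_of_mandatory_link_removed(self, branch):
        # u's E end has a single link to s's B end; s's B end has no
        # competitors, but each of a, b, c has a single link to s's E end
        # whose competitors are the links to the other two
        enforce_mandatory_links(branch)
        # a's B..E single link to (s,E) makes the other two superfluous,
        # but the same rule holds symmetrically for b and c; the fixed
        # point keeps exactly one of the three (the first processed wins)
        assert len(links_of_end(branch, SegmentEnd("s", "E"))) == 1

    def test_single_link_end_prunes_other_end_links(self):
        # x's E end has the single link to y's B end, so the two
        # competing links of y's B end are superfluous
        g = GfaGraph.from_text(
            "S\tx\tAC\nS\ty\tGT\nS\tp\tAA\nS\tq\tCC\n"
            "L\tx\t+\ty\t+\t0M\n"
            "L\tp\t+\ty\t+\t0M\n"
            "L\tq\t+\ty\t+\t0M\n"
            "L\tp\t+\tq\t-\t0M\n")
        enforce_mandatory_links(g)
        keys = {(l.from_name, l.to_name) for l in g.links}
        assert keys == {("x", "y"), ("p", "q")}

    def test_cascades_to_fixed_point(self):
        # true chain a-b-c-d with two spurious shortcuts from a's E end;
        # pruning at c exposes a new single-link end, pruning again at a
        g = GfaGraph.from_text(
            "S\ta\tAC\nS\tb\tGT\nS\tc\tAA\nS\td\tCC\n"
            "L\ta\t+\tb\t+\t0M\n"
            "L\tb\t+\tc\t+\t0M\n"
            "L\tc\t+\td\t+\t0M\n"
            "L\ta\t+\tc\t+\t0M\n"   # spurious
            "L\ta\t+\td\t+\t0M\n")  # spurious
        enforce_mandatory_links(g)
        keys = {(l.from_name, l.to_name) for l in g.links}
        assert keys == {("a", "b"), ("b", "c"), ("c", "d")}

    def test_sole_self_link_kept(self):
        g = GfaGraph.from_text("S\tA\tACGT\nL\tA\t+\tA\t+\t0M\n")
        enforce_mandatory_links(g)
        assert len(g.links) == 1

    def test_self_link_with_other_links_removed(self):
        g = toy_graph("self_loop")
        enforce_mandatory_links(g)
        assert all(l.from_name != l.to_name for l in g.links)

    def test_idempotent(self):
        rng = random.Random(21)
        for _ in range(20):
            g = backbone_graph(rng, rng.randint(3, 8), rng.randint(0, 4))
            enforce_mandatory_links(g)
            once = g.to_text()
            enforce_mandatory_links(g)
            assert g.to_text() == once

    def test_never_removes_unique_link_of_both_ends(self, chain):
        before = len(chain.links)
        enforce_mandatory_links(chain)
        assert len(chain.links) == before

    def test_hamiltonian_safety_on_small_backbones(self):
        """Links used by every Hamiltonian end-to-end traversal survive
        (exhaustive enumeration on graphs of <= 8 segments)."""
        rng = random.Random(77)
        checked = 0
        for _ in range(60):
            n = rng.randint(3, 8)
            g = backbone_graph(rng, n, rng.randint(0, 3))
            hams = _hamiltonian_traversals(g)
            if not hams:
                continue
            essential = set.intersection(*[set(h) for h in hams])
            enforce_mandatory_links(g)
            surviving = {id(l) for l in g.links}
            assert essential <= surviving
            checked += 1
        assert checked >= 10

    def test_orient_then_enforce_examples(self):
        # e has one link to e2; e2 carries three links: two deleted
        g = GfaGraph.from_text(
            "S\ta\tAC\nS\tb\tGT\nS\tc\tAA\nS\td\tCC\n"
            "L\ta\t+\tb\t+\t0M\nL\tc\t+\tb\t+\t0M\nL\td\t+\tb\t+\t0M\n"
            "L\tc\t+\td\t+\t0M\n")
        enforce_mandatory_links(g)
        assert len(links_of_end(g, SegmentEnd("b", "B"))) == 1


def _hamiltonian_traversals(g: GfaGraph):
    """All molecule traversals visiting every segment exactly once and
    starting/ending at dead ends, as tuples of link ids (brute force).

    The mandatory-link rule assumes the component is one molecule whose
    ends are known, so only dead-end-to-dead-end traversals qualify.
    """
    from gfakit.ends import other_link_end

    names = sorted(g.segments)
    dead = {SegmentEnd(n, et) for n in names for et in "BE"
            if not links_of_end(g, SegmentEnd(n, et))}
    results = []

    def step(exit_end, used, trail):
        if len(used) == len(names):
            if exit_end in dead:
                results.append(tuple(trail))
            return
        for link in links_of_end(g, exit_end):
            nxt = other_link_end(link, exit_end)
            if nxt.segment in used:
                continue
            step(nxt.other, used | {nxt.segment}, trail + [id(link)])

    for start in dead:
        step(start.other, {start.segment}, [])
    return results


class TestInvertibleSegments:
    def test_catalogue_example_detected(self):
        g = toy_graph("invertible")
        assert find_invertible_segments(g) == ["X"]

    def test_one_sided_linkage_not_invertible(self, chain):
        assert find_invertible_segments(chain) == []

    def test_self_link_excluded(self):
        g = toy_graph("invertible")
        g.add_line("L\tX\t+\tX\t+\t0M")
        assert find_invertible_segments(g) == []

    def test_inversion_interval_of_uvu(self):
        # ACG | T | CGT : u = ACG, v = T
        assert inversion_interval("ACGTCGT") == (4, 4)

    def test_inversion_interval_palindrome_empty(self):
        seq = "ACGT"  # perfect reverse-complement palindrome
        assert inversion_interval(seq) == (3, 2)

    def test_random_orientation_prunes_to_one_link_per_end(self):
        g = toy_graph("invertible")
        randomly_orient_invertibles(g, seed=5)
        assert len(links_of_end(g, SegmentEnd("X", "B"))) == 1
        assert len(links_of_end(g, SegmentEnd("X", "E"))) == 1
        assert g.segment("X").get_tag("rn") == [4, 4]

    def test_reproducible_for_same_seed(self):
        texts = set()
        for _ in range(3):
            g = toy_graph("invertible")
            randomly_orient_invertibles(g, seed=17)
            texts.add(g.to_text())
        assert len(texts) == 1

    def test_component_granular_interval_from_tracking(self):
        # merged segment w x w' where w' = revcomp(w): rn covers x
        w, x = "ACGTT", "GGAGGAG"
        seq = w + x + "AACGT"
        g = GfaGraph.from_text(
            f"S\tM\t{seq}\tor:Z:w,x,w2\tmp:B:i,1,6,13\n"
            "S\tA\tACCA\nS\tC\tTGGT\n"
            "L\tA\t+\tM\t+\t0M\nL\tA\t+\tM\t-\t0M\n"
            "L\tM\t+\tC\t+\t0M\nL\tM\t-\tC\t+\t0M\n")
        randomly_orient_invertibles(g, seed=1)
        assert g.segment("M").get_tag("rn") == [6, 12]


class TestCoverageFilter:
    params = CoverageParams("RC", 1)

    def test_low_coverage_removed(self, bubble):
        # b1 has RC 40 over 6 bp -> coverage 6.7, below the 10x cutoff
        filter_by_coverage(bubble, 10, 0, self.params)
        assert "b1" not in bubble.segments
        assert {"A", "b2", "C"} <= set(bubble.segments)

    def test_thresholds(self):
        g = GfaGraph.from_text(
            "S\tlo\t" + "A" * 10 + "\tRC:i:50\n"     # coverage 5
            "S\thi\t" + "C" * 10 + "\tRC:i:500\n"    # coverage 50
            "L\tlo\t+\thi\t+\t0M\n")
        filter_by_coverage(g, 10, 0, self.params)
        assert set(g.segments) == {"hi"}

    def test_short_isolated_removed_linked_kept(self):
        g = GfaGraph.from_text(
            "S\tiso\t" + "A" * 150 + "\tRC:i:100000\n"
            "S\tl1\t" + "C" * 150 + "\tRC:i:100000\n"
            "S\tl2\t" + "G" * 150 + "\tRC:i:100000\n"
            "L\tl1\t+\tl2\t+\t0M\n")
        filter_by_coverage(g, 10, 200, self.params)
        assert set(g.segments) == {"l1", "l2"}


class TestPBubbles:
    params = CoverageParams("RC", 1)

    def test_lower_coverage_branch_discarded(self, bubble):
        remove_p_bubbles(bubble, self.params)
        assert "b1" not in bubble.segments
        assert "b2" in bubble.segments
        assert bubble.validate_references() == []

    def test_equal_coverage_tie_deletes_larger_name(self):
        g = toy_graph("bubble")
        g.segment("b1").set_tag("RC", 300)  # same as b2
        remove_p_bubbles(g, self.params)
        assert "b1" in g.segments and "b2" not in g.segments

    def test_side_link_disqualifies_bubble(self, bubble):
        bubble.add_line("S\tW\tTTTT\tRC:i:9\n")
        bubble.add_line("L\tb1\t+\tW\t+\t0M")
        before = set(bubble.segments)
        remove_p_bubbles(bubble, self.params)
        assert set(bubble.segments) == before


def test_operators_never_break_referential_integrity():
    rng = random.Random(31)
    for _ in range(10):
        g = backbone_graph(rng, rng.randint(3, 8), rng.randint(0, 4))
        for seg in g.segments.values():
            seg.set_tag("RC", rng.randint(10, 400))
        n_before = len(g.segments) + len(g.links)
        enforce_mandatory_links(g)
        remove_p_bubbles(g, CoverageParams("RC", 1))
        filter_by_coverage(g, 1.0, 0, CoverageParams("RC", 1))
        assert len(g.segments) + len(g.links) <= n_before
        assert g.validate_references() == []
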