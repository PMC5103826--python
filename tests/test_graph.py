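"""Graph container: indexing, cascade deletion, renaming, stats, I/O."""

import random

import networkx as nx
import pytest

from gfakit import (
    GfaGraph,
    LinkRecord,
    SegmentRecord,
    diff_graphs,
    read_gfa,
    toy_graph,
    write_gfa,
)
from gfakit.errors import (
    DanglingReferences,
    DuplicateName,
    MissingLength,
    ParseError,
    UnknownName,
    UnknownSegment,
)
from gfakit.fixtures import TOY_GRAPHS

from conftest import random_graph


class TestAddRecord:
    def test_duplicate_segment_name(self):
        g = GfaGraph().add_line("S\tA\tACGT")
        with pytest.raises(DuplicateName):
            g.add_line("S\tA\tTTTT")

    def test_link_before_segments_resolves_later(self):
        g = GfaGraph().add_line("L\tA\t+\tB\t+\t0M")
        assert len(g.validate_references()) == 2
        g.add_line("S\tA\tACGT").add_line("S\tB\tACGT")
        assert g.validate_references() == []

    def test_header_appended(self):
        g = GfaGraph().add_line("H\tVN:Z:1.0")
        assert len(g.headers) == 1

    def test_strand_flipped_duplicate_link_stored_once(self):
        g = GfaGraph().add_line("S\tA\tAC").add_line("S\tB\tGT")
        g.add_line("L\tA\t+\tB\t+\t0M")
        g.add_line("L\tB\t-\tA\t-\t0M")  # same junction, other strand
        assert len(g.links) == 1


class TestDeleteSegment:
    def test_cascade_removes_links(self, chain):
        chain.delete_segment("B")
        assert "B" not in chain.segments
        assert all("B" not in (l.from_name, l.to_name) for l in chain.links)
        assert {"A", "C", "D", "E"} <= set(chain.segments)

    def test_cascade_removes_whole_path(self):
        g = toy_graph("chain")
        g.add_line("P\tp1\tA+,B+\t0M")
        g.delete_segment("B")
        assert "p1" not in g.paths

    def test_no_cascade_raises_on_references(self, chain):
        with pytest.raises(DanglingReferences):
            chain.delete_segment("B", cascade=False)

    def test_unknown_segment(self, chain):
        with pytest.raises(UnknownSegment):
            chain.delete_segment("nope")

    def test_no_stale_references_after_cascade(self, any_toy_graph):
        g = any_toy_graph
        for name in list(g.segments):
            g.delete_segment(name)
            cited = {n for l in g.links for n in (l.from_name, l.to_name)}
            cited |= {n for c in g.containments for n in (c.from_name, c.to_name)}
            cited |= {n for p in g.paths.values() for n, _ in p.segment_names}
            assert name not in cited


class TestRename:
    def test_link_references_updated(self, chain):
        chain.rename("A", "X")
        assert any(l.from_name == "X" for l in chain.links)
        assert chain.validate_references() == []

    def test_path_rename_leaves_segments(self):
        g = toy_graph("chain")
        g.add_line("P\tp1\tA+,B+\t0M")
        g.rename("p1", "p2")
        assert "p2" in g.paths and "p1" not in g.paths
        assert set(g.segments) == {"A", "B", "C", "D", "E"}

    def test_rename_to_existing_name(self, chain):
        with pytest.raises(DuplicateName):
            chain.rename("A", "B")

    def test_rename_unknown(self, chain):
        with pytest.raises(UnknownName):
            chain.rename("zz", "yy")


class TestInfo:
    def test_single_isolated_segment(self):
        g = GfaGraph().add_line("S\tA\tACGT")
        info = g.info()
        assert info.n_connected_components == 1
        assert info.n_dead_ends == 2

    def test_n50_small_example(self):
        g = GfaGraph()
        for i, n in enumerate([2, 3, 4, 5, 6]):
            g.add_record(SegmentRecord(name=f"s{i}", sequence="A" * n))
        assert g.info().n50 == 5

    def test_two_disjoint_pairs(self):
        info = toy_graph("two_components").info()
        assert info.n_connected_components == 2
        assert info.n_dead_ends == 4

    def test_missing_length(self):
        g = GfaGraph().add_line("S\tA\t*")
        with pytest.raises(MissingLength):
            g.info()

    def test_against_bruteforce_oracle(self):
        rng = random.Random(7)
        for _ in range(20):
            g = random_graph(rng, n_segments=rng.randint(1, 50))
            info = g.info()
            lengths = sorted((len(s.sequence) for s in g.segments.values()),
                             reverse=True)
            total = sum(lengths)
            acc, n50 = 0, 0
            for length in lengths:
                acc += length
                if 2 * acc >= total:
                    n50 = length
                    break
            assert info.n50 == n50
            assert info.total_length == total
            nxg = nx.Graph()
            nxg.add_nodes_from(g.segments)
            nxg.add_edges_from((l.from_name, l.to_name) for l in g.links)
            assert info.n_connected_components == nx.number_connected_components(nxg)


class TestIO:
    def test_toy_file_roundtrip(self, tmp_path):
        text = "H\tVN:Z:1.0\nS\tA\tACGT\nS\tB\tTTTT\n"
        path = tmp_path / "toy.gfa"
        path.write_text(text)
        g = read_gfa(path)
        assert len(g.segments) == 2
        assert write_gfa(g) == text

    @pytest.mark.parametrize("name", TOY_GRAPHS)
    def test_write_read_empty_diff(self, name):
        g = toy_graph(name)
        again = GfaGraph.from_text(write_gfa(g))
        assert diff_graphs(g, again).empty

    def test_strict_mode_names_missing_segment(self, tmp_path):
        path = tmp_path / "bad.gfa"
        path.write_text("S\tA\tACGT\nL\tA\t+\tZmissing\t+\t0M\n")
        with pytest.raises(UnknownName, match="Zmissing"):
            read_gfa(path, strict=True)

    def test_parse_error_carries_line_number(self, tmp_path):
        path = tmp_path / "bad.gfa"
        path.write_text("S\tA\tACGT\nX\twhat\n")
        with pytest.raises(ParseError, match="line 2"):
            read_gfa(path)

    def test_lenient_mode_keeps_opaque_lines(self, tmp_path):
        path = tmp_path / "bad.gfa"
        path.write_text("S\tA\tACGT\nX\twhat\n")
        g = read_gfa(path, lenient=True)
        assert len(g.opaque) == 1
        assert "X\twhat" in write_gfa(g)

    def test_empty_lines_skipped(self):
        g = GfaGraph.from_text("\nS\tA\tACGT\n\n")
        assert set(g.segments) == {"A"}


class TestPathValidation:
    def test_complete_toy_graph_clean(self, any_toy_graph):
        assert any_toy_graph.validate_references() == []

    def test_unsupported_path_junction(self):
        g = GfaGraph.from_text("S\tA\tAC\nS\tB\tGT\nP\tp\tA+,B+\t*\n")
        assert len(g.validate_references()) == 1

    def test_path_junction_matches_either_strand(self):
        g = GfaGraph.from_text(
            "S\tA\tAC\nS\tB\tGT\nL\tB\t-\tA\t-\t0M\nP\tp\tA+,B+\t0M\n")
        assert g.validate_references() == []


def test_referential_integrity_after_random_operations():
    """add/delete/rename sequences keep the graph internally consistent."""
    rng = random.Random(99)
    for _ in range(10):
        g = random_graph(rng, n_segments=12)
        for _ in range(30):
            op = rng.choice(["delete", "rename", "add"])
            names = sorted(g.segments)
            if op == "delete" and names:
                g.delete_segment(rng.choice(names))
            elif op == "rename" and names:
                new = f"r{rng.randint(0, 10**6)}"
                if new not in g.segments:
                    g.rename(rng.choice(names), new)
            else:
                new = f"n{rng.randint(0, 10**6)}"
                if new not in g.segments:
                    g.add_record(SegmentRecord(name=new, sequence="ACGT"))
        assert g.validate_references() == []
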