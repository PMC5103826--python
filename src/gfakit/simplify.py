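"""Topology-driven cleanup operators.

These operators assume (like the assembly-finishing workflow they come
from) that each connected component of the graph represents a single
molecule whose ends are known — either two dead ends or a circular
structure.  Under that assumption:

* **mandatory links** — if a segment end has exactly one link, that link
  must be used by any Hamiltonian path, so every *other* link of the end
  it connects to is superfluous and can be removed; self-links are
  superfluous unless they are the segment's only link.  The rule is
  iterated to a fixed point, since each removal can create new
  single-link ends.
* **invertible segments** — a segment whose two ends both link to the
  same two foreign ends has an undecidable orientation; it can be
  oriented at random, recording the coordinates of the possible
  inversion in the custom ``rn`` integer-array tag.  Writing the segment
  as u v u' with u' the reverse complement of the longest such prefix u,
  the two orientations differ only in v, so ``rn`` stores v's 1-based
  interval.
* **coverage filter** — removes segments below a minimal coverage and
  isolated segments shorter than a length cutoff.
* **p-bubbles** — two parallel segments spanning the same pair of ends
  with no other links (a polymorphism/error signature); the lower
  coverage branch is discarded.
"""

from __future__ import annotations

import logging
import random

from ._sequence import revcomp
from .coverage import CoverageParams, segment_coverage
from .ends import SegmentEnd, link_ends, links_of_end
from .errors import MissingSequence
from .graph import GfaGraph

logger = logging.getLogger(__name__)

__all__ = ["enforce_mandatory_links", "find_invertible_segments",
           "randomly_orient_invertibles", "filter_by_coverage",
           "remove_p_bubbles", "inversion_interval"]


def _component_assumption_warnings(graph: GfaGraph) -> None:
    """Warn for components that look neither linear (two dead ends) nor
    circular; the mandatory-link rule may be unsafe there."""
    comp: dict[str, str] = {}
    for name in graph.segments:
        comp[name] = name

    def find(x: str) -> str:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for link in graph.links:
        if link.from_name in comp and link.to_name in comp:
            ra, rb = find(link.from_name), find(link.to_name)
            if ra != rb:
                comp[ra] = rb
    dead: dict[str, int] = {}
    for name in graph.segments:
        root = find(name)
        for et in "BE":
            if not links_of_end(graph, SegmentEnd(name, et)):
                dead[root] = dead.get(root, 0) + 1
        dead.setdefault(root, dead.get(root, 0))
    for root, n_dead in dead.items():
        if n_dead not in (0, 2):  # 0 = circular, 2 = linear molecule
            logger.warning(
                "component of %r has %d dead ends; the one-molecule "
                "assumption of mandatory-link enforcement may not hold",
                root, n_dead)


def enforce_mandatory_links(graph: GfaGraph) -> GfaGraph:
    """Remove all links that compete with a mandatory link (fixed point).

    Ends are processed in lexicographic (name, B before E) order; the
    fixed point does not depend on the order, only the log does.
    """
    _component_assumption_warnings(graph)
    # superfluous self-links first
    for name in sorted(graph.segments):
        self_links = [l for l in graph.links_of_segment(name)
                      if l.from_name == l.to_name == name]
        if self_links and len(graph.links_of_segment(name)) > len(self_links):
            for link in self_links:
                graph.delete_link(link)
        elif len(self_links) > 1:  # keep one, the rest are superfluous
            for link in self_links[1:]:
                graph.delete_link(link)
    changed = True
    while changed:
        changed = False
        for name in sorted(graph.segments):
            for et in "BE":
                e = SegmentEnd(name, et)
                links = links_of_end(graph, e)
                if len(links) != 1:
                    continue
                mandatory = links[0]
                if mandatory.from_name == mandatory.to_name:
                    continue  # a sole self-link is kept, nothing competes
                e1, e2 = link_ends(mandatory)
                other = e2 if e1 == e else e1
                for competitor in links_of_end(graph, other):
                    if competitor is not mandatory:
                        graph.delete_link(competitor)
                        changed = True
    return graph


def find_invertible_segments(graph: GfaGraph) -> list[str]:
    """Segments whose B and E ends link to the same two foreign ends."""
    out = []
    for name in sorted(graph.segments):
        ends = {SegmentEnd(name, "B"), SegmentEnd(name, "E")}
        neighbour_sets = []
        for e in ends:
            nbrs = set()
            for link in links_of_end(graph, e):
                e1, e2 = link_ends(link)
                nbrs.add(e2 if e1 == e else e1)
            neighbour_sets.append(nbrs)
        a, b = neighbour_sets
        if a == b and len(a) == 2 and not (a & ends):
            out.append(name)
    return out


def inversion_interval(seq: str) -> tuple[int, int]:
    """1-based interval [|u|+1, |s|-|u|] of the middle part v of s = u v u',
    u the longest prefix whose reverse complement u' is a suffix.

    For a perfect palindrome (empty v) the interval is empty
    (start = |u|+1, stop = |u|).
    """
    n = len(seq)
    best = 0
    for k in range(1, n // 2 + 1):
        if seq[n - k:] == revcomp(seq[:k]):
            best = k
    return (best + 1, n - best)


def randomly_orient_invertibles(graph: GfaGraph, seed: int) -> GfaGraph:
    """Fix a random orientation for every invertible segment.

    For each such segment one of the two link pairings is kept (the
    duplicate pair is deleted so that each end retains a single link)
    and the possible-inversion coordinates are stored in the ``rn`` tag.
    If the segment carries ``or``/``mp`` merge tracking and its first
    and last components are reverse complements of each other, the
    stored interval is that of the middle components.
    """
    rng = random.Random(seed)
    for name in find_invertible_segments(graph):
        seg = graph.segment(name)
        if seg.sequence == "*":
            raise MissingSequence(f"invertible segment {name!r} has no sequence")
        b_end, e_end = SegmentEnd(name, "B"), SegmentEnd(name, "E")
        foreign = sorted({(e2 if e1 == b_end else e1)
                          for l in links_of_end(graph, b_end)
                          for e1, e2 in [link_ends(l)]})
        f1, f2 = foreign
        # keep (B-f1, E-f2) or (B-f2, E-f1), at random
        if rng.random() < 0.5:
            keep = {(b_end, f1), (e_end, f2)}
        else:
            keep = {(b_end, f2), (e_end, f1)}
        for e in (b_end, e_end):
            for link in links_of_end(graph, e):
                e1, e2 = link_ends(link)
                other = e2 if e1 == e else e1
                if (e, other) not in keep:
                    graph.delete_link(link)

        interval = None
        origins = seg.get_tag("or")
        mp = seg.get_tag("mp")
        if origins and mp:
            tokens = origins.split(",")
            if len(tokens) >= 3 and len(tokens) == len(mp):
                first_len = mp[1] - mp[0]
                last_start = mp[-1]
                last_len = len(seg.sequence) - last_start + 1
                if (first_len == last_len
                        and seg.sequence[last_start - 1:]
                        == revcomp(seg.sequence[:first_len])):
                    interval = (mp[1], last_start - 1)
        if interval is None:
            interval = inversion_interval(seg.sequence)
        seg.set_tag("rn", list(interval))
    return graph


def filter_by_coverage(graph: GfaGraph, min_cov: float,
                       min_isolated_len: int,
                       coverage_params: CoverageParams) -> GfaGraph:
    """Delete segments with coverage < min_cov, plus isolated segments
    shorter than min_isolated_len.  Conditions are evaluated on the
    input graph, then deletions cascade."""
    doomed = []
    for name in sorted(graph.segments):
        seg = graph.segment(name)
        if segment_coverage(seg, coverage_params) < min_cov:
            doomed.append(name)
            continue
        isolated = not graph.links_of_segment(name)
        if isolated and graph.segment_length(name) < min_isolated_len:
            doomed.append(name)
    for name in doomed:
        graph.delete_segment(name, cascade=True)
    return graph


def _bubble_signature(graph: GfaGraph, name: str):
    """(frozen pair of foreign attachment ends) if the segment's links
    are exactly one per end to two distinct foreign ends, else None."""
    b_links = links_of_end(graph, SegmentEnd(name, "B"))
    e_links = links_of_end(graph, SegmentEnd(name, "E"))
    if len(b_links) != 1 or len(e_links) != 1 or b_links[0] is e_links[0]:
        return None
    attach = []
    for e, link in ((SegmentEnd(name, "B"), b_links[0]),
                    (SegmentEnd(name, "E"), e_links[0])):
        e1, e2 = link_ends(link)
        other = e2 if e1 == e else e1
        if other.segment == name:
            return None
        attach.append(other)
    return frozenset(attach)


def remove_p_bubbles(graph: GfaGraph, coverage_params: CoverageParams) -> GfaGraph:
    """Remove simple two-branch bubbles, keeping the higher coverage
    branch (ties: the lexicographically smaller name survives)."""
    changed = True
    while changed:
        changed = False
        sigs: dict[frozenset, list[str]] = {}
        for name in sorted(graph.segments):
            sig = _bubble_signature(graph, name)
            if sig is not None:
                sigs.setdefault(sig, []).append(name)
        for sig, members in sorted(sigs.items(),
                                   key=lambda kv: sorted(kv[1])):
            if len(members) < 2:
                continue
            a, b = members[0], members[1]
            cov = {n: segment_coverage(graph.segment(n), coverage_params)
                   for n in (a, b)}
            # delete the lower coverage branch; on a tie the larger name
            if cov[a] == cov[b]:
                loser = max(a, b)
            else:
                loser = a if cov[a] < cov[b] else b
            graph.delete_segment(loser, cascade=True)
            changed = True
            break  # signatures may have changed; rescan
    return graph
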