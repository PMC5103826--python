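"""Estimate copy numbers from read counts, then multiply a repeat.

A segment covered at twice the single-copy depth represents two joined
occurrences of the same sequence.  Multiplication replaces it by two
copies (counts divided) and, because everything reachable is
single-copy, distributes the three links of its E end over the copies
so that two links per copy remain traversable in any combination.
"""

from gfakit import (
    CopyNumberParams,
    CoverageParams,
    MultiplicationSpec,
    SegmentEnd,
    multiply,
    tag_copy_numbers,
    toy_graph,
)
from gfakit.ends import links_of_end

graph = toy_graph("branch")   # segment s: 1 link on B, 3 links on E

tag_copy_numbers(graph, CoverageParams("RC", 1), CopyNumberParams(scov=10))
for name, seg in sorted(graph.segments.items()):
    print(f"{name}: coverage tag RC={seg.get_tag('RC')}  cn={seg.get_tag('cn')}")
# s has double the read count of its neighbours -> cn = 2

copies = multiply(graph, MultiplicationSpec(segment="s", factor=2,
                                            distribution="E"))
print("\ncopies:", copies)
for name in copies:
    partners = sorted(l.to_name for l in links_of_end(graph, SegmentEnd(name, "E")))
    print(f"{name} E-end links -> {partners}")
# with n=3 links and m=2 copies each copy keeps n-m+1 = 2 links:
# {a,b} on the first copy and {b,c} on the second
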