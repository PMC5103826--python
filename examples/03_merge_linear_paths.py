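"""Collapse unambiguous chains of segments into single segments.

A segment with exactly one link at each end is internal to a linear
path; merging concatenates the sequences (reverse-complementing
segments entered from their E end), sums the count tags and records
the component origins (or) and their start offsets (mp).
"""

from gfakit import find_linear_paths, merge_all_linear_paths, toy_graph

graph = toy_graph("chain")
paths = find_linear_paths(graph)
print("linear paths found:", [[str(os) for os in p.items] for p in paths])

merge_all_linear_paths(graph, track=True)
(merged,) = graph.segments.values()
print("merged segment:", merged.name)
print("sequence:      ", merged.sequence)
print("origins (or):  ", merged.get_tag("or"))
print("offsets (mp):  ", merged.get_tag("mp"))
print("summed RC:     ", merged.get_tag("RC"))
# the mp offsets are the 1-based start of each original segment inside
# the merged sequence; RC is the sum of the component read counts
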