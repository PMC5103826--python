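"""Parse a small GFA1 graph, inspect it, edit it, write it back.

The graph statistics summarise assembly fragmentation: segment count,
connected components, dead ends (segment ends without links) and the
N50 of the segment lengths.
"""

from gfakit import GfaGraph, write_gfa

TEXT = """\
H\tVN:Z:1.0
S\tcontig1\tACGTACGTAC\tRC:i:120
S\tcontig2\tTTGACC\tRC:i:80
S\tcontig3\tGGCAT\tRC:i:15
L\tcontig1\t+\tcontig2\t+\t0M
"""

graph = GfaGraph.from_text(TEXT)

info = graph.info()
print("segments:", info.n_segments, "links:", info.n_links)
print("components:", info.n_connected_components,
      "dead ends:", info.n_dead_ends)
print("total bp:", info.total_length, "N50:", info.n50)
# contig3 is isolated, so it contributes one component and two dead ends

graph.rename("contig3", "orphan")          # all references follow the name
graph.segment("orphan").set_tag("xx", 1)   # custom tags are one call
graph.delete_segment("contig2")            # cascades to the link

print("\nedited graph:")
print(write_gfa(graph), end="")
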