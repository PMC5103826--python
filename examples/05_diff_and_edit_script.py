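"""Compare two graphs semantically and replay the difference.

Tag order, line order, float formatting and the strand in which a link
is written are ignored; real differences are reported per field and can
be serialized as an edit script whose replay turns the first graph into
the second.
"""

from gfakit import (
    apply_edit_script,
    diff_graphs,
    emit_edit_script,
    graphs_equal,
    render_report,
    toy_graph,
)

g1 = toy_graph("chain")
g2 = toy_graph("chain")
g2.segments["C"].set_tag("RC", 9999)   # field-level change
g2.delete_segment("E")                 # removal (cascades to the D-E link)
g2.add_line("S\tnew\tGGGG")            # addition

report = diff_graphs(g1, g2)
print(render_report(report), end="")
# '<' removed, '>' added, '|' changed-in-place records

script = emit_edit_script(report)
print("\nedit script:")
print("\n".join(script))

apply_edit_script(g1, script)
print("\nafter replay, graphs equal:", graphs_equal(g1, g2))
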