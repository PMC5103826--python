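"""Topology cleanup: p-bubbles, mandatory links, invertible segments.

These operators assume each connected component is a single molecule
with known ends.  A p-bubble (two parallel segments between the same
end pair) keeps the higher-coverage branch; a segment end with a single
link makes that link mandatory, so competitors at the far end are
superfluous; a segment whose both ends link to the same two foreign
ends has an undecidable orientation and is oriented at random, the
ambiguous interval being recorded in the rn tag.
"""

from gfakit import (
    CoverageParams,
    enforce_mandatory_links,
    find_invertible_segments,
    randomly_orient_invertibles,
    remove_p_bubbles,
    toy_graph,
)

bubble = toy_graph("bubble")
remove_p_bubbles(bubble, CoverageParams("RC", 1))
print("bubble survivors:", sorted(bubble.segments))
# b1 (40x) lost against b2 (300x)

chain = toy_graph("chain")
n_before = len(chain.links)
enforce_mandatory_links(chain)
print(f"chain links: {n_before} -> {len(chain.links)} (all mandatory, none removed)")

inv = toy_graph("invertible")
print("invertible segments:", find_invertible_segments(inv))
randomly_orient_invertibles(inv, seed=42)
x = inv.segment("X")
print("chosen orientation is recorded; possible inversion at rn =",
      x.get_tag("rn"))
# rn is the 1-based interval of the middle part v of X = u v u'
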