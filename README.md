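# gfakit

Library and command-line toolkit for handling **GFA 1.0 assembly
graphs**: parsing, validation, editing, graph simplification, semantic
comparison, and a worked application — detecting CRISPR arrays in de
Bruijn graphs.

Assembly programs (de Bruijn- and string-graph-based alike) can export
their graph in the Graphical Fragment Assembly (GFA) text format:
segments (S) carrying double-stranded sequences, links (L) and
containments (C) representing suffix–prefix matches between oriented
segments, paths (P) and headers (H).  The graph holds strictly more
information than the contig FASTA — every alternative resolution of a
repeat is still in there — so finishing an assembly, or mining the
graph for biological signatures, is a matter of *editing the graph*.
gfakit is aimed at bioinformaticians who want to script such edits in
Python instead of clicking through a GUI.

## The model in brief

**Segment ends.**  Every segment `s` has a B end (before the first base
of the forward strand) and an E end (after the last).  A link touches
one end of each segment: the B end collects links *from s in reverse*
or *to s in forward* orientation, the E end the complementary cases.
All traversal code works on ends; λ(s, ω) denotes the number of links
of end ω.

**Coverage and copy number.**  With count `c` (RC reads / KC k-mers /
FC fragments) and unit length ℓ,

    coverage(c, s, ℓ) = c / (|s| − ℓ + 1)

and for a user-supplied single-copy coverage *scov* (minimal coverage
*mincov* = 0.25·*scov* by default),

    cn = 0                      if cov < mincov
    cn = 1                      if mincov ≤ cov < 1.5·scov
    cn = ⌊cov/scov + 0.5⌋       otherwise.

**Multiplication with link distribution.**  A segment with cn = m is
replaced by m copies (counts divided).  If everything reachable is
single-copy, the n links of one end are distributed over the copies:
copy `i` receives links `Lᵢ … L_{i+n−m}` (n − m + 1 each when n > m),
which removes spurious duplicates while keeping every combination of m
of the n links traversable.

**Linear paths.**  A chain through single-link ends and internal
segments (λ = 1 at both ends) is merged into one segment —
reverse-complementing components entered at their E end, trimming `nM`
junction overlaps, summing counts, and recording origins/offsets in the
`or`/`mp` tags.

**Cleanup operators.**  Under the one-molecule-per-component
assumption: a single-link end makes its link *mandatory* and all
competitors at the far end superfluous; two parallel segments spanning
the same end pair form a *p-bubble* (the lower-coverage branch is
dropped); a segment whose two ends link to the same two foreign ends is
*invertible* and gets a random orientation with the ambiguous interval
recorded in the `rn` tag.

**Semantic diff.**  Graphs are compared at field granularity — blind to
line order, tag order, float formatting, JSON whitespace and link
strand-flips — and the difference can be emitted as a replayable edit
script.

**CRISPR detection.**  In a merged de Bruijn graph (odd k < repeat
length), a CRISPR repeat is a short high-copy-number unitig `r` whose
spacers loop from it back to it.  A bounded DFS from each candidate
(cn(r) > cmin, lrmin ≤ |r| ≤ lrmax) counts *circles* (paths returning
to r; the overlap-trimmed path length |u| equals the spacer length) and
*termini* (paths longer than |r| + 2·lsmax).  A candidate with
cn(r) − 1 circles and 2 termini is reported; a circle with |u| > lsmax
flags a probable inexact repeat instance bridged by the path
(|u| = |sᵢ| + |r| + |sᵢ₊₁|).

## Worked example

```bash
python examples/06_crispr_detection.py
```

```
perfect array:
  repeat unitig 'k500^_k501_k502^_k503^_k504_k505_k506^_k507', length 28 bp, copy number 6
  circles 5, termini 2, inexact 0
  spacer lengths [32, 32, 32, 32, 32]
  total repeat instances 6
mismatch in instance 3:
  repeat unitig 'k500^_k501_k502^_k503^_k504_k505_k506^_k507', length 28 bp, copy number 5
  circles 4, termini 2, inexact 1
  spacer lengths [32, 32, 32]
  total repeat instances 6
```

A synthetic locus (six 28 bp repeat instances, five unique 32 bp
spacers, 500 bp flanks) is turned into a k = 21 de Bruijn graph, linear
paths are merged, and the detector reports the repeat unitig with five
spacer circles of 32 bp and the two flank termini.  With a single-base
substitution at the centre of the third instance, that instance's
k-mers become unique: the repeat's copy number drops to 5 and one long
circle (32 + 28 + 32 = 92 bp) bridges the inexact instance — the
instance total is still six, one flagged as probably inexact.

The other examples (`examples/01…05`) walk through parsing and editing,
copy numbers and multiplication, linear-path merging, cleanup operators,
and the diff/edit-script round trip.  The same operations are available
from the shell via the `gfakit` command (`gfakit info`, `diff`,
`apply-edits`, `merge`, `multiply`, `simplify`, `tag-cn`, `debruijn`,
`crispr`, `synth-crispr`).

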