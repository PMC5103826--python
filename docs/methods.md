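# Methods

This note documents the models, conventions and numerical choices
behind gfakit, in the order a graph flows through the toolkit.

## GFA 1.0 records and tags

Lines are parsed into typed records (H/S/L/C/P) with positional fields
validated against the GFA 1.0 regular expressions and tags against the
SAM-style datatype grammar (A, i, f, Z, J, H, B).  Values convert to
native Python objects; on output, floats use the shortest round-trip
decimal representation and JSON is emitted compactly with sorted keys.
Equality of records ignores tag order and compares J structurally and
f numerically, so formatting noise can never register as a difference.
Choices worth noting:

* an H line declaring a version other than 1.0 logs a warning but is
  kept — version drift should not make files unreadable;
* empty lines are skipped; other unparseable lines are an error, unless
  the reader is in lenient mode, in which case they are logged and kept
  verbatim as opaque records and round-trip unchanged;
* duplicate tags on one line are rejected at parse time — there is no
  meaningful merge rule for them;
* a link equal to an existing one up to reverse-complement rewriting
  (from/to swapped, both orientations flipped) is the same
  double-stranded junction and is stored once.

## Segment ends

Topology is reasoned about in terms of segment ends (B/E) rather than
orientations, converting from the link fields by the rule stated in the
ends module.  One boundary case is fixed by convention: a palindromic
self-link (`s + s -`) touches the same end twice but counts **once**
in λ, because λ feeds "single link" decisions and the record is one
link.  An ordinary self-link (`s + s +`) counts once at each end.

## Coverage and copy number

`coverage = c / (|s| − ℓ + 1)` with ℓ defaulting to 1 (the safe
degenerate case `c/|s|`); ℓ = k is the exact choice for KC counts.  The
copy-number estimator is the three-branch rule in the README with a
strict upper bound on the cn = 1 band: cov = 1.5·scov rounds to 2.
Comparisons use plain float arithmetic, no epsilon: the bands are wide
and an epsilon would only move the ambiguity.  Estimating scov from the
coverage distribution is deliberately out of scope — the user supplies
it.

## Multiplication and link distribution

Counts are divided rounding half up (`⌊c/m + 0.5⌋`), since count tags
are integers; the copies' total can therefore drift from the original
by at most m/2.  Copies are named `<name>_c<i>`; paths or containments
citing the original are cascade-deleted with a warning (multiplication
is meant for path-free working graphs).  For distribution the links of
the chosen end are ordered lexicographically by (other segment, other
end) — the distribution rule needs *an* order and this one is
reproducible.  The end-selection heuristic, where the choice was open:
an end is eligible with λ ≥ 2; an end with λ = m exactly is preferred
(one link per copy, maximal elimination); otherwise the end with λ > m
minimising the excess λ − m; otherwise the eligible end with the
largest λ; ties go to E.  Distribution requires a `cn` tag equal to 1
on every segment reachable from the multiplied one — a missing tag is
an error rather than a silent assumption.

## Linear-path merging

Enumeration extends a chain from any segment through ends with λ = 1 on
both sides of each junction; closed cycles of internal segments have no
terminus and are not reported.  Merging emits the path starting from
the endpoint with the lexicographically smaller name, making output
independent of enumeration order.  Junction overlaps must be `*`, `0M`
or `nM`; the n bases are trimmed from the oriented start of the
successor, the convention of unitig construction that matches the
(k−1)M links of de Bruijn graphs.  Count tags are summed; other tags of
internal components are dropped.  With tracking, `or` stores the
comma-joined component names (`^` marking reverse-complemented use) and
`mp` the 1-based start of each component in the merged sequence;
components that were themselves merged are treated as atomic tokens
rather than expanded, so `len(mp) == len(or)` always holds.  Merged
names longer than 80 characters are truncated with an 8-hex-digit
suffix to stay single-token.  Paths of `*`-sequence segments merge to a
`*` record with LN set when all lengths are known; mixing `*` and
explicit sequences is an error.

## Cleanup operators

*Mandatory links* iterate to a fixed point, processing ends in
lexicographic (name, B before E) order.  Under the one-molecule
assumption (each component linear with two dead ends, or circular) the
fixed point is order-independent; components violating the assumption
only produce a warning, and there the processing order documents which
of several mutually contradictory prunings wins.  Self-links are
superfluous unless they are the segment's only link.

*Random orientation* decomposes an invertible segment as s = u·v·u′
(u the longest prefix whose reverse complement is a suffix) and stores
v's 1-based interval in `rn`; a perfect palindrome yields the empty
interval `[|u|+1, |u|]`.  If `or`/`mp` tracking shows the segment as
w·x·w′ at component granularity, x's interval is stored instead, since
the components are the meaningful units.  The RNG is a local
`random.Random(seed)` — the seed is a required argument and there is no
hidden global state.

*The coverage filter* evaluates its two conditions (cov < min_cov;
isolated and shorter than min_isolated_len) on a snapshot, then deletes
with cascade.

*p-bubbles* are restricted to two-branch simple bubbles: both ends of
each branch carry exactly one link, to the same two foreign ends.  The
lower-coverage branch is deleted; ties delete the lexicographically
larger name.  The scan iterates to a fixed point, so a triple bubble
resolves to its best branch.

## Semantic diff and edit scripts

Headers are compared as one multiset of tags pooled over all H lines;
segments and paths match by name and diff per field and per tag; links
match by key up to reverse-complement rewriting.  Containments match by
exact key: the strand-flipped form of a GFA1 containment changes `pos`
in a way that cannot be computed without sequence lengths, so flipping
is not attempted.  The edit script is a line-delimited, language-neutral
format (`add`, `del`, `set_field`, `set_tag`, `del_tag`, header-tag
ops); deletions are ordered links/containments/paths before segments so
that cascade deletion cannot orphan a later edit.  The defining
contract — replaying the script emitted from diff(g1, g2) on g1 yields
a graph diff-equal to g2 — is exercised by randomized property tests.

## De Bruijn graphs

One segment per distinct canonical k-mer (lexicographic minimum of
k-mer and reverse complement), KC = total occurrences pooled over both
strands (single-stranded inputs counted once per occurrence), one link
per *observed* (k−1)-overlap between consecutive k-mers, deduplicated
up to strand flip.  k must be odd so that no k-mer is its own reverse
complement, which would make end incidence ambiguous.  Segment names
are `k<index>` in first-seen order, so the builder is deterministic in
the input order.

## CRISPR detection

Copy numbers come from `cn` tags if present, else from KC coverage with
ℓ = k against a user-supplied per-k-mer single-copy coverage.  Seeds
are segments with cn > cmin (strict, as defined) and length within
[lrmin, lrmax].  The DFS explores both ends of the seed; the path
length |u| adds each traversed segment's length and subtracts every
traversed link's overlap, including the links leaving and re-entering
the seed — for a clean spacer path this telescopes exactly to the
spacer length, independent of how the spacer region happens to split
into unitigs.  Each segment is visited at most cn(s) times **globally
per seed** (the alternative, per-path budgets, would double-count
circles reachable from both ends).  A branch terminates when
|u| > |r| + 2·lsmax; that budget deliberately allows a circle bridging
one inexact internal repeat instance (|u| = |sᵢ| + |r| + |sᵢ₊₁|) but
not two consecutive ones.  A candidate needs exactly cn(r) − 1 circles
and exactly 2 termini.  A circle is an exact spacer when
lsmin ≤ |u| ≤ lsmax and flags a probable inexact instance when
|u| > lsmax — with the default bounds a bridged instance always
satisfies |u| ≥ 2·lsmin + lrmin = 76 > lsmax = 72, while a true spacer
never exceeds lsmax, so the two cases cannot collide.  The reported
instance count is circles + 1 + inexact circles.  Child order in the
DFS is lexicographic by neighbour for determinism.

## Synthetic data

The CRISPR locus generator emulates the canonical array geometry —
defaults: 6 instances of a 28 bp repeat, five 32 bp spacers, 500 bp
flanks, k = 21 — with spacers and flanks rejection-sampled so that no
canonical (k−1)-mer is shared between any two sampled units or with the
repeat.  A whole-locus check then requires that any *repeated*
(k−1)-mer window has all its occurrences overlapping a repeat instance:
windows straddling an instance boundary may legitimately recur (with
more instances than alphabet letters two instances must share a context
base), and such sharing leaves both the repeat unitig length and the
telescoped |u| values unchanged.  The optional mismatch substitutes one
base at the centre of a chosen instance.  What the generator does *not*
emulate: sequencing errors, coverage fluctuations, k-mers missing from
the read set, or partially degenerate repeats — passing tests therefore
demonstrate the graph algorithms and the detection logic on exact-count
graphs, not robustness to real read data.

## Problem sizes and determinism

The test suite and the acceptance script run on toy graphs (≤ 50
segments), random 200-mers for sequence-conservation checks,
exhaustively enumerable ≤ 8-segment graphs for the Hamiltonian-safety
oracle, and ~1.3 kbp synthetic loci for detection — sizes at which
every independent oracle (brute-force enumeration, networkx component
counts) is exact and the whole suite completes in seconds.  Every
stochastic routine takes an explicit seed, and every generator is a
pure function of its arguments.

## Known limitations

GFA 2.0 records are out of scope; CIGAR junctions other than `nM` make
a path unmergeable; containments contribute neither to connectivity nor
to traversal; diff does not match records under renaming
(graph-isomorphism matching is a non-goal); the CRISPR detector assumes
exact counts and requires exactly two termini, so arrays at contig
boundaries with branching flanks are reported only as logged
near-misses.
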