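# Methods

## The time model

All annotation works in reverse ("coalescent") time: observed sequences sit
at t = 0, ancestors at larger t, and the root of the tree is its oldest
node. A *merge event* records the coalescence of two lineages at a positive
time; the internal node whose descendant leaf set equals the union of the
two merged clades takes that time. Leaves are pinned at exactly 0. The node
time table must be monotone — a parent at least as old as every timed
descendant — and a violation is a hard error naming the offending edge,
never a silent repair.

A *mutation event* carries a time t, a 1-based site, the ancestral
nucleotide x (the lineage's state at t+ε) and the derived nucleotide y (the
state at t). ε is purely symbolic, "immediately older than t"; no numeric
epsilon is ever added to a time. The display label is the concatenation
`xy###` (`AG54` = A→G at site 54), with multiple labels on one branch kept
as an ordered list (descending event time, then ascending site) and
serialized comma-joined inside one `mutations={...}` annotation.

## Matching events to branches

The linkage between a logged event and a branch is exact leaf-set equality:
an event whose clade is {a, b, c} belongs on the branch above the unique
node whose descendant leaves are exactly {a, b, c}. No nearest-clade
guessing is done — if a merge event matches nothing the run fails
(`CladeMatchError`), and if *every* mutation event is unmatched the
tree/log pairing is presumed wrong (`AnnotationError`). Individual
unmatched mutation events are reported and counted but not fatal, since a
log may legitimately describe events on lineages pruned from the displayed
tree. Internal nodes with no merge event keep no time (with a warning);
this happens naturally, e.g. for a cherry of identical sequences whose
coalescence the upstream tool never dated.

When Newick branch lengths disagree with log-derived time differences
beyond a 1e-6 relative tolerance, a warning is issued; log times win for
annotation and branch lengths are left untouched, because the viewer
displays the lengths as written.

## Ancestral-sequence reconstruction

The state of a leaf's lineage at target time T is obtained by starting from
the observed sequence and undoing (derived → ancestral) every on-path event
with time ≤ T, in ascending time order. Repeat mutations at one site chain
correctly because each undo uses the event's own recorded pair. At exactly
an event's time the lineage's state is, strictly, the derived nucleotide;
the ≤ rule means reconstruction *at* T returns the state immediately older
than T, which is what "the ancestral sequence at the merge" means in
practice and is what the merge-node consistency tests verify (reconstruction
via either child of a merge node gives the same sequence).

## Grouping and colorization

Without a group file, a taxon's group is its name with the maximal trailing
run of decimal digits stripped (`Eu_Am22` → `Eu_Am`); an all-digit name, or
one with no trailing digits, is its own group. An explicit group file wins
for its members, with membership exclusive across groups. Colors: explicit
overrides first, then a fixed 12-color palette assigned in sorted
group-name order, cycling — no randomness anywhere, so identical inputs
give byte-identical output. Internal branches use monophyletic propagation:
a node is colored iff all its descendant leaves share one group, otherwise
it stays black (the ordinary color of an unadorned tree). Black was chosen
over majority-group coloring for mixed clades because a majority rule
invents a claim the data does not make.

## Newick and Nexus dialects

Newick follows the standard: quoted labels with `''` escaping; underscores
in unquoted labels are *not* converted to spaces (population-sample names
like `Eu_Am5` must survive). Child order is preserved exactly as written.
Zero-length and absent branch lengths are distinct states. Bracketed
comments in input Newick are stripped with a warning: this package's own
annotations are authoritative on output, and preserving foreign comments
would create conflicting dialects on re-annotation. Branch lengths are
serialized with the shortest decimal representation that round-trips
exactly, so write∘read is the identity on floats as well as topology.
Multi-tree inputs use the first tree and warn. Unrooted inputs (basal
multifurcation) are treated as rooted at the written root; the rooting flag
is recorded and emitted as `[&R]`/`[&U]`.

The Nexus output is deliberately rigid — LF newlines, lowercase keywords,
single-tab indentation, annotation items always in the order `!color`,
`mutations`, `time` — so golden-file tests can compare bytes and decimal
times survive a write/read cycle as identical text. Only `taxa` and `trees`
blocks are emitted; the reader is the inverse of the writer on its own
output and tolerant of keyword case, but it is not a general third-party
Nexus parser (no characters blocks, no translate tables).

## The fixture simulator

`simulate()` draws a neutral coalescent: with k active lineages the next
merge comes after an Exponential gap with rate k(k−1)/2 (the standard
pairwise-coalescence intensity; any strictly increasing scheme would do for
testing, and this one matches what upstream coalescent reconstructions
emulate). The merging pair is uniform. Mutations fall on each branch as a
Poisson process at `mutation_rate` per unit time per lineage (default 0.5 —
of order one mutation per branch on coalescent-scale branch lengths, enough
signal to exercise every code path without saturating sites), with uniform
sites and a uniform choice among the three alternative nucleotides;
sequences propagate from a uniform random root. With
`allow_repeat_sites=False` the sites mutated on any single branch are
distinct, which makes per-branch label counts equal endpoint Hamming
distances — the property the equivalence tests check. Emitted Newick branch
lengths equal time differences exactly, so the tree and log agree by
construction.

Default shape: 52 leaves in two groups (34 `Eu_Am`, 18 `YRI`) over 100
sites — the shape of a small two-population haplotype study. The simulator
reproduces the *bookkeeping* of such data, not its population genetics: no
recombination, no demographic structure between the groups (group labels
are names only; the genealogy ignores them), frequencies are arbitrary
integers in 1–5, and mutation times are uniform within a branch rather than
model-derived. Passing tests therefore demonstrate that parsing, matching,
annotation and serialization are exact on internally consistent inputs;
they say nothing about the inference quality of any upstream tree builder.

Problem sizes used in the test suite — up to 60 leaves and 200 sites, 100
replicate simulations in the end-to-end recovery test, 200 documents in the
round-trip identity test, 200 replicates in the rate-calibration check —
were chosen as comfortably covering the package's intended input range
while keeping the whole suite fast to run locally.

## Numerical choices

* Branch-length equality in tree comparison: 1e-9 relative tolerance;
  monotonicity slack 1e-12 absolute (guards float summation only).
* Time/length disagreement warning threshold: 1e-6 relative.
* Floats are always serialized via the shortest-round-trip representation,
  so every time and length survives file round trips bit-exactly.
* Ties in label ordering (equal event times) break by ascending site.

## Known limitations

* Interoperability with the original upstream tool's private file formats
  cannot be claimed: their grammars were never published, so this package
  defines its own documented dialect with symmetric readers and writers.
* Whether an original implementation would color mixed internal branches by
  majority group, or attach merge times to branches rather than nodes, is
  unknowable; this package's choices (black; node annotations) are fixed
  and documented.
* The Nexus reader exists for round-tripping this package's own output,
  not for arbitrary Nexus in the wild.
* Trees whose topology disagrees with their event log (re-rooted,
  ladderized, pruned at internal nodes) are rejected by design.
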