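# cladepaint

Colorize and annotate Newick phylogenies into FigTree-dialect Nexus files.

Phylogeny reconstruction programs emit plain Newick trees, which carry
topology and branch lengths but no display metadata: no branch colors, no
record of *which* mutation happened *where* and *when*. When a tree comes
from a coalescent-style reconstruction that also logs its inferred events —
lineage merge times and nucleotide substitutions — all of that information
is invisible in the Newick text. `cladepaint` is for researchers who want
to look at such trees: it turns any Newick tree (from any producer) plus
optional sequence/group/event-log files into a Nexus file that FigTree-style
viewers render with

* **per-group branch colors** — taxa are grouped either by an explicit group
  file or automatically by name (the maximal trailing digit run is stripped,
  so `Eu_Am5` and `Eu_Am22` join group `Eu_Am`, `YRI7` joins `YRI`), and a
  group's color propagates to an internal branch only when *all* its
  descendant leaves belong to that group (mixed clades stay black);
* **mutation labels** in the `xy###` grammar: `x` is the ancestral
  nucleotide at time t+ε, `y` the derived nucleotide at time t, `###` the
  1-based site — `AG54` means "A mutated to G at site 54" on that branch;
* **coalescent node times** — reverse time, observed sequences at t = 0,
  the most recent common ancestor oldest.

Events are matched to branches by exact leaf-set equality and mismatches
fail loudly: a tree that was re-rooted or ladderized after its log was
written is rejected rather than silently mislabelled. The package also
reconstructs ancestral sequences: starting from an observed leaf sequence it
undoes every logged substitution on the root-ward path up to a target time.

A seeded coalescent simulator (`cladepaint.simulate`) generates internally
consistent tree + log + sequence + group bundles with recorded ground truth,
so the whole pipeline is testable without any external data.

## Worked example

The three-taxon case: `Eu_Am6` and `Eu_Am22` carry identical sequences; the
mutation A→G at site 54 at t = 2.0099 makes `Eu_Am5` a distinct lineage.

```python
from cladepaint import (EventLog, MergeEvent, MutationEvent, NexusDocument,
                        annotate_tree, assign_groups, build_color_map,
                        color_tree, parse_newick, write_nexus_text)

tree = parse_newick("((Eu_Am6:0.0,Eu_Am22:0.0):2.0099,Eu_Am5:2.0099);")
log = EventLog(
    mutations=[MutationEvent(2.0099, 54, "A", "G", frozenset({"Eu_Am5"}))],
    merges=[MergeEvent(2.0099, frozenset({"Eu_Am5"}),
                       frozenset({"Eu_Am6", "Eu_Am22"}))],
)
print(annotate_tree(tree, log))
assignment = assign_groups(tree)                 # all three -> group "Eu_Am"
color_tree(tree, assignment, build_color_map(assignment, {"Eu_Am": "#0000ff"}))
print(write_nexus_text(NexusDocument.from_tree(tree, tree_name="fig")))
```

prints

```
events attached=1 unmatched=0 timed nodes=4
#NEXUS
begin taxa;
	dimensions ntax=3;
	taxlabels
	Eu_Am6[&!color=#0000ff]
	Eu_Am22[&!color=#0000ff]
	Eu_Am5[&!color=#0000ff]
	;
end;
begin trees;
	tree fig = [&R] ((Eu_Am6[&!color=#0000ff,time=0]:0,Eu_Am22[&!color=#0000ff,time=0]:0)[&!color=#0000ff]:2.0099,Eu_Am5[&!color=#0000ff,mutations={"AG54"},time=0]:2.0099)[&!color=#0000ff,time=2.0099];
end;
```

One mutation event was attached (`AG54` on the branch above `Eu_Am5`), the
root — the common ancestor of all three taxa — carries `time=2.0099`, the
leaves sit at `time=0`, and every branch is blue because all leaves share
one group. A FigTree-compatible viewer renders the `[&...]` metadata
directly.

### Command line

```sh
cladepaint simulate --outdir demo --group Eu_Am=4 --group YRI=3 \
    --sites 60 --rate 0.6 --seed 11
# wrote demo: leaves=7 sites=60 mutations=1 merges=6
cladepaint run --newick demo/tree.tre --log demo/events.log \
    --groups demo/groups.txt --output demo/out.nxs \
    --color Eu_Am=#0000ff --color YRI=#ff0000
# leaves=7 groups=2 events attached=1 unmatched=0 timed nodes=13
```

With only `--newick`, the tree is still colorized by name inference — the
scenario for trees produced by other phylogeny packages, which come with no
event log and therefore cannot be annotated. Exit codes: 0 success, 2 usage,
3 input parse error, 4 event-matching error.

### Input file dialect

Plain text, `#` comments, one record per line (writers prepend the header
`# cladepaint-dialect v1`):

| file | line format |
|---|---|
| sequences | `Eu_Am5 ACTG 3` (name, ACGT sequence, frequency) |
| groups | `Eu_Am: Eu_Am5 Eu_Am6 Eu_Am22` |
| event log | `merge t=2.0099 left=Eu_Am5 right=Eu_Am6,Eu_Am22` / `mutation t=2.0099 site=54 from=A to=G clade=Eu_Am5` |

The log reader is tolerant (logs are debugging output): unparseable lines
are skipped, counted and reported.

### Default palette

Groups without an explicit color take, in sorted group-name order (cycling):
`#e6194b #4363d8 #3cb44b #f58231 #911eb4 #42d4f4 #f032e6 #bfef45 #fabed4
#469990 #9a6324 #808000`. Mixed internal branches and the reserved
`_default` group are `#000000`.

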