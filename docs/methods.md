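# Methods

This note records the formal model implemented by `domgran`, the
parameters and defaults it exposes, the scope of the data generator, and
the numerical and interpretive choices made where the underlying
conceptual framework leaves latitude. Every quantitative statement here
is recomputed by the test suite; nothing is asserted that the code does
not check.

## Granular partitions and granularity trees

A granular partition is given extensionally as cells (id → nonempty
member set) plus a subcell relation. `validate_granular_partition` checks
the four conditions independently and returns witnesses per failure:

1. **partial order** — the reflexive-transitive closure of the subcell
   relation is transitive, reflexive, and antisymmetric, decided by
   exhaustive triple enumeration (the universes of interest are small;
   no incremental or symbolic reasoning is attempted);
2. **unique root** — exactly one maximal cell;
3. **finite chains** — for finite input this reduces to acyclicity,
   checked by cycle enumeration;
4. **no partial overlap** — any two cells with intersecting member sets
   must be related by subcellhood.

`build_granularity_tree` constructs the tree from `directProperPartOf`
assertions under a chosen root, rejecting multi-parent nodes (partial
overlap) and cycles. Extents are computed bottom-up; the ground units are
exactly the leaves of the asserted partonomy — the engine never invents
sub-leaf matter, so an "atom-free" organism simply bottoms out at
molecules.

**Cut convention.** A granularity level is a *strict depth cut*: the set
of nodes at exactly depth *k*, for *k* = 1…max depth. The alternative
antichain reading (depth-*k* nodes plus shallower leaves) is exposed
separately as `complete_cut`; its extents partition the root extent by
construction, whereas strict cuts may fail the summation check — that
failure is the diagnostic signal, not an error.

**Summation check.** A cut passes iff the union of its members' extents
equals the root extent; set-union on frozensets, no arithmetic tolerance
is involved anywhere in the package (all comparisons are exact set and
integer comparisons).

**Diagnosis.** A tree is *constitutive* iff every strict cut is
type-homogeneous, every non-root node's parent lies in the immediately
coarser cut, and every cut passes summation; otherwise
*cumulative-constitutive*. On the shipped worked example the cumulative
variant fails summation at cuts 2, 3, and 4 (uncovered interstitial and
free intracellular matter), while the constitutive variant passes
everywhere.

## Building-block levels and intrinsic classification

The six-level inventory (atom < molecule < single-membrane-enclosed
entity < membrane-within-membrane entity < epithelially-delimited
compartment < epithelially-delimited multi-cellular organism) is decided
*intrinsically* from asserted physical coverings:

| covering | level |
| --- | --- |
| electron shell | 1 |
| shared electron shell | 2 |
| plasma membrane, no membrane-covered proper part | 3 |
| plasma membrane, with membrane-covered proper part | 4 |
| epithelium, inside an epithelium-covered whole | 5 |
| epithelium, outermost | 6 |

Entities without a qualifying covering (aggregates, fiat regions) have no
intrinsic level; their per-frame category is derived from their direct
proper parts' levels and from asserted `connectedTo` adjacency.
Self-connectedness is read from the asserted adjacency graph (connected
subgraph over the members); no geometry is computed.

## Frame-dependent classification

The frame inventory comprises one spatio-structural frame per
building-block level plus a functional and a historical/evolutionary
frame. At a spatio-structural frame of level *L*, an entity with
intrinsic level *l* classifies as: the building block itself (*l* = *L*);
a bona fide cluster of *L*-blocks (*l* > *L*); a fiat *L*-part when it
lies inside an *L*-block; otherwise a non-countable self-connected
portion of *l*-matter. Coverless aggregates classify by their coarsest
constituent level and connectedness into cluster / group / fiat-cluster /
group-of-fiat / scattered-portion categories. Countability is false
exactly for categories descending from `portion of matter entity`.

Representation chains link consecutive classified spatio-structural
frames fine-to-coarse with `hasCoarserGranRep`, switching to
`co_n-c_GranRep` when a countable reading becomes non-countable and
`co_c_GranRep` for the reverse; functional and historical/evolutionary
readings attach as side links. A gap between populated frames truncates
the chain and is reported rather than bridged.

## Perspectives: parameters and modelling choices

The registry is declarative and deterministic per configuration mode.

**Mode parameter.** `printed_total` (default for the registry dump)
instantiates the seven general region-based perspective types over seven
spatio-structural reference contexts — the level-3 frame is split into an
organelle context and a prokaryotic-cell context — yielding 7 × 7 = 49
specific region-based perspectives. `canonical` keeps six contexts
(42 perspectives). The split-context reading reproduces the framework's
stated total of 49 while exposing the arithmetic tension with its six
spatio-structural frames; it is a configuration choice, not a claim about
intent.

**Representation units.** The resolution-based (RBR, RBCR) and
function/history-based (F-BR, H/E-BR) perspectives granulate
frame-specific *representations* of entities, encoded as `entity@frame`
units — one unit per granular representation. This keeps the "entity in
at most one level per perspective" constraint satisfiable for entities
that are represented at several frames at once.

**Level-member disjointness.** Within one level of a populated
perspective, members must be pairwise disjoint in extent. Because overlap
in a parthood tree implies containment, `populate_registry` prunes each
(perspective, level) group of entity members to its maximal elements;
representation units are exempt (their extents are not defined, and
distinct representations of nested entities are distinct individuals).

**Level ordinals** run finest = 1 upward in every perspective.
Data-driven level counts (CFU, CH/EU, unbounded region-based types) are
numbered by nesting depth of the relevant category chain; any actual
dataset bounds them. A perspective whose population covers fewer than two
levels is not instantiated on that dataset and is reported as a warning.

**Intransitivity rule.** A granulation criterion whose domain and range
categories differ (frame indices aside) is intransitive, and the
perspective is capped at exactly two levels; this is enforced both at
registry build time (fixed level policies) and at validation time.

## Data generator

`random_organism` produces organisms from exact branching counts (organs,
cells per organ, organelles per cell, molecules per organelle) plus
optional cumulative attachments (extracellular molecules per organ, free
intracellular molecules per cell, free cells). The parthood topology is a
deterministic function of the counts; the seed randomises only the
`connectedTo` spanning chains among sibling cells and organelles, so
identical specifications serialise byte-identically. The generator emits
only the two organisational patterns above — it does not generate
syncytia, engineered assemblies, or multi-rooted partonomies, and all
generated coverings follow the type → covering table used by the worked
example.

## Serialisation

TSV and JSON assertion dialects are self-describing and round-trip
byte-identically (sorted rows, fixed headers). RDF export uses a
canonical Turtle emitter — sorted prefixes, sorted triples, one triple
per line — instead of a library serialiser, so identical inputs always
produce byte-identical documents; re-import goes through rdflib and
re-canonicalisation is the round-trip check. Relation names whose
conventional spellings are not legal IRI local names (e.g.
`Hist/EvGranRep`) are sanitised to snake case with the original spelling
preserved as an `rdfs:label`.

## Limitations

* Self-connectedness is assertion-driven; absent `connectedTo` facts bias
  classification toward scattered/group categories.
* The engine classifies only entities present in the assertion set; it
  does not hypothesise unobserved finer matter, so frames finer than the
  asserted ground units are populated by cluster readings only.
* Engineered assemblies are carried in the causal-unity registry but no
  classification rule currently keys on them.
* Region-based functional and historical/evolutionary perspectives are
  not part of the default registry.
* The worked example fixes one concrete letter-to-type reading of the
  idealised organism; the constants are exposed and editable.
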