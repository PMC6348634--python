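# domgran

A domain granularity framework engine for the life sciences: granular
partitions, building-block levels, multi-perspective classification of
material entities, and cross-granular representation chains.

## The scientific problem

Biological material entities are organised across many levels of
granularity — atoms, molecules, organelles, cells, organs, organisms — but
biological parthood is *cumulative-constitutive* rather than neatly
layered: extracellular molecules hang directly off an organ, free-living
cells attach directly to the organism, and a "level" such as *molecule*
has instances scattered across several depths of any concrete partonomy.
Naive level-based data models therefore break on real anatomies: levels
fail to sum to the whole, types cannot be identified with tree depths, and
whether an entity counts as a bona fide object or as a fiat portion of
matter depends on the granular frame of reference it is viewed in.

`domgran` makes this framework executable:

* **Granular partitions.** A partonomy is validated against the four
  granular-partition conditions — the subcell relation is a partial order,
  there is a unique root, chains are finite, and no two cells partially
  overlap — and represented as a *granularity tree*. Levels are *cuts*
  through the tree; each cut can be checked for whether its members'
  mereological sum equals the whole (the *summation check*). A tree whose
  cuts are type-homogeneous, depth-adjacent, and summing is diagnosed as
  *constitutive*; anything else is *cumulative-constitutive*.
* **Building-block levels.** Six canonical levels — atom, molecule,
  single-membrane-enclosed entity, membrane-within-membrane (eukaryotic
  cell) entity, epithelially-delimited compartment, epithelially-delimited
  multi-cellular organism — are decided intrinsically from each entity's
  asserted *physical covering* (electron shell, shared electron shell,
  plasma membrane, epithelium) rather than from tree depth.
* **Sortation-by-type.** Types sediment to the finest cut occupied by any
  of their instances, turning an instance tree into a type-level
  granularity structure even when instances of one type span many cuts.
* **Frame-dependent classification.** One concrete entity instantiates a
  different category of the extended `material entity` taxonomy in every
  frame of reference: a eukaryotic cell is a *bona fide cluster of
  molecules* at the molecule frame, a *eukaryotic cell* at its own frame,
  and a *fiat organism part* at the organism frame; a free extracellular
  molecule becomes a non-countable *portion of molecule matter* at
  intermediate frames. The per-frame readings are linked fine-to-coarse
  into a representation chain (`hasCoarserGranRep`, with
  `co_n-c_GranRep`/`co_c_GranRep` marking countability flips).
* **Granular perspectives.** A declarative registry pairs each granulation
  criterion with a granularity type and enforces the formal constraints:
  at least two levels, strictly ordered; each entity in at most one level
  per perspective; level members pairwise disjoint in extent; perspectives
  built on an intransitive granulation relation capped at exactly two
  levels. The default registry comprises the compositional building-block
  (CBB) backbone, per-frame cluster perspectives, seven general
  region-based perspective types instantiated per spatio-structural
  reference context, functional and historical/evolutionary unit
  perspectives, and the resolution-based representation perspectives.

## Worked example

The package ships a deterministic worked-example organism in two variants.
The cumulative-constitutive variant has two organs (`i`, `j`), five cells,
three organelles, and nine molecules — two of which (`g`, `h`) float in
the interstitial space directly under the whole organism, and several of
which (`k`, `l`, `w`, `u`, `s`) sit free inside organs or cells.

```console
$ python -c "import domgran; from domgran.io import write_assertions; \
             write_assertions(domgran.worked_example('cumulative')[0], 'organism.tsv')"
$ domgran validate organism.tsv
[COND-FINITE_CHAINS] pass
[COND-NO_PARTIAL_OVERLAP] pass
[COND-PARTIAL_ORDER] pass
[COND-UNIQUE_ROOT] pass
[CUT-1-SUMMATION] pass
[CUT-2-SUMMATION] fail: uncovered ['g', 'h']
[CUT-3-SUMMATION] fail: uncovered ['g', 'h', 'k', 'l', 'o', 'p']
[CUT-4-SUMMATION] fail: uncovered ['g', 'h', 'k', 'l', 'o', 'p', 's', 't', 'u', 'w']
[ORGANIZATION] cumulative-constitutive
```

The partition itself is valid, but only the organ-level cut sums to the
whole: every finer cut misses the free-floating matter — the signature of
a cumulative-constitutive hierarchy. Sortation-by-type still recovers a
clean type-level ranking, with `molecule` sedimenting to the finest cut
even though its nine instances span all four cuts:

```console
$ domgran sortate organism.tsv
type	level	instance_count
organ	1	2
cell	2	5
organelle	3	3
molecule	4	9
```

The same library calls are available programmatically:

```python
import domgran as dg

aset, tree = dg.worked_example("cumulative")
types = dg.worked_example_types("cumulative")
dg.diagnose_organization(tree, types)   # 'cumulative-constitutive'
tmap = dg.sortation_by_type(tree, types)
tmap.span("molecule")                   # {1, 2, 3, 4}
```

Other commands: `domgran classify` (per-frame categories and
countability), `domgran registry` (the perspective inventory as JSON),
`domgran filter --perspective CBB` (reduce a graph to one perspective),
`domgran simulate --seed N` (parameterised random organisms), and
`domgran export` (canonical Turtle).

## Layout

| Path | Contents |
| --- | --- |
| `src/domgran/core.py` | entities, assertions, building-block levels, causal unity, frames, taxonomy |
| `src/domgran/partition.py` | order checks, partition validation, granularity trees, cuts, diagnosis |
| `src/domgran/sortation.py` | sortation-by-type and type-level structure |
| `src/domgran/classification.py` | intrinsic levels, per-frame classification, representation chains |
| `src/domgran/perspectives.py` | perspective registry, level assignment, constraint validation |
| `src/domgran/fixtures.py` | the worked example and the seeded organism generator |
| `src/domgran/io.py` | TSV/JSON dialects, canonical Turtle, perspective filtering |
| `src/domgran/cli.py` | the `domgran` command-line interface |
| `docs/methods.md` | methods note: model, parameters, numerical choices, limitations |
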