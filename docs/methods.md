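# Methods

## Model and assumptions

An organism's metabolism is reduced to what KEGG curates for it: the
set of reference pathways it instantiates, each pathway's reaction
content, and each pathway's compound inventory. This buys automation
and cross-organism comparability (every position in every organism's
matrix is the same reference pathway) at the cost of inheriting KEGG's
coverage and curation decisions. Three assumptions matter:

1. **Reaction identity is the R-number.** Direction/reversibility
   attributes in KGML are ignored; two pathways "share" a reaction iff
   they name the same accession. No reaction-similarity scoring (EC
   distance, atom mapping) is attempted — the method is positioned
   against alignment-style comparison, not on top of it.
2. **Compound content comes from `entry type="compound"` elements**,
   i.e. the map-level compound inventory, not from reaction
   substrate/product sub-elements. Map entries are what KEGG shows as
   the pathway's compounds, which is the notion of "shared compound"
   the structural level encodes. If reconstruction ever diverges from
   KEGG map connectivity, this is the first choice to revisit.
3. **Maplink entries are parsed and discarded.** KEGG's own pathway
   cross-links are display aids, not a reliable connectivity source;
   structural edges are recomputed from shared compounds instead.

A shared compound can mean production/consumption coupling, pathway
overlap, or incidental co-occurrence; the structural level deliberately
collapses all three into one unweighted edge type.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| universe | from config file | reference pathways compared; fixed ascending order aligns all matrices |
| ubiquitous list | C00001, C00002, C00008, C00009 | water/ATP/ADP/phosphate; removed before edge computation to avoid connecting nearly everything to everything. The canonical list is open-ended ("such as"), so it is fully overridable |
| mode | `set` | `set` compares distinct reaction accessions; `multiset` weights repeated occurrences (intersection = per-accession min of counts, union = max, cardinality = sum) |
| edge threshold | ≥ 1 shared non-ubiquitous compound | edge existence is binary for SimS; the shared count is kept as an export weight only |

## Index conventions and edge cases

* The global denominator *n* counts pathways present (physical or
  reaction) in **at least one** of the two organisms. Universe pathways
  absent from both stay in the matrices (diagonal −1) but enter no sum.
* A pathway with a KGML file in both organisms but reactions in only
  one falls between the defined cases ("physical in both" vs "reaction
  in both"). It is scored as the empty-vs-nonempty Jaccard, i.e. 0, and
  flagged with its own case label `3*` so reports can surface it. This
  is the conservative reading: the two organisms demonstrably realise
  the function differently.
* SimS case 3 (isolated in one graph, connected in the other) uses the
  degree *k* of the **connected** occurrence, giving 1/(1+k). Reading
  the degree from the isolated side would make the case identically 1
  and collapse it into case 2.
* A 1.0 can mean "physical in both" (case 2) or "identical reaction
  sets" (case 3); the per-row case labels in every report disambiguate
  what the value alone deliberately conflates.
* PsimW weights each pathway by |R ∪ R′| in the active mode; physical
  pathways weigh 0, and a singly-present reaction pathway contributes
  its own reaction count to the denominator (with SimP = 0). When no
  reaction pathway exists anywhere, PsimW is undefined: it is reported
  as NaN with a warning, and clustering refuses (rather than imputes)
  matrices containing such entries.

## Numerical choices

All indexes are computed in double precision with no intermediate
rounding; the 4-decimal values on the CLI are display-only, and CSV/TSV
files carry full-precision reprs. Tests compare at absolute tolerance
1e−9. Determinism is structural, not incidental: universe order is
sorted, graph serialisations emit sorted elements, and fixture
generation draws from a single seeded generator in a fixed order, so
repeated runs are byte-identical.

## Clustering

Similarity matrices (symmetric, unit diagonal) are converted to
distances d = 1 − s — the minimal monotone transform keeping d in
[0, 1]; nothing canonical fixes another choice — and agglomerated with
complete linkage (scipy). Organisms are sorted lexicographically before
linkage so equal-distance merges resolve identically on every platform;
with distinct distances the sort is irrelevant. Dendrograms serialise
to Newick with branch length = parent height − child height, children
ordered lexicographically. Heatmaps map similarity through viridis
(high = yellow, low = blue/purple) with fixed limits [0, 1].

## What the synthetic fixtures emulate — and what they do not

The fixture generator emits real KGML documents (compound entries with
`cpd:` prefixes, reaction declarations with repeated `rn:` tokens for
multiplicities, a maplink decoy entry that parsers must skip) under a
controllable design: per-pathway presence/physical/reaction status,
reaction overlap via shared per-pathway pools each organism subsamples,
structural edges via dedicated per-pathway-pair compounds, and planted
ubiquitous decoys that downstream filtering must remove. Accessions use
reserved high ranges (`9xxxx`, `R9xxxx`, `C9xxxx`) so fixtures cannot
collide with real KEGG content in a mixed cache.

Default generator conditions: 6 pathways, 15% absence and 15%
physical probability per (organism, pathway), reaction pools of 15 with
keep-probability 0.6 and multiplicities 1–3, pairwise compound-sharing
probability 0.5, ubiquitous-decoy probability 0.5 — small metabolisms
with substantial but partial overlap, the regime where every index case
actually occurs. The end-to-end sweeps run 100 specs of ≤ 8 pathways
and ≤ 15 reactions per pool, sizes at which the brute-force oracle (a
fully independent enumeration over expanded element lists) is exact and
instantaneous.

What passing these tests shows: the pipeline computes exactly the
defined indexes on any input with KGML's structure. What it does not
show: anything about biological realism — fixtures have no
stoichiometry, no gene/enzyme entries, and compound-sharing patterns
far sparser than real KEGG maps — nor about index values on live KEGG,
which move with every database release.

## Known limitations

* KEGG is the single source of truth; gaps or inconsistencies in its
  curation propagate directly into the indexes.
* The KEGG REST client is a convenience layer; it serialises requests
  (350 ms default spacing) and caches absence as marker files, but bulk
  mirroring and authentication are out of scope.
* Only complete linkage is validated; the distance transform and the
  clustering of a similarity matrix with undefined PsimW entries are
  fixed choices, not options.
* Interactive visualisation (organism pickers, neighbourhood pop-ups,
  global-map rendering) is out of scope; exports are static GraphML,
  DOT, TSV, CSV, Newick and PNG.
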