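# Methods

## Knowledgebase model

The knowledgebase is a typed graph over seven entity classes — GO
terms, NCBI genes, transcript and protein accessions, Enzyme
Commission (EC) classes, KEGG reactions and KEGG compounds — with six
primary edge types (gene–GO, gene–transcript, transcript–protein,
protein–EC, EC–reaction, reaction–compound) assembled from five flat
sources: a GO OBO release, NCBI `gene2go` and `gene2accession`,
Expasy `enzyme.dat`, and KEGG REST `link` dumps for EC→reaction and
reaction→compound. Protein→EC links come from a pre-fetched
two-column table, because a reproducible offline build cannot depend
on live NCBI queries; without that table all active EC classes are
catalogued but no compound can attach to a GO term and the build
stops with a "no GO-linked compounds" error.

Restrictions applied during assembly:

* **Ontology.** Only `[Term]` stanzas and `is_a` edges; `part_of`,
  `regulates` and other relationship types are ignored as the
  conservative hierarchy definition. The build keeps the
  reflexive-transitive closure under the metabolic-process root
  (GO:0008152 by default). Obsolete terms are excluded and their
  parent links discarded; `alt_id` accessions resolve to primary ids
  on any lookup.
* **Taxon.** One taxon per build (default 9606). gene2go rows with a
  `NOT` qualifier are negated annotations and are excluded.
* **Versions.** Accession version suffixes are stripped everywhere;
  the raw sources disagree on versions and joins must not depend on
  them.
* **Enzyme status.** `Transferred entry`/`Deleted entry` descriptions
  mark non-active EC classes; any reaction links they carry in the
  KEGG dumps are ignored.
* **Closure.** Entities survive only if reachable from a kept gene
  along the edge chain, so the knowledgebase never contains orphan
  transcripts, enzymes, reactions or compounds. A derived
  gene→protein join table is stored alongside the six primary edge
  types so that proteins recorded without an RNA accession remain
  reachable and an archive reload reproduces the build exactly.

**Annotation propagation.** Gene→term annotation is *direct* by
default: a gene annotated to a term does not count for the term's
ancestors. True-path propagation is available (`propagate=True` /
`--propagate`) but off, matching the observation that per-term gene
counts in this style of knowledgebase are far smaller than
propagation would produce; direct annotation also keeps term compound
sets sharply distinct between siblings.

For each kept term *T*, `term_to_compounds(T)` is the union of
compounds reachable from *T*'s annotated genes via
protein → EC → reaction → compound, and `background_n` (*N*) is the
size of the union over all terms — the population of the
hypergeometric test. The archive serialization is sorted TSV tables
in a zip container with fixed member timestamps, making rebuilds from
identical sources byte-identical.

## Over-representation statistic

For a term with *y* linked compounds, *a = N − y* compounds outside
it, and *b* input compounds mapped into the universe, of which *x*
overlap the term's set, the p-value is the hypergeometric upper tail
P[X ≥ x], evaluated through `scipy.stats.hypergeom.sf` (log-space;
accurate deep into the tail and verified against exact combinatorial
enumeration for all populations up to size 12).

A note on the complement parameter *a*: with the nucleoside-salvage
frame (N = 2212, y = 61, b = 62, x = 13) the complement against the
universe, a = N − y = 2151, gives p = 4.218424e-09, while taking the
complement against the mapped input, a = N − b = 2150, gives
4.241376e-09 — about 0.5 % apart. Published descriptions of this test
have used both numbers interchangeably at this frame. `metabogo` uses
a = N − y, the statistically correct universe complement (the y
compounds of the term and the a outside it must partition the
population that the b draws come from); `hypergeom_upper_tail(x, y,
a, b)` is public, so either parameterization can be evaluated
verbatim.

**Filters.** Before multiple-testing adjustment, terms must satisfy
x ≥ 3, gene_count ≥ 3 and x > 0.05·y (strict inequality: x equal to
5 % of y fails). The thresholds are exposed on `OraQuery`
(`min_overlap`, `min_genes`, `min_overlap_fraction`). Filtering
precedes FDR, so the Benjamini–Hochberg denominator *m* is the number
of filter-passing terms; `fdr_all_terms=True` adjusts over every
tested term instead, for sensitivity analysis. BH adjustment is
delegated to `statsmodels.stats.multitest.multipletests` and checked
in the tests against a hand-coded step-up formula. Significance is
q < alpha (default 0.05).

Determinism: results are sorted by (p, term_id); permuting the input
list changes nothing; duplicate input ids collapse with a warning;
the impact table floors p at 1e-300 before the −log10 transform to
avoid infinities.

## Networks

The **ontology network** contains terms significant at q < alpha plus
all their is_a ancestors (marked `significant=false` when not
themselves significant); its edges are exactly the is_a pairs inside
the node set, so it is always a sub-DAG of the ontology. The
**focused reaction network** for one term expands its genes along the
knowledgebase chain with relation labels encodes / translates_to /
catalyzes / participates / substrate_product; reaction–compound edges
stand in for KEGG's discontinued reactant-pair (atomic mapping)
resource, with the relation kept distinct so a pair table could be
plugged in later. A `detected` compound set subsets the network to
measured compounds, dropping reactions left without any participant —
always a subgraph of the full network. Hub cofactors can be removed
via an explicit exclusion list; none is applied by default.
Serialization is Cytoscape SIF (sorted lines, isolated nodes as
single-column rows) plus a node-attribute TSV (union-of-keys header,
blank cells for absent attributes, numerics at 6 significant digits,
NCBI/KEGG/Expasy cross-reference URLs as attributes).

## Synthetic data

`generate_mock_sources` writes miniature, syntactically exact
versions of all five sources — a random is_a DAG under GO:0008152
with an obsolete term, an alt_id and a disconnected decoy term;
gene2go rows including NOT-qualified, foreign-taxon and
outside-the-sub-ontology decoys; gene2accession rows with version
suffixes and placeholder-only genomic rows; enzyme.dat with active,
transferred and deleted records; KEGG link tables with a glycan
participant — plus a `truth.json` computed by direct construction,
against which the builder is tested. Generation is a pure function
of (spec, seed); the default spec (8 terms, 6 genes, 4 ECs, 6
reactions, 12 compounds, seed 7) is committed under
`tests/data/mock_sources/` and a test pins the generator to those
bytes. The fixtures emulate format and statistical structure only:
no pathway topology, compound chemistry or realistic entity counts,
so green tests demonstrate correctness of parsing, assembly and
statistics, not biological plausibility of any particular enrichment.
With so small a universe no term can reach q < 0.05; CLI tests that
need a non-empty significant set therefore run at a lenient alpha,
and the empty-network path is exercised explicitly.

`worked_example_kb` reproduces the nucleoside-salvage statistical
frame exactly — a 2,212-compound universe, a 61-compound term under a
catch-all root, five annotated genes, and a 62-compound input list
with a 13-compound overlap — with synthetic compound identities drawn
from a seeded RNG. Every statistic computed from it is
seed-invariant.

## Numerical and design choices

* Hypergeometric tail: survival function, never `1 − cdf`;
  P[X ≥ 0] short-circuits to 1 (covers the empty population).
* p floor 1e-300 only in the impact table's log transform; raw
  p-values are reported unfloored.
* Tie-break: p ascending then term_id lexicographic, for
  deterministic reports.
* Excel export goes through pandas/openpyxl; cell values are
  contractual, binary layout is not.
* Exit codes (0 ok, 2 parse/build, 3 empty mapping, 4 lookup) are
  fixed for scripting.

## Limitations

* Compound-level evidence only: abundances are ignored (no
  GSEA-style ranked test, no topology weighting).
* The background universe is knowledgebase-derived, not
  assay-derived; compounds the assay could not have measured still
  count in *N*.
* Protein→EC coverage is only as good as the supplied table; the
  unfiltered-EC fallback cannot link compounds to terms.
* Only `is_a` semantics; terms related through `part_of` or
  `regulates` are invisible to the sub-ontology restriction.
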