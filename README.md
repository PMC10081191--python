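# metabogo

Gene Ontology (GO) over-representation analysis for metabolite lists.

Pathway analysis of metabolomics data usually stops at curated pathway
maps, whose definitions and metabolite coverage differ between
databases. `metabogo` instead interprets a list of significant
metabolites against GO *metabolic process* terms, the same controlled
vocabulary used for gene and protein enrichment. It does this in two
stages:

1. **Knowledgebase build** — integrate public flat files into one graph
   linking GO terms → genes → transcripts → proteins → EC enzyme
   classes → KEGG reactions → KEGG compounds, restricted to the
   sub-ontology under GO:0008152 (metabolic process) and to one taxon
   (human by default). From the graph, each GO term receives the set
   of compounds reachable from its annotated genes; the union of those
   sets is the background universe of size *N*.
2. **Over-representation analysis (ORA)** — map an input list of KEGG
   C-numbers onto the universe and test each GO term with the
   hypergeometric upper tail. For a term with *y* linked compounds
   (*a = N − y* outside it) and *b* mapped input compounds of which
   *x* fall in the term's set,

   *p* = P[X ≥ x],  X ~ Hypergeometric(*y* successes, *a* failures, *b* draws)

   i.e. R's `phyper(x-1, y, a, b, lower.tail = FALSE)`. Terms are kept
   only when x ≥ 3, the term has ≥ 3 annotated genes, and x > 5 % of
   *y*; Benjamini–Hochberg q-values are then computed over the
   filter-passing terms and significance is declared at q < 0.05.

Results export as CSV/Excel tables, an impact table (set size vs
−log10 *p*), and Cytoscape SIF networks (the is_a sub-DAG of
significant terms, and per-term focused reaction networks with gene,
transcript, protein, enzyme, reaction and compound nodes).

## Worked example

The package ships a synthetic knowledgebase reproducing a published
statistical frame for the *nucleoside salvage* term (GO:0043174): a
2,212-compound GO-linked universe, 61 compounds linked to the term,
and a 62-compound input list overlapping it in 13.

```python
from metabogo import OraQuery, run_ora, worked_example_kb

example = worked_example_kb()
query = OraQuery(input_ids=example.input_ids,
                 min_overlap=1, min_genes=1, min_overlap_fraction=0.0)
report = run_ora(example.kb, query)
res = {r.term_id: r for r in report.results}["GO:0043174"]
print(res.x, res.y, res.a, res.b, res.p_value)
```

prints

```
13 61 2151 62 4.218423776237081e-09
```

meaning: 13 of the 62 mapped input compounds hit the 61-compound term;
drawing 13 or more by chance from the 2,212-compound universe has
probability 4.218424e-09, so the term is strongly over-represented.

## Command line

```bash
metabogo build-kb SOURCES/ -o kb.zip      # go.obo, gene2go, gene2accession,
                                          # enzyme.dat, KEGG link tables,
                                          # ec2protein.tsv
metabogo stats kb.zip
metabogo analyze -k kb.zip -i compounds.txt -o results/
metabogo network -k kb.zip -t GO:0043174 -o nets/ [--detected detected.txt]
metabogo query   -k kb.zip C00043
```

Exit codes: 0 ok, 2 parse/build failure, 3 no input compound mapped,
4 identifier not found. Miniature, fully valid source files for all
formats can be generated offline with
`metabogo.generate_mock_sources` (see `tests/data/mock_sources/`).

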