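"""Network construction and Cytoscape export.

Two graph views are produced: the GO-ontology network (significant
terms plus their is_a ancestors, a sub-DAG of the ontology) and the
per-term focused reaction network (genes, transcripts, proteins,
enzyme classes, reactions and compounds annotated to one GO term).
Both serialize to Cytoscape SIF plus a node-attribute TSV, ready for
layout and styling in Cytoscape desktop.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import KBLookupError
from .kb import KnowledgeBase, term_ancestors
from .ora import P_FLOOR, OraReport

log = logging.getLogger(__name__)

ENTITY_KINDS = ("go_term", "gene", "transcript", "protein",
                "enzyme", "reaction", "compound")

_URL_TEMPLATES = {
    "go_term": "https://amigo.geneontology.org/amigo/term/{id}",
    "gene": "https://www.ncbi.nlm.nih.gov/gene/{id}",
    "transcript": "https://www.ncbi.nlm.nih.gov/nuccore/{id}",
    "protein": "https://www.ncbi.nlm.nih.gov/protein/{id}",
    "enzyme": "https://enzyme.expasy.org/EC/{id}",
    "reaction": "https://www.kegg.jp/entry/{id}",
    "compound": "https://www.kegg.jp/entry/{id}",
}


@dataclass
class NetworkNode:
    node_id: str
    entity_kind: str
    label: str = ""
    attributes: dict[str, object] = field(default_factory=dict)


@dataclass
class NetworkEdge:
    source: str
    target: str
    relation: str  # is_a | encodes | translates_to | catalyzes | participates | substrate_product


@dataclass
class Network:
    nodes: list[NetworkNode]
    edges: list[NetworkEdge]
    kind: str = "ontology"  # ontology | reaction

    def node_ids(self) -> set[str]:
        return {n.node_id for n in self.nodes}

    def _validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids in network")
        known = set(ids)
        for e in self.edges:
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge endpoint missing from node set: "
                                 f"{e.source} -{e.relation}- {e.target}")
            if e.source == e.target:
                raise ValueError(f"self-loop on {e.source}")


def _add_edge(edges: list[NetworkEdge], seen: set[tuple[str, str, str]],
              source: str, relation: str, target: str) -> None:
    """Append an edge unless its undirected (source, relation, target)
    signature was seen before."""
    if source == target:
        return
    key = (min(source, target), relation, max(source, target))
    if key in seen:
        return
    seen.add(key)
    edges.append(NetworkEdge(source=source, target=target, relation=relation))


def go_ontology_network(report: OraReport, kb: KnowledgeBase,
                        alpha: float = 0.05) -> Network:
    """Sub-DAG of the ontology spanning the significant terms.

    Nodes are the terms with q < alpha among the filter-passing results
    plus all their is_a ancestors up to the metabolic root; ancestors
    that are not themselves significant carry ``significant=False``.
    Tested terms carry ``neg_log10_p`` and ``q_value`` attributes (node
    size in Cytoscape can encode significance).
    """
    significant = {r.term_id for r in report.results
                   if r.passed_filters and r.q_value < alpha}
    if not significant:
        log.info("no term significant at alpha=%g: ontology network is empty", alpha)
        return Network(nodes=[], edges=[], kind="ontology")

    node_set: set[str] = set()
    for tid in significant:
        node_set.add(tid)
        node_set |= term_ancestors(kb.terms, tid)

    by_term = {r.term_id: r for r in report.results}
    nodes: list[NetworkNode] = []
    for tid in sorted(node_set):
        term = kb.terms[tid]
        attrs: dict[str, object] = {
            "significant": tid in significant,
            "url": _URL_TEMPLATES["go_term"].format(id=tid),
        }
        if tid in by_term:
            r = by_term[tid]
            attrs["neg_log10_p"] = -math.log10(max(r.p_value, P_FLOOR))
            if not math.isnan(r.q_value):
                attrs["q_value"] = r.q_value
        nodes.append(NetworkNode(node_id=tid, entity_kind="go_term",
                                 label=term.name or tid, attributes=attrs))

    edges: list[NetworkEdge] = []
    seen: set[tuple[str, str, str]] = set()
    for tid in sorted(node_set):
        for parent in sorted(kb.terms[tid].parents):
            if parent in node_set:
                _add_edge(edges, seen, tid, "is_a", parent)
    net = Network(nodes=nodes, edges=edges, kind="ontology")
    net._validate()
    return net


def reaction_network(
    kb: KnowledgeBase,
    term_id: str,
    detected: set[str] | None = None,
    include_protein_layer: bool = True,
    exclude_compounds: Iterable[str] = (),
) -> Network:
    """Focused biochemical network for one GO term.

    Expands the term's annotated genes along the knowledgebase chain:
    gene -encodes-> transcript -translates_to-> protein -catalyzes-> EC
    -participates-> reaction -substrate_product-> compound.  With
    ``include_protein_layer=False`` the transcript/protein layers are
    suppressed and genes link to enzymes directly.  ``detected``
    restricts compounds to a measured set (reactions left without any
    compound are dropped with them); ``exclude_compounds`` removes hub
    cofactors (water, protons, ...) that would otherwise dominate.
    """
    term_id = kb.resolve_term(term_id)
    genes = sorted(kb.term_to_genes.get(term_id, ()))
    if not genes:
        raise KBLookupError(f"term {term_id} has no annotated genes in the KB")
    gene_set = set(genes)
    exclude = set(exclude_compounds)

    gene_transcripts = {(g, t) for g, t in kb.gene_transcript if g in gene_set}
    transcripts = {t for _, t in gene_transcripts}
    gene_prots = {(g, p) for g, p in kb.gene_protein if g in gene_set}
    prots = {p for _, p in gene_prots}
    rna_prot = {(t, p) for t, p in kb.transcript_protein
                if t in transcripts and p in prots}
    prot_ec = {(p, ec) for p, ec in kb.protein_ec if p in prots}
    ecs = {ec for _, ec in prot_ec}
    ec_rn = {(ec, rn) for ec, rn in kb.ec_reaction if ec in ecs}
    rns = {rn for _, rn in ec_rn}
    rn_cpd = {(rn, c) for rn, c in kb.reaction_compound
              if rn in rns and c not in exclude}
    if detected is not None:
        rn_cpd = {(rn, c) for rn, c in rn_cpd if c in detected}
        kept_rns = {rn for rn, _ in rn_cpd}
        dropped = rns - kept_rns
        if dropped:
            log.info("detected-only subset: dropping %d reaction(s) with no "
                     "detected compound", len(dropped))
        rns = kept_rns
        ec_rn = {(ec, rn) for ec, rn in ec_rn if rn in rns}
    cpds = {c for _, c in rn_cpd}

    nodes: list[NetworkNode] = []

    def add_node(node_id: str, kind: str, label: str,
                 extra: dict[str, object] | None = None) -> None:
        attrs: dict[str, object] = {"url": _URL_TEMPLATES[kind].format(id=node_id)}
        if extra:
            attrs.update(extra)
        nodes.append(NetworkNode(node_id=node_id, entity_kind=kind,
                                 label=label, attributes=attrs))

    for g in genes:
        gene = kb.genes[g]
        add_node(str(g), "gene", gene.symbol or str(g))
    if include_protein_layer:
        for t in sorted(transcripts):
            add_node(t, "transcript", t)
        for p in sorted(prots):
            add_node(p, "protein", p)
    for ec in sorted(ecs):
        add_node(ec, "enzyme", kb.enzymes[ec].description or ec)
    for rn in sorted(rns):
        add_node(rn, "reaction", rn)
    for c in sorted(cpds):
        comp = kb.compounds.get(c)
        extra = {} if detected is None else {"detected": c in detected}
        add_node(c, "compound", (comp.name if comp and comp.name else c), extra)

    edges: list[NetworkEdge] = []
    seen: set[tuple[str, str, str]] = set()
    if include_protein_layer:
        for g, t in sorted(gene_transcripts):
            _add_edge(edges, seen, str(g), "encodes", t)
        for t, p in sorted(rna_prot):
            _add_edge(edges, seen, t, "translates_to", p)
        for p, ec in sorted(prot_ec):
            _add_edge(edges, seen, p, "catalyzes", ec)
    else:
        # collapse gene -> ... -> EC into a single catalyzes edge
        prots_of_gene: dict[int, set[str]] = {}
        for g, p in gene_prots:
            prots_of_gene.setdefault(g, set()).add(p)
        for g in genes:
            for p in sorted(prots_of_gene.get(g, ())):
                for p2, ec in sorted(prot_ec):
                    if p2 == p:
                        _add_edge(edges, seen, str(g), "catalyzes", ec)
    for ec, rn in sorted(ec_rn):
        _add_edge(edges, seen, ec, "participates", rn)
    for rn, c in sorted(rn_cpd):
        _add_edge(edges, seen, rn, "substrate_product", c)

    net = Network(nodes=nodes, edges=edges, kind="reaction")
    net._validate()
    return net


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_sif(network: Network, stream: IO[str]) -> None:
    """Write Cytoscape SIF: one ``source<TAB>relation<TAB>target`` line
    per edge, isolated nodes as single-column lines, lines sorted."""
    network._validate()
    connected = {e.source for e in network.edges} | {e.target for e in network.edges}
    lines = sorted(f"{e.source}\t{e.relation}\t{e.target}" for e in network.edges)
    lines += sorted(n.node_id for n in network.nodes if n.node_id not in connected)
    for line in lines:
        stream.write(line + "\n")


def _format_attr(value: object) -> str:
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def write_node_attributes(network: Network, stream: IO[str]) -> None:
    """Write a node-attribute TSV: node_id, entity_kind, label, then one
    column per attribute key (union over nodes, blank when absent);
    rows sorted by node_id, numeric values at 6 significant digits."""
    keys = sorted({k for n in network.nodes for k in n.attributes})
    stream.write("\t".join(["node_id", "entity_kind", "label"] + keys) + "\n")
    for node in sorted(network.nodes, key=lambda n: n.node_id):
        cells = [node.node_id, node.entity_kind, node.label]
        cells += [_format_attr(node.attributes[k]) if k in node.attributes else ""
                  for k in keys]
        stream.write("\t".join(cells) + "\n")


def plot_impact(impact: "pd.DataFrame", path, top_labels: int = 10) -> None:
    """Static impact plot: term set size vs -log10(p), the most
    significant terms labelled."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(impact["set_size"], impact["neg_log10_p"],
               s=30, alpha=0.7, edgecolors="none")
    for _, row in impact.nlargest(top_labels, "neg_log10_p").iterrows():
        ax.annotate(row["name"] or row["term_id"],
                    (row["set_size"], row["neg_log10_p"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("GO term compound-set size (y)")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title("GO term impact plot")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
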