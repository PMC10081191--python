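"""Knowledgebase assembly: the integrated graph of GO terms, genes,
transcripts, proteins, enzyme classes, reactions and compounds.

The build restricts the ontology to the metabolic sub-tree rooted at
GO:0008152 (metabolic process) and to genes of a single taxon (human,
9606, by default), then keeps only entities reachable from those genes
along the chain

    gene -> transcript -> protein -> EC -> reaction -> compound

From the assembled graph two derived maps drive the statistics: for
each GO term the set of KEGG compounds reachable from its annotated
genes, and the set of those genes themselves.  The background universe
``background_n`` is the number of distinct compounds linked to at
least one GO term; it is the population size of the hypergeometric
test.

Gene-to-term annotation is *direct* by default: a gene annotated to a
term does not count for the term's is_a ancestors.  Pass
``propagate=True`` for classic true-path propagation.
"""

from __future__ import annotations

import datetime
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .errors import BuildError, KBLookupError
from .parsers import (
    AccessionRow,
    EnzymeClass,
    GoTerm,
    parse_ec2protein,
    parse_enzyme_dat,
    parse_gene2accession,
    parse_gene2go,
    parse_go_obo,
    parse_kegg_link,
)

log = logging.getLogger(__name__)

METABOLIC_ROOT = "GO:0008152"
DEFAULT_TAX_ID = 9606


@dataclass
class Gene:
    gene_id: int
    symbol: str = ""
    tax_id: int = DEFAULT_TAX_ID


@dataclass
class Reaction:
    reaction_id: str
    compounds: set[str] = field(default_factory=set)


@dataclass
class Compound:
    compound_id: str
    name: str | None = None


@dataclass
class SourceBundle:
    """Paths of the raw source files consumed by the builder.

    ``ec2protein_path`` is optional: it is the pre-fetched replacement
    for live NCBI protein-to-EC retrieval.  Without it no protein-EC
    edges exist, so no compound can be tied to a GO term and the build
    fails with "no GO-linked compounds"; all active EC classes are
    still catalogued and the condition is reported.
    """

    obo_path: Path
    gene2go_path: Path
    gene2accession_path: Path
    enzyme_dat_path: Path
    ec2reaction_path: Path
    reaction2compound_path: Path
    ec2protein_path: Path | None = None

    def validate(self) -> None:
        for name in ("obo_path", "gene2go_path", "gene2accession_path",
                     "enzyme_dat_path", "ec2reaction_path", "reaction2compound_path"):
            p = Path(getattr(self, name))
            if not p.is_file():
                raise FileNotFoundError(f"missing mandatory source file: {p} ({name})")


@dataclass
class KnowledgeBase:
    """The integrated entity/edge graph plus derived term maps."""

    terms: dict[str, GoTerm]
    genes: dict[int, Gene]
    transcripts: dict[str, str]            # accession -> accession (identity map)
    proteins: dict[str, str]
    enzymes: dict[str, EnzymeClass]
    reactions: dict[str, Reaction]
    compounds: dict[str, Compound]
    # typed edge sets
    gene_go: set[tuple[int, str]]
    gene_transcript: set[tuple[int, str]]
    gene_protein: set[tuple[int, str]]     # direct join; covers rows lacking an RNA accession
    transcript_protein: set[tuple[str, str]]
    protein_ec: set[tuple[str, str]]
    ec_reaction: set[tuple[str, str]]
    reaction_compound: set[tuple[str, str]]
    # derived maps
    term_to_compounds: dict[str, set[str]]
    term_to_genes: dict[str, set[int]]
    background_n: int
    alt_to_primary: dict[str, str]
    manifest: dict[str, object]

    # -- lookups -----------------------------------------------------------

    def resolve_term(self, term_id: str) -> str:
        """Map an alt_id onto its primary accession; raise if unknown."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_to_primary:
            return self.alt_to_primary[term_id]
        raise KBLookupError(f"unknown GO term: {term_id}")

    @property
    def compound_universe(self) -> set[str]:
        """Distinct compounds linked to >=1 GO term (size background_n)."""
        universe: set[str] = set()
        for comps in self.term_to_compounds.values():
            universe |= comps
        return universe


# ---------------------------------------------------------------------------
# ontology restriction
# ---------------------------------------------------------------------------

def metabolic_subontology(terms: Mapping[str, GoTerm], root_id: str) -> set[str]:
    """Return the root plus every non-obsolete term whose is_a chain
    reaches the root (reflexive-transitive closure over parents)."""
    if root_id not in terms:
        raise KBLookupError(f"root term not in ontology: {root_id}")
    children: dict[str, set[str]] = {}
    for term in terms.values():
        if term.obsolete:
            continue
        for parent in term.parents:
            children.setdefault(parent, set()).add(term.term_id)
    kept = {root_id}
    stack = [root_id]
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):  # obsolete terms never enter
            if child not in kept:
                kept.add(child)
                stack.append(child)
    return kept


def term_ancestors(terms: Mapping[str, GoTerm], term_id: str) -> set[str]:
    """All is_a ancestors of a term (the term itself excluded)."""
    seen: set[str] = set()
    stack = list(terms[term_id].parents)
    while stack:
        node = stack.pop()
        if node in seen or node not in terms:
            continue
        seen.add(node)
        stack.extend(terms[node].parents)
    return seen


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def build_knowledgebase(
    sources: SourceBundle,
    tax_id: int = DEFAULT_TAX_ID,
    root_id: str = METABOLIC_ROOT,
    propagate: bool = False,
) -> KnowledgeBase:
    """Assemble the knowledgebase from the raw sources.

    Steps: restrict the ontology to the metabolic sub-tree; keep taxon
    genes annotated to a kept term; keep their transcripts/proteins;
    keep EC classes tied to kept proteins (all active classes when the
    protein-EC table is absent); keep the reactions of kept ECs and the
    compounds of kept reactions; derive the per-term compound and gene
    maps and the background universe size.
    """
    sources.validate()

    all_terms = parse_go_obo(sources.obo_path)
    kept_term_ids = metabolic_subontology(all_terms, root_id)
    terms = {tid: all_terms[tid] for tid in kept_term_ids}
    # prune parent links leaving the sub-ontology
    for term in terms.values():
        term.parents = {p for p in term.parents if p in terms}
    alt_to_primary = {
        alt: term.term_id for term in terms.values() for alt in term.alt_ids
    }

    # genes annotated to >=1 kept metabolic term (direct annotations)
    annotations = parse_gene2go(sources.gene2go_path, tax_id)
    gene_go: set[tuple[int, str]] = set()
    for gene_id, go_id in annotations:
        go_id = alt_to_primary.get(go_id, go_id)
        if go_id in terms:
            gene_go.add((gene_id, go_id))
    kept_genes = {g for g, _ in gene_go}

    # transcript / protein layer
    acc_rows = parse_gene2accession(sources.gene2accession_path, tax_id)
    genes: dict[int, Gene] = {g: Gene(gene_id=g, tax_id=tax_id) for g in kept_genes}
    transcripts: dict[str, str] = {}
    proteins: dict[str, str] = {}
    gene_transcript: set[tuple[int, str]] = set()
    transcript_protein: set[tuple[str, str]] = set()
    gene_protein: set[tuple[int, str]] = set()
    for row in sorted(acc_rows):
        if row.gene_id not in kept_genes:
            continue
        if row.symbol:
            genes[row.gene_id].symbol = row.symbol
        if row.rna:
            transcripts[row.rna] = row.rna
            gene_transcript.add((row.gene_id, row.rna))
        if row.protein:
            proteins[row.protein] = row.protein
            gene_protein.add((row.gene_id, row.protein))
        if row.rna and row.protein:
            transcript_protein.add((row.rna, row.protein))
    gene_proteins: dict[int, set[str]] = {g: set() for g in kept_genes}
    for g, prot in gene_protein:
        gene_proteins[g].add(prot)

    # enzyme classes; transferred/deleted entries never carry links
    all_enzymes = parse_enzyme_dat(sources.enzyme_dat_path)
    active_ecs = {ec for ec, e in all_enzymes.items() if e.status == "active"}
    protein_ec: set[tuple[str, str]] = set()
    ec_filtered = sources.ec2protein_path is not None
    if ec_filtered:
        for prot, ec in parse_ec2protein(sources.ec2protein_path):
            if prot in proteins and ec in active_ecs:
                protein_ec.add((prot, ec))
        kept_ecs = {ec for _, ec in protein_ec}
    else:
        log.warning("no protein-EC table supplied: keeping all active EC classes "
                    "(unfiltered-EC build)")
        kept_ecs = set(active_ecs)
    enzymes = {ec: all_enzymes[ec] for ec in kept_ecs}

    # reactions and compounds downstream of kept ECs
    ec_reaction_raw = parse_kegg_link(sources.ec2reaction_path, "ec", "rn")
    reaction_compound_raw = parse_kegg_link(sources.reaction2compound_path, "rn", "cpd")
    ec_reaction = {(ec, rn) for ec, rn in ec_reaction_raw if ec in kept_ecs}
    kept_reactions = {rn for _, rn in ec_reaction}
    reaction_compound = {
        (rn, c) for rn, c in reaction_compound_raw if rn in kept_reactions
    }
    reactions: dict[str, Reaction] = {}
    for rn, c in reaction_compound:
        reactions.setdefault(rn, Reaction(reaction_id=rn)).compounds.add(c)
    # a reaction with no compound rows carries no information downstream
    empty = kept_reactions - set(reactions)
    if empty:
        log.info("dropping %d reaction(s) with no compound participants", len(empty))
        ec_reaction = {(ec, rn) for ec, rn in ec_reaction if rn in reactions}
    compounds = {c: Compound(compound_id=c) for _, c in reaction_compound}

    # per-gene reachable compound sets along protein -> EC -> reaction
    ec_by_protein: dict[str, set[str]] = {}
    for prot, ec in protein_ec:
        ec_by_protein.setdefault(prot, set()).add(ec)
    rn_by_ec: dict[str, set[str]] = {}
    for ec, rn in ec_reaction:
        rn_by_ec.setdefault(ec, set()).add(rn)
    gene_compounds: dict[int, set[str]] = {}
    for gene_id in kept_genes:
        reach: set[str] = set()
        for prot in gene_proteins[gene_id]:
            for ec in ec_by_protein.get(prot, ()):
                for rn in rn_by_ec.get(ec, ()):
                    reach |= reactions[rn].compounds
        gene_compounds[gene_id] = reach

    # derived term maps (direct annotations; optional ancestor propagation)
    term_to_genes: dict[str, set[int]] = {}
    for gene_id, go_id in gene_go:
        targets = {go_id}
        if propagate:
            targets |= term_ancestors(terms, go_id)
        for t in targets:
            term_to_genes.setdefault(t, set()).add(gene_id)
    term_to_compounds: dict[str, set[str]] = {}
    for t, gene_set in term_to_genes.items():
        comps: set[str] = set()
        for g in gene_set:
            comps |= gene_compounds[g]
        if comps:
            term_to_compounds[t] = comps

    universe: set[str] = set()
    for comps in term_to_compounds.values():
        universe |= comps
    if not universe:
        raise BuildError("no GO-linked compounds: the build yields an empty "
                         "background universe")

    manifest = {
        "tool": "metabogo",
        "version": __version__,
        "schema": 1,
        "tax_id": tax_id,
        "root_id": root_id,
        "propagate": propagate,
        "ec_filtered": ec_filtered,
        "built": datetime.date.today().isoformat(),
    }
    return KnowledgeBase(
        terms=terms, genes=genes, transcripts=transcripts, proteins=proteins,
        enzymes=enzymes, reactions=reactions, compounds=compounds,
        gene_go=gene_go, gene_transcript=gene_transcript,
        gene_protein=gene_protein,
        transcript_protein=transcript_protein, protein_ec=protein_ec,
        ec_reaction=ec_reaction, reaction_compound=reaction_compound,
        term_to_compounds=term_to_compounds, term_to_genes=term_to_genes,
        background_n=len(universe), alt_to_primary=alt_to_primary,
        manifest=manifest,
    )


def kb_statistics(kb: KnowledgeBase) -> dict[str, int]:
    """Entity-class counts of a built knowledgebase."""
    return {
        "terms_in_subontology": len(kb.terms),
        "terms_with_gene": len(kb.term_to_genes),
        "terms_with_compound": len(kb.term_to_compounds),
        "genes": len(kb.genes),
        "transcripts": len(kb.transcripts),
        "proteins": len(kb.proteins),
        "enzymes": len(kb.enzymes),
        "reactions": len(kb.reactions),
        "compounds": len(kb.compounds),
        "background_n": kb.background_n,
    }


# ---------------------------------------------------------------------------
# archive serialization (relational TSV tables in one zip container)
# ---------------------------------------------------------------------------

_EPOCH = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp for byte-reproducibility


def _tsv(rows) -> str:
    return "".join("\t".join(str(f) for f in row) + "\n" for row in rows)


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the knowledgebase as TSV tables inside one zip archive.

    Rows are sorted and the member timestamp is fixed, so rebuilding
    from identical sources is byte-identical.
    """
    members: dict[str, str] = {
        "manifest.json": json.dumps(
            {**kb.manifest, "background_n": kb.background_n},
            indent=1, sort_keys=True) + "\n",
        "terms.tsv": _tsv(
            (t.term_id, t.name, t.namespace,
             ";".join(sorted(t.parents)), ";".join(sorted(t.alt_ids)),
             int(t.obsolete))
            for t in sorted(kb.terms.values(), key=lambda t: t.term_id)),
        "genes.tsv": _tsv(
            (g.gene_id, g.symbol, g.tax_id)
            for g in sorted(kb.genes.values(), key=lambda g: g.gene_id)),
        "transcripts.tsv": _tsv((t,) for t in sorted(kb.transcripts)),
        "proteins.tsv": _tsv((p,) for p in sorted(kb.proteins)),
        "enzymes.tsv": _tsv(
            (e.ec_number, e.description, e.status)
            for e in sorted(kb.enzymes.values(), key=lambda e: e.ec_number)),
        "compounds.tsv": _tsv(
            (c.compound_id, c.name or "")
            for c in sorted(kb.compounds.values(), key=lambda c: c.compound_id)),
        "edges_gene_go.tsv": _tsv(sorted(kb.gene_go)),
        "edges_gene_transcript.tsv": _tsv(sorted(kb.gene_transcript)),
        "edges_gene_protein.tsv": _tsv(sorted(kb.gene_protein)),
        "edges_transcript_protein.tsv": _tsv(sorted(kb.transcript_protein)),
        "edges_protein_ec.tsv": _tsv(sorted(kb.protein_ec)),
        "edges_ec_reaction.tsv": _tsv(sorted(kb.ec_reaction)),
        "edges_reaction_compound.tsv": _tsv(sorted(kb.reaction_compound)),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(members):
            info = zipfile.ZipInfo(name, date_time=_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, members[name])


def load_kb(path: str | Path) -> KnowledgeBase:
    """Reload a knowledgebase archive written by :func:`save_kb`.

    The derived term maps are recomputed from the stored edge tables
    rather than stored, which keeps the archive normalized and makes
    the derivation a load-time consistency check.
    """
    with zipfile.ZipFile(path) as zf:
        def lines(name: str) -> list[list[str]]:
            text = zf.read(name).decode("utf-8")
            return [ln.split("\t") for ln in text.splitlines()]

        manifest = json.loads(zf.read("manifest.json"))
        terms = {}
        for tid, name, ns, parents, alt_ids, obsolete in lines("terms.tsv"):
            terms[tid] = GoTerm(
                term_id=tid, name=name, namespace=ns,
                parents=set(parents.split(";")) if parents else set(),
                alt_ids=set(alt_ids.split(";")) if alt_ids else set(),
                obsolete=bool(int(obsolete)))
        genes = {int(g): Gene(int(g), sym, int(tax))
                 for g, sym, tax in lines("genes.tsv")}
        transcripts = {r[0]: r[0] for r in lines("transcripts.tsv")}
        proteins = {r[0]: r[0] for r in lines("proteins.tsv")}
        enzymes = {ec: EnzymeClass(ec, de, status)
                   for ec, de, status in lines("enzymes.tsv")}
        compounds = {c: Compound(c, name or None)
                     for c, name in lines("compounds.tsv")}
        gene_go = {(int(g), t) for g, t in lines("edges_gene_go.tsv")}
        gene_transcript = {(int(g), t) for g, t in lines("edges_gene_transcript.tsv")}
        gene_protein = {(int(g), p) for g, p in lines("edges_gene_protein.tsv")}
        transcript_protein = {tuple(r) for r in lines("edges_transcript_protein.tsv")}
        protein_ec = {tuple(r) for r in lines("edges_protein_ec.tsv")}
        ec_reaction = {tuple(r) for r in lines("edges_ec_reaction.tsv")}
        reaction_compound = {tuple(r) for r in lines("edges_reaction_compound.tsv")}

    reactions: dict[str, Reaction] = {}
    for rn, c in reaction_compound:
        reactions.setdefault(rn, Reaction(rn)).compounds.add(c)
    kb = KnowledgeBase(
        terms=terms, genes=genes, transcripts=transcripts, proteins=proteins,
        enzymes=enzymes, reactions=reactions, compounds=compounds,
        gene_go=gene_go, gene_transcript=gene_transcript,
        gene_protein=gene_protein,
        transcript_protein=transcript_protein, protein_ec=protein_ec,
        ec_reaction=ec_reaction, reaction_compound=reaction_compound,
        term_to_compounds={}, term_to_genes={}, background_n=0,
        alt_to_primary={alt: t.term_id for t in terms.values()
                        for alt in t.alt_ids},
        manifest=manifest,
    )
    _derive_term_maps(kb, propagate=bool(manifest.get("propagate", False)))
    if kb.background_n != manifest.get("background_n", kb.background_n):
        raise BuildError(
            f"archive {path}: derived background_n={kb.background_n} does not "
            f"match manifest value {manifest['background_n']}")
    return kb


def _derive_term_maps(kb: KnowledgeBase, propagate: bool = False) -> None:
    """(Re)compute term_to_genes / term_to_compounds / background_n
    from the raw edge tables in place."""
    gene_proteins: dict[int, set[str]] = {}
    for g, prot in kb.gene_protein:
        gene_proteins.setdefault(g, set()).add(prot)
    ec_by_protein: dict[str, set[str]] = {}
    for prot, ec in kb.protein_ec:
        ec_by_protein.setdefault(prot, set()).add(ec)
    rn_by_ec: dict[str, set[str]] = {}
    for ec, rn in kb.ec_reaction:
        rn_by_ec.setdefault(ec, set()).add(rn)

    kb.term_to_genes = {}
    for g, t in kb.gene_go:
        targets = {t}
        if propagate:
            targets |= term_ancestors(kb.terms, t)
        for tid in targets:
            kb.term_to_genes.setdefault(tid, set()).add(g)
    kb.term_to_compounds = {}
    universe: set[str] = set()
    for t, gene_set in kb.term_to_genes.items():
        comps: set[str] = set()
        for g in gene_set:
            for prot in gene_proteins.get(g, ()):
                for ec in ec_by_protein.get(prot, ()):
                    for rn in rn_by_ec.get(ec, ()):
                        comps |= kb.reactions[rn].compounds
        if comps:
            kb.term_to_compounds[t] = comps
            universe |= comps
    kb.background_n = len(universe)
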