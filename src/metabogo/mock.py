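"""Deterministic miniature source files for offline testing.

:func:`generate_mock_sources` writes syntactically exact, tiny versions
of every raw source the knowledgebase builder consumes — an OBO
ontology forming a random DAG under GO:0008152, NCBI gene2go /
gene2accession tables, an Expasy enzyme.dat, KEGG link tables and a
protein-to-EC table — together with a JSON "truth" file holding the
entity and edge sets the builder is expected to produce, computed here
by direct construction so builder tests have an independent oracle.

The files mimic format and statistical structure only; no attempt is
made at biological realism (pathway topology, compound chemistry).

:func:`worked_example_kb` builds a synthetic knowledgebase that
reproduces the statistical frame of the nucleoside-salvage enrichment
example (one term with 61 linked compounds inside a 2,212-compound
universe, and an input list of 62 mapped compounds overlapping it in
13); compound identities are synthetic.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from .kb import (
    Compound,
    Gene,
    KnowledgeBase,
    METABOLIC_ROOT,
    Reaction,
    SourceBundle,
)
from .parsers import EnzymeClass, GoTerm

NON_METABOLIC_TERM = "GO:0099999"
OBSOLETE_TERM = "GO:0098765"
ALT_ID = "GO:7654321"


@dataclass
class FixtureSpec:
    """Size knobs for the mock sources; generation is a pure function
    of (spec, seed)."""

    n_terms: int = 8          # metabolic terms, root included
    n_genes: int = 6
    n_ecs: int = 4
    n_reactions: int = 6
    n_compounds: int = 12
    seed: int = 7
    tax_id: int = 9606

    def __post_init__(self) -> None:
        for name in ("n_terms", "n_genes", "n_ecs", "n_reactions", "n_compounds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _term_id(i: int) -> str:
    return METABOLIC_ROOT if i == 0 else f"GO:{1000000 + i:07d}"


def generate_mock_sources(spec: FixtureSpec, out_dir: str | Path) -> SourceBundle:
    """Write all mock source files plus ``truth.json`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    # ---- ontology: a random DAG rooted at the metabolic-process term ----
    term_ids = [_term_id(i) for i in range(spec.n_terms)]
    parents: dict[str, list[str]] = {term_ids[0]: []}
    for i in range(1, spec.n_terms):
        k = min(len(term_ids[:i]), rng.choice([1, 1, 2]))
        parents[term_ids[i]] = sorted(rng.sample(term_ids[:i], k))

    obo_lines = [
        "format-version: 1.2",
        "ontology: go-mock",
        "",
        "[Term]",
        f"id: {term_ids[0]}",
        "name: metabolic process",
        "namespace: biological_process",
        f"alt_id: {ALT_ID}",
        "",
    ]
    for tid in term_ids[1:]:
        obo_lines += ["[Term]", f"id: {tid}",
                      f"name: mock process {tid[-4:]}",
                      "namespace: biological_process"]
        obo_lines += [f"is_a: {p} ! parent" for p in parents[tid]]
        obo_lines.append("")
    obo_lines += [
        "[Term]", f"id: {NON_METABOLIC_TERM}", "name: unrelated signaling",
        "namespace: biological_process", "",
        "[Term]", f"id: {OBSOLETE_TERM}", "name: outdated process",
        "namespace: biological_process", f"is_a: {term_ids[0]}",
        "is_obsolete: true", "",
        "[Typedef]", "id: part_of", "name: part of", "",
    ]
    (out / "go.obo").write_text("\n".join(obo_lines))

    # ---- gene annotations -----------------------------------------------
    gene_ids = [1001 + i for i in range(spec.n_genes)]
    annotations: dict[int, list[str]] = {}
    for g in gene_ids:
        k = min(rng.choice([1, 1, 2]), len(term_ids))
        annotations[g] = sorted(rng.sample(term_ids, k))
    decoy_gene = 1001 + spec.n_genes  # annotated only outside the sub-ontology

    g2g_rows = [("#tax_id", "GeneID", "GO_ID", "Evidence", "Qualifier",
                 "GO_term", "PubMed", "Category")]
    for g in gene_ids:
        for t in annotations[g]:
            g2g_rows.append((str(spec.tax_id), str(g), t, "IDA", "-",
                             "mock", "-", "Process"))
    # negated annotation, foreign taxon and non-metabolic rows: all excluded
    g2g_rows.append((str(spec.tax_id), str(gene_ids[0]), term_ids[-1], "IEA",
                     "NOT", "mock", "-", "Process"))
    g2g_rows.append(("10090", str(gene_ids[0]), term_ids[0], "IDA", "-",
                     "mock", "-", "Process"))
    g2g_rows.append((str(spec.tax_id), str(decoy_gene), NON_METABOLIC_TERM,
                     "IDA", "-", "mock", "-", "Process"))
    (out / "gene2go.tsv").write_text(
        "".join("\t".join(r) + "\n" for r in g2g_rows))

    # ---- accession table -------------------------------------------------
    acc_rows = [("#tax_id", "GeneID", "status",
                 "RNA_nucleotide_accession.version", "RNA_nucleotide_gi",
                 "protein_accession.version", "protein_gi",
                 "genomic_nucleotide_accession.version",
                 "genomic_nucleotide_gi", "start_position_on_the_genomic_accession",
                 "end_position_on_the_genomic_accession", "orientation",
                 "assembly", "mature_peptide_accession.version",
                 "mature_peptide_gi", "Symbol")]
    gene_transcripts: dict[int, list[str]] = {}
    gene_proteins: dict[int, list[str]] = {}
    rna_protein: list[tuple[str, str]] = []
    acc_counter = 0
    for g in gene_ids + [decoy_gene]:
        n_iso = rng.choice([1, 1, 2])
        gene_transcripts[g], gene_proteins[g] = [], []
        for _ in range(n_iso):
            acc_counter += 1
            rna = f"NM_{100000 + acc_counter:06d}"
            prot = f"NP_{100000 + acc_counter:06d}"
            gene_transcripts[g].append(rna)
            gene_proteins[g].append(prot)
            rna_protein.append((rna, prot))
            acc_rows.append((str(spec.tax_id), str(g), "REVIEWED",
                             f"{rna}.{rng.randint(1, 3)}", "111",
                             f"{prot}.{rng.randint(1, 3)}", "222",
                             "-", "-", "-", "-", "?", "-", "-", "-",
                             f"GENE{g}"))
        # genomic-only row: placeholder in both accession columns, dropped
        acc_rows.append((str(spec.tax_id), str(g), "REVIEWED", "-", "-",
                         "-", "-", "NC_000001.11", "333", "1", "2", "+",
                         "-", "-", "-", f"GENE{g}"))
    (out / "gene2accession.tsv").write_text(
        "".join("\t".join(r) + "\n" for r in acc_rows))

    # ---- enzyme classes ---------------------------------------------------
    active_ecs = [f"1.1.1.{i + 1}" for i in range(spec.n_ecs)]
    enz_lines: list[str] = []
    for ec in active_ecs:
        enz_lines += [f"ID   {ec}", f"DE   Mock enzyme {ec}.", "//"]
    enz_lines += ["ID   2.2.2.2", "DE   Transferred entry: 1.1.1.1.", "//",
                  "ID   3.3.3.3", "DE   Deleted entry.", "//"]
    (out / "enzyme.dat").write_text("\n".join(enz_lines) + "\n")

    # ---- protein-EC table -------------------------------------------------
    kept_prots = sorted(p for g in gene_ids for p in gene_proteins[g])
    protein_ec = sorted(
        {(rng.choice(kept_prots), ec) for ec in active_ecs})
    (out / "ec2protein.tsv").write_text(
        "#protein_accession\tec_number\n"
        + "".join(f"{p}.1\t{ec}\n" for p, ec in protein_ec))

    # ---- KEGG link tables -------------------------------------------------
    reaction_ids = [f"R{i + 1:05d}" for i in range(spec.n_reactions)]
    ec_reaction = sorted((rng.choice(active_ecs), rn) for rn in reaction_ids)
    kegg_ec2rn = [f"ec:{ec}\trn:{rn}\n" for ec, rn in ec_reaction]
    kegg_ec2rn.append(f"ec:2.2.2.2\trn:{reaction_ids[0]}\n")  # transferred EC: ignored
    (out / "ec2reaction.tsv").write_text("".join(kegg_ec2rn))

    compound_ids = [f"C{i + 1:05d}" for i in range(spec.n_compounds)]
    reaction_compound = sorted(
        (rn, c)
        for rn in reaction_ids
        for c in rng.sample(compound_ids, min(len(compound_ids), rng.choice([2, 2, 3])))
    )
    kegg_rn2cpd = [f"rn:{rn}\tcpd:{c}\n" for rn, c in reaction_compound]
    kegg_rn2cpd.append(f"rn:{reaction_ids[0]}\tgl:G00001\n")  # glycan participant: dropped
    (out / "reaction2compound.tsv").write_text("".join(kegg_rn2cpd))

    bundle = SourceBundle(
        obo_path=out / "go.obo",
        gene2go_path=out / "gene2go.tsv",
        gene2accession_path=out / "gene2accession.tsv",
        enzyme_dat_path=out / "enzyme.dat",
        ec2reaction_path=out / "ec2reaction.tsv",
        reaction2compound_path=out / "reaction2compound.tsv",
        ec2protein_path=out / "ec2protein.tsv",
    )

    # ---- expected knowledgebase, by direct construction -------------------
    kept_ecs = sorted({ec for _, ec in protein_ec})
    kept_ec_reaction = sorted((ec, rn) for ec, rn in ec_reaction if ec in kept_ecs)
    kept_rns = sorted({rn for _, rn in kept_ec_reaction})
    kept_rn_cpd = sorted((rn, c) for rn, c in reaction_compound if rn in kept_rns)
    rn_comps: dict[str, set[str]] = {}
    for rn, c in kept_rn_cpd:
        rn_comps.setdefault(rn, set()).add(c)

    ecs_of_prot: dict[str, set[str]] = {}
    for p, ec in protein_ec:
        ecs_of_prot.setdefault(p, set()).add(ec)
    gene_comps: dict[int, set[str]] = {}
    for g in gene_ids:
        reach: set[str] = set()
        for p in gene_proteins[g]:
            for ec in ecs_of_prot.get(p, ()):
                for ec2, rn in kept_ec_reaction:
                    if ec2 == ec:
                        reach |= rn_comps.get(rn, set())
        gene_comps[g] = reach

    term_to_genes: dict[str, set[int]] = {}
    for g in gene_ids:
        for t in annotations[g]:
            term_to_genes.setdefault(t, set()).add(g)
    term_to_compounds = {
        t: set().union(*(gene_comps[g] for g in gs))
        for t, gs in term_to_genes.items()
    }
    term_to_compounds = {t: cs for t, cs in term_to_compounds.items() if cs}
    universe = sorted(set().union(*term_to_compounds.values())
                      if term_to_compounds else set())

    truth = {
        "terms": sorted(term_ids),
        "genes": sorted(gene_ids),
        "transcripts": sorted(t for g in gene_ids for t in gene_transcripts[g]),
        "proteins": sorted(p for g in gene_ids for p in gene_proteins[g]),
        "enzymes": kept_ecs,
        "reactions": kept_rns,
        "compounds": sorted({c for _, c in kept_rn_cpd}),
        "edges": {
            "gene_go": sorted([g, t] for g in gene_ids for t in annotations[g]),
            "gene_transcript": sorted(
                [g, t] for g in gene_ids for t in gene_transcripts[g]),
            "gene_protein": sorted(
                [g, p] for g in gene_ids for p in gene_proteins[g]),
            "transcript_protein": sorted(
                [t, p] for t, p in rna_protein
                if any(t in gene_transcripts[g] for g in gene_ids)),
            "protein_ec": sorted([p, ec] for p, ec in protein_ec),
            "ec_reaction": [list(e) for e in kept_ec_reaction],
            "reaction_compound": [list(e) for e in kept_rn_cpd],
        },
        "term_to_compounds": {t: sorted(cs)
                              for t, cs in sorted(term_to_compounds.items())},
        "term_to_genes": {t: sorted(gs)
                          for t, gs in sorted(term_to_genes.items())},
        "background_n": len(universe),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")

    # a ready-made input list: half the universe plus one unknown id
    picked = universe[: max(1, len(universe) // 2)]
    (out / "input_compounds.txt").write_text(
        "".join(c + "\n" for c in picked) + "C99999\n")
    return bundle


class WorkedExample(NamedTuple):
    kb: KnowledgeBase
    input_ids: list[str]


def worked_example_kb(seed: int = 43174) -> WorkedExample:
    """Synthetic KB reproducing the nucleoside-salvage test frame.

    One focal term (GO:0043174) carries 61 of the 2,212 GO-linked
    compounds; the catch-all metabolic root carries all of them.  The
    accompanying input list holds 62 universe compounds of which 13
    overlap the focal term, so an ORA run yields (x, y, b) =
    (13, 61, 62) with background N = 2,212.
    """
    rng = random.Random(seed)
    universe = [f"C{i + 1:05d}" for i in range(2212)]
    term_compounds = sorted(rng.sample(universe, 61))
    rest = sorted(set(universe) - set(term_compounds))
    input_ids = sorted(rng.sample(term_compounds, 13) + rng.sample(rest, 49))

    root = GoTerm(term_id=METABOLIC_ROOT, name="metabolic process",
                  namespace="biological_process")
    focal = GoTerm(term_id="GO:0043174", name="nucleoside salvage",
                   namespace="biological_process", parents={METABOLIC_ROOT})
    gene_ids = [101, 102, 103, 104, 105]
    kb = KnowledgeBase(
        terms={t.term_id: t for t in (root, focal)},
        genes={g: Gene(gene_id=g, symbol=f"GENE{g}") for g in gene_ids},
        transcripts={}, proteins={},
        enzymes={}, reactions={},
        compounds={c: Compound(compound_id=c) for c in universe},
        gene_go={(g, focal.term_id) for g in gene_ids},
        gene_transcript=set(), gene_protein=set(), transcript_protein=set(),
        protein_ec=set(), ec_reaction=set(), reaction_compound=set(),
        term_to_compounds={
            METABOLIC_ROOT: set(universe),
            focal.term_id: set(term_compounds),
        },
        term_to_genes={
            METABOLIC_ROOT: set(gene_ids),
            focal.term_id: set(gene_ids),
        },
        background_n=len(universe),
        alt_to_primary={},
        manifest={"tool": "metabogo", "version": "worked-example",
                  "tax_id": 9606, "root_id": METABOLIC_ROOT},
    )
    return WorkedExample(kb=kb, input_ids=input_ids)
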