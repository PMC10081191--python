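"""Parsers for the five raw knowledgebase sources.

Each parser accepts either a filesystem path (plain text or gzip; a
``.gz`` suffix triggers transparent decompression) or an open text
stream, and returns plain Python containers.  Dialects handled:

* OBO 1.2/1.4 ontology flat files (``[Term]`` stanzas only),
* NCBI ``gene2go`` / ``gene2accession`` tab-delimited tables
  (``#`` header line, ``-`` placeholder),
* Expasy ``enzyme.dat`` flat-file records (``//`` terminated),
* KEGG REST ``link`` two-column tables with ``ec:``/``rn:``/``cpd:``
  database prefixes.

Malformed input raises :class:`~metabogo.errors.FormatError` with a
line number (tabular files) or byte offset (OBO stanzas).
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, NamedTuple, Union

from .errors import FormatError

log = logging.getLogger(__name__)

GO_ID_RE = re.compile(r"^GO:\d{7}$")
EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
REACTION_RE = re.compile(r"^R\d{5}$")
COMPOUND_RE = re.compile(r"^C\d{5}$")

Source = Union[str, Path, IO[str]]


@dataclass
class GoTerm:
    """One ontology node; ``parents`` holds is_a targets only."""

    term_id: str
    name: str = ""
    namespace: str = ""
    parents: set[str] = field(default_factory=set)
    alt_ids: set[str] = field(default_factory=set)
    obsolete: bool = False


class AccessionRow(NamedTuple):
    """One taxon-filtered gene2accession row, version suffixes stripped.

    ``rna`` / ``protein`` are None when the source column held the
    ``-`` placeholder (rows with both missing are dropped upstream).
    """

    gene_id: int
    rna: str | None
    protein: str | None
    symbol: str = ""


@dataclass
class EnzymeClass:
    ec_number: str
    description: str = ""
    status: str = "active"  # active | transferred | deleted


def _open_text(source: Source) -> tuple[IO[str], bool]:
    """Return (text stream, needs_close). Paths ending .gz are gunzipped."""
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix == ".gz":
            return io.TextIOWrapper(gzip.open(p, "rb"), encoding="utf-8"), True
        return open(p, "rt", encoding="utf-8"), True
    return source, False


def _iter_lines(source: Source) -> Iterator[str]:
    stream, needs_close = _open_text(source)
    try:
        yield from stream
    finally:
        if needs_close:
            stream.close()


def strip_version(accession: str) -> str:
    """Drop a trailing ``.N`` version suffix from an accession."""
    head, dot, tail = accession.rpartition(".")
    if dot and tail.isdigit():
        return head
    return accession


# ---------------------------------------------------------------------------
# OBO ontology
# ---------------------------------------------------------------------------

def parse_go_obo(source: Source) -> dict[str, GoTerm]:
    """Parse ``[Term]`` stanzas of an OBO file into :class:`GoTerm` records.

    Only the tags the knowledgebase needs are read: ``id``, ``name``,
    ``namespace``, ``is_a``, ``alt_id``, ``is_obsolete``.  Non-Term
    stanzas (``[Typedef]`` etc.) and header lines are skipped.  Obsolete
    terms retain no parents.  is_a targets that never appear as a
    primary id in the same file are pruned with a warning so that parent
    links always resolve within the load.
    """
    terms: dict[str, GoTerm] = {}
    current: GoTerm | None = None
    in_term = False
    stanza_offset = 0
    offset = 0

    def finish() -> None:
        nonlocal current
        if current is not None:
            if current.obsolete:
                current.parents.clear()
            terms[current.term_id] = current
            current = None

    for raw in _iter_lines(source):
        line = raw.rstrip("\n")
        line_offset = offset
        offset += len(raw.encode("utf-8"))
        stripped = line.strip()
        if stripped.startswith("["):
            finish()
            in_term = stripped == "[Term]"
            stanza_offset = line_offset
            continue
        if not in_term or not stripped or stripped.startswith("!"):
            continue
        tag, _, value = stripped.partition(":")
        value = value.split("!")[0].strip()
        if tag == "id":
            if current is not None:
                finish()
            current = GoTerm(term_id=value)
        elif current is None:
            if tag in {"name", "namespace", "is_a", "alt_id", "is_obsolete"}:
                raise FormatError(
                    f"[Term] stanza at byte offset {stanza_offset} has no id line"
                )
        elif tag == "name":
            current.name = value
        elif tag == "namespace":
            current.namespace = value
        elif tag == "is_a":
            current.parents.add(value.split()[0])
        elif tag == "alt_id":
            current.alt_ids.add(value)
        elif tag == "is_obsolete" and value == "true":
            current.obsolete = True
    finish()

    known = set(terms)
    for term in terms.values():
        dangling = term.parents - known
        if dangling:
            log.warning(
                "term %s: pruning %d is_a target(s) absent from this load: %s",
                term.term_id, len(dangling), ", ".join(sorted(dangling)),
            )
            term.parents -= dangling
    return terms


# ---------------------------------------------------------------------------
# NCBI tab-delimited tables
# ---------------------------------------------------------------------------

def parse_gene2go(source: Source, tax_id: int) -> set[tuple[int, str]]:
    """Extract (gene_id, go_id) pairs for one taxon from NCBI gene2go.

    Rows carrying a NOT qualifier (negated annotations) are excluded;
    duplicate pairs collapse to one.
    """
    pairs: set[tuple[int, str]] = set()
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise FormatError(f"gene2go line {lineno}: expected >=5 columns, got {len(fields)}")
        row_tax, gene, go_id, _evidence, qualifier = fields[:5]
        if int(row_tax) != tax_id:
            continue
        if "NOT" in qualifier.split("|"):
            continue
        pairs.add((int(gene), go_id))
    return pairs


def parse_gene2accession(source: Source, tax_id: int) -> set[AccessionRow]:
    """Extract gene/transcript/protein accession rows for one taxon.

    Version suffixes are stripped so joins against other sources do not
    depend on accession versions.  Rows with the ``-`` placeholder in
    both the RNA and protein columns carry no linkage and are dropped.
    """
    rows: set[AccessionRow] = set()
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 16:
            raise FormatError(
                f"gene2accession line {lineno}: expected >=16 columns, got {len(fields)}"
            )
        if int(fields[0]) != tax_id:
            continue
        rna = fields[3] if fields[3] != "-" else None
        protein = fields[5] if fields[5] != "-" else None
        if rna is None and protein is None:
            continue
        rows.add(AccessionRow(
            gene_id=int(fields[1]),
            rna=strip_version(rna) if rna else None,
            protein=strip_version(protein) if protein else None,
            symbol=fields[15] if fields[15] != "-" else "",
        ))
    return rows


# ---------------------------------------------------------------------------
# Expasy enzyme.dat
# ---------------------------------------------------------------------------

def parse_enzyme_dat(source: Source) -> dict[str, EnzymeClass]:
    """Parse Expasy enzyme.dat records into :class:`EnzymeClass` entries.

    A record is the lines up to a ``//`` terminator; ``ID`` gives the EC
    number and concatenated ``DE`` lines the description.  Descriptions
    beginning ``Transferred entry`` or ``Deleted entry`` mark
    non-active classes that must carry no reaction links downstream.
    """
    enzymes: dict[str, EnzymeClass] = {}
    ec: str | None = None
    de_parts: list[str] = []

    def finish() -> None:
        nonlocal ec, de_parts
        if ec is None:
            if de_parts:
                raise FormatError("enzyme.dat record lacking an ID line")
            return
        description = " ".join(de_parts)
        if description.startswith("Transferred entry"):
            status = "transferred"
        elif description.startswith("Deleted entry"):
            status = "deleted"
        else:
            status = "active"
        enzymes[ec] = EnzymeClass(ec_number=ec, description=description, status=status)
        ec, de_parts = None, []

    for raw in _iter_lines(source):
        line = raw.rstrip("\n")
        if line.startswith("//"):
            finish()
        elif line.startswith("ID"):
            ec = line[2:].strip()
        elif line.startswith("DE"):
            de_parts.append(line[2:].strip())
    finish()
    return enzymes


# ---------------------------------------------------------------------------
# KEGG REST link tables
# ---------------------------------------------------------------------------

def parse_kegg_link(
    source: Source, from_prefix: str, to_prefix: str
) -> set[tuple[str, str]]:
    """Parse a KEGG REST ``link`` dump into prefix-stripped id pairs.

    Glycan (``gl:``) targets are silently dropped — glycans are not part
    of the compound universe.  Any other unexpected prefix drops the row
    with a warning.
    """
    pairs: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"KEGG link line {lineno}: expected 2 columns, got {len(fields)}")
        src, dst = fields
        if src.startswith("gl:") or dst.startswith("gl:"):
            continue
        if not src.startswith(from_prefix + ":") or not dst.startswith(to_prefix + ":"):
            log.warning("KEGG link line %d: unexpected prefixes %r -> %r; row dropped",
                        lineno, src, dst)
            continue
        pairs.add((src.split(":", 1)[1], dst.split(":", 1)[1]))
    return pairs


def parse_ec2protein(source: Source) -> set[tuple[str, str]]:
    """Parse a pre-fetched two-column ``protein_accession<TAB>ec_number``
    table (the offline stand-in for live NCBI protein/EC retrieval).
    Protein versions are stripped; a ``#`` header line is allowed."""
    pairs: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"ec2protein line {lineno}: expected 2 columns, got {len(fields)}"
            )
        pairs.add((strip_version(fields[0]), fields[1]))
    return pairs


def read_compound_list(source: Source) -> list[str]:
    """Read a newline-delimited KEGG C-number list, preserving order.

    Blank lines and ``#`` comments are skipped; surrounding whitespace
    is trimmed.  Validation happens at mapping time, not here.
    """
    ids: list[str] = []
    for raw in _iter_lines(source):
        entry = raw.strip()
        if entry and not entry.startswith("#"):
            ids.append(entry)
    return ids


def read_id_map(source: Source) -> dict[str, str]:
    """Read an optional two-column TSV mapping foreign identifiers
    (e.g. PubChem CIDs) to KEGG C-numbers, applied before analysis."""
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"id-map line {lineno}: expected 2 columns, got {len(fields)}")
        mapping[fields[0]] = fields[1]
    return mapping
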