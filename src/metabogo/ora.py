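"""Over-representation analysis of a metabolite list against GO terms.

The statistic: given a background universe of N GO-linked KEGG
compounds, a GO term with y linked compounds (so a = N - y compounds
outside the term), and b input compounds mapped into the universe, of
which x fall in the term's set, the p-value is the hypergeometric
upper tail

    p = P[X >= x],   X ~ Hypergeometric(successes=y, failures=a, draws=b)

equivalently R's ``phyper(x - 1, y, a, b, lower.tail = FALSE)``.

Three relevance filters are applied before multiple-testing
adjustment: overlap x >= 3, at least 3 genes annotated to the term,
and x strictly greater than 5% of the term's compound-set size y.
Benjamini-Hochberg q-values are then computed over the filter-passing
terms (``fdr_all_terms=True`` adjusts over every tested term instead,
for sensitivity analysis); significance is declared at q < 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .kb import KnowledgeBase
from .parsers import COMPOUND_RE

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # floor before the -log10 transform of the impact table


@dataclass
class OraQuery:
    """Input list plus thresholds; defaults mirror the published analysis."""

    input_ids: list[str]
    alpha: float = 0.05
    min_overlap: int = 3
    min_genes: int = 3
    min_overlap_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1): {self.alpha}")
        if self.min_overlap < 1:
            raise ValueError(f"min_overlap must be >= 1: {self.min_overlap}")
        if not 0 <= self.min_overlap_fraction < 1:
            raise ValueError(
                f"min_overlap_fraction must lie in [0, 1): {self.min_overlap_fraction}")


@dataclass
class MappedInput:
    found: set[str]
    missing: list[str]

    @property
    def b(self) -> int:
        return len(self.found)


@dataclass
class OraResult:
    term_id: str
    term_name: str
    x: int
    y: int
    a: int
    b: int
    gene_count: int
    p_value: float
    overlap_compounds: set[str]
    q_value: float = math.nan
    passed_filters: bool = False


@dataclass
class OraReport:
    """All per-term results, sorted by (p_value, term_id)."""

    results: list[OraResult]
    query: OraQuery
    mapped: MappedInput
    kb_version: str = ""

    def significant(self) -> list[OraResult]:
        """Filter-passing terms with q below the query's FDR cutoff."""
        return [r for r in self.results
                if r.passed_filters and r.q_value < self.query.alpha]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"term_id": r.term_id, "name": r.term_name, "x": r.x, "y": r.y,
             "a": r.a, "b": r.b, "gene_count": r.gene_count,
             "p_value": r.p_value, "q_value": r.q_value,
             "passed_filters": r.passed_filters,
             "overlap_compounds": ";".join(sorted(r.overlap_compounds))}
            for r in self.results])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_excel(self, path: str | Path) -> None:
        self.to_frame().to_excel(path, index=False, sheet_name="GO ORA")


def map_input_ids(kb: KnowledgeBase, input_ids: Iterable[str]) -> MappedInput:
    """Intersect the input list with the KB's GO-linked compound universe.

    Duplicates are collapsed with a warning; syntactically invalid
    entries are reported and treated as unmapped.  An input that maps
    nothing at all is an error — no statistic is defined on b = 0.
    """
    universe = kb.compound_universe
    seen: set[str] = set()
    found: set[str] = set()
    missing: list[str] = []
    n_dup = 0
    for cid in input_ids:
        if cid in seen:
            n_dup += 1
            continue
        seen.add(cid)
        if not COMPOUND_RE.match(cid):
            log.warning("input id %r is not a KEGG C-number; treated as unmapped", cid)
            missing.append(cid)
        elif cid in universe:
            found.add(cid)
        else:
            missing.append(cid)
    if n_dup:
        log.warning("input list contains %d duplicate id(s); each counted once", n_dup)
    if not found:
        raise AnalysisError("no input compounds mapped into the knowledgebase")
    return MappedInput(found=found, missing=missing)


def hypergeom_upper_tail(x: int, y: int, a: int, b: int) -> float:
    """P[X >= x] drawing b items from y successes and a failures.

    Evaluated through the survival function of
    ``scipy.stats.hypergeom``, which works in log space and is accurate
    far into the tail.
    """
    for name, v in (("x", x), ("y", y), ("a", a), ("b", b)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer: {v}")
    if x > min(y, b):
        raise ValueError(f"x={x} exceeds min(y={y}, b={b})")
    if b > y + a:
        raise ValueError(f"cannot draw b={b} items from a population of {y + a}")
    if x == 0:
        return 1.0  # P[X >= 0] is certain; also covers the empty population
    return float(hypergeom.sf(x - 1, y + a, y, b))


def apply_filters(result: OraResult, query: OraQuery) -> bool:
    """Relevance filters: x >= min_overlap, gene_count >= min_genes and
    x strictly above min_overlap_fraction of the term set size y."""
    return (result.x >= query.min_overlap
            and result.gene_count >= query.min_genes
            and result.x > query.min_overlap_fraction * result.y)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    if len(p_values) == 0:
        return np.empty(0)
    return multipletests(p_values, method="fdr_bh")[1]


def run_ora(kb: KnowledgeBase, query: OraQuery,
            fdr_all_terms: bool = False) -> OraReport:
    """Score every GO term with at least one linked compound.

    q-values are computed over the filter-passing terms by default, so
    the BH denominator m is the filtered term count; terms outside the
    adjustment keep q = NaN.
    """
    mapped = map_input_ids(kb, query.input_ids)
    n = kb.background_n
    results: list[OraResult] = []
    for term_id in sorted(kb.term_to_compounds):
        comps = kb.term_to_compounds[term_id]
        overlap = mapped.found & comps
        x, y = len(overlap), len(comps)
        a = n - y
        res = OraResult(
            term_id=term_id,
            term_name=kb.terms[term_id].name if term_id in kb.terms else "",
            x=x, y=y, a=a, b=mapped.b,
            gene_count=len(kb.term_to_genes.get(term_id, ())),
            p_value=hypergeom_upper_tail(x, y, a, mapped.b),
            overlap_compounds=overlap,
        )
        res.passed_filters = apply_filters(res, query)
        results.append(res)

    adjusted = results if fdr_all_terms else [r for r in results if r.passed_filters]
    qs = bh_fdr([r.p_value for r in adjusted])
    for r, q in zip(adjusted, qs):
        r.q_value = float(q)

    results.sort(key=lambda r: (r.p_value, r.term_id))
    return OraReport(results=results, query=query, mapped=mapped,
                     kb_version=str(kb.manifest.get("version", "")))


def impact_table(report: OraReport) -> pd.DataFrame:
    """Set size vs significance for the filter-passing terms.

    Small y with large -log10(p) marks processes specific to the input
    list; p is floored at 1e-300 before the log transform.
    """
    rows = [
        {"term_id": r.term_id, "name": r.term_name, "set_size": r.y,
         "neg_log10_p": -math.log10(max(r.p_value, P_FLOOR)),
         "q_value": r.q_value, "passed": r.passed_filters}
        for r in report.results if r.passed_filters
    ]
    return pd.DataFrame(
        rows, columns=["term_id", "name", "set_size", "neg_log10_p",
                       "q_value", "passed"])
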