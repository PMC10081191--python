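"""Over-representation statistics: hypergeometric tail, filters,
BH-FDR and the full per-term analysis."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabogo import (
    KnowledgeBase,
    OraQuery,
    OraResult,
    apply_filters,
    bh_fdr,
    hypergeom_upper_tail,
    impact_table,
    map_input_ids,
    run_ora,
)
from metabogo.errors import AnalysisError
from metabogo.kb import Compound, Gene
from metabogo.parsers import GoTerm


def exact_upper_tail(x: int, y: int, a: int, b: int) -> Fraction:
    """Independent oracle: P[X >= x] by exact combinatorial enumeration."""
    total = math.comb(y + a, b)
    num = sum(math.comb(y, k) * math.comb(a, b - k)
              for k in range(x, min(y, b) + 1))
    return Fraction(num, total)


def _tiny_kb(term_to_compounds, term_to_genes=None, names=None):
    """Assemble a minimal in-memory KB around given term->compound sets."""
    universe = set().union(*term_to_compounds.values())
    terms = {t: GoTerm(term_id=t, name=(names or {}).get(t, t))
             for t in term_to_compounds}
    genes = term_to_genes or {t: {1, 2, 3} for t in term_to_compounds}
    gene_ids = {g for gs in genes.values() for g in gs}
    return KnowledgeBase(
        terms=terms,
        genes={g: Gene(gene_id=g) for g in gene_ids},
        transcripts={}, proteins={}, enzymes={}, reactions={},
        compounds={c: Compound(compound_id=c) for c in universe},
        gene_go=set(), gene_transcript=set(), gene_protein=set(),
        transcript_protein=set(), protein_ec=set(), ec_reaction=set(),
        reaction_compound=set(),
        term_to_compounds={t: set(cs) for t, cs in term_to_compounds.items()},
        term_to_genes={t: set(gs) for t, gs in genes.items()},
        background_n=len(universe), alt_to_primary={}, manifest={},
    )


RELAXED = dict(min_overlap=1, min_genes=1, min_overlap_fraction=0.0)


class TestHypergeomUpperTail:
    def test_nucleoside_salvage_frame(self):
        """13 of 62 drawn compounds hit a 61-compound term inside the
        2,212-compound universe."""
        p = hypergeom_upper_tail(13, 61, 2212 - 61, 62)
        assert p == pytest.approx(4.218424e-09, rel=1e-6)

    def test_both_complement_conventions_close(self):
        """Taking the complement against the universe (a = N - y) or
        against the unmapped remainder (a = N - b) moves p by < 2%."""
        p_universe = hypergeom_upper_tail(13, 61, 2212 - 61, 62)
        p_remainder = hypergeom_upper_tail(13, 61, 2212 - 62, 62)
        # value frozen from R 4.3.3: phyper(12, 61, 2150, 62, lower.tail=FALSE)
        assert p_remainder == pytest.approx(4.241376e-09, rel=1e-6)
        assert abs(p_remainder - p_universe) / p_universe < 0.02

    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 7, 3) == 1.0

    def test_two_from_two_enumeration(self):
        # C(4,2)=6 equally likely draws; exactly one contains both successes
        assert hypergeom_upper_tail(2, 2, 2, 2) == pytest.approx(1 / 6, abs=1e-15)

    def test_exhaustive_enumeration_small_populations(self):
        """Survival probabilities match exact enumeration for every
        population with y + a <= 12, all draws and all overlaps."""
        for y in range(0, 13):
            for a in range(0, 13 - y):
                for b in range(0, y + a + 1):
                    for x in range(0, min(y, b) + 1):
                        expected = float(exact_upper_tail(x, y, a, b))
                        got = hypergeom_upper_tail(x, y, a, b)
                        assert got == pytest.approx(expected, abs=1e-12), \
                            (x, y, a, b)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.data())
    def test_monotone_nonincreasing_in_overlap(self, data):
        y = data.draw(st.integers(0, 30))
        a = data.draw(st.integers(0, 30))
        b = data.draw(st.integers(0, y + a))
        ps = [hypergeom_upper_tail(x, y, a, b) for x in range(min(y, b) + 1)]
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_pmf_reconstructed_from_tail_differences_sums_to_one(self):
        y, a, b = 8, 15, 6
        tails = [hypergeom_upper_tail(x, y, a, b) for x in range(min(y, b) + 1)]
        tails.append(0.0)  # P[X >= min(y, b) + 1] is impossible
        pmf = [t1 - t2 for t1, t2 in zip(tails, tails[1:])]
        assert sum(pmf) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("args", [(5, 4, 10, 10), (3, 5, 0, 10), (-1, 5, 5, 5)])
    def test_invalid_arguments_raise(self, args):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(*args)


class TestMapInput:
    def test_found_missing_and_b(self):
        kb = _tiny_kb({"GO:1": {"C00001", "C00002", "C00003"}})
        mapped = map_input_ids(kb, ["C00001", "C00002", "C00009"])
        assert mapped.found == {"C00001", "C00002"}
        assert mapped.missing == ["C00009"]
        assert mapped.b == 2

    def test_duplicates_collapse(self, caplog):
        kb = _tiny_kb({"GO:1": {"C00001"}})
        with caplog.at_level("WARNING"):
            mapped = map_input_ids(kb, ["C00001", "C00001"])
        assert mapped.b == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_invalid_syntax_reported_not_fatal(self, caplog):
        kb = _tiny_kb({"GO:1": {"C00001"}})
        with caplog.at_level("WARNING"):
            mapped = map_input_ids(kb, ["C00001", "HMDB0000122"])
        assert mapped.found == {"C00001"}
        assert "HMDB0000122" in mapped.missing

    def test_nothing_mapped_is_an_error(self):
        kb = _tiny_kb({"GO:1": {"C00001"}})
        with pytest.raises(AnalysisError, match="no input compounds mapped"):
            map_input_ids(kb, ["C00009"])


class TestFilters:
    def _res(self, x, y, gene_count):
        return OraResult(term_id="GO:1", term_name="", x=x, y=y, a=0, b=0,
                         gene_count=gene_count, p_value=1.0,
                         overlap_compounds=set())

    @pytest.mark.parametrize("x,y,genes,expected", [
        (13, 61, 5, True),    # published example: 13>=3, 5>=3, 13 > 3.05
        (2, 10, 5, False),    # overlap below 3
        (3, 10, 5, True),     # overlap boundary passes
        (3, 10, 2, False),    # too few genes
        (3, 10, 3, True),     # gene boundary passes
        (4, 100, 10, False),  # 4 not strictly > 5 = 0.05*100
        (5, 100, 10, False),  # equality fails the strict rule
        (6, 100, 10, True),
        (3, 60, 3, False),    # x equals ceil(0.05*60)=3 and 3 > 3.0 is false
    ])
    def test_default_filter_semantics(self, x, y, genes, expected):
        assert apply_filters(self._res(x, y, genes), OraQuery(input_ids=["C00001"])) \
            is expected

    def test_relaxed_thresholds(self):
        q = OraQuery(input_ids=["C00001"], **RELAXED)
        assert apply_filters(self._res(1, 100, 1), q)


class TestBhFdr:
    def _step_up(self, ps):
        """Independent oracle: direct BH step-up formula."""
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        q = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * ps[i] / rank)
            q[i] = running
        return q

    def test_hand_computed_vector(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_identity(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_step_up_formula_and_bounds(self, ps):
        qs = bh_fdr(ps)
        assert qs == pytest.approx(self._step_up(ps), abs=1e-12)
        assert np.all(qs >= np.asarray(ps) - 1e-12)
        assert np.all(qs <= 1.0 + 1e-12)

    def test_monotone_in_p_rank(self):
        ps = [0.3, 0.001, 0.04, 0.9, 0.04]
        qs = bh_fdr(ps)
        ordered = [q for _, q in sorted(zip(ps, qs))]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(ordered, ordered[1:]))


class TestRunOra:
    @pytest.fixture()
    def six_compound_kb(self):
        return _tiny_kb({
            "GO:0000001": {"C00001", "C00002", "C00003"},
            "GO:0000002": {"C00003", "C00004", "C00005", "C00006"},
        })

    def test_enumerated_p_values(self, six_compound_kb):
        """With universe 6 and input {C1,C2,C3}: P[X>=3 | y=3,a=3,b=3] is
        1/C(6,3) = 1/20; the second term cannot miss entirely (only two
        failures for three draws), so P[X>=1] = 1."""
        report = run_ora(six_compound_kb,
                         OraQuery(input_ids=["C00001", "C00002", "C00003"],
                                  **RELAXED))
        by_term = {r.term_id: r for r in report.results}
        assert by_term["GO:0000001"].p_value == pytest.approx(0.05, abs=1e-12)
        assert by_term["GO:0000002"].p_value == pytest.approx(1.0, abs=1e-12)
        assert by_term["GO:0000001"].a == 3
        assert by_term["GO:0000002"].a == 2

    def test_disjoint_input_all_p_one(self, six_compound_kb):
        report = run_ora(
            six_compound_kb,
            OraQuery(input_ids=["C00004", "C00005"], **RELAXED))
        res = {r.term_id: r for r in report.results}
        assert res["GO:0000001"].x == 0
        assert res["GO:0000001"].p_value == 1.0

    def test_default_filters_exclude_gene_poor_terms(self):
        kb = _tiny_kb(
            {"GO:0000001": {"C00001", "C00002", "C00003"},
             "GO:0000002": {"C00003", "C00004", "C00005", "C00006"}},
            term_to_genes={"GO:0000001": {1, 2, 3}, "GO:0000002": {1}})
        report = run_ora(kb, OraQuery(input_ids=["C00001", "C00002", "C00003"]))
        res = {r.term_id: r for r in report.results}
        assert res["GO:0000001"].passed_filters
        assert not res["GO:0000002"].passed_filters
        assert math.isnan(res["GO:0000002"].q_value)

    def test_fdr_denominator_is_filtered_count(self):
        """Two filter-passing terms out of three tested: m = 2, so the
        larger passing p is adjusted as 2*p/2 = p."""
        kb = _tiny_kb(
            {"GO:0000001": {f"C0000{i}" for i in range(1, 6)},
             "GO:0000002": {f"C0000{i}" for i in range(4, 9)},
             "GO:0000003": {"C00009"}},
            term_to_genes={"GO:0000001": {1, 2, 3},
                           "GO:0000002": {4, 5, 6},
                           "GO:0000003": {7}})
        q = OraQuery(input_ids=["C00001", "C00002", "C00003", "C00004"],
                     min_overlap=1, min_genes=3, min_overlap_fraction=0.0)
        report = run_ora(kb, q)
        passing = [r for r in report.results if r.passed_filters]
        assert len(passing) == 2
        ps = sorted(r.p_value for r in passing)
        expected_q = [min(2 * ps[0] / 1, 2 * ps[1] / 2, 1.0),
                      min(2 * ps[1] / 2, 1.0)]
        assert sorted(r.q_value for r in passing) == pytest.approx(expected_q)
        report_all = run_ora(kb, q, fdr_all_terms=True)
        assert not any(math.isnan(r.q_value) for r in report_all.results)

    def test_sorted_by_p_then_term_id(self, six_compound_kb):
        report = run_ora(six_compound_kb,
                         OraQuery(input_ids=["C00001", "C00002", "C00003"],
                                  **RELAXED))
        keys = [(r.p_value, r.term_id) for r in report.results]
        assert keys == sorted(keys)

    def test_input_order_never_changes_statistics(self, six_compound_kb):
        ids = ["C00001", "C00004", "C00002", "C00006"]
        r1 = run_ora(six_compound_kb, OraQuery(input_ids=ids, **RELAXED))
        r2 = run_ora(six_compound_kb, OraQuery(input_ids=ids[::-1], **RELAXED))
        assert [(r.term_id, r.x, r.p_value, r.q_value) for r in r1.results] == \
            [(r.term_id, r.x, r.p_value, r.q_value) for r in r2.results]

    def test_q_never_below_p(self, six_compound_kb):
        report = run_ora(six_compound_kb,
                         OraQuery(input_ids=["C00001", "C00003"], **RELAXED))
        for r in report.results:
            assert r.q_value >= r.p_value - 1e-12


class TestImpactTable:
    def test_columns_and_log_transform(self, worked_example):
        report = run_ora(worked_example.kb,
                         OraQuery(input_ids=worked_example.input_ids, **RELAXED))
        table = impact_table(report)
        row = table.set_index("term_id").loc["GO:0043174"]
        assert row["set_size"] == 61
        assert row["neg_log10_p"] == pytest.approx(8.374850, abs=1e-4)

    def test_p_of_one_maps_to_zero(self):
        kb = _tiny_kb({"GO:0000001": {"C00001", "C00002"}})
        report = run_ora(kb, OraQuery(input_ids=["C00002"], **RELAXED))
        table = impact_table(report)
        assert list(table["neg_log10_p"]) == [0.0]

    def test_only_filter_passing_terms_listed(self):
        kb = _tiny_kb(
            {"GO:0000001": {"C00001", "C00002", "C00003"},
             "GO:0000002": {"C00004"}},
            term_to_genes={"GO:0000001": {1, 2, 3}, "GO:0000002": {1}})
        report = run_ora(kb, OraQuery(input_ids=["C00001", "C00002", "C00003"]))
        table = impact_table(report)
        assert list(table["term_id"]) == ["GO:0000001"]


class TestWorkedExample:
    def test_statistical_frame(self, worked_example):
        kb = worked_example.kb
        assert kb.background_n == 2212
        assert len(kb.term_to_compounds["GO:0043174"]) == 61
        assert len(worked_example.input_ids) == 62
        overlap = set(worked_example.input_ids) & kb.term_to_compounds["GO:0043174"]
        assert len(overlap) == 13

    def test_run_ora_recovers_x_y_b_and_p(self, worked_example):
        report = run_ora(worked_example.kb,
                         OraQuery(input_ids=worked_example.input_ids, **RELAXED))
        res = {r.term_id: r for r in report.results}["GO:0043174"]
        assert (res.x, res.y, res.b) == (13, 61, 62)
        assert res.a == 2212 - 61
        assert res.p_value == pytest.approx(4.218424e-09, rel=1e-6)
        assert res.passed_filters


def test_query_validation():
    with pytest.raises(ValueError):
        OraQuery(input_ids=["C00001"], alpha=1.5)
    with pytest.raises(ValueError):
        OraQuery(input_ids=["C00001"], min_overlap=0)
    with pytest.raises(ValueError):
        OraQuery(input_ids=["C00001"], min_overlap_fraction=1.0)
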