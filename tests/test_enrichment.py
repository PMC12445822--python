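"""Contingency construction, Fisher exact tail, GO/KEGG parsing, enrichment."""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

from kacmeta.enrichment import (
    ContingencyTable,
    OntologyDAG,
    build_contingency,
    fisher_exact_greater,
    fold_enrichment,
    parse_kegg_htext,
    parse_obo,
    propagate_annotations,
    run_enrichment,
)
from kacmeta.synthetic_data import SyntheticSpec, generate_annotations


def hypergeom_tail(a: int, N: int, K: int, n: int) -> Fraction:
    """Independent full-enumeration oracle for the one-sided Fisher p."""
    return sum(
        (Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
         for x in range(a, min(K, n) + 1)),
        Fraction(0),
    )


class TestParseObo:
    def test_chain_closure(self, toy_obo):
        dag = parse_obo(toy_obo)
        assert dag.ancestors("GO:0000001") == {"GO:0000002", "GO:0000003"}

    def test_two_parents_both_ancestors(self, toy_obo):
        dag = parse_obo(toy_obo)
        assert dag.ancestors("GO:0000004") == {"GO:0000002", "GO:0000003"}

    def test_names_and_namespaces_loaded(self, toy_obo):
        dag = parse_obo(toy_obo)
        assert dag.terms["GO:0000003"] == ("root", "biological_process")

    def test_malformed_stanza_reports_line(self, tmp_path):
        path = tmp_path / "bad.obo"
        path.write_text("[Term]\nid: GO:1\nname missing colon\n")
        with pytest.raises(ValueError, match=":3:"):
            parse_obo(path)

    def test_cycle_is_error(self, tmp_path):
        path = tmp_path / "cyc.obo"
        path.write_text(
            "format-version: 1.2\nontology: cyc\n\n"
            "[Term]\nid: GO:1\nname: a\nis_a: GO:2\n\n"
            "[Term]\nid: GO:2\nname: b\nis_a: GO:1\n")
        with pytest.raises(ValueError, match="cycle"):
            parse_obo(path)

    def test_ancestors_equal_transitive_closure_oracle(self):
        """Random 30-term DAG: ancestor sets equal networkx reachability."""
        rng = np.random.default_rng(12)
        terms = [f"GO:{i:07d}" for i in range(30)]
        graph = nx.DiGraph()
        graph.add_nodes_from(terms)
        for i in range(1, 30):  # edges only to lower indices: acyclic
            for j in rng.choice(i, size=min(i, 2), replace=False):
                graph.add_edge(terms[i], terms[int(j)])
        dag = OntologyDAG(
            terms={t: ("", "") for t in terms},
            parents={t: frozenset(graph.successors(t)) for t in terms},
        )
        for t in terms:
            assert dag.ancestors(t) == nx.descendants(graph, t)


class TestParseKegg:
    def test_kos_map_to_enclosing_pathway(self, toy_kegg):
        h = parse_kegg_htext(toy_kegg)
        assert h.ko_to_pathways["K01810"] == {"00010"}
        assert h.ko_to_pathways["K01647"] == {"00020"}

    def test_ko_under_two_pathways_maps_twice(self, toy_kegg):
        h = parse_kegg_htext(toy_kegg)
        assert h.ko_to_pathways["K00844"] == {"00010", "00020"}

    def test_mapping_equals_hand_built_table(self, toy_kegg):
        h = parse_kegg_htext(toy_kegg)
        assert dict(h.ko_to_pathways) == {
            "K00844": frozenset({"00010", "00020"}),
            "K01810": frozenset({"00010"}),
            "K01647": frozenset({"00020"}),
            "K02108": frozenset({"00190"}),
        }
        assert h.pathway_names["00010"] == "Glycolysis / Gluconeogenesis"

    def test_orphan_ko_flagged(self, tmp_path):
        path = tmp_path / "orphan.keg"
        path.write_text("A09100 Metabolism\nD      K99999  orphan entry\n")
        h = parse_kegg_htext(path)
        assert "K99999" in h.orphan_kos
        assert "K99999" not in h.ko_to_pathways


class TestPropagation:
    def test_single_edge(self, toy_obo):
        dag = parse_obo(toy_obo)
        out = propagate_annotations({"g1": {"GO:0000002"}}, dag)
        assert out["g1"] == {"GO:0000002", "GO:0000003"}

    def test_toggle_off_is_identity(self, toy_obo):
        dag = parse_obo(toy_obo)
        out = propagate_annotations({"g1": {"GO:0000001"}}, dag, enabled=False)
        assert out["g1"] == {"GO:0000001"}

    def test_unknown_term_kept_but_not_propagated(self, toy_obo):
        dag = parse_obo(toy_obo)
        out = propagate_annotations({"g1": {"GO:9999999"}}, dag)
        assert out["g1"] == {"GO:9999999"}


class TestContingency:
    def test_planted_arithmetic(self):
        genes = [f"g{i}" for i in range(100)]
        ann = {g: {"T"} if i < 10 else set() for i, g in enumerate(genes)}
        study = set(genes[5:15])  # 5 with the term, 5 without
        table = build_contingency("T", study, set(genes), ann)
        assert (table.a, table.b, table.c, table.d) == (5, 5, 5, 85)

    def test_study_equal_background_collapses(self):
        genes = {"g1", "g2", "g3"}
        ann = {"g1": {"T"}, "g2": set(), "g3": set()}
        table = build_contingency("T", genes, genes, ann)
        assert (table.c, table.d) == (0, 0)
        assert table.a + table.b == len(genes)

    def test_empty_term(self):
        genes = {"g1", "g2"}
        table = build_contingency("T", {"g1"}, genes, {g: set() for g in genes})
        assert (table.a, table.c) == (0, 0)

    def test_study_outside_background_is_error(self):
        with pytest.raises(ValueError, match="not in background"):
            build_contingency("T", {"gX"}, {"g1"}, {})


class TestFisherExact:
    def test_zero_overlap_gives_p_one(self):
        assert fisher_exact_greater(ContingencyTable(0, 5, 5, 85)) == 1.0

    def test_study_fully_inside_term_closed_form(self):
        # N=20, K=n=a=3: p = C(3,3)C(17,0)/C(20,3) = 1/1140
        p = fisher_exact_greater(ContingencyTable(3, 0, 0, 17))
        assert p == pytest.approx(1 / 1140, rel=1e-12)

    def test_matches_enumeration_oracle(self):
        p = fisher_exact_greater(ContingencyTable(5, 5, 5, 85))
        q = float(hypergeom_tail(5, 100, 10, 10))
        assert p == pytest.approx(q, rel=1e-12)

    def test_monotone_nonincreasing_in_a(self):
        N, K, n = 40, 12, 15
        previous = 1.1
        for a in range(max(0, n - (N - K)), min(K, n) + 1):
            table = ContingencyTable(a, n - a, K - a, N - K - n + a)
            p = fisher_exact_greater(table)
            assert p <= previous + 1e-15
            previous = p

    def test_large_background_stable(self):
        # log-space path: must neither overflow nor hit zero spuriously
        p = fisher_exact_greater(ContingencyTable(50, 950, 950, 998_050))
        assert 0.0 < p < 1e-20

    def test_fold_enrichment_one_at_equal_proportions(self):
        table = ContingencyTable(5, 45, 10, 90)  # 10% in study and background
        assert fold_enrichment(table) == pytest.approx(1.0)


class TestRunEnrichment:
    def test_planted_term_flagged_significant(self):
        spec = SyntheticSpec(seed=0)
        ann, study, ledger = generate_annotations(spec)
        results = run_enrichment(study, set(ann), ann, alpha=0.01)
        significant = {r.term_id for r in results if r.significant}
        assert ledger["planted_term"] in significant

    def test_results_sorted_by_fold_then_p(self):
        spec = SyntheticSpec(seed=1)
        ann, study, _ = generate_annotations(spec)
        results = run_enrichment(study, set(ann), ann)
        folds = [r.fold_enrichment for r in results]
        assert folds == sorted(folds, reverse=True)

    def test_null_term_at_fold_one_not_significant(self):
        genes = [f"g{i}" for i in range(100)]
        ann = {g: ({"T"} if i < 10 else set()) for i, g in enumerate(genes)}
        study = set(genes[0:1]) | set(genes[10:19])  # 1/10 with term = background rate
        results = run_enrichment(study, set(genes), ann, alpha=0.01)
        assert not any(r.significant for r in results)

    def test_annotated_universe_drops_unannotated_study_genes(self):
        ann = {"g1": {"T"}, "g2": {"T"}, "g3": set(), "g4": {"U"}}
        # g3 has no annotation: outside the annotated universe
        results = run_enrichment({"g1", "g3"}, None, ann)
        table = {r.term_id: r.table for r in results}["T"]
        assert table.study_size == 1

    def test_fully_unannotated_study_is_error(self):
        ann = {"g1": {"T"}, "g2": set()}
        with pytest.raises(ValueError, match="no study gene"):
            run_enrichment({"g2"}, None, ann)

    def test_empty_study_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            run_enrichment(set(), {"g1"}, {"g1": {"T"}})

    def test_bh_correction_never_more_permissive(self):
        spec = SyntheticSpec(seed=2)
        ann, study, _ = generate_annotations(spec)
        raw = {r.term_id for r in run_enrichment(study, set(ann), ann)
               if r.significant}
        adj = {r.term_id
               for r in run_enrichment(study, set(ann), ann, correction="bh")
               if r.significant}
        assert adj <= raw

    def test_go_propagation_reaches_ancestor_terms(self, toy_obo):
        dag = parse_obo(toy_obo)
        ann = {f"g{i}": ({"GO:0000001"} if i < 5 else set()) for i in range(20)}
        study = {f"g{i}" for i in range(5)}
        results = run_enrichment(study, {f"g{i}" for i in range(20)}, ann,
                                 dag=dag)
        assert {"GO:0000001", "GO:0000002", "GO:0000003"} <= \
            {r.term_id for r in results}
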