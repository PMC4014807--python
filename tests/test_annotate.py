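import gzip

import numpy as np
import pytest

import screensift as ss
from screensift.annotate import AnnotationStore, connected_genes
from conftest import make_table
from oracles import brute_force_subnetwork, hypergeom_fisher_greater

GO_FIXTURE = """#tax_id\tGeneID\tGO_ID\tGO_term\tCategory
9606\t101\tGO:0005794\tGolgi apparatus\tComponent
9606\t101\tGO:0006886\tintracellular protein transport\tProcess
9606\t102\tGO:0005794\tGolgi apparatus\tComponent
9606\t102\tGO:0005794\tGolgi apparatus\tComponent
9606\t103\tGO:0000502\tproteasome complex\tComponent
9606\t104\tGO:0000502\tproteasome complex\tComponent
9606\t104\tGO:0016887\tATP hydrolysis activity\tFunction
9606\t105\tGO:0006886\tintracellular protein transport\tProcess
9606\t106\tGO:0005794\tGolgi membrane\tComponent
9606\t107\tGO:9999999\tmystery term\tNotACategory
"""

PPI_FIXTURE = """#tax_id\tgene_id\tinteractant_id\tprovenance
9606\t101\t102\ta
9606\t102\t101\tduplicate reversed
9606\t103\t103\tself loop
9606\t104\t105\tb
9606\t106\tnotanumber\tbad row
9606\t101\t105\tc
"""


@pytest.fixture
def go_store(tmp_path):
    p = tmp_path / "go.tsv"
    p.write_text(GO_FIXTURE)
    return ss.load_go(p)


@pytest.fixture
def ppi_store(tmp_path):
    p = tmp_path / "ppi.tsv"
    p.write_text(PPI_FIXTURE)
    return ss.load_ppi(p)


class TestLoadGo:
    def test_counts_match_hand_tally(self, go_store):
        # 10 rows: 1 duplicate collapsed, 1 unmappable category skipped
        assert go_store.go_report.rows_read == 10
        assert go_store.go_report.rows_skipped == 1
        assert go_store.go_report.duplicates_collapsed == 1
        assert sum(len(s) for s in go_store.go_map.values()) == 8

    def test_category_strings_map_to_namespaces(self, go_store):
        ns = {a.namespace for a in go_store.go_map[101]}
        assert ns == {"CC", "BP"}
        assert {a.namespace for a in go_store.go_map[104]} == {"CC", "MF"}

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "go.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(GO_FIXTURE)
        store = ss.load_go(p)
        assert sum(len(s) for s in store.go_map.values()) == 8


class TestLoadPpi:
    def test_edges_canonical_dedup_no_self_loops(self, ppi_store):
        assert ppi_store.ppi == {(101, 102), (104, 105), (101, 105)}
        assert ppi_store.ppi_report.rows_skipped == 2  # self loop + bad row
        assert ppi_store.ppi_report.duplicates_collapsed == 1

    def test_positional_columns_fallback(self, tmp_path):
        p = tmp_path / "pairs.tsv"
        p.write_text("a\tb\n7\t8\n8\t7\n")
        store = ss.load_ppi(p)
        assert store.ppi == {(7, 8)}


class TestEnrichment:
    def test_paper_table_counts_and_default_genome(self, go_store):
        res = ss.go_enrichment({101, 102, 106}, go_store, namespace="CC")
        golgi = [r for r in res if r.term == "Golgi apparatus"][0]
        assert (golgi.g_c, golgi.x, golgi.G_c, golgi.N) == (2, 3, 2, 22000)

    def test_p_matches_independent_hypergeometric_oracle(self):
        store = AnnotationStore()
        # fixture: x=10 selected, g_c=5 in category, G_c=100, N=22000
        for g in range(1, 101):
            store.add_annotation(g, "GO:X", "planted category", "BP")
        selected = set(range(1, 6)) | set(range(1001, 1006))
        res = ss.go_enrichment(selected, store, namespace="BP")
        r = res[0]
        assert (r.g_c, r.x, r.G_c) == (5, 10, 100)
        expected = hypergeom_fisher_greater(5, 100, 5, 21900)
        assert r.p_value == pytest.approx(expected, abs=1e-10)

    def test_smallest_p_for_fully_overlapping_category(self, go_store):
        res = ss.go_enrichment({101, 102, 106}, go_store, namespace="CC", p_threshold=1.0)
        assert res[0].term == "Golgi apparatus"
        assert res == sorted(res, key=lambda r: r.p_value)

    def test_p_threshold_filters(self):
        store = AnnotationStore()
        for g in range(1, 6):
            store.add_annotation(g, "GO:A", "tight category", "BP")
        for g in range(1, 15000):
            store.add_annotation(g, "GO:B", "huge category", "BP")
        res = ss.go_enrichment(set(range(1, 6)), store, p_threshold=0.01)
        assert {r.go_id for r in res} == {"GO:A"}

    def test_enrichment_p_monotone_in_overlap(self):
        # larger overlap never yields a larger one-sided p, other counts fixed
        x, G_c, N = 20, 150, 22000
        last = 1.1
        for g_c in range(1, x + 1):
            p = hypergeom_fisher_greater(g_c, G_c, x - g_c, N - G_c)
            assert p <= last + 1e-12
            last = p

    def test_standard_background_differs_and_matches_oracle(self):
        store = AnnotationStore()
        for g in range(1, 101):
            store.add_annotation(g, "GO:X", "category", "BP")
        selected = set(range(1, 11))
        printed = ss.go_enrichment(selected, store)[0]
        standard = ss.go_enrichment(selected, store, background="standard")[0]
        assert printed.p_value != standard.p_value
        expected = hypergeom_fisher_greater(10, 90, 0, 22000 - 100)
        assert standard.p_value == pytest.approx(expected, abs=1e-10)

    def test_empty_selection_rejected(self, go_store):
        with pytest.raises(ValueError):
            ss.go_enrichment(set(), go_store)


class TestSearchAndExclude:
    def test_golgi_query_in_cc(self, go_store):
        assert ss.search_go(go_store, "Golgi", namespace="CC") == {101, 102, 106}

    def test_query_matching_nothing(self, go_store):
        assert ss.search_go(go_store, "mitochondrion") == set()

    def test_substring_match_is_case_insensitive(self, go_store):
        assert ss.search_go(go_store, "golgi app", namespace="CC") == {101, 102}

    def test_flagged_set_matches_exhaustive_scan(self, go_store):
        for query, ns in [("transport", "BP"), ("protea", None), ("activity", "MF")]:
            expected = set()
            for gene, annots in go_store.go_map.items():
                for a in annots:
                    if (ns is None or a.namespace == ns) and query.lower() in a.term.lower():
                        expected.add(gene)
            assert ss.search_go(go_store, query, namespace=ns) == expected

    def test_exclude_proteasome_genes(self, go_store):
        genes = ["A", "B", "C", "D", "E"]
        t = make_table({1: [0.1] * 5}, genes=genes)
        t.records["entrez_id"] = [101, 102, 103, 104, 105]  # 103/104 proteasomal
        out = ss.exclude_by_go(t, go_store, "proteasome")
        assert len(out) == 3
        assert set(out.records["entrez_id"]) == {101, 102, 105}
        assert "proteasome" in out.derivation_log[-1]

    def test_exclude_nothing_is_identity_and_partition(self, go_store):
        t = make_table({1: [0.1] * 3})
        t.records["entrez_id"] = [101, 102, 105]
        out = ss.exclude_by_go(t, go_store, "spliceosome")
        assert len(out) == 3
        kept = ss.exclude_by_go(t, go_store, "Golgi apparatus")
        dropped = set(t.records["entrez_id"]) - set(kept.records["entrez_id"])
        assert dropped | set(kept.records["entrez_id"]) == {101, 102, 105}
        assert dropped & set(kept.records["entrez_id"]) == set()


class TestSubnetwork:
    def test_planted_edge_found(self, ppi_store):
        assert ss.ppi_subnetwork({101, 102, 999}, ppi_store) == [(101, 102)]

    def test_single_gene_has_no_edges(self, ppi_store):
        assert ss.ppi_subnetwork({101}, ppi_store) == []

    def test_matches_brute_force_enumeration(self, rng):
        genes = list(range(1, 201))
        store = AnnotationStore()
        for _ in range(400):
            a, b = rng.choice(genes, 2, replace=False)
            store.add_edge(int(a), int(b))
        selection = set(rng.choice(genes, 80, replace=False).astype(int).tolist())
        got = ss.ppi_subnetwork(selection, store)
        assert got == brute_force_subnetwork(selection, store.ppi)

    def test_union_superset_property(self, rng):
        store = AnnotationStore()
        for _ in range(100):
            a, b = rng.integers(1, 60, 2)
            if a != b:
                store.add_edge(int(a), int(b))
        s1 = set(range(1, 25))
        s2 = set(range(20, 50))
        union_edges = set(ss.ppi_subnetwork(s1 | s2, store))
        assert union_edges >= set(ss.ppi_subnetwork(s1, store)) | set(
            ss.ppi_subnetwork(s2, store)
        )

    def test_connected_genes_flagging(self, ppi_store):
        edges = ss.ppi_subnetwork({101, 102, 104, 999}, ppi_store)
        assert connected_genes(edges) == {101, 102}


class TestNetworkExport:
    def test_sif_line_format(self, tmp_path):
        p = ss.export_network([(101, 102)], tmp_path / "n.sif", fmt="sif")
        assert p.read_text() == "101 pp 102\n"

    def test_empty_network_empty_file(self, tmp_path):
        p = ss.export_network([], tmp_path / "n.tsv")
        assert p.read_text() == ""
        assert ss.load_network(p) == []

    @pytest.mark.parametrize("fmt", ["tsv", "sif"])
    def test_round_trip(self, tmp_path, fmt):
        edges = [(1, 2), (2, 9), (4, 5)]
        p = ss.export_network(edges, tmp_path / f"n.{fmt}", fmt=fmt)
        assert ss.load_network(p) == sorted(edges)
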