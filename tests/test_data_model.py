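import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from spanet import synthetic
from spanet.data_model import (
    SENTINELS,
    induced_subgraph,
    interactome_from_edges,
    read_annotations,
    read_interactions,
    read_network,
    write_network,
)
from spanet.errors import EmptyInteractomeError, FormatError

from _oracles import edges_of, random_adjacency

BG_HEADER = (
    "Official Symbol Interactor A\tOfficial Symbol Interactor B\t"
    "Experimental System Type\n"
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadInteractions:
    def test_biogrid_dialect_filters_and_dedups(self, tmp_path):
        p = write(
            tmp_path,
            "bg.tsv",
            BG_HEADER + "A\tB\tphysical\nA\tA\tphysical\nA\tB\tgenetic\n",
        )
        g = read_interactions(p, physical_only=True)
        assert set(g.nodes) == {"A", "B"}
        assert g.number_of_edges() == 1

    def test_genetic_rows_kept_when_not_physical_only(self, tmp_path):
        p = write(
            tmp_path, "bg.tsv", BG_HEADER + "A\tB\tphysical\nA\tC\tgenetic\n"
        )
        g = read_interactions(p, physical_only=False)
        assert g.number_of_edges() == 2

    def test_two_column_edge_list(self, tmp_path):
        p = write(tmp_path, "e.tsv", "A\tB\nB\tC\nC\tD\nD\tA\n")
        g = read_interactions(p)
        assert g.number_of_edges() == 4

    def test_missing_column_named_in_error(self, tmp_path):
        p = write(
            tmp_path,
            "bad.tsv",
            "Official Symbol Interactor A\tOfficial Symbol Interactor B\nA\tB\n",
        )
        with pytest.raises(FormatError, match="Experimental System Type"):
            read_interactions(p)

    def test_empty_interactome_is_an_error(self, tmp_path):
        p = write(tmp_path, "bg.tsv", BG_HEADER + "A\tA\tphysical\n")
        with pytest.raises(EmptyInteractomeError):
            read_interactions(p)

    @settings(max_examples=25, deadline=None)
    @given(rnd=st.randoms(use_true_random=False))
    def test_idempotent_under_duplication_and_reorder(self, tmp_path_factory, rnd):
        # property: duplicated, shuffled rows load to the same graph
        tmp = tmp_path_factory.mktemp("dup")
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("A", "D"), ("B", "D")]
        rows = [f"{a}\t{b}" for a, b in edges] * 2
        rnd.shuffle(rows)
        p = write(tmp, "e.tsv", "\n".join(rows) + "\n")
        g = read_interactions(p)
        assert sorted(map(tuple, map(sorted, g.edges))) == sorted(
            map(tuple, map(sorted, edges))
        )


class TestRoundTrips:
    @pytest.mark.parametrize("fmt,name", [("tsv", "g.tsv"), ("graphml", "g.graphml")])
    def test_write_read_identity(self, tmp_path, fmt, name):
        g = synthetic.generate_interactome(100, 2, seed=5)
        path = tmp_path / name
        write_network(g, path, format=fmt)
        back = read_network(path)
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}

    def test_triangle_writes_three_rows(self, tmp_path):
        g = interactome_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        p = tmp_path / "t.tsv"
        write_network(g, p)
        rows = [ln for ln in p.read_text().splitlines() if not ln.startswith("#")]
        assert len(rows) == 3

    def test_empty_graph_refused(self, tmp_path):
        with pytest.raises(EmptyInteractomeError):
            write_network(nx.Graph(), tmp_path / "e.tsv")


class TestReadAnnotations:
    def test_three_column_aspects(self, tmp_path):
        p = write(tmp_path, "a.tsv", "X\tP\tGO:1\nX\tF\tGO:2\nX\tC\tGO:3\n")
        t = read_annotations(p)
        ann = t.get("X")
        assert ann.process == {"GO:1"}
        assert ann.function == {"GO:2"}
        assert ann.component == {"GO:3"}

    def test_sentinel_fill_for_missing_aspects(self, tmp_path):
        p = write(tmp_path, "a.tsv", "X\tP\tGO:1\n")
        ann = read_annotations(p).get("X")
        assert ann.function == {SENTINELS["function"]}
        assert ann.component == {SENTINELS["component"]}

    def test_unknown_aspect_code_rejected_with_row(self, tmp_path):
        p = write(tmp_path, "a.tsv", "X\tP\tGO:1\nY\tQ\tGO:2\n")
        with pytest.raises(FormatError, match="row 2"):
            read_annotations(p)

    def test_interactome_proteins_get_sentinel_records(self, tmp_path):
        p = write(tmp_path, "a.tsv", "A\tP\tGO:1\n")
        g = interactome_from_edges([("A", "B")])
        t = read_annotations(p, interactome=g)
        assert "B" in t
        assert t.get("B").process == {SENTINELS["process"]}

    def test_gaf_style_rows(self, tmp_path):
        fields = ["SGD", "S000001", "ABC1", "", "GO:0001", "PMID:1", "IDA", "",
                  "P", "desc", "", "protein", "taxon:4932", "20110101", "SGD"]
        p = write(tmp_path, "a.gaf", "!gaf-version: 2.0\n" + "\t".join(fields) + "\n")
        t = read_annotations(p)
        assert t.get("ABC1").process == {"GO:0001"}


class TestInducedSubgraph:
    def test_triangle_keep_two(self):
        g = interactome_from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        h = induced_subgraph(g, {"A", "B"})
        assert h.number_of_edges() == 1

    def test_keep_all_is_identity(self):
        g = synthetic.generate_interactome(30, 2, seed=0)
        h = induced_subgraph(g, set(g.nodes))
        assert nx.utils.graphs_equal(g, h)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_edge_filter(self, seed):
        adj = random_adjacency(50, 0.08, seed)
        g = interactome_from_edges(edges_of(adj), nodes=adj)
        import random as _r

        keep = set(_r.Random(seed).sample(sorted(adj), 20))
        h = induced_subgraph(g, keep)
        expected = {
            frozenset((a, b)) for a, b in edges_of(adj) if a in keep and b in keep
        }
        assert {frozenset(e) for e in h.edges} == expected
        assert set(h.nodes) == keep & set(adj)
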