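"""Node annotation, triad selection, cross-tabulation and exports."""

import networkx as nx
import pandas as pd
import pytest

from coexmir.integrate import (
    COLOR_KEYS,
    annotate_network,
    select_triad,
    summarize_mapping_by_network,
    write_graphml,
    write_node_attributes,
    write_sif,
)
from coexmir.network import CoexpressionNetwork


def _net(edges, condition):
    g = nx.Graph()
    g.add_edges_from(edges)
    return CoexpressionNetwork(condition, g, 1.0)


@pytest.fixture()
def networks():
    return {
        "null": _net([("g1", "g2"), ("g2", "g3")], "null"),
        "mir142": _net([("g4", "g5"), ("g5", "g6"), ("g4", "g6")], "mir142"),
    }


@pytest.fixture()
def de_calls():
    return pd.DataFrame(
        {
            "gene": ["g4", "g5", "g1"],
            "direction": ["down", "up", "down"],
            "log2fc": [-2.0, 1.5, -0.5],
        }
    )


class TestAnnotate:
    def test_every_node_annotated_with_defaults(self, networks, de_calls):
        annotated = annotate_network(networks, {"g4": "exact-5p"}, de_calls)
        assert sorted(annotated["gene"]) == ["g1", "g2", "g3", "g4", "g5", "g6"]
        g4 = annotated.set_index("gene").loc["g4"]
        assert (g4["color_key"], g4["shape_key"]) == ("dark-red", "down-arrow")
        g2 = annotated.set_index("gene").loc["g2"]
        assert (g2["seed_class"], g2["de_status"]) == ("none", "ns")
        assert (g2["color_key"], g2["shape_key"]) == ("plain", "ellipse")

    def test_exact_both_gets_combined_color(self, networks):
        annotated = annotate_network(networks, {"g1": "exact-both"})
        assert annotated.set_index("gene").loc["g1", "color_key"] == "dark-red+dark-green"

    def test_duplicate_de_records_rejected(self, networks, de_calls):
        doubled = pd.concat([de_calls, de_calls.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            annotate_network(networks, {}, doubled)

    def test_membership_columns(self, networks):
        annotated = annotate_network(networks, {}).set_index("gene")
        assert annotated.loc["g2", "in_null"] and not annotated.loc["g2", "in_mir142"]
        assert annotated.loc["g5", "in_mir142"] and not annotated.loc["g5", "in_null"]

    def test_annotation_matches_joined_manifests(self, small_study):
        """On synthetic data the annotation is the join of the ground truths."""
        from coexmir.network import coexpression_network
        from coexmir.seeds import classify_genes, scan_utrs

        matrix, records, truth = small_study
        nets = {c: coexpression_network(matrix, c) for c in ("null", "mir142")}
        classes = classify_genes(scan_utrs(records), genes=[g for g, _, _ in records])
        de = pd.DataFrame(
            [(g, d, -5.0 if d == "down" else 5.0) for g, d in truth.de.items()],
            columns=["gene", "direction", "log2fc"],
        )
        annotated = annotate_network(nets, classes, de).set_index("gene")
        expected_classes = truth.expected_classes()
        for gene, row in annotated.iterrows():
            assert row["seed_class"] == expected_classes.get(gene, "none")
            assert row["de_status"] == truth.de.get(gene, "ns")
            assert row["in_null"] == (gene in nets["null"].nodes)
            assert row["in_mir142"] == (gene in nets["mir142"].nodes)


class TestTriad:
    def test_equals_brute_force_triple_intersection(self, networks, de_calls):
        classes = {"g4": "exact-5p", "g5": "inexact-3p", "g1": "exact-3p"}
        annotated = annotate_network(networks, classes, de_calls)
        triad = select_triad(annotated, condition="mir142")
        brute = sorted(
            set(networks["mir142"].nodes)
            & {g for g, c in classes.items() if c != "none"}
            & set(de_calls.loc[de_calls["direction"] == "down", "gene"])
        )
        assert triad == brute == ["g4"]

    def test_failed_conjunct_excluded(self, networks, de_calls):
        # g5 is in the network with a seed site but is up-regulated
        annotated = annotate_network(networks, {"g5": "inexact-both"}, de_calls)
        assert select_triad(annotated, condition="mir142") == []

    def test_empty_network_gives_empty_list(self):
        annotated = annotate_network({"mir142": _net([], "mir142")}, {})
        assert select_triad(annotated, condition="mir142") == []

    def test_planted_triad_recovered_on_synthetic_data(self, small_study):
        from coexmir.network import coexpression_network
        from coexmir.seeds import classify_genes, scan_utrs

        matrix, records, truth = small_study
        nets = {c: coexpression_network(matrix, c) for c in ("null", "mir142")}
        classes = classify_genes(scan_utrs(records), genes=[g for g, _, _ in records])
        de = pd.DataFrame(
            [(g, d, -5.0 if d == "down" else 5.0) for g, d in truth.de.items()],
            columns=["gene", "direction", "log2fc"],
        )
        annotated = annotate_network(nets, classes, de)
        triad = select_triad(annotated, condition="mir142")
        planted_triad = sorted(
            set(nets["mir142"].nodes)
            & {g for g, c in truth.expected_classes().items() if c != "none"}
            & {g for g, d in truth.de.items() if d == "down"}
        )
        assert triad == planted_triad
        assert len(triad) >= 1  # generator plants mir142-clique + site + DE-down genes


class TestSummarize:
    def test_counts_match_manifest_cross_tabulation(self, networks):
        classes = {"g1": "exact-5p", "g2": "inexact-3p", "g4": "exact-5p", "g5": "inexact-both"}
        counts = summarize_mapping_by_network(annotate_network(networks, classes))
        assert counts.loc["exact-5p", "null"] == 1
        assert counts.loc["exact-5p", "mir142"] == 1
        assert counts.loc["inexact-3p", "null"] == 1
        assert counts.loc["inexact-both", "mir142"] == 1
        assert counts["null"].sum() + 1 == counts.attrs["n_nodes"]["null"]  # g3 unmapped
        assert counts.attrs["mapped_fraction"]["null"] == pytest.approx(2 / 3)

    def test_no_mapped_genes_gives_zero_rows(self, networks):
        counts = summarize_mapping_by_network(annotate_network(networks, {}))
        assert (counts.to_numpy() == 0).all()
        assert counts.attrs["mapped_fraction"]["mir142"] == 0.0


class TestExports:
    def test_sif_and_attribute_round_trip(self, tmp_path, networks, de_calls):
        annotated = annotate_network(networks, {"g4": "exact-5p"}, de_calls)
        sif = tmp_path / "net.sif"
        write_sif(networks["mir142"], sif)
        lines = sif.read_text().splitlines()
        assert lines == ["g4\tcoexp\tg5", "g4\tcoexp\tg6", "g5\tcoexp\tg6"]

        attrs = tmp_path / "nodes.tsv"
        write_node_attributes(annotated, attrs)
        frame = pd.read_csv(attrs, sep="\t")
        assert set(frame.columns) == {
            "gene", "seed_class", "color_key", "de_status", "shape_key", "log2fc"
        }
        assert set(frame["color_key"]) <= set(COLOR_KEYS.values())

    def test_graphml_preserves_attributes(self, tmp_path, networks, de_calls):
        annotated = annotate_network(networks, {"g4": "exact-5p"}, de_calls)
        path = tmp_path / "net.graphml"
        write_graphml(networks["mir142"], annotated, path)
        loaded = nx.read_graphml(path)
        assert loaded.nodes["g4"]["color_key"] == "dark-red"
        assert loaded.nodes["g4"]["de_status"] == "down"
        assert {tuple(sorted(e)) for e in loaded.edges} == {
            tuple(sorted(e)) for e in networks["mir142"].graph.edges
        }
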