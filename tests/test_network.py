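"""Similarity networks: reciprocity, weights, components, exports."""

import numpy as np
import pytest

from paravirome import synthetic as syn
from paravirome.network import (
    Thresholds,
    build_marker_network,
    build_phage_network,
    build_protein_identity_network,
    components_and_orphans,
    export_network,
    load_network,
    reciprocal_pairs,
)


def _proteomes(shared, identity=100.0, seed=5, n_background=3, length=180):
    return syn.generate_proteome_clusters(
        len(shared), np.array(shared), identity, seed=seed,
        n_background=n_background, protein_length=length,
    )


def test_planted_identical_homologs_all_pair_up():
    proteomes, _ = _proteomes([[0, 3], [3, 0]])
    pairs = reciprocal_pairs(proteomes["phage1"], proteomes["phage2"])
    assert len(pairs) == 3


def test_seventy_percent_identity_is_below_the_edge_threshold():
    proteomes, _ = _proteomes([[0, 1], [1, 0]], identity=70.0, seed=6)
    assert reciprocal_pairs(proteomes["phage1"], proteomes["phage2"]) == []


def test_asymmetric_coverage_excludes_fragment_hits():
    rng = np.random.default_rng(8)
    full = syn.random_protein(300, rng)
    fragment = full[100:160]  # perfect identity, 20% coverage on the full protein
    a = {"a|frag": fragment}
    b = {"b|full": full}
    assert reciprocal_pairs(a, b) == []


def test_phage_network_weights_match_planted_matrix():
    shared = [[0, 3, 0], [3, 0, 1], [0, 1, 0]]
    proteomes, _ = _proteomes(shared, identity=90.0, seed=7)
    g = build_phage_network(proteomes)
    assert set(g.edges) == {("phage1", "phage2"), ("phage2", "phage3")}
    assert g.edges["phage1", "phage2"]["weight"] == 3
    assert g.edges["phage2", "phage3"]["weight"] == 1


def test_unrelated_proteomes_give_edgeless_network_of_orphans():
    proteomes, _ = _proteomes([[0, 0], [0, 0]], seed=9)
    g = build_phage_network(proteomes)
    clusters, orphans = components_and_orphans(g)
    assert g.number_of_edges() == 0
    assert clusters == [] and orphans == ["phage1", "phage2"]


def test_duplicated_proteome_weight_equals_proteome_size():
    proteomes, _ = _proteomes([[0, 0], [0, 0]], seed=10, n_background=4)
    proteomes["copy"] = {
        pid.replace("phage1", "copy"): seq for pid, seq in proteomes["phage1"].items()
    }
    g = build_phage_network(proteomes)
    assert g.edges["copy", "phage1"]["weight"] == len(proteomes["phage1"])


def test_edge_weight_never_exceeds_smaller_proteome():
    proteomes, _ = _proteomes([[0, 2], [2, 0]], seed=11, n_background=1)
    g = build_phage_network(proteomes)
    for a, b, data in g.edges(data=True):
        assert data["weight"] <= min(len(proteomes[a]), len(proteomes[b]))


def test_network_is_invariant_under_input_order():
    shared = [[0, 2, 1], [2, 0, 0], [1, 0, 0]]
    proteomes, _ = _proteomes(shared, identity=95.0, seed=12)
    g1 = build_phage_network(proteomes)
    reordered = dict(reversed(list(proteomes.items())))
    g2 = build_phage_network(reordered)
    assert set(g1.edges) == set(g2.edges)
    for e in g1.edges:
        assert g1.edges[e]["weight"] == g2.edges[e]["weight"]


def test_marker_network_edges_and_missing_marker_flag():
    rng = np.random.default_rng(13)
    integrase = syn.random_protein(320, rng)
    markers = {
        "A": ("A|int", integrase),
        "B": ("B|int", integrase),
        "C": ("C|int", syn.random_protein(320, rng)),
        "D": None,
    }
    g = build_marker_network(markers)
    assert set(g.edges) == {("A", "B")}
    assert g.edges["A", "B"]["weight"] == 1
    assert g.nodes["D"]["missing_marker"] is True
    _, orphans = components_and_orphans(g)
    assert orphans == ["C", "D"]


def test_protein_identity_network_thresholds():
    rng = np.random.default_rng(14)
    base = syn.random_protein(250, rng)
    prots = {
        "m1": base,
        "m2": syn.mutate_to_identity(base, 85.0, 1),
        "m3": syn.mutate_to_identity(base, 70.0, 2),
        "m4": base,
    }
    g = build_protein_identity_network(prots)
    assert ("m1", "m2") in g.edges
    assert ("m1", "m4") in g.edges
    assert ("m1", "m3") not in g.edges


def test_relaxing_thresholds_never_removes_edges():
    proteomes, _ = _proteomes([[0, 2, 0], [2, 0, 1], [0, 1, 0]], identity=82.0, seed=15)
    strict = build_phage_network(proteomes, Thresholds())
    for relaxed in (
        Thresholds(evalue_max=1e-5),
        Thresholds(query_coverage_min=50.0),
        Thresholds(identity_min=60.0),
    ):
        g = build_phage_network(proteomes, relaxed)
        assert set(strict.edges) <= set(g.edges)


def test_exports_round_trip_and_preserve_types(tmp_path):
    proteomes, _ = _proteomes([[0, 2], [2, 0]], seed=16)
    g = build_phage_network(proteomes, node_attrs={"phage1": {"family": "Siphoviridae"}})
    for fmt in ("graphml", "gexf"):
        path = tmp_path / f"net.{fmt}"
        export_network(g, path, fmt)
        back = load_network(path, fmt)
        assert set(back.nodes) == set(g.nodes)
        assert set(back.edges) == set(g.edges)
        for e in g.edges:
            assert back.edges[e]["weight"] == g.edges[e]["weight"]
            assert isinstance(back.edges[e]["weight"], int)
        assert back.nodes["phage1"]["family"] == "Siphoviridae"
    tsv = tmp_path / "net.tsv"
    export_network(g, tsv, "tsv")
    rows = tsv.read_text().strip().splitlines()
    assert len(rows) - 1 == g.number_of_edges()
    with pytest.raises(ValueError, match="unknown export format"):
        export_network(g, tmp_path / "x", "dot")
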