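"""Circuit graph: construction, chain/motif enumeration, adjacency, export."""

import itertools

import numpy as np
import pytest

from iplconnect import (
    CircuitGraph,
    MotifClass,
    VolumeMeta,
    adjacency_census,
    alternating_chain_census,
    build_graph,
    classify_motifs,
    export_graph,
    find_chains,
    import_graphml,
    motif_catalog,
)

from conftest import ModelBuilder


# -- independent brute-force oracle ---------------------------------------


def _directed_adjacency(g: CircuitGraph):
    succ, pred = {}, {}
    for u, v, k, d in g.edges(keys=True, data=True):
        if d["directed"]:
            succ.setdefault(u, set()).add(v)
            pred.setdefault(v, set()).add(u)
    return succ, pred


def brute_force_maximal_paths(g: CircuitGraph, interior_ok=None, max_depth=12):
    """Exhaustively enumerate every simple directed node-path, then keep the
    maximal ones by direct application of the definition."""
    interior_ok = interior_ok or (lambda n: True)
    succ, pred = _directed_adjacency(g)
    all_paths = []

    def grow(path):
        if len(path) >= 2:
            all_paths.append(tuple(path))
        if len(path) - 1 >= max_depth:
            return
        if len(path) >= 2 and not interior_ok(path[-1]):
            return
        for w in succ.get(path[-1], ()):
            if w not in path:
                grow(path + [w])

    for start in g.nodes:
        grow([start])

    def tail_extendable(p):
        return (interior_ok(p[-1]) and any(w not in p for w in succ.get(p[-1], ()))
                and len(p) - 1 < max_depth)

    def head_extendable(p):
        return interior_ok(p[0]) and any(w not in p for w in pred.get(p[0], ()))

    out = set()
    for p in all_paths:
        if len(p) - 1 == max_depth:
            out.add(p)
        elif not tail_extendable(p) and not head_extendable(p):
            out.add(p)
    return out


def random_circuit(seed: int, n_max: int = 12) -> CircuitGraph:
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, n_max + 1))
    classes = ["GABA_AC", "GLY_AC", "ON_CBC", "GC"]
    g = CircuitGraph()
    for i in range(n):
        g.add_node(i, cell_class=classes[int(rng.integers(len(classes)))])
    n_edges = int(rng.integers(1, 2 * n))
    for _ in range(n_edges):
        u, v = int(rng.integers(n)), int(rng.integers(n))
        if u == v:
            continue
        if rng.random() < 0.15:  # some undirected contacts to be excluded
            g.add_edge(min(u, v), max(u, v), contact_type="gap_junction",
                       directed=False, channel="")
        else:
            g.add_edge(u, v, contact_type="conventional_synapse",
                       directed=True, channel="")
    return g


class TestBuildGraph:
    def test_single_synapse(self, builder):
        a = builder.cell("A")
        b = builder.cell("B")
        builder.contact(a, b)
        g = build_graph(builder.build())
        assert g.number_of_edges() == 1
        ((u, v, d),) = g.edges(data=True)
        assert (u, v, d["directed"]) == (a, b, True)

    def test_local_network(self, local_network_model):
        model, ids = local_network_model
        g = build_graph(model)
        directed = g.directed_edges()
        undirected = g.undirected_edges()
        assert len(directed) == 2 and len(undirected) == 1
        assert {(u, v) for u, v, k, d in directed} == {
            (ids["rod"], ids["aii"]),
            (ids["aii"], ids["off"]),
        }

    def test_edge_count_matches_links(self, generated):
        model, _ = generated
        g = build_graph(model)
        assert g.number_of_edges() == len(model.structure_links)


class TestFindChains:
    def test_single_edge(self, builder):
        a = builder.cell("A")
        b = builder.cell("B")
        builder.contact(a, b)
        chains, mx = find_chains(build_graph(builder.build()))
        assert mx == 1 and len(chains) == 1 and chains[0].cells == (a, b)

    def test_six_stage_fixture(self, six_stage_chain_model):
        model, ids = six_stage_chain_model
        chains, mx = find_chains(build_graph(model))
        assert mx == 6
        longest = [c for c in chains if c.stages == 6]
        expect = {
            (ids["bc1"], ids[a], ids["c6011"], ids["aii"], ids["c174"], ids["bc2"], ids["gc"])
            for a in ("ac_a", "ac_b")
        }
        assert {c.cells for c in longest} == expect

    def test_stage_count_invariant(self, six_stage_chain_model):
        model, _ = six_stage_chain_model
        chains, _ = find_chains(build_graph(model))
        for c in chains:
            assert c.stages == len(c.edges) == len(c.cells) - 1

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force(self, seed):
        g = random_circuit(seed)
        chains, _ = find_chains(g, max_depth=8)
        assert {c.cells for c in chains} == brute_force_maximal_paths(g, max_depth=8)

    def test_interior_filter(self):
        g = CircuitGraph()
        for i, cls in enumerate(["ON_CBC", "GABA_AC", "GC", "ON_CBC"]):
            g.add_node(i, cell_class=cls)
        for u, v in [(0, 1), (1, 2), (2, 3)]:
            g.add_edge(u, v, contact_type="conventional_synapse", directed=True, channel="")
        from iplconnect import amacrine_interior

        chains, mx = find_chains(g, node_filter=amacrine_interior)
        # the ganglion cell cannot be an interior node, so the chain stops there
        assert mx == 2
        assert (0, 1, 2) in {c.cells for c in chains}


class TestAlternatingChains:
    def test_fixture_three_alternations(self, builder):
        """A glycinergic OFF amacrine cell drives a GABAergic AI cell, which
        drives a glycinergic AII cell, which drives a GABA+ amacrine cell:
        three GABA/glycine alternations."""
        g_off = builder.cell("GLY_AC")
        ai = builder.cell("AI_AC")
        aii = builder.cell("AII_AC")
        gac = builder.cell("GABA_AC")
        builder.contact(g_off, ai)
        builder.contact(ai, aii)
        builder.contact(aii, gac)
        g = build_graph(builder.build())
        labels = {g_off: "glycine+", ai: "GABA+", aii: "glycine+", gac: "GABA+"}
        by_len = alternating_chain_census(g, labels)
        assert max(by_len) == 3
        assert by_len[3][0].cells == (g_off, ai, aii, gac)

    def test_all_gaba_has_no_alternations(self, builder):
        cells = [builder.cell("GABA_AC") for _ in range(4)]
        for a, b in zip(cells, cells[1:]):
            builder.contact(a, b)
        g = build_graph(builder.build())
        by_len = alternating_chain_census(g, {c: "GABA+" for c in cells})
        assert by_len == {}

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(10_000 + seed)
        g = random_circuit(10_000 + seed)
        labels = {
            n: ["GABA+", "glycine+", "other"][int(rng.integers(3))] for n in g.nodes
        }
        by_len = alternating_chain_census(g, labels, max_depth=8)
        got = {c.cells for chains in by_len.values() for c in chains}

        # oracle: restrict to the alternating sub-digraph, then reuse the
        # exhaustive maximal-path enumeration
        h = CircuitGraph()
        ok = {n for n in g.nodes if labels[n] in ("GABA+", "glycine+")}
        for n in ok:
            h.add_node(n, cell_class="")
        for u, v, k, d in g.edges(keys=True, data=True):
            if d["directed"] and u in ok and v in ok and labels[u] != labels[v]:
                h.add_edge(u, v, contact_type=d["contact_type"], directed=True, channel="")
        assert got == brute_force_maximal_paths(h, max_depth=8)


class TestClassifyMotifs:
    def test_reentrant(self, builder):
        a = builder.cell("STARBURST_AC")
        b = builder.cell("STARBURST_AC")
        builder.contact(a, b)
        motifs = classify_motifs(build_graph(builder.build()))
        assert {m.kind for m in motifs} == {"reentrant"}
        (m,) = motifs
        assert m.classes_involved == ("STARBURST_AC",)

    def test_empty_graph(self):
        assert classify_motifs(CircuitGraph()) == set()

    def test_reciprocal_and_loop(self, builder):
        a = builder.cell("A")
        b = builder.cell("B")
        c = builder.cell("C")
        builder.contact(a, b)
        builder.contact(b, a)
        builder.contact(b, c)
        builder.contact(c, a)
        motifs = classify_motifs(build_graph(builder.build()))
        kinds = {m.kind for m in motifs}
        assert "reciprocal" in kinds
        loops = [m for m in motifs if m.kind == "looping"]
        assert any(set(m.classes_involved) == {"A", "B", "C"} for m in loops)

    def test_planted_loop_recovered(self, generated_graph):
        """The generated wiring contains the AII -> GABA+ amacrine ->
        bipolar-axon veto -> AII class loop."""
        g, _ = generated_graph
        motifs = classify_motifs(g)
        loops = {frozenset(m.classes_involved) for m in motifs if m.kind == "looping"}
        assert any({"AII_AC", "GABA_AC", "OFF_CBC"} <= s for s in loops) or \
            frozenset({"AII_AC", "GABA_AC", "OFF_CBC"}) in loops

    def test_relabeling_invariance(self):
        g1 = random_circuit(7)
        mapping = {n: n + 100 for n in g1.nodes}
        g2 = CircuitGraph()
        for n, d in g1.nodes(data=True):
            g2.add_node(mapping[n], **d)
        for u, v, k, d in g1.edges(keys=True, data=True):
            g2.add_edge(mapping[u], mapping[v], **d)
        m1 = {(m.kind, m.classes_involved) for m in classify_motifs(g1)}
        m2 = {(m.kind, m.classes_involved) for m in classify_motifs(g2)}
        assert m1 == m2

    def test_motifclass_invariants(self):
        with pytest.raises(ValueError):
            MotifClass("reentrant", ("A", "B"))
        with pytest.raises(ValueError):
            MotifClass("looping", ("A", "B"))


class TestMotifCatalog:
    def test_seventeen_motifs_twelve_classes(self, aii_catalog_model):
        model, aii = aii_catalog_model
        n_motifs, n_classes, _ = motif_catalog(build_graph(model), aii)
        assert (n_motifs, n_classes) == (17, 12)

    def test_channel_split_off_collapses_corelease(self, aii_catalog_model):
        model, aii = aii_catalog_model
        n_motifs, n_classes, _ = motif_catalog(build_graph(model), aii, channel_split=False)
        assert (n_motifs, n_classes) == (15, 12)

    def test_isolated_cell(self, builder):
        c = builder.cell("AII_AC")
        n_motifs, n_classes, motifs = motif_catalog(build_graph(builder.build()), c)
        assert (n_motifs, n_classes, motifs) == (0, 0, set())

    def test_generated_catalog_matches_truth(self, generated_graph):
        g, truth = generated_graph
        _, _, motifs = motif_catalog(g, truth.focal_cell)
        assert motifs == truth.catalog


class TestAdjacencyCensus:
    def _pair_model(self, dx_px: float, n_slices: int, linked: bool):
        b = ModelBuilder(VolumeMeta(pixel_size_nm=1.0, slice_count=50))
        a = b.cell("GC")
        c = b.cell("MULLER")
        for z in range(n_slices):
            b.location(a, z, 0, 0, r=10)
            b.location(c, z, dx_px, 0, r=10)
        if linked:
            b.contact(a, c)
        return b.build(), (a, c)

    def test_synaptic_pair(self):
        model, (a, c) = self._pair_model(20, 5, linked=True)
        pairs = adjacency_census(model, epsilon_nm=0, min_slices=3)
        assert pairs == {(a, c): "synaptic"}

    def test_fictive_pair_spanning_many_slices(self):
        model, (a, c) = self._pair_model(20, 11, linked=False)
        pairs = adjacency_census(model, epsilon_nm=0, min_slices=3)
        assert pairs == {(a, c): "fictive_adjacency"}

    def test_distant_cells_not_reported(self):
        model, _ = self._pair_model(100, 11, linked=False)
        assert adjacency_census(model, epsilon_nm=30, min_slices=1) == {}

    def test_epsilon_monotonicity(self, generated):
        model, _ = generated
        small = set(adjacency_census(model, epsilon_nm=0, min_slices=1))
        large = set(adjacency_census(model, epsilon_nm=50, min_slices=1))
        assert small <= large

    def test_min_slices_gates_short_runs(self):
        model, _ = self._pair_model(20, 2, linked=False)
        assert adjacency_census(model, epsilon_nm=0, min_slices=3) == {}
        assert len(adjacency_census(model, epsilon_nm=0, min_slices=1)) == 1


class TestExport:
    def test_graphml_round_trip(self, generated_graph, tmp_path):
        g, _ = generated_graph
        path = export_graph(g, tmp_path / "g.graphml")
        h = import_graphml(path)
        as_multiset = lambda gr: sorted(
            (u, v, d["contact_type"], d["directed"], d["channel"])
            for u, v, k, d in gr.edges(keys=True, data=True)
        )
        assert sorted(g.nodes) == sorted(h.nodes)
        assert as_multiset(g) == as_multiset(h)

    def test_empty_graph(self, tmp_path):
        g = CircuitGraph()
        h = import_graphml(export_graph(g, tmp_path / "e.graphml"))
        assert h.number_of_nodes() == 0

    def test_dot_node_count(self, six_stage_chain_model, tmp_path):
        model, _ = six_stage_chain_model
        g = build_graph(model)
        text = export_graph(g, tmp_path / "g.dot").read_text()
        assert text.count("label=") - g.number_of_edges() == 8  # 8 node lines

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError):
            export_graph(CircuitGraph(), tmp_path / "g.xyz", fmt="xyz")
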