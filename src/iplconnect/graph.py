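"""Cell-level connectome multigraph and chain / motif / adjacency analyses.

The graph has one node per cell and one edge per structure link, resolved to
the parent cells of the two child structures.  Chemical synapses, ribbon
synapses and cistern contacts are directed (pre -> post); gap junctions and
membrane appositions are undirected and stored once under a canonical node
order with ``directed=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np

from .model import (
    AnnotationModel,
    DIRECTED_CONTACT_TYPES,
    UNDIRECTED_CONTACT_TYPES,
    ValidationError,
)

__all__ = [
    "CircuitGraph",
    "Chain",
    "MotifClass",
    "build_graph",
    "find_chains",
    "classify_motifs",
    "alternating_chain_census",
    "motif_catalog",
    "adjacency_census",
    "export_graph",
    "import_graphml",
    "amacrine_interior",
    "AMACRINE_CLASSES",
]

#: Cell-class labels treated as amacrine for interior-node filters.
AMACRINE_CLASSES = frozenset(
    {
        "AII_AC",
        "AI_AC",
        "GABA_AC",
        "GLY_AC",
        "PEPTIDE_AC",
        "GABA_PEPTIDE_AC",
        "ON_GABA_AC",
        "OFF_GABA_AC",
        "STARBURST_AC",
    }
)


@dataclass(frozen=True)
class Chain:
    """A simple directed synaptic path.  ``stages`` counts synaptic edges."""

    cells: tuple[int, ...]
    edges: tuple[tuple, ...]  # edge keys (u, v, k)

    @property
    def stages(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class MotifClass:
    """A class-level wiring motif.

    ``kind`` is one of ``reentrant`` (within-class signaling, A_j -> A_j),
    ``reciprocal`` (two classes targeting each other), ``looping`` (a
    directed cycle over >= 3 distinct classes) or ``simple_chain`` (a
    repeat-free directed path of distinct classes).  ``witness_edges``
    retains cell-level edge keys realizing the motif.
    """

    kind: str
    classes_involved: tuple[str, ...]
    witness_edges: tuple[tuple, ...] = ()

    def __post_init__(self):
        n = len(self.classes_involved)
        if self.kind == "reentrant" and n != 1:
            raise ValueError("reentrant motif involves exactly one class")
        if self.kind == "reciprocal" and n != 2:
            raise ValueError("reciprocal motif involves exactly two classes")
        if self.kind == "looping" and n < 3:
            raise ValueError("looping motif needs >= 3 classes")


class CircuitGraph(nx.MultiDiGraph):
    """Connectome multigraph; nodes are cells, edges are typed contacts.

    Undirected contacts are stored once, from ``min(u, v)`` to ``max(u, v)``,
    with edge attribute ``directed=False``.
    """

    def directed_edges(self):
        return [
            (u, v, k, d)
            for u, v, k, d in self.edges(keys=True, data=True)
            if d["directed"]
        ]

    def undirected_edges(self):
        return [
            (u, v, k, d)
            for u, v, k, d in self.edges(keys=True, data=True)
            if not d["directed"]
        ]

    def synaptic_successors(self, u) -> dict:
        """Map successor -> sorted directed edge keys from ``u``."""
        out: dict = {}
        for _, v, k, d in self.out_edges(u, keys=True, data=True):
            if d["directed"]:
                out.setdefault(v, []).append((u, v, k))
        return {v: sorted(ks) for v, ks in out.items()}

    def synaptic_predecessors(self, v) -> dict:
        out: dict = {}
        for u, _, k, d in self.in_edges(v, keys=True, data=True):
            if d["directed"]:
                out.setdefault(u, []).append((u, v, k))
        return {u: sorted(ks) for u, ks in out.items()}


def build_graph(model: AnnotationModel) -> CircuitGraph:
    """Resolve structure links to parent cells, one edge per link."""
    g = CircuitGraph()
    for cell in model.cells():
        g.add_node(cell.id, cell_class=cell.cell_class)
    for i, link in enumerate(model.structure_links):
        src_child = model.structures.get(link.source)
        tgt_child = model.structures.get(link.target)
        if src_child is None or tgt_child is None:
            raise ValidationError("link endpoint missing", [(link.source, link.target)])
        u = model.parent_cell(link.source).id
        v = model.parent_cell(link.target).id
        ct = src_child.contact_type
        directed = ct in DIRECTED_CONTACT_TYPES
        if not directed:
            u, v = min(u, v), max(u, v)
        g.add_edge(
            u,
            v,
            key=i,
            contact_type=ct,
            directed=directed,
            channel=link.channel,
            source_child=link.source,
            target_child=link.target,
            compartment=tgt_child.compartment,
        )
    return g


# -- chain enumeration ----------------------------------------------------


def _maximal_simple_paths(
    succ: Mapping, pred: Mapping, nodes: Iterable, interior_ok: Callable, max_depth: int
):
    """All maximal simple directed node-paths with filtered interior nodes.

    ``succ``/``pred`` map node -> iterable of neighbors.  A path is reported
    when it cannot be extended at either end (extension would repeat a node,
    or would turn an endpoint that fails ``interior_ok`` into an interior
    node) or when it has reached ``max_depth`` edges.
    """
    paths = set()

    def extendable_at_head(path, seen):
        # prepending w -> path makes the old head interior
        head = path[0]
        if not interior_ok(head):
            return False
        return any(w not in seen for w in pred.get(head, ()))

    def dfs(path, seen):
        if len(path) - 1 >= max_depth:
            paths.add(tuple(path))
            return
        tail = path[-1]
        extended = False
        if interior_ok(tail):  # appending makes the old tail interior
            for w in sorted(succ.get(tail, ())):
                if w in seen:
                    continue
                seen.add(w)
                path.append(w)
                dfs(path, seen)
                path.pop()
                seen.remove(w)
                extended = True
        if not extended and not extendable_at_head(path, seen):
            paths.add(tuple(path))

    for start in sorted(nodes):
        for w in sorted(succ.get(start, ())):
            dfs([start, w], {start, w})
    return sorted(paths)


def find_chains(
    g: CircuitGraph,
    node_filter: Callable[[int, dict], bool] | None = None,
    max_depth: int = 12,
) -> tuple[list[Chain], int]:
    """Enumerate maximal simple synaptic chains.

    A chain is a simple directed path over synaptic (directed) edges whose
    *interior* nodes satisfy ``node_filter``; endpoints are unconstrained.
    Chains are maximal: no synaptic edge extends them at either end without
    repeating a cell or violating the interior filter — except that search
    is truncated at ``max_depth`` edges.  Parallel synapses between the same
    cell pair are collapsed to one hop; the lexicographically smallest edge
    key is recorded as witness.

    Returns the chains in deterministic (lexicographic) order plus the
    maximum stage count (0 for a graph with no synaptic edge).
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if node_filter is None:
        interior_ok = lambda n: True
    else:
        interior_ok = lambda n: node_filter(n, g.nodes[n])
    succ = {u: g.synaptic_successors(u) for u in g.nodes}
    pred = {v: g.synaptic_predecessors(v) for v in g.nodes}
    node_paths = _maximal_simple_paths(
        {u: list(m) for u, m in succ.items()},
        {v: list(m) for v, m in pred.items()},
        g.nodes,
        interior_ok,
        max_depth,
    )
    chains = []
    for path in node_paths:
        edges = tuple(succ[u][v][0] for u, v in zip(path, path[1:]))
        chains.append(Chain(cells=path, edges=edges))
    max_stages = max((c.stages for c in chains), default=0)
    return chains, max_stages


def amacrine_interior(node: int, data: dict) -> bool:
    """Interior-node filter restricting chains to amacrine cells."""
    return data.get("cell_class") in AMACRINE_CLASSES


def alternating_chain_census(
    g: CircuitGraph, label_map: Mapping[int, str], max_depth: int = 12
) -> dict[int, list[Chain]]:
    """Maximal simple synaptic paths alternating GABA+ / glycine+ cells.

    ``label_map`` assigns each cell one of ``"GABA+"``, ``"glycine+"`` or
    ``"other"``.  Paths run over GABA+/glycine+ cells only and consecutive
    cells carry different labels.  Returns chains grouped by length
    (number of alternations = synaptic edges); single cells do not count.
    """
    labeled = {n for n in g.nodes if label_map.get(n) in ("GABA+", "glycine+")}
    succ = {}
    pred = {}
    for u in labeled:
        succ[u] = [
            v for v in g.synaptic_successors(u) if v in labeled and label_map[v] != label_map[u]
        ]
    for v in labeled:
        pred[v] = [
            u for u in g.synaptic_predecessors(v) if u in labeled and label_map[u] != label_map[v]
        ]
    node_paths = _maximal_simple_paths(succ, pred, labeled, lambda n: True, max_depth)
    by_len: dict[int, list[Chain]] = {}
    all_succ = {u: g.synaptic_successors(u) for u in g.nodes}
    for path in node_paths:
        edges = tuple(all_succ[u][v][0] for u, v in zip(path, path[1:]))
        by_len.setdefault(len(edges), []).append(Chain(cells=path, edges=edges))
    return by_len


# -- class-level motifs ---------------------------------------------------


def classify_motifs(g: CircuitGraph) -> set[MotifClass]:
    """Detect class-level synaptic motifs.

    Motifs are read off the class-level digraph obtained by mapping every
    directed synaptic edge to (class(source) -> class(target)):

    * ``reentrant`` — an edge within one class (A_j -> A_j);
    * ``reciprocal`` — edges both ways between two distinct classes;
    * ``looping`` — a directed cycle over >= 3 distinct classes;
    * ``simple_chain`` — a maximal repeat-free directed class path that
      extends none of the above.

    Cell-level witness edges are attached to each motif.
    """
    class_edges: dict[tuple[str, str], list] = {}
    for u, v, k, d in g.directed_edges():
        cu = g.nodes[u]["cell_class"]
        cv = g.nodes[v]["cell_class"]
        class_edges.setdefault((cu, cv), []).append((u, v, k))

    cg = nx.DiGraph()
    for (cu, cv) in class_edges:
        cg.add_edge(cu, cv)

    motifs: set[MotifClass] = set()
    for cu, cv in cg.edges:
        if cu == cv:
            motifs.add(
                MotifClass("reentrant", (cu,), tuple(sorted(class_edges[(cu, cv)])))
            )
        elif cg.has_edge(cv, cu) and cu < cv:
            wit = sorted(class_edges[(cu, cv)]) + sorted(class_edges[(cv, cu)])
            motifs.add(MotifClass("reciprocal", (cu, cv), tuple(wit)))

    simple = nx.DiGraph((e for e in cg.edges if e[0] != e[1]))
    for cycle in nx.simple_cycles(simple):
        if len(cycle) < 3:
            continue
        # canonical rotation: start at smallest class
        i = cycle.index(min(cycle))
        cyc = tuple(cycle[i:] + cycle[:i])
        wit = []
        for a, b in zip(cyc, cyc[1:] + (cyc[0],)):
            wit.extend(sorted(class_edges[(a, b)]))
        motifs.add(MotifClass("looping", cyc, tuple(wit)))

    # simple chains: maximal repeat-free directed class paths
    succ = {u: sorted(v for v in simple.successors(u)) for u in simple.nodes}
    pred = {v: sorted(u for u in simple.predecessors(v)) for v in simple.nodes}
    for path in _maximal_simple_paths(succ, pred, simple.nodes, lambda n: True, 32):
        wit = []
        for a, b in zip(path, path[1:]):
            wit.extend(sorted(class_edges[(a, b)]))
        motifs.add(MotifClass("simple_chain", tuple(path), tuple(wit)))
    return motifs


def motif_catalog(
    g: CircuitGraph, focal_cell: int, channel_split: bool = True
) -> tuple[int, int, set[tuple[str, str, str]]]:
    """Census of distinct input/output motifs around one cell.

    Each motif is a triple (partner cell class, contact label, direction),
    where direction is ``in``, ``out`` or ``coupled`` (gap junction /
    adjacency) and the contact label is the contact type plus, when
    ``channel_split`` is on, the transmitter channel — so dopamine and
    glutamate input from the same axonal-cell class count as two motifs.

    Returns ``(motif_count, partner_class_count, motifs)``; the focal class
    itself counts as a partner class when self-coupled.
    """
    if focal_cell not in g.nodes:
        raise KeyError(focal_cell)
    motifs: set[tuple[str, str, str]] = set()
    for u, v, k, d in g.edges(keys=True, data=True):
        if focal_cell not in (u, v):
            continue
        partner = v if u == focal_cell else u
        if partner == focal_cell and u != v:
            continue
        label = d["contact_type"]
        if channel_split and d.get("channel"):
            label = f"{label}:{d['channel']}"
        if not d["directed"]:
            direction = "coupled"
        else:
            direction = "out" if u == focal_cell else "in"
        motifs.add((g.nodes[partner]["cell_class"], label, direction))
    classes = {m[0] for m in motifs}
    return len(motifs), len(classes), motifs


# -- fictive adjacency ----------------------------------------------------


def adjacency_census(
    model: AnnotationModel,
    epsilon_nm: float = 30.0,
    min_slices: int = 3,
) -> dict[tuple[int, int], str]:
    """Find apposed cell pairs and split them into synaptic vs fictive.

    Two cells are apposed on a slice when any circle of one comes within
    ``epsilon_nm`` of touching a circle of the other (centre distance <=
    r_a + r_b + epsilon, physical units).  A pair is reported when apposed
    on at least ``min_slices`` consecutive slices; volume-level skipped
    slices do not break a run.  A reported pair is ``"fictive_adjacency"``
    iff no structure link of any contact type joins the two cells,
    otherwise ``"synaptic"``.
    """
    if epsilon_nm < 0:
        raise ValueError("epsilon_nm must be >= 0")
    if min_slices < 1:
        raise ValueError("min_slices must be >= 1")
    px = model.meta.pixel_size_nm

    owner = {}
    for l in model.locations.values():
        owner[l.id] = model.parent_cell(l.structure_id).id

    by_slice: dict[int, list] = {}
    for l in model.locations.values():
        by_slice.setdefault(l.z, []).append(l)

    apposed: dict[tuple[int, int], set[int]] = {}
    for z, locs in by_slice.items():
        pts = np.array([(l.center_x, l.center_y) for l in locs]) * px
        rad = np.array([l.radius for l in locs]) * px
        own = np.array([owner[l.id] for l in locs])
        n = len(locs)
        if n < 2:
            continue
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        thresh = rad[:, None] + rad[None, :] + epsilon_nm
        ii, jj = np.nonzero(dist <= thresh)
        for i, j in zip(ii, jj):
            if i >= j or own[i] == own[j]:
                continue
            pair = (min(own[i], own[j]), max(own[i], own[j]))
            apposed.setdefault(pair, set()).add(z)

    linked: set[tuple[int, int]] = set()
    for link in model.structure_links:
        a = model.parent_cell(link.source).id
        b = model.parent_cell(link.target).id
        linked.add((min(a, b), max(a, b)))

    skipped = model.meta.skipped_slices
    out: dict[tuple[int, int], str] = {}
    for pair, zs in apposed.items():
        if _longest_run(sorted(zs), skipped) < min_slices:
            continue
        out[pair] = "synaptic" if pair in linked else "fictive_adjacency"
    return out


def _longest_run(zs: list[int], skipped: frozenset[int]) -> int:
    """Longest run of consecutive slices, bridging volume-skipped slices."""
    best = run = 1
    for prev, cur in zip(zs, zs[1:]):
        gap = range(prev + 1, cur)
        if all(z in skipped for z in gap):
            run += 1
        else:
            run = 1
        best = max(best, run)
    return best if zs else 0


# -- export ---------------------------------------------------------------


def export_graph(g: CircuitGraph, path: str | Path, fmt: str | None = None) -> Path:
    """Write the graph as GraphML (round-trippable) or DOT (for display)."""
    path = Path(path)
    if fmt is None:
        fmt = "dot" if path.suffix == ".dot" else "graphml"
    fmt = fmt.lower()
    if fmt == "graphml":
        h = nx.MultiDiGraph()
        for n, d in g.nodes(data=True):
            h.add_node(n, cell_class=d.get("cell_class", ""))
        for u, v, k, d in g.edges(keys=True, data=True):
            h.add_edge(
                u,
                v,
                key=k,
                contact_type=d["contact_type"],
                directed=d["directed"],
                channel=d.get("channel", ""),
            )
        nx.write_graphml(h, path)
    elif fmt == "dot":
        lines = ["digraph connectome {"]
        for n, d in sorted(g.nodes(data=True)):
            lines.append(f'  n{n} [label="{n}\\n{d.get("cell_class", "")}"];')
        for u, v, k, d in sorted(g.edges(keys=True, data=True)):
            style = "" if d["directed"] else " dir=none style=dashed"
            lines.append(f'  n{u} -> n{v} [label="{d["contact_type"]}"{style}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def import_graphml(path: str | Path) -> CircuitGraph:
    """Read a GraphML file written by :func:`export_graph`."""
    h = nx.read_graphml(Path(path), node_type=int, force_multigraph=True)
    g = CircuitGraph()
    for n, d in h.nodes(data=True):
        g.add_node(n, cell_class=d.get("cell_class", ""))
    for u, v, k, d in h.edges(keys=True, data=True):
        g.add_edge(
            u,
            v,
            contact_type=d["contact_type"],
            directed=bool(d["directed"]) if not isinstance(d["directed"], str) else d["directed"] == "True",
            channel=d.get("channel", ""),
        )
    return g
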