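"""Minimum-spanning networks over haplotypes.

A minimum-spanning network (MSN) is the union of all minimum spanning trees
of the complete haplotype graph weighted by substitution distances,
optionally relaxed by an integer ``epsilon``: edges up to ``epsilon`` steps
longer than the current distance class are also admitted.  Unlike a single
MST, the MSN retains every alternative minimum connection, which is the
conventional way to display reticulate relationships among mtDNA
haplotypes.

Construction is Kruskal-style by distance class.  At the opening of each
class the connected components are snapshotted; every class edge joining
two distinct *snapshot* components is admitted, so the result does not
depend on within-class edge order.  An admitted class edge is marked
``in_all_msts`` when it is a bridge of the class's component multigraph,
i.e. when no alternative same-class connection exists between its two
snapshot components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .haplotyping import HaplotypeRecord, hamming_distance


class NetworkError(ValueError):
    """Invalid input to network construction (duplicate sequences, etc.)."""


@dataclass
class HaploNetwork:
    """A haplotype network: a connected weighted graph with MST annotations."""

    graph: nx.Graph
    epsilon: int = 0

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


class _DisjointSet:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def snapshot(self) -> dict[str, str]:
        return {x: self.find(x) for x in self.parent}


def _multigraph_bridges(
    edges: Sequence[tuple[str, str, tuple[str, str]]]
) -> set[tuple[str, str]]:
    """Bridges of a multigraph given as (component_u, component_v, edge_id).

    An edge is a bridge iff removing it disconnects its endpoints; parallel
    edges between the same component pair are never bridges.
    """
    bridges: set[tuple[str, str]] = set()
    g = nx.MultiGraph()
    for u, v, key in edges:
        g.add_edge(u, v, key=key)
    for u, v, key in edges:
        g.remove_edge(u, v, key=key)
        if not nx.has_path(g, u, v):
            bridges.add(key)
        g.add_edge(u, v, key=key)
    return bridges


def build_msn(
    haplotypes: Sequence[HaplotypeRecord],
    epsilon: int = 0,
    *,
    counts: Optional[Mapping[str, int]] = None,
    group_counts: Optional[Mapping[str, Mapping[str, int]]] = None,
) -> HaploNetwork:
    """Build the minimum-spanning network over a set of haplotypes.

    Parameters
    ----------
    haplotypes
        Haplotype records with pairwise-distinct window sequences.
    epsilon
        Relaxation: within each distance class, edges up to
        ``class minimum + epsilon`` joining distinct snapshot components are
        also admitted (marked ``in_all_msts=False``).
    counts, group_counts
        Optional total and per-group observation counts stored as node
        attributes, so that frequency-scaled, region-coloured renderings can
        be derived from the export.
    """
    if not haplotypes:
        raise NetworkError("need at least one haplotype")
    if epsilon < 0:
        raise NetworkError("epsilon must be >= 0")
    names = [h.name for h in haplotypes]
    if len(set(names)) != len(names):
        raise NetworkError("duplicate haplotype names")

    graph = nx.Graph()
    for h in haplotypes:
        attrs = {
            "haplogroup": h.haplogroup,
            "subhaplogroup": h.subhaplogroup or "",
            "count": int(counts.get(h.name, 0)) if counts else 0,
        }
        if group_counts:
            for group, table in group_counts.items():
                attrs[f"count_{group}"] = int(table.get(h.name, 0))
        graph.add_node(h.name, **attrs)

    all_edges: list[tuple[int, str, str]] = []
    for i, a in enumerate(haplotypes):
        for b in haplotypes[i + 1 :]:
            d = hamming_distance(a.window_seq, b.window_seq)
            if d == 0:
                raise NetworkError(
                    f"haplotypes {a.name!r} and {b.name!r} have identical "
                    "sequences; collapse them before building the network"
                )
            all_edges.append((d, a.name, b.name))
    all_edges.sort()

    dsu = _DisjointSet(names)
    i = 0
    while i < len(all_edges):
        d_class = all_edges[i][0]
        snap = dsu.snapshot()
        # class edges: exactly this distance; relaxed edges: within epsilon above
        class_edges = []
        relaxed_edges = []
        j = i
        while j < len(all_edges) and all_edges[j][0] == d_class:
            class_edges.append(all_edges[j])
            j += 1
        if epsilon > 0:
            k = j
            while k < len(all_edges) and all_edges[k][0] <= d_class + epsilon:
                relaxed_edges.append(all_edges[k])
                k += 1

        joining = [
            (d, u, v) for d, u, v in class_edges if snap[u] != snap[v]
        ]
        comp_edges = [(snap[u], snap[v], (u, v)) for d, u, v in joining]
        bridges = _multigraph_bridges(comp_edges)
        for d, u, v in joining:
            graph.add_edge(u, v, weight=d, in_all_msts=(u, v) in bridges)
            dsu.union(u, v)
        for d, u, v in relaxed_edges:
            if snap[u] != snap[v] and not graph.has_edge(u, v):
                graph.add_edge(u, v, weight=d, in_all_msts=False)
        i = j

    assert len(haplotypes) == 1 or nx.is_connected(graph)
    return HaploNetwork(graph=graph, epsilon=epsilon)


# --------------------------------------------------------------------- export

_FORMATS = ("dot", "graphml", "edge_tsv")


def export_network(net: HaploNetwork, path: str | Path, fmt: str) -> None:
    """Write a network to ``dot``, ``graphml``, or ``edge_tsv``.

    Node ordering in all formats is name-sorted, so repeated exports of the
    same network are byte-identical.  ``edge_tsv`` round-trips losslessly
    through :func:`read_edge_tsv`.
    """
    if fmt not in _FORMATS:
        raise NetworkError(f"unknown export format {fmt!r}; choose from {_FORMATS}")
    path = Path(path)
    g = net.graph
    nodes = sorted(g.nodes)
    edges = sorted((min(u, v), max(u, v)) for u, v in g.edges)

    if fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("u\tv\tweight\tin_all_msts\n")
            for u, v in edges:
                data = g.edges[u, v]
                fh.write(f"{u}\t{v}\t{data['weight']}\t{int(data['in_all_msts'])}\n")
    elif fmt == "dot":
        with open(path, "w") as fh:
            fh.write("graph haplotypes {\n")
            for name in nodes:
                attrs = g.nodes[name]
                fh.write(
                    f'  "{name}" [haplogroup="{attrs.get("haplogroup", "")}" '
                    f'count={attrs.get("count", 0)}];\n'
                )
            for u, v in edges:
                data = g.edges[u, v]
                style = "solid" if data["in_all_msts"] else "dashed"
                fh.write(
                    f'  "{u}" -- "{v}" [label={data["weight"]} style={style}];\n'
                )
            fh.write("}\n")
    else:  # graphml
        ordered = nx.Graph()
        for name in nodes:
            ordered.add_node(name, **g.nodes[name])
        for u, v in edges:
            ordered.add_edge(u, v, **g.edges[u, v])
        nx.write_graphml(ordered, str(path))


def read_edge_tsv(path: str | Path) -> nx.Graph:
    """Read back an ``edge_tsv`` export as a weighted graph."""
    g = nx.Graph()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["u", "v", "weight", "in_all_msts"]:
            raise NetworkError(f"unexpected edge_tsv header {header}")
        for line in fh:
            if not line.strip():
                continue
            u, v, w, mand = line.rstrip("\n").split("\t")
            g.add_edge(u, v, weight=int(w), in_all_msts=bool(int(mand)))
    return g


def write_node_table(net: HaploNetwork, path: str | Path) -> None:
    """Write the node annotation table (name, haplogroup, counts) as TSV."""
    g = net.graph
    group_cols = sorted(
        {key for _, attrs in g.nodes(data=True) for key in attrs if key.startswith("count_")}
    )
    with open(path, "w") as fh:
        fh.write("name\thaplogroup\tsubhaplogroup\ttotal_count")
        for col in group_cols:
            fh.write(f"\t{col}")
        fh.write("\n")
        for name in sorted(g.nodes):
            attrs = g.nodes[name]
            fh.write(
                f"{name}\t{attrs.get('haplogroup', '')}\t"
                f"{attrs.get('subhaplogroup', '')}\t{attrs.get('count', 0)}"
            )
            for col in group_cols:
                fh.write(f"\t{attrs.get(col, 0)}")
            fh.write("\n")
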