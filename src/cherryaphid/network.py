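"""Haplotype collapsing and a statistical-parsimony-style network.

Identical aligned sequences are merged into haplotypes; the network is a
minimum spanning network over raw Hamming (step) distances — all edges
of a deterministic minimum spanning tree plus every non-tree edge whose
step count ties the bottleneck (minimax) distance along the tree path —
with edges above a parsimony connection limit dropped. The published
analysis used TCS; the Templeton–Crandall–Sing 95% probability limit is
not re-derived here, the connection limit is an explicit parameter whose
default (10 steps) is of the magnitude TCS yields for ~600 bp. The
in-group maximum distance is 3 steps, so any limit >= 3 reproduces the
published connectivity.

The "outgroup probability" root weighting is a documented surrogate for
the Castelloe–Templeton calculation: weight proportional to haplotype
frequency times (1 + node degree), normalised to sum 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .seqstats import Alignment


@dataclass
class Haplotype:
    hap_id: int
    sequence: str
    members: list[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeTable:
    haplotypes: list[Haplotype]

    def __len__(self) -> int:
        return len(self.haplotypes)

    def by_id(self, hap_id: int) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)

    @property
    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]


def collapse_haplotypes(alignment: Alignment) -> HaplotypeTable:
    """Merge identical sequences; ids assigned by descending count, ties
    broken by first occurrence in the alignment."""
    order: list[str] = []
    groups: dict[str, list[str]] = {}
    for rid, seq in alignment.records:
        if seq not in groups:
            groups[seq] = []
            order.append(seq)
        groups[seq].append(rid)
    ranked = sorted(order, key=lambda s: (-len(groups[s]), order.index(s)))
    return HaplotypeTable(
        [Haplotype(i + 1, seq, groups[seq]) for i, seq in enumerate(ranked)]
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class HaplotypeNetwork:
    graph: nx.Graph  # nodes: hap ids with count/root_weight; edges: steps
    connection_limit: int
    root_candidate: int | None = None

    @property
    def edges(self) -> list[tuple[int, int, int]]:
        return sorted(
            (min(u, v), max(u, v), d["steps"])
            for u, v, d in self.graph.edges(data=True)
        )

    def is_connected(self) -> bool:
        return nx.is_connected(self.graph)

    def to_tsv(self, edge_path: str | Path, node_path: str | Path) -> None:
        with open(edge_path, "w") as fh:
            fh.write("hap_a\thap_b\tsteps\n")
            for a, b, steps in self.edges:
                fh.write(f"{a}\t{b}\t{steps}\n")
        with open(node_path, "w") as fh:
            fh.write("hap_id\tcount\troot_weight\tis_root_candidate\n")
            for node in sorted(self.graph.nodes):
                d = self.graph.nodes[node]
                fh.write(
                    f"{node}\t{d['count']}\t{d.get('root_weight', '')}\t"
                    f"{int(node == self.root_candidate)}\n"
                )

    def to_dot(self) -> str:
        lines = ["graph haplotypes {"]
        for node in sorted(self.graph.nodes):
            d = self.graph.nodes[node]
            shape = "box" if node == self.root_candidate else "ellipse"
            lines.append(
                f'  h{node} [label="hap{node} (n={d["count"]})", shape={shape}];'
            )
        for a, b, steps in self.edges:
            lines.append(f'  h{a} -- h{b} [label="{steps}"];')
        lines.append("}")
        return "\n".join(lines)


def build_network(
    table: HaplotypeTable, connection_limit: int = 10
) -> HaplotypeNetwork:
    """Minimum spanning network under a parsimony connection limit.

    Kruskal with a fixed (steps, id-pair) ordering makes the tree
    deterministic; tied alternative connections are kept as extra edges.
    A limit that disconnects the haplotypes yields a forest plus a
    warning, mirroring the behaviour of parsimony networks when variants
    exceed the connection limit.
    """
    if connection_limit < 1:
        raise ValueError("connection_limit must be >= 1")
    haps = table.haplotypes
    g = nx.Graph()
    for h in haps:
        g.add_node(h.hap_id, count=h.count)
    candidates = []
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            steps = _hamming(haps[i].sequence, haps[j].sequence)
            if steps <= connection_limit:
                candidates.append(
                    (steps, min(haps[i].hap_id, haps[j].hap_id),
                     max(haps[i].hap_id, haps[j].hap_id))
                )
    candidates.sort()

    # deterministic Kruskal
    parent = {h.hap_id: h.hap_id for h in haps}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_edges = []
    for steps, a, b in candidates:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree_edges.append((a, b, steps))
            g.add_edge(a, b, steps=steps)

    # tied alternative connections: direct distance equals the bottleneck
    # (max edge) weight on the spanning path
    tree = nx.Graph()
    tree.add_weighted_edges_from(tree_edges, weight="steps")
    for steps, a, b in candidates:
        if g.has_edge(a, b):
            continue
        if a in tree and b in tree and nx.has_path(tree, a, b):
            path = nx.shortest_path(tree, a, b)
            bottleneck = max(
                tree[u][v]["steps"] for u, v in zip(path, path[1:])
            )
            if steps == bottleneck:
                g.add_edge(a, b, steps=steps)

    net = HaplotypeNetwork(graph=g, connection_limit=connection_limit)
    if len(haps) > 1 and not net.is_connected():
        warnings.warn(
            f"haplotype network disconnected at connection limit "
            f"{connection_limit} steps",
            stacklevel=2,
        )
    return net


def root_weights(
    network: HaplotypeNetwork, table: HaplotypeTable
) -> HaplotypeNetwork:
    """Attach normalised root-candidate weights.

    weight(h) ~ count(h) * (1 + degree(h)); the argmax is flagged as the
    root candidate, ties broken by larger degree then smaller id.
    """
    g = network.graph
    raw = {
        h.hap_id: h.count * (1 + g.degree(h.hap_id)) for h in table.haplotypes
    }
    total = sum(raw.values())
    for hap_id, w in raw.items():
        g.nodes[hap_id]["root_weight"] = w / total
    network.root_candidate = min(
        raw, key=lambda h: (-raw[h], -g.degree(h), h)
    )
    return network
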