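"""Native distance and parsimony tree machinery.

Neighbor joining (Saitou–Nei) on K2P distance matrices, Fitch parsimony
length, exhaustive maximum-parsimony search at haplotype scale with
consistency and retention indices, and seeded site-resampling bootstrap
support. Heuristic tree search, model-based (ML/Bayesian) inference and
model selection are deliberately out of scope: at haplotype scale the
distance and parsimony analyses carry the reproducible content, and the
published study reports all four tree methods as topologically
concordant.

Determinism rules (fixed so outputs are byte-stable): NJ ties on the
Q-criterion are broken by the earliest (i, j) pair in the current node
ordering; negative NJ branch lengths are clamped to zero with the
deficit transferred to the sister branch.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seqstats import Alignment, DistanceMatrix, distance_matrix


# ---------------------------------------------------------------------------
# Unrooted tree container
# ---------------------------------------------------------------------------

class Tree:
    """Unrooted tree: leaves are string labels, internal nodes integers."""

    def __init__(self) -> None:
        self.adj: dict = {}

    def add_edge(self, u, v, length: float = 0.0) -> None:
        self.adj.setdefault(u, {})[v] = length
        self.adj.setdefault(v, {})[u] = length

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.adj if isinstance(n, str))

    def branch_length(self, u, v) -> float:
        return self.adj[u][v]

    def _side_leaves(self, u, v) -> frozenset:
        """Leaves reachable from u when the edge (u, v) is cut."""
        seen, stack, out = {v, u}, [u], []
        while stack:
            node = stack.pop()
            if isinstance(node, str):
                out.append(node)
            for nbr in self.adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append(nbr)
        return frozenset(out)

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the lexicographically smallest leaf."""
        leaves = set(self.leaves)
        ref = min(leaves)
        out: set[frozenset] = set()
        done = set()
        for u in self.adj:
            for v in self.adj[u]:
                key = (min(str(u), str(v)), max(str(u), str(v)))
                if key in done:
                    continue
                done.add(key)
                side = self._side_leaves(u, v)
                if 2 <= len(side) <= len(leaves) - 2:
                    out.add(side if ref not in side else frozenset(leaves - side))
        return out

    def newick(self, decimals: int = 6) -> str:
        internal = [n for n in self.adj if not isinstance(n, str)]
        root = internal[-1] if internal else next(iter(self.adj))

        def rec(node, parent) -> str:
            children = [n for n in self.adj[node] if n != parent]
            if not children:
                label = str(node)
            else:
                label = "(" + ",".join(rec(c, node) for c in children) + ")"
            if parent is None:
                return label
            return f"{label}:{self.adj[node][parent]:.{decimals}f}"

        return rec(root, None) + ";"


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking."""
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = {}
    nodes: list = list(matrix.ids)
    for i, a in enumerate(matrix.ids):
        for j, b in enumerate(matrix.ids):
            if i != j:
                d[(a, b)] = float(matrix.matrix[i, j])
    tree = Tree()
    next_internal = 0
    active = list(nodes)

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        best_q = None
        for i in range(m):
            for j in range(i + 1, m):
                a, b = active[i], active[j]
                q = (m - 2) * d[(a, b)] - r[a] - r[b]
                if best_q is None or q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        dab = d[(a, b)]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        u = next_internal
        next_internal += 1
        tree.add_edge(a, u, la)
        tree.add_edge(b, u, lb)
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[(a, c)] + d[(b, c)] - dab)
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = active
    u = next_internal
    la = 0.5 * (d[(a, b)] + d[(a, c)] - d[(b, c)])
    lb = 0.5 * (d[(a, b)] + d[(b, c)] - d[(a, c)])
    lc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
    tree.add_edge(a, u, max(la, 0.0))
    tree.add_edge(b, u, max(lb, 0.0))
    tree.add_edge(c, u, max(lc, 0.0))
    return tree


def nj_k2p(alignment: Alignment) -> Tree:
    """Convenience builder: K2P distance matrix then neighbor joining."""
    return nj_tree(distance_matrix(alignment))


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _compressed_columns(
    alignment: Alignment, leaf_order: list[str]
) -> list[tuple[tuple[str, ...], int]]:
    seqs = dict(alignment.records)
    missing = [l for l in leaf_order if l not in seqs]
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {missing}")
    cols = Counter(
        tuple(seqs[l][j] for l in leaf_order) for j in range(alignment.length)
    )
    return list(cols.items())


def _fitch_site_tree(tree: Tree, leaf_state: dict[str, str]) -> int:
    leaves = tree.leaves
    root_leaf = leaves[0]
    (v,) = tree.adj[root_leaf].keys()
    changes = 0

    def rec(node, parent) -> set[str]:
        nonlocal changes
        children = [n for n in tree.adj[node] if n != parent]
        if not children:
            return {leaf_state[node]}
        acc = rec(children[0], node)
        for c in children[1:]:
            s = rec(c, node)
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                changes += 1
        return acc

    top = rec(v, root_leaf)
    if leaf_state[root_leaf] not in top:
        changes += 1
    return changes


def fitch_length(alignment: Alignment, tree: Tree) -> int:
    """Fitch parsimony length of the tree on the alignment (sum over
    sites of set-intersection changes)."""
    leaves = tree.leaves
    total = 0
    for col, mult in _compressed_columns(alignment, leaves):
        if len(set(col)) == 1:
            continue
        total += mult * _fitch_site_tree(tree, dict(zip(leaves, col)))
    return total


# ---------------------------------------------------------------------------
# Exhaustive maximum parsimony
# ---------------------------------------------------------------------------

def _insert_subtree(sub, taxon):
    """All placements of taxon on edges inside sub or the edge above it."""
    out = [(sub, taxon)]
    if isinstance(sub, tuple):
        l, r = sub
        out += [(nl, r) for nl in _insert_subtree(l, taxon)]
        out += [(l, nr) for nr in _insert_subtree(r, taxon)]
    return out


def enumerate_topologies(labels: list[str]) -> list[tuple]:
    """All unrooted binary topologies over the labels, each represented
    as a 3-tuple of subtrees hanging off a virtual degree-3 root."""
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    trees: list[tuple] = [tuple(labels[:3])]
    for taxon in labels[3:]:
        nxt = []
        for a, b, c in trees:
            nxt += [(na, b, c) for na in _insert_subtree(a, taxon)]
            nxt += [(a, nb, c) for nb in _insert_subtree(b, taxon)]
            nxt += [(a, b, nc) for nc in _insert_subtree(c, taxon)]
        trees = nxt
    return trees


def _fitch_site_nested(top3, leaf_state: dict[str, str]) -> int:
    a, b, c = top3
    changes = 0

    def rec(sub) -> set[str]:
        nonlocal changes
        if not isinstance(sub, tuple):
            return {leaf_state[sub]}
        sl, sr = rec(sub[0]), rec(sub[1])
        inter = sl & sr
        if inter:
            return inter
        changes += 1
        return sl | sr

    # root the 3-tuple on the edge above c: score is rooting-invariant
    sl, sr = rec((a, b)), rec(c)
    if not (sl & sr):
        changes += 1
    return changes


def topology_newick(top3) -> str:
    def rec(sub) -> str:
        if not isinstance(sub, tuple):
            return str(sub)
        return "(" + ",".join(rec(s) for s in sub) + ")"

    return rec(top3) + ";"


@dataclass
class ParsimonyResult:
    best_trees: list[tuple]
    length: int
    ci: float
    ri: float
    min_changes: int
    max_changes: int
    n_topologies: int = 0
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def best_newicks(self) -> list[str]:
        return [topology_newick(t) for t in self.best_trees]


def exhaustive_mp(alignment: Alignment, max_taxa: int = 8) -> ParsimonyResult:
    """Enumerate all unrooted binary topologies over the distinct
    sequences and return every minimum-length tree with CI and RI.

    Identical sequences are collapsed first (one representative per
    haplotype; members recorded), since resolutions among identical
    sequences carry no parsimony information. CI = (minimum possible
    changes) / (realised changes); RI = (G - S) / (G - M) with G the sum
    over sites of (n - count of the most frequent state), M the minimum
    and S the realised length. Both default to 1.0 on an invariant
    alignment.
    """
    groups: dict[str, list[str]] = {}
    order = []
    for rid, seq in alignment.records:
        if seq not in groups:
            groups[seq] = []
            order.append(seq)
        groups[seq].append(rid)
    labels = [groups[s][0] for s in order]
    if len(labels) > max_taxa:
        raise ValueError(
            f"{len(labels)} distinct sequences exceed the exhaustive-search "
            f"limit of {max_taxa}; use the neighbor-joining heuristic instead"
        )
    members = {groups[s][0]: groups[s] for s in order}
    sub = alignment.subset(labels)
    n = len(labels)

    cols = _compressed_columns(sub, labels)
    m_min = 0
    g_max = 0
    variable = []
    for col, mult in cols:
        counts = Counter(col)
        if len(counts) > 1:
            m_min += mult * (len(counts) - 1)
            g_max += mult * (n - max(counts.values()))
            variable.append((col, mult))

    if n < 3:
        raise ValueError("exhaustive search requires at least 3 distinct sequences")

    best_len = None
    best: list[tuple] = []
    topologies = enumerate_topologies(labels)
    for top in topologies:
        s = sum(
            mult * _fitch_site_nested(top, dict(zip(labels, col)))
            for col, mult in variable
        )
        if best_len is None or s < best_len:
            best_len, best = s, [top]
        elif s == best_len:
            best.append(top)

    if best_len == 0:
        ci = ri = 1.0
    else:
        ci = m_min / best_len
        ri = (g_max - best_len) / (g_max - m_min) if g_max > m_min else float("nan")
    return ParsimonyResult(
        best_trees=best,
        length=int(best_len),
        ci=float(ci),
        ri=float(ri),
        min_changes=m_min,
        max_changes=g_max,
        n_topologies=len(topologies),
        members=members,
    )


# ---------------------------------------------------------------------------
# Bootstrap support
# ---------------------------------------------------------------------------

def bootstrap_support(
    alignment: Alignment,
    builder=nj_k2p,
    n_reps: int = 100,
    seed: int = 0,
) -> dict[frozenset, float]:
    """Site-resampling bootstrap: percent of replicates containing each
    bipartition of the builder's tree on resampled alignments."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    tally: Counter = Counter()
    ids = alignment.ids
    seqs = [seq for _, seq in alignment.records]
    L = alignment.length
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        resampled = Alignment(
            [(rid, "".join(seq[j] for j in idx)) for rid, seq in zip(ids, seqs)]
        )
        tree = builder(resampled)
        for split in tree.splits():
            tally[split] += 1
    return {split: 100.0 * c / n_reps for split, c in tally.items()}


def support_table_tsv(support: dict[frozenset, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("split\tsupport_pct\n")
        for split in sorted(support, key=lambda s: (-support[s], sorted(s))):
            fh.write("|".join(sorted(split)) + f"\t{support[split]:.1f}\n")
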