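"""Minimal rooted-tree container used across simulation and phylogenetics.

A tree is a `Node` hierarchy; unrooted trees are represented rooted at a
(basal) multifurcation. Newick parsing is delegated to DendroPy; writing is
done directly so that branch supports land where the rest of the package
expects them (as internal-node labels).
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional

import dendropy
import networkx as nx
import numpy as np


class Node:
    __slots__ = ("name", "length", "support", "children", "flags")

    def __init__(self, name: Optional[str] = None, length: float = 0.0,
                 children: Optional[list["Node"]] = None,
                 support: Optional[float] = None):
        self.name = name
        self.length = float(length)
        self.support = support
        self.children: list[Node] = children or []
        self.flags: list[str] = []

    # -- traversal ---------------------------------------------------------
    def walk(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.walk() if n is not self)

    # -- serialisation -----------------------------------------------------
    def newick(self, with_support: bool = True, with_lengths: bool = True) -> str:
        return self._nwk(with_support, with_lengths) + ";"

    def _nwk(self, ws: bool, wl: bool) -> str:
        if self.is_leaf():
            body = self.name or ""
        else:
            inner = ",".join(c._nwk(ws, wl) for c in self.children)
            label = ""
            if ws and self.support is not None:
                label = f"{self.support:g}"
            elif self.name:
                label = self.name
            body = f"({inner}){label}"
        if wl:
            body += f":{self.length:g}"
        return body

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.newick()})"


def parse_newick(text: str) -> Node:
    """Parse a Newick string into a Node tree (missing lengths become 0)."""
    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=True)

    def conv(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon else dnode.label
        n = Node(name=name, length=dnode.edge.length or 0.0)
        n.children = [conv(c) for c in dnode.child_nodes()]
        return n

    return conv(dt.seed_node)


# ---------------------------------------------------------------------------
# unrooted-view utilities


def bipartitions(root: Node) -> set[frozenset]:
    """Non-trivial splits of the unrooted tree, each as the side NOT
    containing the lexicographically smallest leaf (canonical form)."""
    all_leaves = frozenset(root.leaf_names())
    anchor = min(all_leaves)
    out: set[frozenset] = set()
    for node in root.walk():
        if node is root or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def tree_distance_matrix(root: Node, labels: Optional[list[str]] = None
                         ) -> tuple[list[str], np.ndarray]:
    """Additive (path-length) leaf-to-leaf distance matrix."""
    if labels is None:
        labels = sorted(root.leaf_names())
    g = to_graph(root)
    name2id = {g.nodes[v]["name"]: v for v in g if g.nodes[v].get("name")}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = nx.shortest_path_length(
            g, name2id[labels[i]], name2id[labels[j]], weight="length")
    return labels, d


def to_graph(root: Node) -> nx.Graph:
    """Undirected adjacency view; leaf nodes carry a 'name' attribute."""
    g = nx.Graph()
    counter = itertools.count()
    def add(node: Node) -> int:
        nid = next(counter)
        g.add_node(nid, name=node.name if node.is_leaf() else None)
        for c in node.children:
            cid = add(c)
            g.add_edge(nid, cid, length=c.length)
        return nid
    add(root)
    return g


def from_graph(g: nx.Graph, root_id) -> Node:
    """Re-root an adjacency view at `root_id` and rebuild a Node tree."""
    def build(v, parent, length) -> Node:
        n = Node(name=g.nodes[v].get("name"), length=length)
        for w in sorted(g.neighbors(v)):
            if w != parent:
                n.children.append(build(w, v, g.edges[v, w]["length"]))
        return n
    return build(root_id, None, 0.0)


def reroot_at_leaf_edge(root: Node, leaf_name: str) -> Node:
    """Return a binary-rooted copy with `leaf_name` as the outgroup child.

    Every internal node of the result has exactly two children when the
    input is an unrooted binary tree (basal trifurcation)."""
    g = to_graph(root)
    leaf_id = next(v for v in g if g.nodes[v].get("name") == leaf_name)
    (nbr,) = list(g.neighbors(leaf_id))
    length = g.edges[leaf_id, nbr]["length"]
    g.remove_edge(leaf_id, nbr)
    new_root = Node()
    leaf = Node(name=leaf_name, length=length / 2.0)
    rest = from_graph(g, nbr)
    rest.length = length / 2.0
    new_root.children = [leaf, rest]
    return new_root


def random_binary_tree(rng: np.random.Generator, n_taxa: int,
                       blen_range: tuple[float, float] = (0.05, 1.0),
                       prefix: str = "t") -> Node:
    """Random topology by sequential pair-joining; branch lengths uniform."""
    lo, hi = blen_range
    nodes = [Node(name=f"{prefix}{i + 1}") for i in range(n_taxa)]
    for n in nodes:
        n.length = float(rng.uniform(lo, hi))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(lo, hi)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    root.children = nodes
    return root
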