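"""Distance phylogenetics: Poisson- and PAM250-corrected distances,
neighbor joining, OLS minimum evolution (NNI), Fitch parsimony, and
column-bootstrap supports.

The Poisson correction d = -ln(1 - p) converts an observed amino-acid
mismatch fraction into an expected substitution count under an
equal-rates model. The PAM250 route uses Scoredist-style normalisation of
the summed PAM250 alignment score, which degrades gracefully toward
saturation for distant pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

from .trees import Node, bipartitions, from_graph, reroot_at_leaf_edge, to_graph

GAP_CHARS = set("-.")


class SaturatedDistance(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for name, row in zip(self.labels, self.d):
            lines.append(name.ljust(12) + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# distances


def _compared_columns(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b))
            if x not in GAP_CHARS and y not in GAP_CHARS]


def p_distance(msa: dict[str, str], pair: tuple[str, str]) -> float:
    """Mismatch fraction with pairwise deletion of gapped columns."""
    a, b = msa[pair[0]], msa[pair[1]]
    cols = _compared_columns(a, b)
    if not cols:
        raise ValueError(f"no comparable columns for {pair}")
    mism = sum(a[i] != b[i] for i in cols)
    return mism / len(cols)


def poisson_distance(p: float) -> float:
    """Multiple-hit correction d = -ln(1-p); p >= 1 is saturated."""
    if not 0 <= p:
        raise ValueError("p must be non-negative")
    if p >= 1:
        raise SaturatedDistance(f"p = {p} is saturated")
    return -math.log1p(-p)


_PAM250 = substitution_matrices.load("PAM250")


def pam250_distance(msa: dict[str, str], pair: tuple[str, str]) -> float:
    """Scoredist-style PAM250 distance.

    sigma = (S_obs - S_rand) / (S_max - S_rand) over pairwise-complete
    columns, with S_max the mean of the two self-scores and S_rand the
    expectation under the rows' residue frequencies; d = -ln(sigma).
    """
    a, b = msa[pair[0]], msa[pair[1]]
    alpha = set(_PAM250.alphabet)
    cols = [i for i in _compared_columns(a, b)
            if a[i] in alpha and b[i] in alpha]
    if not cols:
        raise ValueError(f"no comparable columns for {pair}")
    ra = [a[i] for i in cols]
    rb = [b[i] for i in cols]
    s_obs = sum(_PAM250[x, y] for x, y in zip(ra, rb))
    s_max = 0.5 * (sum(_PAM250[x, x] for x in ra)
                   + sum(_PAM250[y, y] for y in rb))
    n = len(cols)
    fa: dict[str, float] = {}
    fb: dict[str, float] = {}
    for x in ra:
        fa[x] = fa.get(x, 0) + 1 / n
    for y in rb:
        fb[y] = fb.get(y, 0) + 1 / n
    s_rand = n * sum(pa * pb * _PAM250[x, y]
                     for x, pa in fa.items() for y, pb in fb.items())
    sigma = (s_obs - s_rand) / (s_max - s_rand)
    if sigma <= 0:
        raise SaturatedDistance(f"sigma = {sigma:.4f} <= 0 for {pair}")
    return -math.log(sigma)


def distance_matrix(msa: dict[str, str], model: str = "poisson",
                    saturation_factor: float = 1.5) -> DistanceMatrix:
    """All-pairs matrix; saturated pairs get the largest finite distance
    times `saturation_factor` and are listed in `saturated_pairs`."""
    labels = sorted(msa)
    n = len(labels)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n), 2):
        pair = (labels[i], labels[j])
        try:
            if model == "poisson":
                v = poisson_distance(p_distance(msa, pair))
            elif model == "p":
                v = p_distance(msa, pair)
            elif model == "pam250":
                v = pam250_distance(msa, pair)
            else:
                raise ValueError(f"unknown distance model {model!r}")
        except SaturatedDistance:
            v = math.nan
            saturated.append(pair)
        d[i, j] = d[j, i] = v
    if saturated:
        finite = d[np.isfinite(d)]
        if not finite.size or finite.max() == 0:
            raise SaturatedDistance("all pairs saturated")
        fill = finite.max() * saturation_factor
        d[np.isnan(d)] = fill
    return DistanceMatrix(labels=labels, d=d, saturated_pairs=saturated)


# ---------------------------------------------------------------------------
# neighbor joining


def nj(dm: DistanceMatrix) -> Node:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-ties are broken by the lexicographically smallest sorted pair of
    subtree keys (key = smallest leaf label in the subtree). Negative
    branch-length estimates are clamped to 0 and flagged on the node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if np.isnan(dm.d).any():
        raise ValueError("distance matrix contains NaN")
    nodes = [Node(name=lab) for lab in dm.labels]
    keys = [lab for lab in dm.labels]
    d = dm.d.copy()
    active = list(range(n))

    def clamp(node: Node, length: float) -> None:
        if length < 0:
            node.flags.append("clamped-negative-branch")
            length = 0.0
        node.length = length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d[i, j] - r[i] - r[j]
            tie = tuple(sorted((keys[i], keys[j])))
            cand = (q, tie, i, j)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = Node(children=[nodes[i], nodes[j]])
        clamp(nodes[i], li)
        clamp(nodes[j], lj)
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for kx in active:
            if kx in (i, j):
                continue
            d[u, kx] = d[kx, u] = 0.5 * (d[i, kx] + d[j, kx] - d[i, j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [x for x in active if x not in (i, j)] + [u]

    i, j, k = active
    a = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    b = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    c = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = Node()
    for idx, length in ((i, a), (j, b), (k, c)):
        clamp(nodes[idx], length)
    order = sorted(((keys[x], x) for x in (i, j, k)))
    root.children = [nodes[x] for _, x in order]
    return root


# ---------------------------------------------------------------------------
# OLS minimum evolution with NNI


def _ols_lengths(g: nx.Graph, dm: DistanceMatrix) -> tuple[np.ndarray, list]:
    leaves = {g.nodes[v]["name"]: v for v in g if g.nodes[v].get("name")}
    edges = sorted(g.edges())
    eidx = {tuple(sorted(e)): i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(dm.labels, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    lab_i = {lab: i for i, lab in enumerate(dm.labels)}
    for row, (x, z) in enumerate(pairs):
        path = nx.shortest_path(g, leaves[x], leaves[z])
        for u, v in zip(path, path[1:]):
            A[row, eidx[tuple(sorted((u, v)))]] = 1.0
        y[row] = dm.d[lab_i[x], lab_i[z]]
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    return lengths, edges


def _tree_length(g: nx.Graph, dm: DistanceMatrix) -> float:
    lengths, _ = _ols_lengths(g, dm)
    return float(lengths.sum())


def _nni_neighbours(g: nx.Graph, u: int, v: int):
    """The two NNI rearrangements around internal edge (u, v)."""
    au = [w for w in sorted(g.neighbors(u)) if w != v]
    av = [w for w in sorted(g.neighbors(v)) if w != u]
    if len(au) != 2 or len(av) != 2:
        return
    b = au[1]
    for c in av:
        h = g.copy()
        h.remove_edge(u, b)
        h.remove_edge(v, c)
        h.add_edge(u, c, length=0.0)
        h.add_edge(v, b, length=0.0)
        yield h


def minimum_evolution(start: Node, dm: DistanceMatrix,
                      max_rounds: int = 50) -> Node:
    """NNI hill climbing on the OLS total-tree-length criterion.

    Deterministic sweep over internal edges (sorted node ids); the first
    improving rearrangement is applied and the sweep restarts; stops at a
    local optimum (an additive matrix keeps the NJ tree unchanged).
    """
    g = to_graph(start)
    best_len = _tree_length(g, dm)
    for _ in range(max_rounds):
        improved = False
        internal = sorted((u, v) for u, v in g.edges()
                          if g.degree(u) > 1 and g.degree(v) > 1)
        for u, v in internal:
            for h in _nni_neighbours(g, u, v):
                cand = _tree_length(h, dm)
                if cand < best_len - 1e-12:
                    g, best_len, improved = h, cand, True
                    break
            if improved:
                break
        if not improved:
            break
    lengths, edges = _ols_lengths(g, dm)
    for (u, v), l in zip(edges, lengths):
        g.edges[u, v]["length"] = max(float(l), 0.0)
    root_id = next(v for v in sorted(g.nodes) if not g.nodes[v].get("name"))
    return from_graph(g, root_id)


# ---------------------------------------------------------------------------
# Fitch parsimony


def parsimony_score(msa: dict[str, str], tree: Node) -> int:
    """Fitch small-parsimony changes summed over columns (gaps missing)."""
    leaves = tree.leaf_names()
    missing = [l for l in leaves if l not in msa]
    if missing:
        raise ValueError(f"tree leaves absent from MSA: {missing}")
    rooted = reroot_at_leaf_edge(tree, min(leaves))
    length = len(next(iter(msa.values())))
    total = 0
    for col in range(length):
        states = {l: msa[l][col] for l in leaves}

        def fitch(node: Node) -> Optional[frozenset]:
            nonlocal total
            if node.is_leaf():
                ch = states[node.name]
                return None if ch in GAP_CHARS or ch == "X" else frozenset(ch)
            sets = [s for s in (fitch(c) for c in node.children)
                    if s is not None]
            if not sets:
                return None
            cur = sets[0]
            for s in sets[1:]:
                inter = cur & s
                if inter:
                    cur = inter
                else:
                    cur = cur | s
                    total += 1
            return cur

        fitch(rooted)
    return total


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(msa: dict[str, str], n_reps: int = 500,
                      distance: str = "poisson", seed: int = 0,
                      tree_builder=nj) -> tuple[Node, int]:
    """Column-resampling bootstrap supports on the point-estimate NJ tree.

    Supports are the percentage of successful replicates containing each
    internal bipartition; replicates whose distance matrix cannot be
    computed (all pairs saturated) are dropped and counted.
    """
    if len(msa) < 4:
        raise ValueError("bootstrap needs >= 4 sequences")
    rng = np.random.default_rng(seed)
    labels = sorted(msa)
    arr = {k: np.frombuffer(msa[k].encode(), dtype="S1") for k in labels}
    length = len(next(iter(msa.values())))
    point = tree_builder(distance_matrix(msa, model=distance))
    counts: dict[frozenset, int] = {b: 0 for b in bipartitions(point)}
    dropped = 0
    for _ in range(n_reps):
        idx = rng.integers(0, length, size=length)
        rep = {k: arr[k][idx].tobytes().decode() for k in labels}
        try:
            t = tree_builder(distance_matrix(rep, model=distance))
        except (SaturatedDistance, ValueError):
            dropped += 1
            continue
        reps = bipartitions(t)
        for b in counts:
            if b in reps:
                counts[b] += 1
    ok = n_reps - dropped
    if ok == 0:
        raise SaturatedDistance("every bootstrap replicate failed")
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    for node in point.walk():
        if node is point or node.is_leaf():
            continue
        side = frozenset(node.leaf_names())
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = 100.0 * counts[side] / ok
    return point, dropped
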