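"""EST clustering, perfect-match refinement, consensus calling, counting.

Clustering follows the classical identity-matrix strategy: single-linkage
grouping of reads whose best gapless overlap (found via shared k-mer
diagonals; both strands are tried) reaches a seed identity, followed by a
refinement pass that keeps only perfectly agreeing cores, re-homes the
excluded reads, and calls a per-column majority consensus. EST counts per
final cDNA serve as a crude expression proxy; zero-count genes are
reported as putatively non-expressed.

Reads are assumed to differ by substitutions (sequencing miscalls), not
indels; the diagonal-overlap model is exact for that error process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqs import IUPAC, revcomp
from .simulate import ESTRecord


@dataclass(frozen=True)
class ClusterParams:
    min_overlap: int = 40
    perfect_identity: float = 1.0
    seed_identity: float = 0.90
    min_est_len: int = 100
    kmer: int = 15

    def __post_init__(self):
        if not 0 < self.seed_identity <= self.perfect_identity <= 1.0:
            raise ValueError("need 0 < seed_identity <= perfect_identity <= 1")


@dataclass
class ESTCluster:
    cluster_id: str
    members: list[tuple[str, str]]            # (est_id, orientation)
    offsets: dict[str, int]                   # canonical coords of each member
    seqs: dict[str, str]                      # canonical-orientation sequences
    consensus: str = ""
    depth: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    flags: list[str] = field(default_factory=list)

    @property
    def est_count(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# gapless overlap detection


def _diagonal_overlap(a: str, b: str, k: int, min_overlap: int
                      ) -> Optional[tuple[float, int, int]]:
    """Best gapless overlap of b against a: (identity, length, offset),
    where b[j] pairs with a[j + offset]."""
    if len(a) < k or len(b) < k:
        return None
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i:i + k], []).append(i)
    votes: dict[int, int] = {}
    for j in range(len(b) - k + 1):
        for i in index.get(b[j:j + k], ()):
            off = i - j
            votes[off] = votes.get(off, 0) + 1
    if not votes:
        return None
    best = None
    for off in sorted(votes, key=lambda o: (-votes[o], o))[:8]:
        j0 = max(0, -off)
        j1 = min(len(b), len(a) - off)
        if j1 - j0 < min_overlap:
            continue
        m = sum(1 for j in range(j0, j1) if b[j] == a[j + off])
        ident = m / (j1 - j0)
        cand = (ident, j1 - j0, off)
        if best is None or cand[:2] > best[:2]:
            best = cand
    return best


def overlap_identity(a: str, b: str, k: int = 15, min_overlap: int = 40
                     ) -> Optional[tuple[float, int, str, int]]:
    """(identity, overlap_len, strand_of_b, offset) of the best overlap."""
    fwd = _diagonal_overlap(a, b, k, min_overlap)
    rev = _diagonal_overlap(a, revcomp(b), k, min_overlap)
    cand = []
    if fwd:
        cand.append((fwd[0], fwd[1], "+", fwd[2]))
    if rev:
        cand.append((rev[0], rev[1], "-", rev[2]))
    if not cand:
        return None
    return max(cand, key=lambda c: (c[0], c[1], c[2] == "+"))


# ---------------------------------------------------------------------------
# clustering


def _trim(seq: str) -> str:
    return seq.strip("Nn")


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_ests(ests: Sequence[ESTRecord], params: ClusterParams
                 ) -> list[ESTCluster]:
    """Single-linkage clusters under the seed-identity overlap criterion."""
    seqs = {}
    for rec in ests:
        t = _trim(rec.seq)
        if len(t) >= params.min_est_len:
            seqs[rec.est_id] = t
    ids = sorted(seqs)
    if not ids:
        return []
    dsu = _DSU(ids)
    edges: dict[tuple[str, str], tuple[float, int, str, int]] = {}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = ids[x], ids[y]
            ov = overlap_identity(seqs[a], seqs[b], params.kmer,
                                  params.min_overlap)
            if ov and ov[0] >= params.seed_identity:
                dsu.union(a, b)
                edges[(a, b)] = ov
    comp: dict[str, list[str]] = {}
    for est in ids:
        comp.setdefault(dsu.find(est), []).append(est)

    clusters = []
    for idx, root in enumerate(sorted(comp), 1):
        members = sorted(comp[root])
        cluster = _orient_component(members, seqs, edges,
                                    f"cl{idx:04d}")
        clusters.append(cluster)
    return clusters


def _orient_component(members: list[str], seqs: dict[str, str],
                      edges: dict, cluster_id: str) -> ESTCluster:
    """Assign orientations/offsets by BFS from the longest member."""
    adj: dict[str, list[tuple[str, str]]] = {m: [] for m in members}
    for (a, b), ov in edges.items():
        if a in adj and b in adj:
            adj[a].append((b, ov[2]))
            adj[b].append((a, ov[2]))
    ref = max(members, key=lambda m: (len(seqs[m]), m))
    orient = {ref: "+"}
    flags: list[str] = []
    queue = [ref]
    while queue:
        cur = queue.pop(0)
        for nbr, strand in sorted(adj[cur]):
            want = orient[cur] if strand == "+" else ("-" if orient[cur] == "+"
                                                     else "+")
            if nbr not in orient:
                orient[nbr] = want
                queue.append(nbr)
            elif orient[nbr] != want:
                flags.append(f"orientation-conflict:{nbr}")
    for m in members:                       # singletons / unreached
        orient.setdefault(m, "+")
    canon = {m: seqs[m] if orient[m] == "+" else revcomp(seqs[m])
             for m in members}
    offsets = {ref: 0}
    queue = [ref]
    while queue:
        cur = queue.pop(0)
        for nbr, _ in sorted(adj[cur]):
            if nbr in offsets:
                continue
            ov = _diagonal_overlap(canon[cur], canon[nbr], 15, 20)
            if ov is None:
                continue
            offsets[nbr] = offsets[cur] + ov[2]
            queue.append(nbr)
    for m in members:
        offsets.setdefault(m, 0)
    base = min(offsets.values())
    offsets = {m: o - base for m, o in offsets.items()}
    return ESTCluster(cluster_id=cluster_id,
                      members=[(m, orient[m]) for m in members],
                      offsets=offsets, seqs=canon, flags=flags)


# ---------------------------------------------------------------------------
# refinement


def _perfect_match(a: str, b: str, off_a: int, off_b: int,
                   min_overlap: int, perfect: float) -> Optional[bool]:
    """None if the pair does not overlap, else whether it agrees."""
    off = off_b - off_a                    # b[j] ~ a[j + off]
    j0 = max(0, -off)
    j1 = min(len(b), len(a) - off)
    if j1 - j0 < min_overlap:
        return None
    m = sum(1 for j in range(j0, j1) if b[j] == a[j + off])
    return m / (j1 - j0) >= perfect


def refine_clusters(clusters: Sequence[ESTCluster], params: ClusterParams
                    ) -> tuple[list[ESTCluster], list[str]]:
    """Split clusters into perfectly agreeing cores; re-home the rest.

    Excluded reads are re-tested against every refined core's consensus
    and join the best core they match at `perfect_identity`; reads
    matching nowhere become flagged singleton clusters. Idempotent.
    """
    cores: list[ESTCluster] = []
    excluded: list[tuple[str, str]] = []       # (est_id, canonical seq)
    for cl in clusters:
        ids = [m for m, _ in cl.members]
        dsu = _DSU(ids)
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                a, b = ids[x], ids[y]
                ok = _perfect_match(cl.seqs[a], cl.seqs[b], cl.offsets[a],
                                    cl.offsets[b], params.min_overlap,
                                    params.perfect_identity)
                if ok:
                    dsu.union(a, b)
        comp: dict[str, list[str]] = {}
        for est in ids:
            comp.setdefault(dsu.find(est), []).append(est)
        parts = sorted(comp.values(), key=lambda ms: (-len(ms), ms[0]))
        for ms in parts:
            if len(ms) >= 2:
                orient = dict(cl.members)
                sub = ESTCluster(
                    cluster_id="", members=[(m, orient[m]) for m in sorted(ms)],
                    offsets={m: cl.offsets[m] for m in ms},
                    seqs={m: cl.seqs[m] for m in ms})
                base = min(sub.offsets.values())
                sub.offsets = {m: o - base for m, o in sub.offsets.items()}
                cores.append(sub)
            else:
                excluded.extend((m, cl.seqs[m]) for m in ms)

    for core in cores:
        call_consensus(core)
    leftover: list[str] = []
    for est_id, seq in sorted(excluded):
        best = None
        for core in cores:
            ov = overlap_identity(core.consensus, seq, params.kmer,
                                  params.min_overlap)
            if ov and ov[0] >= params.perfect_identity:
                cand = (ov[0], ov[1], core)
                if best is None or cand[:2] > best[:2]:
                    best = cand
        if best is None:
            canon = seq
            cores.append(ESTCluster(cluster_id="", members=[(est_id, "+")],
                                    offsets={est_id: 0},
                                    seqs={est_id: canon}, consensus=canon,
                                    depth=np.ones(len(canon), dtype=int),
                                    flags=["unplaced"]))
            leftover.append(est_id)
        else:
            ov_id, ov_len, core = best
            ov = overlap_identity(core.consensus, seq, params.kmer,
                                  params.min_overlap)
            strand, off = ov[2], ov[3]
            canon = seq if strand == "+" else revcomp(seq)
            core.members.append((est_id, strand))
            core.members.sort()
            core.seqs[est_id] = canon
            core.offsets[est_id] = off
            base = min(core.offsets.values())
            core.offsets = {m: o - base for m, o in core.offsets.items()}
            call_consensus(core)
    cores.sort(key=lambda c: c.members[0][0])
    for i, core in enumerate(cores, 1):
        core.cluster_id = f"rcl{i:04d}"
    return cores, leftover


# ---------------------------------------------------------------------------
# consensus


def call_consensus(cluster: ESTCluster) -> str:
    """Per-column majority base; ties become IUPAC codes; gaps become N."""
    if not cluster.members:
        raise ValueError("empty cluster")
    length = max(cluster.offsets[m] + len(cluster.seqs[m])
                 for m, _ in cluster.members)
    counts = np.zeros((length, 4), dtype=int)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    bases = "ACGT"
    for m, _ in cluster.members:
        off = cluster.offsets[m]
        for i, ch in enumerate(cluster.seqs[m]):
            if ch in base_idx:
                counts[off + i, base_idx[ch]] += 1
    depth = counts.sum(axis=1)
    cons = []
    for pos in range(length):
        if depth[pos] == 0:
            cons.append("N")
            continue
        mx = counts[pos].max()
        top = frozenset(bases[k] for k in range(4) if counts[pos, k] == mx)
        cons.append(IUPAC[top] if len(top) > 1 else next(iter(top)))
    cluster.consensus = "".join(cons)
    cluster.depth = depth
    return cluster.consensus


# ---------------------------------------------------------------------------
# EST counting


def count_ests(cdnas: dict[str, str], ests: Sequence[ESTRecord],
               params: ClusterParams) -> pd.DataFrame:
    """Assign each EST to its single best-identity cDNA and count.

    Ties across genes leave the EST unassigned (reported in the
    'unassigned' pseudo-row); genes with zero ESTs are kept in the table
    (putatively non-expressed)."""
    counts = {g: 0 for g in cdnas}
    unassigned = 0
    for rec in sorted(ests, key=lambda r: r.est_id):
        seq = _trim(rec.seq)
        scored = []
        for gid in sorted(cdnas):
            ov = overlap_identity(cdnas[gid], seq, params.kmer,
                                  params.min_overlap)
            if ov and ov[0] >= params.seed_identity:
                scored.append((ov[0], ov[1], gid))
        if not scored:
            unassigned += 1
            continue
        scored.sort(key=lambda s: (-s[0], -s[1], s[2]))
        if len(scored) > 1 and scored[0][:2] == scored[1][:2]:
            unassigned += 1
            continue
        counts[scored[0][2]] += 1
    rows = [dict(gene_id=g, est_count=c,
                 status="putatively non-expressed" if c == 0 else "expressed")
            for g, c in sorted(counts.items())]
    rows.append(dict(gene_id="unassigned", est_count=unassigned, status="tie"))
    return pd.DataFrame(rows)
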