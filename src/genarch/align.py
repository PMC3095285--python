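"""Progressive protein multiple alignment (profile Needleman-Wunsch).

Self-contained aligner for family-sized inputs: a guide tree from 3-mer
composition distances (UPGMA), then profile-profile global alignment with
PAM250 expected-score columns and affine gaps (open -10, extend -1). The
horizontal gap state is vectorised with a running-maximum reformulation,
so each merge is O(L^2) numpy work rather than a Python triple loop.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from Bio.Align import substitution_matrices

from .seqs import AMINO_ACIDS

_AA_IDX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_PAM = substitution_matrices.load("PAM250")
_S = np.array([[float(_PAM[a, b]) for b in AMINO_ACIDS]
               for a in AMINO_ACIDS])

# Affine gap costs in raw PAM250 units. PAM250 entries are large (self
# scores 2..17), so weak penalties produce spurious register-shifting gaps
# between divergent-but-ungapped homologs; these values keep equal-length
# families gap-free up to ~50% divergence while still allowing terminal
# extensions (transit peptides, anchors) to open gaps.
GAP_OPEN = -14.0
GAP_EXT = -3.0
NEG = -1e30


def _profile(rows: list[str]) -> np.ndarray:
    """L x 20 frequency profile (gap mass dropped, columns renormalised
    by the number of sequences)."""
    L = len(rows[0])
    prof = np.zeros((L, 20))
    for r in rows:
        for i, ch in enumerate(r):
            j = _AA_IDX.get(ch)
            if j is not None:
                prof[i, j] += 1.0
    return prof / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str]
                    ) -> tuple[list[str], list[str]]:
    """Global affine profile alignment; returns gapped copies of both."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    S = pa @ _S @ pb.T                       # la x lb column-pair scores

    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)       # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)       # gap in A (consume B)
    Yk = np.zeros((la + 1, lb + 1), dtype=np.int32)   # Y origin column
    M[0, 0] = 0.0
    js = np.arange(lb + 1)
    Y[0, 1:] = GAP_OPEN + GAP_EXT * (js[1:] - 1)
    X[1:, 0] = GAP_OPEN + GAP_EXT * (np.arange(1, la + 1) - 1)
    for i in range(1, la + 1):
        X[i, 1:] = np.maximum(M[i - 1, 1:] + GAP_OPEN, X[i - 1, 1:] + GAP_EXT)
        prev_best = np.maximum.reduce([M[i - 1, :-1], X[i - 1, :-1],
                                       Y[i - 1, :-1]])
        M[i, 1:] = S[i - 1] + prev_best
        # Y[i, j] = GAP_OPEN + GAP_EXT*(j-1) + max_{k<j} (best_k - GAP_EXT*k)
        base = np.maximum(M[i, :-1], X[i, :-1])
        a = base - GAP_EXT * js[:-1]
        racc = np.maximum.accumulate(a)
        ridx = np.maximum.accumulate(
            np.where(a >= racc, js[:-1], 0))
        Y[i, 1:] = GAP_OPEN + GAP_EXT * (js[1:] - 1) + racc
        Yk[i, 1:] = ridx

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    ga: list[tuple[int, int]] = []   # (consumed_a, consumed_b) steps reversed
    while i > 0 or j > 0:
        if state == 0:               # match column
            ga.append((1, 1))
            pb_best = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(pb_best)) if (i or j) else 0
        elif state == 1:             # gap in B, consume A
            ga.append((1, 0))
            if M[i - 1, j] + GAP_OPEN >= X[i - 1, j] + GAP_EXT:
                state = 0
            i -= 1
        else:                        # gap in A, consume B (possibly a run)
            k = int(Yk[i, j])
            for _ in range(j - k):
                ga.append((0, 1))
            j = k
            state = 0 if M[i, j] >= X[i, j] else 1
            if i == 0 and j == 0:
                state = 0
    ga.reverse()
    pos_a = pos_b = 0
    cols_a, cols_b = [], []
    for da, db in ga:
        cols_a.append(pos_a if da else None)
        cols_b.append(pos_b if db else None)
        pos_a += da
        pos_b += db
    for r in rows_a:
        out_a.append("".join(r[c] if c is not None else "-" for c in cols_a))
    for r in rows_b:
        out_b.append("".join(r[c] if c is not None else "-" for c in cols_b))
    return out_a, out_b


def _kmer_vectors(seqs: list[str], k: int = 3) -> np.ndarray:
    vocab: dict[str, int] = {}
    rows = []
    for s in seqs:
        counts: dict[int, int] = {}
        for i in range(len(s) - k + 1):
            key = s[i:i + k]
            idx = vocab.setdefault(key, len(vocab))
            counts[idx] = counts.get(idx, 0) + 1
        rows.append(counts)
    mat = np.zeros((len(seqs), len(vocab)))
    for r, counts in enumerate(rows):
        for idx, c in counts.items():
            mat[r, idx] = c
    return mat


def progressive_align(seqs: dict[str, str]) -> dict[str, str]:
    """Align a family of protein sequences; deterministic."""
    names = sorted(seqs)
    if len(names) == 1:
        return dict(seqs)
    mat = _kmer_vectors([seqs[n] for n in names])
    if len(names) == 2:
        merges = [(0, 1)]
    else:
        d = pdist(mat, metric="cosine")
        d = np.nan_to_num(d, nan=1.0)
        merges = [(int(a), int(b)) for a, b, *_ in linkage(d, method="average")]
    groups: dict[int, list[str]] = {i: [n] for i, n in enumerate(names)}
    aligned: dict[int, list[str]] = {i: [seqs[n]] for i, n in enumerate(names)}
    nxt = len(names)
    for a, b in merges:
        ra, rb = _align_profiles(aligned[a], aligned[b])
        groups[nxt] = groups[a] + groups[b]
        aligned[nxt] = ra + rb
        del groups[a], groups[b], aligned[a], aligned[b]
        nxt += 1
    (gid,) = groups.keys() if len(groups) == 1 else (max(groups),)
    result = dict(zip(groups[gid], aligned[gid]))
    return {n: result[n] for n in names}
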