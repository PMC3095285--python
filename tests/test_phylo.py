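"""Distances, neighbor joining, minimum evolution, parsimony, bootstrap."""

import itertools

import numpy as np
import pytest

from genarch.phylo import (DistanceMatrix, SaturatedDistance,
                           bootstrap_support, distance_matrix,
                           minimum_evolution, nj, p_distance,
                           pam250_distance, parsimony_score, poisson_distance,
                           _ols_lengths, _tree_length)
from genarch.trees import (bipartitions, parse_newick, random_binary_tree,
                           to_graph, tree_distance_matrix)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# distances


def test_p_distance_identical_rows():
    assert p_distance({"a": "MKVL", "b": "MKVL"}, ("a", "b")) == 0.0


def test_p_distance_counts_mismatch_fraction():
    assert p_distance({"a": "AAAA", "b": "AAAT"}, ("a", "b")) == 0.25


def test_p_distance_uses_pairwise_deletion():
    assert p_distance({"a": "A-CD", "b": "AB-D"}, ("a", "b")) == 0.0


def test_p_distance_all_gap_columns_error():
    with pytest.raises(ValueError):
        p_distance({"a": "--", "b": "AB"}, ("a", "b"))


@pytest.mark.parametrize("p,expected", [
    (0.0, 0.0), (0.5, 0.693147), (0.95, 2.995732),
])
def test_poisson_closed_form(p, expected):
    assert poisson_distance(p) == pytest.approx(expected, abs=1e-6)


def test_poisson_saturation_flagged():
    with pytest.raises(SaturatedDistance):
        poisson_distance(1.0)


def test_poisson_correction_exceeds_p():
    for p in np.linspace(0.01, 0.95, 20):
        assert poisson_distance(p) > p
    assert poisson_distance(0.0) == 0.0


def test_pam250_identical_rows_zero():
    msa = {"a": "MKVLWAAGH" * 10, "b": "MKVLWAAGH" * 10}
    assert pam250_distance(msa, ("a", "b")) == pytest.approx(0.0, abs=1e-12)


def test_pam250_distance_grows_with_substitutions():
    rng = np.random.default_rng(3)
    s = "".join(AA[i] for i in rng.integers(0, 20, 100))
    q = list(s)
    prev = -1.0
    for step in range(10):
        for pos in range(step * 5, step * 5 + 5):
            q[pos] = AA[(AA.index(q[pos]) + 7) % 20]
        d = pam250_distance({"r": s, "q": "".join(q)}, ("r", "q"))
        assert d > prev
        prev = d


def test_unrelated_rows_saturate_or_exceed_two():
    rng = np.random.default_rng(4)
    a = "".join(AA[i] for i in rng.integers(0, 20, 200))
    b = "".join(AA[i] for i in rng.integers(0, 20, 200))
    try:
        assert pam250_distance({"a": a, "b": b}, ("a", "b")) > 2.0
    except SaturatedDistance:
        pass


def test_saturated_pairs_filled_and_listed():
    rng = np.random.default_rng(5)
    base = "".join(AA[i] for i in rng.integers(0, 20, 80))
    far = "".join(AA[(i + 9) % 20] for i in rng.integers(0, 20, 80))
    msa = {"a": base, "b": base[:-1] + "W", "c": far}
    dm = distance_matrix(msa, model="pam250")
    if dm.saturated_pairs:
        i, j = dm.labels.index("a"), dm.labels.index("c")
        finite_max = max(dm.d[dm.labels.index("a")][dm.labels.index("b")],
                         1e-9)
        assert dm.d[i, j] >= finite_max


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxon_closed_form():
    dm = DistanceMatrix(["A", "B", "C"],
                        np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
    tree = nj(dm)
    lengths = {c.name: c.length for c in tree.children}
    assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 4.0})


def test_four_taxon_additive_matrix_recovered_exactly():
    # tree ((A:1,B:2):1,(C:3,D:4))
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                 float)
    dm = DistanceMatrix(list("ABCD"), d)
    tree = nj(dm)
    assert bipartitions(tree) == {frozenset({"C", "D"})}
    _, induced = tree_distance_matrix(tree, list("ABCD"))
    assert np.abs(induced - d).max() < 1e-9


def test_equal_distance_matrix_is_deterministic():
    d = np.ones((5, 5)) - np.eye(5)
    dm = DistanceMatrix(list("ABCDE"), d)
    assert nj(dm).newick() == nj(dm).newick()


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        nj(DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float)))


def test_nj_inverts_random_additive_matrices():
    rng = np.random.default_rng(6)
    for _ in range(10):
        n = int(rng.integers(5, 13))
        tree = random_binary_tree(rng, n, (0.05, 1.0))
        labels, d = tree_distance_matrix(tree)
        out = nj(DistanceMatrix(labels, d))
        assert bipartitions(out) == bipartitions(tree)
        _, induced = tree_distance_matrix(out, labels)
        assert np.abs(induced - d).max() < 1e-9


def test_nj_matches_scikit_bio_topology():
    """Independent cross-check against an established implementation."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(7)
    tree = random_binary_tree(rng, 7, (0.1, 0.9))
    labels, d = tree_distance_matrix(tree)
    noisy = d + rng.normal(0, 0.01, d.shape)
    noisy = np.triu(noisy, 1)
    noisy = noisy + noisy.T
    ours = nj(DistanceMatrix(labels, noisy))
    ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=labels))
    ref_bips = set()
    names = set(labels)
    anchor = min(names)
    for node in ref.non_tips():
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(names - side)
        if 1 < len(side) < len(names) - 1:
            ref_bips.add(side)
    assert bipartitions(ours) == ref_bips


# ---------------------------------------------------------------------------
# minimum evolution


def test_me_keeps_nj_tree_on_additive_matrix():
    rng = np.random.default_rng(8)
    tree = random_binary_tree(rng, 6, (0.1, 0.8))
    labels, d = tree_distance_matrix(tree)
    dm = DistanceMatrix(labels, d)
    start = nj(dm)
    out = minimum_evolution(start, dm)
    assert bipartitions(out) == bipartitions(start)


def test_me_never_longer_than_nj_start():
    rng = np.random.default_rng(9)
    tree = random_binary_tree(rng, 7, (0.1, 0.8))
    labels, d = tree_distance_matrix(tree)
    noise = rng.normal(0, 0.01, d.shape)
    noise = np.triu(noise, 1)
    d = d + noise + noise.T
    dm = DistanceMatrix(labels, d)
    start = nj(dm)
    out = minimum_evolution(start, dm)
    assert _tree_length(to_graph(out), dm) <= \
        _tree_length(to_graph(start), dm) + 1e-9


def test_me_is_identity_for_three_taxa():
    dm = DistanceMatrix(["A", "B", "C"],
                        np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
    start = nj(dm)
    assert minimum_evolution(start, dm).newick(with_support=False) == \
        start.newick(with_support=False)


# ---------------------------------------------------------------------------
# parsimony


def test_identical_alignment_scores_zero():
    msa = {k: "MKVLW" for k in "ABCD"}
    tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert parsimony_score(msa, tree) == 0


def test_fitch_on_four_taxon_column():
    msa = {"A": "A", "B": "A", "C": "B", "D": "B"}
    assert parsimony_score(msa, parse_newick("((A:1,B:1):1,(C:1,D:1):1);")) == 1
    assert parsimony_score(msa, parse_newick("((A:1,C:1):1,(B:1,D:1):1);")) == 2


def test_score_invariant_under_rerooting():
    rng = np.random.default_rng(10)
    labels = [f"t{i}" for i in range(1, 7)]
    msa = {l: "".join(AA[i] for i in rng.integers(0, 4, 30)) for l in labels}
    tree = random_binary_tree(rng, 6)
    base = parsimony_score(msa, tree)
    from genarch.trees import reroot_at_leaf_edge
    for leaf in labels:
        assert parsimony_score(msa, reroot_at_leaf_edge(tree, leaf)) == base


def test_gaps_are_missing_data():
    msa = {"A": "A-", "B": "A-", "C": "BA", "D": "BA"}
    tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert parsimony_score(msa, tree) == 1


# ---------------------------------------------------------------------------
# bootstrap


def _two_clade_msa(seed, n_cols=500):
    rng = np.random.default_rng(seed)
    base1 = "".join(AA[i] for i in rng.integers(0, 20, n_cols))
    base2 = list(base1)
    for pos in rng.choice(n_cols, n_cols // 2, replace=False):
        base2[pos] = AA[int(rng.integers(20))]
    base2 = "".join(base2)

    def mut(s, n):
        s = list(s)
        for pos in rng.choice(len(s), n, replace=False):
            s[pos] = AA[int(rng.integers(20))]
        return "".join(s)

    return {"a1": base1, "a2": mut(base1, 10),
            "b1": base2, "b2": mut(base2, 10)}


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_two_clade_msa_gets_strong_central_support(seed):
    tree, dropped = bootstrap_support(_two_clade_msa(seed), n_reps=200,
                                      seed=seed)
    supports = [n.support for n in tree.walk()
                if n.support is not None]
    assert supports and min(supports) >= 99
    assert dropped == 0


def test_single_replicate_supports_are_binary():
    tree, _ = bootstrap_support(_two_clade_msa(4), n_reps=1, seed=9)
    for n in tree.walk():
        if n.support is not None:
            assert n.support in (0.0, 100.0)


def test_bootstrap_is_deterministic_per_seed():
    msa = _two_clade_msa(5)
    t1, _ = bootstrap_support(msa, n_reps=50, seed=7)
    t2, _ = bootstrap_support(msa, n_reps=50, seed=7)
    assert t1.newick() == t2.newick()
    supports = [n.support for n in t1.walk() if n.support is not None]
    assert all(0 <= s <= 100 for s in supports)


def test_end_to_end_topology_recovery_from_synthetic_families():
    """Poisson+NJ trees recover the generating topology for most families."""
    from genarch.align import progressive_align
    from genarch.simulate import EvolParams, simulate_family
    rng = np.random.default_rng(11)
    hits = 0
    n = 10
    for k in range(n):
        tree = random_binary_tree(rng, 6, (0.1, 0.25))
        p = EvolParams(tree=tree.newick(with_support=False), seed=k,
                       n_codons=320, n_ancestral_introns=3)
        fam = simulate_family(p)
        msa = progressive_align(fam.proteins)
        out = nj(distance_matrix(msa, model="poisson"))
        hits += bipartitions(out) == bipartitions(tree)
    assert hits >= int(0.9 * n)
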