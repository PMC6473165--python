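"""Distance models, neighbor joining, bootstrap, monophyly."""

import itertools
import math

import numpy as np
import pytest

from apvkit.phylo import (
    DistanceModel,
    Tree,
    TreeNode,
    bootstrap,
    distance_matrix,
    is_monophyletic,
    model_distance,
    nj_tree,
)
from apvkit.synth import _mutate
from apvkit.taxonomy import Alignment


def seq_with_counts(n: int, transitions: int, transversions: int) -> tuple[str, str]:
    a = "A" * n
    b = "G" * transitions + "C" * transversions + "A" * (n - transitions - transversions)
    return a, b


def test_k2p_closed_form():
    a, b = seq_with_counts(100, 10, 0)  # P=0.1, Q=0
    d = model_distance(a, b, DistanceModel("K2P"))
    assert d == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
    assert d == pytest.approx(0.1116, abs=5e-5)


def test_identical_sequences_zero_distance():
    s = "ACGT" * 25
    for m in ("p", "K2P", "TN93"):
        assert model_distance(s, s, DistanceModel(m)) == 0.0


def test_gamma_large_shape_converges_to_plain():
    a, b = seq_with_counts(200, 20, 6)
    plain = model_distance(a, b, DistanceModel("K2P"))
    gamma = model_distance(a, b, DistanceModel("K2P", gamma_shape=1e6))
    assert abs(plain - gamma) < 1e-6


def test_saturation_flagged_infinite():
    a = "A" * 40 + "C" * 40
    b = "G" * 40 + "T" * 40  # every site a transition: 1-2P-Q <= 0
    assert model_distance(a, b, DistanceModel("K2P")) == math.inf


def test_invariant_fraction_rescales():
    a, b = seq_with_counts(200, 10, 4)
    d0 = model_distance(a, b, DistanceModel("K2P"))
    d1 = model_distance(a, b, DistanceModel("K2P", prop_invariant=0.3))
    assert d1 > d0  # fewer variable sites must explain the same mismatches


def test_distance_symmetric_and_monotone():
    rng = np.random.default_rng(6)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    m = DistanceModel("TN93", gamma_shape=0.9)
    prev = 0.0
    for q in (0.02, 0.05, 0.1, 0.2):
        b = _mutate(base, q, 4.0, np.random.default_rng(1), False)
        d = model_distance(base, b, m)
        assert d == pytest.approx(model_distance(b, base, m))
        assert d >= prev
        prev = d


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def topology_bipartitions(pairs, labels) -> set:
    """Canonical internal bipartitions of the 5-taxon tree with two cherries."""
    all_l = frozenset(labels)
    ref = min(all_l)
    out = set()
    for pair in pairs:
        side = frozenset(pair)
        out.add(side if ref not in side else all_l - side)
    return out


def additive_matrix(pairs, lengths, labels):
    """Distances on the ((a1,a2),e,(b1,b2)) unrooted shape."""
    (a1, a2), (b1, b2) = pairs
    (e,) = [x for x in labels if x not in pairs[0] + pairs[1]]
    # edges: leaf stems la1, la2, lb1, lb2, le and internal iu (u-w), iv (w-v)
    la1, la2, lb1, lb2, le, iu, iv = lengths
    stem = {a1: la1, a2: la2, b1: lb1, b2: lb2, e: le}
    extra = {a1: iu, a2: iu, b1: iv, b2: iv, e: 0.0}  # distance from cherry node to w
    n = len(labels)
    D = np.zeros((n, n))
    idx = {l: i for i, l in enumerate(labels)}
    for x, y in itertools.combinations(labels, 2):
        if {x, y} == set(pairs[0]) or {x, y} == set(pairs[1]):
            d = stem[x] + stem[y]
        else:
            d = stem[x] + extra[x] + extra[y] + stem[y]
        D[idx[x], idx[y]] = D[idx[y], idx[x]] = d
    return D


def all_five_taxon_topologies(labels):
    out = []
    for pa in itertools.combinations(labels, 2):
        rest = [x for x in labels if x not in pa]
        for pb in itertools.combinations(rest, 2):
            key = frozenset([frozenset(pa), frozenset(pb)])
            if key not in {frozenset([frozenset(a), frozenset(b)]) for a, b in out}:
                out.append((pa, pb))
    return out


def ls_fit_sse(pairs, D, labels):
    """Ordinary least-squares branch fit of one topology; returns SSE."""
    (a1, a2), (b1, b2) = pairs
    (e,) = [x for x in labels if x not in pairs[0] + pairs[1]]
    cols = [a1, a2, b1, b2, e, "iu", "iv"]
    rows, target = [], []
    idx = {l: i for i, l in enumerate(labels)}
    on_a = {a1, a2}
    for x, y in itertools.combinations(labels, 2):
        r = np.zeros(7)
        r[cols.index(x)] = 1
        r[cols.index(y)] = 1
        if {x, y} != on_a and {x, y} != {b1, b2}:
            for z in (x, y):
                if z in on_a:
                    r[5] = 1
                if z in (b1, b2):
                    r[6] = 1
        rows.append(r)
        target.append(D[idx[x], idx[y]])
    A = np.array(rows)
    sol, *_ = np.linalg.lstsq(A, np.array(target), rcond=None)
    return float(np.sum((A @ sol - np.array(target)) ** 2))


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    t = nj_tree(D, list("ABC"))
    lengths = {c.name: c.length for c in t.root.children}
    assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
    assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
    assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)


def test_nj_four_taxon_additive_recovery():
    # planted tree ((A:1,B:2):3,(C:1,D:2)) as an additive matrix
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 3], [6, 7, 3, 0]], float
    )
    t = nj_tree(D, list("ABCD"))
    assert t.bipartitions() == {frozenset("CD")}
    assert is_monophyletic(t, {"A", "B"}) and not is_monophyletic(t, {"A", "C"})


def test_nj_input_validation():
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float), list("ABC"))
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), list("AB"))


@pytest.mark.parametrize("seed", range(10))
def test_nj_equals_brute_force_least_squares(seed):
    labels = list("ABCDE")
    rng = np.random.default_rng(seed)
    topos = all_five_taxon_topologies(labels)
    pairs = topos[rng.integers(0, len(topos))]
    lengths = rng.uniform(0.5, 3.0, 7)
    D = additive_matrix(pairs, lengths, labels)
    sses = {p: ls_fit_sse(p, D, labels) for p in topos}
    best = min(sses, key=sses.get)
    assert sses[best] == pytest.approx(0.0, abs=1e-18)
    t = nj_tree(D, labels)
    assert t.bipartitions() == topology_bipartitions(best, labels)


def test_nj_matches_dendropy_oracle():
    dendropy = pytest.importorskip("dendropy")
    from dendropy.calculate import treecompare

    rng = np.random.default_rng(23)
    root = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
    rows = [_mutate(root, q, 2.0, np.random.default_rng(i), False) for i, q in enumerate((0.02, 0.05, 0.1, 0.15, 0.2, 0.25))]
    ids = [f"t{i}" for i in range(6)]
    aln = Alignment(ids, rows)
    D = distance_matrix(aln, DistanceModel("p"))
    mine = nj_tree(D, ids)

    csv = "," + ",".join(ids) + "\n"
    for i, r in enumerate(ids):
        csv += r + "," + ",".join(str(D[i, j]) for j in range(6)) + "\n"
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=io.StringIO(csv))
    ref = pdm.nj_tree()
    tns = ref.taxon_namespace
    mine_d = dendropy.Tree.get(data=mine.newick(), schema="newick", taxon_namespace=tns)
    ref.encode_bipartitions()
    mine_d.encode_bipartitions()
    assert treecompare.symmetric_difference(ref, mine_d) == 0


# ---------------------------------------------------------------------------
# Bootstrap and monophyly
# ---------------------------------------------------------------------------

def two_clade_alignment(seed=0, n=300):
    rng = np.random.default_rng(seed)
    root = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    anc_a = _mutate(root, 0.2, 2.0, rng, False)
    anc_b = _mutate(root, 0.2, 2.0, rng, False)
    rows = [_mutate(anc_a, 0.01, 2.0, rng, False) for _ in range(3)]
    rows += [_mutate(anc_b, 0.01, 2.0, rng, False) for _ in range(3)]
    return Alignment(["a1", "a2", "a3", "b1", "b2", "b3"], rows)


def test_bootstrap_supports_planted_split():
    aln = two_clade_alignment()
    tree, bs = bootstrap(aln, DistanceModel("K2P"), n_reps=200, seed=7)
    key = frozenset(["b1", "b2", "b3"])  # canonical side (excludes 'a1')
    assert bs.support[key] >= 95.0


def test_bootstrap_determinism_and_single_rep():
    aln = two_clade_alignment(seed=5)
    _, b1 = bootstrap(aln, DistanceModel("p"), n_reps=25, seed=13)
    _, b2 = bootstrap(aln, DistanceModel("p"), n_reps=25, seed=13)
    assert b1.support == b2.support
    _, single = bootstrap(aln, DistanceModel("p"), n_reps=1, seed=1)
    assert set(single.support.values()) <= {0.0, 100.0}


def test_bootstrap_needs_four_sequences():
    aln = Alignment(["a", "b", "c"], ["ACGT" * 5] * 3)
    with pytest.raises(ValueError, match="< 4"):
        bootstrap(aln, n_reps=2, seed=0)


def test_monophyly_examples():
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 3], [6, 7, 3, 0]], float
    )
    t = nj_tree(D, list("ABCD"))
    assert is_monophyletic(t, {"A"})
    assert is_monophyletic(t, {"A", "B"})
    assert not is_monophyletic(t, {"A", "C"})
    with pytest.raises(ValueError, match="unknown"):
        is_monophyletic(t, {"Z"})
    with pytest.raises(ValueError):
        is_monophyletic(t, {"A", "B", "C", "D"})


def test_monophyly_matches_exhaustive_enumeration():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(31)
    labels = [f"x{i}" for i in range(6)]
    for rep in range(5):
        M = rng.uniform(1, 10, (6, 6))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        t = nj_tree(D, labels)
        dt = dendropy.Tree.get(data=t.newick(), schema="newick")
        dt.encode_bipartitions()
        sides = set()
        for edge in dt.preorder_edge_iter():
            if edge.head_node is dt.seed_node:
                continue
            leaves = frozenset(
                lf.taxon.label for lf in edge.head_node.leaf_iter()
            )
            sides.add(leaves)
        full = frozenset(labels)
        for r in range(1, 6):
            for sub in itertools.combinations(labels, r):
                s = frozenset(sub)
                want = s in sides or (full - s) in sides or len(s) == 1
                assert is_monophyletic(t, s) == want


def test_outgroup_rooted_interpretation():
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 3], [6, 7, 3, 0]], float
    )
    t = nj_tree(D, list("ABCD"))
    assert is_monophyletic(t, {"A", "B"}, outgroup={"D"})
    assert not is_monophyletic(t, {"A", "D"}, outgroup={"D"})


def test_newick_output_parses(tmp_path):
    D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
    t = nj_tree(D, ["l1", "l2", "l3"])
    text = t.newick()
    assert text.endswith(";") and "l1" in text
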