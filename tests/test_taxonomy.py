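"""p-distance identities, demarcation cascade, substitution classing."""

import itertools

import numpy as np
import pytest

from apvkit.synth import (
    SENSE_CODONS,
    ClusterDesign,
    EvolSpec,
    evolve_alignment,
)
from apvkit.taxonomy import (
    Alignment,
    DemarcationConfig,
    align_pair,
    assign_rank,
    cluster_types,
    group_mean_identity,
    p_distance,
    pairwise_identity,
    substitution_summary,
)

RECOVERY_IDENTITIES = {
    # within-subtype divergence 0.2%, within-type 5%, within-species 20%,
    # within-genus 35%, between-genus 45%
    "subtype": 99.8,
    "type": 95.0,
    "species": 80.0,
    "genus": 65.0,
    "between_genus": 55.0,
}


def random_root(seed: int, n_codons: int = 600) -> str:
    rng = np.random.default_rng(seed)
    return "".join(SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons))


def test_p_distance_examples():
    assert p_distance("A" * 100, "A" * 100) == 0.0
    b = "C" + "A" * 99
    assert p_distance("A" * 100, b) == 0.01
    with pytest.raises(ValueError, match="comparable"):
        p_distance("NN--", "AC-G")


def test_p_distance_pairwise_deletion_oracle():
    rng = np.random.default_rng(9)
    alphabet = "ACGTN-"
    for _ in range(50):
        n = int(rng.integers(10, 120))
        a = "".join(alphabet[i] for i in rng.integers(0, 6, n))
        b = "".join(alphabet[i] for i in rng.integers(0, 6, n))
        comp = [(x, y) for x, y in zip(a, b) if x in "ACGT" and y in "ACGT"]
        if not comp:
            with pytest.raises(ValueError):
                p_distance(a, b)
            continue
        want = sum(1 for x, y in comp if x != y) / len(comp)
        assert p_distance(a, b) == pytest.approx(want)


def test_group_mean_identity_singletons_and_enumeration():
    # two singleton groups differing at 16% of columns -> 84.0
    a = "A" * 100
    b = "C" * 16 + "A" * 84
    aln = Alignment(["x", "y"], [a, b])
    m = group_mean_identity(aln, {"x": "G1", "y": "G2"})
    assert m.get("G1", "G2") == pytest.approx(84.0)
    assert m.get("G1", "G1") == 100.0

    # 2x2 groups: the entry equals the mean of the four cross pairs
    rng = np.random.default_rng(1)
    rows = ["".join("ACGT"[i] for i in rng.integers(0, 4, 60)) for _ in range(4)]
    aln = Alignment(list("abcd"), rows)
    groups = {"a": "G", "b": "G", "c": "H", "d": "H"}
    m = group_mean_identity(aln, groups)
    pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
    want = 100 * (1 - np.mean([p_distance(rows[i], rows[j]) for i, j in pairs]))
    assert m.get("G", "H") == pytest.approx(want)
    with pytest.raises(ValueError, match="empty group"):
        group_mean_identity(aln, {"a": "G", "zz": "H"})  # H has no members present


@pytest.mark.parametrize(
    "identity,expected",
    [
        (99.5, "same_subtype"),
        (91.0, "same_type"),
        (90.0, "same_species"),  # strict boundary: exactly 90 is NOT same type
        (75.0, "same_species"),
        (65.0, "same_genus"),
        (55.0, "different_genus"),
        (100.0, "same_subtype"),
    ],
)
def test_assign_rank_cascade(identity, expected):
    assert assign_rank(identity) == expected


def test_assign_rank_inclusive_boundary():
    cfg = DemarcationConfig(strict_inequality=False)
    assert assign_rank(90.0, cfg) == "same_type"


def test_cluster_types_trivial_cases():
    rows = ["ACGTACGT" * 10] * 3
    aln = Alignment(["a", "b", "c"], rows)
    assign = cluster_types(aln)
    assert len(assign.clusters["subtype"]) == 1

    a = "ACGTACGTAC" * 10
    b = ("TGCA" * 25)[:100]
    aln2 = Alignment(["a", "b"], [a, b])
    if 100 * (1 - p_distance(a, b)) < 60:
        assert len(cluster_types(aln2).clusters["genus"]) == 2


def test_cluster_types_input_order_invariant():
    aln, labels, _ = evolve_alignment(
        random_root(3), EvolSpec(seed=3, design=ClusterDesign(identities=dict(RECOVERY_IDENTITIES)))
    )
    a1 = cluster_types(aln)
    perm = list(reversed(range(len(aln.ids))))
    aln2 = Alignment([aln.ids[i] for i in perm], [aln.rows[i] for i in perm])
    a2 = cluster_types(aln2)
    for rank in ("genus", "species", "type", "subtype"):
        assert {frozenset(c) for c in a1.clusters[rank]} == {
            frozenset(c) for c in a2.clusters[rank]
        }


@pytest.mark.parametrize("seed", range(5))
def test_cluster_types_recovers_planted_partition(seed):
    aln, labels, _ = evolve_alignment(
        random_root(seed),
        EvolSpec(seed=seed, design=ClusterDesign(identities=dict(RECOVERY_IDENTITIES))),
    )
    assign = cluster_types(aln)
    for rank in ("genus", "species", "type", "subtype"):
        truth = {}
        for x in aln.ids:
            truth.setdefault(labels[x][rank], set()).add(x)
        assert {frozenset(s) for s in truth.values()} == {
            frozenset(c) for c in assign.clusters[rank]
        }


def test_substitution_summary_examples():
    s = substitution_summary("GGA", "GGG")
    assert (s.n_sub, s.n_syn, s.n_nonsyn) == (1, 1, 0)
    s = substitution_summary("ATG", "ACG")
    assert (s.n_sub, s.n_syn, s.n_nonsyn) == (1, 0, 1)


def test_substitution_summary_matches_translate_oracle():
    from Bio.Seq import Seq

    rng = np.random.default_rng(12)
    for _ in range(30):
        n = int(rng.integers(5, 60))
        a = "".join(SENSE_CODONS[i] for i in rng.integers(0, 61, n))
        # mutate a few positions
        b = list(a)
        for _ in range(int(rng.integers(0, 12))):
            p = int(rng.integers(0, 3 * n))
            b[p] = "ACGT"[rng.integers(0, 4)]
        b = "".join(b)
        s = substitution_summary(a, b)
        n_sub = n_syn = 0
        for i in range(0, 3 * n, 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            d = sum(x != y for x, y in zip(ca, cb))
            n_sub += d
            if d and str(Seq(ca).translate()) == str(Seq(cb).translate()):
                n_syn += d
        assert (s.n_sub, s.n_syn) == (n_sub, n_syn)
        assert s.n_syn + s.n_nonsyn == s.n_sub


def test_substitution_summary_frame_and_identity():
    a = "GGGA" + "TTT" * 10
    b = "GGGA" + "TTC" * 10
    s = substitution_summary(a, b, frame_offset=1)
    assert s.n_sub == 10 and s.n_nonsyn == 0
    assert s.identity_pct == pytest.approx(100 * (1 - 10 / 33))


def test_identity_symmetry_and_self():
    rng = np.random.default_rng(8)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    b = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    aln = Alignment(["a", "b"], [a, b])
    m = pairwise_identity(aln)
    assert m.values[0, 1] == m.values[1, 0]
    assert m.values[0, 0] == 100.0


def test_bundled_aligner_scores():
    a, b = align_pair("ACGTACGT", "ACGACGT")
    assert len(a) == len(b)
    assert a.replace("-", "") == "ACGTACGT"
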