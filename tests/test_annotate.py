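"""ORF calling, L1-start detection, positional gene naming."""

import numpy as np
import pytest

from apvkit.annotate import (
    MIN_AA_ACCESSORY,
    OrfCall,
    assign_orf_names,
    annotate_genome,
    detect_l1_start,
    find_orfs,
    find_splice_acceptors,
)
from apvkit.genome import CircularGenome, Interval, STOP_CODONS
from apvkit.synth import GenomeSpec, generate_genome


def test_find_orfs_single_linear():
    g = CircularGenome("g", "ATGAAATAA", "linear")
    orfs = find_orfs(g, min_aa=2)
    assert len(orfs) == 1
    o = orfs[0]
    assert (o.iv.start, o.iv.end, o.aa_len) == (1, 9, 2)


def test_find_orfs_gtg_gating():
    g = CircularGenome("g", "GTGAAATAA", "linear")
    assert find_orfs(g, min_aa=2, allow_gtg=False) == []
    orfs = find_orfs(g, min_aa=2, allow_gtg=True)
    assert len(orfs) == 1 and orfs[0].start_codon == "GTG"


def test_find_orfs_wraps_origin():
    # ATG begins 2 nt before the end; the ORF runs across the origin
    body = "CCC" * 4
    g = CircularGenome("g", "GAAATAACCC" + body + "AT", "circular")
    orfs = [o for o in find_orfs(g, min_aa=2) if o.iv.wraps_origin]
    assert orfs, "expected a wrap-around ORF"
    o = orfs[0]
    assert o.iv.start == g.length_nt - 1 and o.iv.end == 7


def _orf_oracle(seq: str, min_aa: int) -> set:
    """Replicated-sequence scan written independently of the implementation.

    A start is maximal when it is the first ATG after the previous in-frame
    stop *on the circle*; recording starts only from the middle copy of the
    tripled sequence gives each one its true circular upstream context.
    """
    L = len(seq)
    scan = seq * 3
    found = set()
    for frame in range(3):
        pending = None
        for i in range(frame, 3 * L - 2, 3):
            c = scan[i : i + 3]
            if c in STOP_CODONS:
                if (
                    pending is not None
                    and L <= pending < 2 * L
                    and (i + 3 - pending) <= L
                    and (i + 3 - pending) // 3 - 1 >= min_aa
                ):
                    found.add((pending % L + 1, (i + 2) % L + 1))
                pending = None
            elif pending is None and c == "ATG":
                pending = i
    return found


def test_find_orfs_matches_doubled_oracle():
    rng = np.random.default_rng(5)
    for _ in range(25):
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(60, 300))))
        g = CircularGenome("g", s, "circular")
        got = {(o.iv.start, o.iv.end) for o in find_orfs(g, min_aa=5)}
        assert got == _orf_oracle(s, 5)


def test_splice_acceptor_examples():
    g = CircularGenome("g", "TTTTTTTTTTTTAG", "linear")
    hits = find_splice_acceptors(g)
    assert any(h.pos == 14 and h.score == 1.0 for h in hits)
    g = CircularGenome("g", "AAAAAAAAAAAAAG", "linear")
    hits = [h for h in find_splice_acceptors(g) if h.pos == 14]
    assert hits[0].score == 0.0


def test_splice_acceptor_counting_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        g = CircularGenome("g", s, "circular")
        for h in find_splice_acceptors(g, window=12):
            j = h.pos - 1
            assert s[(j - 1) % 80] == "A" and s[j] == "G"
            up = [s[(j - 1 - k) % 80] for k in range(1, 13)]
            assert h.score == sum(1 for b in up if b in "CT") / 12


def _mk_candidate(g, start0, codon="ATG", min_aa=1):
    # candidate ORF built directly for detect_l1_start fixtures
    L = g.length_nt
    j = start0 + 3
    scan = g.seq + g.seq
    while scan[j : j + 3] not in STOP_CODONS:
        j += 3
    from apvkit.annotate import _make_orf

    return _make_orf(g, start0, j + 2, codon)


def test_detect_l1_start_prefers_atg_overlap_then_length():
    # L2 stop TAA at 10..12 (1-based); two ATG candidates overlap it
    s = "ATGAAAAAATAATGGCCGCCGCCTAAATGCCGCCGCCGCCGCCTAACCCCCC"
    g = CircularGenome("g", s, "circular")
    l2 = _mk_candidate(g, 0)
    c_short = _mk_candidate(g, 11)  # ATG at 12..14 overlaps stop by 1 nt
    # a longer candidate that does NOT overlap
    c_far = _mk_candidate(g, 26)
    chosen = detect_l1_start(g, l2, [c_far, c_short], [])
    assert chosen is c_short and chosen.name == "L1"


def test_detect_l1_start_two_overlap_candidates_longer_wins():
    # stop TGA admits ATG starts at both stop-1 and stop+2
    s = "ATGAAATGATGCCGCCGCCTAACCCCCC"
    g = CircularGenome("g", s, "circular")
    l2 = _mk_candidate(g, 0)  # ATG AAA TGA
    c_a = _mk_candidate(g, 5)
    c_b = _mk_candidate(g, 8)
    assert c_a.aa_len > c_b.aa_len
    chosen = detect_l1_start(g, l2, [c_b, c_a], [])
    assert chosen is c_a


def test_detect_l1_start_error_without_candidates():
    s = "ATGAAAAAATAATGGCCGCCGCCTAACCCCCCCCCCCCCCCCCCCCCCCCCC"
    g = CircularGenome("g", s, "circular")
    l2 = _mk_candidate(g, 0)
    with pytest.raises(ValueError, match="L1 not found"):
        detect_l1_start(g, l2, [], [])


def test_detect_l1_start_gtg_requires_acceptor(gtg_genome):
    g, truth = gtg_genome
    ann = assign_orf_names(g)
    l1 = ann.orf("L1")
    assert l1.start_codon == "GTG"
    assert l1.iv == truth.orf("L1").iv


@pytest.mark.parametrize("seed", range(8))
def test_assign_orf_names_recovers_generator_truth(seed):
    g, truth = generate_genome(GenomeSpec(seed=100 + seed))
    ann = assign_orf_names(g)
    got = {(o.name, o.iv.start, o.iv.end) for o in ann.orfs}
    want = {(o.name, o.iv.start, o.iv.end) for o in truth.orfs}
    assert got == want
    assert ann.lcr == truth.lcr and ann.ncr == truth.ncr


def test_orfs_retranslate_without_internal_stops(default_genome):
    g, _ = default_genome
    ann = assign_orf_names(g)
    for o in ann.orfs:
        body = o.protein.seq.rstrip("*")
        assert "*" not in body


def test_missing_e6_reported_not_silent():
    g, truth = generate_genome(GenomeSpec(seed=21, omit_orfs=("E6",)))
    ann = assign_orf_names(g)
    assert ann.orf("E6") is None and "E6" in ann.missing
    for name in ("E7", "E1", "E2", "L2", "L1", "E9"):
        assert ann.orf(name) is not None


def test_ncr_below_floor_absent():
    g, truth = generate_genome(GenomeSpec(seed=22, ncr_len=1))
    ann = assign_orf_names(g)
    assert ann.ncr is None and truth.ncr is None


def test_rotation_equivariance(default_genome):
    """Rotating the circle rotates coordinates but changes nothing else."""
    g, _ = default_genome
    ann = assign_orf_names(g)
    L = g.length_nt
    for offset in (1, 137, L // 2):
        rot = g.rotated(offset)
        ann_r = assign_orf_names(rot)
        for o in ann.orfs:
            o2 = ann_r.orf(o.name)
            assert o2 is not None
            assert (o.iv.start - 1 - offset) % L + 1 == o2.iv.start
            assert o2.protein.seq == o.protein.seq


def test_annotate_genome_reports_e6_first(default_genome):
    g, _ = default_genome
    rot, ann = annotate_genome(g.rotated(500))
    assert ann.orf("E6").iv.start == 1
    assert ann.rotation_offset != 0
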