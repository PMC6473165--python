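"""Synthetic avian-papillomavirus-like data with known ground truth.

Three generators provide the test substrate for the rest of the package:

* :func:`generate_genome` — a circular genome with the canonical APV layout
  (E6-E7-E1(E9 nested)-E2-NCR-L2-L1-LCR, all on one strand), planted
  protein and regulatory motifs at known coordinates, the L2-stop/L1-start
  codon overlap (ATG or the puffin-like GTG variant), and no spurious ORFs
  or motif hits: non-coding filler is rejection-sampled and coding regions
  are locally repaired until the maximal-ORF scan returns exactly the
  planted complement.
* :func:`evolve_alignment` — gapless alignments evolved from a root coding
  sequence under a transition-biased (K2P-like) substitution process, with
  divergence calibrated by bisection to hit target identities at nested
  subtype/type/species/genus levels, optionally restricted to synonymous
  changes.
* :func:`generate_cohort` — individual-level cohorts with level-specific
  Bernoulli prevalence.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .annotate import GenomeAnnotation, OrfCall
from .epi import CohortTable
from .genome import STOP_CODONS, CircularGenome, Interval, ProteinSeq
from .motifs import builtin_patterns, scan
from .phylo import Tree, TreeNode
from .taxonomy import Alignment

log = logging.getLogger(__name__)

SENSE_CODONS = sorted(standard_dna_table.forward_table)
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    CODONS_BY_AA.setdefault(standard_dna_table.forward_table[_codon], []).append(_codon)
AA_LETTERS = sorted(CODONS_BY_AA)

#: synonymous single-base alternatives: codon -> position -> other bases
SYN_SINGLE: dict[str, dict[int, str]] = {}
for _codon in SENSE_CODONS:
    aa = standard_dna_table.forward_table[_codon]
    alts: dict[int, str] = {}
    for pos in range(3):
        opts = ""
        for b in "ACGT":
            if b != _codon[pos]:
                alt = _codon[:pos] + b + _codon[pos + 1 :]
                if standard_dna_table.forward_table.get(alt) == aa:
                    opts += b
        if opts:
            alts[pos] = opts
    SYN_SINGLE[_codon] = alts

MIN_AA_ACCESSORY = 60

DEFAULT_ORF_AA = {"E6": 90, "E7": 120, "E1": 650, "E9": 70, "E2": 380, "L2": 470, "L1": 510}

#: motifs planted per protein (aa index -> residues); Walker boxes sit well
#: outside the E9 window, which occupies E1 codons ~10-81
PROTEIN_PLANTS: dict[str, list[tuple[int, str]]] = {
    "E6": [(5, "CAAC"), (49, "CAAC")],  # CXXC pairs, 40-residue spacer
    "E7": [(20, "LACAE"), (60, "CAAC"), (104, "CAAC")],  # pRb LXCXE + zinc
    "E1": [(430, "GATDSGKT"), (470, "LLDD"), (500, "LTSN")],  # Walker A/B/C
    "E2": [(300, "GATAQLKTIRAR")],  # DNA-binding domain
    "L2": [(8, "RAKR"), (120, "GAAAG"), (200, "FANPAF"), (300, "DQILQ")],
}

#: which scan pattern corresponds to each planted motif, for omission checks
PLANT_PATTERNS: dict[str, list[str]] = {
    "E6": ["e6_zinc"],
    "E7": ["e7_prb", "e6_zinc"],
    "E1": ["walker_a", "walker_b", "walker_c"],
    "E2": ["e2_dbd"],
    "L2": ["furin", "gxxxg", "snx17", "syntaxin18"],
}

#: plants grouped by the pattern they realize, so single motifs can be omitted
PLANT_BY_PATTERN: dict[str, list[tuple[str, int, str]]] = {
    "e6_zinc": [("E6", 5, "CAAC"), ("E6", 49, "CAAC"), ("E7", 60, "CAAC"), ("E7", 104, "CAAC")],
    "e7_prb": [("E7", 20, "LACAE")],
    "walker_a": [("E1", 430, "GATDSGKT")],
    "walker_b": [("E1", 470, "LLDD")],
    "walker_c": [("E1", 500, "LTSN")],
    "e2_dbd": [("E2", 300, "GATAQLKTIRAR")],
    "furin": [("L2", 8, "RAKR")],
    "gxxxg": [("L2", 120, "GAAAG")],
    "snx17": [("L2", 200, "FANPAF")],
    "syntaxin18": [("L2", 300, "DQILQ")],
}


@dataclass
class GenomeSpec:
    length_target: int = 7500
    orf_lengths: dict = field(default_factory=lambda: dict(DEFAULT_ORF_AA))
    ncr_len: int = 30
    lcr_len: int = 600
    e2bs_atypical_n: int = 5
    e2bs_typical_n: int = 0
    tata: bool = True
    polya: bool = True
    l1_start: str = "ATG"
    omit_orfs: tuple = ()
    omit_motifs: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l1_start not in ("ATG", "GTG"):
            raise ValueError("l1_start must be ATG or GTG")
        if not 0 <= self.e2bs_atypical_n <= 9 or not 0 <= self.e2bs_typical_n <= 3:
            raise ValueError("E2BS copy numbers out of range")
        if not 1 <= self.ncr_len <= 80:
            raise ValueError("ncr_len out of range")


# ---------------------------------------------------------------------------
# Protein / nucleotide construction helpers
# ---------------------------------------------------------------------------

def _rand_protein(rng: np.random.Generator, n: int) -> list[str]:
    return [AA_LETTERS[i] for i in rng.integers(0, len(AA_LETTERS), n)]


def _reverse_translate(rng: np.random.Generator, aa: list[str]) -> list[str]:
    out = []
    for a in aa:
        opts = CODONS_BY_AA[a]
        out.append(opts[rng.integers(0, len(opts))])
    return out


def _build_protein(
    rng: np.random.Generator,
    name: str,
    n: int,
    omit: set[str],
    max_tries: int = 200,
) -> tuple[list[str], set[int]]:
    """Random protein with its motif plants; returns (aa list, planted aa set).

    Omitted motifs are left unplanted and the sequence is re-drawn until it
    carries no accidental hit of them.
    """
    pats = builtin_patterns()
    plants = [
        (pos, text)
        for pname, entries in PLANT_BY_PATTERN.items()
        for (gene, pos, text) in entries
        if gene == name and pname not in omit
    ]
    check = [p for p in PLANT_PATTERNS.get(name, []) if p in omit]
    for _ in range(max_tries):
        aa = _rand_protein(rng, n)
        aa[0] = "M"
        planted: set[int] = {0}
        for pos, text in plants:
            for k, ch in enumerate(text):
                aa[pos + k] = ch
                planted.add(pos + k)
        s = "".join(aa)
        if all(not scan(s, pats[p]) for p in check):
            return aa, planted
    raise RuntimeError(f"could not draw {name} avoiding omitted motifs")


def _pyrimidine_filler(rng: np.random.Generator, n: int) -> str:
    return "".join("CT"[i] for i in rng.integers(0, 2, n))


def _lcr(
    rng: np.random.Generator, spec: GenomeSpec, max_tries: int = 1000
) -> tuple[str, dict[str, list[int]]]:
    """LCR with exact planted regulatory-site counts and no ATG anywhere.

    Returns the sequence and 0-based site start offsets per pattern.
    """
    pats = builtin_patterns()

    def site(kind: str) -> str:
        if kind == "e2bs_typical":
            return "ACC" + "".join("ACT"[i] for i in rng.integers(0, 3, 6)) + "GGT"
        if kind == "e2bs_atypical":
            return "ACC" + "".join("ACT"[i] for i in rng.integers(0, 3, 4)) + "GGT"
        if kind == "tata_box":
            w = "AT"
            return "TATA" + w[rng.integers(0, 2)] + "A" + w[rng.integers(0, 2)]
        return "A" + "AT"[rng.integers(0, 2)] + "TAAA"  # polya

    kinds = (
        ["tata_box"] * int(spec.tata)
        + ["e2bs_typical"] * spec.e2bs_typical_n
        + ["e2bs_atypical"] * spec.e2bs_atypical_n
        + ["polya_site"] * int(spec.polya)
    )
    want = {k: kinds.count(k) for k in ("tata_box", "e2bs_typical", "e2bs_atypical", "polya_site")}
    for attempt in range(max_tries):
        order = list(kinds)
        rng.shuffle(order)
        sites = [site(k) for k in order]
        filler_total = spec.lcr_len - sum(len(s) for s in sites)
        n_chunks = len(sites) + 1
        if filler_total < 2 * n_chunks:
            raise ValueError("lcr_len too small for the requested sites")
        extra = rng.multinomial(filler_total - 2 * n_chunks, [1.0 / n_chunks] * n_chunks)
        fillers = [2 + int(e) for e in extra]
        parts, offsets, cursor = [], {k: [] for k in want}, 0
        for i, s in enumerate(sites):
            f = "".join("CAT"[j] for j in rng.integers(0, 3, fillers[i]))
            parts.append(f)
            cursor += len(f)
            offsets[order[i]].append(cursor)
            parts.append(s)
            cursor += len(s)
        parts.append("".join("CAT"[j] for j in rng.integers(0, 3, fillers[-1])))
        lcr = "".join(parts)
        assert len(lcr) == spec.lcr_len
        if "ATG" in lcr:
            continue
        ok = True
        for k, n in want.items():
            found = {h.iv.start - 1 for h in scan(lcr, pats[k])}
            if len(found) != n or not {o for o in offsets[k]} <= found:
                ok = False
                break
        if ok:
            return lcr, offsets
    raise RuntimeError("LCR rejection sampling exhausted")


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------

class _Assembly:
    """Mutable genome under construction, with gene and protection maps."""

    def __init__(self) -> None:
        self.seq: list[str] = []
        self.genes: dict[str, tuple[int, int]] = {}  # name -> (start0, end0 incl. stop)
        self.protected: set[int] = set()
        self.e9_window: tuple[int, int] | None = None  # [s, e) 0-based

    def append(self, s: str) -> int:
        start = len(self.seq)
        self.seq.extend(s)
        return start

    def protect(self, start: int, length: int) -> None:
        self.protected.update(range(start, start + length))


def _embed_e9(
    rng: np.random.Generator, e1_codons: list[str], e9_aa: int, max_tries: int = 2000
) -> tuple[list[str], tuple[int, int]]:
    """Write an E9 ORF into the E1 CDS at frame offset +1 (E1-codon 10 + 1 nt).

    The E9 reading frame gets ATG + sense codons + TAA; E1 codons overlapping
    the window are then repaired to stay stop-free by re-drawing E9 codons.
    """
    s = 31  # 0-based nt offset of the E9 ATG within the E1 CDS
    n_nt = 3 * (e9_aa + 1)
    nt = list("".join(e1_codons))
    e9 = ["ATG"] + [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), e9_aa - 1)] + ["TAA"]

    def write() -> None:
        nt[s : s + n_nt] = list("".join(e9))

    write()
    first_c, last_c = s // 3, (s + n_nt - 1) // 3
    for _ in range(max_tries):
        bad = None
        for c in range(first_c, last_c + 1):
            if "".join(nt[3 * c : 3 * c + 3]) in STOP_CODONS:
                bad = c
                break
        # also: no ATG in the E9 frame upstream of the planted start, inside E1
        if bad is None:
            up = "".join(nt[: s + 2])
            for q in range(1, s, 3):
                if up[q : q + 3] == "ATG":
                    bad = q // 3  # repair the E1 codon containing it
                    break
        if bad is None:
            return ["".join(nt[3 * c : 3 * c + 3]) for c in range(len(e1_codons))], (s, s + n_nt)
        # re-draw the E9 codon(s) overlapping the offending E1 codon
        lo = max(1, (3 * bad - s) // 3)
        hi = min(e9_aa, (3 * bad + 2 - s) // 3)
        if 3 * bad + 2 < s or 3 * bad > s + n_nt - 1:  # outside window: redraw E1 codon
            nt[3 * bad : 3 * bad + 3] = list(SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))])
            continue
        for k in range(lo, hi + 1):
            if 1 <= k <= e9_aa - 1:
                e9[k] = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
        write()
    raise RuntimeError("E9 embedding failed")


def _find_gene_at(asm: _Assembly, pos: int) -> str | None:
    for name, (a, b) in asm.genes.items():
        if a <= pos <= b:
            return name
    return None


def _e9_frames_ok(asm: _Assembly) -> bool:
    """Nested E9 frame intact: ATG start, internal codons sense."""
    if asm.e9_window is None:
        return True
    ws = asm.genes["E1"][0] + asm.e9_window[0]
    we = asm.genes["E1"][0] + asm.e9_window[1]
    if "".join(asm.seq[ws : ws + 3]) != "ATG":
        return False
    for e9c in range(ws, we - 3, 3):
        if "".join(asm.seq[e9c : e9c + 3]) in STOP_CODONS:
            return False
    return True


def _try_replace_codon(asm: _Assembly, pos: int, rng: np.random.Generator, goal) -> bool:
    """Re-draw the host-gene codon covering ``pos`` with a sense codon so
    that ``goal()`` holds and the nested E9 frame stays valid."""
    seq = asm.seq
    if pos in asm.protected:
        return False
    gene = _find_gene_at(asm, pos)
    if gene is None:
        return False  # non-coding regions are ATG-free by construction
    gstart, _ = asm.genes[gene]
    cpos = gstart + 3 * ((pos - gstart) // 3)
    if any(p in asm.protected for p in range(cpos, cpos + 3)):
        return False
    for idx in rng.permutation(len(SENSE_CODONS)):
        cand = SENSE_CODONS[idx]
        old = seq[cpos : cpos + 3]
        seq[cpos : cpos + 3] = list(cand)
        if goal() and _e9_frames_ok(asm):
            return True
        seq[cpos : cpos + 3] = old
    return False


def _kill_atg(asm: _Assembly, q: int, rng: np.random.Generator) -> bool:
    """Break the ATG at 0-based q..q+2 by re-drawing one covering codon."""
    seq = asm.seq
    L = len(seq)

    def gone() -> bool:
        trip = "".join(seq[q : q + 3] if q + 3 <= L else seq[q:] + seq[: (q + 3) % L])
        return trip != "ATG"

    for off in range(3):
        if _try_replace_codon(asm, (q + off) % L, rng, gone):
            return True
    return False


def _plant_stop(asm: _Assembly, start0: int, rng: np.random.Generator, max_codons: int = 58) -> bool:
    """Truncate the reading frame opening at ``start0`` below the ORF length
    floor by introducing an early in-frame stop (fallback when the start
    codon itself is protected by a planted motif)."""
    seq = asm.seq
    L = len(seq)

    def frame_len() -> int:
        for k in range(1, max_codons + 2):
            p = (start0 + 3 * k) % L
            trip = "".join(seq[p : p + 3] if p + 3 <= L else seq[p:] + seq[: (p + 3) % L])
            if trip in STOP_CODONS:
                return k
        return max_codons + 2

    for k in range(1, max_codons + 1):
        for off in range(3):
            pos = (start0 + 3 * k + off) % L
            if _try_replace_codon(asm, pos, rng, lambda: frame_len() <= max_codons):
                return True
    return False


def _expected_set(asm: _Assembly) -> dict[str, tuple[int, int]]:
    return dict(asm.genes)


def _is_benign(o: OrfCall, genes: dict[str, tuple[int, int]], L: int) -> bool:
    """Planted ORF, or a same-frame truncation of one (shares end and frame)."""
    s0, e0 = o.iv.start - 1, o.iv.end - 1
    for a, b in genes.values():
        if s0 == a and e0 == b % L:
            return True
        if e0 == b % L and (s0 - a) % 3 == 0 and (s0 - a) % L <= (b - a):
            return True
    return False


def generate_genome(spec: GenomeSpec) -> tuple[CircularGenome, GenomeAnnotation]:
    """Assemble a PV-like circular genome with its ground-truth annotation."""
    from .annotate import find_orfs  # local import to avoid cycle at module load

    omit = set(spec.omit_motifs)
    for attempt in range(10):
        rng = np.random.default_rng((spec.seed + 1000003 * attempt) % (2**31))
        try:
            return _generate_once(spec, rng, omit, find_orfs)
        except RuntimeError as exc:
            log.warning("genome generation attempt %d re-seeded: %s", attempt, exc)
    raise RuntimeError("genome generation failed after re-seeding")


def _generate_once(spec, rng, omit, find_orfs) -> tuple[CircularGenome, GenomeAnnotation]:
    asm = _Assembly()
    aa_len = spec.orf_lengths
    order_early = [n for n in ("E6", "E7") if n not in spec.omit_orfs]

    def add_gap() -> None:
        asm.append(_pyrimidine_filler(rng, int(rng.integers(4, 9))))

    # early region -------------------------------------------------------
    for name in order_early:
        aa, planted = _build_protein(rng, name, aa_len[name], omit)
        codons = _reverse_translate(rng, aa)
        start = asm.append("".join(codons) + "TAA")
        asm.genes[name] = (start, start + 3 * len(codons) + 2)
        for p in planted:
            asm.protect(start + 3 * p, 3)
        asm.protect(start + 3 * len(codons), 3)  # stop codon
        add_gap()

    # E1 with nested E9 ---------------------------------------------------
    e1_aa, e1_planted = _build_protein(rng, "E1", aa_len["E1"], omit)
    e1_codons = _reverse_translate(rng, e1_aa)
    if "E9" not in spec.omit_orfs:
        e1_codons, window = _embed_e9(rng, e1_codons, aa_len["E9"])
    else:
        window = None
    e1_start = asm.append("".join(e1_codons) + "TAA")
    asm.genes["E1"] = (e1_start, e1_start + 3 * len(e1_codons) + 2)
    for p in e1_planted:
        asm.protect(e1_start + 3 * p, 3)
    asm.protect(e1_start + 3 * len(e1_codons), 3)
    if window is not None:
        asm.e9_window = window
        asm.genes["E9"] = (e1_start + window[0], e1_start + window[1] - 1)
        asm.protect(e1_start + window[0], 3)  # E9 start
        asm.protect(e1_start + window[1] - 3, 3)  # E9 stop
    add_gap()

    # E2, NCR -------------------------------------------------------------
    e2_aa, e2_planted = _build_protein(rng, "E2", aa_len["E2"], omit)
    e2_codons = _reverse_translate(rng, e2_aa)
    e2_start = asm.append("".join(e2_codons) + "TAA")
    asm.genes["E2"] = (e2_start, e2_start + 3 * len(e2_codons) + 2)
    for p in e2_planted:
        asm.protect(e2_start + 3 * p, 3)
    asm.protect(e2_start + 3 * len(e2_codons), 3)
    ncr_start = asm.append(_pyrimidine_filler(rng, spec.ncr_len))

    # L2 with acceptor tail, L1 with overlapping start --------------------
    l2_aa, l2_planted = _build_protein(rng, "L2", aa_len["L2"], omit)
    l2_codons = _reverse_translate(rng, l2_aa)
    l2_codons[-4:] = ["TTT", "TCT", "TTC", "CAG"]  # polypyrimidine tract + AG acceptor
    stop = "TAA" if spec.l1_start == "ATG" else "TAG"
    l2_start = asm.append("".join(l2_codons) + stop)
    l2_end = l2_start + 3 * len(l2_codons) + 2
    asm.genes["L2"] = (l2_start, l2_end)
    for p in l2_planted:
        asm.protect(l2_start + 3 * p, 3)
    asm.protect(l2_end - 14, 15)  # tail + stop: acceptor context stays intact

    l1_aa, l1_planted = _build_protein(rng, "L1", aa_len["L1"], omit)
    l1_codons = _reverse_translate(rng, l1_aa[1:])  # first codon comes from the junction
    l1_start0 = l2_end - 2 + 2  # start codon overlaps the stop by 1 nt
    asm.append("TG")  # completes ATG/GTG from the stop codon's last base
    asm.append("".join(l1_codons) + "TAA")
    l1_end = l1_start0 + 3 * (len(l1_codons) + 1) + 2
    asm.genes["L1"] = (l1_start0, l1_end)
    asm.protect(l1_start0, 3)
    for p in l1_planted:
        if p > 0:
            asm.protect(l1_start0 + 3 * p, 3)
    asm.protect(l1_end - 2, 3)

    # LCR ------------------------------------------------------------------
    lcr_seq, offsets = _lcr(rng, spec)
    lcr_start = asm.append(lcr_seq)
    asm.protect(lcr_start, len(lcr_seq))

    total = len(asm.seq)
    if total > spec.length_target + 200:
        raise ValueError(
            f"infeasible spec: assembled {total} nt exceeds target {spec.length_target}+200"
        )

    # repair: remove every spurious maximal ORF ----------------------------
    genes_cds = {n: iv for n, iv in asm.genes.items()}
    for _ in range(300):
        g = CircularGenome("tmp", "".join(asm.seq), "circular")
        orfs = find_orfs(g, min_aa=MIN_AA_ACCESSORY, allow_gtg=False)
        spurious = [o for o in orfs if not _is_benign(o, genes_cds, total)]
        if not spurious:
            break
        progressed = False
        for o in spurious:
            if _kill_atg(asm, o.iv.start - 1, rng) or _plant_stop(asm, o.iv.start - 1, rng):
                progressed = True
        if not progressed:
            raise RuntimeError("ORF repair stuck on protected positions")
    else:
        raise RuntimeError("ORF repair did not converge")

    seq = "".join(asm.seq)
    genome = CircularGenome(f"synth-{spec.seed}", seq, "circular")

    # ground truth ---------------------------------------------------------
    ann = GenomeAnnotation(genome_id=genome.id)
    for name in ("E6", "E7", "E1", "E9", "E2", "L2", "L1"):
        if name not in asm.genes:
            ann.missing.append(name)
            continue
        a, b = asm.genes[name]
        iv = Interval(a + 1, b + 1)
        nt = seq[a : b + 1]
        start_codon = nt[:3] if nt[:3] in ("ATG", "GTG") else "ATG"
        prot = str(Seq(nt[:-3]).translate())
        if start_codon == "GTG":
            prot = "M" + prot[1:]
        ann.orfs.append(
            OrfCall(name, iv, start_codon, len(nt) // 3 - 1, ProteinSeq(name, prot))
        )
    first_early = ann.orf(order_early[0]) if order_early else ann.orf("E1")
    l1_iv = ann.orf("L1").iv
    ann.lcr = Interval(l1_iv.end + 1, total) if first_early.iv.start == 1 else None
    if spec.ncr_len >= 2:
        ann.ncr = Interval(ncr_start + 1, ncr_start + spec.ncr_len)
    for kind, store in (
        ("tata_box", ann.tata),
        ("polya_site", ann.polya),
        ("e2bs_typical", ann.e2bs_typical),
        ("e2bs_atypical", ann.e2bs_atypical),
    ):
        lens = {"tata_box": 7, "polya_site": 6, "e2bs_typical": 12, "e2bs_atypical": 10}
        for off in offsets[kind]:
            store.append(Interval(lcr_start + off + 1, lcr_start + off + lens[kind]))
    return genome, ann


# ---------------------------------------------------------------------------
# Alignment evolution
# ---------------------------------------------------------------------------

#: target leaf-pair identities (%) for pairs whose deepest shared group is
#: the given rank; "between_genus" is the cross-genus identity
LEVEL_TARGETS_DEFAULT = {
    "subtype": 99.5,
    "type": 95.0,
    "species": 80.0,
    "genus": 65.0,
    "between_genus": 55.0,
}


@dataclass
class ClusterDesign:
    """Nested group counts, coarse to fine, with target cross-group identities."""

    n_genera: int = 2
    species_per_genus: int = 1
    types_per_species: int = 2
    subtypes_per_type: int = 2
    seqs_per_subtype: int = 2
    identities: dict = field(default_factory=lambda: dict(LEVEL_TARGETS_DEFAULT))


@dataclass
class EvolSpec:
    design: ClusterDesign | None = None
    tree: Tree | None = None
    kappa: float = 4.0
    coding_constraint: str = "none"  # {"none", "synonymous_only"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.coding_constraint not in ("none", "synonymous_only"):
            raise ValueError("bad coding_constraint")
        if self.tree is not None and self.design is not None:
            raise ValueError("give either a tree or a cluster design, not both")
        if self.tree is None and self.design is None:
            self.design = ClusterDesign()


def _mutate(
    seq: str,
    q: float,
    kappa: float,
    rng: np.random.Generator,
    synonymous_only: bool,
) -> str:
    """Site-wise substitution with per-site probability q, transition-biased."""
    TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
    TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    s = list(seq)
    hit = np.nonzero(rng.random(len(s)) < q)[0]
    p_ts = kappa / (kappa + 2.0)
    for i in hit:
        if synonymous_only:
            ci = i // 3
            codon = seq[3 * ci : 3 * ci + 3]
            codon_now = "".join(s[3 * ci : 3 * ci + 3])
            opts = SYN_SINGLE.get(codon_now, {}).get(i % 3, "")
            if not opts:
                continue
            ts = TRANSITION[s[i]]
            if ts in opts and rng.random() < p_ts:
                s[i] = ts
            else:
                pool = [b for b in opts if b != ts] or list(opts)
                s[i] = pool[rng.integers(0, len(pool))]
        else:
            if rng.random() < p_ts:
                s[i] = TRANSITION[s[i]]
            else:
                tv = TRANSVERSIONS[s[i]]
                s[i] = tv[rng.integers(0, 2)]
    return "".join(s)


def _identity(a: str, b: str) -> float:
    return 100.0 * sum(1 for x, y in zip(a, b) if x == y) / len(a)


def _mutate_coupled(
    seq: str,
    q: float,
    kappa: float,
    u: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    synonymous_only: bool,
) -> str:
    """Like :func:`_mutate` but driven by pre-drawn uniforms (u: hit, v:
    transition choice, w: transversion pick), so the realization varies
    smoothly and monotonically with q during calibration."""
    TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
    s = list(seq)
    p_ts = kappa / (kappa + 2.0)
    for i in np.nonzero(u < q)[0]:
        if synonymous_only:
            ci = i // 3
            codon_now = "".join(s[3 * ci : 3 * ci + 3])
            opts = SYN_SINGLE.get(codon_now, {}).get(i % 3, "")
            if not opts:
                continue
            ts = TRANSITION[s[i]]
            if ts in opts and v[i] < p_ts:
                s[i] = ts
            else:
                pool = [b for b in opts if b != ts] or list(opts)
                s[i] = pool[int(w[i] * len(pool)) % len(pool)]
        else:
            if v[i] < p_ts:
                s[i] = TRANSITION[s[i]]
            else:
                tv = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}[s[i]]
                s[i] = tv[int(w[i] * 2) % 2]
    return "".join(s)


def _calibrate(
    root: str,
    target: float,
    downstream: list[float],
    kappa: float,
    rng: np.random.Generator,
    synonymous_only: bool,
    tol: float = 0.2,
    max_iter: int = 40,
    n_probe: int = 6,
) -> float:
    """Bisection on the per-branch substitution probability q at one level.

    Two lineages split at this level each receive one branch at rate q plus
    one branch per finer level (``downstream``, already calibrated); q is
    tuned until the probe leaf pairs average ~target% identity.  Raises when
    the target is unreachable (e.g. under the synonymous-only constraint).
    """
    lo, hi = 0.0, 0.95
    L = len(root)
    n_steps = 1 + len(downstream)
    # pre-drawn random fields: the probe realization is a fixed function of q
    U = rng.random((n_probe * 2, n_steps, L))
    V = rng.random((n_probe * 2, n_steps, L))
    W = rng.random((n_probe * 2, n_steps, L))

    def chain(k: int, q: float) -> str:
        seq = root
        for step, qd in enumerate([q] + downstream):
            seq = _mutate_coupled(seq, qd, kappa, U[k, step], V[k, step], W[k, step], synonymous_only)
        return seq

    def measure(q: float) -> float:
        vals = [
            _identity(chain(2 * p, q), chain(2 * p + 1, q)) for p in range(n_probe)
        ]
        return float(np.mean(vals))

    if measure(hi) > target + 1.0:
        raise RuntimeError(f"identity target {target}% unreachable")
    best = 0.5 * (lo + hi)
    for _ in range(max_iter):
        q = 0.5 * (lo + hi)
        got = measure(q)
        best = q
        if abs(got - target) <= tol:
            return q
        if got > target:
            lo = q
        else:
            hi = q
    return best


def evolve_alignment(
    root: str, es: EvolSpec
) -> tuple[Alignment, dict[str, dict[str, int]], Tree]:
    """Evolve sequences down a nested cluster design (or an explicit tree).

    Returns the gapless alignment, per-sequence true cluster labels
    (rank -> group index), and the true topology.
    """
    root = root.upper().replace("U", "T")
    syn = es.coding_constraint == "synonymous_only"
    if syn and len(root) % 3:
        raise ValueError("root length must be divisible by 3 under the coding constraint")
    rng = np.random.default_rng(es.seed)

    if es.tree is not None:
        rows, ids = [], []

        def walk(node: TreeNode, seq: str) -> None:
            q = 1.0 - float(np.exp(-max(node.length, 0.0)))
            seq = _mutate(seq, q, es.kappa, rng, syn)
            if node.is_leaf:
                ids.append(node.name)
                rows.append(seq)
            else:
                for c in node.children:
                    walk(c, seq)

        for c in es.tree.root.children:
            walk(c, root)
        return Alignment(ids, rows), {i: {} for i in ids}, es.tree

    d = es.design
    # Branch rates per level, calibrated finest-first so each coarser level
    # accounts for the divergence its descendants will add.  A leaf receives
    # one branch per level: root -(between_genus)-> genus ancestor
    # -(genus)-> species -(species)-> type -(type)-> subtype -(subtype)-> leaf.
    levels = ["between_genus", "genus", "species", "type", "subtype"]
    counts = {
        "between_genus": d.n_genera,
        "genus": d.species_per_genus,
        "species": d.types_per_species,
        "type": d.subtypes_per_type,
        "subtype": d.seqs_per_subtype,
    }
    qs: dict[str, float] = {}
    downstream: list[float] = []
    for lv in reversed(levels):
        if counts[lv] <= 1:
            qs[lv] = 0.0  # no split at this level: no divergence to calibrate
        else:
            qs[lv] = _calibrate(root, d.identities[lv], downstream, es.kappa, rng, syn)
        downstream.insert(0, qs[lv])

    ids, rows = [], []
    labels: dict[str, dict[str, int]] = {}
    tree_root = TreeNode()
    rank_of = {"between_genus": "genus", "genus": "species", "species": "type", "type": "subtype"}
    counters = {r: 0 for r in ("genus", "species", "type", "subtype")}

    def expand(seq: str, level_idx: int, label: dict[str, int], parent: TreeNode) -> None:
        lv = levels[level_idx]
        if lv == "subtype":
            for _ in range(counts[lv]):
                leaf_seq = _mutate(seq, qs[lv], es.kappa, rng, syn)
                name = "g{genus}_s{species}_t{type}_u{subtype}_{i}".format(i=len(ids), **label)
                ids.append(name)
                rows.append(leaf_seq)
                labels[name] = dict(label)
                parent.children.append(TreeNode(name=name, length=qs[lv]))
            return
        rank = rank_of[lv]
        for _ in range(counts[lv]):
            child_seq = _mutate(seq, qs[lv], es.kappa, rng, syn)
            node = TreeNode(length=qs[lv])
            parent.children.append(node)
            sub = dict(label)
            sub[rank] = counters[rank]
            counters[rank] += 1
            expand(child_seq, level_idx + 1, sub, node)

    expand(root, 0, {}, tree_root)
    return Alignment(ids, rows), labels, Tree(tree_root)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    levels: list  # (level name, n, true prevalence)
    factor: str = "group"
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n, p in self.levels:
            if n < 1 or not 0.0 <= p <= 1.0:
                raise ValueError(f"bad level spec {name!r}")


def generate_cohort(cs: CohortSpec) -> CohortTable:
    """Independent Bernoulli status per individual, level-specific prevalence."""
    import pandas as pd

    rng = np.random.default_rng(cs.seed)
    rows = []
    i = 0
    for name, n, p in cs.levels:
        draws = rng.random(n) < p
        for pos in draws:
            rows.append(
                {
                    "individual": f"ind{i}",
                    cs.factor: name,
                    "status": "positive" if pos else "negative",
                }
            )
            i += 1
    return CohortTable(pd.DataFrame(rows))
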