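"""Degenerate-motif compilation and scanning.

The regulatory and protein motifs characteristic of papillomaviruses are
written as degenerate consensi: IUPAC codes for nucleotides (the E2-binding
site ACCNNNNNNGGT and its avian "atypical" short-spacer form ACCNNNNGGT,
the TATA box TATAWAW, polyadenylation signals), and position classes for
amino acids (X = any residue, bracket sets like [T/S], and the hydrophobic
class written Φ in Walker-motif notation).  The E6 zinc-binding domain is a
compound motif: two CXXC pairs separated by a 39-42 residue spacer.

Patterns compile to explicit position-class lists and are scanned by direct
enumeration — every start position and every admissible spacer length —
so overlapping and origin-spanning hits are all reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

from Bio.Data.IUPACData import ambiguous_dna_values

from .annotate import GenomeAnnotation
from .genome import AA_ALPHABET, CircularGenome, Interval, subsequence

#: hydrophobic residue class Φ (Kyte-Doolittle-positive set); overridable
HYDROPHOBIC = frozenset("AVLIMFWYC")

Spacer = tuple  # ("spacer", min, max)


@dataclass(frozen=True)
class MotifPattern:
    name: str
    alphabet: str  # {"nt", "aa"}
    elements: tuple  # frozenset position classes and ("spacer", lo, hi) gaps

    def __post_init__(self) -> None:
        classes = [e for e in self.elements if isinstance(e, frozenset)]
        if not classes:
            raise ValueError("pattern needs at least one non-spacer element")
        for e in self.elements:
            if isinstance(e, tuple):
                _, lo, hi = e
                if lo > hi or lo < 0:
                    raise ValueError("bad spacer range")

    @property
    def min_len(self) -> int:
        return sum(1 if isinstance(e, frozenset) else e[1] for e in self.elements)

    def spacer_ranges(self) -> list[range]:
        return [range(e[1], e[2] + 1) for e in self.elements if isinstance(e, tuple)]


@dataclass
class MotifHit:
    pattern_name: str
    iv: Interval
    matched_text: str


# ---------------------------------------------------------------------------
# Pattern parsing
# ---------------------------------------------------------------------------

def _parse(name: str, text: str, alphabet: str, phi: frozenset = HYDROPHOBIC) -> MotifPattern:
    """Parse a consensus string into a MotifPattern.

    ``X`` (aa) and ``N`` (nt) are wildcards; ``[A/B]`` is a two-letter set;
    ``Φ`` is the hydrophobic class; other letters are IUPAC codes (nt) or
    literal residues (aa).
    """
    elements: list = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.index("]", i)
            members = frozenset(text[i + 1 : j].replace("/", ""))
            elements.append(members)
            i = j + 1
            continue
        if ch == "Φ":
            elements.append(frozenset(phi))
        elif alphabet == "aa":
            if ch == "X":
                elements.append(frozenset(AA_ALPHABET))
            else:
                elements.append(frozenset(ch))
        else:
            elements.append(frozenset(ambiguous_dna_values[ch].replace("U", "T")))
        i += 1
    return MotifPattern(name, alphabet, tuple(elements))


def builtin_patterns(phi: frozenset = HYDROPHOBIC) -> dict[str, MotifPattern]:
    """The named motif catalogue used across APV genomes.

    The generic Walker A/B/C forms are included alongside the APV-conserved
    Walker A specialization (GXXDSGK[T/S]); the APV Walker B and C forms
    (ΦΦDD, ΦTSN) are matched by the generic patterns, ΦTSN being a subset of
    Φ[T/S][T/S]N.
    """
    pats = {
        "e2bs_typical": _parse("e2bs_typical", "ACCNNNNNNGGT", "nt"),
        "e2bs_atypical": _parse("e2bs_atypical", "ACCNNNNGGT", "nt"),
        "tata_box": _parse("tata_box", "TATAWAW", "nt"),
        "polya_site": _parse("polya_site", "AWTAAA", "nt"),  # ATTAAA or AATAAA
        "e7_prb": _parse("e7_prb", "LXCXE", "aa", phi),
        "walker_a": _parse("walker_a", "GXXXXGK[T/S]", "aa", phi),
        "walker_b": _parse("walker_b", "ΦΦDD", "aa", phi),
        "walker_c": _parse("walker_c", "Φ[T/S][T/S]N", "aa", phi),
        "walker_a_apv": _parse("walker_a_apv", "GXXDSGK[T/S]", "aa", phi),
        "e2_dbd": _parse("e2_dbd", "GXTXQ[L/V]KTIRXR", "aa", phi),
        "furin": _parse("furin", "RX[K/R]R", "aa", phi),
        "gxxxg": _parse("gxxxg", "GXXXG", "aa", phi),
        "snx17": _parse("snx17", "[F/Y]XNPX[F/Y]", "aa", phi),
        "syntaxin18": _parse("syntaxin18", "D[Q/K]IL[Q/K]", "aa", phi),
    }
    # E6 zinc domain: two CXXC pairs separated by 39-42 residues
    cxxc = (frozenset("C"), frozenset(AA_ALPHABET), frozenset(AA_ALPHABET), frozenset("C"))
    pats["e6_zinc"] = MotifPattern("e6_zinc", "aa", cxxc + (("spacer", 39, 42),) + cxxc)
    return pats


#: which patterns the profiling step looks for in each protein
ORF_PATTERNS: dict[str, tuple[str, ...]] = {
    "E6": ("e6_zinc",),
    "E7": ("e7_prb", "e6_zinc"),
    "E1": ("walker_a", "walker_a_apv", "walker_b", "walker_c"),
    "E2": ("e2_dbd",),
    "L2": ("furin", "gxxxg", "snx17", "syntaxin18"),
}


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def scan(seq: str, p: MotifPattern, circular: bool = False) -> list[MotifHit]:
    """All matches of ``p`` in ``seq``, overlapping ones included.

    For spacer patterns, each distinct (start, spacer-lengths) combination
    is a separate hit.  On circular sequences hits may span the origin but
    never exceed the sequence length.  Ambiguity codes in the *input*
    (N, X) match nothing.
    """
    seq = seq.upper()
    L = len(seq)
    ext = seq + seq if circular else seq
    hits: list[MotifHit] = []
    combos = list(itertools.product(*p.spacer_ranges())) or [()]
    for spacers in combos:
        # concretize the element list for this spacer combination
        concrete: list[frozenset | None] = []
        it = iter(spacers)
        for e in p.elements:
            if isinstance(e, frozenset):
                concrete.append(e)
            else:
                concrete.extend([None] * next(it))
        m = len(concrete)
        if m > L:
            continue
        last = L if circular else L - m + 1
        for s in range(max(last, 0)):
            ok = True
            for k, cls in enumerate(concrete):
                if cls is not None and ext[s + k] not in cls:
                    ok = False
                    break
            if ok:
                end0 = s + m - 1
                iv = Interval(s + 1, (end0 % L) + 1, wraps_origin=end0 >= L)
                hits.append(MotifHit(p.name, iv, ext[s : s + m]))
    hits.sort(key=lambda h: (h.iv.start, len(h.matched_text)))
    return hits


def count_e2bs(
    ann: GenomeAnnotation, g: CircularGenome, genome_wide: bool = False
) -> tuple[int, int]:
    """Count typical and atypical E2-binding sites (distinct starts) in the LCR.

    ``genome_wide=True`` counts across the whole circle instead, for
    genomes where the regulatory sites spill out of the long control region.
    """
    pats = builtin_patterns()
    if genome_wide:
        region, circ = g.seq, g.is_circular
    else:
        if ann.lcr is None:
            raise ValueError("annotation has no LCR")
        region, circ = subsequence(g, ann.lcr), False
    n_typ = len({h.iv.start for h in scan(region, pats["e2bs_typical"], circ)})
    n_atyp = len({h.iv.start for h in scan(region, pats["e2bs_atypical"], circ)})
    return n_typ, n_atyp


def _region_to_genome(iv: Interval, region_start: int, L: int) -> Interval:
    s = ((region_start - 1 + iv.start - 1) % L) + 1
    e = ((region_start - 1 + iv.end - 1) % L) + 1
    return Interval(s, e, wraps_origin=s > e)


def locate_regulatory_sites(ann: GenomeAnnotation, g: CircularGenome) -> GenomeAnnotation:
    """Fill the annotation's TATA/polyA/E2BS interval lists (genome coordinates).

    E2-binding sites and the TATA box are sought in the LCR; the late-gene
    polyadenylation signal in the LCR and, when present, the NCR.
    """
    pats = builtin_patterns()
    L = g.length_nt
    ann.tata, ann.polya, ann.e2bs_typical, ann.e2bs_atypical = [], [], [], []
    regions = [ann.lcr] if ann.lcr is not None else []
    for iv in regions:
        s = subsequence(g, iv)
        for key, store in (
            ("tata_box", ann.tata),
            ("polya_site", ann.polya),
            ("e2bs_typical", ann.e2bs_typical),
            ("e2bs_atypical", ann.e2bs_atypical),
        ):
            starts = set()
            for h in scan(s, pats[key], False):
                if h.iv.start not in starts:
                    starts.add(h.iv.start)
                    store.append(_region_to_genome(h.iv, iv.start, L))
    if ann.ncr is not None:
        s = subsequence(g, ann.ncr)
        for h in scan(s, pats["polya_site"], False):
            ann.polya.append(_region_to_genome(h.iv, ann.ncr.start, L))
    return ann


def profile_proteins(
    ann: GenomeAnnotation, g: CircularGenome, phi: frozenset = HYDROPHOBIC
) -> dict[str, dict]:
    """Per-ORF motif report: hits and presence/absence flags.

    Mirrors the motif tabulation one would assemble across APV genomes —
    zinc domains for E6/E7, the pRb-binding LXCXE in E7, Walker boxes in
    the E1 helicase, the DNA-binding domain in E2, and the entry/egress
    motifs of the L2 capsid protein.
    """
    pats = builtin_patterns(phi)
    report: dict[str, dict] = {}
    for orf in ann.orfs:
        wanted = ORF_PATTERNS.get(orf.name)
        if not wanted:
            continue
        aa = orf.protein.seq.rstrip("*")
        entry = {"hits": {}, "present": {}}
        for pname in wanted:
            hs = scan(aa, pats[pname], circular=False)
            entry["hits"][pname] = hs
            entry["present"][pname] = bool(hs)
        report[orf.name] = entry
    return report
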