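"""Structural annotation of papillomavirus genomes.

Avian papillomaviruses (APVs) share one gene layout, with every ORF on
the same strand and in the order E6-E7-E1(E9 nested)-E2-[NCR]-L2-L1-[LCR]
around the circle.  Annotation is therefore positional: find all plus-strand
ORFs, identify the L2/L1 junction by the start/stop codon overlap that is
diagnostic for PV late genes, and name the rest by size and genome order.

Two APV-specific rules are implemented:

* the L1 start codon may be GTG instead of ATG (observed in the puffin
  virus), accepted only when it overlaps the L2 stop codon and lies just
  downstream of a plausible splice-acceptor site;
* E9, an avian-specific small ORF, is nested inside E1 in a different
  reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import (
    STOP_CODONS,
    CircularGenome,
    Interval,
    ProteinSeq,
    subsequence,
    translate,
)

START_CODONS_DEFAULT = ("ATG",)
PYRIMIDINES = frozenset("CT")

#: accessory ORFs (E6 is only 81-99 aa in APVs; E9 is small) must reach this many codons
MIN_AA_ACCESSORY = 60
#: core ORFs (E1 587-722 aa, E2, L1, L2) must reach this many codons
MIN_AA_CORE = 300

#: NCR between E2 and L2 is reported only when 2-50 nt; longer gaps are flagged
NCR_MIN_NT = 2
NCR_MAX_NT = 50

CORE_ORFS = ("E1", "E2", "L1", "L2")
ALL_ORFS = ("E6", "E7", "E1", "E9", "E2", "L2", "L1")


@dataclass
class OrfCall:
    name: str  # {E6,E7,E1,E2,E9,L1,L2,unassigned}
    iv: Interval
    start_codon: str  # {ATG, GTG}
    aa_len: int
    protein: ProteinSeq
    flags: set = field(default_factory=set)

    def span(self, L: int) -> int:
        return self.iv.span(L)


@dataclass
class SpliceAcceptorHit:
    """An AG dinucleotide scored by the pyrimidine content upstream.

    ``pos`` is the 1-based position of the acceptor AG's G.  The score is a
    plain polypyrimidine-tract fraction in [0, 1]; it is a plumbing
    heuristic, not a trained splice-site model.
    """

    pos: int
    score: float


@dataclass
class GenomeAnnotation:
    genome_id: str
    orfs: list[OrfCall] = field(default_factory=list)
    lcr: Interval | None = None
    ncr: Interval | None = None
    tata: list[Interval] = field(default_factory=list)
    polya: list[Interval] = field(default_factory=list)
    e2bs_typical: list[Interval] = field(default_factory=list)
    e2bs_atypical: list[Interval] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    flags: set = field(default_factory=set)
    rotation_offset: int = 0

    def orf(self, name: str) -> OrfCall | None:
        for o in self.orfs:
            if o.name == name:
                return o
        return None


def _circular_dist(a: int, b: int, L: int) -> int:
    """Steps forward along the circle from position a to position b (1-based)."""
    return (b - a) % L


def _make_orf(g: CircularGenome, start0: int, stop_end0: int, codon: str) -> OrfCall:
    """Build an OrfCall from 0-based doubled-scan coordinates."""
    L = g.length_nt
    wraps = stop_end0 >= L
    iv = Interval(start0 + 1, (stop_end0 % L) + 1, wraps_origin=wraps)
    nt = subsequence(g, iv)
    prot = translate(nt, gtg_start=(codon == "GTG"))
    aa_len = len(nt) // 3 - 1
    return OrfCall("unassigned", iv, codon, aa_len, ProteinSeq("orf", prot.seq))


def find_orfs(g: CircularGenome, min_aa: int = MIN_AA_ACCESSORY, allow_gtg: bool = False) -> list[OrfCall]:
    """All maximal start->stop reading frames on the plus strand.

    Maximal means the ORF opens at the first permissible start codon after
    the previous in-frame stop.  Circular genomes are scanned on the doubled
    sequence; ORFs must start in the first copy and span less than the
    genome length.  Result is sorted longest-first (ties by start).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = g.length_nt
    if L < 3:
        raise ValueError("genome shorter than 3 nt")
    # Circular genomes are scanned on the tripled sequence and only starts
    # falling in the middle copy are recorded: by then the pending-start /
    # last-stop state reflects the true circular upstream context, which
    # makes the result invariant under rotation of the origin.
    scan = g.seq * 3 if g.is_circular else g.seq
    lo, hi = (L, 2 * L) if g.is_circular else (0, L)
    starts = ("ATG", "GTG") if allow_gtg else ("ATG",)
    seen: set[tuple[int, int]] = set()
    out: list[OrfCall] = []
    for frame in range(3):
        pending: int | None = None
        pending_codon = ""
        for i in range(frame, len(scan) - 2, 3):
            codon = scan[i : i + 3]
            if codon in STOP_CODONS:
                if pending is not None:
                    span = i + 3 - pending
                    if lo <= pending < hi and span <= L and span // 3 - 1 >= min_aa:
                        key = (pending % L, (i + 2) % L)
                        if key not in seen:
                            seen.add(key)
                            out.append(_make_orf(g, pending % L, (pending % L) + span - 1, pending_codon))
                    pending = None
            elif pending is None and codon in starts:
                pending, pending_codon = i, codon
    out.sort(key=lambda o: (-o.span(L), o.iv.start))
    return out


def find_splice_acceptors(g: CircularGenome, window: int = 12) -> list[SpliceAcceptorHit]:
    """Score every AG dinucleotide by its upstream polypyrimidine tract.

    Score = (pyrimidines among the ``window`` nt upstream of the A) / window;
    on linear sequences, missing upstream context counts as non-pyrimidine.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    L = g.length_nt
    hits: list[SpliceAcceptorHit] = []
    for j in range(L):  # j = 0-based index of the G
        i = (j - 1) % L
        if g.is_circular or j >= 1:
            if g.seq[i] == "A" and g.seq[j] == "G":
                count = 0
                for k in range(1, window + 1):
                    u = i - k
                    if u < 0:
                        if not g.is_circular:
                            continue
                        u %= L
                    if g.seq[u] in PYRIMIDINES:
                        count += 1
                hits.append(SpliceAcceptorHit(pos=j + 1, score=count / window))
    return hits


def _codon_positions(start: int, L: int) -> set[int]:
    return {((start - 1 + k) % L) + 1 for k in range(3)}


def _overlaps_stop(candidate: OrfCall, l2: OrfCall, L: int) -> bool:
    """>= 1 shared nt between the candidate's start codon and the L2 stop codon."""
    stop = _codon_positions(((l2.iv.end - 3) % L) + 1, L)
    return bool(_codon_positions(candidate.iv.start, L) & stop)


def _acceptor_near(candidate: OrfCall, acceptors: list[SpliceAcceptorHit], L: int, window: int) -> bool:
    for a in acceptors:
        d = _circular_dist(a.pos, candidate.iv.start, L)
        if 1 <= d <= window:
            return True
    return False


def detect_l1_start(
    g: CircularGenome,
    l2: OrfCall,
    candidates: list[OrfCall],
    acceptors: list[SpliceAcceptorHit] | None = None,
    acceptor_window: int = 10,
) -> OrfCall:
    """Pick the L1 ORF among candidates downstream of L2.

    Preference order: an ATG whose start codon overlaps the L2 stop codon;
    failing that, a GTG overlapping the stop with a splice-acceptor hit
    within ``acceptor_window`` nt upstream; failing that, the longest
    downstream candidate, flagged ``no_l2_overlap``.  Ties go to the longer
    ORF, then the smaller start coordinate.
    """
    L = g.length_nt
    acceptors = acceptors or []

    def rank(group: list[OrfCall]) -> OrfCall:
        return sorted(group, key=lambda o: (-o.span(L), o.iv.start))[0]

    atg = [c for c in candidates if c.start_codon == "ATG" and _overlaps_stop(c, l2, L)]
    if atg:
        chosen = rank(atg)
    else:
        gtg = [
            c
            for c in candidates
            if c.start_codon == "GTG"
            and _overlaps_stop(c, l2, L)
            and _acceptor_near(c, acceptors, L, acceptor_window)
        ]
        if gtg:
            chosen = rank(gtg)
        else:
            # fallback: longest candidate starting downstream of the L2 stop
            down = [
                c
                for c in candidates
                if 0 < _circular_dist(l2.iv.end, c.iv.start, L) <= L // 2
            ]
            if not down:
                raise ValueError("L1 not found")
            chosen = rank(down)
            chosen.flags.add("no_l2_overlap")
    chosen.name = "L1"
    return chosen


def _overlap_candidates(
    g: CircularGenome, l2: OrfCall, min_aa: int, allow_gtg: bool
) -> list[OrfCall]:
    """ORFs whose start codon shares >= 1 nt with l2's stop codon.

    Built directly from the junction rather than from maximal ORFs, because
    the biologically meaningful L1 start codon need not be the most
    upstream start of its reading frame.
    """
    L = g.length_nt
    scan = g.seq + g.seq if g.is_circular else g.seq
    stop_first0 = (l2.iv.end - 3) % L  # 0-based first base of the stop codon
    starts = ("ATG", "GTG") if allow_gtg else ("ATG",)
    found: list[OrfCall] = []
    for off in range(-2, 3):  # start codons sharing >=1 nt with the stop codon
        q = (stop_first0 + off) % L
        if q + 3 > len(scan):  # linear genome: no room for a codon here
            continue
        codon = scan[q : q + 3]
        if codon not in starts:
            continue
        # extend to the next in-frame stop
        j = q + 3
        limit = q + L  # an ORF cannot exceed the genome length
        while j + 3 <= len(scan) and j + 3 <= limit:
            if scan[j : j + 3] in STOP_CODONS:
                if (j + 3 - q) // 3 - 1 >= min_aa:
                    found.append(_make_orf(g, q, j + 2, codon))
                break
            j += 3
    return found


def assign_orf_names(
    g: CircularGenome,
    orfs: list[OrfCall] | None = None,
    acceptors: list[SpliceAcceptorHit] | None = None,
    allow_gtg: bool = True,
    min_aa_core: int = MIN_AA_CORE,
    min_aa_acc: int = MIN_AA_ACCESSORY,
) -> GenomeAnnotation:
    """Name the ORF complement and locate LCR/NCR by the positional rule set.

    Missing core ORFs are recorded in ``annotation.missing`` rather than
    silently dropped.
    """
    L = g.length_nt
    if orfs is None:
        orfs = find_orfs(g, min_aa=min_aa_acc, allow_gtg=False)
    if acceptors is None:
        acceptors = find_splice_acceptors(g)
    ann = GenomeAnnotation(genome_id=g.id)
    pool = list(orfs)
    core = [o for o in pool if o.aa_len >= min_aa_core]
    if len(pool) < 4:
        ann.flags.add("too_few_orfs")

    # --- L2/L1 via the start/stop overlap signature --------------------
    best_pair: tuple[OrfCall, OrfCall] | None = None
    for u in core:
        cands = _overlap_candidates(g, u, min_aa_core, allow_gtg)
        # ATG candidates always admissible; GTG requires a nearby acceptor
        ok = [
            c
            for c in cands
            if c.start_codon == "ATG" or _acceptor_near(c, acceptors, L, 10)
        ]
        if not ok:
            continue
        v = sorted(ok, key=lambda o: (-o.span(L), o.iv.start))[0]
        if best_pair is None or u.span(L) + v.span(L) > best_pair[0].span(L) + best_pair[1].span(L):
            best_pair = (u, v)

    l1 = l2 = None
    if best_pair is not None:
        l2 = best_pair[0]
        cands = _overlap_candidates(g, l2, min_aa_core, allow_gtg)
        l1 = detect_l1_start(g, l2, cands, acceptors)
        # drop any maximal ORF occupying L1's frame segment from the pool
        pool = [
            o
            for o in pool
            if o is not l2 and not (o.iv.end == l1.iv.end and o.iv.wraps_origin == l1.iv.wraps_origin)
        ]
        l2.name = "L2"
    else:
        # no overlapping junction: fall back to size ordering
        ann.flags.add("no_l2_overlap")
        core_sorted = sorted(core, key=lambda o: (-o.span(L), o.iv.start))
        if len(core_sorted) >= 2:
            l1 = core_sorted[1]
            l1.name = "L1"
            pool.remove(l1)
            upstream = [o for o in pool if o.aa_len >= min_aa_core and o is not l1]
            if upstream:
                l2 = min(upstream, key=lambda o: _circular_dist(o.iv.end, l1.iv.start, L))
                l2.name = "L2"
                pool.remove(l2)

    core_left = [o for o in pool if o.aa_len >= min_aa_core and o.name == "unassigned"]

    # --- E1 = longest remaining core ORF --------------------------------
    e1 = None
    if core_left:
        e1 = sorted(core_left, key=lambda o: (-o.span(L), o.iv.start))[0]
        e1.name = "E1"
        pool.remove(e1)

    def nested_in_e1(o: OrfCall) -> bool:
        if e1 is None:
            return False
        off = _circular_dist(e1.iv.start, o.iv.start, L)
        return off + o.span(L) <= e1.span(L)

    # --- E2 = first ORF downstream of E1 (not nested in it) --------------
    e2 = None
    if e1 is not None:
        after_e1 = [o for o in pool if o.name == "unassigned" and not nested_in_e1(o)]
        if after_e1:
            e2 = min(after_e1, key=lambda o: _circular_dist(e1.iv.end, o.iv.start, L))
            e2.name = "E2"
            pool.remove(e2)

    # --- E9 = ORF nested within E1, different frame relative to E1 -------
    e9 = None
    if e1 is not None:
        nested = [
            o
            for o in pool
            if o.name == "unassigned"
            and nested_in_e1(o)
            and _circular_dist(e1.iv.start, o.iv.start, L) % 3 != 0
        ]
        if nested:
            e9 = sorted(nested, key=lambda o: (-o.span(L), o.iv.start))[0]
            e9.name = "E9"
            pool.remove(e9)

    # --- E6/E7 = the short ORFs between L1's end and E1's start ----------
    e6 = e7 = None
    if e1 is not None and l1 is not None:
        arc = _circular_dist(l1.iv.end, e1.iv.start, L)
        early = [
            o
            for o in pool
            if o.name == "unassigned"
            and _circular_dist(l1.iv.end, o.iv.start, L) < arc
            and not nested_in_e1(o)
        ]
        early.sort(key=lambda o: _circular_dist(l1.iv.end, o.iv.start, L))
        if len(early) >= 2:
            e6, e7 = early[0], early[1]
        elif len(early) == 1:
            cand = early[0]
            gap_before = _circular_dist(l1.iv.end, cand.iv.start, L)
            gap_after = _circular_dist(cand.iv.end, e1.iv.start, L)
            if gap_after <= gap_before:
                e7 = cand
            else:
                e6 = cand
        if e6 is not None:
            e6.name = "E6"
        if e7 is not None:
            e7.name = "E7"

    named = [o for o in (e6, e7, e1, e9, e2, l2, l1) if o is not None]
    ann.orfs = named
    ann.missing = [n for n in ALL_ORFS if ann.orf(n) is None]

    # --- LCR: gap from L1 end to the first early ORF ----------------------
    first_early = e6 or e7 or e1
    if l1 is not None and first_early is not None:
        gap = _circular_dist(l1.iv.end, first_early.iv.start, L) - 1
        if gap >= 1:
            s = (l1.iv.end % L) + 1
            e = ((first_early.iv.start - 2) % L) + 1
            ann.lcr = Interval(s, e, wraps_origin=s > e)

    # --- NCR: gap from E2 end to L2 start, 2-50 nt -----------------------
    if e2 is not None and l2 is not None:
        gap = _circular_dist(e2.iv.end, l2.iv.start, L) - 1
        if gap >= NCR_MIN_NT:
            s = (e2.iv.end % L) + 1
            e = ((l2.iv.start - 2) % L) + 1
            ann.ncr = Interval(s, e, wraps_origin=s > e)
            if gap > NCR_MAX_NT:
                ann.flags.add("atypical_ncr")
    return ann


def _shift_interval(iv: Interval, offset: int, L: int) -> Interval:
    s = ((iv.start - 1 - offset) % L) + 1
    e = ((iv.end - 1 - offset) % L) + 1
    return Interval(s, e, wraps_origin=s > e, strand=iv.strand)


def rotate_annotation(ann: GenomeAnnotation, offset: int, L: int) -> GenomeAnnotation:
    """Shift all coordinates so old position offset+1 becomes position 1."""
    out = GenomeAnnotation(
        genome_id=ann.genome_id,
        missing=list(ann.missing),
        flags=set(ann.flags),
        rotation_offset=offset,
    )
    for o in ann.orfs:
        out.orfs.append(
            OrfCall(o.name, _shift_interval(o.iv, offset, L), o.start_codon, o.aa_len, o.protein, set(o.flags))
        )
    for attr in ("lcr", "ncr"):
        iv = getattr(ann, attr)
        setattr(out, attr, _shift_interval(iv, offset, L) if iv is not None else None)
    for attr in ("tata", "polya", "e2bs_typical", "e2bs_atypical"):
        setattr(out, attr, [_shift_interval(iv, offset, L) for iv in getattr(ann, attr)])
    return out


def annotate_genome(
    g: CircularGenome, allow_gtg: bool = True, rotate: bool = True, **kwargs
) -> tuple[CircularGenome, GenomeAnnotation]:
    """Annotate and (by convention) report the genome rotated so E6 starts at 1.

    Returns the possibly-rotated genome together with its annotation; the
    applied offset is recorded in ``annotation.rotation_offset``.
    """
    ann = assign_orf_names(g, allow_gtg=allow_gtg, **kwargs)
    if rotate and g.is_circular:
        anchor = ann.orf("E6") or ann.orf("E7") or ann.orf("E1")
        if anchor is not None and anchor.iv.start != 1:
            offset = anchor.iv.start - 1
            return g.rotated(offset), rotate_annotation(ann, offset, g.length_nt)
    return g, ann
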