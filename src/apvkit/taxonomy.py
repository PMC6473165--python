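"""L1-identity typing and taxon demarcation.

Papillomavirus taxonomy is demarcated on nucleotide identity of the L1
ORF: isolates sharing >90% identity are the same type, >99% the same
subtype, while the species and genus boundaries sit at 70% and 60%.
Identity is the inverse of the p-distance (proportion of differing sites
over comparable columns, gaps and ambiguities excluded pairwise).

This module computes pairwise and group-mean identity matrices from an
alignment, applies the demarcation cascade by single-linkage clustering,
and classifies substitutions between coding sequences as synonymous or
non-synonymous.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import Seq

UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class Alignment:
    """Equal-length gapped rows over {A,C,G,T,N,-} with unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids")
        self.rows = [r.upper().replace("U", "T") for r in self.rows]
        w = len(self.rows[0])
        if any(len(r) != w for r in self.rows):
            raise ValueError("rows have unequal lengths")
        bad = set("".join(self.rows)) - UNAMBIGUOUS - {"N", "-"}
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        # read directly (not via genome.read_fasta) to keep gap characters
        ids, rows = [], []
        with open(path) as fh:
            rid, chunks = None, []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if rid is not None:
                        ids.append(rid)
                        rows.append("".join(chunks))
                    rid, chunks = line[1:].split()[0], []
                elif line:
                    chunks.append(line)
            if rid is not None:
                ids.append(rid)
                rows.append("".join(chunks))
        return cls(ids, rows)


@dataclass
class DemarcationConfig:
    """Identity thresholds (percent) of the demarcation cascade."""

    subtype_min: float = 99.0
    type_min: float = 90.0
    species_min: float = 70.0
    genus_min: float = 60.0
    strict_inequality: bool = True

    def __post_init__(self) -> None:
        if not (self.genus_min < self.species_min < self.type_min < self.subtype_min):
            raise ValueError("thresholds must be strictly ordered")

    def levels(self) -> list[tuple[str, float]]:
        """Coarse-to-fine (rank name, threshold) pairs."""
        return [
            ("genus", self.genus_min),
            ("species", self.species_min),
            ("type", self.type_min),
            ("subtype", self.subtype_min),
        ]


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # percent identities
    level: str  # {"pairwise", "group_mean"}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


@dataclass
class SubstitutionSummary:
    n_sub: int
    n_syn: int
    n_nonsyn: int
    identity_pct: float


# ---------------------------------------------------------------------------
# Distances and identities
# ---------------------------------------------------------------------------

def comparable_columns(a: str, b: str) -> list[int]:
    """Column indices where both rows carry an unambiguous base."""
    return [i for i, (x, y) in enumerate(zip(a, b)) if x in UNAMBIGUOUS and y in UNAMBIGUOUS]


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over comparable columns (pairwise deletion)."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    cols = comparable_columns(a, b)
    if not cols:
        raise ValueError("no comparable positions")
    diff = sum(1 for i in cols if a[i] != b[i])
    return diff / len(cols)


def identity_pct(a: str, b: str) -> float:
    return 100.0 * (1.0 - p_distance(a, b))


def pairwise_identity(aln: Alignment) -> IdentityMatrix:
    n = len(aln.ids)
    m = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        m[i, j] = m[j, i] = identity_pct(aln.rows[i], aln.rows[j])
    return IdentityMatrix(list(aln.ids), m, "pairwise")


def group_mean_identity(aln: Alignment, groups: dict[str, str]) -> IdentityMatrix:
    """Mean cross-pair identity between groups, 100*(1 - mean p-distance).

    The diagonal uses within-group pairs (100 for singleton groups).
    """
    members = {g: [i for i, x in enumerate(aln.ids) if groups.get(x) == g] for g in set(groups.values())}
    for g, mem in members.items():
        if not mem:
            raise ValueError(f"empty group {g!r}")
    if not members:
        raise ValueError("empty group map")
    names = sorted(members, key=lambda g: members[g][0])
    k = len(names)
    m = np.zeros((k, k))
    for a in range(k):
        for b in range(a, k):
            if a == b:
                pairs = list(itertools.combinations(members[names[a]], 2))
                if not pairs:
                    m[a, a] = 100.0
                    continue
            else:
                pairs = [(i, j) for i in members[names[a]] for j in members[names[b]]]
            d = np.mean([p_distance(aln.rows[i], aln.rows[j]) for i, j in pairs])
            m[a, b] = m[b, a] = 100.0 * (1.0 - d)
    return IdentityMatrix(names, m, "group_mean")


# ---------------------------------------------------------------------------
# Demarcation
# ---------------------------------------------------------------------------

RANKS_FINE_TO_COARSE = ("same_subtype", "same_type", "same_species", "same_genus", "different_genus")


def assign_rank(identity: float, cfg: DemarcationConfig | None = None) -> str:
    """Finest rank whose threshold the identity exceeds."""
    cfg = cfg or DemarcationConfig()
    if not 0.0 <= identity <= 100.0:
        raise ValueError("identity must be a percentage")

    def passes(t: float) -> bool:
        return identity > t if cfg.strict_inequality else identity >= t

    if passes(cfg.subtype_min):
        return "same_subtype"
    if passes(cfg.type_min):
        return "same_type"
    if passes(cfg.species_min):
        return "same_species"
    if passes(cfg.genus_min):
        return "same_genus"
    return "different_genus"


def _single_linkage(indices: list[int], idm: np.ndarray, threshold: float, strict: bool) -> list[list[int]]:
    """Connected components of the 'identity above threshold' graph."""
    clusters: list[list[int]] = []
    assigned: dict[int, int] = {}
    for i in indices:
        links = set()
        for j in indices:
            if j in assigned and j != i:
                v = idm[i, j]
                if (v > threshold) if strict else (v >= threshold):
                    links.add(assigned[j])
        if not links:
            clusters.append([i])
            assigned[i] = len(clusters) - 1
        else:
            tgt = min(links)
            for c in sorted(links - {tgt}, reverse=True):
                for k in clusters[c]:
                    assigned[k] = tgt
                clusters[tgt].extend(clusters[c])
                clusters[c] = []
            clusters[tgt].append(i)
            assigned[i] = tgt
    out = [sorted(c) for c in clusters if c]
    out.sort(key=lambda c: c[0])
    return out


def _complete_linkage(indices: list[int], idm: np.ndarray, threshold: float, strict: bool) -> list[list[int]]:
    """Greedy complete-linkage: every member pair must clear the threshold."""
    clusters: list[list[int]] = []
    for i in indices:
        for c in clusters:
            ok = all((idm[i, j] > threshold) if strict else (idm[i, j] >= threshold) for j in c)
            if ok:
                c.append(i)
                break
        else:
            clusters.append([i])
    return clusters


@dataclass
class TypeAssignment:
    """Nested genus ⊃ species ⊃ type ⊃ subtype partition of alignment ids."""

    ids: list[str]
    labels: dict[str, dict[str, int]] = field(default_factory=dict)  # id -> rank -> cluster index
    clusters: dict[str, list[list[str]]] = field(default_factory=dict)  # rank -> member lists

    def frequency(self, rank: str, member: str) -> tuple[int, int]:
        """(cluster size, parent-cluster size) for the cluster holding ``member``.

        For subtypes the parent is the type; for types the species, etc.
        """
        order = ["genus", "species", "type", "subtype"]
        r = order.index(rank)
        idx = self.labels[member][rank]
        size = len(self.clusters[rank][idx])
        if r == 0:
            return size, len(self.ids)
        parent_rank = order[r - 1]
        pidx = self.labels[member][parent_rank]
        return size, len(self.clusters[parent_rank][pidx])


def cluster_types(
    aln: Alignment,
    cfg: DemarcationConfig | None = None,
    linkage: str = "single",
) -> TypeAssignment:
    """Apply the demarcation cascade from genus down to subtype.

    Single linkage reproduces the 'same type iff >90% to any member'
    reading of the demarcation rule; complete linkage is available for
    comparison.  Nesting is preserved by clustering each rank within its
    parent clusters; labels are deterministic (ordered by first member).
    """
    cfg = cfg or DemarcationConfig()
    idm = pairwise_identity(aln).values
    link = _single_linkage if linkage == "single" else _complete_linkage
    assign = TypeAssignment(ids=list(aln.ids), labels={x: {} for x in aln.ids})
    parents: list[list[int]] = [list(range(len(aln.ids)))]
    for rank, threshold in cfg.levels():
        level_clusters: list[list[int]] = []
        for parent in parents:
            level_clusters.extend(link(parent, idm, threshold, cfg.strict_inequality))
        level_clusters.sort(key=lambda c: c[0])
        assign.clusters[rank] = [[aln.ids[i] for i in c] for c in level_clusters]
        for ci, c in enumerate(level_clusters):
            for i in c:
                assign.labels[aln.ids[i]][rank] = ci
        parents = level_clusters
    return assign


# ---------------------------------------------------------------------------
# Synonymous / non-synonymous tallies
# ---------------------------------------------------------------------------

def substitution_summary(a: str, b: str, frame_offset: int = 0) -> SubstitutionSummary:
    """Count substitutions between two aligned coding sequences by codon.

    A substitution is synonymous iff its codon pair translates identically;
    when a codon differs at more than one position and the translations
    differ, all its substitutions count as non-synonymous.  Codons with a
    gap or ambiguity in either row are excluded whole, keeping the codon
    frame interpretable.
    """
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    a, b = a.upper()[frame_offset:], b.upper()[frame_offset:]
    usable = len(a) - len(a) % 3
    n_sub = n_syn = n_nonsyn = 0
    n_cols = n_diff = 0
    for i in range(0, usable, 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca) <= UNAMBIGUOUS and set(cb) <= UNAMBIGUOUS:
            n_cols += 3
            diffs = sum(1 for x, y in zip(ca, cb) if x != y)
            n_diff += diffs
            if diffs:
                n_sub += diffs
                if str(Seq(ca).translate()) == str(Seq(cb).translate()):
                    n_syn += diffs
                else:
                    n_nonsyn += diffs
    if n_cols == 0:
        raise ValueError("no comparable codons")
    ident = 100.0 * (1.0 - n_diff / n_cols)
    return SubstitutionSummary(n_sub, n_syn, n_nonsyn, ident)


# ---------------------------------------------------------------------------
# Bundled pairwise aligner (for self-contained tests; not a Clustal stand-in)
# ---------------------------------------------------------------------------

def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment, match +1 / mismatch -1 / gap -2."""
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1, gap_score=-2
    )
    best = aligner.align(a.upper(), b.upper())[0]
    return str(best[0]), str(best[1])
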