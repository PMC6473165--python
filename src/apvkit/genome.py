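"""Core sequence data model and standard-format I/O.

Papillomaviruses carry small circular double-stranded DNA genomes
(roughly 5.7-8.6 kb across the family).  Everything downstream —
ORF calling, motif scanning, typing — operates on the
:class:`CircularGenome` container defined here, with 1-based inclusive
coordinates (GenBank convention) expressed as :class:`Interval` objects
that may wrap the arbitrary origin of the circle.

All coordinates are on the plus strand: avian papillomavirus ORFs all
lie on one DNA strand, so the annotator never reports minus-strand
features.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: stop codons of the standard genetic code
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def _normalize_nt(seq: str) -> str:
    """Upper-case a nucleotide string and map U -> T."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    return s


@dataclass
class CircularGenome:
    """A (possibly circular) nucleotide sequence with an identifier."""

    id: str
    seq: str
    topology: str = "linear"  # {"circular", "linear"}

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.seq = _normalize_nt(self.seq)
        if not self.seq:
            raise ValueError("empty sequence")

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def rotated(self, offset: int) -> "CircularGenome":
        """Return the genome re-linearized so old position ``offset+1`` is new position 1.

        Only meaningful for circular genomes; offset is taken mod length.
        """
        if not self.is_circular:
            raise ValueError("cannot rotate a linear genome")
        k = offset % self.length_nt
        return CircularGenome(self.id, self.seq[k:] + self.seq[:k], "circular")


@dataclass(frozen=True)
class Interval:
    """1-based inclusive span on a genome; may wrap the circular origin."""

    start: int
    end: int
    wraps_origin: bool = False
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based and positive")
        if not self.wraps_origin and self.start > self.end:
            raise ValueError("start > end on a non-wrapping interval")
        if self.strand != "+":
            raise ValueError("only plus-strand features are supported")

    def span(self, parent_length: int) -> int:
        if self.wraps_origin:
            return parent_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def positions(self, parent_length: int) -> Iterator[int]:
        """Yield the 1-based positions covered, in 5'->3' order."""
        if self.wraps_origin:
            yield from range(self.start, parent_length + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)

    def validate(self, parent_length: int) -> None:
        if self.start > parent_length or self.end > parent_length:
            raise ValueError(
                f"interval {self.start}..{self.end} out of bounds for length {parent_length}"
            )


@dataclass
class ProteinSeq:
    """Amino-acid sequence; at most one '*' and only as the final symbol."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty protein")
        body = self.seq[:-1] if self.seq.endswith("*") else self.seq
        bad = set(body) - AA_ALPHABET - {"X"}
        if bad or "*" in body:
            raise ValueError(f"invalid amino-acid characters: {sorted(bad | ({'*'} if '*' in body else set()))}")

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[CircularGenome]:
    """Read a FASTA file into :class:`CircularGenome` records.

    Topology is taken from a ``topology=circular`` token in the header;
    the default is linear.  Sequences are upper-cased and U is mapped to T.
    """
    records: list[CircularGenome] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(ln.strip() for ln in lines):
        raise ValueError(f"{path}: empty FASTA file")

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"{path}: record ending at line {line_no} has no sequence")
        tokens = header.split()
        rid = tokens[0]
        topology = "circular" if "topology=circular" in tokens[1:] else "linear"
        records.append(CircularGenome(rid, seq, topology))
        header, chunks = None, []

    for i, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(i)
            header = line[1:].strip()
            if not header:
                raise ValueError(f"{path}: empty FASTA header at line {i}")
        else:
            if header is None:
                raise ValueError(f"{path}: sequence before any header at line {i}")
            chunks.append(line)
    flush(len(lines) + 1)
    return records


def write_fasta(genomes: Iterable[CircularGenome], path, width: int = 70) -> None:
    """Write records with the topology token preserved for circular genomes."""
    with open(path, "w") as fh:
        for g in genomes:
            topo = " topology=circular" if g.is_circular else ""
            fh.write(f">{g.id}{topo}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Sequence operations
# ---------------------------------------------------------------------------

def subsequence(g: CircularGenome, iv: Interval) -> str:
    """Extract the bases spanned by ``iv`` (wrap-aware)."""
    iv.validate(g.length_nt)
    if iv.wraps_origin:
        if not g.is_circular:
            raise ValueError("wrapping interval on a linear genome")
        return g.seq[iv.start - 1 :] + g.seq[: iv.end]
    return g.seq[iv.start - 1 : iv.end]


def translate(nt: str, table: int = 1, gtg_start: bool = False) -> ProteinSeq:
    """Translate an in-frame nucleotide string with the standard code.

    Stops render as ``*``; codons containing N render as ``X`` (unless the
    ambiguity is synonymous-neutral, which Biopython resolves).  With
    ``gtg_start`` a leading GTG is read as initiator methionine, the rule
    needed for the puffin-virus L1.
    """
    s = _normalize_nt(nt)
    if len(s) % 3:
        raise ValueError(f"length {len(s)} not divisible by 3")
    aa = str(Seq(s).translate(table=table))
    if gtg_start and s[:3] == "GTG":
        aa = "M" + aa[1:]
    # internal stop is permitted here; ORF-level checks live in annotate
    return ProteinSeq("translation", aa)


# ---------------------------------------------------------------------------
# GFF3 output
# ---------------------------------------------------------------------------

def write_gff3(annotation, genome: CircularGenome, path) -> None:
    """Write a GenomeAnnotation as GFF3.

    Feature types: ``gene``/``CDS`` for ORFs, ``region`` for LCR and NCR,
    ``misc_feature`` for motif sites.  Wrap-around features are split into
    two location lines sharing an ID, per the GFF3 discontinuous-feature
    convention.
    """
    L = genome.length_nt

    def rows(iv: Interval, ftype: str, fid: str, extra: str = "") -> list[str]:
        attrs = f"ID={fid}" + (";" + extra if extra else "")
        base = [genome.id, "apvkit", ftype]
        if iv.wraps_origin:
            return [
                "\t".join(base + [str(iv.start), str(L), ".", "+", ".", attrs]),
                "\t".join(base + ["1", str(iv.end), ".", "+", ".", attrs]),
            ]
        return ["\t".join(base + [str(iv.start), str(iv.end), ".", "+", ".", attrs])]

    out: list[str] = ["##gff-version 3", f"##sequence-region {genome.id} 1 {L}"]
    for orf in annotation.orfs:
        extra = f"Name={orf.name};start_codon={orf.start_codon}"
        out += rows(orf.iv, "gene", f"gene-{orf.name}", extra)
        out += rows(orf.iv, "CDS", f"cds-{orf.name}", extra)
    if annotation.lcr is not None:
        out += rows(annotation.lcr, "region", "LCR", "Name=LCR")
    if annotation.ncr is not None:
        out += rows(annotation.ncr, "region", "NCR", "Name=NCR")
    for kind, ivs in (
        ("TATA_box", annotation.tata),
        ("polyA_signal", annotation.polya),
        ("E2BS_typical", annotation.e2bs_typical),
        ("E2BS_atypical", annotation.e2bs_atypical),
    ):
        for j, iv in enumerate(ivs, 1):
            out += rows(iv, "misc_feature", f"{kind}-{j}", f"Name={kind}")
    text = "\n".join(out) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
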