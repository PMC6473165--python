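# Methods

This note documents the models and procedures apvkit implements, the
choices made where the design was genuinely open, and what its synthetic
test substrate does and does not establish about real data.

## Coordinate model and genome annotation

Genomes are circular plus-strand sequences with 1-based inclusive
coordinates (GenBank convention); intervals may wrap the arbitrary origin.
All avian papillomavirus ORFs lie on one strand, so only that strand is
annotated; the reverse complement is never scanned.

**ORF calling.** A maximal ORF opens at the first permitted start codon
after the previous in-frame stop and runs to the next in-frame stop
(interval includes the stop; `aa_len` excludes it). On a circle,
"previous" must be read circularly: the scanner walks the tripled sequence
and records only starts falling in the middle copy, where the pending
start/stop state already reflects the true circular upstream context. This
makes the call set invariant under rotation of the origin, which a plain
doubled-sequence scan is not. Length floors default to 300 codons for the
core genes (E1 is 587–722 aa in APVs; E2, L2, L1 all exceed 300) and 60 for
the accessory genes, low enough to keep E6 (81–99 aa in these viruses) and
the small E9.

**Gene naming is positional, not homology-based.** The L2/L1 junction is
identified first: in papillomaviruses the L1 start codon overlaps the L2
stop codon, so the annotator looks for start codons sharing at least one
nucleotide with each candidate stop. An ATG there is accepted outright; a
GTG is accepted only when a splice-acceptor-like AG sits within 10 nt
upstream — the configuration reported for the puffin virus L1 and nowhere
else among APVs. When no overlapping start exists the longest downstream
ORF is chosen and flagged. E1 is the longest remaining core ORF, E2 the
first ORF downstream of E1, E9 the longest ORF nested inside E1 in a
shifted frame, and E6/E7 the short ORFs between L1's end and E1's start
(E6 first; a single candidate is assigned E7 when it abuts E1, which
handles genomes that lack E6, as the grey-parrot virus does). The LCR is
the gap from L1's end to the first early ORF; the NCR is the E2→L2 gap
when it spans 2–50 nt, reported-but-flagged when longer. Missing genes are
listed explicitly rather than silently omitted. Annotated genomes are
reported rotated so E6 starts at position 1, with the offset recorded.

**Splice acceptors.** The stand-in acceptor score is the pyrimidine
fraction of the 12 nt upstream of each AG. It is deliberately simple
plumbing — monotone in polypyrimidine content, in [0, 1] — and is used
only as an existence filter for the GTG rule, never as a trained
splice-site model.

## Motif scanning

Patterns are explicit position-class lists: IUPAC expansion for
nucleotides, literal residues / `X` wildcards / bracket sets for amino
acids, and bounded spacers for the compound zinc motif
(CXXC–x(39,42)–CXXC). Matching enumerates every start position and every
admissible spacer length, so overlapping hits and, on circles,
origin-spanning hits are all reported; E2-binding-site *counts* use
distinct start positions. The hydrophobic class Φ is
{A,V,L,I,M,F,W,Y,C} — the standard Kyte–Doolittle-positive set — and is
overridable, since the Walker-motif literature does not fix it. `N`/`X`
in the *input* sequence match nothing (conservative). E2BS counting is
restricted to the LCR by default with a genome-wide option, because the
published copy numbers are promoter-region counts. The generic Walker A/B/C
patterns are catalogued alongside the APV-conserved Walker A
specialization; the APV B and C forms (ΦΦDD, ΦTSN) are subsets of the
generic patterns and need no separate entries.

## Typing and demarcation

Identity is 100·(1 − p), with the p-distance computed over columns where
both sequences carry an unambiguous base (pairwise deletion, matching the
common distance-software default; gaps and N drop per pair, not per
alignment). Demarcation uses strict thresholds — >99% subtype, >90% type,
>70% species, >60% genus — because the published rules are phrased with
strict inequalities; a flag switches to inclusive boundaries. Clustering
is single linkage at each threshold, applied coarse to fine within parent
clusters so the partition is nested by construction; single linkage
realizes the "same type iff >90% to *any* member" reading, and complete
linkage is available for comparison. Cluster labels are deterministic
(ordered by first member), so results are invariant to input order.

Synonymous/non-synonymous tallies compare codon pairs: a substitution is
synonymous iff its codon pair translates identically; when a codon differs
at several positions and the translations differ, all its substitutions
count as non-synonymous, since whole-ORF tallies cannot attribute
individual positions. Codons containing a gap or ambiguity in either
sequence are excluded whole, keeping the frame interpretable and the
identity `n_syn + n_nonsyn = n_sub` exact.

The bundled pairwise aligner is Biopython's global aligner at
match +1 / mismatch −1 / gap −2; it exists so the tests are self-contained
and is not a progressive multiple aligner.

## Distance phylogenetics

K2P: d = −½ln(1−2P−Q) − ¼ln(1−2Q) with P, Q the transition and
transversion mismatch proportions. TN93 uses the standard closed form with
the two transition classes and empirical base frequencies taken from the
sequence pair. Gamma rate variation follows the convention used by the
common distance software: every −c·ln(w) term becomes c·α(w^(−1/α) − 1).
An invariant-site fraction p_inv (supplied, not estimated) rescales the
observed mismatch proportions by 1/(1−p_inv) and the final distance by
(1−p_inv). Saturation (a non-positive logarithm argument) yields an
explicit infinite distance, never a silent NaN.

Neighbor joining is the Saitou–Nei agglomeration with two determinism
rules: Q-criterion ties break to the smallest index pair, and negative
branch lengths clamp to zero with the deficit moved to the sister branch
so path lengths are preserved. Maximum-likelihood inference is
deliberately out of scope — the trees serve qualitative clade-composition
questions (monophyly of host clades), not branch-length estimation — so a
monophyly query checks whether any edge of the unrooted tree bipartitions
exactly the queried leaf set, optionally relative to an outgroup.
Bootstrap resamples alignment columns with one seeded generator; support
is the percentage of replicate NJ trees containing each internal
bipartition of the point tree; replicates that saturate are redrawn, with
a bound.

## Prevalence and group comparisons

The analysis unit is the individual, not the sample: repeated swabs of one
bird collapse to one row, positive if any sample was positive. Prevalence
is k/n as a percentage (half-up to one decimal, the survey's printing
convention) with a Wilson 95% interval — chosen over Wald for its behavior
at small k, and never compared against published values, which carry no
intervals. The group test is the binomial-GLM deviance (likelihood-ratio)
χ², computed two independent ways: directly as G = 2·Σ o·ln(o/e) over the
level×status table (zero cells contribute nothing), and as the
null-minus-residual deviance of a statsmodels IRLS logit fit; the package
asserts their agreement to 1e-8. The deviance statistic — not Pearson's —
is the one that reproduces the published values exactly from the printed
counts. Levels with 0% or 100% positivity are reported as boundary cases;
their fitted proportions still equal k/n. p-values come from the χ² upper
tail with df = levels − 1.

Two published duck comparisons cannot be reconstructed from the printed
totals (the age contrast χ²=15.41 and the species contrast χ²=1.70, which
disagree with every count table consistent with the published totals,
presumably because birds of unknown age were excluded at analysis time);
they are excluded from automated checks. The seasonality comparison is
described as age-adjusted in prose, yet the printed χ² equals the
unadjusted 2×2 deviance; the unadjusted test is what is implemented.

## Synthetic data

**Genomes.** `generate_genome` assembles the canonical layout with the
default sizes E6 90 / E7 120 / E1 650 (E9 70 nested at frame +1) /
E2 380 / L2 470 / L1 510 aa, a 2–50 nt NCR, a 400–800 nt LCR and 0–9
atypical plus 0–3 typical E2-binding sites — all inside the ranges
reported for real APVs. Protein motifs are planted at fixed residues;
regulatory sites at random LCR offsets. Three mechanisms keep the ground
truth exact: non-coding filler is drawn G-free (pyrimidine-rich) so it can
contain no start codon; the LCR is rejection-sampled until its
regulatory-site counts are exactly the planted ones and it contains no
ATG; and after assembly a repair loop re-scans the genome and re-draws
codons (respecting both frames inside the E9 window and never touching
planted-motif positions, with an early-stop fallback when a spurious start
overlaps a protected motif) until the maximal-ORF scan returns exactly the
planted complement. Every generator is a pure function of spec and seed;
failed construction re-seeds deterministically and is logged.

**Alignments.** `evolve_alignment` mutates a root coding sequence down a
nested design (genera / species / types / subtypes / isolates) under a
transition-biased site-substitution process (transition probability
κ/(κ+2), default κ=4). Per-level branch rates are calibrated finest-first
by bisection against target leaf-pair identities — defaults 99.5% within
subtype, 95% within type, 80% within species, 65% within genus, 55%
between genera, mirroring the identity structure of the published typing
tables — using a coupled pre-drawn random field so the probe is monotone
in the rate. A synonymous-only mode restricts proposals to single-base
codon-preserving changes and raises when a target is unreachable under
that constraint. No indels, no recombination, no codon-usage realism are
simulated.

**Cohorts.** Independent Bernoulli status per individual with
level-specific prevalence, sized by the spec.

**What passing these tests shows.** Recovery of planted annotations,
motifs, partitions and prevalences demonstrates internal correctness of
each algorithm under the layout and divergence structure described above.
It does not demonstrate robustness to features real genomes have and the
generator omits: sequencing error, indels and length variation, overlapping
genes beyond E9, promoter architecture beyond the planted sites, codon
bias, or rate heterogeneity along the genome.

## Problem sizes used by the test suite

The suite annotates 100 randomly sized genomes (7.3–8.1 kb), checks the
motif scanner against an exhaustive oracle on 1000 random strings per
pattern, compares NJ with brute-force least squares on 50 planted 5-taxon
trees, verifies demarcation recovery on 50 replicate 16-leaf alignments of
1.8 kb, and calibrates the deviance test's type-I error on 1000 null
cohorts of 113 individuals — sizes chosen to exercise each method at the
scale of the real study while keeping the whole suite under a minute.

## Known limitations

- Naming is purely positional; a genome with a rearranged layout would be
  mis-annotated rather than rejected.
- The TN93 estimator uses pair-specific empirical base frequencies, so
  distances from overlapping pairs are not jointly consistent the way a
  single-alignment frequency estimate would be.
- The splice-acceptor heuristic has no calibrated score scale.
- `+I` requires the invariant fraction as an input; no internal estimation.
- The demarcation cascade assumes identity thresholds apply to the whole
  aligned span; partial sequences are handled by pairwise deletion, and
  pairs sharing fewer than 60% of columns should be interpreted with care.
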