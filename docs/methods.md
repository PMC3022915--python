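# Methods

This note documents the models, conventions and numerical choices behind
niltkit, and what the synthetic validation does and does not demonstrate.

## Gene models and coordinates

Internal coordinates are 0-based half-open everywhere; GFF3 on disk is
1-based inclusive, converted at the boundary (the conversion is a bijection,
property-tested by round trips). Exon features carry a *role* — LP, Ig1,
Ig2, CP, TM, Cyt1, Cyt2 — and genes are assembled by sorting exons in
transcription order (descending coordinates on the minus strand) with introns
derived as the gaps. Exon-1 lengths are **coding** lengths (5'UTR excluded)
and the terminal stop codon is counted inside the Cyt2 exon; with these two
conventions the per-gene exon sums equal the ORF lengths exactly, which is
what makes the structure table internally consistent.

Intron phase is the cumulative coding length modulo 3 (phase 0 = between
codons), so the canonical NILT pattern is phase 1 for every intron upstream
of the terminal, ITIM-bearing exon and phase 0 for the final intron. The
two-Ig gene variant adds one phase-1 intron after its second Ig exon.

Pseudogene screening flags, rather than rejects: in-frame stops before the
final codon (first stop's locus coordinate reported), coding length not a
multiple of 3, a missing CP/TM/Cyt2 exon in an otherwise LP+Ig gene, and
introns that do not begin GT and end AG on the transcribed strand. The
splice check is GT-AG only, and non-canonical sites flag the gene instead of
rejecting it, since minor splice classes exist.

## Region partition and receptor features

Region boundaries come from exon roles, not from signal-peptide or TM
predictors. At a phase-1 (or phase-2) exon junction the split codon is
assigned to the downstream region, i.e. the region holding a boundary at
coding position *b* starts at amino acid ⌊b/3⌋. The TM exon encodes both the
membrane helix and the start of the cytoplasmic region; lacking any boundary
annotation inside that exon, the helix is taken as the exon's first 23 aa
(a typical single-pass TM length; configurable via `tm_aa`), and the exon
remainder joins Cyt1+Cyt2 as the cytoplasmic region. Partial gene models
without a TM exon are partitioned through their last annotated region.

Cysteine architecture: the fold cysteines are the ones nearest the 1-based
anchor positions 17 and 89 within a ±5 window; domains without a cysteine in
a window are flagged, never force-fit. An additional pair strictly between
the fold pair defines the spacing class CXnC with n the residue gap (3, 6 or
7 in this family; anything else is `other`). ITIM scanning reports every
long-form match `(S/I/V/L)xYxx(I/V/L)`; short-form matches `Yxx(I/V/L)` are
added only for tyrosines not already covered, so each distinct tyrosine
yields at most one hit. `x` means any residue, including S/I/V/L/Y.

Group classification applies only to CX3C domains. The diagnostic positions
(20, the 32–35 motif immediately after the third cysteine, and 66) are
defined in a reference Ig-domain coordinate frame and transferred to the
query by global alignment; the packaged default reference is a *synthetic*
116-aa domain constructed to carry the canonical architecture (it is a
stand-in, and any real Ig domain can be supplied instead). A group needs a
2-of-3 majority — full agreement is not required because the group-2 motif
itself is degenerate, (P/R)V(F/L)N.

## Alignment, identity, entropy

Pairwise alignment is optimal Needleman–Wunsch with affine gaps (BLOSUM62,
open 10 / extend 0.5 for proteins; +5/−4 for nucleotides). Percent identity
uses the gap-excluded denominator (residue–residue columns only); similarity
additionally counts positive-scoring substitutions. These conventions are
stated explicitly because published identity tables rarely say which
denominator they used; with the gap-excluded one, self-identity is always
100 and identity ≤ similarity.

The multiple aligner is progressive: UPGMA guide tree on 1 − identity/100,
then profile–profile Needleman–Wunsch with sum-of-pairs column scores (gap
symbols score 0) and a linear gap penalty of 8 per column; two-sequence
problems use the optimal affine aligner directly. No iterative refinement is
done and no claim of bit-compatibility with any external aligner is made —
the MSA exists to support entropy profiles and guide distance estimation,
both of which are robust to small alignment differences in this family of
77–96 %-identical domains.

Per-column variability is Shannon entropy in bits over the residues observed
in the column, gaps excluded from the frequencies; an all-gap column has
undefined entropy (NaN) and is never called variable. The variability
threshold defaults to 1.3 bits, the conventional cut-off for calling a
position variable in receptor-family alignments.

## Phylogeny

Distances are p-distances with pairwise deletion (the era-typical default
for this analysis; a Poisson correction −ln(1−p) is available). Neighbor
joining follows Saitou–Nei with two determinism guarantees: net divergences
are computed with exact (fsum) summation and Q-ties are broken by the
lexicographically smallest pair of subtree labels, so the topology is
independent of taxon input order and platform. Negative branch-length
estimates are clamped to zero with the deficit moved to the sister branch,
preserving the joined pair's path length. NJ is exact on additive matrices;
the test suite verifies this against an exhaustive least-squares topology
search up to 6 taxa and against an independent NJ implementation.

Bootstrap support of an internal edge is the percentage of column-resampled
replicates whose NJ tree contains the same bipartition. Replicate *r* draws
its columns from an RNG substream seeded by (seed, r), so supports are
reproducible and independent of evaluation order. The default is 1000
replicates — enough for stable desk-scale supports — with 10,000 available
by flag for publication-scale runs. Outgroup rooting splits the outgroup's
pendant edge; supports are re-attached by bipartition, which leaves them
invariant under rooting.

## Repertoire survey

Clones are screened by best translated identity (first stop-free forward
frame) against the known Ig domains; the positivity threshold defaults to
70 % — far above the ~10–20 % expected for unrelated sequences and below the
~77 % floor of within-family identity — and is configurable. Dedup is exact
at the nucleotide level; only sequences observed more than once are retained,
and the once-observed remainder is translated and deduplicated at the
amino-acid level to give the singleton count (synonymous singletons
collapse). Retained sequences are assigned to known genes by exact
nucleotide identity over the amplified interval after trimming degenerate
primer bases; everything else is novel and group-classified from its
translation. Both nucleotide- and amino-acid-level retained tallies are
reported, since survey write-ups are often ambiguous about the level.

## The synthetic generator and what passing tests mean

The generator's defaults are the study conditions: the six salmon gene
templates with their published exon/intron lengths, cysteine classes (CX3C
for the one-Ig genes, CX6C/CX7C for the two-Ig gene), ITIM counts (5,4,5,4,
4,4), connecting-peptide Ser/Thr counts (29/56, 22/45, 15/33, 36/68, 22/39*,
20/37), two pseudogenes (internal stop in Ig1; missing CP exon), mixed
strands, and 10 PCRs × 10 clones for the library. (*The published 22/38 for
the fifth gene is inconsistent with its 117-nt CP exon = 39 aa; the
generator plants 22 S/T in 39 aa and the package reports computed values
only.) The clone-library error model is substitution-only at a default
2×10⁻³ per base, a realistic Taq-class misincorporation-plus-cloning rate
for a ~350-bp amplicon; indels are excluded because the survey compares
equal-length Ig intervals. Intergenic spacers are uniform-random sequence
(default 10 kb), standing in for the transposable-element-rich spacers of
real loci.

Planted features are exact by construction: background residues exclude
cysteine and tyrosine, so the only Cys pairs and ITIM tyrosines are the
planted ones, and the CP background excludes Ser/Thr so the planted count is
exact. The generator still re-annotates every gene with the analysis modules
before committing it and regenerates on any mismatch (bounded at 100
attempts). Pseudogene truth: the internal-stop and missing-exon lesions
produce exactly their intended flag; a 1-nt frameshift rewrites every
downstream codon, so incidental downstream stops are near-certain, and the
recorded truth for that mode is the lesion's actual build-time consequence
set (asserted to include the frameshift flag).

Passing the recovery property — annotation reproduces every planted truth
field over 50 seeded configurations — demonstrates that the coordinate
arithmetic, strand handling, translation, region partition, and all motif
scanners are mutually consistent and lossless. It does **not** demonstrate
performance on real data, where Ig domains diverge, motifs degenerate,
annotations carry errors, and repeats confound mapping; the published
single-individual clone counts (81 positive, 7 sequences, 19 singletons) are
properties of one fish and real PCR and are deliberately not targets.

## Problem sizes and determinism

All randomness flows from single integer seeds through numpy's PCG64;
fixed-seed outputs are byte-identical. Test and acceptance runs use
desk-scale sizes chosen as the package's own defaults for quick validation:
spacers of 0.3–2 kb, 50 recovery configurations, 60 additive matrices up to
6 taxa, 100–200 bootstrap replicates on 5-taxon/60-column alignments, and
100-clone libraries.
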