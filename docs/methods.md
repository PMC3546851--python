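# Methods

This note records the models, conventions and design choices behind
seqsuite, in the order a user meets them.

## Sequence model and conventions

A `Sequence` is an immutable, typed string of upper-case residues.
Alphabet detection follows a threshold rule: text is nucleic when the
fraction of A/C/G/T/U characters (after stripping whitespace, digits and
the `\ / |` separators common in pasted GenBank ORIGIN blocks) reaches the
`nucleic_threshold`.  The default threshold is 0.85: high enough to
reject real protein sequences (which rarely exceed ~50% of those five
letters), low enough to tolerate IUB degeneracy codes and sequencing Ns in
genuine DNA.  RNA input is stored with U mapped to T so one code path
serves searching and translation; an `is_rna` flag restores U on output,
making the round-trip lossless.

All user-facing coordinates are 1-based inclusive on the forward strand;
internal computation is 0-based half-open.  A `-` strand hit means the
query matches the reverse complement of the reported interval.

## File formats

FASTA parsing uses Biopython's parser; GenBank support is deliberately
minimal — LOCUS name, DEFINITION and the ORIGIN block — because the
toolkit's job is sequence manipulation, not annotation round-tripping
(feature tables are ignored on input and never written).  The GenBank
writer emits the canonical 60-residue / 10-column ORIGIN layout and a
column-correct LOCUS line; Biopython parses its output cleanly, which a
test verifies.

GCG Wisconsin codon-usage tables are read tolerantly: header lines are
skipped, U-codons are accepted, missing codons are filled with count 0,
and per-amino-acid fractions are renormalized whenever they deviate from 1
by more than 1e-3 (from counts when available, uniformly when an amino
acid has no data — so a sole-codon amino acid like Trp always ends with
fraction 1).

BLOSUM62 ships as an NCBI-format text fixture and is cross-checked
entry-by-entry against Biopython's copy in the test suite; the same parser
reads any user-supplied NCBI-format matrix.

## Translation and ORFs

Genetic codes come from the NCBI translation tables.  Start codons
default to ATG only — the NCBI tables' alternative starts (TTG, CTG)
produce many spurious ORFs in bench use; the set is configurable.
Degenerate codons translate to the unique amino acid when every IUB
expansion agrees, else X.

Uniform reverse translation emits, per residue, the minimal single IUB
codon covering its codon set, computed per position (the per-position
minimum is the global minimum).  Exact covers exist for 17 amino acids;
Leu, Arg, Ser and the stop sign have none, so their covers overgenerate —
`uniform_cover_report()` flags exactness per residue.  X maps to NNN.
Usage-table reverse translation either picks the modal codon
(deterministic, ties broken lexicographically) or samples codons by their
fractions under a caller-supplied seed; in both modes translating the
result returns the input protein exactly.

An ORF spans start codon to in-frame stop, stop included, which makes its
length divisible by 3 and the protein length nt/3 − 1.  One ORF is
reported per stop — the most upstream start, i.e. the longest reading —
rather than every nested start.  With a usage table, each ORF gets a mean
log₂ codon fraction (stop excluded) with fractions floored at 1e-4 so an
absent codon penalizes smoothly instead of producing −∞; ORFs are then
ranked by that score, ties by length.  The combination rule (usage first,
length second) is a design choice; length-only ranking is the default when
no table is given.

## Statistics

n-gram counts use overlapping windows (counts sum to L − n + 1).  %GC
windows count G, C and the degenerate S (C-or-G) as GC and all other
codes as 0 — a convention, documented here, chosen so fully ambiguous
positions cannot inflate GC.  GRAVY is the mean Kyte–Doolittle hydropathy
over standard residues only (X/*/- excluded from both numerator and
denominator); the constants are in `stats.KYTE_DOOLITTLE` and are verified
against Biopython's scale in a test.

## PSFM, information content and logos

`psfm_from_sites` applies background-weighted pseudocounts:
f(b,j) = (count(b,j) + α·p(b)) / (n + α), with α = 1 as the discovery
default so sampling weights and R_i scores never hit log 0.  Degenerate
letters in input sites spread their count over the IUB expansion,
background-weighted.  `psfm_from_consensus` puts uniform mass on each
position's expansion.

Information content per position is either mutual information
(log₂|A| − H) or relative entropy (Σ f log₂(f/p)); the identity between
the two under a uniform background is verified to 1e-9 in the tests.
R_i scoring of a window sums log₂|A| + log₂ f (or log₂ f/p); a window
crossing a zero-frequency cell of a pseudocount-free PSFM scores −∞, a
sentinel rather than an exception, so exhaustive scans never abort.  A
degenerate subject letter (e.g. N in a contig) scores the
background-weighted mean of f over its expansion — 0 bits against a
uniform background, as it should.

The consensus logo is a fixed-row text grid: column j's consensus letter
(ties by alphabet order) sits on the row nearest IC(j)/max_bits · rows,
zero-information letters on the bottom row; the axis is a column of
vertical bars with the bit maximum (2.0 for DNA, 4.3 for protein) printed
at the top and the flat consensus beneath.  The fixed-row grid is the
terminal-friendly, testable analogue of variable letter heights; the
numeric per-position heights are always returned alongside so nothing is
lost to rounding.

## Motif discovery

Both algorithms assume one site per sequence and search the given strand
unless `both_strands` is set (which adds reverse-complement windows as
candidates; a motif may then legitimately be reported in either global
orientation).

*Gibbs sampler*: per restart, random initial sites; then `inner_steps`
(default 100 per sequence) hold-out steps in round-robin order — the
round-robin schedule visits every sequence equally often, reducing
variance relative to random selection.  The hold-out's new site is drawn
with probability ∝ Π_j f(s_j,j)/p(s_j) from the pseudocount-smoothed PSFM
of the other sites.  After every full sweep a phase-shift move evaluates
sliding all sites together by up to ±2 positions and keeps the register
with the highest information content.  Without it the sampler visibly
locks one base off the optimal register in a few percent of planted-motif
runs (every restart falls into the same shifted attractor); the move is
the standard correction from the Gibbs site-sampler literature.

*Greedy search*: per restart, shuffle the sequence order, seed with one
random w-mer from the lead sequence, grow by adding each next sequence's
IC-maximizing w-mer, then refine by coordinate ascent (re-choosing each
sequence's site with the others held fixed, at most 10 passes).  An
exhaustive seeding mode (grow from every lead w-mer) is available; the
random-seed default already recovers planted motifs reliably and is an
order of magnitude faster.

Restarts are ranked by the information content of the final,
pseudocount-free PSFM — so a reported motif's IC is exactly recomputable
from its sites.

*String dyad discovery* enumerates every placement of two equal-length
half-sites (length dyad_len ± d_tol, spacer ± s_tol, direct and/or
inverted) and reports those within the mismatch budget; the score is the
mismatch count.  Both half-sites share one sampled length — allowing the
halves to differ would square the search space for little practical gain.

## Searches

All searches are exhaustive window scans, checked against brute-force
double-loop oracles on random sequences in the test suite.  IUB letters
in a nucleotide pattern match for free (any base in the expansion);
ambiguity in the subject matches when the two expansions intersect.
Protein patterns take no IUB semantics; with a substitution matrix the
window score is the summed pair score and the threshold is a minimum
score rather than a mismatch budget.  Gapped search constrains the total
mismatch count across both halves (per-half counts are reported).
Dyad-pattern search sums the two halves' R_i; by default only the
combined threshold filters, with a per-half floor of 0 bits.

## Alignment

Needleman-Wunsch and Smith-Waterman with a linear (per-character) gap
penalty; affine gaps are out of scope for this version.  Defaults: DNA
match +1 / mismatch −1, gap −2; protein BLOSUM62, gap −4.  The DP matrix
is filled row-wise in NumPy; the within-row LEFT dependency is resolved
with a running-maximum transform, so a 2,500 × 2,500 protein alignment
fills in well under a second.  Traceback re-derives each move from the
stored scores with the fixed tie order DIAG > UP > LEFT (score equality
tested at 1e-9, exact for integer scoring).  Local tracebacks stop at the
first zero cell, and the maximum cell is taken in row-major order for
determinism; an all-negative comparison yields the empty alignment with
score 0 and zeroed coordinates.

## Synthetic data

The generators are pure functions of their spec, seed included.
`generate_planted` draws i.i.d. background residues (uniform ACGT unless
a distribution is given) and overwrites exactly one motif instance per
sequence — sampled per position when the motif is a PSFM — returning a
truth table of planted positions and strands.  `generate_random_genome`
draws bases from a GC-parameterized distribution and can overwrite
stop-free ORFs or spaced dyads, again with a truth table.  These emulate
the *location* structure of real motif data (one site per sequence,
unconstrained flanks) but not its correlations: real genomic background
is not i.i.d., real sites vary in strength, and real collections contain
misannotated sites.  Passing the planted-recovery benchmark therefore
demonstrates algorithmic correctness and convergence, not performance on
curated genomic collections.

The recovery benchmark plants a fully conserved random 8-mer in each of
ten 100-bp uniform sequences and runs 50 independent trials (each trial
draws its own motif, positions and algorithm seed from the master seed);
a trial succeeds when at least 9 of 10 reported site starts equal the
planted ones.  Problem sizes across the test suite (sequences ≤ 1 kb for
search oracles, length ≤ 8 for alignment path enumeration, 50 trials for
recovery) keep the whole suite and the acceptance script to a few minutes
on one CPU while leaving each check statistically meaningful.

## Known limitations

GenBank features are discarded; no affine gaps, banded DP or multiple
alignment; no statistical significance (E-values) for motif or search
scores; no genome-scale indexing — scans are linear per window; protein
logos use the full 20-letter alphabet only.
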