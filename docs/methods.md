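# Methods

## The profiling statistic

A phylogenetic profile labels each of N genomes YES or NO for a trait —
here, presence of a marker gene system — with prevalence p = K/N. Partial
phylogenetic profiling (PPP) scores one protein at a time: its similarity
hit list is walked from the best hit downward, and at each admissible score
cutoff the prefix of hits covers n distinct genomes, y of them YES. Under
the null hypothesis that genomes enter the prefix independently of the
trait, y ~ Binomial(n, p), and the prefix is scored

    score(y, n) = log10 P(X >= y),   X ~ Binomial(n, p).

The protein's score is the minimum over cutoffs (most negative = most
trait-enriched), together with the (y, n, depth) of the winning cutoff,
where depth counts protein hits traversed (a genome hit by several paralogs
counts once in n but each hit in depth, so depth >= n). Ranking a genome's
proteins by this score surfaces candidate trait-linked families and,
simultaneously, a working score cutoff for each family.

Numerics: the tail is computed in log space — log-gamma for the binomial
coefficients and a log-sum-exp over the y..n terms — with two exact
branches: y = 0 gives 0, and y = n gives n·log10(p) exactly (the perfect-
prefix identity, used below for calibration). Point probabilities sum to 1
within 1e-12 for n <= 200. No multiple-testing correction is applied over
cutoff depth; published tables for this method show none.

Cutoff-walk conventions:

- tie blocks of equal bit score are atomic — a cutoff can never separate
  them;
- equal scores resolve to the shallower cutoff (the most parsimonious
  family);
- the empty prefix scores 0 and is a legal outcome;
- the query's self-hit and genome are counted by default (configurable).

### Prevalence calibration against published tables

The exact genome composition behind the published score tables is not
recoverable, but any perfect row (y = n) pins down the prevalence through
the identity score = n·log10(p). The acceptance checks calibrate
p = 10^(−94.521/97) for the PQQ-profile table and p = 10^(−42.079/28) for
the mycofactocin-profile table from their perfect top rows and then
recompute the remaining printed rows, which the upper-tail form reproduces
within 0.005 log10 units. (The point-probability form misses several rows
by ~0.01–0.015, which is what fixes the functional form.) One published row
prints a score identical to the row above it and inconsistent with its own
(y, n) under any calibration; it is treated as a typographical anomaly and
not asserted.

## SIMBAL window mapping

SIMBAL applies the same optimal-cutoff statistic to every subsequence
window of a probe protein. The training set is a protein family partitioned
into TRUE/FALSE by the genome-level profile, with fragments removed
(length < 0.5 × partition median) and each partition greedily thinned so no
kept pair exceeds 80% global-alignment identity (identity = identities /
aligned columns, end gaps counted; "greater than 80%" is strict, so pairs
at exactly 80% are both kept). Two deliberate differences from full-length
profiling:

- each training **sequence** is its own profile unit (no genome collapsing),
  and the null prevalence is p_t = |TRUE| / (|TRUE| + |FALSE|);
- scores are displayed as **−log10 tail** (positive, hotter = larger).

Windows are enumerated on a triangular grid — lengths min_len, min_len +
len_step, … plus the full length, starts stepped by pos_step — so there is
exactly one full-length window (the apex), whose score equals the negated
full-length profiling score of the probe against the training set treated
as single-member genomes (asserted as an invariant). Defaults min_len = 8,
len_step = 4, pos_step = 2 resolve the short diagnostic features the method
is used for while keeping a 150-residue probe to ~1,300 windows; all three
are config-exposed. Window scores are not monotone in window length and no
such property is assumed. Hit ordering uses raw Smith–Waterman scores
(BLOSUM62, gap open 11, extend 1, a length-k gap costing 11 + (k−1)·1);
since only the ordering and tie structure enter the statistic, no bit-score
conversion or E-value model is needed, and the exact scorer has no
word-size heuristics to tune for short windows. Mapping a hot window onto a
homolog of known structure is done by global alignment, reporting the
1-based homolog interval and any gapped positions.

## Short-ORF and motif scanning

Six-frame translation (bacterial/archaeal table 11 only; alternative starts
ATG/GTG/TTG read as Met when initiating) enumerates complete start-to-stop
ORFs with peptide lengths in [20, 120] by default, bracketing the 34–78
residue range of the precursor predictions this scan targets. Because start
sites of short peptides are unreliably predicted, the default reports the
most upstream qualifying start per stop (the longest in-bounds form); a
flag emits all internal starts. Codons containing N translate to X and
never act as starts or stops; ORFs without an in-frame stop are excluded.
Coordinates are 1-based inclusive on the forward strand, stop codon
included, and every emitted ORF re-translates to its peptide (asserted
invariant). A C-terminal motif (literal residues plus `x` wildcards, with a
maximum distance from the terminus, default 0) filters the ORFs. Alignment
conservation is summarized per column over non-gap rows; a column is
invariant iff its dominant fraction is 1, with a helper reporting "k
invariant among the last m columns".

## The synthetic-data generator

Real genome collections at published scale (~1450 genomes) are out of reach
for a test suite, so the generator emulates the statistical structure the
engines assume, with truth labels:

- **marker families**: single-copy, in all and only trait-positive genomes
  (the profile decision rule);
- **dependent families**: only in trait-positive genomes, copy number 1–4
  per genome by default (0 allowed by configuration — a dependent family
  may be absent from any one trait-positive genome, but never present in a
  trait-negative one, which `TruthLabels` enforces);
- **sister clades**: one per dependent family, in every genome, derived
  from the same ancestor and differing *only* inside a planted 15-residue
  diagnostic window (TRUE residue set vs. a position-wise different FALSE
  set, each copied at 90% identity), so windows overlapping the diagnostic
  region discriminate the partitions while the rest of the sequence does
  not;
- **background families**: one copy everywhere, no trait signal;
- **contigs**: per genome, with precursor genes (random N-terminus + a
  conserved 23-residue C-terminal region whose last 8 residues are 7/8
  invariant, ending CGVY) planted only in trait-positive genomes, and decoy
  short genes with a shuffled C-terminal region planted everywhere. Each
  planted cassette is preceded by an in-frame stop so its coordinates are
  exactly recoverable.

Family members are independent substitution-only copies of an ancestor at
75% identity (so ~56% pairwise), which keeps dereplication at 80% from
collapsing partitions. Substitutions hit an exact count of positions
(round((1−identity)·L), without replacement) with BLOSUM62-weighted
replacements, making the realized identity equal the target up to rounding;
no indels, tree structure, or codon-usage realism are simulated, so passing
tests demonstrate the engines' statistical behaviour, not robustness to
alignment-length variation or phylogenetic autocorrelation.

Model-based hit tables (score = 2·L·identity + Gaussian noise, self-hit on
top; a dependent/sister pair shares one table neighbourhood) let the
profiling engine run without any aligner; at zero noise each hit list is
exactly its family ordered by identity.

**Default scale.** 40 genomes, ~160 proteins each, trait prevalence 10%
(4 trait-positive genomes) — the sparser of the two published regimes that
remains informative at 40 genomes. A 3% prevalence at 40 genomes would
yield a single trait-positive genome, making every planted family's score
ceiling (y = n = K with K = 1) reachable by any background protein's
self-hit, i.e. planted/background separation is impossible at that scale;
the ~3% regime is therefore provided as the `sparse` preset (134 genomes,
4 trait-positive). With K = 4 the marker score is 4·log10(0.1) = −4.0 and
the chance a background protein reaches it is ~1e−6 per protein.

## Known limitations

- Raw Smith–Waterman scores stand in for BLAST bit scores; orderings can
  differ from BLAST's heuristic search on real data.
- SIMBAL runtime is quadratic-ish in probe length via the window grid;
  desk-scale probes (a few hundred residues) and training sets (tens of
  sequences after thinning) are the intended regime.
- The generator's trait-positive genomes are unrelated draws; real
  collections carry phylogenetic correlation that inflates profiling scores
  of clade-specific but trait-unlinked families.
- Only translation table 11 is supported in the ORF scanner.
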