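# Methods

## Scope and model

`ddgbs` models the dry-lab side of a double-digest genotyping-by-
sequencing experiment. Genomic DNA is cut by two restriction enzymes
(A, a rarer cutter whose overhang receives the barcoded adapter; B, a
frequent cutter receiving the common adapter). Only fragments with one
end from each enzyme (class AB) acquire both adapters, survive size
selection, and are sequenced single-end from the barcoded end. The
package predicts that fragment pool from a reference sequence, scores
candidate enzyme pairs, and evaluates the resulting genotype data.

## In silico digestion

Coordinates are 0-based and half-open; a cut position *p* severs the
backbone between bases *p − 1* and *p* (the top-strand nick of the
recognition site). This convention makes fragment arithmetic exact —
fragments tile each sequence, and lengths always sum to the sequence
length — and exports directly to BED.

Recognition motifs are IUPAC strings with ambiguity codes; overlapping
matches each produce a cut and duplicate coordinates are deduplicated,
matching physical digestion. Motif letters other than `N` match only
concrete A/C/G/T bases, so ambiguity characters in an assembly (N runs)
never produce spurious sites. Non-palindromic motifs are scanned on
both strands with the reverse-strand top-strand cut at
*i + L − offset*; all seven shipped enzymes (EcoRI, HinP1I, ApeKI,
PstI, MseI, MspI, BglII) are reverse-complement palindromes, for which
the forward scan is exhaustive. Note one consequence of the
single-coordinate convention: mapping cuts through reverse
complementation shifts them by the overhang length *L − 2·offset*; the
test suite asserts that exact relation rather than naive equality.

When both enzymes cut at the same coordinate the cut is counted once
and labelled with enzyme A (a documented precedence rule; the choice
only affects fragment class labels at pathological sites).

Size selection is a hard window (default 300–650 bp) over AB fragments
only. Terminal fragments (touching a sequence boundary) lack one
ligatable overhang and are excluded from all library simulation. Soft
bead-selection tails are deliberately not part of the digest model.

## Library design

Barcodes are drawn by seeded rejection sampling under the constraints
used for variable-length GBS barcode sets: lengths 6–9 nt (staggering
the restriction-site position across sequencing cycles), no `GG` start
(two-channel chemistry reads G as a dark base), pairwise Hamming
distance over the shared prefix ≥ 3 by default (demultiplexing is
prefix-based, so the shared-prefix distance is the one that matters),
and no recreation of either recognition site when the barcode is
followed by the enzyme-A overhang remnant. Exhaustion of the constraint
space raises an error naming the binding constraint.

Adapter molar parts are proportional to the predicted cut counts of the
two enzymes, scaled to a user-chosen total and rounded to one decimal.
The published wet-lab ratio for EcoRI–MseI (0.8:15) reflects additional
bench factors and is not reproduced exactly; the proportionality rule
is the computable content.

Demultiplexing is exact-prefix matching ("good barcode reads");
mismatch tolerance is out of scope. Nested barcodes resolve longest
match first. The residual enzyme overhang is kept on the trimmed read
(trimming it would break tag identity with reads from partial
digests; the choice is documented rather than consequential).

## Evaluation statistics

All CVs are sample SD (n − 1) over mean; at the two decimals reported,
the n vs n − 1 choice is immaterial for the table sizes involved.
Report rounding is decimal half-up throughout.

SNP density tables have a *report-comparison mode* (default) that rounds
per-chromosome densities to integer SNPs/Mb before taking the mean and
CV, because published tables print integers and their summary rows are
consistent with rounded inputs; full precision is retained internally
and both modes agree at the reported precision.

`cv_depth_distribution` computes one CV per fragment across samples,
excluding (and counting) fragments with zero depth everywhere.

## Saturation analysis, ORP and SRP

Subsampling is *nested*: one seeded permutation of the pooled reads is
drawn, and each proportion takes a prefix. This guarantees the
monotonicity of fragment counts that the saturation curve assumes;
independent per-proportion draws would not. A fragment is counted at a
point when at least one of its tags occurs ≥ c times in the subsample
(c = 3 by default, the usual minimum-tag-count rule for separating
real tags from error tags). Unit cost is cost-per-read × reads /
fragments, with cost-per-read = 1 by default so unit cost equals depth.

The ORP is reported on the observed grid with no interpolation (it is
defined on observed points); a minimum on the first or last grid point
is flagged as a boundary, i.e. "not (interior-)reached". The default
proportion grid is {0.1, 0.2, 0.5, 0.8, 1.0}; a finer grid extending
lower (e.g. down to 0.01) locates the minimum better when full-volume
depth is high, and is what the test suite uses.

The SRP uses finite-difference slopes between consecutive points: it is
the first point whose incoming slope is ≤ `slope_tol` (default one new
fragment per 10⁵ reads) with all later slopes also below tolerance;
absent when the curve is still rising at full volume. With zero
tolerance this is the first point at which the fragment count has
stopped increasing.

## Genotype QC

Genotypes are codes 0/1/2/missing over sites × samples with optional
per-call depth and quality; positions are 1-based for VCF fidelity
(via cyvcf2 on read).

Filtering order is fixed and documented: per-call DP/GQ masking first,
then site filters — biallelic, MAF (computed from the non-missing calls
that remain after masking; threshold is ≥, default 0.05), site call
rate ≥ 0.6 — then the sample call-rate filter (≥ 0.01). Re-applying the
same filter to its own output is a no-op in all ordinary cases; it can
differ only when the sample filter removed samples, which changes
per-site MAF/call-rate denominators.

Concordance against array genotypes matches sites on (chrom, pos),
harmonizes REF/ALT orientation (direct, swapped, and opposite-strand
complemented orientations accepted), and drops strand-ambiguous A/T and
C/G sites, counting them. At each depth threshold d ∈ {2..12} only
GBS calls with depth ≥ d are compared; homozygous consistency is
computed over chip-homozygous calls, heterozygous over
chip-heterozygous, and the total is call-weighted (not the average of
the two percentages — a documented choice).

LD is the squared Pearson correlation of allele-dosage vectors over
samples where both calls are present (genotype-based r²; no phasing is
assumed), binned by pairwise distance within chromosomes. Monomorphic
pairs are excluded and counted. The decay distance is the first bin
center whose mean r² falls to or below the threshold (default 0.1).

## Simulator

The generator emulates the study conditions at reduced scale:

- genome: i.i.d. bases at a target GC of 0.42 (avian-like); default
  3 Mb, which yields ≈ 170 AB fragments in the 300–650 bp window under
  EcoRI–MseI — enough for stable curve and CV statistics while keeping
  a full simulate→demultiplex→count cycle under ~2 s;
- reads: 91 nt single-end (the trimmed read length of the platform
  being emulated), from the barcoded end only, with substitution errors
  at 10⁻³ per base by default;
- per-fragment abundance: each fragment × sample draws an independent
  lognormal weight with unit mean and scale σ (default 0.8, matching
  the mid-range of observed depth-CV distributions); read counts are
  Poisson around mean_depth × weight (default mean depth 30×, the
  regime in which single libraries were sequenced). The closed form
  CV = √(e^{σ²} − 1) links σ to the expected per-fragment depth CV,
  making the dispersion machinery directly testable;
- planted SNPs: biallelic, inside read-covered fragment ends (clear of
  the motif remnants), alternate-allele frequency uniform on
  [0.05, 0.5], genotypes Hardy–Weinberg per sample;
- chip matrix: the truth genotypes with independent errors at a
  configurable rate;
- sequencing-style calls (`simulate_gbs_genotypes`): Poisson depth,
  optional binomial allele sampling for heterozygotes (error-free base
  calls), and an optional planted het→hom error rate for recovery
  tests.

What the simulator does **not** emulate: PCR duplicates, indels,
quality-score profiles, methylation-dependent digestion failure,
index hopping, alignment ambiguity from repeats, and population
structure/LD between planted SNPs (sites are independent). Passing
tests therefore validate the arithmetic and the statistical machinery
under clean assumptions, not robustness to those real-data artifacts —
in particular, real CV_depth distributions also carry GC and length
biases that the single lognormal knob collapses into one parameter.

### Statistical notes on test conditions

- The sample CV of a heavy-tailed distribution is biased low at small
  sample counts (for lognormal σ = 0.8, the expected sample CV at
  n = 8 is ≈ 0.76 against a population value of 0.947). Dispersion-
  recovery checks therefore use a 48-plex simulated library, where the
  bias is within the tolerance band; real ddGBS libraries are 96-plex,
  so this is also the realistic regime.
- Depth-CV recovery needs high depth (Poisson noise adds ≈ e^{σ²}/D to
  the squared CV); the default 30× keeps that term small.
- Saturation tests use a proportion grid extended down to 0.01 so the
  unit-cost minimum is interior at 30× full-volume depth.

## Numerical and degenerate-input conventions

- Half-up decimal rounding for all reported values (FCI 4 decimals,
  depth 2, category percents 3, exonic subpercents 2).
- CV of fewer than two values: error in `cv`; NaN for the
  density-table CV of a single chromosome.
- Empty size selection or fully filtered SNP matrices return valid
  empty results with a warning, not an error.
- Zero-depth calls are missing; zero-fragment saturation points carry
  infinite unit cost.
- Seeds: every stochastic routine takes an explicit seed and is
  byte-reproducible given it.
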