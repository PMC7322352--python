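# Methods

## Problem and model

`mrequant` quantifies the expression of microRNA response elements (MREs) —
canonical seed-match sites in 3′UTRs — from RNA-Seq alignments, and selects
the MREs whose expression is specific to one target condition among several
groups. The reporting unit throughout the statistical stages is the
**(gene, microRNA family) pair**: all retained sites of one family on one
gene's UTR are pooled into a single count, since reads rarely distinguish
overlapping site types and the biological question ("does this microRNA
engage this transcript differently in the target condition?") is posed at
the pair level. Site-level detail (type, offset, sequence) is preserved in
the catalog output.

## Catalog

Site sequences are derived from the microRNA seed region (positions 2–8).
With S the DNA reverse complement of positions 2–8, the four canonical site
types on the mRNA are `7mer-m8 = S`, `8mer = S+"A"`, `7mer-A1 = S[1:]+"A"`,
`6mer = S[1:]`; the appended adenine opposite position 1 is recognized
directly by Argonaute rather than by pairing, so it is an A regardless of
the microRNA's first base.

Candidate sites are located by **exact string matching** on the spliced,
sense-strand UTR sequence. For 6–8-nt motifs this is equivalent to a
probabilistic motif scan at any sensible threshold under a zero-order
background — a short exact-match motif either occurs or it does not — and
it makes the catalog deterministic and dependency-free. `N` bases never
match. When site occurrences of one family overlap at a locus, only the
longest is kept (an 8mer occurrence suppresses the 7mer/6mer occurrences it
contains), so one genomic locus yields one site; equal-length ties at an
identical interval keep the first type in canonical order (7mer-m8 before
7mer-A1). Coordinates are 0-based half-open everywhere (BED convention);
`utr_offset` is on the spliced transcript-sense sequence, and a site's
genomic footprint is recovered through the interval map (splice-aware,
strand-aware).

Annotation input is BED6 plus FASTA; the FASTA may be a genome (sequences
extracted by coordinates, spliced in transcript order, reverse-complemented
for minus-strand genes) or per-gene UTR sequences, auto-detected by whether
every gene id appears among the FASTA ids.

## Quantification

Reads are assigned to every gene whose UTR intervals they overlap by at
least `min_overlap` (default 1 nt; a read overlapping two genes' UTRs
counts for both). The per-sample library size N_s is the number of distinct
read ids assigned to at least one UTR — a self-contained definition that
does not require whole-genome totals, and under which a mate pair counts
once.

Two counting modes:

* **sequence** (default): each assigned read is scanned for exact
  occurrences of the family's retained site sequences, in both orientations
  by default (unstranded libraries such as standard TruSeq preparations);
  `--stranded` restricts to transcript-sense matches. Every motif
  occurrence counts, overlapping occurrences included; an occurrence found
  at the same position in both orientations (palindromic site) counts once.
  Soft-clipped bases are part of the scanned sequence but not of the
  aligned span.
* **coordinate**: a read supports a site when its aligned span fully
  contains the site's genomic interval; support is deduplicated per
  fragment (read id), so mates never double-count a site.

The modes agree exactly when reads are error-free substrings of the UTR (a
property the test suite checks on simulated data); on real data sequence
mode is robust to soft-clipping and indels near sites, while coordinate
mode is robust to motif hits created by sequencing error.

## Normalization

Counts c become RPKM-like log2 values

    y_pre = log2(c + 0.5) − log2(N_s / 10⁶) − log2(L_g / 10³),

with L_g the gene's UTR length in nt. The pseudocount 0.5 (log-CPM
practice) keeps zeros finite; both offsets vanish at N_s = 10⁶, L_g = 10³.

The systematic per-sample GC effect is removed by a **binned-median offset
model**: rows are binned by their gene's GC fraction (default B = 20
equal-width bins on [0,1]; bins with fewer than `min_sites` = 50 rows are
merged into their smaller neighbor), m[s,b] is the median of y_pre in bin b
for sample s, m̄[b] the median of m[·,b] across samples, and the correction
δ_s(gc) interpolates m[s,b] − m̄[b] linearly between bin centers (constant
beyond the outer centers). This captures the same systematic trend a
conditional-quantile fit targets while staying deterministic and exactly
testable: at bin centers the corrected per-sample bin medians equal the
grand medians to machine precision. The length/GC covariates are per-gene
and applied to every MRE row of that gene — normalization of site counts
against the properties of the UTR that hosts them. The interpolation makes
the correction vary smoothly *within* a bin, so within-bin ranks are exactly
preserved only when GC values coincide (e.g. at bin centers); for
well-separated values the orderings are unchanged in practice. The fitted
model (bin edges, offsets) is serialized to JSON for reproducibility.

## Selection statistics

**DTK pairwise comparisons (Dunnett's C).** On normalized values, for every
pair of groups (i, j) with means x̄, unbiased variances s², sizes n:

    SE_ij = √(s_i²/n_i + s_j²/n_j)
    q*_ij = [q(α,k,ν_i)·s_i²/n_i + q(α,k,ν_j)·s_j²/n_j] / SE_ij²
    w_ij  = q*_ij · SE_ij / √2,      ν_i = n_i − 1

with q(α,k,ν) the upper-α studentized-range quantile for k groups. The pair
is significant when 0 falls outside d_ij ± w_ij. The procedure is valid
under unequal variances and group sizes, reduces to Tukey-Kramer under
homoscedasticity, and at k = 2 collapses to the unpooled two-sample t
interval via q(α,2,ν) = √2·t_{α/2,ν}. It is conservative (simulated
family-wise error ≈ 0.03 at nominal α = 0.05 with k = 6, n = 13). A pair
with zero variance in both groups is non-significant at d = 0 and flagged
degenerate-significant at d ≠ 0. An MRE is **target-specific** when all
k−1 pairs involving the target group are significant *and* the k−1
target-minus-other differences share one sign; the sign-consistency
requirement is switchable but on by default, since a site that is higher
than some groups and lower than others is not "specific" in any direction.

**NB exact differential test.** On raw counts between the target tumor
group and its normal-adjacent counterpart, following the classic exact-test
structure:

* *TMM factors*: reference column = the one whose upper quartile of
  scaled counts is closest to the mean upper quartile; M/A values on rows
  positive in both columns; 30% of M and 5% of A trimmed from each tail;
  factor = 2^(inverse-asymptotic-variance-weighted mean of trimmed M);
  factors rescaled to geometric mean 1.
* *Common dispersion* by method of moments: counts scaled to the common
  effective library (geometric mean of f_s·N_s); per row and condition
  φ̂ = (v̂ − μ̂)/μ̂²; averaged over conditions, median over rows, floored at 0.
  No empirical-Bayes tagwise shrinkage — a deliberate simplification; the
  common-dispersion median is robust for the matrix sizes targeted here.
* *Conditional exact test*: scaled counts are summed per condition and
  rounded to T and N. Given z = T + N, with a common NB success
  probability the conditional law of T is negative-hypergeometric with
  weights r_T = n_T/φ and r_N = n_N/φ (independent of the mean; binomial
  with p = n_T/(n_T+n_N) in the Poisson limit φ = 0). The two-sided p-value
  sums P(t) over all outcomes with P(t) ≤ P(T) (observed included once;
  a 1e-10 log-scale tolerance absorbs floating-point ties).
  log2FC = log2((T/n_T + 0.5)/(N/n_N + 0.5)).
* *BH step-up* adjustment; selection at FDR < 0.05 and |log2FC| ≥ 2.

**Intersection.** The condition-specific set is the intersection of the
DTK-specific set and the DE-selected set — the two tests see different
aspects (all-groups specificity on normalized values vs paired-condition
effect size on raw counts), and requiring both controls the intersection's
false discoveries at least as tightly as either parent.

**Decoupling** maps the selected (gene, family) set to its unique gene
list, unique microRNA list, pair table, and per-gene multiplicity, all in
deterministic lexicographic order; keys serialize as `gene|family`.

## Synthetic data

The generator emulates the target study design: k = 6 groups (three
subtypes × tumor/normal-adjacent), n = 13 samples per group, one target
tumor group carrying the planted effects. Defaults (the reference
conditions for all end-to-end tests): 200 genes, UTR lengths uniform on
600–1500 nt, GC uniform on 0.35–0.65, 50 microRNA families, 5 planted 8mer
sites per gene (1,000 gene–family rows), 10% of rows target-specific with
|log2FC| = 3 and random sign, baseline mean μ = 20 reads per site per
sample, NB dispersion φ = 0.2, read length 50, zero background reads, mild
lognormal per-sample size factors (σ = 0.15). μ and φ are chosen as
realistic site-level coverage for a deeply sequenced bulk library and a
typical bulk biological coefficient of variation (√φ ≈ 0.45); the effect
size and design sizes mirror the six-group, 13-pairs-per-subtype setting
the pipeline targets.

Truth is exact by construction: family seed motifs are rejection-sampled so
that no site sequence (or its reverse complement) is a substring of
another family's sites, planted sites are spaced more than a read length
apart, and flanking sequence is repaired by GC-preserving base swaps until
it contains no site motif in either orientation. Consequently the catalog
equals the planted site list, coordinate-mode quantification reproduces the
truth counts exactly, and sequence mode agrees. UTR GC is exact to rounding
(the flank composition compensates for the planted sites' bases).

What the simulator does *not* emulate — and what passing tests therefore do
not demonstrate about real data: sequencing errors and quality variation,
paired-end fragments (reads are single-end; mate deduplication is exercised
by hand-built unit fixtures), multi-interval UTRs (splicing is exercised in
annotation unit tests), multi-mapping, alignment artifacts, motif hits
created by error, expression-dependent GC bias curvature beyond a smooth
per-sample trend, and correlation between tumor and matched normal samples
(the exact test is unpaired, see limitations).

Determinism: one `numpy` Generator seeded from `SimConfig.seed` drives
every draw in a fixed order; outputs are byte-identical across re-runs and
platforms for a fixed seed.

## Numerical choices

* Studentized-range quantiles from `scipy.stats.studentized_range.ppf`,
  cached per (α, k, ν) — one evaluation per distinct group size.
* Conditional exact-test pmf evaluated in log space via `gammaln` and
  normalized by `logsumexp`; enumeration over t = 0..z is vectorized.
* Degenerate inputs: zero library size is an error (a sample with no UTR
  reads cannot be normalized); zero-variance DTK pairs as above; all-zero
  DE rows give p = 1, log2FC = 0; empty co-positive row sets give TMM
  factor 1 with a warning.
* GC bins that would be fit on fewer than 50 rows are merged before
  fitting; with all mass in one bin the correction reduces to per-sample
  median centering.
* Tie-break in the two-sided exact test: outcomes whose probability equals
  the observed one (within 1e-10 in log space) are included once.

## Design choices made where the design was open

* Which site types enter the catalog is a setting (default: all four);
  precomputed site sequences can also be supplied directly in the motif
  table, bypassing seed expansion.
* Occurrences (not reads) are tallied in sequence mode, matching per-match
  motif-scan semantics; switchable in the API by using coordinate mode.
* The DE comparison is target tumor vs its normal-adjacent group,
  configurable via `de_reference_group` (inferred from the `*_tumor` →
  `*_normal` naming convention when possible).
* Sign consistency across the k−1 target comparisons is required (and
  switchable via `select_target_specific`).

## Limitations

* The exact test ignores tumor/normal pairing; with strongly correlated
  pairs it is conservative.
* Common (not tagwise) dispersion: rows with atypical dispersion are
  mis-calibrated in proportion to their deviation from the median.
* Binned-median GC correction removes monotone-ish smooth trends; sharp
  within-bin GC structure is only attenuated.
* Exact matching does not model non-canonical or bulged sites, conserved-
  site scoring, or 3′-supplementary pairing — out of scope by design.
* Sequence-mode counts can include motif occurrences created by sequencing
  error in real reads; coordinate mode avoids this at the cost of requiring
  full site containment.
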