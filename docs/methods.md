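# Methods

This note documents the models and procedures implemented in trfkit, the
parameters that matter, the design choices made where a published
description left the design open, and what the synthetic benchmark does and
does not demonstrate.

## Reference construction

Mature tRNA references are built from genomic tRNA gene sequences by
excising annotated introns, appending one `CCA` trinucleotide, and merging
genes whose processed sequences are identical into single entries. The CCA
tail is appended unconditionally — genomic tRNA genes do not encode it, so
an existing `CCA` suffix on a gene is genomic coincidence, and adding a
single uniform tail keeps the reference construction rule simple and
reversible. Merged entries take the isotype/anticodon annotation of the
lexicographically first contributing gene (disagreements are warned about;
they indicate annotation conflicts upstream). Reference ids are assigned by
sorting on (isotype, anticodon, sequence), which makes outputs diff-stable
across runs and input orderings.

Extended references keep every locus separate and pad the *unspliced*
genomic sequence with 50 nt of flanking context per side (no splicing, no
CCA): fragments of the 5′ leader and 3′ trailer are products of the
unprocessed precursor, and their flanking sequence is locus-specific even
when gene bodies are identical. All coordinates in reports are 1-based
inclusive. Sequences live in DNA space (`T`, not `U`); FASTA inputs
containing `U` are normalized on read.

## Mapping

Reads are size-filtered to the library's physical size selection
(15–35 nt, inclusive) and matched as exact, full-length, sense-strand
substrings of the references. A read with k placements — counting every
position on every reference, including multiple positions within one
reference — receives weight 1/k at each placement, so total weight per
mapped read is exactly 1. Exact matching is a deliberate simplification:
it is fully reproducible, sufficient for the synthetic benchmark (reads are
error-free fragment copies), and conservative on real data, where a small
loss of mismatched reads trades against zero mapping ambiguity. Mapping
runs mature-first: reads placed on any mature sequence are never offered to
the extended reference, which prevents mature-fragment coverage from being
double counted as precursor coverage. The precedence direction is a design
choice; the reverse order would misattribute the (much more abundant)
mature fragments to precursor loci.

Per-(reference, library) profiles accumulate boundary and depth coverage:
`start_counts[p]`, `end_counts[p]` and `depth[p]` as summed alignment
weights. Weight conservation (Σ start = Σ end = Σ weights) holds to 1e−9
and is asserted in tests.

## Fragment calling

Fragment boundaries are detected on profiles pooled across all libraries,
so that one fragment catalog is shared by the cohort and per-library
quantification is comparable. A position is a boundary peak when its count
is (i) at least `min_count` (default 2), (ii) at least `noise_fraction`
(default 0.10) of the maximum within ±`window` (default 4) positions, and
(iii) maximal within that window, ties resolved toward the smaller
position. Candidate (start, end) pairs within the size window become calls
only when the summed weight of reads matching *both* boundaries within
±`tol` (default 0) reaches `min_support` (default 5). Joint boundary
support is the central correctness decision: with two overlapping fragment
populations, the spurious pairing of one population's start with the
other's end has no jointly matching reads and is never emitted.

These defaults were chosen so that planted fragments with ≥ 50 supporting
reads are recovered exactly against low uniform background; all four knobs
are exposed on the CLI. The caller is this package's own boundary-detection
procedure, specified and tested as above.

Quantification re-maps reads to the catalog by exact sequence identity; a
read equal to k identical-sequence calls contributes 1/k to each, and the
subsequent merge restores the full count, conserving total mass exactly.

## Catalog classification

Calls with identical sequences are merged into one tRF per distinct
sequence (sequencing cannot attribute an identical read to one locus).
Classes are computed from the member with the highest pre-merge support,
ties broken by (ref_id, start); minority members' labels are retained in a
diagnostics column. Classification rules, all on the mature (spliced,
CCA-appended) sequence, 1-based:

* origin: 3′ end at position ≤ 40 → 5′-derived; 5′ end at position ≥ 30 →
  3′-derived; otherwise "other". For fragments of length ≥ 15 the rules are
  provably disjoint (both firing would force length ≤ 11); the test suite
  verifies this by exhaustive enumeration.
* type: start 1 → `5e`; 12–23 → `D`; 31–39 → `A`; 45–49 → `V`; 50–60 →
  `3e`. Starts in the gaps stay `unclassified` rather than being snapped to
  the nearest class: the ranges are treated as exact, and the fixed ranges
  are not adjusted per tRNA for long variable loops.
* pre-tRNA: fragments entirely upstream/downstream of the mature gene on an
  extended reference are leader (5′U) / trailer (3′U) fragments, with the
  gap in nucleotides to the mature boundary (0 = directly adjacent); any
  overlap with the gene body voids the label.

Summaries (length, origin, type, start/end position, adjacency) are
computed twice: by uniqueness (each tRF counted once) and by abundance
(weighted by summed counts). Type and origin summaries cover mature-derived
tRFs; leader/trailer tRFs are summarised separately, including the fraction
within 1 nt of the mature boundary.

## Differential expression

Counts are normalized as parts per million of the library's total mapped
reads (not just catalog reads). Each tRF is tested with the pooled
two-proportion Z-test — the construction of Kal's test for comparing a
tag's relative frequency between two count libraries:

    p1 = x1/N1,  p2 = x2/N2,  p0 = (x1+x2)/(N1+N2)
    z  = (p1 − p2) / sqrt(p0 (1 − p0) (1/N1 + 1/N2))

two-sided p from the standard normal, no continuity correction, degenerate
inputs (x1 = x2 = 0, or pooled proportion 0/1) returning (0, 1). Fractional
counts from multi-mapper splitting are accepted. Counts are pooled within a
group before testing — each sequencing library is itself a pool of samples,
and the test compares one proportion per group; replicate-aware dispersion
modeling (negative binomial etc.) is intentionally out of scope for this
design. Bonferroni m = number of tRFs with nonzero pooled count in at least
one of the two groups (the most conservative natural family). Fold changes
are computed in ppm space with a baseline of 1 substituted for zero ppm, so
appearance/disappearance events remain finite; |fold| ≥ 4 marks strong
changes. tRFs significant in every case-group comparison are intersected
and categorized as consistently up, consistently down, or mixed.

## Biomarker

ΔCT = CT(target) − CT(reference gene); ΔΔCT subtracts a calibrator, which
defaults to the mean ΔCT of the control group (configurable — the choice of
calibrator only rescales all relative expressions by one constant);
relative expression = 2^−ΔΔCT with amplification efficiency fixed at 2.
Samples without a reference-gene CT are excluded with a warning. The
biomarker score is the ratio of the up-regulated to the down-regulated
tRF's relative expression; both the geometric and arithmetic group means
are reported.

Mann-Whitney U uses midranks for ties and reports U = min(U1, U2). With at
most 7 observations per group the two-sided p is exact — all C(n1+n2, n1)
labelings are enumerated and p = min(1, 2 × smaller tail count / total);
larger samples use the normal approximation with the tie correction and no
continuity correction.

Survival strata come from a median split of the ratio (ties to "low"; a
fixed published cutoff can be supplied instead — an optimized cutoff is
deliberately not offered as it would bias the p-value). The two-group
log-rank statistic compares observed events per stratum with their
hypergeometric expectation under the pooled risk set at each distinct event
time; chi-square with 1 df. Strata with subjects but no events contribute
risk only and keep the statistic finite.

## Synthetic data

The generator emulates the statistical structure of a pooled small-RNA tRF
study; its defaults are the benchmark conditions:

* **Gene set**: 80 random genes of 70–95 nt, 10% exact duplicates (these
  collapse in the mature reference), 15% carrying one 10–20 nt intron after
  gene position 37, and 3 intron-free gene pairs sharing their first 40 nt
  so that short 5′ fragments genuinely multi-map. Random sequences are not
  folded cloverleaves; classification uses fixed position ranges, so
  realistic secondary structure is unnecessary — a documented limitation.
* **Fragments**: 200 mature fragments with class-anchored starts (1 for
  `5e`; uniform in 12–23 / 31–39 / 45–49 / 50–60 for `D`/`A`/`V`/`3e`) and
  lengths drawn from a 15–35 nt distribution with mode 19 (40% mass) and a
  25–29 nt shoulder; plus 12 leader/trailer fragments whose gap
  distributions put ~60% (trailers) and ~30% (leaders) within 1 nt of the
  mature boundary. Class read mass follows the abundance mix exactly
  (`5e` 0.75, `D` 0.07, `A` 0.06, `V` 0.05, `3e` 0.07; pre-tRNA fragments
  share a separate 3% pool, reflecting their overall low expression), with
  i.i.d. lognormal (σ_log = 1) heterogeneity within classes for realistic
  rank-abundance curves.
* **Boundary identifiability**: distinct planted start (or end) values on
  one reference must differ by more than the caller's ±4 peak window
  (shared equal boundaries are allowed), and this constraint is enforced at
  every reference where a fragment's sequence occurs. Without it, two
  planted boundaries within one window would suppress each other by
  construction and recovery would measure the packing, not the caller.
* **Libraries**: one pooled library per group, multinomial at 1e5 reads
  (exact depth simplifies conservation assertions; no sequencing error or
  adapter read-through is modeled). Expected ppm of a fragment equals 1e6 ×
  its group probability.
* **Group effects**: 10 fragments ×4 and 10 fragments ×1/4 in the case
  group, placed on mid-abundance (20th–80th percentile) fragments, with the
  down-regulated mass chosen to approximately offset the up-regulated mass.
  The balancing matters because the libraries renormalize to fixed depth:
  grossly unbalanced effects would shift every null fragment's proportion
  between groups and turn the compositional artifact into spurious DE. (In
  real libraries the ppm denominator is dominated by non-catalog reads, so
  the artifact is negligible there.)
* **qPCR cohort**: reference-gene CT ~ Normal(20, 0.2) cycles; target CT =
  reference CT + true ΔCT + Normal(0, 0.2), with true ΔCT shifted by
  −log2(fold) in affected groups. Default groups: control (n = 40, no
  follow-up), cured (n = 20, mild opposing effects ×2 / ×0.5, baseline
  hazard 1/60 per month) and recurrent (n = 20, strong effects ×8 / ×0.125,
  hazard ×3), with independent Uniform(0, 120 months) censoring — so the
  ratio-defined strata coincide with the true hazard strata.

All generators are pure functions of (config, seed); identical inputs give
byte-identical outputs, which the determinism tests assert at the file
level for the whole pipeline.

## What the benchmark does and does not show

Passing the planted-truth suite shows the pipeline's bookkeeping is exact
(weights, profiles, merges conserve mass to 1e−9), its caller recovers
identifiable boundaries, its classifier implements the stated rules
exactly, and its tests are calibrated (Bonferroni FWER ≤ 0.05 on nulls,
planted ≥ 4-fold effects detected with high power at 1e5 reads). It does
not show performance under sequencing error, adapter contamination,
RNA-modification-induced mismatches or truncations, fuzzy fragment ends, or
real tRNA sequence conservation, all of which make real boundary calling
harder than the synthetic case. Problem sizes (80 genes, 200 + 12
fragments, 1e5 reads/library, 200 null replicates) are the package's
benchmark defaults; all are configurable upward.

## Degenerate inputs and numerical conventions

Empty read sets, empty catalogs and all-zero profiles yield empty outputs,
not errors. Unmapped reads are a status. Zero ppm uses the baseline-1
convention in fold changes only; tests report them untested with p = 1.
All percentages sum to 100 within 1e−9 per view. Ties: boundary peaks to
the smaller position; catalog representatives by (ref_id, start); median
dichotomization to "low". Floats are written with `%.10g`, which makes
written outputs byte-stable.
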