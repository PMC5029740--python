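# trfkit

A tested, reusable pipeline for discovering, quantifying, classifying and
comparing **tRNA-derived fragments (tRFs)** in small RNA sequencing data,
with a qPCR/survival biomarker module. It is aimed at transcriptomics
researchers who work with size-selected (15–35 nt) small-RNA libraries and
want a transparent, fully scripted alternative to GUI-driven tRF analyses.

## What it does

1. **Reference construction.** From a set of genomic tRNA genes (FASTA plus
   a GtRNAdb-style annotation with isotype, anticodon, introns and genomic
   flanks) it builds two mapping targets:
   * a *mature* reference — introns excised, the post-transcriptional `CCA`
     tail appended, and genes with identical processed sequences merged into
     single entries;
   * an *extended* reference — each unspliced gene padded with 50 bp of
     genomic context per side, for fragments of the pre-tRNA 5′ leader and
     3′ trailer.
2. **Mapping.** Reads are size-filtered to 15–35 nt and exact-matched to the
   references. A read with k placements carries weight 1/k at each (equal
   division across multi-mapping locations); reads are mapped mature-first
   so precursor coverage is not double counted.
3. **Fragment calling.** Candidate 5′/3′ boundaries are local maxima of the
   pooled start/end coverage profiles (±4 nt window, noise floor). A
   (start, end) pair becomes a fragment call only when enough reads match
   *both* boundaries jointly, which prevents chimeric calls from overlapping
   fragment populations.
4. **Catalog.** Calls with identical sequences are merged into unique tRFs
   (counts summed), then classified: 5′-derived (3′ end at mature position
   ≤ 40) vs 3′-derived (5′ end at position ≥ 30); the five positional
   classes keyed on the start position — `5e` (1), `D` (12–23), `A` (31–39),
   `V` (45–49), `3e` (50–60); and leader/trailer status with the gap to the
   mature boundary. Summaries are reported both by *uniqueness* (each tRF
   once) and by *abundance* (weighted by reads).
5. **Differential expression.** Counts are normalized to parts per million
   and compared between pooled libraries with the two-proportion Z-test on
   pooled counts (Kal's test),

   `z = (p1 − p2) / sqrt(p0 (1 − p0) (1/N1 + 1/N2))`, `p0 = (x1+x2)/(N1+N2)`,

   Bonferroni-corrected across the catalog, with a baseline of 1 ppm for
   unexpressed tRFs and a ≥ 4-fold flag; tRFs significant in every case
   group are intersected and categorized by direction agreement.
6. **Biomarker.** qPCR CTs are converted to relative expression by the
   ΔΔCT method (2^−ΔΔCT, normalized to a reference gene, calibrated on the
   control group); the ratio of an up- and a down-regulated tRF is compared
   between groups by the Mann-Whitney U test and used to stratify
   progression-free survival (median split, two-group log-rank test).

A seeded synthetic-data module generates tRNA gene sets, fragment
populations, multinomial sequencing libraries with planted ≥ 4-fold group
effects, and qPCR/survival cohorts with known ground truth, so every stage
is testable end to end without external downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic preset (seed 7; small tables land in `results/`, bulky data in
`scratch/`):

```bash
python analysis/01_simulate_study.py
python analysis/02_run_pipeline.py
python analysis/03_differential_expression.py
python analysis/04_biomarker_survival.py
```

`02_run_pipeline.py` prints:

```
fragment calls (pre-merge): 221
unique tRFs (post-merge):   212
boundary recovery: 209/209 well-sequenced planted fragments (100.0%)
class accuracy:    200/200 (100.0%)
pre-tRNA labels:   12/12 (100.0%)

type-class proportions (% of unique tRFs / % of reads):
       uniqueness_pct  abundance_pct
3e                7.0            7.1
5e               75.0           74.5
A                 6.0            6.0
D                 7.0            7.4
V                 5.0            5.1
```

Reading: 221 boundary calls collapse to 212 unique tRFs after
identical-sequence merging (multi-mapped fragments were called on several
references); every planted fragment with ≥ 50 reads is recovered with exact
boundaries and lands in its planted class; the abundance-weighted share of
5′-end fragments reproduces the planted 75% mix.

`03_differential_expression.py` plants a 12-tRF signature shared by three
case groups and recovers it:

```
PCa6 vs NAP: 12 significant tRFs (7 with >=4-fold change)
PCa7 vs NAP: 14 significant tRFs (3 with >=4-fold change)
PCa8 vs NAP: 14 significant tRFs (2 with >=4-fold change)

common to all case groups: 12 tRFs (5 up, 6 down, 1 mixed)
```

`04_biomarker_survival.py` shows the ratio biomarker separating cured from
recurrent disease and stratifying survival:

```
  PCa_cured (geomean 4.49) vs PCa_recurrent (geomean 68.46): U=0, p=6.30e-08
log-rank, high vs low ratio (median split): chi2=6.68, p=0.0098 (n=20/20, events=15/13)
```

The same stages are available as a CLI (`trf build-ref`, `trf map`,
`trf call`, `trf classify`, `trf de`, `trf biomarker`, `trf simulate`, and
`trf run --config run.yaml` for the one-shot pipeline).

## Layout

```
src/trfkit/        library: reference, mapping, caller, catalog, de,
                   biomarker, simulate, evaluation, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             unit, property and acceptance tests (pytest)
scripts/           acceptance.py
docs/methods.md    models, assumptions, parameter choices, limitations
```
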