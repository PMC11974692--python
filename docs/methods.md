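# Methods notes

This note records the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions that matter for
reproducibility. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and gene models

Internal coordinates are 0-based half-open; GFF3/GTF (1-based
inclusive) is converted on read/write. Multi-transcript genes are
collapsed to one representative transcript — the largest exonic length,
ties broken by lexicographically smallest transcript ID — because the
retention statistic is defined per annotated intron, not per isoform.
Intron and exon ordinals count in transcription order (ordinal 1 is
5′-most), so "first intron" and the 5′/3′ flanking exons are
strand-aware; unstranded annotations are rejected rather than guessed.
Overlapping genes are not disambiguated: each junction or intron is
attributed to the gene the input table assigns it to.

## Intron retention (IDratio)

* **Statistic.** Intron mean depth over the mean of both flanking-exon
  depths; first/last introns use only the 3′/5′ flanking exon because
  terminal-exon coverage is distorted by library-preparation bias. A
  single-intron gene's intron is both first and last; it uses the
  symmetric two-exon average and is in any case removed by filter
  criterion 5.
* **Prefilter.** Mean raw-scale IDratio ≥ 0.15 in at least one group
  (means over replicates where the ratio is defined). This keeps the
  imputation step honest: columns retain enough finite values to
  estimate their moments.
* **Imputation.** Per sample column on the log2 scale: non-finite
  entries are drawn from Normal(m − 1.8·s, (0.3·s)²), with m, s the
  finite-entry mean/SD of that column — the left-censoring convention
  from desktop proteomics, whose (1.8, 0.3) parameter pair these values
  are. The "0.3" is read as the width factor, not a mean multiplier;
  that is the convention the parameter pair comes from. Columns with
  fewer than 3 finite values raise an error instructing a wider
  prefilter rather than imputing from meaningless moments.
* **Test.** Student's pooled-variance two-sample t on log2 IDratios
  (Welch available via `RiParams(equal_var=False)`). Fold change is
  2^(mean difference) of the imputed log2 values, so introns undefined
  in one group remain testable; the raw-scale means used by filter
  criteria 3/4/6 are never imputed. Degenerate case: both groups with
  zero variance and equal means gives p = 1 by convention (p = 0 when
  the means differ).
* **Filter cascade.** Boundary semantics follow the filter definitions
  exactly: ≤ for p, ≥ for FC and intron depth, strict > for RPKM and
  the criterion-6 IDratio, ≥ for the 15% prefilter. No multiple-testing
  correction is applied to retention calls — the cascade filters on raw
  p ≤ 0.05 by design; the permutation FDR machinery exists only on the
  proteomics side.

## Junction events

An end of a junction is *annotated* when it coincides with the
corresponding boundary of an annotated intron. Exon skipping requires
both ends annotated on different introns with at least one whole exon
strictly inside; a junction with annotated acceptor but novel donor
(strand-aware) is an alternative donor, the mirror case an alternative
acceptor, and both-novel junctions that do not skip a whole exon are
combined donor+acceptor. Partial exon overlap with novel ends therefore
falls to the combined class, a deliberate tie-break.

The per-replicate usage statistic is (junction reads + 0.5) / gene
reads; the pseudocount keeps log2 finite at zero counts. The exact
normalisation used by depth-extractor pipelines varies, so it is
defined here explicitly and echoed in output headers. Events with fewer
than 2 supporting reads in every replicate of both groups are not
tested. Gates: gene RPKM ≥ 1 (events on genes below 1 are dropped;
"< 1" is strict), p ≤ 0.05, FC ≥ 1.5 or ≤ 1/1.5.

## LFQ enrichment

* **Filtering.** Intensities are log2-transformed (zeros are missing,
  the MaxQuant convention); a protein is kept with ≥ 3 finite values in
  at least one group — bait-exclusive proteins are signal, not noise.
  The in-group minimum is configurable because upstream filters differ
  between labs.
* **Moderated statistic.** d = (mean difference)/(pooled SE + S0) with
  S0 = 2; at S0 = 0 this is exactly the pooled t, which the tests
  assert to 1e-12.
* **Permutation FDR.** All distinct balanced relabelings of the sample
  columns, identity excluded and complements de-duplicated (9 for
  3 vs 3, so the null is exhaustive and the procedure deterministic; a
  seeded subsample caps larger designs at `n_permutations`). For a
  candidate cutoff c, the false-discovery proportion is estimated as
  the *mean* permuted count of |d| ≥ c over the observed count — the
  expected-false-positives form. The median form is deliberately not
  used: with a handful of exhaustive permutations the median count at
  the top observed |d| is 0 roughly half the time under the null, which
  would grant a free false positive on null data. The loosest cutoff
  with estimate ≤ FDR is selected (step-up); because the passing set is
  nested in the target FDR, the significant set shrinks monotonically
  as the target tightens.
* **Interaction-change classification.** Relative to the full-length
  bait's significant, positively enriched set: *lost* = no longer
  significant with the variant bait; *reduced* = significant but log2
  difference at least 1 below the full bait's; else *retained*.

## Biotin signature ion and SILIA

The diagnostic fragment is the immonium ion of biotinyl-lysine after
ammonia loss: residue mass − CO + H + biotin (C10H14N2O2S, +226.0776)
− NH3 = 310.1589 for 14N peptides; metabolically 15N-labeled peptides
retain exactly one labelable nitrogen in this fragment (one lysine
nitrogen leaves with the NH3; the biotin moiety is added post-labeling
and stays light), giving 311.1559. The filter accepts a spectrum when
any peak lies within 20 ppm of either value — matching the typical MS2
search tolerance; an absolute-Da window can be passed instead. Spectra
are written at full precision, not the rounded 310.16, so the tolerance
logic is genuinely exercised.

Full-15N labeling shifts a peptide by (number of N atoms) × 0.9970349
Da, counted over backbone and side chains from the elemental
composition. Bait/control ratios honour the reciprocal design (Fw:
light/heavy, Rv: heavy/light); a zero-control ratio is reported at a
documented ceiling of 1000. Protein ratios are medians of peptide
ratios ("medium ratio" in common usage notes is read as median);
peptide-level high-confidence calls need ≥ 10-fold in ≥ 3 of 4
experiments. Intensities are taken from the input table; XIC
integration is upstream.

## Network integration

Tiers are evaluated 1 → 5, first match wins, which turns the
"exclusively"/"not already" phrasing of tiered evidence schemes into a
deterministic, order-independent rule; baits are force-included in
tier 1. Tiers 1–3 accept ACINUS evidence at either protein or peptide
level, as the scheme states; only tier 5 applies the stricter 3-of-4 /
≥10-fold peptide rule. The hypergeometric overlap test needs an
explicit universe size: the number of features tested in both compared
analyses is the honest default, and the functions refuse to guess.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed); one master seed
fans out to per-generator child seeds through `SeedSequence` spawn
keys, so generators are independent of call order.

* **Depths.** Per-gene expression is log-normal (log-mean 4.5, log-SD
  0.8 → median depth ≈ 90); replicate noise is negative binomial with
  size 20 (variance μ + μ²/20), a typical biological-replicate
  overdispersion. Intron depth is gene expression × a true retention
  fraction (uniform 0.2–0.5 by default so the 15% prefilter is
  non-trivially exercised); spiked introns multiply the test-group
  retention by a drawn fold change (default choices 1.5/2/3), capped at
  0.95. Optional zeroing of flanking exons creates genuinely undefined
  IDratios for the imputation path. Not emulated: positional coverage
  bias within features, GC effects, mappability — the generator feeds
  the depth-table contract, not an aligner.
* **Junctions.** Spiked novel junctions are constructed per class and
  verified against the classifier at construction, so truth labels are
  exact by definition; counts are Poisson around usage × gene reads.
  Splice-site sequence context is not modelled.
* **LFQ.** Log-normal intensities (log2 baseline 25 ± 2, replicate SD
  0.3), missingness logistic in the latent intensity (intercept −2,
  slope 0.8 → ≈ 12% missing at the mean, strongly left-censored). Not
  emulated: shared-peptide protein grouping, ratio compression,
  between-run normalisation drift.
* **Benchmarks and their scope.** The type-I-error suite runs the full
  IDratio pipeline on spike-free data at ~10⁴ introns and checks the
  p ≤ 0.05 fraction against a binomial 3σ band — this validates test
  calibration under NB noise, not power. The recovery benchmarks are
  run in the low-noise regime on purpose: the RI fixture uses deep
  coverage (log-mean 5.5) with near-Poisson noise (NB size 100) and 20
  spikes at fold change 3, the LFQ fixture 50 proteins at log2 effect 4
  with missingness disabled, because a protein censored out of one
  group is unidentifiable by any caller after left-censored imputation.
  Passing them shows the callers recover strong, well-measured effects
  exactly; it says nothing about sensitivity at 1.5-fold effects or
  under heavy censoring, which the defaults deliberately leave hard.
  Problem sizes (10⁴ introns; 500 proteins; ~600-intron recovery
  fixtures) were chosen as the smallest scales at which the binomial
  bands are meaningful.

## Known limitations

* One representative transcript per gene; isoform-resolved retention is
  out of scope.
* The junction-usage statistic is a reconstruction of common practice,
  recorded in output metadata, not a reimplementation of any specific
  extractor's internals.
* The permutation FDR with 9 relabelings has a granular null; with
  larger designs (more permutations) the threshold estimate smooths
  out.
* PSM-level search, match-between-runs, and protein grouping belong to
  the upstream search engine and are not modelled.
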