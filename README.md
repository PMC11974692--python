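# proxisplice

Analysis toolkit for two intertwined questions about the plant
alternative-splicing (AS) machinery:

1. **Which introns and splice sites change?** Quantify intron retention
   from RNA-seq read-depth tables via the *IDratio* statistic and call
   exon-skipping / alternative donor / alternative acceptor events from
   non-annotated splice junctions, with the full filter cascade used in
   retained-intron studies of *Arabidopsis* mutants.
2. **Which proteins sit near a splicing factor in vivo?** Analyse
   TurboID proximity-labeling mass-spectrometry data: S0-moderated
   enrichment testing with permutation FDR on LFQ intensity matrices,
   biotin signature-ion filtering of MS2 peaklists, 14N/15N SILIA ratio
   quantification with reciprocal labeling, and five-tier integration of
   the evidence into a high-confidence interactome network.

It is written for bioinformaticians working on plant RNA processing who
have depth/junction tables from a read-depth extractor and protein
tables from a search engine, and want the downstream statistics to be
reproducible, seeded and tested. A synthetic-data module generates every
input format with known ground truth.

## The statistics at the core

**IDratio.** For an intron with mean read depth $d_I$ flanked by exons
with mean depths $d_{5'}$ and $d_{3'}$,

$$\mathrm{IDratio} = \frac{d_I}{(d_{5'} + d_{3'})/2},$$

an estimate of the fraction of the gene's transcripts that retain the
intron (IDratio 0.10 ⇒ ~10% retention). First and last introns divide
by the 3′ or 5′ flanking exon alone, because terminal-exon coverage is
biased. Undefined ratios (zero denominator) are imputed per sample from
a downshifted normal, $\mathcal N(m - 1.8s,\ (0.3s)^2)$, on the log2
scale. Group differences are tested with a two-tailed two-sample
t-test on log2 IDratios (n = 4 vs 4 by default), and an intron is called
*increased* retention when all of: p ≤ 0.05; fold change ≥ 1.5; gene
RPKM > 1; mean intron depth in the test group ≥ 5; the gene has more
than one intron; and the test-group mean IDratio > 0.15. For
*decreased* calls the depth and IDratio gates use the reference group
and FC ≤ 1/1.5. Only introns with a mean IDratio ≥ 15% in at least one
group enter testing.

**S0-moderated enrichment.** Per protein, on log2 LFQ intensities,

$$d = \frac{\bar x_\text{bait} - \bar x_\text{control}}{se_\text{pooled} + S_0},
\qquad S_0 = 2,$$

the SAM-style moderated t. Significance is thresholded on $|d|$ by a
permutation FDR: the null is built from all distinct balanced
relabelings of the samples (exhaustive for the 3 vs 3 design), and the
loosest cutoff whose estimated false-discovery proportion is ≤ 0.05 is
selected.

**Biotin signature ion.** Biotinylated-lysine spectra carry the ImKBio
− NH₃ diagnostic fragment at m/z 310.1589 (14N) / 311.1559 (15N);
peaklists are screened for a peak within 20 ppm of either value before
search. SILIA bait/control ratios are light/heavy in forward mixes and
heavy/light in reverse mixes; protein ratios are peptide-ratio medians,
and peptide-level hits require ≥ 10-fold enrichment in ≥ 3 of 4
reciprocally labeled experiments.

**Network integration.** Evidence from three baits (ACINUS, PININ,
SR45) is combined tier by tier, first match wins: (1) all three baits;
(2) ACINUS + PININ; (3) ACINUS + SR45; (4) ACINUS at both protein and
peptide level; (5) peptide-level only under the 3-of-4 / ≥10-fold rule.
Overlaps between result sets are tested with the hypergeometric upper
tail.

## Worked example

Simulate a 4-vs-4 depth experiment with 5% of introns spiked at 1.5–3×
retention, fit the model, and call events:

```python
import proxisplice as px
from proxisplice.simulate import gen_gene_models, gen_depth_experiment

models = gen_gene_models(n_genes=200, seed=1)
depths, truth = gen_depth_experiment(models, ri_spike_fraction=0.05, seed=1)
res = px.IntronRetentionModel(depths, px.RiParams(seed=1)).fit()
print(res.summary())
```

```
Intron retention (IDratio) differential analysis
================================================
introns (total / prefiltered for testing): 775 / 775
groups: wt (ref) vs mut (test)
alpha=0.05  FC cutoff=1.5  min RPKM=1.0  min depth=5.0
increased retention events: 36
decreased retention events: 11
```

```python
inc = res.call_events("increased")
print(inc[["feature_id", "mean_idr_ref", "mean_idr_test",
           "fold_change", "p_value"]].head(5).to_string(index=False))
```

```
        feature_id  mean_idr_ref  mean_idr_test  fold_change  p_value
GENE00007:intron:4      0.378274       0.775148     2.059652 0.000906
GENE00010:intron:6      0.223431       0.490311     2.167241 0.000646
GENE00010:intron:5      0.455148       1.266243     2.760547 0.000049
GENE00023:intron:3      0.407814       0.916670     2.358502 0.020281
GENE00038:intron:5      0.356046       1.153736     3.704281 0.008364
```

Each row is one intron: its mean IDratio per group (retention fraction
estimate), the test/reference fold change on the log2-mean scale and
the t-test p-value. Comparing against the generator's truth table, 26
of the 36 called events are planted spikes (39 were planted; the
misses are mostly 1.5× spikes, at the edge of what n = 4 can detect,
and the extra calls are borderline nulls passing all six gates). The
same objects drive the proteomics side (`ProximityEnrichmentModel`,
`filter_peaklist`, `quantify_proteins`, `build_network`), and the
`proxisplice` CLI chains everything
(`simulate / ri / events / lfq / silia-filter / silia-quant /
integrate / overlap / tally / compare`).

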