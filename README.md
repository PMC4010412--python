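# strandtx

Strand-specific RNA-class analysis of two-group RNA-seq designs: transcript
classification and novelty/confidence filtering, strand-aware read counting
per RNA class, bias-adjusted differential transcription with an exact
negative-binomial test, window-based alternative-polyadenylation (APA)
calling, Fisher-z correlation combining across groups, and isoform-proportion
shift detection — with a synthetic-data generator that injects every one of
those effects with known ground truth.

The package is aimed at transcriptomics analysts who want the *whole* picture
of a disease-vs-control total-RNA experiment — coding genes, lncRNAs,
small-RNA subclasses (pri-miRNA, C/D and H/ACA box snoRNA, scaRNA),
repeat subclasses (ERV families, LINE, SINE), antisense transcription, novel
loci — rather than a coding-gene-only differential-expression table, and who
need every step testable without patient data.

## Methods at a glance

- **Counting rules.** A read counts for a transcript only when it overlaps
  its exons on the same strand and touches exactly one gene and one RNA
  class; reads on the antisense strand of a coding gene quantify antisense
  transcription; everything else is excluded with a tallied reason. Gene-level
  counts count each read once however many isoforms it is compatible with.
- **Differential transcription.** Counts are filtered (≥3 reads in ≥3
  samples), scaled to equal totals (equal-total-RNA assumption), and the
  fold-change-vs-baseline trend is removed by loess. Per-feature p-values come
  from an exact conditional NB test: with group sums
  $Y_A \sim \mathrm{NB}(n_A\mu, \phi/n_A)$, $Y_B \sim \mathrm{NB}(n_B\mu, \phi/n_B)$,
  the null law of $Y_A$ given $Y_A + Y_B = t$ is negative hypergeometric with
  shapes $n_A/\phi, n_B/\phi$, and the two-sided p sums the probabilities of
  all splits no more likely than the observed one ($\phi = 0$ degenerates to
  an exact binomial split). BH step-up gives q-values; per-class percent
  changes compare pooled normalized class totals with a Welch test on
  per-sample class proportions.
- **APA.** Each annotated cleavage site's isoform expression is the number of
  reads whose 5′ end falls in the 200-base window transcriptionally upstream
  of the cleavage point. Per gene, proximal-vs-distal counts summed within
  groups form a 2×2 table; the relative ratio
  $R = (p_{case}/d_{case}) / (p_{ctrl}/d_{ctrl})$ with a two-sided Fisher
  exact p calls a shorter ($R>2$) or longer ($1/R>2$) 3′UTR at $p<0.01$,
  after a ≥10-read support filter per isoform.
- **Correlation combining.** Pearson r within each group, Fisher transform
  $z = \operatorname{atanh} r$, unweighted average, back-transform — applied
  to sense–antisense pairs, lncRNA/neighboring-gene pairs binned by distance
  and strand geometry, and miRNA target sets versus background.
- **Isoform shifts.** Group-pooled isoform proportions per gene; each isoform
  is tested against the rest of its gene with the same exact Fisher core;
  a gene is flagged when some isoform moves by ≥5 percentage points with
  $p<0.05$, and case-favored vs control-favored isoforms are compared for
  exon count (Mann–Whitney).

## Worked example

Run the default synthetic study (8 control and 9 case libraries, ~640
transcripts across all classes, NB dispersion 0.1, class effects of realistic
sign and size) end to end:

```python
from strandtx.pipeline import RunConfig, run

res = run(RunConfig(outdir="demo", seed=1))
s = res.summary
print(s["diffexp"], s["class_changes"]["coding"], s["apa"])
```

which prints (seed 1):

```
DE transcripts (p<0.01, q<0.2): 125 of 642
class changes: {'coding': -21.69, 'lncRNA': -12.24, 'smallRNA': -6.21,
                'repeat': -24.74, 'novel_locus': 38.18, 'smallRNA:priMiRNA': 32.16}
APA: {'n_genes': 120, 'n_unanalyzable': 0, 'n_longer': 5, 'n_shorter': 6}
sense-antisense r: 0.113   antisense/sense reads: 0.0322
classify: {'u': 150, 'j': 30}
```

Reading this: 125 of 642 expressed features pass the p<0.01 & q<0.2 operating
point; total coding transcription is down ~22% in cases while novel-locus
transcription is up ~38% and pri-miRNAs up ~32% (the injected effects were
−15%, +45% and +38% before renormalization against the shifted totals); 11 of
120 coding genes get a 3′UTR length call (5 longer, 6 shorter, matching the
6 shorter + 5 longer injected shifts); antisense reads run at ~1/30 of sense
reads with a weak positive sense–antisense correlation; and all 150 novel
loci classify as intergenic ("u") with the 30 novel isoforms as
novel-junction ("j").

The same stages are available from a shell:

```sh
strandtx run-all --seed 1 --outdir demo          # all stages on synthetic data
strandtx run-all --config run.yaml --stages simulate,diffexp,apa
```

Each run writes per-stage TSVs (`diffexp.tsv`, `apa.tsv`, `isoform_shifts.tsv`,
`classification.tsv`, ...), the serialized config, a log with the seed and a
config hash, and a machine-readable `summary.json`.

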