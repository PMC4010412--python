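# Methods

## Scope and data model

`strandtx` analyzes a two-group (control vs case), single-end, strand-specific
total-RNA experiment against a multi-class transcript annotation. The unit of
annotation is a transcript: an exon chain (0-based half-open genomic
intervals) on one strand, belonging to one gene, carrying exactly one RNA
class out of coding, lncRNA, smallRNA:{priMiRNA, snoRNA_CD, snoRNA_HACA,
scaRNA}, repeat:{ERV1, ERVK, ERVL, LTR_other, L1, SINE_Alu, SINE1_7SL},
novel_locus, novel_isoform. The unit of evidence is one strand-tagged read
placement (chrom, start, end, strand, sample, unique flag). All interchange
formats are plain text: GTF (1-based inclusive on disk), BED6 for cleavage
sites, headerless TSV for alignments, TSV count matrices, YAML for config and
ground truth.

## Transcript classification and filters

Class codes relate a query transcript to a reference annotation by its
ordered junction chain: `=` identical chain in a same-strand reference
transcript (single-exon queries additionally need exonic overlap, since their
chain is empty and would otherwise match vacuously); `j` shares ≥1 junction
without being `=`; `o` overlaps a reference transcript without sharing a
junction; `u` overlaps nothing, either strand, exon or intron. Queries
overlapping only an intron are folded into `o`: the four-code set has no
intronic code, and the partition property (exactly one code per query) needs
a home for that case. `u` is deliberately strand-blind so that antisense
transcription over a known gene is never called a novel locus.

High novelty: a `u` locus is high-novelty iff its span intersects no
transcript span in any auxiliary annotation track; a `j` isoform iff at least
one of its junctions appears in no track (and no track transcript contains
its full chain). High confidence: ≥10 uniquely mapped reads in ≥6 samples;
loci additionally need pooled depth (unique reads × read length / spliced
length) strictly above 10×. Depth pools all samples — the only reading under
which 10× is reachable for rare loci — and uses the configured read length
(50 bases by default).

## Counting rules

A read is assigned by exonic overlap (≥1 base) against an interval index:
same-strand overlap with exactly one gene → sense (counted once per
compatible isoform at transcript level, once at gene level; reads compatible
with exactly one isoform and flagged unique feed the high-confidence filter);
overlap with ≥2 genes or ≥2 RNA classes → excluded; opposite-strand-only
overlap with one coding gene → antisense; opposite-strand-only overlap with
non-coding features → excluded (antisense is quantified for coding genes
only); no overlap → intergenic. Sense assignment takes precedence over
antisense so the partition is deterministic. Class conflicts are evaluated at
the gene level, so a novel isoform of a coding gene does not make its gene's
reads "multi-class".

Class summaries aggregate sense counts per major class and per repeat /
small-RNA subclass, with a molar-concentration adjustment (pooled reads per
base of summed class length) so classes of very different footprint can be
compared.

## Differential transcription

1. **Expression filter**: keep features with ≥3 reads in ≥3 samples
   (raw counts).
2. **Normalization**: scale every library to the mean total over the filtered
   set (equal amount of total RNA between samples).
3. **Loess adjustment**: the log2 fold change is regressed on
   log10(mean + 1) with lowess (span 0.5, 2 robustness iterations) and the
   fitted trend subtracted. This removes a fold-change-vs-baseline dependence
   and, as a side effect, centers the global group difference at ~0. The
   span is a free parameter recorded in the run config; ≥50 features are
   required for the local fit to have support.
4. **Exact NB test**: samples are collapsed to group sums after
   normalization. For group sizes n_A, n_B and dispersion φ
   (var = μ + φμ²), the sum of i.i.d. NB variables is NB with dispersion
   φ/n, and conditional on the grand total t the group-A sum follows a
   negative hypergeometric law with shapes n_A/φ, n_B/φ. The two-sided
   p-value sums probabilities of all splits no more probable than the
   observed one. At φ = 0 the law is binomial(t, n_A/(n_A+n_B)) and is
   evaluated in exact integer arithmetic (so ties are exact, not
   float-coincidences) for t ≤ 10,000; the φ > 0 branch works in log-space
   with a 1e-7 relative near-tie tolerance, the convention shared by exact
   tests in R. All-zero features get p = 1.
5. **Dispersion**: a moment estimator pooled over transcripts and groups,
   φ̂ = Σ(v − m) / Σ(m² − v/n) clipped at 0, where m, v are the per-group
   sample mean and variance of normalized counts (m² − v/n is unbiased for
   μ²). On 2,000 transcripts it recovers φ = 0.2 within ~±10%; the package
   default dispersion for simulation is φ = 0.1, a free choice in the
   realistic bulk-RNA-seq range, not an inference from data.
6. **FDR**: Benjamini–Hochberg step-up. The reporting operating point is
   p < 0.01 and q < 0.2.

Class-level change is the ratio of per-sample-mean pooled normalized class
totals minus 1. (For equal group sizes this equals the plain pooled ratio;
for 8 vs 9 libraries the plain ratio would carry a 9/8 bias.) Its p-value is
a two-sided Welch t-test on per-sample class proportions — chosen over a
pooled-count binomial test, which is anti-conservative under NB
overdispersion. Because normalization fixes totals, a class change is always
relative to total RNA: injecting +38% into a small class while depressing
large classes yields a measured value slightly off ±38% by exactly the shift
of the total.

## Alternative polyadenylation

A cleavage site is a boundary coordinate with a rank along the transcript's
3′ direction (rank 1 = most proximal = shortest 3′UTR). The isoform ending at
a site is quantified by the reads whose 5′-most base (start on `+`, end−1 on
`-`) lies in the half-open 200-base window transcriptionally upstream:
[pos−200, pos) on `+`, [pos, pos+200) on `-`. These conventions make window
counts exactly invariant under coordinate reflection plus strand flip.

Per gene, sites supported by <10 pooled reads (summed over **all** samples —
the per-group reading is also defensible; pooled was fixed and recorded) are
dropped; the most proximal and most distal survivors form the 2×2 table
[proximal, distal] × [control, case] of group-summed counts. The relative
ratio uses +0.5 on zero cells only; the Fisher exact test always sees the raw
integers. Calls: shorter iff R > 2 and p < 0.01; longer iff 1/R > 2 and
p < 0.01; genes with <2 supported sites are tallied unanalyzable. The
reported ratio is both oriented (R) and folded (max(R, 1/R)).

The Fisher 2×2 test itself enumerates the hypergeometric support with exact
integer weights over a common denominator, so "as or less likely" is decided
by exact integer comparison; above n = 2000 it switches to a log-space
evaluation with the same 1e-7 near-tie tolerance as the NB test (big-integer
binomials beyond that size cost more than they buy).

## Correlation combining

For each pair of expression profiles: Pearson r within each group on
log2(x+1)-transformed normalized counts, z = atanh(r) with r clipped to
±(1−1e−12), unweighted average of the two z's (an n-weighted average is a
natural alternative; unweighted is the recorded choice), tanh back. Pairs
with zero variance in either group are flagged invalid and excluded from
averages. Applications:

- **Sense–antisense**: per coding gene, gene-level sense counts vs antisense
  counts; the summary also reports the pooled antisense:sense read ratio.
- **lncRNA neighbors**: pairs within 100 kb, split by relative position
  (upstream/downstream of the coding gene in its orientation) and strand
  relation, binned by distance (default edges 0, 10, 25, 50, 100 kb).
  Distance anchors: TSS-to-TSS for upstream lncRNAs, coding 3′ end to nearest
  lncRNA point for downstream — "distance" needs a fixed anchor and these are
  the recorded ones. A baseline is the mean combined r over ≥1,000 random
  lncRNA–gene pairs. Empty bins are reported with n = 0 and NaN, not zero.
- **Target sets**: mean ± SE of a per-gene statistic (adjusted log2FC or a
  combined r) over each miRNA target list against all non-target coding
  genes, with a two-sided Mann–Whitney p; lists with <5 measurable genes are
  flagged low-power.

## Isoform shifts

Isoform proportions come from group-pooled transcript counts; single-isoform
genes are excluded, genes with a zero group total skipped with a tally. Each
isoform is tested as [this isoform, rest of gene] × [control, case] with the
shared Fisher core — chosen over an all-isoform chi-square because the
flagging rule is per-isoform. A gene is flagged when some isoform satisfies
|Δ| ≥ 0.05 (absolute proportion points — the natural reading of "changed by
5%") **and** p < 0.05. Flagged case-favored (Δ > 0) vs control-favored
(Δ < 0) isoforms are compared on exon counts with a two-sided Mann–Whitney
test; fewer than 5 per side flags the comparison underpowered.

Because the test pools counts across biological replicates, it is
anti-conservative under between-sample overdispersion: at the default
simulation conditions a substantial fraction of flagged genes are
pooled-noise false positives, which dilutes the exon-complexity contrast.
This is a property of the prescribed test, kept as specified; the recovery
guarantee the suite enforces is about injected shifts being found, not about
the null rate of this particular test.

## The synthetic-data generator

The generator is first-class, tested code. It emulates:

- a study design of 8 control and 9 case libraries with 50-base strand-
  specific single-end reads;
- a multi-class annotation in disjoint coordinate regions per class — coding
  genes (4–8 exons, 1–3 isoforms built by skipping internal exons, a 1.5 kb
  terminal exon hosting 2–4 cleavage sites 250 bases apart), lncRNAs placed
  around coding genes on a cycle of geometries (up/downstream × same/opposite
  strand) and distances (2–95 kb, every 10th at 150 kb to exercise the
  exclusion rule), small-RNA and repeat subclasses with class-typical
  lengths, ≥97% single-exon novel loci (every 50th locus gets a second exon),
  and novel isoforms created by dropping an extra exon into a coding gene's
  first intron;
- NB counts with mean = baseline × library factor × 2^(group effect),
  var = μ + φμ², drawn as gamma–Poisson; baselines log-uniform on
  (20, 200) reads/transcript by default; library factors log-normal with
  unit mean and CV 0.15 — the nuisance the normalization step exists to
  remove;
- group effects at class level (defaults emulate the observed study
  conditions: coding and antisense −15%, novel loci +45%, small RNAs −5%
  overall with pri-miRNA +38% (log2 0.465) and snoRNA classes down, ERV
  families consistently down, SINE1/7SL up), per-gene log2FCs, APA usage
  shifts (the extreme site's weight multiplied by the injected ratio in
  cases), isoform-proportion shifts toward a named isoform, and extra
  depression of miRNA target sets;
- correlation structure through shared per-gene, per-sample log-normal
  latent factors (σ = 0.6 by default, active only when a correlation is
  requested so that marginal counts stay exactly NB): antisense profiles
  couple to sense with the injected correlation; lncRNA neighbors couple
  with ρ decaying linearly to zero at 100 kb upstream, constant for
  downstream-same-strand, zero for downstream-opposite;
- an optional explicit fold-change-vs-baseline slope in log space for
  exercising the loess adjustment (the mechanism behind the real bias is
  unknown, so it is injected, not derived);
- alignment records that conserve counts exactly: one record per counted
  read, APA reads placed uniformly inside their site's 200-base window
  (only window membership matters to the method), other reads uniformly
  inside one exon, antisense reads on the flipped strand.

What it does **not** emulate — and what passing tests therefore cannot show
about real data: sequencing error and quality, junction-spanning reads,
multi-mapping beyond a boolean flag, fragment-length and positional coverage
biases, correlated class effects, batch structure, or any property of actual
patient monocytes. The latent-factor correlations are attenuated by counting
noise, so the measured sense–antisense correlation at default depth
(~0.11 for an injected 0.19) is expected behavior, not a defect; recovery
tests that check the injected value directly use high depth and φ = 0 where
the attenuation vanishes.

## Numerical choices and degenerate inputs

- Exact-test ties: integer-exact in the small-table Fisher branch and the
  φ = 0 binomial branch; 1e-7 relative tolerance in log-space branches.
- Zero margins (Fisher), all-zero features (NB test): p = 1 by convention.
- Ratios with zero cells: +0.5 per cell, ratio only.
- atanh clipping at 1 − 1e−12 before Fisher-z.
- log2(x + 0.5) pseudocount for fold changes, log10(x + 1) for baselines,
  log2(x + 1) for correlation inputs.
- Determinism: every stochastic step flows from one integer seed through
  numpy SeedSequence spawning; identical (config, effects, seed) give
  byte-identical serialized outputs. Counting is order-invariant.

## Problem sizes

The test suite and the acceptance script run everything on synthetic data
sized for a workstation: catalogs of 300–4,000 features, 10–20 seeds per
Monte-Carlo claim, ~10⁵–10⁶ simulated reads per run. These sizes were chosen
so each statistical claim has enough resolution (binomial envelopes, ≥200
supporting reads per APA gene, ≥2,000 features for calibration) while the
whole suite stays interactive.

## Known limitations

- The common-dispersion estimator is moment-based, not conditional maximum
  likelihood; it is adequate for the recovery guarantees here but noisier
  than qCML at small feature counts, and there is no tagwise/trended
  shrinkage (explicitly out of scope).
- The class-level p-value is a Welch test on per-sample proportions, a
  deliberately conservative substitute for whatever test produced the very
  small class-level p-values reported for patient data; those exact values
  are not reproducible from the published description.
- Multi-site APA genes are reduced to their extreme supported sites; usage
  changes confined to middle sites are invisible by design.
- The isoform-shift test pools replicates (see above).
- Reads are assigned by exon-interval overlap against the genomic layout;
  junction-spanning reads do not exist in the generator, so spliced-reference
  subtleties (reads crossing exon boundaries) are untested.
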