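# Methods

`methlink` re-creates, as a tested and reusable pipeline, an integrative
analysis of whole-genome bisulfite sequencing (WGBS) and RNA-seq from a
three-genotype sheep-ovary design (HPBB, LPBB, LPB+, three replicate ewes
each).  The pipeline starts at per-cytosine methylated/unmethylated read
counts and gene-level expression counts; read-level processing (filtering,
bisulfite conversion, alignment) is upstream and out of scope.

## Methylome model and summaries

Each cytosine is classified by its two downstream bases on its own strand
into CG, CHG or CHH (H = A, C or T).  Site methylation level is
m / (m + u).  Genome-wide summaries are count-weighted pooled levels
(sum m / sum(m + u)) per context rather than means of site levels — the
weighted form is stable at low coverage; mean-of-sites is reported
alongside.  The per-context share of methylated calls and a ten-bin
site-level histogram reproduce the standard global-methylation figures.
Because "a methylated site" requires a binarisation rule that the level
does not, the summary also reports the fraction of covered sites with at
least one methylated read, labelled separately.

The two symmetric CG cytosines are kept as separate sites; no destranding
or merging is applied (coverage pooling across replicates already feeds
the region test).

## DMR calling

Candidate regions are greedy chains of same-context sites: a site joins
the open region while the inter-site gap is at most `max_gap` (default
300 bp) and the region span at most `window_span` (default 1000 bp).
Chains partition the covered sites; a region never mixes contexts.  These
two knobs replace the unpublished internal segmentation of the caller the
original analysis used and are exposed in the configuration.

Replicate counts are pooled per group (element-wise sums) and each region
is tested on the 2x2 table [[m_A, u_A], [m_B, u_B]] with a two-sided
Fisher's exact test under the point-probability rule (sum the
probabilities of all tables with the same margins whose probability does
not exceed the observed one).  Tables with at most 1024 total reads are
evaluated in exact integer arithmetic; larger tables use a vectorised
log-gamma evaluation with binary search for the opposite-tail boundary and
outward tail-sum recurrences (tie tolerance 1e-7 relative, the convention
of mainstream implementations).

A region is a DMR when (strict inequalities throughout):
* it holds >= 3 methylation sites,
* |pooled level difference| > 0.3 for CG, > 0.2 for CHG/CHH,
* Fisher p < 0.05.

Delta is computed from the pooled group counts, consistent with the pooled
Fisher table; hyper means higher methylation in the first-named group of
the comparison.  No multiplicity correction filters DMRs (the criteria are
raw-p by design); a Benjamini-Hochberg column is emitted for information
only.  Pooling replicates (rather than testing per-replicate means) is the
default because it is the only reading under which a 2x2 Fisher test is
well defined; the per-replicate mean level is a reported alternative.

## Genomic elements and DMR-related genes

The promoter is the 3,000 bp immediately upstream of the TSS
(strand-aware, clipped at chromosome edges); the gene body runs TSS to
TTS; introns are the gene body minus exons; everything hit by no promoter
or gene body is distal intergenic.  Multi-transcript genes use the longest
transcript (most-upstream TSS selectable).

Two deliberately different overlap rules serve two different questions:

* element *distribution* (one label per DMR): midpoint containment with
  precedence promoter > exon > intron > gene body > distal intergenic;
  ties across genes break by nearest TSS, then lexicographic gene id —
  a total, deterministic assignment;
* DMR -> gene mapping (DMGs): any >= 1 bp interval overlap with a
  promoter or gene body, so one DMR may support several genes and a gene
  is partitioned into promoter-only / body-only / both.  A gene carrying
  both hyper and hypo DMRs is summarised as direction "both".

Coordinates are 1-based inclusive everywhere except inside BED files
(0-based half-open, converted at the file boundary).

## Differential expression

FPKM = count / (length/1e3 x library/1e6).  Tests run on
log2(normalised count + 1) with total-count library normalisation
(median-of-ratios available).  The default test is an empirical-Bayes
moderated t: per-gene pooled variances (4 df at 3 vs 3) are shrunk toward
a scaled-inverse-chi-square prior fitted across genes by moment matching
on log variances (trigamma inversion), and the t statistic is referred to
d0 + d degrees of freedom.  This choice is deliberate: with three
replicates an unmoderated per-gene variance floors attainable p-values
near 1e-3, and essentially no gene survives an FDR threshold even at
four-fold changes; variance moderation is the field-standard remedy and
keeps the test transparent and self-contained.  A plain Welch test and an
exact balanced-relabeling permutation test (20 relabelings at 3 vs 3, p on
multiples of 1/20) remain available.

A gene is a DEG when BH q < 0.05 and |log2 fold change| > 1 (strict),
with log2fc = log2((mean_A + 1) / (mean_B + 1)) on normalised means.
DEG heatmap ordering uses average-linkage clustering on 1 - Pearson of
z-scored log10(FPKM + 1) rows; constant rows are flagged and enter as
zero vectors by convention.

## Integration

Restricted to the CG context (essentially all differential methylation
sits there).  Expressed genes are split into quartile strata (highest,
medium-high, medium-low, lowest) of mean log10(FPKM + 1) in the
comparison's first-named group; ties resolve by stable gene order, and a
fully degenerate all-equal input collapses to one stratum with a warning.
The TSS metaprofile pools counts per stratum in 100 x 40 bp bins tiling
TSS +/- 2000 bp (strand-aware, upstream negative); empty bins are missing,
never zero.  The per-gene correlation uses the count-weighted CG level
over TSS +/- 2000 bp against log10(FPKM + 1), Spearman, with a seeded
two-sided permutation p (>= 1999 relabelings).

DMG-and-DEG genes are classified hyper-down / hypo-up / hyper-up /
hypo-down relative to the same first-named group; genes with mixed
methylation direction are set aside as both-mixed.  Mismatched comparison
orientations are a hard error because silent flips corrupt every category.

## Enrichment

Over-representation is one-sided.  The central null is
P(X >= k), X ~ Hypergeom(N, K, n).  The Wallenius noncentral null biases
the urn by gene weights: the term's odds omega = mean weight in the term /
mean weight outside, and the PMF is computed by the sequential biased-urn
recurrence (after i draws with j successes the next draw succeeds with
probability omega(K-j) / (omega(K-j) + (N-K) - (i-j))), normalised; at
omega = 1 it reduces exactly to the central hypergeometric.  Default
weights come from a detection-bias fit: genes binned by length, per-bin
selection fraction isotonic-regressed on length, floored to stay
positive.  Term databases are user-supplied TSV; the package does no
database retrieval, so runs are reproducible offline.

## Wet-lab validation arithmetic

BSP: at each CpG of the untreated reference region a clone base C is
methylated (protected from conversion), T is unmethylated, anything else
(including alignment gaps) is missing, never imputed.  Equal-length clones
are scored by direct indexing; clones with small indels go through an
end-anchored global alignment.  Region level = methylated calls /
non-missing calls.

qPCR: dCt = Ct(target) - Ct(reference gene, GAPDH by default); ddCt
subtracts the calibrator group's per-gene mean dCt; fold = 2^-ddCt.  Group
summaries report mean +/- SEM of per-sample folds plus the fold from the
mean ddCt (exactly 1 for the calibrator).  The per-group calibrator mean
(rather than a single calibrator sample) is the default.

## Synthetic data generator

The generator emulates the statistical regime the analysis assumes, not
any particular dataset:

* design: 3 groups x 3 replicates (configurable, >= 2 replicates each);
* methylome: CG baseline pooled level 0.70, CHG/CHH 0.006, coverage ~
  Poisson(30) per site and sample, methylated counts beta-binomial with
  overdispersion rho = 0.1 (the beta draw is the between-replicate
  biological variance — the real study never reports between-ewe variance,
  so this is a chosen, not inferred, default);
* promoters: each gene's promoter CG sites share a gene-specific level
  drawn from a Beta with mean 0.70 and sd 0.15, giving the
  methylation-expression coupling between-gene variance to act on;
* expression: negative binomial with size 10, per-gene baseline
  log2-mean ~ Normal(7, 1), +/- 8% lognormal library wobble;
  log2 mean = baseline + coupling x promoter methylation + planted log2fc
  (coupling <= 0, in log2 units per unit methylation, default 0);
* plants: DMR plants shift every context site in a region by delta in the
  first-named comparison group only; regions are chosen as maximal site
  chains under the caller's own gap/span rule so each plant coincides with
  one candidate region, and a region's background level is overridden
  when needed to keep the shifted level inside [0, 1] (a +0.4 shift on the
  0.70 background would overflow).  DEG plants scale the first-named
  group's mean by 2^log2fc.  The truth tables enumerate every non-null
  feature; everything else is null by construction.

What the generator does not model: read-level artefacts (conversion
failure, M-bias, mapping bias), CpG islands and other sequence
autocorrelation (bases are i.i.d. at 42% GC), gene-body methylation
coupling (a config option, default off), and realistic gene-density or
isoform structure.  Passing tests therefore demonstrate correctness of the
statistical machinery under its stated assumptions, not performance on
real ovary data.

## Benchmark problem sizes

The calibration/recovery scenarios (also used by the reproduction script)
run at: null calibration — one 5 Mb chromosome, 30x, 3 vs 3, repeated over
20 count-level seeds (10 in the script) with one shared genome; DMR
recovery — 200 planted CG regions (|delta| = 0.4, >= 5 sites) on 5 Mb;
DEG recovery — 200 planted genes (|log2fc| = 2) among 1000; integration —
1.5 Mb, 400 genes, coupling -2, 40 promoter-hyper plants paired with
down-regulation.  These sizes are the package's own desk-scale choices;
the real study's genome-scale counts are not reproducible from them and no
attempt is made to match them numerically.

## Numerical and degenerate-input conventions

All randomness flows through numpy Generators seeded from a single
configuration seed with fixed per-stream salts, so every output table is
byte-reproducible.  Zero-coverage sites are missing, not zero.  All-zero
Fisher tables are undefined and skipped with a log entry.  Genes with zero
counts everywhere are excluded from testing and reported as `ns`.
Constant methylation makes the integration correlation undefined (error,
not NaN propagation).  The run manifest records the configuration hash
(analysis parameters only, not output paths), input checksums, seed,
per-table row counts and a timestamp; two same-seed runs agree
byte-for-byte on every table and differ only in the manifest timestamp.

## Known limitations

* The original study's headline counts (tens of thousands of DMRs, etc.)
  derive from nine real ewes at genome scale and cannot be checked at desk
  scale; correctness is established against oracles and planted truth.
* The Fisher test on pooled replicates treats reads as exchangeable within
  a group; with strong between-replicate overdispersion the raw p is
  anti-conservative, which is why the delta and site-count filters, not p
  alone, carry the false-call control (measured: < 2% of candidate regions
  under the null at default settings).
* The moderated-t DE engine assumes roughly common log-scale variance
  structure across genes; strongly mean-dependent variance would call for
  a trend on the prior, which is not implemented.
* BSP scoring assumes the clone aligns to the untreated reference frame;
  heavily rearranged clones fail alignment rather than being rescued.
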