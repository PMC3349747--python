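# Methods

`occupancy-scan` re-implements, as a reusable and tested pipeline, the
genome-wide occupancy analysis used to characterize a sequence-specific
factor that binds the gene bodies of an entire gene family (the
motivating case is a zinc-finger regulator of collagen genes in
pre-osteoblastic cells): consensus peak definition from two independent
antibodies, peak-to-gene annotation, metagene profiling, a permutation
null for chromatin-state positivity of a target gene set, gene-body
coverage correlation with RNA polymerase II, expression quantile
comparison, PWM motif scanning, and ChIP-qPCR percent-input rules.
Because the underlying sequencing data carry no public accession, every
stage is exercised on a bundled synthetic-data generator with fully
known planted truth; the tests are therefore statements about truth
propagation through the pipeline, not about any particular biological
dataset.

## Coordinates and annotation

All coordinates are 0-based half-open internally; GFF3 (1-based
inclusive) is converted on read. One gene model per gene is kept (the
first listed transcript when a GFF3 has several). The per-base feature
classifier labels every position `promoter`, `exon`, `intron` or
`intergenic` with fixed precedence promoter > exon > intron >
intergenic across all overlapping genes. The promoter is
`[TSS − w, TSS + w)` with `w = 2,500 bp` by default — a conventional
promoter definition, configurable because the source analysis did not
publish its own.

## Peak caller

The caller is a reconstruction in the MACS lineage, deliberately
parameterized rather than claimed faithful to any specific tool:
sliding windows (200 bp every 50 bp) are scored against a Poisson
expectation

    lambda = max(genome-wide rate × window, local control count in a
                 10-kb span rescaled to the window),

with control counts scaled by the IP/control total-tag ratio; tag 5′
positions are shifted 100 bp toward the fragment midpoint before
counting. Window p-values get Benjamini–Hochberg control; windows with
q ≤ 0.05 and fold ≥ 4 merge across gaps ≤ 100 bp. The summit is the
argmax of the shifted-tag counts smoothed with a fragment-width boxcar
(an approximation of fragment pileup that removes the ~tens-of-bp
jitter a raw point-mass argmax shows); ties break leftmost. An empty
control is an error unless `global_background_only` is set, in which
case the IP-derived uniform rate is the expectation.

Consensus ("high-confidence") targets are the exact intersection
segments of the two antibodies' peak sets (any overlap by default). We
emit exact segments rather than forcing one interval per a-peak so that
the covered base set equals the brute-force intersection — the property
the acceptance suite verifies; when an a-peak meets a contiguous run of
b-peaks (the typical case) there is exactly one output per a-peak.
"Shrunk" peaks — fixed ±100 bp windows around summits — feed the motif
stage.

## Peak-to-gene assignment

`assign_peaks_to_genes` is pure nearest-TSS (peak center = summit),
signed by gene orientation (upstream negative), unassigned beyond
150 kb; the default range deliberately accommodates a genuinely distal
enhancer ~100 kb from its gene when no other TSS is nearer. The
pipeline-level annotation additionally gives **containment priority**:
a peak centered inside a gene body belongs to that gene even if a
neighbour's TSS is closer. Without this, a 3′-end body peak in a long
gene is routinely handed to the downstream neighbour, and the statement
"a gene contains a peak" stops meaning what it says. Categories are
promoter (|d| ≤ w), gene_body (center inside the assigned gene), else
upstream/downstream distal by sign; assigned peaks partition exactly.
Distance ties break toward the lexicographically smaller gene id.

## Metagene profile

Fixed-bp upstream bins plus a gene body rescaled to a fixed number of
equal-fraction bins (percent of gene length); minus-strand genes are
flipped. Per-bin signal is tags/bp, averaged over genes with equal
weight so long genes do not dominate. Genes shorter than the bin count
are excluded with a warning.

## Permutation enrichment

Positivity is a per-gene boolean: a mark peak overlapping
`[TSS − w, TSS + w)` (histone marks) or the gene span (Pol II; the mode
is configurable because the source analysis does not say which was
used). The null draws `n_iter` (default 100, matching the source's 100
iterations) size-matched gene sets without replacement from the
universe, which includes the targets. Reported: observed percent, null
mean/sd, z, and the one-sided add-one empirical p-value
`(1 + #{null ≥ obs}) / (1 + n_iter)`; z is NaN when the null has zero
spread.

## Gene-body densities and correlation

Density is tags in `[start, end)` divided by length. Correlation is
Pearson by default (Spearman by flag); zero variance is an error, not a
silent NaN.

## Expression Q-Q

Percentiles 1–99 via linear-interpolation quantiles of target genes vs
*all* genes (targets included). Median shift and the two-sample KS
statistic are auxiliary summaries; fewer than 20 usable targets is an
error. Note that when targets are a large fraction of the universe the
median shift under-states the planted per-gene shift, because the
all-gene median moves too — visible in the default synthetic run, where
~38% of genes are targets.

## Motif p-score

The match score of window *w* against a PWM is the
information-content-weighted similarity

    pscore(w) = Σ_i IC_i · f_i(w_i) / Σ_i IC_i · max_b f_i(b),
    IC_i = 2 + Σ_b f_i(b) log2 f_i(b),

normalized so the consensus scores exactly 1; this is the
MatInspector-family normalized score that "p-score" conventionally
denotes. A PWM with zero total information cannot be scanned (explicit
error); windows with ambiguous bases are skipped, not errors. Scanning
covers both strands, reverse-strand windows scored on the reverse
complement at forward offsets.

De novo discovery is reduced to exhaustive k-mer enrichment (reverse
complements collapsed to the lexicographically smaller form) of shrunk
peaks against caller-supplied background, ranked by one-sided binomial
p then log2 odds (+0.5 pseudocounts on rates). Significance-first
ranking is intentional: with a finite background sample, k-mers absent
from the background by chance have unbounded odds and would outrank a
genuinely enriched k-mer with a nonzero background count. Top-k-mer
occurrences (both orientations) are stacked into a PWM (pseudocount
0.01) and scanned back.

## ChIP-qPCR

Percent input is `100 × 2^((Ct_input − log2(1/input_fraction)) −
Ct_IP)` — the standard dilution-adjusted ΔCt form; the source prints no
formula, so this is documented practice, not replication. The noise
threshold is the **maximum** percent input across negative-control
regions, and a region counts as enriched only when **strictly above**
it. Along-gene profiles are compared per anchor offset with an unpaired
two-sided Student's t-test (Welch by flag), matching the per-point
testing style of the motivating analysis.

Enhancer signature: `enhancer_like` requires H3K4me1 fold ≥ 2 and a
K4me3/K4me1 ratio < 1; `promoter_like` requires H3K4me3 fold ≥ 4 and
ratio ≥ 1; H3K27ac ≥ 2 sets an "active" flag. Thresholds are
conservative defaults (unstated in the source) and configurable.

## Synthetic experiments

The generator emulates the complete data structure behind the analysis:

- **Genome**: two 5-Mb chromosomes, 300 non-overlapping stranded genes
  with exon/intron structure, including a designated family of 43 long
  (log-normal, median ≈ 22 kb) densely exonic "collagen-like" genes;
  i.i.d. sequence at GC 0.42 except planted motif copies.
- **Factor antibodies**: two tag sets sharing planted sites but sampled
  independently at different background rates (0.10 and 0.08 tags/bp —
  ~1 M tags per antibody), mirroring two polyclonal antibodies against
  the same factor. Gene-body sites (400 bp, fold ~8, floored at 6) in
  42 of the 43 family genes, exon-centered with probability 0.6;
  promoter and body sites for further target genes; a handful of
  intergenic distal sites. Planted sites are point-source (fragment
  centers ~ Normal(midpoint, width/8)); uniform placement is reserved
  for extended domains, since a uniform "binding site" has no summit to
  recover.
- **Pol II**: TSS-site positivity (0.8 targets / 0.3 background) plus
  gene-body mass over family genes coupled to the factor's per-gene
  fold by a Gaussian copula on log scale (r = 0.9).
- **Histone marks**: H3K4me3 promoter sites with probability 0.8 for
  targets vs 0.3 otherwise; H3K9me3 0.30 vs 0.15.
- **Expression**: log-normal (log2 mean 5, sd 1.5), targets shifted
  +1.0 log2 units.
- **Motifs**: a 10-bp consensus (`GGTACTCAGG`, GG-flanked like the
  motivating consensus) planted in ~60% of factor sites, plus a
  three-copy configuration inside one long family exon.

Every random draw comes from a stream namespaced by `(seed, artifact
name)`, so runs are byte-identical under a fixed seed and adding an
artifact never perturbs the others. Emitted files are plain text
(FASTA/GFF3/BED6/TSV/JSON) with a SHA-256 manifest.

What the generator does **not** emulate: mappability and duplication
artifacts, nucleosome positioning, GC bias in the tags, diploid
genomes, or a realistic genome-to-gene-count ratio. Passing tests
therefore demonstrate correct truth propagation through the pipeline's
logic and statistics at realistic signal-to-noise, not performance on
real libraries.

## Problem sizes and numerical choices

Default analyses run on the 2 × 5 Mb / 300-gene / ~1 M-tags-per-antibody
configuration (seconds per stage on one CPU); the test suite uses
smaller instances of the same structure (1–1.5 Mb chromosomes, 1-Mb
null and recovery runs, 20-seed replicate loops). The acceptance
script runs the full default configuration once plus 20 one-megabase
null calibrations. Peak-caller p-values use `scipy.stats.poisson.sf`
(regularized-gamma tail, stable in log space); BH control uses
`scipy.stats.false_discovery_control`. Summit and distance ties break
leftmost/lexicographically for determinism. Degenerate inputs
(empty control, zero-information PWM, zero-variance densities, < 20
usable targets, genes shorter than the bin count) raise explicit errors
or documented exclusions rather than propagating NaNs; a pipeline stage
that fails leaves a failure record in the report and a nonzero exit.

Pipeline intermediates are not cached: runs are deterministic under
seed and fast at this scale, so regeneration equals any cache by
construction.

## Known limitations

- The peak caller is a plausible 2010-era reconstruction; parameters
  are exposed rather than tuned to reproduce any published peak list.
- Consensus intersection can emit more than one segment for an a-peak
  that spans a gap between two b-peaks.
- The k-mer stage is a discovery *stand-in*: it finds planted or
  strongly enriched words, but it is not a full de novo motif finder.
- `percent_input` assumes perfect primer efficiency (exact doubling per
  cycle).
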