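# occupancy-scan

ChIP-seq occupancy analysis for factors that bind inside gene bodies —
consensus peak definition from two antibodies, peak-to-gene annotation,
metagene profiling, permutation-based chromatin-state enrichment,
gene-body coverage correlation with RNA polymerase II, expression Q-Q
comparison, PWM motif scanning with a normalized [0,1] p-score, and
ChIP-qPCR percent-input rules — together with a synthetic-data
generator that plants every truth the pipeline is supposed to recover.

The motivating use case is a transcriptional regulator occupying the
gene bodies (predominantly exons) of an entire gene family, sustaining
RNA polymerase II occupancy there: the analysis must define
high-confidence targets as the overlap of two independent antibodies'
peak sets, ask how peaks distribute around TSSs and across genomic
features, test whether target genes are enriched for active chromatin
against size-matched random gene sets, and correlate factor and Pol II
gene-body densities.

## The statistics at the core

**Peak calling** — sliding windows scored by a Poisson upper tail
against `λ = max(genome-wide rate·w, local control in 10 kb scaled
to w)`, control scaled by depth ratio, Benjamini–Hochberg FDR, fold
floor, merge, summit at smoothed coverage argmax.

**Permutation enrichment** — for a target gene set of size *k*, draw
`n_iter` random *k*-gene sets from the universe and compare the percent
of genes positive for a mark:

    z = (obs − mean_null) / sd_null,
    p = (1 + #{null ≥ obs}) / (1 + n_iter).

**Motif p-score** — information-content-weighted PWM similarity,
`Σ IC_i·f_i(w_i) / Σ IC_i·max_b f_i(b)`, equal to 1 exactly at the
consensus sequence.

**Percent input** — `100 · 2^((Ct_input − log2(1/f)) − Ct_IP)` with
input fraction *f*; a region is enriched only strictly above the
highest negative-control value.

See `docs/methods.md` for the full model description, defaults and
limitations.

## Worked example

Simulate a small experiment and run the full pipeline:

```bash
occupancy-scan simulate --seed 3 --out sim/ --config small.yaml
occupancy-scan run --indir sim/ --seed 3 --out out/
```

or in Python:

```python
from occupancy_scan import SimulationConfig, simulate_experiment
from occupancy_scan.pipeline import PipelineParams, run_from_experiment

exp = simulate_experiment(SimulationConfig(), seed=1)
rep = run_from_experiment(exp, PipelineParams(seed=1))
print(rep["consensus_count"], rep["family_coverage"])
print({m: round(v["z"], 2) for m, v in rep["permutation_enrichment"].items()})
```

which prints (seed 1, default configuration):

```
117 {'family': 'collagen_like', 'with_peak': 42, 'size': 43}
{'h3k4me3': 8.25, 'h3k9me3': 4.54, 'polii': 8.14}
```

Reading: the two factor antibodies overlap in 117 consensus loci; 42 of
the 43 collagen-like genes contain at least one — exactly the planted
configuration; and target genes are strongly enriched for H3K4me3 and
Pol II positivity (z ≈ 8 against 100 size-matched random gene sets),
more weakly for H3K9me3, mirroring the planted positivity rates
(0.8/0.3 vs 0.3/0.15). The report also carries category proportions,
the exonic fraction of family peak centers (61.9% here vs 61.9% of
planted site centers falling in exons), the factor–Pol II gene-body
density correlation, the expression median shift of targets, and the
top enriched k-mers — with `CCTGAG`, a canonicalized substring of the
planted consensus `GGTACTCAGG`, ranked first.

## Layout

```
src/occupancy_scan/
  genome_annotation.py   gene models, GFF3/BED12 I/O, feature classifier
  peaks.py               tags, coverage, Poisson caller, consensus, shrink
  target_assignment.py   nearest-TSS assignment, categories, target tables
  occupancy_stats.py     metagene, densities, permutation test, qPCR, profiles
  expression_compare.py  expression table + Q-Q comparison
  motif.py               PWM p-score, scanning, k-mer enrichment
  synthetic_data.py      genome/tag/expression/motif generators with truth
  pipeline.py, cli.py    orchestration and the occupancy-scan CLI
```
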