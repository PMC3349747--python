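"""End-to-end orchestration of the occupancy analysis.

Stages run in dependency order: peak calling per antibody -> consensus
intersection -> peak-to-gene assignment, categorization and feature
classification -> metagene profiles -> mark positivity + permutation
enrichment -> gene-body density correlation -> expression Q-Q -> peak
shrinking + k-mer motif stage.  The report is a plain dict (JSON-ready)
echoing the configuration and seed, so two runs with the same inputs
are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .expression_compare import qq_compare
from .genome_annotation import build_feature_index
from .motif import kmer_enrichment, pwm_from_occurrences, scan_sequences
from .occupancy_stats import (
    coverage_correlation,
    gene_body_density,
    mark_positivity,
    metagene_profile,
    permutation_enrichment,
)
from .peaks import call_peaks, coverage_track, intersect_peak_sets, shrink_peaks
from .synthetic_data import SyntheticExperiment, stream
from .target_assignment import (
    annotate_assignments,
    family_coverage,
    gene_target_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Every tunable stage parameter, with the package defaults."""

    window: int = 200
    step: int = 50
    shift: int = 100
    local_lambda_span: int = 10_000
    fdr: float = 0.05
    merge_gap: int = 100
    min_fold: float = 4.0
    min_overlap: int = 1
    promoter_window: int = 2_500
    max_distance: int = 150_000
    upstream_bp: int = 2_000
    upstream_binsize: int = 100
    n_body_bins: int = 40
    positivity_window: int = 2_500
    n_permutations: int = 100
    shrink_halfwidth: int = 100
    kmer_k: int = 6
    kmer_top_m: int = 10
    scan_threshold: float = 0.95
    seed: int = 0


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and (obj != obj):
        return None
    return obj


def run_from_experiment(
    exp: SyntheticExperiment,
    params: PipelineParams | None = None,
    skip: set[str] | None = None,
) -> dict:
    """Run the full analysis on an in-memory experiment; return the report.

    ``skip`` may name stages to leave out: metagene, enrichment,
    correlation, qq, motif.
    """
    params = params or PipelineParams(seed=exp.seed)
    skip = skip or set()
    genes = exp.gene_models
    chrom_sizes = exp.chrom_sizes
    control = exp.tags["igg"]
    call_kw = dict(
        window=params.window, step=params.step, shift=params.shift,
        local_lambda_span=params.local_lambda_span, fdr=params.fdr,
        merge_gap=params.merge_gap, min_fold=params.min_fold,
        chrom_sizes=chrom_sizes,
    )
    report: dict = {
        "version": __version__,
        "seed": params.seed,
        "params": asdict(params),
        "config": exp.config,
    }

    peak_sets = {}
    for label in ("factor_ab1", "factor_ab2", "h3k4me3", "h3k9me3", "polii"):
        peak_sets[label] = call_peaks(exp.tags[label], control, **call_kw)
    report["peak_counts"] = {k: len(v) for k, v in peak_sets.items()}

    consensus = intersect_peak_sets(
        peak_sets["factor_ab1"], peak_sets["factor_ab2"], params.min_overlap
    )
    report["consensus_count"] = len(consensus)

    findex = build_feature_index(genes, params.promoter_window)
    assignments = annotate_assignments(
        consensus, genes, findex, params.max_distance, params.promoter_window
    )
    n_asn = len(assignments)
    report["category_proportions"] = {
        cat: sum(a.category == cat for a in assignments) / max(n_asn, 1)
        for cat in ("promoter", "gene_body", "upstream_distal",
                    "downstream_distal", "unassigned")
    }
    table = gene_target_table(assignments)
    target_gene_ids = sorted(table)
    report["n_target_genes"] = len(target_gene_ids)

    family = exp.collagen_family
    hit, total = family_coverage(table, family)
    report["family_coverage"] = {"family": "collagen_like", "with_peak": hit, "size": total}
    fam_set = set(family)
    fam_features = [a.center_feature for a in assignments if a.gene_id in fam_set]
    report["family_center_features"] = {
        feat: (sum(f == feat for f in fam_features) / len(fam_features)
               if fam_features else 0.0)
        for feat in ("promoter", "exon", "intron", "intergenic")
    }

    failures: dict[str, str] = {}

    def _stage(name, fn):
        if name in skip:
            return
        try:
            fn()
        except Exception as err:  # partial report + failure record
            logger.error("stage %s failed: %s", name, err)
            failures[name] = str(err)

    def _metagene():
        prof = {}
        for label in ("factor_ab1", "factor_ab2", "igg"):
            track = coverage_track(exp.tags[label], params.shift, chrom_sizes)
            mp = metagene_profile(
                track, genes, params.upstream_bp, params.upstream_binsize,
                params.n_body_bins, label=label,
            )
            prof[label] = {
                "n_genes": mp.n_genes,
                "upstream": mp.upstream_bins,
                "body": mp.body_bins,
            }
        report["metagene"] = prof

    def _enrichment():
        universe = [g.gene_id for g in genes]
        enrich = {}
        for mark, mode in (("h3k4me3", "tss_window"), ("h3k9me3", "tss_window"),
                           ("polii", "gene_overlap")):
            if mark not in peak_sets:
                continue
            pos = mark_positivity(genes, peak_sets[mark], params.positivity_window, mode)
            res = permutation_enrichment(
                target_gene_ids, universe, pos,
                n_iter=params.n_permutations, seed=params.seed,
            )
            enrich[mark] = {
                "observed_percent": res.observed_percent,
                "null_mean": res.null_mean, "null_sd": res.null_sd,
                "z": res.z, "empirical_p": res.empirical_p,
                "n_iterations": res.n_iterations, "set_size": res.set_size,
                "mode": mode,
            }
        report["permutation_enrichment"] = enrich

    def _correlation():
        ab1_track = coverage_track(exp.tags["factor_ab1"], params.shift, chrom_sizes)
        pol_track = coverage_track(exp.tags["polii"], params.shift, chrom_sizes)
        fam_genes = [g for g in genes if g.gene_id in fam_set]
        da = [gene_body_density(ab1_track, g) for g in fam_genes]
        db = [gene_body_density(pol_track, g) for g in fam_genes]
        report["body_density_correlation"] = coverage_correlation(da, db)

    def _qq():
        qq = qq_compare(target_gene_ids, {k: np.log2(v) for k, v in exp.expression.items()})
        report["expression_qq"] = {
            "ks_statistic": qq.ks_statistic, "ks_p": qq.ks_p,
            "median_shift_log2": qq.median_shift,
            "n_targets": qq.n_targets, "n_all": qq.n_all,
        }

    _stage("metagene", _metagene)
    _stage("enrichment", _enrichment)
    _stage("correlation", _correlation)
    _stage("qq", _qq)

    def _motif():
        shrunk = shrink_peaks(consensus, params.shrink_halfwidth)
        fg = [exp.chrom_seqs[c][max(0, s): e] for c, s, e in shrunk]
        fg = [s for s in fg if len(s) >= params.kmer_k]
        rng = stream(params.seed, "kmer_background")
        bg = []
        chroms = sorted(chrom_sizes)
        for s in fg:
            for _ in range(5):  # 5x background stabilizes the rate estimate
                c = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(0, chrom_sizes[c] - len(s)))
                bg.append(exp.chrom_seqs[c][start: start + len(s)])
        ranked = kmer_enrichment(fg, bg, k=params.kmer_k, top_m=params.kmer_top_m)
        report["kmer_top"] = ranked
        from .motif import reverse_complement

        top = ranked[0]["kmer"]
        top_rc = reverse_complement(top)
        occurrences = []
        for s in fg:
            su = s.upper()
            for i in range(len(su) - params.kmer_k + 1):
                window = su[i: i + params.kmer_k]
                if window == top:
                    occurrences.append(window)
                elif window == top_rc:
                    occurrences.append(top)  # re-orient to the canonical strand
        if len(occurrences) >= 5:
            pwm = pwm_from_occurrences(occurrences, name=f"top_{top}")
            hits = scan_sequences(
                pwm, [(f"peak_{i}", s) for i, s in enumerate(fg)],
                threshold=params.scan_threshold,
            )
            report["motif_scan"] = {
                "pwm_consensus": pwm.consensus, "n_hits": len(hits),
                "threshold": params.scan_threshold,
            }

    _stage("motif", _motif)

    if failures:
        report["stage_failures"] = failures
    return _json_safe(report)


def write_report(report: dict, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
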