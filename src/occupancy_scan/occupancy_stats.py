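"""Occupancy statistics: metagene profiles, gene-body densities and their
correlation, per-gene positivity, the random-gene-set permutation test,
ChIP-qPCR percent-input arithmetic with the noise-threshold rule,
along-gene profile comparison, and enhancer-signature classification.

The permutation test asks whether a target gene set carries a chromatin
mark (or Pol II) more often than size-matched random gene sets drawn
from the universe: the observed positivity percentage is compared to the
null distribution over ``n_iter`` draws without replacement, reported as
a z-score and an add-one-corrected one-sided empirical p-value.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import interval_arrays, merge_intervals
from .genome_annotation import GeneModel, tss_of
from .peaks import CoverageTrack, Peak

logger = logging.getLogger(__name__)

Z_UNDEFINED = float("nan")  # sentinel when the null has zero spread


# ---------------------------------------------------------------------------
# metagene
# ---------------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Mean tag density around the TSS and along percent-scaled gene bodies.

    ``upstream_bins``: (offset of bin left edge in bp relative to TSS,
    mean density).  ``body_bins``: (percent of gene length at the bin's
    right edge, mean density).  Densities are tags/bp averaged over
    genes with equal weight, so long genes do not dominate.
    """

    upstream_bins: list[tuple[int, float]]
    body_bins: list[tuple[float, float]]
    n_genes: int
    antibody_label: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [("upstream", off, d) for off, d in self.upstream_bins]
        rows += [("body", pct, d) for pct, d in self.body_bins]
        return pd.DataFrame(rows, columns=["zone", "position", "mean_density"])


def metagene_profile(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    upstream_bp: int = 2000,
    upstream_binsize: int = 100,
    n_body_bins: int = 40,
    label: str = "",
) -> MetageneProfile:
    """Average tag density: fixed-bp upstream bins + percent-of-length body bins.

    Minus-strand genes are flipped so that increasing x runs in gene
    orientation.  Genes shorter than ``n_body_bins`` bp are excluded.
    """
    n_up = upstream_bp // upstream_binsize
    up_acc = np.zeros(n_up)
    body_acc = np.zeros(n_body_bins)
    used = 0
    for g in genes:
        if g.body_length < n_body_bins:
            logger.warning("gene %s shorter than n_body_bins; excluded", g.gene_id)
            continue
        t = tss_of(g)
        # upstream: oriented offsets x in [-upstream_bp, 0)
        for j in range(n_up):
            a = -upstream_bp + j * upstream_binsize
            b = a + upstream_binsize
            if g.strand == "+":
                lo, hi = t + a, t + b
            else:  # x = t - pos  ->  pos in (t - b, t - a]
                lo, hi = t - b + 1, t - a + 1
            up_acc[j] += track.range_sum(g.chrom, lo, hi) / upstream_binsize
        # body: n equal fractions of [start, end), oriented
        edges = g.start + np.round(
            np.linspace(0, g.body_length, n_body_bins + 1)
        ).astype(np.int64)
        sums = track.range_sums(g.chrom, edges[:-1], edges[1:])
        widths = np.maximum(edges[1:] - edges[:-1], 1)
        dens = sums / widths
        if g.strand == "-":
            dens = dens[::-1]
        body_acc += dens
        used += 1
    if used == 0:
        raise ValueError("no genes long enough for the requested body bins")
    ups = [
        (-upstream_bp + j * upstream_binsize, float(up_acc[j] / used))
        for j in range(n_up)
    ]
    body = [
        (100.0 * (j + 1) / n_body_bins, float(body_acc[j] / used))
        for j in range(n_body_bins)
    ]
    return MetageneProfile(ups, body, used, label)


# ---------------------------------------------------------------------------
# gene-body density and correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneBodyDensity:
    gene_id: str
    tags_in_body: int
    body_length: int
    density: float  # tags per bp

    def __post_init__(self):
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")


def gene_body_density(track: CoverageTrack, gene: GeneModel) -> GeneBodyDensity:
    tags = track.range_sum(gene.chrom, gene.start, gene.end)
    return GeneBodyDensity(gene.gene_id, tags, gene.body_length, tags / gene.body_length)


def coverage_correlation(
    densities_a: Sequence[GeneBodyDensity],
    densities_b: Sequence[GeneBodyDensity],
    method: str = "pearson",
) -> dict:
    """Correlation of per-gene densities from two tracks, paired by gene_id."""
    a_map = {d.gene_id: d.density for d in densities_a}
    b_map = {d.gene_id: d.density for d in densities_b}
    shared = sorted(set(a_map) & set(b_map))
    if len(shared) < 3:
        raise ValueError("need >= 3 genes shared between the two density sets")
    x = np.array([a_map[g] for g in shared])
    y = np.array([b_map[g] for g in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a density vector; correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return {"r": float(res.statistic), "p": float(res.pvalue), "n": len(shared)}


# ---------------------------------------------------------------------------
# positivity and permutation enrichment
# ---------------------------------------------------------------------------


def mark_positivity(
    genes: Sequence[GeneModel],
    mark_peaks: Sequence[Peak],
    window_bp: int = 2500,
    mode: str = "tss_window",
) -> dict[str, bool]:
    """Per-gene boolean: does a mark peak fall in the scored window?

    ``tss_window``: any overlap with [TSS - w, TSS + w) (histone marks);
    ``gene_overlap``: any overlap with the gene span (Pol II).
    """
    if mode not in ("tss_window", "gene_overlap"):
        raise ValueError(f"unknown positivity mode {mode!r}")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for pk in mark_peaks:
        by_chrom.setdefault(pk.chrom, []).append((pk.start, pk.end))
    arrays = {
        c: interval_arrays(merge_intervals(iv)) for c, iv in by_chrom.items()
    }
    out = {}
    for g in genes:
        if mode == "tss_window":
            t = tss_of(g)
            lo, hi = max(0, t - window_bp), t + window_bp
        else:
            lo, hi = g.start, g.end
        starts, ends = arrays.get(g.chrom, (np.empty(0), np.empty(0)))
        if starts.size == 0:
            out[g.gene_id] = False
            continue
        j = int(np.searchsorted(starts, hi))
        out[g.gene_id] = bool(j > 0 and ends[j - 1] > lo)
    return out


@dataclass
class PermutationEnrichment:
    observed_percent: float
    null_mean: float
    null_sd: float
    z: float
    empirical_p: float
    n_iterations: int
    set_size: int
    seed: int
    null_percents: list[float] = field(default_factory=list, repr=False)

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("null_percents")
        return json.dumps(d, indent=2, allow_nan=True)


def permutation_enrichment(
    target_genes: Sequence[str],
    universe: Sequence[str],
    positivity: Mapping[str, bool],
    n_iter: int = 100,
    seed: int = 0,
) -> PermutationEnrichment:
    """Positivity of targets vs size-matched random gene sets.

    Null sets are drawn without replacement from the universe (which
    includes the targets); the empirical p-value is one-sided for
    enrichment with the add-one correction (1 + #{null >= obs}) /
    (1 + n_iter), so it is never exactly zero.
    """
    targets = list(dict.fromkeys(target_genes))
    uni = list(dict.fromkeys(universe))
    if not set(targets) <= set(uni):
        raise ValueError("target_genes must be a subset of the universe")
    if n_iter < 1 or len(uni) < len(targets):
        raise ValueError("need n_iter >= 1 and |universe| >= |targets|")
    obs = 100.0 * float(np.mean([bool(positivity.get(g, False)) for g in targets]))
    pos_arr = np.array([bool(positivity.get(g, False)) for g in uni])
    rng = np.random.default_rng(seed)
    k = len(targets)
    null = np.empty(n_iter)
    for i in range(n_iter):
        draw = rng.choice(len(uni), size=k, replace=False)
        null[i] = 100.0 * pos_arr[draw].mean()
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    z = (obs - null_mean) / null_sd if null_sd > 0 else Z_UNDEFINED
    emp_p = (1 + int(np.sum(null >= obs))) / (1 + n_iter)
    return PermutationEnrichment(
        observed_percent=obs, null_mean=null_mean, null_sd=null_sd, z=z,
        empirical_p=emp_p, n_iterations=n_iter, set_size=k, seed=seed,
        null_percents=[float(v) for v in null],
    )


# ---------------------------------------------------------------------------
# ChIP-qPCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QPCRRecord:
    region_id: str
    ct_ip: float
    ct_input: float
    input_fraction: float = 0.01  # fraction of chromatin used as input
    is_negative_control: bool = False

    def __post_init__(self):
        for v in (self.ct_ip, self.ct_input):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{self.region_id}: Ct values must be finite and > 0")
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must be in (0, 1]")


def percent_input(rec: QPCRRecord) -> float:
    """Percent-input enrichment with dilution adjustment.

    The input Ct is corrected by log2(1/input_fraction) cycles to what a
    100% input would have given; enrichment is 100 x 2^-(ct_ip - adjusted).
    """
    adjusted = rec.ct_input - math.log2(1.0 / rec.input_fraction)
    return 100.0 * 2.0 ** (adjusted - rec.ct_ip)


def qpcr_noise_threshold(records: Sequence[QPCRRecord]) -> float:
    """Highest percent-input among negative-control regions."""
    negatives = [r for r in records if r.is_negative_control]
    if not negatives:
        raise ValueError("no negative-control qPCR records supplied")
    return max(percent_input(r) for r in negatives)


def is_enriched(value_percent: float, noise_threshold: float) -> bool:
    """Strictly above the highest negative-control noise value."""
    return value_percent > noise_threshold


def read_qpcr_table(path) -> list[QPCRRecord]:
    """TSV: region_id, ct_ip, ct_input, input_fraction, is_negative."""
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "ct_ip", "ct_input"}
    if not required <= set(df.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            QPCRRecord(
                region_id=str(row.region_id),
                ct_ip=float(row.ct_ip),
                ct_input=float(row.ct_input),
                input_fraction=float(getattr(row, "input_fraction", 0.01)),
                is_negative_control=bool(getattr(row, "is_negative", False)),
            )
        )
    return recs


# ---------------------------------------------------------------------------
# along-gene profiles
# ---------------------------------------------------------------------------


def along_gene_profile(
    track: CoverageTrack, gene: GeneModel, anchors: Sequence[int], halfwidth: int = 250
) -> list[tuple[int, float]]:
    """Mean depth in windows centered at TSS + offset (gene-oriented offsets)."""
    t = tss_of(gene)
    out = []
    for off in anchors:
        pos = t + off if gene.strand == "+" else t - off
        lo, hi = pos - halfwidth, pos + halfwidth + 1
        out.append((int(off), track.range_sum(gene.chrom, lo, hi) / (hi - lo)))
    return out


def compare_profiles(
    a: Mapping[int, Sequence[float]],
    b: Mapping[int, Sequence[float]],
    welch: bool = False,
) -> list[tuple[int, float, float]]:
    """Per-offset unpaired two-sided t-test between replicate sets.

    Returns (offset, mean(a) - mean(b), p) sorted by offset.  Student's
    t (equal variances) by default; set ``welch=True`` for the Welch
    correction.
    """
    if set(a) != set(b):
        raise ValueError("profiles have unmatched offsets")
    out = []
    for off in sorted(a):
        xa, xb = np.asarray(a[off], dtype=float), np.asarray(b[off], dtype=float)
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"offset {off}: >= 2 replicates required per condition")
        res = stats.ttest_ind(xa, xb, equal_var=not welch)
        p = float(res.pvalue)
        if np.isnan(p):  # identical constant replicates: no evidence of difference
            p = 1.0
        out.append((int(off), float(xa.mean() - xb.mean()), p))
    return out


# ---------------------------------------------------------------------------
# enhancer signature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnhancerCall:
    region_id: str
    h3k4me1_fold: float
    h3k27ac_fold: float
    h3k4me3_fold: float
    label: str  # enhancer_like | promoter_like | none
    active: bool  # H3K27ac above threshold


def classify_enhancer_signature(
    region_id: str,
    h3k4me1_fold: float,
    h3k27ac_fold: float,
    h3k4me3_fold: float,
    tau_k4me1: float = 2.0,
    tau_k27ac: float = 2.0,
    tau_k4me3: float = 4.0,
    rho: float = 1.0,
) -> EnhancerCall:
    """Enhancer-like vs promoter-like chromatin signature from fold enrichments.

    enhancer_like: H3K4me1 >= tau and K4me3/K4me1 ratio < rho (high
    mono-, low tri-methylation); promoter_like: H3K4me3 >= tau and
    ratio >= rho.  H3K27ac above its threshold flags the region active.
    """
    folds = (h3k4me1_fold, h3k27ac_fold, h3k4me3_fold)
    if any(f < 0 for f in folds):
        raise ValueError("fold enrichments must be non-negative")
    active = h3k27ac_fold >= tau_k27ac
    if h3k4me1_fold == 0:
        logger.warning("%s: H3K4me1 fold is 0; classifying by H3K4me3 alone", region_id)
        label = "promoter_like" if h3k4me3_fold >= tau_k4me3 else "none"
    else:
        ratio = h3k4me3_fold / h3k4me1_fold
        if h3k4me1_fold >= tau_k4me1 and ratio < rho:
            label = "enhancer_like"
        elif h3k4me3_fold >= tau_k4me3 and ratio >= rho:
            label = "promoter_like"
        else:
            label = "none"
    return EnhancerCall(region_id, *folds, label=label, active=active)
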