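"""Synthetic ChIP-seq experiments with fully known planted truth.

Generates a toy genome (non-overlapping stranded genes with exon/intron
structure, including a designated "collagen-like" family of 43 long
multi-exon genes), per-antibody tag sets (two factor antibodies sharing
planted sites over independent sampling noise, an IgG background, Pol II
with gene-body mass coupled to the factor's by a Gaussian copula, and
two histone marks with different promoter-positivity rates for target
vs non-target genes), an expression table with a log-scale shift for
targets, and planted motif copies — everything reproducible from a seed
and emitted as plain-text files with a SHA-256 manifest.

Every random draw comes from a stream namespaced by (seed, artifact
name), so adding one artifact never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_annotation import GeneModel, tss_of, write_bed12
from .motif import PWM, write_fasta
from .peaks import TagSet, write_tags

logger = logging.getLogger(__name__)


def stream(seed: int, name: str) -> np.random.Generator:
    """Named random stream: (seed, crc32(name)) -> independent Generator."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for the default synthetic experiment.

    The scale (two 5-Mb chromosomes, 300 genes of which 43 are
    collagen-like, ~1 M tags per antibody) keeps a full run at desk
    scale while preserving every structural feature the pipeline
    consumes.
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 300
    n_collagen_like: int = 43
    n_collagen_with_sites: int = 42  # one family member left without a site
    n_promoter_targets: int = 35
    n_body_targets: int = 25
    n_distal_sites: int = 15
    gc: float = 0.42
    gene_length_log_mean: float = math.log(9_000.0)
    gene_length_log_sigma: float = 0.55
    collagen_length_log_mean: float = math.log(22_000.0)
    collagen_length_log_sigma: float = 0.25
    intergenic_spacing: float = 8_000.0
    margin: int = 20_000
    fragment: int = 200
    site_width: int = 400
    site_fold: float = 8.0
    fold_log_sigma: float = 0.5
    exon_center_prob: float = 0.6
    rates: dict = field(default_factory=lambda: {
        "factor_ab1": 0.10, "factor_ab2": 0.08, "igg": 0.10,
        "polii": 0.05, "h3k4me3": 0.05, "h3k9me3": 0.05,
    })
    polii_site_fold: float = 8.0
    polii_body_corr: float = 0.9
    polii_body_density: float = 0.10
    polii_body_log_sigma: float = 0.8
    mark_site_width: int = 1_000
    mark_site_fold: float = 12.0
    p_target: dict = field(default_factory=lambda: {"h3k4me3": 0.8, "h3k9me3": 0.30, "polii": 0.8})
    p_background: dict = field(default_factory=lambda: {"h3k4me3": 0.3, "h3k9me3": 0.15, "polii": 0.3})
    expression_mu_log2: float = 5.0
    expression_sigma_log2: float = 1.5
    expression_shift_log2: float = 1.0
    motif_consensus: str = "GGTACTCAGG"
    motif_copy_prob: float = 0.6

    def to_dict(self) -> dict:
        return asdict(self)


def default_pwm(consensus: str = "GGTACTCAGG", dominant: float = 0.85) -> PWM:
    """A sharply peaked PWM whose consensus is the given sequence."""
    from .motif import _BASE_INDEX

    width = len(consensus)
    freqs = np.full((width, 4), (1.0 - dominant) / 3.0)
    for i, base in enumerate(consensus):
        freqs[i, _BASE_INDEX[base]] = dominant
    return PWM(freqs, name="planted_motif")


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _make_exons(length: int, rng: np.random.Generator, dense: bool) -> tuple[tuple[int, int], ...]:
    """Exon/intron layout spanning [0, length); collagen-like genes get
    many short exons (``dense``)."""
    per_exon = 1_200 if dense else 3_000
    n_ex = max(1, min(int(round(length / per_exon)), length // 600, 60))
    if n_ex <= 1:
        return ((0, length),)
    ex_lens = rng.integers(80, 250, size=n_ex)
    intron_total = length - int(ex_lens.sum())
    if intron_total <= 0:
        return ((0, length),)
    intron_lens = rng.multinomial(intron_total, np.full(n_ex - 1, 1.0 / (n_ex - 1)))
    exons = []
    pos = 0
    for i in range(n_ex):
        exons.append((pos, pos + int(ex_lens[i])))
        pos += int(ex_lens[i])
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    # stretch last exon to end exactly at the gene 3' end
    s, _ = exons[-1]
    exons[-1] = (s, length)
    return tuple(exons)


def generate_genome(
    n_genes: int = 300,
    n_chroms: int = 2,
    chrom_length: int = 5_000_000,
    n_collagen_like: int = 43,
    gene_length_log_mean: float = math.log(9_000.0),
    gene_length_log_sigma: float = 0.55,
    collagen_length_log_mean: float = math.log(22_000.0),
    collagen_length_log_sigma: float = 0.25,
    intergenic_spacing: float = 8_000.0,
    margin: int = 20_000,
    gc: float = 0.42,
    seed: int = 0,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Non-overlapping stranded genes plus i.i.d. genome sequence.

    Returns (gene models, chromosome sequences).  Gene ids are
    ``colgene_01..NN`` for the collagen-like family and ``gene_0001...``
    otherwise; family members are long with dense short exons.
    """
    if n_genes < 1 or n_collagen_like > n_genes:
        raise ValueError("need n_genes >= 1 and n_collagen_like <= n_genes")
    rng = stream(seed, "genome")
    specs = []
    for i in range(n_collagen_like):
        length = int(rng.lognormal(collagen_length_log_mean, collagen_length_log_sigma))
        specs.append((f"colgene_{i + 1:02d}", max(length, 2_000), True))
    for i in range(n_genes - n_collagen_like):
        length = int(rng.lognormal(gene_length_log_mean, gene_length_log_sigma))
        specs.append((f"gene_{i + 1:04d}", max(length, 600), False))
    order = rng.permutation(len(specs))
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    genes: list[GeneModel] = []
    ci = 0
    cursor = margin
    for idx in order:
        gene_id, length, dense = specs[idx]
        spacing = int(rng.exponential(intergenic_spacing)) + 2_000
        while cursor + spacing + length > chrom_length - margin:
            ci += 1
            cursor = margin
            if ci >= n_chroms:
                need = sum(s[1] for s in specs) + n_genes * (int(intergenic_spacing) + 2_000)
                raise ValueError(
                    f"genes do not fit: need roughly {need // n_chroms} bp per "
                    f"chromosome, have {chrom_length}"
                )
        cursor += spacing
        start, end = cursor, cursor + length
        strand = "+" if rng.integers(0, 2) else "-"
        exons = tuple(
            (start + s, start + e) for s, e in _make_exons(length, rng, dense)
        )
        genes.append(GeneModel(gene_id, chroms[ci], start, end, strand, exons))
        cursor = end
    seqs = {}
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom in chroms:
        r = stream(seed, f"sequence:{chrom}")
        seqs[chrom] = alphabet[r.choice(4, size=chrom_length, p=p)].tobytes().decode()
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes, seqs


# ---------------------------------------------------------------------------
# tags
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """An enriched interval; ``shape`` controls where fragment centers
    fall: ``point`` concentrates them at the site midpoint (a discrete
    binding site), ``uniform`` spreads them over the interval (an
    extended domain, e.g. elongating polymerase over a gene body)."""

    chrom: str
    start: int
    end: int
    fold: float
    shape: str = "point"


@dataclass
class AntibodyDesign:
    background_rate: float  # tags per bp
    planted_sites: list[PlantedSite] = field(default_factory=list)
    fragment: int = 200


def _tagset_from_centers(
    label: str, per_chrom: Mapping[str, tuple[np.ndarray, np.ndarray]],
    fragment: int, chrom_sizes: Mapping[str, int],
) -> TagSet:
    positions, strands = {}, {}
    half = fragment // 2
    for chrom, (centers, strand) in per_chrom.items():
        pos = centers + half * (-strand.astype(np.int64))
        np.clip(pos, 0, chrom_sizes[chrom] - 1, out=pos)
        order = np.argsort(pos, kind="stable")
        positions[chrom] = pos[order]
        strands[chrom] = strand[order].astype(np.int8)
    return TagSet(label, positions, strands)


def generate_tags(
    chrom_sizes: Mapping[str, int],
    design: Mapping[str, AntibodyDesign],
    seed: int = 0,
) -> dict[str, TagSet]:
    """Per-antibody tag sets: homogeneous Poisson background plus extra
    Poisson mass inside planted sites at (fold - 1) x background rate.

    Fragment centers are drawn first; 5' tag positions sit fragment/2
    upstream (+ strand) or downstream (- strand) of the center, so a
    coverage track shifted by fragment/2 re-centers both strands.
    """
    out = {}
    for label, d in design.items():
        if d.background_rate <= 0:
            raise ValueError(f"{label}: background_rate must be positive")
        rng = stream(seed, f"tags:{label}")
        per_chrom: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for chrom, size in sorted(chrom_sizes.items()):
            n_bg = int(rng.poisson(d.background_rate * size))
            centers = rng.integers(0, size, size=n_bg)
            strand = (rng.integers(0, 2, size=n_bg) * 2 - 1)
            per_chrom[chrom] = [(centers, strand)]
        for site in d.planted_sites:
            if site.fold < 1:
                raise ValueError("planted fold must be >= 1")
            extra_rate = (site.fold - 1.0) * d.background_rate
            width = site.end - site.start
            n = int(rng.poisson(extra_rate * width))
            if site.shape == "point":
                mid = (site.start + site.end) // 2
                centers = np.clip(
                    np.round(rng.normal(mid, max(width / 8.0, 1.0), size=n)),
                    site.start, site.end - 1,
                ).astype(np.int64)
            else:
                centers = rng.integers(site.start, site.end, size=n)
            strand = (rng.integers(0, 2, size=n) * 2 - 1)
            per_chrom[site.chrom].append((centers, strand))
        merged = {
            chrom: (
                np.concatenate([c for c, _ in parts]).astype(np.int64),
                np.concatenate([s for _, s in parts]),
            )
            for chrom, parts in per_chrom.items()
        }
        out[label] = _tagset_from_centers(label, merged, d.fragment, chrom_sizes)
    return out


def generate_correlated_body_tags(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    r: float = 0.9,
    mean_density: float = 0.1,
    log_sigma: float = 0.8,
    fragment: int = 200,
    seed: int = 0,
    labels: tuple[str, str] = ("factor_body", "polii_body"),
) -> tuple[TagSet, TagSet, dict[str, tuple[float, float]]]:
    """Two tag sets whose per-gene body densities share correlation ``r``.

    Log-densities are bivariate normal (Gaussian copula on the log
    scale) with unit-variance marginals scaled by ``log_sigma`` and mean
    chosen so E[density] = ``mean_density``; tag counts are Poisson.
    Returns both tag sets and the planted per-gene density pairs.
    """
    if not (-1.0 <= r <= 1.0):
        raise ValueError("correlation r must lie in [-1, 1]")
    rng = stream(seed, "correlated_body")
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=len(genes), method="cholesky")
    mu = math.log(mean_density) - 0.5 * log_sigma**2
    dens = np.exp(mu + log_sigma * z)  # (n_genes, 2)
    truth = {}
    parts: list[dict[str, list]] = [dict(), dict()]
    for gi, g in enumerate(genes):
        truth[g.gene_id] = (float(dens[gi, 0]), float(dens[gi, 1]))
        for k in (0, 1):
            n = int(rng.poisson(dens[gi, k] * g.body_length))
            centers = rng.integers(g.start, g.end, size=n)
            strand = (rng.integers(0, 2, size=n) * 2 - 1)
            parts[k].setdefault(g.chrom, []).append((centers, strand))
    tagsets = []
    for k, label in enumerate(labels):
        merged = {
            chrom: (
                np.concatenate([c for c, _ in lst]).astype(np.int64),
                np.concatenate([s for _, s in lst]),
            )
            for chrom, lst in parts[k].items()
        }
        tagsets.append(_tagset_from_centers(label, merged, fragment, chrom_sizes))
    return tagsets[0], tagsets[1], truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    gene_models: Sequence[GeneModel],
    target_ids: Sequence[str],
    mu_log2: float = 5.0,
    sigma_log2: float = 1.5,
    shift_log2: float = 1.0,
    seed: int = 0,
) -> dict[str, float]:
    """Log-normal expression; targets shifted by +``shift_log2`` log2 units.

    ``gene_models`` may be GeneModel objects or bare gene_id strings.
    """
    if not math.isfinite(shift_log2):
        raise ValueError("shift must be finite")
    rng = stream(seed, "expression")
    targets = set(target_ids)
    out = {}
    for g in gene_models:
        gid = g if isinstance(g, str) else g.gene_id
        x = rng.normal(mu_log2, sigma_log2)
        if gid in targets:
            x += shift_log2
        out[gid] = float(2.0 ** x)
    return out


def write_expression_table(expression: Mapping[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gid in sorted(expression):
            fh.write(f"{gid}\t{expression[gid]:.6f}\n")


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------


def plant_motifs(
    chrom_seqs: Mapping[str, str],
    motif: str,
    placements: Sequence[tuple[str, int, str]],
) -> tuple[dict[str, str], list[dict]]:
    """Write motif copies into the genome at (chrom, offset, strand).

    Copies must fall within bounds and not overlap each other; planting
    is idempotent (re-planting the same copies is a no-op).
    """
    from .motif import reverse_complement

    seqs = {c: bytearray(s, "ascii") for c, s in chrom_seqs.items()}
    w = len(motif)
    seen: dict[str, list[tuple[int, int]]] = {}
    truth = []
    for chrom, pos, strand in placements:
        if chrom not in seqs:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if pos < 0 or pos + w > len(seqs[chrom]):
            raise ValueError(f"motif copy at {chrom}:{pos} out of bounds")
        for s, e in seen.get(chrom, []):
            if pos < e and pos + w > s:
                raise ValueError(f"overlapping motif copies at {chrom}:{pos}")
        seen.setdefault(chrom, []).append((pos, pos + w))
        copy = motif if strand == "+" else reverse_complement(motif)
        seqs[chrom][pos: pos + w] = copy.encode("ascii")
        truth.append({"chrom": chrom, "offset": pos, "strand": strand, "sequence": copy})
    return {c: bytes(b).decode() for c, b in seqs.items()}, truth


# ---------------------------------------------------------------------------
# whole experiment
# ---------------------------------------------------------------------------


@dataclass
class SyntheticExperiment:
    config: dict
    seed: int
    gene_models: list[GeneModel]
    chrom_sizes: dict[str, int]
    chrom_seqs: dict[str, str]
    tags: dict[str, TagSet]
    expression: dict[str, float]
    truth: dict
    manifest: dict = field(default_factory=dict)

    @property
    def collagen_family(self) -> list[str]:
        return list(self.truth["collagen_family"])


def _site_center_for_gene(
    g: GeneModel, exonic: bool, rng: np.random.Generator
) -> int:
    if exonic or len(g.exons) == 1:
        s, e = g.exons[rng.integers(0, len(g.exons))]
        return (s + e) // 2
    # intron midpoint between two adjacent exons
    i = int(rng.integers(0, len(g.exons) - 1))
    return (g.exons[i][1] + g.exons[i + 1][0]) // 2


def simulate_experiment(
    config: SimulationConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> SyntheticExperiment:
    """Generate the full synthetic experiment; optionally emit files.

    Planted structure: gene-body sites (exon-biased centers) in 42 of
    the 43 collagen-like genes shared by both factor antibodies,
    promoter and gene-body sites for additional target genes, a handful
    of intergenic distal sites, Pol II and histone-mark tracks, a
    shifted expression table, and motif copies in factor sites plus a
    three-copy exon configuration.
    """
    cfg = config or SimulationConfig()
    genes, seqs = generate_genome(
        n_genes=cfg.n_genes, n_chroms=cfg.n_chroms, chrom_length=cfg.chrom_length,
        n_collagen_like=cfg.n_collagen_like,
        gene_length_log_mean=cfg.gene_length_log_mean,
        gene_length_log_sigma=cfg.gene_length_log_sigma,
        collagen_length_log_mean=cfg.collagen_length_log_mean,
        collagen_length_log_sigma=cfg.collagen_length_log_sigma,
        intergenic_spacing=cfg.intergenic_spacing, margin=cfg.margin,
        gc=cfg.gc, seed=seed,
    )
    chrom_sizes = {c: len(s) for c, s in seqs.items()}
    gene_map = {g.gene_id: g for g in genes}
    family = sorted(g.gene_id for g in genes if g.gene_id.startswith("colgene_"))
    regular = sorted(g.gene_id for g in genes if not g.gene_id.startswith("colgene_"))

    rng = stream(seed, "design")
    covered = family[: cfg.n_collagen_with_sites]
    others = list(rng.choice(regular, size=cfg.n_promoter_targets + cfg.n_body_targets,
                             replace=False))
    promoter_targets = sorted(others[: cfg.n_promoter_targets])
    body_targets = sorted(others[cfg.n_promoter_targets:])
    target_ids = sorted(set(covered) | set(promoter_targets) | set(body_targets))

    # factor sites; collagen folds modulated jointly with Pol II body mass
    cov = np.array([[1.0, cfg.polii_body_corr], [cfg.polii_body_corr, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=len(covered), method="cholesky")
    half = cfg.site_width // 2
    factor_sites: list[PlantedSite] = []
    exonic_flags: list[bool] = []
    collagen_site_by_gene: dict[str, PlantedSite] = {}
    for gi, gid in enumerate(covered):
        g = gene_map[gid]
        exonic = bool(rng.random() < cfg.exon_center_prob)
        center = _site_center_for_gene(g, exonic, rng)
        fold = cfg.site_fold * math.exp(
            cfg.fold_log_sigma * z[gi, 0] - 0.5 * cfg.fold_log_sigma**2
        )
        # floor keeps every family site comfortably callable
        site = PlantedSite(g.chrom, max(0, center - half), center + half, max(6.0, fold))
        factor_sites.append(site)
        exonic_flags.append(exonic)
        collagen_site_by_gene[gid] = site
    for gid in promoter_targets:
        g = gene_map[gid]
        t = tss_of(g)
        factor_sites.append(PlantedSite(g.chrom, max(0, t - half), t + half, cfg.site_fold))
    for gid in body_targets:
        g = gene_map[gid]
        center = _site_center_for_gene(g, bool(rng.random() < 0.5), rng)
        factor_sites.append(PlantedSite(g.chrom, max(0, center - half), center + half, cfg.site_fold))
    # distal sites: genuinely intergenic yet within assignment range of a TSS
    distal_sites: list[PlantedSite] = []
    chroms = sorted(chrom_sizes)
    gene_spans = {c: [(g.start - 5_000, g.end + 5_000) for g in genes if g.chrom == c]
                  for c in chroms}
    attempts = 0
    while len(distal_sites) < cfg.n_distal_sites and attempts < 10_000:
        attempts += 1
        anchor = gene_map[regular[int(rng.integers(0, len(regular)))]]
        offset = int(rng.integers(8_000, 60_000)) * (1 if rng.integers(0, 2) else -1)
        t = tss_of(anchor)
        pos = t + offset if anchor.strand == "+" else t - offset
        c = anchor.chrom
        if not (cfg.margin <= pos < chrom_sizes[c] - cfg.margin):
            continue
        if any(s <= pos < e for s, e in gene_spans[c]):
            continue
        if any(d.chrom == c and abs(pos - (d.start + half)) < 2 * cfg.site_width
               for d in distal_sites):
            continue
        distal_sites.append(PlantedSite(c, pos - half, pos + half, cfg.site_fold))
    factor_sites = factor_sites + distal_sites

    # histone marks: promoter sites present with class-dependent probability
    mark_sites: dict[str, list[PlantedSite]] = {}
    mark_positive: dict[str, dict[str, bool]] = {}
    mhalf = cfg.mark_site_width // 2
    for mark in ("h3k4me3", "h3k9me3", "polii"):
        r_mark = stream(seed, f"positivity:{mark}")
        sites, positives = [], {}
        for g in genes:
            p = cfg.p_target[mark] if g.gene_id in target_ids else cfg.p_background[mark]
            pos = bool(r_mark.random() < p)
            positives[g.gene_id] = pos
            if pos:
                t = tss_of(g)
                fold = cfg.mark_site_fold if mark != "polii" else cfg.polii_site_fold
                sites.append(PlantedSite(g.chrom, max(0, t - mhalf), t + mhalf, fold))
        mark_sites[mark] = sites
        mark_positive[mark] = positives

    # Pol II gene-body mass for collagen genes, coupled to factor fold
    polii_body_sites = []
    polii_density_truth = {}
    for gi, gid in enumerate(covered):
        g = gene_map[gid]
        dens = cfg.polii_body_density * math.exp(
            cfg.polii_body_log_sigma * z[gi, 1] - 0.5 * cfg.polii_body_log_sigma**2
        )
        fold = 1.0 + dens / cfg.rates["polii"]
        polii_body_sites.append(PlantedSite(g.chrom, g.start, g.end, fold, shape="uniform"))
        polii_density_truth[gid] = dens

    design = {
        "factor_ab1": AntibodyDesign(cfg.rates["factor_ab1"], list(factor_sites), cfg.fragment),
        "factor_ab2": AntibodyDesign(cfg.rates["factor_ab2"], list(factor_sites), cfg.fragment),
        "igg": AntibodyDesign(cfg.rates["igg"], [], cfg.fragment),
        "polii": AntibodyDesign(cfg.rates["polii"], mark_sites["polii"] + polii_body_sites, cfg.fragment),
        "h3k4me3": AntibodyDesign(cfg.rates["h3k4me3"], mark_sites["h3k4me3"], cfg.fragment),
        "h3k9me3": AntibodyDesign(cfg.rates["h3k9me3"], mark_sites["h3k9me3"], cfg.fragment),
    }
    tags = generate_tags(chrom_sizes, design, seed=seed)

    expression = generate_expression(
        genes, target_ids, cfg.expression_mu_log2, cfg.expression_sigma_log2,
        cfg.expression_shift_log2, seed=seed,
    )

    # motif copies: one per factor site (with probability), plus a
    # three-copy configuration inside one long collagen-like exon
    r_motif = stream(seed, "motifs")
    w = len(cfg.motif_consensus)
    placements: list[tuple[str, int, str]] = []
    for site in factor_sites:
        if r_motif.random() < cfg.motif_copy_prob:
            center = (site.start + site.end) // 2
            strand = "+" if r_motif.integers(0, 2) else "-"
            placements.append((site.chrom, center - w // 2, strand))
    host = gene_map[covered[0]]
    long_exon = max(host.exons, key=lambda ex: ex[1] - ex[0])
    exon_mid = (long_exon[0] + long_exon[1]) // 2
    triple = [(host.chrom, exon_mid + d, "+") for d in (-2 * w - 10, 0, 2 * w + 10)]
    placements = [
        p for p in placements
        if not (p[0] == host.chrom and abs(p[1] - exon_mid) < 4 * w + 40)
    ] + triple
    # drop any copy overlapping an earlier one (overlapping planted sites)
    kept: list[tuple[str, int, str]] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for chrom, pos, strand in placements:
        if any(pos < e and pos + w > s for s, e in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((pos, pos + w))
        kept.append((chrom, pos, strand))
    seqs, motif_truth = plant_motifs(seqs, cfg.motif_consensus, kept)

    truth = {
        "target_gene_ids": target_ids,
        "collagen_family": family,
        "collagen_with_sites": covered,
        "collagen_without_sites": sorted(set(family) - set(covered)),
        "planted_sites": {
            label: [asdict(s) for s in d.planted_sites] for label, d in design.items()
        },
        "factor_site_exonic_fraction": float(np.mean(exonic_flags)),
        "collagen_sites": [
            {"gene_id": gid, **asdict(collagen_site_by_gene[gid]), "exonic": bool(fl)}
            for gid, fl in zip(covered, exonic_flags)
        ],
        "positivity_rates": {m: {"p_target": cfg.p_target[m], "p_background": cfg.p_background[m]}
                             for m in ("h3k4me3", "h3k9me3", "polii")},
        "mark_positive": mark_positive,
        "polii_body_corr": cfg.polii_body_corr,
        "polii_body_density": polii_density_truth,
        "expression_shift_log2": cfg.expression_shift_log2,
        "motif_consensus": cfg.motif_consensus,
        "motif_copies": motif_truth,
        "triple_motif_exon": {
            "gene_id": host.gene_id, "chrom": host.chrom,
            "exon_start": long_exon[0], "exon_end": long_exon[1],
            "offsets": [p[1] for p in triple],
        },
    }
    exp = SyntheticExperiment(
        config=cfg.to_dict(), seed=seed, gene_models=genes,
        chrom_sizes=chrom_sizes, chrom_seqs=seqs, tags=tags,
        expression=expression, truth=truth,
    )
    if outdir is not None:
        exp.manifest = write_experiment(exp, outdir)
    return exp


def write_experiment(exp: SyntheticExperiment, outdir: str | Path) -> dict:
    """Emit all artifacts as plain text and return the SHA-256 manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(sorted(exp.chrom_seqs.items()), out / "genome.fa")
    write_gff3(exp.gene_models, out / "genes.gff3")
    write_bed12(exp.gene_models, out / "genes.bed12")
    for label, ts in sorted(exp.tags.items()):
        write_tags(ts, out / f"{label}.bed")
    write_expression_table(exp.expression, out / "expression.tsv")
    with open(out / "collagen_like.txt", "w") as fh:
        fh.write("\n".join(exp.truth["collagen_family"]) + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump({"config": exp.config, "seed": exp.seed, **exp.truth}, fh, indent=2)
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or not f.is_file():
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_experiment(indir: str | Path) -> SyntheticExperiment:
    """Re-assemble a SyntheticExperiment from an emitted directory."""
    from .genome_annotation import read_gene_models
    from .motif import read_fasta
    from .peaks import read_tags

    indir = Path(indir)
    with open(indir / "truth.json") as fh:
        payload = json.load(fh)
    config = payload.pop("config")
    seed = payload.pop("seed")
    genes = read_gene_models(indir / "genes.gff3", "gff3")
    seqs = dict(read_fasta(indir / "genome.fa"))
    tags = {}
    for label in ("factor_ab1", "factor_ab2", "igg", "polii", "h3k4me3", "h3k9me3"):
        path = indir / f"{label}.bed"
        if path.exists():
            tags[label] = read_tags(path, label)
    expression = {}
    with open(indir / "expression.tsv") as fh:
        next(fh)
        for line in fh:
            gid, val = line.split("\t")
            expression[gid] = float(val)
    manifest = {}
    mpath = indir / "manifest.json"
    if mpath.exists():
        with open(mpath) as fh:
            manifest = json.load(fh)
    return SyntheticExperiment(
        config=config, seed=seed,
        gene_models=sorted(genes, key=lambda g: (g.chrom, g.start)),
        chrom_sizes={c: len(s) for c, s in seqs.items()}, chrom_seqs=seqs,
        tags=tags, expression=expression, truth=payload, manifest=manifest,
    )


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsynthetic\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
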