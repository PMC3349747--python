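"""Metagene profiles, density correlation, positivity, permutation test,
qPCR arithmetic, profile comparison, enhancer signatures."""

import math

import numpy as np
import pytest

from occupancy_scan.genome_annotation import GeneModel
from occupancy_scan.occupancy_stats import (
    QPCRRecord,
    classify_enhancer_signature,
    compare_profiles,
    coverage_correlation,
    gene_body_density,
    mark_positivity,
    metagene_profile,
    percent_input,
    permutation_enrichment,
    qpcr_noise_threshold,
    is_enriched,
    GeneBodyDensity,
)
from occupancy_scan.peaks import Peak, TagSet, coverage_track


def _uniform_genes(n=50, length=10_000, gap=5_000):
    genes = []
    cursor = 3_000
    for i in range(n):
        genes.append(GeneModel(f"g{i:02d}", "chr1", cursor, cursor + length,
                               "+" if i % 2 else "-", ((cursor, cursor + length),)))
        cursor += length + gap
    return genes


class TestMetagene:
    def test_uniform_tags_give_flat_profile(self, rng):
        genes = _uniform_genes()
        span = genes[-1].end + 5_000
        n_tags = 160_000  # >= 200 expected per body bin across 50 genes
        tags = TagSet.from_tags(
            "u", [("chr1", int(p), "+") for p in rng.integers(0, span, n_tags)]
        )
        track = coverage_track(tags, shift=0, chrom_sizes={"chr1": span})
        prof = metagene_profile(track, genes, n_body_bins=20)
        dens = [d for _, d in prof.body_bins] + [d for _, d in prof.upstream_bins]
        assert max(dens) / min(dens) <= 1.5

    def test_tss_planted_tags_peak_at_zero(self, rng):
        genes = _uniform_genes(n=20)
        span = genes[-1].end + 5_000
        items = []
        for g in genes:
            t = g.start if g.strand == "+" else g.end - 1
            for p in rng.integers(t - 200, t + 200, size=100):
                items.append(("chr1", int(max(p, 0)), "+"))
        track = coverage_track(TagSet.from_tags("t", items), shift=0,
                               chrom_sizes={"chr1": span})
        prof = metagene_profile(track, genes, upstream_bp=2_000,
                                upstream_binsize=100, n_body_bins=20)
        combined = prof.upstream_bins + [(pct, d) for pct, d in prof.body_bins]
        dens = [d for _, d in combined]
        best = int(np.argmax(dens))
        # the maximum-density bin touches x = 0 (last upstream or first body)
        n_up = len(prof.upstream_bins)
        assert best in (n_up - 1, n_up, n_up - 2)

    def test_body_bins_invariant_under_length_scaling(self):
        """Stretching genes and tags together preserves per-bin tag counts."""
        g1 = GeneModel("a", "chr1", 0, 1_000, "+", ((0, 1_000),))
        g2 = GeneModel("a", "chr1", 0, 2_000, "+", ((0, 2_000),))
        pos = [10, 250, 251, 700, 990]
        t1 = TagSet.from_tags("x", [("chr1", p, "+") for p in pos])
        t2 = TagSet.from_tags("x", [("chr1", 2 * p, "+") for p in pos])
        p1 = metagene_profile(coverage_track(t1, 0, {"chr1": 1_000}), [g1],
                              upstream_bp=0, n_body_bins=10)
        p2 = metagene_profile(coverage_track(t2, 0, {"chr1": 2_000}), [g2],
                              upstream_bp=0, n_body_bins=10)
        counts1 = [d * 100 for _, d in p1.body_bins]   # bin width 100
        counts2 = [d * 200 for _, d in p2.body_bins]   # bin width 200
        assert counts1 == pytest.approx(counts2)

    def test_body_mass_matches_total_body_tags(self, rng):
        g = GeneModel("a", "chr1", 100, 5_100, "-", ((100, 5_100),))
        tags = TagSet.from_tags(
            "x", [("chr1", int(p), "+") for p in rng.integers(100, 5_100, 400)]
        )
        track = coverage_track(tags, 0, {"chr1": 6_000})
        prof = metagene_profile(track, [g], upstream_bp=0, n_body_bins=25)
        width = 5_000 / 25
        mass = sum(d * width for _, d in prof.body_bins)
        assert mass == pytest.approx(400, rel=0.01)

    def test_short_genes_excluded(self):
        g = GeneModel("tiny", "chr1", 0, 10, "+", ((0, 10),))
        track = coverage_track(TagSet.from_tags("x", [("chr1", 5, "+")]), 0)
        with pytest.raises(ValueError):
            metagene_profile(track, [g], n_body_bins=40)


class TestDensityCorrelation:
    def test_density_arithmetic(self):
        g = GeneModel("a", "chr1", 0, 10_000, "+", ((0, 10_000),))
        tags = TagSet.from_tags("x", [("chr1", p, "+") for p in range(100)])
        d = gene_body_density(coverage_track(tags, 0, {"chr1": 10_000}), g)
        assert d.density == pytest.approx(0.01)
        assert d.tags_in_body == 100

    def test_identity_and_sign(self):
        a = [GeneBodyDensity(f"g{i}", i, 100, i / 100) for i in range(1, 6)]
        b = [GeneBodyDensity(f"g{i}", 0, 100, (6 - i) / 100) for i in range(1, 6)]
        assert coverage_correlation(a, a)["r"] == pytest.approx(1.0)
        assert coverage_correlation(a, b)["r"] == pytest.approx(-1.0)

    def test_matches_hand_formula(self):
        x = [0.10, 0.35, 0.20, 0.50, 0.05]
        y = [1.2, 2.1, 1.1, 3.0, 0.7]
        a = [GeneBodyDensity(f"g{i}", 0, 100, v) for i, v in enumerate(x)]
        b = [GeneBodyDensity(f"g{i}", 0, 100, v) for i, v in enumerate(y)]
        n = 5
        sx, sy = sum(x), sum(y)
        sxx, syy = sum(v * v for v in x), sum(v * v for v in y)
        sxy = sum(u * v for u, v in zip(x, y))
        want = (n * sxy - sx * sy) / math.sqrt(
            (n * sxx - sx * sx) * (n * syy - sy * sy)
        )
        assert coverage_correlation(a, b)["r"] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_rejected(self):
        a = [GeneBodyDensity(f"g{i}", 0, 100, 0.5) for i in range(5)]
        with pytest.raises(ValueError):
            coverage_correlation(a, a)


class TestPositivity:
    def test_boundary_window(self):
        g = GeneModel("g", "chr1", 50_000, 60_000, "+", ((50_000, 60_000),))
        covering = [Peak("chr1", 49_950, 50_050, 50_000, 1, 0.5, 0.5)]
        assert mark_positivity([g], covering, 2_500)["g"] is True
        just_out = [Peak("chr1", 52_501, 52_600, 52_550, 1, 0.5, 0.5)]
        assert mark_positivity([g], just_out, 2_500)["g"] is False
        at_edge = [Peak("chr1", 52_499, 52_600, 52_500, 1, 0.5, 0.5)]
        assert mark_positivity([g], at_edge, 2_500)["g"] is True

    def test_gene_overlap_mode(self):
        g = GeneModel("g", "chr1", 50_000, 60_000, "+", ((50_000, 60_000),))
        mid = [Peak("chr1", 55_000, 55_200, 55_100, 1, 0.5, 0.5)]
        assert mark_positivity([g], mid, mode="gene_overlap")["g"] is True
        assert mark_positivity([g], mid, mode="tss_window")["g"] is False

    def test_recovers_planted_rate(self, rng):
        genes = _uniform_genes(n=200, length=4_000, gap=3_000)
        p = 0.4
        peaks = []
        truth = 0
        for g in genes:
            if rng.random() < p:
                truth += 1
                t = g.start if g.strand == "+" else g.end - 1
                peaks.append(Peak("chr1", t - 100, t + 100, t, 1, 0.5, 0.5))
        pos = mark_positivity(genes, peaks, 2_500)
        assert sum(pos.values()) == truth


class TestPermutation:
    def test_degenerate_target_equals_universe(self):
        genes = [f"g{i}" for i in range(10)]
        pos = {g: i % 2 == 0 for i, g in enumerate(genes)}
        res = permutation_enrichment(genes, genes, pos, n_iter=50, seed=1)
        assert res.null_sd == 0.0
        assert math.isnan(res.z)
        assert res.empirical_p >= 1 / 51

    def test_sampled_null_matches_exhaustive_enumeration(self):
        """Universe of 6, targets of 2: compare against the C(6,2)=15 null."""
        from itertools import combinations

        universe = [f"g{i}" for i in range(6)]
        pos = {g: g in {"g0", "g1", "g2"} for g in universe}
        exact = {}
        for pair in combinations(universe, 2):
            pct = 100.0 * sum(pos[g] for g in pair) / 2
            exact[pct] = exact.get(pct, 0) + 1 / 15
        res = permutation_enrichment(["g0", "g1"], universe, pos,
                                     n_iter=10_000, seed=7)
        sampled = {}
        for v in res.null_percents:
            sampled[v] = sampled.get(v, 0) + 1 / 10_000
        for pct, mass in exact.items():
            assert abs(sampled.get(pct, 0.0) - mass) <= 0.02

    def test_reproducible_given_seed(self):
        universe = [f"g{i}" for i in range(100)]
        pos = {g: i % 3 == 0 for i, g in enumerate(universe)}
        a = permutation_enrichment(universe[:20], universe, pos, 100, seed=42)
        b = permutation_enrichment(universe[:20], universe, pos, 100, seed=42)
        assert a.null_percents == b.null_percents

    def test_target_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            permutation_enrichment(["x"], ["a", "b"], {}, 10, 0)


class TestQPCR:
    def test_percent_input_closed_forms(self):
        # IP Ct equal to the dilution-adjusted input Ct -> 100%
        rec = QPCRRecord("r", ct_ip=20.0, ct_input=20.0 + math.log2(100), input_fraction=0.01)
        assert percent_input(rec) == pytest.approx(100.0)
        # one log2(10) cycle later -> 10%
        rec10 = QPCRRecord("r", ct_ip=20.0 + math.log2(10),
                           ct_input=20.0 + math.log2(100), input_fraction=0.01)
        assert percent_input(rec10) == pytest.approx(10.0)
        # undiluted input
        assert percent_input(
            QPCRRecord("r", 20.0, 20.0, input_fraction=1.0)
        ) == pytest.approx(100.0)

    def test_noise_threshold_is_max_and_boundary_strict(self):
        def neg(rid, pct):
            ct_in = 25.0 + math.log2(100)
            return QPCRRecord(rid, ct_ip=ct_in - math.log2(100) - math.log2(pct / 100),
                              ct_input=ct_in, input_fraction=0.01,
                              is_negative_control=True)

        records = [neg("n1", 0.01), neg("n2", 0.03), neg("n3", 0.02)]
        thr = qpcr_noise_threshold(records)
        assert thr == pytest.approx(0.03)
        assert not is_enriched(thr, thr)  # exactly at threshold: not enriched
        assert is_enriched(thr * 1.001, thr)
        assert qpcr_noise_threshold([records[0]]) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            qpcr_noise_threshold([QPCRRecord("p", 20, 25)])

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            QPCRRecord("r", float("nan"), 20.0)


class TestProfileComparison:
    def test_identical_replicates_show_no_difference(self):
        prof = {0: [1.0, 1.1, 0.9], 6_200: [0.5, 0.6, 0.4]}
        for off, diff, p in compare_profiles(prof, prof):
            assert diff == 0.0
            assert p == pytest.approx(1.0)

    def test_matches_hand_student_t(self):
        a = {0: [2.0, 2.5, 2.2]}
        b = {0: [1.0, 1.3, 1.1]}
        (off, diff, p) = compare_profiles(a, b)[0]
        xa, xb = np.array(a[0]), np.array(b[0])
        na, nb = 3, 3
        sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
        t = (xa.mean() - xb.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy import stats

        want_p = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert diff == pytest.approx(xa.mean() - xb.mean())
        assert p == pytest.approx(want_p, abs=1e-10)

    def test_unmatched_offsets_rejected(self):
        with pytest.raises(ValueError):
            compare_profiles({0: [1, 2]}, {100: [1, 2]})

    def test_detects_planted_downstream_drop(self, rng):
        """A 50% drop beyond +6 kb is flagged at p < 0.05 in >= 90% of sims."""
        offsets = [0, 2_000, 6_200, 10_000, 15_000]
        drop_offsets = {6_200, 10_000, 15_000}
        flagged = 0
        n_sim = 100
        for _ in range(n_sim):
            wt = {o: list(1.0 + 0.10 * rng.standard_normal(4)) for o in offsets}
            mut = {
                o: list((0.5 if o in drop_offsets else 1.0)
                        + 0.10 * rng.standard_normal(4) * (0.5 if o in drop_offsets else 1.0))
                for o in offsets
            }
            res = dict((o, p) for o, _, p in compare_profiles(wt, mut))
            if all(res[o] < 0.05 for o in drop_offsets):
                flagged += 1
        assert flagged >= 90


class TestEnhancerSignature:
    @pytest.mark.parametrize(
        "folds,label,active",
        [
            ((8.0, 6.0, 1.0), "enhancer_like", True),
            ((1.0, 1.0, 10.0), "promoter_like", False),
            ((1.0, 1.0, 1.0), "none", False),
        ],
    )
    def test_examples(self, folds, label, active):
        call = classify_enhancer_signature("r", *folds)
        assert (call.label, call.active) == (label, active)

    def test_zero_k4me1_falls_back_to_k4me3(self):
        assert classify_enhancer_signature("r", 0.0, 0.0, 8.0).label == "promoter_like"
        assert classify_enhancer_signature("r", 0.0, 0.0, 1.0).label == "none"

    def test_negative_fold_rejected(self):
        with pytest.raises(ValueError):
            classify_enhancer_signature("r", -1.0, 1.0, 1.0)
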