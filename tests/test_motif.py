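"""PWM p-score scanning and k-mer enrichment."""

import numpy as np
import pytest

from occupancy_scan.motif import (
    PWM,
    ZeroInformationError,
    kmer_enrichment,
    pwm_from_occurrences,
    pwm_pscore,
    reverse_complement,
    scan_sequences,
)
from occupancy_scan.synthetic_data import default_pwm, plant_motifs

TOY_FREQS = np.array([
    [0.70, 0.10, 0.10, 0.10],
    [0.10, 0.60, 0.20, 0.10],
    [0.05, 0.05, 0.85, 0.05],
    [0.25, 0.25, 0.25, 0.25],
])


def brute_pscore(freqs, window):
    """Independent re-derivation: IC-weighted similarity, normalized."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    ic = [2 + sum(p * np.log2(p) for p in row if p > 0) for row in freqs]
    num = sum(ic[i] * freqs[i][idx[b]] for i, b in enumerate(window))
    den = sum(ic[i] * max(freqs[i]) for i in range(len(freqs)))
    return num / den


class TestPscore:
    def test_consensus_scores_exactly_one(self):
        pwm = default_pwm("GGTACTCAGG")
        assert pwm_pscore(pwm, "GGTACTCAGG") == pytest.approx(1.0)
        assert pwm.consensus == "GGTACTCAGG"

    def test_uniform_pwm_raises_zero_information(self):
        uniform = PWM(np.full((4, 4), 0.25))
        with pytest.raises(ZeroInformationError):
            pwm_pscore(uniform, "ACGT")
        with pytest.raises(ZeroInformationError):
            scan_sequences(uniform, [("s", "ACGTACGT")], 0.5)

    def test_all_256_windows_match_brute_force(self):
        pwm = PWM(TOY_FREQS)
        for i in range(256):
            window = "".join("ACGT"[(i >> (2 * j)) & 3] for j in range(4))
            assert pwm_pscore(pwm, window) == pytest.approx(
                brute_pscore(TOY_FREQS, window), abs=1e-12
            )

    def test_ambiguous_base_skipped_not_error(self):
        pwm = PWM(TOY_FREQS)
        assert pwm_pscore(pwm, "ACNG") is None

    def test_invariant_under_joint_reverse_complement(self, rng):
        pwm = PWM(TOY_FREQS)
        rc = pwm.reverse_complement()
        for _ in range(50):
            window = "".join(rng.choice(list("ACGT"), 4))
            assert pwm_pscore(pwm, window) == pytest.approx(
                pwm_pscore(rc, reverse_complement(window)), abs=1e-12
            )

    def test_mutating_high_ic_position_never_raises_score(self):
        pwm = default_pwm("GGTACTCAGG")
        consensus = pwm.consensus
        top = int(np.argmax(pwm.information_content))
        base_score = pwm_pscore(pwm, consensus)
        for b in "ACGT":
            if b == consensus[top]:
                continue
            mutated = consensus[:top] + b + consensus[top + 1:]
            assert pwm_pscore(pwm, mutated) < base_score


class TestPscoreProperties:
    from hypothesis import given, settings, strategies as st

    @staticmethod
    def _pwm_from_seed(seed):
        r = np.random.default_rng(seed)
        counts = r.integers(1, 50, size=(6, 4))
        return PWM.from_counts(counts, pseudocount=0.5)

    @given(seed=st.integers(0, 10_000), window=st.text("ACGT", min_size=6, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_reverse_complement_invariance(self, seed, window):
        pwm = self._pwm_from_seed(seed)
        assert pwm_pscore(pwm, window) == pytest.approx(
            pwm_pscore(pwm.reverse_complement(), reverse_complement(window)),
            abs=1e-12,
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scores_bounded_with_consensus_maximal(self, seed):
        pwm = self._pwm_from_seed(seed)
        r = np.random.default_rng(seed + 1)
        window = "".join(r.choice(list("ACGT"), 6))
        score = pwm_pscore(pwm, window)
        assert score <= 1.0 + 1e-12
        assert score <= pwm_pscore(pwm, pwm.consensus) + 1e-12


class TestScan:
    def test_embedded_consensus_found_once(self, rng):
        pwm = default_pwm("GGTACTCAGG")
        flank = "".join(rng.choice(list("ACGT"), 80))
        seq = flank + "GGTACTCAGG" + flank
        hits = scan_sequences(pwm, [("s", seq)], threshold=0.95)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1 and fwd[0].offset == 80
        # non-palindromic motif: no reverse-strand hit at the embedding
        assert not any(h.strand == "-" and h.offset == 80 for h in hits)

    def test_threshold_zero_counts_all_windows(self):
        pwm = PWM(TOY_FREQS)
        seq = "ACGTACGTAC"
        hits = scan_sequences(pwm, [("s", seq)], threshold=0.0)
        assert len(hits) == 2 * (len(seq) - 4 + 1)

    def test_hits_equal_brute_force_on_short_sequences(self, rng):
        pwm = PWM(TOY_FREQS)
        seq = "".join(rng.choice(list("ACGT"), 300))
        threshold = 0.9
        hits = scan_sequences(pwm, [("s", seq)], threshold)
        brute = []
        for off in range(len(seq) - 3):
            window = seq[off: off + 4]
            if brute_pscore(TOY_FREQS, window) >= threshold - 1e-12:
                brute.append((off, "+"))
            if brute_pscore(TOY_FREQS, reverse_complement(window)) >= threshold - 1e-12:
                brute.append((off, "-"))
        assert sorted((h.offset, h.strand) for h in hits) == sorted(brute)

    def test_three_planted_copies_all_detected(self, rng):
        """Three consensus copies inside one synthetic exon sequence."""
        consensus = "GGTACTCAGG"
        background = "".join(rng.choice(list("ACGT"), 600))
        seqs, truth = plant_motifs(
            {"exon": background},
            consensus,
            [("exon", 100, "+"), ("exon", 300, "+"), ("exon", 500, "+")],
        )
        hits = scan_sequences(default_pwm(consensus), [("exon", seqs["exon"])], 0.95)
        fwd_offsets = {h.offset for h in hits if h.strand == "+"}
        assert {100, 300, 500} <= fwd_offsets


class TestKmerEnrichment:
    def test_null_foreground_has_small_odds(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 200)) for _ in range(30)]
        ranked = kmer_enrichment(seqs, seqs, k=5)
        assert all(abs(r["log2_odds"]) < 0.01 for r in ranked)

    def test_planted_kmer_ranks_first(self, rng):
        planted = "GGTACTCA"
        fg = []
        for i in range(60):
            s = "".join(rng.choice(list("ACGT"), 150))
            if i % 2 == 0:
                s = s[:70] + planted + s[78:]
            fg.append(s)
        bg = ["".join(rng.choice(list("ACGT"), 150)) for _ in range(120)]
        ranked = kmer_enrichment(fg, bg, k=8)
        canonical = min(planted, reverse_complement(planted))
        assert ranked[0]["kmer"] == canonical

    def test_counts_match_hand_enumeration(self):
        fg = ["ACGTACG", "TTTT", "ACG"]
        bg = ["ACGTACGT"]
        ranked = kmer_enrichment(fg, bg, k=4, top_m=100)
        by_kmer = {r["kmer"]: r for r in ranked}
        # ACGT occurs at offsets 0 and (as CGTA->revcomp TACG) etc. enumerate:
        def hand_counts(seqs):
            counts = {}
            for s in seqs:
                for i in range(len(s) - 3):
                    w = s[i: i + 4]
                    key = min(w, reverse_complement(w))
                    counts[key] = counts.get(key, 0) + 1
            return counts

        want_fg = hand_counts(fg)
        want_bg = hand_counts(bg)
        for kmer, rec in by_kmer.items():
            assert rec["fg_count"] == want_fg[kmer]
            assert rec["bg_count"] == want_bg.get(kmer, 0)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGT"], ["ACGT"], k=3)


class TestPwmFromOccurrences:
    def test_identical_occurrences_give_consensus(self):
        pwm = pwm_from_occurrences(["GGTACT"] * 10)
        assert pwm.consensus == "GGTACT"
        assert pwm.information_content.min() > 1.9

    def test_uniform_position_near_quarter(self):
        occs = ["GATA", "GCTA", "GGTA", "GTTA"] * 3
        pwm = pwm_from_occurrences(occs)
        assert pwm.freqs[1] == pytest.approx([0.25, 0.25, 0.25, 0.25], abs=0.01)

    def test_roundtrip_scan_finds_source_occurrences(self, rng):
        occ = "GGTACTCA"
        flanks = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(8)]
        seqs = [(f"s{i}", f[:20] + occ + f[20:]) for i, f in enumerate(flanks)]
        pwm = pwm_from_occurrences([occ] * 8)
        hits = scan_sequences(pwm, seqs, threshold=1.0)
        assert {(h.sequence_id, h.offset) for h in hits if h.strand == "+"} == {
            (f"s{i}", 20) for i in range(8)
        }

    def test_validation(self):
        with pytest.raises(ValueError):
            pwm_from_occurrences(["ACGT"] * 4)  # too few
        with pytest.raises(ValueError):
            pwm_from_occurrences(["ACGT", "ACG", "ACGT", "ACGT", "ACGT"])
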