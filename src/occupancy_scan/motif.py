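"""PWM match scoring ("p-score"), strand-aware scanning, and k-mer
enrichment as a light-weight discovery stage.

The p-score of a window against a position weight matrix is the
information-content-weighted matrix similarity

    pscore = sum_i IC_i * f_i(w_i) / sum_i IC_i * max_b f_i(b),
    IC_i = 2 + sum_b f_i(b) log2 f_i(b),

normalized so the consensus sequence scores exactly 1.  High-information
positions dominate; a PWM with zero total information cannot be scanned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class ZeroInformationError(ValueError):
    """The PWM is uniform at every position; match scores are undefined."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else -> 4 (ambiguous)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


@dataclass
class PWM:
    """Per-position base probabilities over A, C, G, T."""

    freqs: np.ndarray  # (width, 4)
    name: str = "pwm"
    pseudocount: float = 0.0

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 4:
            raise ValueError("PWM needs shape (width >= 4, 4)")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        self.freqs = f

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    @property
    def information_content(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.freqs > 0, self.freqs * np.log2(self.freqs), 0.0)
        return 2.0 + terms.sum(axis=1)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.freqs[::-1, ::-1].copy(), name=f"{self.name}_rc",
                   pseudocount=self.pseudocount)

    @classmethod
    def from_counts(cls, counts, name: str = "pwm", pseudocount: float = 0.01) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(c / c.sum(axis=1, keepdims=True), name=name, pseudocount=pseudocount)

    # -- TSV / MEME interchange -------------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# PWM {self.name}; columns: A C G T (probabilities)\n")
            fh.write("A\tC\tG\tT\n")
            for row in self.freqs:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "PWM":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line[0].isalpha():
                    continue
                rows.append([float(x) for x in line.split()])
        return cls(np.asarray(rows), name=name or str(path))

    def to_meme(self, path) -> None:
        """Minimal MEME motif format for interoperability."""
        with open(path, "w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
            fh.write("strands: + -\n\n")
            fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
            fh.write(f"MOTIF {self.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {self.width}\n")
            for row in self.freqs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def pwm_pscore(pwm: PWM, window: str) -> float | None:
    """Normalized [., 1] match score; None for windows with ambiguous bases."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != PWM width {pwm.width}")
    ic = pwm.information_content
    denom = float((ic * pwm.freqs.max(axis=1)).sum())
    if denom <= 0:
        raise ZeroInformationError(
            f"PWM {pwm.name} carries no information; scanning is disabled"
        )
    enc = _encode(window)
    if (enc == 4).any():
        return None  # ambiguous base: skipped, not an error
    num = float((ic * pwm.freqs[np.arange(pwm.width), enc]).sum())
    return num / denom


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    pscore: float
    matched_subsequence: str

    def __post_init__(self):
        if not (0.0 <= self.pscore <= 1.0 + 1e-12):
            raise ValueError("pscore out of [0, 1]")


def _scan_one_strand(weights: np.ndarray, enc: np.ndarray, denom: float) -> np.ndarray:
    """Scores for every window on an encoded sequence; NaN where ambiguous."""
    w = weights.shape[0]
    n = enc.size - w + 1
    if n <= 0:
        return np.empty(0)
    padded = np.concatenate([weights, np.full((w, 1), np.nan)], axis=1)  # col 4 = N
    scores = np.zeros(n)
    for i in range(w):
        scores += padded[i, enc[i: i + n]]
    return scores / denom


def scan_sequences(
    pwm: PWM,
    sequences: Iterable[tuple[str, str]],
    threshold: float = 0.8,
) -> list[MotifHit]:
    """All windows on both strands with pscore >= threshold.

    ``sequences`` yields (sequence_id, sequence) pairs (use
    :func:`read_fasta` for files).  Reverse-strand windows are scored on
    the reverse complement and reported at their forward-strand offset.
    Hits are sorted by (sequence_id, offset, strand).
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    ic = pwm.information_content
    denom = float((ic * pwm.freqs.max(axis=1)).sum())
    if denom <= 0:
        raise ZeroInformationError(
            f"PWM {pwm.name} carries no information; scanning is disabled"
        )
    weights = ic[:, None] * pwm.freqs
    rc_weights = weights[::-1, ::-1]
    hits: list[MotifHit] = []
    for seq_id, seq in sequences:
        enc = _encode(seq)
        for strand, wts in (("+", weights), ("-", rc_weights)):
            scores = _scan_one_strand(wts, enc, denom)
            ok = np.flatnonzero(~np.isnan(scores) & (scores >= threshold - 1e-12))
            for off in ok:
                sub = seq[off: off + pwm.width].upper()
                hits.append(
                    MotifHit(seq_id, int(off), strand,
                             float(min(scores[off], 1.0)), sub)
                )
    hits.sort(key=lambda h: (h.sequence_id, h.offset, h.strand))
    return hits


def hits_to_bed6(hits: Sequence[MotifHit], path, width: int) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.offset}\t{h.offset + width}\t"
                f"{h.matched_subsequence}\t{int(round(1000 * h.pscore))}\t{h.strand}\n"
            )


# ---------------------------------------------------------------------------
# k-mer enrichment (discovery stage)
# ---------------------------------------------------------------------------


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return min(kmer, rc)


def _count_kmers(seqs: Sequence[str], k: int) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        s = seq.upper()
        if len(s) < k:
            logger.warning("sequence shorter than k=%d skipped", k)
            continue
        for i in range(len(s) - k + 1):
            kmer = s[i: i + k]
            if any(c not in _BASE_INDEX for c in kmer):
                continue
            counts[_canonical(kmer)] = counts.get(_canonical(kmer), 0) + 1
            total += 1
    return counts, total


def kmer_enrichment(
    fg: Sequence[str], bg: Sequence[str], k: int = 6, top_m: int = 20
) -> list[dict]:
    """Reverse-complement-collapsed k-mer over-representation fg vs bg.

    log2 odds uses +0.5 pseudocounts on the rates; p is a one-sided
    binomial test of the foreground count given the background rate.
    Ranked by p, then log2_odds: significance-first ranking is robust
    to the inflated odds of k-mers that are absent from a finite
    background sample by chance.
    """
    if not (4 <= k <= 12):
        raise ValueError("k must be between 4 and 12")
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    fg_counts, fg_total = _count_kmers(fg, k)
    bg_counts, bg_total = _count_kmers(bg, k)
    if fg_total == 0 or bg_total == 0:
        raise ValueError("no scorable windows in foreground or background")
    rows = []
    for kmer, fc in fg_counts.items():
        bc = bg_counts.get(kmer, 0)
        fr = (fc + 0.5) / (fg_total + 0.5)
        br = (bc + 0.5) / (bg_total + 0.5)
        lo = float(np.log2(fr / br))
        p = float(
            stats.binomtest(fc, fg_total, min(bc / bg_total, 1.0) or 0.5 / bg_total,
                            alternative="greater").pvalue
        )
        rows.append(
            {"kmer": kmer, "fg_count": fc, "bg_count": bc, "log2_odds": lo, "p": p}
        )
    rows.sort(key=lambda r: (r["p"], -r["log2_odds"], r["kmer"]))
    return rows[:top_m]


def pwm_from_occurrences(
    occurrences: Sequence[str], name: str = "derived", pseudocount: float = 0.01
) -> PWM:
    """Build a PWM from aligned equal-length occurrences (>= 5 required)."""
    if len(occurrences) < 5:
        raise ValueError("need >= 5 occurrences")
    lengths = {len(o) for o in occurrences}
    if len(lengths) != 1:
        raise ValueError("occurrences must have equal length")
    width = lengths.pop()
    counts = np.zeros((width, 4))
    for occ in occurrences:
        enc = _encode(occ)
        if (enc == 4).any():
            raise ValueError(f"ambiguous base in occurrence {occ!r}")
        counts[np.arange(width), enc] += 1
    return PWM.from_counts(counts, name=name, pseudocount=pseudocount)


# ---------------------------------------------------------------------------
# FASTA plumbing (Biopython-backed)
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i: i + line_width] + "\n")
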