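"""Tag sets, coverage tracks, and a local-lambda Poisson peak caller.

Aligned sequencing reads enter as 5'-end "tags" (BED6).  Windows along
each chromosome are scored against a control-derived Poisson expectation
lambda = max(global control rate, local control rate), with control
counts scaled to the IP sequencing depth — the standard local-background
model for ChIP-seq enrichment.  Significant windows (Benjamini–Hochberg
FDR plus a fold floor) are merged into peaks; the summit is the IP
coverage maximum inside the peak, leftmost on ties.

Consensus (high-confidence) targets come from intersecting the peak
sets of two independent antibodies; "shrunk" peaks are fixed windows
around summits used as motif-discovery input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._intervals import intersect_merged, merge_intervals

logger = logging.getLogger(__name__)


@dataclass
class TagSet:
    """5'-end tag positions per chromosome, sorted, with aligned strands."""

    label: str
    positions: dict[str, np.ndarray] = field(default_factory=dict)  # int64, sorted
    strands: dict[str, np.ndarray] = field(default_factory=dict)  # int8: +1 / -1

    @property
    def total_count(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    @property
    def chroms(self) -> list[str]:
        return sorted(self.positions)

    def iter_tags(self):
        for chrom in self.chroms:
            for p, s in zip(self.positions[chrom], self.strands[chrom]):
                yield chrom, int(p), "+" if s > 0 else "-"

    @classmethod
    def from_tags(cls, label: str, tags: Iterable[tuple[str, int, str]]) -> "TagSet":
        acc: dict[str, list[tuple[int, int]]] = {}
        for chrom, pos, strand in tags:
            if pos < 0:
                raise ValueError(f"negative tag position {pos} on {chrom}")
            acc.setdefault(chrom, []).append((pos, 1 if strand == "+" else -1))
        positions, strands = {}, {}
        for chrom, items in acc.items():
            arr = np.asarray(items, dtype=np.int64)
            order = np.argsort(arr[:, 0], kind="stable")
            positions[chrom] = arr[order, 0]
            strands[chrom] = arr[order, 1].astype(np.int8)
        return cls(label, positions, strands)

    def shifted_positions(self, shift: int) -> dict[str, np.ndarray]:
        """Per-chromosome sorted positions after strand-aware shifting."""
        out = {}
        for chrom in self.positions:
            p = self.positions[chrom] + shift * self.strands[chrom].astype(np.int64)
            np.clip(p, 0, None, out=p)
            p.sort()
            out[chrom] = p
        return out


def read_tags(path, label: str | None = None) -> TagSet:
    """Read a 6-column BED tag file; 5' position = start (+) or end-1 (-)."""
    label = label or str(path)
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            usecols=[0, 1, 2, 5], names=["chrom", "start", "end", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty tag file %s", path)
        return TagSet(label)
    except ValueError as err:
        raise ValueError(f"{path}: BED6 with a strand column required ({err})") from None
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df["strand"].isin(["+", "-"]), "strand"].iloc[0]
        raise ValueError(f"{path}: invalid strand value {bad!r}")
    pos5 = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    strand_num = np.where(df["strand"] == "+", 1, -1).astype(np.int8)
    positions, strands = {}, {}
    for chrom, idx in df.groupby("chrom", sort=True).groups.items():
        p = pos5[idx.to_numpy()]
        s = strand_num[idx.to_numpy()]
        order = np.argsort(p, kind="stable")
        positions[str(chrom)] = p[order]
        strands[str(chrom)] = s[order]
    return TagSet(label, positions, strands)


def write_tags(tags: TagSet, path, read_length: int = 36) -> None:
    """Emit a TagSet as sorted BED6 (one fixed-length record per tag)."""
    with open(path, "w") as fh:
        i = 0
        for chrom in tags.chroms:
            for p, s in zip(tags.positions[chrom], tags.strands[chrom]):
                if s > 0:
                    start, end, strand = p, p + read_length, "+"
                else:
                    start, end, strand = max(0, p - read_length + 1), p + 1, "-"
                fh.write(f"{chrom}\t{start}\t{end}\tt{i}\t0\t{strand}\n")
                i += 1


@dataclass
class CoverageTrack:
    """Dense 1-bp depth per chromosome after strand-aware tag shifting."""

    depth: dict[str, np.ndarray]
    shift: int
    _cums: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def total(self) -> int:
        return int(sum(int(d.sum()) for d in self.depth.values()))

    def _cum(self, chrom: str) -> np.ndarray:
        if chrom not in self._cums:
            d = self.depth.get(chrom)
            if d is None:
                return np.zeros(1, dtype=np.int64)
            self._cums[chrom] = np.concatenate([[0], np.cumsum(d, dtype=np.int64)])
        return self._cums[chrom]

    def range_sum(self, chrom: str, start: int, end: int) -> int:
        """Total depth over [start, end)."""
        cum = self._cum(chrom)
        n = cum.size - 1
        lo, hi = max(0, min(start, n)), max(0, min(end, n))
        return int(cum[hi] - cum[lo])

    def range_sums(self, chrom: str, starts, ends) -> np.ndarray:
        cum = self._cum(chrom)
        n = cum.size - 1
        lo = np.clip(np.asarray(starts, dtype=np.int64), 0, n)
        hi = np.clip(np.asarray(ends, dtype=np.int64), 0, n)
        return cum[hi] - cum[lo]


def coverage_track(
    tags: TagSet, shift: int, chrom_sizes: dict[str, int] | None = None
) -> CoverageTrack:
    """Depth track: each tag contributes +1 at its shifted 5' position.

    With shift = fragment/2, tags from both strands pile up at the
    fragment midpoint.  Positions shifted below 0 clip to 0.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    depth = {}
    shifted = tags.shifted_positions(shift)
    for chrom, pos in shifted.items():
        size = (chrom_sizes or {}).get(chrom, int(pos[-1]) + 1 if pos.size else 1)
        size = max(size, int(pos[-1]) + 1 if pos.size else 1)
        depth[chrom] = np.bincount(pos, minlength=size).astype(np.int32)
    if chrom_sizes:
        for chrom, size in chrom_sizes.items():
            depth.setdefault(chrom, np.zeros(size, dtype=np.int32))
    return CoverageTrack(depth=depth, shift=shift)


def poisson_tail_p(k, lam):
    """Upper-tail probability P(X >= k) for X ~ Poisson(lam), stable."""
    k_arr = np.asarray(k)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(k_arr < 0) or np.any(lam_arr < 0):
        raise ValueError("k and lam must be non-negative")
    out = stats.poisson.sf(k_arr - 1, lam_arr)
    if np.isscalar(k) and np.isscalar(lam):
        return float(out)
    return out


@dataclass(frozen=True)
class Peak:
    """An enriched interval with summit, fold enrichment and significance."""

    chrom: str
    start: int
    end: int
    summit: int
    score: float  # fold enrichment: IP rate / lambda
    pvalue: float
    qvalue: float
    name: str = ""

    def __post_init__(self):
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak [{self.start}, {self.end})"
            )
        if self.score < 0 or not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("invalid peak score or p-value")

    @property
    def center(self) -> int:
        return self.summit

    @property
    def width(self) -> int:
        return self.end - self.start


DEFAULT_CALL_PARAMS = dict(
    window=200, step=50, shift=100, local_lambda_span=10_000,
    fdr=0.05, merge_gap=100, min_fold=4.0,
)


def call_peaks(
    ip: TagSet,
    control: TagSet | None,
    *,
    window: int = 200,
    step: int = 50,
    shift: int = 100,
    local_lambda_span: int = 10_000,
    fdr: float = 0.05,
    merge_gap: int = 100,
    min_fold: float = 4.0,
    global_background_only: bool = False,
    chrom_sizes: dict[str, int] | None = None,
) -> list[Peak]:
    """Call enriched peaks in IP tags against a control.

    Sliding windows (``window`` bp every ``step`` bp) are scored with a
    Poisson upper tail against lambda = max(global rate x window, local
    control count in ``local_lambda_span`` rescaled to the window),
    control counts linearly scaled by total-depth ratio.  Windows that
    pass BH FDR <= ``fdr`` and fold >= ``min_fold`` are merged across
    gaps <= ``merge_gap``; the summit is the shifted-IP coverage argmax.
    """
    if ip.total_count == 0:
        raise ValueError("IP tag set is empty")
    use_control = not global_background_only
    if use_control:
        if control is None or control.total_count == 0:
            raise ValueError(
                "control has no tags; pass global_background_only=True to score "
                "against the IP-derived uniform background instead"
            )
        ctrl_shifted = control.shifted_positions(shift)
        scale = ip.total_count / control.total_count
    ip_shifted = ip.shifted_positions(shift)
    sizes = dict(chrom_sizes or {})
    for chrom, pos in ip_shifted.items():
        sizes.setdefault(chrom, int(pos[-1]) + window if pos.size else window)
    genome_len = float(sum(sizes.values()))
    lam_global = ip.total_count / genome_len * window  # control scaled == IP depth

    recs = []  # (chrom, start, k, lam, p)
    for chrom, size in sorted(sizes.items()):
        ipos = ip_shifted.get(chrom, np.empty(0, dtype=np.int64))
        starts = np.arange(0, max(size - window, 0) + 1, step, dtype=np.int64)
        k = np.searchsorted(ipos, starts + window) - np.searchsorted(ipos, starts)
        lam = np.full(starts.shape, lam_global)
        if use_control:
            cpos = ctrl_shifted.get(chrom, np.empty(0, dtype=np.int64))
            centers = starts + window // 2
            half = local_lambda_span // 2
            local = (
                np.searchsorted(cpos, centers + half)
                - np.searchsorted(cpos, np.maximum(centers - half, 0))
            ) * (window / local_lambda_span) * scale
            lam = np.maximum(lam, local)
        p = poisson_tail_p(k, lam)
        recs.append((chrom, starts, k, lam, p))

    all_p = np.concatenate([r[4] for r in recs])
    all_q = stats.false_discovery_control(all_p, method="bh")
    peaks: list[Peak] = []
    offset = 0
    for chrom, starts, k, lam, p in recs:
        q = all_q[offset: offset + starts.size]
        offset += starts.size
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.where(lam > 0, k / lam, 0.0)
        sig = (q <= fdr) & (fold >= min_fold) & (k > 0)
        if not sig.any():
            continue
        ipos = ip_shifted.get(chrom, np.empty(0, dtype=np.int64))
        idx = np.flatnonzero(sig)
        run_start = idx[0]
        prev = idx[0]
        runs = []
        for i in idx[1:]:
            gap = (starts[i]) - (starts[prev] + window)
            if gap > merge_gap:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        for a, b in runs:
            s, e = int(starts[a]), int(starts[b]) + window
            in_reg = ipos[(ipos >= s) & (ipos < e)]
            if in_reg.size:
                counts = np.bincount((in_reg - s).astype(np.int64), minlength=e - s)
                # boxcar of ~fragment width approximates fragment pileup,
                # giving a stable summit from shifted 5' point masses
                k = max(1, 2 * shift)
                smooth = np.convolve(counts, np.ones(k), mode="same")
                summit = s + int(np.argmax(smooth))  # leftmost tie wins
            else:
                summit = (s + e) // 2
            win_slice = slice(a, b + 1)
            best = int(np.argmin(p[win_slice])) + a
            peaks.append(
                Peak(
                    chrom=chrom, start=s, end=e, summit=summit,
                    score=float(fold[win_slice].max()),
                    pvalue=float(p[best]),
                    qvalue=float(q[best]),
                    name=f"{ip.label}_peak_{len(peaks) + 1}",
                )
            )
    return peaks


def intersect_peak_sets(
    a: Sequence[Peak], b: Sequence[Peak], min_overlap: int = 1
) -> list[Peak]:
    """High-confidence consensus: intersections of a-peaks with b-peaks.

    For every a-peak overlapping at least one b-peak by >= ``min_overlap``
    bases, the exact intersection segments are returned (adjacent
    segments coalesced per a-peak), so the covered base set equals the
    brute-force intersection of the two peak sets.  Summit and scores
    are inherited from the a-peak, the summit clamped into the segment.
    """
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for pk in b:
        by_chrom_b.setdefault(pk.chrom, []).append((pk.start, pk.end))
    merged_b = {c: merge_intervals(iv) for c, iv in by_chrom_b.items()}
    out: list[Peak] = []
    for pk in sorted(a, key=lambda p: (p.chrom, p.start, p.end)):
        bl = merged_b.get(pk.chrom)
        if not bl:
            continue
        segs = intersect_merged([(pk.start, pk.end)], bl)
        segs = [(s, e) for s, e in segs if e - s >= min_overlap]
        if not segs:
            continue
        segs = merge_intervals(segs)
        for s, e in segs:
            out.append(
                Peak(
                    chrom=pk.chrom, start=s, end=e,
                    summit=min(max(pk.summit, s), e - 1),
                    score=pk.score, pvalue=pk.pvalue, qvalue=pk.qvalue,
                    name=f"consensus_{len(out) + 1}",
                )
            )
    return out


def shrink_peaks(
    peaks: Sequence[Peak], halfwidth: int = 100, clip_to_peak: bool = False
) -> list[tuple[str, int, int]]:
    """Fixed windows [summit - hw, summit + hw) per peak, for motif input."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    out = []
    for pk in peaks:
        s, e = pk.summit - halfwidth, pk.summit + halfwidth
        if clip_to_peak:
            s, e = max(s, pk.start), min(e, pk.end)
        out.append((pk.chrom, max(0, s), e))
    return out


# ---------------------------------------------------------------------------
# narrowPeak-style I/O
# ---------------------------------------------------------------------------


def write_narrowpeak(peaks: Sequence[Peak], path) -> None:
    """BED6+4: fold, -log10 p, -log10 q, summit offset from start."""
    with open(path, "w") as fh:
        for pk in peaks:
            logp = -np.log10(max(pk.pvalue, 1e-300))
            logq = -np.log10(max(pk.qvalue, 1e-300))
            fh.write(
                f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.name or '.'}\t"
                f"{min(1000, int(round(pk.score * 10)))}\t.\t"
                f"{pk.score:.4f}\t{logp:.4f}\t{logq:.4f}\t{pk.summit - pk.start}\n"
            )


def read_narrowpeak(path) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if not f:
                continue
            start, end = int(f[1]), int(f[2])
            summit = start + int(f[9]) if len(f) > 9 else (start + end) // 2
            peaks.append(
                Peak(
                    chrom=f[0], start=start, end=end, summit=summit,
                    score=float(f[6]) if len(f) > 6 else 0.0,
                    pvalue=10 ** -float(f[7]) if len(f) > 7 else 1.0,
                    qvalue=10 ** -float(f[8]) if len(f) > 8 else 1.0,
                    name=f[3],
                )
            )
    return peaks
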