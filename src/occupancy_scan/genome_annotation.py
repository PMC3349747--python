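"""Gene annotation parsing and base-level genomic feature classification.

Gene models are held in 0-based half-open coordinates throughout the
package; GFF3 (1-based inclusive) is converted on read.  The
:class:`FeatureIndex` assigns every genomic base exactly one label among
``promoter``, ``exon``, ``intron`` and ``intergenic`` with the fixed
precedence promoter > exon > intron > intergenic, mirroring conventional
ChIP-seq peak annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._intervals import interval_arrays, merge_intervals, points_in_intervals

logger = logging.getLogger(__name__)

DEFAULT_PROMOTER_WINDOW = 2500

FEATURE_LABELS = ("promoter", "exon", "intron", "intergenic")


class AnnotationError(ValueError):
    """Raised for malformed annotation input; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with exon structure.

    Coordinates are 0-based half-open; ``exons`` are sorted,
    non-overlapping sub-intervals of ``[start, end)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: at least one exon required")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = self.start
        for s, e in exons:
            if s < self.start or e > self.end or s >= e:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon ({s}, {e}) outside gene span"
                )
            if s < prev_end and (s, e) != exons[0]:
                raise AnnotationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = max(prev_end, e)

    @property
    def tss(self) -> int:
        return tss_of(self)

    @property
    def body_length(self) -> int:
        return self.end - self.start


def tss_of(gene: GeneModel) -> int:
    """Transcription start site: 5'-most base in gene orientation."""
    return gene.start if gene.strand == "+" else gene.end - 1


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_gene_models(path, dialect: str = "gff3") -> list[GeneModel]:
    """Parse gene models from GFF3 or BED12.

    GFF3 handling is restricted to the gene/mRNA/exon dialect with
    ``ID``/``Parent`` attributes; one model per gene (the first listed
    transcript if several).  BED12 blocks become exons.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _gff3_attributes(text: str, line_no: int) -> dict[str, str]:
    out = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise AnnotationError(f"malformed GFF3 attribute {item!r}", line_no)
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _read_gff3(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_order: dict[str, list[str]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"expected 9 tab-separated fields, got {len(fields)}", line_no
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError("non-integer coordinates", line_no) from None
            start, end = start1 - 1, end1  # GFF3 1-based inclusive -> half-open
            if end <= start:
                raise AnnotationError(f"end ({end1}) <= start ({start1})", line_no)
            attrs = _gff3_attributes(attr_s, line_no)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise AnnotationError("gene record without ID attribute", line_no)
                genes[gid] = dict(chrom=chrom, start=start, end=end, strand=strand)
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise AnnotationError("transcript without ID/Parent", line_no)
                tx_parent[tid] = parent
                tx_order.setdefault(parent, []).append(tid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise AnnotationError("exon without Parent attribute", line_no)
                exons.setdefault(parent, []).append((start, end))
    models = []
    for gid, g in genes.items():
        ex: list[tuple[int, int]] = []
        if gid in exons:
            ex = exons[gid]
        elif gid in tx_order:
            ex = exons.get(tx_order[gid][0], [])  # first listed transcript
        if not ex:
            ex = [(g["start"], g["end"])]
        models.append(GeneModel(gid, g["chrom"], g["start"], g["end"], g["strand"], tuple(ex)))
    return models


def _read_bed12(path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 12:
                raise AnnotationError(f"expected 12 BED fields, got {len(f)}", line_no)
            try:
                start, end = int(f[1]), int(f[2])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError:
                raise AnnotationError("non-integer BED12 field", line_no) from None
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise AnnotationError(
                    f"blockCount {n_blocks} inconsistent with "
                    f"{len(sizes)} sizes / {len(offsets)} starts",
                    line_no,
                )
            if end <= start:
                raise AnnotationError(f"end ({end}) <= start ({start})", line_no)
            ex = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            try:
                models.append(GeneModel(f[3], f[0], start, end, f[5], ex))
            except AnnotationError as err:
                raise AnnotationError(str(err), line_no) from None
    return models


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.start) for s, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n"
            )


def write_tss_bed6(genes: Iterable[GeneModel], path, flank: int = 0) -> None:
    """Write TSS positions (optionally flanked both sides) as BED6."""
    with open(path, "w") as fh:
        for g in genes:
            t = tss_of(g)
            fh.write(
                f"{g.chrom}\t{max(0, t - flank)}\t{t + flank + 1}\t"
                f"{g.gene_id}\t0\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# feature index
# ---------------------------------------------------------------------------


@dataclass
class FeatureIndex:
    """Base position -> feature label, precedence promoter > exon > intron."""

    promoter_window: int
    _sets: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = field(repr=False, default_factory=dict)

    def classify(self, chrom: str, pos: int) -> str:
        return self.classify_many(chrom, [pos])[0]

    def classify_many(self, chrom: str, positions) -> list[str]:
        pos = np.asarray(positions, dtype=np.int64)
        labels = np.full(pos.shape, "intergenic", dtype=object)
        sets = self._sets.get(chrom)
        if sets is None:
            return list(labels)
        unset = np.ones(pos.shape, dtype=bool)
        for label in ("promoter", "exon", "intron"):
            starts, ends = sets[label]
            hit = points_in_intervals(starts, ends, pos) & unset
            labels[hit] = label
            unset &= ~hit
        return list(labels)


def build_feature_index(
    genes: Sequence[GeneModel], promoter_window: int = DEFAULT_PROMOTER_WINDOW
) -> FeatureIndex:
    """Build the per-base classifier from gene models.

    Promoters are ``[TSS - w, TSS + w)``; bases covered by several genes
    take the highest-precedence feature across all of them.
    """
    if promoter_window < 0:
        raise ValueError("promoter_window must be non-negative")
    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for g in genes:
        d = by_chrom.setdefault(g.chrom, {"promoter": [], "exon": [], "body": []})
        t = tss_of(g)
        lo, hi = max(0, t - promoter_window), t + promoter_window
        if hi > lo:
            d["promoter"].append((lo, hi))
        d["exon"].extend(g.exons)
        d["body"].append((g.start, g.end))
    sets: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for chrom, d in by_chrom.items():
        sets[chrom] = {
            "promoter": interval_arrays(merge_intervals(d["promoter"])) if d["promoter"] else interval_arrays([]),
            "exon": interval_arrays(merge_intervals(d["exon"])),
            "intron": interval_arrays(merge_intervals(d["body"])),
        }
    return FeatureIndex(promoter_window=promoter_window, _sets=sets)
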