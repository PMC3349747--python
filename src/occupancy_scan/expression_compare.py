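"""Quantile–quantile comparison of target-gene expression vs all genes.

Plots target-gene expression quantiles against the quantiles of the full
gene complement: points on the diagonal mean identical distributions; a
curve above the diagonal means the targets are shifted upward.  The
two-sample Kolmogorov–Smirnov statistic and the median shift are
reported as auxiliary summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_TARGETS = 20


def read_expression_table(path, log2: bool = False) -> dict[str, float]:
    """TSV with header ``gene_id<TAB>value``; optional log2 transform."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "value"} <= set(df.columns):
        raise ValueError("expression table needs columns gene_id and value")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in expression table")
    values = df["value"].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("non-finite expression values")
    if log2:
        if (values <= 0).any():
            raise ValueError("log2 transform requires positive values")
        values = np.log2(values)
    return dict(zip(df["gene_id"].astype(str), values))


@dataclass
class QQComparison:
    quantile_pairs: list[tuple[int, float, float]]  # (percentile, target, all)
    ks_statistic: float
    ks_p: float
    median_shift: float
    n_targets: int
    n_all: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.quantile_pairs, columns=["percentile", "value_target", "value_all"]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "ks_statistic": self.ks_statistic,
                "ks_p": self.ks_p,
                "median_shift": self.median_shift,
                "n_targets": self.n_targets,
                "n_all": self.n_all,
                "quantile_pairs": self.quantile_pairs,
            },
            indent=2,
        )


def qq_compare(targets: Sequence[str], table: Mapping[str, float]) -> QQComparison:
    """Percentile pairs (1..99), KS statistic and median shift.

    "All genes" means the full table including the targets.  Targets
    missing from the table are dropped with a logged count; fewer than
    20 usable targets is an error.
    """
    target_vals = np.array([table[g] for g in targets if g in table], dtype=float)
    missing = len(targets) - target_vals.size
    if missing:
        logger.info("qq_compare: %d target genes missing from table", missing)
    if target_vals.size < MIN_TARGETS:
        raise ValueError(
            f"need >= {MIN_TARGETS} target genes present in the table, "
            f"got {target_vals.size}"
        )
    all_vals = np.asarray(list(table.values()), dtype=float)
    qs = np.arange(1, 100)
    tq = np.percentile(target_vals, qs)  # linear interpolation quantiles
    aq = np.percentile(all_vals, qs)
    ks = stats.ks_2samp(target_vals, all_vals, method="asymp")
    return QQComparison(
        quantile_pairs=[(int(q), float(t), float(a)) for q, t, a in zip(qs, tq, aq)],
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        median_shift=float(np.median(target_vals) - np.median(all_vals)),
        n_targets=int(target_vals.size),
        n_all=int(all_vals.size),
    )
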