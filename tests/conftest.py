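import numpy as np
import pytest

from occupancy_scan.genome_annotation import GeneModel


@pytest.fixture
def toy_genes() -> list[GeneModel]:
    """Two genes on chr1 (one per strand) and one on chr2."""
    return [
        GeneModel("geneA", "chr1", 10_000, 30_000, "+",
                  ((10_000, 10_500), (15_000, 15_400), (29_000, 30_000))),
        GeneModel("geneB", "chr1", 60_000, 75_000, "-",
                  ((60_000, 61_000), (74_000, 75_000))),
        GeneModel("geneC", "chr2", 5_000, 9_000, "+", ((5_000, 9_000),)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_gene_set(rng, n_genes=30, chrom_len=200_000, chroms=("chr1", "chr2")):
    """Small random non-overlapping annotation for oracle comparisons."""
    genes = []
    gi = 0
    for chrom in chroms:
        cursor = int(rng.integers(500, 3_000))
        while gi < n_genes and cursor < chrom_len - 6_000:
            length = int(rng.integers(800, 5_000))
            n_ex = int(rng.integers(1, 4))
            edges = np.sort(rng.choice(np.arange(1, length), 2 * n_ex - 2, replace=False)) \
                if n_ex > 1 else np.array([], dtype=int)
            bounds = [0, *edges.tolist(), length]
            exons = tuple(
                (cursor + bounds[2 * k], cursor + bounds[2 * k + 1])
                for k in range(n_ex)
            )
            strand = "+" if rng.integers(0, 2) else "-"
            genes.append(GeneModel(f"g{gi:03d}", chrom, cursor, cursor + length,
                                   strand, exons))
            gi += 1
            cursor += length + int(rng.integers(500, 4_000))
    return genes
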