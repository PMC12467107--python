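"""Cluster-enrichment check on single-cell expression data.

Given a cells × genes count matrix and precomputed cluster labels, decide
for a gene whether its transcripts look like an evenly distributed
maternal reservoir (UNIFORM across clusters) or show lineage-specific
localization (ENRICHED in particular clusters), as a maternally loaded
transcript pool versus an early lineage-restricted one.

Enrichment is defined on *detection*: the fraction of cells in a cluster
with count > 0, compared against the fraction outside.  At the low
expression levels typical of early embryos, presence/absence is the robust
signal; mean counts are dominated by a handful of high cells.  The test is
one-vs-rest hypergeometric on the expressing-cell overlap with the
cluster, Benjamini–Hochberg-corrected across the clusters of the gene; a
cluster is called enriched when it passes both the fold and the q-value
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class CellExpressionMatrix:
    """Cells × genes non-negative count (or normalized) matrix."""

    cells: list[str]
    genes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if (self.counts < 0).any():
            raise ValueError("negative entries in count matrix")

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None


@dataclass
class ClusterAssignment:
    """Per-cell cluster ids in 0..K-1; every cell assigned exactly once."""

    labels: np.ndarray
    n_clusters: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-d array")
        k = int(self.labels.max()) + 1 if self.labels.size else 0
        self.n_clusters = self.n_clusters or k
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.labels.min() < 0 or k > self.n_clusters:
            raise ValueError("labels must lie in 0..K-1")


class Distribution(str, Enum):
    UNIFORM = "UNIFORM"
    ENRICHED = "ENRICHED"
    NO_CALL = "NO_CALL"


@dataclass(frozen=True)
class DistributionCall:
    kind: Distribution
    clusters: tuple[int, ...] = ()


@dataclass
class EnrichmentResult:
    """Per-cluster detection statistics for one gene.

    ``table`` columns: cluster, n_cells, n_expressing, expressing_fraction,
    fold_enrichment, p_value, q_value.
    """

    gene: str
    table: pd.DataFrame
    n_cells: int
    n_expressing: int
    min_cells: int

    @property
    def underpowered(self) -> bool:
        return self.n_expressing < self.min_cells


def score_cluster_enrichment(
    matrix: CellExpressionMatrix,
    clusters: ClusterAssignment,
    gene: str,
    min_cells: int = 20,
) -> EnrichmentResult:
    """Detection-based one-vs-rest enrichment statistics for one gene.

    For each cluster c: expressing fraction inside c; fold = (smoothed)
    inside fraction over outside fraction with add-one smoothing on
    expressing-cell counts; p = upper hypergeometric tail of the
    expressing-cell overlap with c; q = Benjamini–Hochberg across the
    clusters of this gene.  With fewer than ``min_cells`` expressing cells
    in total the gene is underpowered and downstream calls are NO_CALL.
    """
    if len(clusters.labels) != len(matrix.cells):
        raise ValueError("cluster assignment does not match cell count")
    x = matrix.counts[:, matrix.gene_index(gene)]
    expressing = x > 0
    n_total = len(matrix.cells)
    k_total = int(expressing.sum())

    rows = []
    for c in range(clusters.n_clusters):
        in_c = clusters.labels == c
        n_c = int(in_c.sum())
        if n_c == 0:
            raise ValueError(f"cluster {c} has no cells")
        k_c = int((expressing & in_c).sum())
        frac_in = k_c / n_c
        fold = ((k_c + 1) / (n_c + 1)) / (
            (k_total - k_c + 1) / (n_total - n_c + 1)
        )
        p = float(hypergeom.sf(k_c - 1, n_total, k_total, n_c))
        rows.append((c, n_c, k_c, frac_in, fold, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster", "n_cells", "n_expressing",
            "expressing_fraction", "fold_enrichment", "p_value",
        ],
    )
    table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return EnrichmentResult(
        gene=gene, table=table, n_cells=n_total,
        n_expressing=k_total, min_cells=min_cells,
    )


def classify_distribution(
    result: EnrichmentResult, fold_min: float = 2.0, q_max: float = 0.05
) -> DistributionCall:
    """ENRICHED with the sorted clusters meeting fold ≥ fold_min AND
    q ≤ q_max; UNIFORM if none; NO_CALL for underpowered genes."""
    if result.underpowered:
        return DistributionCall(Distribution.NO_CALL)
    t = result.table
    hits = t.loc[
        (t["fold_enrichment"] >= fold_min) & (t["q_value"] <= q_max), "cluster"
    ]
    if hits.empty:
        return DistributionCall(Distribution.UNIFORM)
    return DistributionCall(Distribution.ENRICHED, tuple(sorted(int(c) for c in hits)))


# ---------------------------------------------------------------------------
# Plain-text I/O (MatrixMarket + TSV sidecars)


def read_cell_matrix(
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> CellExpressionMatrix:
    """Read an MTX matrix with feature/barcode sidecars.

    Orientation is inferred from the sidecar lengths; genes × cells input
    (the common features × barcodes convention) is transposed to
    cells × genes.
    """
    m = mmread(str(mtx_path))
    if hasattr(m, "toarray"):
        m = m.toarray()
    m = np.asarray(m)
    genes = [ln.split("\t")[0].strip() for ln in Path(features_path).read_text().splitlines() if ln.strip()]
    cells = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
    if m.shape == (len(genes), len(cells)):
        m = m.T
    elif m.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {m.shape} matches neither cells x genes nor genes x cells"
        )
    return CellExpressionMatrix(cells=cells, genes=genes, counts=np.asarray(m))


def read_cluster_assignment(path: str | Path) -> ClusterAssignment:
    """TSV of cell-barcode <tab> cluster-id (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    col = df.iloc[:, -1]
    if not np.issubdtype(col.dtype, np.number):  # header row present
        df = pd.read_csv(path, sep="\t", comment="#")
        col = df.iloc[:, -1]
    return ClusterAssignment(labels=col.to_numpy(dtype=int))
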