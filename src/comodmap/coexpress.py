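"""Spearman co-expression, 1−r hierarchical clustering and module extraction.

The workflow mirrors the classic gene co-expression analysis: log2-transform
the count matrix (immaterial for a rank statistic, kept for fidelity to the
conventional preprocessing), compute the genes x genes matrix of Spearman
rank correlations r_s across cells, agglomerate genes on the distance
d = 1 − r_s (complete linkage by default), cut the dendrogram, and keep flat
clusters that are both large enough and internally correlated enough to call
modules.  Ties in expression values — ubiquitous in sparse single-cell
counts, where zeros dominate — receive average ranks, the standard Spearman
treatment.

A "visual inspection" step in an interactive heatmap is replaced here by two
explicit module criteria: minimum size and minimum mean intra-module r_s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .errors import DataError, ParameterError
from .expression import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "Dendrogram",
    "Module",
    "ModuleSet",
    "log2_transform",
    "spearman_matrix",
    "hierarchical_cluster",
    "extract_modules",
    "module_stats",
]


@dataclass
class CorrelationMatrix:
    """Symmetric genes x genes Spearman correlation matrix.

    Genes with constant expression have undefined correlations; their rows
    and columns hold NaN and their ids are listed in ``missing_genes``.
    """

    values: np.ndarray
    gene_ids: list[str]
    missing_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.gene_ids)
        if self.values.shape != (n, n):
            raise ParameterError("correlation matrix shape must match gene_ids")
        if len(set(self.gene_ids)) != n:
            raise ParameterError("duplicate gene ids")
        finite = np.isfinite(self.values)
        filled = np.where(finite, self.values, 0.0)
        if not (np.allclose(filled, filled.T, atol=1e-12) and (finite == finite.T).all()):
            raise ParameterError("correlation matrix must be symmetric")
        diag = np.diag(self.values)
        if not np.allclose(diag[np.isfinite(diag)], 1.0, atol=1e-12):
            raise ParameterError("correlation matrix diagonal must be 1")
        if np.any(np.abs(self.values[finite]) > 1 + 1e-12):
            raise ParameterError("|r| must be <= 1")

    @property
    def has_missing(self) -> bool:
        return len(self.missing_genes) > 0

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([pos[g] for g in genes], dtype=int)
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.gene_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CorrelationMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy()
        missing = [g for g, row in zip(frame.index, np.isnan(values)) if row.all()]
        return cls(values, [str(g) for g in frame.index], missing)


@dataclass
class Dendrogram:
    """Agglomeration of genes on 1−r distance (scipy linkage encoding)."""

    linkage_matrix: np.ndarray  # (n-1, 4) scipy format
    gene_ids: list[str]
    method: str = "complete"

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = sch.leaves_list(self.linkage_matrix)
        return [self.gene_ids[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with branch lengths equal to merge-height deltas."""
        tree = sch.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.gene_ids[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        root = tree
        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


@dataclass
class Module:
    module_id: str
    genes: list[str]
    mean_intra_r: float
    min_intra_r: float
    max_intra_r: float


@dataclass
class ModuleSet:
    modules: list[Module]
    parameters: dict

    def __len__(self) -> int:
        return len(self.modules)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m.module_id, gene, m.mean_intra_r, m.min_intra_r, m.max_intra_r)
            for m in self.modules
            for gene in m.genes
        ]
        return pd.DataFrame(
            rows,
            columns=["module_id", "gene", "mean_intra_r", "min_intra_r", "max_intra_r"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def log2_transform(mat: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return a matrix with every value x replaced by log2(x + pseudocount)."""
    if pseudocount <= 0 and np.any(mat.counts == 0):
        raise ParameterError("pseudocount must be > 0 when zeros are present")
    return ExpressionMatrix(
        np.log2(mat.counts + pseudocount),
        list(mat.gene_ids),
        list(mat.cell_ids),
        list(mat.cell_types),
    )


def spearman_matrix(mat: ExpressionMatrix) -> CorrelationMatrix:
    """Pairwise Spearman r_s between genes across all cells.

    Ranks are averaged over ties.  Genes with constant expression across all
    cells have no defined rank correlation: their entries are NaN and they
    are reported in ``missing_genes`` (diagonal stays 1).
    """
    if mat.n_cells < 3:
        raise DataError("need at least 3 cells for a rank correlation")
    if mat.n_genes < 2:
        raise DataError("need at least 2 genes")
    ranks = np.apply_along_axis(rankdata, 1, mat.counts)
    sd = ranks.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.corrcoef(ranks)
    values = np.asarray(values, dtype=float)
    values[constant, :] = np.nan
    values[:, constant] = np.nan
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    missing = [g for g, c in zip(mat.gene_ids, constant) if c]
    if missing:
        warnings.warn(
            f"{len(missing)} constant gene(s) have undefined correlations: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    return CorrelationMatrix(values, list(mat.gene_ids), missing)


def hierarchical_cluster(
    cor: CorrelationMatrix,
    linkage: Literal["complete", "average", "single"] = "complete",
) -> Dendrogram:
    """Agglomerative clustering of genes on d = 1 − r_s."""
    if linkage not in ("complete", "average", "single"):
        raise ParameterError(
            f"linkage must be one of complete/average/single, got {linkage!r}"
        )
    if cor.has_missing or not np.all(np.isfinite(cor.values)):
        raise DataError(
            "correlation matrix contains missing values; drop constant genes "
            "upstream before clustering"
        )
    dist = 1.0 - cor.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    linkage_matrix = sch.linkage(condensed, method=linkage)
    return Dendrogram(linkage_matrix, list(cor.gene_ids), linkage)


def _intra_stats(sub: np.ndarray) -> tuple[float, float, float]:
    iu = np.triu_indices(sub.shape[0], k=1)
    vals = sub[iu]
    return float(vals.min()), float(vals.mean()), float(vals.max())


def extract_modules(
    dendro: Dendrogram,
    cor: CorrelationMatrix,
    cut_height: float | None = None,
    n_clusters: int | None = None,
    min_size: int = 10,
    min_mean_intra_r: float = 0.3,
) -> ModuleSet:
    """Cut the dendrogram and keep clusters that qualify as co-expression modules.

    Exactly one of ``cut_height`` (distance threshold on 1−r) or
    ``n_clusters`` must be given.  Clusters with at least ``min_size`` genes
    and mean intra-cluster r_s >= ``min_mean_intra_r`` are returned sorted by
    mean intra-module correlation, highest first, relabelled M1, M2, ...
    An empty result is a warning, not an error.
    """
    if (cut_height is None) == (n_clusters is None):
        raise ParameterError("give exactly one of cut_height= or n_clusters=")
    if min_size < 2:
        raise ParameterError("min_size must be >= 2")
    if cut_height is not None:
        labels = sch.fcluster(dendro.linkage_matrix, t=cut_height, criterion="distance")
    else:
        labels = sch.fcluster(dendro.linkage_matrix, t=n_clusters, criterion="maxclust")

    candidates = []
    for lab in np.unique(labels):
        genes = [g for g, l in zip(dendro.gene_ids, labels) if l == lab]
        if len(genes) < min_size:
            continue
        lo, mean, hi = _intra_stats(cor.submatrix(genes))
        if mean >= min_mean_intra_r:
            candidates.append((genes, mean, lo, hi))
    candidates.sort(key=lambda c: -c[1])
    modules = [
        Module(f"M{i + 1}", genes, mean, lo, hi)
        for i, (genes, mean, lo, hi) in enumerate(candidates)
    ]
    params = {
        "cut_height": cut_height,
        "n_clusters": n_clusters,
        "min_size": min_size,
        "min_mean_intra_r": min_mean_intra_r,
        "linkage": dendro.method,
    }
    if not modules:
        warnings.warn("no cluster passed the module criteria", stacklevel=2)
    return ModuleSet(modules, params)


def module_stats(
    genes: Sequence[str],
    cor: CorrelationMatrix,
    other: Sequence[str] | None = None,
) -> dict:
    """Min/mean/max of intra-set off-diagonal r_s, and cross-set r_s if given.

    A singleton set has no intra pairs; its statistics are reported as NaN.
    ``other`` must be disjoint from ``genes``.
    """
    known = set(cor.gene_ids)
    if not set(genes).issubset(known):
        raise ParameterError("genes not present in correlation matrix")
    genes = list(genes)
    out: dict = {"n_genes": len(genes)}
    if len(genes) < 2:
        out.update(intra_min=float("nan"), intra_mean=float("nan"), intra_max=float("nan"))
    else:
        lo, mean, hi = _intra_stats(cor.submatrix(genes))
        out.update(intra_min=lo, intra_mean=mean, intra_max=hi)
    if other is not None:
        other = list(other)
        if set(genes) & set(other):
            raise ParameterError("gene sets must be disjoint for cross statistics")
        if not set(other).issubset(known):
            raise ParameterError("other genes not present in correlation matrix")
        pos = {g: i for i, g in enumerate(cor.gene_ids)}
        block = cor.values[
            np.ix_([pos[g] for g in genes], [pos[g] for g in other])
        ]
        out.update(
            cross_min=float(block.min()),
            cross_mean=float(block.mean()),
            cross_max=float(block.max()),
            n_other=len(other),
        )
    return out
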