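"""Hypergeometric enrichment statistics.

Three flavours of the same test:

* :func:`category_enrichment` — is a gene module enriched in disease-annotated
  genes relative to its background network?  With k positives among n module
  genes, K among the N background genes, the p-value is the upper tail
  P(X >= k) of Hypergeometric(N, K, n) and the fold enrichment is
  (k/n)/(K/N).
* :func:`ora` — generic over-representation analysis of a query gene set
  against a GMT collection, with Benjamini–Hochberg FDR across all tested
  terms in the collection.
* :func:`term_overlap_test` — do two lists of enriched terms share more terms
  than expected from a universe of annotatable terms?  The same upper tail,
  with terms playing the role of genes.

The upper tail includes the observed count (P(X >= k)), the standard
over-representation convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DataError, FormatError, ParameterError

__all__ = [
    "HypergeomQuery",
    "GeneCategoryTable",
    "GeneSetCollection",
    "CategoryEnrichmentResult",
    "hypergeom_upper_tail",
    "bh_adjust",
    "category_enrichment",
    "ora",
    "term_overlap_test",
    "read_category_table",
    "load_module26_categories",
    "CATEGORY_VOCABULARY",
]

CATEGORY_VOCABULARY = ("epilepsy", "epilepsy_related", "none")
DEFAULT_POSITIVE = frozenset({"epilepsy", "epilepsy_related"})


@dataclass(frozen=True)
class HypergeomQuery:
    """Counts for one hypergeometric upper-tail test.

    N: population size, K: successes in the population, n: draw size,
    k: observed successes in the draw.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N):
            raise ParameterError(f"need 0 <= K <= N, got K={self.K}, N={self.N}")
        if not (0 <= self.n <= self.N):
            raise ParameterError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ParameterError(
                f"need 0 <= k <= min(n, K), got k={self.k}, n={self.n}, K={self.K}"
            )


def hypergeom_upper_tail(query: HypergeomQuery) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); 1 when k = 0."""
    return float(hypergeom.sf(query.k - 1, query.N, query.K, query.n))


@dataclass
class GeneCategoryTable:
    """Per-gene disease category from the closed vocabulary
    {epilepsy, epilepsy_related, none}."""

    categories: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.categories.values() if c not in CATEGORY_VOCABULARY}
        if bad:
            raise FormatError(
                f"unknown categories {sorted(bad)}; allowed: {CATEGORY_VOCABULARY}"
            )

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def genes(self) -> set[str]:
        return set(self.categories)

    def positives(self, positive: Iterable[str] = DEFAULT_POSITIVE) -> set[str]:
        positive = set(positive)
        bad = positive - set(CATEGORY_VOCABULARY)
        if bad:
            raise ParameterError(f"unknown positive categories {sorted(bad)}")
        return {g for g, c in self.categories.items() if c in positive}

    def percent_positive(
        self,
        genes: Iterable[str] | None = None,
        positive: Iterable[str] = DEFAULT_POSITIVE,
    ) -> int:
        """Integer-rounded percentage of positive genes among ``genes``
        (all genes of the table when omitted)."""
        genes = set(genes) if genes is not None else self.genes
        if not genes:
            raise ParameterError("empty gene set")
        k = len(genes & self.positives(positive))
        return round(100.0 * k / len(genes))


def read_category_table(path: str | Path) -> GeneCategoryTable:
    """Read a TSV with columns ``gene`` and ``category`` (extras ignored).

    Unknown category labels and genes repeated with conflicting categories
    raise :class:`FormatError` / :class:`DataError`; an empty file yields an
    empty table.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return GeneCategoryTable({})
    if not {"gene", "category"}.issubset(frame.columns):
        raise FormatError("category table needs columns 'gene' and 'category'")
    categories: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        gene, cat = str(row.gene), str(row.category)
        if gene in categories and categories[gene] != cat:
            raise DataError(f"gene {gene} listed with conflicting categories")
        categories[gene] = cat
    return GeneCategoryTable(categories)


def load_module26_categories() -> GeneCategoryTable:
    """Disease categories of the 26-gene conserved fly co-expression module
    (7 epilepsy + 6 epilepsy-related + 13 unannotated genes)."""
    path = resources.files("comodmap").joinpath("data/m30_module26_categories.tsv")
    with resources.as_file(path) as p:
        return read_category_table(p)


@dataclass
class CategoryEnrichmentResult:
    k: int
    n: int
    K: int
    N: int
    fold: float | None
    p: float

    @property
    def percent_module(self) -> int:
        return round(100.0 * self.k / self.n)


def category_enrichment(
    module: Iterable[str],
    background: Iterable[str],
    categories: GeneCategoryTable,
    positive: Iterable[str] = DEFAULT_POSITIVE,
) -> CategoryEnrichmentResult:
    """Hypergeometric enrichment of positive-category genes in a module
    relative to its background gene set (module must be a subset)."""
    module = set(module)
    background = set(background)
    if not module:
        raise ParameterError("empty module")
    if not module.issubset(background):
        raise ParameterError("module must be a subset of the background")
    pos = categories.positives(positive)
    k = len(module & pos)
    K = len(background & pos)
    n, N = len(module), len(background)
    if K == 0:
        return CategoryEnrichmentResult(k, n, K, N, None, 1.0 if k == 0 else 0.0)
    p = hypergeom_upper_tail(HypergeomQuery(N=N, K=K, n=n, k=k))
    fold = (k / n) / (K / N)
    return CategoryEnrichmentResult(k, n, K, N, fold, p)


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe (GMT-serializable)."""

    sets: dict[str, tuple[str, frozenset[str]]]  # term_id -> (description, genes)
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        for term, (_, genes) in self.sets.items():
            if not frozenset(genes).issubset(self.universe):
                raise FormatError(f"term {term} contains genes outside the universe")
            self.sets[term] = (self.sets[term][0], frozenset(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for term, (desc, genes) in self.sets.items():
                fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")

    @classmethod
    def read_gmt(
        cls, path: str | Path, universe: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        """Parse a GMT file (term_id, description, then gene ids, tab-separated).

        When no universe is given, the union of all sets is used.
        """
        sets: dict[str, tuple[str, frozenset[str]]] = {}
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT line {line_no}: need term_id, description and >=1 gene"
                )
            term, desc, genes = parts[0], parts[1], frozenset(parts[2:])
            if term in sets:
                raise FormatError(f"duplicate term id {term}")
            sets[term] = (desc, genes)
        if universe is None:
            universe = frozenset().union(*(g for _, g in sets.values())) if sets else frozenset()
        return cls(sets, frozenset(universe))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg FDR adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return fdr


def ora(
    query: Iterable[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Over-representation analysis of a query gene set against a collection.

    Returns one row per term — columns term_id, description, k, n, K, N,
    fold, p_raw, fdr, significant — sorted by raw p.  The background
    defaults to the collection universe; query genes outside it are dropped
    with a warning, and an empty effective query is an error.  BH adjustment
    spans all terms of the collection.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must be in (0, 1)")
    universe = frozenset(background) if background is not None else sets.universe
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background dropped",
            stacklevel=2,
        )
    query &= universe
    if not query:
        raise DataError("query is empty after restricting to the background")
    N, n = len(universe), len(query)
    rows = []
    for term, (desc, genes) in sets.sets.items():
        term_genes = genes & universe
        K = len(term_genes)
        k = len(query & term_genes)
        p = hypergeom_upper_tail(HypergeomQuery(N=N, K=K, n=n, k=k)) if K else 1.0
        fold = (k / n) / (K / N) if K else float("nan")
        rows.append((term, desc, k, n, K, N, fold, p))
    frame = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "n", "K", "N", "fold", "p_raw"]
    )
    frame["fdr"] = bh_adjust(frame["p_raw"].to_numpy())
    frame["significant"] = frame["fdr"] < alpha
    frame = frame.sort_values("p_raw", kind="mergesort", ignore_index=True)
    return frame


def term_overlap_test(
    n_terms_a: int, n_terms_b: int, overlap: int, universe_size: int
) -> float:
    """Upper-tail probability of >= ``overlap`` shared terms between two term
    lists drawn from a universe of ``universe_size`` terms (symmetric in a/b)."""
    if overlap > min(n_terms_a, n_terms_b):
        raise ParameterError("overlap cannot exceed the smaller list")
    if max(n_terms_a, n_terms_b) > universe_size:
        raise ParameterError("list sizes cannot exceed the universe")
    return hypergeom_upper_tail(
        HypergeomQuery(N=universe_size, K=n_terms_a, n=n_terms_b, k=overlap)
    )
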