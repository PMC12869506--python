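"""Cross-species ortholog expansion of a human gene list into a fly catalog.

A scored ortholog table (human_gene, fly_gene, integer DIOPT-style score) is
first thresholded — the convention throughout is score >= min_score, default
3 — and then expanded into a catalog of unique fly genes annotated with one
of three mapping categories:

* ``one_to_one``  — the human gene has a single fly partner that serves no
  other human gene;
* ``many_to_one`` — several human genes share a single fly partner (a
  conserved family collapsed in the fly);
* ``one_to_many`` — a human gene has several fly partners with high and
  similar scores; "similar" is made explicit as all partners within
  ``tie_window`` (default 1) of the best score for that human gene.

Gene identifiers are opaque strings; no symbol conversion is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "OrthologRecord",
    "OrthologTable",
    "MappingCatalog",
    "filter_by_score",
    "classify_and_expand",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("one_to_one", "many_to_one", "one_to_many")


@dataclass(frozen=True)
class OrthologRecord:
    human_gene: str
    fly_gene: str
    score: int

    def __post_init__(self) -> None:
        if not self.human_gene or not self.fly_gene:
            raise ParameterError("gene ids must be non-empty")
        if self.score < 0:
            raise ParameterError("ortholog score must be >= 0")


@dataclass
class OrthologTable:
    """Ordered list of scored human->fly pairs; (human, fly) pairs unique."""

    records: list[OrthologRecord]

    def __post_init__(self) -> None:
        pairs = [(r.human_gene, r.fly_gene) for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise FormatError("duplicate (human_gene, fly_gene) pairs in ortholog table")

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.human_gene, r.fly_gene, r.score) for r in self.records],
            columns=["human_gene", "fly_gene", "score"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrthologTable":
        required = {"human_gene", "fly_gene", "score"}
        if not required.issubset(frame.columns):
            raise FormatError(
                f"ortholog table needs columns {sorted(required)}, "
                f"got {list(frame.columns)}"
            )
        records = [
            OrthologRecord(str(r.human_gene), str(r.fly_gene), int(r.score))
            for r in frame.itertuples(index=False)
        ]
        return cls(records)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OrthologTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class MappingCatalog:
    """Unique fly genes with mapping category and human source genes.

    ``fly_genes`` preserves first-appearance order of the kept records;
    ``provenance`` maps each fly gene to its category and the ordered list
    of human genes it represents.
    """

    fly_genes: list[str]
    provenance: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        if len(set(self.fly_genes)) != len(self.fly_genes):
            raise FormatError("catalog fly genes must be unique")
        for fly in self.fly_genes:
            category, sources = self.provenance[fly]
            if category not in CATEGORIES:
                raise FormatError(f"unknown category {category!r} for {fly}")
            if not sources:
                raise FormatError(f"fly gene {fly} has no source human genes")

    def __len__(self) -> int:
        return len(self.fly_genes)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for fly in self.fly_genes:
            counts[self.provenance[fly][0]] += 1
        return counts

    def source_human_genes(self) -> set[str]:
        return {h for fly in self.fly_genes for h in self.provenance[fly][1]}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (fly, self.provenance[fly][0], ";".join(self.provenance[fly][1]))
            for fly in self.fly_genes
        ]
        return pd.DataFrame(rows, columns=["fly_gene", "category", "source_genes"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MappingCatalog":
        frame = pd.read_csv(path, sep="\t")
        fly_genes = [str(g) for g in frame["fly_gene"]]
        provenance = {
            str(r.fly_gene): (str(r.category), str(r.source_genes).split(";"))
            for r in frame.itertuples(index=False)
        }
        return cls(fly_genes, provenance)


def filter_by_score(table: OrthologTable, min_score: int = 3) -> OrthologTable:
    """Keep records with score >= ``min_score``, preserving order."""
    if min_score < 0:
        raise ParameterError("min_score must be >= 0")
    return OrthologTable([r for r in table.records if r.score >= min_score])


def classify_and_expand(table: OrthologTable, tie_window: int = 1) -> MappingCatalog:
    """Expand a score-filtered ortholog table into a unique fly-gene catalog.

    Per human gene: a single fly partner is kept as is; with several
    partners, all whose score is within ``tie_window`` of that human gene's
    best score are kept (the one-to-many expansion).  A fly gene reached from
    several human genes appears once, with all sources recorded; if different
    paths imply different categories the first assignment (in input record
    order) wins and the conflict is logged.
    """
    if tie_window < 0:
        raise ParameterError("tie_window must be >= 0")
    if not table.records:
        return MappingCatalog([], {})

    partners: dict[str, list[OrthologRecord]] = {}
    for rec in table.records:
        partners.setdefault(rec.human_gene, []).append(rec)

    # First pass: decide which records are kept and the per-pair category
    # proposal (one_to_many for multi-partner humans, provisional one_to_one
    # otherwise — promoted to many_to_one below when the fly gene is shared).
    kept: list[tuple[OrthologRecord, str]] = []
    fly_sources: dict[str, list[str]] = {}
    for rec in table.records:
        recs = partners[rec.human_gene]
        if len(recs) == 1:
            kept.append((rec, "single"))
            fly_sources.setdefault(rec.fly_gene, []).append(rec.human_gene)
        else:
            best = max(r.score for r in recs)
            if rec.score >= best - tie_window:
                kept.append((rec, "one_to_many"))
                fly_sources.setdefault(rec.fly_gene, []).append(rec.human_gene)

    fly_genes: list[str] = []
    provenance: dict[str, tuple[str, list[str]]] = {}
    for rec, proposal in kept:
        if proposal == "single":
            category = (
                "many_to_one" if len(set(fly_sources[rec.fly_gene])) > 1 else "one_to_one"
            )
        else:
            category = "one_to_many"
        if rec.fly_gene not in provenance:
            fly_genes.append(rec.fly_gene)
            provenance[rec.fly_gene] = (category, [rec.human_gene])
        else:
            first_category, sources = provenance[rec.fly_gene]
            if rec.human_gene not in sources:
                sources.append(rec.human_gene)
            if category != first_category:
                logger.warning(
                    "fly gene %s reached as %s and %s; keeping first label %s",
                    rec.fly_gene, first_category, category, first_category,
                )
    return MappingCatalog(fly_genes, provenance)
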