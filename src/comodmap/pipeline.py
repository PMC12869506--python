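"""End-to-end orchestration: orthologs -> gene filter -> cell selection ->
correlation -> clustering -> modules -> enrichment -> report.

A single YAML (or JSON) config drives the run.  Every intermediate is
persisted to the output directory — catalog TSV, retained gene list,
correlation TSV, Newick dendrogram, clustered leaf order, module TSV,
enrichment tables — so each reported number can be recomputed from stored
stage outputs.  Reruns with identical config and inputs are byte-identical
except for the timestamp in the report's provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .coexpress import (
    extract_modules,
    hierarchical_cluster,
    log2_transform,
    module_stats,
    spearman_matrix,
)
from .enrichment import (
    CATEGORY_VOCABULARY,
    GeneSetCollection,
    category_enrichment,
    ora,
    read_category_table,
)
from .errors import ConfigError, DataError
from .expression import (
    FilterParams,
    filter_genes_by_total_counts,
    read_expression,
    select_cells_by_type,
)
from .orthologs import OrthologTable, classify_and_expand, filter_by_score

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_ALLOWED_LINKAGE = ("complete", "average", "single")
_ALLOWED_FORMATS = ("mtx", "tsv", "loom")

_KNOWN_KEYS = {
    "ortholog_table", "min_score", "tie_window",
    "expression", "expression_format",
    "min_total_counts", "count_filter_inclusive", "filter_scope",
    "cell_types_include", "cell_types_exclude", "cell_types_include_file",
    "log2_pseudocount", "linkage",
    "cut_height", "n_clusters", "min_module_size", "min_mean_intra_r",
    "category_table", "positive_categories", "gene_sets", "alpha",
    "output_dir",
}


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration (see validate_config)."""

    ortholog_table: Path
    expression: Path
    output_dir: Path
    expression_format: str = "mtx"
    min_score: int = 3
    tie_window: int = 1
    min_total_counts: float = 5000.0
    count_filter_inclusive: bool = True
    filter_scope: str = "full_dataset"
    cell_types_include: list[str] | None = None
    cell_types_exclude: list[str] | None = None
    log2_pseudocount: float = 1.0
    linkage: str = "complete"
    cut_height: float | None = None
    n_clusters: int | None = None
    min_module_size: int = 10
    min_mean_intra_r: float = 0.3
    category_table: Path | None = None
    positive_categories: list[str] = field(
        default_factory=lambda: ["epilepsy", "epilepsy_related"]
    )
    gene_sets: Path | None = None
    alpha: float = 0.05


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML/JSON config, filling documented defaults.

    Errors name the offending key: unknown keys, missing input files,
    out-of-range or unrecognized values all raise :class:`ConfigError`.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"config does not parse as YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping of keys to values")

    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("ortholog_table", "expression", "output_dir"):
        if key not in raw:
            raise ConfigError(f"missing required config key: {key}")

    base = path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    include_file = raw.pop("cell_types_include_file", None)
    cfg = PipelineConfig(
        ortholog_table=resolve(raw["ortholog_table"]),
        expression=resolve(raw["expression"]),
        output_dir=resolve(raw["output_dir"]),
        **{
            k: v
            for k, v in raw.items()
            if k not in ("ortholog_table", "expression", "output_dir",
                         "category_table", "gene_sets")
        },
    )
    if raw.get("category_table"):
        cfg.category_table = resolve(raw["category_table"])
    if raw.get("gene_sets"):
        cfg.gene_sets = resolve(raw["gene_sets"])
    if include_file:
        cfg.cell_types_include = [
            line for line in resolve(include_file).read_text().splitlines() if line.strip()
        ]

    for key in ("ortholog_table", "expression", "category_table", "gene_sets"):
        value = getattr(cfg, key)
        if value is not None and not Path(value).exists():
            raise ConfigError(f"{key}: file not found: {value}")
    if cfg.expression_format not in _ALLOWED_FORMATS:
        raise ConfigError(
            f"expression_format: {cfg.expression_format!r} not in {_ALLOWED_FORMATS}"
        )
    if cfg.linkage not in _ALLOWED_LINKAGE:
        raise ConfigError(f"linkage: {cfg.linkage!r} not in {_ALLOWED_LINKAGE}")
    if cfg.filter_scope not in ("full_dataset", "selected_cells"):
        raise ConfigError("filter_scope: must be 'full_dataset' or 'selected_cells'")
    if cfg.min_score < 0:
        raise ConfigError("min_score: must be >= 0")
    if cfg.min_total_counts < 0:
        raise ConfigError("min_total_counts: must be >= 0")
    if not (0 < cfg.alpha < 1):
        raise ConfigError("alpha: must be in (0, 1)")
    if cfg.cut_height is not None and cfg.n_clusters is not None:
        raise ConfigError("give only one of cut_height / n_clusters")
    if cfg.cut_height is None and cfg.n_clusters is None:
        cfg.cut_height = 1.0  # documented default cut on d = 1 - r
    if cfg.cell_types_include is not None and cfg.cell_types_exclude is not None:
        raise ConfigError("give only one of cell_types_include / cell_types_exclude")
    bad = set(cfg.positive_categories) - set(CATEGORY_VOCABULARY)
    if bad:
        raise ConfigError(f"positive_categories: unknown {sorted(bad)}")
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    payload = {k: str(v) for k, v in asdict(cfg).items()}
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order, persisting every intermediate.

    Returns the report dictionary (also written to ``report.json``).  Any
    stage failure raises with the stage name; outputs of completed stages
    remain on disk.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(cfg),
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    }
    stage = "map_orthologs"
    try:
        t0 = time.perf_counter()
        table = OrthologTable.read_tsv(cfg.ortholog_table)
        filtered = filter_by_score(table, cfg.min_score)
        catalog = classify_and_expand(filtered, cfg.tie_window)
        catalog.write_tsv(out / "catalog.tsv")
        report["catalog"] = {
            "n_fly_genes": len(catalog),
            "category_counts": catalog.category_counts(),
            "n_source_human_genes": len(catalog.source_human_genes()),
        }
        logger.info("%s: %d fly genes (%.2fs)", stage, len(catalog), time.perf_counter() - t0)

        stage = "filter_genes"
        t0 = time.perf_counter()
        mat = read_expression(cfg.expression, cfg.expression_format)
        params = FilterParams(
            cfg.min_total_counts, cfg.count_filter_inclusive, cfg.filter_scope
        )
        if cfg.filter_scope == "full_dataset":
            retained = filter_genes_by_total_counts(mat, catalog.fly_genes, params)
        else:
            retained = None  # applied after cell selection below
        stage = "select_cells"
        if cfg.cell_types_include is not None:
            mat = select_cells_by_type(mat, include=cfg.cell_types_include)
        elif cfg.cell_types_exclude is not None:
            mat = select_cells_by_type(mat, exclude=cfg.cell_types_exclude)
        if retained is None:
            retained = filter_genes_by_total_counts(mat, catalog.fly_genes, params)
        (out / "retained_genes.txt").write_text("".join(f"{g}\n" for g in retained))
        report["retained_genes"] = {"n": len(retained)}
        report["cells"] = {"n": mat.n_cells}
        if len(retained) < 2:
            raise DataError("fewer than 2 genes retained; cannot correlate")
        logger.info("filter/select: %d genes x %d cells (%.2fs)",
                    len(retained), mat.n_cells, time.perf_counter() - t0)

        stage = "correlate"
        t0 = time.perf_counter()
        sub = mat.subset_genes(retained)
        cor = spearman_matrix(log2_transform(sub, cfg.log2_pseudocount))
        if cor.has_missing:
            keep = [g for g in cor.gene_ids if g not in set(cor.missing_genes)]
            sub = sub.subset_genes(keep)
            cor = spearman_matrix(log2_transform(sub, cfg.log2_pseudocount))
        cor.write_tsv(out / "correlation.tsv")
        logger.info("correlate: %d genes (%.2fs)", len(cor.gene_ids), time.perf_counter() - t0)

        stage = "cluster"
        t0 = time.perf_counter()
        dendro = hierarchical_cluster(cor, cfg.linkage)
        dendro.write_newick(out / "dendrogram.nwk")
        (out / "leaf_order.txt").write_text("".join(f"{g}\n" for g in dendro.leaf_order))
        logger.info("cluster: done (%.2fs)", time.perf_counter() - t0)

        stage = "extract_modules"
        t0 = time.perf_counter()
        mods = extract_modules(
            dendro, cor,
            cut_height=cfg.cut_height, n_clusters=cfg.n_clusters,
            min_size=cfg.min_module_size, min_mean_intra_r=cfg.min_mean_intra_r,
        )
        mods.write_tsv(out / "modules.tsv")
        report["modules"] = [
            {
                "module_id": m.module_id,
                "n_genes": len(m.genes),
                "genes": sorted(m.genes),
                "mean_intra_r": m.mean_intra_r,
                "min_intra_r": m.min_intra_r,
                "max_intra_r": m.max_intra_r,
            }
            for m in mods.modules
        ]
        logger.info("extract_modules: %d module(s) (%.2fs)", len(mods), time.perf_counter() - t0)

        if cfg.category_table is not None and mods.modules:
            stage = "category_enrichment"
            categories = read_category_table(cfg.category_table)
            module_genes = set(mods.modules[0].genes)
            background = set(cor.gene_ids)
            res = category_enrichment(
                module_genes, background, categories, cfg.positive_categories
            )
            enr = {
                "k": res.k, "n": res.n, "K": res.K, "N": res.N,
                "fold": res.fold, "p": res.p,
                "percent_module": res.percent_module,
            }
            (out / "category_enrichment.json").write_text(json.dumps(enr, indent=2) + "\n")
            report["category_enrichment"] = enr

        if cfg.gene_sets is not None and mods.modules:
            stage = "ora"
            sets = GeneSetCollection.read_gmt(cfg.gene_sets)
            res = ora(set(mods.modules[0].genes), sets, cfg.alpha)
            res.to_csv(out / "ora.tsv", sep="\t", index=False)
            report["ora"] = {
                "n_terms": int(len(res)),
                "n_significant": int(res["significant"].sum()),
                "top_term": res.iloc[0]["term_id"] if len(res) else None,
            }
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
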