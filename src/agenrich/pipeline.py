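"""Orchestration: run every analysis block and export significance matrices.

``run_all`` loads a universe, the antigen test sets and whatever inputs a
run configuration names, builds the ALL/PCG/PCGLE sets, and runs per
reference set: the numeric-feature WMW block, one binary ORA block per
annotation namespace (including the motif namespace assembled from
sequence scanning and precomputed predictions), the ancient-domain
UNIVERSAL block, and the per-organism mimicry block. Each block yields a
sorted results TSV plus one category x test-set significance matrix per
reference, with cells holding -log10 of the BH-adjusted p for results
that pass the filters and 0 otherwise — the tabular equivalent of the
side-by-side heat maps such studies report.
"""

from __future__ import annotations

import logging
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import ancient_domains as ad
from . import mimicry as mi
from .features import (
    DEFAULT_NORMALIZE_SCALE,
    exon_length_feature,
    feature_wmw,
    load_feature_tsv,
    normalize_by_exon_length,
)
from .gene_universe import (
    ALL_NAME,
    DEFAULT_EXON_LENGTH_THRESHOLD,
    AnnotationCatalog,
    GeneSet,
    Universe,
    build_all_set,
    build_long_exon_reference,
    build_pcg_reference,
    read_gmt,
)
from .motif_scan import (
    build_motif_catalog,
    load_motif_annotations,
    merge_catalogs,
    read_fasta,
)
from .stats_core import (
    FilterConfig,
    OraResult,
    WmwResult,
    bh_adjust,
    ora_analysis,
    ora_results_to_tsv,
    wmw_results_to_tsv,
)

logger = logging.getLogger("agenrich")


@dataclass
class RunConfig:
    """Paths and thresholds of one full pipeline run."""

    universe: str
    test_sets: str
    output: str
    annotations: dict[str, str] = field(default_factory=dict)
    features: str | None = None
    normalize_features: list[str] = field(default_factory=list)
    sequences: str | None = None
    motif: str = "ELR"
    motif_annotations: list[str] = field(default_factory=list)
    organism_metadata: str | None = None
    organism_domains: dict[str, str] = field(default_factory=dict)
    domain_genes: dict[str, str] = field(default_factory=dict)
    blast: str | None = None
    subject_organism: str | None = None
    query_gene: str | None = None
    mimicry_organisms: str | None = None
    references: list[str] = field(default_factory=lambda: ["PCG", "PCGLE"])
    exon_length_threshold: float = DEFAULT_EXON_LENGTH_THRESHOLD
    min_domains: int = ad.DEFAULT_MIN_DOMAINS
    universal_fraction: float = ad.DEFAULT_UNIVERSAL_FRACTION
    min_score: float = mi.DEFAULT_MIN_SCORE
    max_evalue: float = mi.DEFAULT_MAX_EVALUE
    normalize_scale: float = DEFAULT_NORMALIZE_SCALE
    filters: FilterConfig = field(default_factory=FilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        filters = FilterConfig(**raw.pop("filters", {}))
        cfg = cls(filters=filters, **raw)
        # paths are relative to the config file's directory
        base = path.parent
        for name in ("universe", "test_sets", "features", "sequences",
                     "organism_metadata", "blast", "subject_organism",
                     "query_gene", "mimicry_organisms", "output"):
            value = getattr(cfg, name)
            if value is not None:
                setattr(cfg, name, str(base / value))
        for mapping in (cfg.annotations, cfg.organism_domains, cfg.domain_genes):
            for key in mapping:
                mapping[key] = str(base / mapping[key])
        cfg.motif_annotations = [str(base / p) for p in cfg.motif_annotations]
        return cfg


def export_matrix(
    results: Sequence[OraResult | WmwResult],
    sets_order: Sequence[str],
    categories_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Dense categories x sets matrix of -log10 adjusted p for passing cells.

    WMW results (which carry no reporting filters) count as passing when
    their adjusted p is below 0.05 by convention of the caller; here any
    result without a ``passes_filters`` attribute uses ``p_adjusted``
    alone. Cells for failing results are 0. Rows are ordered by
    descending maximum significance, ties broken lexically, unless an
    explicit order is given.
    """
    cells: dict[tuple[str, str], float] = {}
    for r in results:
        category = getattr(r, "category_id", None) or getattr(r, "feature_id")
        key = (category, r.set_name)
        if key in cells:
            raise ValueError(f"duplicate (category, set) pair {key}")
        if hasattr(r, "passes_filters"):
            passing = r.passes_filters
        else:
            passing = r.p_adjusted < 0.05
        value = 0.0
        if passing and r.p_adjusted > 0:
            value = -math.log10(r.p_adjusted)
        elif passing:
            value = math.inf
        cells[key] = value

    categories = sorted({c for c, _ in cells})
    matrix = pd.DataFrame(
        0.0, index=categories, columns=list(sets_order), dtype=float
    )
    for (category, set_name), value in cells.items():
        if set_name in matrix.columns:
            matrix.loc[category, set_name] = value
    if categories_order is not None:
        matrix = matrix.reindex(categories_order, fill_value=0.0)
    else:
        order = sorted(
            matrix.index, key=lambda c: (-matrix.loc[c].max(), c)
        )
        matrix = matrix.loc[order]
    matrix.index.name = "category"
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")


def render_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Optional image rendering; a thin veneer over the TSV matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axis = plt.subplots(
        figsize=(2 + 0.5 * matrix.shape[1], 1 + 0.3 * matrix.shape[0])
    )
    image = axis.imshow(matrix.to_numpy(), aspect="auto", cmap="Reds")
    axis.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90)
    axis.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    axis.set_title(title)
    fig.colorbar(image, ax=axis, label="-log10 adjusted p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _load_references(
    cfg: RunConfig, universe: Universe, test_sets: list[GeneSet]
) -> dict[str, GeneSet]:
    all_set = build_all_set(test_sets)
    pcg = build_pcg_reference(universe, all_set)
    references: dict[str, GeneSet] = {}
    for name in cfg.references:
        if name == "PCG":
            references["PCG"] = pcg
        elif name == "PCGLE":
            references["PCGLE"] = build_long_exon_reference(
                pcg, universe, cfg.exon_length_threshold
            )
        else:
            raise ValueError(f"unknown reference set {name!r}")
    return references


def _restrict_test_set(test: GeneSet, reference: GeneSet) -> GeneSet:
    """A test set is always made disjoint from its reference before testing."""
    overlap = test.members & reference.members
    if overlap:
        logger.warning(
            "test set %s overlaps reference %s by %d gene(s); removed from "
            "the test side", test.name, reference.name, len(overlap),
        )
        return GeneSet(test.name, test.members - overlap, test.description)
    return test


def run_all(cfg: RunConfig) -> dict:
    """Run every configured analysis block; return the result bundle.

    Outputs (sorted TSV tables plus one matrix per block and reference)
    are written to ``cfg.output`` only after every stage has succeeded, so
    a failing stage leaves no partial bundle behind.
    """
    universe = Universe.from_tsv(cfg.universe)
    test_sets = read_gmt(cfg.test_sets)
    if not test_sets:
        raise ValueError("no test sets in GMT input")
    all_set = build_all_set(test_sets)
    analysis_sets = test_sets + [all_set]
    references = _load_references(cfg, universe, test_sets)
    set_order = [s.name for s in analysis_sets]

    catalogs: list[AnnotationCatalog] = []
    for namespace in sorted(cfg.annotations):
        catalogs.append(
            AnnotationCatalog.from_tsv(cfg.annotations[namespace], namespace)
        )
    motif_parts = []
    if cfg.sequences:
        sequences = read_fasta(cfg.sequences)
        motif_parts.append(build_motif_catalog(sequences, cfg.motif))
    for path in cfg.motif_annotations:
        motif_parts.append(load_motif_annotations(path))
    if motif_parts:
        catalogs.append(merge_catalogs(*motif_parts))

    feature_tables = []
    if cfg.features:
        feature_tables = load_feature_tsv(cfg.features)
        for table in list(feature_tables):
            if table.feature_id in cfg.normalize_features:
                feature_tables.append(
                    normalize_by_exon_length(table, universe, cfg.normalize_scale)
                )
    feature_tables.insert(0, exon_length_feature(universe))

    universals = []
    if cfg.organism_metadata and cfg.organism_domains:
        tables_by_scheme = {
            scheme: ad.read_organism_tables(
                cfg.organism_metadata, path, scheme
            )
            for scheme, path in sorted(cfg.organism_domains.items())
        }
        maps_by_scheme = {
            scheme: ad.read_domain_gene_map(path)
            for scheme, path in sorted(cfg.domain_genes.items())
        }
        universals = ad.build_universal_sets(
            tables_by_scheme, maps_by_scheme,
            cfg.min_domains, cfg.universal_fraction,
        )

    hit_lists = []
    if cfg.blast and cfg.subject_organism and cfg.query_gene:
        hits = mi.filter_hits(
            mi.parse_blast_tabular(cfg.blast), cfg.min_score, cfg.max_evalue
        )
        organisms = _read_organism_meta(
            cfg.mimicry_organisms or cfg.organism_metadata
        )
        hit_lists = mi.build_hit_lists(
            hits,
            mi.read_two_column_map(cfg.subject_organism),
            organisms,
            mi.read_two_column_map(cfg.query_gene),
        )

    bundle: dict = {"references": {}}
    for ref_name, reference in references.items():
        block: dict = {"wmw": [], "ora": {}, "ancient": [], "mimicry": []}
        for test in analysis_sets:
            test_r = _restrict_test_set(test, reference)
            if feature_tables:
                wmw_results = [
                    feature_wmw(test_r, reference, table)
                    for table in feature_tables
                ]
                adjusted = bh_adjust([r.p_raw for r in wmw_results])
                for r, a in zip(wmw_results, adjusted):
                    r.p_adjusted = a
                block["wmw"].extend(wmw_results)
            for catalog in catalogs:
                block["ora"].setdefault(catalog.namespace, []).extend(
                    ora_analysis(test_r, reference, catalog, cfg.filters)
                )
            if universals:
                block["ancient"].extend(
                    ad.universal_analysis(test_r, reference, universals,
                                          cfg.filters)
                )
            if hit_lists:
                block["mimicry"].extend(
                    mi.mimicry_ora(test_r, reference, hit_lists, cfg.filters)
                )
        bundle["references"][ref_name] = block

    _write_bundle(cfg, bundle, set_order)
    return bundle


def _read_organism_meta(path: str | Path) -> dict[str, mi.OrganismMeta]:
    organisms: dict[str, mi.OrganismMeta] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("organism_id\t"):
                continue
            fields = line.split("\t")
            organisms[fields[0]] = mi.OrganismMeta(
                fields[0], fields[1], fields[2] == "1"
            )
    return organisms


def _write_bundle(cfg: RunConfig, bundle: dict, set_order: list[str]) -> None:
    outdir = Path(cfg.output)
    staging = outdir.with_name(outdir.name + ".partial")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        for ref_name, block in bundle["references"].items():
            prefix = staging / ref_name
            prefix.mkdir()
            if block["wmw"]:
                wmw_results_to_tsv(block["wmw"], prefix / "wmw_features.tsv")
                write_matrix(
                    export_matrix(block["wmw"], set_order),
                    prefix / "matrix_wmw_features.tsv",
                )
            for namespace, results in sorted(block["ora"].items()):
                ora_results_to_tsv(results, prefix / f"ora_{namespace}.tsv")
                write_matrix(
                    export_matrix(results, set_order),
                    prefix / f"matrix_ora_{namespace}.tsv",
                )
            for key, stem in (("ancient", "ora_universal"),
                              ("mimicry", "ora_mimicry")):
                if block[key]:
                    ora_results_to_tsv(block[key], prefix / f"{stem}.tsv")
                    write_matrix(
                        export_matrix(block[key], set_order),
                        prefix / f"matrix_{stem}.tsv",
                    )
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    if outdir.exists():
        shutil.rmtree(outdir)
    staging.rename(outdir)
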