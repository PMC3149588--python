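"""Numeric per-gene features (exon length, SNP and mutation counts).

Feature tables map gene identifiers to non-negative values; genes absent
from a table are *missing* for that feature, not zero — absence from a
variant database is not evidence of zero variants. Count features can be
normalized per kilobase of mean exon length to separate density effects
from the sheer length effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .gene_universe import GeneSet, Universe
from .stats_core import WmwResult, wmw_test

logger = logging.getLogger("agenrich")

NORMALIZED_SUFFIX = "_norm"
DEFAULT_NORMALIZE_SCALE = 1000.0  # per kilobase


@dataclass
class NumericFeatureTable:
    """Per-gene values of one feature; file inputs are validated to be
    non-negative counts, but derived tables (e.g. log transforms used for
    rank-invariance checks) may hold any reals."""

    feature_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


def load_feature_tsv(path: str | Path) -> list[NumericFeatureTable]:
    """Read a feature TSV: header ``gene_id`` then one column per feature.

    Empty cells and ``NA`` mark missing values; a non-numeric cell or a
    duplicated gene row is an error.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene_id":
            raise ValueError(f"{path}: first header column must be 'gene_id'")
        feature_ids = header[1:]
        tables = [NumericFeatureTable(fid) for fid in feature_ids]
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            gene_id = fields[0]
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            for col, cell in enumerate(fields[1:], start=1):
                if cell == "" or cell.upper() == "NA":
                    continue
                try:
                    value = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric cell {cell!r} in "
                        f"column {header[col]!r}"
                    ) from None
                if value < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative value {value} in "
                        f"column {header[col]!r}"
                    )
                tables[col - 1].values[gene_id] = value
    return tables


def write_feature_tsv(
    tables: list[NumericFeatureTable], path: str | Path
) -> None:
    """Write feature tables as one TSV; missing values become empty cells."""
    path = Path(path)
    gene_ids = sorted(set().union(*(t.values.keys() for t in tables)))
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(t.feature_id for t in tables) + "\n")
        for g in gene_ids:
            cells = [
                f"{t.values[g]:.6g}" if g in t.values else "" for t in tables
            ]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def normalize_by_exon_length(
    feature: NumericFeatureTable,
    universe: Universe,
    scale: float = DEFAULT_NORMALIZE_SCALE,
) -> NumericFeatureTable:
    """Per-length variant of a count feature: ``value * scale / exon_length``.

    With the default scale of 1000 this is a per-kilobase density. Genes
    with zero exon length are dropped with a warning.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    out: dict[str, float] = {}
    dropped = 0
    for gene_id, value in feature.values.items():
        if gene_id not in universe:
            raise KeyError(f"gene {gene_id!r} of feature {feature.feature_id!r} "
                           "is missing from the universe")
        length = universe.mean_exon_length(gene_id)
        if length <= 0:
            dropped += 1
            continue
        out[gene_id] = value * scale / length
    if dropped:
        logger.warning(
            "normalize_by_exon_length: dropped %d gene(s) with zero exon length "
            "from %s", dropped, feature.feature_id,
        )
    return NumericFeatureTable(feature.feature_id + NORMALIZED_SUFFIX, out)


def exon_length_feature(universe: Universe) -> NumericFeatureTable:
    """The universe's exon-length column, reusable as a WMW feature."""
    return NumericFeatureTable(
        "mean_exon_length",
        {rec.gene_id: rec.mean_exon_length for rec in universe},
    )


def feature_wmw(
    test: GeneSet,
    reference: GeneSet,
    feature: NumericFeatureTable,
) -> WmwResult:
    """One-tailed WMW of a numeric feature, test set vs reference set.

    Genes without a value for the feature are excluded from that side and
    counted in the result's missing tallies.
    """
    test_vals = [feature.values[g] for g in test.members if g in feature.values]
    ref_vals = [
        feature.values[g] for g in reference.members if g in feature.values
    ]
    if not test_vals or not ref_vals:
        raise ValueError(
            f"feature {feature.feature_id!r}: no scored genes on "
            f"{'test' if not test_vals else 'reference'} side"
        )
    result = wmw_test(
        test_vals, ref_vals, set_name=test.name, feature_id=feature.feature_id
    )
    result.n_missing_test = len(test.members) - len(test_vals)
    result.n_missing_ref = len(reference.members) - len(ref_vals)
    return result
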