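"""Molecular-mimicry analysis from BLAST tabular hits.

Cross-reactive immune recognition of a self-protein that resembles a
foreign protein is operationalized here through BLAST similarity: hits
of human proteins against other organisms' proteomes are kept when the
bit score is at least 100 and the E-value at most 0.001, restricted to
completely sequenced organisms, and collapsed into one hit list of
"similar" human genes per organism. Each organism's hit list is then a
binary category for an ORA of the antigen sets against the reference,
with one BH family spanning all organisms for a given test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .gene_universe import GeneSet
from .stats_core import (
    FilterConfig,
    OraResult,
    apply_filters,
    bh_adjust,
    ora_test,
    sort_ora_results,
)

logger = logging.getLogger("agenrich")

DEFAULT_MIN_SCORE = 100.0
DEFAULT_MAX_EVALUE = 0.001

BLAST_COLUMNS = 12


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column BLAST tabular output (outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        for name in ("q_start", "q_end", "s_start", "s_end"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (1-based coordinates)")


@dataclass
class OrganismMeta:
    organism_id: str
    kingdom: str
    complete: bool


@dataclass
class OrganismHitList:
    """Human genes with >=1 surviving BLAST hit in one organism."""

    organism_id: str
    kingdom: str
    similar_genes: set[str]


def parse_blast_tabular(path: str | Path) -> list[BlastHit]:
    """Parse 12-column tab-separated BLAST output; ``#`` comments allowed."""
    hits: list[BlastHit] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != BLAST_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {BLAST_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            hits.append(BlastHit(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                alignment_length=int(fields[3]),
                mismatches=int(fields[4]),
                gap_opens=int(fields[5]),
                q_start=int(fields[6]),
                q_end=int(fields[7]),
                s_start=int(fields[8]),
                s_end=int(fields[9]),
                evalue=float(fields[10]),
                bit_score=float(fields[11]),
            ))
    return hits


def filter_hits(
    hits: Iterable[BlastHit],
    min_score: float = DEFAULT_MIN_SCORE,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[BlastHit]:
    """Keep hits with bit score >= ``min_score`` and E-value <= ``max_evalue``.

    Both thresholds are inclusive ("at least" / "at most").
    """
    return [
        h for h in hits if h.bit_score >= min_score and h.evalue <= max_evalue
    ]


def build_hit_lists(
    hits: Iterable[BlastHit],
    subject_organism: Mapping[str, str],
    organisms: Mapping[str, OrganismMeta],
    query_gene: Mapping[str, str],
) -> list[OrganismHitList]:
    """Group filtered hits into per-organism hit lists of similar human genes.

    Hits to subjects without an organism mapping, to organisms missing
    from the metadata, or to organisms whose genome is not completely
    sequenced are dropped (with counted warnings). Organisms with no
    surviving hit are omitted.
    """
    if not subject_organism or not query_gene:
        raise ValueError("subject_organism and query_gene maps must be non-empty")
    genes_by_org: dict[str, set[str]] = {}
    n_unmapped_subject = n_unmapped_query = n_incomplete = 0
    for h in hits:
        organism_id = subject_organism.get(h.subject_id)
        if organism_id is None:
            n_unmapped_subject += 1
            continue
        meta = organisms.get(organism_id)
        if meta is None or not meta.complete:
            n_incomplete += 1
            continue
        gene_id = query_gene.get(h.query_id)
        if gene_id is None:
            n_unmapped_query += 1
            continue
        genes_by_org.setdefault(organism_id, set()).add(gene_id)
    if n_unmapped_subject or n_unmapped_query or n_incomplete:
        logger.warning(
            "build_hit_lists: dropped %d hit(s) with unmapped subjects, "
            "%d to incomplete/unknown organisms, %d with unmapped queries",
            n_unmapped_subject, n_incomplete, n_unmapped_query,
        )
    return [
        OrganismHitList(
            organism_id=org,
            kingdom=organisms[org].kingdom,
            similar_genes=genes,
        )
        for org, genes in sorted(genes_by_org.items())
    ]


def mimicry_ora(
    test: GeneSet,
    reference: GeneSet,
    hit_lists: list[OrganismHitList],
    cfg: FilterConfig | None = None,
) -> list[OraResult]:
    """Per-organism ORA of one test set; BH family = all organisms.

    Each organism's hit list is a binary category over the full
    test+reference population; the prevalence denominator is the test-set
    size.
    """
    cfg = cfg or FilterConfig()
    population = test.members | reference.members
    results = [
        ora_test(
            test, reference, hl.similar_genes, population,
            namespace="mimicry", category_id=hl.organism_id,
        )
        for hl in sorted(hit_lists, key=lambda h: h.organism_id)
    ]
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adjusted):
        r.p_adjusted = a
    apply_filters(results, cfg, max(len(test.members & population), 1))
    return sort_ora_results(results)


def read_two_column_map(path: str | Path) -> dict[str, str]:
    """Read a ``key<TAB>value`` TSV (subject->organism, query->gene maps)."""
    mapping: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            mapping[fields[0]] = fields[1]
    return mapping
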