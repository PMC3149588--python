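"""Ancient ("universal") protein-domain gene sets and their enrichment.

For each kingdom of life (Bacteria, Archaea, Eukaryota) and each domain
classification scheme (CATH-like, Pfam-like), the pipeline keeps the
completely sequenced organisms annotated with at least 150 domains,
extracts the domains present in at least 70% of those species, and maps
them to genes. A gene belongs to the resulting UNIVERSAL set if it
carries at least one such ancient domain. Antigen sets are then tested
against the UNIVERSAL sets by ORA over the full test+reference
population (ancient-domain membership is defined for every gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
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

KINGDOMS = ("BACTERIA", "ARCHAEA", "EUKARYOTA")
SCHEMES = ("CATH", "PFAM")

DEFAULT_MIN_DOMAINS = 150
DEFAULT_UNIVERSAL_FRACTION = 0.70


@dataclass
class OrganismDomainTable:
    """One organism's domain complement under one classification scheme."""

    organism_id: str
    kingdom: str
    complete: bool
    domains: set[str]
    scheme: str

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {self.kingdom!r}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")


@dataclass
class UniversalDomainSet:
    kingdom: str
    scheme: str
    domains: set[str]
    gene_set: GeneSet

    @property
    def name(self) -> str:
        return f"UNIVERSAL_{self.kingdom}_{self.scheme}"


def read_organism_tables(
    metadata_path: str | Path,
    domains_path: str | Path,
    scheme: str,
) -> list[OrganismDomainTable]:
    """Assemble organism tables for one scheme from the two TSVs.

    Metadata TSV: ``organism_id  kingdom  complete(0/1)  scheme`` (rows of
    other schemes are skipped). Organism-domain TSV: ``organism_id
    domain_id``, one pair per line.
    """
    domains_by_org: dict[str, set[str]] = {}
    with Path(domains_path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{domains_path}:{lineno}: expected 'organism_id<TAB>domain_id'"
                )
            domains_by_org.setdefault(fields[0], set()).add(fields[1])

    tables: list[OrganismDomainTable] = []
    seen: set[str] = set()
    with Path(metadata_path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("organism_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(
                    f"{metadata_path}:{lineno}: expected 4 columns "
                    "(organism_id, kingdom, complete, scheme)"
                )
            organism_id, kingdom, complete, row_scheme = fields
            if row_scheme != scheme:
                continue
            if organism_id in seen:
                raise ValueError(
                    f"{metadata_path}:{lineno}: duplicate organism "
                    f"{organism_id!r} for scheme {scheme}"
                )
            seen.add(organism_id)
            tables.append(OrganismDomainTable(
                organism_id=organism_id,
                kingdom=kingdom,
                complete=complete == "1",
                domains=domains_by_org.get(organism_id, set()),
                scheme=scheme,
            ))
    return tables


def read_domain_gene_map(path: str | Path) -> dict[str, set[str]]:
    """Read ``domain_id<TAB>gene_id`` pairs into a domain -> genes mapping."""
    mapping: dict[str, set[str]] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'domain_id<TAB>gene_id'"
                )
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def filter_organisms(
    tables: Iterable[OrganismDomainTable],
    min_domains: int = DEFAULT_MIN_DOMAINS,
) -> list[OrganismDomainTable]:
    """Keep completely sequenced organisms with at least ``min_domains``."""
    if min_domains < 1:
        raise ValueError("min_domains must be >= 1")
    return [t for t in tables if t.complete and len(t.domains) >= min_domains]


def universal_domains(
    organisms: Iterable[OrganismDomainTable],
    kingdom: str,
    fraction: float = DEFAULT_UNIVERSAL_FRACTION,
) -> set[str]:
    """Domains present in at least ``fraction`` of the kingdom's species."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    of_kingdom = [t for t in organisms if t.kingdom == kingdom]
    if not of_kingdom:
        raise ValueError(f"no retained organisms of kingdom {kingdom}")
    counts: dict[str, int] = {}
    for t in of_kingdom:
        for d in t.domains:
            counts[d] = counts.get(d, 0) + 1
    n = len(of_kingdom)
    # k/n >= fraction without float division error at the boundary
    return {d for d, c in counts.items() if c >= fraction * n - 1e-9}


def map_domains_to_genes(
    domains: set[str],
    domain_gene_map: Mapping[str, set[str]],
    kingdom: str,
    scheme: str,
) -> UniversalDomainSet:
    """Union the genes carrying any universal domain into a UNIVERSAL set."""
    if not domain_gene_map:
        raise ValueError("domain_gene_map must be non-empty")
    genes: set[str] = set()
    skipped = 0
    for d in sorted(domains):
        mapped = domain_gene_map.get(d)
        if mapped is None:
            skipped += 1
            continue
        genes |= mapped
    if skipped:
        logger.warning(
            "map_domains_to_genes: %d universal domain(s) absent from the "
            "domain-gene map (%s/%s)", skipped, kingdom, scheme,
        )
    if not genes:
        logger.warning("UNIVERSAL_%s_%s gene set is empty", kingdom, scheme)
    name = f"UNIVERSAL_{kingdom}_{scheme}"
    return UniversalDomainSet(
        kingdom=kingdom, scheme=scheme, domains=set(domains),
        gene_set=GeneSet(name=name, members=frozenset(genes),
                         description=f"genes with ancient {scheme} domains"),
    )


def build_universal_sets(
    tables_by_scheme: Mapping[str, list[OrganismDomainTable]],
    maps_by_scheme: Mapping[str, Mapping[str, set[str]]],
    min_domains: int = DEFAULT_MIN_DOMAINS,
    fraction: float = DEFAULT_UNIVERSAL_FRACTION,
) -> list[UniversalDomainSet]:
    """All kingdom x scheme UNIVERSAL sets (six when both schemes supplied)."""
    out: list[UniversalDomainSet] = []
    for scheme in SCHEMES:
        if scheme not in tables_by_scheme:
            logger.warning("scheme %s not supplied; its UNIVERSAL sets are "
                           "skipped", scheme)
            continue
        retained = filter_organisms(tables_by_scheme[scheme], min_domains)
        for kingdom in KINGDOMS:
            domains = universal_domains(retained, kingdom, fraction)
            out.append(map_domains_to_genes(
                domains, maps_by_scheme[scheme], kingdom, scheme
            ))
    if len(out) < len(KINGDOMS) * len(SCHEMES):
        logger.warning("emitted %d UNIVERSAL set(s) instead of %d",
                       len(out), len(KINGDOMS) * len(SCHEMES))
    return out


def universal_ora(
    test: GeneSet,
    reference: GeneSet,
    universal: UniversalDomainSet,
) -> OraResult:
    """ORA of one test set against one UNIVERSAL gene set (full population)."""
    population = test.members | reference.members
    return ora_test(
        test, reference, set(universal.gene_set.members), population,
        namespace="ancient_domains", category_id=universal.name,
    )


def universal_analysis(
    test: GeneSet,
    reference: GeneSet,
    universals: list[UniversalDomainSet],
    cfg: FilterConfig | None = None,
) -> list[OraResult]:
    """Test one set against all UNIVERSAL sets; one BH family per test set.

    The population covers every test and reference gene, so the prevalence
    denominator is the test-set size within the population.
    """
    cfg = cfg or FilterConfig()
    results = [universal_ora(test, reference, u) for u in universals]
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adjusted):
        r.p_adjusted = a
    denominator = max(len(test.members & (test.members | reference.members)), 1)
    apply_filters(results, cfg, denominator)
    return sort_ora_results(results)
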