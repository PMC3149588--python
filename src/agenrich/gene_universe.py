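"""Gene universe, gene sets, and the antigen test/reference set construction.

The analyses in this package compare *test sets* of antigen-encoding genes
against a *reference set* drawn from the full population of protein-coding
genes. Two reference sets are supported:

* ``ProteinCodingGenes`` (PCG): every gene in the universe that is not a
  member of the pooled antigen set ``ALL``.
* ``ProteinCodingGenesLongerExons`` (PCGLE): the subset of PCG whose mean
  exon length is strictly greater than a threshold (default 3100 nt). This
  length-matched reference removes the exon-length bias that antigen sets
  otherwise carry into length-dependent analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger("agenrich")

DEFAULT_EXON_LENGTH_THRESHOLD = 3100.0

PCG_NAME = "ProteinCodingGenes"
PCGLE_NAME = "ProteinCodingGenesLongerExons"
ALL_NAME = "ALL"


@dataclass(frozen=True)
class GeneRecord:
    """A single gene: opaque identifier plus its mean exon length in nt."""

    gene_id: str
    mean_exon_length: float
    has_sequence: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be a non-empty string")
        if self.mean_exon_length < 0:
            raise ValueError(
                f"mean_exon_length must be >= 0, got {self.mean_exon_length!r} "
                f"for gene {self.gene_id!r}"
            )


class Universe:
    """The gene population the hypergeometric population N is drawn from.

    Keys are unique gene identifiers; identifiers are opaque strings (no
    symbol or Entrez resolution is attempted here).
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self._genes: dict[str, GeneRecord] = {}
        for rec in records:
            if rec.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id in universe: {rec.gene_id!r}")
            self._genes[rec.gene_id] = rec
        if not self._genes:
            raise ValueError("a universe must contain at least one gene")

    def __len__(self) -> int:
        return len(self._genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._genes[gene_id]

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._genes.values())

    @property
    def gene_ids(self) -> set[str]:
        return set(self._genes)

    def mean_exon_length(self, gene_id: str) -> float:
        return self._genes[gene_id].mean_exon_length

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Universe":
        """Read a universe TSV with header ``gene_id<TAB>mean_exon_length``."""
        path = Path(path)
        records = []
        with path.open("r", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["gene_id", "mean_exon_length"]:
                raise ValueError(
                    f"{path}: expected header 'gene_id\\tmean_exon_length', "
                    f"got {header[:2]!r}"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                records.append(GeneRecord(fields[0], float(fields[1])))
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_id\tmean_exon_length\n")
            for gene_id in sorted(self._genes):
                rec = self._genes[gene_id]
                fh.write(f"{gene_id}\t{rec.mean_exon_length:.6g}\n")


@dataclass
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AnnotationCatalog:
    """One annotation namespace (GO-like, pathway-like, domain-like, ...).

    Maps category identifiers to the set of annotated gene identifiers.
    """

    namespace: str
    categories: dict[str, set[str]] = field(default_factory=dict)

    @property
    def annotated_genes(self) -> set[str]:
        """Union of all genes carrying at least one annotation."""
        out: set[str] = set()
        for members in self.categories.values():
            out |= members
        return out

    @classmethod
    def from_tsv(cls, path: str | Path, namespace: str) -> "AnnotationCatalog":
        """Read annotation pairs ``gene_id<TAB>category_id``, one per line."""
        path = Path(path)
        catalog = cls(namespace=namespace)
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'gene_id<TAB>category_id'"
                    )
                gene_id, category_id = fields
                catalog.categories.setdefault(category_id, set()).add(gene_id)
        return catalog

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for category_id in sorted(self.categories):
                for gene_id in sorted(self.categories[category_id]):
                    fh.write(f"{gene_id}\t{category_id}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (Broad dialect: name, description, members...).

    Duplicate members within a line are collapsed with a warning; a line
    with fewer than three tab-separated fields is a parse error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %r contains %d duplicate member(s); collapsed",
                    path, lineno, name, len(members) - len(unique),
                )
            sets.append(GeneSet(name=name, members=unique, description=description))
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets as GMT, members sorted for byte-stable output."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            fields = [gs.name, gs.description, *sorted(gs.members)]
            fh.write("\t".join(fields) + "\n")


def build_all_set(sets: list[GeneSet], name: str = ALL_NAME) -> GeneSet:
    """Union of all antigen test sets (the pooled ``ALL`` set)."""
    if not sets:
        raise ValueError("build_all_set requires at least one input set")
    members: set[str] = set()
    for gs in sets:
        members |= gs.members
    return GeneSet(name=name, members=frozenset(members),
                   description="union of all antigen sets")


def build_pcg_reference(universe: Universe, all_set: GeneSet) -> GeneSet:
    """All universe genes minus the pooled antigens — the PCG reference."""
    missing = all_set.members - universe.gene_ids
    if missing:
        logger.warning(
            "%d antigen gene(s) absent from the universe are ignored "
            "when building %s", len(missing), PCG_NAME,
        )
    members = universe.gene_ids - all_set.members
    if not members:
        logger.warning("%s is empty: every universe gene is an antigen", PCG_NAME)
    return GeneSet(name=PCG_NAME, members=frozenset(members),
                   description="protein-coding genes minus antigens")


def build_long_exon_reference(
    pcg: GeneSet,
    universe: Universe,
    threshold: float = DEFAULT_EXON_LENGTH_THRESHOLD,
) -> GeneSet:
    """PCG genes with mean exon length strictly greater than ``threshold``.

    The strict inequality means a gene sitting exactly on the threshold is
    excluded.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    missing = pcg.members - universe.gene_ids
    if missing:
        raise KeyError(
            f"{len(missing)} PCG gene(s) missing from the universe, "
            f"e.g. {sorted(missing)[:3]}"
        )
    members = frozenset(
        g for g in pcg.members if universe.mean_exon_length(g) > threshold
    )
    return GeneSet(name=PCGLE_NAME, members=members,
                   description=f"PCG with mean exon length > {threshold:g} nt")
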