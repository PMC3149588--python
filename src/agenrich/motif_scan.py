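"""Sequence motif scanning for binary sequence-derived annotations.

Exact tripeptide scanning (the ELR Glu-Leu-Arg motif of ELR+ CXC
chemokines by default) is implemented here; other sequence features such
as Granzyme-B cleavage sites or coiled-coil segments come from external
predictors and enter the pipeline as precomputed annotation TSVs in the
same "motif" namespace. Presence/absence of at least one hit — not the
hit count — defines the binary category fed to the ORA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .gene_universe import AnnotationCatalog

logger = logging.getLogger("agenrich")

MOTIF_NAMESPACE = "motif"
DEFAULT_MOTIF = "ELR"

#: the 20 standard amino acids; X is tolerated in sequences but never matches
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    position: int  # 1-based start of the match
    matched: str


def _validate_sequence(sequence: str, *, allow_x: bool) -> str:
    seq = sequence.upper()
    allowed = AMINO_ACIDS | ({"X"} if allow_x else set())
    for i, ch in enumerate(seq, start=1):
        if ch not in allowed:
            raise ValueError(
                f"illegal amino-acid character {ch!r} at position {i}"
            )
    return seq


def scan_tripeptide(
    sequence: str, motif: str = DEFAULT_MOTIF, gene_id: str = ""
) -> list[MotifHit]:
    """All (possibly overlapping) exact matches of ``motif``, 1-based.

    Scanning is case-insensitive; the wildcard residue X never matches.
    """
    if len(motif) < 1:
        raise ValueError("motif must have length >= 1")
    motif = _validate_sequence(motif, allow_x=False)
    seq = _validate_sequence(sequence, allow_x=True)
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(
            MotifHit(gene_id=gene_id, motif_id=motif,
                     position=start + 1, matched=motif)
        )
        start = seq.find(motif, start + 1)
    return hits


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein FASTA into ``{gene_id: sequence}``; duplicate ids error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate FASTA id {record.id!r}")
        sequences[record.id] = str(record.seq)
    return sequences


def build_motif_catalog(
    sequences: dict[str, str], motif: str = DEFAULT_MOTIF
) -> AnnotationCatalog:
    """Binary annotation catalog: genes whose protein has >=1 motif hit."""
    catalog = AnnotationCatalog(namespace=MOTIF_NAMESPACE)
    if not sequences:
        logger.warning("build_motif_catalog: no input sequences")
        return catalog
    members = {
        gene_id
        for gene_id, seq in sequences.items()
        if scan_tripeptide(seq, motif, gene_id=gene_id)
    }
    catalog.categories[motif.upper()] = members
    return catalog


def load_motif_annotations(path: str | Path) -> AnnotationCatalog:
    """Precomputed motif predictions (GrB sites, coiled-coils) as a catalog."""
    return AnnotationCatalog.from_tsv(path, namespace=MOTIF_NAMESPACE)


def merge_catalogs(*catalogs: AnnotationCatalog) -> AnnotationCatalog:
    """Merge catalogs sharing a namespace; duplicate categories error."""
    namespaces = {c.namespace for c in catalogs}
    if len(namespaces) != 1:
        raise ValueError(f"cannot merge across namespaces: {sorted(namespaces)}")
    merged = AnnotationCatalog(namespace=namespaces.pop())
    for c in catalogs:
        for category_id, members in c.categories.items():
            if category_id in merged.categories:
                raise ValueError(f"duplicate category {category_id!r} in merge")
            merged.categories[category_id] = set(members)
    return merged
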