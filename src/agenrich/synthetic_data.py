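"""Seeded synthetic corpora with planted effects for the whole pipeline.

Every input the analyses consume can be generated here: a gene universe
with right-skewed (log-normal) exon lengths, antigen-like test sets with
a configurable exon-length shift, sparse binary annotation catalogs with
planted odds-ratio enrichments, count features that scale with exon
length, protein sequences with motif tripeptides inserted at per-group
rates, per-kingdom organism x domain presence tables with a controllable
universal-domain fraction, and BLAST-style hit tables with planted
per-organism enrichment. A ground-truth manifest records every planted
parameter so each stage's recovery can be checked without re-running the
generators.

Randomness comes from one master seed fanned out into independent named
substreams, so adding a generator never perturbs the outputs of the
existing ones.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ancient_domains import KINGDOMS, SCHEMES, OrganismDomainTable
from .features import NumericFeatureTable, write_feature_tsv
from .gene_universe import (
    AnnotationCatalog,
    GeneRecord,
    GeneSet,
    Universe,
    write_gmt,
)
from .mimicry import OrganismMeta

logger = logging.getLogger("agenrich")

AMINO_ACIDS_STR = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedCategory:
    """A category enriched in one test set: annotation prob ``test_prob``
    for that set's genes instead of the base probability."""

    set_index: int
    namespace: str
    category_index: int
    test_prob: float


@dataclass(frozen=True)
class MimicryPlant:
    """An organism with elevated hit probability for test-set genes."""

    organism_index: int
    test_prob: float
    ref_prob: float


@dataclass
class SimConfig:
    """Parameters of the synthetic corpus.

    Defaults describe the standard study conditions used throughout the
    test suite: a universe of 2000 genes, one antigen-like test set of
    200 genes with a +0.4 shift on the exon-length log-mean, sparse
    annotations (5% base rate) with one planted category at 50%
    annotation probability, universal-domain gene membership of 0.6 in
    the test set versus 0.2 in the background, and three of ten organisms
    planted with mimicry hit probability 0.5 versus 0.05.
    """

    seed: int = 0
    n_genes: int = 2000
    test_set_sizes: Sequence[int] = (200,)
    exon_length_log_mean: float = 8.0
    exon_length_log_sd: float = 0.6
    exon_shift_per_set: Sequence[float] = (0.4,)
    namespaces: Sequence[str] = ("GO", "KEGG", "DOMAIN", "LOCATION")
    n_categories_per_namespace: int = 50
    base_annotation_prob: float = 0.05
    planted_categories: Sequence[PlantedCategory] = (
        PlantedCategory(0, "GO", 0, 0.5),
    )
    # numeric count features (per-nucleotide Poisson rates)
    snp_rate_per_nt: float = 0.002
    mutation_rate_per_nt: float = 0.0005
    feature_rate_multiplier_per_set: Sequence[float] = (1.0,)
    # protein sequences and motif planting
    sequence_length: int = 200
    motif: str = "ELR"
    motif_rate_test: float = 0.3
    motif_rate_ref: float = 0.1
    # organism x domain tables
    n_organisms_per_kingdom: int = 10
    n_domains_per_scheme: int = 400
    domain_universality_prob: float = 0.3
    domain_presence_prob: float = 0.35
    universal_gene_prob_test: float = 0.6
    universal_gene_prob_ref: float = 0.2
    # mimicry BLAST hits
    n_mimicry_organisms: int = 10
    mimicry_plants: Sequence[MimicryPlant] = (
        MimicryPlant(0, 0.5, 0.05),
        MimicryPlant(1, 0.5, 0.05),
        MimicryPlant(2, 0.5, 0.05),
    )
    mimicry_null_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if any(s < 1 for s in self.test_set_sizes):
            raise ValueError("test-set sizes must be positive")
        if sum(self.test_set_sizes) > self.n_genes:
            raise ValueError(
                f"test sets ({sum(self.test_set_sizes)} genes) exceed the "
                f"universe ({self.n_genes} genes)"
            )
        if len(self.exon_shift_per_set) != len(self.test_set_sizes):
            raise ValueError("exon_shift_per_set must match test_set_sizes")
        if len(self.feature_rate_multiplier_per_set) != len(self.test_set_sizes):
            raise ValueError(
                "feature_rate_multiplier_per_set must match test_set_sizes"
            )
        for name in (
            "base_annotation_prob", "domain_universality_prob",
            "domain_presence_prob", "universal_gene_prob_test",
            "universal_gene_prob_ref", "motif_rate_test", "motif_rate_ref",
            "mimicry_null_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for pc in self.planted_categories:
            if not 0 <= pc.test_prob <= 1:
                raise ValueError("planted test_prob must be in [0, 1]")
            if pc.set_index >= len(self.test_set_sizes):
                raise ValueError(f"planted set_index {pc.set_index} out of range")
            if pc.namespace not in self.namespaces:
                raise ValueError(f"planted namespace {pc.namespace!r} unknown")
            if pc.category_index >= self.n_categories_per_namespace:
                raise ValueError("planted category_index out of range")
        for mp in self.mimicry_plants:
            if mp.organism_index >= self.n_mimicry_organisms:
                raise ValueError("mimicry organism_index out of range")
            if not (0 <= mp.test_prob <= 1 and 0 <= mp.ref_prob <= 1):
                raise ValueError("mimicry plant probabilities must be in [0, 1]")


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A SimConfig with every planted effect switched off."""
    defaults = dict(
        seed=seed,
        exon_shift_per_set=(0.0,),
        planted_categories=(),
        motif_rate_test=0.1,
        motif_rate_ref=0.1,
        universal_gene_prob_test=0.2,
        universal_gene_prob_ref=0.2,
        mimicry_plants=(),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def _rng(cfg: SimConfig, stream: str) -> np.random.Generator:
    """Independent, named, seed-stable substream of the master seed."""
    return np.random.default_rng([cfg.seed, zlib.crc32(stream.encode())])


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_universe(
    cfg: SimConfig,
) -> tuple[Universe, list[GeneSet], dict]:
    """Universe with log-normal exon lengths and disjoint test sets.

    Genes of test set ``i`` draw their exon length with the log-mean
    shifted by ``exon_shift_per_set[i]``.
    """
    rng = _rng(cfg, "universe")
    ids = _gene_ids(cfg.n_genes)
    log_mean = np.full(cfg.n_genes, cfg.exon_length_log_mean)

    order = rng.permutation(cfg.n_genes)
    sets: list[GeneSet] = []
    offset = 0
    membership: dict[str, list[str]] = {}
    for i, size in enumerate(cfg.test_set_sizes):
        idx = order[offset:offset + size]
        offset += size
        log_mean[idx] += cfg.exon_shift_per_set[i]
        name = f"TestSet{i + 1}"
        members = sorted(ids[j] for j in idx)
        sets.append(GeneSet(name=name, members=frozenset(members),
                            description=f"synthetic antigen set {i + 1}"))
        membership[name] = members

    lengths = np.exp(rng.normal(log_mean, cfg.exon_length_log_sd))
    universe = Universe(
        GeneRecord(g, float(lengths[j])) for j, g in enumerate(ids)
    )
    truth = {
        "exon_shift_per_set": list(cfg.exon_shift_per_set),
        "test_set_sizes": list(cfg.test_set_sizes),
        "test_sets": {name: members for name, members in membership.items()},
    }
    return universe, sets, truth


def generate_annotations(
    cfg: SimConfig,
    universe: Universe,
    sets: list[GeneSet],
) -> tuple[list[AnnotationCatalog], dict]:
    """Sparse binary annotations with planted per-set enrichments."""
    ids = sorted(universe.gene_ids)
    index = {g: j for j, g in enumerate(ids)}
    catalogs: list[AnnotationCatalog] = []
    planted_records = []
    for namespace in cfg.namespaces:
        rng = _rng(cfg, f"annotations:{namespace}")
        probs = np.full(
            (len(ids), cfg.n_categories_per_namespace), cfg.base_annotation_prob
        )
        for pc in cfg.planted_categories:
            if pc.namespace != namespace:
                continue
            rows = [index[g] for g in sets[pc.set_index].members]
            probs[rows, pc.category_index] = pc.test_prob
            planted_records.append({
                "set_name": sets[pc.set_index].name,
                "namespace": namespace,
                "category_id": f"{namespace}:cat{pc.category_index:04d}",
                "test_prob": pc.test_prob,
            })
        draws = rng.random(probs.shape) < probs
        catalog = AnnotationCatalog(namespace=namespace)
        for c in range(cfg.n_categories_per_namespace):
            members = {ids[j] for j in np.flatnonzero(draws[:, c])}
            catalog.categories[f"{namespace}:cat{c:04d}"] = members
        catalogs.append(catalog)
    truth = {
        "base_annotation_prob": cfg.base_annotation_prob,
        "planted_categories": planted_records,
    }
    return catalogs, truth


def generate_features(
    cfg: SimConfig,
    universe: Universe,
    sets: list[GeneSet],
) -> tuple[list[NumericFeatureTable], dict]:
    """Count features scaling with exon length (SNP and mutation counts).

    Counts are Poisson with mean ``rate * mean_exon_length``; genes of
    test set ``i`` have their rates multiplied by the configured per-set
    factor, so the default factor of 1 plants no density effect while the
    raw counts still inherit any exon-length shift.
    """
    rng = _rng(cfg, "features")
    ids = sorted(universe.gene_ids)
    lengths = np.array([universe.mean_exon_length(g) for g in ids])
    mult = np.ones(len(ids))
    index = {g: j for j, g in enumerate(ids)}
    for i, gs in enumerate(sets):
        for g in gs.members:
            mult[index[g]] = cfg.feature_rate_multiplier_per_set[i]
    tables = []
    feature_rates = [
        ("snp_synonymous", cfg.snp_rate_per_nt),
        ("snp_nonsynonymous", cfg.snp_rate_per_nt * 0.6),
        ("somatic_mutation_count", cfg.mutation_rate_per_nt),
    ]
    for feature_id, rate in feature_rates:
        counts = rng.poisson(rate * lengths * mult)
        tables.append(NumericFeatureTable(
            feature_id, {g: float(counts[j]) for j, g in enumerate(ids)}
        ))
    truth = {
        "feature_rate_multiplier_per_set":
            list(cfg.feature_rate_multiplier_per_set),
    }
    return tables, truth


def generate_sequences(
    cfg: SimConfig,
    universe: Universe,
    sets: list[GeneSet],
) -> tuple[dict[str, str], dict]:
    """Protein sequences with the motif inserted at per-group rates.

    Accidental motif occurrences are scrubbed before insertion, so a gene
    carries the motif exactly when the generator planted it — the ground
    truth lists those genes exactly.
    """
    rng = _rng(cfg, "sequences")
    motif = cfg.motif.upper()
    test_genes = set().union(*(gs.members for gs in sets)) if sets else set()
    sequences: dict[str, str] = {}
    planted: list[str] = []
    for gene_id in sorted(universe.gene_ids):
        letters = rng.choice(list(AMINO_ACIDS_STR), size=cfg.sequence_length)
        seq = "".join(letters)
        # scrub chance occurrences so planting is exact
        while motif in seq:
            pos = seq.index(motif)
            seq = seq[:pos + 1] + "G" + seq[pos + 2:]
        rate = cfg.motif_rate_test if gene_id in test_genes else cfg.motif_rate_ref
        if rng.random() < rate:
            pos = int(rng.integers(0, cfg.sequence_length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
            planted.append(gene_id)
        sequences[gene_id] = seq
    truth = {
        "motif": motif,
        "motif_rate_test": cfg.motif_rate_test,
        "motif_rate_ref": cfg.motif_rate_ref,
        "genes_with_motif": planted,
    }
    return sequences, truth


def generate_organism_domains(
    cfg: SimConfig,
    universe: Universe,
    sets: list[GeneSet],
) -> tuple[
    dict[str, list[OrganismDomainTable]], dict[str, dict[str, set[str]]], dict
]:
    """Per-kingdom organism x domain tables and domain -> gene maps.

    Each domain is flagged universal with ``domain_universality_prob``;
    universal domains occur in every organism, the rest occur with
    ``domain_presence_prob``. Genes join the universal gene pool with the
    test/background membership probabilities and receive one universal
    (pool) or one non-universal (background) domain accordingly.
    """
    ids = sorted(universe.gene_ids)
    test_genes = set().union(*(gs.members for gs in sets)) if sets else set()
    tables_by_scheme: dict[str, list[OrganismDomainTable]] = {}
    maps_by_scheme: dict[str, dict[str, set[str]]] = {}
    truth: dict = {"schemes": {}}
    for scheme in SCHEMES:
        rng = _rng(cfg, f"domains:{scheme}")
        n_dom = cfg.n_domains_per_scheme
        domain_ids = [f"{scheme}:dom{j:04d}" for j in range(n_dom)]
        universal_flags = rng.random(n_dom) < cfg.domain_universality_prob
        universal_idx = np.flatnonzero(universal_flags)
        other_idx = np.flatnonzero(~universal_flags)

        tables: list[OrganismDomainTable] = []
        for kingdom in KINGDOMS:
            for i in range(cfg.n_organisms_per_kingdom):
                present = universal_flags | (
                    rng.random(n_dom) < cfg.domain_presence_prob
                )
                tables.append(OrganismDomainTable(
                    organism_id=f"{scheme.lower()}_{kingdom.lower()}_{i:02d}",
                    kingdom=kingdom,
                    complete=True,
                    domains={domain_ids[j] for j in np.flatnonzero(present)},
                    scheme=scheme,
                ))
        tables_by_scheme[scheme] = tables

        mapping: dict[str, set[str]] = {d: set() for d in domain_ids}
        pool: list[str] = []
        for g in ids:
            p = (cfg.universal_gene_prob_test if g in test_genes
                 else cfg.universal_gene_prob_ref)
            if universal_idx.size and rng.random() < p:
                d = domain_ids[int(rng.choice(universal_idx))]
                pool.append(g)
            elif other_idx.size:
                d = domain_ids[int(rng.choice(other_idx))]
            else:
                d = domain_ids[int(rng.choice(universal_idx))]
                pool.append(g)
            mapping[d].add(g)
        maps_by_scheme[scheme] = {d: m for d, m in mapping.items() if m}
        truth["schemes"][scheme] = {
            "n_universal_domains": int(universal_idx.size),
            "universal_gene_pool_size": len(pool),
        }
    truth["universal_gene_prob_test"] = cfg.universal_gene_prob_test
    truth["universal_gene_prob_ref"] = cfg.universal_gene_prob_ref
    return tables_by_scheme, maps_by_scheme, truth


def generate_blast_hits(
    cfg: SimConfig,
    universe: Universe,
    sets: list[GeneSet],
) -> tuple[list[str], dict[str, str], dict[str, str], dict[str, OrganismMeta], dict]:
    """BLAST tabular rows with planted per-organism enrichment.

    Returns (rows, subject->organism map, query->gene map, organism
    metadata, ground truth). Generated scores and E-values fall on the
    keep side of the default thresholds (bit score >= 100, E <= 0.001).
    """
    rng = _rng(cfg, "mimicry")
    ids = sorted(universe.gene_ids)
    test_genes = set().union(*(gs.members for gs in sets)) if sets else set()
    plants = {mp.organism_index: mp for mp in cfg.mimicry_plants}

    organisms: dict[str, OrganismMeta] = {}
    rows: list[str] = []
    subject_organism: dict[str, str] = {}
    query_gene: dict[str, str] = {f"q_{g}": g for g in ids}
    truth_orgs = {}
    subject_serial = 0
    for i in range(cfg.n_mimicry_organisms):
        organism_id = f"mimic_org{i:02d}"
        kingdom = KINGDOMS[i % len(KINGDOMS)]
        organisms[organism_id] = OrganismMeta(organism_id, kingdom, True)
        mp = plants.get(i)
        p_test = mp.test_prob if mp else cfg.mimicry_null_prob
        p_ref = mp.ref_prob if mp else cfg.mimicry_null_prob
        hit_genes = []
        for g in ids:
            p = p_test if g in test_genes else p_ref
            if rng.random() < p:
                hit_genes.append(g)
                subject_id = f"s{subject_serial:06d}"
                subject_serial += 1
                subject_organism[subject_id] = organism_id
                identity = 40.0 + 50.0 * rng.random()
                length = int(rng.integers(80, 400))
                bit = 120.0 + 300.0 * rng.random()
                evalue = 10.0 ** (-rng.uniform(5, 30))
                rows.append(
                    f"q_{g}\t{subject_id}\t{identity:.1f}\t{length}\t"
                    f"{int(length * (1 - identity / 100))}\t0\t1\t{length}\t"
                    f"1\t{length}\t{evalue:.2e}\t{bit:.1f}"
                )
        truth_orgs[organism_id] = {
            "planted": mp is not None,
            "test_prob": p_test,
            "ref_prob": p_ref,
            "n_hit_genes": len(hit_genes),
        }
    truth = {"organisms": truth_orgs}
    return rows, subject_organism, query_gene, organisms, truth


def write_corpus(cfg: SimConfig, outdir: str | Path) -> dict:
    """Generate the full corpus and write every pipeline input to ``outdir``.

    Returns the ground-truth manifest (also written as ``manifest.json``).
    File formats are exactly those the analysis modules read.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    universe, sets, truth_u = generate_universe(cfg)
    universe.to_tsv(outdir / "universe.tsv")
    write_gmt(sets, outdir / "test_sets.gmt")

    catalogs, truth_a = generate_annotations(cfg, universe, sets)
    for catalog in catalogs:
        catalog.to_tsv(outdir / f"annotations_{catalog.namespace}.tsv")

    features, truth_f = generate_features(cfg, universe, sets)
    write_feature_tsv(features, outdir / "features.tsv")

    sequences, truth_s = generate_sequences(cfg, universe, sets)
    with (outdir / "sequences.fasta").open("w", encoding="utf-8",
                                           newline="\n") as fh:
        for gene_id in sorted(sequences):
            fh.write(f">{gene_id}\n")
            seq = sequences[gene_id]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")

    tables_by_scheme, maps_by_scheme, truth_d = generate_organism_domains(
        cfg, universe, sets
    )
    with (outdir / "organisms.tsv").open("w", encoding="utf-8",
                                         newline="\n") as fh:
        fh.write("organism_id\tkingdom\tcomplete\tscheme\n")
        for scheme in SCHEMES:
            for t in tables_by_scheme[scheme]:
                fh.write(f"{t.organism_id}\t{t.kingdom}\t"
                         f"{int(t.complete)}\t{t.scheme}\n")
    for scheme in SCHEMES:
        with (outdir / f"organism_domains_{scheme}.tsv").open(
            "w", encoding="utf-8", newline="\n"
        ) as fh:
            for t in tables_by_scheme[scheme]:
                for d in sorted(t.domains):
                    fh.write(f"{t.organism_id}\t{d}\n")
        with (outdir / f"domain_genes_{scheme}.tsv").open(
            "w", encoding="utf-8", newline="\n"
        ) as fh:
            for d in sorted(maps_by_scheme[scheme]):
                for g in sorted(maps_by_scheme[scheme][d]):
                    fh.write(f"{d}\t{g}\n")

    rows, subject_organism, query_gene, organisms, truth_m = (
        generate_blast_hits(cfg, universe, sets)
    )
    (outdir / "blast.tsv").write_text(
        "# synthetic BLAST tabular output\n" + "".join(r + "\n" for r in rows),
        encoding="utf-8",
    )
    with (outdir / "subject_organism.tsv").open("w", encoding="utf-8",
                                                newline="\n") as fh:
        for s in sorted(subject_organism):
            fh.write(f"{s}\t{subject_organism[s]}\n")
    with (outdir / "query_gene.tsv").open("w", encoding="utf-8",
                                          newline="\n") as fh:
        for q in sorted(query_gene):
            fh.write(f"{q}\t{query_gene[q]}\n")
    with (outdir / "mimicry_organisms.tsv").open("w", encoding="utf-8",
                                                 newline="\n") as fh:
        fh.write("organism_id\tkingdom\tcomplete\tscheme\n")
        for organism_id in sorted(organisms):
            meta = organisms[organism_id]
            fh.write(f"{organism_id}\t{meta.kingdom}\t"
                     f"{int(meta.complete)}\tCATH\n")

    manifest = {
        "config": _config_to_jsonable(cfg),
        "universe": truth_u,
        "annotations": truth_a,
        "features": truth_f,
        "sequences": truth_s,
        "domains": truth_d,
        "mimicry": truth_m,
    }
    with (outdir / "manifest.json").open("w", encoding="utf-8",
                                         newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _config_to_jsonable(cfg: SimConfig) -> dict:
    out = asdict(cfg)
    out["planted_categories"] = [asdict(pc) for pc in cfg.planted_categories]
    out["mimicry_plants"] = [asdict(mp) for mp in cfg.mimicry_plants]
    for key in ("test_set_sizes", "exon_shift_per_set", "namespaces",
                "feature_rate_multiplier_per_set"):
        out[key] = list(out[key])
    return out
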