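# Methods

## Overview

`agenrich` tests whether sets of antigen-encoding genes differ from the
protein-coding background in binary annotations (over-representation
analysis, ORA) and numeric features (rank-shift tests), with multiple-
testing correction and reporting filters, plus two derived analyses:
enrichment of "ancient" (universal) protein-domain gene sets and
per-organism molecular-mimicry enrichment from BLAST hit tables. The
package also contains the seeded generator that produces every input
with planted, recoverable effects.

## Test and reference sets

Antigen test sets arrive as GMT files of opaque gene identifiers; no
symbol or Entrez resolution is attempted, since identifier mapping
happens upstream of this artifact. The pooled set `ALL` is the union of
all test sets. Two reference sets are built from a gene universe (TSV of
gene id and mean exon length, in nucleotides):

* **PCG** — all universe genes minus `ALL`. Test-set members missing
  from the universe are kept in the test set with a warning; they simply
  contribute nothing to statistics that need universe attributes
  (antigen compilations routinely predate any given annotation build).
* **PCGLE** — PCG genes with mean exon length **strictly** greater than
  the threshold (default 3100 nt). The strict inequality follows the
  "greater than" definition of the set; a gene at exactly 3100 nt is
  excluded.

Before every test the test set is made disjoint from its reference
(reference construction already excludes antigens; the check is a
safety net for user-supplied references).

## ORA

For population *N*, category carriers *K*, test-set size *n* and overlap
*k*, the enrichment p-value is the hypergeometric upper tail
P(X ≥ k), evaluated through the stable survival function of
`scipy.stats.hypergeom`. Only enrichment (right tail) is offered — the
analysis questions are one-sided and a depletion mode would double the
testing burden for no use case here.

Two population conventions exist in enrichment tools. By default the
population is restricted to genes carrying ≥ 1 annotation in the tested
namespace, since unannotated genes are uninformative for that namespace;
a `FilterConfig.restrict_population=False` switch uses the full
test ∪ reference population instead. For ancient-domain and mimicry
categories the full population is always used, because membership there
is defined for every gene.

## Rank-shift (WMW) test

For a numeric feature, U counts (test, reference) pairs with
test > reference, tied pairs at weight ½ (equivalently, midrank sum
minus n₁(n₁+1)/2). When n₁+n₂ ≤ 12 the one-sided p-value is exact: all
C(n₁+n₂, n₁) equally likely assignments of the pooled values are
enumerated, which handles ties correctly by construction. Above that
limit a normal approximation is used with tie-corrected variance

Var(U) = n₁n₂/12 · [(n+1) − Σ(t³−t)/(n(n−1))]

and a 0.5 continuity correction. The cutoff of 12 keeps the exact branch
below a thousand enumerated assignments while the approximation error at
that size is already below 0.01 in p. If every pooled value is
identical the test degenerates and returns p = 1 with a warning.

Missing feature values exclude a gene from that test instead of being
imputed as 0: absence from a variant database is not evidence of zero
variants. "Normalized" count features are per-kilobase densities,
value·scale/exon_length with scale defaulting to 1000; the scale and the
denominator are config-exposed because density normalization conventions
vary between sources.

## Multiple testing and filters

Benjamini–Hochberg adjustment (step-up, adj⁽ⁱ⁾ = min_{j≥i} p⁽ʲ⁾·m/j,
capped at 1) is applied per analysis family: all categories of one
namespace for one test set; all numeric features for one test set; all
six UNIVERSAL sets for one test set; all organisms for one test set.
Joint correction across organisms is the deliberate choice for mimicry —
the analysis screens hundreds of organisms simultaneously.

A result is flagged as passing when all three hold:

* p_adj < α (strict; α default 0.05),
* K ≥ 2 within the tested population,
* prevalence k/D ≥ 5% (inclusive), where the denominator D is by
  default the number of test-set genes with ≥ 1 annotation in the
  namespace ("annotated" basis); a "test_size" basis is available by
  config. For the full-population analyses (ancient domains, mimicry)
  the denominator is the test-set size.

Nothing is deleted by filtering; every result row is written with its
flag, so the filters are auditable.

## Sequence motifs

Exact tripeptide scanning (default ELR, the Glu-Leu-Arg motif of ELR+
CXC chemokines) reports all, possibly overlapping, 1-based match
positions; scanning is case-insensitive and the wildcard residue X never
matches. Presence of ≥ 1 hit — not the count — defines the binary
category, matching the ORA framing. Granzyme-B cleavage sites and
coiled-coil segments are outputs of external predictors; they enter as
precomputed `gene_id → category` TSVs in the same "motif" namespace
rather than being re-predicted here.

## Ancient (UNIVERSAL) domain sets

Per scheme (CATH-like, Pfam-like): completely sequenced organisms with
≥ 150 annotated domains are retained (both conditions inclusive); per
kingdom, domains present in ≥ 70% of retained species (inclusive, with
an epsilon guard against float-division artifacts at the exact boundary)
are "universal"; genes carrying ≥ 1 universal domain form
UNIVERSAL_\<KINGDOM\>_\<SCHEME\>. Six sets result when both schemes are
supplied; fewer, with a warning, otherwise. Kingdom labels come from the
organism metadata TSV — no taxonomy lookups.

## Mimicry

BLAST tabular input is the standard 12-column dialect. "Similarity
score" is read as the bit score (column 12): the 12-column format
carries no raw alignment score, so exposing a raw-score switch would be
vacuous. Hits survive at bit score ≥ 100 **and** E-value ≤ 0.001 (both
inclusive), are restricted to completely sequenced organisms, and
collapse into one deduplicated hit list of human genes per organism;
organisms with zero surviving hits are omitted. Unmapped subjects or
queries drop their hits with counted warnings.

## Synthetic corpus

The generator emulates the shape of the real inputs, not their content:

* **Exon lengths** are log-normal (log-mean 8.0, log-sd 0.6), giving a
  right-skewed, strictly positive distribution with mean ≈ 3600 nt —
  the magnitude real protein-coding universes show. Test-set genes add a
  configurable shift on the log-mean (default +0.4, reproducing the
  "antigens have longer exons" signal).
* **Annotations** are sparse independent Bernoulli draws (base rate
  0.05) per gene × category; a planted category raises the probability
  to 0.5 for one test set's genes.
* **Count features** are Poisson with mean proportional to exon length,
  so raw counts inherit the length bias while per-kilobase densities are
  null unless a per-set rate multiplier is configured — mirroring the
  raw-vs-normalized contrast the PCGLE reference is designed for.
* **Sequences** are uniform random residues with the motif inserted at
  per-group rates; accidental motif occurrences are scrubbed before
  insertion so the ground truth lists motif carriers exactly.
* **Organism × domain tables**: each domain is flagged universal with
  probability 0.3; universal domains occur in every organism, others
  with probability 0.35, which keeps every synthetic organism above the
  150-domain filter at the default 400 domains per scheme. Genes join
  the universal gene pool with probability 0.6 (test) / 0.2
  (background).
* **BLAST hits** are drawn per (gene, organism) with planted
  probabilities (default: 3 of 10 organisms at 0.5 vs 0.05, the rest
  null at 0.05); generated scores and E-values fall on the keep side of
  the default thresholds so threshold tests use dedicated fixtures.

One master seed fans out into named, CRC-keyed substreams, so adding a
generator never perturbs existing outputs and identical configurations
produce byte-identical corpora. The generator does **not** emulate GO's
DAG structure, correlations between namespaces, realistic BLAST score
distributions, or overlap between antigen sets — so passing recovery
tests demonstrate correctness of the statistical machinery under
independence, not robustness to the dependency structure of real
annotation databases.

## Numerical and calibration notes

Default simulation sizes (universe 2000–2200 genes, test sets 100–200,
50–500 categories, 10 organisms per kingdom, 100 replicate seeds for
power estimates) were chosen to give planted effects ≥ 95% detection
power while keeping the full suite fast on a single CPU.

The exact one-sided hypergeometric test is conservative because its
p-values are discrete: under a null corpus the raw-p rejection rate at
α = 0.05 measures ≈ 0.034, not 0.05. Calibration is therefore asserted
two-sidedly against the per-replicate binomial standard error (500
categories per corpus) and one-sidedly — validity, rate ≤ α up to pooled
noise — against the pooled standard error. No correct exact discrete
test could match 0.05 to the pooled precision.

Determinism: every output table is sorted ((set, namespace, p_adj,
category) for results; descending max significance then lexical for
matrix rows), so result bundles are byte-identical across reruns and
across row permutations of the inputs.

## Known limitations

* Only enrichment is tested; no depletion, no GSEA-style ranked tests,
  no FWER procedures.
* The BH family boundaries and the population convention of the original
  web-tool analyses are not documented anywhere authoritative; both are
  config switches here rather than silent guesses.
* Mimicry consumes precomputed BLAST output; it never runs BLAST.
* Heat-map images are a thin rendering of the matrix TSVs; no row or
  column clustering is provided.
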