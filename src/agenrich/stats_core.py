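"""Core statistics: hypergeometric ORA, one-tailed WMW, BH correction, filters.

Two tests drive every analysis in this package:

* Over-Representation Analysis (ORA) for binary categories. With a
  population of ``N`` genes of which ``K`` carry the category, and a test
  set of ``n`` genes of which ``k`` carry it, the one-sided enrichment
  p-value is the hypergeometric upper tail ``P(X >= k)``.
* The unpaired one-tailed Wilcoxon-Mann-Whitney (WMW) test for numeric
  per-gene features, asking whether the test set's value distribution is
  shifted to the right of the reference set's.

Raw p-values are adjusted per analysis family with the Benjamini-Hochberg
step-up procedure, and ORA results are flagged against three filters:
adjusted significance (alpha, default 0.05), a minimum category size
(default 2 genes within the tested population), and a prevalence filter
(at least 5% of the test set's annotated genes must carry the category).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .gene_universe import AnnotationCatalog, GeneSet

logger = logging.getLogger("agenrich")

#: combined-sample-size limit below which the WMW p-value is computed by
#: exact enumeration of rank assignments rather than a normal approximation
WMW_EXACT_LIMIT = 12


@dataclass
class FilterConfig:
    """Significance and reporting filters applied to ORA results."""

    alpha: float = 0.05
    min_category_size: int = 2
    prevalence_fraction: float = 0.05
    #: prevalence denominator: "annotated" = test genes with >=1 annotation
    #: in the namespace; "test_size" = all test genes in the population
    prevalence_basis: str = "annotated"
    #: restrict the ORA population to genes with >=1 annotation in the
    #: tested namespace (unannotated genes are uninformative there)
    restrict_population: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_category_size < 1:
            raise ValueError("min_category_size must be >= 1")
        if not 0 <= self.prevalence_fraction <= 1:
            raise ValueError("prevalence_fraction must be in [0, 1]")
        if self.prevalence_basis not in ("annotated", "test_size"):
            raise ValueError(f"unknown prevalence_basis {self.prevalence_basis!r}")


@dataclass
class OraResult:
    """One (test set x category) over-representation test."""

    set_name: str
    namespace: str
    category_id: str
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adjusted: float = float("nan")
    prevalence: float = float("nan")
    passes_filters: bool = False


@dataclass
class WmwResult:
    """One (test set x numeric feature) rank-shift test (direction: greater)."""

    set_name: str
    feature_id: str
    n_test: int
    n_ref: int
    u_statistic: float
    p_raw: float
    p_adjusted: float = float("nan")
    direction: str = "greater"
    n_missing_test: int = 0
    n_missing_ref: int = 0


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    ``X`` counts category members among ``n`` draws without replacement
    from a population of ``N`` genes containing ``K`` category members.
    """
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"require 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X > k-1) = P(X >= k); scipy computes this stably
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def ora_test(
    test: GeneSet,
    reference: GeneSet,
    category_members: set[str],
    namespace_universe: set[str],
    *,
    set_name: str | None = None,
    namespace: str = "",
    category_id: str = "",
) -> OraResult:
    """One-sided over-representation test of a binary category.

    The population is ``(test ∪ reference) ∩ namespace_universe``; test
    genes outside the namespace universe do not count toward ``n``.
    """
    if test.members & reference.members:
        raise ValueError(
            f"test set {test.name!r} and reference {reference.name!r} overlap"
        )
    population = (test.members | reference.members) & namespace_universe
    if not population:
        raise ValueError("empty population: no test/reference gene in namespace")
    n_set = test.members & population
    if not n_set:
        raise ValueError(f"no gene of test set {test.name!r} is in the population")
    cat = category_members & population
    N = len(population)
    K = len(cat)
    n = len(n_set)
    k = len(cat & n_set)
    return OraResult(
        set_name=set_name if set_name is not None else test.name,
        namespace=namespace,
        category_id=category_id,
        N=N, K=K, n=n, k=k,
        p_raw=hypergeom_tail(k, N, K, n),
    )


def _u_statistic(test_values: np.ndarray, ref_values: np.ndarray) -> float:
    """Mann-Whitney U for the test sample via midranks."""
    pooled = np.concatenate([test_values, ref_values])
    ranks = sps.rankdata(pooled)
    n1 = len(test_values)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def wmw_test(
    test_values: Sequence[float],
    ref_values: Sequence[float],
    *,
    exact_limit: int = WMW_EXACT_LIMIT,
    set_name: str = "",
    feature_id: str = "",
) -> WmwResult:
    """Unpaired one-tailed WMW test for a rightward shift of the test sample.

    ``U`` counts (test, ref) pairs with test > ref, tied pairs at half
    weight. For small samples (combined size <= ``exact_limit``) the
    p-value is exact, from enumeration of all equally likely assignments
    of the pooled values to the two groups; otherwise a normal
    approximation with midranks, tie-corrected variance and continuity
    correction is used.
    """
    x = np.asarray(test_values, dtype=float)
    y = np.asarray(ref_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wmw_test requires non-empty samples on both sides")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    ntot = n1 + n2

    if tie_counts.size == 1:
        # every value identical in both groups: no evidence of any shift
        logger.warning("wmw_test: all values identical across both groups")
        p = 1.0
    elif ntot <= exact_limit:
        # permutation-exact: every subset of positions equally likely under H0
        offset = n1 * (n1 + 1) / 2.0
        count = 0
        total = 0
        for idx in itertools.combinations(range(ntot), n1):
            u_perm = ranks[list(idx)].sum() - offset
            if u_perm >= u_obs - 1e-9:
                count += 1
            total += 1
        p = count / total
    else:
        mu = n1 * n2 / 2.0
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / (ntot * (ntot - 1))
        var = n1 * n2 / 12.0 * ((ntot + 1) - tie_term)
        z = (u_obs - mu - 0.5) / math.sqrt(var)
        p = float(sps.norm.sf(z))
    return WmwResult(
        set_name=set_name, feature_id=feature_id,
        n_test=n1, n_ref=n2, u_statistic=u_obs,
        p_raw=min(max(p, 0.0), 1.0),
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, in the input order.

    For sorted ``p_(1) <= ... <= p_(m)`` the adjusted value is
    ``min_{j >= i} p_(j) * m / j``, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must all lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj.tolist()


def apply_filters(
    results: list[OraResult],
    cfg: FilterConfig,
    prevalence_denominator: int,
) -> list[OraResult]:
    """Set ``prevalence`` and ``passes_filters`` on each result in place.

    A result passes when its adjusted p is strictly below alpha, the
    category holds at least ``min_category_size`` genes of the tested
    population, and the prevalence ``k / denominator`` reaches the
    prevalence fraction (inclusive). Nothing is deleted.
    """
    if prevalence_denominator < 1:
        raise ValueError("prevalence_denominator must be >= 1")
    for r in results:
        r.prevalence = r.k / prevalence_denominator
        r.passes_filters = (
            r.p_adjusted < cfg.alpha
            and r.K >= cfg.min_category_size
            and r.prevalence >= cfg.prevalence_fraction
        )
    return results


def ora_analysis(
    test: GeneSet,
    reference: GeneSet,
    catalog: AnnotationCatalog,
    cfg: FilterConfig | None = None,
) -> list[OraResult]:
    """Run the ORA of one test set against every category of a namespace.

    All categories of the namespace form one BH family. The population is
    restricted to annotated genes unless ``cfg.restrict_population`` is
    off, and the prevalence denominator follows ``cfg.prevalence_basis``.
    """
    cfg = cfg or FilterConfig()
    if cfg.restrict_population:
        namespace_universe = catalog.annotated_genes
    else:
        namespace_universe = test.members | reference.members
    population = (test.members | reference.members) & namespace_universe
    test_in_pop = test.members & population
    if cfg.prevalence_basis == "annotated":
        denominator = len(test_in_pop & catalog.annotated_genes)
    else:
        denominator = len(test_in_pop)
    denominator = max(denominator, 1)

    results = [
        ora_test(
            test, reference, members, namespace_universe,
            namespace=catalog.namespace, category_id=category_id,
        )
        for category_id, members in sorted(catalog.categories.items())
    ]
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adjusted):
        r.p_adjusted = a
    apply_filters(results, cfg, denominator)
    return sort_ora_results(results)


def sort_ora_results(results: list[OraResult]) -> list[OraResult]:
    """Deterministic result order: set, namespace, adjusted p, category."""
    return sorted(
        results,
        key=lambda r: (r.set_name, r.namespace, r.p_adjusted, r.category_id),
    )


ORA_TSV_COLUMNS = (
    "set_name", "namespace", "category_id", "N", "K", "n", "k",
    "p_raw", "p_adjusted", "prevalence", "passes_filters",
)


def ora_results_to_tsv(results: Iterable[OraResult], path: str | Path) -> None:
    """Write ORA results as the sorted, byte-stable results TSV."""
    rows = sort_ora_results(list(results))
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ORA_TSV_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.set_name}\t{r.namespace}\t{r.category_id}\t"
                f"{r.N}\t{r.K}\t{r.n}\t{r.k}\t"
                f"{r.p_raw:.6e}\t{r.p_adjusted:.6e}\t{r.prevalence:.6f}\t"
                f"{int(r.passes_filters)}\n"
            )


def wmw_results_to_tsv(results: Iterable[WmwResult], path: str | Path) -> None:
    rows = sorted(results, key=lambda r: (r.set_name, r.p_adjusted, r.feature_id))
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "set_name\tfeature_id\tn_test\tn_ref\tu_statistic\t"
            "p_raw\tp_adjusted\tdirection\n"
        )
        for r in rows:
            fh.write(
                f"{r.set_name}\t{r.feature_id}\t{r.n_test}\t{r.n_ref}\t"
                f"{r.u_statistic:.6g}\t{r.p_raw:.6e}\t{r.p_adjusted:.6e}\t"
                f"{r.direction}\n"
            )
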