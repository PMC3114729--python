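"""Cumulative-binomial enrichment of annotation classes and pathways.

The statistic for a class observed x times in a subset of size n, with
background frequency p, is the binomial tail.  The upper tail
P(X >= x) is the enrichment p-value (values near zero mean the class
is over-represented in the subset); the lower tail P(X <= x) measures
depletion.  Both tails are always computed.  Three modes are provided:

* annotation classes in an organism's expressed genes against its
  genome-wide annotation frequency;
* pathways against the enzyme functions expressed by both organisms
  (the shared-activity mode);
* pathways against genes carrying enzyme functions expressed by only
  one organism (the unique-activity mode).

No multiple-testing correction is applied; the number of tests run is
recorded so users can post-correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .types import (
    AnnotationTable,
    GeneCatalog,
    Organism,
    PathwayDefinition,
    matching_ecs,
)


@dataclass(frozen=True)
class EnrichmentQuery:
    annot: str   # annotation code or pathway id
    x: int       # successes in the subset
    n: int       # subset size
    p: float     # background success probability

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError(f"{self.annot}: need 0 <= x <= n, got x={self.x}, n={self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"{self.annot}: p must lie in [0, 1], got {self.p}")


@dataclass
class EnrichmentResult:
    query: EnrichmentQuery
    pvalue_enrich: float
    pvalue_deplete: float
    coverage: float           # fraction of the class's members observed
    organism: Organism | None = None
    extras: dict = field(default_factory=dict)
    reported: bool = False


def cbd(x: int, n: int, p: float) -> float:
    """Cumulative binomial distribution P(X <= x), X ~ Binomial(n, p).

    Computed through the regularized incomplete beta function, stable
    for n well beyond 1e5.
    """
    EnrichmentQuery("cbd", x, n, p)  # domain validation
    return float(stats.binom.cdf(x, n, p))


def depletion_pvalue(x: int, n: int, p: float) -> float:
    """Lower-tail P(X <= x): small values mean the class is depleted."""
    return cbd(x, n, p)


def enrichment_pvalue(x: int, n: int, p: float) -> float:
    """Upper-tail P(X >= x): small values mean the class is enriched."""
    EnrichmentQuery("enrich", x, n, p)
    if x == 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, p))


def _result(annot: str, x: int, n: int, p: float, coverage: float, **kw) -> EnrichmentResult:
    q = EnrichmentQuery(annot, x, n, p)
    return EnrichmentResult(
        query=q,
        pvalue_enrich=enrichment_pvalue(x, n, p),
        pvalue_deplete=depletion_pvalue(x, n, p),
        coverage=coverage,
        **kw,
    )


# ---------------------------------------------------------------------------
# mode 1: annotation classes in expressed genes vs. the genome
# ---------------------------------------------------------------------------

def annotation_enrichment(
    expressed_genes: Iterable[str],
    annot_table: AnnotationTable,
    catalog: GeneCatalog,
    class_code: str,
    organism: Organism,
) -> EnrichmentResult:
    """Is *class_code* over-represented among one organism's expressed genes?

    x = expressed members of the class, n = expressed genes of the
    organism, p = genomic frequency of the class in that organism.
    ``coverage`` is the fraction of the class's genomic members seen
    expressed (the "% expressed" of a transporter report).
    """
    genome = catalog.gene_ids_of(organism)
    expressed = set(expressed_genes) & genome
    class_members = annot_table.genes_with(class_code) & genome
    x = len(expressed & class_members)
    n = len(expressed)
    if not class_members:
        raise ValueError(
            f"class {class_code!r} has no members in the {organism.value} genome"
        )
    p = len(class_members) / len(genome)
    coverage = x / len(class_members)
    res = _result(class_code, x, n, p, coverage, organism=organism)
    res.extras["n_genomic"] = len(class_members)
    return res


# ---------------------------------------------------------------------------
# mode 2: pathways enriched for enzyme functions expressed by both organisms
# ---------------------------------------------------------------------------

def pathway_enrichment_shared(
    ecs_a: Iterable[str],
    ecs_b: Iterable[str],
    pathways: Sequence[PathwayDefinition],
) -> list[EnrichmentResult]:
    """Pathway enrichment over the shared expressed enzyme functions.

    x = pathway functions expressed by both organisms, n = all shared
    expressed functions, p = pathway size over the total number of
    functions expressed by either organism.  ``extras['pct_shared']``
    is x over the pathway functions expressed by either organism;
    ``coverage`` is x over the full pathway size.
    """
    ecs_a, ecs_b = set(ecs_a), set(ecs_b)
    shared = ecs_a & ecs_b
    union = ecs_a | ecs_b
    results: list[EnrichmentResult] = []
    if not union:
        return results
    n = len(shared)
    for pw in pathways:
        in_pw_shared = matching_ecs(pw.ec_set, shared)
        in_pw_either = matching_ecs(pw.ec_set, union)
        x = len(in_pw_shared)
        if x == 0:
            continue
        p = min(1.0, len(pw.ec_set) / len(union))
        coverage = x / len(pw.ec_set)
        res = _result(pw.pathway_id, x, n, p, coverage)
        res.extras["pct_shared"] = x / len(in_pw_either) if in_pw_either else 0.0
        res.extras["name"] = pw.name
        res.extras["class"] = pw.class_label
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# mode 3: pathways enriched for functions unique to one organism
# ---------------------------------------------------------------------------

def pathway_enrichment_unique(
    ecs_only: Iterable[str],
    expressed_genes: Iterable[str],
    ec_annotations: AnnotationTable,
    catalog: GeneCatalog,
    organism: Organism,
    pathways: Sequence[PathwayDefinition],
) -> list[EnrichmentResult]:
    """Pathway enrichment for one organism's partner-absent functions.

    A success is an expressed gene of the organism carrying an enzyme
    function that (a) the partner does not express and (b) maps to the
    pathway.  n = the organism's expressed genes; the background p is
    the genomic frequency of genes mapping to the pathway.
    ``coverage`` (``extras['unique_fraction']``) is the fraction of the
    pathway's functions among the organism-unique set.
    """
    ecs_only = set(ecs_only)
    genome = catalog.gene_ids_of(organism)
    expressed = set(expressed_genes) & genome
    results: list[EnrichmentResult] = []
    if not ecs_only or not expressed:
        return results
    n = len(expressed)
    for pw in pathways:
        unique_in_pw = matching_ecs(pw.ec_set, ecs_only)
        if not unique_in_pw:
            continue
        genomic_mappers = {
            g for g in genome if matching_ecs(pw.ec_set, ec_annotations.codes_of(g))
        }
        if not genomic_mappers:
            continue
        successes = {
            g
            for g in expressed
            if matching_ecs(unique_in_pw, ec_annotations.codes_of(g))
        }
        x = len(successes)
        p = len(genomic_mappers) / len(genome)
        unique_fraction = len(unique_in_pw) / len(pw.ec_set)
        res = _result(pw.pathway_id, x, n, p, unique_fraction, organism=organism)
        res.extras["unique_fraction"] = unique_fraction
        res.extras["name"] = pw.name
        res.extras["class"] = pw.class_label
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report_filter(
    results: Iterable[EnrichmentResult],
    alpha: float = 0.01,
    min_coverage: float = 0.25,
) -> list[EnrichmentResult]:
    """Keep results significant at *alpha* whose coverage is at least
    *min_coverage*; marks ``reported`` on every input."""
    kept: list[EnrichmentResult] = []
    for res in results:
        res.reported = res.pvalue_enrich < alpha and res.coverage >= min_coverage
        if res.reported:
            kept.append(res)
    return kept
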