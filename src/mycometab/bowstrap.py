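"""Bootstrap-style significance calling of gene expression from
all-alignments short-read data.

A read that aligns to several candidate locations is, at each
iteration, assigned uniformly at random to one of them; per-gene RPKM
is recomputed each iteration, and the across-iteration mean (mu) and
standard deviation (sigma) feed a cumulative-normal p-value

    p = Phi(-mu / sigma)

i.e. the probability mass the bootstrap-normal places at or below zero
expression.  Degenerate cases follow an explicit precedence: mu = 0
gives p = 1 (nothing observed), else sigma = 0 gives p = 0 (constant
non-zero signal).  A gene is called expressed when p falls below the
significance threshold, by default in every biological replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneCatalog, MultiAlignmentSet, Organism

RPKM_DENOMINATORS = ("mapped_reads", "library_reads")


@dataclass
class BowstrapConfig:
    iterations: int = 1000
    rpkm_denominator: str = "mapped_reads"
    alpha: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.rpkm_denominator not in RPKM_DENOMINATORS:
            raise ValueError(f"rpkm_denominator must be one of {RPKM_DENOMINATORS}")


@dataclass(frozen=True)
class ExpressionEstimate:
    gene_id: str
    mu: float        # mean RPKM across iterations
    sigma: float     # population SD of RPKM across iterations
    se: float        # sigma / sqrt(iterations), reported alongside
    pvalue: float
    expressed: bool


class ExpressionTable:
    """Per-gene bootstrap expression estimates covering the whole catalog."""

    def __init__(
        self,
        estimates: Mapping[str, ExpressionEstimate],
        config: BowstrapConfig,
        total_reads: int,
        mapped_reads: int,
    ) -> None:
        self.estimates = dict(estimates)
        self.config = config
        self.total_reads = total_reads
        self.mapped_reads = mapped_reads

    def __getitem__(self, gene_id: str) -> ExpressionEstimate:
        return self.estimates[gene_id]

    def __len__(self) -> int:
        return len(self.estimates)

    def expressed_genes(self, alpha: float | None = None) -> set[str]:
        alpha = self.config.alpha if alpha is None else alpha
        return {g for g, e in self.estimates.items() if e.pvalue < alpha}

    def to_dataframe(self, catalog: GeneCatalog | None = None) -> pd.DataFrame:
        rows = []
        for g, e in self.estimates.items():
            organism = catalog[g].organism.value if catalog is not None else ""
            rows.append((g, organism, e.mu, e.sigma, e.se, e.pvalue, e.expressed))
        return pd.DataFrame(
            rows, columns=["gene_id", "organism", "mu", "sigma", "se", "pvalue", "expressed"]
        )

    def write_tsv(self, path: str | Path, catalog: GeneCatalog | None = None) -> None:
        df = self.to_dataframe(catalog)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_expression_tsv(path: str | Path, config: BowstrapConfig | None = None) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    config = config or BowstrapConfig()
    est = {
        r.gene_id: ExpressionEstimate(
            r.gene_id, float(r.mu), float(r.sigma), float(r.se), float(r.pvalue), bool(r.expressed)
        )
        for r in df.itertuples()
    }
    return ExpressionTable(est, config, total_reads=0, mapped_reads=0)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def rpkm(count: float, length_bp: int, denominator_reads: int) -> float:
    """Reads per kilobase of gene model per million reads."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if denominator_reads < 1:
        raise ValueError("denominator_reads must be >= 1")
    return count / (length_bp / 1e3) / (denominator_reads / 1e6)


def cnd_pvalue(mu: float, sigma: float) -> float:
    """Cumulative-normal p-value of zero expression.

    Precedence: mu = 0 -> 1, else sigma = 0 -> 0, else Phi(-mu/sigma).
    """
    if mu < 0 or sigma < 0:
        raise ValueError("mu and sigma must be non-negative")
    if mu == 0:
        return 1.0
    if sigma == 0:
        return 0.0
    return float(stats.norm.sf(mu / sigma))


# ---------------------------------------------------------------------------
# iteration machinery
# ---------------------------------------------------------------------------

class _CompiledAlignments:
    """Alignment set flattened into numpy arrays for fast resampling.

    Assignment is uniform over candidate *locations*; several locations
    within the same gene all credit that gene, so a read whose
    candidates all fall in one gene is effectively unique.
    """

    def __init__(self, alignments: MultiAlignmentSet, catalog: GeneCatalog) -> None:
        index = {gid: i for i, gid in enumerate(catalog.gene_ids)}
        self.n_genes = len(catalog)
        base = np.zeros(self.n_genes, dtype=np.int64)
        flat: list[int] = []
        offsets: list[int] = [0]
        for rid, locs in alignments.reads.items():
            gidx = [index[loc.gene_id] for loc in locs]
            if len(set(gidx)) == 1:
                base[gidx[0]] += 1
            else:
                flat.extend(gidx)
                offsets.append(len(flat))
        self.base_counts = base
        self.multi_flat = np.asarray(flat, dtype=np.int64)
        self.multi_offsets = np.asarray(offsets, dtype=np.int64)
        self.n_multi = len(offsets) - 1
        self.mapped_reads = alignments.n_mapped
        # genes whose count can vary across iterations
        self.variable_genes = np.unique(self.multi_flat) if self.n_multi else np.array([], dtype=np.int64)

    def draw_counts(self, rng: np.random.Generator) -> np.ndarray:
        counts = self.base_counts.copy()
        if self.n_multi:
            widths = np.diff(self.multi_offsets)
            picks = self.multi_offsets[:-1] + rng.integers(0, widths)
            chosen = self.multi_flat[picks]
            counts += np.bincount(chosen, minlength=self.n_genes)
        return counts


def assign_iteration(
    alignments: MultiAlignmentSet,
    catalog: GeneCatalog,
    rng: np.random.Generator,
) -> np.ndarray:
    """One bootstrap draw: per-gene read counts in catalog order.

    Each read contributes exactly 1 to exactly one gene, chosen
    uniformly over its candidate locations, so the counts sum to the
    number of mapped reads.
    """
    return _CompiledAlignments(alignments, catalog).draw_counts(rng)


def run_bowstrap(
    alignments: MultiAlignmentSet,
    catalog: GeneCatalog,
    config: BowstrapConfig,
) -> ExpressionTable:
    """Full bootstrap expression calling, deterministic given the seed.

    Per-iteration RNG streams are spawned from one master seed, so
    results do not depend on execution order.
    """
    comp = _CompiledAlignments(alignments, catalog)
    gene_ids = catalog.gene_ids
    lengths = np.array([catalog[g].length_bp for g in gene_ids], dtype=np.float64)
    denom = (
        comp.mapped_reads
        if config.rpkm_denominator == "mapped_reads"
        else alignments.total_reads_in_library
    )
    if denom == 0:
        estimates = {
            g: ExpressionEstimate(g, 0.0, 0.0, 0.0, 1.0, False) for g in gene_ids
        }
        return ExpressionTable(estimates, config, alignments.total_reads_in_library, 0)

    scale = 1e9 / (lengths * denom)  # count -> RPKM
    base_rpkm = comp.base_counts * scale

    b = config.iterations
    var_idx = comp.variable_genes
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(b)]
    if len(var_idx):
        # store per-iteration counts only for genes multireads can touch
        var_counts = np.empty((b, len(var_idx)), dtype=np.int64)
        pos_of = {g: i for i, g in enumerate(var_idx)}
        widths = np.diff(comp.multi_offsets)
        for it, rng in enumerate(streams):
            picks = comp.multi_offsets[:-1] + rng.integers(0, widths)
            chosen = comp.multi_flat[picks]
            extra = np.bincount(chosen, minlength=comp.n_genes)
            var_counts[it] = extra[var_idx]
        var_rpkm = (var_counts + comp.base_counts[var_idx]) * scale[var_idx]
        var_mu = var_rpkm.mean(axis=0)
        var_sigma = var_rpkm.std(axis=0)  # population SD (divisor B)
    else:
        var_mu = var_sigma = np.array([])

    mu = base_rpkm.copy()
    sigma = np.zeros_like(mu)
    if len(var_idx):
        mu[var_idx] = var_mu
        sigma[var_idx] = var_sigma

    se = sigma / np.sqrt(b)
    estimates: dict[str, ExpressionEstimate] = {}
    for i, g in enumerate(gene_ids):
        p = cnd_pvalue(float(mu[i]), float(sigma[i]))
        estimates[g] = ExpressionEstimate(
            g, float(mu[i]), float(sigma[i]), float(se[i]), p, p < config.alpha
        )
    return ExpressionTable(
        estimates, config, alignments.total_reads_in_library, comp.mapped_reads
    )


# ---------------------------------------------------------------------------
# replicate handling and diagnostics
# ---------------------------------------------------------------------------

def intersect_replicates(tables: Sequence[ExpressionTable], alpha: float | None = None) -> set[str]:
    """Genes significant at *alpha* in every biological replicate."""
    if len(tables) < 2:
        raise ValueError("need at least two replicate tables")
    gene_sets = [set(t.estimates) for t in tables]
    if any(s != gene_sets[0] for s in gene_sets[1:]):
        raise ValueError("replicate tables cover different gene catalogs")
    out = tables[0].expressed_genes(alpha)
    for t in tables[1:]:
        out &= t.expressed_genes(alpha)
    return out


def overlap_significance(set_a: set, set_b: set, universe_size: int) -> float:
    """Hypergeometric upper-tail probability of the observed overlap.

    Probability of drawing at least ``|A & B|`` members of A when
    sampling ``|B|`` items without replacement from the universe.
    """
    n_a, n_b = len(set_a), len(set_b)
    if n_a > universe_size or n_b > universe_size:
        raise ValueError("set sizes exceed the universe")
    k = len(set_a & set_b)
    if k > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    return float(stats.hypergeom.sf(k - 1, universe_size, n_a, n_b))


def alignment_accounting(
    genemodel_alignments: MultiAlignmentSet,
    genome_alignments: MultiAlignmentSet | None = None,
    total_reads: int | None = None,
) -> dict[str, float | None]:
    """Fractions of reads by alignment category.

    Categories: gene_model_only, genome_only, both, neither (a
    partition of the read universe) plus multi_location, the fraction
    of reads with more than one candidate gene-model location.  Genome
    categories are ``None`` when no genome alignment set is supplied.
    """
    total = total_reads if total_reads is not None else genemodel_alignments.total_reads_in_library
    if total < 1:
        raise ValueError("total_reads must be >= 1")
    gm_reads = set(genemodel_alignments.reads)
    if len(gm_reads) > total:
        raise ValueError("more mapped reads than reads in the library")
    multi = len(genemodel_alignments.multiread_ids()) / total
    if genome_alignments is None:
        return {
            "gene_model_only": None,
            "genome_only": None,
            "both": None,
            "neither": None,
            "gene_model": len(gm_reads) / total,
            "multi_location": multi,
        }
    if genome_alignments.total_reads_in_library not in (0, total):
        raise ValueError("gene-model and genome alignment sets cover different read universes")
    gn_reads = set(genome_alignments.reads)
    both = len(gm_reads & gn_reads)
    gm_only = len(gm_reads - gn_reads)
    gn_only = len(gn_reads - gm_reads)
    neither = total - len(gm_reads | gn_reads)
    return {
        "gene_model_only": gm_only / total,
        "genome_only": gn_only / total,
        "both": both / total,
        "neither": neither / total,
        "gene_model": len(gm_reads) / total,
        "multi_location": multi,
    }
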