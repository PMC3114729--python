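"""Synthetic fixtures with planted ground truth.

Everything the pipeline consumes can be generated here: a two-organism
gene catalog, all-alignments SAM libraries with controlled
multimapping, annotation tables with planted enriched classes, a toy
reaction database with a designed exchange economy, and pathway
definitions with planted coverage.  Each generator records its own
truth so downstream modules can be scored without re-reading the plan.

Reads are emitted directly as alignment records: candidate locations
are planted, not re-discovered by an aligner, which gives exact control
of the multimapping structure.  Multimapping is modelled through
duplicated gene pairs — two identical gene copies whose reads align to
both — mirroring how paralogs produce multireads in real catalogs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_io import (
    write_annotation_table,
    write_gene_fasta,
    write_pathway_table,
    write_reaction_table,
    write_transporter_map,
)
from .enrichment import EnrichmentQuery, EnrichmentResult
from .exchange import GO_ALLANTOIN_TRANSPORT, default_transporter_map
from .types import (
    AnnotationTable,
    CandidateLocation,
    GeneCatalog,
    GeneModel,
    MultiAlignmentSet,
    Organism,
    PathwayDefinition,
    ReactionRecord,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationPlan:
    """Study conditions for the synthetic experiment.

    Defaults emulate the shape of a deep dual-organism mRNA-seq study
    at desk scale: two catalogs of 100 gene models, 50,000 aligned
    46-bp reads, 18% of reads multi-mapped (82% unique), and roughly
    60% of gene models transcribed.
    """

    n_genes_a: int = 100
    n_genes_b: int = 100
    length_range: tuple[int, int] = (500, 3000)
    n_reads: int = 50_000
    read_length: int = 46
    multimapped_fraction: float = 0.18
    n_duplicate_pairs_a: int = 9
    n_duplicate_pairs_b: int = 9
    silent_fraction: float = 0.4       # gene models with no transcription
    expression_log_sigma: float = 1.0  # lognormal spread of expression levels
    unmapped_fraction: float = 0.0
    replicate_dispersion: float = 0.05  # lognormal jitter on weights between replicates
    seed: int = 0
    # planted annotation classes (organism A unless noted)
    enriched_class_code: str = "GO:0099999"
    enriched_class_size: int = 24       # all expressed -> strong enrichment
    null_class_code: str = "GO:0088888"
    null_class_size: int = 20
    # planted pathway-coverage structure
    n_toy_pathways: int = 10
    n_detected_pathways: int = 6

    def __post_init__(self) -> None:
        for name in ("multimapped_fraction", "silent_fraction", "unmapped_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_genes_a", "n_genes_b", "n_reads", "read_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.length_range[0] < self.read_length:
            raise ValueError("minimum gene length must be at least the read length")
        for org, n_genes, n_pairs in (
            ("a", self.n_genes_a, self.n_duplicate_pairs_a),
            ("b", self.n_genes_b, self.n_duplicate_pairs_b),
        ):
            active = n_genes - round(self.silent_fraction * n_genes)
            if 2 * n_pairs > active:
                raise ValueError(
                    f"plan infeasible: organism {org} has {active} transcribed genes "
                    f"but needs {2 * n_pairs} for duplicate pairs"
                )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationPlan":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["length_range"] = tuple(d["length_range"])
        return cls(**d)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLibrary:
    """One sequencing library: alignments plus per-read and per-gene truth."""

    alignments: MultiAlignmentSet
    read_sequences: dict[str, str]
    read_truth: pd.DataFrame   # read_id, source_gene, n_candidates
    gene_truth: pd.DataFrame   # gene_id, organism, length_bp, true_count, true_rpkm, se_rpkm, ...

    def write_sam(self, path: str | Path, catalog: GeneCatalog) -> None:
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for gid in catalog.gene_ids:
                fh.write(f"@SQ\tSN:{gid}\tLN:{catalog[gid].length_bp}\n")
            for rid in self.read_sequences:
                seq = self.read_sequences[rid]
                locs = self.alignments.reads.get(rid)
                if locs is None:
                    fh.write(f"{rid}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                    continue
                for i, loc in enumerate(locs):
                    flag = 0 if i == 0 else 256
                    fh.write(
                        f"{rid}\t{flag}\t{loc.gene_id}\t{loc.start + 1}\t255\t"
                        f"{len(seq)}M\t*\t0\t0\t{seq}\t*\n"
                    )


@dataclass
class SimulatedExperiment:
    plan: SimulationPlan
    catalog: GeneCatalog
    sequences: dict[str, str]
    duplicate_pairs: list[tuple[str, str]]
    silent_genes: set[str]
    libraries: list[SimulatedLibrary]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for org, key in ((Organism.A, "fasta_a"), (Organism.B, "fasta_b")):
            p = outdir / f"catalog_{org.value}.fasta"
            write_gene_fasta(
                {g.gene_id: self.sequences[g.gene_id] for g in self.catalog.genes(org)}, p
            )
            paths[key] = p
        for i, lib in enumerate(self.libraries, start=1):
            p = outdir / f"rep{i}.sam"
            lib.write_sam(p, self.catalog)
            paths[f"sam_rep{i}"] = p
            lib.gene_truth.to_csv(
                outdir / f"rep{i}.gene_truth.tsv", sep="\t", index=False, float_format="%.10g"
            )
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _simulate_catalog(plan: SimulationPlan, rng: np.random.Generator):
    catalog = GeneCatalog()
    sequences: dict[str, str] = {}
    silent: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for org, n_genes, n_pairs in (
        (Organism.A, plan.n_genes_a, plan.n_duplicate_pairs_a),
        (Organism.B, plan.n_genes_b, plan.n_duplicate_pairs_b),
    ):
        ids = [f"{org.value}{i:04d}" for i in range(1, n_genes + 1)]
        n_silent = round(plan.silent_fraction * n_genes)
        silent_here = set(rng.choice(ids, size=n_silent, replace=False)) if n_silent else set()
        active = [g for g in ids if g not in silent_here]
        pair_members = list(rng.choice(active, size=2 * n_pairs, replace=False))
        pairs_here = [(pair_members[2 * i], pair_members[2 * i + 1]) for i in range(n_pairs)]
        lengths = {g: int(rng.integers(plan.length_range[0], plan.length_range[1] + 1)) for g in ids}
        seqs = {g: _random_seq(rng, lengths[g]) for g in ids}
        for g1, g2 in pairs_here:  # identical duplicated copies
            lengths[g2] = lengths[g1]
            seqs[g2] = seqs[g1]
        for g in ids:
            catalog.add(GeneModel(g, org, lengths[g]))
            sequences[g] = seqs[g]
        silent |= silent_here
        pairs.extend(pairs_here)
    return catalog, sequences, silent, pairs


def _group_weights(plan, catalog, silent, pairs, rng):
    """Expression weight per 'group' (a duplicate pair, or a single gene).

    Duplicate-pair groups jointly carry the planted multimapped read
    mass; members of a pair share it equally.
    """
    pair_of = {g: i for i, (g1, g2) in enumerate(pairs) for g in (g1, g2)}
    gene_ids = catalog.gene_ids
    raw = np.exp(rng.normal(0.0, plan.expression_log_sigma, size=len(gene_ids)))
    weights = np.zeros(len(gene_ids))
    dup_mask = np.array([g in pair_of for g in gene_ids])
    active_mask = np.array([g not in silent for g in gene_ids])
    # one draw per pair, split equally between members
    pair_draw = np.exp(rng.normal(0.0, plan.expression_log_sigma, size=len(pairs)))
    for i, g in enumerate(gene_ids):
        if not active_mask[i]:
            continue
        if g in pair_of:
            weights[i] = pair_draw[pair_of[g]] / 2.0
        else:
            weights[i] = raw[i]
    dup_total = weights[dup_mask].sum()
    rest_total = weights[~dup_mask].sum()
    f = plan.multimapped_fraction
    if dup_total > 0:
        weights[dup_mask] *= f / dup_total
    if rest_total > 0:
        weights[~dup_mask] *= (1.0 - f) / rest_total
    return weights / weights.sum(), pair_of


def _build_library(plan, catalog, sequences, pairs, pair_of, weights, rng, denom_is_mapped=True):
    gene_ids = catalog.gene_ids
    n_mapped = plan.n_reads - round(plan.unmapped_fraction * plan.n_reads)
    counts = rng.multinomial(n_mapped, weights)
    partner = {}
    for g1, g2 in pairs:
        partner[g1], partner[g2] = g2, g1

    reads: dict[str, list[CandidateLocation]] = {}
    read_seqs: dict[str, str] = {}
    truth_rows = []
    rid_n = 0
    for gi, g in enumerate(gene_ids):
        c = int(counts[gi])
        if c == 0:
            continue
        length = catalog[g].length_bp
        starts = rng.integers(0, length - plan.read_length + 1, size=c)
        for s in starts:
            rid_n += 1
            rid = f"r{rid_n:07d}"
            s = int(s)
            locs = [CandidateLocation(g, s, "+")]
            if g in pair_of:
                # identical copy: the same read aligns at the same offset in the twin
                locs.append(CandidateLocation(partner[g], s, "+"))
            reads[rid] = locs
            read_seqs[rid] = sequences[g][s : s + plan.read_length]
            truth_rows.append((rid, g, len(locs)))
    for _ in range(plan.n_reads - n_mapped):
        rid_n += 1
        rid = f"r{rid_n:07d}"
        read_seqs[rid] = _random_seq(rng, plan.read_length)
        truth_rows.append((rid, "", 0))

    denom = n_mapped if denom_is_mapped else plan.n_reads
    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "organism": [catalog[g].organism.value for g in gene_ids],
            "length_bp": [catalog[g].length_bp for g in gene_ids],
            "true_count": counts,
            "true_rpkm": counts * 1e9 / (np.array([catalog[g].length_bp for g in gene_ids]) * denom),
            "se_rpkm": np.sqrt(counts) * 1e9
            / (np.array([catalog[g].length_bp for g in gene_ids]) * denom),
            "duplicated": [g in pair_of for g in gene_ids],
            "expressed": counts > 0,
        }
    )
    read_truth = pd.DataFrame(truth_rows, columns=["read_id", "source_gene", "n_candidates"])
    alignments = MultiAlignmentSet(reads=reads, total_reads_in_library=plan.n_reads)
    return SimulatedLibrary(alignments, read_seqs, read_truth, gene_truth)


def simulate_reads(plan: SimulationPlan, n_replicates: int = 1) -> SimulatedExperiment:
    """Generate the catalog and one or more read libraries.

    Biological replicates share the underlying expression weights, each
    jittered by a lognormal factor with spread
    ``plan.replicate_dispersion`` before read counts are redrawn.
    Deterministic given ``plan.seed``.
    """
    master = np.random.SeedSequence(plan.seed)
    s_cat, s_weights, *s_reps = master.spawn(2 + n_replicates)
    rng_cat = np.random.default_rng(s_cat)
    catalog, sequences, silent, pairs = _simulate_catalog(plan, rng_cat)
    weights, pair_of = _group_weights(plan, catalog, silent, pairs, np.random.default_rng(s_weights))

    libraries = []
    for s_rep in s_reps:
        rng = np.random.default_rng(s_rep)
        w = weights
        if plan.replicate_dispersion > 0:
            jitter = np.exp(rng.normal(0.0, plan.replicate_dispersion, size=len(weights)))
            # keep duplicate-pair members jittered in lockstep
            for g1, g2 in pairs:
                i1 = catalog.gene_ids.index(g1)
                i2 = catalog.gene_ids.index(g2)
                jitter[i2] = jitter[i1]
            w = weights * jitter
            w = w / w.sum()
        libraries.append(_build_library(plan, catalog, sequences, pairs, pair_of, w, rng))
    return SimulatedExperiment(plan, catalog, sequences, pairs, silent, libraries)


def reversed_read_control(reads: Iterable[str]) -> list[str]:
    """Reverse (not reverse-complement) every read.

    The control preserves each read's length and nucleotide
    composition while destroying its biological sequence, providing a
    specificity baseline for alignment: reversed reads should almost
    never align.
    """
    out = []
    for r in reads:
        if set(r) - set("ACGTN"):
            raise ValueError(f"read contains non-nucleotide characters: {r!r}")
        out.append(r[::-1])
    return out


# ---------------------------------------------------------------------------
# hand-built miniature symbiosis (toy exchange economy)
# ---------------------------------------------------------------------------

# compound ids (KEGG-style)
SUCROSE, GLUCOSE, FRUCTOSE = "C00089", "C00031", "C00095"
G6P, F6P = "C00668", "C00085"
OXOGLUTARATE, AMMONIA, GLUTAMATE = "C00026", "C00014", "C00025"
OXALOACETATE, ASPARTATE = "C00036", "C00049"
SERINE, THF, GLYCINE, CH2THF = "C00065", "C00101", "C00037", "C00143"
CO2, URATE, ALLANTOIN, ALLANTOATE = "C00011", "C00366", "C01551", "C00499"
UREIDOGLYCOLATE, UREA = "C00603", "C00086"


@dataclass
class ToySymbiosis:
    """A miniature two-partner metabolic economy with a designed answer.

    Organism A (the autotroph) uniquely hydrolyses sucrose into
    hexoses; organism B (the heterotroph) uniquely synthesizes
    glutamate, glycine and the ureide allantoin.  Hexose transport is
    enriched in B, amino-acid transport in both; ammonium and phosphate
    transport are not enriched.  The designed exchange set is
    {glucose, fructose} from A and {glutamate, glycine, allantoin}
    from B.  Allantoin utilization is expected outside the sampled
    tissue, so it rides the consumption allow-list.
    """

    reactions: list[ReactionRecord]
    ecs_a: set[str]
    ecs_b: set[str]
    transporter_map: dict[str, tuple[str, frozenset[str]]]
    transporter_enrichment: list[EnrichmentResult]
    consumption_allowlist: set[str]
    expected_exchange: dict[str, Organism]
    pathways: list[PathwayDefinition] = field(default_factory=list)


def _evidence(code: str, organism: Organism, p: float) -> EnrichmentResult:
    return EnrichmentResult(
        query=EnrichmentQuery(code, 0, 0, 0.0),
        pvalue_enrich=p,
        pvalue_deplete=1.0 - p,
        coverage=1.0,
        organism=organism,
    )


def _rx(rid, ecs, subs, prods, rev=False):
    return ReactionRecord(
        rid, frozenset(ecs), frozenset(subs), frozenset(prods), reversible=rev
    )


def toy_symbiosis() -> ToySymbiosis:
    reactions = [
        # organism A: sucrose hydrolysis and amino-acid utilization
        _rx("R_INV", ["3.2.1.26"], [SUCROSE], [GLUCOSE, FRUCTOSE]),          # invertase
        _rx("R_AAT", ["2.6.1.1"], [GLUTAMATE, OXALOACETATE], [ASPARTATE, OXOGLUTARATE]),
        _rx("R_GCS", ["1.4.4.2"], [GLYCINE, THF], [AMMONIA, CO2, CH2THF]),   # glycine cleavage
        # organism B: hexose uptake metabolism and nitrogen anabolism
        _rx("R_HK", ["2.7.1.1"], [GLUCOSE], [G6P]),                          # hexokinase
        _rx("R_FK", ["2.7.1.4"], [FRUCTOSE], [F6P]),                         # fructokinase
        _rx("R_GDH", ["1.4.1.2"], [OXOGLUTARATE, AMMONIA], [GLUTAMATE]),     # glutamate dehydrogenase
        _rx("R_SHMT", ["2.1.2.1"], [SERINE, THF], [GLYCINE, CH2THF]),        # serine hydroxymethyltransferase
        _rx("R_UOX", ["1.7.3.3"], [URATE], [ALLANTOIN, CO2]),                # urate oxidase
        _rx("R_ALN", ["3.5.2.5"], [ALLANTOIN], [ALLANTOATE]),                # allantoinase
        _rx("R_ALC", ["3.5.3.4"], [ALLANTOATE], [UREIDOGLYCOLATE, UREA]),    # allantoicase
        _rx("R_URE", ["3.5.1.5"], [UREA], [AMMONIA, CO2]),                   # urease
        # shared housekeeping step
        _rx("R_PGI", ["5.3.1.9"], [G6P], [F6P], rev=True),                   # phosphoglucose isomerase
        # genomic capacity never expressed by either partner
        _rx("R_NIT", ["1.7.99.4"], ["C00244"], ["C00088"]),                  # nitrate reductase
    ]
    ecs_a = {"3.2.1.26", "2.6.1.1", "1.4.4.2", "5.3.1.9"}
    ecs_b = {
        "2.7.1.1", "2.7.1.4", "1.4.1.2", "2.1.2.1",
        "1.7.3.3", "3.5.2.5", "3.5.3.4", "3.5.1.5", "5.3.1.9",
    }
    tmap = default_transporter_map()
    tmap[GO_ALLANTOIN_TRANSPORT] = ("allantoin transport", frozenset({ALLANTOIN}))
    evidence = [
        _evidence("GO:0006865", Organism.A, 0.031),  # amino acid transport, enriched in both
        _evidence("GO:0006865", Organism.B, 0.038),
        _evidence("GO:0005351", Organism.A, 0.372),  # sugar porter, enriched only in B
        _evidence("GO:0005351", Organism.B, 0.023),
        _evidence("GO:0008519", Organism.A, 0.567),  # ammonium transport, not enriched
        _evidence("GO:0008519", Organism.B, 0.116),
        _evidence("GO:0005315", Organism.A, 0.519),  # phosphate transport, not enriched
        _evidence("GO:0005315", Organism.B, 0.130),
        _evidence(GO_ALLANTOIN_TRANSPORT, Organism.B, 0.020),
    ]
    pathways = [
        PathwayDefinition(
            "TOY00330", "amino acid metabolism", frozenset({"1.4.1.2", "2.6.1.1", "2.1.2.1", "1.4.4.2"}),
            "Amino Acid Metabolism",
        ),
        PathwayDefinition(
            "TOY00500", "sugar metabolism",
            frozenset({"3.2.1.26", "2.7.1.1", "2.7.1.4", "5.3.1.9"}),
            "Carbohydrate Metabolism",
        ),
        PathwayDefinition(
            "TOY00230", "ureide metabolism",
            frozenset({"1.7.3.3", "3.5.2.5", "3.5.3.4", "3.5.1.5"}),
            "Nucleotide Metabolism",
        ),
    ]
    return ToySymbiosis(
        reactions=reactions,
        ecs_a=ecs_a,
        ecs_b=ecs_b,
        transporter_map=tmap,
        transporter_enrichment=evidence,
        consumption_allowlist={ALLANTOIN},
        expected_exchange={
            GLUCOSE: Organism.A,
            FRUCTOSE: Organism.A,
            GLUTAMATE: Organism.B,
            GLYCINE: Organism.B,
            ALLANTOIN: Organism.B,
        },
        pathways=pathways,
    )


# ---------------------------------------------------------------------------
# planted annotation / pathway fixtures
# ---------------------------------------------------------------------------

@dataclass
class PlantedEnrichment:
    """Pure-set enrichment fixture: a genome, an expressed subset, one
    strongly enriched class and one null class, with recorded truth."""

    genome: list[str]
    expressed: set[str]
    enriched_class: set[str]
    null_class: set[str]
    truth: dict

    def as_tables(self, class_code="GO:0099999", null_code="GO:0088888"):
        catalog = GeneCatalog(GeneModel(g, Organism.A, 1000) for g in self.genome)
        table = AnnotationTable(kind="GO")
        for g in sorted(self.enriched_class):
            table.add(g, class_code)
        for g in sorted(self.null_class):
            table.add(g, null_code)
        return catalog, table


def plant_enrichment_sets(
    n_genome: int = 5000,
    n_expressed: int = 500,
    class_size: int = 40,
    class_expressed: int = 30,
    null_size: int = 40,
    seed: int = 0,
) -> PlantedEnrichment:
    rng = np.random.default_rng(seed)
    genome = [f"g{i:05d}" for i in range(n_genome)]
    expressed = set(rng.choice(genome, size=n_expressed, replace=False))
    silent = [g for g in genome if g not in expressed]
    enriched = set(rng.choice(sorted(expressed), size=class_expressed, replace=False))
    enriched |= set(rng.choice(silent, size=class_size - class_expressed, replace=False))
    null_class = set(rng.choice(genome, size=null_size, replace=False))
    return PlantedEnrichment(
        genome=genome,
        expressed=expressed,
        enriched_class=enriched,
        null_class=null_class,
        truth={
            "x": class_expressed,
            "n": n_expressed,
            "p": class_size / n_genome,
            "coverage": class_expressed / class_size,
        },
    )


@dataclass
class SimulatedAnnotations:
    """Annotation, pathway, reaction and transporter fixtures tied to a
    simulated catalog, with the planted truth recorded."""

    ec_table: AnnotationTable
    go_table: AnnotationTable
    reactions: list[ReactionRecord]
    pathways: list[PathwayDefinition]
    transporter_map: dict[str, tuple[str, frozenset[str]]]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ec": outdir / "ec_annotations.tsv",
            "go": outdir / "go_annotations.tsv",
            "reactions": outdir / "reactions.tsv",
            "pathways": outdir / "pathways.tsv",
            "transporters": outdir / "transporters.tsv",
        }
        write_annotation_table(self.ec_table, paths["ec"])
        write_annotation_table(self.go_table, paths["go"])
        write_reaction_table(self.reactions, paths["reactions"])
        write_pathway_table(self.pathways, paths["pathways"])
        write_transporter_map(self.transporter_map, paths["transporters"])
        return paths


# transporter classes planted in the simulated GO table:
# (code, organism, members, expressed members) — amino-acid transport is
# planted enriched in both organisms, sugar porters only in B, ammonium
# proportional to the background (null).
_PLANTED_TRANSPORTERS = [
    ("GO:0006865", Organism.A, 14, 14),
    ("GO:0006865", Organism.B, 14, 14),
    ("GO:0005351", Organism.A, 10, 6),
    ("GO:0005351", Organism.B, 14, 14),
    ("GO:0015720", Organism.B, 14, 14),
    ("GO:0008519", Organism.A, 10, 6),
    ("GO:0008519", Organism.B, 10, 6),
    ("GO:0005315", Organism.A, 4, 2),
    ("GO:0005315", Organism.B, 2, 1),
]


def simulate_annotations(
    plan: SimulationPlan,
    catalog: GeneCatalog,
    expressed_a: set[str],
    expressed_b: set[str],
    seed: int | None = None,
) -> SimulatedAnnotations:
    """Plant annotations over a simulated catalog.

    EC codes realize the toy symbiosis on the expressed genes of each
    organism (so the reaction network and exchange prediction have a
    designed answer); GO codes plant transporter classes with the toy's
    enrichment pattern plus one strongly enriched and one null generic
    class; pathways carry a planted detected/undetected coverage split.
    """
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    toy = toy_symbiosis()
    ec_table = AnnotationTable(kind="EC")
    go_table = AnnotationTable(kind="GO")

    per_org = {
        Organism.A: (sorted(expressed_a), sorted(catalog.gene_ids_of(Organism.A) - expressed_a)),
        Organism.B: (sorted(expressed_b), sorted(catalog.gene_ids_of(Organism.B) - expressed_b)),
    }

    # EC planting: each expressed function goes on two expressed genes
    for org, ecs in ((Organism.A, toy.ecs_a), (Organism.B, toy.ecs_b)):
        expressed, _ = per_org[org]
        slots = list(expressed)
        for k, ec in enumerate(sorted(ecs)):
            for j in range(2):
                ec_table.add(slots[(2 * k + j) % len(slots)], ec)
    # genomic-only capacity: the never-expressed function sits on silent genes
    for org in (Organism.A, Organism.B):
        _, silent = per_org[org]
        if silent:
            ec_table.add(silent[0], "1.7.99.4")

    planted_classes = []
    for code, org, n_members, n_expr in _PLANTED_TRANSPORTERS:
        expressed, silent = per_org[org]
        members = list(rng.choice(expressed, size=n_expr, replace=False))
        members += list(rng.choice(silent, size=n_members - n_expr, replace=False))
        for g in members:
            go_table.add(g, code)
        planted_classes.append(
            {"code": code, "organism": org.value, "n_members": n_members, "n_expressed": n_expr}
        )
    # generic enriched / null classes on organism A
    expressed, silent = per_org[Organism.A]
    for g in rng.choice(expressed, size=plan.enriched_class_size, replace=False):
        go_table.add(g, plan.enriched_class_code)
    frac = len(expressed) / (len(expressed) + len(silent))
    n_null_expr = round(plan.null_class_size * frac)
    null_members = list(rng.choice(expressed, size=n_null_expr, replace=False))
    null_members += list(rng.choice(silent, size=plan.null_class_size - n_null_expr, replace=False))
    for g in null_members:
        go_table.add(g, plan.null_class_code)

    # pathways with planted coverage: detected ones carry 3 expressed
    # functions out of 10, the rest only 1
    expressed_ecs = sorted(toy.ecs_a | toy.ecs_b)
    pathways = []
    dummy_n = 0
    for i in range(plan.n_toy_pathways):
        detected = i < plan.n_detected_pathways
        n_expr_ecs = 3 if detected else 1
        ecs = list(rng.choice(expressed_ecs, size=n_expr_ecs, replace=False))
        while len(ecs) < 10:
            dummy_n += 1
            ecs.append(f"9.9.{1 + dummy_n // 100}.{1 + dummy_n % 100}")
        pathways.append(
            PathwayDefinition(f"TOYPW{i:02d}", f"planted pathway {i}", frozenset(ecs), "planted")
        )

    truth = {
        "planted_transporters": planted_classes,
        "enriched_class": {"code": plan.enriched_class_code, "size": plan.enriched_class_size},
        "null_class": {"code": plan.null_class_code, "size": plan.null_class_size},
        "detected_pathway_fraction": plan.n_detected_pathways / plan.n_toy_pathways,
        "expected_exchange": {c: o.value for c, o in toy.expected_exchange.items()},
        "consumption_allowlist": sorted(toy.consumption_allowlist),
        "n_reactions_included": len(toy.reactions) - 1,  # R_NIT stays out
        "toy_ecs_a": sorted(toy.ecs_a),
        "toy_ecs_b": sorted(toy.ecs_b),
    }
    return SimulatedAnnotations(
        ec_table=ec_table,
        go_table=go_table,
        reactions=toy.reactions,
        pathways=pathways,
        transporter_map=toy.transporter_map,
        truth=truth,
    )
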