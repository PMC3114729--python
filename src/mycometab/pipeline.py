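"""End-to-end orchestration: expression calling per replicate,
replicate intersection, enrichment, network construction and exchange
prediction, with table-style reports and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bowstrap import BowstrapConfig, intersect_replicates, run_bowstrap
from .data_io import (
    read_annotation_table,
    read_gene_catalog,
    read_multialignments,
    read_pathway_table,
    read_reaction_table,
    read_transporter_map,
    write_network,
)
from .enrichment import (
    annotation_enrichment,
    pathway_enrichment_shared,
    pathway_enrichment_unique,
    report_filter,
)
from .exchange import annotate_network_highlights, predict_exchange
from .metabolome import build_network, pathway_coverage, unique_function_partition
from .types import Organism

log = logging.getLogger("mycometab")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        yield
    except Exception as e:  # noqa: BLE001 - abort naming the stage
        raise PipelineError(name, e) from e
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one run; serializes to/from YAML."""

    fasta_a: str
    fasta_b: str
    sam_replicates: list[str]
    ec_annotations: str
    go_annotations: str
    reactions: str
    pathways: str
    transporter_map: str
    outdir: str = "results"
    iterations: int = 1000
    rpkm_denominator: str = "mapped_reads"
    alpha_expr: float = 0.001      # per-replicate expression call
    alpha_report: float = 0.01     # enrichment reporting
    coverage_min: float = 0.25     # enrichment reporting
    transporter_gate: float = 0.05  # exchange criterion 2
    pathway_detect: float = 0.30   # pathway-coverage detection
    partner_depth: int = 1
    consumption_allowlist: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_expr", "alpha_report", "coverage_min", "transporter_gate",
                     "pathway_detect"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if len(self.sam_replicates) < 1:
            raise ValueError("at least one SAM replicate is required")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.outdir``.

    Deterministic: identical config, inputs and seed yield bit-identical
    outputs and manifest digests.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    bundle: dict = {"outputs": outputs}

    with _stage("bowstrap"):
        catalog = read_gene_catalog(
            [(config.fasta_a, Organism.A), (config.fasta_b, Organism.B)]
        )
        tables = []
        for i, sam in enumerate(config.sam_replicates, start=1):
            aln = read_multialignments(sam, catalog)
            bs_cfg = BowstrapConfig(
                iterations=config.iterations,
                rpkm_denominator=config.rpkm_denominator,
                alpha=config.alpha_expr,
                seed=config.seed + i,
            )
            table = run_bowstrap(aln, catalog, bs_cfg)
            p = outdir / f"expression_rep{i}.tsv"
            table.write_tsv(p, catalog)
            outputs[f"expression_rep{i}"] = p
            tables.append(table)
        if len(tables) > 1:
            expressed = intersect_replicates(tables, config.alpha_expr)
        else:
            expressed = tables[0].expressed_genes()
        expressed_df = pd.DataFrame(
            {
                "gene_id": sorted(expressed),
                "organism": [catalog[g].organism.value for g in sorted(expressed)],
            }
        )
        p = outdir / "expressed_genes.tsv"
        _write_tsv(expressed_df, p)
        outputs["expressed_genes"] = p
        bundle["expression_tables"] = tables
        bundle["expressed_genes"] = expressed

    with _stage("enrichment"):
        ec_table = read_annotation_table(config.ec_annotations, "EC", catalog)
        go_table = read_annotation_table(config.go_annotations, "GO", catalog)
        pathways = read_pathway_table(config.pathways)
        tmap = read_transporter_map(config.transporter_map)

        expressed_by_org = {o: expressed & catalog.gene_ids_of(o) for o in Organism}
        ecs = {
            o: ec_table.codes_over(expressed_by_org[o]) for o in Organism
        }

        # per-class annotation enrichment (every GO class with genomic members)
        annot_results = []
        for org in Organism:
            genome = catalog.gene_ids_of(org)
            codes = sorted(go_table.codes_over(genome))
            for code in codes:
                annot_results.append(
                    annotation_enrichment(expressed, go_table, catalog, code, org)
                )
        rows = [
            {
                "code": r.query.annot,
                "organism": r.organism.value,
                "n_genomic": r.extras["n_genomic"],
                "pct_expressed": 100.0 * r.coverage,
                "pvalue": r.pvalue_enrich,
                "transporter_class": r.query.annot in tmap,
            }
            for r in annot_results
        ]
        annot_df = pd.DataFrame(rows)
        p = outdir / "annotation_report.tsv"
        _write_tsv(annot_df, p)
        outputs["annotation_report"] = p
        transporter_results = [r for r in annot_results if r.query.annot in tmap]
        trans_df = annot_df[annot_df["transporter_class"]].drop(columns="transporter_class")
        trans_df.insert(0, "name", [tmap[c][0] for c in trans_df["code"]])
        p = outdir / "transporter_report.tsv"
        _write_tsv(trans_df, p)
        outputs["transporter_report"] = p

        shared_results = pathway_enrichment_shared(ecs[Organism.A], ecs[Organism.B], pathways)
        report_filter(shared_results, config.alpha_report, config.coverage_min)
        shared_df = pd.DataFrame(
            {
                "pathway": [r.query.annot for r in shared_results],
                "name": [r.extras["name"] for r in shared_results],
                "pct_shared": [100.0 * r.extras["pct_shared"] for r in shared_results],
                "pvalue": [r.pvalue_enrich for r in shared_results],
                "coverage": [r.coverage for r in shared_results],
                "reported": [r.reported for r in shared_results],
            }
        )
        p = outdir / "pathway_shared.tsv"
        _write_tsv(shared_df, p)
        outputs["pathway_shared"] = p

        only_a, only_b, _ = unique_function_partition(ecs[Organism.A], ecs[Organism.B])
        for org, only in ((Organism.A, only_a), (Organism.B, only_b)):
            uniq = pathway_enrichment_unique(
                only, expressed_by_org[org], ec_table, catalog, org, pathways
            )
            report_filter(uniq, config.alpha_report, config.coverage_min)
            df = pd.DataFrame(
                {
                    "pathway": [r.query.annot for r in uniq],
                    "name": [r.extras["name"] for r in uniq],
                    "unique_pct": [100.0 * r.extras["unique_fraction"] for r in uniq],
                    "pvalue": [r.pvalue_enrich for r in uniq],
                    "reported": [r.reported for r in uniq],
                }
            )
            p = outdir / f"pathway_unique_{org.value}.tsv"
            _write_tsv(df, p)
            outputs[f"pathway_unique_{org.value}"] = p
        bundle["ecs"] = ecs
        bundle["transporter_results"] = transporter_results
        bundle["annotation_results"] = annot_results

    with _stage("metabolome"):
        reactions = read_reaction_table(config.reactions)
        network = build_network(ecs[Organism.A], ecs[Organism.B], reactions)
        counts = network.counts
        p = outdir / "network_counts.tsv"
        _write_tsv(pd.DataFrame([counts]), p)
        outputs["network_counts"] = p

        coverage, detected_fraction = pathway_coverage(
            network.ecs_a | network.ecs_b, pathways, config.pathway_detect
        )
        cov_df = pd.DataFrame(
            [
                {"pathway": pid, **{k: v for k, v in d.items()}}
                for pid, d in coverage.items()
            ]
        )
        p = outdir / "pathway_coverage.tsv"
        _write_tsv(cov_df, p)
        outputs["pathway_coverage"] = p
        bundle["network"] = network
        bundle["detected_pathway_fraction"] = detected_fraction

    with _stage("exchange"):
        candidates = predict_exchange(
            network,
            transporter_results,
            tmap,
            gate=config.transporter_gate,
            partner_depth=config.partner_depth,
            consumption_allowlist=config.consumption_allowlist,
        )
        cand_df = pd.DataFrame(
            {
                "compound": [c.compound_id for c in candidates],
                "producer": [c.producer.value for c in candidates],
                "producing_reactions": [";".join(c.producing_reactions) for c in candidates],
                "transporter_evidence": [
                    ";".join(f"{code}|{org}|{p:.4g}" for code, org, p in c.transporter_evidence)
                    for c in candidates
                ],
                "consuming_reactions": [";".join(c.consuming_reactions) for c in candidates],
                "via_allowlist": [c.via_allowlist for c in candidates],
            }
        )
        p = outdir / "exchange_candidates.tsv"
        _write_tsv(cand_df, p)
        outputs["exchange_candidates"] = p

        graph = network.to_networkx()
        annotate_network_highlights(graph, tmap, candidates)
        for fmt in ("graphml", "sif"):
            for written in write_network(graph, outdir / "network", fmt):
                outputs[f"network_{fmt}"] = written
        bundle["candidates"] = candidates

    with _stage("manifest"):
        cfg = asdict(config)
        # paths are captured by the input digests; keep only the
        # scientific parameters so manifests compare across directories
        for path_field in ("outdir", "fasta_a", "fasta_b", "sam_replicates",
                           "ec_annotations", "go_annotations", "reactions",
                           "pathways", "transporter_map"):
            cfg.pop(path_field)
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": cfg,
            "input_digests": {
                name: _sha256(getattr(config, name))
                for name in (
                    "fasta_a", "fasta_b", "ec_annotations", "go_annotations",
                    "reactions", "pathways", "transporter_map",
                )
            }
            | {f"sam_rep{i}": _sha256(s) for i, s in enumerate(config.sam_replicates, 1)},
            "output_digests": {
                name: _sha256(path) for name, path in sorted(outputs.items())
            },
        }
        p = outdir / "manifest.json"
        with open(p, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["manifest"] = p
        bundle["manifest"] = manifest

    return bundle
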