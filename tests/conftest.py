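import numpy as np
import pytest

from mycometab.pipeline import PipelineConfig, run_pipeline
from mycometab.simulate import (
    SimulationPlan,
    simulate_annotations,
    simulate_reads,
    toy_symbiosis,
)
from mycometab.types import Organism


@pytest.fixture(scope="session")
def toy():
    return toy_symbiosis()


@pytest.fixture(scope="session")
def small_plan():
    return SimulationPlan(n_reads=6000, seed=5)


@pytest.fixture(scope="session")
def small_experiment(small_plan):
    return simulate_reads(small_plan, n_replicates=2)


def expressed_truth(experiment):
    """Genes with at least one planted read in every replicate, per organism."""
    per_org = {}
    frames = [lib.gene_truth.set_index("gene_id") for lib in experiment.libraries]
    for org in Organism:
        genes = experiment.catalog.gene_ids_of(org)
        per_org[org] = {
            g for g in genes if all(f.loc[g, "true_count"] > 0 for f in frames)
        }
    return per_org


@pytest.fixture(scope="session")
def fixture_bundle(small_plan, small_experiment, tmp_path_factory):
    """Synthetic input files plus a pipeline config, written once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = small_experiment.write(outdir)
    truth = expressed_truth(small_experiment)
    ann = simulate_annotations(
        small_plan, small_experiment.catalog, truth[Organism.A], truth[Organism.B]
    )
    paths.update(ann.write(outdir))
    config = PipelineConfig(
        fasta_a=str(paths["fasta_a"]),
        fasta_b=str(paths["fasta_b"]),
        sam_replicates=[str(paths["sam_rep1"]), str(paths["sam_rep2"])],
        ec_annotations=str(paths["ec"]),
        go_annotations=str(paths["go"]),
        reactions=str(paths["reactions"]),
        pathways=str(paths["pathways"]),
        transporter_map=str(paths["transporters"]),
        outdir=str(outdir / "results"),
        iterations=150,
        consumption_allowlist=ann.truth["consumption_allowlist"],
        seed=small_plan.seed,
    )
    return {
        "paths": paths,
        "config": config,
        "annotations": ann,
        "experiment": small_experiment,
        "expressed_truth": truth,
        "outdir": outdir,
    }


@pytest.fixture(scope="session")
def pipeline_bundle(fixture_bundle):
    bundle = run_pipeline(fixture_bundle["config"])
    bundle["fixture"] = fixture_bundle
    return bundle


# ---------------------------------------------------------------------------
# independent brute-force oracle for the three exchange criteria
# ---------------------------------------------------------------------------

def exchange_oracle(reactions, ecs_a, ecs_b, transporter_map, evidence_p, gate,
                    allowlist=frozenset()):
    """Re-derive exchange candidates by plain scans of the raw reaction table.

    ``evidence_p`` maps (class_code, organism) -> enrichment p-value.
    Depth-1 semantics: the partner must directly consume the compound.
    Returns a set of (compound_id, producer) pairs.
    """
    expressed = set(ecs_a) | set(ecs_b)
    out = set()
    for producer, mine, theirs in (
        (Organism.A, set(ecs_a), set(ecs_b)),
        (Organism.B, set(ecs_b), set(ecs_a)),
    ):
        unique_mine = mine - theirs
        for rx in reactions:
            rx_expressed = {ec for ec in rx.ec_set if ec in expressed}
            if not rx_expressed or not rx_expressed <= unique_mine:
                continue  # criterion 1 fails for this reaction
            made = set(rx.products) | (set(rx.substrates) if rx.reversible else set())
            for compound in made:
                transported = False
                for code, (_, subs) in transporter_map.items():
                    if compound not in subs:
                        continue
                    for org in (Organism.A, Organism.B):
                        if evidence_p.get((code, org), 1.0) < gate:
                            transported = True
                if not transported:
                    continue  # criterion 2 fails
                consumed = False
                for rx2 in reactions:
                    inputs = set(rx2.substrates) | (
                        set(rx2.products) if rx2.reversible else set()
                    )
                    if compound in inputs and rx2.ec_set & theirs:
                        consumed = True
                        break
                if consumed or compound in allowlist:
                    out.add((compound, producer))
    return out


def toy_evidence_p(toy):
    return {
        (r.query.annot, r.organism): r.pvalue_enrich for r in toy.transporter_enrichment
    }
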