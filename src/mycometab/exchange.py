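"""Prediction of metabolites exchanged between the two symbionts.

A compound is an exchange candidate for a producer organism when three
criteria hold simultaneously:

1. it is produced by at least one reaction whose expressed catalyzing
   functions are all unique to the producer;
2. it is a known substrate of a membrane-transporter class whose
   expression is enriched (below the configured gate) in either
   organism;
3. the partner organism expresses at least one reaction consuming it
   (within a configurable reaction depth), or the compound is on an
   explicit consumption allow-list for cases where utilization is
   expected in tissues outside the sampled material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enrichment import EnrichmentResult
from .metabolome import MetabolomeNetwork, Provenance, ReactionEdge
from .types import Organism

# GO classes used for the default transporter -> substrate map
GO_AMINO_ACID_TRANSPORT = "GO:0006865"
GO_AMMONIUM_TRANSPORT = "GO:0008519"
GO_SUGAR_PORTER = "GO:0005351"
GO_PHOSPHATE_TRANSPORT = "GO:0005315"
GO_ALLANTOIN_TRANSPORT = "GO:0015720"

_PROTEINOGENIC_AA = frozenset(
    {
        "C00037",  # glycine
        "C00041",  # L-alanine
        "C00065",  # L-serine
        "C00188",  # L-threonine
        "C00097",  # L-cysteine
        "C00183",  # L-valine
        "C00123",  # L-leucine
        "C00407",  # L-isoleucine
        "C00073",  # L-methionine
        "C00148",  # L-proline
        "C00079",  # L-phenylalanine
        "C00082",  # L-tyrosine
        "C00078",  # L-tryptophan
        "C00049",  # L-aspartate
        "C00025",  # L-glutamate
        "C00152",  # L-asparagine
        "C00064",  # L-glutamine
        "C00047",  # L-lysine
        "C00062",  # L-arginine
        "C00135",  # L-histidine
    }
)

_HEXOSES_AND_SUGARS = frozenset(
    {
        "C00031",  # D-glucose
        "C00095",  # D-fructose
        "C00089",  # sucrose
        "C00124",  # D-galactose
        "C00159",  # D-mannose
    }
)


def default_transporter_map() -> dict[str, tuple[str, frozenset[str]]]:
    """Shipped transporter-class -> substrate-compound mapping.

    Keys are GO class codes; values are (display name, compound ids).
    Fully user-overridable: any mapping of the same shape is accepted
    by :func:`predict_exchange`.
    """
    return {
        GO_SUGAR_PORTER: ("sugar porter activity", _HEXOSES_AND_SUGARS),
        GO_AMINO_ACID_TRANSPORT: ("amino acid transport", _PROTEINOGENIC_AA),
        GO_AMMONIUM_TRANSPORT: (
            "ammonium transporter activity",
            frozenset({"C00014", "C01342"}),  # ammonia, ammonium
        ),
        GO_PHOSPHATE_TRANSPORT: (
            "inorganic phosphate transporter activity",
            frozenset({"C00009"}),  # orthophosphate
        ),
    }


@dataclass
class ExchangeCandidate:
    compound_id: str
    producer: Organism
    producing_reactions: list[str]
    transporter_evidence: list[tuple[str, str, float]]  # (class_code, organism, p_enrich)
    consuming_reactions: list[str]
    criteria_met: tuple[bool, bool, bool] = (True, True, True)
    via_allowlist: bool = False

    @property
    def best_transporter_p(self) -> float:
        return min(p for *_, p in self.transporter_evidence)


def _outputs(edge: ReactionEdge) -> frozenset[str]:
    rx = edge.reaction
    return rx.products | rx.substrates if rx.reversible else rx.products


def _inputs(edge: ReactionEdge) -> frozenset[str]:
    rx = edge.reaction
    return rx.substrates | rx.products if rx.reversible else rx.substrates


def _partner_expresses(edge: ReactionEdge, partner: Organism) -> bool:
    unique = Provenance.A_ONLY if partner is Organism.A else Provenance.B_ONLY
    return any(p in (unique, Provenance.SHARED) for p in edge.ec_provenance.values())


def _consumed_within_depth(
    compound: str,
    partner_edges: Sequence[ReactionEdge],
    all_edges: Sequence[ReactionEdge],
    depth: int,
) -> list[str]:
    """Reactions through which the partner consumes *compound*, searching
    up to *depth* reaction steps through the included network."""
    frontier = {compound}
    visited: set[str] = set()
    for _ in range(depth):
        hits = [e.reaction.reaction_id for e in partner_edges if _inputs(e) & frontier]
        if hits:
            return sorted(hits)
        visited |= frontier
        nxt: set[str] = set()
        for e in all_edges:
            if _inputs(e) & frontier:
                nxt |= _outputs(e)
        frontier = nxt - visited
        if not frontier:
            break
    return []


def predict_exchange(
    network: MetabolomeNetwork,
    enrichment_results: Iterable[EnrichmentResult],
    transporter_map: Mapping[str, tuple[str, frozenset[str]]],
    gate: float = 0.05,
    partner_depth: int = 1,
    consumption_allowlist: Iterable[str] = (),
) -> list[ExchangeCandidate]:
    """Apply the three exchange criteria to every compound in the network.

    ``enrichment_results`` must carry the transporter-class enrichment
    evidence (class code in ``query.annot``, organism set).  Candidates
    are sorted by transporter enrichment strength, then compound id.
    """
    if not transporter_map:
        raise ValueError("a transporter-class -> substrate map is required")
    if partner_depth < 1:
        raise ValueError("partner_depth must be >= 1")
    allow = set(consumption_allowlist)

    # enriched transporter classes and the compounds they move
    class_p: dict[tuple[str, Organism], float] = {}
    for res in enrichment_results:
        if res.organism is not None and res.query.annot in transporter_map:
            class_p[(res.query.annot, res.organism)] = res.pvalue_enrich

    all_edges = list(network.reaction_edges.values())
    candidates: list[ExchangeCandidate] = []
    for producer in (Organism.A, Organism.B):
        partner = producer.partner
        unique_label = Provenance.A_ONLY if producer is Organism.A else Provenance.B_ONLY
        producing = [e for e in all_edges if e.provenance is unique_label]
        partner_edges = [e for e in all_edges if _partner_expresses(e, partner)]
        produced: dict[str, list[str]] = {}
        for e in producing:
            for c in sorted(_outputs(e)):
                produced.setdefault(c, []).append(e.reaction.reaction_id)
        for compound, rids in sorted(produced.items()):
            evidence = [
                (code, org.value, class_p[(code, org)])
                for (code, org) in sorted(class_p, key=lambda k: (k[0], k[1].value))
                if compound in transporter_map[code][1]
                and class_p[(code, org)] < gate
                and org in (producer, partner)
            ]
            if not evidence:
                continue
            consuming = _consumed_within_depth(compound, partner_edges, all_edges, partner_depth)
            via_allowlist = False
            if not consuming:
                if compound in allow:
                    via_allowlist = True
                else:
                    continue
            candidates.append(
                ExchangeCandidate(
                    compound_id=compound,
                    producer=producer,
                    producing_reactions=sorted(rids),
                    transporter_evidence=evidence,
                    consuming_reactions=consuming,
                    via_allowlist=via_allowlist,
                )
            )
    candidates.sort(key=lambda c: (c.best_transporter_p, c.compound_id))
    return candidates


def annotate_network_highlights(
    graph: nx.DiGraph,
    transporter_map: Mapping[str, tuple[str, frozenset[str]]],
    candidates: Sequence[ExchangeCandidate],
) -> nx.DiGraph:
    """Flag compound nodes by class: sugars, amino acids, and predicted
    exchange compounds (boolean node attributes, GraphML-safe)."""
    sugars = transporter_map.get(GO_SUGAR_PORTER, ("", frozenset()))[1]
    aminos = transporter_map.get(GO_AMINO_ACID_TRANSPORT, ("", frozenset()))[1]
    exchanged = {c.compound_id for c in candidates}
    for node in graph.nodes:
        graph.nodes[node]["sugar"] = node in sugars
        graph.nodes[node]["amino_acid"] = node in aminos
        graph.nodes[node]["exchange"] = node in exchanged
    return graph
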