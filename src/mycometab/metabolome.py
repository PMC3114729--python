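"""Merged dual-organism metabolome network.

A reaction from the reference reaction table enters the network when
at least one enzyme function (EC number) catalyzing it is expressed by
either organism; all metabolites of included reactions are included.
Each expressed function carries a provenance label — expressed only by
organism A, only by B, or by both — and each reaction edge rolls these
up: a reaction is organism-unique only when *every* expressed function
catalyzing it is unique to that organism.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .types import PathwayDefinition, ReactionRecord, matching_ecs


class Provenance(str, Enum):
    A_ONLY = "A_only"
    B_ONLY = "B_only"
    SHARED = "shared"


def unique_function_partition(
    ecs_a: Iterable[str], ecs_b: Iterable[str]
) -> tuple[set[str], set[str], set[str]]:
    """Exact partition of two expressed EC sets: (A-only, B-only, shared)."""
    a, b = set(ecs_a), set(ecs_b)
    return a - b, b - a, a & b


@dataclass
class ReactionEdge:
    reaction: ReactionRecord
    expressed_ecs: frozenset[str]
    ec_provenance: dict[str, Provenance]

    @property
    def provenance(self) -> Provenance:
        labels = set(self.ec_provenance.values())
        if labels == {Provenance.A_ONLY}:
            return Provenance.A_ONLY
        if labels == {Provenance.B_ONLY}:
            return Provenance.B_ONLY
        return Provenance.SHARED


class MetabolomeNetwork:
    """Compound nodes joined by expressed-reaction edges with provenance."""

    def __init__(
        self,
        reaction_edges: Mapping[str, ReactionEdge],
        ecs_a: set[str],
        ecs_b: set[str],
    ) -> None:
        self.reaction_edges = dict(reaction_edges)
        self.ecs_a = set(ecs_a)
        self.ecs_b = set(ecs_b)
        self.compounds: set[str] = set()
        for edge in self.reaction_edges.values():
            self.compounds |= edge.reaction.substrates | edge.reaction.products

    @property
    def functions(self) -> set[str]:
        out: set[str] = set()
        for edge in self.reaction_edges.values():
            out |= edge.expressed_ecs
        return out

    @property
    def counts(self) -> dict[str, int]:
        funcs = self.functions
        prov = {ec: p for e in self.reaction_edges.values() for ec, p in e.ec_provenance.items()}
        n_a = sum(1 for ec in funcs if prov[ec] is Provenance.A_ONLY)
        n_b = sum(1 for ec in funcs if prov[ec] is Provenance.B_ONLY)
        return {
            "n_compounds": len(self.compounds),
            "n_reactions": len(self.reaction_edges),
            "n_functions": len(funcs),
            "n_unique_A": n_a,
            "n_unique_B": n_b,
            "n_shared": len(funcs) - n_a - n_b,
        }

    def to_networkx(self) -> nx.DiGraph:
        """Directed compound graph; reversible reactions yield both directions
        (the reaction itself is still counted once)."""
        g = nx.DiGraph()
        for c in sorted(self.compounds):
            g.add_node(c)
        for rid in sorted(self.reaction_edges):
            edge = self.reaction_edges[rid]
            ecs = ";".join(sorted(edge.expressed_ecs))
            prov = edge.provenance.value
            pairs = [
                (s, p)
                for s in sorted(edge.reaction.substrates)
                for p in sorted(edge.reaction.products)
            ]
            if edge.reaction.reversible:
                pairs += [(p, s) for s, p in pairs]
            for u, v in pairs:
                g.add_edge(u, v, reaction_id=rid, ec=ecs, provenance=prov)
        return g


def build_network(
    ecs_a: Iterable[str],
    ecs_b: Iterable[str],
    reactions: Sequence[ReactionRecord],
    partial_ec: bool = True,
) -> MetabolomeNetwork:
    """Assemble the network from two expressed EC sets and a reaction table.

    Adding a function to either expressed set can only grow the network
    (monotone); rebuilding from the same inputs is idempotent.
    """
    ecs_a, ecs_b = set(ecs_a), set(ecs_b)
    edges: dict[str, ReactionEdge] = {}
    for rx in reactions:
        matched_a = matching_ecs(rx.ec_set, ecs_a, partial=partial_ec)
        matched_b = matching_ecs(rx.ec_set, ecs_b, partial=partial_ec)
        expressed = matched_a | matched_b
        if not expressed:
            continue
        prov = {}
        for ec in expressed:
            if ec in matched_a and ec in matched_b:
                prov[ec] = Provenance.SHARED
            elif ec in matched_a:
                prov[ec] = Provenance.A_ONLY
            else:
                prov[ec] = Provenance.B_ONLY
        edges[rx.reaction_id] = ReactionEdge(rx, frozenset(expressed), prov)
    return MetabolomeNetwork(edges, ecs_a, ecs_b)


def pathway_coverage(
    network_ecs: Iterable[str],
    pathways: Sequence[PathwayDefinition],
    threshold: float = 0.30,
) -> tuple[dict[str, dict], float]:
    """Per-pathway fraction of enzyme functions expressed.

    A pathway is *detected* when at least ``threshold`` of its
    functions are expressed; the summary value is the detected fraction
    over all pathways.
    """
    ecs = set(network_ecs)
    per_pathway: dict[str, dict] = {}
    n_detected = 0
    for pw in pathways:
        hit = matching_ecs(pw.ec_set, ecs)
        cov = len(hit) / len(pw.ec_set)
        detected = cov >= threshold
        n_detected += detected
        per_pathway[pw.pathway_id] = {
            "name": pw.name,
            "coverage": cov,
            "detected": detected,
            "n_expressed": len(hit),
            "n_total": len(pw.ec_set),
        }
    summary = n_detected / len(pathways) if pathways else 0.0
    return per_pathway, summary


def global_map_projection(
    network: MetabolomeNetwork,
    reference_reactions: Sequence[ReactionRecord],
) -> dict[str, float]:
    """Fraction of a reference reaction universe with expressed catalysis,
    overall and per organism."""
    def frac(ecs: set[str]) -> float:
        if not reference_reactions:
            return 0.0
        hit = sum(1 for rx in reference_reactions if matching_ecs(rx.ec_set, ecs))
        return hit / len(reference_reactions)

    return {
        "overall": frac(network.ecs_a | network.ecs_b),
        "A": frac(network.ecs_a),
        "B": frac(network.ecs_b),
    }
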