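"""Core domain containers shared by every pipeline stage.

Two symbiotic organisms (labelled ``A`` and ``B``, e.g. a host plant and
its fungal partner) contribute gene models to one combined alignment
reference.  Everything downstream — expression calling, enrichment,
network construction — is keyed on the gene catalog defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")
GO_PATTERN = re.compile(r"^GO:\d{7}$")


class Organism(str, Enum):
    """One of the two symbiotic partners."""

    A = "A"
    B = "B"

    @property
    def partner(self) -> "Organism":
        return Organism.B if self is Organism.A else Organism.A


@dataclass(frozen=True)
class GeneModel:
    """A predicted gene structure; the unit reads are aligned to."""

    gene_id: str
    organism: Organism
    length_bp: int

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.length_bp < 1:
            raise ValueError(
                f"gene {self.gene_id!r}: length_bp must be >= 1, got {self.length_bp}"
            )


class GeneCatalog:
    """All gene models of both organisms, with unique ids.

    Iteration order is insertion order, which makes every downstream
    computation that walks the catalog deterministic.
    """

    def __init__(
        self,
        models: Iterable[GeneModel] = (),
        display_names: Mapping[Organism, str] | None = None,
    ) -> None:
        self._models: dict[str, GeneModel] = {}
        self.display_names: dict[Organism, str] = {
            Organism.A: "organism A",
            Organism.B: "organism B",
        }
        if display_names:
            self.display_names.update(display_names)
        for m in models:
            self.add(m)

    def add(self, model: GeneModel) -> None:
        if model.gene_id in self._models:
            raise ValueError(f"duplicate gene_id {model.gene_id!r} in catalog")
        self._models[model.gene_id] = model

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._models

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._models.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._models[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return list(self._models)

    def genes(self, organism: Organism | None = None) -> list[GeneModel]:
        if organism is None:
            return list(self._models.values())
        return [m for m in self._models.values() if m.organism is organism]

    def gene_ids_of(self, organism: Organism) -> set[str]:
        return {m.gene_id for m in self._models.values() if m.organism is organism}

    @property
    def organism_totals(self) -> dict[Organism, int]:
        totals = {Organism.A: 0, Organism.B: 0}
        for m in self._models.values():
            totals[m.organism] += 1
        return totals


def validate_code(code: str, kind: str) -> bool:
    if kind == "EC":
        return bool(EC_PATTERN.match(code))
    if kind == "GO":
        return bool(GO_PATTERN.match(code))
    raise ValueError(f"unknown annotation kind {kind!r}")


def ec_match(a: str, b: str) -> bool:
    """Whether two EC codes refer to the same function.

    A ``-`` at any level is a wildcard (partial annotation) and matches
    any completion at that level.
    """
    fa, fb = a.split("."), b.split(".")
    if len(fa) != 4 or len(fb) != 4:
        return a == b
    return all(x == y or x == "-" or y == "-" for x, y in zip(fa, fb))


def matching_ecs(targets: Iterable[str], pool: Iterable[str], partial: bool = True) -> set[str]:
    """Subset of *targets* with at least one match in *pool*.

    With ``partial=False`` only exact 4-level string equality counts.
    """
    targets = set(targets)
    pool = set(pool)
    if not partial:
        return targets & pool
    exact = targets & pool
    remaining = targets - exact
    if not remaining:
        return exact
    fuzzy = {t for t in remaining if any(ec_match(t, p) for p in pool)}
    return exact | fuzzy


@dataclass
class AnnotationTable:
    """Flat gene -> annotation-code mapping (EC numbers or GO terms)."""

    kind: str  # "EC" or "GO"
    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("EC", "GO"):
            raise ValueError(f"kind must be 'EC' or 'GO', got {self.kind!r}")

    def add(self, gene_id: str, code: str) -> None:
        if not validate_code(code, self.kind):
            raise ValueError(f"malformed {self.kind} code {code!r} for gene {gene_id!r}")
        self.entries.setdefault(gene_id, set()).add(code)

    def codes_of(self, gene_id: str) -> set[str]:
        return self.entries.get(gene_id, set())

    def genes_with(self, code: str, partial: bool = True) -> set[str]:
        """Genes annotated with *code* (EC wildcards honoured by default)."""
        if self.kind == "EC" and partial:
            return {
                g for g, codes in self.entries.items() if any(ec_match(code, c) for c in codes)
            }
        return {g for g, codes in self.entries.items() if code in codes}

    def all_codes(self) -> set[str]:
        out: set[str] = set()
        for codes in self.entries.values():
            out |= codes
        return out

    def codes_over(self, gene_ids: Iterable[str]) -> set[str]:
        """Union of codes carried by the given genes."""
        out: set[str] = set()
        for g in gene_ids:
            out |= self.entries.get(g, set())
        return out


@dataclass(frozen=True)
class CandidateLocation:
    """One possible alignment placement of a read within a gene model."""

    gene_id: str
    start: int  # 0-based half-open
    strand: str = "+"


class MultiAlignmentSet:
    """All candidate alignment locations per read.

    Reads that did not align contribute to ``total_reads_in_library``
    but carry no candidate list.
    """

    def __init__(
        self,
        reads: Mapping[str, list[CandidateLocation]] | None = None,
        total_reads_in_library: int = 0,
    ) -> None:
        self.reads: dict[str, list[CandidateLocation]] = dict(reads or {})
        for rid, locs in self.reads.items():
            if not locs:
                raise ValueError(f"read {rid!r} has an empty candidate list")
        self.total_reads_in_library = int(total_reads_in_library)

    @property
    def n_mapped(self) -> int:
        return len(self.reads)

    def multiread_ids(self) -> list[str]:
        return [r for r, locs in self.reads.items() if len(locs) > 1]


@dataclass(frozen=True)
class ReactionRecord:
    """One enzymatic transformation: substrates -> products via EC functions."""

    reaction_id: str
    ec_set: frozenset[str]
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    allow_overlap: bool = False  # polymer-style reactions may share compounds on both sides

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ValueError("reaction_id must be non-empty")
        for name, s in (("ec_set", self.ec_set), ("substrates", self.substrates),
                        ("products", self.products)):
            if not s:
                raise ValueError(f"reaction {self.reaction_id!r}: {name} must be non-empty")
        for ec in self.ec_set:
            if not EC_PATTERN.match(ec):
                raise ValueError(f"reaction {self.reaction_id!r}: malformed EC {ec!r}")
        overlap = self.substrates & self.products
        if overlap and not self.allow_overlap:
            raise ValueError(
                f"reaction {self.reaction_id!r}: compounds {sorted(overlap)} appear on "
                "both sides (set allow_overlap for polymer-style reactions)"
            )


@dataclass(frozen=True)
class PathwayDefinition:
    """A named set of enzyme functions (one metabolic map)."""

    pathway_id: str
    name: str
    ec_set: frozenset[str]
    class_label: str = ""

    def __post_init__(self) -> None:
        if not self.ec_set:
            raise ValueError(f"pathway {self.pathway_id!r}: ec_set must be non-empty")
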