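"""Readers and writers for every external format the pipeline touches.

Formats: gene-model FASTA, two-column annotation TSVs, all-alignments
SAM, reaction/pathway/transporter TSVs, and network exports (SIF,
GraphML, node/edge attribute TSV pair).  All readers validate against
the gene catalog and the type invariants; every reader/writer pair
round-trips losslessly.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pysam
from Bio import SeqIO

from .types import (
    AnnotationTable,
    CandidateLocation,
    GeneCatalog,
    GeneModel,
    MultiAlignmentSet,
    Organism,
    PathwayDefinition,
    ReactionRecord,
    validate_code,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene catalogs (FASTA)
# ---------------------------------------------------------------------------

def read_gene_catalog(
    fasta_paths_with_labels: Sequence[tuple[str | Path, Organism | str]],
    display_names: dict[Organism, str] | None = None,
) -> GeneCatalog:
    """Build a catalog from FASTA files, one organism label per file.

    The first whitespace-delimited token of each header is the gene id;
    the record length is the gene-model length in bp.
    """
    catalog = GeneCatalog(display_names=display_names)
    for path, label in fasta_paths_with_labels:
        organism = Organism(label)
        n = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            if len(rec.seq) == 0:
                raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
            catalog.add(GeneModel(rec.id, organism, len(rec.seq)))
            n += 1
        if n == 0:
            raise ValueError(f"{path}: no FASTA records found")
    return catalog


def write_gene_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, seq in sequences.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# annotation tables (TSV: gene_id <TAB> code, one pair per line)
# ---------------------------------------------------------------------------

def read_annotation_table(
    tsv_path: str | Path,
    kind: str,
    catalog: GeneCatalog,
    on_unknown: str = "error",
) -> AnnotationTable:
    """Read a two-column (gene_id, code) TSV; repeated gene lines accumulate.

    ``on_unknown`` controls genes absent from the catalog: ``"error"``
    raises, ``"warn"`` logs and skips the line.
    """
    if on_unknown not in ("error", "warn"):
        raise ValueError("on_unknown must be 'error' or 'warn'")
    table = AnnotationTable(kind=kind)
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{tsv_path}:{lineno}: expected 2 tab-separated columns")
            gene_id, code = fields[0].strip(), fields[1].strip()
            if gene_id not in catalog:
                msg = f"{tsv_path}:{lineno}: gene {gene_id!r} not in catalog"
                if on_unknown == "error":
                    raise ValueError(msg)
                warnings.warn(msg)
                continue
            if not validate_code(code, kind):
                raise ValueError(f"{tsv_path}:{lineno}: malformed {kind} code {code!r}")
            table.add(gene_id, code)
    return table


def write_annotation_table(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={table.kind}\n")
        for gene_id in sorted(table.entries):
            for code in sorted(table.entries[gene_id]):
                fh.write(f"{gene_id}\t{code}\n")


# ---------------------------------------------------------------------------
# all-alignments SAM
# ---------------------------------------------------------------------------

def read_multialignments(sam_path: str | Path, catalog: GeneCatalog) -> MultiAlignmentSet:
    """Group mapped SAM records by read name into candidate lists.

    SAM POS is 1-based; pysam exposes it 0-based, which is the internal
    convention.  Candidate lists are de-duplicated on
    (gene_id, start, strand).  Unmapped reads are counted in the library
    total but carry no candidates.
    """
    reads: dict[str, list[CandidateLocation]] = {}
    seen: dict[str, set[tuple[str, int, str]]] = {}
    read_names: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            read_names.add(rec.query_name)
            if rec.is_unmapped:
                continue
            gene_id = rec.reference_name
            if gene_id not in catalog:
                raise ValueError(
                    f"{sam_path}: read {rec.query_name!r} aligned to unknown "
                    f"reference {gene_id!r}"
                )
            strand = "-" if rec.is_reverse else "+"
            key = (gene_id, rec.reference_start, strand)
            if key in seen.setdefault(rec.query_name, set()):
                continue
            seen[rec.query_name].add(key)
            reads.setdefault(rec.query_name, []).append(
                CandidateLocation(gene_id, rec.reference_start, strand)
            )
    return MultiAlignmentSet(reads=reads, total_reads_in_library=len(read_names))


# ---------------------------------------------------------------------------
# reaction / pathway / transporter tables
# ---------------------------------------------------------------------------

def _split_semicolon(field: str) -> frozenset[str]:
    return frozenset(x.strip() for x in field.split(";") if x.strip())


def read_reaction_table(path: str | Path, allow_overlap: bool = False) -> list[ReactionRecord]:
    """TSV: reaction_id, EC list, substrates, products, reversibility (R/I).

    Multi-valued fields are semicolon-joined.  Partial EC numbers
    (trailing ``-`` levels) are retained as-is.
    """
    records: list[ReactionRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            rid, ecs, subs, prods, rev = (f.strip() for f in fields)
            if rid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate reaction_id {rid!r}")
            seen.add(rid)
            if rev not in ("R", "I"):
                raise ValueError(f"{path}:{lineno}: reversibility must be 'R' or 'I', got {rev!r}")
            records.append(
                ReactionRecord(
                    reaction_id=rid,
                    ec_set=_split_semicolon(ecs),
                    substrates=_split_semicolon(subs),
                    products=_split_semicolon(prods),
                    reversible=(rev == "R"),
                    allow_overlap=allow_overlap,
                )
            )
    return records


def write_reaction_table(reactions: Iterable[ReactionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# reaction_id\tec_set\tsubstrates\tproducts\treversible\n")
        for r in reactions:
            fh.write(
                "\t".join(
                    [
                        r.reaction_id,
                        ";".join(sorted(r.ec_set)),
                        ";".join(sorted(r.substrates)),
                        ";".join(sorted(r.products)),
                        "R" if r.reversible else "I",
                    ]
                )
                + "\n"
            )


def read_pathway_table(path: str | Path) -> list[PathwayDefinition]:
    """TSV: pathway_id, name, class label, semicolon-joined EC list."""
    pathways: list[PathwayDefinition] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            pid, name, class_label, ecs = (f.strip() for f in fields)
            if pid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pathway_id {pid!r}")
            seen.add(pid)
            pathways.append(
                PathwayDefinition(pid, name, _split_semicolon(ecs), class_label)
            )
    return pathways


def write_pathway_table(pathways: Iterable[PathwayDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# pathway_id\tname\tclass\tec_set\n")
        for p in pathways:
            fh.write(f"{p.pathway_id}\t{p.name}\t{p.class_label}\t{';'.join(sorted(p.ec_set))}\n")


def read_transporter_map(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """TSV: class_code, display name, semicolon-joined substrate compound ids."""
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            code, name, subs = (f.strip() for f in fields)
            compounds = _split_semicolon(subs)
            if not compounds:
                raise ValueError(f"{path}:{lineno}: empty substrate set for {code!r}")
            out[code] = (name, compounds)
    return out


def write_transporter_map(tmap: dict[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# class_code\tname\tsubstrates\n")
        for code in sorted(tmap):
            name, subs = tmap[code]
            fh.write(f"{code}\t{name}\t{';'.join(sorted(subs))}\n")


# ---------------------------------------------------------------------------
# network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def write_network(graph: nx.Graph, prefix: str | Path, format: str) -> list[Path]:
    """Export an attributed compound/reaction graph.

    ``sif`` writes one substrate -> product line per edge with the
    reaction and EC as the relation; ``graphml`` and ``tsv`` (a
    node/edge attribute file pair) are lossless.
    """
    prefix = Path(prefix)
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    if format == "graphml":
        path = prefix.with_suffix(".graphml")
        nx.write_graphml(graph, path)
        return [path]
    if format == "sif":
        path = prefix.with_suffix(".sif")
        with open(path, "w") as fh:
            for u, v, data in sorted(graph.edges(data=True)):
                rel = data.get("reaction_id", "rx")
                ecs = data.get("ec", "")
                fh.write(f"{u}\t{rel}:{ecs}\t{v}\n")
        return [path]
    nodes_path = prefix.parent / (prefix.name + ".nodes.tsv")
    edges_path = prefix.parent / (prefix.name + ".edges.tsv")
    node_keys = sorted({k for _, d in graph.nodes(data=True) for k in d})
    edge_keys = sorted({k for *_, d in graph.edges(data=True) for k in d})
    with open(nodes_path, "w") as fh:
        fh.write("\t".join(["node"] + node_keys) + "\n")
        for n, d in sorted(graph.nodes(data=True)):
            fh.write("\t".join([str(n)] + [str(d.get(k, "")) for k in node_keys]) + "\n")
    with open(edges_path, "w") as fh:
        fh.write("\t".join(["source", "target"] + edge_keys) + "\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write("\t".join([str(u), str(v)] + [str(d.get(k, "")) for k in edge_keys]) + "\n")
    return [nodes_path, edges_path]


def read_network(prefix: str | Path, format: str) -> nx.DiGraph:
    """Re-import a network written by :func:`write_network` (lossless formats)."""
    prefix = Path(prefix)
    if format == "graphml":
        g = nx.read_graphml(prefix.with_suffix(".graphml"))
        return nx.DiGraph(g)
    if format == "tsv":
        g = nx.DiGraph()
        nodes_path = prefix.parent / (prefix.name + ".nodes.tsv")
        edges_path = prefix.parent / (prefix.name + ".edges.tsv")
        with open(nodes_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                attrs = {k: v for k, v in zip(header, fields[1:]) if v != ""}
                g.add_node(fields[0], **attrs)
        with open(edges_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[2:]
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                attrs = {k: v for k, v in zip(header, fields[2:]) if v != ""}
                g.add_edge(fields[0], fields[1], **attrs)
        return g
    raise ValueError(f"cannot re-import format {format!r}")
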