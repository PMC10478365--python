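"""Domain types and flat-file readers/writers for the comorbidity pipeline.

Every file the pipeline touches is tab-separated UTF-8; lines whose first
non-blank character is ``#`` are comments and are skipped everywhere.  Gene
symbols keep their original capitalization for display but are matched
case-insensitively across files (database extracts disagree on case), via
:func:`canon`.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx

logger = logging.getLogger("comorbid_rank")

__all__ = [
    "PipelineError",
    "ParseError",
    "ValidationError",
    "canon",
    "InteractionType",
    "REGULATORY_TYPES",
    "NodeClass",
    "NodeRecord",
    "EdgeRecord",
    "AssociativeNetwork",
    "DiseaseAssociation",
    "DiseaseAssociationTable",
    "GOAnnotations",
    "DiseaseProcessLinks",
    "SNPRecord",
    "ExternalScoreTable",
    "SCORE_DIRECTIONS",
    "PriorityRow",
    "PriorityReport",
    "read_network",
    "write_network",
    "read_disease_genes",
    "write_disease_genes",
    "read_go_inputs",
    "write_go_annotations",
    "write_disease_process_links",
    "read_snp_catalog",
    "write_snp_catalog",
    "read_external_scores",
    "write_external_scores",
    "read_comorbid_diseases",
    "write_comorbid_diseases",
    "read_priority_report",
    "write_priority_report",
]


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, path: str | Path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class ValidationError(PipelineError):
    """Input content violates a documented invariant."""


def canon(symbol: str) -> str:
    """Canonical (case-insensitive) matching key for a gene symbol."""
    return symbol.strip().upper()


# --------------------------------------------------------------------------
# network types
# --------------------------------------------------------------------------

class InteractionType(str, enum.Enum):
    """The seven typed relations an associative gene network may carry."""

    ACTIVITY_REGULATION = "activity_regulation"
    DEGRADATION_REGULATION = "degradation_regulation"
    EXPRESSION_REGULATION = "expression_regulation"
    TRANSPORT_REGULATION = "transport_regulation"
    DOWNREGULATION = "downregulation"
    ASSOCIATIVE = "associative"
    PROTEIN_PROTEIN = "protein_protein"

    @classmethod
    def parse(cls, label: str) -> "InteractionType":
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(t.value for t in cls)
            raise ValueError(f"unknown interaction type {label!r} (valid: {valid})")


#: Regulatory edge categories: everything that is not a generic association or
#: a physical protein-protein binding.  Degradation regulation is included by
#: default (it is a regulation category); callers may override.
REGULATORY_TYPES: frozenset[InteractionType] = frozenset(InteractionType) - {
    InteractionType.ASSOCIATIVE,
    InteractionType.PROTEIN_PROTEIN,
}


class NodeClass(str, enum.Enum):
    GENE = "gene"
    PROTEIN = "protein"

    @classmethod
    def parse(cls, label: str) -> "NodeClass":
        try:
            return cls(label)
        except ValueError:
            raise ValueError(f"unknown node class {label!r} (valid: gene, protein)")


@dataclass(frozen=True)
class NodeRecord:
    """A gene or protein node.  The same symbol may appear as both classes."""

    id: str
    node_class: NodeClass

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("node id must be non-empty")


@dataclass(frozen=True)
class EdgeRecord:
    """A directed typed interaction; identical (source, target, type) collapse."""

    source: NodeRecord
    target: NodeRecord
    itype: InteractionType


@dataclass
class AssociativeNetwork:
    """A typed gene/protein interaction graph.

    Gene and protein nodes sharing a symbol are distinct nodes here, but are
    merged into one *entity* (see :meth:`entity_graph`) for prioritization:
    the final ranking is over symbols, not node classes.
    """

    name: str = ""
    nodes: set[NodeRecord] = field(default_factory=set)
    edges: set[EdgeRecord] = field(default_factory=set)

    # -- construction ------------------------------------------------------

    def add_node(self, node: NodeRecord) -> None:
        self.nodes.add(node)

    def add_edge(
        self,
        source: str,
        source_class: NodeClass,
        target: str,
        target_class: NodeClass,
        itype: InteractionType,
    ) -> bool:
        """Add a typed edge (and its endpoints); return False if it collapsed
        onto an already-present identical edge."""
        s = NodeRecord(source, source_class)
        t = NodeRecord(target, target_class)
        self.nodes.add(s)
        self.nodes.add(t)
        edge = EdgeRecord(s, t, itype)
        if edge in self.edges:
            return False
        self.edges.add(edge)
        return True

    # -- basic accounting --------------------------------------------------

    @property
    def n_gene_nodes(self) -> int:
        return sum(1 for n in self.nodes if n.node_class is NodeClass.GENE)

    @property
    def n_protein_nodes(self) -> int:
        return sum(1 for n in self.nodes if n.node_class is NodeClass.PROTEIN)

    def __len__(self) -> int:
        return len(self.nodes)

    # -- entity (symbol) level view ---------------------------------------

    def entity_display(self) -> dict[str, str]:
        """Map canonical symbol -> display symbol (lexicographically smallest
        spelling seen, for determinism)."""
        out: dict[str, str] = {}
        for node in self.nodes:
            key = canon(node.id)
            if key not in out or node.id < out[key]:
                out[key] = node.id
        return out

    def entities(self) -> list[str]:
        """Sorted display symbols of all entities in the network."""
        return sorted(self.entity_display().values(), key=str.upper)

    def entity_graph(self) -> nx.Graph:
        """Simple undirected graph over canonical symbols.

        Edge types, edge direction and gene/protein node classes are
        collapsed; self-loops are dropped.  Isolated entities are kept.
        """
        g = nx.Graph()
        g.add_nodes_from(sorted({canon(n.id) for n in self.nodes}))
        for e in sorted(
            self.edges, key=lambda e: (e.source.id, e.target.id, e.itype.value)
        ):
            u, v = canon(e.source.id), canon(e.target.id)
            if u != v:
                g.add_edge(u, v)
        return g

    def induced_on(self, canon_symbols: set[str], name: str = "") -> "AssociativeNetwork":
        """Subnetwork induced on the given canonical entity symbols."""
        keep = {s.upper() for s in canon_symbols}
        sub = AssociativeNetwork(name=name)
        sub.nodes = {n for n in self.nodes if canon(n.id) in keep}
        sub.edges = {
            e
            for e in self.edges
            if canon(e.source.id) in keep and canon(e.target.id) in keep
        }
        return sub


# --------------------------------------------------------------------------
# disease-gene associations
# --------------------------------------------------------------------------

_ASSOC_SOURCES = ("network_db", "genecards")


@dataclass(frozen=True)
class DiseaseAssociation:
    gene: str
    disease: str
    source: str  # "network_db" | "genecards"
    relevance_score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in _ASSOC_SOURCES:
            raise ValidationError(
                f"unknown association source {self.source!r} (valid: {_ASSOC_SOURCES})"
            )
        if self.relevance_score is not None:
            if self.source != "genecards":
                raise ValidationError(
                    f"relevance_score given for source={self.source!r}; only "
                    "genecards rows carry a relevance score"
                )
            if self.relevance_score < 0:
                raise ValidationError("relevance_score must be nonnegative")


@dataclass
class DiseaseAssociationTable:
    """Gene-disease links with their provenance (network DB vs. GeneCards)."""

    rows: list[DiseaseAssociation] = field(default_factory=list)

    def diseases(self) -> set[str]:
        return {r.disease for r in self.rows}

    def has_disease(self, disease: str) -> bool:
        key = disease.strip().lower()
        return any(r.disease.strip().lower() == key for r in self.rows)

    def genes_for(self, disease: str) -> set[str]:
        """Canonical symbols associated with `disease`, union over sources."""
        if not self.has_disease(disease):
            raise ValidationError(f"disease {disease!r} not present in association table")
        key = disease.strip().lower()
        return {canon(r.gene) for r in self.rows if r.disease.strip().lower() == key}


# --------------------------------------------------------------------------
# GO annotations and disease-process links
# --------------------------------------------------------------------------

GO_ID_RE = re.compile(r"^GO:\d{7}$")


@dataclass
class GOAnnotations:
    """Biological-process annotations: process id -> canonical gene set."""

    genes_by_process: dict[str, frozenset[str]] = field(default_factory=dict)
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, genes in self.genes_by_process.items():
            if not GO_ID_RE.match(pid):
                raise ValidationError(f"malformed GO id {pid!r}")
            if not genes:
                raise ValidationError(f"process {pid} has an empty gene set")

    @property
    def universe(self) -> frozenset[str]:
        """All annotated genes (the enrichment background)."""
        out: set[str] = set()
        for genes in self.genes_by_process.values():
            out |= genes
        return frozenset(out)

    def processes(self) -> frozenset[str]:
        return frozenset(self.genes_by_process)

    def processes_of(self, gene: str) -> frozenset[str]:
        g = canon(gene)
        return frozenset(
            pid for pid, members in self.genes_by_process.items() if g in members
        )


@dataclass
class DiseaseProcessLinks:
    """Disease -> set of GO biological-process ids."""

    by_disease: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for disease, pids in self.by_disease.items():
            for pid in pids:
                if not GO_ID_RE.match(pid):
                    raise ValidationError(
                        f"malformed GO id {pid!r} for disease {disease!r}"
                    )

    def has_disease(self, disease: str) -> bool:
        key = disease.strip().lower()
        return any(d.strip().lower() == key for d in self.by_disease)

    def processes_for(self, disease: str) -> set[str]:
        key = disease.strip().lower()
        for d, pids in self.by_disease.items():
            if d.strip().lower() == key:
                return set(pids)
        raise ValidationError(f"disease {disease!r} not present in process links")


# --------------------------------------------------------------------------
# SNP catalog
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SNPRecord:
    """One SNP: host gene, eQTL tissues, minor-allele frequency, diseases.

    `gene_length_nt` is a gene-level attribute duplicated on each row so the
    flat file stays self-contained (it feeds the SNP-density statistic).
    """

    snp_id: str
    gene: str
    eqtl_tissues: frozenset[str]
    maf: float
    associated_diseases: frozenset[str]
    gene_length_nt: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValidationError(
                f"SNP {self.snp_id}: maf {self.maf} outside [0, 1]"
            )
        if self.gene_length_nt <= 0:
            raise ValidationError(
                f"SNP {self.snp_id}: gene_length_nt must be positive"
            )


# --------------------------------------------------------------------------
# external prioritizer scores
# --------------------------------------------------------------------------

#: Fixed score directions: criterion 1 is a GeneCards-style relevance score
#: (higher is better), criterion 2 an Endeavour-style p-value (lower is
#: better), criterion 3 a ToppGene-style average score (higher is better).
SCORE_DIRECTIONS: dict[int, str] = {
    1: "higher_is_better",
    2: "lower_is_better",
    3: "higher_is_better",
}


@dataclass
class ExternalScoreTable:
    """Per-gene scores from an external prioritizer (criteria 1-3)."""

    criterion_id: int
    scores: dict[str, float]  # canonical symbol -> score
    direction: str = ""

    def __post_init__(self) -> None:
        if self.criterion_id not in SCORE_DIRECTIONS:
            raise ValidationError(
                f"external score tables exist only for criteria 1-3, "
                f"got {self.criterion_id}"
            )
        expected = SCORE_DIRECTIONS[self.criterion_id]
        if not self.direction:
            self.direction = expected
        elif self.direction != expected:
            raise ValidationError(
                f"criterion {self.criterion_id} direction must be {expected}"
            )


# --------------------------------------------------------------------------
# priority report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorityRow:
    gene: str
    ranks: tuple[float, ...]  # ranks for criteria 1..10
    average_rank: float

    def __post_init__(self) -> None:
        if len(self.ranks) != 10:
            raise ValidationError("a priority row carries exactly 10 ranks")


@dataclass
class PriorityReport:
    """Final priority table: one row per candidate, sorted by average rank
    ascending (lower average rank = higher priority), ties alphabetical."""

    rows: list[PriorityRow] = field(default_factory=list)

    def sorted_rows(self) -> list[PriorityRow]:
        return sorted(self.rows, key=lambda r: (r.average_rank, r.gene.upper()))

    def top(self, k: int) -> list[PriorityRow]:
        return self.sorted_rows()[:k]


# --------------------------------------------------------------------------
# low-level line handling
# --------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields) skipping comments/blanks."""
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield line_no, line.split("\t")


def _require_header(
    path: str | Path, line_no: int, fields: list[str], expected: list[str]
) -> None:
    if [f.strip() for f in fields] != expected:
        raise ParseError(
            path, line_no, f"expected header {expected}, got {fields}"
        )


# --------------------------------------------------------------------------
# network I/O
# --------------------------------------------------------------------------

_NETWORK_HEADER = ["source", "source_class", "target", "target_class", "interaction_type"]


def read_network(path: str | Path, dialect: str = "tsv") -> AssociativeNetwork:
    """Read a typed network from a TSV edge list or a SIF file.

    The TSV dialect has header ``source, source_class, target, target_class,
    interaction_type``; the SIF dialect uses the interaction type as the
    relation token and defaults every node class to ``protein``.  Duplicate
    identical edges collapse to one.
    """
    if dialect not in ("tsv", "sif"):
        raise ValidationError(f"unknown network dialect {dialect!r}")
    net = AssociativeNetwork(name=Path(path).stem)
    lines = _data_lines(path)
    if dialect == "tsv":
        try:
            line_no, fields = next(lines)
        except StopIteration:
            raise ParseError(path, 1, "empty network file (header required)")
        _require_header(path, line_no, fields, _NETWORK_HEADER)
        for line_no, fields in lines:
            if len(fields) != 5:
                raise ParseError(path, line_no, f"expected 5 columns, got {len(fields)}")
            src, src_cls, tgt, tgt_cls, itype = (f.strip() for f in fields)
            try:
                net.add_edge(
                    src,
                    NodeClass.parse(src_cls),
                    tgt,
                    NodeClass.parse(tgt_cls),
                    InteractionType.parse(itype),
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(path, line_no, str(exc))
    else:  # sif: source <TAB> relation <TAB> target [<TAB> target ...]
        for line_no, fields in lines:
            if len(fields) < 3:
                raise ParseError(path, line_no, "SIF line needs source, relation, target")
            src = fields[0].strip()
            try:
                itype = InteractionType.parse(fields[1].strip())
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc))
            for tgt in fields[2:]:
                try:
                    net.add_edge(
                        src, NodeClass.PROTEIN, tgt.strip(), NodeClass.PROTEIN, itype
                    )
                except ValidationError as exc:
                    raise ParseError(path, line_no, str(exc))
    logger.info(
        "read network %s: %d nodes (%d gene, %d protein), %d edges",
        path, len(net.nodes), net.n_gene_nodes, net.n_protein_nodes, len(net.edges),
    )
    return net


def write_network(net: AssociativeNetwork, path: str | Path) -> None:
    """Write a network in the canonical TSV dialect (deterministic order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_NETWORK_HEADER) + "\n")
        for e in sorted(
            net.edges,
            key=lambda e: (
                e.source.id, e.source.node_class.value,
                e.target.id, e.target.node_class.value, e.itype.value,
            ),
        ):
            fh.write(
                f"{e.source.id}\t{e.source.node_class.value}\t"
                f"{e.target.id}\t{e.target.node_class.value}\t{e.itype.value}\n"
            )


# --------------------------------------------------------------------------
# disease-gene I/O
# --------------------------------------------------------------------------

_DISEASE_HEADER = ["gene", "disease", "source", "relevance_score"]


def read_disease_genes(path: str | Path) -> DiseaseAssociationTable:
    """Read gene-disease association rows; duplicates are dropped with a warning."""
    lines = _data_lines(path)
    try:
        line_no, fields = next(lines)
    except StopIteration:
        raise ParseError(path, 1, "empty disease-gene file (header required)")
    _require_header(path, line_no, fields, _DISEASE_HEADER)
    table = DiseaseAssociationTable()
    seen: set[tuple[str, str, str]] = set()
    for line_no, fields in lines:
        if len(fields) != 4:
            raise ParseError(path, line_no, f"expected 4 columns, got {len(fields)}")
        gene, disease, source, score_txt = (f.strip() for f in fields)
        score: float | None = None
        if score_txt:
            try:
                score = float(score_txt)
            except ValueError:
                raise ParseError(path, line_no, f"bad relevance_score {score_txt!r}")
        key = (canon(gene), disease.lower(), source)
        if key in seen:
            logger.warning("%s:%d: duplicate association %s dropped", path, line_no, key)
            continue
        try:
            table.rows.append(DiseaseAssociation(gene, disease, source, score))
        except ValidationError as exc:
            raise ParseError(path, line_no, str(exc))
        seen.add(key)
    return table


def write_disease_genes(table: DiseaseAssociationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_DISEASE_HEADER) + "\n")
        for r in sorted(table.rows, key=lambda r: (r.gene, r.disease, r.source)):
            score = "" if r.relevance_score is None else f"{r.relevance_score:g}"
            fh.write(f"{r.gene}\t{r.disease}\t{r.source}\t{score}\n")


# --------------------------------------------------------------------------
# GO annotation / disease-process I/O
# --------------------------------------------------------------------------

def read_go_inputs(
    annotation_path: str | Path, links_path: str | Path
) -> tuple[GOAnnotations, DiseaseProcessLinks]:
    """Read GO biological-process annotations plus disease-process links.

    The annotation file is either two-column ``process_id<TAB>gene`` or
    GMT-style ``process_id<TAB>name<TAB>gene...``; the format is detected from
    the column counts.  The links file is two-column ``disease<TAB>process_id``.
    """
    rows = list(_data_lines(annotation_path))
    if not rows:
        raise ParseError(annotation_path, 1, "empty annotation file")
    is_gmt = any(len(fields) > 2 for _, fields in rows)
    genes_by_process: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for line_no, fields in rows:
        pid = fields[0].strip()
        if not GO_ID_RE.match(pid):
            raise ParseError(annotation_path, line_no, f"malformed GO id {pid!r}")
        if is_gmt:
            if len(fields) < 3:
                raise ParseError(
                    annotation_path, line_no, f"GMT line for {pid} lists no genes"
                )
            names[pid] = fields[1].strip()
            genes = [canon(g) for g in fields[2:] if g.strip()]
        else:
            genes = [canon(fields[1])]
        genes_by_process.setdefault(pid, set()).update(genes)
    ann = GOAnnotations(
        genes_by_process={p: frozenset(g) for p, g in genes_by_process.items()},
        names=names,
    )
    logger.info(
        "read %d GO processes over a universe of %d genes",
        len(ann.genes_by_process), len(ann.universe),
    )

    by_disease: dict[str, set[str]] = {}
    for line_no, fields in _data_lines(links_path):
        if len(fields) != 2:
            raise ParseError(links_path, line_no, f"expected 2 columns, got {len(fields)}")
        disease, pid = fields[0].strip(), fields[1].strip()
        if not GO_ID_RE.match(pid):
            raise ParseError(links_path, line_no, f"malformed GO id {pid!r}")
        by_disease.setdefault(disease, set()).add(pid)
    return ann, DiseaseProcessLinks(by_disease=by_disease)


def write_go_annotations(ann: GOAnnotations, path: str | Path) -> None:
    """Write annotations in GMT form (process, name, member genes)."""
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sorted(ann.genes_by_process):
            name = ann.names.get(pid, pid)
            members = "\t".join(sorted(ann.genes_by_process[pid]))
            fh.write(f"{pid}\t{name}\t{members}\n")


def write_disease_process_links(links: DiseaseProcessLinks, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for disease in sorted(links.by_disease):
            for pid in sorted(links.by_disease[disease]):
                fh.write(f"{disease}\t{pid}\n")


# --------------------------------------------------------------------------
# SNP catalog I/O
# --------------------------------------------------------------------------

_SNP_HEADER = [
    "snp_id", "gene", "eqtl_tissues", "maf", "associated_diseases", "gene_length_nt",
]


def _split_multi(txt: str) -> frozenset[str]:
    return frozenset(t.strip() for t in txt.split(";") if t.strip())


def read_snp_catalog(path: str | Path) -> list[SNPRecord]:
    """Read the per-SNP catalog (eQTL tissues and diseases semicolon-joined)."""
    lines = _data_lines(path)
    try:
        line_no, fields = next(lines)
    except StopIteration:
        raise ParseError(path, 1, "empty SNP catalog (header required)")
    _require_header(path, line_no, fields, _SNP_HEADER)
    records: list[SNPRecord] = []
    seen: set[tuple[str, str]] = set()
    for line_no, fields in lines:
        if len(fields) != 6:
            raise ParseError(path, line_no, f"expected 6 columns, got {len(fields)}")
        snp_id, gene, tissues, maf_txt, diseases, length_txt = (f.strip() for f in fields)
        try:
            rec = SNPRecord(
                snp_id=snp_id,
                gene=gene,
                eqtl_tissues=_split_multi(tissues),
                maf=float(maf_txt),
                associated_diseases=_split_multi(diseases),
                gene_length_nt=int(length_txt),
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(path, line_no, str(exc))
        key = (rec.snp_id, canon(rec.gene))
        if key in seen:
            raise ParseError(path, line_no, f"duplicate SNP row {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_snp_catalog(records: Iterable[SNPRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_SNP_HEADER) + "\n")
        for r in sorted(records, key=lambda r: (r.gene, r.snp_id)):
            fh.write(
                f"{r.snp_id}\t{r.gene}\t{';'.join(sorted(r.eqtl_tissues))}\t"
                f"{r.maf:g}\t{';'.join(sorted(r.associated_diseases))}\t"
                f"{r.gene_length_nt}\n"
            )


# --------------------------------------------------------------------------
# external score I/O
# --------------------------------------------------------------------------

def read_external_scores(path: str | Path, criterion_id: int) -> ExternalScoreTable:
    """Read a (gene, score) table for one of the external criteria 1-3."""
    if criterion_id not in SCORE_DIRECTIONS:
        raise ValidationError(
            f"external score tables exist only for criteria 1-3, got {criterion_id}"
        )
    scores: dict[str, float] = {}
    for line_no, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(path, line_no, f"expected 2 columns, got {len(fields)}")
        gene_txt, score_txt = fields[0].strip(), fields[1].strip()
        if gene_txt.lower() == "gene" and not scores:
            continue  # optional header
        gene = canon(gene_txt)
        if gene in scores:
            raise ParseError(path, line_no, f"duplicate gene {gene_txt!r}")
        try:
            scores[gene] = float(score_txt)
        except ValueError:
            raise ParseError(path, line_no, f"bad score {score_txt!r}")
    return ExternalScoreTable(criterion_id=criterion_id, scores=scores)


def write_external_scores(table: ExternalScoreTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tscore\n")
        for gene in sorted(table.scores):
            fh.write(f"{gene}\t{table.scores[gene]:.10g}\n")


# --------------------------------------------------------------------------
# comorbid-disease list I/O
# --------------------------------------------------------------------------

def read_comorbid_diseases(path: str | Path) -> list[str]:
    """Read a comorbid-disease whitelist, one disease name per line."""
    out: list[str] = []
    seen: set[str] = set()
    for _, fields in _data_lines(path):
        name = "\t".join(fields).strip()
        if name.lower() not in seen:
            out.append(name)
            seen.add(name.lower())
    return out


def write_comorbid_diseases(diseases: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in diseases:
            fh.write(f"{name}\n")


# --------------------------------------------------------------------------
# priority report I/O
# --------------------------------------------------------------------------

_REPORT_HEADER = ["gene"] + [f"rank{i}" for i in range(1, 11)] + ["average_rank"]


def write_priority_report(report: PriorityReport, path: str | Path) -> None:
    """Write the final priority table, ascending by average rank (6 decimals)."""
    if not report.rows:
        raise ValidationError("refusing to write an empty priority report")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_REPORT_HEADER) + "\n")
        for row in report.sorted_rows():
            ranks = "\t".join(f"{r:.6f}" for r in row.ranks)
            fh.write(f"{row.gene}\t{ranks}\t{row.average_rank:.6f}\n")


def read_priority_report(path: str | Path) -> PriorityReport:
    lines = _data_lines(path)
    try:
        line_no, fields = next(lines)
    except StopIteration:
        raise ParseError(path, 1, "empty priority report")
    _require_header(path, line_no, fields, _REPORT_HEADER)
    rows: list[PriorityRow] = []
    for line_no, fields in lines:
        if len(fields) != 12:
            raise ParseError(path, line_no, f"expected 12 columns, got {len(fields)}")
        try:
            ranks = tuple(float(f) for f in fields[1:11])
            avg = float(fields[11])
        except ValueError as exc:
            raise ParseError(path, line_no, str(exc))
        rows.append(PriorityRow(gene=fields[0].strip(), ranks=ranks, average_rank=avg))
    return PriorityReport(rows=rows)
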