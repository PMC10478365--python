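"""Self-contained synthetic study bundles with planted comorbidity drivers.

The generator emulates the database extracts the pipeline normally ingests:
two overlapping disease gene sets, a sparse typed association network over
all genes (associative edges dominate, mirroring real extract proportions),
GO biological-process annotations with a handful of processes linked to both
diseases, an eQTL SNP catalog, and external prioritizer score tables.

A small set of *driver* genes inside the disease overlap is planted with the
signatures a true comorbidity candidate would show — denser connectivity to
the shared gene set (partly through regulatory edges), preferential
annotation to the disease-shared processes, brain-eQTL SNPs with common
minor alleles and disease associations, and better external scores.  The
strength of every planted effect scales with a single `driver_signal` knob;
at 0 the drivers are statistically indistinguishable from the other shared
genes, which makes null calibration checks possible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .io_model import (
    AssociativeNetwork,
    DiseaseAssociation,
    EdgeRecord,
    DiseaseAssociationTable,
    DiseaseProcessLinks,
    ExternalScoreTable,
    GOAnnotations,
    InteractionType,
    NodeClass,
    PriorityReport,
    SNPRecord,
    ValidationError,
    canon,
    write_comorbid_diseases,
    write_disease_genes,
    write_disease_process_links,
    write_external_scores,
    write_go_annotations,
    write_network,
    write_snp_catalog,
)

logger = logging.getLogger("comorbid_rank")

__all__ = [
    "DEFAULT_TYPE_MIX",
    "COMORBID_DISEASES",
    "SyntheticConfig",
    "PlantedTruth",
    "StudyBundle",
    "generate_network",
    "network_from_type_counts",
    "generate_study",
    "write_study",
    "recovery_report",
]

_TYPE_ORDER = tuple(InteractionType)

#: Default per-type edge proportions, taken from the interaction-type
#: breakdown of a literature-extracted disease network (generic associations
#: dominate by two orders of magnitude); cosmetic realism only.
_ADHD_TYPE_COUNTS = (623, 16, 863, 4931, 4838, 131844, 5863)
DEFAULT_TYPE_MIX: dict[InteractionType, float] = {
    t: c / sum(_ADHD_TYPE_COUNTS) for t, c in zip(_TYPE_ORDER, _ADHD_TYPE_COUNTS)
}

#: Disorders recurrently reported comorbid with attention/reading disorders;
#: used as the criterion-10 whitelist of the synthetic study.
COMORBID_DISEASES: tuple[str, ...] = (
    "alcohol dependence",
    "major depressive disorder",
    "obesity",
    "Parkinson's disease",
    "schizophrenia",
)

#: Regulatory-tilted type mix used for the extra edges planted on drivers, so
#: the centrality signal reaches the regulatory subnetwork too.
_DRIVER_EDGE_MIX: dict[InteractionType, float] = {
    InteractionType.ACTIVITY_REGULATION: 0.10,
    InteractionType.DEGRADATION_REGULATION: 0.02,
    InteractionType.EXPRESSION_REGULATION: 0.18,
    InteractionType.TRANSPORT_REGULATION: 0.10,
    InteractionType.DOWNREGULATION: 0.10,
    InteractionType.ASSOCIATIVE: 0.35,
    InteractionType.PROTEIN_PROTEIN: 0.15,
}


def _rng(seed: int, artifact: str) -> np.random.Generator:
    """One pseudo-random stream per generated artifact, split by name, so
    adding an artifact never perturbs the others."""
    digest = hashlib.sha256(artifact.encode("utf-8")).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "big")])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-generation parameters.

    `overlap_fraction` fixes |A ∩ B| = round(overlap_fraction * n_genes);
    `driver_signal` in [0, 1] scales every planted driver effect.
    """

    n_genes: int = 200
    n_processes: int = 100
    overlap_fraction: float = 0.25
    n_drivers: int = 5
    edge_density: float = 0.08
    driver_signal: float = 0.9
    seed: int = 0
    disease_a: str = "ADHD"
    disease_b: str = "dyslexia"
    n_shared_processes: int = 8
    n_disease_only_processes: int = 10
    annotation_rate: float = 0.05
    mean_snps_per_gene: float = 2.0
    type_mix: Mapping[InteractionType, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_MIX)
    )

    @property
    def overlap_size(self) -> int:
        return int(round(self.overlap_fraction * self.n_genes))

    def validate(self) -> None:
        if self.n_genes < 4:
            raise ValidationError("n_genes must be at least 4")
        if not 0.0 < self.overlap_fraction < 1.0:
            raise ValidationError("overlap_fraction must lie in (0, 1)")
        if self.n_drivers > self.overlap_size:
            raise ValidationError(
                f"n_drivers={self.n_drivers} exceeds the disease overlap "
                f"({self.overlap_size} genes)"
            )
        if not 0.0 < self.edge_density <= 1.0:
            raise ValidationError("edge_density must lie in (0, 1]")
        if not 0.0 <= self.driver_signal <= 1.0:
            raise ValidationError("driver_signal must lie in [0, 1]")
        if not 0.0 < self.annotation_rate < 1.0:
            raise ValidationError("annotation_rate must lie in (0, 1)")
        if self.n_shared_processes < 2:
            raise ValidationError("need at least 2 disease-shared processes")
        if (
            self.n_shared_processes + 2 * self.n_disease_only_processes
            > self.n_processes
        ):
            raise ValidationError("not enough processes for the disease links")
        total = sum(self.type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"type_mix proportions sum to {total}, not 1")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated study."""

    drivers: frozenset[str]
    shared_processes: frozenset[str]
    driver_has_qualifying_snp: Mapping[str, bool]

    def to_json(self) -> str:
        return json.dumps(
            {
                "drivers": sorted(self.drivers),
                "shared_processes": sorted(self.shared_processes),
                "driver_has_qualifying_snp": dict(
                    sorted(self.driver_has_qualifying_snp.items())
                ),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        obj = json.loads(text)
        return cls(
            drivers=frozenset(obj["drivers"]),
            shared_processes=frozenset(obj["shared_processes"]),
            driver_has_qualifying_snp=dict(obj["driver_has_qualifying_snp"]),
        )


@dataclass
class StudyBundle:
    """Every input the pipeline consumes, in memory."""

    config: SyntheticConfig
    network: AssociativeNetwork
    disease_genes: DiseaseAssociationTable
    annotations: GOAnnotations
    process_links: DiseaseProcessLinks
    snp_catalog: list[SNPRecord]
    external_scores: dict[int, ExternalScoreTable]
    comorbid_diseases: list[str]


def _sample_types(
    rng: np.random.Generator, size: int, mix: Mapping[InteractionType, float]
) -> list[InteractionType]:
    probs = np.array([mix.get(t, 0.0) for t in _TYPE_ORDER], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(_TYPE_ORDER), size=size, p=probs)
    return [_TYPE_ORDER[i] for i in idx]


def generate_network(
    n_genes: int,
    edge_density: float,
    type_mix: Mapping[InteractionType, float],
    seed: int,
) -> AssociativeNetwork:
    """Erdos-Renyi-style simple typed network over `n_genes` gene entities."""
    if not 0.0 < edge_density <= 1.0:
        raise ValidationError("edge_density must lie in (0, 1]")
    total = sum(type_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"type_mix proportions sum to {total}, not 1")
    rng = _rng(seed, "standalone_network")
    symbols = [f"GENE{i:04d}" for i in range(n_genes)]
    net = AssociativeNetwork(name="synthetic")
    for s in symbols:
        net.add_node(_node(s, NodeClass.GENE))
    pairs = [(i, j) for i in range(n_genes) for j in range(i + 1, n_genes)]
    mask = rng.random(len(pairs)) < edge_density
    chosen = [p for p, m in zip(pairs, mask) if m]
    types = _sample_types(rng, len(chosen), type_mix)
    for (i, j), t in zip(chosen, types):
        net.add_edge(symbols[i], NodeClass.GENE, symbols[j], NodeClass.GENE, t)
    return net


def _node(symbol: str, node_class: NodeClass):
    from .io_model import NodeRecord

    return NodeRecord(symbol, node_class)


def network_from_type_counts(
    n_gene_nodes: int,
    n_protein_nodes: int,
    per_type_counts: Mapping[InteractionType, int],
    seed: int = 0,
    name: str = "reconstructed",
) -> AssociativeNetwork:
    """Random typed network with *exactly* the requested node and per-type
    edge counts (for reproducing published accounting tables)."""
    total_nodes = n_gene_nodes + n_protein_nodes
    needed = sum(per_type_counts.values())
    if total_nodes < 2 and needed > 0:
        raise ValidationError("cannot place edges on fewer than 2 nodes")
    capacity = total_nodes * (total_nodes - 1)  # directed, no self-loops
    if any(c > capacity for c in per_type_counts.values()):
        raise ValidationError("per-type count exceeds the number of ordered node pairs")
    rng = _rng(seed, f"type_counts:{name}")
    nodes = [
        _node(f"G{i:04d}", NodeClass.GENE) for i in range(n_gene_nodes)
    ] + [
        _node(f"P{i:04d}", NodeClass.PROTEIN) for i in range(n_protein_nodes)
    ]
    net = AssociativeNetwork(name=name)
    for node in nodes:
        net.add_node(node)
    for itype, count in per_type_counts.items():
        placed: set[int] = set()
        while len(placed) < count:  # batched rejection sampling of ordered pairs
            batch = max(1024, 2 * (count - len(placed)))
            ii = rng.integers(0, total_nodes, size=batch)
            jj = rng.integers(0, total_nodes, size=batch)
            for code in (ii * total_nodes + jj)[ii != jj].tolist():
                if code not in placed:
                    placed.add(code)
                    if len(placed) == count:
                        break
        edge_set = net.edges
        for code in placed:  # endpoints are pre-registered nodes
            edge_set.add(
                EdgeRecord(nodes[code // total_nodes], nodes[code % total_nodes], itype)
            )
    return net


def generate_study(config: SyntheticConfig) -> tuple[StudyBundle, PlantedTruth]:
    """Generate the full input bundle plus its planted ground truth.

    Deterministic given the config (one stream per artifact, keyed by the
    config seed).
    """
    config.validate()
    seed = config.seed
    n = config.n_genes
    symbols = [f"GENE{i:04d}" for i in range(n)]

    # ---- disease assignment and drivers ---------------------------------
    rng = _rng(seed, "assignment")
    perm = rng.permutation(n)
    n_ov = config.overlap_size
    shared = [symbols[i] for i in perm[:n_ov]]
    rest = [symbols[i] for i in perm[n_ov:]]
    half = len(rest) // 2
    a_only, b_only = rest[:half], rest[half:]
    drivers = sorted(rng.choice(shared, size=config.n_drivers, replace=False).tolist())
    driver_set = set(drivers)
    sig = config.driver_signal

    # ---- disease association table --------------------------------------
    rng = _rng(seed, "associations")
    assoc_rows: list[DiseaseAssociation] = []
    for disease, members in (
        (config.disease_a, shared + a_only),
        (config.disease_b, shared + b_only),
    ):
        for g in sorted(members):
            in_db = rng.random() < 0.75
            in_gc = rng.random() < 0.6
            if not in_db and not in_gc:
                in_db = True
            if in_db:
                assoc_rows.append(DiseaseAssociation(g, disease, "network_db"))
            if in_gc:
                score = round(float(rng.uniform(1.0, 100.0)), 2)
                assoc_rows.append(DiseaseAssociation(g, disease, "genecards", score))
    disease_genes = DiseaseAssociationTable(rows=assoc_rows)

    # ---- global typed network -------------------------------------------
    rng = _rng(seed, "network")
    has_protein = {g: bool(rng.random() < 0.5) for g in symbols}
    net = AssociativeNetwork(name="global")
    for g in symbols:
        net.add_node(_node(g, NodeClass.GENE))
        if has_protein[g]:
            net.add_node(_node(g, NodeClass.PROTEIN))

    def _endpoint_class(g: str) -> NodeClass:
        if has_protein[g] and rng.random() < 0.5:
            return NodeClass.PROTEIN
        return NodeClass.GENE

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    mask = rng.random(len(pairs)) < config.edge_density
    chosen = [p for p, m in zip(pairs, mask) if m]
    types = _sample_types(rng, len(chosen), config.type_mix)
    for (i, j), t in zip(chosen, types):
        u, v = symbols[i], symbols[j]
        net.add_edge(u, _endpoint_class(u), v, _endpoint_class(v), t)
    # extra driver connectivity into the shared gene set
    n_extra = int(round(sig * 0.4 * max(len(shared) - 1, 0)))
    for d in drivers:
        partners = [g for g in shared if g != d]
        if not partners or n_extra == 0:
            continue
        picked = rng.choice(partners, size=min(n_extra, len(partners)), replace=False)
        for partner, t in zip(picked, _sample_types(rng, len(picked), _DRIVER_EDGE_MIX)):
            net.add_edge(d, _endpoint_class(d), str(partner), _endpoint_class(str(partner)), t)

    # ---- GO annotations and disease-process links -----------------------
    rng = _rng(seed, "annotations")
    processes = [f"GO:{i + 1:07d}" for i in range(config.n_processes)]
    proc_idx = rng.permutation(config.n_processes)
    shared_procs = [processes[i] for i in proc_idx[: config.n_shared_processes]]
    a_procs = [
        processes[i]
        for i in proc_idx[
            config.n_shared_processes : config.n_shared_processes
            + config.n_disease_only_processes
        ]
    ]
    b_procs = [
        processes[i]
        for i in proc_idx[
            config.n_shared_processes
            + config.n_disease_only_processes : config.n_shared_processes
            + 2 * config.n_disease_only_processes
        ]
    ]
    base = config.annotation_rate
    p_shared_gene = min(0.95, base + 0.20 * sig)  # comorbid genes on shared processes
    p_driver = min(0.95, base + 0.90 * sig)  # drivers on shared processes
    shared_set = set(shared)
    genes_by_process: dict[str, set[str]] = {}
    for pid in processes:
        members: set[str] = set()
        on_shared_proc = pid in shared_procs
        for g in symbols:
            if on_shared_proc and g in driver_set:
                p = p_driver
            elif on_shared_proc and g in shared_set:
                p = p_shared_gene
            else:
                p = base
            if rng.random() < p:
                members.add(canon(g))
        if not members:  # keep every process annotated (non-empty invariant)
            members.add(canon(symbols[int(rng.integers(0, n))]))
        genes_by_process[pid] = members
    annotations = GOAnnotations(
        genes_by_process={p: frozenset(g) for p, g in genes_by_process.items()},
        names={p: f"synthetic process {i + 1}" for i, p in enumerate(processes)},
    )
    process_links = DiseaseProcessLinks(
        by_disease={
            config.disease_a: set(shared_procs) | set(a_procs),
            config.disease_b: set(shared_procs) | set(b_procs),
        }
    )

    # ---- SNP catalog -----------------------------------------------------
    rng = _rng(seed, "snps")
    other_tissues = ("liver", "blood", "muscle")
    snp_catalog: list[SNPRecord] = []
    snp_counter = 0
    gene_length = {
        g: int(rng.integers(5_000, 200_000)) for g in symbols
    }
    driver_snp_flag: dict[str, bool] = {}

    def _new_snp(
        gene: str,
        tissues: frozenset[str],
        maf: float,
        diseases: frozenset[str],
    ) -> SNPRecord:
        nonlocal snp_counter
        snp_counter += 1
        return SNPRecord(
            snp_id=f"rs{snp_counter:06d}",
            gene=gene,
            eqtl_tissues=tissues,
            maf=round(maf, 4),
            associated_diseases=diseases,
            gene_length_nt=gene_length[gene],
        )

    for g in symbols:
        for _ in range(int(rng.poisson(config.mean_snps_per_gene))):
            tissues = set()
            if rng.random() < 0.4:
                tissues.add("brain")
            tissues.add(other_tissues[int(rng.integers(0, len(other_tissues)))])
            maf = float(rng.uniform(0.0, 0.5))
            diseases: set[str] = set()
            if rng.random() < 0.04:
                pool = (config.disease_a, config.disease_b) + COMORBID_DISEASES
                diseases.add(pool[int(rng.integers(0, len(pool)))])
            snp_catalog.append(
                _new_snp(g, frozenset(tissues), maf, frozenset(diseases))
            )
    for d in drivers:
        planted = bool(rng.random() < sig)
        driver_snp_flag[d] = planted
        if planted:
            snp_catalog.append(
                _new_snp(
                    d,
                    frozenset({"brain"}),
                    float(rng.uniform(0.05, 0.5)),
                    frozenset({config.disease_a, COMORBID_DISEASES[0]}),
                )
            )

    # ---- external prioritizer scores ------------------------------------
    external: dict[int, ExternalScoreTable] = {}
    rng = _rng(seed, "external_scores")
    scores1 = {
        canon(g): round(float(rng.uniform(1.0, 30.0)) + (50.0 * sig if g in driver_set else 0.0), 4)
        for g in shared
    }
    scores2 = {
        canon(g): round(
            float(rng.uniform(1e-3, 1.0)) * ((1.0 - 0.95 * sig) if g in driver_set else 1.0),
            8,
        )
        for g in shared
    }
    scores3 = {
        canon(g): round(float(rng.uniform(0.0, 1.0)) + (2.0 * sig if g in driver_set else 0.0), 4)
        for g in shared
    }
    external[1] = ExternalScoreTable(criterion_id=1, scores=scores1)
    external[2] = ExternalScoreTable(criterion_id=2, scores=scores2)
    external[3] = ExternalScoreTable(criterion_id=3, scores=scores3)

    bundle = StudyBundle(
        config=config,
        network=net,
        disease_genes=disease_genes,
        annotations=annotations,
        process_links=process_links,
        snp_catalog=snp_catalog,
        external_scores=external,
        comorbid_diseases=list(COMORBID_DISEASES),
    )
    truth = PlantedTruth(
        drivers=frozenset(drivers),
        shared_processes=frozenset(shared_procs),
        driver_has_qualifying_snp=driver_snp_flag,
    )
    return bundle, truth


def write_study(bundle: StudyBundle, truth: PlantedTruth, out_dir: str | Path) -> dict[str, Path]:
    """Materialize the bundle as pipeline-ready flat files plus truth.json.

    Returns the mapping of logical input name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "disease_genes": out / "disease_genes.tsv",
        "go_annotations": out / "go_annotations.gmt",
        "disease_process_links": out / "disease_processes.tsv",
        "snp_catalog": out / "snp_catalog.tsv",
        "external_scores_1": out / "scores_criterion1.tsv",
        "external_scores_2": out / "scores_criterion2.tsv",
        "external_scores_3": out / "scores_criterion3.tsv",
        "comorbid_diseases": out / "comorbid_diseases.txt",
        "truth": out / "truth.json",
    }
    write_network(bundle.network, paths["network"])
    write_disease_genes(bundle.disease_genes, paths["disease_genes"])
    write_go_annotations(bundle.annotations, paths["go_annotations"])
    write_disease_process_links(bundle.process_links, paths["disease_process_links"])
    write_snp_catalog(bundle.snp_catalog, paths["snp_catalog"])
    for cid in (1, 2, 3):
        write_external_scores(bundle.external_scores[cid], paths[f"external_scores_{cid}"])
    write_comorbid_diseases(bundle.comorbid_diseases, paths["comorbid_diseases"])
    paths["truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    return paths


def recovery_report(priority: PriorityReport, truth: PlantedTruth, k: int) -> float:
    """Fraction of planted drivers among the top-k rows of the report."""
    if not truth.drivers:
        raise ValidationError("empty planted truth: no drivers to recover")
    rows = priority.sorted_rows()
    if k > len(rows):
        raise ValidationError(f"k={k} exceeds the report size {len(rows)}")
    top = {canon(r.gene) for r in rows[:k]}
    drivers = {canon(d) for d in truth.drivers}
    return len(drivers & top) / len(drivers)
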