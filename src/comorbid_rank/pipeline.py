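"""End-to-end orchestration: files in, per-criterion intermediates and the
final priority report out.

Every stage's result is materialized as a TSV in the output directory for
auditability, and a JSON manifest records the thresholds, input digests and
seed needed to reproduce a run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import network_analysis as na
from . import enrichment as enr
from . import process_specificity as spec
from . import snp_criteria as snp
from . import prioritization as prio
from .io_model import (
    REGULATORY_TYPES,
    ExternalScoreTable,
    InteractionType,
    PipelineError,
    PriorityReport,
    ValidationError,
    read_comorbid_diseases,
    read_disease_genes,
    read_external_scores,
    read_go_inputs,
    read_network,
    read_snp_catalog,
    write_priority_report,
)

logger = logging.getLogger("comorbid_rank")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All paths, disease names and thresholds of one pipeline run."""

    network_path: str
    disease_genes_path: str
    go_annotations_path: str
    disease_process_links_path: str
    snp_catalog_path: str
    comorbid_diseases_path: str
    output_dir: str
    disease_a: str = "ADHD"
    disease_b: str = "dyslexia"
    network_dialect: str = "tsv"
    external_score_paths: dict[int, str | None] = field(
        default_factory=lambda: {1: None, 2: None, 3: None}
    )
    enrichment_alpha: float = 0.01
    enrichment_ease_offset: int = 0
    specificity_alpha: float = 0.05
    snp_tissue: str = "brain"
    snp_maf_min: float = 0.05
    hub_bc_min: float = 0.005
    hub_cc_min: float = 0.2
    hub_degree_gt: int = 40
    regulatory_types: frozenset[InteractionType] = REGULATORY_TYPES
    seed: int = 0

    def validate(self) -> None:
        for label, p in self.input_paths().items():
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input {label} not found: {p}")
        if not 0 < self.enrichment_alpha < 1 or not 0 < self.specificity_alpha < 1:
            raise ValidationError("significance levels must lie in (0, 1)")
        if not 0 < self.snp_maf_min < 1:
            raise ValidationError("snp_maf_min must lie in (0, 1)")

    def input_paths(self) -> dict[str, str | None]:
        out: dict[str, str | None] = {
            "network": self.network_path,
            "disease_genes": self.disease_genes_path,
            "go_annotations": self.go_annotations_path,
            "disease_process_links": self.disease_process_links_path,
            "snp_catalog": self.snp_catalog_path,
            "comorbid_diseases": self.comorbid_diseases_path,
        }
        for cid in (1, 2, 3):
            out[f"external_scores_{cid}"] = self.external_score_paths.get(cid)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent

        def _resolve(p):
            return None if p is None else str((base / p) if not Path(p).is_absolute() else Path(p))

        inputs = raw.get("inputs", {})
        thresholds = raw.get("thresholds", {})
        ext = inputs.get("external_scores", {}) or {}
        reg = raw.get("regulatory_types")
        return cls(
            network_path=_resolve(inputs["network"]),
            disease_genes_path=_resolve(inputs["disease_genes"]),
            go_annotations_path=_resolve(inputs["go_annotations"]),
            disease_process_links_path=_resolve(inputs["disease_process_links"]),
            snp_catalog_path=_resolve(inputs["snp_catalog"]),
            comorbid_diseases_path=_resolve(inputs["comorbid_diseases"]),
            output_dir=_resolve(raw.get("output_dir", "results")),
            disease_a=raw.get("disease_a", "ADHD"),
            disease_b=raw.get("disease_b", "dyslexia"),
            network_dialect=inputs.get("network_dialect", "tsv"),
            external_score_paths={
                cid: _resolve(ext.get(cid, ext.get(str(cid)))) for cid in (1, 2, 3)
            },
            enrichment_alpha=float(thresholds.get("enrichment.alpha", 0.01)),
            enrichment_ease_offset=int(thresholds.get("enrichment.ease_offset", 0)),
            specificity_alpha=float(thresholds.get("specificity.alpha", 0.05)),
            snp_tissue=str(thresholds.get("snp.tissue", "brain")),
            snp_maf_min=float(thresholds.get("snp.maf_min", 0.05)),
            hub_bc_min=float(thresholds.get("hub.bc_min", 0.005)),
            hub_cc_min=float(thresholds.get("hub.cc_min", 0.2)),
            hub_degree_gt=int(thresholds.get("hub.degree_gt", 40)),
            regulatory_types=(
                frozenset(InteractionType.parse(t) for t in reg)
                if reg is not None
                else REGULATORY_TYPES
            ),
            seed=int(raw.get("seed", 0)),
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager that renames any stage failure after the stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, PipelineError):
            raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(config: RunConfig) -> PriorityReport:
    """Execute every stage and write the intermediates, report and manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _Stage("read_inputs"):
        global_net = read_network(config.network_path, dialect=config.network_dialect)
        assoc = read_disease_genes(config.disease_genes_path)
        annotations, links = read_go_inputs(
            config.go_annotations_path, config.disease_process_links_path
        )
        catalog = read_snp_catalog(config.snp_catalog_path)
        comorbid = read_comorbid_diseases(config.comorbid_diseases_path)
        externals: list[ExternalScoreTable | None] = []
        missing_external: list[int] = []
        for cid in (1, 2, 3):
            path = config.external_score_paths.get(cid)
            if path is None:
                missing_external.append(cid)
                externals.append(None)
            else:
                externals.append(read_external_scores(path, cid))

    with _Stage("intersect_networks"):
        complete = na.intersect_disease_networks(
            assoc, config.disease_a, config.disease_b, global_net
        )
        candidates = complete.entities()
        if not candidates:
            raise ValidationError(
                f"no shared genes: {config.disease_a!r} and {config.disease_b!r} "
                "have an empty comorbidity gene set in the global network"
            )
        regulatory = na.extract_regulatory_subnetwork(complete, config.regulatory_types)
        na.write_network_summary(
            na.summarize_network(complete), out / "network_summary_complete.tsv"
        )
        na.write_network_summary(
            na.summarize_network(regulatory), out / "network_summary_regulatory.tsv"
        )

    with _Stage("enrichment"):
        enriched_complete = enr.enrich_processes(
            candidates,
            annotations,
            alpha=config.enrichment_alpha,
            ease_offset=config.enrichment_ease_offset,
        )
        reg_entities = regulatory.entities()
        enriched_regulatory = (
            enr.enrich_processes(
                reg_entities,
                annotations,
                alpha=config.enrichment_alpha,
                ease_offset=config.enrichment_ease_offset,
            )
            if reg_entities and set(c.upper() for c in reg_entities) & set(annotations.universe)
            else []
        )
        enr.write_enrichment(enriched_complete, out / "enrichment_complete.tsv")
        enr.write_enrichment(enriched_regulatory, out / "enrichment_regulatory.tsv")
        c4 = enr.criterion4_counts(enriched_complete, enriched_regulatory, candidates)
        with open(out / "criterion4_counts.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene\tn1\tn2\tn_total\n")
            for g in candidates:
                key = g.upper()
                fh.write(
                    f"{g}\t{c4.n1.get(key, 0)}\t{c4.n2.get(key, 0)}\t{c4.n_total(g)}\n"
                )

    with _Stage("centralities"):
        cent_complete = na.compute_centralities(complete)
        na.write_centralities(cent_complete, out / "centralities_complete.tsv")
        if len(regulatory.entity_graph()) >= 2:
            cent_regulatory = na.compute_centralities(regulatory)
        else:
            logger.warning(
                "regulatory network has fewer than 2 entities; centrality "
                "criterion falls back to all-zero scores"
            )
            cent_regulatory = []
        na.write_centralities(cent_regulatory, out / "centralities_regulatory.tsv")
        hubs = na.detect_hubs(
            cent_complete,
            na.HubCriteria(
                bc_min=config.hub_bc_min,
                cc_min=config.hub_cc_min,
                degree_gt=config.hub_degree_gt,
            ),
        )
        (out / "hubs_complete.txt").write_text(
            "".join(f"{h}\n" for h in sorted(hubs)), encoding="utf-8"
        )

    with _Stage("process_specificity"):
        sets = spec.build_test_control_sets(
            links, config.disease_a, config.disease_b, annotations
        )
        c7 = spec.criterion7_scores(
            candidates, annotations, sets, alpha=config.specificity_alpha
        )
        spec.write_specificity(c7, out / "specificity.tsv")

    with _Stage("snp_criteria"):
        index = snp.filter_qualifying_snps(
            catalog, tissue=config.snp_tissue, maf_min=config.snp_maf_min
        )
        c8 = snp.binary_snp_criterion(candidates, index, 8)
        c9 = snp.binary_snp_criterion(
            candidates, index, 9, disease_whitelist={config.disease_a, config.disease_b}
        )
        c10 = snp.binary_snp_criterion(candidates, index, 10, disease_whitelist=comorbid)
        for cid, ranks in ((8, c8), (9, c9), (10, c10)):
            snp.write_binary_ranks(ranks, out / f"criterion{cid}_ranks.tsv")

    with _Stage("aggregate"):
        matrix = prio.assemble_rank_matrix(
            externals, c4, cent_complete, cent_regulatory, c7, c8, c9, c10, candidates
        )
        prio.write_rank_matrix(matrix, out / "rank_matrix.tsv")
        report = prio.aggregate_average_rank(matrix)
        write_priority_report(report, out / "priority_report.tsv")

    with _Stage("manifest"):
        manifest = {
            "diseases": [config.disease_a, config.disease_b],
            "n_candidates": len(candidates),
            "seed": config.seed,
            "thresholds": {
                "enrichment.alpha": config.enrichment_alpha,
                "enrichment.ease_offset": config.enrichment_ease_offset,
                "specificity.alpha": config.specificity_alpha,
                "snp.tissue": config.snp_tissue,
                "snp.maf_min": config.snp_maf_min,
                "hub.bc_min": config.hub_bc_min,
                "hub.cc_min": config.hub_cc_min,
                "hub.degree_gt": config.hub_degree_gt,
            },
            "regulatory_types": sorted(t.value for t in config.regulatory_types),
            "missing_external_criteria": missing_external,
            "input_digests": {
                label: (None if p is None else _sha256(p))
                for label, p in config.input_paths().items()
            },
            "criterion_provenance": {
                str(cid): prov for cid, prov in sorted(matrix.provenance.items())
            },
        }
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return report
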