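"""Configuration-driven three-stage pipeline driver.

Stage 1 builds the disease context, stage 2 collects enriched disease-map
and pathway diagrams and the refined text-mining network, stage 3 merges
everything into one CellDesigner-SBML map and bundles it with the data
overlays.  Every stage writes its outputs under ``output_dir``, and
``run_pipeline`` is literally the composition of the five stage functions,
each reading the files the previous one wrote — so running the stages
individually produces byte-identical results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import assembly, context as ctx, diagram_io, enrichment, network, overlays
from .model import SourceKind, diagram_stats

log = logging.getLogger("mapforge")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Declarative run configuration; mirrors every tunable of the workflow."""

    disease: dict = field(default_factory=dict)
    sources_dir: str = "sources"
    disease_maps_dir: Optional[str] = None
    wikipathways_dir: Optional[str] = None
    reactome_dir: Optional[str] = None
    string_edges: Optional[str] = None
    directed_edges: Optional[str] = None
    deg_table: Optional[str] = None
    output_dir: str = "output"
    disgenet_min_score: float = 0.3
    disgenet_max_genes: int = 100
    opentargets_min_score: float = 0.3
    vep_af_threshold: float = 0.01
    populations: list = field(default_factory=lambda: ["EUR", "AFR", "EAS"])
    hpo_top_k: int = 5
    max_disease_map_diagrams: int = 3
    max_pathways_per_collection: int = 5
    string_min_score: int = 700
    string_max_new_neighbors: int = 100
    layout_seed: int = 42
    layout_iterations: int = 100
    layout_width: float = 1000.0
    layout_height: float = 1000.0
    margin: float = 20.0
    highlight_color: str = "#0000FF"
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f.name for f in fields(cls)} - {"base_dir"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"unknown configuration key(s): {sorted(unknown)}; "
                f"known keys: {sorted(known)}"
            )
        cfg = cls(**raw, base_dir=path.parent)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        d = self.disease or {}
        if bool(d.get("orpha_ids")) == bool(d.get("hpo_terms")):
            raise ConfigError(
                "disease must provide exactly one of orpha_ids / hpo_terms"
            )
        for name in ("disgenet_min_score", "opentargets_min_score"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} outside [0,1]: {v}")
        if not 0 < self.vep_af_threshold <= 1:
            raise ConfigError(
                f"vep_af_threshold outside (0,1]: {self.vep_af_threshold}"
            )
        if not 0 <= self.string_min_score <= 1000:
            raise ConfigError(
                f"string_min_score outside [0,1000]: {self.string_min_score}"
            )
        if self.disgenet_max_genes < 1 or self.max_pathways_per_collection < 1:
            raise ConfigError("count limits must be >= 1")

    def path(self, p: str | None) -> Optional[Path]:
        if p is None:
            return None
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    @property
    def out(self) -> Path:
        out = self.path(self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def _query(cfg: PipelineConfig) -> ctx.DiseaseQuery:
    d = cfg.disease or {}
    return ctx.DiseaseQuery(
        orpha_ids=list(d.get("orpha_ids") or []),
        hpo_terms=list(d.get("hpo_terms") or []),
    )


# ---------------------------------------------------------------------------
# Stage 1 — context
# ---------------------------------------------------------------------------

def stage_context(cfg: PipelineConfig) -> ctx.DiseaseContext:
    sources = ctx.AssociationSources.from_dir(cfg.path(cfg.sources_dir))
    thresholds = {
        "disgenet": cfg.disgenet_min_score,
        "opentargets": cfg.opentargets_min_score,
    }
    context = ctx.build_context(
        _query(cfg),
        sources,
        score_thresholds=thresholds,
        max_genes=cfg.disgenet_max_genes,
        af_threshold=cfg.vep_af_threshold,
        populations=cfg.populations,
        hpo_top_k=cfg.hpo_top_k,
    )
    out = cfg.out
    context.to_tsv(out / "context.tsv")
    context.discrepancy_report.to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "context.json").write_text(
        json.dumps(
            {
                "genes": context.genes,
                "variants": [
                    {
                        "variant_id": v.variant_id,
                        "gene": v.gene,
                        "clinical_significance": v.clinical_significance,
                        "score": v.score,
                        "source": v.source,
                    }
                    for v in context.variants
                ],
                "provenance": {
                    k: sorted(v) for k, v in sorted(context.provenance.items())
                },
                "warnings": context.warnings,
            },
            indent=2,
        )
        + "\n"
    )
    log.info(
        "stage 1: %d genes, %d variants (thresholds disgenet>=%s, "
        "opentargets>=%s, AF<%s over %s)",
        len(context.genes), len(context.variants), cfg.disgenet_min_score,
        cfg.opentargets_min_score, cfg.vep_af_threshold, cfg.populations,
    )
    return context


def _load_context(cfg: PipelineConfig) -> dict:
    p = cfg.out / "context.json"
    if not p.exists():
        raise ConfigError(f"missing stage input: {p} (run the context stage first)")
    return json.loads(p.read_text())


# ---------------------------------------------------------------------------
# Stage 2a/2b — enrichment over diagram collections
# ---------------------------------------------------------------------------

_COLLECTIONS = (
    ("disease_maps", "disease_maps_dir", "disease_map"),
    ("wikipathways", "wikipathways_dir", "wikipathways"),
    ("reactome", "reactome_dir", "reactome"),
)


def stage_enrich(cfg: PipelineConfig) -> dict[str, list]:
    genes = _load_context(cfg)["genes"]
    out = cfg.out
    results: dict[str, list] = {}
    for name, attr, collection_kind in _COLLECTIONS:
        directory = cfg.path(getattr(cfg, attr))
        if directory is None or not Path(directory).exists():
            log.info("stage 2: collection %s not configured; skipped", name)
            results[name] = []
            continue
        sets = enrichment.load_gene_set_collection(
            Path(directory) / "sets.gmt",
            Path(directory) / "sets_meta.tsv",
            collection=collection_kind,
        )
        max_results = (
            cfg.max_disease_map_diagrams
            if name == "disease_maps"
            else cfg.max_pathways_per_collection
        )
        res = enrichment.enrich_collection(genes, sets, max_results=max_results)
        if collection_kind == "reactome":
            res = enrichment.filter_reactome(res, {s.set_id: s for s in sets})
        set_index = {s.set_id: s for s in sets}
        frame = enrichment.results_to_frame(res)
        # stored relative to the collection directory, keeping stage
        # outputs location-independent
        frame["diagram_path"] = [
            (Path(set_index[r.set_id].diagram_path).name
             if set_index[r.set_id].diagram_path else "")
            for r in res
        ]
        frame.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
        log.info("stage 2: %s -> %d enriched diagram(s) (max %d)",
                 name, len(res), max_results)
        results[name] = res
    return results


# ---------------------------------------------------------------------------
# Stage 2c — text-mining network
# ---------------------------------------------------------------------------

def stage_network(cfg: PipelineConfig) -> None:
    genes = _load_context(cfg)["genes"]
    out = cfg.out
    if cfg.string_edges is None:
        log.info("stage 2c: no scored-interaction table configured; skipped")
        (out / "textmining.gpml").write_text("")
        return
    scored = network.read_scored_edges(cfg.path(cfg.string_edges))
    directed = (
        network.read_directed_edges(cfg.path(cfg.directed_edges))
        if cfg.directed_edges
        else []
    )
    params = network.LayoutParams(
        width=cfg.layout_width,
        height=cfg.layout_height,
        iterations=cfg.layout_iterations,
        seed=cfg.layout_seed,
    )
    warnings: list[str] = []
    gpml, nodes, refined, unsupported = network.build_textmining_network(
        genes, scored, directed,
        min_score=cfg.string_min_score,
        max_new=cfg.string_max_new_neighbors,
        layout=params,
        warnings=warnings,
    )
    (out / "textmining.gpml").write_text(gpml)
    pd.DataFrame(
        [(e.a, e.b, e.score) for e in unsupported],
        columns=["protein1", "protein2", "combined_score"],
    ).to_csv(out / "textmining_undirected_sidecar.tsv", sep="\t", index=False)
    log.info(
        "stage 2c: %d nodes, %d directed interactions kept "
        "(min_score=%d, max_new=%d, layout seed=%d)",
        len(nodes), len(refined), cfg.string_min_score,
        cfg.string_max_new_neighbors, cfg.layout_seed,
    )


# ---------------------------------------------------------------------------
# Stage 3a — assembly
# ---------------------------------------------------------------------------

_COLLECTION_DIRS = {name: attr for name, attr, _ in _COLLECTIONS}


def _enriched_diagrams(cfg: PipelineConfig, name: str) -> list:
    p = cfg.out / f"enrichment_{name}.tsv"
    if not p.exists():
        return []
    base = cfg.path(getattr(cfg, _COLLECTION_DIRS[name]))
    df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    diagrams = []
    for r in df.itertuples():
        if not r.diagram_path:
            continue
        d, _report = diagram_io.parse_diagram_file(base / r.diagram_path)
        diagrams.append(d)
    return diagrams


def stage_assemble(cfg: PipelineConfig) -> None:
    out = cfg.out
    dm = _enriched_diagrams(cfg, "disease_maps")
    pw = _enriched_diagrams(cfg, "wikipathways") + _enriched_diagrams(
        cfg, "reactome"
    )
    tm_path = out / "textmining.gpml"
    tm = tm_path.read_text() if tm_path.exists() else None
    warnings: list[str] = []
    final, _report = assembly.assemble_map(
        dm, tm or None, pw, margin=cfg.margin, warnings=warnings
    )
    (out / "map.xml").write_text(diagram_io.write_celldesigner_sbml(final))
    elements, interactions = diagram_stats(final)
    log.info("stage 3a: merged map with %d unique elements and %d interactions",
             elements, interactions)


# ---------------------------------------------------------------------------
# Stage 3b-3d — overlays and bundle
# ---------------------------------------------------------------------------

def stage_overlay(cfg: PipelineConfig) -> Path:
    out = cfg.out
    data = _load_context(cfg)
    map_path = out / "map.xml"
    if not map_path.exists():
        raise ConfigError(f"missing stage input: {map_path} (run assemble first)")
    context = ctx.DiseaseContext(
        genes=data["genes"],
        variants=[
            ctx.VariantAssociation(
                variant_id=v["variant_id"],
                gene=v["gene"],
                clinical_significance=v["clinical_significance"],
                score=v["score"],
                source=v["source"],
            )
            for v in data["variants"]
        ],
    )
    overlay_files = {
        "genes": overlays.render_gene_overlay(
            overlays.build_gene_overlay(context, color=cfg.highlight_color)
        ),
        "variants": overlays.render_variant_overlay(
            overlays.build_variant_overlay(context.variants)
        ),
    }
    deg_survivors = 0
    if cfg.deg_table is not None and Path(cfg.path(cfg.deg_table)).exists():
        deg = pd.read_csv(cfg.path(cfg.deg_table), sep="\t")
        surviving = overlays.filter_deg(deg)
        deg_survivors = len(surviving)
        if deg_survivors:
            overlay_files["expression"] = overlays.render_expression_overlay(
                overlays.normalize_logfc(surviving)
            )
    bundle_path = overlays.write_bundle(
        map_path.read_text(), overlay_files, out / "map_bundle.zip"
    )
    log.info("stage 3: bundle written to %s (%d DEG survivors)",
             bundle_path, deg_survivors)
    return bundle_path


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> tuple[Path, dict]:
    """Execute the three stages and write ``report.json``.

    Returns (bundle path, run report).  The report carries the counts that
    describe a run: genes and variants in the context, diagrams retrieved
    per collection, text-mining interactions, and final map statistics.
    """
    context = stage_context(cfg)
    enriched = stage_enrich(cfg)
    stage_network(cfg)
    stage_assemble(cfg)
    bundle = stage_overlay(cfg)

    out = cfg.out
    tm_gpml = (out / "textmining.gpml").read_text()
    tm_interactions = 0
    if tm_gpml:
        tm_diag, _ = diagram_io.parse_gpml(tm_gpml)
        tm_interactions = len(tm_diag.arcs)
    final = diagram_io.parse_celldesigner_sbml((out / "map.xml").read_text())
    elements, interactions = diagram_stats(final)
    deg_survivors = 0
    if cfg.deg_table is not None and Path(cfg.path(cfg.deg_table)).exists():
        deg_survivors = len(
            overlays.filter_deg(pd.read_csv(cfg.path(cfg.deg_table), sep="\t"))
        )
    report = {
        "genes": len(context.genes),
        "variants": len(context.variants),
        "diagrams_retrieved": {k: len(v) for k, v in enriched.items()},
        "textmining_interactions": tm_interactions,
        "map_unique_elements": elements,
        "map_interactions": interactions,
        "deg_survivors": deg_survivors,
        "parameters": {
            "disgenet_min_score": cfg.disgenet_min_score,
            "opentargets_min_score": cfg.opentargets_min_score,
            "vep_af_threshold": cfg.vep_af_threshold,
            "max_disease_map_diagrams": cfg.max_disease_map_diagrams,
            "max_pathways_per_collection": cfg.max_pathways_per_collection,
            "string_min_score": cfg.string_min_score,
            "string_max_new_neighbors": cfg.string_max_new_neighbors,
            "layout_seed": cfg.layout_seed,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return bundle, report
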