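"""Deterministic synthetic input worlds with planted ground truth.

The generator emits every file the pipeline consumes — phenotype
annotations, gene/variant association tables, allele frequencies, the
ORPHA↔EFO map, disease-map CellDesigner diagrams, WikiPathways GPML and
Reactome SBML+layout collections with sidecar metadata, STRING-style scored
and OmniPath-style directed interaction tables, and an edgeR-style
differential-expression table — all synthetic, into one world directory,
together with a ``ground_truth.json`` record and a ready-to-run
``config.yaml``.

Planted signal is separable by construction, not statistically: planted
pathway sets contain >= 80% disease genes while decoy sets contain at most
one, disease-gene association scores sit well above the recommended
thresholds while decoy scores sit well below, and common variants carry
population allele frequencies orders of magnitude above the rarity
threshold.  Recovery tests against the ground truth are therefore exact.

The synthetic differential-expression table stands in for a real
RNA-seq-derived per-gene statistics table; by default it plants 371 rows
passing the FDR < 0.05, |FC| > 2 filter — the survivor count of the
retinitis-pigmentosa organoid dataset this workflow is demonstrated on —
plus a bed of failing rows.

All randomness flows from one seeded generator; the same spec produces
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from lxml import etree

from .diagram_io import (
    GPML_NS,
    LAYOUT_NS,
    SBML_L3_NS,
    write_celldesigner_sbml,
)
from .model import Arc, ArcClass, Diagram, Glyph, GlyphClass, SourceKind


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Knobs of the synthetic world; defaults mirror the demonstrated
    workflow runs (3 disease-map areas retrieved, 5 pathways per database,
    rarity threshold 1%, STRING minimum score 700)."""

    seed: int = 0
    orpha_id: str = "ORPHA:900001"
    efo_id: str = "EFO:0900001"
    n_disease_genes: int = 20
    n_decoy_genes: int = 60
    n_variants: int = 6            # rare pathogenic, survive the AF filter
    n_common_variants: int = 3     # high population AF, removed by the filter
    n_benign_variants: int = 2     # scored sources + ClinVar-benign conflict
    n_pathways: int = 8            # per pathway collection
    genes_per_pathway: int = 8
    n_planted_pathways: int = 3
    n_disease_map_areas: int = 6
    n_planted_disease_maps: int = 3
    n_neighbors: int = 10          # planted STRING neighbors
    string_module_score: tuple[int, int] = (900, 999)
    string_neighbor_score: tuple[int, int] = (850, 950)
    string_background_score: tuple[int, int] = (150, 400)
    af_rare: tuple[float, float] = (1e-5, 1e-3)
    af_common: tuple[float, float] = (0.1, 0.3)
    populations: tuple[str, ...] = ("EUR", "AFR", "EAS")
    disgenet_score_range: tuple[float, float] = (0.6, 0.95)
    decoy_score_range: tuple[float, float] = (0.05, 0.25)
    n_deg_pass: int = 371
    n_deg_fail: int = 129

    def validate(self) -> None:
        if self.n_planted_pathways > self.n_pathways:
            raise FixtureError("planted pathways exceed total pathways")
        if self.n_planted_disease_maps > self.n_disease_map_areas:
            raise FixtureError("planted disease maps exceed total areas")
        for name in ("n_disease_genes", "n_decoy_genes", "n_variants",
                     "n_pathways", "genes_per_pathway"):
            if getattr(self, name) < 0:
                raise FixtureError(f"{name} must be >= 0")
        if self.genes_per_pathway > self.n_disease_genes:
            raise FixtureError("genes_per_pathway exceeds disease gene count")


@dataclass
class GroundTruth:
    """What the generator planted; the pipeline should recover exactly."""

    orpha_id: str
    disease_genes: list[str]
    decoy_genes: list[str]
    neighbor_genes: list[str]
    rare_variants: list[str]
    common_variants: list[str]
    benign_conflict_variants: list[str]
    planted_disease_map_sets: list[str]
    planted_wikipathways_sets: list[str]
    planted_reactome_sets: list[str]
    directed_module_edges: list[list[str]]
    deg_pass_genes: list[str]
    n_deg_fail: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _write_tsv(path: Path, header: Sequence[str],
               rows: Sequence[Sequence]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(c) for c in row))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Diagram writers used only by the generator
# ---------------------------------------------------------------------------

def _grid_positions(n: int, cell_w: float = 120.0, cell_h: float = 60.0,
                    cols: int = 4):
    return [((i % cols) * cell_w + 10, (i // cols) * cell_h + 10)
            for i in range(n)]


def make_gene_diagram(genes: Sequence[str], title: str) -> Diagram:
    """Small protein diagram: genes on a grid, chained state transitions."""
    d = Diagram(title=title, source_kind=SourceKind.DISEASE_MAP,
                source_id=title)
    for i, (g, (x, y)) in enumerate(zip(genes, _grid_positions(len(genes)))):
        d.glyphs.append(
            Glyph(
                id=f"g{i + 1}", label=g, glyph_class=GlyphClass.PROTEIN,
                x=x, y=y, width=80, height=25,
                annotations=frozenset({("hgnc.symbol", g)}),
            )
        )
    for i in range(len(genes) - 1):
        d.arcs.append(
            Arc(id=f"a{i + 1}", source_id=f"g{i + 1}", target_id=f"g{i + 2}",
                arc_class=ArcClass.STATE_TRANSITION, directed=True)
        )
    return d


def write_gpml_pathway(genes: Sequence[str], title: str) -> str:
    root = etree.Element(f"{{{GPML_NS}}}Pathway", nsmap={None: GPML_NS})
    root.set("Name", title)
    for i, (g, (x, y)) in enumerate(zip(genes, _grid_positions(len(genes)))):
        dn = etree.SubElement(root, f"{{{GPML_NS}}}DataNode")
        dn.set("TextLabel", g)
        dn.set("GraphId", f"n{i + 1}")
        dn.set("Type", "GeneProduct")
        gfx = etree.SubElement(dn, f"{{{GPML_NS}}}Graphics")
        gfx.set("CenterX", _fmt(x + 40))
        gfx.set("CenterY", _fmt(y + 12.5))
        gfx.set("Width", "80")
        gfx.set("Height", "25")
        xref = etree.SubElement(dn, f"{{{GPML_NS}}}Xref")
        xref.set("Database", "HGNC")
        xref.set("ID", g)
    for i in range(len(genes) - 1):
        inter = etree.SubElement(root, f"{{{GPML_NS}}}Interaction")
        inter.set("GraphId", f"i{i + 1}")
        gfx = etree.SubElement(inter, f"{{{GPML_NS}}}Graphics")
        for ref, arrow in ((f"n{i + 1}", None), (f"n{i + 2}", "Arrow")):
            pt = etree.SubElement(gfx, f"{{{GPML_NS}}}Point")
            pt.set("X", "0")
            pt.set("Y", "0")
            pt.set("GraphRef", ref)
            if arrow:
                pt.set("ArrowHead", arrow)
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode()


def write_sbml_layout_pathway(genes: Sequence[str], title: str) -> str:
    """SBML L3 + layout document: laid-out protein species, one reaction
    between the first two species."""
    nsmap = {None: SBML_L3_NS, "layout": LAYOUT_NS}
    sbml = etree.Element(f"{{{SBML_L3_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    model = etree.SubElement(sbml, f"{{{SBML_L3_NS}}}model")
    model.set("id", title.replace(" ", "_"))
    model.set("name", title)
    los = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfSpecies")
    for i, g in enumerate(genes):
        sp = etree.SubElement(los, f"{{{SBML_L3_NS}}}species")
        sp.set("id", f"sp{i + 1}")
        sp.set("name", g)
        sp.set("sboTerm", "SBO:0000252")
    if len(genes) >= 2:
        lor = etree.SubElement(model, f"{{{SBML_L3_NS}}}listOfReactions")
        rx = etree.SubElement(lor, f"{{{SBML_L3_NS}}}reaction")
        rx.set("id", "rx1")
    lol = etree.SubElement(model, f"{{{LAYOUT_NS}}}listOfLayouts")
    layout = etree.SubElement(lol, f"{{{LAYOUT_NS}}}layout")
    layout.set("id", "layout1")
    lsg = etree.SubElement(layout, f"{{{LAYOUT_NS}}}listOfSpeciesGlyphs")
    for i, (g, (x, y)) in enumerate(zip(genes, _grid_positions(len(genes)))):
        sg = etree.SubElement(lsg, f"{{{LAYOUT_NS}}}speciesGlyph")
        sg.set("id", f"sg{i + 1}")
        sg.set("species", f"sp{i + 1}")
        bb = etree.SubElement(sg, f"{{{LAYOUT_NS}}}boundingBox")
        pos = etree.SubElement(bb, f"{{{LAYOUT_NS}}}position")
        pos.set("x", _fmt(x))
        pos.set("y", _fmt(y))
        dim = etree.SubElement(bb, f"{{{LAYOUT_NS}}}dimensions")
        dim.set("width", "80")
        dim.set("height", "25")
    if len(genes) >= 2:
        lrg = etree.SubElement(layout, f"{{{LAYOUT_NS}}}listOfReactionGlyphs")
        rg = etree.SubElement(lrg, f"{{{LAYOUT_NS}}}reactionGlyph")
        rg.set("id", "rg1")
        rg.set("reaction", "rx1")
        lsrg = etree.SubElement(rg,
                                f"{{{LAYOUT_NS}}}listOfSpeciesReferenceGlyphs")
        for ref, role in (("sg1", "substrate"), ("sg2", "product")):
            srg = etree.SubElement(lsrg,
                                   f"{{{LAYOUT_NS}}}speciesReferenceGlyph")
            srg.set("id", f"srg_{ref}")
            srg.set("speciesGlyph", ref)
            srg.set("role", role)
    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True).decode()


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def gen_world(spec: FixtureSpec, outdir) -> GroundTruth:
    """Generate a complete synthetic input world under ``outdir``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = Path(outdir)
    for sub in ("sources", "disease_maps", "wikipathways", "reactome",
                "interactions"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    disease_genes = [f"GDIS{i:03d}" for i in range(1, spec.n_disease_genes + 1)]
    decoy_genes = [f"GDEC{i:03d}" for i in range(1, spec.n_decoy_genes + 1)]
    neighbor_genes = [f"GNBR{i:03d}" for i in range(1, spec.n_neighbors + 1)]
    decoy_orphas = [f"ORPHA:91{i:04d}" for i in range(1, 4)]

    # --- phenotype annotations -------------------------------------------
    hpo_pool = [f"HP:{i:07d}" for i in range(1, 21)]
    pheno_rows = [(spec.orpha_id, h) for h in hpo_pool[:6]]
    for j, orpha in enumerate(decoy_orphas):
        pheno_rows += [(orpha, h) for h in hpo_pool[8 + 4 * j: 12 + 4 * j]]
    _write_tsv(out / "sources/phenotype_annotations.tsv",
               ["orpha_id", "hpo_id"], pheno_rows)

    # --- gene associations ------------------------------------------------
    lo, hi = spec.disgenet_score_range
    dlo, dhi = spec.decoy_score_range
    gene_rows = []
    for i, g in enumerate(disease_genes):
        # every planted gene clears the recommended 0.3 threshold in at
        # least one scored source; a third also appears in orphanet
        score = rng.uniform(lo, hi)
        gene_rows.append(("disgenet", spec.orpha_id, g, _fmt(score)))
        if i % 2 == 0:
            score = rng.uniform(lo, hi)
            gene_rows.append(("opentargets", spec.efo_id, g, _fmt(score)))
        if i % 3 == 0:
            gene_rows.append(("orphanet", spec.orpha_id, g, "1.0"))
    for g in decoy_genes[: spec.n_decoy_genes // 2]:
        # decoys on the query disease, scores below every sane threshold
        gene_rows.append(("disgenet", spec.orpha_id, g, _fmt(rng.uniform(dlo, dhi))))
    for g in decoy_genes[spec.n_decoy_genes // 2:]:
        gene_rows.append(
            ("disgenet", decoy_orphas[0], g, _fmt(rng.uniform(lo, hi)))
        )
    _write_tsv(out / "sources/gene_associations.tsv",
               ["source", "orpha_id", "gene", "score"], gene_rows)

    # --- variants ---------------------------------------------------------
    def variant_id(i: int) -> str:
        contig = f"chr{1 + i % 5}"
        pos = 100000 + 1000 * i + int(rng.integers(1, 999))
        ref, alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")][i % 4]
        return f"{contig}:{pos}:{ref}:{alt}"

    rare_variants = [variant_id(i) for i in range(spec.n_variants)]
    common_variants = [variant_id(100 + i) for i in range(spec.n_common_variants)]
    benign_variants = [variant_id(200 + i) for i in range(spec.n_benign_variants)]

    var_rows = []
    for i, vid in enumerate(rare_variants + common_variants):
        gene = disease_genes[i % len(disease_genes)]
        var_rows.append(("clinvar", spec.orpha_id, vid, gene, "pathogenic", ""))
    for i, vid in enumerate(benign_variants):
        gene = disease_genes[(i + 3) % len(disease_genes)]
        var_rows.append(("opentargets", spec.efo_id, vid, gene, "uncertain",
                         _fmt(rng.uniform(lo, hi))))
        var_rows.append(("clinvar", spec.orpha_id, vid, gene, "benign", ""))
    # decoy-disease variants never reach the query
    var_rows.append(("clinvar", decoy_orphas[0], variant_id(300),
                     decoy_genes[0], "pathogenic", ""))
    _write_tsv(out / "sources/variant_associations.tsv",
               ["source", "orpha_id", "variant_id", "gene", "significance",
                "score"], var_rows)

    # --- allele frequencies ----------------------------------------------
    af_rows = []
    # the last rare variant has no AF record at all: missing data is kept
    for vid in rare_variants[:-1] if rare_variants else []:
        for pop in spec.populations:
            af_rows.append((vid, pop, _fmt(rng.uniform(*spec.af_rare))))
    for vid in common_variants:
        for pop in spec.populations:
            af_rows.append((vid, pop, _fmt(rng.uniform(*spec.af_common))))
    for vid in benign_variants:
        for pop in spec.populations:
            af_rows.append((vid, pop, _fmt(rng.uniform(*spec.af_rare))))
    _write_tsv(out / "sources/allele_frequencies.tsv",
               ["variant_id", "population", "af"], af_rows)

    _write_tsv(out / "sources/orpha_efo_map.tsv", ["orpha_id", "efo_id"],
               [(spec.orpha_id, spec.efo_id)]
               + [(o, f"EFO:091{i:04d}") for i, o in enumerate(decoy_orphas)])

    # --- pathway collections ---------------------------------------------
    def make_collection(prefix: str, directory: Path, writer, suffix: str,
                        n_total: int, n_planted: int):
        gmt_lines = []
        meta_rows = []
        planted_ids = []
        for i in range(n_total):
            set_id = f"{prefix}{i + 1:03d}"
            if i < n_planted:
                k = spec.genes_per_pathway
                n_dis = max(int(np.ceil(0.8 * k)), k - 1)
                picked = list(rng.choice(disease_genes, size=n_dis,
                                         replace=False))
                picked += list(rng.choice(decoy_genes, size=k - n_dis,
                                          replace=False))
                planted_ids.append(set_id)
            else:
                # decoy sets carry at most one disease gene, so planted and
                # decoy enrichment p-values are separated by construction
                picked = [str(rng.choice(disease_genes))] + list(
                    rng.choice(decoy_genes, size=spec.genes_per_pathway - 1,
                               replace=False)
                )
            fname = f"{set_id}{suffix}"
            (directory / fname).write_text(writer(picked, set_id))
            gmt_lines.append("\t".join([set_id, f"{prefix} set {i + 1}"]
                                       + picked))
            meta_rows.append((set_id, "true", "", fname))
        (directory / "sets.gmt").write_text("\n".join(gmt_lines) + "\n")
        _write_tsv(directory / "sets_meta.tsv",
                   ["set_id", "has_layout", "parent_id", "diagram_path"],
                   meta_rows)
        return planted_ids

    planted_dm = make_collection(
        "DMAP", out / "disease_maps",
        lambda genes, title: write_celldesigner_sbml(
            make_gene_diagram(genes, title)
        ),
        ".xml", spec.n_disease_map_areas, spec.n_planted_disease_maps,
    )
    planted_wp = make_collection(
        "WP", out / "wikipathways", write_gpml_pathway, ".gpml",
        spec.n_pathways, spec.n_planted_pathways,
    )
    planted_re = make_collection(
        "RHSA", out / "reactome", write_sbml_layout_pathway, ".sbml.xml",
        spec.n_pathways, spec.n_planted_pathways,
    )

    # --- interaction tables ----------------------------------------------
    string_rows = []
    mlo, mhi = spec.string_module_score
    nlo, nhi = spec.string_neighbor_score
    blo, bhi = spec.string_background_score
    for i in range(len(disease_genes) - 1):
        string_rows.append((disease_genes[i], disease_genes[i + 1],
                            int(rng.integers(mlo, mhi + 1))))
    for i, nb in enumerate(neighbor_genes):
        seed_gene = disease_genes[i % len(disease_genes)]
        string_rows.append((seed_gene, nb, int(rng.integers(nlo, nhi + 1))))
    for i in range(0, len(decoy_genes) - 1, 2):
        string_rows.append((decoy_genes[i], decoy_genes[i + 1],
                            int(rng.integers(blo, bhi + 1))))
    # low-score seed edges that must fail the threshold
    for g in disease_genes[:3]:
        string_rows.append((g, f"GOUT{disease_genes.index(g) + 1:03d}",
                            int(rng.integers(blo, bhi + 1))))
    _write_tsv(out / "interactions/string_edges.tsv",
               ["protein1", "protein2", "combined_score"], string_rows)

    signs = ["activation", "inhibition", "unknown"]
    tm_nodes = disease_genes + neighbor_genes
    directed_rows = []
    module_edges = []
    for i in range(len(disease_genes) - 1):
        s, t = disease_genes[i], disease_genes[i + 1]
        sign = signs[i % 3]
        directed_rows.append((s, t, sign))
        module_edges.append([s, t, sign])
    for i, nb in enumerate(neighbor_genes):
        s = disease_genes[(i + 1) % len(disease_genes)]
        sign = signs[(i + 1) % 3]
        directed_rows.append((s, nb, sign))
        module_edges.append([s, nb, sign])
    # edges with an endpoint outside the text-mining nodes: must be dropped
    directed_rows.append((disease_genes[0], "GOUT900", "activation"))
    directed_rows.append(("GOUT901", disease_genes[1], "inhibition"))
    _write_tsv(out / "interactions/directed_edges.tsv",
               ["source", "target", "sign"], directed_rows)
    module_edges.sort()

    # --- differential expression (synthetic stand-in table) ---------------
    deg_rows = []
    deg_pass_genes = []
    for i in range(spec.n_deg_pass):
        gene = (disease_genes[i] if i < min(5, len(disease_genes))
                else f"GEXP{i:04d}")
        lfc = rng.uniform(1.1, 6.0) * (1 if i % 2 == 0 else -1)
        fdr = rng.uniform(1e-8, 0.045)
        deg_rows.append((gene, _fmt(lfc), _fmt(fdr)))
        deg_pass_genes.append(gene)
    for i in range(spec.n_deg_fail):
        gene = f"GEXN{i:04d}"
        if i % 2 == 0:  # insignificant
            lfc = rng.uniform(1.1, 6.0)
            fdr = rng.uniform(0.06, 0.9)
        else:  # weak effect
            lfc = rng.uniform(0.0, 0.9)
            fdr = rng.uniform(1e-8, 0.045)
        deg_rows.append((gene, _fmt(lfc), _fmt(fdr)))
    _write_tsv(out / "deg.tsv", ["gene", "logFC", "FDR"], deg_rows)

    # --- pipeline configuration ------------------------------------------
    config = f"""\
disease:
  orpha_ids: ["{spec.orpha_id}"]
sources_dir: sources
disease_maps_dir: disease_maps
wikipathways_dir: wikipathways
reactome_dir: reactome
string_edges: interactions/string_edges.tsv
directed_edges: interactions/directed_edges.tsv
deg_table: deg.tsv
output_dir: output
disgenet_min_score: 0.3
disgenet_max_genes: 100
opentargets_min_score: 0.3
vep_af_threshold: 0.01
populations: [EUR, AFR, EAS]
max_disease_map_diagrams: {spec.n_planted_disease_maps}
max_pathways_per_collection: {spec.n_planted_pathways}
string_min_score: 700
string_max_new_neighbors: {spec.n_neighbors}
layout_seed: 42
layout_iterations: 100
layout_width: 1000
layout_height: 1000
margin: 20
highlight_color: "#0000FF"
"""
    (out / "config.yaml").write_text(config)

    truth = GroundTruth(
        orpha_id=spec.orpha_id,
        disease_genes=disease_genes,
        decoy_genes=decoy_genes,
        neighbor_genes=neighbor_genes,
        rare_variants=rare_variants,
        common_variants=common_variants,
        benign_conflict_variants=benign_variants,
        planted_disease_map_sets=planted_dm,
        planted_wikipathways_sets=planted_wp,
        planted_reactome_sets=planted_re,
        directed_module_edges=module_edges,
        deg_pass_genes=deg_pass_genes,
        n_deg_fail=spec.n_deg_fail,
    )
    truth.to_json(out / "ground_truth.json")
    return truth
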