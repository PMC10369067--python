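"""Readers and writers for the pathway-diagram dialects the pipeline touches.

Four dialects are handled:

* **GPML 2013a** (WikiPathways) — read.
* **SBML Level 3 + layout (+ render)** (Reactome exports) — read; the render
  package is deliberately ignored and recorded as a dropped feature.
* **CellDesigner-extended SBML Level 2 Version 4** — read and write; this is
  the harmonized target dialect of the final merged map.
* **SIF** (simple interaction format) — read.

Every reader returns the common :class:`~mapforge.model.Diagram` plus a
:class:`~mapforge.model.ConversionReport`; lossy steps never fail silently.
Conversions are deliberately conservative: anything the common model cannot
represent (embedded images, endpoint-less interactions, render styles, extra
reaction participants) lands in the report.
"""

from __future__ import annotations

import math
from typing import Optional

from lxml import etree

from .model import (
    Arc,
    ArcClass,
    ConversionReport,
    DialectError,
    Diagram,
    DiagramError,
    Glyph,
    GlyphClass,
    SourceKind,
)

GPML_NS = "http://pathvisio.org/GPML/2013a"
SBML_L3_NS = "http://www.sbml.org/sbml/level3/version1/core"
LAYOUT_NS = "http://www.sbml.org/sbml/level3/version1/layout/version1"
RENDER_NS = "http://www.sbml.org/sbml/level3/version1/render/version1"
SBML_L2V4_NS = "http://www.sbml.org/sbml/level2/version4"
CELLDESIGNER_NS = "http://www.sbml.org/2001/ns/celldesigner"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"


class ParseError(ValueError):
    """Malformed input document; the message names the offending line."""


# GPML DataNode @Type -> glyph class. Fixed decision table; anything absent
# maps to UNKNOWN with a warning in the report.
GPML_TYPE_MAP = {
    "GeneProduct": GlyphClass.PROTEIN,
    "Protein": GlyphClass.PROTEIN,
    "Gene": GlyphClass.GENE,
    "Rna": GlyphClass.RNA,
    "Metabolite": GlyphClass.METABOLITE,
    "Complex": GlyphClass.COMPLEX,
    "Pathway": GlyphClass.PHENOTYPE,
}

_GPML_ARROW_MAP = {
    "Arrow": (ArcClass.STATE_TRANSITION, True),
    "mim-stimulation": (ArcClass.STATE_TRANSITION, True),
    "mim-conversion": (ArcClass.STATE_TRANSITION, True),
    "mim-catalysis": (ArcClass.CATALYSIS, True),
    "TBar": (ArcClass.INHIBITION, True),
    "mim-inhibition": (ArcClass.INHIBITION, True),
}


def _parse_xml(document: str) -> etree._Element:
    try:
        return etree.fromstring(document.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML at line {exc.lineno}: {exc.msg}") from exc


def _localname(el: etree._Element) -> str:
    return etree.QName(el).localname


# ---------------------------------------------------------------------------
# GPML
# ---------------------------------------------------------------------------

def parse_gpml(document: str) -> tuple[Diagram, ConversionReport]:
    """Parse a GPML 2013a pathway into the common model.

    DataNodes become glyphs (GPML center coordinates converted to top-left),
    Groups of DataNodes become complex glyphs, and Interactions whose first
    and last points both reference an existing node become arcs.
    Interactions missing an endpoint reference, Labels, Shapes (including
    embedded images) and States are dropped and recorded in the report.
    """
    root = _parse_xml(document)
    if etree.QName(root).namespace != GPML_NS:
        raise DialectError(
            f"unsupported dialect: expected GPML namespace {GPML_NS}, "
            f"got {etree.QName(root).namespace!r}"
        )
    report = ConversionReport()
    diagram = Diagram(
        title=root.get("Name", ""),
        source_kind=SourceKind.WIKIPATHWAYS,
        source_id=root.get("Name", ""),
    )

    auto_id = 0

    def next_id() -> str:
        nonlocal auto_id
        auto_id += 1
        return f"auto{auto_id}"

    group_members: dict[str, list[Glyph]] = {}
    for dn in root.findall(f"{{{GPML_NS}}}DataNode"):
        gfx = dn.find(f"{{{GPML_NS}}}Graphics")
        if gfx is None:
            report.drop("datanode", dn.get("GraphId", "?"),
                        "DataNode without Graphics dropped")
            continue
        w = float(gfx.get("Width", 80))
        h = float(gfx.get("Height", 25))
        cx = float(gfx.get("CenterX", 0))
        cy = float(gfx.get("CenterY", 0))
        gtype = dn.get("Type", "Unknown")
        gclass = GPML_TYPE_MAP.get(gtype)
        if gclass is None:
            gclass = GlyphClass.UNKNOWN
            report.warnings.append(
                f"DataNode type {gtype!r} has no mapping; treated as unknown"
            )
        annotations = set()
        xref = dn.find(f"{{{GPML_NS}}}Xref")
        if xref is not None and xref.get("ID"):
            annotations.add((xref.get("Database", ""), xref.get("ID")))
        glyph = Glyph(
            id=dn.get("GraphId") or next_id(),
            label=dn.get("TextLabel", ""),
            glyph_class=gclass,
            x=cx - w / 2,
            y=cy - h / 2,
            width=w,
            height=h,
            annotations=frozenset(annotations),
        )
        diagram.glyphs.append(glyph)
        if dn.get("GroupRef"):
            group_members.setdefault(dn.get("GroupRef"), []).append(glyph)

    # Groups of DataNodes become complex glyphs wrapping their members.
    group_ids: dict[str, str] = {}
    for grp in root.findall(f"{{{GPML_NS}}}Group"):
        group_id = grp.get("GroupId") or next_id()
        members = group_members.get(group_id, [])
        if not members:
            report.drop("group", group_id, f"empty Group {group_id!r} dropped")
            continue
        pad = 8.0
        x0 = min(m.x for m in members) - pad
        y0 = min(m.y for m in members) - pad
        x1 = max(m.x + m.width for m in members) + pad
        y1 = max(m.y + m.height for m in members) + pad
        gid = grp.get("GraphId") or f"group_{group_id}"
        diagram.glyphs.append(
            Glyph(
                id=gid,
                label=grp.get("TextLabel", ""),
                glyph_class=GlyphClass.COMPLEX,
                x=x0,
                y=y0,
                width=x1 - x0,
                height=y1 - y0,
            )
        )
        group_ids[group_id] = gid
        for m in members:
            m.parent_id = gid

    known = {g.id for g in diagram.glyphs}
    for inter in root.findall(f"{{{GPML_NS}}}Interaction"):
        iid = inter.get("GraphId") or next_id()
        gfx = inter.find(f"{{{GPML_NS}}}Graphics")
        points = [] if gfx is None else gfx.findall(f"{{{GPML_NS}}}Point")
        refs = [p.get("GraphRef") for p in points]
        if len(points) < 2 or refs[0] not in known or refs[-1] not in known:
            report.drop(
                "arc", iid,
                f"Interaction {iid!r} lacks an anchored reactant/product; dropped",
            )
            continue
        arrow = points[-1].get("ArrowHead")
        arc_class, directed = _GPML_ARROW_MAP.get(
            arrow, (ArcClass.INTERACTION, False)
        )
        waypoints = [
            (float(p.get("X", 0)), float(p.get("Y", 0))) for p in points[1:-1]
        ]
        diagram.arcs.append(
            Arc(
                id=iid,
                source_id=refs[0],
                target_id=refs[-1],
                arc_class=arc_class,
                directed=directed,
                waypoints=waypoints,
            )
        )

    for tag in ("Label", "Shape", "State", "GraphicalLine"):
        for el in root.findall(f"{{{GPML_NS}}}{tag}"):
            kind = "image" if tag == "Shape" else tag.lower()
            report.drop(
                kind,
                el.get("GraphId") or el.get("TextLabel") or tag,
                f"GPML {tag} element dropped (not representable)",
            )

    diagram.validate()
    return diagram, report


# ---------------------------------------------------------------------------
# SBML Level 3 + layout (+ render)
# ---------------------------------------------------------------------------

_SBO_CLASS_MAP = {
    "SBO:0000252": GlyphClass.PROTEIN,   # polypeptide chain
    "SBO:0000247": GlyphClass.METABOLITE,  # simple chemical
    "SBO:0000278": GlyphClass.RNA,
    "SBO:0000243": GlyphClass.GENE,
    "SBO:0000253": GlyphClass.COMPLEX,   # non-covalent complex
}


def parse_sbml_layout(document: str) -> tuple[Diagram, ConversionReport]:
    """Parse SBML L3 with the layout package into the common model.

    Species with a species glyph in the first layout become glyphs; each
    reaction glyph becomes one state-transition arc from its first substrate
    to its first product (modifiers become catalysis arcs onto the product).
    Species without layout, extra participants and render styles are recorded
    in the report.  Documents without a layout section are rejected: the
    workflow only consumes diagrams with layout.
    """
    root = _parse_xml(document)
    ns = etree.QName(root).namespace
    if ns not in (SBML_L3_NS,):
        raise DialectError(f"unsupported dialect: not SBML Level 3 ({ns!r})")
    report = ConversionReport()
    model = root.find(f"{{{SBML_L3_NS}}}model")
    if model is None:
        raise ParseError("SBML document has no model element")
    layouts = model.find(f"{{{LAYOUT_NS}}}listOfLayouts")
    layout = None if layouts is None else layouts.find(f"{{{LAYOUT_NS}}}layout")
    if layout is None:
        raise DiagramError("layout required: SBML document carries no layout package")

    diagram = Diagram(
        title=model.get("name", model.get("id", "")),
        source_kind=SourceKind.REACTOME,
        source_id=model.get("id", ""),
    )

    species_meta: dict[str, tuple[str, GlyphClass]] = {}
    los = model.find(f"{{{SBML_L3_NS}}}listOfSpecies")
    if los is not None:
        for sp in los.findall(f"{{{SBML_L3_NS}}}species"):
            cls = _SBO_CLASS_MAP.get(sp.get("sboTerm", ""), GlyphClass.UNKNOWN)
            species_meta[sp.get("id")] = (sp.get("name", sp.get("id")), cls)

    sglyphs = layout.find(f"{{{LAYOUT_NS}}}listOfSpeciesGlyphs")
    glyph_for_species: dict[str, str] = {}
    glyph_by_layout_id: dict[str, str] = {}
    if sglyphs is not None:
        for sg in sglyphs.findall(f"{{{LAYOUT_NS}}}speciesGlyph"):
            bb = sg.find(f"{{{LAYOUT_NS}}}boundingBox")
            if bb is None:
                report.drop("species", sg.get("species", "?"),
                            "species glyph without bounding box dropped")
                continue
            pos = bb.find(f"{{{LAYOUT_NS}}}position")
            dim = bb.find(f"{{{LAYOUT_NS}}}dimensions")
            species_id = sg.get("species", "")
            label, cls = species_meta.get(species_id, (species_id, GlyphClass.UNKNOWN))
            gid = sg.get("id") or f"sg_{species_id}"
            diagram.glyphs.append(
                Glyph(
                    id=gid,
                    label=label,
                    glyph_class=cls,
                    x=float(pos.get("x", 0)) if pos is not None else 0.0,
                    y=float(pos.get("y", 0)) if pos is not None else 0.0,
                    width=float(dim.get("width", 80)) if dim is not None else 80.0,
                    height=float(dim.get("height", 25)) if dim is not None else 25.0,
                )
            )
            glyph_for_species.setdefault(species_id, gid)
            glyph_by_layout_id[gid] = gid

    for species_id in species_meta:
        if species_id not in glyph_for_species:
            report.drop(
                "species", species_id,
                f"species {species_id!r} has no layout glyph; dropped",
            )

    rglyphs = layout.find(f"{{{LAYOUT_NS}}}listOfReactionGlyphs")
    if rglyphs is not None:
        for rg in rglyphs.findall(f"{{{LAYOUT_NS}}}reactionGlyph"):
            rid = rg.get("id") or rg.get("reaction", "reaction")
            roles: dict[str, list[str]] = {"substrate": [], "product": [],
                                           "modifier": []}
            lsrg = rg.find(f"{{{LAYOUT_NS}}}listOfSpeciesReferenceGlyphs")
            if lsrg is None:
                report.drop("arc", rid, f"reaction glyph {rid!r} has no "
                            "species references; dropped")
                continue
            for srg in lsrg.findall(f"{{{LAYOUT_NS}}}speciesReferenceGlyph"):
                role = srg.get("role", "undefined")
                ref = srg.get("speciesGlyph", "")
                if role in ("substrate", "sidesubstrate"):
                    roles["substrate"].append(ref)
                elif role in ("product", "sideproduct"):
                    roles["product"].append(ref)
                elif role in ("modifier", "activator", "inhibitor"):
                    roles["modifier"].append(ref)
            subs = [r for r in roles["substrate"] if r in glyph_by_layout_id]
            prods = [r for r in roles["product"] if r in glyph_by_layout_id]
            if not subs or not prods:
                report.drop("arc", rid, f"reaction glyph {rid!r} lacks an "
                            "anchored reactant/product; dropped")
                continue
            diagram.arcs.append(
                Arc(
                    id=rid,
                    source_id=subs[0],
                    target_id=prods[0],
                    arc_class=ArcClass.STATE_TRANSITION,
                    directed=True,
                )
            )
            for extra in subs[1:] + prods[1:]:
                report.drop("participant", f"{rid}:{extra}",
                            None)
            for i, mod in enumerate(roles["modifier"]):
                diagram.arcs.append(
                    Arc(
                        id=f"{rid}_mod{i}",
                        source_id=mod,
                        target_id=prods[0],
                        arc_class=ArcClass.CATALYSIS,
                        directed=True,
                    )
                )

    n_styles = len(root.findall(f".//{{{RENDER_NS}}}style"))
    if root.find(f".//{{{RENDER_NS}}}listOfRenderInformation") is not None or n_styles:
        report.drop("render", f"{n_styles} styles",
                    "render package ignored; target dialect carries its own styling")

    diagram.validate()
    return diagram, report


# ---------------------------------------------------------------------------
# CellDesigner SBML (harmonized target dialect)
# ---------------------------------------------------------------------------

_CD_CLASS_MAP = {
    GlyphClass.PROTEIN: "PROTEIN",
    GlyphClass.GENE: "GENE",
    GlyphClass.RNA: "RNA",
    GlyphClass.METABOLITE: "SIMPLE_MOLECULE",
    GlyphClass.COMPLEX: "COMPLEX",
    GlyphClass.PHENOTYPE: "PHENOTYPE",
    GlyphClass.UNKNOWN: "UNKNOWN",
}
_CD_CLASS_INV = {v: k for k, v in _CD_CLASS_MAP.items()}

_CD_REACTION_MAP = {
    ArcClass.STATE_TRANSITION: "STATE_TRANSITION",
    ArcClass.CATALYSIS: "CATALYSIS",
    ArcClass.INHIBITION: "INHIBITION",
    ArcClass.INTERACTION: "INTERACTION",
}
_CD_REACTION_INV = {v: k for k, v in _CD_REACTION_MAP.items()}

_CD = f"{{{CELLDESIGNER_NS}}}"
_RDF = f"{{{RDF_NS}}}"
_BQ = f"{{{BQBIOL_NS}}}"


def write_celldesigner_sbml(d: Diagram) -> str:
    """Serialize a diagram as CellDesigner-extended SBML Level 2 Version 4.

    One species plus one species alias per glyph; the alias carries the
    bounding box.  Complexes become ``complexSpeciesAlias`` entries with one
    nesting level; compartment glyphs become SBML compartments with a
    ``compartmentAlias``.  Catalysis and inhibition arcs are written as
    reactions whose source is a modifier species reference.  Annotations are
    emitted as MIRIAM resource URIs (``urn:miriam:<namespace>:<id>``).
    """
    d.validate()

    nsmap = {
        None: SBML_L2V4_NS,
        "celldesigner": CELLDESIGNER_NS,
        "rdf": RDF_NS,
        "bqbiol": BQBIOL_NS,
    }
    sbml = etree.Element(f"{{{SBML_L2V4_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "2")
    sbml.set("version", "4")
    model = etree.SubElement(sbml, f"{{{SBML_L2V4_NS}}}model")
    model.set("id", "model_1")
    if d.title:
        model.set("name", d.title)

    annotation = etree.SubElement(model, f"{{{SBML_L2V4_NS}}}annotation")
    extension = etree.SubElement(annotation, _CD + "extension")
    etree.SubElement(extension, _CD + "modelVersion").text = "4.0"
    lo_aliases = etree.SubElement(extension, _CD + "listOfSpeciesAliases")
    lo_complex_aliases = etree.SubElement(
        extension, _CD + "listOfComplexSpeciesAliases"
    )
    lo_comp_aliases = etree.SubElement(extension, _CD + "listOfCompartmentAliases")

    lo_compartments = etree.SubElement(model, f"{{{SBML_L2V4_NS}}}listOfCompartments")
    default_comp = etree.SubElement(
        lo_compartments, f"{{{SBML_L2V4_NS}}}compartment"
    )
    default_comp.set("id", "default")
    default_comp.set("size", "1")

    species_id: dict[str, str] = {}
    complex_alias_id: dict[str, str] = {}
    compartment_sbml_id: dict[str, str] = {}

    compartments = [g for g in d.glyphs if g.glyph_class is GlyphClass.COMPARTMENT]
    others = [g for g in d.glyphs if g.glyph_class is not GlyphClass.COMPARTMENT]

    for i, g in enumerate(compartments, start=1):
        cid = f"c{i}"
        compartment_sbml_id[g.id] = cid
        comp = etree.SubElement(lo_compartments, f"{{{SBML_L2V4_NS}}}compartment")
        comp.set("id", cid)
        comp.set("name", g.label)
        comp.set("outside", "default")
        comp.set("size", "1")
        alias = etree.SubElement(lo_comp_aliases, _CD + "compartmentAlias")
        alias.set("id", f"ca{i}")
        alias.set("compartment", cid)
        bounds = etree.SubElement(alias, _CD + "bounds")
        bounds.set("x", repr(g.x))
        bounds.set("y", repr(g.y))
        bounds.set("w", repr(g.width))
        bounds.set("h", repr(g.height))

    lo_species = etree.SubElement(model, f"{{{SBML_L2V4_NS}}}listOfSpecies")
    for i, g in enumerate(others, start=1):
        sid = f"s{i}"
        species_id[g.id] = sid
        sp = etree.SubElement(lo_species, f"{{{SBML_L2V4_NS}}}species")
        sp.set("id", sid)
        sp.set("name", g.label)
        comp = "default"
        if g.parent_id is not None and g.parent_id in compartment_sbml_id:
            comp = compartment_sbml_id[g.parent_id]
        sp.set("compartment", comp)
        sp.set("initialAmount", "0")
        sp_ann = etree.SubElement(sp, f"{{{SBML_L2V4_NS}}}annotation")
        sp_ext = etree.SubElement(sp_ann, _CD + "extension")
        ident = etree.SubElement(sp_ext, _CD + "speciesIdentity")
        etree.SubElement(ident, _CD + "class").text = _CD_CLASS_MAP[g.glyph_class]
        etree.SubElement(ident, _CD + "name").text = g.label
        if g.annotations:
            rdf = etree.SubElement(sp_ann, _RDF + "RDF")
            desc = etree.SubElement(rdf, _RDF + "Description")
            desc.set(_RDF + "about", f"#{sid}")
            bq = etree.SubElement(desc, _BQ + "is")
            bag = etree.SubElement(bq, _RDF + "Bag")
            for namespace, ident_str in sorted(g.annotations):
                li = etree.SubElement(bag, _RDF + "li")
                li.set(_RDF + "resource", f"urn:miriam:{namespace}:{ident_str}")

    n_csa = 0
    alias_index: dict[str, etree._Element] = {}
    for i, g in enumerate(others, start=1):
        sid = species_id[g.id]
        if g.glyph_class is GlyphClass.COMPLEX:
            n_csa += 1
            csa = etree.SubElement(lo_complex_aliases, _CD + "complexSpeciesAlias")
            csa.set("id", f"csa{n_csa}")
            csa.set("species", sid)
            complex_alias_id[g.id] = f"csa{n_csa}"
            bounds = etree.SubElement(csa, _CD + "bounds")
        else:
            alias = etree.SubElement(lo_aliases, _CD + "speciesAlias")
            alias.set("id", f"sa{i}")
            alias.set("species", sid)
            alias_index[g.id] = alias
            bounds = etree.SubElement(alias, _CD + "bounds")
        bounds.set("x", repr(g.x))
        bounds.set("y", repr(g.y))
        bounds.set("w", repr(g.width))
        bounds.set("h", repr(g.height))

    # Members of a complex point at the complex alias (one nesting level).
    for g in others:
        if g.parent_id in complex_alias_id and g.id in alias_index:
            alias_index[g.id].set("complexSpeciesAlias", complex_alias_id[g.parent_id])

    if d.arcs:
        lo_reactions = etree.SubElement(model, f"{{{SBML_L2V4_NS}}}listOfReactions")
        for k, a in enumerate(d.arcs, start=1):
            rx = etree.SubElement(lo_reactions, f"{{{SBML_L2V4_NS}}}reaction")
            rx.set("id", f"re{k}")
            rx.set("reversible", "false" if a.directed else "true")
            rann = etree.SubElement(rx, f"{{{SBML_L2V4_NS}}}annotation")
            rext = etree.SubElement(rann, _CD + "extension")
            etree.SubElement(rext, _CD + "reactionType").text = _CD_REACTION_MAP[
                a.arc_class
            ]
            if a.arc_class in (ArcClass.CATALYSIS, ArcClass.INHIBITION):
                prods = etree.SubElement(rx, f"{{{SBML_L2V4_NS}}}listOfProducts")
                pref = etree.SubElement(prods, f"{{{SBML_L2V4_NS}}}speciesReference")
                pref.set("species", species_id[a.target_id])
                mods = etree.SubElement(rx, f"{{{SBML_L2V4_NS}}}listOfModifiers")
                mref = etree.SubElement(
                    mods, f"{{{SBML_L2V4_NS}}}modifierSpeciesReference"
                )
                mref.set("species", species_id[a.source_id])
            else:
                reacts = etree.SubElement(rx, f"{{{SBML_L2V4_NS}}}listOfReactants")
                rref = etree.SubElement(reacts, f"{{{SBML_L2V4_NS}}}speciesReference")
                rref.set("species", species_id[a.source_id])
                prods = etree.SubElement(rx, f"{{{SBML_L2V4_NS}}}listOfProducts")
                pref = etree.SubElement(prods, f"{{{SBML_L2V4_NS}}}speciesReference")
                pref.set("species", species_id[a.target_id])

    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def parse_celldesigner_sbml(document: str) -> Diagram:
    """Parse CellDesigner-extended SBML produced by this package (or a
    compatible minimal subset) back into the common model.

    Inverse of :func:`write_celldesigner_sbml` up to field defaults; glyph
    ids are the SBML species/compartment ids.
    """
    root = _parse_xml(document)
    if CELLDESIGNER_NS not in root.nsmap.values() and root.find(
        f".//{_CD}extension"
    ) is None:
        raise DialectError(
            "unsupported dialect: CellDesigner extension namespace missing"
        )
    sbml_ns = etree.QName(root).namespace
    model = root.find(f"{{{sbml_ns}}}model")
    if model is None:
        raise ParseError("SBML document has no model element")

    diagram = Diagram(
        title=model.get("name", ""),
        source_kind=SourceKind.DISEASE_MAP,
        source_id=model.get("id", ""),
    )

    # Compartment aliases -> compartment glyphs.
    for ca in model.findall(f".//{_CD}compartmentAlias"):
        bounds = ca.find(f"{_CD}bounds")
        cid = ca.get("compartment", ca.get("id"))
        comp_el = None
        for c in model.findall(f".//{{{sbml_ns}}}compartment"):
            if c.get("id") == cid:
                comp_el = c
                break
        diagram.glyphs.append(
            Glyph(
                id=cid,
                label=comp_el.get("name", cid) if comp_el is not None else cid,
                glyph_class=GlyphClass.COMPARTMENT,
                x=float(bounds.get("x", 0)),
                y=float(bounds.get("y", 0)),
                width=float(bounds.get("w", 1)),
                height=float(bounds.get("h", 1)),
            )
        )
    compartment_glyphs = {g.id for g in diagram.glyphs}

    species_info: dict[str, tuple[str, GlyphClass, frozenset, str]] = {}
    for sp in model.findall(f".//{{{sbml_ns}}}species"):
        cls_el = sp.find(f".//{_CD}speciesIdentity/{_CD}class")
        cls = _CD_CLASS_INV.get(
            cls_el.text if cls_el is not None else "", GlyphClass.UNKNOWN
        )
        annotations = set()
        for li in sp.findall(f".//{_RDF}li"):
            resource = li.get(_RDF + "resource", "")
            if resource.startswith("urn:miriam:"):
                _, _, rest = resource.partition("urn:miriam:")
                namespace, _, ident = rest.rpartition(":")
                annotations.add((namespace, ident))
        species_info[sp.get("id")] = (
            sp.get("name", ""),
            cls,
            frozenset(annotations),
            sp.get("compartment", "default"),
        )

    csa_species: dict[str, str] = {}
    for csa in model.findall(f".//{_CD}complexSpeciesAlias"):
        sid = csa.get("species")
        csa_species[csa.get("id")] = sid
        bounds = csa.find(f"{_CD}bounds")
        name, cls, ann, comp = species_info.get(
            sid, ("", GlyphClass.COMPLEX, frozenset(), "default")
        )
        diagram.glyphs.append(
            Glyph(
                id=sid,
                label=name,
                glyph_class=GlyphClass.COMPLEX,
                x=float(bounds.get("x", 0)),
                y=float(bounds.get("y", 0)),
                width=float(bounds.get("w", 1)),
                height=float(bounds.get("h", 1)),
                annotations=ann,
                parent_id=comp if comp in compartment_glyphs else None,
            )
        )

    for alias in model.findall(f".//{_CD}speciesAlias"):
        sid = alias.get("species")
        bounds = alias.find(f"{_CD}bounds")
        name, cls, ann, comp = species_info.get(
            sid, (sid, GlyphClass.UNKNOWN, frozenset(), "default")
        )
        parent = None
        if alias.get("complexSpeciesAlias") in csa_species:
            parent = csa_species[alias.get("complexSpeciesAlias")]
        elif comp in compartment_glyphs:
            parent = comp
        diagram.glyphs.append(
            Glyph(
                id=sid,
                label=name,
                glyph_class=cls,
                x=float(bounds.get("x", 0)) if bounds is not None else 0.0,
                y=float(bounds.get("y", 0)) if bounds is not None else 0.0,
                width=float(bounds.get("w", 80)) if bounds is not None else 80.0,
                height=float(bounds.get("h", 25)) if bounds is not None else 25.0,
                annotations=ann,
                parent_id=parent,
            )
        )

    for rx in model.findall(f".//{{{sbml_ns}}}reaction"):
        rid = rx.get("id", "")
        rtype_el = rx.find(f".//{_CD}reactionType")
        arc_class = _CD_REACTION_INV.get(
            rtype_el.text if rtype_el is not None else "", ArcClass.STATE_TRANSITION
        )
        directed = rx.get("reversible", "false") != "true"
        if arc_class in (ArcClass.CATALYSIS, ArcClass.INHIBITION):
            src_el = rx.find(
                f".//{{{sbml_ns}}}modifierSpeciesReference"
            )
            tgt_el = rx.find(
                f".//{{{sbml_ns}}}listOfProducts/{{{sbml_ns}}}speciesReference"
            )
        else:
            src_el = rx.find(
                f".//{{{sbml_ns}}}listOfReactants/{{{sbml_ns}}}speciesReference"
            )
            tgt_el = rx.find(
                f".//{{{sbml_ns}}}listOfProducts/{{{sbml_ns}}}speciesReference"
            )
        if src_el is None or tgt_el is None:
            continue
        diagram.arcs.append(
            Arc(
                id=rid,
                source_id=src_el.get("species"),
                target_id=tgt_el.get("species"),
                arc_class=arc_class,
                directed=directed,
            )
        )

    diagram.validate()
    return diagram


# ---------------------------------------------------------------------------
# SIF
# ---------------------------------------------------------------------------

def read_sif(text: str) -> list[tuple[str, str, str]]:
    """Read simple-interaction-format triples (source, relation, target).

    One whitespace-delimited triple per line; blank lines are skipped; a line
    with any other token count raises :class:`ParseError` naming the line.
    """
    triples: list[tuple[str, str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) != 3:
            raise ParseError(
                f"SIF line {lineno}: expected 3 tokens, got {len(tokens)}"
            )
        triples.append((tokens[0], tokens[1], tokens[2]))
    return triples


# ---------------------------------------------------------------------------
# Dispatch by content
# ---------------------------------------------------------------------------

def parse_diagram_file(path) -> tuple[Diagram, ConversionReport]:
    """Sniff a diagram file's dialect and parse it.

    GPML, SBML L3 + layout and CellDesigner SBML are recognized by their
    root namespace.
    """
    text = open(path, encoding="utf-8").read()
    root = _parse_xml(text)
    ns = etree.QName(root).namespace
    if ns == GPML_NS:
        return parse_gpml(text)
    if ns == SBML_L3_NS:
        return parse_sbml_layout(text)
    if CELLDESIGNER_NS in root.nsmap.values():
        return parse_celldesigner_sbml(text), ConversionReport()
    raise DialectError(f"unrecognized diagram dialect in {path} (namespace {ns!r})")
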