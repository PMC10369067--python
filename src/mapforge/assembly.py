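"""Stage 3a — merging every component into the final harmonized map.

Components are combined in a fixed order — (1) disease-map diagrams merged,
(2) the text-mining GPML converted, (3) pathway diagrams (WikiPathways GPML
and Reactome SBML+layout) converted and merged, (4) the three blocks merged —
into one CellDesigner-SBML diagram.  "Merge" is a mesh layout: whole
components are placed on a row-major, near-square grid, each keeping its
internal layout; nothing is deduplicated across components, so the same gene
in two sources stays as two glyphs and overlays highlight all copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .diagram_io import parse_gpml
from .model import Arc, ConversionReport, Diagram, DiagramError, Glyph, SourceKind


class AssemblyError(ValueError):
    pass


def _shift_component(d: Diagram, tag: str, dx: float, dy: float) -> Diagram:
    """Copy of ``d`` with ids prefixed by ``tag`` and coordinates offset."""
    glyphs = [
        replace(
            g,
            id=f"{tag}__{g.id}",
            parent_id=None if g.parent_id is None else f"{tag}__{g.parent_id}",
            x=g.x + dx,
            y=g.y + dy,
        )
        for g in d.glyphs
    ]
    arcs = [
        replace(
            a,
            id=f"{tag}__{a.id}",
            source_id=f"{tag}__{a.source_id}",
            target_id=f"{tag}__{a.target_id}",
            waypoints=[(x + dx, y + dy) for x, y in a.waypoints],
        )
        for a in d.arcs
    ]
    return Diagram(glyphs=glyphs, arcs=arcs, title=d.title,
                   source_kind=d.source_kind, source_id=d.source_id)


def mesh_merge(diagrams: Sequence[Diagram], margin: float = 20.0,
               tags: Optional[Sequence[str]] = None) -> Diagram:
    """Place whole diagrams on a row-major grid and union them.

    Grid has ``ceil(sqrt(m))`` columns; each cell is the component's bounding
    box plus ``margin`` on the right and bottom; a row is as tall as its
    tallest cell.  Ids are prefixed with a unique per-component tag, so the
    union is id-disjoint, and every component keeps its internal layout.
    """
    if not diagrams:
        raise AssemblyError("mesh_merge needs at least one diagram")
    if margin < 0:
        raise AssemblyError("margin must be >= 0")
    m = len(diagrams)
    tags = list(tags) if tags is not None else [f"c{i}" for i in range(m)]
    if len(set(tags)) != len(tags):
        raise AssemblyError(f"duplicate component tags: {tags}")
    columns = math.ceil(math.sqrt(m))
    merged = Diagram(title="merged map", source_kind=SourceKind.MERGED)
    x_cursor = 0.0
    y_cursor = 0.0
    row_height = 0.0
    for i, d in enumerate(diagrams):
        if i > 0 and i % columns == 0:
            y_cursor += row_height
            x_cursor = 0.0
            row_height = 0.0
        w, h = d.bbox
        shifted = _shift_component(d, tags[i], x_cursor, y_cursor)
        merged.glyphs.extend(shifted.glyphs)
        merged.arcs.extend(shifted.arcs)
        x_cursor += w + margin
        row_height = max(row_height, h + margin)
    merged.validate()
    return merged


def component_offsets(
    diagrams: Sequence[Diagram], margin: float = 20.0
) -> list[tuple[float, float]]:
    """Cell origins the mesh merge assigns to each component, in order."""
    columns = math.ceil(math.sqrt(len(diagrams)))
    offsets = []
    x_cursor = y_cursor = row_height = 0.0
    for i, d in enumerate(diagrams):
        if i > 0 and i % columns == 0:
            y_cursor += row_height
            x_cursor = 0.0
            row_height = 0.0
        offsets.append((x_cursor, y_cursor))
        w, h = d.bbox
        x_cursor += w + margin
        row_height = max(row_height, h + margin)
    return offsets


def assemble_map(
    disease_map_diagrams: Sequence[Diagram] = (),
    textmining_gpml: str | None = None,
    pathway_diagrams: Sequence[Diagram] = (),
    margin: float = 20.0,
    warnings: list[str] | None = None,
) -> tuple[Diagram, ConversionReport]:
    """Merge the three component blocks in the prescribed order.

    Step 1 merges the disease-map diagrams, step 2 converts the text-mining
    GPML into the common model, step 3 merges the converted pathway diagrams
    (GPML and SBML-layout inputs already parsed), step 4 merges the up-to-
    three blocks.  Empty components are skipped with a warning; all empty is
    an error.
    """
    warnings = warnings if warnings is not None else []
    report = ConversionReport()
    blocks: list[Diagram] = []
    tags: list[str] = []

    if disease_map_diagrams:
        blocks.append(mesh_merge(list(disease_map_diagrams), margin,
                                 tags=[f"dm{i}" for i in
                                       range(len(disease_map_diagrams))]))
        tags.append("diseasemaps")
    else:
        warnings.append("no disease-map component; skipped")

    if textmining_gpml:
        tm, tm_report = parse_gpml(textmining_gpml)
        tm.source_kind = SourceKind.TEXTMINING
        report.dropped_features.extend(tm_report.dropped_features)
        report.warnings.extend(tm_report.warnings)
        blocks.append(tm)
        tags.append("textmining")
    else:
        warnings.append("no text-mining component; skipped")

    if pathway_diagrams:
        blocks.append(mesh_merge(list(pathway_diagrams), margin,
                                 tags=[f"pw{i}" for i in
                                       range(len(pathway_diagrams))]))
        tags.append("pathways")
    else:
        warnings.append("no pathway component; skipped")

    if not blocks:
        raise AssemblyError("nothing to assemble: all components empty")
    final = mesh_merge(blocks, margin, tags=tags)
    final.title = "ad-hoc disease map"
    final.source_kind = SourceKind.MERGED
    return final, report
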