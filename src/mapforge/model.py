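"""Common diagram model shared by every format converter.

All source dialects (GPML, SBML layout+render, CellDesigner SBML) are parsed
into this glyph-and-arc representation with 2-D layout, and the final merged
map is written back out of it.  Coordinates follow the GPML convention:
top-left origin, y grows downward, units are pixels, a glyph's (x, y) is its
top-left corner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class GlyphClass(str, Enum):
    PROTEIN = "protein"
    GENE = "gene"
    RNA = "rna"
    METABOLITE = "metabolite"
    COMPLEX = "complex"
    PHENOTYPE = "phenotype"
    COMPARTMENT = "compartment"
    UNKNOWN = "unknown"


class ArcClass(str, Enum):
    STATE_TRANSITION = "state_transition"
    CATALYSIS = "catalysis"
    INHIBITION = "inhibition"
    INTERACTION = "interaction"


class SourceKind(str, Enum):
    DISEASE_MAP = "disease_map"
    WIKIPATHWAYS = "wikipathways"
    REACTOME = "reactome"
    TEXTMINING = "textmining"
    MERGED = "merged"


class DiagramError(ValueError):
    """Invalid diagram content or a violated model invariant."""


class DialectError(ValueError):
    """Input document is not in the expected XML dialect."""


@dataclass
class Glyph:
    """A node of the diagram: molecule, complex, compartment or phenotype."""

    id: str
    label: str
    glyph_class: GlyphClass = GlyphClass.UNKNOWN
    x: float = 0.0
    y: float = 0.0
    width: float = 80.0
    height: float = 25.0
    annotations: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    parent_id: Optional[str] = None

    def validate(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise DiagramError(
                f"glyph {self.id!r}: non-positive size {self.width}x{self.height}"
            )


@dataclass
class Arc:
    """An interaction between two glyphs, optionally directed and signed."""

    id: str
    source_id: str
    target_id: str
    arc_class: ArcClass = ArcClass.INTERACTION
    directed: bool = True
    waypoints: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class ConversionReport:
    """Record of everything a lossy format conversion discarded."""

    dropped_features: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def dropped_arcs(self) -> int:
        return sum(1 for kind, _ in self.dropped_features if kind == "arc")

    def drop(self, kind: str, detail: str, warn: str | None = None) -> None:
        self.dropped_features.append((kind, detail))
        if warn:
            self.warnings.append(warn)


@dataclass
class Diagram:
    glyphs: list[Glyph] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)
    title: str = ""
    source_kind: SourceKind = SourceKind.MERGED
    source_id: str = ""

    @property
    def bbox(self) -> tuple[float, float]:
        """(width, height) of the extent from the origin, covering every
        glyph rectangle and arc waypoint."""
        w = 0.0
        h = 0.0
        for g in self.glyphs:
            w = max(w, g.x + g.width)
            h = max(h, g.y + g.height)
        for a in self.arcs:
            for (x, y) in a.waypoints:
                w = max(w, x)
                h = max(h, y)
        return (w, h)

    def glyph_by_id(self, gid: str) -> Glyph:
        for g in self.glyphs:
            if g.id == gid:
                return g
        raise KeyError(gid)

    def validate(self) -> None:
        ids = [g.id for g in self.glyphs]
        if len(ids) != len(set(ids)):
            raise DiagramError("duplicate glyph ids")
        arc_ids = [a.id for a in self.arcs]
        if len(arc_ids) != len(set(arc_ids)):
            raise DiagramError("duplicate arc ids")
        id_set = set(ids)
        by_id = {g.id: g for g in self.glyphs}
        for g in self.glyphs:
            g.validate()
            if g.parent_id is not None:
                if g.parent_id not in id_set:
                    raise DiagramError(
                        f"glyph {g.id!r}: parent {g.parent_id!r} does not exist"
                    )
                parent = by_id[g.parent_id]
                if parent.glyph_class not in (
                    GlyphClass.COMPLEX,
                    GlyphClass.COMPARTMENT,
                ):
                    raise DiagramError(
                        f"glyph {g.id!r}: parent {g.parent_id!r} is neither a "
                        "complex nor a compartment"
                    )
                if (
                    parent.glyph_class is GlyphClass.COMPLEX
                    and parent.parent_id is not None
                    and by_id[parent.parent_id].glyph_class is GlyphClass.COMPLEX
                ):
                    raise DiagramError("complex nesting deeper than one level")
        for a in self.arcs:
            if a.source_id not in id_set or a.target_id not in id_set:
                raise DiagramError(
                    f"arc {a.id!r}: endpoint missing "
                    f"({a.source_id!r} -> {a.target_id!r})"
                )
            if not a.directed and a.arc_class is not ArcClass.INTERACTION:
                raise DiagramError(
                    f"arc {a.id!r}: undirected arcs must be plain interactions"
                )


def diagram_stats(d: Diagram) -> tuple[int, int]:
    """(unique_elements, interactions): glyphs excluding compartments, and arcs.

    These are the two headline numbers used to describe a map's size.
    """
    elements = sum(
        1 for g in d.glyphs if g.glyph_class is not GlyphClass.COMPARTMENT
    )
    return (elements, len(d.arcs))


def union_bbox(diagrams: Iterable[Diagram]) -> tuple[float, float]:
    w = 0.0
    h = 0.0
    for d in diagrams:
        bw, bh = d.bbox
        w = max(w, bw)
        h = max(h, bh)
    return (w, h)
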