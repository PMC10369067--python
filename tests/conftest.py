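import numpy as np
import pytest

from mapforge.fixtures import FixtureSpec, gen_world
from mapforge.model import Arc, ArcClass, Diagram, Glyph, GlyphClass

GPML_NS = "http://pathvisio.org/GPML/2013a"


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """One synthetic input world (seed 7) shared across the session."""
    path = tmp_path_factory.mktemp("world")
    truth = gen_world(FixtureSpec(seed=7), path)
    return path, truth


def random_diagram(rng: np.random.Generator, n_glyphs: int = 8,
                   n_arcs: int = 6) -> Diagram:
    """Random valid diagram exercising all glyph/arc classes, complexes
    (one nesting level) and compartments."""
    classes = [GlyphClass.PROTEIN, GlyphClass.GENE, GlyphClass.RNA,
               GlyphClass.METABOLITE, GlyphClass.PHENOTYPE,
               GlyphClass.UNKNOWN]
    d = Diagram(title=f"random-{rng.integers(1e6)}")
    d.glyphs.append(
        Glyph(id="comp", label="cytosol", glyph_class=GlyphClass.COMPARTMENT,
              x=0, y=0, width=1000, height=1000)
    )
    d.glyphs.append(
        Glyph(id="cplx", label="complex A", glyph_class=GlyphClass.COMPLEX,
              x=10, y=10, width=200, height=120)
    )
    for i in range(n_glyphs):
        parent = None
        if i == 0:
            parent = "cplx"
        elif i == 1:
            parent = "comp"
        d.glyphs.append(
            Glyph(
                id=f"g{i}",
                label=f"N{i}",
                glyph_class=classes[int(rng.integers(len(classes)))],
                x=float(np.round(rng.uniform(0, 900), 3)),
                y=float(np.round(rng.uniform(0, 900), 3)),
                width=float(np.round(rng.uniform(20, 120), 3)),
                height=float(np.round(rng.uniform(15, 60), 3)),
                annotations=frozenset({("hgnc.symbol", f"N{i}")}),
                parent_id=parent,
            )
        )
    arc_classes = [ArcClass.STATE_TRANSITION, ArcClass.CATALYSIS,
                   ArcClass.INHIBITION, ArcClass.INTERACTION]
    for j in range(min(n_arcs, n_glyphs - 1)):
        cls = arc_classes[int(rng.integers(len(arc_classes)))]
        d.arcs.append(
            Arc(
                id=f"a{j}",
                source_id=f"g{j}",
                target_id=f"g{j + 1}",
                arc_class=cls,
                directed=cls is not ArcClass.INTERACTION,
            )
        )
    d.validate()
    return d


def glyph_signature(d: Diagram):
    """Order- and id-independent summary: (label, class, x, y, w, h)."""
    return sorted(
        (g.label, g.glyph_class.value, round(g.x, 3), round(g.y, 3),
         round(g.width, 3), round(g.height, 3))
        for g in d.glyphs
    )


def arc_signature(d: Diagram):
    label = {g.id: g.label for g in d.glyphs}
    return sorted(
        (label[a.source_id], label[a.target_id], a.arc_class.value, a.directed)
        for a in d.arcs
    )


SIMPLE_GPML = f"""<?xml version="1.0" encoding="UTF-8"?>
<Pathway xmlns="{GPML_NS}" Name="demo">
  <DataNode TextLabel="TP53" GraphId="n1" Type="GeneProduct">
    <Graphics CenterX="100" CenterY="100" Width="80" Height="25"/>
    <Xref Database="HGNC" ID="TP53"/>
  </DataNode>
  <DataNode TextLabel="MDM2" GraphId="n2" Type="Protein">
    <Graphics CenterX="300" CenterY="100" Width="80" Height="25"/>
  </DataNode>
  <DataNode TextLabel="ATP" GraphId="n3" Type="Metabolite">
    <Graphics CenterX="200" CenterY="250" Width="60" Height="20"/>
  </DataNode>
  <Interaction GraphId="i1">
    <Graphics>
      <Point X="140" Y="100" GraphRef="n1"/>
      <Point X="260" Y="100" GraphRef="n2" ArrowHead="Arrow"/>
    </Graphics>
  </Interaction>
  <Interaction GraphId="i2">
    <Graphics>
      <Point X="200" Y="240" GraphRef="n3"/>
      <Point X="100" Y="112" GraphRef="n1" ArrowHead="TBar"/>
    </Graphics>
  </Interaction>
</Pathway>
"""
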