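"""Format converters: GPML and SBML-layout reading, CellDesigner round
trips, SIF parsing, diagram statistics."""

import numpy as np
import pytest
from lxml import etree

from mapforge.diagram_io import (
    CELLDESIGNER_NS,
    GPML_NS,
    LAYOUT_NS,
    RENDER_NS,
    SBML_L3_NS,
    ParseError,
    parse_celldesigner_sbml,
    parse_gpml,
    parse_sbml_layout,
    read_sif,
    write_celldesigner_sbml,
)
from mapforge.fixtures import write_sbml_layout_pathway
from mapforge.model import (
    Arc,
    ArcClass,
    DialectError,
    Diagram,
    DiagramError,
    Glyph,
    GlyphClass,
    diagram_stats,
)

from conftest import SIMPLE_GPML, arc_signature, glyph_signature, random_diagram


class TestParseGpml:
    def test_datanodes_and_interactions(self):
        d, report = parse_gpml(SIMPLE_GPML)
        assert len(d.glyphs) == 3
        assert len(d.arcs) == 2
        assert report.dropped_arcs == 0
        by_label = {g.label: g for g in d.glyphs}
        assert by_label["TP53"].glyph_class is GlyphClass.PROTEIN
        assert by_label["ATP"].glyph_class is GlyphClass.METABOLITE
        # center (100,100) at 80x25 -> top-left (60, 87.5)
        assert by_label["TP53"].x == pytest.approx(60)
        assert by_label["TP53"].y == pytest.approx(87.5)
        assert by_label["TP53"].annotations == frozenset({("HGNC", "TP53")})
        arcs = {a.id: a for a in d.arcs}
        assert arcs["i1"].arc_class is ArcClass.STATE_TRANSITION
        assert arcs["i2"].arc_class is ArcClass.INHIBITION

    def test_interaction_with_missing_endpoint_is_dropped(self):
        doc = f"""<Pathway xmlns="{GPML_NS}" Name="x">
          <DataNode TextLabel="A" GraphId="n1" Type="GeneProduct">
            <Graphics CenterX="0" CenterY="0" Width="10" Height="10"/>
          </DataNode>
          <Interaction GraphId="i1"><Graphics>
            <Point X="0" Y="0" GraphRef="n1"/>
            <Point X="5" Y="5"/>
          </Graphics></Interaction>
        </Pathway>"""
        d, report = parse_gpml(doc)
        assert d.arcs == []
        assert report.dropped_arcs == 1
        assert len(report.warnings) == 1

    def test_empty_pathway(self):
        d, report = parse_gpml(f'<Pathway xmlns="{GPML_NS}" Name="empty"/>')
        assert (len(d.glyphs), len(d.arcs)) == (0, 0)

    def test_malformed_xml_names_line(self):
        with pytest.raises(ParseError, match="line"):
            parse_gpml("<Pathway>\n<broken\n")

    def test_unknown_namespace_rejected(self):
        with pytest.raises(DialectError, match="unsupported"):
            parse_gpml('<Pathway xmlns="http://example.org/not-gpml"/>')

    def test_group_becomes_complex(self):
        doc = f"""<Pathway xmlns="{GPML_NS}" Name="g">
          <DataNode TextLabel="A" GraphId="n1" Type="GeneProduct" GroupRef="gr1">
            <Graphics CenterX="50" CenterY="50" Width="40" Height="20"/>
          </DataNode>
          <DataNode TextLabel="B" GraphId="n2" Type="GeneProduct" GroupRef="gr1">
            <Graphics CenterX="120" CenterY="50" Width="40" Height="20"/>
          </DataNode>
          <Group GroupId="gr1" GraphId="grp"/>
        </Pathway>"""
        d, _ = parse_gpml(doc)
        complexes = [g for g in d.glyphs if g.glyph_class is GlyphClass.COMPLEX]
        assert len(complexes) == 1
        members = [g for g in d.glyphs if g.parent_id == complexes[0].id]
        assert {m.label for m in members} == {"A", "B"}

    def test_unmapped_type_warns_and_maps_to_unknown(self):
        doc = f"""<Pathway xmlns="{GPML_NS}" Name="u">
          <DataNode TextLabel="X" GraphId="n1" Type="Exotic">
            <Graphics CenterX="0" CenterY="0" Width="10" Height="10"/>
          </DataNode>
        </Pathway>"""
        d, report = parse_gpml(doc)
        assert d.glyphs[0].glyph_class is GlyphClass.UNKNOWN
        assert any("Exotic" in w for w in report.warnings)

    def test_images_recorded_as_dropped(self):
        doc = f"""<Pathway xmlns="{GPML_NS}" Name="img">
          <Shape GraphId="sh1"><Graphics CenterX="0" CenterY="0"
            Width="10" Height="10" ShapeType="Image"/></Shape>
        </Pathway>"""
        _, report = parse_gpml(doc)
        assert ("image", "sh1") in report.dropped_features


class TestParseSbmlLayout:
    def test_species_and_reaction(self):
        doc = write_sbml_layout_pathway(["A", "B", "C", "D"], "demo")
        d, report = parse_sbml_layout(doc)
        assert len(d.glyphs) == 4
        assert len(d.arcs) == 1
        assert d.arcs[0].arc_class is ArcClass.STATE_TRANSITION
        assert {g.label for g in d.glyphs} == {"A", "B", "C", "D"}

    def test_missing_layout_is_error(self):
        doc = f"""<sbml xmlns="{SBML_L3_NS}" level="3" version="1">
          <model id="m"><listOfSpecies>
            <species id="s1" name="A"/>
          </listOfSpecies></model></sbml>"""
        with pytest.raises(DiagramError, match="layout required"):
            parse_sbml_layout(doc)

    def test_render_styles_recorded(self):
        doc = f"""<sbml xmlns="{SBML_L3_NS}"
            xmlns:layout="{LAYOUT_NS}" xmlns:render="{RENDER_NS}"
            level="3" version="1">
          <model id="m">
            <layout:listOfLayouts><layout:layout id="l1">
              <render:listOfRenderInformation>
                <render:renderInformation><render:listOfStyles>
                  <render:style id="st1"/>
                </render:listOfStyles></render:renderInformation>
              </render:listOfRenderInformation>
            </layout:layout></layout:listOfLayouts>
          </model></sbml>"""
        _, report = parse_sbml_layout(doc)
        assert ("render", "1 styles") in report.dropped_features

    def test_species_without_layout_glyph_dropped(self):
        doc = f"""<sbml xmlns="{SBML_L3_NS}" xmlns:layout="{LAYOUT_NS}"
            level="3" version="1">
          <model id="m">
            <listOfSpecies><species id="s1" name="A"/></listOfSpecies>
            <layout:listOfLayouts><layout:layout id="l1"/>
            </layout:listOfLayouts>
          </model></sbml>"""
        d, report = parse_sbml_layout(doc)
        assert d.glyphs == []
        assert ("species", "s1") in report.dropped_features


class TestCellDesignerRoundTrip:
    def test_single_protein_counts(self):
        d = Diagram(glyphs=[Glyph(id="p", label="TP53",
                                  glyph_class=GlyphClass.PROTEIN)])
        doc = write_celldesigner_sbml(d)
        root = etree.fromstring(doc.encode())
        ns = {"s": "http://www.sbml.org/sbml/level2/version4",
              "cd": CELLDESIGNER_NS}
        assert len(root.findall(".//s:species", ns)) == 1
        assert len(root.findall(".//cd:speciesAlias", ns)) == 1

    def test_empty_diagram_is_valid(self):
        doc = write_celldesigner_sbml(Diagram())
        assert parse_celldesigner_sbml(doc).glyphs == []

    def test_nonpositive_size_rejected_before_writing(self):
        d = Diagram(glyphs=[Glyph(id="p", label="x", width=0.0)])
        with pytest.raises(DiagramError, match="non-positive"):
            write_celldesigner_sbml(d)

    def test_plain_sbml_rejected(self):
        doc = f'<sbml xmlns="{SBML_L3_NS}" level="3" version="1"><model id="m"/></sbml>'
        with pytest.raises(DialectError, match="CellDesigner"):
            parse_celldesigner_sbml(doc)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_diagram_round_trip(self, seed):
        """Write-then-parse preserves counts, labels, classes and
        coordinates exactly (well within the 0.5 px contract)."""
        d = random_diagram(np.random.default_rng(seed))
        back = parse_celldesigner_sbml(write_celldesigner_sbml(d))
        assert len(back.glyphs) == len(d.glyphs)
        assert len(back.arcs) == len(d.arcs)
        assert glyph_signature(back) == glyph_signature(d)
        assert arc_signature(back) == arc_signature(d)

    def test_annotations_round_trip(self):
        d = Diagram(glyphs=[
            Glyph(id="p", label="TP53", glyph_class=GlyphClass.PROTEIN,
                  annotations=frozenset({("hgnc.symbol", "TP53"),
                                         ("uniprot", "P04637")}))
        ])
        back = parse_celldesigner_sbml(write_celldesigner_sbml(d))
        assert back.glyphs[0].annotations == d.glyphs[0].annotations

    def test_complex_membership_round_trip(self):
        d = Diagram(glyphs=[
            Glyph(id="c", label="cplx", glyph_class=GlyphClass.COMPLEX,
                  x=0, y=0, width=200, height=100),
            Glyph(id="m", label="sub", glyph_class=GlyphClass.PROTEIN,
                  x=10, y=10, parent_id="c"),
        ])
        back = parse_celldesigner_sbml(write_celldesigner_sbml(d))
        member = next(g for g in back.glyphs if g.label == "sub")
        parent = back.glyph_by_id(member.parent_id)
        assert parent.glyph_class is GlyphClass.COMPLEX
        assert parent.label == "cplx"

    def test_gpml_to_celldesigner_chain(self):
        gpml_diag, _ = parse_gpml(SIMPLE_GPML)
        back = parse_celldesigner_sbml(write_celldesigner_sbml(gpml_diag))
        assert glyph_signature(back) == glyph_signature(gpml_diag)
        assert arc_signature(back) == arc_signature(gpml_diag)


class TestSif:
    def test_single_line(self):
        assert read_sif("A activates B") == [("A", "activates", "B")]

    def test_empty_and_blank_lines(self):
        assert read_sif("") == []
        assert read_sif("\n\nA rel B\n\n") == [("A", "rel", "B")]

    def test_wrong_token_count_names_line(self):
        with pytest.raises(ParseError, match="line 2"):
            read_sif("A rel B\nA B\n")


class TestDiagramStats:
    def test_compartments_excluded(self):
        d = Diagram(glyphs=[
            Glyph(id="c", label="", glyph_class=GlyphClass.COMPARTMENT,
                  width=500, height=500),
            Glyph(id="p1", label="a", glyph_class=GlyphClass.PROTEIN),
            Glyph(id="p2", label="b", glyph_class=GlyphClass.PROTEIN),
            Glyph(id="p3", label="c3", glyph_class=GlyphClass.PROTEIN),
        ], arcs=[
            Arc(id="a1", source_id="p1", target_id="p2"),
            Arc(id="a2", source_id="p2", target_id="p3"),
        ])
        assert diagram_stats(d) == (3, 2)

    def test_empty(self):
        assert diagram_stats(Diagram()) == (0, 0)

    def test_additive_over_disjoint_union(self):
        rng = np.random.default_rng(0)
        a, b = random_diagram(rng), random_diagram(rng)
        union = Diagram(
            glyphs=[*a.glyphs,
                    *(Glyph(**{**g.__dict__, "id": "u_" + g.id,
                               "parent_id": None if g.parent_id is None
                               else "u_" + g.parent_id})
                      for g in b.glyphs)],
            arcs=[*a.arcs,
                  *(Arc(id="u_" + x.id, source_id="u_" + x.source_id,
                        target_id="u_" + x.target_id, arc_class=x.arc_class,
                        directed=x.directed) for x in b.arcs)],
        )
        sa, sb, su = diagram_stats(a), diagram_stats(b), diagram_stats(union)
        assert su == (sa[0] + sb[0], sa[1] + sb[1])
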