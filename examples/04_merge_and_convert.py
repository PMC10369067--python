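"""Convert pathway dialects into the common model and mesh-merge them
into one CellDesigner SBML map."""

from mapforge.assembly import assemble_map
from mapforge.diagram_io import (
    parse_celldesigner_sbml,
    parse_sbml_layout,
    write_celldesigner_sbml,
)
from mapforge.fixtures import (
    make_gene_diagram,
    write_gpml_pathway,
    write_sbml_layout_pathway,
)
from mapforge.model import diagram_stats

disease_maps = [make_gene_diagram(["ITPKC", "ORAI1", "STIM1"], "calcium")]
textmining = write_gpml_pathway(["FCGR2A", "BLK"], "textmining")
reactome_doc = write_sbml_layout_pathway(["CASP3", "XIAP", "BIRC2"],
                                         "apoptosis")
pathways = [parse_sbml_layout(reactome_doc)[0]]

final, report = assemble_map(disease_maps, textmining, pathways, margin=20)
elements, interactions = diagram_stats(final)
print(f"merged map: {elements} unique elements, {interactions} interactions")

document = write_celldesigner_sbml(final)
back = parse_celldesigner_sbml(document)
print("round trip preserves stats:", diagram_stats(back) == (elements,
                                                             interactions))
print("first 3 lines of the CellDesigner SBML output:")
print("\n".join(document.splitlines()[:3]))
# Components keep their internal layouts and are tiled on a near-square
# grid; "unique elements" counts glyphs excluding compartments, the two
# numbers a map's size is usually quoted by.
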