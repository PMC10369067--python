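"""Refined text-mining network: neighbor expansion, directed intersection,
force-directed layout and GPML export."""

from mapforge.diagram_io import parse_gpml
from mapforge.network import (
    DirectedEdge,
    LayoutParams,
    ScoredEdge,
    build_textmining_network,
)

seeds = ["FCGR2A", "BLK", "CASP3"]
scored = [
    ScoredEdge("FCGR2A", "BLK", 920),     # strong, in module
    ScoredEdge("FCGR2A", "SYK", 880),     # strong, pulls in a neighbor
    ScoredEdge("CASP3", "XIAP", 830),
    ScoredEdge("BLK", "WEAK1", 300),      # below threshold, ignored
]
directed = [
    DirectedEdge("FCGR2A", "BLK", "activation"),
    DirectedEdge("XIAP", "CASP3", "inhibition"),
    DirectedEdge("FCGR2A", "ELSEWHERE", "activation"),  # partner outside
]

gpml, nodes, refined, unsupported = build_textmining_network(
    seeds, scored, directed,
    min_score=700, max_new=5,
    layout=LayoutParams(width=800, height=600, iterations=150, seed=42),
)

print("text-mining nodes:", nodes)
print("directed interactions kept:",
      [(e.source, e.target, e.sign) for e in refined])
print("undirected edges without curated direction:",
      [(e.a, e.b, e.score) for e in unsupported])

diagram, report = parse_gpml(gpml)
print(f"GPML diagram: {len(diagram.glyphs)} nodes, {len(diagram.arcs)} "
      f"interactions, {report.dropped_arcs} dropped")
# Only interactions whose BOTH partners appear in the scored text-mining
# results keep their curated direction and sign; the rest go to a sidecar.
# The layout is deterministic for a fixed seed.
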