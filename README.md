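# mapforge

Ad-hoc assembly of molecular disease maps for rare diseases, entirely
offline against file-backed data sources.

Rare disorders are usually too sparsely covered by pathway databases for a
research group to find a ready-made mechanistic map, and curating one from
scratch is expensive. `mapforge` automates the prototyping step: starting
from a standardized disease definition — an Orphanet identifier such as
`ORPHA:2331`, or a list of HPO phenotype terms such as
`HP:0001644, HP:0002617` — it

1. **builds the disease context**: consolidates gene–disease and
   variant–disease associations across emulated DisGeNET, OpenTargets,
   ClinVar and Orphanet sources (with per-source score thresholds and a
   cross-source discrepancy report), and filters variants for rarity by
   population allele frequency;
2. **collects a network of mechanisms**: finds disease-map areas and
   WikiPathways/Reactome diagrams enriched for the context genes by
   over-representation analysis, and builds a refined text-mining network —
   STRING-style scored neighbor expansion intersected with OmniPath-style
   curated directed interactions — laid out with the Fruchterman–Reingold
   algorithm;
3. **assembles an interactive prototype**: converts every component (GPML,
   SBML Level 3 + layout/render, CellDesigner SBML) into one common
   glyph-and-arc model, mesh-merges them into a single CellDesigner-SBML
   map preserving each source's layout, and bundles the map with gene,
   variant and expression data overlays into one ZIP archive ready for a
   map-hosting platform.

Every live web service of the original workflow is replaced by a documented
file-backed table or diagram collection, so runs are reproducible and
seed-deterministic end to end.

## The statistics at the core

Pathway enrichment is classic over-representation: for a query of *n* genes
drawn from a universe of *N*, overlapping a set of size *K* in *k* genes,

p = Σᵢ₌ₖ^min(K,n) C(K,i) · C(N−K, n−i) / C(N,n)

(the hypergeometric upper tail, equivalently a one-sided Fisher exact test),
computed with exact integer arithmetic, with Benjamini–Hochberg adjusted
values reported alongside. Reactome results are narrowed to sets that have
a diagram layout and to topmost sets when nested sets are both enriched.
Variant rarity uses the maximum allele frequency across the configured
populations (drop iff max AF ≥ threshold; variants absent from the panel
are kept). Differential expression is consumed as an edgeR-style per-gene
table and filtered at FDR < 0.05 and linear fold change > 2, with log₂ fold
changes scaled to [−1, 1] by their maximum absolute value for the overlay.

## Worked example

```bash
mapforge fixtures --seed 7 -o world     # synthetic input world
mapforge run -c world/config.yaml       # full three-stage workflow
```

or, from Python, `python examples/05_full_pipeline.py`, which prints:

```
world: 20 planted disease genes, 3 planted pathway sets per collection
{
  "genes": 20,
  "variants": 8,
  "diagrams_retrieved": {
    "disease_maps": 3,
    "wikipathways": 3,
    "reactome": 3
  },
  "textmining_interactions": 29,
  "map_unique_elements": 102,
  "map_interactions": 74,
  "deg_survivors": 371
}
bundle members: ['map.xml', 'overlays/expression.txt', 'overlays/genes.txt',
                 'overlays/variants.txt', 'manifest.json']
```

Reading: the context stage recovered the 20 planted disease genes and 8
rare variants (3 planted common variants were removed by the 1% allele-
frequency filter); enrichment retrieved the 3 planted diagrams from each
collection; the refined text-mining network kept 29 directed interactions;
the merged map holds 102 unique elements (glyphs excluding compartments)
and 74 interactions; 371 differentially expressed genes survived the
FDR/fold-change filter and ship as the expression overlay. `map.xml` is
the merged CellDesigner-SBML diagram.

The other scripts under `examples/` each demonstrate one capability
(context building, enrichment, text-mining network, format conversion and
merging) on small inline inputs.

## Layout of the package

| module | role |
| --- | --- |
| `mapforge.model` | common glyph-and-arc diagram model |
| `mapforge.diagram_io` | GPML / SBML+layout / CellDesigner SBML / SIF converters with loss reports |
| `mapforge.context` | stage 1: disease context from association tables |
| `mapforge.enrichment` | stage 2a/b: over-representation analysis over diagram collections |
| `mapforge.network` | stage 2c: text-mining network, refinement, FR layout |
| `mapforge.assembly` | stage 3a: mesh merge into one CellDesigner map |
| `mapforge.overlays` | stage 3b–d: overlay tables and the ZIP bundle |
| `mapforge.fixtures` | synthetic input worlds with planted ground truth |
| `mapforge.pipeline`, `mapforge.cli` | configuration-driven driver and the `mapforge` command |

See `docs/methods.md` for the modelling choices, parameter semantics and
known limitations.
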