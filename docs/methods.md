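# Methods

This note documents the models, conventions and design choices behind
`mapforge`, and what the synthetic-data tests do and do not demonstrate.

## The common diagram model

All source dialects are converted into one glyph-and-arc model. Glyphs
carry a class (`protein`, `gene`, `rna`, `metabolite`, `complex`,
`phenotype`, `compartment`, `unknown`), a top-left-anchored bounding box in
pixels (GPML convention: origin top-left, y growing downward; SBML layout
coordinates are adopted unchanged), identifier annotations as
(namespace, id) pairs, and an optional parent (complex or compartment,
complex nesting capped at one level — deeper nesting is flattened). Arcs
are `state_transition`, `catalysis`, `inhibition` or undirected
`interaction`.

Conversions are deliberately lossy-but-audited: anything the model cannot
represent (GPML Labels/Shapes/embedded images, interactions missing an
anchored endpoint, SBML render styles, extra reaction participants,
species without layout) is recorded in a `ConversionReport` rather than
silently discarded. The GPML `Type → class` mapping is a fixed table
(GeneProduct/Protein → protein, Gene → gene, Rna → rna, Metabolite →
metabolite, Pathway → phenotype, Complex → complex; anything else →
unknown with a warning), and GPML Groups of DataNodes become complex
glyphs. An SBML-layout reaction glyph maps to a single
first-substrate → first-product arc (its modifiers become catalysis arcs),
so one reaction contributes one interaction to map statistics.

The harmonized output dialect is CellDesigner-extended SBML Level 2
Version 4: one species plus one species alias (carrying the bounding box)
per glyph, `complexSpeciesAlias` for complexes, SBML compartments with
compartment aliases for compartment glyphs, catalysis/inhibition encoded
as modifier species references, and annotations as MIRIAM
`urn:miriam:<namespace>:<id>` resource URIs. The level/version choice is
an assumption of this implementation; round trips through the writer and
reader preserve counts, labels, classes and coordinates exactly (the
contract is ±0.5 px).

Map size is quoted as `(unique elements, interactions)` where unique
elements counts glyphs excluding compartments. Nothing is deduplicated
across merged components, so "unique" means distinct glyphs in the merged
map, and a gene present in two source diagrams is highlighted twice by
overlays — source layouts are kept verbatim by design.

## Disease context

A disease is defined by Orphanet ids or by HPO terms. HPO queries are
matched to diseases by Jaccard similarity between the query set and each
disease's annotation set (symmetric, threshold-free; zero-score diseases
excluded, ties broken by ascending Orphanet id). Association sources are
file-backed tables with documented TSV/JSON schemas; OpenTargets rows are
keyed by EFO ids and reached through a required ORPHA↔EFO mapping table
(unmapped ids are skipped with a warning).

Per-source rules: DisGeNET and OpenTargets rows are kept at score ≥ the
source's threshold and truncated to the configured maximum per source
(descending score, ties by symbol); Orphanet and ClinVar rows carry score
1.0 and are always kept; ClinVar contributes only pathogenic and
likely-pathogenic variants. The discrepancy report lists, per entity,
which sources contain it, and flags every DisGeNET/OpenTargets variant
whose ClinVar significance is benign/likely-benign (`clinvar_conflict`) —
flagged variants are retained, not deleted, so the analyst decides.

Rarity filtering removes a variant iff its **maximum** allele frequency
over the configured populations is ≥ the threshold (default 0.01) — the
maximum is the conservative aggregation for a rarity claim. Variants with
no frequency record in any configured population are kept: rare-disease
variants are frequently absent from population panels and dropping them
would defeat the workflow's purpose. Finally the gene list is augmented
with the genes carrying surviving variants (original order first, new
genes alphabetically).

## Enrichment

"Enrichment" here is over-representation analysis: the gene list is
unranked, so the exact hypergeometric upper tail applies. It is computed
with integer arithmetic (`Fraction` of binomial coefficients), making unit
comparisons against exhaustive draw enumeration exact rather than
approximate. The universe defaults to the union of the collection's gene
sets (the choice is configurable); query genes outside the universe are
dropped with a warning. Results need overlap ≥ 1, are ranked by raw
p-value with a deterministic set-id tie-break, and truncated by count only
— the only retrieval control the workflow exposes is "maximum number of
diagrams". Benjamini–Hochberg adjusted values (via
`scipy.stats.false_discovery_control`) are reported for the record.
Reactome results are additionally narrowed to sets with a layout and to
topmost sets when nested sets are both enriched (the surviving set ids form
an antichain in the nesting order).

## Text-mining network

Scored undirected interactions use the STRING detail-file convention
(integer scores 0–1000). The configured score bound is interpreted as a
**minimum** (STRING semantics). "First *n* neighbors" is implemented as
best-score-first global truncation across all seeds — candidate
non-seed nodes are ranked by the best score of any edge linking them to a
seed — rather than per-seed quotas, for determinism and simplicity.
Directed refinement keeps exactly the directed, signed edges whose both
partners are text-mining nodes; undirected edges without directed support
are excluded from the diagram but written to a sidecar table. Isolated
nodes remain in the diagram as unconnected elements.

The layout is the classic Fruchterman–Reingold algorithm: ideal distance
`k = sqrt(area/|V|)` (constant C = 1), repulsion `k²/d` between all pairs,
attraction `d²/k` along edges, displacement capped by a temperature that
cools linearly to zero, positions clamped to the frame, initial positions
uniform from a seeded generator. Fixed seed ⇒ bitwise-identical
coordinates. Defaults: 1000×1000 px frame, 100 iterations, initial
temperature 100 px. A two-node network settles at distance ≈ k, which the
tests verify against an independent two-body force simulation.

## Assembly

"Mesh layout" is a row-major near-square grid: `ceil(sqrt(m))` columns,
each cell sized to its component's bounding box plus a margin (default
20 px) on the right and bottom, row height following the tallest cell.
Component ids are prefixed with a unique tag, coordinates offset by the
cell origin, internal layouts untouched; component bounding boxes are
pairwise disjoint by construction. The final map merges, in order, the
disease-map block, the text-mining block and the pathway block; empty
components are skipped with a warning.

## Overlays and bundle

The fold-change filter keeps rows with FDR < 0.05 and linear fold change
> 2 (i.e. |log₂FC| > 1); a `scale="log"` toggle compares |log₂FC| against
the bound directly. Normalization to [−1, 1] divides by the maximum
absolute log-fold-change (clipping at ±1 was the alternative; max-abs
preserves the ordering of magnitudes and is what the overlay legend
assumes). Variant overlay rows require genomic coordinates
(`chrom:pos:ref:alt` identifiers); protein-level positions come only from
input tables and are never imputed. The overlay files use a simple TSV
dialect with `#NAME=`/`#TYPE=` header lines (variants marked
`GENETIC_VARIANT`); the writer is isolated so the dialect can be swapped.
ZIP members are written with a fixed timestamp so identical runs are
byte-identical.

## Synthetic worlds and what the tests show

The fixture generator emits every input the pipeline consumes, from a
single seeded generator (same seed ⇒ byte-identical files). Its defaults
describe a small but complete study: 20 disease genes against 60 decoys
(association scores 0.6–0.95 vs 0.05–0.25 around the 0.3 threshold), 6
rare pathogenic variants (one deliberately absent from the frequency
panel), 3 common variants (AF 0.1–0.3) and 2 ClinVar-benign conflicts, 3
planted diagram areas per collection with ≥ 80 % disease genes versus
decoy sets carrying at most one, a high-score STRING module (900–999) with
10 planted neighbors (850–950) over a 150–400 background, and a
differential-expression table planting 371 filter survivors — the survivor
count of the retinitis-pigmentosa organoid dataset this workflow is
demonstrated on — among 129 failing rows. The retrieval limits in the
generated configuration (3 disease-map diagrams, pathway cap per
database, 100-neighbor budget) mirror the demonstrated runs.

Because the planted signal is separable by construction, recovery tests
are exact, not statistical: they verify the machinery (thresholds,
ranking, filtering, intersection, merging) faithfully, but they say
nothing about behaviour on noisy real data, where association scores,
set overlaps and interaction scores are not cleanly separated and where
the headline counts depend on live database versions. The synthetic
differential-expression table is a labelled stand-in, not the real
RNA-seq-derived table.

## Numerical and degenerate-input choices

Exact integer arithmetic for the enrichment tail; float coordinates
written at full precision (`repr`) for lossless round trips; FR layout
guards zero distances with ε = 1e-9; empty seed sets, empty collections
and all-empty assembly inputs are warnings or named errors, never silent;
all ties everywhere break deterministically (score then symbol, p-value
then set id, lexicographic edges).

## Known limitations

No live web clients (the adapter schemas document what a client must
produce); no SBGN-ML or image export; CellDesigner state variables,
residues and deep complex nesting are out of scope; single-component FR
layout only (disconnected components may drift to frame edges); merged
maps keep each source's style — harmonizing the patchwork is left to the
analyst, as is splitting a large map into sub-maps.
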