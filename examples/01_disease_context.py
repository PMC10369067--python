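"""Build a disease context from small in-memory association tables.

Consolidates gene and variant associations across emulated DisGeNET,
OpenTargets, ClinVar and Orphanet sources, flags ClinVar-benign conflicts,
and applies the population allele-frequency rarity filter.
"""

import pandas as pd

from mapforge.context import AssociationSources, DiseaseQuery, build_context

sources = AssociationSources(
    phenotype_annotations=pd.DataFrame(
        [("ORPHA:2331", "HP:0001644"), ("ORPHA:2331", "HP:0002617")],
        columns=["orpha_id", "hpo_id"],
    ),
    gene_associations=pd.DataFrame(
        [
            ("disgenet", "ORPHA:2331", "FCGR2A", "0.7"),
            ("disgenet", "ORPHA:2331", "CASP3", "0.55"),
            ("disgenet", "ORPHA:2331", "WEAKHIT", "0.1"),
            ("opentargets", "EFO:0004246", "ITPKC", "0.8"),
            ("orphanet", "ORPHA:2331", "BLK", "1.0"),
        ],
        columns=["source", "orpha_id", "gene", "score"],
    ),
    variant_associations=pd.DataFrame(
        [
            ("clinvar", "ORPHA:2331", "chr1:161479745:G:A", "FCGR2A",
             "pathogenic", ""),
            ("clinvar", "ORPHA:2331", "chr4:184627900:C:T", "CASP3",
             "benign", ""),
            ("opentargets", "EFO:0004246", "chr4:184627900:C:T", "CASP3",
             "uncertain", "0.6"),
        ],
        columns=["source", "orpha_id", "variant_id", "gene", "significance",
                 "score"],
    ),
    allele_frequencies=pd.DataFrame(
        [("chr1:161479745:G:A", "EUR", "0.0002")],
        columns=["variant_id", "population", "af"],
    ),
    orpha_efo_map=pd.DataFrame(
        [("ORPHA:2331", "EFO:0004246")], columns=["orpha_id", "efo_id"]
    ),
)

context = build_context(
    DiseaseQuery(orpha_ids=["ORPHA:2331"]),
    sources,
    score_thresholds={"disgenet": 0.3, "opentargets": 0.3},
    af_threshold=0.01,
    populations=["EUR"],
)

print("disease-relevant genes:", context.genes)
print("surviving variants:", [v.variant_id for v in context.variants])
print(context.discrepancy_report.to_string(index=False))
# The gene list unions all sources above their score thresholds (WEAKHIT
# falls below 0.3) plus genes carrying surviving variants; the report row
# with clinvar_conflict=True marks the OpenTargets variant that ClinVar
# calls benign - kept in the context, but flagged for the analyst.
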