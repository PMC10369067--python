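"""Disease-context assembly: phenotype matching, source consolidation,
ClinVar reconciliation, allele-frequency filtering, gene augmentation."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapforge.context import (
    AssociationSources,
    ConfigurationError,
    ContextError,
    DiseaseQuery,
    NoPhenotypeMatchError,
    VariantAssociation,
    build_context,
    collect_genes,
    collect_variants,
    filter_by_allele_frequency,
    genes_from_variants,
    match_hpo_to_orphanet,
    reconcile_clinvar,
)


def annotations(pairs):
    return pd.DataFrame(pairs, columns=["orpha_id", "hpo_id"])


def make_sources(genes=(), variants=(), afs=(), efo=()):
    return AssociationSources(
        phenotype_annotations=annotations([]),
        gene_associations=pd.DataFrame(
            genes, columns=["source", "orpha_id", "gene", "score"]
        ).astype(str),
        variant_associations=pd.DataFrame(
            variants,
            columns=["source", "orpha_id", "variant_id", "gene",
                     "significance", "score"],
        ).astype(str),
        allele_frequencies=pd.DataFrame(
            afs, columns=["variant_id", "population", "af"]
        ).astype(str),
        orpha_efo_map=pd.DataFrame(
            efo, columns=["orpha_id", "efo_id"]
        ).astype(str),
    )


class TestDiseaseQuery:
    def test_requires_exactly_one_list(self):
        with pytest.raises(ContextError):
            DiseaseQuery()
        with pytest.raises(ContextError):
            DiseaseQuery(orpha_ids=["ORPHA:1"], hpo_terms=["HP:0000001"])

    def test_normalization(self):
        q = DiseaseQuery(orpha_ids=["2331", "Orphanet_791"])
        assert q.orpha_ids == ["ORPHA:2331", "ORPHA:791"]
        q = DiseaseQuery(hpo_terms=["HP_0001644"])
        assert q.hpo_terms == ["HP:0001644"]

    def test_invalid_identifier(self):
        with pytest.raises(ContextError, match="invalid"):
            DiseaseQuery(orpha_ids=["ORPHA:xyz"])


class TestHpoMatching:
    def test_jaccard_score(self):
        ann = annotations([
            ("ORPHA:1", "HP:0000001"), ("ORPHA:1", "HP:0000002"),
            ("ORPHA:1", "HP:0000003"), ("ORPHA:2", "HP:0000004"),
        ])
        out = match_hpo_to_orphanet(["HP:0000001", "HP:0000002"], ann, top_k=5)
        assert out == [("ORPHA:1", pytest.approx(2 / 3))]

    def test_exact_annotation_set_scores_one(self):
        ann = annotations([
            ("ORPHA:1", "HP:0000001"), ("ORPHA:1", "HP:0000002"),
            ("ORPHA:2", "HP:0000001"), ("ORPHA:2", "HP:0000002"),
            ("ORPHA:2", "HP:0000003"),
        ])
        out = match_hpo_to_orphanet(["HP:0000001", "HP:0000002"], ann)
        assert out[0] == ("ORPHA:1", 1.0)

    def test_ties_break_by_ascending_orpha_id(self):
        ann = annotations([
            ("ORPHA:20", "HP:0000001"), ("ORPHA:10", "HP:0000001"),
        ])
        out = match_hpo_to_orphanet(["HP:0000001"], ann)
        assert [o for o, _ in out] == ["ORPHA:10", "ORPHA:20"]

    def test_no_match_is_error(self):
        ann = annotations([("ORPHA:1", "HP:0000009")])
        with pytest.raises(NoPhenotypeMatchError):
            match_hpo_to_orphanet(["HP:0000001"], ann)

    def test_top_k_truncation(self):
        ann = annotations([(f"ORPHA:{i}", "HP:0000001") for i in range(9)])
        assert len(match_hpo_to_orphanet(["HP:0000001"], ann, top_k=3)) == 3


class TestCollectGenes:
    def test_threshold(self):
        src = make_sources(genes=[
            ("disgenet", "ORPHA:1", "G1", "0.4"),
            ("disgenet", "ORPHA:1", "G2", "0.2"),
        ])
        out = collect_genes(["ORPHA:1"], src, {"disgenet": 0.3})
        assert [a.gene for a in out] == ["G1"]

    def test_max_genes_truncation_by_score(self):
        src = make_sources(genes=[
            ("disgenet", "ORPHA:1", "GLOW", "0.8"),
            ("disgenet", "ORPHA:1", "GHI", "0.9"),
        ])
        out = collect_genes(["ORPHA:1"], src, max_genes=1)
        assert [a.gene for a in out] == ["GHI"]

    def test_orphanet_rows_always_kept_with_score_one(self):
        src = make_sources(genes=[("orphanet", "ORPHA:1", "G1", "")])
        out = collect_genes(["ORPHA:1"], src, {"disgenet": 0.99})
        assert out[0].score == 1.0

    def test_opentargets_matched_via_efo_map(self):
        src = make_sources(
            genes=[("opentargets", "EFO:1", "G1", "0.9")],
            efo=[("ORPHA:1", "EFO:1")],
        )
        out = collect_genes(["ORPHA:1"], src)
        assert [a.gene for a in out] == ["G1"]
        # without a mapping the row is unreachable, with a warning
        warnings = []
        src2 = make_sources(genes=[("opentargets", "EFO:1", "G1", "0.9")])
        assert collect_genes(["ORPHA:1"], src2, warnings=warnings) == []

    def test_unknown_orpha_warns_not_errors(self):
        warnings = []
        src = make_sources(genes=[("disgenet", "ORPHA:1", "G1", "0.4")])
        out = collect_genes(["ORPHA:999"], src, warnings=warnings)
        assert out == [] and warnings

    def test_empty_sources(self):
        assert collect_genes(["ORPHA:1"], make_sources()) == []

    @given(thr=st.floats(0, 1), thr2=st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotonicity(self, thr, thr2):
        lo, hi = sorted([thr, thr2])
        src = make_sources(genes=[
            ("disgenet", "ORPHA:1", f"G{i}", str(i / 10)) for i in range(11)
        ])
        n_lo = len(collect_genes(["ORPHA:1"], src, {"disgenet": lo}))
        n_hi = len(collect_genes(["ORPHA:1"], src, {"disgenet": hi}))
        assert n_hi <= n_lo


class TestCollectVariants:
    def test_clinvar_pathogenic_only(self):
        src = make_sources(variants=[
            ("clinvar", "ORPHA:1", "V1", "G1", "pathogenic", ""),
            ("clinvar", "ORPHA:1", "V2", "G1", "benign", ""),
        ])
        out = collect_variants(["ORPHA:1"], src)
        assert [v.variant_id for v in out] == ["V1"]
        assert out[0].score == 1.0

    def test_scored_source_threshold(self):
        src = make_sources(variants=[
            ("disgenet", "ORPHA:1", "V1", "G1", "uncertain", "0.2"),
        ])
        assert collect_variants(["ORPHA:1"], src, {"disgenet": 0.5}) == []

    def test_no_sources(self):
        assert collect_variants(["ORPHA:1"], make_sources()) == []


class TestReconcileClinvar:
    def test_benign_conflict_flagged_but_kept(self):
        variants = [VariantAssociation("V1", "G1", "uncertain", 0.8,
                                       "opentargets")]
        table = pd.DataFrame(
            [("clinvar", "ORPHA:1", "V1", "G1", "benign", "")],
            columns=["source", "orpha_id", "variant_id", "gene",
                     "significance", "score"],
        )
        report = reconcile_clinvar(variants, table)
        row = report[report.entity == "V1"].iloc[0]
        assert bool(row.clinvar_conflict)
        assert row.present_in == "opentargets"

    def test_pathogenic_everywhere_unflagged(self):
        variants = [
            VariantAssociation("V1", "G1", "pathogenic", 1.0, "clinvar"),
            VariantAssociation("V1", "G1", "pathogenic", 0.9, "disgenet"),
            VariantAssociation("V1", "G1", "pathogenic", 0.9, "opentargets"),
        ]
        table = pd.DataFrame(
            [("clinvar", "ORPHA:1", "V1", "G1", "pathogenic", "")],
            columns=["source", "orpha_id", "variant_id", "gene",
                     "significance", "score"],
        )
        report = reconcile_clinvar(variants, table)
        row = report[report.entity == "V1"].iloc[0]
        assert not bool(row.clinvar_conflict)
        assert row.present_in == "clinvar,disgenet,opentargets"

    def test_empty_inputs(self):
        report = reconcile_clinvar([], pd.DataFrame(
            columns=["source", "orpha_id", "variant_id", "gene",
                     "significance", "score"]))
        assert report.empty


class TestAlleleFrequencyFilter:
    AFS = [("V1", "EUR", "0.20"), ("V1", "AFR", "0.05"),
           ("V2", "EUR", "0.001")]

    def variants(self, *ids):
        return [VariantAssociation(v, "G") for v in ids]

    def test_max_af_rule_removes_common(self):
        src = make_sources(afs=self.AFS)
        out = filter_by_allele_frequency(
            self.variants("V1"), src.allele_frequencies, 0.01, ["EUR", "AFR"]
        )
        assert out == []

    def test_missing_record_kept(self):
        src = make_sources(afs=self.AFS)
        out = filter_by_allele_frequency(
            self.variants("V9"), src.allele_frequencies, 0.01, ["EUR"]
        )
        assert [v.variant_id for v in out] == ["V9"]

    def test_threshold_one_removes_nothing(self):
        src = make_sources(afs=self.AFS)
        out = filter_by_allele_frequency(
            self.variants("V1", "V2"), src.allele_frequencies, 1.0, ["EUR"]
        )
        assert len(out) == 2

    def test_unknown_population_is_config_error(self):
        src = make_sources(afs=self.AFS)
        with pytest.raises(ConfigurationError, match="AFR"):
            filter_by_allele_frequency(
                self.variants("V1"), src.allele_frequencies, 0.01, ["MARS"]
            )

    @given(t=st.floats(0.001, 1.0), t2=st.floats(0.001, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_survivors_nested_in_threshold(self, t, t2):
        t1, t2 = sorted([t, t2])
        src = make_sources(afs=self.AFS)
        vs = self.variants("V1", "V2", "V9")
        s1 = {v.variant_id for v in filter_by_allele_frequency(
            vs, src.allele_frequencies, t1, ["EUR"])}
        s2 = {v.variant_id for v in filter_by_allele_frequency(
            vs, src.allele_frequencies, t2, ["EUR"])}
        assert s1 <= s2


class TestGenesFromVariants:
    def test_union_with_stated_order(self):
        vs = [VariantAssociation("v1", "G1"), VariantAssociation("v2", "G2")]
        assert genes_from_variants(["G2", "G3"], vs) == ["G2", "G3", "G1"]

    def test_no_variants_unchanged(self):
        assert genes_from_variants(["G2", "G1"], []) == ["G2", "G1"]

    def test_variants_only_alphabetical(self):
        vs = [VariantAssociation("v1", "GB"), VariantAssociation("v2", "GA")]
        assert genes_from_variants([], vs) == ["GA", "GB"]


class TestBuildContextOnWorld:
    def test_planted_genes_recovered_exactly(self, world):
        path, truth = world
        sources = AssociationSources.from_dir(path / "sources")
        context = build_context(
            DiseaseQuery(orpha_ids=[truth.orpha_id]),
            sources,
            score_thresholds={"disgenet": 0.3, "opentargets": 0.3},
            af_threshold=0.01,
            populations=["EUR", "AFR", "EAS"],
        )
        assert sorted(context.genes) == sorted(truth.disease_genes)
        surviving = {v.variant_id for v in context.variants}
        assert surviving == set(truth.rare_variants) | set(
            truth.benign_conflict_variants
        )
        # every entity has non-empty provenance from configured sources
        for g in context.genes:
            assert context.provenance[g] <= {"orphanet", "disgenet",
                                             "opentargets", "clinvar"}
            assert context.provenance[g]
        flagged = context.discrepancy_report
        conflicts = set(flagged[flagged.clinvar_conflict].entity)
        assert conflicts == set(truth.benign_conflict_variants)

    def test_hpo_entry_point_resolves_disease(self, world):
        path, truth = world
        sources = AssociationSources.from_dir(path / "sources")
        matches = match_hpo_to_orphanet(
            ["HP:0000001", "HP:0000002"], sources.phenotype_annotations
        )
        assert matches[0][0] == truth.orpha_id
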