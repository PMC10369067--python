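"""Stage 1 — disease context.

Builds the consolidated list of disease-relevant genes and variants, with
per-source provenance and a cross-source discrepancy report, from an
Orphanet identifier (or a list of HPO phenotype terms) and file-backed
association tables emulating DisGeNET, OpenTargets, ClinVar and a VEP
allele-frequency extract.

Table schemas (TSV with header, JSON list-of-records also accepted):

* phenotype annotations: ``orpha_id, hpo_id``
* gene associations:     ``source, orpha_id, gene, score``
  (for ``opentargets`` rows the ``orpha_id`` column carries the EFO id,
  resolved through the ORPHA↔EFO map)
* variant associations:  ``source, orpha_id, variant_id, gene, significance,
  score``
* allele frequencies:    ``variant_id, population, af``
* ORPHA↔EFO map:         ``orpha_id, efo_id``
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

ORPHA_RE = re.compile(r"^ORPHA:\d+$")
HPO_RE = re.compile(r"^HP:\d{7}$")

GENE_SOURCES = ("orphanet", "disgenet", "opentargets", "clinvar")
PATHOGENIC = ("pathogenic", "likely_pathogenic")
BENIGN = ("benign", "likely_benign")


class ContextError(ValueError):
    pass


class NoPhenotypeMatchError(ContextError):
    """No disease shares a single HPO term with the query."""


class ConfigurationError(ContextError):
    pass


def _normalize_orpha(value: str) -> str:
    v = value.strip()
    if v.isdigit():
        v = f"ORPHA:{v}"
    v = v.replace("Orphanet_", "ORPHA:").replace("ORPHA_", "ORPHA:")
    if not ORPHA_RE.match(v):
        raise ContextError(f"invalid Orphanet identifier: {value!r}")
    return v


def _normalize_hpo(value: str) -> str:
    v = value.strip().replace("HP_", "HP:")
    if not HPO_RE.match(v):
        raise ContextError(f"invalid HPO identifier: {value!r}")
    return v


@dataclass
class DiseaseQuery:
    """Disease definition: Orphanet ids, or HPO terms to be matched."""

    orpha_ids: list[str] = field(default_factory=list)
    hpo_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if bool(self.orpha_ids) == bool(self.hpo_terms):
            raise ContextError(
                "exactly one of orpha_ids / hpo_terms must be provided"
            )
        self.orpha_ids = [_normalize_orpha(v) for v in self.orpha_ids]
        self.hpo_terms = [_normalize_hpo(v) for v in self.hpo_terms]


@dataclass
class GeneAssociation:
    gene: str
    orpha_id: str
    score: float
    source: str


@dataclass
class VariantAssociation:
    variant_id: str
    gene: str
    clinical_significance: str = "unreported"
    score: Optional[float] = None
    source: str = ""

    def coordinates(self) -> Optional[tuple[str, int, str, str]]:
        """(contig, pos, ref, alt) if the id is chrom:pos:ref:alt, else None."""
        parts = self.variant_id.split(":")
        if len(parts) == 4 and parts[1].isdigit() and int(parts[1]) >= 1:
            return (parts[0], int(parts[1]), parts[2], parts[3])
        return None


@dataclass
class DiseaseContext:
    """Consolidated disease-relevant genes and variants with provenance."""

    genes: list[str] = field(default_factory=list)
    variants: list[VariantAssociation] = field(default_factory=list)
    gene_associations: list[GeneAssociation] = field(default_factory=list)
    provenance: dict[str, set[str]] = field(default_factory=dict)
    discrepancy_report: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["entity", "entity_type", "present_in", "absent_from",
                     "clinvar_conflict"]
        )
    )
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        rows = []
        for g in self.genes:
            rows.append(
                {"entity": g, "entity_type": "gene",
                 "sources": ",".join(sorted(self.provenance.get(g, set())))}
            )
        for v in self.variants:
            rows.append(
                {"entity": v.variant_id, "entity_type": "variant",
                 "sources": ",".join(
                     sorted(self.provenance.get(v.variant_id, set()))
                 )}
            )
        pd.DataFrame(rows, columns=["entity", "entity_type", "sources"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Table loading
# ---------------------------------------------------------------------------

def load_table(path) -> pd.DataFrame:
    """Load a TSV (header row) or JSON (list of records) association table."""
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path, sep="\t", dtype=str).astype(str)


@dataclass
class AssociationSources:
    """File-backed stand-ins for the live association services.

    Each field is a DataFrame in the documented schema; an adapter querying
    the real web APIs would produce the same frames.
    """

    phenotype_annotations: pd.DataFrame
    gene_associations: pd.DataFrame
    variant_associations: pd.DataFrame
    allele_frequencies: pd.DataFrame
    orpha_efo_map: pd.DataFrame

    @classmethod
    def from_dir(cls, directory) -> "AssociationSources":
        directory = Path(directory)

        def load(stem: str, columns: Sequence[str]) -> pd.DataFrame:
            for suffix in (".tsv", ".json"):
                p = directory / f"{stem}{suffix}"
                if p.exists():
                    return load_table(p)
            return pd.DataFrame(columns=list(columns))

        return cls(
            phenotype_annotations=load(
                "phenotype_annotations", ["orpha_id", "hpo_id"]
            ),
            gene_associations=load(
                "gene_associations", ["source", "orpha_id", "gene", "score"]
            ),
            variant_associations=load(
                "variant_associations",
                ["source", "orpha_id", "variant_id", "gene", "significance",
                 "score"],
            ),
            allele_frequencies=load(
                "allele_frequencies", ["variant_id", "population", "af"]
            ),
            orpha_efo_map=load("orpha_efo_map", ["orpha_id", "efo_id"]),
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def match_hpo_to_orphanet(
    hpo_terms: Sequence[str],
    annotations: pd.DataFrame,
    top_k: int = 5,
) -> list[tuple[str, float]]:
    """Rank Orphanet diseases by Jaccard similarity of HPO annotation sets.

    ``score(d) = |query ∩ annot(d)| / |query ∪ annot(d)|``; zero-score
    diseases are excluded; ties break by ascending Orphanet id.
    """
    if not hpo_terms:
        raise ContextError("empty HPO query")
    if annotations.empty:
        raise NoPhenotypeMatchError("phenotype annotation table is empty")
    query = {_normalize_hpo(t) for t in hpo_terms}
    scored = []
    for orpha_id, grp in annotations.groupby("orpha_id"):
        annot = set(grp["hpo_id"])
        inter = len(query & annot)
        if inter == 0:
            continue
        scored.append((str(orpha_id), inter / len(query | annot)))
    if not scored:
        raise NoPhenotypeMatchError(
            "no phenotype match: no disease shares an HPO term with the query"
        )
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_k]


def resolve_query(
    query: DiseaseQuery,
    sources: AssociationSources,
    top_k: int = 5,
) -> list[str]:
    """Orphanet ids for a query, matching HPO terms when no id was given."""
    if query.orpha_ids:
        return list(query.orpha_ids)
    matches = match_hpo_to_orphanet(
        query.hpo_terms, sources.phenotype_annotations, top_k=top_k
    )
    return [orpha for orpha, _ in matches]


def _efo_for(orpha_ids: Iterable[str], efo_map: pd.DataFrame,
             warnings: list[str]) -> set[str]:
    if efo_map.empty:
        return set()
    mapping = dict(zip(efo_map["orpha_id"], efo_map["efo_id"]))
    efo_ids = set()
    for oid in orpha_ids:
        if oid in mapping:
            efo_ids.add(mapping[oid])
        else:
            warnings.append(f"no EFO mapping for {oid}; opentargets skipped for it")
    return efo_ids


def collect_genes(
    query_orpha_ids: Sequence[str],
    sources: AssociationSources,
    score_thresholds: Mapping[str, float] | None = None,
    max_genes: int = 100,
    warnings: list[str] | None = None,
) -> list[GeneAssociation]:
    """Gather gene–disease associations per source.

    Score thresholds apply to disgenet/opentargets; orphanet (and clinvar)
    rows carry score 1.0 and are always kept.  Per-source lists are
    truncated to ``max_genes`` by descending score, ties by symbol.
    """
    warnings = warnings if warnings is not None else []
    thresholds = dict(score_thresholds or {})
    if max_genes < 1:
        raise ContextError("max_genes must be >= 1")
    for src, thr in thresholds.items():
        if not 0 <= float(thr) <= 1:
            raise ContextError(f"threshold for {src} outside [0,1]: {thr}")
    table = sources.gene_associations
    if table.empty:
        return []
    efo_ids = _efo_for(query_orpha_ids, sources.orpha_efo_map, warnings)
    wanted = set(query_orpha_ids)

    out: list[GeneAssociation] = []
    matched_any = False
    for source in GENE_SOURCES:
        rows = table[table["source"] == source]
        if rows.empty:
            continue
        ids = efo_ids if source == "opentargets" else wanted
        rows = rows[rows["orpha_id"].isin(ids)]
        if rows.empty:
            continue
        matched_any = True
        assoc = [
            GeneAssociation(
                gene=r.gene,
                orpha_id=r.orpha_id,
                score=(1.0 if source in ("orphanet", "clinvar")
                       else float(r.score)),
                source=source,
            )
            for r in rows.itertuples()
        ]
        if source in ("disgenet", "opentargets"):
            thr = float(thresholds.get(source, 0.0))
            assoc = [a for a in assoc if a.score >= thr]
            assoc.sort(key=lambda a: (-a.score, a.gene))
            assoc = assoc[:max_genes]
        else:
            assoc.sort(key=lambda a: a.gene)
        out.extend(assoc)
    if not matched_any:
        warnings.append(
            f"no source contains any of {sorted(wanted)}; empty gene list"
        )
    return out


def collect_variants(
    query_orpha_ids: Sequence[str],
    sources: AssociationSources,
    score_thresholds: Mapping[str, float] | None = None,
    max_variants: int = 1000,
    warnings: list[str] | None = None,
) -> list[VariantAssociation]:
    """Gather variant–disease associations per source.

    ClinVar contributes pathogenic/likely_pathogenic rows only; scored
    sources are thresholded and truncated like genes.
    """
    warnings = warnings if warnings is not None else []
    thresholds = dict(score_thresholds or {})
    table = sources.variant_associations
    if table.empty:
        return []
    efo_ids = _efo_for(query_orpha_ids, sources.orpha_efo_map, warnings)
    wanted = set(query_orpha_ids)

    out: list[VariantAssociation] = []
    for source in ("clinvar", "disgenet", "opentargets"):
        rows = table[table["source"] == source]
        ids = efo_ids if source == "opentargets" else wanted
        rows = rows[rows["orpha_id"].isin(ids)]
        if rows.empty:
            continue
        assoc = [
            VariantAssociation(
                variant_id=r.variant_id,
                gene=r.gene,
                clinical_significance=getattr(r, "significance", "unreported"),
                score=(None if str(getattr(r, "score", "")) in ("", "nan")
                       else float(r.score)),
                source=source,
            )
            for r in rows.itertuples()
        ]
        if source == "clinvar":
            assoc = [
                a for a in assoc if a.clinical_significance in PATHOGENIC
            ]
            for a in assoc:
                a.score = 1.0
            assoc.sort(key=lambda a: a.variant_id)
        else:
            thr = float(thresholds.get(source, 0.0))
            assoc = [a for a in assoc if (a.score or 0.0) >= thr]
            assoc.sort(key=lambda a: (-(a.score or 0.0), a.variant_id))
            assoc = assoc[:max_variants]
        out.extend(assoc)
    return out


def reconcile_clinvar(
    merged_variants: Sequence[VariantAssociation],
    clinvar_table: pd.DataFrame,
    gene_associations: Sequence[GeneAssociation] = (),
    configured_sources: Sequence[str] = GENE_SOURCES,
) -> pd.DataFrame:
    """Cross-source discrepancy report.

    Flags every DisGeNET/OpenTargets variant whose ClinVar significance is
    benign/likely_benign (``clinvar_conflict``) — the variant stays in the
    context, the report carries the conflict — and lists, per gene and per
    variant, which configured sources contain it and which do not.
    """
    clinvar_sig: dict[str, str] = {}
    if not clinvar_table.empty:
        cv = clinvar_table[clinvar_table["source"] == "clinvar"]
        clinvar_sig = dict(zip(cv["variant_id"], cv["significance"]))

    rows = []
    by_variant: dict[str, set[str]] = {}
    for v in merged_variants:
        by_variant.setdefault(v.variant_id, set()).add(v.source)
    for vid in sorted(by_variant):
        present = by_variant[vid]
        conflict = (
            bool(present & {"disgenet", "opentargets"})
            and clinvar_sig.get(vid) in BENIGN
        )
        rows.append(
            {
                "entity": vid,
                "entity_type": "variant",
                "present_in": ",".join(sorted(present)),
                "absent_from": ",".join(
                    sorted(set(configured_sources) - present)
                ),
                "clinvar_conflict": conflict,
            }
        )
    by_gene: dict[str, set[str]] = {}
    for a in gene_associations:
        by_gene.setdefault(a.gene, set()).add(a.source)
    for v in merged_variants:
        if v.gene:
            by_gene.setdefault(v.gene, set()).add(v.source)
    for gene in sorted(by_gene):
        present = by_gene[gene]
        rows.append(
            {
                "entity": gene,
                "entity_type": "gene",
                "present_in": ",".join(sorted(present)),
                "absent_from": ",".join(
                    sorted(set(configured_sources) - present)
                ),
                "clinvar_conflict": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["entity", "entity_type", "present_in", "absent_from",
                 "clinvar_conflict"],
    )


def filter_by_allele_frequency(
    variants: Sequence[VariantAssociation],
    af_table: pd.DataFrame,
    af_threshold: float = 0.01,
    populations: Sequence[str] = (),
    warnings: list[str] | None = None,
) -> list[VariantAssociation]:
    """Rarity filter: drop a variant iff its maximum allele frequency over
    the configured populations is >= ``af_threshold``.

    Variants with no frequency record in any configured population are
    kept — rare-disease variants are often absent from population panels.
    """
    warnings = warnings if warnings is not None else []
    if not 0 < af_threshold <= 1:
        raise ConfigurationError(f"af_threshold outside (0,1]: {af_threshold}")
    if af_table.empty:
        return list(variants)
    known_pops = sorted(set(af_table["population"]))
    for p in populations:
        if p not in known_pops:
            raise ConfigurationError(
                f"unknown population {p!r}; known populations: {known_pops}"
            )
    pops = set(populations) if populations else set(known_pops)
    sub = af_table[af_table["population"].isin(pops)]
    max_af = sub.assign(af=sub["af"].astype(float)).groupby("variant_id")[
        "af"
    ].max()
    kept = []
    removed = 0
    for v in variants:
        af = max_af.get(v.variant_id)
        if af is not None and af >= af_threshold:
            removed += 1
        else:
            kept.append(v)
    warnings.append(
        f"allele-frequency filter removed {removed} variant(s) at "
        f"threshold {af_threshold}"
    )
    return kept


def genes_from_variants(
    genes: Sequence[str], variants: Sequence[VariantAssociation]
) -> list[str]:
    """Union of the gene list and the genes carrying surviving variants.

    Order: original gene order first, then new variant-derived genes
    alphabetically.
    """
    seen = set()
    out = []
    for g in genes:
        if g not in seen:
            seen.add(g)
            out.append(g)
    extra = sorted({v.gene for v in variants if v.gene} - seen)
    out.extend(extra)
    return out


def build_context(
    query: DiseaseQuery,
    sources: AssociationSources,
    score_thresholds: Mapping[str, float] | None = None,
    max_genes: int = 100,
    af_threshold: float = 0.01,
    populations: Sequence[str] = (),
    hpo_top_k: int = 5,
) -> DiseaseContext:
    """Run the whole stage-1 chain: resolve → collect → reconcile → filter →
    augment; returns the consolidated :class:`DiseaseContext`."""
    warnings: list[str] = []
    orpha_ids = resolve_query(query, sources, top_k=hpo_top_k)
    gene_assoc = collect_genes(
        orpha_ids, sources, score_thresholds, max_genes, warnings
    )
    variants = collect_variants(
        orpha_ids, sources, score_thresholds, warnings=warnings
    )
    report = reconcile_clinvar(
        variants, sources.variant_associations, gene_assoc
    )
    variants = filter_by_allele_frequency(
        variants, sources.allele_frequencies, af_threshold, populations,
        warnings,
    )
    gene_order = []
    seen = set()
    for a in gene_assoc:
        if a.gene not in seen:
            seen.add(a.gene)
            gene_order.append(a.gene)
    genes = genes_from_variants(gene_order, variants)

    provenance: dict[str, set[str]] = {}
    for a in gene_assoc:
        provenance.setdefault(a.gene, set()).add(a.source)
    for v in variants:
        provenance.setdefault(v.variant_id, set()).add(v.source)
        if v.gene:
            provenance.setdefault(v.gene, set()).add(v.source)
    return DiseaseContext(
        genes=genes,
        variants=variants,
        gene_associations=gene_assoc,
        provenance=provenance,
        discrepancy_report=report,
        warnings=warnings,
    )
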