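"""Stage 2a/2b — over-representation analysis over diagram collections.

The disease-relevant gene list is tested against named gene sets (disease-map
areas, WikiPathways, Reactome), each set optionally pointing at a diagram
file with layout.  Enrichment is one-sided hypergeometric over-representation
(equivalently one-sided Fisher exact): the gene list is unranked, so the
classic ORA statistic applies.  Benjamini–Hochberg adjusted p-values are
reported alongside; ranking uses the raw p with a deterministic set-id
tie-break.

Reactome results are additionally narrowed to sets that have a layout and to
the topmost sets when nested sets are both enriched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy import stats


class EnrichmentError(ValueError):
    pass


@dataclass
class GeneSet:
    set_id: str
    name: str
    genes: frozenset[str]
    diagram_path: Optional[str] = None
    has_layout: bool = True
    parent_id: Optional[str] = None
    collection: str = "wikipathways"

    def __post_init__(self) -> None:
        if not self.genes:
            raise EnrichmentError(f"gene set {self.set_id!r} is empty")


@dataclass
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    adjusted_p: float = 1.0
    rank: int = 0


def ora_p_value(overlap: int, set_size: int, query_size: int,
                universe_size: int) -> float:
    """Hypergeometric upper-tail probability of seeing >= ``overlap`` query
    genes in a set: P(X >= k) for X ~ Hypergeom(N, K, n).

    Computed with exact integer arithmetic
    (``sum_i C(K,i) C(N-K,n-i) / C(N,n)`` over ``i = k..min(K,n)``), so the
    result is the correctly rounded float of the exact rational tail.
    """
    k, K, n, N = overlap, set_size, query_size, universe_size
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise EnrichmentError(
            f"hypergeometric bounds violated: k={k}, K={K}, n={n}, N={N}"
        )
    numerator = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return float(Fraction(numerator, math.comb(N, n)))


def adjust_bh(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, in input order, capped at 1."""
    ps = list(p_values)
    if not ps:
        return []
    for p in ps:
        if not 0 < p <= 1:
            raise EnrichmentError(f"p-value outside (0,1]: {p}")
    adjusted = stats.false_discovery_control(ps, method="bh")
    return [float(min(1.0, a)) for a in adjusted]


def enrich_collection(
    query_genes: Iterable[str],
    collection: Sequence[GeneSet],
    universe: Optional[Iterable[str]] = None,
    max_results: int = 5,
    warnings: list[str] | None = None,
) -> list[EnrichmentResult]:
    """ORA of the query against every set of a collection.

    Universe defaults to the union of the collection's gene sets; query
    genes outside the universe are dropped with a warning.  Results with
    overlap >= 1 are sorted by raw p ascending (ties by set id), truncated
    to ``max_results``, and ranked 1..m.
    """
    warnings = warnings if warnings is not None else []
    query = set(query_genes)
    if not query:
        raise EnrichmentError("empty query gene list")
    if universe is None:
        uni: set[str] = set()
        for s in collection:
            uni |= s.genes
    else:
        uni = set(universe)
        for s in collection:
            outside = s.genes - uni
            if outside:
                warnings.append(
                    f"set {s.set_id}: {len(outside)} gene(s) outside universe "
                    "dropped"
                )
    dropped = query - uni
    if dropped:
        warnings.append(
            f"{len(dropped)} query gene(s) outside the universe dropped"
        )
        query &= uni
    if not query:
        return []

    N = len(uni)
    n = len(query)
    tested: list[tuple[GeneSet, int, float]] = []
    for s in collection:
        genes = s.genes & uni
        if not genes:
            continue
        k = len(genes & query)
        p = ora_p_value(k, len(genes), n, N)
        tested.append((s, k, p))
    adjusted = adjust_bh([p for _, _, p in tested])
    results = [
        EnrichmentResult(
            set_id=s.set_id,
            overlap=k,
            set_size=len(s.genes & uni),
            query_size=n,
            universe_size=N,
            p_value=p,
            adjusted_p=adj,
        )
        for (s, k, p), adj in zip(tested, adjusted)
        if k >= 1
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    results = results[:max_results]
    for i, r in enumerate(results, start=1):
        r.rank = i
    return results


def filter_reactome(
    results: Sequence[EnrichmentResult], sets: Mapping[str, GeneSet]
) -> list[EnrichmentResult]:
    """Apply the Reactome constraints: keep only sets with layout, and when
    nested sets are both enriched keep only the topmost ancestor present."""
    kept = [r for r in results if sets[r.set_id].has_layout]
    present = {r.set_id for r in kept}

    def has_enriched_ancestor(set_id: str) -> bool:
        seen = set()
        parent = sets[set_id].parent_id
        while parent is not None and parent not in seen:
            seen.add(parent)
            if parent in present:
                return True
            parent = sets[parent].parent_id if parent in sets else None
        return False

    return [r for r in kept if not has_enriched_ancestor(r.set_id)]


# ---------------------------------------------------------------------------
# GMT + sidecar loading
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[tuple[str, str, list[str]]]:
    """GMT: one set per line, ``set_id<TAB>name<TAB>gene1<TAB>gene2...``."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise EnrichmentError(f"GMT line with fewer than 3 fields: {line!r}")
        out.append((parts[0], parts[1], [g for g in parts[2:] if g]))
    return out


def load_gene_set_collection(
    gmt_path, sidecar_path=None, collection: str = "wikipathways",
    base_dir=None,
) -> list[GeneSet]:
    """Load gene sets from a GMT file plus an optional sidecar TSV carrying
    ``set_id, has_layout, parent_id, diagram_path`` columns."""
    meta: dict[str, dict] = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        df = pd.read_csv(sidecar_path, sep="\t", dtype=str).fillna("")
        for r in df.itertuples():
            meta[r.set_id] = {
                "has_layout": str(getattr(r, "has_layout", "true")).lower()
                in ("true", "1", "yes"),
                "parent_id": getattr(r, "parent_id", "") or None,
                "diagram_path": getattr(r, "diagram_path", "") or None,
            }
    base = Path(base_dir) if base_dir is not None else Path(gmt_path).parent
    sets = []
    for set_id, name, genes in read_gmt(gmt_path):
        m = meta.get(set_id, {})
        dp = m.get("diagram_path")
        sets.append(
            GeneSet(
                set_id=set_id,
                name=name,
                genes=frozenset(genes),
                diagram_path=str(base / dp) if dp else None,
                has_layout=m.get("has_layout", True),
                parent_id=m.get("parent_id"),
                collection=collection,
            )
        )
    return sets


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "set_id": r.set_id,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "query_size": r.query_size,
                "universe_size": r.universe_size,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ],
        columns=["rank", "set_id", "overlap", "set_size", "query_size",
                 "universe_size", "p_value", "adjusted_p"],
    )
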