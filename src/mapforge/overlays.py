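"""Stage 3b–3d — data overlays and the final ZIP bundle.

Three overlay tables are produced for visual exploration on top of the
merged map: disease-related genes (highlight color), genetic variants
(genomic position plus optional protein-level mapping), and differential
expression (log2 fold changes normalized to [-1, 1]).  The differential-
expression input is an edgeR-style per-gene statistics table (``gene,
logFC, FDR``); significance filtering keeps FDR < 0.05 and linear fold
change > 2 by default.  Everything is bundled into one ZIP archive —
``map.xml`` plus ``overlays/*.txt`` and a ``manifest.json`` — ready for a
map-hosting platform import.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .context import DiseaseContext, VariantAssociation

DEFAULT_HIGHLIGHT = "#0000FF"

# zipfile embeds mtimes; a fixed date keeps identical runs byte-identical.
_ZIP_EPOCH = (1980, 1, 1, 0, 0, 0)


class OverlayError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class GeneOverlayRow:
    name: str
    value: Optional[float] = None
    color: Optional[str] = None


@dataclass
class VariantOverlayRow:
    contig: str
    position: int
    original_dna: str
    alternative_dna: str
    gene: str
    protein_position: Optional[int] = None
    amino_acid_change: Optional[str] = None


def _deg_frame(rows) -> pd.DataFrame:
    """Accept a DataFrame or records; normalize edgeR-style column names."""
    df = pd.DataFrame(rows).copy()
    rename = {}
    for col in df.columns:
        low = str(col).lower()
        if low in ("logfc", "log_fc", "log2fc"):
            rename[col] = "log_fc"
        elif low in ("fdr", "adj_p", "padj"):
            rename[col] = "fdr"
        elif low == "gene":
            rename[col] = "gene"
    df = df.rename(columns=rename)
    missing = {"gene", "log_fc", "fdr"} - set(df.columns)
    if missing:
        raise DataError(f"DEG table missing columns: {sorted(missing)}")
    df["log_fc"] = df["log_fc"].astype(float)
    df["fdr"] = df["fdr"].astype(float)
    return df


def filter_deg(rows, fdr_max: float = 0.05, fc_min: float = 2.0,
               scale: str = "linear") -> pd.DataFrame:
    """Keep differentially expressed genes with FDR < ``fdr_max`` and
    absolute fold change > ``fc_min``.

    ``fc_min`` is on the linear scale by default (|log2FC| > log2(fc_min));
    ``scale="log"`` compares |log2FC| > fc_min directly.
    """
    if fc_min <= 1 and scale == "linear":
        raise OverlayError(f"fc_min must be > 1: {fc_min}")
    df = _deg_frame(rows)
    bad = df[(df["fdr"] < 0) | (df["fdr"] > 1)]
    if not bad.empty:
        row = bad.iloc[0]
        raise DataError(
            f"FDR outside [0,1] for gene {row['gene']!r}: {row['fdr']}"
        )
    if scale == "linear":
        fc_ok = np.power(2.0, df["log_fc"].abs()) > fc_min
    else:
        fc_ok = df["log_fc"].abs() > fc_min
    return df[(df["fdr"] < fdr_max) & fc_ok].reset_index(drop=True)


def normalize_logfc(rows) -> pd.DataFrame:
    """Scale log2 fold changes to [-1, 1] by the maximum absolute value.

    Sign and the ordering of magnitudes are preserved; an all-zero column
    stays all-zero.
    """
    df = _deg_frame(rows)
    if df.empty:
        raise OverlayError("empty DEG table")
    max_abs = df["log_fc"].abs().max()
    df = df.copy()
    df["value"] = 0.0 if max_abs == 0 else df["log_fc"] / max_abs
    return df


def build_gene_overlay(
    context: DiseaseContext, color: str = DEFAULT_HIGHLIGHT
) -> list[GeneOverlayRow]:
    """One highlight row per context gene, in context order, deduplicated."""
    if not context.genes:
        raise OverlayError("context has no genes")
    seen = set()
    rows = []
    for g in context.genes:
        if g in seen:
            continue
        seen.add(g)
        rows.append(GeneOverlayRow(name=g, color=color))
    return rows


def build_variant_overlay(
    variants: Sequence[VariantAssociation],
    protein_mapping: Mapping[str, tuple[int, str]] | None = None,
    warnings: list[str] | None = None,
) -> list[VariantOverlayRow]:
    """Variant rows sorted by (contig, position).

    Variants whose identifier does not encode genomic coordinates
    (e.g. bare dbSNP ids without a coordinate record) are skipped with a
    warning.  Protein-level mapping (position, amino-acid change) is filled
    from the provided table and never imputed.
    """
    warnings = warnings if warnings is not None else []
    protein_mapping = protein_mapping or {}
    rows = []
    for v in variants:
        coords = v.coordinates()
        if coords is None:
            warnings.append(
                f"variant {v.variant_id!r} lacks genomic coordinates; "
                "skipped in variant overlay"
            )
            continue
        contig, pos, ref, alt = coords
        pp, aac = protein_mapping.get(v.variant_id, (None, None))
        rows.append(
            VariantOverlayRow(
                contig=contig,
                position=pos,
                original_dna=ref,
                alternative_dna=alt,
                gene=v.gene,
                protein_position=pp,
                amino_acid_change=aac,
            )
        )
    rows.sort(key=lambda r: (r.contig, r.position))
    return rows


# ---------------------------------------------------------------------------
# Overlay TSV dialect and the ZIP bundle
# ---------------------------------------------------------------------------

def render_gene_overlay(rows: Sequence[GeneOverlayRow],
                        name: str = "disease genes") -> str:
    lines = [f"#NAME={name}", "#TYPE=GENERIC", "name\tvalue\tcolor"]
    for r in rows:
        value = "" if r.value is None else f"{r.value:.6g}"
        lines.append(f"{r.name}\t{value}\t{r.color or ''}")
    return "\n".join(lines) + "\n"


def render_expression_overlay(df: pd.DataFrame,
                              name: str = "differential expression") -> str:
    lines = [f"#NAME={name}", "#TYPE=GENERIC", "name\tvalue"]
    for r in df.itertuples():
        lines.append(f"{r.gene}\t{r.value:.6g}")
    return "\n".join(lines) + "\n"


def render_variant_overlay(rows: Sequence[VariantOverlayRow],
                           name: str = "disease variants") -> str:
    lines = [
        f"#NAME={name}",
        "#TYPE=GENETIC_VARIANT",
        "position\toriginal_dna\talternative_dna\tname\tcontig"
        "\tprotein_position\tamino_acid_change",
    ]
    for r in rows:
        lines.append(
            f"{r.position}\t{r.original_dna}\t{r.alternative_dna}\t{r.gene}"
            f"\t{r.contig}\t{'' if r.protein_position is None else r.protein_position}"
            f"\t{r.amino_acid_change or ''}"
        )
    return "\n".join(lines) + "\n"


def _overlay_row_count(text: str) -> int:
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    return max(0, len(lines) - 1)  # minus the column header


def write_bundle(
    map_document: str,
    overlays: Mapping[str, str],
    path,
) -> Path:
    """Write the final ZIP bundle.

    ``overlays`` maps member stem ("genes", "variants", "expression") to
    rendered overlay text; members absent from the mapping are omitted.
    The manifest records each member's row count, and re-reading the archive
    reproduces those counts exactly.
    """
    if not map_document:
        raise OverlayError("empty map document")
    path = Path(path)
    manifest = {
        "map": "map.xml",
        "overlays": [
            {
                "file": f"overlays/{stem}.txt",
                "type": ("GENETIC_VARIANT" if stem == "variants" else "GENERIC"),
                "rows": _overlay_row_count(text),
            }
            for stem, text in overlays.items()
        ],
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        def add(name: str, data: str) -> None:
            info = zipfile.ZipInfo(name, date_time=_ZIP_EPOCH)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, data)

        add("map.xml", map_document)
        for stem, text in overlays.items():
            add(f"overlays/{stem}.txt", text)
        add("manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_bundle(path) -> dict:
    """Re-open a bundle: returns {"map": text, "overlays": {stem: text},
    "manifest": dict}."""
    out: dict = {"overlays": {}}
    with zipfile.ZipFile(path) as zf:
        for name in zf.namelist():
            data = zf.read(name).decode("utf-8")
            if name == "map.xml":
                out["map"] = data
            elif name == "manifest.json":
                out["manifest"] = json.loads(data)
            elif name.startswith("overlays/"):
                stem = Path(name).stem
                out["overlays"][stem] = data
    return out
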