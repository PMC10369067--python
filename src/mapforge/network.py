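"""Stage 2c — the refined text-mining interaction diagram.

From the disease-relevant genes, the undirected scored interaction table
(STRING detail-file dialect: ``protein1, protein2, combined_score`` with
scores 0–1000) is expanded by the best-scoring new neighbors; the directed,
signed table (OmniPath-style: ``source, target, sign``) is then intersected
with the text-mining node set, so only directed edges with both partners in
the text-mining results survive.  The resulting network is laid out with the
classic Fruchterman–Reingold force-directed algorithm and exported as GPML.

The layout follows the original formulation: ideal edge length
``k = sqrt(area / |V|)`` (C = 1), repulsive force ``k^2/d`` between every
pair, attractive force ``d^2/k`` along edges, displacement capped by a
temperature cooling linearly to zero, positions clamped to the frame.
Initial positions come from a seeded pseudo-random stream, so a fixed seed
gives bitwise-identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from .diagram_io import GPML_NS


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class ScoredEdge:
    """Undirected interaction with a STRING-convention score in 0–1000."""

    a: str
    b: str
    score: int

    def __post_init__(self):
        if self.a == self.b:
            raise NetworkError(f"self-interaction {self.a!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass(frozen=True)
class DirectedEdge:
    source: str
    target: str
    sign: str = "unknown"  # activation | inhibition | unknown


@dataclass
class LayoutParams:
    width: float = 1000.0
    height: float = 1000.0
    iterations: int = 100
    initial_temperature: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise NetworkError("iterations must be >= 1")


def read_scored_edges(path) -> list[ScoredEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        ScoredEdge(r.protein1, r.protein2, int(r.combined_score))
        for r in df.itertuples()
    ]


def read_directed_edges(path) -> list[DirectedEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [DirectedEdge(r.source, r.target, r.sign) for r in df.itertuples()]


def expand_neighbors(
    seeds: Iterable[str],
    edges: Sequence[ScoredEdge],
    min_score: int = 700,
    max_new: int = 100,
    warnings: list[str] | None = None,
) -> tuple[list[str], list[ScoredEdge]]:
    """Scored-neighbor expansion of the seed genes.

    Candidate neighbors are non-seed nodes linked to at least one seed with
    score >= ``min_score``, ranked by their best such score (descending,
    ties by symbol), truncated to ``max_new``.  Returns the node list
    (sorted) and the induced subgraph of passing edges.
    """
    warnings = warnings if warnings is not None else []
    if min_score < 0:
        raise NetworkError(f"min_score must be >= 0: {min_score}")
    if max_new < 0:
        raise NetworkError(f"max_new must be >= 0: {max_new}")
    seed_set = set(seeds)
    if not seed_set:
        warnings.append("empty seed set; text-mining network is empty")
        return [], []

    best: dict[str, int] = {}
    passing = [e for e in edges if e.score >= min_score]
    for e in passing:
        if e.a in seed_set and e.b not in seed_set:
            best[e.b] = max(best.get(e.b, -1), e.score)
        elif e.b in seed_set and e.a not in seed_set:
            best[e.a] = max(best.get(e.a, -1), e.score)
    ranked = sorted(best, key=lambda n: (-best[n], n))
    chosen = ranked[:max_new]
    nodes = seed_set | set(chosen)
    induced = [e for e in passing if e.a in nodes and e.b in nodes]
    # one record per unordered pair, best score wins
    per_pair: dict[tuple[str, str], ScoredEdge] = {}
    for e in induced:
        cur = per_pair.get(e.pair)
        if cur is None or e.score > cur.score:
            per_pair[e.pair] = e
    return sorted(nodes), [per_pair[p] for p in sorted(per_pair)]


def refine_directed(
    tm_nodes: Iterable[str], directed: Sequence[DirectedEdge]
) -> list[DirectedEdge]:
    """Keep exactly the directed edges with both partners in the text-mining
    node set; output in (source, target) lexicographic order."""
    nodes = set(tm_nodes)
    kept = {
        (e.source, e.target, e.sign)
        for e in directed
        if e.source in nodes and e.target in nodes
    }
    return [DirectedEdge(*t) for t in sorted(kept)]


def fr_layout(
    nodes: Sequence[str],
    edges: Sequence[tuple[str, str]],
    params: LayoutParams,
) -> dict[str, tuple[float, float]]:
    """Classic Fruchterman–Reingold layout; node -> (x, y) center positions.

    Deterministic under a fixed ``params.seed``.
    """
    nodes = list(nodes)
    n = len(nodes)
    if n == 0:
        return {}
    rng = np.random.default_rng(params.seed)
    pos = np.column_stack(
        [
            rng.uniform(0, params.width, size=n),
            rng.uniform(0, params.height, size=n),
        ]
    )
    index = {v: i for i, v in enumerate(nodes)}
    edge_idx = np.array(
        [[index[a], index[b]] for a, b in edges if a in index and b in index],
        dtype=int,
    ).reshape(-1, 2)
    area = params.width * params.height
    k = np.sqrt(area / n)
    eps = 1e-9
    t0 = params.initial_temperature
    iters = params.iterations
    for it in range(iters):
        t = t0 * (1 - it / iters)
        disp = np.zeros_like(pos)
        # repulsion between all pairs: f_r(d) = k^2 / d
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((delta**2).sum(axis=2))
        np.fill_diagonal(dist, np.inf)
        dist = np.maximum(dist, eps)
        rep = (k * k) / dist
        disp += (delta / dist[:, :, None] * rep[:, :, None]).sum(axis=1)
        # attraction along edges: f_a(d) = d^2 / k
        if len(edge_idx):
            dvec = pos[edge_idx[:, 0]] - pos[edge_idx[:, 1]]
            d = np.maximum(np.sqrt((dvec**2).sum(axis=1)), eps)
            att = (d * d) / k
            pull = dvec / d[:, None] * att[:, None]
            np.add.at(disp, edge_idx[:, 0], -pull)
            np.add.at(disp, edge_idx[:, 1], pull)
        # cap by temperature, clamp to frame
        length = np.maximum(np.sqrt((disp**2).sum(axis=1)), eps)
        step = disp / length[:, None] * np.minimum(length, t)[:, None]
        pos = pos + step
        pos[:, 0] = np.clip(pos[:, 0], 0, params.width)
        pos[:, 1] = np.clip(pos[:, 1], 0, params.height)
    return {v: (float(pos[i, 0]), float(pos[i, 1])) for v, i in index.items()}


_SIGN_ARROW = {
    "activation": "Arrow",
    "inhibition": "TBar",
    "unknown": None,
}

NODE_WIDTH = 80.0
NODE_HEIGHT = 25.0


def network_to_gpml(
    nodes: Sequence[str],
    directed_edges: Sequence[DirectedEdge],
    positions: Mapping[str, tuple[float, float]],
    title: str = "Text mining network",
) -> str:
    """Emit the refined network as a GPML pathway.

    One DataNode per node at its layout position (80x25), one Interaction
    per directed edge with the arrowhead carrying the sign (activation ->
    Arrow, inhibition -> TBar, unknown -> plain line).  Nodes without a
    surviving directed edge are included as unconnected DataNodes.
    """
    for v in nodes:
        if v not in positions:
            raise NetworkError(f"node {v!r} has no layout position")
    root = etree.Element(f"{{{GPML_NS}}}Pathway", nsmap={None: GPML_NS})
    root.set("Name", title)
    root.set("Version", "20130621")
    node_ids = {}
    for i, v in enumerate(nodes, start=1):
        gid = f"n{i}"
        node_ids[v] = gid
        dn = etree.SubElement(root, f"{{{GPML_NS}}}DataNode")
        dn.set("TextLabel", v)
        dn.set("GraphId", gid)
        dn.set("Type", "GeneProduct")
        gfx = etree.SubElement(dn, f"{{{GPML_NS}}}Graphics")
        x, y = positions[v]
        gfx.set("CenterX", repr(float(x)))
        gfx.set("CenterY", repr(float(y)))
        gfx.set("Width", repr(NODE_WIDTH))
        gfx.set("Height", repr(NODE_HEIGHT))
        xref = etree.SubElement(dn, f"{{{GPML_NS}}}Xref")
        xref.set("Database", "HGNC")
        xref.set("ID", v)
    for j, e in enumerate(directed_edges, start=1):
        inter = etree.SubElement(root, f"{{{GPML_NS}}}Interaction")
        inter.set("GraphId", f"e{j}")
        gfx = etree.SubElement(inter, f"{{{GPML_NS}}}Graphics")
        for endpoint, arrow in (
            (e.source, None),
            (e.target, _SIGN_ARROW.get(e.sign)),
        ):
            pt = etree.SubElement(gfx, f"{{{GPML_NS}}}Point")
            x, y = positions[endpoint]
            pt.set("X", repr(float(x)))
            pt.set("Y", repr(float(y)))
            pt.set("GraphRef", node_ids[endpoint])
            if arrow:
                pt.set("ArrowHead", arrow)
    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def build_textmining_network(
    seeds: Iterable[str],
    scored_edges: Sequence[ScoredEdge],
    directed_edges: Sequence[DirectedEdge],
    min_score: int = 700,
    max_new: int = 100,
    layout: LayoutParams | None = None,
    warnings: list[str] | None = None,
) -> tuple[str, list[str], list[DirectedEdge], list[ScoredEdge]]:
    """Full stage-2c chain; returns (gpml text, nodes, refined directed
    edges, undirected edges without directed support)."""
    layout = layout or LayoutParams()
    nodes, induced = expand_neighbors(
        seeds, scored_edges, min_score, max_new, warnings
    )
    refined = refine_directed(nodes, directed_edges)
    directed_pairs = {
        tuple(sorted((e.source, e.target))) for e in refined
    }
    unsupported = [e for e in induced if e.pair not in directed_pairs]
    positions = fr_layout(
        nodes, [(e.source, e.target) for e in refined], layout
    )
    gpml = network_to_gpml(nodes, refined, positions)
    return gpml, nodes, refined, unsupported
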