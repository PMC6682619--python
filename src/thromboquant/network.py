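"""Protein-interaction network clustering and effect annotation.

Loads a confidence-weighted edge list (STRING-style export), filters by
combined-score confidence, identifies densely interconnected complexes with
a self-contained MCODE implementation, and annotates nodes with the
per-strain thrombus-signature or adhesion effect sizes measured by the
flow-chamber pipeline.

MCODE (molecular complex detection) weights every vertex by the density of
the highest k-core of its closed neighborhood multiplied by that core
number, then grows clusters outward from the highest-weighted unvisited
seed, including neighbors whose weight is at least ``(1 - node_score_cutoff)``
times the seed weight. Clusters are post-processed with a 2-core "haircut"
and must themselves contain a k-core at the configured k. The cluster score
is subgraph density times node count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import networkx as nx
import pandas as pd

logger = logging.getLogger("thromboquant")


class InvalidInputError(ValueError):
    pass


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# loading STRING-style edge lists
# ---------------------------------------------------------------------------

def load_edges(
    path: Union[str, Path],
    min_confidence: float = 0.40,
    core_nodes: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Load a TSV edge list (node1, node2, combined_score) into a graph.

    Both STRING score dialects are accepted: integer 0-1000 scores (any
    value > 1 in the file) are divided by 1000, floats in [0, 1] are used
    directly. Edges below ``min_confidence`` are dropped; duplicates are
    collapsed keeping the highest confidence; self-loops are discarded.
    Nodes listed in ``core_nodes`` get ``class="core"``, all others
    ``class="novel"``.
    """
    path = Path(path)
    rows: List[Tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if lineno == 1 and len(parts) >= 3 and parts[0].lower() in (
                "node1", "protein1", "source"
            ):
                continue  # header
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts[0], parts[1], parts[2]
            try:
                score = float(raw)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {raw!r}") from exc
            if score < 0:
                raise ParseError(f"{path}:{lineno}: negative score {score}")
            rows.append((a, b, score))
    if not rows:
        logger.warning("edge file %s is empty", path)
        return nx.Graph()
    max_score = max(r[2] for r in rows)
    divisor = 1000.0 if max_score > 1.0 else 1.0
    g = nx.Graph()
    for a, b, score in rows:
        conf = score / divisor
        if conf < min_confidence:
            continue
        if a == b:
            logger.warning("dropping self-loop on %s", a)
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    core = set(core_nodes or ())
    for n in g.nodes:
        g.nodes[n]["class"] = "core" if n in core else "novel"
    return g


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    """A densely connected complex found by MCODE."""

    members: Tuple[str, ...]
    seed: str
    score: float
    n_edges: int

    @property
    def n_nodes(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(g: nx.Graph, degree_cutoff: int) -> Dict[str, float]:
    """Core-clustering weight: k-core number of the closed neighborhood's
    densest core times that core's density. Vertices with degree below the
    cutoff are scored zero."""
    weights: Dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = set(g[v]) | {v}
        sub = g.subgraph(nbhd)
        core_num = nx.core_number(sub)
        k = max(core_num.values())
        if k == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in core_num.items() if c >= k]
        core = sub.subgraph(core_nodes)
        weights[v] = k * _density(core)
    return weights


def mcode(
    graph: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = True,
    fluff_density_cutoff: float = 0.1,
) -> List[Cluster]:
    """Run MCODE complex detection on a simple undirected graph.

    Stage 1 scores every vertex (see module docstring). Stage 2 repeatedly
    seeds from the highest-weighted unvisited vertex and grows the cluster
    breadth-first up to ``max_depth``, admitting neighbors whose weight is
    >= ``seed_weight * (1 - node_score_cutoff)``; admitted vertices are not
    reused by later clusters. Post-processing applies the 2-core haircut
    (on by default) and "fluff" (on by default): boundary neighbors whose
    closed-neighborhood density exceeds ``fluff_density_cutoff`` are
    admitted, which restores complex members whose vertex weight falls just
    outside the seed-score window; fluffed vertices may belong to several
    clusters. Clusters that do not contain a k-core at ``k_core`` are
    discarded.

    Clusters are returned sorted by score (density x node count)
    descending, ties broken by size then lexicographic seed symbol; all
    remaining ties in vertex weights break lexicographically for
    determinism.
    """
    if graph.is_directed() or graph.is_multigraph():
        raise InvalidInputError("mcode requires a simple undirected graph")
    if any(graph.has_edge(v, v) for v in graph.nodes):
        raise InvalidInputError("graph contains self-loops")
    if graph.number_of_edges() == 0:
        return []
    weights = _vertex_weights(graph, degree_cutoff)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    clusters: List[Cluster] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt: List[str] = []
            for v in frontier:
                for u in sorted(graph[v], key=str):
                    if u in visited or u in members:
                        continue
                    if weights[u] >= threshold - 1e-9:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        sub = graph.subgraph(members).copy()
        visited.add(seed)
        if haircut:
            # iteratively strip vertices with fewer than 2 connections in
            # the cluster (equivalently, keep the cluster's 2-core)
            core_num = nx.core_number(sub)
            keep = [v for v, c in core_num.items() if c >= 2]
            sub = sub.subgraph(keep).copy()
        # only vertices surviving the haircut are consumed: a vertex pulled
        # in over a spurious edge and stripped again stays available to the
        # cluster it actually belongs to
        visited |= set(sub.nodes)
        if fluff:
            # fluffed nodes are not consumed and may overlap between clusters
            boundary = set()
            for v in list(sub.nodes):
                for u in graph[v]:
                    if u in sub:
                        continue
                    nb = set(graph[u]) | {u}
                    if _density(graph.subgraph(nb)) > fluff_density_cutoff:
                        boundary.add(u)
            sub = graph.subgraph(set(sub.nodes) | boundary).copy()
        if sub.number_of_nodes() < 2:
            continue
        if max(nx.core_number(sub).values()) < k_core:
            continue
        score = _density(sub) * sub.number_of_nodes()
        clusters.append(
            Cluster(
                members=tuple(sorted(sub.nodes, key=str)),
                seed=seed,
                score=score,
                n_edges=sub.number_of_edges(),
            )
        )
    clusters.sort(key=lambda c: (-c.score, -c.n_nodes, str(c.seed)))
    return clusters


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Cluster table: cluster_id, score, n_nodes, n_edges, seed, members."""
    return pd.DataFrame(
        [
            {
                "cluster_id": i + 1,
                "score": c.score,
                "n_nodes": c.n_nodes,
                "n_edges": c.n_edges,
                "seed": c.seed,
                "members": ";".join(c.members),
            }
            for i, c in enumerate(clusters)
        ]
    )


# ---------------------------------------------------------------------------
# effect annotation and export
# ---------------------------------------------------------------------------

def annotate_effects(
    graph: nx.Graph,
    deltas,
    mode: str = "signature",
    surface: str = "M1",
) -> Tuple[pd.DataFrame, List[str]]:
    """Attach measured effect sizes to core nodes of the network.

    ``mode="signature"`` uses the summed relevant-filtered P2-P5 delta at
    the given surface (thrombus signature change); ``mode="adhesion"`` uses
    the P1 delta. A strain id containing ``/`` (a dual deficiency) maps the
    same effect onto each of its gene nodes. Novel nodes receive a neutral
    (0) effect. Core nodes without a matching strain are returned in the
    unmatched list, not raised.

    Effects are also written into the graph's node attributes (``effect``,
    ``direction``, ``cluster_id`` untouched) so the graph can be exported.
    """
    if mode not in ("signature", "adhesion"):
        raise InvalidInputError(f"mode must be 'signature' or 'adhesion', got {mode!r}")
    params = ("P2", "P3", "P4", "P5") if mode == "signature" else ("P1",)
    cols = deltas.columns_for(surface, params)
    filt = deltas.filtered()
    gene_effect: Dict[str, float] = {}
    for strain in deltas.delta.index:
        val = float(filt.loc[strain, cols].sum()) if cols else 0.0
        for gene in str(strain).split("/"):
            gene = gene.strip()
            # a gene probed by several strains keeps the largest-magnitude effect
            if gene not in gene_effect or abs(val) > abs(gene_effect[gene]):
                gene_effect[gene] = val
    rows = []
    unmatched: List[str] = []
    for n in sorted(graph.nodes, key=str):
        cls = graph.nodes[n].get("class", "novel")
        if cls == "core":
            if n in gene_effect:
                eff = gene_effect[n]
            else:
                unmatched.append(n)
                eff = 0.0
        else:
            eff = 0.0
        direction = "reducing" if eff < 0 else ("stimulating" if eff > 0 else "neutral")
        graph.nodes[n]["effect"] = eff
        graph.nodes[n]["direction"] = direction
        rows.append({"node": n, "class": cls, "effect": eff, "direction": direction})
    return pd.DataFrame(rows), unmatched


def write_graphml(graph: nx.Graph, path: Union[str, Path]) -> None:
    nx.write_graphml(graph, Path(path))


def write_sif(graph: nx.Graph, path: Union[str, Path],
              relation: str = "pp") -> None:
    """Write the simple-interaction format used by network viewers."""
    with open(Path(path), "w") as fh:
        for a, b in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in sorted(nx.isolates(graph), key=str):
            fh.write(f"{n}\n")
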