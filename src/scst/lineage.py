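"""Digital lineage tracing across developmental time points.

Cell populations at adjacent stages are summarized by the mean
log2-expression of their member cells over a stated gene set (typically
the differential genes of the stage pair), connected when they are
mutual nearest neighbours in Euclidean distance, and exported as a
genealogy (Sankey-style) with log2-distance edge weights.  The
nearest-neighbour candidate set of a population includes not only its
minimum-distance partner but any partner whose distance lies within a
relative tolerance (default 10%, (d_max - d_min)/d_min < 0.10) of that
minimum — this is what lets a parent keep both children of a
bifurcation.  Single cells can be chained by plain minimum distance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PopulationProfile",
    "population_profiles",
    "stage_distances",
    "connect_stages",
    "build_lineage_graph",
    "trace_single_cells",
    "export_sankey",
    "import_sankey",
    "edge_table",
]


@dataclass(frozen=True)
class PopulationProfile:
    """Mean log2 expression of a labelled cell population at one stage."""

    label: str
    stage: str
    profile: pd.Series  # indexed by gene
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"population {self.label!r} has no cells")
        if len(self.profile) < 1:
            raise ValueError("gene set must be non-empty")
        if not np.all(np.isfinite(self.profile.to_numpy())):
            raise ValueError(f"non-finite profile for population {self.label!r}")


def population_profiles(
    cells: pd.DataFrame,
    labels: Mapping[str, Sequence[str]],
    stage: str,
    gene_set: Sequence[str],
) -> list[PopulationProfile]:
    """Per-population arithmetic mean in log2 space over ``gene_set``
    (``cells`` is genes x cells; ``labels`` maps population -> cell ids)."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    missing = [g for g in gene_set if g not in cells.index]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:10]}")
    out = []
    for label in labels:
        ids = list(labels[label])
        if not ids:
            raise ValueError(f"population {label!r} has no member cells")
        profile = cells.loc[gene_set, ids].mean(axis=1)
        out.append(PopulationProfile(label=str(label), stage=stage, profile=profile, n_cells=len(ids)))
    return out


def stage_distances(
    profiles_a: Sequence[PopulationProfile],
    profiles_b: Sequence[PopulationProfile],
) -> pd.DataFrame:
    """All-pairs Euclidean distances between the populations of two
    adjacent stages (rows: first stage, columns: second)."""
    genes = list(profiles_a[0].profile.index)
    for p in list(profiles_a) + list(profiles_b):
        if list(p.profile.index) != genes:
            raise ValueError(f"gene-set mismatch for population {p.label!r}")
    A = np.array([p.profile.to_numpy() for p in profiles_a])
    B = np.array([p.profile.to_numpy() for p in profiles_b])
    d = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=[p.label for p in profiles_a], columns=[p.label for p in profiles_b])


def _candidates(distances: np.ndarray, variation_threshold: float) -> list[np.ndarray]:
    """Per row: indices of the minimum-distance column plus any column
    within the relative variation threshold of that minimum.  A zero
    minimum admits only exact ties (the limit of the ratio rule)."""
    out = []
    for row in distances:
        d_min = row.min()
        if d_min == 0.0:
            out.append(np.flatnonzero(row == 0.0))
        else:
            within = (row - d_min) / d_min < variation_threshold
            out.append(np.flatnonzero(within | (row == d_min)))
    return out


def connect_stages(
    distance_table: pd.DataFrame,
    variation_threshold: float = 0.10,
    strict: bool = False,
) -> list[tuple[str, str, float]]:
    """Mutual-nearest-neighbour edges between two adjacent stages.

    Each population's candidate partners are its nearest population on
    the other stage plus any within ``variation_threshold`` relative
    distance of that minimum; an edge (a, b) is kept when b is a
    candidate of a and a is a candidate of b.  ``strict=True`` restricts
    candidates to exact argmins (no expansion).

    Returns ``(label_from, label_to, distance)`` triples in row-major
    table order.
    """
    if distance_table.empty:
        raise ValueError("empty distance table")
    d = distance_table.to_numpy(dtype=float)
    thr = 0.0 if strict else variation_threshold
    fwd = _candidates(d, thr)
    bwd = _candidates(d.T, thr)
    edges = []
    for i, row_candidates in enumerate(fwd):
        for j in row_candidates:
            if i in bwd[j]:
                edges.append(
                    (str(distance_table.index[i]), str(distance_table.columns[j]), float(d[i, j]))
                )
    return edges


def build_lineage_graph(
    staged_profiles: Sequence[Sequence[PopulationProfile]],
    variation_threshold: float = 0.10,
    strict: bool = False,
) -> nx.DiGraph:
    """Connect consecutive stages of a developmental series into a
    genealogy.  Nodes are keyed (stage, label); edges carry the raw
    distance ``d``, its display weight ``log2(d)`` (d floored at machine
    epsilon, flagged by ``floored``), and the rule that admitted them."""
    g = nx.DiGraph()
    for profiles in staged_profiles:
        for p in profiles:
            g.add_node((p.stage, p.label), n_cells=p.n_cells, stage=p.stage)
    for earlier, later in zip(staged_profiles, staged_profiles[1:]):
        table = stage_distances(earlier, later)
        strict_edges = {(a, b) for a, b, _ in connect_stages(table, strict=True)}
        for a, b, dist in connect_stages(table, variation_threshold, strict=strict):
            floored = dist < np.finfo(float).eps
            g.add_edge(
                (earlier[0].stage, a),
                (later[0].stage, b),
                distance=dist,
                log2_distance=math.log2(max(dist, np.finfo(float).eps)),
                floored=bool(floored),
                rule="strict-MNN" if (a, b) in strict_edges else "within-10%-expansion",
            )
    return g


def trace_single_cells(
    cells_by_stage: Sequence[pd.DataFrame],
    gene_set: Sequence[str],
) -> list[list[str]]:
    """Chain individual cells across stages by plain minimum distance
    (no mutuality, no candidate expansion): each cell at stage t links to
    its closest cell at stage t+1; chains start from every stage-1 cell."""
    if len(cells_by_stage) < 2:
        raise ValueError("need at least 2 stages")
    gene_set = list(gene_set)
    for m in cells_by_stage:
        if m.shape[1] == 0:
            raise ValueError("a stage has no cells")
    links: list[dict[str, str]] = []
    for cur, nxt in zip(cells_by_stage, cells_by_stage[1:]):
        A = cur.loc[gene_set].to_numpy(dtype=float).T
        B = nxt.loc[gene_set].to_numpy(dtype=float).T
        d = np.sqrt(((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2))
        nearest = d.argmin(axis=1)
        links.append(
            {str(cur.columns[i]): str(nxt.columns[j]) for i, j in enumerate(nearest)}
        )
    chains = []
    for start in cells_by_stage[0].columns:
        chain = [str(start)]
        for link in links:
            chain.append(link[chain[-1]])
        chains.append(chain)
    return chains


def export_sankey(graph: nx.DiGraph) -> dict:
    """Node/link document (plotly-style Sankey schema) with log2-distance
    link values; nodes sorted by (stage, label) for determinism."""
    nodes = sorted(graph.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    links = [
        {
            "source": index[u],
            "target": index[v],
            "distance": data["distance"],
            "value": data["log2_distance"],
            "rule": data["rule"],
            "floored": data["floored"],
        }
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    return {
        "nodes": [
            {"stage": s, "label": l, "n_cells": graph.nodes[(s, l)].get("n_cells")}
            for s, l in nodes
        ],
        "links": links,
    }


def import_sankey(document: dict) -> nx.DiGraph:
    """Inverse of :func:`export_sankey`."""
    g = nx.DiGraph()
    nodes = [(n["stage"], n["label"]) for n in document["nodes"]]
    for node, meta in zip(nodes, document["nodes"]):
        g.add_node(node, n_cells=meta.get("n_cells"), stage=node[0])
    for link in document["links"]:
        g.add_edge(
            nodes[link["source"]],
            nodes[link["target"]],
            distance=link["distance"],
            log2_distance=link["value"],
            floored=link["floored"],
            rule=link["rule"],
        )
    return g


def edge_table(graph: nx.DiGraph) -> pd.DataFrame:
    """Edge list in the interchange TSV layout."""
    rows = [
        {
            "stage_from": u[0],
            "pop_from": u[1],
            "stage_to": v[0],
            "pop_to": v[1],
            "distance": data["distance"],
            "log2_distance": data["log2_distance"],
            "rule": data["rule"],
        }
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    return pd.DataFrame(rows)
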