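"""PPI shortest-path tracing with a permutation background filter.

A STRING-style weighted edge list becomes an undirected graph whose edge
distance decreases with interaction confidence. For every unordered pair
of seed proteins one minimum-distance path is traced (Dijkstra, with the
lexicographically smallest node sequence among ties); each non-seed
interior protein's "betweenness" counts the seed pairs whose path runs
through it. Proteins that also bridge random seed sets (universal hubs
such as TP53 or UBC) are flagged by a permutation test and removed from
the related-protein ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .io import ValidationError, load_ppi_edges

__all__ = [
    "score_to_distance",
    "PPIGraph",
    "load_string_edges",
    "PathTraceResult",
    "trace_all_pairs",
    "PermutationFilter",
    "permutation_background",
    "select_related",
]


def score_to_distance(combined_score, method: str = "linear") -> float:
    """Edge distance from a STRING combined score (0 < score <= 1000).

    'linear' (default): 1001 - score, strictly positive and strictly
    decreasing in confidence. 'neglog': -ln(score/1000).
    """
    s = float(combined_score)
    if not 0 < s <= 1000:
        raise ValueError(f"combined score must be in (0, 1000], got {combined_score}")
    if method == "linear":
        return 1001.0 - s
    if method == "neglog":
        return float(-np.log(s / 1000.0))
    raise ValueError("method must be 'linear' or 'neglog'")


@dataclass
class PPIGraph:
    """Undirected weighted protein graph (edge attrs: score, distance)."""

    graph: nx.Graph
    distance_method: str = "linear"

    @classmethod
    def from_edges(
        cls,
        edges: pd.DataFrame,
        score_floor: int = 400,
        distance_method: str = "linear",
    ) -> "PPIGraph":
        """Build from an edge frame, dropping low-confidence edges.

        Duplicate undirected edges keep the maximum score; self-loops are
        dropped.
        """
        g = nx.Graph()
        for p1, p2, score in edges[["protein1", "protein2", "combined_score"]].itertuples(index=False):
            if p1 == p2:
                continue
            score = int(score)
            if score < score_floor:
                continue
            if g.has_edge(p1, p2) and g[p1][p2]["score"] >= score:
                continue
            g.add_edge(
                p1, p2, score=score,
                distance=score_to_distance(score, distance_method),
            )
        if g.number_of_edges() == 0:
            warnings.warn("graph has no edges after filtering")
        return cls(graph=g, distance_method=distance_method)

    @property
    def proteins(self) -> list:
        return sorted(self.graph.nodes)


def load_string_edges(
    path, score_floor: int = 400, distance_method: str = "linear"
) -> PPIGraph:
    """Load a STRING-style TSV into a :class:`PPIGraph`."""
    return PPIGraph.from_edges(
        load_ppi_edges(path), score_floor=score_floor, distance_method=distance_method
    )


@dataclass
class PathTraceResult:
    """Seed-pair shortest-path trace with per-intermediate betweenness."""

    seeds: list
    betweenness: pd.Series  # non-seed intermediates only, >= 1 path each
    unreachable_pairs: list
    unmapped_seeds: list
    n_pairs: int


def _lexicographic_shortest_path(g: nx.Graph, s, t, dist_to_t: dict, tol: float = 1e-9):
    """Reconstruct the lexicographically smallest shortest s->t path.

    ``dist_to_t`` maps nodes to their shortest distance to t. Greedy
    forward walk: at each node take the smallest neighbour that stays on
    some shortest path.
    """
    path = [s]
    cur = s
    while cur != t:
        d_cur = dist_to_t[cur]
        nxt = None
        for v in sorted(g.neighbors(cur)):
            dv = dist_to_t.get(v)
            if dv is None:
                continue
            if abs(g[cur][v]["distance"] + dv - d_cur) <= tol * max(1.0, d_cur):
                nxt = v
                break
        if nxt is None:  # numerical dead end; should not happen
            raise RuntimeError(f"path reconstruction failed between {s} and {t}")
        path.append(nxt)
        cur = nxt
    return path


def trace_all_pairs(
    ppi: PPIGraph, seeds, count_all_shortest: bool = False
) -> PathTraceResult:
    """Trace one shortest path per unordered seed pair; count intermediates.

    Seeds missing from the graph are reported and skipped; unreachable
    pairs are recorded. With ``count_all_shortest`` every tied shortest
    path contributes (Brandes-style enumeration) instead of the single
    lexicographic path.
    """
    g = ppi.graph
    seeds = list(dict.fromkeys(seeds))  # dedupe, keep order
    unmapped = [s for s in seeds if s not in g]
    if unmapped:
        warnings.warn(f"{len(unmapped)} seed(s) not in the graph: {unmapped[:10]}")
    mapped = sorted(s for s in seeds if s in g)
    if len(mapped) < 2:
        raise ValueError("need at least 2 seeds mapped to the graph")

    dist_from = {
        s: nx.single_source_dijkstra_path_length(g, s, weight="distance")
        for s in mapped
    }
    seed_set = set(mapped)
    counts: dict = {}
    unreachable = []
    n_pairs = 0
    for s, t in combinations(mapped, 2):  # mapped is sorted, so s < t
        n_pairs += 1
        if t not in dist_from[s]:
            unreachable.append((s, t))
            continue
        if count_all_shortest:
            for path in nx.all_shortest_paths(g, s, t, weight="distance"):
                for v in path[1:-1]:
                    if v not in seed_set:
                        counts[v] = counts.get(v, 0) + 1
        else:
            path = _lexicographic_shortest_path(g, s, t, dist_from[t])
            for v in path[1:-1]:
                if v not in seed_set:
                    counts[v] = counts.get(v, 0) + 1
    bet = pd.Series(counts, dtype=int).sort_values(ascending=False)
    return PathTraceResult(
        seeds=mapped,
        betweenness=bet,
        unreachable_pairs=unreachable,
        unmapped_seeds=unmapped,
        n_pairs=n_pairs,
    )


@dataclass
class PermutationFilter:
    """Background frequency of high-betweenness proteins over random seed sets."""

    n_rounds: int
    seed_count: int
    betweenness_floor: float
    frequency: pd.Series  # rounds in which the protein cleared the floor
    removal_fraction: float
    removal_list: list


def permutation_background(
    ppi: PPIGraph,
    seed_count: int,
    n_rounds: int = 100,
    betweenness_floor: float = 100.0,
    removal_fraction: float = 0.5,
    rng_seed: int = 0,
) -> PermutationFilter:
    """Repeat the trace on random seed sets to find promiscuous bridges.

    Each round draws ``seed_count`` proteins uniformly without
    replacement and records which proteins reach the betweenness floor;
    proteins doing so in at least ``removal_fraction`` of rounds form the
    removal list.
    """
    nodes = ppi.proteins
    if len(nodes) == 0:
        raise ValueError("empty graph")
    if seed_count > len(nodes):
        raise ValueError(f"seed_count {seed_count} exceeds node count {len(nodes)}")
    rng = np.random.default_rng(rng_seed)
    freq: dict = {}
    for _ in range(n_rounds):
        sample = rng.choice(len(nodes), size=seed_count, replace=False)
        seeds = [nodes[i] for i in sample]
        if len(seeds) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = trace_all_pairs(ppi, seeds)
        hot = trace.betweenness[trace.betweenness >= betweenness_floor]
        for protein in hot.index:
            freq[protein] = freq.get(protein, 0) + 1
    frequency = pd.Series(freq, dtype=int).sort_values(ascending=False)
    cutoff = removal_fraction * n_rounds
    removal = sorted(frequency.index[frequency >= cutoff])
    return PermutationFilter(
        n_rounds=n_rounds,
        seed_count=seed_count,
        betweenness_floor=betweenness_floor,
        frequency=frequency,
        removal_fraction=removal_fraction,
        removal_list=removal,
    )


def select_related(
    result: PathTraceResult,
    filter: PermutationFilter | None = None,
    floor: float = 100.0,
    id_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank related proteins: betweenness >= floor, minus the background list.

    Ties rank by protein id. If an id map (gene_symbol, protein_id) is
    given, gene symbols are attached.
    """
    bet = result.betweenness
    keep = bet[bet >= floor]
    removed = set(filter.removal_list) if filter is not None else set()
    keep = keep[~keep.index.isin(removed)]
    order = sorted(keep.index, key=lambda pid: (-keep[pid], pid))
    out = pd.DataFrame(
        {"protein_id": order, "betweenness": [int(keep[p]) for p in order]}
    )
    if filter is not None:
        out["background_freq"] = [
            int(filter.frequency.get(p, 0)) for p in out["protein_id"]
        ]
    if id_map is not None:
        sym = id_map.set_index("protein_id")["gene_symbol"]
        out["gene_symbol"] = [sym.get(p, "") for p in out["protein_id"]]
    return out
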