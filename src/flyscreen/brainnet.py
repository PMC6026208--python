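"""Connector-gene analysis on a gene interaction network.

Given a weighted undirected network and a list of seed genes (e.g. CNV
genes and their experimentally identified modifiers), this module:

* optionally thresholds edges by weight and then treats the graph as
  unweighted;
* enumerates ALL geodesics (shortest paths) between every pair of mapped
  seed genes, using breadth-first predecessor DAGs with dynamic-programming
  path counting (no explicit path enumeration);
* collects the connector genes — non-seed nodes interior to at least one
  seed-pair geodesic — and, per edge, the criticality c_e = number of
  (pair, geodesic) memberships;
* tests the connector set for annotation enrichment with a one-sided
  Fisher's exact test (hypergeometric tail) against the non-seed network
  nodes, and compares against random seed sets drawn from a control pool.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

Edge = tuple[str, str]


def _edge(u, v) -> Edge:
    return (u, v) if u <= v else (v, u)


@dataclass
class ConnectorResult:
    seeds_mapped: list[str]
    seeds_unmapped: list[str]
    connectors: set[str]
    edge_criticality: dict[Edge, int]
    node_path_counts: dict[str, int]
    pair_geodesics: dict[Edge, tuple[int, int]]  # pair -> (length, count)
    disconnected_pairs: list[Edge]
    nodes: list[str] = field(repr=False, default_factory=list)
    weight_cutoff: float | None = None


@dataclass
class EnrichmentTable:
    """One-sided Fisher 2x2: connectors vs the rest of the background."""

    a: int  # connectors annotated
    b: int  # connectors not annotated
    c: int  # non-connector background annotated
    d: int  # non-connector background not annotated
    odds_ratio: float
    p: float
    odds_ratio_defined: bool


def _bfs_counts(adj: Mapping[str, list[str]], source: str
                ) -> tuple[dict[str, int], dict[str, int]]:
    """BFS distances and geodesic counts from one source (Brandes-style)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                sigma[v] = 0
                queue.append(v)
            if dist[v] == dist[u] + 1:
                sigma[v] += sigma[u]
    return dist, sigma


def threshold_graph(network: nx.Graph, weight_cutoff: float | None) -> nx.Graph:
    """Drop edges with weight below the cutoff (None keeps every edge)."""
    if weight_cutoff is None:
        return network
    kept = nx.Graph()
    kept.add_nodes_from(network.nodes)
    kept.add_edges_from((u, v) for u, v, data in network.edges(data=True)
                        if data.get("weight", 1.0) >= weight_cutoff)
    return kept


def connector_analysis(network: nx.Graph, seeds: Sequence[str],
                       weight_cutoff: float | None = None) -> ConnectorResult:
    """All-geodesic connector analysis among the mapped seed genes.

    For each seed pair (s, t) at distance d, a node v lies on a geodesic iff
    dist(s, v) + dist(v, t) = d, in which case sigma_s(v) * sigma_t(v)
    geodesics pass through it; an edge (u, v) oriented from s to t carries
    sigma_s(u) * sigma_t(v) geodesics iff dist(s, u) + 1 + dist(v, t) = d.
    Connectors are the non-seed interior nodes; seed genes sitting on other
    pairs' geodesics are never reported as connectors.
    """
    seeds = list(dict.fromkeys(seeds))  # dedupe, keep order
    mapped = [s for s in seeds if s in network]
    unmapped = [s for s in seeds if s not in network]
    if len(mapped) < 2:
        raise ValueError("fewer than 2 seed genes map to the network")

    graph = threshold_graph(network, weight_cutoff)
    adj = {u: sorted(graph.neighbors(u)) for u in graph.nodes}
    per_seed = {s: _bfs_counts(adj, s) for s in mapped}
    seed_set = set(mapped)

    connectors: set[str] = set()
    edge_crit: dict[Edge, int] = {}
    node_counts: dict[str, int] = {}
    pair_geo: dict[Edge, tuple[int, int]] = {}
    disconnected: list[Edge] = []

    for s, t in itertools.combinations(mapped, 2):
        dist_s, sigma_s = per_seed[s]
        dist_t, sigma_t = per_seed[t]
        if t not in dist_s:
            disconnected.append(_edge(s, t))
            continue
        d = dist_s[t]
        pair_geo[_edge(s, t)] = (d, sigma_s[t])
        on_path = [v for v in dist_s
                   if v in dist_t and dist_s[v] + dist_t[v] == d]
        for v in on_path:
            if v in (s, t):
                continue
            n_through = sigma_s[v] * sigma_t[v]
            node_counts[v] = node_counts.get(v, 0) + n_through
            if v not in seed_set:
                connectors.add(v)
        on_path_set = set(on_path)
        for u in on_path:
            for v in adj[u]:
                if v in on_path_set and dist_s.get(u, -2) + 1 + dist_t.get(v, -2) == d:
                    key = _edge(u, v)
                    edge_crit[key] = edge_crit.get(key, 0) + sigma_s[u] * sigma_t[v]

    return ConnectorResult(seeds_mapped=mapped, seeds_unmapped=unmapped,
                           connectors=connectors, edge_criticality=edge_crit,
                           node_path_counts=node_counts, pair_geodesics=pair_geo,
                           disconnected_pairs=disconnected,
                           nodes=sorted(network.nodes),
                           weight_cutoff=weight_cutoff)


def enrich_connectors(result: ConnectorResult, annotation: Iterable[str],
                      background: Iterable[str] | None = None) -> EnrichmentTable:
    """One-sided (greater) Fisher's exact test of connector annotation.

    The default background is the set of non-seed network nodes — the frame
    the connectors are drawn from. The hypergeometric tail is computed with
    the connectors inside the background universe and excluded from the
    comparison margin.
    """
    if not result.connectors:
        raise ValueError("connector set is empty; nothing to test")
    annotation = set(annotation)
    if background is None:
        background = set(result.nodes) - set(result.seeds_mapped) \
            - set(result.seeds_unmapped)
    background = set(background) | set(result.connectors)
    n_bg = len(background)
    n_annot = len(background & annotation)
    n_conn = len(result.connectors)
    k = len(result.connectors & annotation)
    p = float(stats.hypergeom.sf(k - 1, n_bg, n_annot, n_conn))
    a, b = k, n_conn - k
    c, d = n_annot - k, (n_bg - n_annot) - (n_conn - k)
    if b > 0 and c > 0:
        odds = (a * d) / (b * c)
        defined = True
    else:
        odds = float("inf") if a > 0 and d > 0 else float("nan")
        defined = False
    return EnrichmentTable(a=a, b=b, c=c, d=d, odds_ratio=float(odds), p=p,
                           odds_ratio_defined=defined)


def random_seed_control(network: nx.Graph, seed_pool: Sequence[str], k: int,
                        n_iter: int, annotation: Iterable[str],
                        seed: int | None = None,
                        weight_cutoff: float | None = None
                        ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Connector enrichment distribution for random k-gene seed sets.

    Draws ``n_iter`` random k-subsets of ``seed_pool``, reruns the connector
    analysis and Fisher test for each, and returns the per-draw table plus
    summary quantiles of the enrichment p-values and odds ratios. Draws
    whose connector set is empty (or with < 2 mapped seeds) are recorded
    with NaN statistics.
    """
    seed_pool = list(dict.fromkeys(seed_pool))
    if len(seed_pool) < k:
        raise ValueError("seed pool smaller than the requested draw size")
    annotation = set(annotation)
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        draw = sorted(rng.choice(seed_pool, size=k, replace=False))
        try:
            result = connector_analysis(network, draw, weight_cutoff)
            table = enrich_connectors(result, annotation)
            rows.append((it, len(result.connectors), table.odds_ratio,
                         table.p, "ok"))
        except ValueError as exc:
            rows.append((it, 0, np.nan, np.nan, str(exc)))
    table = pd.DataFrame(rows, columns=["iteration", "n_connectors",
                                        "odds_ratio", "p", "status"])
    finite_or = table["odds_ratio"].to_numpy(dtype=float)
    finite_or = finite_or[np.isfinite(finite_or)]
    ps = table["p"].to_numpy(dtype=float)
    ps = ps[np.isfinite(ps)]
    summary = {
        "n_ok": int((table["status"] == "ok").sum()),
        "median_odds_ratio": float(np.median(finite_or)) if len(finite_or) else float("nan"),
        "q25_odds_ratio": float(np.quantile(finite_or, 0.25)) if len(finite_or) else float("nan"),
        "q75_odds_ratio": float(np.quantile(finite_or, 0.75)) if len(finite_or) else float("nan"),
        "median_p": float(np.median(ps)) if len(ps) else float("nan"),
    }
    return table, summary


def export_graph(result: ConnectorResult, network: nx.Graph,
                 annotation: Iterable[str] | None = None) -> nx.Graph:
    """Attributed subgraph of seeds + connectors for visualisation tools.

    Node attributes: role (seed/connector), degree in the full network,
    annotated flag, and geodesic path count; edge attribute: criticality.
    Write it with :func:`flyscreen.io.write_graphml` and/or the TSV tables
    from :func:`attribute_tables`.
    """
    annotation = set(annotation or ())
    keep = set(result.seeds_mapped) | result.connectors
    out = nx.Graph()
    for node in sorted(keep):
        out.add_node(node,
                     role="seed" if node in result.seeds_mapped else "connector",
                     degree=int(network.degree(node)),
                     annotated=bool(node in annotation),
                     path_count=int(result.node_path_counts.get(node, 0)))
    for (u, v), crit in sorted(result.edge_criticality.items()):
        if u in keep and v in keep:
            weight = network.edges[u, v].get("weight", 1.0) if network.has_edge(u, v) else 1.0
            out.add_edge(u, v, criticality=int(crit), weight=float(weight))
    return out


def attribute_tables(graph: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge attribute tables for an exported connector graph."""
    nodes = pd.DataFrame(
        [{"node": n, **data} for n, data in sorted(graph.nodes(data=True))])
    edges = pd.DataFrame(
        [{"node1": u, "node2": v, **data}
         for u, v, data in sorted(graph.edges(data=True))])
    return nodes, edges
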