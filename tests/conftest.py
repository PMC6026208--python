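import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def cell_table():
    """Build a long-format score table from explicit per-genotype replicates."""

    def _build(control, a, b, ab, pair_id="pair", gene_a="ga", gene_b="gb"):
        rows = []
        for genotype, values in [("control", control), ("A", a), ("B", b),
                                 ("AB", ab)]:
            for rep, value in enumerate(values, 1):
                rows.append((pair_id, gene_a, gene_b, genotype, rep,
                             float(value)))
        return pd.DataFrame(rows, columns=["pair_id", "gene_a", "gene_b",
                                           "genotype", "replicate", "score"])

    return _build


def brute_force_geodesics(graph: nx.Graph, seeds):
    """Exhaustive connector/criticality oracle: enumerate every simple path
    of geodesic length between each seed pair."""
    seeds_in = [s for s in seeds if s in graph]
    seed_set = set(seeds_in)
    connectors, criticality = set(), {}
    pair_geodesics = {}
    for s, t in itertools.combinations(seeds_in, 2):
        try:
            d = nx.shortest_path_length(graph, s, t)
        except nx.NetworkXNoPath:
            continue
        count = 0
        for path in nx.all_simple_paths(graph, s, t, cutoff=d):
            if len(path) - 1 != d:
                continue
            count += 1
            for v in path[1:-1]:
                if v not in seed_set:
                    connectors.add(v)
            for u, v in zip(path, path[1:]):
                key = (u, v) if u <= v else (v, u)
                criticality[key] = criticality.get(key, 0) + 1
        key = (s, t) if s <= t else (t, s)
        pair_geodesics[key] = (d, count)
    return connectors, criticality, pair_geodesics


def brute_force_bh(p):
    """Step-up BH from the textbook definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        idx = order[rank_from_top]
        value = min(1.0, p[idx] * n / (rank_from_top + 1))
        running_min = min(running_min, value)
        adjusted[idx] = running_min
    return adjusted
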