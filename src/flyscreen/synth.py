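"""Synthetic study generators with known ground truth.

Every input the analysis stages consume can be generated here: eye-surface
images of hexagonally packed ommatidia with controllable positional disorder,
replicate phenotype-score tables for two-hit knockdown designs with planted
interaction classes, multi-model differential-expression studies with planted
enriched gene sets, and random weighted gene networks with known seed sets.

All generators are deterministic under a fixed seed. A master seed can be
fanned out into independent child streams with :func:`child_seeds`, so adding
one generator to a pipeline never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .eyescore import EyeImage

ROW_PITCH = np.sqrt(3.0) / 2.0  # hexagonal row pitch in units of spacing

INTERACTION_CLASSES = ("none", "additive", "suppressor", "enhancer", "full_rescue")


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Spawn ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Eye images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeSpec:
    """Parameters of a synthetic ommatidial lattice.

    ``jitter_sigma`` is the standard deviation (pixels) of isotropic Gaussian
    positional noise added independently to each lattice site — the disorder
    dial that emulates rough-eye phenotypes. ``dropout_rate`` removes sites
    independently; ``fusion_rate`` merges a site with its nearest surviving
    neighbour into a single blob at their midpoint.
    """

    n_rows: int = 20
    n_cols: int = 20
    spacing: float = 10.0
    ommatidium_radius: float = 3.0
    jitter_sigma: float = 0.0
    dropout_rate: float = 0.0
    fusion_rate: float = 0.0
    background_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("lattice dimensions must be positive")
        if self.spacing <= self.ommatidium_radius:
            raise ValueError("spacing must exceed the ommatidium radius")
        for name in ("dropout_rate", "fusion_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")


def ideal_lattice(spec: LatticeSpec) -> np.ndarray:
    """Ideal offset-row hexagonal lattice centers as an (n, 2) (x, y) array."""
    margin = 1.5 * spec.spacing
    rows = np.arange(spec.n_rows)
    cols = np.arange(spec.n_cols)
    jj, ii = np.meshgrid(cols, rows)
    x = margin + jj * spec.spacing + (ii % 2) * spec.spacing / 2.0
    y = margin + ii * spec.spacing * ROW_PITCH
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def _image_shape(spec: LatticeSpec) -> tuple[int, int]:
    margin = 1.5 * spec.spacing
    width = 2 * margin + (spec.n_cols - 1) * spec.spacing + spec.spacing / 2.0
    height = 2 * margin + (spec.n_rows - 1) * spec.spacing * ROW_PITCH
    return int(np.ceil(height)) + 1, int(np.ceil(width)) + 1


def _render(centers: np.ndarray, shape: tuple[int, int], blob_sd: float) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    reach = int(np.ceil(3 * blob_sd))
    h, w = shape
    for cx, cy in centers:
        x0, x1 = max(0, int(np.floor(cx)) - reach), min(w, int(np.ceil(cx)) + reach + 1)
        y0, y1 = max(0, int(np.floor(cy)) - reach), min(h, int(np.ceil(cy)) + reach + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        r2 = ys[:, None] ** 2 + xs[None, :] ** 2
        blob = np.exp(-r2 / (2 * blob_sd**2))
        blob[r2 > (3 * blob_sd) ** 2] = 0.0  # truncate at 3 SD
        img[y0:y1, x0:x1] += blob
    return img


def generate_eye_image(spec: LatticeSpec) -> tuple[EyeImage, np.ndarray]:
    """Render a synthetic eye-surface image.

    Returns the image and the ground-truth centers (post dropout and fusion)
    as an (n, 2) array of (x, y) coordinates. The random draws are laid out
    so that two specs differing only in ``jitter_sigma`` share identical
    standard-normal jitter draws (the offsets scale with sigma).
    """
    rng = np.random.default_rng(spec.seed)
    centers = ideal_lattice(spec)
    n_sites = len(centers)

    centers = centers + rng.standard_normal((n_sites, 2)) * spec.jitter_sigma
    keep = rng.random(n_sites) >= spec.dropout_rate
    centers = centers[keep]

    fuse = rng.random(len(centers)) < spec.fusion_rate
    if fuse.any() and len(centers) >= 2:
        consumed: set[int] = set()
        merged: list[np.ndarray] = []
        tree = cKDTree(centers)
        for i in np.flatnonzero(fuse):
            if i in consumed:
                continue
            # nearest surviving neighbour not already consumed
            dists, idx = tree.query(centers[i], k=min(len(centers), 8))
            j = next((int(q) for q in np.atleast_1d(idx)[1:]
                      if q not in consumed and q != i), None)
            if j is None:
                continue
            consumed.update((i, int(j)))
            merged.append((centers[i] + centers[j]) / 2.0)
        survivors = [c for k, c in enumerate(centers) if k not in consumed]
        centers = np.array(survivors + merged) if survivors or merged else centers[:0]

    shape = _image_shape(spec)
    img = _render(centers, shape, blob_sd=spec.ommatidium_radius / 2.0)
    if spec.background_noise_sd > 0:
        img = img + rng.normal(0.0, spec.background_noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    image = EyeImage(pixels=img, provenance=f"synthetic lattice seed={spec.seed}")
    return image, centers


# ---------------------------------------------------------------------------
# Two-hit phenotype score tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionTruth:
    """Planted two-hit interaction for one gene pair.

    ``effect_a``/``effect_b`` are one-hit mean shifts relative to control and
    ``interaction_shift`` is the planted interaction contrast
    (mean(AB) − mean(A)) − (mean(B) − mean(control)). For ``full_rescue`` the
    shift is derived so the two-hit mean equals the control mean.
    """

    gene_a: str
    gene_b: str
    class_label: str
    effect_a: float = 0.0
    effect_b: float = 0.0
    interaction_shift: float = 0.0
    within_sd: float = 1.0
    n_replicates: int = 12
    pair_id: str = ""

    def __post_init__(self):
        if self.class_label not in INTERACTION_CLASSES:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        shift = self.interaction_shift
        if self.class_label == "suppressor" and not shift < 0:
            raise ValueError("suppressor requires interaction_shift < 0")
        if self.class_label == "enhancer" and not shift > 0:
            raise ValueError("enhancer requires interaction_shift > 0")
        if self.class_label in ("additive", "none") and shift != 0:
            raise ValueError(f"{self.class_label} requires interaction_shift == 0")
        if self.class_label == "full_rescue" and self.effect_a <= 0:
            raise ValueError("full_rescue requires a positive one-hit effect_a")
        if not self.pair_id:
            object.__setattr__(self, "pair_id", f"{self.gene_a}:{self.gene_b}")

    def cell_means(self, control_mean: float) -> dict[str, float]:
        means = {
            "control": control_mean,
            "A": control_mean + self.effect_a,
            "B": control_mean + self.effect_b,
            "AB": control_mean + self.effect_a + self.effect_b + self.interaction_shift,
        }
        if self.class_label == "full_rescue":
            means["AB"] = control_mean
        return means


def generate_score_table(truths: Sequence[InteractionTruth], control_mean: float,
                         seed: int) -> pd.DataFrame:
    """Emit replicate severity scores for control / A / B / AB genotypes."""
    if not truths:
        raise ValueError("truths must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for truth in truths:
        means = truth.cell_means(control_mean)
        for genotype in ("control", "A", "B", "AB"):
            scores = means[genotype] + rng.normal(0, truth.within_sd, truth.n_replicates)
            for rep, score in enumerate(scores, 1):
                rows.append((truth.pair_id, truth.gene_a, truth.gene_b,
                             genotype, rep, float(score)))
    return pd.DataFrame(rows, columns=["pair_id", "gene_a", "gene_b",
                                       "genotype", "replicate", "score"])


# ---------------------------------------------------------------------------
# Expression studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTruth:
    """Planted multi-model differential-expression study.

    ``planted_terms`` are (term id, member genes, log2FC shift) triples whose
    members are shifted in every model. Each model carries one knockdown gene
    whose planted log2FC sits just below −1 (about a 50% expression drop).
    ``shared_de_fraction`` controls what fraction of each model's additional
    DE genes are drawn from a pool common to all models.
    """

    n_genes: int = 10000
    n_models: int = 6
    planted_terms: tuple[tuple[str, tuple[str, ...], float], ...] = ()
    knockdown_genes: tuple[str, ...] | None = None
    null_logfc_sd: float = 0.3
    shared_de_fraction: float = 0.4
    n_de_per_model: int = 100
    n_random_terms: int = 40
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.shared_de_fraction <= 1:
            raise ValueError("shared_de_fraction must lie in [0, 1]")
        for term_id, members, _shift in self.planted_terms:
            if len(members) > self.n_genes:
                raise ValueError(
                    f"planted term {term_id!r} larger than the gene universe")
            if len(members) >= 500:
                raise ValueError(
                    f"planted term {term_id!r} must have fewer than 500 genes")
        if self.knockdown_genes is not None and len(self.knockdown_genes) != self.n_models:
            raise ValueError("need one knockdown gene per model")


class ExpressionStudy(NamedTuple):
    de_tables: dict[str, pd.DataFrame]
    gene_sets: dict[str, set[str]]
    truth: dict


def gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def generate_expression_study(truth: ExpressionTruth) -> ExpressionStudy:
    """Generate per-model DE tables, a gene-set collection, and a truth record.

    The FDR column is assigned, not fitted: any gene whose final |log2FC|
    exceeds 1 receives FDR < 0.05, all others FDR >= 0.05, so the standard
    DE filter recovers exactly the planted DE genes.
    """
    rng = np.random.default_rng(truth.seed)
    genes = gene_ids(truth.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    models = [f"model{j + 1}" for j in range(truth.n_models)]
    kd_genes = truth.knockdown_genes or tuple(genes[: truth.n_models])

    n_shared = int(round(truth.shared_de_fraction * truth.n_de_per_model))
    pool = [g for g in genes if g not in kd_genes]
    shared_de = list(rng.choice(pool, size=n_shared, replace=False)) if n_shared else []
    remaining = [g for g in pool if g not in set(shared_de)]

    de_tables: dict[str, pd.DataFrame] = {}
    de_truth: dict[str, list[str]] = {}
    for j, model in enumerate(models):
        lfc = rng.normal(0.0, truth.null_logfc_sd, truth.n_genes)
        specific = list(rng.choice(remaining, size=truth.n_de_per_model - n_shared,
                                   replace=False))
        de_genes = shared_de + specific
        magnitudes = rng.uniform(1.5, 3.0, len(de_genes))
        signs = rng.choice([-1.0, 1.0], len(de_genes))
        for g, mag, sign in zip(de_genes, magnitudes, signs):
            lfc[gene_index[g]] = sign * mag
        for term_id, members, shift in truth.planted_terms:
            for g in members:
                lfc[gene_index[g]] += shift
        lfc[gene_index[kd_genes[j]]] = rng.uniform(-1.3, -1.05)  # ~50% knockdown
        is_de = np.abs(lfc) > 1.0
        fdr = np.where(is_de, rng.uniform(0.001, 0.049, truth.n_genes),
                       rng.uniform(0.05, 1.0, truth.n_genes))
        de_tables[model] = pd.DataFrame({"gene": genes, "log2FC": lfc, "FDR": fdr})
        de_truth[model] = [g for g, flag in zip(genes, is_de) if flag]

    gene_sets: dict[str, set[str]] = {
        term_id: set(members) for term_id, members, _ in truth.planted_terms
    }
    sizes = rng.integers(10, 101, truth.n_random_terms)
    for t, size in enumerate(sizes):
        gene_sets[f"random_term_{t:03d}"] = set(rng.choice(genes, size=size,
                                                           replace=False))
    record = {
        "models": models,
        "knockdown_genes": list(kd_genes),
        "shared_de_genes": sorted(shared_de),
        "de_genes_per_model": {m: sorted(v) for m, v in de_truth.items()},
        "planted_terms": [(t, sorted(m), s) for t, m, s in truth.planted_terms],
    }
    return ExpressionStudy(de_tables, gene_sets, record)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class SyntheticNetwork(NamedTuple):
    graph: nx.Graph
    seeds: list[str]
    annotation: set[str]
    took_giant_component: bool


def generate_network(n_nodes: int, edge_model: Mapping, n_seeds: int,
                     annotation_fraction: float, seed: int) -> SyntheticNetwork:
    """Generate a weighted undirected network with seed genes and annotations.

    ``edge_model`` is ``{"kind": "erdos_renyi", "p": ...}`` or
    ``{"kind": "small_world", "k": ..., "p": ...}``. If the raw graph is
    disconnected its giant component is kept and flagged in the output.
    """
    if n_seeds > n_nodes:
        raise ValueError("cannot sample more seeds than nodes")
    if not 0 <= annotation_fraction <= 1:
        raise ValueError("annotation_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    kind = edge_model.get("kind", "erdos_renyi")
    graph_seed = int(rng.integers(2**31))
    if kind == "erdos_renyi":
        raw = nx.gnp_random_graph(n_nodes, edge_model["p"], seed=graph_seed)
    elif kind == "small_world":
        raw = nx.watts_strogatz_graph(n_nodes, edge_model["k"], edge_model["p"],
                                      seed=graph_seed)
    else:
        raise ValueError(f"unknown edge model kind {kind!r}")

    if raw.number_of_nodes() == 0:
        raise ValueError("edge model produced an empty graph")
    took_giant = not nx.is_connected(raw)
    if took_giant:
        raw = raw.subgraph(max(nx.connected_components(raw), key=len)).copy()

    graph = nx.Graph()
    mapping = {old: f"n{old:04d}" for old in raw.nodes}
    graph.add_nodes_from(mapping.values())
    for u, v in sorted(raw.edges):
        graph.add_edge(mapping[u], mapping[v], weight=float(1.0 - rng.random()))

    nodes = sorted(graph.nodes)
    if n_seeds > len(nodes):
        raise ValueError("giant component smaller than the requested seed count")
    seeds = sorted(rng.choice(nodes, size=n_seeds, replace=False))
    annotation = {n for n, draw in zip(nodes, rng.random(len(nodes)))
                  if draw < annotation_fraction}
    return SyntheticNetwork(graph, list(seeds), annotation, took_giant)
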