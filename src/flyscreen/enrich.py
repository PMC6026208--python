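"""Transcriptome stage: DE filtering, parametric gene-set enrichment, and the
cross-model overlap permutation test.

The gene-set statistic is the parametric (PAGE-style) Z-score. With per-gene
log2 fold-changes, a term of m measured member genes with mean fold-change
S_m is compared against the global mean mu and standard deviation delta of
all measured fold-changes:

    Z = (S_m - mu) * sqrt(m) / delta

Under a null in which member fold-changes are exchangeable with the rest of
the transcriptome, Z is approximately standard normal, so a two-sided normal
p-value is attached and corrected across terms with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def call_de_genes(table: pd.DataFrame, lfc_threshold: float = 1.0,
                  fdr_threshold: float = 0.05) -> set[str]:
    """Differentially expressed genes: |log2FC| > lfc AND FDR < threshold.

    Both inequalities are strict; a gene sitting exactly on either threshold
    is excluded.
    """
    for col in ("gene", "log2FC", "FDR"):
        if col not in table.columns:
            raise ValueError(f"DE table is missing required column {col!r}")
    lfc = table["log2FC"].to_numpy(dtype=float)
    fdr = table["FDR"].to_numpy(dtype=float)
    mask = (np.abs(lfc) > lfc_threshold) & (fdr < fdr_threshold)
    return set(table.loc[mask, "gene"])


def map_homologs(genes: Iterable[str], mapping: pd.DataFrame,
                 policy: str = "keep_all") -> tuple[set[str], dict]:
    """Translate gene ids through a many-to-many homolog mapping table.

    ``policy='keep_all'`` emits every mapped partner; ``policy='best_score'``
    keeps only the highest-scoring partner per input gene (ties broken by
    lexicographic id for determinism). Unmapped genes are dropped and
    counted in the returned report.
    """
    if policy not in ("keep_all", "best_score"):
        raise ValueError("policy must be 'keep_all' or 'best_score'")
    if len(mapping) == 0:
        raise ValueError("empty homolog mapping table")
    genes = set(genes)
    sub = mapping[mapping["fly_gene"].isin(genes)]
    if policy == "best_score":
        sub = sub.sort_values(["fly_gene", "score", "human_gene"],
                              ascending=[True, False, True])
        sub = sub.groupby("fly_gene", as_index=False).first()
    translated = set(sub["human_gene"])
    mapped_inputs = set(sub["fly_gene"])
    report = {
        "n_input": len(genes),
        "n_mapped": len(mapped_inputs),
        "n_unmapped": len(genes - mapped_inputs),
        "unmapped": sorted(genes - mapped_inputs),
    }
    return translated, report


def page_zscores(table: pd.DataFrame, sets: Mapping[str, Iterable[str]],
                 max_set_size: int | None = 500, min_set_size: int = 2,
                 sqrt_m: bool = True,
                 significance_threshold: float = 0.01) -> pd.DataFrame:
    """Parametric gene-set Z-scores over a DE table.

    Terms are intersected with the measured genes; terms with fewer than
    ``min_set_size`` or at least ``max_set_size`` measured members are
    dropped (``max_set_size=None`` disables the cap). ``sqrt_m=False``
    omits the sqrt(m) factor, i.e. scores the raw set mean against the gene
    population spread. ``delta`` is the sample standard deviation (n-1) of
    all measured fold-changes.
    """
    if "gene" not in table.columns or "log2FC" not in table.columns:
        raise ValueError("DE table needs 'gene' and 'log2FC' columns")
    lfc = pd.Series(table["log2FC"].to_numpy(dtype=float),
                    index=table["gene"].to_numpy())
    mu = float(lfc.mean())
    delta = float(lfc.std(ddof=1))
    if delta == 0 or not np.isfinite(delta):
        raise ValueError("degenerate expression table: zero spread in log2FC")
    rows = []
    for term in sorted(sets):
        members = lfc.index.intersection(pd.Index(sorted(set(sets[term]))))
        m = len(members)
        if m < min_set_size:
            continue
        if max_set_size is not None and m >= max_set_size:
            continue
        s_m = float(lfc.loc[members].mean())
        z = (s_m - mu) / delta
        if sqrt_m:
            z *= np.sqrt(m)
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append((term, m, s_m, mu, delta, float(z), p))
    result = pd.DataFrame(rows, columns=["term", "m", "S_m", "mu", "delta",
                                         "Z", "p"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["p_adj"] < significance_threshold
    else:
        result["p_adj"] = []
        result["significant"] = []
    return result


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("bh_adjust expects a non-empty 1-D array")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class OverlapResult:
    """Cross-model overlap permutation test result.

    ``observed[k]`` counts universe genes differentially expressed in at
    least k models; ``p_empirical[k]`` is the add-one permutation p-value
    (b + 1) / (n_perm + 1).
    """

    observed: dict[int, int]
    p_empirical: dict[int, float]
    n_perm: int
    set_sizes: dict[str, int]
    universe_size: int
    null_counts: dict[int, np.ndarray] | None = None


def overlap_permutation_test(de_sets: Mapping[str, Iterable[str]],
                             universe: Iterable[str],
                             ks: Sequence[int] = (2, 3), n_perm: int = 9999,
                             seed: int | None = None,
                             keep_null: bool = False) -> OverlapResult:
    """Is the gene overlap across models higher than chance?

    For each permutation, each model's set is resampled uniformly without
    replacement from the annotation universe at its observed size, and the
    number of genes present in >= k resampled sets is compared to the
    observed count. The resampling pool is the universe itself because the
    statistic counts universe genes.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    universe = sorted(set(universe))
    index = {g: i for i, g in enumerate(universe)}
    n_universe = len(universe)
    sizes: dict[str, int] = {}
    membership = np.zeros(n_universe, dtype=np.int64)
    for model in sorted(de_sets):
        genes = set(de_sets[model])
        extra = genes - set(universe)
        if extra:
            raise ValueError(
                f"model {model!r} has genes outside the universe "
                f"(e.g. {sorted(extra)[:3]}); restrict sets to the universe first")
        sizes[model] = len(genes)
        if len(genes) > n_universe:
            raise ValueError(f"model {model!r} set larger than the universe")
        for g in genes:
            membership[index[g]] += 1

    observed = {k: int((membership >= k).sum()) for k in ks}

    rng = np.random.default_rng(seed)
    null = {k: np.empty(n_perm, dtype=np.int64) for k in ks}
    chunk = 2000
    done = 0
    size_list = list(sizes.values())
    while done < n_perm:
        block = min(chunk, n_perm - done)
        counts = np.zeros((block, n_universe), dtype=np.int16)
        rows = np.arange(block)[:, None]
        for m in size_list:
            if m == 0:
                continue
            draws = np.argpartition(rng.random((block, n_universe)), m - 1,
                                    axis=1)[:, :m]
            counts[rows, draws] += 1
        for k in ks:
            null[k][done:done + block] = (counts >= k).sum(axis=1)
        done += block

    p_emp = {k: float((1 + (null[k] >= observed[k]).sum()) / (n_perm + 1))
             for k in ks}
    return OverlapResult(observed=observed, p_empirical=p_emp, n_perm=n_perm,
                         set_sizes=sizes, universe_size=n_universe,
                         null_counts=null if keep_null else None)


def score_set_enrichment(scores: Mapping[str, float], gene_set: Iterable[str],
                         alternative: str = "greater"):
    """One-sided t-test of a user-supplied per-gene score, members vs rest.

    Optional helper for annotation-set enrichment of an arbitrary gene-level
    quantity; not part of the default pipeline because the choice of score
    is analysis-specific.
    """
    gene_set = set(gene_set)
    inside = np.array([v for g, v in scores.items() if g in gene_set], dtype=float)
    outside = np.array([v for g, v in scores.items() if g not in gene_set],
                       dtype=float)
    if len(inside) < 2 or len(outside) < 2:
        raise ValueError("need >= 2 genes inside and outside the set")
    return stats.ttest_ind(inside, outside, alternative=alternative,
                           equal_var=False)
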