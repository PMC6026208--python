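"""Two-hit interaction classification.

A modifier screen compares four genotypes per gene pair: control, one-hit
knockdown of gene A, one-hit knockdown of gene B, and the two-hit double
knockdown. With higher score meaning more severe phenotype, the 2x2
factorial decision model is:

* interaction contrast = Δ1 − Δ2 where Δ1 = mean(AB) − mean(A) and
  Δ2 = mean(B) − mean(control);
* if the two-way ANOVA interaction term (df = 1) is significant, gene B is a
  suppressor (contrast < 0) or enhancer (contrast > 0) of the gene A
  phenotype;
* otherwise, a significant B main effect means the two genes act additively
  (B shifts the phenotype equally in both backgrounds);
* otherwise there is no interaction.

A suppressor whose two-hit flies are statistically indistinguishable from
control — while the one-hit A flies are not — is additionally flagged as a
full rescue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust

GENOTYPES = ("control", "A", "B", "AB")


@dataclass
class AnovaResult:
    """Two-way factorial ANOVA for one pair: knockdown-of-A x knockdown-of-B."""

    ss: dict[str, float]
    df: dict[str, int]
    f: dict[str, float]
    p: dict[str, float]
    ss_resid: float
    df_resid: int
    balanced: bool
    f_undefined: bool = False  # zero residual variance


@dataclass
class InteractionCall:
    pair_id: str
    gene_a: str
    gene_b: str
    delta1: float
    delta2: float
    contrast: float
    interaction_class: str
    full_rescue: bool
    p_interaction: float
    p_b_main: float
    p_ab_vs_control: float
    p_a_vs_control: float
    f_interaction: float
    df_interaction: int
    anova: AnovaResult = field(repr=False, default=None)


def _cells(table: pd.DataFrame) -> dict[str, np.ndarray]:
    cells = {}
    for genotype in GENOTYPES:
        y = table.loc[table["genotype"] == genotype, "score"].to_numpy(dtype=float)
        if len(y) == 0:
            raise ValueError(f"missing genotype cell: {genotype!r}")
        cells[genotype] = y
    return cells


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    return float(resid @ resid)


def two_way_anova_cells(cells: dict[str, np.ndarray]) -> AnovaResult:
    """ANOVA from the four genotype cells.

    Balanced designs use the classical cell-mean decomposition; unbalanced
    designs use type-II sums of squares from nested least-squares fits (no
    a-priori ordering of the two factors). The interaction has df = 1.
    """
    counts = {g: len(v) for g, v in cells.items()}
    n_total = sum(counts.values())
    df_resid = n_total - 4
    if min(counts.values()) < 2 or df_resid < 1:
        raise ValueError("each genotype cell needs >= 2 replicates for a "
                         "valid residual df")
    balanced = len(set(counts.values())) == 1
    y_all = np.concatenate([cells[g] for g in GENOTYPES])
    means = {g: float(np.mean(cells[g])) for g in GENOTYPES}
    ss_resid = float(sum(((cells[g] - means[g]) ** 2).sum() for g in GENOTYPES))

    if balanced:
        r = counts["control"]
        grand = float(np.mean(list(means.values())))
        mean_a1 = (means["A"] + means["AB"]) / 2      # A knocked down
        mean_a0 = (means["control"] + means["B"]) / 2
        mean_b1 = (means["B"] + means["AB"]) / 2
        mean_b0 = (means["control"] + means["A"]) / 2
        ss_a = 2 * r * ((mean_a1 - grand) ** 2 + (mean_a0 - grand) ** 2)
        ss_b = 2 * r * ((mean_b1 - grand) ** 2 + (mean_b0 - grand) ** 2)
        # each cell's interaction effect is +/- interaction/4, so
        # SS = r * 4 * (interaction/4)^2
        interaction = means["AB"] - means["A"] - means["B"] + means["control"]
        ss_ab = r * interaction**2 / 4.0
    else:
        a = np.concatenate([np.full(counts[g], 1.0 if g in ("A", "AB") else 0.0)
                            for g in GENOTYPES])
        b = np.concatenate([np.full(counts[g], 1.0 if g in ("B", "AB") else 0.0)
                            for g in GENOTYPES])
        one = np.ones_like(a)
        x_full = np.column_stack([one, a, b, a * b])
        x_ab = np.column_stack([one, a, b])
        x_a = np.column_stack([one, a])
        x_b = np.column_stack([one, b])
        rss_full = _rss(x_full, y_all)
        rss_ab = _rss(x_ab, y_all)
        ss_a = _rss(x_b, y_all) - rss_ab   # type II: A after B
        ss_b = _rss(x_a, y_all) - rss_ab   # type II: B after A
        ss_ab = rss_ab - rss_full
        ss_resid = rss_full

    ss = {"A": max(ss_a, 0.0), "B": max(ss_b, 0.0), "A:B": max(ss_ab, 0.0)}
    df = {"A": 1, "B": 1, "A:B": 1}
    scale = max(float(np.ptp(y_all)) ** 2, 1.0)
    f_undefined = ss_resid <= 1e-12 * scale
    f_vals, p_vals = {}, {}
    for effect in ss:
        if f_undefined:
            f_vals[effect] = float("nan")
            p_vals[effect] = float("nan")
        else:
            f_vals[effect] = ss[effect] / (ss_resid / df_resid)
            p_vals[effect] = float(stats.f.sf(f_vals[effect], 1, df_resid))
    return AnovaResult(ss=ss, df=df, f=f_vals, p=p_vals, ss_resid=ss_resid,
                       df_resid=df_resid, balanced=balanced,
                       f_undefined=f_undefined)


def two_way_anova(table: pd.DataFrame) -> AnovaResult:
    """Two-way ANOVA on the score-table rows of a single pair."""
    return two_way_anova_cells(_cells(table))


def interaction_contrast(table: pd.DataFrame) -> tuple[float, float, float]:
    """(Δ1, Δ2, contrast) with Δ1 = mean(AB) − mean(A), Δ2 = mean(B) − mean(control)."""
    cells = _cells(table)
    d1 = float(np.mean(cells["AB"]) - np.mean(cells["A"]))
    d2 = float(np.mean(cells["B"]) - np.mean(cells["control"]))
    return d1, d2, d1 - d2


def classify_interaction(table: pd.DataFrame, alpha: float = 0.05,
                         rescue_alpha: float = 0.05,
                         alternative: str = "two-sided") -> InteractionCall:
    """Classify one pair as none / additive / suppressor / enhancer.

    ``alternative`` selects the Mann-Whitney sidedness used for the
    rescue-supporting comparisons (two-sided by default).
    """
    cells = _cells(table)
    anova = two_way_anova_cells(cells)
    d1 = float(np.mean(cells["AB"]) - np.mean(cells["A"]))
    d2 = float(np.mean(cells["B"]) - np.mean(cells["control"]))
    contrast = d1 - d2

    p_int, p_b = anova.p["A:B"], anova.p["B"]
    if np.isfinite(p_int) and p_int < alpha:
        cls = "suppressor" if contrast < 0 else "enhancer"
    elif np.isfinite(p_b) and p_b < alpha:
        cls = "additive"
    else:
        cls = "none"

    def _mwu(x, y):
        try:
            return float(stats.mannwhitneyu(x, y, alternative=alternative).pvalue)
        except ValueError:  # identical constant samples
            return float("nan")

    p_ab_ctrl = _mwu(cells["AB"], cells["control"])
    p_a_ctrl = _mwu(cells["A"], cells["control"])
    full_rescue = (cls == "suppressor"
                   and np.isfinite(p_ab_ctrl) and p_ab_ctrl >= rescue_alpha
                   and np.isfinite(p_a_ctrl) and p_a_ctrl < rescue_alpha)

    first = table.iloc[0]
    return InteractionCall(
        pair_id=str(first.get("pair_id", "")),
        gene_a=str(first.get("gene_a", "A")),
        gene_b=str(first.get("gene_b", "B")),
        delta1=d1, delta2=d2, contrast=contrast, interaction_class=cls,
        full_rescue=bool(full_rescue), p_interaction=p_int, p_b_main=p_b,
        p_ab_vs_control=p_ab_ctrl, p_a_vs_control=p_a_ctrl,
        f_interaction=anova.f["A:B"], df_interaction=1, anova=anova)


def screen(tables: pd.DataFrame, alpha: float = 0.05,
           rescue_alpha: float = 0.05,
           multiple_testing: str = "none") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the classifier over every pair in a long-format score table.

    Returns (calls table, heatmap matrix). The heatmap matrix holds the
    two-hit minus one-hit change Δ1 with modifier genes (gene B) as rows and
    primary genes (gene A) as columns. Per-pair failures are recorded in the
    calls table (status column) and the screen continues. With
    ``multiple_testing='BH'`` the interaction p-values are BH-adjusted across
    pairs and the significance gate re-applied on the adjusted values.
    """
    if multiple_testing not in ("none", "BH"):
        raise ValueError("multiple_testing must be 'none' or 'BH'")
    pair_ids = tables["pair_id"].unique()
    if len(pair_ids) == 0:
        raise ValueError("screen requires at least one pair")
    records, failures = [], []
    for pair_id in pair_ids:
        sub = tables[tables["pair_id"] == pair_id]
        try:
            call = classify_interaction(sub, alpha=alpha, rescue_alpha=rescue_alpha)
            records.append(call)
        except Exception as exc:
            failures.append((pair_id, str(exc)))

    rows = [{
        "pair_id": c.pair_id, "gene_a": c.gene_a, "gene_b": c.gene_b,
        "delta1": c.delta1, "delta2": c.delta2, "contrast": c.contrast,
        "interaction_class": c.interaction_class, "full_rescue": c.full_rescue,
        "F": c.f_interaction, "p_interaction": c.p_interaction,
        "p_b_main": c.p_b_main, "status": "ok", "error": "",
    } for c in records]
    rows += [{"pair_id": pid, "gene_a": "", "gene_b": "", "delta1": np.nan,
              "delta2": np.nan, "contrast": np.nan, "interaction_class": "",
              "full_rescue": False, "F": np.nan, "p_interaction": np.nan,
              "p_b_main": np.nan, "status": "error", "error": msg}
             for pid, msg in failures]
    calls = pd.DataFrame(rows)

    if multiple_testing == "BH" and len(records) > 0:
        ok = calls["status"] == "ok"
        p_raw = calls.loc[ok, "p_interaction"].to_numpy(dtype=float)
        finite = np.isfinite(p_raw)
        adj = np.full_like(p_raw, np.nan)
        if finite.any():
            adj[finite] = bh_adjust(p_raw[finite])
        calls.loc[ok, "p_interaction_adj"] = adj
        # re-gate the epistatic calls on adjusted interaction p
        for idx in calls.index[ok]:
            p_adj = calls.at[idx, "p_interaction_adj"]
            contrast = calls.at[idx, "contrast"]
            p_b = calls.at[idx, "p_b_main"]
            if np.isfinite(p_adj) and p_adj < alpha:
                cls = "suppressor" if contrast < 0 else "enhancer"
            elif np.isfinite(p_b) and p_b < alpha:
                cls = "additive"
            else:
                cls = "none"
            if cls != "suppressor":
                calls.at[idx, "full_rescue"] = False
            calls.at[idx, "interaction_class"] = cls

    ok_calls = calls[calls["status"] == "ok"]
    heatmap = ok_calls.pivot_table(index="gene_b", columns="gene_a",
                                   values="delta1", aggfunc="mean")
    return calls, heatmap
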