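"""Readers and writers for the tabular and graph formats used by the pipeline.

All tables are UTF-8, tab-delimited with a header row. Floats are written
with 6 significant digits so that repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

SCORE_TABLE_COLUMNS = ["pair_id", "gene_a", "gene_b", "genotype", "replicate", "score"]
GENOTYPES = ("control", "A", "B", "AB")

FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return FLOAT_FMT % value
    return str(value)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame as TSV with deterministic float formatting."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: str | os.PathLike, required: Iterable[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


# -- score tables ------------------------------------------------------------

def read_score_table(path: str | os.PathLike) -> pd.DataFrame:
    df = read_table(path, required=SCORE_TABLE_COLUMNS)
    bad = set(df["genotype"]) - set(GENOTYPES)
    if bad:
        raise FormatError(
            f"{path}: unknown genotype value(s) {sorted(bad)}; expected {GENOTYPES}"
        )
    if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite scores present")
    return df


def write_score_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    write_table(df[SCORE_TABLE_COLUMNS], path)


# -- DE tables and mappings --------------------------------------------------

def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a differential-expression table (gene, log2FC, FDR)."""
    df = read_table(path, required=["gene", "log2FC", "FDR"])
    fdr = df["FDR"].to_numpy(dtype=float)
    if ((fdr < 0) | (fdr > 1)).any():
        raise FormatError(f"{path}: FDR values outside [0, 1]")
    if df["gene"].duplicated().any():
        dupes = df.loc[df["gene"].duplicated(), "gene"].unique()[:3]
        raise FormatError(f"{path}: duplicate gene ids (e.g. {list(dupes)})")
    return df


def read_mapping_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a fly-to-human homolog mapping (fly_gene, human_gene, score)."""
    return read_table(path, required=["fly_gene", "human_gene", "score"])


# -- gene sets (GMT) and gene lists ------------------------------------------

def read_gmt(path: str | os.PathLike) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Parse a GMT file into (term -> gene set, term -> description)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT rows need term, description and >=1 gene"
                )
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term!r}")
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene set for {term!r}")
            sets[term] = set(genes)
            descriptions[term] = desc
    return sets, descriptions


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sets:
            desc = (descriptions or {}).get(term, "na")
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_gene_list(path: str | os.PathLike) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# -- networks ----------------------------------------------------------------

def read_edge_list(path: str | os.PathLike) -> nx.Graph:
    """Read a weighted undirected edge list (node1, node2, weight).

    Self-loops, duplicate edges, and out-of-range weights are rejected with
    the offending line number.
    """
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["node1", "node2", "weight"]:
            raise FormatError(f"{path}:1: expected header 'node1\\tnode2\\tweight'")
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            u, v, w_str = fields
            try:
                w = float(w_str)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad weight {w_str!r}") from exc
            if u == v:
                raise FormatError(f"{path}:{lineno}: self-loop on {u!r}")
            if not 0 < w <= 1:
                raise FormatError(f"{path}:{lineno}: weight {w} outside (0, 1]")
            if graph.has_edge(u, v):
                raise FormatError(f"{path}:{lineno}: duplicate edge {u!r}-{v!r}")
            graph.add_edge(u, v, weight=w)
    return graph


def write_edge_list(graph: nx.Graph, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node1\tnode2\tweight\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{_fmt(data.get('weight', 1.0))}\n")


def write_graphml(graph: nx.Graph, path: str | os.PathLike) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path: str | os.PathLike) -> nx.Graph:
    return nx.read_graphml(path)


# -- images ------------------------------------------------------------------

def write_image(pixels: np.ndarray, path: str | os.PathLike) -> None:
    """Write a [0, 1] float image as 16-bit TIFF or 8-bit PNG by extension."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, np.round(pixels * 65535).astype(np.uint16))
    elif path.lower().endswith(".png"):
        Image.fromarray(np.round(pixels * 255).astype(np.uint8), mode="L").save(path)
    else:
        raise ValueError(f"unsupported image extension: {path}")


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a grayscale PNG/TIFF into a [0, 1] float array."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        raw = tifffile.imread(path)
    elif path.lower().endswith(".png"):
        raw = np.asarray(Image.open(path).convert("L"))
    else:
        raise ValueError(f"unsupported image extension: {path}")
    raw = np.asarray(raw)
    if raw.ndim != 2:
        raise FormatError(f"{path}: expected a 2-D grayscale image")
    info = np.iinfo(raw.dtype) if raw.dtype.kind in "iu" else None
    scale = info.max if info is not None else 1.0
    return raw.astype(float) / scale
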