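"""Orchestration: one config, five stages, a reproducible manifest.

The pipeline ties the synthetic-study generator to the four analysis stages
(eye scoring, epistasis screening, enrichment, network connectors). A single
master seed is fanned out into independent child streams per stage, every
table is written with fixed float formatting, and a JSON manifest records
parameters, seeds, versions, and per-stage status, so re-running the same
config reproduces byte-identical tabular outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, brainnet, enrich, epistasis, eyescore, io, synth

log = logging.getLogger("flyscreen")

STAGES = ("synth", "eyescore", "epistasis", "enrich", "brainnet")

_DEFAULTS: dict = {
    "stages": list(STAGES),
    "seed": 0,
    "outdir": "flyscreen_run",
    "log_level": "INFO",
    "synth": {
        "n_images_per_level": 2,
        "jitter_levels": [0.0, 0.05, 0.15, 0.30],  # units of lattice spacing
        "lattice": {"n_rows": 14, "n_cols": 14, "spacing": 10.0,
                    "ommatidium_radius": 3.0, "dropout_rate": 0.0,
                    "fusion_rate": 0.0, "background_noise_sd": 0.05},
        "n_pairs_per_class": 2,
        "control_mean": 20.0,
        "effect_size": 9.0,
        "within_sd": 3.0,
        "n_replicates": 12,
        "expression": {"n_genes": 4000, "n_models": 4, "n_de_per_model": 80,
                       "shared_de_fraction": 0.4, "null_logfc_sd": 0.3,
                       "n_random_terms": 30},
        "planted_term_size": 40,
        "planted_term_shift": 1.0,
        "network": {"n_nodes": 150, "p": 0.04, "n_seeds": 8,
                    "annotation_fraction": 0.15},
    },
    "eyescore": {"expected_spacing": 10.0, "threshold_quantile": 0.9,
                 "length_weight": 1.0, "angle_weight": 1.0},
    "epistasis": {"alpha": 0.05, "rescue_alpha": 0.05,
                  "multiple_testing": "none"},
    "enrich": {"lfc_threshold": 1.0, "fdr_threshold": 0.05,
               "max_set_size": 500, "min_set_size": 2, "sqrt_m": True,
               "n_perm": 999, "overlap_ks": [2, 3]},
    "brainnet": {"weight_cutoff": None, "n_random_iter": 20},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    merged = {}
    for key, default in defaults.items():
        if key in override:
            value = override[key]
            if isinstance(default, dict) and isinstance(value, dict):
                merged[key] = _merge(default, value, f"{path}{key}.")
            else:
                merged[key] = value
        else:
            merged[key] = default
    unknown = set(override) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): "
                         f"{', '.join(path + k for k in sorted(unknown))}")
    return merged


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``default_config`` for keys)."""

    options: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        options = _merge(_DEFAULTS, raw or {})
        bad = set(options["stages"]) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        return cls(options=options)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.options[key]


def default_config(outdir: str, seed: int = 0) -> RunConfig:
    """The bundled synthetic demo study."""
    return RunConfig.from_dict({"outdir": outdir, "seed": seed})


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def run(config: RunConfig) -> dict:
    """Run the configured stages in dependency order; return the manifest."""
    opts = config.options
    outdir = Path(opts["outdir"])
    stages = [s for s in STAGES if s in opts["stages"]]
    logging.basicConfig(level=opts["log_level"])

    # pre-flight: dependent stages need the generator's in-memory artifacts
    if any(s != "synth" for s in stages) and "synth" not in stages:
        raise ValueError("the analysis stages require the 'synth' stage; "
                         "run standalone analyses through the CLI subcommands")

    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, synth.child_seeds(opts["seed"], len(STAGES))))
    manifest: dict = {
        "config": {k: v for k, v in opts.items()},
        "versions": {"flyscreen": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__,
                     "networkx": nx.__version__},
        "seeds": seeds,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    artifacts: dict = {}
    for stage in stages:
        t0 = time.time()
        try:
            outputs = _STAGE_RUNNERS[stage](opts, seeds[stage], outdir, artifacts)
            status = {"status": "ok", "outputs": outputs}
        except Exception as exc:
            log.exception("stage %s failed", stage)
            status = {"status": "error", "error": str(exc), "outputs": []}
        status["seconds"] = round(time.time() - t0, 3)
        manifest["stages"][stage] = status
        log.info("stage %s: %s in %.2fs", stage, status["status"],
                 status["seconds"])

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_json(manifest, outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def _run_synth(opts, seed, outdir: Path, artifacts) -> list[str]:
    cfg = opts["synth"]
    sub_seeds = synth.child_seeds(seed, 4)
    outputs = []

    # eye images over the jitter grid
    image_dir = outdir / "images"
    image_dir.mkdir(exist_ok=True)
    truths = {}
    images = []
    img_seeds = synth.child_seeds(sub_seeds[0],
                                  len(cfg["jitter_levels"]) * cfg["n_images_per_level"])
    idx = 0
    for level in cfg["jitter_levels"]:
        for rep in range(cfg["n_images_per_level"]):
            spec = synth.LatticeSpec(jitter_sigma=level * cfg["lattice"]["spacing"],
                                     seed=img_seeds[idx], **cfg["lattice"])
            image, centers = synth.generate_eye_image(spec)
            name = f"jitter{level:g}_rep{rep}"
            io.write_image(image.pixels, image_dir / f"{name}.tif")
            truths[name] = centers.tolist()
            images.append((f"jitter={level:g}", image))
            idx += 1
    _write_json({"centers": truths}, image_dir / "truth_centers.json")
    outputs += [image_dir.name]
    artifacts["images"] = images

    # score table with planted interaction classes
    classes = ["none", "additive", "suppressor", "enhancer", "full_rescue"]
    truth_list = []
    e = cfg["effect_size"]
    for cls in classes:
        for i in range(cfg["n_pairs_per_class"]):
            shift = {"suppressor": -e, "enhancer": e}.get(cls, 0.0)
            truth_list.append(synth.InteractionTruth(
                gene_a=f"{cls}_a{i}", gene_b=f"{cls}_b{i}", class_label=cls,
                effect_a=e, effect_b=0.0 if cls in ("none", "full_rescue") else e / 2,
                interaction_shift=shift, within_sd=cfg["within_sd"],
                n_replicates=cfg["n_replicates"]))
    scores = synth.generate_score_table(truth_list, cfg["control_mean"],
                                        seed=sub_seeds[1])
    io.write_score_table(scores, outdir / "scores.tsv")
    _write_json({"classes": {t.pair_id: t.class_label for t in truth_list}},
                outdir / "score_truth.json")
    artifacts["score_table"] = scores
    artifacts["score_truth"] = {t.pair_id: t.class_label for t in truth_list}
    outputs += ["scores.tsv", "score_truth.json"]

    # expression study with one planted term
    expr_cfg = cfg["expression"]
    term_size = cfg["planted_term_size"]
    members = tuple(synth.gene_ids(expr_cfg["n_genes"])[-term_size:])
    truth = synth.ExpressionTruth(
        planted_terms=(("planted_term", members, cfg["planted_term_shift"]),),
        seed=sub_seeds[2], **expr_cfg)
    study = synth.generate_expression_study(truth)
    de_dir = outdir / "de_tables"
    de_dir.mkdir(exist_ok=True)
    for model, table in study.de_tables.items():
        io.write_table(table, de_dir / f"{model}.tsv")
    io.write_gmt(study.gene_sets, outdir / "gene_sets.gmt")
    _write_json(study.truth, outdir / "expression_truth.json")
    artifacts["expression"] = study
    outputs += [de_dir.name, "gene_sets.gmt", "expression_truth.json"]

    # network
    net_cfg = cfg["network"]
    network = synth.generate_network(
        net_cfg["n_nodes"], {"kind": "erdos_renyi", "p": net_cfg["p"]},
        net_cfg["n_seeds"], net_cfg["annotation_fraction"], seed=sub_seeds[3])
    io.write_edge_list(network.graph, outdir / "network_edges.tsv")
    io.write_gene_list(network.seeds, outdir / "network_seeds.txt")
    io.write_gene_list(sorted(network.annotation), outdir / "network_annotation.txt")
    artifacts["network"] = network
    outputs += ["network_edges.tsv", "network_seeds.txt", "network_annotation.txt"]
    return outputs


def _run_eyescore(opts, seed, outdir: Path, artifacts) -> list[str]:
    if "images" not in artifacts:
        raise ValueError("eyescore stage needs the synth stage's images")
    cfg = opts["eyescore"]
    table = eyescore.score_batch(artifacts["images"], cfg["expected_spacing"],
                                 cfg["threshold_quantile"], cfg["length_weight"],
                                 cfg["angle_weight"])
    io.write_table(table, outdir / "eye_scores.tsv")
    return ["eye_scores.tsv"]


def _run_epistasis(opts, seed, outdir: Path, artifacts) -> list[str]:
    if "score_table" not in artifacts:
        raise ValueError("epistasis stage needs the synth stage's score table")
    cfg = opts["epistasis"]
    calls, heatmap = epistasis.screen(artifacts["score_table"],
                                      alpha=cfg["alpha"],
                                      rescue_alpha=cfg["rescue_alpha"],
                                      multiple_testing=cfg["multiple_testing"])
    io.write_table(calls, outdir / "interaction_calls.tsv")
    io.write_table(heatmap.reset_index(), outdir / "delta1_heatmap.tsv")
    return ["interaction_calls.tsv", "delta1_heatmap.tsv"]


def _run_enrich(opts, seed, outdir: Path, artifacts) -> list[str]:
    if "expression" not in artifacts:
        raise ValueError("enrich stage needs the synth stage's expression study")
    cfg = opts["enrich"]
    study = artifacts["expression"]
    outputs = []
    page_dir = outdir / "page"
    page_dir.mkdir(exist_ok=True)
    de_sets = {}
    for model, table in study.de_tables.items():
        result = enrich.page_zscores(table, study.gene_sets,
                                     max_set_size=cfg["max_set_size"],
                                     min_set_size=cfg["min_set_size"],
                                     sqrt_m=cfg["sqrt_m"])
        io.write_table(result, page_dir / f"{model}.tsv")
        de_sets[model] = enrich.call_de_genes(table, cfg["lfc_threshold"],
                                              cfg["fdr_threshold"])
    outputs.append(page_dir.name)

    # annotation universe for the demo = all measured genes
    universe = set(next(iter(study.de_tables.values()))["gene"])
    restricted = {m: s & universe for m, s in de_sets.items()}
    overlap = enrich.overlap_permutation_test(
        restricted, universe, ks=tuple(cfg["overlap_ks"]),
        n_perm=cfg["n_perm"], seed=seed)
    _write_json({"observed": overlap.observed,
                 "p_empirical": overlap.p_empirical,
                 "n_perm": overlap.n_perm,
                 "universe_size": overlap.universe_size,
                 "set_sizes": overlap.set_sizes},
                outdir / "overlap_test.json")
    outputs.append("overlap_test.json")
    return outputs


def _run_brainnet(opts, seed, outdir: Path, artifacts) -> list[str]:
    if "network" not in artifacts:
        raise ValueError("brainnet stage needs the synth stage's network")
    cfg = opts["brainnet"]
    network = artifacts["network"]
    result = brainnet.connector_analysis(network.graph, network.seeds,
                                         cfg["weight_cutoff"])
    enrichment = brainnet.enrich_connectors(result, network.annotation)
    control, summary = brainnet.random_seed_control(
        network.graph, sorted(network.graph.nodes), k=len(network.seeds),
        n_iter=cfg["n_random_iter"], annotation=network.annotation, seed=seed,
        weight_cutoff=cfg["weight_cutoff"])
    exported = brainnet.export_graph(result, network.graph, network.annotation)
    io.write_graphml(exported, outdir / "connector_graph.graphml")
    nodes, edges = brainnet.attribute_tables(exported)
    io.write_table(nodes, outdir / "connector_nodes.tsv")
    io.write_table(edges, outdir / "connector_edges.tsv")
    io.write_table(control, outdir / "random_seed_control.tsv")
    _write_json({
        "n_connectors": len(result.connectors),
        "n_seed_pairs": len(result.pair_geodesics),
        "n_disconnected_pairs": len(result.disconnected_pairs),
        "fisher": {"a": enrichment.a, "b": enrichment.b, "c": enrichment.c,
                   "d": enrichment.d, "odds_ratio": enrichment.odds_ratio,
                   "p": enrichment.p},
        "random_control_summary": summary,
    }, outdir / "connector_summary.json")
    return ["connector_graph.graphml", "connector_nodes.tsv",
            "connector_edges.tsv", "random_seed_control.tsv",
            "connector_summary.json"]


_STAGE_RUNNERS = {
    "synth": _run_synth,
    "eyescore": _run_eyescore,
    "epistasis": _run_epistasis,
    "enrich": _run_enrich,
    "brainnet": _run_brainnet,
}
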