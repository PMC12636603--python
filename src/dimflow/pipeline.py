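"""Pipeline stages shared by the command-line interface and the analysis
scripts.

Each stage is a pure function from (config, directories, seed) to output
files; a run manifest records parameters, derived seeds and input digests
so that identical config + seed reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, dimorphism, enrichment, flow, synth, traversal
from .graph import ConnectomeGraph, read_edge_table, write_edge_table
from .labels import DEFAULT_DOMAINS, DEFAULT_MODALITIES

STAGES = ["simulate", "dimorphism", "flow", "cluster", "traverse", "enrich"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def run_simulate(cfg: dict, outdir: Path, seed: int) -> dict:
    pc = synth.PairedGenConfig(seed=stage_seed(seed, "simulate"),
                               **cfg.get("paired", {}))
    male, female, truth = synth.generate_paired_connectomes(pc)
    write_edge_table(male, outdir / "male_edges.csv")
    write_edge_table(female, outdir / "female_edges.csv")
    ann = pd.concat([male.types, female.types], ignore_index=True)
    ann.to_csv(outdir / "annotations.csv", index=False)
    _write_json({"edge_dimorphism": {f"{k[0]}->{k[1]}": v
                                     for k, v in truth.edge_dimorphism.items()},
                 "type_category": truth.type_category,
                 "true_scale": truth.true_scale},
                outdir / "truth.json")
    sc = synth.SensorimotorGenConfig(seed=stage_seed(seed, "simulate.sm"),
                                     **cfg.get("sensorimotor", {}))
    smg, smtruth = synth.generate_sensorimotor_graph(sc)
    write_edge_table(smg, outdir / "sensorimotor_edges.csv")
    smg.types.to_csv(outdir / "sensorimotor_types.csv", index=False)
    _write_json({"planted_routes": smtruth.planted_routes,
                 "route_membership": {k: list(v) for k, v in
                                      smtruth.route_membership.items()},
                 "layer_index": smtruth.layer_index},
                outdir / "sensorimotor_truth.json")
    return {"files": ["male_edges.csv", "female_edges.csv", "annotations.csv",
                      "truth.json", "sensorimotor_edges.csv",
                      "sensorimotor_types.csv", "sensorimotor_truth.json"]}


def _load_pair(outdir: Path):
    ann = pd.read_csv(outdir / "annotations.csv")
    male = read_edge_table(outdir / "male_edges.csv",
                           types=ann[ann["dataset"] == "male"], dataset="male")
    female = read_edge_table(outdir / "female_edges.csv",
                             types=ann[ann["dataset"] == "female"],
                             dataset="female")
    return male, female, ann


def run_dimorphism(cfg: dict, outdir: Path, seed: int) -> dict:
    male, female, ann = _load_pair(outdir)
    d = cfg.get("dimorphism", {})
    paired = dimorphism.build_paired_table(male, female)
    thresholds = (d.get("noise_male", dimorphism.DEFAULT_NOISE_THRESHOLDS[0]),
                  d.get("noise_female", dimorphism.DEFAULT_NOISE_THRESHOLDS[1]))
    res = dimorphism.classify_edges(
        paired, q_threshold=d.get("q_threshold", 0.1),
        min_rel_diff=d.get("min_rel_diff", 0.3), thresholds=thresholds,
        scale_factor=d.get("scale_factor"))
    res = dimorphism.reconcile_with_type_labels(res, ann)
    res.to_csv(outdir / "dimorphism_results.csv", index=False)
    summ = dimorphism.dimorphism_summary(
        res, ann, secondary_min_frac=d.get("secondary_min_frac", 0.0))
    out = summ.to_dict()
    out["scale_factor"] = float(res["scale_factor"].iloc[0])
    out["n_noisy"] = int((res["category"] == "noisy").sum())
    out["n_tested"] = int((res["category"] != "noisy").sum())
    _write_json(out, outdir / "dimorphism_summary.json")
    return {"files": ["dimorphism_results.csv", "dimorphism_summary.json"],
            "scale_factor": out["scale_factor"]}


def _load_sensorimotor(outdir: Path) -> ConnectomeGraph:
    types = pd.read_csv(outdir / "sensorimotor_types.csv")
    return read_edge_table(outdir / "sensorimotor_edges.csv", types=types)


def run_flow(cfg: dict, outdir: Path, seed: int) -> dict:
    graph = _load_sensorimotor(outdir)
    f = cfg.get("flow", {})
    modalities = f.get("modalities", DEFAULT_MODALITIES)
    domains = f.get("domains", DEFAULT_DOMAINS)
    profile = flow.flow_profile(graph, modalities, domains)
    M = profile.flow_matrix.copy()
    M.columns = [f"{m}:{d}" for m, d in M.columns]
    M.to_csv(outdir / "flow_matrix.csv")
    summary = pd.DataFrame({
        "sensory_specificity": profile.sensory_specificity,
        "motor_specificity": profile.motor_specificity,
        "combined_specificity": profile.combined_specificity,
        "utilization": profile.utilization,
        "preferred_modality": profile.sensory_preference.idxmax(axis=1),
        "preferred_domain": profile.motor_preference.idxmax(axis=1),
    })
    summary.to_csv(outdir / "flow_summary.csv")
    values = pd.DataFrame(
        [{"modality": m, "domain": d, "flow_value": fr.value}
         for (m, d), fr in profile.flows.items()])
    values.to_csv(outdir / "flow_values.csv", index=False)
    return {"files": ["flow_matrix.csv", "flow_summary.csv", "flow_values.csv"]}


def run_cluster(cfg: dict, outdir: Path, seed: int) -> dict:
    graph = _load_sensorimotor(outdir)
    M = pd.read_csv(outdir / "flow_matrix.csv", index_col=0)
    c = cfg.get("cluster", {})
    t = graph.types
    neck = sorted(t.loc[t["superclass"].isin(
        ["descending_neuron", "ascending_neuron"]), "type"])
    prof = M.loc[neck]
    coords = clustering.embed_profiles(
        prof, n_neighbors=min(c.get("n_neighbors", 20), len(neck) - 1),
        min_dist=c.get("min_dist", 0.0), seed=stage_seed(seed, "cluster"),
        method=c.get("method", "umap"))
    model = clustering.cluster_embedding(
        coords, k_range=tuple(c.get("k_range", (2, 60))),
        seed=stage_seed(seed, "cluster.kmeans"), index=neck)
    # cluster-to-cluster synapse matrix for ordering
    lab = model.label_map()
    C = np.zeros((model.k, model.k))
    for pre, post, w in zip(graph.edges["pre"], graph.edges["post"],
                            graph.edges["weight_total"]):
        if pre in lab and post in lab:
            C[lab[pre], lab[post]] += w
    model = clustering.order_clusters(model, C)
    pd.DataFrame({"type": neck, "cluster": model.labels}).to_csv(
        outdir / "clusters.csv", index=False)

    cols = pd.MultiIndex.from_tuples([tuple(s.split(":")) for s in M.columns])
    prof2 = prof.copy()
    prof2.columns = cols
    mean_flows = prof2.groupby(pd.Series(model.label_map())).mean()
    mats = clustering.behaviour_compatibility_matrices()
    scores = clustering.compatibility_scores(mean_flows, mats)
    scores.to_csv(outdir / "compatibility_scores.csv")
    return {"files": ["clusters.csv", "compatibility_scores.csv"],
            "k": model.k, "silhouette": model.silhouette}


def run_traverse(cfg: dict, outdir: Path, seed: int) -> dict:
    graph = _load_sensorimotor(outdir)
    t = cfg.get("traverse", {})
    config = traversal.TraversalConfig(
        threshold=t.get("threshold", 0.3), n_iter=t.get("n_iter", 1000),
        seed=stage_seed(seed, "traverse"))
    seeds = sorted(graph.types.loc[
        graph.types["superclass"].str.contains("sensory"), "type"])
    res = traversal.mean_layers(graph, seeds, config)
    rows = [{"type": n, "mean_layer": res.mean_layer.get(n, float("nan")),
             "sd_layer": res.sd_layer.get(n, float("nan")),
             "unreached_frac": res.unreached_frac[n]}
            for n in sorted(res.unreached_frac)]
    pd.DataFrame(rows).to_csv(outdir / "traversal_layers.csv", index=False)
    return {"files": ["traversal_layers.csv"]}


def run_enrich(cfg: dict, outdir: Path, seed: int) -> dict:
    e = cfg.get("enrich", {})
    assignments, truth = synth.generate_cluster_hierarchy(
        n_types=e.get("n_types", 400), levels=e.get("levels", 3),
        enriched=e.get("enriched"), seed=stage_seed(seed, "enrich"))
    res = enrichment.hypergeometric_enrichment(
        assignments, truth.type_category, alpha=e.get("alpha", 0.01))
    res.to_csv(outdir / "enrichment.csv", index=False)
    _write_json({"planted": sorted(c for _, c in truth.enriched_clusters),
                 "detected_level0": sorted(
                     res.loc[(res["level"] == 0) & res["enriched"],
                             "cluster"].tolist())},
                outdir / "enrichment_truth.json")
    return {"files": ["enrichment.csv", "enrichment_truth.json"]}


RUNNERS = {"simulate": run_simulate, "dimorphism": run_dimorphism,
           "flow": run_flow, "cluster": run_cluster,
           "traverse": run_traverse, "enrich": run_enrich}


def run_pipeline(stages: list[str], cfg: dict, outdir: str | Path,
                 seed: int = 0) -> dict:
    """Run the requested stages in order and write a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "config": cfg, "stages": {}}
    for stage in stages:
        if stage not in RUNNERS:
            raise ValueError(f"unknown stage {stage!r}")
        info = RUNNERS[stage](cfg, outdir, seed)
        info["stage_seed"] = stage_seed(seed, stage)
        info["digests"] = {f: _digest(outdir / f) for f in info.get("files", [])}
        manifest["stages"][stage] = info
    _write_json(manifest, outdir / "manifest.json")
    return manifest
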