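"""Pipeline orchestration: simulate -> dstat -> genetrees/timing -> network.

A single declarative YAML config drives all stages; every output table is
written under the run's output directory together with a manifest
(config hash, seed, package versions) so a rerun with the same config and
seed reproduces the tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dating, dstat, network
from .alignment import read_fasta, read_group_map, read_locus_table, write_fasta
from .simulate import (
    GTR,
    JC,
    DemographicModel,
    LocusLayout,
    Pulse,
    assemble_dataset,
)
from .trees import write_newick

STAGES = ("simulate", "dstat", "genetrees", "timing", "network")

DEFAULTS = {
    "dstat": {"block_size": 50_000, "z_threshold": 3.0, "p_threshold": 1e-4},
    "genetrees": {"root_age": 9.5, "min_locus_length": 500,
                  "min_mean_support": 50.0, "n_bootstrap": 100,
                  "distance_model": "JC"},
    "timing": {"bin_width": 0.25, "recent_cutoff_fraction": 0.2,
               "recent_mass_threshold": 0.05, "pairs": None},
    "network": {"distance_model": "TN93"},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _log(msg: str) -> None:
    print(f"[introphy {time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def model_from_config(sim_cfg: dict) -> DemographicModel:
    pulses = [
        Pulse(time=float(p["time"]), source=str(p["source"]),
              dest=str(p["dest"]), proportion=float(p["proportion"]))
        for p in sim_cfg.get("pulses", []) or []
    ]
    return DemographicModel(
        species_tree=sim_cfg["species_tree"],
        ne=sim_cfg.get("ne", 1e5),
        pulses=pulses,
        mutation_rate=float(sim_cfg.get("mutation_rate", 1e-8)),
        generation_time=float(sim_cfg.get("generation_time", 5.0)),
    )


def run_pipeline(config: dict, output_dir=None, seed: int | None = None) -> dict:
    """Execute the configured stages in dependency order.

    Returns a summary dict; writes result tables, Newick/NEXUS artifacts
    and ``manifest.json`` under ``output_dir``.  A stage failure raises
    :class:`PipelineError` naming the stage and leaves a FAILED marker next
    to any partial outputs.
    """
    cfg = dict(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg.get("seed", 0))
    outdir = Path(output_dir or cfg.get("output_dir", "introphy_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg.get("stages") or
                  (["simulate"] if "simulate" in cfg else []) +
                  ["dstat", "genetrees", "timing", "network"])
    summary: dict = {"stages": stages, "seed": seed}

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "introphy_version": __version__,
        "numpy_version": np.__version__,
        "defaults_used": {
            s: {k: v for k, v in DEFAULTS.get(s, {}).items()
                if k not in (cfg.get(s) or {})}
            for s in STAGES if s in stages
        },
    }

    alignment = None
    group_map = None
    current = None
    try:
        for current in stages:
            t0 = time.time()
            _log(f"stage {current} started")
            if current == "simulate":
                sim = cfg["simulate"]
                model = model_from_config(sim)
                layout = LocusLayout(
                    n_loci=int(sim.get("n_loci", 100)),
                    locus_length=int(sim.get("locus_length", 1000)),
                    spacing=int(sim.get("spacing", 0)),
                )
                subst = (GTR(**sim["gtr"]) if "gtr" in sim else
                         JC(alpha=sim.get("gamma_alpha")))
                ds = assemble_dataset(model, layout, seed=seed, subst_model=subst)
                alignment = ds.alignment
                group_map = sim.get("groups") or _default_groups(model)
                write_fasta(alignment, outdir / "alignment.fasta")
                alignment.loci.to_csv(outdir / "loci.tsv", sep="\t", index=False)
                pd.DataFrame(sorted(group_map.items()),
                             columns=["taxon", "group"]).to_csv(
                    outdir / "groups.tsv", sep="\t", index=False)
                write_newick(ds.true_gene_trees, outdir / "true_gene_trees.nwk")
                (outdir / "simulation_provenance.json").write_text(
                    json.dumps(ds.provenance, indent=2, default=str))
                summary["simulate"] = {"n_loci": layout.n_loci,
                                       "alignment_sites": alignment.n_sites}
            else:
                if alignment is None:
                    inputs = cfg["inputs"]
                    alignment = read_fasta(inputs["alignment"])
                    if "loci" in inputs:
                        alignment.loci = read_locus_table(inputs["loci"])
                    group_map = read_group_map(inputs["groups"])
                summary.update(
                    _run_analysis_stage(current, cfg, alignment, group_map,
                                        outdir, seed, summary)
                )
            _log(f"stage {current} done in {time.time() - t0:.1f}s")
    except Exception as exc:  # noqa: BLE001 - report failing stage
        (outdir / "FAILED").write_text(f"stage {current} failed: {exc}\n")
        raise PipelineError(current, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    _write_summary(summary, outdir / "summary.txt")
    return summary


def _default_groups(model: DemographicModel) -> dict[str, str]:
    # two clades under the root define the default grouping
    kids = model.tree.root.children
    if len(kids) != 2:
        raise ValueError("cannot infer groups: species-tree root is not binary")
    groups = {}
    for gi, kid in enumerate(kids):
        stack = [kid]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                groups[n.name] = f"clade{gi + 1}"
            stack.extend(n.children)
    return groups


def _stage_cfg(cfg: dict, stage: str) -> dict:
    merged = dict(DEFAULTS.get(stage, {}))
    merged.update(cfg.get(stage) or {})
    return merged


def _run_analysis_stage(stage, cfg, alignment, group_map, outdir, seed, summary):
    out = {}
    if stage == "dstat":
        sc = _stage_cfg(cfg, "dstat")
        res = dstat.run_dstat(alignment, group_map, block_size=int(sc["block_size"]))
        res.to_csv(outdir / "dstat_all_triplets.tsv", sep="\t", index=False,
                   float_format="%.6g")
        sig = dstat.significant_triplets(res, sc["z_threshold"], sc["p_threshold"])
        sig.to_csv(outdir / "dstat_significant.tsv", sep="\t", index=False,
                   float_format="%.6g")
        out["dstat"] = {"n_triplets": len(res), "n_significant": len(sig)}
        gs = sorted(set(group_map.values()))
        if len(gs) == 2:
            d1 = res[res.group == gs[0]]["D"].dropna()
            d2 = res[res.group == gs[1]]["D"].dropna()
            if len(d1) and len(d2):
                cmp_ = dstat.compare_groups(d1, d2)
                out["dstat"]["mann_whitney"] = {
                    "W": cmp_.w, "p": cmp_.p, "groups": gs}
    elif stage == "genetrees":
        sc = _stage_cfg(cfg, "genetrees")
        config = dating.DatingConfig(
            root_age=float(sc["root_age"]),
            min_locus_length=int(sc["min_locus_length"]),
            min_mean_support=float(sc["min_mean_support"]),
            n_bootstrap=int(sc["n_bootstrap"]),
            distance_model=sc["distance_model"],
        )
        dated, report = dating.date_gene_trees(alignment, group_map, config,
                                               seed=seed)
        report.to_csv(outdir / "genetrees_report.tsv", sep="\t", index=False,
                      float_format="%.6g")
        write_newick([d.tree for d in dated], outdir / "dated_gene_trees.nwk")
        summary["_dated"] = dated
        out["genetrees"] = {
            "n_dated": len(dated),
            "n_filtered": int((report.status != "dated").sum()),
        }
    elif stage == "timing":
        sc = _stage_cfg(cfg, "timing")
        dated = summary.get("_dated")
        if not dated:
            raise ValueError("timing stage requires the genetrees stage")
        taxa = sorted({leaf for d in dated for leaf in d.tree.leaf_names()})
        pairs = sc["pairs"] or [
            [a, b] for i, a in enumerate(taxa) for b in taxa[i + 1:]
        ]
        rows, labels = [], {}
        for a, b in pairs:
            ages = dating.pair_divergence_times(dated, (a, b))
            for lid, age in zip([d.locus_id for d in dated], ages):
                rows.append((a, b, lid, age))
            try:
                tc = dating.classify_timing(
                    ages, sc["recent_cutoff_fraction"],
                    sc["recent_mass_threshold"], sc["bin_width"])
                labels[f"{a}--{b}"] = {
                    "label": tc.label, "mode_age": tc.mode_age,
                    "recent_fraction": tc.recent_fraction}
            except dating.DatingError:
                labels[f"{a}--{b}"] = {"label": "underpowered"}
        pd.DataFrame(rows, columns=["taxonA", "taxonB", "locus_id", "age_mya"]) \
            .to_csv(outdir / "pair_divergence_times.tsv", sep="\t", index=False,
                    float_format="%.6g")
        (outdir / "timing_labels.json").write_text(json.dumps(labels, indent=2))
        out["timing"] = labels
    elif stage == "network":
        sc = _stage_cfg(cfg, "network")
        dm = network.genetic_distances(alignment, model=sc["distance_model"])
        dm.to_csv(outdir / "distances.tsv", sep="\t", float_format="%.8g")
        system = network.neighbor_net(dm)
        network.write_nexus_splits(system, outdir / "splits.nex")
        graph, taxon_node = network.build_splits_graph(system)
        network.write_edge_list(graph, system, outdir / "splits_graph_edges.tsv")
        out["network"] = {"n_splits": len(system.splits),
                          "n_nodes": graph.number_of_nodes(),
                          "n_edges": graph.number_of_edges()}
        if len(set(group_map.values())) == 2:
            degs = network.group_degrees(graph, taxon_node, group_map, system)
            g1, g2 = sorted(degs)
            try:
                cmp_ = network.poisson_glm_compare(degs[g1], degs[g2])
                out["network"]["degree_comparison"] = {
                    "groups": [g1, g2], "coef": cmp_.coef, "se": cmp_.se,
                    "z": cmp_.z, "p": cmp_.p}
            except network.NetworkError as exc:
                out["network"]["degree_comparison"] = {"error": str(exc)}
            (outdir / "degree_comparison.json").write_text(
                json.dumps(out["network"].get("degree_comparison", {}), indent=2))
    return out


def _write_summary(summary: dict, path: Path) -> None:
    clean = {k: v for k, v in summary.items() if not k.startswith("_")}
    lines = ["introphy run summary", "====================", ""]
    lines.append(json.dumps(clean, indent=2, default=str))
    path.write_text("\n".join(lines) + "\n")
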