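"""End-to-end orchestration: generator -> analyses -> summary tables.

``run_pipeline`` executes the four analysis modalities (MET currents,
bundle stiffness, confocal ratios, gene-set overlap) on synthetic inputs,
writes per-stage CSV/JSON outputs, and records a manifest (config, seeds,
version, per-stage status).  Outputs are deterministic given the config
and seed: rerunning reproduces byte-identical tables.  A failing stage is
recorded in the manifest and does not stop independent stages; a stage
absent from the config is skipped and the manifest says so.
"""

from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bundle_motion import estimate_stiffness, reslice_kymograph, track_displacement
from .cohort import compare_groups
from .confocal import Landmark, local_ratio, profile_cells, reduction_table
from .genesets import GeneSet, filter_degs, panel_overlap, venn_partition
from .met_traces import build_iv_and_reversal, summaries_to_frame
from .synthetic import (
    ChannelModel,
    FluidJetModel,
    GeneSetSpec,
    GeneUniverseSpec,
    MovieSpec,
    StackSpec,
    TraceProtocol,
    simulate_bundle_movie,
    simulate_confocal_stack,
    simulate_gene_tables,
    simulate_met_traces,
)

__all__ = ["DEFAULT_CONFIG", "run_pipeline"]

log = logging.getLogger("metkit.pipeline")

DEFAULT_CONFIG: dict = {
    "met": {
        "genotypes": {"control": {"n_channels": 160}, "ko": {"n_channels": 40}},
        "p_rest": 0.5,
        "buffers": ["EGTA_1mM", "BAPTA_5mM"],
        "n_cells": 3,
    },
    "bundle": {
        "genotypes": {"control": {"k_true": 3.0}, "ko": {"k_true": 1.5}},
        "force_nN": 0.3,
        "n_cells": 3,
    },
    "confocal": {
        "control_ratio_scale": 1.0,
        "ko_ratio_scale": 0.1,
        "n_cells": 4,
        "age": "P20",
    },
    "genes": {
        "universe_size": 20000,
        "ko_size": 1739,
        "maturation_size": 3266,
        "overlap": 1007,
        "panel_size": 64,
        "panel_in_degs": 16,
        "panel_frac_down": 0.875,
    },
}


def _stage_met(cfg: dict, seed: int, out: Path) -> dict:
    rows = []
    iv_info = {}
    rng_seeds = np.random.SeedSequence(seed).generate_state(1000)
    k = 0
    for genotype, params in cfg["genotypes"].items():
        channel = ChannelModel(p_rest=cfg.get("p_rest", 0.5), **params)
        jet = FluidJetModel()
        for buffer_label in cfg.get("buffers", ["EGTA_1mM"]):
            for c in range(cfg.get("n_cells", 3)):
                protocol = TraceProtocol(buffer_label=buffer_label)
                sim = simulate_met_traces(
                    channel, jet, protocol, int(rng_seeds[k] % 2**31),
                    cell_id=f"{genotype}_{buffer_label}_{c}", genotype=genotype,
                )
                k += 1
                df = summaries_to_frame(sim.traces)
                rows.append(df)
                iv = build_iv_and_reversal(sim.traces)
                iv_info[f"{genotype}/{buffer_label}/cell{c}"] = iv.reversal_mV
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(out / "met_summaries.csv", index=False)
    return {"table": "met_summaries.csv", "reversal_mV": iv_info}


def _stage_bundle(cfg: dict, seed: int, out: Path) -> dict:
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(1000)
    k = 0
    force = cfg.get("force_nN", 0.3)
    for genotype, params in cfg["genotypes"].items():
        jet = FluidJetModel(**params)
        for c in range(cfg.get("n_cells", 3)):
            spec = MovieSpec()
            sim = simulate_bundle_movie(
                spec, jet, [(force, 60.0, 90.0)], int(seeds[k] % 2**31)
            )
            k += 1
            kymo = reslice_kymograph(sim.movie)
            trace = track_displacement(kymo)
            est = estimate_stiffness(trace, sim.movie.stimulus_force)
            rows.append(
                {"genotype": genotype, "cell_id": f"{genotype}_{c}",
                 "force_nN": est.force, "x_steady_nm": est.x_steady,
                 "k_mN_per_m": est.k, "k_true": jet.k_true,
                 "quality": est.quality, "flags": ";".join(est.flags)}
            )
    table = pd.DataFrame(rows)
    table.to_csv(out / "bundle_stiffness.csv", index=False)
    groups = {g: table.loc[table["genotype"] == g, "k_mN_per_m"].to_numpy()
              for g in cfg["genotypes"]}
    info: dict = {"table": "bundle_stiffness.csv"}
    names = list(groups)
    if len(names) == 2 and all(len(v) >= 2 for v in groups.values()):
        cmpres = compare_groups(groups[names[0]], groups[names[1]],
                                test="mann_whitney",
                                label_a=names[0], label_b=names[1])
        info["comparison"] = {"test": cmpres.test, "p": cmpres.p_value}
    return info


def _stage_confocal(cfg: dict, seed: int, out: Path) -> dict:
    seeds = np.random.SeedSequence(seed).generate_state(1000)
    k = 0
    measurements = []
    base = StackSpec()
    scales = {"control": cfg.get("control_ratio_scale", 1.0),
              "ko": cfg.get("ko_ratio_scale", 0.1)}
    for genotype, scale in scales.items():
        spec = base.scaled_ratios(scale)
        for c in range(cfg.get("n_cells", 4)):
            sim = simulate_confocal_stack(spec, int(seeds[k] % 2**31))
            k += 1
            for name, pos in spec.landmarks.items():
                measurements.append(
                    local_ratio(sim.stack, Landmark(name, pos),
                                cell_id=f"{genotype}_{c}", genotype=genotype,
                                age=cfg.get("age", "P20"))
                )
    summary = profile_cells(measurements)
    summary.to_csv(out / "confocal_summary.csv", index=False)
    red = reduction_table(summary, ko="ko", control="control")
    red.to_csv(out / "confocal_reduction.csv", index=False)
    return {"summary": "confocal_summary.csv",
            "reduction": "confocal_reduction.csv"}


def _stage_genes(cfg: dict, seed: int, out: Path) -> dict:
    spec = GeneUniverseSpec(
        universe_size=cfg.get("universe_size", 20000),
        sets=(GeneSetSpec("ko_p30", cfg.get("ko_size", 1739)),
              GeneSetSpec("maturation", cfg.get("maturation_size", 3266))),
        overlaps={("ko_p30", "maturation"): cfg.get("overlap", 1007)},
        seed=seed,
    )
    sim = simulate_gene_tables(spec)
    ko = filter_degs(sim.tables["ko_p30"], label="ko_p30")
    mat = filter_degs(sim.tables["maturation"], label="maturation")
    venn = venn_partition(ko.genes, mat.genes)

    # hair-bundle gene panel drawn from the ground truth with a known
    # number of panel members among the knockout DEGs
    rng = np.random.default_rng(seed + 1)
    in_degs = sorted(sim.truth_sets["ko_p30"])
    out_degs = sorted(set(f"gene{i:05d}" for i in range(spec.universe_size))
                      - sim.truth_sets["ko_p30"])
    n_in = cfg.get("panel_in_degs", 16)
    n_panel = cfg.get("panel_size", 64)
    panel_genes = (list(rng.choice(in_degs, n_in, replace=False))
                   + list(rng.choice(out_degs, n_panel - n_in, replace=False)))
    panel = GeneSet.from_iterable("bundle_panel", panel_genes)
    rep = panel_overlap(panel, ko)
    doc = {
        "venn": {"only_ko": venn.only_a, "intersection": venn.intersection,
                 "only_maturation": venn.only_b,
                 "pct_of_ko": venn.pct_of_a.raw,
                 "pct_of_maturation": venn.pct_of_b.raw},
        "panel": {"size": len(panel), "overlap": rep.intersection,
                  "pct": rep.pct_of_a.raw},
    }
    (out / "gene_overlap.json").write_text(json.dumps(doc, indent=1))
    return {"report": "gene_overlap.json", **doc}


_STAGES = {
    "met": _stage_met,
    "bundle": _stage_bundle,
    "confocal": _stage_confocal,
    "genes": _stage_genes,
}


def run_pipeline(config=None, out_dir="pipeline_out", seed: int = 0) -> dict:
    """Run all configured stages and return the manifest.

    ``config`` may be a dict, a path to a YAML/JSON document, or None for
    the default synthetic configuration.  Each stage receives a seed
    derived deterministically from ``seed`` and its name, so outputs are
    replayable from the manifest alone.
    """
    if config is None:
        config = DEFAULT_CONFIG
    elif isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"version": __version__, "seed": seed,
                      "config": config, "stages": {}}
    for name, fn in _STAGES.items():
        if name not in config:
            manifest["stages"][name] = {"status": "skipped",
                                        "reason": "not in config"}
            log.info("stage %s skipped (not configured)", name)
            continue
        stage_seed = int(
            np.random.SeedSequence(
                [seed, zlib.crc32(name.encode()) % 2**31]
            ).generate_state(1)[0]
            % 2**31
        )
        log.info("stage %s: seed %d", name, stage_seed)
        try:
            info = fn(config[name], stage_seed, out)
            manifest["stages"][name] = {"status": "ok", "seed": stage_seed,
                                        **info}
        except Exception as exc:  # independent stages keep running
            log.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "failed", "seed": stage_seed,
                                        "error": f"{type(exc).__name__}: {exc}"}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
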