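"""Pipeline orchestration: simulate → render → cytometry → noise → compare → enrich.

A YAML run configuration (versioned schema) selects stages and their
parameters.  All randomness derives from one master seed: per-stage child
seeds are spawned deterministically (`numpy.random.SeedSequence`, canonical
stage order) and recorded, with input/output paths and SHA-256 checksums,
in a JSON run manifest sufficient to re-run any stage in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import ConfigError
from .comparisons import dunns_method, kruskal_wallis, mann_whitney_u, significance_label
from .cytometry import extract_measurements
from .enrichment import (
    classify_intronless,
    crosstab_mae,
    fisher_exact,
    parse_gff3,
    term_overrepresentation,
)
from .noise import normalize_per_experiment, per_cell_intrinsic_noise, summarize_noise
from .params import SimulationParams
from .stack import load_tiff, save_tiff
from .synthetic import (
    NucleusGeometry,
    generate_annotation_fixture,
    render_image_stack,
    simulate_population,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "render", "cytometry", "noise", "compare", "enrich")
SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "out_dir": "allelenoise_run",
    "stages": ["simulate", "noise", "compare"],
    "simulate": {
        "groups": [
            {"group_label": "introns", "silencing_q": 0.02},
            {"group_label": "intronless", "silencing_q": 0.30},
        ],
        "n_experiments": 3,
        "cells_per_experiment": 60,
        "ploidy_N": 2,
        "tissue": "muscle",
    },
    "render": {"n_cells": 20, "radius": 4, "background": 5.0},
    "cytometry": {"min_voxels": 10, "experiment_id": "exp1",
                  "group_label": "rendered", "tissue": "muscle"},
    "noise": {"means": "pooled"},
    "compare": {"test": "auto"},
    "enrich": {"n_genes": 1000, "frac_intronless": 0.06,
               "frac_mae_intronless": 0.64, "frac_mae_intronful": 0.20},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a YAML mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema check; raises :class:`ConfigError` before any stage runs."""
    if cfg.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {cfg.get('schema_version')!r}")
    if not isinstance(cfg.get("seed", 0), int):
        raise ConfigError("seed must be an integer")
    stages = cfg.get("stages", [])
    if not stages:
        raise ConfigError("stages must be a non-empty list")
    for s in stages:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}; known: {list(STAGES)}")
    order = [STAGES.index(s) for s in stages]
    if order != sorted(order):
        raise ConfigError("stages must be listed in dependency order")
    # every externally referenced input must exist up front
    def need(path_key, stage, producer):
        block = cfg.get(stage, {}) or {}
        p = block.get(path_key)
        if p is None:
            if producer not in stages:
                raise ConfigError(
                    f"stage {stage!r} needs {path_key!r} or the {producer!r} stage"
                )
        elif not Path(p).exists():
            raise ConfigError(f"stage {stage!r}: input path {p!r} does not exist")

    if "render" in stages:
        need("input", "render", "simulate")
    if "cytometry" in stages:
        need("input", "cytometry", "render")
    if "noise" in stages:
        need("input", "noise", "simulate")
    if "compare" in stages:
        need("input", "compare", "noise")
    enrich = cfg.get("enrich", {}) or {}
    if "enrich" in stages and "gff" in enrich:
        for key in ("gff", "mae", "terms"):
            p = enrich.get(key)
            if p is None or not Path(p).exists():
                raise ConfigError(f"stage 'enrich': input path for {key!r} missing")


def _merged(cfg: dict, stage: str) -> dict:
    out = dict(DEFAULT_CONFIG.get(stage, {}))
    out.update(cfg.get(stage, {}) or {})
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _child_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        s: int(c.generate_state(1)[0] % 2**31) for s, c in zip(STAGES, children)
    }


def run_pipeline(config: dict | str | Path) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    validate_config(cfg)
    out_dir = Path(cfg.get("out_dir", DEFAULT_CONFIG["out_dir"]))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    seeds = _child_seeds(seed)
    stages = cfg["stages"]

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "master_seed": seed,
        "stages": [],
    }
    produced: dict[str, Path] = {}

    def record(name, inputs, outputs, status="ok", error=None):
        manifest["stages"].append(
            {
                "name": name,
                "seed": seeds[name],
                "status": status,
                "error": error,
                "inputs": [str(p) for p in inputs],
                "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            }
        )

    failed = False
    for stage in stages:
        if failed:
            manifest["stages"].append({"name": stage, "status": "skipped"})
            continue
        try:
            inputs, outputs = _run_stage(stage, cfg, seeds[stage], out_dir, produced)
            record(stage, inputs, outputs)
        except Exception as exc:  # recorded, downstream skipped, re-raised at end
            logger.error("stage %s failed: %s", stage, exc)
            record(stage, [], [], status="failed", error=str(exc))
            failed = True
            failure = exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    if failed:
        raise failure
    return manifest


def _run_stage(stage, cfg, seed, out_dir: Path, produced: dict):
    block = _merged(cfg, stage)
    if stage == "simulate":
        groups = block.pop("groups")
        frames, truths = [], []
        ss = np.random.SeedSequence(seed).spawn(len(groups))
        for gblock, child in zip(groups, ss):
            pkw = {**{k: v for k, v in block.items()}, **gblock}
            pkw["seed"] = int(child.generate_state(1)[0] % 2**31)
            cells, truth = simulate_population(SimulationParams(**pkw))
            frames.append(cells)
            truths.append(truth.assign(group_label=pkw.get("group_label", "group")))
        cells_path = out_dir / "cells.csv"
        truth_path = out_dir / "ground_truth.csv"
        pd.concat(frames, ignore_index=True).to_csv(cells_path, index=False)
        pd.concat(truths, ignore_index=True).to_csv(truth_path, index=False)
        produced["cells"] = cells_path
        produced["truth"] = truth_path
        return [], [cells_path, truth_path]

    if stage == "render":
        src = Path(block.get("input") or produced["cells"])
        cells = pd.read_csv(src).head(int(block.get("n_cells", 20)))
        geom = NucleusGeometry(
            radius=int(block.get("radius", 4)),
            background=float(block.get("background", 5.0)),
        )
        stack, rois = render_image_stack(cells, geom, seed=seed)
        tif = out_dir / "stack.tif"
        roi_csv = out_dir / "rois.csv"
        save_tiff(stack, tif)
        rois.to_csv(roi_csv, index=False)
        produced["stack"] = tif
        return [src], [tif, roi_csv]

    if stage == "cytometry":
        src = Path(block.get("input") or produced["stack"])
        stack = load_tiff(src)
        df = extract_measurements(
            stack,
            experiment_id=block.get("experiment_id", "exp1"),
            group_label=block.get("group_label", "rendered"),
            tissue=block.get("tissue", "muscle"),
            min_voxels=int(block.get("min_voxels", 10)),
        )
        out = out_dir / "measured_cells.csv"
        df.to_csv(out, index=False)
        produced["measured"] = out
        return [src], [out]

    if stage == "noise":
        src = Path(block.get("input") or produced["cells"])
        cells = pd.read_csv(src)
        norm = normalize_per_experiment(cells)
        frames, summaries = [], {}
        for grp in sorted(norm["group_label"].unique()):
            pc = per_cell_intrinsic_noise(norm, grp, means=block.get("means", "pooled"))
            frames.append(pc)
            summaries[grp] = summarize_noise(pc["intrinsic_noise"]).to_dict()
        noise_path = out_dir / "noise.csv"
        summary_path = out_dir / "noise_summary.json"
        pd.concat(frames, ignore_index=True).to_csv(noise_path, index=False)
        summary_path.write_text(json.dumps(summaries, indent=2))
        produced["noise"] = noise_path
        return [src], [noise_path, summary_path]

    if stage == "compare":
        src = Path(block.get("input") or produced["noise"])
        noise = pd.read_csv(src)
        labels = block.get("groups") or sorted(noise["group_label"].unique())
        samples = [
            noise.loc[noise["group_label"] == g, "intrinsic_noise"].to_numpy()
            for g in labels
        ]
        rows, report = [], {"groups": labels}
        test = block.get("test", "auto")
        if test == "auto":
            test = "mann-whitney" if len(labels) == 2 else "kruskal-dunn"
        if test == "mann-whitney":
            r = mann_whitney_u(samples[0], samples[1])
            rows.append(
                {"comparison": f"{labels[0]} vs {labels[1]}", "statistic": r.statistic,
                 "p": r.p_value, "adjusted_p": "", "label": significance_label(r.p_value)}
            )
            report["mann_whitney"] = {"U": r.statistic, "p": r.p_value, "method": r.method}
        else:
            kw = kruskal_wallis(samples)
            report["kruskal_wallis"] = {"H": kw.statistic, "df": kw.df, "p": kw.p_value}
            for r in dunns_method(samples, labels=labels):
                rows.append(
                    {"comparison": f"{r.pair[0]} vs {r.pair[1]}", "statistic": r.statistic,
                     "p": r.p_value, "adjusted_p": r.adjusted_p,
                     "label": significance_label(r.adjusted_p)}
                )
        tsv = out_dir / "comparisons.tsv"
        rep = out_dir / "comparisons.json"
        pd.DataFrame(rows).to_csv(tsv, sep="\t", index=False)
        rep.write_text(json.dumps(report, indent=2))
        return [src], [tsv, rep]

    if stage == "enrich":
        inputs = []
        if "gff" in block:
            gff_text = Path(block["gff"]).read_text()
            mae = pd.read_csv(block["mae"], sep="\t")
            terms = pd.read_csv(block["terms"], sep="\t")
            inputs = [block["gff"], block["mae"], block["terms"]]
        else:
            fx = generate_annotation_fixture(
                n_genes=int(block.get("n_genes", 1000)),
                frac_intronless=float(block.get("frac_intronless", 0.06)),
                frac_mae_intronless=float(block.get("frac_mae_intronless", 0.64)),
                frac_mae_intronful=float(block.get("frac_mae_intronful", 0.20)),
                seed=seed,
            )
            gff_text, mae, terms = fx.gff3, fx.mae_table, fx.term_map
        models = parse_gff3(gff_text)
        intronless = classify_intronless(models)
        table = crosstab_mae(intronless, mae)
        fisher = fisher_exact(table)
        background = {m.gene_id for m in models}
        term_results = term_overrepresentation(intronless, background, terms)
        tsv = out_dir / "enrichment.tsv"
        rep = out_dir / "enrichment.json"
        pd.DataFrame(
            [
                {"term_id": r.term_id, "k": r.k, "K": r.K, "m": r.m, "M": r.M,
                 "odds_ratio": r.odds_ratio, "p": r.p_value, "adjusted_p": r.adjusted_p}
                for r in term_results
            ]
        ).to_csv(tsv, sep="\t", index=False)
        rep.write_text(
            json.dumps(
                {
                    "n_genes": len(models),
                    "n_intronless": len(intronless),
                    "crosstab": table.tolist(),
                    "fisher": {"odds_ratio": fisher.odds_ratio, "p": fisher.p_value},
                },
                indent=2,
            )
        )
        return inputs, [tsv, rep]

    raise ConfigError(f"unknown stage {stage!r}")
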