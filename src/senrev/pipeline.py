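"""End-to-end orchestration: generate -> select -> score -> network -> motif
-> markers, from a single YAML configuration, with a reproducible manifest.

All randomness flows from one top-level seed; per-stage seeds are derived
deterministically from it, so two runs with the same configuration produce
byte-identical tabular outputs and identical manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression, io_formats, markers, motif, network, screen, synthdata


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults emulate the study design at reduced
    scale (sizes chosen so a full run stays interactive on one CPU)."""

    seed: int = 0
    output_dir: str = "senrev_out"

    # screen generation + scoring
    library_size: int = 190
    n_reversers: int = 28
    effect_magnitude: float = 4.0
    arms: list = field(default_factory=lambda: ["Group1", "Group2", "Group3"])
    replicates: int = 3
    controls_per_plate: int = 16
    z_threshold: float = 2.0
    min_morph_features: int = 3
    robust_z: bool = False

    # expression selection
    n_genes: int = 1000
    n_up_in_ds: int = 250
    expr_effect_size: float = 5.0
    expr_reps: int = 4
    q_threshold: float = 0.05
    top_n: int = 190

    # network expansion
    n_interactors: int = 33
    extra_edges: int = 20

    # motif enrichment
    consensus: str = synthdata.EGR2_CONSENSUS
    max_mismatches: int = 0
    n_background: int = 1000
    promoter_length: int = 500
    n_universe: int = 300
    fg_motif_fraction: float = 0.5
    bg_motif_fraction: float = 0.05

    # marker gating
    marker_cells: int = 2000
    positive_fraction: float = 0.4
    gate_method: str = "reference"
    gate_k: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def stage_seed(self, index: int) -> int:
        return (self.seed * 1000003 + index) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages (each reads/writes files so the CLI subcommands and run_pipeline
# share one code path)
# ---------------------------------------------------------------------------

def stage_generate(cfg: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Generate every synthetic input and write it under outdir/inputs."""
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    library = [f"si{i + 1:04d}" for i in range(cfg.library_size)]
    reversers = library[: cfg.n_reversers]
    shifts = {s: synthdata.reversal_effect(cfg.effect_magnitude) for s in reversers}
    effects = synthdata.EffectMap(shifts=shifts)
    spec = synthdata.LayoutSpec(
        arms=tuple(cfg.arms),
        replicates=cfg.replicates,
        controls_per_plate=cfg.controls_per_plate,
    )
    cells, layout, truth = synthdata.generate_screen(
        library, spec, synthdata.DEFAULT_PARAMS, effects, seed=cfg.stage_seed(1)
    )
    expr, planted = synthdata.generate_expression(
        cfg.n_genes, cfg.n_up_in_ds, cfg.expr_effect_size, cfg.expr_reps,
        seed=cfg.stage_seed(2),
    )
    genes = list(expr.values.index[: cfg.n_universe])
    rng = np.random.default_rng(cfg.stage_seed(3))
    plant = {
        g: 1
        if rng.random() < (cfg.fg_motif_fraction if g in set(planted) else cfg.bg_motif_fraction)
        else 0
        for g in genes
    }
    promoters = synthdata.generate_promoters(
        genes, cfg.promoter_length, plant, seed=cfg.stage_seed(4),
        motif=cfg.consensus, ensure_motif_free=True,
    )
    edges, annotation = synthdata.generate_network(
        reversers, cfg.n_interactors, cfg.extra_edges, seed=cfg.stage_seed(5)
    )

    paths = {
        "layout": indir / "plate_layout.tsv",
        "cells": indir / "cells.tsv",
        "expression": indir / "expression.tsv",
        "promoters": indir / "promoters.fasta",
        "edges": indir / "edges.tsv",
        "annotation": indir / "annotation.tsv",
        "truth_screen": indir / "truth_screen.tsv",
        "truth_expression": indir / "truth_expression.tsv",
    }
    io_formats.write_plate_map(layout, paths["layout"])
    io_formats.write_cell_table(cells, paths["cells"])
    io_formats.write_expression(expr, paths["expression"])
    io_formats.write_fasta(promoters, paths["promoters"])
    io_formats.write_edge_list(edges, paths["edges"])
    io_formats.write_annotation(annotation, paths["annotation"])
    truth.to_csv(paths["truth_screen"], sep="\t", index=False, float_format="%.4f")
    pd.DataFrame({"gene": planted}).to_csv(
        paths["truth_expression"], sep="\t", index=False
    )
    return paths


def stage_select(cfg: PipelineConfig, expression_path, outdir: Path) -> Path:
    expr = io_formats.read_expression(expression_path)
    up = expression.differential_stats(expr, "EP", "DS")
    down = expression.differential_stats(expr, "DS", "R")
    candidates = expression.select_candidates(
        up, down, q_threshold=cfg.q_threshold, top_n=cfg.top_n
    )
    out = outdir / "candidates.tsv"
    table = up.loc[candidates].rename_axis("gene").reset_index()
    table.insert(1, "rank", np.arange(1, len(table) + 1))
    table.to_csv(out, sep="\t", index=False, float_format="%.4g")
    return out


def stage_score(cfg: PipelineConfig, layout_path, cells_path, outdir: Path):
    layout = io_formats.read_plate_map(layout_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells = io_formats.read_cell_table(cells_path, layout)
    profiles = screen.aggregate_wells(cells, layout)
    z = screen.compute_zscores(profiles, layout, robust=cfg.robust_z)
    hits = screen.call_hits(
        z,
        z_threshold=cfg.z_threshold,
        min_morph_features=cfg.min_morph_features,
    )
    classes = screen.compare_arms(hits)
    summary = screen.summarize_hits(hits)
    paths = {
        "zscores": outdir / "zscores.tsv",
        "hits": outdir / "hits.tsv",
        "arm_classification": outdir / "arm_classification.tsv",
        "hit_summary": outdir / "hit_summary.tsv",
    }
    io_formats.write_zscore_matrix(z.values, paths["zscores"])
    io_formats.write_hit_table(hits, paths["hits"])
    classes.to_csv(paths["arm_classification"], sep="\t", index=False)
    summary.to_csv(paths["hit_summary"], sep="\t", index=False, float_format="%.4f")
    return paths, hits, classes


def stage_network(cfg: PipelineConfig, seeds, edges_path, annotation_path, outdir: Path):
    edges = io_formats.read_edge_list(edges_path)
    annotation = io_formats.read_annotation(annotation_path)
    result = network.expand_seeds(seeds, edges, max_interactors=cfg.n_interactors)
    cat_map, summary = network.categorize(result.merged, annotation)
    out = outdir / "network_expansion.tsv"
    rows = [
        {
            "gene": g,
            "role": "seed" if g in result.seeds else "interactor",
            "category": cat_map[g],
        }
        for g in sorted(result.merged)
    ]
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return out, result, summary


def stage_motif(cfg: PipelineConfig, foreground, promoters_path, outdir: Path):
    promoters = io_formats.read_fasta(promoters_path)
    universe = [g for g, _ in promoters]
    # keep the foreground at most half the universe (rank order preserved) so
    # disjoint size-matched background sampling stays possible
    in_universe = set(universe)
    fg = [g for g in dict.fromkeys(foreground) if g in in_universe]
    fg = fg[: len(universe) // 2]
    model = motif.MotifModel(cfg.consensus, cfg.max_mismatches)
    result = motif.enrichment_test(
        fg, universe, promoters, model,
        n_background=cfg.n_background, seed=cfg.stage_seed(6),
    )
    out = outdir / "enrichment.json"
    payload = {
        "consensus": cfg.consensus,
        "n_foreground": len(fg),
        "n_universe": len(universe),
        "observed_fraction_with_hit": result.observed,
        "background_mean": float(result.background.mean()),
        "n_background": result.n_background,
        "empirical_p": result.p_value,
    }
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return out, result


def stage_markers(cfg: PipelineConfig, outdir: Path):
    """Synthetic marker panel: gate p16/p21, quadrant table, foci comparison."""
    rng = np.random.default_rng(cfg.stage_seed(7))
    n = cfg.marker_cells
    labels = rng.random(n) < cfg.positive_fraction
    p16 = np.where(labels, rng.normal(300, 50, n), rng.normal(100, 20, n)).clip(0)
    p21 = np.where(
        rng.random(n) < cfg.positive_fraction,
        rng.normal(280, 45, n),
        rng.normal(90, 18, n),
    ).clip(0)
    reference = rng.normal(100, 20, 500).clip(0)
    g16 = markers.gate_marker(
        p16, method=cfg.gate_method, reference=reference, k=cfg.gate_k, channel="p16"
    )
    g21 = markers.gate_marker(
        p21, method=cfg.gate_method, reference=reference, k=cfg.gate_k, channel="p21"
    )
    quad = markers.quadrant_fractions(g16.calls, g21.calls)
    foci_ep = rng.poisson(1.0, 60)
    foci_ds = rng.poisson(4.0, 60)
    med_diff, p, _ = markers.compare_foci(foci_ep, foci_ds)
    out = outdir / "markers.json"
    payload = {
        "p16_positive_fraction": g16.positive_fraction,
        "p21_positive_fraction": g21.positive_fraction,
        "planted_positive_fraction": cfg.positive_fraction,
        "quadrant_fractions": quad.fractions,
        "double_negative_fraction": quad.double_negative_fraction,
        "foci_median_difference_DS_minus_EP": med_diff,
        "foci_rank_test_p": p,
    }
    out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; return the manifest dict (also written to disk)."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "status": "incomplete",
        "outputs": {},
    }
    stage = "generate"
    try:
        inputs = stage_generate(cfg, outdir)
        stage = "select"
        cand_path = stage_select(cfg, inputs["expression"], outdir)
        stage = "score"
        score_paths, hits, classes = stage_score(
            cfg, inputs["layout"], inputs["cells"], outdir
        )
        stage = "network"
        seeds = sorted(hits.loc[hits["hit"].fillna(False), "sirna"].unique())
        net_path, _, net_summary = stage_network(
            cfg, seeds, inputs["edges"], inputs["annotation"], outdir
        )
        stage = "motif"
        candidates = pd.read_csv(cand_path, sep="\t")["gene"].tolist()
        motif_path, _ = stage_motif(cfg, candidates, inputs["promoters"], outdir)
        stage = "markers"
        markers_path = stage_markers(cfg, outdir)
    except Exception as exc:  # annotate with the failing stage
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    files = {
        **{f"input_{k}": v for k, v in inputs.items()},
        "candidates": cand_path,
        **score_paths,
        "network_expansion": net_path,
        "enrichment": motif_path,
        "markers": markers_path,
    }
    manifest["outputs"] = {
        name: {"path": str(p), "sha256": _sha256(Path(p))} for name, p in files.items()
    }
    manifest["network_category_counts"] = net_summary
    manifest["status"] = "complete"
    cfg.to_yaml(outdir / "config_used.yaml")
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
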