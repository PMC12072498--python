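"""End-to-end orchestration: simulate/load -> calibrate -> genotype -> tree
-> bootstrap -> annotate -> report.

A run is fully described by a :class:`PipelineConfig` (YAML-serializable) and
a seed; rerunning with the same pair reproduces byte-identical artifacts.
The manifest records the config hash, seed, package version and per-stage
record counts so that a run can be audited without re-executing it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError
from .genotyping import StutterModel, calibrate_stutter_model, genotype_cells, qc_filter
from .io import (
    read_cells,
    read_histograms,
    write_cells,
    write_distance_matrix,
    write_histograms,
    write_matrix,
)
from .panel import STRPanel, default_panel
from .simulate import (
    SimConfig,
    default_stutter_model,
    make_calibration_library,
    simulate_dataset,
)
from .trees import (
    build_tree,
    compute_root_profile,
    encode_genotypes,
    pairwise_distance,
    write_fasta,
    write_newick,
)
from .treestats import (
    bootstrap_trees,
    branch_enrichment,
    depth_comparison,
    enrichment_table,
    tbe_support,
)

log = logging.getLogger("strlineage")


@dataclass
class PipelineConfig:
    """One pipeline run: exactly one of ``simulation`` or ``input`` is set."""

    seed: int
    simulation: SimConfig | None = None
    input: dict[str, str] | None = None  # paths: panel, histograms, cells, model
    n_loci: int = 60
    min_reads: int = 20
    min_loci_frac: float = 0.5
    calibration_reps: int = 30
    bootstrap_replicates: int = 1000
    root_group_subpopulation: str = "HSC-MPP"
    significance: float = 0.05
    depth_mode: str = "length"

    def validate(self) -> None:
        if (self.simulation is None) == (self.input is None):
            raise ConfigError("exactly one of 'simulation' or 'input' must be configured")
        if self.simulation is not None:
            self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ConfigError("config must set a seed")
        sim = raw.pop("simulation", None)
        cfg = cls(
            seed=int(raw.pop("seed")),
            simulation=SimConfig(**sim) if sim is not None else None,
            input=raw.pop("input", None),
            **raw,
        )
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "simulation": asdict(self.simulation) if self.simulation else None,
            "input": self.input,
            "n_loci": self.n_loci,
            "min_reads": self.min_reads,
            "min_loci_frac": self.min_loci_frac,
            "calibration_reps": self.calibration_reps,
            "bootstrap_replicates": self.bootstrap_replicates,
            "root_group_subpopulation": self.root_group_subpopulation,
            "significance": self.significance,
            "depth_mode": self.depth_mode,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _timepoint_group(timepoint: str) -> str:
    return "relapse" if timepoint.startswith("relapse") else "diagnosis"


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every configured stage; returns (and writes) the run manifest."""
    import numpy as np

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
    }

    # ---------------------------------------------------------------- inputs
    if config.simulation is not None:
        log.info("stage=simulate seed=%d", config.seed)
        panel = default_panel(config.n_loci)
        sim_cfg = config.simulation
        model_true = default_stutter_model(panel)
        dataset = simulate_dataset(panel, sim_cfg, model_true)
        cells, histograms = dataset.cells, dataset.histograms
        panel.to_tsv(outdir / "panel.tsv")
        write_cells(cells, outdir / "cells.tsv")
        write_histograms(histograms, outdir / "histograms.tsv")
        (outdir / "true_tree.nwk").write_text(write_newick(dataset.tree))
        log.info("stage=calibrate reps=%d", config.calibration_reps)
        rng = np.random.default_rng([config.seed, 2])
        library = make_calibration_library(
            panel, model_true, config.calibration_reps, sim_cfg.depth_reads, rng
        )
        model = calibrate_stutter_model(library, require=panel)
        manifest["stages"]["calibrate"] = {"library_entries": len(library)}
        manifest["outputs"]["true_tree"] = "true_tree.nwk"
    else:
        paths = config.input
        for key in ("panel", "histograms", "cells", "model"):
            if key not in paths:
                raise ConfigError(f"input mode requires a {key!r} path")
        panel = STRPanel.from_tsv(paths["panel"])
        histograms = read_histograms(paths["histograms"])
        cells = read_cells(paths["cells"])
        model = StutterModel.from_json(paths["model"])
    model.to_json(outdir / "model.json")
    manifest["stages"]["input"] = {
        "n_cells": len(cells),
        "n_loci": len(panel),
        "histogram_rows": int(len(histograms)),
    }

    # -------------------------------------------------------------- genotype
    log.info("stage=genotype cells=%d loci=%d", len(cells), len(panel))
    calls = genotype_cells(histograms, model, panel)
    min_loci = max(1, math.ceil(config.min_loci_frac * len(panel)))
    matrix, qc = qc_filter(calls, panel, min_reads=config.min_reads, min_loci_per_cell=min_loci)
    write_matrix(matrix, outdir / "matrix.tsv")
    (outdir / "qc.json").write_text(
        json.dumps(
            {
                "n_cells_in": qc.n_cells_in,
                "n_cells_out": qc.n_cells_out,
                "dropped_cells": qc.dropped_cells,
                "low_read_calls": qc.low_read_calls,
                "min_reads": qc.min_reads,
                "min_loci_per_cell": qc.min_loci_per_cell,
                "locus_missingness": qc.locus_missingness,
            },
            indent=1,
            sort_keys=True,
        )
    )
    manifest["stages"]["genotype"] = {
        "calls": len(calls),
        "cells_retained": qc.n_cells_out,
        "cells_dropped": len(qc.dropped_cells),
    }

    # ------------------------------------------------------------------ tree
    cell_by_id = {c.cell_id: c for c in cells}
    retained = [str(i) for i in matrix.index]
    root_group = [
        c for c in retained
        if cell_by_id[c].subpopulation == config.root_group_subpopulation
    ]
    if not root_group:
        raise ConfigError(
            f"no retained cells in root group {config.root_group_subpopulation!r}"
        )
    log.info("stage=tree cells=%d root_group=%d", len(retained), len(root_group))
    alignment = encode_genotypes(matrix, panel)
    write_fasta(alignment, outdir / "alignment.fasta")
    dist = pairwise_distance(matrix)
    write_distance_matrix(dist, outdir / "distances.tsv")
    profile = compute_root_profile(matrix, root_group, panel)
    tree = build_tree(dist, profile, matrix, panel)
    manifest["stages"]["tree"] = {"leaves": len(retained)}

    # ------------------------------------------------------------- bootstrap
    B = config.bootstrap_replicates
    if B > 0:
        log.info("stage=bootstrap B=%d", B)
        boot = bootstrap_trees(matrix, root_group, panel, B, seed=config.seed)
        supports = tbe_support(tree, boot.trees)
        mean_dropped = (
            float(np.mean(boot.dropped_locus_fraction))
            if boot.dropped_locus_fraction
            else float("nan")
        )
        manifest["stages"]["bootstrap"] = {
            "replicates_requested": B,
            "replicates_used": len(boot.trees),
            "replicates_skipped": len(boot.skipped),
            "mean_distinct_locus_dropout": round(mean_dropped, 4),
            "supported_branches": len(supports),
        }
    (outdir / "tree.nwk").write_text(write_newick(tree))
    manifest["outputs"].update(
        {
            "tree": "tree.nwk",
            "matrix": "matrix.tsv",
            "alignment": "alignment.fasta",
            "distances": "distances.tsv",
        }
    )

    # ------------------------------------------------------------ enrichment
    log.info("stage=annotate")
    timepoint_labels = {c: _timepoint_group(cell_by_id[c].timepoint) for c in retained}
    subpop_labels = {c: cell_by_id[c].subpopulation for c in retained}
    results = []
    for cat in sorted(set(timepoint_labels.values())):
        results.extend(branch_enrichment(tree, timepoint_labels, cat))
    for cat in sorted(set(subpop_labels.values())):
        results.extend(branch_enrichment(tree, subpop_labels, cat))
    table = enrichment_table(results)
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    relapse_p = table.loc[table.category == "relapse", "p_value"]
    best_relapse_p = float(relapse_p.min()) if len(relapse_p) else float("nan")
    manifest["stages"]["enrichment"] = {
        "rows": len(table),
        "best_relapse_clade_p": best_relapse_p,
        "significant": bool(best_relapse_p < config.significance),
        "significance_bound": config.significance,
    }

    # ----------------------------------------------------- depth comparison
    dx = [c for c in retained if timepoint_labels[c] == "diagnosis"]
    rx = [c for c in retained if timepoint_labels[c] == "relapse"]
    if dx and rx:
        cmp_res = depth_comparison(tree, dx, rx, mode=config.depth_mode)
        depth_report = {
            "mode": cmp_res.mode,
            "method": cmp_res.method,
            "statistic": cmp_res.statistic,
            "p_value": cmp_res.p_value,
            "mean_depth_diagnosis": sum(cmp_res.depths_a) / len(cmp_res.depths_a),
            "mean_depth_relapse": sum(cmp_res.depths_b) / len(cmp_res.depths_b),
        }
        (outdir / "depth.json").write_text(json.dumps(depth_report, indent=1, sort_keys=True))
        manifest["stages"]["depth_comparison"] = depth_report
        manifest["outputs"]["depth"] = "depth.json"

    manifest["outputs"].update({"enrichment": "enrichment.tsv", "qc": "qc.json"})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info("pipeline complete: %s", outdir)
    return manifest
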