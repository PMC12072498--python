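"""Shared fixtures: panels and one fully analyzed standard simulation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import strlineage as sl


@pytest.fixture(scope="session")
def panel60() -> sl.STRPanel:
    return sl.default_panel()


@pytest.fixture(scope="session")
def small_panel() -> sl.STRPanel:
    return sl.default_panel(6)


@dataclass
class StandardAnalysis:
    """One planted-relapse simulation carried through the full analysis."""

    panel: sl.STRPanel
    dataset: sl.SyntheticDataset
    matrix: pd.DataFrame
    tree: object  # dendropy.Tree
    timepoint_labels: dict[str, str]
    subpop_labels: dict[str, str]


def run_standard_analysis(seed: int) -> StandardAnalysis:
    """Simulate -> calibrate -> genotype -> QC -> rooted NJ tree."""
    panel = sl.default_panel()
    config = sl.SimConfig(seed=seed)
    model_true = sl.default_stutter_model(panel)
    dataset = sl.simulate_dataset(panel, config, model_true)
    rng = np.random.default_rng([seed, 2])
    library = sl.make_calibration_library(panel, model_true, 30, config.depth_reads, rng)
    model = sl.calibrate_stutter_model(library, require=panel)
    calls = sl.genotype_cells(dataset.histograms, model, panel)
    matrix, _ = sl.qc_filter(calls, panel, min_reads=20, min_loci_per_cell=30)
    by_id = {c.cell_id: c for c in dataset.cells}
    root_group = [c for c in matrix.index if by_id[str(c)].subpopulation == "HSC-MPP"]
    dist = sl.pairwise_distance(matrix)
    profile = sl.compute_root_profile(matrix, root_group, panel)
    tree = sl.build_tree(dist, profile, matrix, panel)
    timepoints = {
        str(c): ("relapse" if by_id[str(c)].timepoint.startswith("relapse") else "diagnosis")
        for c in matrix.index
    }
    subpops = {str(c): by_id[str(c)].subpopulation for c in matrix.index}
    return StandardAnalysis(
        panel=panel,
        dataset=dataset,
        matrix=matrix,
        tree=tree,
        timepoint_labels=timepoints,
        subpop_labels=subpops,
    )


@pytest.fixture(scope="session")
def standard_analysis() -> StandardAnalysis:
    return run_standard_analysis(seed=1)
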