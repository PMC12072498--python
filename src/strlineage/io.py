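"""Plain-text readers/writers for the pipeline's tabular interchange formats.

All formats are TSV: a cell table (cell_id, timepoint, subpopulation), a
long-format read-histogram table (cell_id, locus_id, repeat_count, reads), a
cells x loci genotype matrix with ``NA`` for missing calls, and a square
labeled distance matrix.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .panel import STRPanel
from .simulate import CellRecord

CELL_COLUMNS = ["cell_id", "timepoint", "subpopulation"]
HIST_COLUMNS = ["cell_id", "locus_id", "repeat_count", "reads"]


def write_cells(cells: list[CellRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(c.cell_id, c.timepoint, c.subpopulation) for c in cells],
        columns=CELL_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_cells(path: str | Path) -> list[CellRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} lacks columns {missing}")
    return [
        CellRecord(
            cell_id=str(r.cell_id),
            timepoint=str(r.timepoint),
            subpopulation=str(r.subpopulation),
        )
        for r in df.itertuples()
    ]


def write_histograms(histograms: pd.DataFrame, path: str | Path) -> None:
    histograms[HIST_COLUMNS].to_csv(path, sep="\t", index=False)


def read_histograms(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"histogram table {path} lacks columns {missing}")
    df["cell_id"] = df["cell_id"].astype(str)
    df["locus_id"] = df["locus_id"].astype(str)
    return df


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "cell_id"
    # genotypes are integral; keep them readable in the TSV
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_matrix(path: str | Path, panel: STRPanel | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="cell_id", na_values=["NA"])
    df.index = df.index.astype(str)
    if panel is not None:
        df = df[panel.ids]
    return df.astype(float)


def write_distance_matrix(dist: pd.DataFrame, path: str | Path) -> None:
    out = dist.copy()
    out.index.name = "cell_id"
    out.to_csv(path, sep="\t")
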