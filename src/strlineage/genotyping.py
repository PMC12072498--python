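"""Stutter-aware STR genotyping.

Single-cell whole-genome-amplified STR reads carry characteristic *stutter*:
reads whose repeat count differs from the template's, predominantly by
contraction. Genotyping therefore compares each observed read histogram
against *model stutter patterns* — one expected frequency vector per
(repeat-unit length, true repeat count) — and calls the candidate whose
pattern is nearest in Euclidean distance.

Patterns live on a window of offsets relative to the true repeat count
(default 5 units below to 2 above, reflecting contraction-biased slippage).
The observed histogram is re-aligned and re-normalized on that window for
every candidate, so the nearest-neighbor search is an exact linear scan over
the candidate repeat range; there is no approximate index.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationGapError, EmptyMatrixError
from .panel import STRLocus, STRPanel

#: default window: offsets -5 .. +2 around the true repeat count
DEFAULT_WINDOW = (5, 2)

ReadHistogram = Mapping[int, int]


def _window_offsets(window: tuple[int, int]) -> np.ndarray:
    below, above = window
    return np.arange(-below, above + 1)


def hist_to_window_vector(
    hist: ReadHistogram, center: int, window: tuple[int, int] = DEFAULT_WINDOW
) -> np.ndarray:
    """Project a read histogram onto the offset window around ``center``.

    Reads outside the window are truncated; the result is normalized to sum
    to 1 when any in-window reads exist, otherwise it is all zeros.
    """
    below, above = window
    vec = np.zeros(below + above + 1, dtype=float)
    for repeat, reads in hist.items():
        off = repeat - center
        if -below <= off <= above:
            vec[off + below] += reads
    total = vec.sum()
    if total > 0:
        vec /= total
    return vec


@dataclass
class StutterModel:
    """Expected stutter frequency vectors keyed by (unit_len, true repeats).

    Each pattern is a probability vector over the offset window
    ``-window[0] .. +window[1]`` relative to the true repeat count.
    """

    patterns: dict[tuple[int, int], np.ndarray]
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        width = self.window[0] + self.window[1] + 1
        for key, vec in self.patterns.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (width,):
                raise ValueError(f"pattern {key} has shape {vec.shape}, expected ({width},)")
            if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"pattern {key} is not a probability vector")
            self.patterns[key] = vec

    @property
    def offsets(self) -> np.ndarray:
        return _window_offsets(self.window)

    def pattern(self, unit_len: int, repeats: int) -> np.ndarray:
        try:
            return self.patterns[(unit_len, repeats)]
        except KeyError:
            raise CalibrationGapError([(unit_len, repeats)]) from None

    def covers(self, panel: STRPanel) -> list[tuple[int, int]]:
        """Return the (unit_len, repeats) pairs required by ``panel`` but absent."""
        needed = {(l.unit_len, r) for l in panel for r in l.repeat_range}
        return sorted(needed - set(self.patterns))

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str | Path) -> None:
        payload = {
            "window": list(self.window),
            "patterns": [
                {"unit_len": u, "repeats": r, "frequencies": vec.tolist()}
                for (u, r), vec in sorted(self.patterns.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "StutterModel":
        payload = json.loads(Path(path).read_text())
        window = tuple(payload["window"])
        patterns = {
            (int(p["unit_len"]), int(p["repeats"])): np.asarray(p["frequencies"], float)
            for p in payload["patterns"]
        }
        return cls(patterns=patterns, window=window)  # type: ignore[arg-type]


def identity_stutter_model(
    panel: STRPanel, window: tuple[int, int] = DEFAULT_WINDOW
) -> StutterModel:
    """Noise-free model: all read mass at the true repeat count."""
    below, _ = window
    width = window[0] + window[1] + 1
    patterns = {}
    for locus in panel:
        for r in locus.repeat_range:
            vec = np.zeros(width)
            vec[below] = 1.0
            patterns[(locus.unit_len, r)] = vec
    return StutterModel(patterns=patterns, window=window)


# ---------------------------------------------------------------- calibration

@dataclass(frozen=True)
class CalibrationEntry:
    """One labeled synthetic-library observation: a histogram of known genotype."""

    locus_id: str
    unit_len: int
    true_repeats: int
    histogram: dict[int, int]


def calibrate_stutter_model(
    library: Iterable[CalibrationEntry],
    window: tuple[int, int] = DEFAULT_WINDOW,
    require: STRPanel | None = None,
) -> StutterModel:
    """Estimate model stutter patterns from a labeled calibration library.

    For every (unit_len, true repeats) label, each histogram is normalized and
    aligned on the offset window around its true repeat count; the pattern is
    the mean of those vectors, re-normalized. Labels pooled across loci that
    share a repeat-unit length.

    ``require`` (a panel) makes missing label coverage a
    :class:`~strlineage.errors.CalibrationGapError`.
    """
    sums: dict[tuple[int, int], np.ndarray] = {}
    counts: dict[tuple[int, int], int] = {}
    for entry in library:
        vec = hist_to_window_vector(entry.histogram, entry.true_repeats, window)
        if vec.sum() == 0:
            continue  # empty or fully out-of-window histogram: uninformative
        key = (entry.unit_len, entry.true_repeats)
        if key in sums:
            sums[key] += vec
            counts[key] += 1
        else:
            sums[key] = vec.copy()
            counts[key] = 1
    patterns = {}
    for key, total in sums.items():
        mean = total / counts[key]
        patterns[key] = mean / mean.sum()
    if require is not None:
        needed = {(l.unit_len, r) for l in require for r in l.repeat_range}
        missing = needed - set(patterns)
        if missing:
            raise CalibrationGapError(missing)
    return StutterModel(patterns=patterns, window=window)


# ----------------------------------------------------------------- genotyping

@dataclass
class GenotypeCall:
    """One per-cell, per-locus repeat-count call."""

    cell_id: str
    locus_id: str
    called_repeats: int
    match_distance: float
    n_reads: int
    pass_qc: bool = True


def genotype_locus(
    hist: ReadHistogram,
    model: StutterModel,
    locus: STRLocus,
    cell_id: str = "",
) -> GenotypeCall | None:
    """Call the repeat count at one locus by nearest model stutter pattern.

    Every candidate repeat in the locus range is scored by the Euclidean
    distance between the candidate's model pattern and the observed histogram
    normalized on the candidate's window; the minimizing candidate wins, with
    ties broken toward the smaller repeat count. An empty histogram yields a
    no-call (``None``), not an exception.
    """
    n_reads = int(sum(hist.values()))
    if n_reads == 0:
        return None
    best_r = None
    best_d = math.inf
    for r in locus.repeat_range:
        pattern = model.pattern(locus.unit_len, r)
        obs = hist_to_window_vector(hist, r, model.window)
        d = float(np.linalg.norm(obs - pattern))
        if d < best_d - 1e-12:  # strict improvement keeps the smaller repeat on ties
            best_d = d
            best_r = r
    assert best_r is not None
    return GenotypeCall(
        cell_id=cell_id,
        locus_id=locus.locus_id,
        called_repeats=best_r,
        match_distance=best_d,
        n_reads=n_reads,
    )


def genotype_cells(
    histograms: pd.DataFrame,
    model: StutterModel,
    panel: STRPanel,
) -> list[GenotypeCall]:
    """Genotype a long-format histogram table (cell_id, locus_id, repeat_count, reads)."""
    calls: list[GenotypeCall] = []
    grouped = histograms.groupby(["cell_id", "locus_id"], sort=True)
    for (cell_id, locus_id), grp in grouped:
        hist = dict(zip(grp["repeat_count"].astype(int), grp["reads"].astype(int)))
        call = genotype_locus(hist, model, panel[locus_id], cell_id=str(cell_id))
        if call is not None:
            calls.append(call)
    return calls


# ------------------------------------------------------------------- QC stage

@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    dropped_cells: list[str]
    locus_missingness: dict[str, float]  # fraction of retained cells missing each locus
    min_reads: int
    min_loci_per_cell: int
    low_read_calls: int = 0


def qc_filter(
    calls: Sequence[GenotypeCall],
    panel: STRPanel,
    min_reads: int = 20,
    min_loci_per_cell: int | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Filter calls into a cells x loci genotype matrix.

    Calls backed by fewer than ``min_reads`` reads become missing; cells with
    fewer than ``min_loci_per_cell`` surviving loci are dropped entirely.
    ``min_loci_per_cell`` defaults to half the panel (rounded up). Columns are
    in panel order; missing entries are NaN.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if min_loci_per_cell is None:
        min_loci_per_cell = math.ceil(len(panel) / 2)
    if min_loci_per_cell < 1:
        raise ValueError("min_loci_per_cell must be >= 1")

    cell_ids: list[str] = []
    for c in calls:
        if c.cell_id not in cell_ids:
            cell_ids.append(c.cell_id)
    matrix = pd.DataFrame(np.nan, index=cell_ids, columns=panel.ids, dtype=float)
    low_reads = 0
    for c in calls:
        if c.n_reads >= min_reads:
            c.pass_qc = True
            matrix.loc[c.cell_id, c.locus_id] = c.called_repeats
        else:
            c.pass_qc = False
            low_reads += 1

    coverage = matrix.notna().sum(axis=1)
    keep = coverage >= min_loci_per_cell
    dropped = [str(c) for c in matrix.index[~keep]]
    matrix = matrix.loc[keep]
    if matrix.empty:
        raise EmptyMatrixError(
            f"all {len(cell_ids)} cells dropped at min_reads={min_reads}, "
            f"min_loci_per_cell={min_loci_per_cell}"
        )
    missingness = (1.0 - matrix.notna().mean(axis=0)).to_dict()
    report = QCReport(
        n_cells_in=len(cell_ids),
        n_cells_out=int(keep.sum()),
        dropped_cells=dropped,
        locus_missingness=missingness,
        min_reads=min_reads,
        min_loci_per_cell=min_loci_per_cell,
        low_read_calls=low_reads,
    )
    matrix.index.name = "cell_id"
    return matrix, report
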