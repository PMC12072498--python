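"""Synthetic single-cell STR data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a clonal expansion recorded as a binary cell-division history, STR
genotypes mutating by stepwise slippage (symmetric +/-1 repeat steps by
default), and per-cell sequencing rendered as stutter-contaminated read
histograms with locus dropout. Two sampling waves are drawn — diagnosis cells
scattered over the expansion, relapse cells concentrated in one designated
late subclone (the "planted" relapse clade) — and every sampled cell carries
a hematopoietic subpopulation label so that clade-enrichment statistics have
ground truth to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigError, SizingError
from .genotyping import (
    DEFAULT_WINDOW,
    CalibrationEntry,
    StutterModel,
    _window_offsets,
)
from .panel import STRPanel

TIMEPOINTS = ("diagnosis", "relapse1", "relapse2")
SUBPOPULATIONS = ("HSC-MPP", "MLP", "GMP", "CMP-MEP", "bulk", "CD34", "other")

#: default subpopulation composition; the planted relapse clade is dominated
#: by lymphoid/myeloid progenitors while the background mixes all fractions.
DEFAULT_SUBPOP_SCHEME: dict[str, dict[str, float]] = {
    "clade": {"MLP": 0.5, "GMP": 0.5},
    "background": {
        "HSC-MPP": 0.28,
        "MLP": 0.22,
        "GMP": 0.22,
        "CMP-MEP": 0.14,
        "bulk": 0.07,
        "CD34": 0.07,
    },
}


@dataclass
class SimConfig:
    """Parameters of one simulated clonal expansion + sampling experiment.

    Defaults define the standard planted-relapse experiment: ~40 sampled
    cells over 14 division generations, a per-locus per-division slippage
    probability of 0.02, 80% of relapse cells forced into one late subclone,
    50x read depth and 5% locus dropout.
    """

    n_divisions: int = 14
    mu: float = 0.02
    step_probs: dict[int, float] = dc_field(default_factory=lambda: {1: 0.5, -1: 0.5})
    n_diagnosis: int = 20
    n_relapse: int = 20
    relapse_clade_fraction: float = 0.8
    depth_reads: int = 50
    dropout_rate: float = 0.05
    seed: int = 0
    diagnosis_divisions: int | None = None  # default: ~65% of n_divisions
    subpop_scheme: dict[str, dict[str, float]] | None = None
    min_root_group: int = 2  # background cells guaranteed the HSC-MPP label
    poisson_depth: bool = False

    @property
    def dx_divisions(self) -> int:
        """Generation at which the diagnosis wave is sampled.

        Relapse cells are sampled at ``n_divisions``; the diagnosis wave is
        earlier, so diagnosis cells carry fewer accumulated mutations and sit
        shallower in the reconstructed tree.
        """
        if self.diagnosis_divisions is not None:
            return self.diagnosis_divisions
        return max(1, round(0.65 * self.n_divisions))

    def validate(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ConfigError(f"mu must be in [0,1], got {self.mu}")
        if not (0.0 <= self.relapse_clade_fraction <= 1.0):
            raise ConfigError("relapse_clade_fraction must be in [0,1]")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigError("dropout_rate must be in [0,1]")
        for name in ("n_divisions", "n_diagnosis", "n_relapse", "depth_reads"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not (1 <= self.dx_divisions <= self.n_divisions):
            raise ConfigError(
                f"diagnosis_divisions must be in [1, n_divisions], got {self.dx_divisions}"
            )
        total = sum(self.step_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"step_probs must sum to 1, got {total}")
        if self.step_probs.get(0, 0.0) != 0.0:
            raise ConfigError("step_probs must assign zero probability to step 0")

    @property
    def scheme(self) -> dict[str, dict[str, float]]:
        return self.subpop_scheme or DEFAULT_SUBPOP_SCHEME


@dataclass
class CellRecord:
    """One sampled cell: identity, annotations, and (simulation) true genotype."""

    cell_id: str
    timepoint: str
    subpopulation: str
    true_genotype: np.ndarray | None = None


# ----------------------------------------------------------------- mutation

def mutate_genotype(
    parent: np.ndarray,
    panel: STRPanel,
    mu: float,
    step_probs: Mapping[int, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """One cell division's worth of stepwise slippage.

    Each locus independently mutates with probability ``mu`` by a signed step
    drawn from ``step_probs``; results are clamped to the locus repeat range.
    """
    child = np.array(parent, dtype=int, copy=True)
    hits = np.flatnonzero(rng.random(len(child)) < mu)
    if hits.size:
        steps = np.array(sorted(step_probs), dtype=int)
        probs = np.array([step_probs[s] for s in sorted(step_probs)], dtype=float)
        drawn = rng.choice(steps, size=hits.size, p=probs)
        child[hits] += drawn
        for i in hits:
            locus = panel[int(i)]
            child[i] = min(max(child[i], locus.min_repeats), locus.max_repeats)
    return child


# ------------------------------------------------------------ stutter model

def default_stutter_model(
    panel: STRPanel, window: tuple[int, int] = DEFAULT_WINDOW
) -> StutterModel:
    """Geometric contraction-biased stutter, stronger at longer repeats.

    The per-unit contraction rate grows linearly with the repeat count
    (slippage is length-dependent) and mononucleotide runs stutter more than
    dinucleotide ones; expansion stutter is rare. Mass at offsets that would
    put the observed repeat below 1 is truncated before normalization.
    """
    offsets = _window_offsets(window)
    patterns: dict[tuple[int, int], np.ndarray] = {}
    params = {1: (0.06, 0.012, 0.04), 2: (0.04, 0.008, 0.02)}
    needed = {(l.unit_len, r) for l in panel for r in l.repeat_range}
    for unit_len, r in sorted(needed):
        base, slope, up = params[unit_len]
        down = min(base + slope * r, 0.35)
        weights = np.empty(len(offsets))
        for i, off in enumerate(offsets):
            if off == 0:
                weights[i] = 1.0
            elif off < 0:
                weights[i] = down ** (-off)
            else:
                weights[i] = up ** off
            if r + off < 1:
                weights[i] = 0.0
        patterns[(unit_len, r)] = weights / weights.sum()
    return StutterModel(patterns=patterns, window=window)


# ------------------------------------------------------------------- reads

def simulate_reads(
    genotype: Sequence[int],
    panel: STRPanel,
    model: StutterModel,
    depth_reads: int,
    dropout_rate: float,
    rng: np.random.Generator,
    poisson_depth: bool = False,
) -> dict[str, dict[int, int]]:
    """Render a genotype as per-locus stutter-contaminated read histograms.

    Each non-dropped locus draws its reads multinomially from the model
    stutter pattern of the true repeat count: fixed ``depth_reads`` total by
    default, Poisson-distributed depth when ``poisson_depth`` is set. Dropped
    loci get empty histograms.
    """
    offsets = model.offsets
    out: dict[str, dict[int, int]] = {}
    for i, locus in enumerate(panel):
        if rng.random() < dropout_rate:
            out[locus.locus_id] = {}
            continue
        r = int(genotype[i])
        pattern = model.pattern(locus.unit_len, r)
        depth = int(rng.poisson(depth_reads)) if poisson_depth else depth_reads
        if depth == 0:
            out[locus.locus_id] = {}
            continue
        counts = rng.multinomial(depth, pattern)
        hist = {int(r + off): int(c) for off, c in zip(offsets, counts) if c > 0}
        out[locus.locus_id] = hist
    return out


def make_calibration_library(
    panel: STRPanel,
    model: StutterModel,
    reps_per_genotype: int,
    depth_reads: int,
    rng: np.random.Generator,
) -> list[CalibrationEntry]:
    """Labeled histograms spanning every candidate genotype of every locus.

    Emulates a synthetic spike-in library: for each locus, every repeat count
    in its modeled range is sequenced ``reps_per_genotype`` times at
    ``depth_reads`` depth through the same stutter process as real cells.
    """
    if reps_per_genotype < 1:
        raise ConfigError("reps_per_genotype must be >= 1")
    offsets = model.offsets
    entries: list[CalibrationEntry] = []
    for locus in panel:
        for r in locus.repeat_range:
            pattern = model.pattern(locus.unit_len, r)
            for _ in range(reps_per_genotype):
                counts = rng.multinomial(depth_reads, pattern)
                hist = {int(r + off): int(c) for off, c in zip(offsets, counts) if c > 0}
                entries.append(
                    CalibrationEntry(
                        locus_id=locus.locus_id,
                        unit_len=locus.unit_len,
                        true_repeats=r,
                        histogram=hist,
                    )
                )
    return entries


# ------------------------------------------------------------------ lineage

def _sample_distinct(rng: np.random.Generator, low: int, high: int, k: int) -> list[int]:
    """k distinct integers from [low, high), order of first draw preserved."""
    if high - low < k:
        raise SizingError(f"cannot draw {k} distinct leaves from a space of {high - low}")
    if high - low <= 4 * k:  # dense case: explicit permutation
        return [int(x) for x in rng.permutation(np.arange(low, high))[:k]]
    seen: set[int] = set()
    out: list[int] = []
    while len(out) < k:
        x = int(rng.integers(low, high))
        if x not in seen:
            seen.add(x)
            out.append(x)
    return out


class _TrieNode:
    __slots__ = ("children", "genotype", "cell_id", "depth")

    def __init__(self, depth: int):
        self.children: dict[int, _TrieNode] = {}
        self.genotype: np.ndarray | None = None
        self.cell_id: str | None = None
        self.depth = depth


def _planted_depth(n_divisions: int, n_forced: int) -> int:
    """Depth of the designated relapse subclone's founding division."""
    if n_forced <= 0:
        return 0
    need = math.ceil(math.log2(n_forced)) if n_forced > 1 else 0
    return max(1, n_divisions - need - 1)


def simulate_lineage(
    panel: STRPanel, config: SimConfig
) -> tuple[dendropy.Tree, list[CellRecord]]:
    """Simulate a clonal expansion and sample labeled cells from it.

    Returns the true lineage tree over the sampled cells (rooted at the
    founder, edge lengths in cell divisions, the planted relapse subclone's
    ancestor labeled ``planted``) and the list of :class:`CellRecord` with
    true genotypes in panel order.

    Relapse cells: at least ``ceil(relapse_clade_fraction * n_relapse)`` are
    drawn from one designated subclone founded ``_planted_depth`` divisions
    after the root; all other cells are drawn outside it, so every leaf of the
    planted clade carries a relapse label.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_div = config.n_divisions
    g = config.dx_divisions  # diagnosis wave is sampled at this earlier generation
    n_total = config.n_diagnosis + config.n_relapse

    n_forced = math.ceil(config.relapse_clade_fraction * config.n_relapse)
    d = _planted_depth(n_div, n_forced)
    clade_size = 2 ** (n_div - d)  # planted prefix = d leading zero bits
    if clade_size < n_forced:
        raise SizingError(
            f"{n_div} divisions cannot host a planted clade of {n_forced} leaves"
        )
    # diagnosis paths are g bits; exclude the region ancestral to / inside the clade
    dx_excluded = 2 ** (g - d) if g > d else 1
    if 2**g - dx_excluded < config.n_diagnosis:
        raise SizingError(
            f"diagnosis wave at generation {g} holds only {2**g - dx_excluded} "
            f"eligible lineages; cannot sample {config.n_diagnosis}"
        )
    n_free = config.n_relapse - n_forced
    if 2**n_div - clade_size < n_free:
        raise SizingError("division history too small for the relapse background")

    forced = _sample_distinct(rng, 0, clade_size, n_forced) if n_forced else []
    diagnosis = _sample_distinct(rng, dx_excluded, 2**g, config.n_diagnosis)
    dx_prefixes = set(diagnosis)
    # free relapse cells: full-depth lineages outside the clade that do not
    # pass through a sampled (hence removed) diagnosis cell
    free_relapse: list[int] = []
    seen: set[int] = set()
    attempts = 0
    while len(free_relapse) < n_free:
        attempts += 1
        if attempts > 10000 * max(n_free, 1):
            raise SizingError("cannot place relapse cells outside sampled diagnosis lineages")
        x = int(rng.integers(clade_size, 2**n_div))
        if x in seen or (x >> (n_div - g)) in dx_prefixes:
            continue
        seen.add(x)
        free_relapse.append(x)

    # --- assemble cells in a fixed order: diagnosis first, then relapse.
    # A path is the bit tuple of a cell's division history; diagnosis paths
    # are shorter because that wave was drawn earlier in the expansion.
    def _path(value: int, nbits: int) -> tuple[int, ...]:
        return tuple((value >> (nbits - 1 - i)) & 1 for i in range(nbits))

    assignments: list[tuple[tuple[int, ...], str, bool]] = []
    for leaf_int in diagnosis:
        assignments.append((_path(leaf_int, g), "diagnosis", False))
    for leaf_int in forced:
        assignments.append((_path(leaf_int, n_div - d), "relapse1", True))
    for leaf_int in free_relapse:
        assignments.append((_path(leaf_int, n_div), "relapse1", False))
    # forced paths above are clade-relative; prepend the planted zero prefix
    assignments = [
        ((0,) * d + path, tp, True) if in_clade else (path, tp, False)
        for path, tp, in_clade in assignments
    ]

    cells: list[CellRecord] = []
    path_to_cell: dict[tuple[int, ...], str] = {}
    n_dx = n_rx = 0
    scheme = config.scheme
    background_subpops: list[int] = []  # indices of cells eligible for HSC-MPP
    for path, timepoint, in_clade in assignments:
        if timepoint == "diagnosis":
            cell_id = f"dx{n_dx:03d}"
            n_dx += 1
        else:
            cell_id = f"rx{n_rx:03d}"
            n_rx += 1
        table = scheme["clade"] if in_clade else scheme["background"]
        labels = sorted(table)
        probs = np.array([table[l] for l in labels], float)
        subpop = str(rng.choice(labels, p=probs / probs.sum()))
        if not in_clade:
            background_subpops.append(len(cells))
        cells.append(CellRecord(cell_id=cell_id, timepoint=timepoint, subpopulation=subpop))
        path_to_cell[path] = cell_id

    # guarantee a usable root group: relabel background cells to HSC-MPP if scarce
    have = [i for i in background_subpops if cells[i].subpopulation == "HSC-MPP"]
    deficit = config.min_root_group - len(have)
    if deficit > 0:
        pool = [i for i in background_subpops if cells[i].subpopulation != "HSC-MPP"]
        for i in pool[:deficit]:
            cells[i].subpopulation = "HSC-MPP"

    # --- build the division trie over sampled leaf paths (first division first)
    root = _TrieNode(0)
    for path, _, _ in assignments:
        node = root
        for bit in path:
            if bit not in node.children:
                node.children[bit] = _TrieNode(node.depth + 1)
            node = node.children[bit]
        node.cell_id = path_to_cell[path]

    # --- evolve genotypes along the trie, deterministic DFS (bit 0 first)
    root.genotype = np.array([l.ref_repeats for l in panel], dtype=int)
    stack = [root]
    while stack:
        node = stack.pop()
        for bit in sorted(node.children, reverse=True):  # pop order: bit 0 first
            child = node.children[bit]
            child.genotype = mutate_genotype(
                node.genotype, panel, config.mu, config.step_probs, rng
            )
            stack.append(child)
    geno_by_cell: dict[str, np.ndarray] = {}

    def _collect(node: _TrieNode) -> None:
        if node.cell_id is not None:
            geno_by_cell[node.cell_id] = node.genotype
        for child in node.children.values():
            _collect(child)

    _collect(root)
    for cell in cells:
        cell.true_genotype = geno_by_cell[cell.cell_id]

    # --- collapse unary chains into the true tree's NEWICK
    planted_prefix_depth = d if n_forced else None

    # mark only the first (shallowest) branching node inside the planted prefix
    nonlocal_seen = [False]

    def _newick_marked(node: _TrieNode, edge: int, on_planted_path: bool) -> str:
        while len(node.children) == 1 and node.cell_id is None:
            (child_bit,) = node.children.keys()
            child = node.children[child_bit]
            if on_planted_path and child_bit != 0 and node.depth < (planted_prefix_depth or 0):
                on_planted_path = False
            edge += child.depth - node.depth
            node = child
        if not node.children:
            return f"{node.cell_id}:{edge}"
        label = ""
        if (
            planted_prefix_depth is not None
            and on_planted_path
            and node.depth >= planted_prefix_depth
            and not nonlocal_seen[0]
        ):
            label = "planted"
            nonlocal_seen[0] = True
        parts = []
        for b in sorted(node.children):
            child = node.children[b]
            child_on_path = (
                on_planted_path and (b == 0 or node.depth >= (planted_prefix_depth or 0))
            )
            parts.append(_newick_marked(child, child.depth - node.depth, child_on_path))
        return f"({','.join(parts)}){label}:{edge}"

    newick = _newick_marked(root, 0, planted_prefix_depth is not None) + ";"
    tree = dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True
    )
    return tree, cells


# --------------------------------------------------------------- full dataset

@dataclass
class SyntheticDataset:
    """Everything one simulated experiment produced."""

    tree: dendropy.Tree
    cells: list[CellRecord]
    histograms: pd.DataFrame  # long format: cell_id, locus_id, repeat_count, reads
    model: StutterModel
    panel: STRPanel
    config: SimConfig


def simulate_dataset(
    panel: STRPanel,
    config: SimConfig,
    model: StutterModel | None = None,
) -> SyntheticDataset:
    """Simulate lineage + genotypes, then sequence every cell."""
    if model is None:
        model = default_stutter_model(panel)
    tree, cells = simulate_lineage(panel, config)
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    for cell in cells:
        hists = simulate_reads(
            cell.true_genotype,
            panel,
            model,
            config.depth_reads,
            config.dropout_rate,
            rng,
            poisson_depth=config.poisson_depth,
        )
        for locus_id, hist in hists.items():
            for repeat, reads in sorted(hist.items()):
                rows.append((cell.cell_id, locus_id, repeat, reads))
    histograms = pd.DataFrame(rows, columns=["cell_id", "locus_id", "repeat_count", "reads"])
    return SyntheticDataset(
        tree=tree, cells=cells, histograms=histograms, model=model, panel=panel, config=config
    )
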