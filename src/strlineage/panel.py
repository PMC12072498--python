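"""STR panel definitions.

A panel is an *ordered* list of short-tandem-repeat loci. The order is
canonical: genotype vectors, encoded alignments and matrix columns all follow
it, so two runs over the same panel file are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import PanelError

_PANEL_COLUMNS = ["locus_id", "unit_len", "ref_repeats", "min_repeats", "max_repeats"]


@dataclass(frozen=True)
class STRLocus:
    """One microsatellite locus.

    Parameters
    ----------
    locus_id
        Unique name within the panel.
    unit_len
        Repeat-unit length in bases; 1 (mononucleotide) or 2 (dinucleotide).
    ref_repeats
        Repeat count in the reference genome; the simulated founder genotype.
    min_repeats, max_repeats
        Bounds of the modeled repeat range (inclusive). Genotype calls and
        simulated mutations are confined to this range.
    """

    locus_id: str
    unit_len: int
    ref_repeats: int
    min_repeats: int
    max_repeats: int

    def __post_init__(self) -> None:
        if self.unit_len not in (1, 2):
            raise PanelError(f"{self.locus_id}: unit_len must be 1 or 2, got {self.unit_len}")
        if self.min_repeats < 1:
            raise PanelError(f"{self.locus_id}: min_repeats must be >= 1")
        if not (self.min_repeats <= self.ref_repeats <= self.max_repeats):
            raise PanelError(
                f"{self.locus_id}: need min_repeats <= ref_repeats <= max_repeats, "
                f"got {self.min_repeats}, {self.ref_repeats}, {self.max_repeats}"
            )

    @property
    def repeat_range(self) -> range:
        """All candidate repeat counts at this locus (inclusive of both ends)."""
        return range(self.min_repeats, self.max_repeats + 1)


class STRPanel:
    """Ordered, immutable collection of :class:`STRLocus`."""

    def __init__(self, loci: Iterable[STRLocus]):
        self._loci = tuple(loci)
        if not self._loci:
            raise PanelError("panel must contain at least one locus")
        ids = [l.locus_id for l in self._loci]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate locus ids in panel: {dupes}")
        self._index = {l.locus_id: i for i, l in enumerate(self._loci)}

    def __len__(self) -> int:
        return len(self._loci)

    def __iter__(self) -> Iterator[STRLocus]:
        return iter(self._loci)

    def __getitem__(self, key) -> STRLocus:
        if isinstance(key, str):
            return self._loci[self._index[key]]
        return self._loci[key]

    @property
    def ids(self) -> list[str]:
        return [l.locus_id for l in self._loci]

    def position(self, locus_id: str) -> int:
        return self._index[locus_id]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_tsv(cls, path: str | Path) -> "STRPanel":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelError(f"panel file {path} lacks columns {missing}")
        loci = [
            STRLocus(
                locus_id=str(row.locus_id),
                unit_len=int(row.unit_len),
                ref_repeats=int(row.ref_repeats),
                min_repeats=int(row.min_repeats),
                max_repeats=int(row.max_repeats),
            )
            for row in df.itertuples()
        ]
        return cls(loci)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [
                (l.locus_id, l.unit_len, l.ref_repeats, l.min_repeats, l.max_repeats)
                for l in self._loci
            ],
            columns=_PANEL_COLUMNS,
        )
        df.to_csv(path, sep="\t", index=False)


def default_panel(n_loci: int = 60, half_width: int = 8) -> STRPanel:
    """Deterministic mixed mono/di panel emulating a targeted STR capture set.

    Alternates mono- and dinucleotide loci. Reference repeat counts cycle over
    10-25 (mono) and 8-19 (di) so that calibration must span many distinct
    genotypes; each locus models ``ref_repeats +/- half_width`` repeat counts.
    """
    loci = []
    for i in range(n_loci):
        if i % 2 == 0:
            unit, ref = 1, 10 + (i // 2) % 16
            tag = "M"
        else:
            unit, ref = 2, 8 + (i // 2) % 12
            tag = "D"
        loci.append(
            STRLocus(
                locus_id=f"STR{tag}{i:03d}",
                unit_len=unit,
                ref_repeats=ref,
                min_repeats=max(1, ref - half_width),
                max_repeats=ref + half_width,
            )
        )
    return STRPanel(loci)
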