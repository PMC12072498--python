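"""Exception hierarchy for strlineage."""


class StrLineageError(Exception):
    """Base class for all package-specific errors."""


class PanelError(StrLineageError):
    """Invalid STR panel definition."""


class SizingError(StrLineageError):
    """A simulated division history is too small to host the requested leaves."""


class CalibrationGapError(StrLineageError):
    """The calibration library does not cover every candidate genotype.

    ``missing`` lists the absent ``(unit_len, repeat_count)`` pairs.
    """

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "calibration library is missing model patterns for "
            f"(unit_len, repeats): {self.missing}"
        )


class EmptyMatrixError(StrLineageError):
    """QC filtering removed every cell."""


class UncomputableDistanceError(StrLineageError):
    """A cell pair shares no co-genotyped locus, so no distance exists.

    ``pair`` holds the offending ``(cell_a, cell_b)`` ids.
    """

    def __init__(self, pair):
        self.pair = tuple(pair)
        super().__init__(
            f"no shared genotyped loci between cells {self.pair[0]!r} and "
            f"{self.pair[1]!r}; distance undefined"
        )


class DegenerateTreeError(StrLineageError):
    """Fewer than three leaves: no informative tree can be built."""


class NewickParseError(StrLineageError):
    """Malformed NEWICK input."""


class ConfigError(StrLineageError):
    """Invalid configuration value."""
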