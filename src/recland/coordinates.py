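"""Interval grids and synaptonemal-complex (SC) axis <-> genomic coordinate conversion.

Pachytene SC axes have an approximately constant DNA packing ratio, so a
position expressed as a fraction of total axis length maps linearly onto the
genome assembly.  This module builds fixed-size interval grids over
chromosomes (the common coordinate frame for every downstream track) and
converts axis fractions into base pairs and interval indices, honouring a
per-chromosome orientation flag used to match centromere-telomere orientation
between karyotypes.

Conventions: coordinates are 0-based half-open; the tip of the short arm sits
at position 0; a position exactly at the chromosome end closes into the final
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "ChromosomeModel",
    "IntervalGrid",
    "HomologyPair",
    "HomologyMap",
    "MissingSCLengthError",
    "DEFAULT_INTERVAL_SIZE",
    "build_interval_grid",
    "interval_physical_length",
    "sc_fraction_to_bp",
    "bp_to_interval_index",
]

DEFAULT_INTERVAL_SIZE = 2_500_000

Orientation = Literal["forward", "inverted"]


class MissingSCLengthError(ValueError):
    """Raised when an operation needs a mean SC length that was not configured."""


@dataclass(frozen=True)
class ChromosomeModel:
    """Static description of one chromosome.

    Parameters
    ----------
    name:
        Chromosome identifier (must match FASTA / annotation / focus-table names).
    assembly_length:
        Assembly length in bp; must be positive.
    mean_sc_length:
        Mean synaptonemal-complex axis length in micrometres, if measured.
    centromere_position:
        Centromere position in bp, if known; must lie within the chromosome.
    orientation:
        ``"forward"`` or ``"inverted"``.  Inverted chromosomes have their axis
        fractions flipped (f -> 1 - f) before genomic scaling, so that the
        short-arm tip of the *matched* karyotype sits at 0.
    """

    name: str
    assembly_length: int
    mean_sc_length: Optional[float] = None
    centromere_position: Optional[int] = None
    orientation: Orientation = "forward"

    def __post_init__(self) -> None:
        if self.assembly_length <= 0:
            raise ValueError(
                f"assembly_length must be > 0, got {self.assembly_length} "
                f"for chromosome {self.name!r}"
            )
        if self.mean_sc_length is not None and self.mean_sc_length <= 0:
            raise ValueError(
                f"mean_sc_length must be > 0, got {self.mean_sc_length} "
                f"for chromosome {self.name!r}"
            )
        if self.centromere_position is not None and not (
            0 <= self.centromere_position <= self.assembly_length
        ):
            raise ValueError(
                f"centromere_position {self.centromere_position} outside "
                f"[0, {self.assembly_length}] for chromosome {self.name!r}"
            )
        if self.orientation not in ("forward", "inverted"):
            raise ValueError(f"orientation must be 'forward' or 'inverted', got {self.orientation!r}")


@dataclass(frozen=True)
class IntervalGrid:
    """A chromosome tiled into fixed-size half-open intervals.

    All intervals have length ``interval_size`` except possibly the last,
    which may be shorter; together they tile ``[0, total_length)`` without gap
    or overlap.
    """

    chromosome: str
    total_length: int
    interval_size: int

    @property
    def n_intervals(self) -> int:
        return -(-self.total_length // self.interval_size)  # ceiling division

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.n_intervals, dtype=np.int64) * self.interval_size

    @property
    def ends(self) -> np.ndarray:
        ends = self.starts + self.interval_size
        ends[-1] = self.total_length
        return ends

    @property
    def lengths(self) -> np.ndarray:
        """Per-interval lengths in bp (the trailing interval keeps its true length)."""
        return self.ends - self.starts

    @property
    def intervals(self) -> list[tuple[int, int]]:
        return list(zip(self.starts.tolist(), self.ends.tolist()))

    def __len__(self) -> int:
        return self.n_intervals

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.intervals)


def build_interval_grid(
    chrom: ChromosomeModel, interval_size: int = DEFAULT_INTERVAL_SIZE
) -> IntervalGrid:
    """Tile a chromosome into ``interval_size`` bins (ceiling division).

    The trailing partial interval is kept, so a 194.4 Mb chromosome at 2.5 Mb
    yields 78 intervals.
    """
    if interval_size <= 0:
        raise ValueError(f"interval_size must be > 0, got {interval_size}")
    if chrom.assembly_length <= 0:  # defensive; ChromosomeModel already enforces it
        raise ValueError(f"assembly_length must be > 0, got {chrom.assembly_length}")
    return IntervalGrid(
        chromosome=chrom.name,
        total_length=chrom.assembly_length,
        interval_size=interval_size,
    )


def interval_physical_length(chrom: ChromosomeModel, grid: IntervalGrid) -> float:
    """Mean physical (axis) length of one grid interval, in micrometres.

    Uses the proportionality of axis length and genomic length:
    ``mean_sc_length / n_intervals``.
    """
    if chrom.mean_sc_length is None:
        raise MissingSCLengthError(
            f"SC length unavailable for chromosome {chrom.name!r}"
        )
    return chrom.mean_sc_length / grid.n_intervals


def sc_fraction_to_bp(fraction: float, chrom: ChromosomeModel) -> int:
    """Convert a fraction of SC axis length into a genomic position in bp.

    Inverted chromosomes flip the fraction first.  The result is rounded to
    the nearest base.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if chrom.orientation == "inverted":
        fraction = 1.0 - fraction
    return int(round(fraction * chrom.assembly_length))


def bp_to_interval_index(pos: int, grid: IntervalGrid) -> int:
    """Map a genomic position to its interval index on the grid.

    Intervals are half-open; ``pos == total_length`` closes into the final
    interval so that the right chromosome edge is not lost.
    """
    if not 0 <= pos <= grid.total_length:
        raise ValueError(
            f"position {pos} outside [0, {grid.total_length}] on {grid.chromosome!r}"
        )
    return min(int(pos) // grid.interval_size, grid.n_intervals - 1)


@dataclass(frozen=True)
class HomologyPair:
    """One homology relation between chromosome segments of two karyotypes.

    Segment bounds are bp ranges (half-open); ``None`` means the whole
    chromosome.  ``inverted`` records whether the B segment runs antiparallel
    to the A segment.
    """

    a_chrom: str
    b_chrom: str
    a_start: Optional[int] = None
    a_end: Optional[int] = None
    b_start: Optional[int] = None
    b_end: Optional[int] = None
    inverted: bool = False


@dataclass
class HomologyMap:
    """Pairings of chromosomes / arms between two karyotypes."""

    pairs: list[HomologyPair] = field(default_factory=list)

    def validate(self, a_chroms: Sequence[str], b_chroms: Sequence[str]) -> None:
        """Check that every pairing names configured chromosomes."""
        a_set, b_set = set(a_chroms), set(b_chroms)
        for pair in self.pairs:
            if pair.a_chrom not in a_set:
                raise ValueError(f"homology names unknown chromosome {pair.a_chrom!r}")
            if pair.b_chrom not in b_set:
                raise ValueError(f"homology names unknown chromosome {pair.b_chrom!r}")

    def mask_for(
        self, chrom: str, side: Literal["a", "b"] = "a"
    ) -> Optional[tuple[Optional[int], Optional[int]]]:
        """Return the restricted bp range for ``chrom`` on one side, if any.

        ``None`` bounds mean "to the chromosome edge"; a fully unrestricted
        pairing returns ``None``.
        """
        for pair in self.pairs:
            name = pair.a_chrom if side == "a" else pair.b_chrom
            if name == chrom:
                start = pair.a_start if side == "a" else pair.b_start
                end = pair.a_end if side == "a" else pair.b_end
                if start is None and end is None:
                    return None
                return (start, end)
        return None
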