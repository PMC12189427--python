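"""MLH1 focus counts to genetic distance (cM) and recombination rate (cM/Mb).

Each MLH1 focus marks one crossover on a pachytene bivalent, i.e. 50 cM of
genetic map averaged over the cells scored.  Foci binned on an interval grid
convert to per-interval genetic length as ``cM_i = 50 * f_i / N`` where ``N``
is the total number of SCs observed for that chromosome, and to a rate by
dividing by the interval's true length in Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .coordinates import (
    ChromosomeModel,
    IntervalGrid,
    bp_to_interval_index,
    sc_fraction_to_bp,
)

__all__ = [
    "FocusTable",
    "RecombinationTrack",
    "TrackSummary",
    "bin_foci",
    "counts_to_cM",
    "cM_to_rate",
    "map_length",
    "build_track",
    "track_summary",
]

FOCUS_COLUMNS = ["cell_id", "chromosome", "sc_length_um", "position", "position_unit"]


@dataclass
class FocusTable:
    """Per-cell, per-bivalent crossover (MLH1 focus) observations.

    ``data`` holds one row per focus with columns ``cell_id``, ``chromosome``,
    ``sc_length_um`` (may be NaN when positions are fractions), ``position``
    and ``position_unit`` (``"fraction"`` or ``"um"``).

    ``n_cells`` is the number of SCs scored per chromosome.  It defaults to
    the number of distinct cell ids observed for that chromosome but can be
    supplied explicitly — necessary when cells without any focus on a
    chromosome were scored, since those contribute to N but have no rows.
    """

    data: pd.DataFrame
    n_cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in FOCUS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"focus table missing columns: {missing}")
        bad_unit = set(self.data["position_unit"].unique()) - {"fraction", "um"}
        if bad_unit:
            raise ValueError(f"unknown position_unit values: {sorted(bad_unit)}")
        for chrom in self.chromosomes():
            self.fractions(chrom)  # validates every record
        for chrom, n in self.n_cells.items():
            observed = self._observed_cells(chrom)
            if n < max(observed, 1):
                raise ValueError(
                    f"n_cells={n} for {chrom!r} below the {observed} distinct "
                    "cells present in the table"
                )

    def chromosomes(self) -> list[str]:
        return sorted(self.data["chromosome"].unique())

    def _observed_cells(self, chrom: str) -> int:
        sub = self.data[self.data["chromosome"] == chrom]
        return int(sub["cell_id"].nunique())

    def cells_scored(self, chrom: str) -> int:
        """N, the total number of SCs observed for ``chrom``."""
        if chrom in self.n_cells:
            return self.n_cells[chrom]
        n = self._observed_cells(chrom)
        if n == 0:
            raise ValueError(f"no cells recorded for chromosome {chrom!r}")
        return n

    def fractions(self, chrom: str) -> np.ndarray:
        """Focus positions for ``chrom`` as fractions of each cell's own SC length.

        Micrometre positions are normalised per cell by that cell's
        ``sc_length_um``.  Invalid records are rejected with the offending
        ``cell_id`` in the message.
        """
        sub = self.data[self.data["chromosome"] == chrom]
        out = np.empty(len(sub), dtype=float)
        for i, row in enumerate(sub.itertuples(index=False)):
            pos = row.position
            if row.position_unit == "um":
                sc = row.sc_length_um
                if sc is None or not np.isfinite(sc) or sc <= 0:
                    raise ValueError(
                        f"cell {row.cell_id!r}: micrometre position requires a "
                        "positive sc_length_um"
                    )
                if not 0 <= pos <= sc:
                    raise ValueError(
                        f"cell {row.cell_id!r}: position {pos} um outside "
                        f"[0, {sc}] um on {chrom!r}"
                    )
                out[i] = pos / sc
            else:
                if not 0 <= pos <= 1:
                    raise ValueError(
                        f"cell {row.cell_id!r}: fraction {pos} outside [0, 1] on {chrom!r}"
                    )
                out[i] = pos
        return out

    def total_foci(self, chrom: str) -> int:
        return int((self.data["chromosome"] == chrom).sum())


@dataclass
class RecombinationTrack:
    """Per-interval focus counts, genetic length and recombination rate."""

    grid: IntervalGrid
    foci: np.ndarray  # f_i, integer counts
    n_cells: int  # N
    cM: np.ndarray
    rate: np.ndarray  # cM/Mb

    @property
    def chromosome(self) -> str:
        return self.grid.chromosome

    @property
    def total_cM(self) -> float:
        return float(self.cM.sum())


def bin_foci(table: FocusTable, grid: IntervalGrid, chrom: ChromosomeModel) -> np.ndarray:
    """Count foci per grid interval via the SC-fraction -> bp -> index chain."""
    fractions = table.fractions(chrom.name)
    counts = np.zeros(grid.n_intervals, dtype=np.int64)
    for f in fractions:
        idx = bp_to_interval_index(sc_fraction_to_bp(float(f), chrom), grid)
        counts[idx] += 1
    return counts


def counts_to_cM(foci: Iterable[int], n_cells: int) -> np.ndarray:
    """cM_i = 50 * f_i / N."""
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    f = np.asarray(foci, dtype=float)
    if (f < 0).any():
        raise ValueError("focus counts must be non-negative")
    return 50.0 * f / n_cells


def cM_to_rate(cM, interval_length) -> np.ndarray | float:
    """Recombination rate in cM/Mb; partial intervals use their true length."""
    length = np.asarray(interval_length, dtype=float)
    if (length <= 0).any() if length.ndim else length <= 0:
        raise ValueError("interval lengths must be > 0")
    rate = np.asarray(cM, dtype=float) / (length / 1e6)
    return float(rate) if rate.ndim == 0 else rate


def map_length(table: FocusTable, chrom: Optional[str] = None) -> float:
    """Total genetic map length in cM: 50 * (total foci) / N.

    With ``chrom=None``, sums over every chromosome in the table.
    """
    chroms = [chrom] if chrom is not None else table.chromosomes()
    if not chroms:
        raise ValueError("empty focus table")
    total = 0.0
    for c in chroms:
        total += 50.0 * table.total_foci(c) / table.cells_scored(c)
    return total


def build_track(table: FocusTable, grid: IntervalGrid, chrom: ChromosomeModel) -> RecombinationTrack:
    """Full foci -> cM -> cM/Mb conversion for one chromosome."""
    foci = bin_foci(table, grid, chrom)
    n = table.cells_scored(chrom.name)
    cM = counts_to_cM(foci, n)
    rate = cM_to_rate(cM, grid.lengths)
    return RecombinationTrack(grid=grid, foci=foci, n_cells=n, cM=cM, rate=rate)


@dataclass(frozen=True)
class TrackSummary:
    min: float
    max: float
    mean: float
    sd: float


def track_summary(tracks: Iterable[RecombinationTrack] | RecombinationTrack) -> TrackSummary:
    """Min/max/mean/sample-sd of per-interval rates pooled over the given tracks."""
    if isinstance(tracks, RecombinationTrack):
        tracks = [tracks]
    tracks = list(tracks)
    rates = np.concatenate([t.rate for t in tracks]) if tracks else np.array([])
    if rates.size == 0:
        raise ValueError("no intervals to summarise")
    sd = float(np.std(rates, ddof=1)) if rates.size > 1 else 0.0
    return TrackSummary(
        min=float(rates.min()), max=float(rates.max()), mean=float(rates.mean()), sd=sd
    )
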