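"""Simulators for genomes, annotations and MLH1 focus datasets.

Two crossover-placement regimes are provided: ``homogeneous_terminal``
(chicken-like — elevated ends, substantial mid-chromosome recombination) and
``polarized`` (guinea-fowl-like — most crossovers packed into the terminal
spans with a recombination desert in the middle).  Both draw per-bivalent
crossover counts from a Poisson and place each crossover from a mixture of a
terminal component (a Beta(1, 8) scaled into each terminal span, mirrored at
the two ends) and a uniform background.

The genome simulator plants a per-interval GC landscape, CpG islands and gene
starts, with an optional Gaussian-copula coupling between the GC landscape
and the planted crossover intensity so that rank-correlation recovery can be
asserted end to end.  CpG dinucleotides outside planted islands are swapped
to GpC (composition-preserving depletion) so the island caller has signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .association import spearman
from .coordinates import (
    ChromosomeModel,
    DEFAULT_INTERVAL_SIZE,
    IntervalGrid,
    build_interval_grid,
)
from .features import feature_profile
from .recmap import FocusTable, build_track, map_length

__all__ = [
    "FocusSimParams",
    "GenomeSimParams",
    "GenomeSim",
    "simulate_focus_dataset",
    "simulate_genome",
    "end_to_end_recovery",
]

Regime = Literal["homogeneous_terminal", "polarized"]

# Regime presets: the polarized regime concentrates ~80% of crossovers in the
# terminal spans; the homogeneous regime keeps a strong uniform background.
REGIME_TERMINAL_WEIGHT = {"homogeneous_terminal": 0.3, "polarized": 0.85}


@dataclass(frozen=True)
class FocusSimParams:
    """Parameters of the crossover (MLH1 focus) placement simulator."""

    regime: Regime
    n_cells: int
    co_mean: float
    obligate_co: bool = False
    terminal_weight: Optional[float] = None  # default depends on regime
    terminal_span: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIME_TERMINAL_WEIGHT:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.co_mean < 0:
            raise ValueError(f"co_mean must be >= 0, got {self.co_mean}")
        if self.obligate_co and self.co_mean == 0:
            raise ValueError("obligate_co requires co_mean > 0")
        tw = self.effective_terminal_weight
        if not 0.0 <= tw <= 1.0:
            raise ValueError(f"terminal_weight must be in [0, 1], got {tw}")
        if not 0.0 < self.terminal_span < 0.5:
            raise ValueError(f"terminal_span must be in (0, 0.5), got {self.terminal_span}")

    @property
    def effective_terminal_weight(self) -> float:
        if self.terminal_weight is not None:
            return self.terminal_weight
        return REGIME_TERMINAL_WEIGHT[self.regime]


def _draw_positions(
    rng: np.random.Generator,
    k: int,
    terminal_weight: float,
    terminal_span: float,
) -> np.ndarray:
    """Mixture placement on [0, 1]: terminal Beta(1, 8) components vs uniform."""
    pos = np.empty(k)
    from_terminal = rng.random(k) < terminal_weight
    n_t = int(from_terminal.sum())
    if n_t:
        t = terminal_span * rng.beta(1.0, 8.0, size=n_t)
        right = rng.random(n_t) < 0.5  # mirror half of the mass to the far end
        pos[from_terminal] = np.where(right, 1.0 - t, t)
    n_u = k - n_t
    if n_u:
        pos[~from_terminal] = rng.random(n_u)
    return pos


def _draw_positions_from_intensity(
    rng: np.random.Generator,
    k: int,
    grid: IntervalGrid,
    intensity: np.ndarray,
) -> np.ndarray:
    """Piecewise-constant placement: interval chosen ∝ intensity × length, uniform inside."""
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != (grid.n_intervals,):
        raise ValueError(
            f"intensity length {intensity.shape} != {grid.n_intervals} intervals"
        )
    if (intensity < 0).any() or intensity.sum() <= 0:
        raise ValueError("intensity must be non-negative with positive total mass")
    w = intensity * grid.lengths
    idx = rng.choice(grid.n_intervals, size=k, p=w / w.sum())
    lo = grid.starts[idx] / grid.total_length
    hi = grid.ends[idx] / grid.total_length
    return lo + rng.random(k) * (hi - lo)


def simulate_focus_dataset(
    params: FocusSimParams,
    chroms: Sequence[ChromosomeModel],
    intensity: Optional[Mapping[str, np.ndarray]] = None,
    intensity_grids: Optional[Mapping[str, IntervalGrid]] = None,
    position_unit: Literal["fraction", "um"] = "fraction",
    sc_length_cv: float = 0.08,
) -> FocusTable:
    """Simulate a per-cell, per-bivalent MLH1 focus table.

    Crossover counts per bivalent are Poisson(``co_mean``), redrawn to >= 1
    when ``obligate_co``.  Positions follow the regime mixture unless a
    per-chromosome ``intensity`` track (with its grid) overrides it.
    Deterministic for a fixed seed.

    With ``position_unit="um"`` each cell gets its own SC length (normal
    around the chromosome mean, CV ``sc_length_cv``) and positions are written
    in micrometres along it.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    n_cells_map: dict[str, int] = {}
    for chrom in chroms:
        n_cells_map[chrom.name] = params.n_cells
        use_intensity = intensity is not None and chrom.name in intensity
        if use_intensity:
            if intensity_grids is None or chrom.name not in intensity_grids:
                raise ValueError(f"intensity for {chrom.name!r} needs its grid")
            grid = intensity_grids[chrom.name]
        for i in range(params.n_cells):
            cell_id = f"cell{i:05d}"
            k = int(rng.poisson(params.co_mean))
            if params.obligate_co:
                while k == 0:
                    k = int(rng.poisson(params.co_mean))
            if position_unit == "um":
                mean_sc = chrom.mean_sc_length if chrom.mean_sc_length else 20.0
                sc_len = -1.0
                while sc_len <= 0:
                    sc_len = rng.normal(mean_sc, sc_length_cv * mean_sc)
                sc_len = round(float(sc_len), 3)
            else:
                sc_len = math.nan
            if k == 0:
                continue
            if use_intensity:
                pos = _draw_positions_from_intensity(rng, k, grid, intensity[chrom.name])
            else:
                pos = _draw_positions(
                    rng, k, params.effective_terminal_weight, params.terminal_span
                )
            for p in np.sort(pos):
                p = float(p)
                if position_unit == "um":
                    rows.append((cell_id, chrom.name, sc_len, round(p * sc_len, 4), "um"))
                else:
                    rows.append((cell_id, chrom.name, sc_len, p, "fraction"))
    data = pd.DataFrame(
        rows, columns=["cell_id", "chromosome", "sc_length_um", "position", "position_unit"]
    )
    return FocusTable(data=data, n_cells=n_cells_map)


@dataclass(frozen=True)
class GenomeSimParams:
    """Parameters of the planted-structure genome simulator."""

    lengths: tuple[int, ...]
    gc_baseline: float = 0.45
    gc_amplitude: float = 0.05
    cgi_rate: float = 3.0  # islands per Mb
    genes_per_Mb: float = 10.0
    coupling_rho: float = 0.0  # Spearman coupling of GC landscape to CO intensity
    seed: int = 0
    names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if not self.lengths or any(l <= 0 for l in self.lengths):
            raise ValueError(f"chromosome lengths must be positive, got {self.lengths}")
        lo = self.gc_baseline - self.gc_amplitude
        hi = self.gc_baseline + self.gc_amplitude
        if not (0.0 < lo and hi < 1.0):
            raise ValueError(
                f"gc_baseline ± gc_amplitude must stay inside (0, 1), got [{lo}, {hi}]"
            )
        if self.cgi_rate < 0 or self.genes_per_Mb < 0:
            raise ValueError("cgi_rate and genes_per_Mb must be >= 0")
        if not -1.0 <= self.coupling_rho <= 1.0:
            raise ValueError(f"coupling_rho must be in [-1, 1], got {self.coupling_rho}")
        if self.names is not None and len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths)

    def chrom_names(self) -> tuple[str, ...]:
        return self.names or tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))


@dataclass
class GenomeSim:
    """A simulated genome with its planted ground truth."""

    sequences: dict[str, str]
    gene_starts: dict[str, np.ndarray]
    chromosomes: list[ChromosomeModel]
    grids: dict[str, IntervalGrid]
    truth: dict  # per-chromosome planted gc targets, intensities, islands, genes


_BASES = np.frombuffer(b"CGAT", dtype=np.uint8)

CPG_DEPLETION = 0.95  # fraction of background CpG dinucleotides swapped to GpC
ISLAND_GC = 0.70
ISLAND_LENGTH_RANGE = (400, 1200)


def _sample_block(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """i.i.d. bases with the given GC target, as uint8 codes."""
    u = rng.random(length)
    probs = np.array([gc / 2, gc, gc + (1 - gc) / 2])  # C | G | A | T breakpoints
    return _BASES[np.searchsorted(probs, u)]


def _deplete_cpg(rng: np.random.Generator, arr: np.ndarray, passes: int = 3) -> None:
    """Swap most CpG dinucleotides to GpC in place (GC content preserved).

    A swap can create a fresh CpG against a neighbouring base, so the sweep
    is repeated; three passes push background obs/exp CpG to ~0.1.
    """
    for _ in range(passes):
        is_cpg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        idx = np.flatnonzero(is_cpg)
        # resolve overlaps left to right: swapping position i consumes i and i+1
        keep = []
        last = -2
        for i in idx:
            if i > last + 1:
                keep.append(i)
                last = i
        idx = np.array(keep, dtype=np.int64)
        if idx.size == 0:
            return
        swap = idx[rng.random(idx.size) < CPG_DEPLETION]
        arr[swap] = ord("G")
        arr[swap + 1] = ord("C")


def _coupled_uniforms(
    rng: np.random.Generator, n: int, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two U(0,1) vectors with Spearman correlation ~rho (Gaussian copula)."""
    r_pearson = 2.0 * math.sin(math.pi * rho / 6.0)
    z1 = rng.standard_normal(n)
    z2 = r_pearson * z1 + math.sqrt(max(0.0, 1.0 - r_pearson**2)) * rng.standard_normal(n)
    return ndtr(z1), ndtr(z2)


def simulate_genome(
    params: GenomeSimParams,
    interval_size: int = DEFAULT_INTERVAL_SIZE,
    with_sequences: bool = True,
) -> GenomeSim:
    """Simulate sequences, gene starts and planted tracks.

    Per interval, a crossover-intensity value and a GC target are drawn from
    a Gaussian copula with Spearman coupling ``coupling_rho``; the sequence is
    sampled i.i.d. at the interval's GC target, background CpGs are swapped
    away, and CpG islands (GC-rich, undepleted segments) are planted at
    ``cgi_rate`` per Mb.  The planted tracks are returned as recovery targets.

    ``with_sequences=False`` skips base-level sampling (empty sequences, no
    planted islands) and only returns the planted tracks — much faster for
    replicate studies that correlate against the planted GC landscape.
    """
    rng = np.random.default_rng(params.seed)
    names = params.chrom_names()
    sequences: dict[str, str] = {}
    gene_starts: dict[str, np.ndarray] = {}
    chroms: list[ChromosomeModel] = []
    grids: dict[str, IntervalGrid] = {}
    truth: dict = {"interval_size": interval_size, "chromosomes": {}}

    for name, length in zip(names, params.lengths):
        chrom = ChromosomeModel(name=name, assembly_length=int(length))
        grid = build_interval_grid(chrom, interval_size)
        n_int = grid.n_intervals

        u_int, u_gc = _coupled_uniforms(rng, n_int, params.coupling_rho)
        intensity = u_int  # relative crossover intensity per interval
        gc_target = params.gc_baseline + params.gc_amplitude * (2.0 * u_gc - 1.0)

        island_spans: list[tuple[int, int]] = []
        if with_sequences:
            blocks = [
                _sample_block(rng, int(l), float(g))
                for l, g in zip(grid.lengths, gc_target)
            ]
            arr = np.concatenate(blocks)
            _deplete_cpg(rng, arr)

            n_islands = int(rng.poisson(params.cgi_rate * length / 1e6))
            if n_islands:
                isl_lengths = rng.integers(*ISLAND_LENGTH_RANGE, size=n_islands)
                isl_starts = np.sort(
                    rng.integers(0, max(1, length - int(isl_lengths.max())), size=n_islands)
                )
                last_end = -1
                for s, l in zip(isl_starts, isl_lengths):
                    s, l = int(s), int(l)
                    if s <= last_end + 1 or s + l > length:
                        continue  # drop overlapping / out-of-range plants
                    block = _sample_block(rng, l, ISLAND_GC)
                    arr[s : s + l] = block
                    island_spans.append((s, s + l))
                    last_end = s + l
            sequences[name] = arr.tobytes().decode("ascii")
        else:
            sequences[name] = ""

        n_genes = int(rng.poisson(params.genes_per_Mb * length / 1e6))
        starts = np.sort(rng.integers(0, length, size=n_genes)) if n_genes else np.array([], dtype=np.int64)
        gene_starts[name] = starts.astype(np.int64)

        chroms.append(chrom)
        grids[name] = grid
        truth["chromosomes"][name] = {
            "length": int(length),
            "gc_target": gc_target.tolist(),
            "intensity": intensity.tolist(),
            "islands": island_spans,
            "n_genes": int(n_genes),
        }

    return GenomeSim(
        sequences=sequences,
        gene_starts=gene_starts,
        chromosomes=chroms,
        grids=grids,
        truth=truth,
    )


def end_to_end_recovery(
    genome_params: GenomeSimParams,
    focus_params: FocusSimParams,
    interval_size: int = DEFAULT_INTERVAL_SIZE,
    couple_foci: bool = True,
    use_sequences: bool = True,
    call_islands: bool = False,
    zero_mode: Literal["all", "nonzero_only"] = "all",
) -> dict:
    """Run simulate -> bin -> rate -> correlate and report recovery statistics.

    Reports the terminal focus fraction under both readings of "terminal"
    (outer 10% of each end, summing to a fifth of the length, and outer 20%
    of each end), the pooled Spearman rho between rate and GC, and the total
    map length per chromosome.

    ``couple_foci`` places crossovers from the planted intensity track (so the
    GC coupling propagates to the realised rates); otherwise the regime
    mixture is used.  ``use_sequences=False`` correlates against the planted
    GC targets instead of realised sequence GC, which is much faster for
    replicate studies.
    """
    genome = simulate_genome(genome_params, interval_size, with_sequences=use_sequences)
    intensity = None
    if couple_foci:
        intensity = {
            name: np.asarray(genome.truth["chromosomes"][name]["intensity"])
            for name in genome.sequences
        }
    table = simulate_focus_dataset(
        focus_params,
        genome.chromosomes,
        intensity=intensity,
        intensity_grids=genome.grids if couple_foci else None,
    )

    all_fracs = np.concatenate(
        [table.fractions(c.name) for c in genome.chromosomes]
    ) if len(table.data) else np.array([])
    if all_fracs.size:
        outer10 = float(((all_fracs < 0.1) | (all_fracs > 0.9)).mean())
        outer20 = float(((all_fracs < 0.2) | (all_fracs > 0.8)).mean())
    else:
        outer10 = outer20 = math.nan

    rates, gcs, central, lengths_cm = [], [], {}, {}
    for chrom in genome.chromosomes:
        grid = genome.grids[chrom.name]
        track = build_track(table, grid, chrom)
        if use_sequences:
            feat = feature_profile(
                genome.sequences[chrom.name],
                genome.gene_starts[chrom.name],
                grid,
                islands=None if call_islands else [],
            )
            gc = feat.gc
        else:
            gc = np.asarray(genome.truth["chromosomes"][chrom.name]["gc_target"])
        rates.append(track.rate)
        gcs.append(gc)
        n = grid.n_intervals
        central[chrom.name] = float(track.rate[n // 3 : n - n // 3].mean())
        lengths_cm[chrom.name] = track.total_cM

    rate_vec = np.concatenate(rates)
    gc_vec = np.concatenate(gcs)
    keep = np.isfinite(gc_vec)
    rate_vec, gc_vec = rate_vec[keep], gc_vec[keep]
    dropped = 0
    from .association import NoRecombiningIntervalsError, exclude_zero_intervals

    pooled_rho = pooled_p = math.nan
    try:
        if zero_mode == "nonzero_only":
            rate_vec, gc_vec, dropped = exclude_zero_intervals(rate_vec, gc_vec)
        pooled_rho, pooled_p = spearman(rate_vec, gc_vec)
    except (NoRecombiningIntervalsError, ValueError):
        pass

    return {
        "terminal_fraction_outer10": outer10,
        "terminal_fraction_outer20": outer20,
        "pooled_rho": pooled_rho,
        "pooled_p": pooled_p,
        "n_pairs": int(rate_vec.size),
        "zero_dropped": dropped,
        "map_length_cM": lengths_cm,
        "total_map_length_cM": float(sum(lengths_cm.values())),
        "central_third_mean_rate": central,
        "planted_coupling_rho": genome_params.coupling_rho,
        "terminal_weight": focus_params.effective_terminal_weight,
    }
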