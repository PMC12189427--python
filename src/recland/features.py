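"""Sequence-feature tracks: GC content, CpG islands and gene density per interval.

CpG islands follow the classic compositional definition: a region longer than
200 bp with GC fraction >= 0.5 and observed/expected CpG >= 0.6, where
obs/exp = N_CpG * L / (N_C * N_G).  The caller seeds candidate regions with
qualifying 200 bp windows (step 1 bp), merges overlapping windows, and within
each merged span reports maximal qualifying sub-regions (longest first,
leftmost on ties, recursing into the flanks).  All criterion comparisons are
done in integer arithmetic so results are exactly reproducible.

Soft-masked (lowercase) bases count as their nucleotide; hard-masked (N)
bases are excluded from GC numerator and denominator and never occur inside a
called island.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .coordinates import IntervalGrid

__all__ = [
    "CpGIsland",
    "FeatureTrack",
    "CGI_WINDOW",
    "CGI_MIN_LENGTH",
    "gc_content",
    "obs_exp_cpg",
    "call_cpg_islands",
    "feature_profile",
]

CGI_WINDOW = 200  # seed window size, bp
CGI_MIN_LENGTH = 201  # "length greater than 200 bp" -> strictly > 200

_VALID_BYTES = frozenset(b"ACGTN")


@dataclass(frozen=True)
class CpGIsland:
    """A called CpG island (0-based half-open coordinates)."""

    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    chrom: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def _encode(seq: str) -> np.ndarray:
    """Uppercase byte array over {A,C,G,T,N}; rejects anything else with its position."""
    arr = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    valid = (
        (arr == ord("A"))
        | (arr == ord("C"))
        | (arr == ord("G"))
        | (arr == ord("T"))
        | (arr == ord("N"))
    )
    if not valid.all():
        pos = int(np.argmin(valid))
        raise ValueError(f"illegal nucleotide {seq[pos]!r} at position {pos}")
    return arr


def gc_content(seq: str) -> float:
    """GC fraction over unmasked bases; NaN when no unmasked base is present."""
    arr = _encode(seq)
    n_n = int((arr == ord("N")).sum())
    denom = arr.size - n_n
    if denom == 0:
        return float("nan")
    gc = int(((arr == ord("G")) | (arr == ord("C"))).sum())
    return gc / denom


def obs_exp_cpg(seq: str) -> float:
    """Observed/expected CpG: N_CpG * L_eff / (N_C * N_G); 0 when C or G absent.

    ``L_eff`` is the number of unmasked (non-N) bases.
    """
    arr = _encode(seq)
    if arr.size == 0:
        raise ValueError("empty sequence")
    n_c = int((arr == ord("C")).sum())
    n_g = int((arr == ord("G")).sum())
    if n_c == 0 or n_g == 0:
        return 0.0
    cpg = int(((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).sum())
    l_eff = arr.size - int((arr == ord("N")).sum())
    return cpg * l_eff / (n_c * n_g)


def _prefix_sums(arr: np.ndarray):
    """Cumulative counts used by the island search; index i = count in arr[:i]."""

    def cum(mask: np.ndarray) -> np.ndarray:
        out = np.zeros(arr.size + 1, dtype=np.int64)
        np.cumsum(mask, out=out[1:])
        return out

    is_c = arr == ord("C")
    is_g = arr == ord("G")
    cpg = np.zeros(arr.size, dtype=bool)
    if arr.size > 1:
        cpg[:-1] = is_c[:-1] & is_g[1:]
    return {
        "gc": cum(is_c | is_g),
        "c": cum(is_c),
        "g": cum(is_g),
        "n": cum(arr == ord("N")),
        # cpg[i] marks the dinucleotide starting at i; a region [a, b) contains
        # the dinucleotides starting at a .. b-2
        "cpg": cum(cpg),
    }


def _region_qualifies(ps, start: int, end: int) -> bool:
    """All three criteria on [start, end), in exact integer arithmetic."""
    length = end - start
    if length < CGI_MIN_LENGTH:
        return False
    if ps["n"][end] - ps["n"][start] > 0:
        return False
    gc = ps["gc"][end] - ps["gc"][start]
    if 2 * gc < length:  # GC fraction >= 0.5
        return False
    n_c = ps["c"][end] - ps["c"][start]
    n_g = ps["g"][end] - ps["g"][start]
    if n_c == 0 or n_g == 0:
        return False
    cpg = ps["cpg"][end - 1] - ps["cpg"][start]
    # obs/exp >= 0.6  <=>  5 * cpg * length >= 3 * n_c * n_g
    return 5 * cpg * length >= 3 * n_c * n_g


def _qualifying_window_starts(ps, n: int) -> np.ndarray:
    if n < CGI_WINDOW:
        return np.array([], dtype=np.int64)
    w = CGI_WINDOW
    starts = np.arange(n - w + 1)
    n_n = ps["n"][starts + w] - ps["n"][starts]
    gc = ps["gc"][starts + w] - ps["gc"][starts]
    n_c = ps["c"][starts + w] - ps["c"][starts]
    n_g = ps["g"][starts + w] - ps["g"][starts]
    cpg = ps["cpg"][starts + w - 1] - ps["cpg"][starts]
    ok = (
        (n_n == 0)
        & (2 * gc >= w)
        & (n_c > 0)
        & (n_g > 0)
        & (5 * cpg * w >= 3 * n_c * n_g)
    )
    return starts[ok]


def _merge_window_coverage(starts: np.ndarray) -> list[tuple[int, int]]:
    """Merge the [s, s+200) coverage of qualifying windows into disjoint spans."""
    if starts.size == 0:
        return []
    spans: list[tuple[int, int]] = []
    lo = int(starts[0])
    hi = lo + CGI_WINDOW
    for s in starts[1:]:
        s = int(s)
        if s <= hi:  # overlapping or adjacent coverage
            hi = s + CGI_WINDOW
        else:
            spans.append((lo, hi))
            lo, hi = s, s + CGI_WINDOW
    spans.append((lo, hi))
    return spans


def _maximal_regions(ps, lo: int, hi: int, out: list[tuple[int, int]]) -> None:
    """Longest qualifying sub-region of [lo, hi), leftmost on ties; recurse on flanks."""
    span = hi - lo
    if span < CGI_MIN_LENGTH:
        return
    for length in range(span, CGI_MIN_LENGTH - 1, -1):
        starts = np.arange(lo, hi - length + 1)
        ends = starts + length
        gc = ps["gc"][ends] - ps["gc"][starts]
        n_c = ps["c"][ends] - ps["c"][starts]
        n_g = ps["g"][ends] - ps["g"][starts]
        cpg = ps["cpg"][ends - 1] - ps["cpg"][starts]
        n_n = ps["n"][ends] - ps["n"][starts]
        ok = (
            (n_n == 0)
            & (2 * gc >= length)
            & (n_c > 0)
            & (n_g > 0)
            & (5 * cpg * length >= 3 * n_c * n_g)
        )
        if ok.any():
            s = int(starts[int(np.argmax(ok))])
            out.append((s, s + length))
            _maximal_regions(ps, lo, s, out)
            _maximal_regions(ps, s + length, hi, out)
            return


def call_cpg_islands(seq: str, chrom: Optional[str] = None) -> list[CpGIsland]:
    """Call CpG islands on a sequence.

    Returns disjoint, sorted islands; every island satisfies length > 200,
    GC >= 0.5 and obs/exp CpG >= 0.6 and contains no N.
    """
    arr = _encode(seq)
    ps = _prefix_sums(arr)
    regions: list[tuple[int, int]] = []
    for lo, hi in _merge_window_coverage(_qualifying_window_starts(ps, arr.size)):
        _maximal_regions(ps, lo, hi, regions)
    regions.sort()
    islands = []
    for s, e in regions:
        sub = seq[s:e]
        islands.append(
            CpGIsland(
                start=s,
                end=e,
                gc_fraction=gc_content(sub),
                obs_exp_cpg=obs_exp_cpg(sub),
                chrom=chrom,
            )
        )
    return islands


@dataclass
class FeatureTrack:
    """Per-interval genomic feature densities on a grid.

    ``gc`` is NaN for all-N intervals; ``gene_pct`` is NaN throughout when the
    chromosome has no annotated gene.
    """

    grid: IntervalGrid
    gc: np.ndarray
    cgi_count: np.ndarray
    gene_count: np.ndarray
    gene_pct: np.ndarray

    @property
    def chromosome(self) -> str:
        return self.grid.chromosome


def feature_profile(
    seq: str,
    gene_starts: Sequence[int] | np.ndarray,
    grid: IntervalGrid,
    islands: Optional[Iterable[CpGIsland]] = None,
) -> FeatureTrack:
    """Compute GC, CGI-count and gene-density tracks on a grid.

    Islands and genes are assigned to intervals by their start position.
    ``islands`` may be passed in to avoid re-calling them; otherwise they are
    called from ``seq``.
    """
    arr = _encode(seq)
    if arr.size != grid.total_length:
        import warnings

        warnings.warn(
            f"sequence length {arr.size} != configured assembly length "
            f"{grid.total_length} for {grid.chromosome!r}",
            stacklevel=2,
        )
    if islands is None:
        islands = call_cpg_islands(seq, chrom=grid.chromosome)

    ps = _prefix_sums(arr)
    starts = np.minimum(grid.starts, arr.size)
    ends = np.minimum(grid.ends, arr.size)
    gc_counts = ps["gc"][ends] - ps["gc"][starts]
    n_counts = ps["n"][ends] - ps["n"][starts]
    denom = (ends - starts) - n_counts
    gc = np.where(denom > 0, gc_counts / np.maximum(denom, 1), np.nan)

    edges = np.append(grid.starts, grid.total_length)
    island_starts = np.array([isl.start for isl in islands], dtype=np.int64)
    cgi_count = np.histogram(island_starts, bins=edges)[0] if island_starts.size else np.zeros(
        grid.n_intervals, dtype=np.int64
    )

    gene_starts = np.asarray(gene_starts, dtype=np.int64)
    if gene_starts.size and (
        (gene_starts < 0).any() or (gene_starts >= grid.total_length).any()
    ):
        bad = gene_starts[(gene_starts < 0) | (gene_starts >= grid.total_length)][0]
        raise ValueError(
            f"gene start {int(bad)} outside [0, {grid.total_length}) on {grid.chromosome!r}"
        )
    gene_count = (
        np.histogram(gene_starts, bins=edges)[0]
        if gene_starts.size
        else np.zeros(grid.n_intervals, dtype=np.int64)
    )
    total_genes = int(gene_count.sum())
    if total_genes > 0:
        gene_pct = 100.0 * gene_count / total_genes
    else:
        gene_pct = np.full(grid.n_intervals, np.nan)

    return FeatureTrack(
        grid=grid,
        gc=gc,
        cgi_count=cgi_count.astype(np.int64),
        gene_count=gene_count.astype(np.int64),
        gene_pct=gene_pct,
    )
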