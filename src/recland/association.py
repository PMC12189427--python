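"""Rank-correlation of recombination rates with genomic feature tracks.

Associations are Spearman rank correlations computed per chromosome and,
optionally, pooled over a list of chromosomes by concatenating interval
pairs.  Intervals with missing feature values are excluded pairwise; an
optional ``nonzero_only`` mode drops intervals with exactly zero
recombination first (guards against zero inflation in strongly polarised
landscapes).  p-values use the t approximation for n > 10 and exact
permutation enumeration for n <= 10.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTrack
from .recmap import RecombinationTrack

__all__ = [
    "AssociationResult",
    "ConstantInputError",
    "NoRecombiningIntervalsError",
    "FEATURES",
    "spearman",
    "exclude_zero_intervals",
    "correlate_tracks",
    "format_matrix",
    "stars",
]

FEATURES = ("gc", "cgi", "gene")

EXACT_PERMUTATION_MAX_N = 10


class ConstantInputError(ValueError):
    """Raised when a correlation input vector is constant (rho undefined)."""


class NoRecombiningIntervalsError(ValueError):
    """Raised when zero-exclusion removes every interval pair."""


@dataclass(frozen=True)
class AssociationResult:
    """One Spearman test between a feature track and the recombination rate."""

    chromosome: str  # chromosome name or "pooled_<a>_<b>"
    feature: str
    rho: Optional[float]
    p_value: Optional[float]
    n_pairs: int
    zero_excluded: bool
    significant: bool
    note: str = ""


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for the rank correlation.

    Enumerates every permutation of one rank vector (n <= 10, so at most
    10! = 3,628,800 arrangements, processed in chunks).
    """
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    target = abs(rho_obs) - 1e-12
    hits = 0
    total = 0
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 200_000))
        if not chunk:
            break
        idx = np.array(chunk, dtype=np.intp)
        rho_perm = (rx_c * ry_c[idx]).sum(axis=1) / denom
        hits += int((np.abs(rho_perm) >= target).sum())
        total += idx.shape[0]
    return hits / total


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  Constant inputs raise
    :class:`ConstantInputError` instead of returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("constant input vector: rank correlation undefined")

    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry).statistic)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def exclude_zero_intervals(
    rates: Sequence[float], features: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Drop interval pairs whose recombination rate is exactly zero.

    Returns the surviving (rates, features) and the number of pairs dropped.
    """
    rates = np.asarray(rates, dtype=float)
    features = np.asarray(features, dtype=float)
    if rates.shape != features.shape:
        raise ValueError(f"length mismatch: {rates.shape} vs {features.shape}")
    keep = rates != 0.0
    dropped = int((~keep).sum())
    if not keep.any():
        raise NoRecombiningIntervalsError("no recombining intervals left after zero-exclusion")
    return rates[keep], features[keep], dropped


def _feature_values(feat: FeatureTrack, feature: str) -> np.ndarray:
    if feature == "gc":
        return feat.gc
    if feature == "cgi":
        return feat.cgi_count.astype(float)
    if feature == "gene":
        return feat.gene_pct
    raise ValueError(f"unknown feature {feature!r}")


def _pairs_for(
    rec: RecombinationTrack,
    feat: FeatureTrack,
    feature: str,
    mask: Optional[tuple[Optional[int], Optional[int]]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    if rec.grid != feat.grid:
        raise ValueError(
            f"grid mismatch between recombination and feature tracks on "
            f"{rec.chromosome!r}"
        )
    rates = rec.rate
    values = _feature_values(feat, feature)
    if mask is not None:
        lo = mask[0] if mask[0] is not None else 0
        hi = mask[1] if mask[1] is not None else rec.grid.total_length
        sel = (rec.grid.starts >= lo) & (rec.grid.ends <= hi)
        rates, values = rates[sel], values[sel]
    finite = np.isfinite(values) & np.isfinite(rates)
    return rates[finite], values[finite]


def _one_result(
    scope: str,
    feature: str,
    rates: np.ndarray,
    values: np.ndarray,
    mode: str,
    alpha: float,
) -> AssociationResult:
    zero_excluded = mode == "nonzero_only"
    note = ""
    if zero_excluded:
        try:
            rates, values, _ = exclude_zero_intervals(rates, values)
        except NoRecombiningIntervalsError as err:
            return AssociationResult(scope, feature, None, None, 0, True, False, str(err))
    n = int(rates.size)
    if n < 3:
        return AssociationResult(
            scope, feature, None, None, n, zero_excluded, False, "fewer than 3 pairs"
        )
    try:
        rho, p = spearman(rates, values)
    except ConstantInputError as err:
        return AssociationResult(scope, feature, None, None, n, zero_excluded, False, str(err))
    return AssociationResult(
        scope, feature, rho, p, n, zero_excluded, bool(p < alpha), note
    )


def correlate_tracks(
    rec: Mapping[str, RecombinationTrack],
    feat: Mapping[str, FeatureTrack],
    mode: Literal["all", "nonzero_only"] = "all",
    pooled: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    features: Sequence[str] = FEATURES,
    masks: Optional[Mapping[str, tuple[Optional[int], Optional[int]]]] = None,
    bh_correct: bool = False,
) -> list[AssociationResult]:
    """Spearman associations per chromosome and, optionally, pooled.

    ``rec`` and ``feat`` map chromosome names to tracks sharing a grid.
    ``pooled`` concatenates interval pairs across the named chromosomes into a
    single ``pooled_<first>_<last>`` scope.  ``masks`` restricts chromosomes
    to bp ranges (e.g. a long arm) before any statistics.  ``bh_correct``
    applies Benjamini-Hochberg across all computed p-values (off by default).
    """
    if mode not in ("all", "nonzero_only"):
        raise ValueError(f"unknown mode {mode!r}")
    if set(rec) != set(feat):
        raise ValueError(
            f"chromosome sets differ: {sorted(rec)} vs {sorted(feat)}"
        )
    masks = masks or {}
    results: list[AssociationResult] = []
    for chrom in rec:
        for feature in features:
            rates, values = _pairs_for(rec[chrom], feat[chrom], feature, masks.get(chrom))
            results.append(_one_result(chrom, feature, rates, values, mode, alpha))
    if pooled:
        missing = [c for c in pooled if c not in rec]
        if missing:
            raise ValueError(f"pooled scope names unknown chromosomes: {missing}")
        scope = f"pooled_{pooled[0]}_{pooled[-1]}"
        for feature in features:
            parts = [
                _pairs_for(rec[c], feat[c], feature, masks.get(c)) for c in pooled
            ]
            rates = np.concatenate([p[0] for p in parts])
            values = np.concatenate([p[1] for p in parts])
            results.append(_one_result(scope, feature, rates, values, mode, alpha))
    if bh_correct:
        results = _benjamini_hochberg(results, alpha)
    return results


def _benjamini_hochberg(results: list[AssociationResult], alpha: float) -> list[AssociationResult]:
    tested = [r for r in results if r.p_value is not None]
    if not tested:
        return results
    p = np.array([r.p_value for r in tested])
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    adjusted = iter(adj)
    out = []
    for r in results:
        if r.p_value is None:
            out.append(r)
        else:
            q = float(next(adjusted))
            out.append(
                AssociationResult(
                    r.chromosome, r.feature, r.rho, q, r.n_pairs, r.zero_excluded,
                    bool(q < alpha), r.note,
                )
            )
    return out


def stars(p: Optional[float]) -> str:
    """Conventional significance stars: * <0.05, ** <0.01, *** <0.001."""
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def format_matrix(results: Sequence[AssociationResult], alpha: float = 0.05) -> pd.DataFrame:
    """Chromosome x feature matrix of "rho stars" cells.

    Only significant cells (p < alpha) are shown, mirroring a
    significant-correlations-only heat map; feature columns with no computable
    result are dropped with a warning.
    """
    if not results:
        raise ValueError("no association results to format")
    scopes = list(dict.fromkeys(r.chromosome for r in results))
    feats = list(dict.fromkeys(r.feature for r in results))
    table = pd.DataFrame("", index=scopes, columns=feats)
    computed = {f: False for f in feats}
    for r in results:
        if r.rho is None or r.p_value is None:
            continue
        computed[r.feature] = True
        if r.p_value < alpha:
            table.loc[r.chromosome, r.feature] = f"{r.rho:.2f} {stars(r.p_value)}".rstrip()
    empty = [f for f, ok in computed.items() if not ok]
    if empty:
        warnings.warn(f"dropping feature columns with no computable result: {empty}", stacklevel=2)
        table = table.drop(columns=empty)
    return table
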