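"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive: plain Python loops and string
counting, no numpy prefix sums, no code shared with the implementation
under test.
"""

from __future__ import annotations

WINDOW = 200
MIN_LEN = 201  # "longer than 200 bp"


def naive_gc(sub: str) -> float:
    sub = sub.upper()
    denom = len(sub) - sub.count("N")
    if denom == 0:
        return float("nan")
    return (sub.count("G") + sub.count("C")) / denom


def naive_obs_exp(sub: str) -> float:
    sub = sub.upper()
    c, g = sub.count("C"), sub.count("G")
    if c == 0 or g == 0:
        return 0.0
    l_eff = len(sub) - sub.count("N")
    return sub.count("CG") * l_eff / (c * g)


def _region_ok(sub: str) -> bool:
    """All three island criteria, in exact integer arithmetic."""
    length = len(sub)
    if length < MIN_LEN or "N" in sub:
        return False
    c, g = sub.count("C"), sub.count("G")
    if 2 * (c + g) < length or c == 0 or g == 0:
        return False
    return 5 * sub.count("CG") * length >= 3 * c * g


def _window_ok(sub: str) -> bool:
    if len(sub) != WINDOW or "N" in sub:
        return False
    c, g = sub.count("C"), sub.count("G")
    if 2 * (c + g) < WINDOW or c == 0 or g == 0:
        return False
    return 5 * sub.count("CG") * WINDOW >= 3 * c * g


def naive_islands(seq: str) -> list[tuple[int, int]]:
    """Brute-force maximal-region island search.

    Seeds candidate spans with every qualifying 200 bp window (tested by
    direct recounting), merges their coverage, then inside each span finds
    the longest qualifying region by full enumeration (leftmost on ties) and
    recurses into the flanks.
    """
    seq = seq.upper()
    n = len(seq)
    qual = [s for s in range(n - WINDOW + 1) if _window_ok(seq[s : s + WINDOW])]
    spans: list[tuple[int, int]] = []
    for s in qual:
        if spans and s <= spans[-1][1]:
            spans[-1] = (spans[-1][0], s + WINDOW)
        else:
            spans.append((s, s + WINDOW))
    regions: list[tuple[int, int]] = []

    def search(lo: int, hi: int) -> None:
        for length in range(hi - lo, MIN_LEN - 1, -1):
            for s in range(lo, hi - length + 1):
                if _region_ok(seq[s : s + length]):
                    regions.append((s, s + length))
                    search(lo, s)
                    search(s + length, hi)
                    return

    for lo, hi in spans:
        search(lo, hi)
    return sorted(regions)


def naive_spearman_rho(x, y) -> float:
    """Spearman rho from first principles: Pearson correlation of average ranks."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den
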