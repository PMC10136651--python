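"""Independent brute-force oracles, implemented in plain Python.

Deliberately naive: no scipy/numpy shortcuts, so they stay independent of
the library code paths they are used to check.
"""

from __future__ import annotations

import math


def midranks(xs: list[float]) -> list[float]:
    """Average (mid-rank) ranks, 1-based."""
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_brute(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def spearman_brute(x: list[float], y: list[float]) -> float:
    """Spearman r = Pearson correlation of mid-ranked vectors."""
    return pearson_brute(midranks(x), midranks(y))


def kendall_tau_b_brute(x: list[float], y: list[float]) -> float:
    """Tau-b by enumerating every pair with explicit tie counting."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


def ols_brute(x: list[float], y: list[float]) -> tuple[float, float]:
    """Slope/intercept from the normal equations."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(a * a for a in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def confusion_brute(
    bm_sets: dict[str, set], pb_sets: dict[str, set], panel_genes: int
) -> tuple[int, int, int, int]:
    """(tp, fn, fp, tn) by enumerating variant keys per pair.

    ``bm_sets``/``pb_sets`` map pair_id -> set of variant identity keys;
    a pair absent from both maps (or with two empty sets) is negative and
    contributes ``panel_genes`` presumed-negative calls.
    """
    tp = fn = fp = 0
    n_negative = 0
    for pid in set(bm_sets) | set(pb_sets):
        b = bm_sets.get(pid, set())
        p = pb_sets.get(pid, set())
        if not b and not p:
            n_negative += 1
            continue
        tp += len(b & p)
        fn += len(b - p)
        fp += len(p - b)
    return tp, fn, fp, n_negative * panel_genes
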