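"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: statistics
are computed by direct per-pair loops over the textbook formulas, and the
Ewens distribution uses sympy's exact Stirling numbers.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hamming(a, b) -> int:
    return sum(x != y for x, y in zip(a, b))


def pair_diffs(rows: list) -> list[int]:
    return [hamming(a, b) for a, b in itertools.combinations(rows, 2)]


def mean_pairwise(rows: list) -> float:
    d = pair_diffs(rows)
    return sum(d) / len(d)


def haplotype_diversity(rows: list) -> float:
    n = len(rows)
    counts = {}
    for r in rows:
        counts[tuple(r)] = counts.get(tuple(r), 0) + 1
    return n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts.values()))


def segregating_sites(rows: list) -> int:
    return sum(1 for col in zip(*rows) if len(set(col)) > 1)


def tajima_d_oracle(rows: list) -> float:
    n = len(rows)
    S = segregating_sites(rows)
    if S == 0 or n < 4:
        return math.nan
    k = mean_pairwise(rows)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def fu_fs_oracle(rows: list) -> float:
    from sympy.functions.combinatorial.numbers import stirling

    n = len(rows)
    theta = mean_pairwise(rows)
    if theta <= 0:
        return math.nan
    K_obs = len({tuple(r) for r in rows})
    rising = 1.0
    for i in range(n):
        rising *= theta + i
    pmf = [float(stirling(n, k, kind=1, signed=False)) * theta**k / rising for k in range(n + 1)]
    sp = sum(pmf[K_obs:])
    return math.log(sp / (1 - sp))


def r2_oracle(rows: list) -> float:
    n = len(rows)
    S = segregating_sites(rows)
    if S == 0:
        return math.nan
    k = mean_pairwise(rows)
    U = [0] * n
    for col in zip(*rows):
        counts = {}
        for v in col:
            counts[v] = counts.get(v, 0) + 1
        for v, c in counts.items():
            if c == 1 and len(counts) > 1:
                U[list(col).index(v)] += 1
    return math.sqrt(sum((u - k / 2) ** 2 for u in U) / n) / S


def phi_st_oracle(rows_a: list, rows_b: list) -> float:
    """Two-level AMOVA via explicit sums; Hamming counts as squared distances."""
    na, nb = len(rows_a), len(rows_b)
    N = na + nb
    allr = list(rows_a) + list(rows_b)
    d = [[hamming(a, b) for b in allr] for a in allr]
    ssd_total = sum(d[i][j] for i in range(N) for j in range(i + 1, N)) / N
    w_a = sum(d[i][j] for i in range(na) for j in range(i + 1, na)) / na
    w_b = sum(d[i][j] for i in range(na, N) for j in range(i + 1, N)) / nb
    ssd_within = w_a + w_b
    ssd_among = ssd_total - ssd_within
    sigma_b = ssd_within / (N - 2)
    n_bar = N - (na**2 + nb**2) / N
    sigma_a = (ssd_among - sigma_b) / n_bar
    denom = sigma_a + sigma_b
    return sigma_a / denom if denom > 0 else 0.0


def random_panel(rng: np.random.Generator, n_max: int = 12, L: int = 20) -> np.ndarray:
    """A random small alignment with at least one segregating site."""
    while True:
        n = int(rng.integers(4, n_max + 1))
        # a few random haplotypes shared among copies, plus noise mutations
        base = rng.integers(0, 2, size=(rng.integers(2, 5), L))
        mat = base[rng.integers(0, base.shape[0], size=n)].copy()
        noise = rng.random(mat.shape) < 0.02
        mat = np.where(noise, 1 - mat, mat)
        if segregating_sites(mat.tolist()) >= 1 and mean_pairwise(mat.tolist()) > 0:
            return mat.astype(np.uint8)
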