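"""Diversity statistics, neutrality tests and pairwise AMOVA Phi_ST.

All statistics operate on the usable sites of an alignment (sites with a gap
or ambiguity code in any sequence are dropped listwise).  Undefined values —
Tajima's D and R2 when there are no segregating sites, Fu's Fs when the mean
pairwise difference is zero — are returned as ``nan``; the ABC layer encodes
them as 0 with an explicit undefined flag.

Null distributions for the neutrality tests come from neutral constant-size
coalescent simulations conditioned on the sample size and the *observed*
number of segregating sites (the DnaSP "given S" convention), not on an
estimate of theta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .data_model import SeqRecordEntry, site_matrix, usable_site_mask

__all__ = [
    "DiversityStats",
    "AmovaResult",
    "diversity",
    "tajima_d",
    "fu_fs",
    "r2",
    "significance",
    "pairwise_phi_st",
    "pairwise_diffs",
    "records_matrix",
]


@dataclass(frozen=True)
class DiversityStats:
    n: int
    H: int
    h: float
    S: int
    k: float
    var_k: float
    pi: float
    usable_sites: int


@dataclass(frozen=True)
class AmovaResult:
    phi_st: float
    sigma2_among: float
    sigma2_within: float
    p_value: float
    n_permutations: int


def records_matrix(records: list[SeqRecordEntry]) -> np.ndarray:
    """Usable-site integer matrix (one row per gene copy) for a record list."""
    seqs = [r.sequence for r in records]
    return site_matrix(seqs, usable_site_mask(seqs))


def pairwise_diffs(mat: np.ndarray) -> np.ndarray:
    """n x n matrix of Hamming distances between rows."""
    n = mat.shape[0]
    if mat.shape[1] == 0:
        return np.zeros((n, n))
    # one-hot contraction: d_ij = L - sum_sites [x_i == x_j]
    d = np.empty((n, n))
    for i in range(n):
        d[i] = (mat != mat[i]).sum(axis=1)
    return d


def _segregating(mat: np.ndarray) -> np.ndarray:
    """Boolean mask over columns: more than one state present."""
    if mat.shape[1] == 0:
        return np.zeros(0, dtype=bool)
    return (mat != mat[0]).any(axis=0)


def _pair_values(mat: np.ndarray) -> np.ndarray:
    d = pairwise_diffs(mat)
    iu = np.triu_indices(mat.shape[0], k=1)
    return d[iu]


def diversity(records: list[SeqRecordEntry] | np.ndarray) -> DiversityStats:
    """Haplotype and nucleotide diversity for one population at one locus.

    h uses Nei's small-sample correction  h = n/(n-1) * (1 - sum p_i^2);
    k is the mean Hamming difference over all C(n,2) pairs and pi = k divided
    by the number of usable sites.
    """
    mat = records if isinstance(records, np.ndarray) else records_matrix(records)
    n = mat.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 gene copies, got {n}")
    _, hap_counts = np.unique(mat, axis=0, return_counts=True)
    p = hap_counts / n
    h = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    pairs = _pair_values(mat)
    k = float(pairs.mean())
    var_k = float(pairs.var())
    S = int(_segregating(mat).sum())
    L = mat.shape[1]
    return DiversityStats(
        n=n,
        H=len(hap_counts),
        h=h,
        S=S,
        k=k,
        var_k=var_k,
        pi=(k / L if L else 0.0),
        usable_sites=L,
    )


# -- Tajima's D --------------------------------------------------------------


@lru_cache(maxsize=None)
def _harmonic(n: int) -> float:
    """a1 = sum_{i<n} 1/i."""
    return sum(1.0 / i for i in range(1, n))


@lru_cache(maxsize=None)
def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajima_d(records: list[SeqRecordEntry] | np.ndarray) -> float:
    """Tajima's D; ``nan`` when undefined (S = 0 or n < 4).

    D contrasts the pairwise-difference estimator of theta with the
    segregating-sites estimator; the variance constants degenerate below
    n = 4, so smaller samples are reported as undefined.
    """
    mat = records if isinstance(records, np.ndarray) else records_matrix(records)
    n = mat.shape[0]
    S = int(_segregating(mat).sum())
    if n < 4 or S == 0:
        return math.nan
    k = float(_pair_values(mat).mean())
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0.0:
        return math.nan
    return (k - S / a1) / denom


# -- Fu's Fs -----------------------------------------------------------------


def _log_stirling_first(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        if m == 1:
            cur[1] = 0.0
        else:
            # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
            cur[1:] = np.logaddexp(prev[1:] + math.log(m - 1), prev[:-1])
        prev = cur
    return prev


def ewens_k_logpmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling formula."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = _log_stirling_first(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    ks = np.arange(n + 1)
    return ls + ks * math.log(theta) - log_rising


def fu_fs(records: list[SeqRecordEntry] | np.ndarray) -> float:
    """Fu's Fs: log-odds of sampling at least the observed number of alleles.

    S' = P(K >= K_obs | theta_hat = k) under the Ewens sampling formula with
    theta_hat the mean pairwise difference; Fs = ln(S'/(1-S')).  Undefined
    (``nan``) when k = 0.
    """
    mat = records if isinstance(records, np.ndarray) else records_matrix(records)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least 2 gene copies")
    k = float(_pair_values(mat).mean())
    if k <= 0:
        return math.nan
    K_obs = int(np.unique(mat, axis=0).shape[0])
    logpmf = ewens_k_logpmf(n, k)
    from scipy.special import logsumexp

    log_tail = logsumexp(logpmf[K_obs:])
    log_head = logsumexp(logpmf[:K_obs]) if K_obs > 0 else -np.inf
    # Fs = log S' - log(1 - S'), computed in log space for stability
    return float(log_tail - log_head)


# -- Ramos-Onsins & Rozas R2 -------------------------------------------------


def r2(records: list[SeqRecordEntry] | np.ndarray) -> float:
    """R2 = sqrt( (1/n) sum_i (U_i - k/2)^2 ) / S, U_i = singletons on copy i.

    Undefined (``nan``) when S = 0.
    """
    mat = records if isinstance(records, np.ndarray) else records_matrix(records)
    n = mat.shape[0]
    seg = _segregating(mat)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    k = float(_pair_values(mat).mean())
    sub = mat[:, seg]
    U = np.zeros(n)
    for j in range(sub.shape[1]):
        states, counts = np.unique(sub[:, j], return_counts=True)
        for st, c in zip(states, counts):
            if c == 1:
                U[np.argmax(sub[:, j] == st)] += 1
    return float(math.sqrt(np.mean((U - k / 2.0) ** 2)) / S)


# -- null simulations and significance ---------------------------------------


def _sim_null_matrix(n: int, S: int, rng: np.random.Generator) -> np.ndarray:
    """One neutral constant-size coalescent genealogy with exactly S mutations.

    Coalescent intervals are exponential with rate C(j,2) (time in units of
    2N generations — the scale cancels because mutations are placed by
    branch-length weighting).  Mutations land on branches proportionally to
    length, each at its own site (infinite sites).
    """
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[i1], active[i2]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        for idx in sorted((i1, i2), reverse=True):
            active.pop(idx)
        active.append(nxt)
        nxt += 1
    # branch lengths for all non-root nodes
    nodes = np.arange(n_nodes - 1)
    lengths = time[parent[nodes]] - time[nodes]
    probs = lengths / lengths.sum()
    hits = rng.choice(n_nodes - 1, size=S, p=probs)
    # leaf sets by propagation: children lists
    mat = np.zeros((n, S), dtype=np.uint8)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    for c in range(n_nodes - 1):
        children[parent[c]].append(c)
    for s_idx, node in enumerate(hits):
        stack = [int(node)]
        while stack:
            v = stack.pop()
            if v < n:
                mat[v, s_idx] = 1
            else:
                stack.extend(children[v])
    return mat


_STAT_FUNCS = {"D": tajima_d, "Fs": fu_fs, "r2": r2}


def significance(
    records: list[SeqRecordEntry] | np.ndarray,
    statistic: str,
    n_sims: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Coalescent-simulation p-value for a neutrality statistic.

    Returns ``(observed, p)``.  The null is a constant-size neutral
    coalescent conditioned on (n, observed S).  Small values are the
    "significant" direction for Fs and R2 (one-tailed, P(null <= obs));
    D is two-tailed.  Add-one correction: p = (b + 1)/(n_sims + 1).
    """
    if statistic not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    mat = records if isinstance(records, np.ndarray) else records_matrix(records)
    obs = _STAT_FUNCS[statistic](mat)
    if math.isnan(obs):
        raise ValueError(f"{statistic} undefined on this input")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = mat.shape[0]
    S = int(_segregating(mat).sum())
    null = np.empty(n_sims)
    f = _STAT_FUNCS[statistic]
    for i in range(n_sims):
        null[i] = f(_sim_null_matrix(n, S, rng))
    null = null[~np.isnan(null)]
    m = len(null)
    if statistic == "D":
        lo = int(np.sum(null <= obs))
        hi = int(np.sum(null >= obs))
        p = min(1.0, 2.0 * (min(lo, hi) + 1) / (m + 1))
    else:
        b = int(np.sum(null <= obs))
        p = (b + 1) / (m + 1)
    return obs, p


# -- pairwise AMOVA Phi_ST ---------------------------------------------------


def _amova_from_distance(
    d: np.ndarray, sizes: tuple[int, int]
) -> tuple[float, float, float]:
    """Two-level AMOVA variance components from a distance matrix.

    Hamming counts are used directly as the squared inter-haplotype
    distances (the Arlequin molecular-distance convention).
    """
    na, nb = sizes
    N = na + nb
    idx_a = np.arange(na)
    idx_b = np.arange(na, N)
    total = d[np.triu_indices(N, k=1)].sum() / N
    within_a = d[np.ix_(idx_a, idx_a)][np.triu_indices(na, k=1)].sum() / na
    within_b = d[np.ix_(idx_b, idx_b)][np.triu_indices(nb, k=1)].sum() / nb
    ssd_within = within_a + within_b
    ssd_among = total - ssd_within
    sigma_b = ssd_within / (N - 2)
    n_bar = (N - (na**2 + nb**2) / N) / (2 - 1)
    sigma_a = (ssd_among / (2 - 1) - sigma_b) / n_bar
    denom = sigma_a + sigma_b
    phi = sigma_a / denom if denom > 0 else 0.0
    return phi, sigma_a, sigma_b


def phi_st_value(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Point estimate of pairwise Phi_ST (no permutations)."""
    full = np.vstack([mat_a, mat_b])
    d = pairwise_diffs(full)
    phi, _, _ = _amova_from_distance(d, (mat_a.shape[0], mat_b.shape[0]))
    return phi


def pairwise_phi_st(
    records_a: list[SeqRecordEntry] | np.ndarray,
    records_b: list[SeqRecordEntry] | np.ndarray,
    n_perms: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
) -> AmovaResult:
    """Two-population AMOVA Phi_ST with a label-permutation test.

    p is the proportion of permutations with Phi_ST >= observed, with the
    add-one correction.  When every sequence is identical Phi_ST is defined
    as 0 with p = 1.
    """
    mat_a = records_a if isinstance(records_a, np.ndarray) else records_matrix(records_a)
    mat_b = records_b if isinstance(records_b, np.ndarray) else records_matrix(records_b)
    na, nb = mat_a.shape[0], mat_b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each population needs at least 2 gene copies")
    if mat_a.shape[1] != mat_b.shape[1]:
        raise ValueError("populations must share the same usable sites")
    full = np.vstack([mat_a, mat_b])
    d = pairwise_diffs(full)
    if not d.any():
        return AmovaResult(0.0, 0.0, 0.0, 1.0, n_perms)
    phi, sa, sb = _amova_from_distance(d, (na, nb))
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    b = 0
    N = na + nb
    for _ in range(n_perms):
        perm = rng.permutation(N)
        dp = d[np.ix_(perm, perm)]
        phi_p, _, _ = _amova_from_distance(dp, (na, nb))
        if phi_p >= phi:
            b += 1
    p = (b + 1) / (n_perms + 1)
    return AmovaResult(phi, sa, sb, p, n_perms)
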