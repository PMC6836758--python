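"""Intra-locus recombination: the PHI test and four-gamete site filtering.

Coalescent genealogies (and hence every downstream analysis here) assume no
recombination within a locus.  Two screens are provided:

* :func:`phi_test` — a pairwise homoplasy index (Phi_w).  For biallelic
  site pairs the incompatibility score is the binary four-gamete indicator
  (1 if all four gametes occur, else 0); Phi_w is the mean score over
  parsimony-informative site pairs lying within ``window_w`` base pairs of
  each other.  Recombination makes incompatibility grow with distance, so a
  small windowed mean relative to site-order permutations is evidence of
  recombination: p = proportion of permutations with Phi_w <= observed.
* :func:`filter_recombinant_sites` — greedy excision of sites until no pair
  of biallelic sites shows all four gametes.  Removal order is by number of
  violating pairs a site participates in, leftmost first on ties, which
  makes the filter deterministic and auditable.

The binary score is a simplification of the refined incompatibility score
used for multi-state characters by SplitsTree's implementation; sites with
more than two states are excluded from pairing and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import SeqRecordEntry, site_matrix, usable_site_mask

__all__ = [
    "PhiTestResult",
    "FilterReport",
    "four_gamete_pairs",
    "filter_recombinant_sites",
    "phi_test",
]


@dataclass(frozen=True)
class PhiTestResult:
    phi_w: float
    p_value: float
    n_informative_sites: int
    window_w: int
    applicable: bool = True


@dataclass
class FilterReport:
    removed_site_positions: list[int]  # 1-based, in original coordinates
    retained_records: list[SeqRecordEntry]
    violating_pairs_before: int
    violating_pairs_after: int


def _full_matrix(records: list[SeqRecordEntry]) -> np.ndarray:
    """Full-length coded matrix (gap columns coded 0 = never biallelic-clean)."""
    seqs = [r.sequence for r in records]
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)
    mask = usable_site_mask(seqs)
    arr = arr.copy()
    arr[:, ~mask] = 0
    return arr


def _biallelic_columns(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(indices of exactly-2-state usable columns, indices of >2-state columns)."""
    bi, multi = [], []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if (col == 0).any():  # masked column
            continue
        n_states = len(np.unique(col))
        if n_states == 2:
            bi.append(j)
        elif n_states > 2:
            multi.append(j)
    return np.asarray(bi, dtype=int), np.asarray(multi, dtype=int)


def _gamete_violation_matrix(arr: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Boolean matrix V[i, j]: biallelic columns cols[i], cols[j] show all
    four gametes."""
    m = len(cols)
    if m == 0:
        return np.zeros((0, 0), dtype=bool)
    # binarize each biallelic column against its first state
    B = np.empty((arr.shape[0], m), dtype=bool)
    for i, c in enumerate(cols):
        B[:, i] = arr[:, c] != arr[0, c]
    V = np.zeros((m, m), dtype=bool)
    Bf = B.astype(np.float64)
    n = B.shape[0]
    n11 = Bf.T @ Bf
    n10 = Bf.T @ (1 - Bf)
    n01 = (1 - Bf).T @ Bf
    n00 = n - n11 - n10 - n01
    V = (n11 > 0) & (n10 > 0) & (n01 > 0) & (n00 > 0)
    np.fill_diagonal(V, False)
    return V


def four_gamete_pairs(records: list[SeqRecordEntry]) -> list[tuple[int, int]]:
    """All violating biallelic site pairs, as 1-based position pairs.

    A pair violates the four-gamete criterion when all four gametes (00,
    01, 10, 11) occur, which under infinite sites implies recombination (or
    recurrent mutation).  Sites with more than two states are excluded from
    pairing.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    arr = _full_matrix(records)
    cols, _ = _biallelic_columns(arr)
    V = _gamete_violation_matrix(arr, cols)
    out = []
    for i, j in zip(*np.nonzero(np.triu(V, k=1))):
        out.append((int(cols[i]) + 1, int(cols[j]) + 1))
    return out


def filter_recombinant_sites(records: list[SeqRecordEntry]) -> FilterReport:
    """Greedily excise sites until the alignment passes the four-gamete test.

    Each round removes the site participating in the most remaining
    violating pairs (leftmost on ties), then recomputes.  The output always
    passes :func:`four_gamete_pairs` with zero violations, and the filter
    is idempotent.
    """
    arr = _full_matrix(records)
    cols, _ = _biallelic_columns(arr)
    V = _gamete_violation_matrix(arr, cols)
    before = int(np.triu(V, k=1).sum())
    removed: list[int] = []
    keep = np.ones(len(cols), dtype=bool)
    while True:
        counts = V.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = int(np.argmax(counts))  # argmax takes the leftmost maximum
        removed.append(int(cols[worst]) + 1)
        keep[worst] = False
        V[worst, :] = False
        V[:, worst] = False
    removed_sorted = sorted(removed)
    drop0 = {p - 1 for p in removed_sorted}
    retained = [
        SeqRecordEntry(
            r.individual,
            r.population,
            r.region,
            "".join(ch for i, ch in enumerate(r.sequence) if i not in drop0),
            r.allele_index,
        )
        for r in records
    ]
    return FilterReport(
        removed_site_positions=removed_sorted,
        retained_records=retained,
        violating_pairs_before=before,
        violating_pairs_after=0,
    )


def _informative_columns(arr: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Parsimony-informative biallelic columns: both states appear >= 2 times."""
    out = []
    for c in cols:
        col = arr[:, c]
        minor = (col != col[0]).sum()
        if 2 <= minor <= len(col) - 2:
            out.append(c)
    return np.asarray(out, dtype=int)


def phi_test(
    records: list[SeqRecordEntry],
    window_w: int = 100,
    n_perms: int = 1000,
    rng_seed: int | np.random.Generator = 0,
) -> PhiTestResult:
    """Pairwise homoplasy index test for intra-locus recombination.

    Requires >= 4 sequences and >= 2 parsimony-informative sites; otherwise
    the result is flagged not applicable.  The permutation null shuffles
    site positions, keeping the pairwise incompatibility structure fixed.
    """
    if len(records) < 4:
        raise ValueError("need at least 4 sequences")
    arr = _full_matrix(records)
    bi, _ = _biallelic_columns(arr)
    inf_cols = _informative_columns(arr, bi)
    m = len(inf_cols)
    if m < 2:
        return PhiTestResult(0.0, 1.0, m, window_w, applicable=False)
    V = _gamete_violation_matrix(arr, inf_cols).astype(np.float64)
    pos = inf_cols.astype(np.float64)

    def windowed_mean(p: np.ndarray) -> float:
        dist = np.abs(p[:, None] - p[None, :])
        close = (dist <= window_w) & ~np.eye(m, dtype=bool)
        n_pairs = close.sum() / 2
        if n_pairs == 0:
            return 0.0
        return float((V * close).sum() / 2 / n_pairs)

    obs = windowed_mean(pos)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    b = 0
    for _ in range(n_perms):
        perm = rng.permutation(m)
        if windowed_mean(pos[perm]) <= obs:
            b += 1
    p = (b + 1) / (n_perms + 1)
    return PhiTestResult(obs, min(p, 1.0), m, window_w)
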