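"""Clustering of domain-bound peptide motifs and isotype specificity.

Short linear motifs bound by a domain in solved structures are compared with
the optimal-string-alignment (restricted Damerau-Levenshtein) distance —
insertions, deletions, substitutions and adjacent transpositions each cost
one.  Complete-linkage hierarchical clustering cut at height ``h`` groups
motifs so that any motif needs more than ``h`` edits to resemble any motif
outside its cluster.  A cluster is isotype-specific when at least ``purity``
of its motifs interact with one isotype group (reference vs non-reference);
domains where the two groups are specific to distinct clusters use different
binding motifs depending on the isotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MotifInteraction",
    "osa_distance",
    "damerau_levenshtein",
    "motif_distance_matrix",
    "cluster_motifs",
    "isotype_specific_clusters",
    "motif_association_test",
]


@dataclass(frozen=True)
class MotifInteraction:
    hmm_name: str
    motif: str
    isotype_simplified: str  # reference | non_reference
    source_id: str = ""

    def __post_init__(self):
        if not self.motif:
            raise ValueError("motif must be non-empty")


def osa_distance(s: str, t: str) -> int:
    """Optimal string alignment distance (restricted Damerau-Levenshtein).

    Like Levenshtein plus transposition of adjacent characters, with the
    restriction that no substring is edited twice.
    """
    m, n = len(s), len(t)
    prev2: List[int] = []
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if s[i - 1] == t[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and s[i - 1] == t[j - 2] and s[i - 2] == t[j - 1]:
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[n]


def damerau_levenshtein(s: str, t: str) -> int:
    """Unrestricted Damerau-Levenshtein distance (true metric)."""
    alphabet = {c: 0 for c in s + t}
    m, n = len(s), len(t)
    maxdist = m + n
    d = [[maxdist] * (n + 2) for _ in range(m + 2)]
    for i in range(m + 1):
        d[i + 1][1] = i
        d[i + 1][0] = maxdist
    for j in range(n + 1):
        d[1][j + 1] = j
        d[0][j + 1] = maxdist
    last_row = dict(alphabet)
    for i in range(1, m + 1):
        last_col = 0
        for j in range(1, n + 1):
            i_ = last_row[t[j - 1]]
            j_ = last_col
            cost = 0 if s[i - 1] == t[j - 1] else 1
            if cost == 0:
                last_col = j
            d[i + 1][j + 1] = min(
                d[i][j] + cost,
                d[i + 1][j] + 1,
                d[i][j + 1] + 1,
                d[i_][j_] + (i - i_ - 1) + 1 + (j - j_ - 1),
            )
        last_row[s[i - 1]] = i
    return d[m + 1][n + 1]


def motif_distance_matrix(motifs: Sequence[str], method: str = "osa") -> np.ndarray:
    """Symmetric integer distance matrix between motif strings."""
    if len(motifs) < 1:
        raise ValueError("need at least one motif")
    fn = {"osa": osa_distance, "dl": damerau_levenshtein}[method]
    n = len(motifs)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = fn(motifs[i], motifs[j])
    return mat


def cluster_motifs(distmat: np.ndarray, h: float = 4.0, method: str = "complete") -> np.ndarray:
    """Hierarchical clustering cut at height ``h``; labels 1..k.

    Equivalent to R's ``hclust`` + ``cutree(h=h)``: clusters keep merges at
    height <= h and split above.
    """
    distmat = np.asarray(distmat, dtype=float)
    n = distmat.shape[0]
    if n == 1:
        return np.array([1])
    Z = linkage(squareform(distmat, checks=False), method=method)
    return fcluster(Z, t=h, criterion="distance")


def isotype_specific_clusters(
    interactions: Sequence[MotifInteraction],
    labels: Sequence[int],
    min_count: int = 3,
    purity: float = 0.8,
) -> Tuple[pd.DataFrame, List[str]]:
    """Per-(domain, cluster) isotype counts and specificity calls.

    A cluster is considered when either isotype group appears >= ``min_count``
    times in it; it is specific to the group holding >= ``purity`` of its
    motifs (inclusive boundary).  The second return value lists domains where
    reference and non-reference are specific to distinct clusters.
    """
    if len(interactions) != len(labels):
        raise ValueError("labels must align with interactions")
    df = pd.DataFrame(
        {
            "hmm_name": [i.hmm_name for i in interactions],
            "cluster": list(labels),
            "isotype": [i.isotype_simplified for i in interactions],
        }
    )
    rows = []
    for (name, cl), sub in df.groupby(["hmm_name", "cluster"], sort=True):
        n_ref = int((sub["isotype"] == "reference").sum())
        n_non = int((sub["isotype"] == "non_reference").sum())
        total = n_ref + n_non
        considered = max(n_ref, n_non) >= min_count
        specific_to = None
        if considered and total > 0:
            if n_ref / total >= purity:
                specific_to = "reference"
            elif n_non / total >= purity:
                specific_to = "non_reference"
        rows.append(
            {
                "hmm_name": name,
                "cluster": cl,
                "n_reference": n_ref,
                "n_non_reference": n_non,
                "considered": considered,
                "specific_to": specific_to,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["hmm_name", "cluster", "n_reference", "n_non_reference", "considered", "specific_to"],
    )
    flagged: List[str] = []
    for name, sub in table.groupby("hmm_name"):
        ref_cl = set(sub.loc[sub["specific_to"] == "reference", "cluster"])
        non_cl = set(sub.loc[sub["specific_to"] == "non_reference", "cluster"])
        if ref_cl and non_cl and ref_cl.isdisjoint(non_cl):
            flagged.append(name)
    return table, flagged


# ---------------------------------------------------------------------------
# Exact k x 2 association test

def _log_table_prob(table: np.ndarray, lgamma=math.lgamma) -> float:
    # fixed-margin probability: prod(r_i!) prod(c_j!) / (N! prod(n_ij!))
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = sum(lgamma(r + 1) for r in rows) + sum(lgamma(c + 1) for c in cols)
    lp -= lgamma(n + 1) + sum(lgamma(v + 1) for v in table.ravel())
    return lp


def _enumerate_pvalue(table: np.ndarray) -> float:
    rows = table.sum(axis=1)
    c1 = int(table[:, 0].sum())
    obs_lp = _log_table_prob(table)
    cutoff = obs_lp + 1e-7  # tolerance for float ties, as exact tests conventionally use
    k = len(rows)
    total = 0.0
    cell = np.zeros(k, dtype=int)

    def rec(i: int, remaining: int, lp_partial: float):
        nonlocal total
        if i == k - 1:
            if remaining <= rows[i]:
                cell[i] = remaining
                t = np.column_stack([cell, rows - cell])
                lp = _log_table_prob(t)
                if lp <= cutoff:
                    total += math.exp(lp)
            return
        lo = max(0, remaining - int(rows[i + 1 :].sum()))
        hi = min(int(rows[i]), remaining)
        for a in range(lo, hi + 1):
            cell[i] = a
            rec(i + 1, remaining - a, 0.0)

    rec(0, c1, 0.0)
    return min(total, 1.0)


def _montecarlo_pvalue(table: np.ndarray, n_draws: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    rows = table.sum(axis=1)
    c1 = int(table[:, 0].sum())
    n = int(table.sum())
    row_id = np.repeat(np.arange(len(rows)), rows)
    obs_lp = _log_table_prob(table)
    cutoff = obs_lp + 1e-7
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(n)
        a = np.bincount(row_id[perm[:c1]], minlength=len(rows))
        t = np.column_stack([a, rows - a])
        if _log_table_prob(t) <= cutoff:
            hits += 1
    return (hits + 1) / (n_draws + 1)


def motif_association_test(
    contingency: Iterable[Iterable[int]],
    max_tables: int = 2_000_000,
    n_draws: int = 100_000,
    seed: int = 0,
) -> float:
    """Fisher's exact test on a k x 2 contingency table.

    Exhaustive enumeration of fixed-margin tables when the table space is
    small (p = total probability of tables no more probable than the
    observed one); seeded Monte-Carlo permutation estimate above the
    enumeration budget.
    """
    table = np.asarray(list(contingency), dtype=int)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("contingency must be k x 2 with k >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    rows = table.sum(axis=1)
    space = np.prod(rows + 1.0)
    if space <= max_tables:
        return _enumerate_pvalue(table)
    return _montecarlo_pvalue(table, n_draws=n_draws, seed=seed)
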