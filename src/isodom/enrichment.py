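"""Overlap enrichment (Fisher + BH-FDR) and isotype-skew testing via
preranked GSEA.

Two complementary questions are answered per protein domain:

* *association* — are the genes carrying this domain overrepresented in a
  gene set?  One-sided (greater) Fisher's exact test on the 2x2 overlap
  table, BH-corrected within each domain's family of sets.
* *skew* — within a significantly associated set, does the set prefer the
  reference or non-reference isotype of the domain?  Genes are ranked by
  their average overall domain variation in decreasing order; a weighted
  Kolmogorov-Smirnov running-sum (preranked GSEA) with gene-label
  permutations tests whether the set concentrates at the top (positive NES:
  non-reference end) or the bottom (negative NES: reference end).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "SkewResult",
    "fisher_exact_2x2",
    "fisher_overlap",
    "bh_adjust",
    "batch_enrichment",
    "read_gmt",
    "write_gmt",
    "filter_gene_sets",
    "rank_genes_by_variation",
    "preranked_gsea",
    "domain_geneset_enrichment",
    "skew_scan",
]


@dataclass
class EnrichmentResult:
    unit: str
    label: str
    a_in: int  # in unit & in target
    a_out: int  # in unit, not target
    b_in: int  # in target, not unit
    b_out: int  # in neither
    odds_ratio: float  # conditional MLE
    sample_odds_ratio: float
    p: float
    fdr: float | None = None


@dataclass
class SkewResult:
    hmm_name: str
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float | None = None

    @property
    def direction(self) -> str:
        return "non_reference" if self.nes > 0 else "reference"


# ---------------------------------------------------------------------------
# Fisher's exact test on 2x2 tables

def fisher_pvalues_fixed_margins(n: int, K: int, N1: int, alternative: str = "two_sided") -> np.ndarray:
    """Fisher p-values for every table with margins (row1=K, col1=N1, total=n).

    Returns one p per feasible top-left cell a = max(0, K+N1-n) .. min(K, N1).
    The two-sided p sums all tables (with the same margins) whose probability
    does not exceed the observed one, with the conventional 1 + 1e-7 relative
    tolerance for float ties — the same definition R's fisher.test and scipy
    use.
    """
    lo = max(0, K + N1 - n)
    hi = min(K, N1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, K, N1)
    if alternative == "greater":
        return np.minimum(np.cumsum(pmf[::-1])[::-1], 1.0)
    if alternative == "less":
        return np.minimum(np.cumsum(pmf), 1.0)
    if alternative != "two_sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    order = np.argsort(pmf, kind="stable")
    csum = np.cumsum(pmf[order])
    out = np.empty_like(pmf)
    sorted_pmf = pmf[order]
    for idx, p_obs in enumerate(pmf):
        k = np.searchsorted(sorted_pmf, p_obs * (1 + 1e-7), side="right")
        out[idx] = csum[k - 1] if k > 0 else 0.0
    return np.minimum(out, 1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "two_sided") -> float:
    """Exact hypergeometric p for the table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    K = a + b  # row-1 margin
    N1 = a + c  # column-1 margin
    lo = max(0, K + N1 - n)
    ps = fisher_pvalues_fixed_margins(n, K, N1, alternative)
    return float(ps[a - lo])


def fisher_overlap(
    set_a: Set[str],
    set_b: Set[str],
    universe: Set[str],
    alternative: str = "greater",
    unit: str = "a",
    label: str = "b",
) -> EnrichmentResult:
    """Fisher's exact test of the overlap of two gene/domain sets.

    Both sets are intersected with the universe; the contingency table is
    built over the universe.  The reported odds ratio is the conditional
    maximum-likelihood estimate (as R's fisher.test prints); the sample
    cross-product ratio is reported alongside.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A = set(set_a) & universe
    B = set(set_b) & universe
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    p = fisher_exact_2x2(a, b, c, d, alternative=alternative)
    table = [[a, b], [c, d]]
    try:
        cond_or = float(_cond_odds_ratio(table, kind="conditional").statistic)
    except Exception:
        cond_or = float("nan")
    sample_or = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return EnrichmentResult(
        unit=unit, label=label, a_in=a, a_out=b, b_in=c, b_out=d,
        odds_ratio=cond_or, sample_odds_ratio=sample_or, p=p,
    )


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    pvals = np.asarray(list(pvals), dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


def batch_enrichment(
    units: Mapping[str, Set[str]],
    targets: Mapping[str, Set[str]],
    universe: Set[str],
    alternative: str = "two_sided",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One Fisher test per unit x target with BH-FDR over the whole family.

    The caller defines the multiple-testing family by what it passes: call
    once per domain for per-domain correction, or once for a whole analysis.
    """
    if not units or not targets:
        raise ValueError("units and targets must be non-empty")
    results: List[EnrichmentResult] = []
    for uname in sorted(units):
        for tname in sorted(targets):
            results.append(
                fisher_overlap(units[uname], targets[tname], universe,
                               alternative=alternative, unit=uname, label=tname)
            )
    fdr = bh_adjust([r.p for r in results])
    rows = []
    for r, q in zip(results, fdr):
        r.fdr = float(q)
        rows.append(
            {
                "unit": r.unit, "label": r.label, "a_in": r.a_in, "a_out": r.a_out,
                "b_in": r.b_in, "b_out": r.b_out, "odds_ratio": r.odds_ratio,
                "sample_odds_ratio": r.sample_odds_ratio, "p": r.p, "fdr": r.fdr,
                "significant": r.fdr < fdr_threshold,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gene-set collections (GMT)

def read_gmt(source: Union[str, Path]) -> Dict[str, Set[str]]:
    """Read a GMT file: name <TAB> description <TAB> gene1 <TAB> gene2 ..."""
    sets: Dict[str, Set[str]] = {}
    for line in Path(source).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], dest: Union[str, Path]) -> None:
    lines = [
        "\t".join([name, "isodom"] + sorted(set(genes))) for name, genes in sorted(sets.items())
    ]
    Path(dest).write_text("\n".join(lines) + "\n")


def filter_gene_sets(
    sets: Mapping[str, Set[str]],
    universe: Set[str] | None = None,
    min_size: int = 10,
    max_size: int = 1000,
) -> Dict[str, Set[str]]:
    """Size-filter gene sets (10..1000 by default), optionally after
    intersecting with the analysis universe."""
    out: Dict[str, Set[str]] = {}
    for name, genes in sets.items():
        g = set(genes) if universe is None else set(genes) & set(universe)
        if min_size <= len(g) <= max_size:
            out[name] = g
    return out


# ---------------------------------------------------------------------------
# Variation ranking and preranked GSEA

def rank_genes_by_variation(
    annotations: pd.DataFrame,
    gene_map: Mapping[str, str],
    hmm_name: str,
) -> Tuple[List[str], np.ndarray]:
    """Genes carrying ``hmm_name`` ranked by decreasing average overall
    variation (ties broken lexicographically by gene symbol).

    Returns the ordered gene list and the aligned score vector.
    """
    sub = annotations[annotations["hmm_name"] == hmm_name].copy()
    if sub.empty:
        raise ValueError(f"domain {hmm_name!r} absent from annotations")
    sub["gene"] = sub["seq_id"].map(dict(gene_map))
    sub = sub.dropna(subset=["gene"])
    if sub.empty:
        raise ValueError(f"no gene mapping for any occurrence of {hmm_name!r}")
    means = sub.groupby("gene")["overall_variation"].mean()
    ordered = sorted(means.index, key=lambda g: (-means[g], g))
    return ordered, means[ordered].to_numpy(dtype=float)


def _running_es(hit_mask: np.ndarray, weights: np.ndarray) -> float:
    """Signed enrichment score: extreme of the weighted KS running sum."""
    n = hit_mask.size
    nh = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all-zero scores inside the set: uniform hit weights
        hit_w = hit_mask.astype(float)
        denom = hit_w.sum()
    steps = hit_w / denom - (~hit_mask).astype(float) / (n - nh)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranked_genes: Sequence[str],
    scores: Sequence[float],
    gene_set: Set[str],
    n_perm: int = 10_000,
    seed: int = 0,
    set_name: str = "",
    hmm_name: str = "",
) -> SkewResult | None:
    """Preranked GSEA with gene-label permutations.

    Weight exponent 1 on |score|.  NES normalises the observed ES by the
    mean |ES| of same-sign permutation scores; the permutation p-value uses
    a +1 pseudocount.  Returns ``None`` (not tested) when the set covers
    none, or all, of the ranked genes.
    """
    genes = list(ranked_genes)
    n = len(genes)
    hit_mask = np.array([g in gene_set for g in genes], dtype=bool)
    nh = int(hit_mask.sum())
    if nh == 0 or nh == n:
        return None
    weights = np.abs(np.asarray(scores, dtype=float))
    es = _running_es(hit_mask, weights)

    rng = np.random.default_rng(seed)
    # vectorised permutations: random size-nh subsets of positions
    keys = rng.random((n_perm, n))
    order = np.argpartition(keys, nh - 1, axis=1)[:, :nh]
    perm_mask = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(perm_mask, order, True, axis=1)

    hit_w = np.where(perm_mask, weights[None, :], 0.0)
    denom = hit_w.sum(axis=1)
    zero = denom == 0
    if np.any(zero):
        hit_w[zero] = perm_mask[zero].astype(float)
        denom = hit_w.sum(axis=1)
    steps = hit_w / denom[:, None] - (~perm_mask).astype(float) / (n - nh)
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    perm_es = running[np.arange(n_perm), idx]

    same_sign = perm_es > 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = 0.0
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / float(np.mean(np.abs(perm_es[same_sign])))
        p = (1 + int(np.sum(np.abs(perm_es[same_sign]) >= abs(es)))) / (1 + n_same)
    return SkewResult(hmm_name=hmm_name, set_name=set_name, es=es, nes=nes, p=float(p))


# ---------------------------------------------------------------------------
# Full domain/gene-set pipeline

def domain_geneset_enrichment(
    annotations: pd.DataFrame,
    gene_map: Mapping[str, str],
    collections: Mapping[str, Set[str]],
    min_set_size: int = 10,
    max_set_size: int = 1000,
    min_genes_per_domain: int = 10,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Domain x gene-set association tests with per-domain BH-FDR.

    Filters: sets sized 10..1000, domains found in >= 10 genes, both reduced
    to the common gene universe, undersized sets dropped again after the
    intersection.  One-sided (greater) Fisher tests.
    """
    ann = annotations.copy()
    ann["gene"] = ann["seq_id"].map(dict(gene_map))
    ann = ann.dropna(subset=["gene"])
    domain_genes = {
        name: set(sub["gene"]) for name, sub in ann.groupby("hmm_name")
    }
    sets0 = filter_gene_sets(collections, None, min_set_size, max_set_size)
    universe = set(ann["gene"]) & set().union(*sets0.values()) if sets0 else set()
    domain_genes = {
        n: g & universe for n, g in domain_genes.items() if len(g & universe) >= min_genes_per_domain
    }
    sets = filter_gene_sets(sets0, universe, min_set_size, max_set_size)
    frames = []
    for dom in sorted(domain_genes):
        df = batch_enrichment(
            {dom: domain_genes[dom]}, sets, universe,
            alternative="greater", fdr_threshold=fdr_threshold,
        )
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["unit", "label", "a_in", "a_out", "b_in", "b_out", "odds_ratio",
                     "sample_odds_ratio", "p", "fdr", "significant"]
        )
    return pd.concat(frames, ignore_index=True)


def skew_scan(
    significant_pairs: Iterable[Tuple[str, str]],
    annotations: pd.DataFrame,
    gene_map: Mapping[str, str],
    collections: Mapping[str, Set[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Isotype-skew test for each significant (domain, gene set) pair.

    Per-domain BH correction across that domain's tested sets.  Pairs whose
    set covers all or none of the domain's ranked genes are reported as not
    tested (NaN scores) and excluded from the correction family.
    """
    pairs = sorted(significant_pairs)
    results: Dict[str, List[SkewResult]] = {}
    not_tested: List[Tuple[str, str]] = []
    rng = np.random.default_rng(seed)
    for dom, set_name in pairs:
        genes, scores = rank_genes_by_variation(annotations, gene_map, dom)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = preranked_gsea(
            genes, scores, collections[set_name], n_perm=n_perm, seed=sub_seed,
            set_name=set_name, hmm_name=dom,
        )
        if res is None:
            not_tested.append((dom, set_name))
        else:
            results.setdefault(dom, []).append(res)
    rows = []
    for dom in sorted(results):
        rs = results[dom]
        fdr = bh_adjust([r.p for r in rs])
        for r, q in zip(rs, fdr):
            r.fdr = float(q)
            rows.append(
                {
                    "hmm_name": r.hmm_name, "set_name": r.set_name, "es": r.es,
                    "nes": r.nes, "p": r.p, "fdr": r.fdr, "direction": r.direction,
                    "significant": r.fdr < fdr_threshold, "tested": True,
                }
            )
    for dom, set_name in not_tested:
        rows.append(
            {
                "hmm_name": dom, "set_name": set_name, "es": math.nan, "nes": math.nan,
                "p": math.nan, "fdr": math.nan, "direction": None,
                "significant": False, "tested": False,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["hmm_name", "set_name", "es", "nes", "p", "fdr", "direction", "significant", "tested"],
    )
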