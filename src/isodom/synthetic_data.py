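"""Seeded synthetic fixtures with known ground truth for every analysis step.

Each generator is a pure function of (parameters, seed) built on
``numpy.random.default_rng``; regenerating with the same inputs is
bit-identical.  The fixtures emulate the *shape* of the real inputs (pfam_scan
records, Cα traces, motif tables, gene sets, TPM matrices) at desk scale, with
planted truth serialisable next to each artifact.  Planted truncation/indel
fractions stay clear of the 0.1 classification threshold by at least 0.02 so
that recovery is exact by construction, never boundary-dependent.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .isotype_core import ISOTYPES, annotate
from .motif_clusters import MotifInteraction, osa_distance
from .pfamscan_io import DomainHit, write_pfamscan
from .struct_compare import DomainStructure, write_pdb

__all__ = [
    "DEFAULT_DOMAIN_CATALOG",
    "simulate_pfamscan",
    "helix_backbone",
    "simulate_structures",
    "simulate_motifs",
    "simulate_genesets",
    "simulate_enrichment",
    "simulate_expression",
    "save_truth",
]

#: (hmm_name, hmm_length) pairs with realistic Pfam reference lengths.
DEFAULT_DOMAIN_CATALOG: Tuple[Tuple[str, int], ...] = (
    ("Pkinase", 264),
    ("His_Phos_1", 213),
    ("Ras", 162),
    ("Trypsin", 219),
    ("PDZ", 83),
    ("SH3_1", 48),
    ("zf-C4", 70),
    ("WD40", 39),
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


def save_truth(truth: Mapping, dest) -> None:
    """Serialise a truth record as JSON next to its fixture."""
    Path(dest).write_text(json.dumps(truth, indent=1, default=str) + "\n")


# ---------------------------------------------------------------------------
# pfam_scan records with planted isotypes

def _planted_trunc(rng, L: int, needed: bool) -> int:
    """End-truncation size whose fraction is >= 0.12 (needed) or <= 0.08."""
    if needed:
        t = int(round(rng.uniform(0.12, 0.35) * L))
        return max(t, math.ceil(0.12 * L))
    return int(rng.integers(0, int(0.08 * L) + 1))


def _planted_indel(rng, L: int, needed: bool, sign: int) -> int:
    if needed:
        d = int(round(rng.uniform(0.12, 0.30) * L))
        return sign * max(d, math.ceil(0.12 * L))
    d = int(rng.integers(0, int(0.06 * L) + 1))
    return sign * d


def simulate_pfamscan(
    n_records: int = 500,
    domains: Sequence[Tuple[str, int]] = DEFAULT_DOMAIN_CATALOG,
    isotype_mix: Mapping[str, float] | Sequence[float] | None = None,
    seed: int = 0,
    path=None,
) -> Tuple[List[DomainHit], pd.DataFrame]:
    """pfam_scan records realising a planted isotype per record.

    ``isotype_mix`` gives the category probabilities (dict keyed by isotype
    or a 5-vector in the order reference, complex, truncation, insertion,
    deletion); defaults to uniform.  When ``path`` is given the records are
    also written in pfam_scan format.

    Returns (hits, truth) where truth has one row per record with the
    planted category and the realised fractions.
    """
    if isotype_mix is None:
        probs = np.full(5, 0.2)
    elif isinstance(isotype_mix, Mapping):
        probs = np.array([float(isotype_mix.get(c, 0.0)) for c in ISOTYPES])
    else:
        probs = np.asarray(list(isotype_mix), dtype=float)
    if probs.size != 5 or abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("isotype_mix must be 5 non-negative probabilities summing to 1")

    rng = np.random.default_rng(seed)
    hits: List[DomainHit] = []
    truth_rows = []
    for i in range(n_records):
        name, L = domains[int(rng.integers(len(domains)))]
        cat = ISOTYPES[int(rng.choice(5, p=probs))]
        need_trunc = cat in ("truncation", "complex")
        need_indel = cat in ("insertion", "deletion", "complex")
        t = _planted_trunc(rng, L, need_trunc)
        n_end = bool(rng.integers(2))  # truncate the N- or C-terminal end
        hmm_start = 1 + t if n_end else 1
        hmm_end = L if n_end else L - t
        aligned_model = hmm_end - hmm_start + 1
        if cat == "insertion":
            sign = 1
        elif cat == "deletion":
            sign = -1
        else:
            sign = int(rng.choice([-1, 1]))
        d = _planted_indel(rng, L, need_indel, sign)
        aligned_seq = aligned_model + d
        aln_start = int(rng.integers(1, 400))
        aln_end = aln_start + aligned_seq - 1
        hit = DomainHit(
            seq_id=f"SP{i:05d}",
            aln_start=aln_start,
            aln_end=aln_end,
            env_start=max(1, aln_start - int(rng.integers(0, 4))),
            env_end=aln_end + int(rng.integers(0, 4)),
            hmm_acc=f"PF{hash(name) % 100000:05d}.1",
            hmm_name=name,
            type="Domain",
            hmm_start=hmm_start,
            hmm_end=hmm_end,
            hmm_length=L,
            bit_score=float(np.round(rng.uniform(30, 400), 1)),
            e_value=float(f"{10 ** rng.uniform(-60, -5):.2g}"),
            significance=1,
            clan="No_clan",
        )
        hits.append(hit)
        truth_rows.append(
            {
                "seq_id": hit.seq_id,
                "hmm_name": name,
                "planted_isotype": cat,
                "trunc_fraction": t / L,
                "indel_fraction": d / L,
            }
        )
    truth = pd.DataFrame(truth_rows)
    if path is not None:
        write_pfamscan(hits, path)
    return hits, truth


# ---------------------------------------------------------------------------
# Toy 3D structures

def helix_backbone(n_residues: int, radius: float = 2.3, rise: float = 1.5, turn_deg: float = 100.0) -> np.ndarray:
    """Idealised α-helix Cα trace (rise 1.5 Å, 100° per residue)."""
    i = np.arange(n_residues)
    theta = np.deg2rad(turn_deg) * i
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def random_sequence(n: int, rng) -> str:
    return "".join(_AA[int(k)] for k in rng.integers(0, len(_AA), size=n))


def simulate_structures(
    hmm_length: int = 35,
    n_ref: int = 3,
    n_nonref: int = 3,
    noise_sd: float = 0.5,
    truncate_frac: float = 0.3,
    seed: int = 0,
    hmm_name: str = "SynthHelix",
    out_dir=None,
) -> Tuple[List[DomainStructure], Dict]:
    """Reference and truncated copies of one idealised helical domain.

    Reference copies are the base helix plus i.i.d. Gaussian coordinate noise
    (``noise_sd`` Å per coordinate); non-reference (truncation-isotype)
    copies lose the first ``ceil(truncate_frac * L)`` residues before the
    same noise is applied.  All copies share the base sequence, so sequence
    alignment recovers the geometric correspondence exactly.
    """
    if not (0 <= truncate_frac <= 0.9):
        raise ValueError("truncate_frac must be in [0, 0.9]")
    if n_ref + n_nonref == 0:
        raise ValueError("need at least one structure")
    rng = np.random.default_rng(seed)
    base = helix_backbone(hmm_length)
    seq = random_sequence(hmm_length, rng)
    n_cut = math.ceil(truncate_frac * hmm_length)
    structures: List[DomainStructure] = []
    for k in range(n_ref):
        coords = base + rng.normal(0.0, noise_sd, size=base.shape)
        structures.append(
            DomainStructure(
                structure_id=f"{hmm_name}_REF{k:02d}",
                chain_id="A",
                residue_ids=np.arange(1, hmm_length + 1),
                sequence=seq,
                backbone_coords=coords,
                isotype="reference",
                hmm_name=hmm_name,
            )
        )
    for k in range(n_nonref):
        coords = base[n_cut:] + rng.normal(0.0, noise_sd, size=(hmm_length - n_cut, 3))
        structures.append(
            DomainStructure(
                structure_id=f"{hmm_name}_TRC{k:02d}",
                chain_id="A",
                residue_ids=np.arange(1, hmm_length - n_cut + 1),
                sequence=seq[n_cut:],
                backbone_coords=coords,
                isotype="truncation",
                hmm_name=hmm_name,
            )
        )
    truth = {
        "seed": seed,
        "hmm_name": hmm_name,
        "hmm_length": hmm_length,
        "noise_sd": noise_sd,
        "truncate_frac": truncate_frac,
        "n_cut": n_cut,
        "isotypes": {s.structure_id: s.isotype for s in structures},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s in structures:
            write_pdb(s, out / f"{s.structure_id}.pdb")
        save_truth(truth, out / "truth.json")
    return structures, truth


# ---------------------------------------------------------------------------
# Motif tables with planted clusters

def _random_motif_seeds(k: int, length: int, min_dist: int, rng) -> List[str]:
    seeds: List[str] = []
    for _ in range(10_000):
        cand = random_sequence(length, rng)
        if all(osa_distance(cand, s) >= min_dist for s in seeds):
            seeds.append(cand)
            if len(seeds) == k:
                return seeds
    raise RuntimeError("could not place motif cluster seeds far enough apart")


def _one_edit(s: str, rng) -> str:
    op = int(rng.integers(3))
    pos = int(rng.integers(len(s)))
    aa = _AA[int(rng.integers(len(_AA)))]
    if op == 0:  # substitution
        return s[:pos] + aa + s[pos + 1 :]
    if op == 1:  # insertion
        return s[:pos] + aa + s[pos:]
    return s[:pos] + s[pos + 1 :] if len(s) > 1 else s  # deletion


def simulate_motifs(
    k_clusters: int = 2,
    per_cluster: int = 6,
    seed: int = 0,
    isotype_purity: float = 1.0,
    hmm_name: str = "Trypsin",
    motif_length: int = 8,
    min_seed_distance: int = 6,
) -> Tuple[List[MotifInteraction], Dict]:
    """Motif-interaction table with ``k_clusters`` planted clusters.

    Each motif is its cluster's seed string with at most one random edit, so
    within-cluster distances are <= 2 while seeds sit >= ``min_seed_distance``
    edits apart.  Clusters alternate their preferred isotype group; each
    motif gets the preferred label with probability ``isotype_purity``.
    """
    if not (0.5 <= isotype_purity <= 1.0):
        raise ValueError("isotype_purity must be in [0.5, 1]")
    if per_cluster < 1:
        raise ValueError("per_cluster must be positive")
    rng = np.random.default_rng(seed)
    seeds = _random_motif_seeds(k_clusters, motif_length, min_seed_distance, rng)
    interactions: List[MotifInteraction] = []
    truth_labels = []
    for ci, seed_str in enumerate(seeds):
        preferred = "reference" if ci % 2 == 0 else "non_reference"
        other = "non_reference" if preferred == "reference" else "reference"
        for m in range(per_cluster):
            motif = seed_str if m == 0 else _one_edit(seed_str, rng)
            label = preferred if rng.random() < isotype_purity else other
            interactions.append(
                MotifInteraction(
                    hmm_name=hmm_name,
                    motif=motif,
                    isotype_simplified=label,
                    source_id=f"pdb{ci}{m:02d}_A",
                )
            )
            truth_labels.append({"motif": motif, "cluster": ci + 1, "preferred": preferred})
    truth = {
        "seed": seed,
        "k_clusters": k_clusters,
        "per_cluster": per_cluster,
        "isotype_purity": isotype_purity,
        "cluster_seeds": seeds,
        "motifs": truth_labels,
    }
    return interactions, truth


# ---------------------------------------------------------------------------
# Gene sets, enrichment and variation-skew fixtures

def simulate_enrichment(
    n_universe: int = 1000,
    unit_size: int = 100,
    n_labels: int = 100,
    n_enriched: int = 5,
    label_size: int = 40,
    odds_ratio: float = 10.0,
    seed: int = 0,
) -> Tuple[Dict[str, set], Dict[str, set], set, Dict]:
    """A unit set plus label sets, ``n_enriched`` of which overlap the unit
    with the planted odds ratio.

    Returns (units, labels, universe, truth); truth names the enriched
    labels.
    """
    rng = np.random.default_rng(seed)
    universe = {f"G{i:05d}" for i in range(n_universe)}
    genes = sorted(universe)
    unit = set(rng.choice(genes, size=unit_size, replace=False))
    inside = sorted(unit)
    outside = sorted(universe - unit)
    p_base = unit_size / n_universe
    # member-level probability of landing in the unit that realises the OR
    p_enriched = odds_ratio * p_base / (odds_ratio * p_base + (1 - p_base))
    labels: Dict[str, set] = {}
    enriched_names = []
    for j in range(n_labels):
        name = f"SET{j:04d}"
        p_in = p_enriched if j < n_enriched else p_base
        n_in = int(np.clip(rng.binomial(label_size, p_in), 0, len(inside)))
        members = set(rng.choice(inside, size=n_in, replace=False)) | set(
            rng.choice(outside, size=label_size - n_in, replace=False)
        )
        labels[name] = members
        if j < n_enriched:
            enriched_names.append(name)
    truth = {"seed": seed, "odds_ratio": odds_ratio, "enriched": enriched_names}
    return {"unit": unit}, labels, universe, truth


def simulate_genesets(
    n_genes: int = 200,
    n_sets: int = 20,
    set_size: int = 25,
    n_skewed: int = 1,
    hmm_name: str = "Ras",
    seed: int = 0,
) -> Tuple[Dict[str, set], pd.DataFrame, Dict[str, str], Dict]:
    """Gene sets plus domain annotations with planted variation skew.

    Every gene carries one occurrence of ``hmm_name``; half the genes carry a
    high-variation (non-reference) copy, half a reference copy.  The first
    ``n_skewed`` sets draw their members preferentially from the top of the
    decreasing-variation ranking (expected NES > 0); the rest sample
    uniformly.  Returns (collections, annotations, gene_map, truth).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    # planted per-gene overall variation: top half clearly non-reference
    variation = np.concatenate(
        [rng.uniform(0.15, 0.45, size=n_genes // 2), np.zeros(n_genes - n_genes // 2)]
    )
    rng.shuffle(variation)
    L = 162
    hits: List[DomainHit] = []
    gene_map: Dict[str, str] = {}
    for g, v in zip(genes, variation):
        t = int(round(v * L))
        hit = DomainHit(
            seq_id=f"{g}-T1",
            aln_start=10,
            aln_end=10 + (L - t) - 1,
            env_start=8,
            env_end=10 + (L - t) + 1,
            hmm_acc="PF00071.1",
            hmm_name=hmm_name,
            type="Domain",
            hmm_start=1 + t,
            hmm_end=L,
            hmm_length=L,
            bit_score=100.0,
            e_value=1e-30,
        )
        hits.append(hit)
        gene_map[f"{g}-T1"] = g
    annotations = annotate(hits)

    var_of = {g: float(v) for g, v in zip(genes, variation)}
    order = sorted(genes, key=lambda g: (-var_of[g], g))  # 0 = highest variation
    collections: Dict[str, set] = {}
    skewed = []
    for j in range(n_sets):
        name = f"SET{j:04d}"
        if j < n_skewed:
            # concentrate members in the top quartile of the ranking
            top = order[: n_genes // 4]
            members = set(rng.choice(top, size=min(set_size, len(top)), replace=False))
            skewed.append(name)
        else:
            members = set(rng.choice(genes, size=set_size, replace=False))
        collections[name] = members
    truth = {
        "seed": seed,
        "hmm_name": hmm_name,
        "skewed_sets": skewed,
        "variation": {g: float(v) for g, v in zip(genes, variation)},
    }
    return collections, annotations, gene_map, truth


# ---------------------------------------------------------------------------
# Expression matrices with planted major-transcript switches

def simulate_expression(
    n_genes: int = 50,
    n_major_switch: int = 10,
    n_isotype_switch: int = 7,
    groups: Sequence[str] = ("TissueA", "TissueB"),
    hmm_name: str = "Pkinase",
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, str], Dict[str, bool], pd.DataFrame, Dict]:
    """TPM matrix + annotations with planted isotype switches.

    Every gene has two coding transcripts.  ``n_major_switch`` genes switch
    their major transcript between the first two groups; of these, the first
    ``n_isotype_switch`` also change the domain isotype (reference ->
    truncation), the rest keep the same isotype in both transcripts.
    Remaining genes keep one major transcript everywhere.

    Returns (expression, gene_map, coding, annotations, truth).
    """
    if n_isotype_switch > n_major_switch or n_major_switch > n_genes:
        raise ValueError("need n_isotype_switch <= n_major_switch <= n_genes")
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    L = 264
    t_cut = int(0.2 * L)  # truncation fraction 0.2, clear of the threshold
    rows = {}
    gene_map: Dict[str, str] = {}
    coding: Dict[str, bool] = {}
    hits: List[DomainHit] = []
    switch_genes = []
    for i in range(n_genes):
        gene = f"GENE{i:04d}"
        t1, t2 = f"{gene}-T1", f"{gene}-T2"
        gene_map[t1] = gene_map[t2] = gene
        coding[t1] = coding[t2] = True
        base = float(rng.uniform(5, 50))
        if i < n_major_switch:
            # T1 wins in the first group, T2 in the second
            e1 = [base if g == groups[0] else base / 4 for g in groups]
            e2 = [base / 4 if g == groups[0] else base for g in groups]
            switch_genes.append(gene)
        else:
            e1 = [base for _ in groups]
            e2 = [base / 4 for _ in groups]
        rows[t1] = e1
        rows[t2] = e2
        isotype_change = i < n_isotype_switch
        for tx, truncated in ((t1, False), (t2, isotype_change)):
            cut = t_cut if truncated else 0
            hits.append(
                DomainHit(
                    seq_id=tx,
                    aln_start=20,
                    aln_end=20 + (L - cut) - 1,
                    env_start=18,
                    env_end=20 + (L - cut) + 1,
                    hmm_acc="PF00069.1",
                    hmm_name=hmm_name,
                    type="Domain",
                    hmm_start=1 + cut,
                    hmm_end=L,
                    hmm_length=L,
                    bit_score=200.0,
                    e_value=1e-50,
                )
            )
    expr = pd.DataFrame.from_dict(rows, orient="index", columns=list(groups))
    annotations = annotate(hits)
    truth = {
        "seed": seed,
        "n_major_switch": n_major_switch,
        "n_isotype_switch": n_isotype_switch,
        "major_switch_genes": switch_genes,
        "isotype_switch_genes": switch_genes[:n_isotype_switch],
    }
    return expr, gene_map, coding, annotations, truth
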