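"""Rigid-body comparison of domain isotype 3D structures.

The pipeline mirrors the classical sequence-guided superposition workflow:

1. globally align the two domain sequences (BLOSUM50, gap open 40 / extend 4;
   the heavy gap penalties tolerate isotypes whose ends or middles are
   missing while keeping the alignment spanning);
2. superpose the matched Cα coordinates with a single least-squares (Kabsch)
   pass — no outlier-trimming cycles, so missing or displaced regions count;
3. report backbone RMSD over the matched pairs and the TM-score

   .. math:: \\mathrm{TM} = \\frac{1}{L_{target}} \\sum_i \\frac{1}{1 + (d_i/d_0)^2},
             \\qquad d_0 = 1.24\\,(L_{target}-15)^{1/3} - 1.8

   normalised by the reference-isotype domain length :math:`L_{target}`
   (d0 floored at 0.5 Å for very short domains, the usual convention).

Pairs are kept only when both aligned subsequences exceed ``min_aln_len``
residues and the non-reference structure's aligned fraction exceeds
``min_coverage`` of its domain length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "DomainStructure",
    "StructuralComparison",
    "RejectedComparison",
    "load_domain_structure",
    "write_pdb",
    "align_domain_sequences",
    "kabsch_superpose",
    "tm_d0",
    "compare_structures",
    "sample_comparisons",
    "summarize_structural_differences",
    "unrelated_baseline",
]


@dataclass
class DomainStructure:
    """Cα trace and sequence of one domain region of one chain."""

    structure_id: str
    chain_id: str
    residue_ids: np.ndarray  # strictly increasing ints
    sequence: str  # one-letter, no X
    backbone_coords: np.ndarray  # N x 3, Å
    isotype: str | None = None
    hmm_name: str | None = None

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.backbone_coords = np.asarray(self.backbone_coords, dtype=float)
        if len(self.sequence) != self.backbone_coords.shape[0]:
            raise ValueError("sequence length and coordinate rows differ")
        if self.residue_ids.size and np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError("residue ids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StructuralComparison:
    pair: Tuple[str, str]
    pair_class: str  # ref_vs_ref | ref_vs_nonref | unrelated
    hmm_name: str | None
    nonref_isotype: str
    aligned_length: int
    coverage_nonref: float
    rmsd: float
    tm_score: float
    l_target: int
    d0: float


@dataclass(frozen=True)
class RejectedComparison:
    pair: Tuple[str, str]
    reason: str  # min_aln_len | coverage
    hmm_name: str | None = None
    pair_class: str | None = None


# ---------------------------------------------------------------------------
# PDB I/O

def load_domain_structure(
    pdb_source: Union[str, Path],
    chain: str | None = None,
    aln_start: int = 1,
    aln_end: int | None = None,
    isotype: str | None = None,
    hmm_name: str | None = None,
    structure_id: str | None = None,
) -> DomainStructure:
    """Extract a domain's Cα trace from a PDB/mmCIF file.

    Residues are numbered 1..N in chain order (matching positions in the
    sequence a domain scanner would see for that chain); only positions in
    ``[aln_start, aln_end]`` of the requested chain (default: first chain)
    are kept, from the first model only.  Residues with unknown identity
    (one-letter X) or without a Cα atom are dropped from both the sequence
    and the coordinates.
    """
    import gemmi

    st = gemmi.read_structure(str(pdb_source))
    if len(st) == 0:
        raise ValueError(f"{pdb_source}: no models")
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise ValueError(f"{pdb_source}: chain {chain!r} not found")

    seq_chars: List[str] = []
    res_ids: List[int] = []
    coords: List[List[float]] = []
    pos = 0
    for res in ch:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        pos += 1
        if pos < aln_start or (aln_end is not None and pos > aln_end):
            continue
        letter = info.one_letter_code.upper()
        if letter == "X" or not letter.isalpha():
            continue
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.altloc in ("", " ", "\x00", "A"):
                ca = atom
                break
        if ca is None:
            continue
        seq_chars.append(letter)
        res_ids.append(pos)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])

    if not seq_chars:
        raise ValueError(f"{pdb_source}: empty domain selection {aln_start}..{aln_end}")
    return DomainStructure(
        structure_id=structure_id or Path(str(pdb_source)).stem,
        chain_id=ch.name,
        residue_ids=np.array(res_ids),
        sequence="".join(seq_chars),
        backbone_coords=np.array(coords),
        isotype=isotype,
        hmm_name=hmm_name,
    )


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def write_pdb(structure: DomainStructure, dest: Union[str, Path]) -> None:
    """Write a Cα-only PDB file readable by :func:`load_domain_structure`."""
    lines = [f"HEADER    SYNTHETIC DOMAIN {structure.structure_id}"]
    for i, (aa, xyz) in enumerate(zip(structure.sequence, structure.backbone_coords)):
        resname = _AA3.get(aa, "UNK")
        resseq = int(structure.residue_ids[i])
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {resname} {structure.chain_id[:1] or 'A'}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"  1.00  0.00           C"
        )
    lines.append("END")
    Path(dest).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignment and superposition

def _make_aligner(end_gap_free: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM50")
    aligner.mode = "global"
    aligner.open_gap_score = -40.0
    aligner.extend_gap_score = -4.0
    # Default is fully global (end gaps penalised), the convention of the
    # pairwise aligners this workflow descends from: it keeps unrelated-pair
    # alignments spanning (so the unrelated baseline is well defined) while
    # still pairing truncated isotypes correctly.  ``end_gap_free`` switches
    # to a semi-global variant.
    if end_gap_free:
        try:
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
            aligner.open_end_deletion_score = 0.0
            aligner.extend_end_deletion_score = 0.0
        except AttributeError:  # Biopython < 1.88 attribute names
            aligner.target_end_open_gap_score = 0.0
            aligner.target_end_extend_gap_score = 0.0
            aligner.query_end_open_gap_score = 0.0
            aligner.query_end_extend_gap_score = 0.0
    return aligner


def align_domain_sequences(seq_a: str, seq_b: str, end_gap_free: bool = False) -> List[Tuple[int, int]]:
    """Matched (i, j) index pairs from the best global alignment."""
    aligner = _make_aligner(end_gap_free)
    alignment = aligner.align(seq_a, seq_b)[0]
    pairs: List[Tuple[int, int]] = []
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        pairs.extend(zip(range(t0, t1), range(q0, q1)))
    return pairs


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> Tuple[np.ndarray, float]:
    """Least-squares superposition of ``Q`` onto ``P`` (paired rows).

    Returns the transformed copy of ``Q`` and the RMSD.  Proper rotation is
    enforced (no reflection).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise ValueError("need >= 3 paired coordinates of equal shape")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    H = Qc.T @ Pc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    Q_fit = Qc @ R + cp
    rmsd = float(np.sqrt(np.mean(np.sum((Q_fit - P) ** 2, axis=1))))
    return Q_fit, rmsd


def tm_d0(l_target: int) -> float:
    """TM-score distance scale; floored at 0.5 Å for short domains."""
    if l_target <= 0:
        raise ValueError("l_target must be positive")
    d0 = 1.24 * (l_target - 15) ** (1.0 / 3.0) - 1.8 if l_target > 15 else 0.5
    return max(d0, 0.5)


def tm_score(distances: np.ndarray, l_target: int) -> float:
    d0 = tm_d0(l_target)
    return float(np.sum(1.0 / (1.0 + (np.asarray(distances) / d0) ** 2)) / l_target)


# ---------------------------------------------------------------------------
# Pairwise comparison

def compare_structures(
    a: DomainStructure,
    b: DomainStructure,
    min_aln_len: int = 20,
    min_coverage: float = 0.8,
    pair_class: str | None = None,
) -> Union[StructuralComparison, RejectedComparison]:
    """Compare structure ``b`` against the reference-role structure ``a``.

    ``a`` plays the reference part of the pair: the TM-score is normalised by
    ``len(a)`` and the coverage filter applies to ``b``.  Returns a
    :class:`RejectedComparison` when a filter fires.
    """
    pairs = align_domain_sequences(a.sequence, b.sequence)
    n_pairs = len(pairs)
    if pair_class is None:
        pair_class = (
            "ref_vs_ref"
            if (a.isotype == "reference" and b.isotype == "reference")
            else "ref_vs_nonref"
        )
    key = (a.structure_id, b.structure_id)
    if n_pairs <= min_aln_len:
        return RejectedComparison(key, "min_aln_len", a.hmm_name, pair_class)
    coverage = n_pairs / len(b)
    if coverage <= min_coverage:
        return RejectedComparison(key, "coverage", a.hmm_name, pair_class)
    if n_pairs < 3:
        raise ValueError("fewer than 3 aligned pairs; superposition degenerate")

    ia = [i for i, _ in pairs]
    ib = [j for _, j in pairs]
    P = a.backbone_coords[ia]
    Q = b.backbone_coords[ib]
    Q_fit, rmsd = kabsch_superpose(P, Q)
    d = np.sqrt(np.sum((Q_fit - P) ** 2, axis=1))
    l_target = len(a)
    return StructuralComparison(
        pair=key,
        pair_class=pair_class,
        hmm_name=a.hmm_name,
        nonref_isotype=(b.isotype or "reference") if pair_class != "unrelated" else "unrelated",
        aligned_length=n_pairs,
        coverage_nonref=coverage,
        rmsd=rmsd,
        tm_score=tm_score(d, l_target),
        l_target=l_target,
        d0=tm_d0(l_target),
    )


# ---------------------------------------------------------------------------
# Sampling, summarising, baseline

def sample_comparisons(
    structures_by_domain: Dict[str, List[DomainStructure]],
    max_ref: int = 9,
    max_nonref: int = 21,
    seed: int = 0,
    min_aln_len: int = 20,
    min_coverage: float = 0.8,
) -> Tuple[List[StructuralComparison], List[RejectedComparison]]:
    """Seeded per-domain sampling and pairwise comparison.

    For each domain, up to ``max_ref`` reference-isotype and ``max_nonref``
    non-reference structures are drawn without replacement; every
    reference x non-reference pair and every reference x reference pair is
    compared.  Returns (passing comparisons, rejected pairs).
    """
    rng = np.random.default_rng(seed)
    passed: List[StructuralComparison] = []
    rejected: List[RejectedComparison] = []
    for name in sorted(structures_by_domain):
        structs = structures_by_domain[name]
        refs = [s for s in structs if s.isotype == "reference"]
        nonrefs = [s for s in structs if s.isotype not in (None, "reference")]
        if len(refs) > max_ref:
            refs = [refs[i] for i in sorted(rng.choice(len(refs), size=max_ref, replace=False))]
        if len(nonrefs) > max_nonref:
            nonrefs = [
                nonrefs[i]
                for i in sorted(rng.choice(len(nonrefs), size=max_nonref, replace=False))
            ]
        for r, s in itertools.product(refs, nonrefs):
            res = compare_structures(r, s, min_aln_len, min_coverage)
            (passed if isinstance(res, StructuralComparison) else rejected).append(res)
        for r1, r2 in itertools.combinations(refs, 2):
            res = compare_structures(r1, r2, min_aln_len, min_coverage, pair_class="ref_vs_ref")
            (passed if isinstance(res, StructuralComparison) else rejected).append(res)
    return passed, rejected


def summarize_structural_differences(
    comparisons: Iterable[StructuralComparison],
    min_comparisons: int = 3,
):
    """Mean RMSD / TM-score per (domain, isotype of the non-reference member).

    Reference-reference pairs appear under isotype ``reference``.  Groups
    with fewer than ``min_comparisons`` surviving comparisons are omitted.
    """
    import pandas as pd

    rows = [
        {
            "hmm_name": c.hmm_name,
            "isotype": c.nonref_isotype,
            "rmsd": c.rmsd,
            "tm_score": c.tm_score,
        }
        for c in comparisons
    ]
    if not rows:
        return pd.DataFrame(columns=["hmm_name", "isotype", "mean_rmsd", "mean_tm_score", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["hmm_name", "isotype"], sort=True)
        .agg(mean_rmsd=("rmsd", "mean"), mean_tm_score=("tm_score", "mean"), n=("rmsd", "size"))
        .reset_index()
    )
    return out[out["n"] >= min_comparisons].reset_index(drop=True)


def unrelated_baseline(
    structures: Sequence[DomainStructure],
    n_domains: int = 150,
    lo: float = 0.05,
    hi: float = 0.95,
    seed: int = 0,
    min_aln_len: int = 20,
    min_coverage: float = 0.8,
) -> Tuple[Tuple[float, float], Tuple[float, float]]:
    """Similarity expected between unrelated domains.

    One random reference-isotype structure is chosen per domain (up to
    ``n_domains`` domains) and all cross-domain pairs are scored; the
    ``lo``–``hi`` percentile intervals of RMSD and TM-score are returned.
    """
    rng = np.random.default_rng(seed)
    by_domain: Dict[str, List[DomainStructure]] = {}
    for s in structures:
        if s.isotype == "reference":
            by_domain.setdefault(s.hmm_name or s.structure_id, []).append(s)
    names = sorted(by_domain)
    if len(names) < 2:
        raise ValueError("need reference structures from >= 2 distinct domains")
    if len(names) > n_domains:
        names = [names[i] for i in sorted(rng.choice(len(names), size=n_domains, replace=False))]
    chosen = [by_domain[n][int(rng.integers(len(by_domain[n])))] for n in names]
    rmsds: List[float] = []
    tms: List[float] = []
    for a, b in itertools.combinations(chosen, 2):
        res = compare_structures(a, b, min_aln_len, min_coverage, pair_class="unrelated")
        if isinstance(res, StructuralComparison):
            rmsds.append(res.rmsd)
            tms.append(res.tm_score)
    if not rmsds:
        raise ValueError("no unrelated comparison survived the filters")
    q = [lo, hi]
    r_iv = tuple(float(v) for v in np.quantile(rmsds, q))
    t_iv = tuple(float(v) for v in np.quantile(tms, q))
    return r_iv, t_iv
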