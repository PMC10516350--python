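"""Tissue / cell-type domain-isotype switches from transcript expression.

For every gene and group (tissue or cell type) the *major transcript* is the
most expressed protein-coding transcript (median TPM).  When a gene's major
transcript differs between groups, the domains encoded by the two
transcripts are compared: the same domain (hmm_name) present in both but
with different five-way isotypes is an *isotype switch*; a domain present in
one major transcript and absent from the other is a *gain/loss*.  The
headline statistic is the fraction of examined domains with an isotype
switch — reported under both denominator conventions (domains shared by the
two majors, and shared + gain/loss events).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = [
    "IsotypeSwitch",
    "major_transcripts",
    "detect_isotype_switches",
    "significant_transcript_cell_assignment",
    "isoform_domain_differences",
    "SwitchReport",
]


@dataclass(frozen=True)
class IsotypeSwitch:
    gene: str
    hmm_name: str
    group_a: str
    group_b: str
    transcript_a: str
    transcript_b: str
    isotype_a: Optional[str]
    isotype_b: Optional[str]
    switch_class: str  # isotype_change | domain_gain_loss


@dataclass
class SwitchReport:
    switches: List[IsotypeSwitch]
    n_shared_domains: int
    n_isotype_changes: int
    n_gain_loss: int

    @property
    def fraction_shared(self) -> float:
        """isotype changes / domains shared by both differing majors."""
        return self.n_isotype_changes / self.n_shared_domains if self.n_shared_domains else 0.0

    @property
    def fraction_with_gain_loss(self) -> float:
        """isotype changes / (shared domains + gain/loss events)."""
        denom = self.n_shared_domains + self.n_gain_loss
        return self.n_isotype_changes / denom if denom else 0.0


def major_transcripts(
    expr: pd.DataFrame,
    gene_map: Mapping[str, str],
    coding: Mapping[str, bool],
) -> Dict[Tuple[str, str], str]:
    """Most expressed protein-coding transcript per (gene, group).

    ``expr`` is transcripts x groups (median TPM).  Exact expression ties are
    broken by the lexicographically smallest transcript id.  Genes without
    any coding transcript are omitted.
    """
    gene_map = dict(gene_map)
    coding = dict(coding)
    tx = [t for t in expr.index if coding.get(t, False) and t in gene_map]
    out: Dict[Tuple[str, str], str] = {}
    sub = expr.loc[tx]
    genes = pd.Series({t: gene_map[t] for t in tx})
    for group in expr.columns:
        vals = sub[group]
        for gene, tids in genes.groupby(genes).groups.items():
            tids = sorted(tids)
            best = max(tids, key=lambda t: (vals[t], _neg_lex(t)))
            out[(gene, group)] = best
    return out


def _neg_lex(s: str):
    # max() with lexicographically *smallest* id winning ties
    return tuple(-ord(c) for c in s)


def _domain_slots(ann: pd.DataFrame, transcript: str) -> Dict[Tuple[str, int], str]:
    """(hmm_name, rank-within-name) -> isotype for one transcript.

    Rank order along the protein pairs repeated domains across isoforms when
    genomic coordinates are not available.
    """
    sub = ann[ann["seq_id"] == transcript].sort_values(["hmm_name", "aln_start"])
    slots: Dict[Tuple[str, int], str] = {}
    counters: Dict[str, int] = {}
    for _, row in sub.iterrows():
        name = row["hmm_name"]
        counters[name] = counters.get(name, 0) + 1
        slots[(name, counters[name])] = row["isotype"]
    return slots


def detect_isotype_switches(
    majors: Mapping[Tuple[str, str], str],
    annotations: pd.DataFrame,
) -> SwitchReport:
    """Domain isotype switches among genes whose major transcript differs
    between groups.

    ``annotations`` is an isotype table whose ``seq_id`` column holds
    transcript ids.  For each gene with >= 2 distinct major transcripts, every
    unordered pair of distinct majors is compared domain slot by domain slot.
    """
    by_gene: Dict[str, Dict[str, str]] = {}
    for (gene, group), tx in majors.items():
        by_gene.setdefault(gene, {})[group] = tx

    switches: List[IsotypeSwitch] = []
    n_shared = n_change = n_gainloss = 0
    for gene in sorted(by_gene):
        groups = by_gene[gene]
        distinct = sorted(set(groups.values()))
        if len(distinct) < 2:
            continue
        first_group = {
            tx: min(g for g, t in groups.items() if t == tx) for tx in distinct
        }
        for i in range(len(distinct)):
            for j in range(i + 1, len(distinct)):
                ta, tb = distinct[i], distinct[j]
                slots_a = _domain_slots(annotations, ta)
                slots_b = _domain_slots(annotations, tb)
                for key in sorted(set(slots_a) | set(slots_b)):
                    name, _rank = key
                    in_a, in_b = key in slots_a, key in slots_b
                    if in_a and in_b:
                        n_shared += 1
                        if slots_a[key] != slots_b[key]:
                            n_change += 1
                            switches.append(
                                IsotypeSwitch(
                                    gene=gene, hmm_name=name,
                                    group_a=first_group[ta], group_b=first_group[tb],
                                    transcript_a=ta, transcript_b=tb,
                                    isotype_a=slots_a[key], isotype_b=slots_b[key],
                                    switch_class="isotype_change",
                                )
                            )
                    else:
                        n_gainloss += 1
                        switches.append(
                            IsotypeSwitch(
                                gene=gene, hmm_name=name,
                                group_a=first_group[ta], group_b=first_group[tb],
                                transcript_a=ta, transcript_b=tb,
                                isotype_a=slots_a.get(key), isotype_b=slots_b.get(key),
                                switch_class="domain_gain_loss",
                            )
                        )
    return SwitchReport(
        switches=switches,
        n_shared_domains=n_shared,
        n_isotype_changes=n_change,
        n_gain_loss=n_gainloss,
    )


def significant_transcript_cell_assignment(
    dtu_table: pd.DataFrame,
    cell_expression: pd.DataFrame,
    p_threshold: float = 0.05,
) -> Dict[str, str]:
    """Assign each differentially used transcript to its top cell type.

    ``dtu_table`` needs columns ``transcript`` and ``adjusted_p``; transcripts
    at adjusted p strictly below the threshold are assigned to the cell type
    (column of ``cell_expression``) where they are most expressed, ties going
    to the lexicographically smallest cell-type name.
    """
    out: Dict[str, str] = {}
    keep = dtu_table[dtu_table["adjusted_p"] < p_threshold]
    cols = sorted(cell_expression.columns)
    for tx in keep["transcript"]:
        if tx not in cell_expression.index:
            continue
        row = cell_expression.loc[tx, cols]
        out[tx] = max(cols, key=lambda c: (row[c], _neg_lex(c)))
    return out


def isoform_domain_differences(
    annotations: pd.DataFrame,
    gene_map: Mapping[str, str],
    genomic_coords: Optional[Mapping[Tuple[str, str, int], Tuple[str, int, int]]] = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Per-gene flags for isoform-level domain differences.

    For genes with >= 2 annotated isoforms: ``presence_absence`` — some
    isoform carries a domain another isoform lacks; ``isotype_difference`` —
    the same domain, paired across isoforms (by genomic overlap when
    ``genomic_coords`` maps (transcript, hmm_name, occurrence) to
    (chrom, start, end) 0-based half-open intervals, otherwise by hmm_name and
    rank order), is classified as different isotypes.

    Returns the per-gene table and global counts of flagged genes.
    """
    ann = annotations.copy()
    ann["gene"] = ann["seq_id"].map(dict(gene_map))
    ann = ann.dropna(subset=["gene"])
    rows = []
    for gene, sub in ann.groupby("gene", sort=True):
        isoforms = sorted(sub["seq_id"].unique())
        if len(isoforms) < 2:
            continue
        presence = False
        isotype_diff = False
        per_iso = {t: _domain_slots(sub, t) for t in isoforms}
        names = {k[0] for slots in per_iso.values() for k in slots}
        for name in names:
            have = [t for t in isoforms if any(k[0] == name for k in per_iso[t])]
            if 0 < len(have) < len(isoforms):
                presence = True
        for i in range(len(isoforms)):
            for j in range(i + 1, len(isoforms)):
                ta, tb = isoforms[i], isoforms[j]
                if genomic_coords is None:
                    shared = set(per_iso[ta]) & set(per_iso[tb])
                    for key in shared:
                        if per_iso[ta][key] != per_iso[tb][key]:
                            isotype_diff = True
                else:
                    for key_a, iso_a in per_iso[ta].items():
                        ca = genomic_coords.get((ta, key_a[0], key_a[1]))
                        if ca is None:
                            continue
                        for key_b, iso_b in per_iso[tb].items():
                            if key_b[0] != key_a[0]:
                                continue
                            cb = genomic_coords.get((tb, key_b[0], key_b[1]))
                            if cb is None or ca[0] != cb[0]:
                                continue
                            if ca[1] < cb[2] and cb[1] < ca[2]:  # interval overlap
                                if iso_a != iso_b:
                                    isotype_diff = True
        rows.append(
            {
                "gene": gene,
                "n_isoforms": len(isoforms),
                "presence_absence": presence,
                "isotype_difference": isotype_diff,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "n_isoforms", "presence_absence", "isotype_difference"])
    counts = {
        "genes_with_presence_absence": int(table["presence_absence"].sum()) if len(table) else 0,
        "genes_with_isotype_difference": int(table["isotype_difference"].sum()) if len(table) else 0,
        "genes_examined": int(len(table)),
    }
    return table, counts
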