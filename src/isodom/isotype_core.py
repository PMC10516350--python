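"""Domain variation metrics and the five-way isotype classification.

A domain occurrence is compared with its Pfam reference model through the
alignment coordinates that pfam_scan reports:

* truncation size — the larger of the two missing ends of the model,
  ``max(hmm_start - 1, hmm_length - hmm_end)``;
* indel size — aligned query length minus aligned model length
  (``(aln_end - aln_start + 1) - (hmm_end - hmm_start + 1)``), positive when
  the observed sequence is longer than the model segment (insertion),
  negative when shorter (deletion);
* fractions divide by ``hmm_length``; the overall variation is
  ``max(trunc_fraction, |indel_fraction|)``.

With thresholds t (truncation) and i (indel), both defaulting to 0.1 with the
inclusive ``>=`` convention, each occurrence receives exactly one of five
mutually exclusive isotypes:

=============  ============================================
reference      no truncation and no indel
complex        both truncation and indel
truncation     truncation only
insertion      indel only, indel fraction > 0
deletion       indel only, indel fraction < 0
=============  ============================================

and the two-way simplification reference / non_reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

import pandas as pd

from .pfamscan_io import DomainHit

__all__ = [
    "VariationMetrics",
    "IsotypeAnnotation",
    "ISOTYPES",
    "compute_variation",
    "classify_isotype",
    "annotate",
]

ISOTYPES = ("reference", "complex", "truncation", "insertion", "deletion")


@dataclass(frozen=True)
class VariationMetrics:
    trunc_size: int
    trunc_fraction: float
    indel_size: int
    indel_fraction: float
    overall_variation: float


@dataclass(frozen=True)
class IsotypeAnnotation:
    metrics: VariationMetrics
    isotype: str
    simplified: str


def compute_variation(hit: DomainHit) -> VariationMetrics:
    """Truncation/indel metrics for one domain occurrence."""
    if hit.hmm_length <= 0:
        raise ValueError(f"non-positive hmm_length {hit.hmm_length}")
    trunc_size = max(hit.hmm_start - 1, hit.hmm_length - hit.hmm_end)
    aligned_model = hit.hmm_end - hit.hmm_start + 1
    aligned_seq = hit.aln_end - hit.aln_start + 1
    indel_size = aligned_seq - aligned_model
    trunc_fraction = trunc_size / hit.hmm_length
    indel_fraction = indel_size / hit.hmm_length
    return VariationMetrics(
        trunc_size=trunc_size,
        trunc_fraction=trunc_fraction,
        indel_size=indel_size,
        indel_fraction=indel_fraction,
        overall_variation=max(trunc_fraction, abs(indel_fraction)),
    )


def classify_isotype(
    metrics: VariationMetrics,
    trunc_threshold: float = 0.1,
    indel_threshold: float = 0.1,
) -> IsotypeAnnotation:
    """Assign the five-way isotype from precomputed metrics.

    A fraction exactly at its threshold counts as having the feature
    (inclusive ``>=``).
    """
    if trunc_threshold < 0 or indel_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    has_trunc = metrics.trunc_fraction >= trunc_threshold
    has_indel = abs(metrics.indel_fraction) >= indel_threshold
    if not has_trunc and not has_indel:
        isotype = "reference"
    elif has_trunc and has_indel:
        isotype = "complex"
    elif has_trunc:
        isotype = "truncation"
    elif metrics.indel_fraction > 0:
        isotype = "insertion"
    else:
        isotype = "deletion"
    simplified = "reference" if isotype == "reference" else "non_reference"
    return IsotypeAnnotation(metrics=metrics, isotype=isotype, simplified=simplified)


#: Column order of the annotation table produced by :func:`annotate`.
ANNOTATION_COLUMNS = [
    "seq_id", "hmm_name", "hmm_acc", "aln_start", "aln_end", "env_start",
    "env_end", "hmm_start", "hmm_end", "hmm_length", "type", "bit_score",
    "e_value", "clan", "occurrence", "aligned_length", "trunc_size",
    "trunc_fraction", "indel_size", "indel_fraction", "overall_variation",
    "isotype", "simplified",
]


def annotate(
    hits: Iterable[DomainHit],
    trunc_threshold: float = 0.1,
    indel_threshold: float = 0.1,
) -> pd.DataFrame:
    """Annotation table: one row per hit with metrics and isotype.

    Rows keep input order.  Duplicate (seq_id, hmm_name, aln_start) keys are
    both retained and distinguished by a 1-based ``occurrence`` index.
    """
    rows: List[dict] = []
    seen: dict = {}
    for hit in hits:
        m = compute_variation(hit)
        ann = classify_isotype(m, trunc_threshold, indel_threshold)
        key = (hit.seq_id, hit.hmm_name, hit.aln_start)
        seen[key] = seen.get(key, 0) + 1
        rows.append(
            {
                "seq_id": hit.seq_id,
                "hmm_name": hit.hmm_name,
                "hmm_acc": hit.hmm_acc,
                "aln_start": hit.aln_start,
                "aln_end": hit.aln_end,
                "env_start": hit.env_start,
                "env_end": hit.env_end,
                "hmm_start": hit.hmm_start,
                "hmm_end": hit.hmm_end,
                "hmm_length": hit.hmm_length,
                "type": hit.type,
                "bit_score": hit.bit_score,
                "e_value": hit.e_value,
                "clan": hit.clan,
                "occurrence": seen[key],
                "aligned_length": hit.aln_end - hit.aln_start + 1,
                "trunc_size": m.trunc_size,
                "trunc_fraction": m.trunc_fraction,
                "indel_size": m.indel_size,
                "indel_fraction": m.indel_fraction,
                "overall_variation": m.overall_variation,
                "isotype": ann.isotype,
                "simplified": ann.simplified,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
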