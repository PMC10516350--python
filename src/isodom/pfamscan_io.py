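"""Reading and writing pfam_scan.pl output.

pfam_scan.pl (and the Pfam web server) emit one space-padded record per domain
hit.  Column order is fixed::

    seq_id aln_start aln_end env_start env_end hmm_acc hmm_name type
    hmm_start hmm_end hmm_length bit_score e_value significance clan
    [predicted_active_site]

The trailing predicted-active-site column is present only for some rows, and
the amount of padding varies between versions, so records are parsed as
whitespace-delimited tokens in fixed order rather than by byte offsets.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Union

import pandas as pd

__all__ = [
    "DomainHit",
    "PfamScanError",
    "read_pfamscan",
    "filter_domains",
    "write_pfamscan",
    "hits_to_frame",
    "KNOWN_TYPES",
]

#: Canonical values of the pfam_scan ``type`` column.  Anything else maps to
#: ``"other"`` so that downstream Domain-only filters fail safe.
KNOWN_TYPES = frozenset(
    {"Domain", "Family", "Repeat", "Motif", "Coiled-coil", "Disordered"}
)

_CANON = {t.lower(): t for t in KNOWN_TYPES}


class PfamScanError(ValueError):
    """Raised for malformed pfam_scan records; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class DomainHit:
    """One pfam_scan record.

    Coordinates are 1-based inclusive.  ``aln_start``/``aln_end`` are the
    seq_start/seq_end columns (alignment coordinates on the query);
    ``env_start``/``env_end`` the envelope coordinates; ``hmm_start``/
    ``hmm_end`` positions on the profile model of full length ``hmm_length``.
    """

    seq_id: str
    aln_start: int
    aln_end: int
    env_start: int
    env_end: int
    hmm_acc: str
    hmm_name: str
    type: str
    hmm_start: int
    hmm_end: int
    hmm_length: int
    bit_score: float
    e_value: float
    significance: int = 1
    clan: str = "No_clan"
    active_site: str | None = None

    def __post_init__(self):
        if not (1 <= self.hmm_start <= self.hmm_end <= self.hmm_length):
            raise PfamScanError(
                f"invalid hmm coordinates {self.hmm_start}..{self.hmm_end} "
                f"for model length {self.hmm_length}"
            )
        if not (1 <= self.aln_start <= self.aln_end):
            raise PfamScanError(
                f"invalid alignment coordinates {self.aln_start}..{self.aln_end}"
            )
        if self.e_value < 0:
            raise PfamScanError(f"negative E-value {self.e_value}")


def normalize_type(raw: str) -> str:
    """Map a raw ``type`` token to its canonical spelling, or ``"other"``."""
    return _CANON.get(raw.strip().lower(), "other")


_HEADER = (
    "# <seq id> <alignment start> <alignment end> <envelope start> "
    "<envelope end> <hmm acc> <hmm name> <type> <hmm start> <hmm end> "
    "<hmm length> <bit score> <E-value> <significance> <clan>"
)


def _parse_line(tokens: List[str], lineno: int) -> DomainHit:
    if len(tokens) < 13:
        raise PfamScanError(
            f"expected at least 13 whitespace-separated fields, got {len(tokens)}",
            lineno,
        )
    try:
        aln_start, aln_end = int(tokens[1]), int(tokens[2])
        env_start, env_end = int(tokens[3]), int(tokens[4])
        hmm_start, hmm_end, hmm_length = (
            int(tokens[8]),
            int(tokens[9]),
            int(tokens[10]),
        )
        bit_score = float(tokens[11])
        e_value = float(tokens[12])
    except ValueError as exc:
        raise PfamScanError(f"non-numeric coordinate or score field ({exc})", lineno)

    # Optional trailing fields: significance (0/1), clan, predicted active site.
    significance = 1
    clan = "No_clan"
    active_site = None
    rest = tokens[13:]
    if rest and rest[0] in ("0", "1"):
        significance = int(rest[0])
        rest = rest[1:]
    if rest and not rest[0].startswith("predicted_active_site"):
        clan = rest[0]
        rest = rest[1:]
    if rest:
        active_site = " ".join(rest)

    try:
        return DomainHit(
            seq_id=tokens[0],
            aln_start=aln_start,
            aln_end=aln_end,
            env_start=env_start,
            env_end=env_end,
            hmm_acc=tokens[5],
            hmm_name=tokens[6],
            type=normalize_type(tokens[7]),
            hmm_start=hmm_start,
            hmm_end=hmm_end,
            hmm_length=hmm_length,
            bit_score=bit_score,
            e_value=e_value,
            significance=significance,
            clan=clan,
            active_site=active_site,
        )
    except PfamScanError as exc:
        raise PfamScanError(str(exc), lineno)


def read_pfamscan(source: Union[str, Path, io.TextIOBase]) -> List[DomainHit]:
    """Parse pfam_scan.pl output into a list of :class:`DomainHit`.

    ``source`` may be a path, a text blob containing newlines, or an open
    text stream.  Comment lines (``#``) and blank lines are skipped; record
    order is preserved.  An empty file yields an empty list.

    Raises
    ------
    PfamScanError
        On any malformed record, naming the offending line number.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and ("\n" in source or not Path(source).exists()):
        # A multi-line string is treated as file content; a bare token that is
        # not an existing path is an error when opened below.
        if "\n" not in source:
            raise FileNotFoundError(source)
        text = source
    else:
        text = Path(source).read_text()

    hits: List[DomainHit] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        hits.append(_parse_line(stripped.split(), lineno))
    return hits


def filter_domains(hits: Iterable[DomainHit]) -> List[DomainHit]:
    """Keep only true domains (``type == "Domain"``), preserving order.

    Families, repeats, motifs, coiled-coils, disordered regions and unknown
    types are all dropped: downstream isotype analysis is defined for
    domains only.
    """
    return [h for h in hits if h.type == "Domain"]


def format_hit(hit: DomainHit) -> str:
    fields = [
        hit.seq_id,
        str(hit.aln_start),
        str(hit.aln_end),
        str(hit.env_start),
        str(hit.env_end),
        hit.hmm_acc,
        hit.hmm_name,
        hit.type,
        str(hit.hmm_start),
        str(hit.hmm_end),
        str(hit.hmm_length),
        f"{hit.bit_score:.1f}",
        f"{hit.e_value:.2g}",
        str(hit.significance),
        hit.clan,
    ]
    if hit.active_site is not None:
        fields.append(hit.active_site)
    return " ".join(fields)


def write_pfamscan(hits: Iterable[DomainHit], dest: Union[str, Path, io.TextIOBase]) -> None:
    """Write hits in pfam_scan.pl format; the result round-trips through
    :func:`read_pfamscan` with field equality (scores at printed precision)."""
    lines = ["# pfam_scan.pl output (isodom writer)", _HEADER, ""]
    lines.extend(format_hit(h) for h in hits)
    text = "\n".join(lines) + "\n"
    if isinstance(dest, io.TextIOBase):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def hits_to_frame(hits: Iterable[DomainHit]) -> pd.DataFrame:
    """Tabulate hits as a DataFrame, one row per record."""
    cols = [
        "seq_id", "aln_start", "aln_end", "env_start", "env_end", "hmm_acc",
        "hmm_name", "type", "hmm_start", "hmm_end", "hmm_length", "bit_score",
        "e_value", "significance", "clan", "active_site",
    ]
    rows = [{c: getattr(h, c) for c in cols} for h in hits]
    return pd.DataFrame(rows, columns=cols)


def _roundtrip_normalize(hit: DomainHit) -> DomainHit:
    """Hit as it will read back after formatting (score precision)."""
    return replace(
        hit,
        bit_score=float(f"{hit.bit_score:.1f}"),
        e_value=float(f"{hit.e_value:.2g}"),
    )
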