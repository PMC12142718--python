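"""TSS-anchored promoter reference handling.

The anchor-species promoter reference (EPDnew-style) provides, for each
gene, a sequence with a known transcription-start-site position.  Windows
are expressed as TSS-relative inclusive coordinates with position 0 being
the TSS base itself, so the core-promoter window (-100, +100) spans 201
bases.  Records that cannot cover the requested window are skipped and
reported, never silently truncated.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-100, 100)

_VALID = set("ACGTN")

# EPDnew FASTA export headers look like
#   >FP004937 pax6a_1; range -499 to 100.
# the simplified dialect is
#   >promoter_id gene_symbol tss=<int>
_EPD_RANGE = re.compile(r"range\s+(-?\d+)\s+to\s+(-?\d+)", re.IGNORECASE)
_TSS_FIELD = re.compile(r"\btss=(-?\d+)\b", re.IGNORECASE)


@dataclass(frozen=True)
class PromoterRecord:
    """One anchor-species promoter with a TSS-anchored window sequence."""

    promoter_id: str
    gene_symbol: str
    sequence: str
    window: tuple[int, int]
    tss_index: int

    def __post_init__(self) -> None:
        u, d = self.window
        if u > d:
            raise ValueError(
                f"window upstream offset {u} exceeds downstream offset {d}"
            )
        expected = d - u + 1
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.promoter_id}: sequence length {len(self.sequence)} "
                f"does not match window {self.window} (expected {expected})"
            )
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"{self.promoter_id}: invalid characters {sorted(bad)}"
            )


class SkipReport(list):
    """List of (entry_id, reason) pairs for entries excluded during loading."""

    def add(self, entry_id: str, reason: str) -> None:
        self.append((entry_id, reason))
        logger.warning("skipped %s: %s", entry_id, reason)


def _sanitize(seq: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN characters (IUPAC ambiguity codes) to N."""
    seq = seq.upper()
    n_mapped = sum(1 for ch in seq if ch not in _VALID)
    if n_mapped:
        seq = "".join(ch if ch in _VALID else "N" for ch in seq)
    return seq, n_mapped


def _parse_header(description: str, seq_len: int) -> tuple[str, str, int]:
    """Return (promoter_id, gene_symbol, tss_index) from a FASTA header.

    The simplified dialect carries an explicit ``tss=<int>`` 0-based index.
    EPDnew exports state the TSS-relative range of the whole entry
    (``range -499 to 100``); the TSS index follows from the range start.
    With neither annotation the TSS is assumed centred (odd-length entries).
    """
    fields = description.split()
    promoter_id = fields[0]
    gene_symbol = fields[1].rstrip(";") if len(fields) > 1 else promoter_id

    m = _TSS_FIELD.search(description)
    if m:
        return promoter_id, gene_symbol, int(m.group(1))
    m = _EPD_RANGE.search(description)
    if m:
        return promoter_id, gene_symbol, -int(m.group(1))
    return promoter_id, gene_symbol, (seq_len - 1) // 2


def load_promoter_reference(
    path: str | Path,
    window: tuple[int, int] = DEFAULT_WINDOW,
    skip_report: SkipReport | None = None,
) -> list[PromoterRecord]:
    """Load an EPDnew-style promoter FASTA, cut to a TSS-anchored window.

    Parameters
    ----------
    path
        FASTA file whose headers carry a promoter identifier and (optionally)
        a TSS annotation; see :func:`_parse_header` for the dialects.
    window
        ``(upstream_offset, downstream_offset)`` TSS-relative inclusive
        positions; ``(-100, 100)`` yields 201-base core promoters.
    skip_report
        Optional :class:`SkipReport` collecting entries whose sequence cannot
        cover the window.

    Returns
    -------
    list of PromoterRecord, one per coverable FASTA entry.
    """
    u, d = window
    if u > d:
        raise ValueError(f"invalid window {window}: upstream > downstream")
    report = skip_report if skip_report is not None else SkipReport()
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq, n_mapped = _sanitize(str(entry.seq))
        promoter_id, gene_symbol, tss = _parse_header(entry.description, len(seq))
        if n_mapped:
            logger.info(
                "%s: %d non-ACGTN characters mapped to N", promoter_id, n_mapped
            )
        if promoter_id in seen:
            raise ValueError(f"duplicate promoter_id {promoter_id!r}")
        seen.add(promoter_id)
        start = tss + u
        end = tss + d  # inclusive
        if start < 0 or end >= len(seq):
            report.add(
                promoter_id,
                f"sequence (length {len(seq)}, TSS index {tss}) cannot cover "
                f"window {window}",
            )
            continue
        records.append(
            PromoterRecord(
                promoter_id=promoter_id,
                gene_symbol=gene_symbol,
                sequence=seq[start : end + 1],
                window=(u, d),
                tss_index=-u,
            )
        )
    return records


def write_promoter_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    """Write window-trimmed records in the simplified header dialect."""
    entries = [
        SeqRecord(
            Seq(r.sequence),
            id=r.promoter_id,
            description=f"{r.gene_symbol} tss={r.tss_index}",
        )
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def validate_unique_ids(records: Sequence[PromoterRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.promoter_id in seen:
            raise ValueError(f"duplicate promoter_id {r.promoter_id!r}")
        seen.add(r.promoter_id)
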