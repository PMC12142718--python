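"""Top-hit promoter homology search against target genomes.

Production runs consume BLAST tabular output (outfmt 6, 12 standard
columns).  For each promoter query only the single top-scoring locus at
>= 70% identity is retained; ranking is bit score (desc), then e-value
(asc), then alignment length (desc), then input order — deterministic and
consistent with how BLAST itself orders hits.

A built-in seed-and-extend matcher (`builtin_scan`) covers test-scale
genomes without external binaries.  It is ungapped and approximate — an
exact-k-mer-seeded scan, not a BLAST re-implementation — and flags its hits
with e_value 0.
"""

from __future__ import annotations

import logging
import subprocess
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import reverse_complement

from .promoter_reference import PromoterRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 70.0

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

HIT_TSV_COLUMNS = (
    "promoter_id contig_id subject_start subject_end strand "
    "percent_identity alignment_length bit_score e_value"
).split()


@dataclass(frozen=True)
class PromoterHit:
    """The single best locus for one promoter in one genome."""

    promoter_id: str
    contig_id: str
    subject_start: int  # 1-based inclusive, start <= end after normalization
    subject_end: int
    strand: str  # '+' or '-'
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float
    subject_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValueError("subject_start must be <= subject_end")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.subject_sequence is not None:
            span = self.subject_end - self.subject_start + 1
            if len(self.subject_sequence) != span:
                raise ValueError(
                    f"subject_sequence length {len(self.subject_sequence)} "
                    f"does not match span {span}"
                )


class HitTableParseError(ValueError):
    pass


def load_hit_table(
    path: str | Path, min_identity: float = DEFAULT_MIN_IDENTITY
) -> list[PromoterHit]:
    """Parse BLAST outfmt 6, dropping hits below the identity threshold.

    Rows with sstart > send are normalized (coordinates swapped, strand set
    to '-').  Malformed rows raise :class:`HitTableParseError` with the
    offending line number.
    """
    hits: list[PromoterHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(OUTFMT6_COLUMNS):
                raise HitTableParseError(
                    f"{path}:{lineno}: expected {len(OUTFMT6_COLUMNS)} "
                    f"tab-separated columns, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise HitTableParseError(f"{path}:{lineno}: {exc}") from exc
            if pident < min_identity:
                continue
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            hits.append(
                PromoterHit(
                    promoter_id=qseqid,
                    contig_id=sseqid,
                    subject_start=sstart,
                    subject_end=send,
                    strand=strand,
                    percent_identity=pident,
                    alignment_length=length,
                    bit_score=bitscore,
                    e_value=evalue,
                )
            )
    return hits


def select_top_hits(hits: Sequence[PromoterHit]) -> list[PromoterHit]:
    """Keep the single highest-ranked hit per promoter.

    Ranking: bit_score desc, e_value asc, alignment_length desc, input
    order.  Output preserves first-appearance order of promoter ids.
    """
    best: dict[str, tuple[tuple, PromoterHit]] = {}
    order: list[str] = []
    for i, hit in enumerate(hits):
        key = (-hit.bit_score, hit.e_value, -hit.alignment_length, i)
        if hit.promoter_id not in best:
            best[hit.promoter_id] = (key, hit)
            order.append(hit.promoter_id)
        elif key < best[hit.promoter_id][0]:
            best[hit.promoter_id] = (key, hit)
    return [best[pid][1] for pid in order]


def attach_subject_sequences(
    hits: Iterable[PromoterHit], genome: str | Path
) -> list[PromoterHit]:
    """Resolve hit coordinates to genome bases.

    Minus-strand hits get the reverse complement, so subject_sequence always
    reads in the query orientation.
    """
    contigs = {e.id: str(e.seq).upper() for e in SeqIO.parse(str(genome), "fasta")}
    out: list[PromoterHit] = []
    for hit in hits:
        if hit.contig_id not in contigs:
            raise KeyError(f"contig {hit.contig_id!r} not found in {genome}")
        contig = contigs[hit.contig_id]
        if hit.subject_end > len(contig):
            raise ValueError(
                f"hit {hit.promoter_id}: subject_end {hit.subject_end} beyond "
                f"contig {hit.contig_id} end ({len(contig)})"
            )
        seq = contig[hit.subject_start - 1 : hit.subject_end]
        if hit.strand == "-":
            seq = reverse_complement(seq)
        out.append(replace(hit, subject_sequence=seq))
    return out


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def builtin_scan(
    promoters: Sequence[PromoterRecord],
    genome: str | Path,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = 11,
) -> list[PromoterHit]:
    """Seed-and-extend ungapped search for promoter queries in a genome.

    Exact k-mer seeds (default k=11) on both strands anchor candidate
    placements; each candidate is scored over the full query length and
    identity = matches / query length.  Hits below ``min_identity`` are
    discarded and top-hit selection is applied, so at most one hit per
    promoter is returned with subject_sequence attached.  Approximate by
    design: ungapped, bit_score = match count, e_value fixed at 0.
    """
    for p in promoters:
        if len(p.sequence) < max(21, k):
            raise ValueError(
                f"promoter {p.promoter_id} shorter than minimum query length"
            )
    raw: list[PromoterHit] = []
    for entry in SeqIO.parse(str(genome), "fasta"):
        contig_id = entry.id
        contig = str(entry.seq).upper()
        index = _kmer_index(contig, k)
        for prom in promoters:
            qlen = len(prom.sequence)
            for strand in "+-":
                query = (
                    prom.sequence
                    if strand == "+"
                    else reverse_complement(prom.sequence)
                )
                starts: set[int] = set()
                for qi in range(qlen - k + 1):
                    for gpos in index.get(query[qi : qi + k], ()):
                        start = gpos - qi
                        if 0 <= start <= len(contig) - qlen:
                            starts.add(start)
                for start in starts:
                    window = contig[start : start + qlen]
                    matches = sum(a == b for a, b in zip(query, window))
                    identity = 100.0 * matches / qlen
                    if identity < min_identity:
                        continue
                    raw.append(
                        PromoterHit(
                            promoter_id=prom.promoter_id,
                            contig_id=contig_id,
                            subject_start=start + 1,
                            subject_end=start + qlen,
                            strand=strand,
                            percent_identity=identity,
                            alignment_length=qlen,
                            bit_score=float(matches),
                            e_value=0.0,
                            subject_sequence=window
                            if strand == "+"
                            else reverse_complement(window),
                        )
                    )
    return select_top_hits(raw)


def write_hit_tsv(hits: Iterable[PromoterHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.promoter_id,
                        h.contig_id,
                        h.subject_start,
                        h.subject_end,
                        h.strand,
                        f"{h.percent_identity:.3f}",
                        h.alignment_length,
                        f"{h.bit_score:.2f}",
                        f"{h.e_value:.3g}",
                    )
                )
                + "\n"
            )


def run_blastn(
    promoters_fasta: str | Path,
    genome_fasta: str | Path,
    out_path: str | Path,
    blast_bin: str = "blastn",
) -> list[str]:
    """Shell out to NCBI blastn for a tabular (outfmt 6) hit table.

    Returns the full command line for run-log provenance.  Word size, gap
    penalties and task are left at blastn defaults; the artifact consumes
    whatever tabular output the aligner produces.
    """
    cmd = [
        blast_bin,
        "-query",
        str(promoters_fasta),
        "-subject",
        str(genome_fasta),
        "-outfmt",
        "6",
        "-out",
        str(out_path),
    ]
    logger.info("running: %s", " ".join(cmd))
    subprocess.run(cmd, check=True)
    return cmd
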