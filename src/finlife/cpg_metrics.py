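"""CpG observed/expected ratio computation.

The CpG O/E ratio (Gardiner-Garden & Frommer style) measures under- or
over-representation of the CG dinucleotide relative to the expectation from
base composition:

    O/E = (count(CG) * N) / (count(C) * count(G))

where N is the effective sequence length.  Bases outside {A,C,G,T} carry no
compositional information: they are excluded from N, C and G, and a
dinucleotide position spanning one is not counted, so N-rich draft
assemblies do not deflate the ratio.  When C or G is absent the ratio is
defined as 0, the same convention used for promoters without a homology
hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .homology_search import PromoterHit

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class CpGCounts:
    """Dinucleotide/nucleotide counts and the derived O/E ratio."""

    cpg: int
    c: int
    g: int
    n: int

    def __post_init__(self) -> None:
        if min(self.cpg, self.c, self.g, self.n) < 0:
            raise ValueError("counts must be non-negative")
        if self.cpg > min(self.c, self.g) or self.c + self.g > self.n:
            raise ValueError("inconsistent counts")

    @property
    def oe_ratio(self) -> float:
        if self.c == 0 or self.g == 0:
            return 0.0
        return (self.cpg * self.n) / (self.c * self.g)

    def __add__(self, other: "CpGCounts") -> "CpGCounts":
        return CpGCounts(
            self.cpg + other.cpg, self.c + other.c, self.g + other.g, self.n + other.n
        )


def count_cpg(sequence: str) -> CpGCounts:
    """Count CG dinucleotides, C, G and effective length of a DNA string.

    Case-insensitive; characters outside {A,C,G,T} are excluded from every
    count and break dinucleotide adjacency.  CG cannot overlap itself, so a
    plain positional scan is overlap-free by construction.
    """
    seq = sequence.upper()
    c = g = n = cpg = 0
    prev_c = False
    for ch in seq:
        if ch in _ACGT:
            n += 1
            if ch == "C":
                c += 1
            elif ch == "G":
                g += 1
                if prev_c:
                    cpg += 1
            prev_c = ch == "C"
        else:
            prev_c = False
    return CpGCounts(cpg=cpg, c=c, g=g, n=n)


def oe_ratio(sequence: str) -> float:
    return count_cpg(sequence).oe_ratio


def promoter_oe_vector(
    hits: Iterable[PromoterHit], promoter_ids: Sequence[str]
) -> np.ndarray:
    """O/E per promoter, aligned to ``promoter_ids``; 0 where no hit.

    A promoter with no retained homology hit contributes a 0 entry, the
    model's encoding for "no matching promoter sequence".
    """
    index: Mapping[str, int] = {pid: i for i, pid in enumerate(promoter_ids)}
    vec = np.zeros(len(promoter_ids), dtype=float)
    for hit in hits:
        if hit.promoter_id not in index:
            raise KeyError(
                f"hit references unknown promoter_id {hit.promoter_id!r}"
            )
        if hit.subject_sequence is None:
            raise ValueError(
                f"hit for {hit.promoter_id!r} has no subject_sequence attached"
            )
        vec[index[hit.promoter_id]] = oe_ratio(hit.subject_sequence)
    return vec


def global_genome_metrics(genome: str | Path) -> tuple[float, int]:
    """Genome-wide CpG O/E and total assembly size in bases.

    Counts are pooled across contigs; dinucleotides never span a contig
    boundary.  Genome size counts every base including ambiguity codes
    (NCBI assembly-length convention), while the pooled O/E uses effective
    (unambiguous) counts only.
    """
    total = CpGCounts(0, 0, 0, 0)
    genome_size = 0
    n_contigs = 0
    for entry in SeqIO.parse(str(genome), "fasta"):
        seq = str(entry.seq)
        genome_size += len(seq)
        total = total + count_cpg(seq)
        n_contigs += 1
    if n_contigs == 0:
        raise ValueError(f"empty FASTA: {genome}")
    return total.oe_ratio, genome_size
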