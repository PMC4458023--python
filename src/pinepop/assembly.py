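"""Reference transcriptome contigs: I/O, assembly summary statistics, retention filters.

The contig set produced by a de novo transcriptome assembler is the coordinate
frame for everything downstream: variants are called against it and consensus
sequences are projected onto it.  This module reads and writes contig FASTA,
computes the usual assembly report (N50, GC, mean length, ...) and applies the
two retention filters used to derive a high-quality unigene set: presence of an
open reading frame, and removal of contigs on an exclusion-id list (e.g. putative
retroelements identified by external homology searches).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ContigSet",
    "TranscriptomeStats",
    "compute_assembly_stats",
    "filter_contigs",
    "has_orf",
    "mean_contig_length",
    "write_stats_tsv",
]

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class ContigSet:
    """An ordered, id-unique collection of DNA contigs.

    Sequences are stored upper-cased; record order is preserved through
    FASTA round trips.
    """

    def __init__(self, records: Iterable[tuple[str, str]] = ()):
        self._seqs: dict[str, str] = {}
        for cid, seq in records:
            self.add(cid, seq)

    def add(self, contig_id: str, sequence: str) -> None:
        if contig_id in self._seqs:
            raise ValueError(f"duplicate contig id: {contig_id!r}")
        if not sequence:
            raise ValueError(f"empty sequence for contig {contig_id!r}")
        self._seqs[contig_id] = sequence.upper()

    @property
    def ids(self) -> list[str]:
        return list(self._seqs)

    def __getitem__(self, contig_id: str) -> str:
        return self._seqs[contig_id]

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._seqs.items())

    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ContigSet":
        cs = cls()
        for rec in SeqIO.parse(str(path), "fasta"):
            cs.add(rec.id, str(rec.seq))
        return cs

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        records = (
            SeqRecord(Seq(seq), id=cid, description="") for cid, seq in self.items()
        )
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


@dataclass(frozen=True)
class TranscriptomeStats:
    """Assembly summary over contigs passing the minimum-length cutoff."""

    max_length: int
    n_contigs_over_min: int
    total_bases: int
    n50: int
    n_contigs_in_n50: int
    gc_percent: float
    non_atgc: int
    mean_length: float


def _n50(lengths: list[int]) -> tuple[int, int]:
    """N50 = the largest length L such that contigs of length >= L together
    contain at least half of the total bases.  Returns (N50, number of
    contigs of length >= N50)."""
    total = sum(lengths)
    ordered = sorted(lengths, reverse=True)
    half = total / 2
    cum = 0
    n50 = ordered[-1]
    for length in ordered:
        cum += length
        if cum >= half:
            n50 = length
            break
    n_in = sum(1 for x in lengths if x >= n50)
    return n50, n_in


def compute_assembly_stats(
    contigs: ContigSet,
    min_length: int = 100,
    length_inclusive: bool = True,
) -> TranscriptomeStats:
    """Summary statistics over contigs of length >= ``min_length``.

    GC percent is computed over A/C/G/T bases only; every other character
    (N, IUPAC ambiguity, gaps) is tallied separately as ``non_atgc``.
    ``length_inclusive=False`` switches the cutoff to a strict ``>``.
    """
    if length_inclusive:
        kept = [s for _, s in contigs.items() if len(s) >= min_length]
    else:
        kept = [s for _, s in contigs.items() if len(s) > min_length]
    if not kept:
        raise ValueError(f"no contigs pass the min_length={min_length} filter")
    lengths = [len(s) for s in kept]
    total = sum(lengths)
    n50, n_in_n50 = _n50(lengths)
    gc = at = other = 0
    for seq in kept:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
        other += len(seq) - seq.count("G") - seq.count("C") - seq.count("A") - seq.count("T")
    denom = gc + at
    return TranscriptomeStats(
        max_length=max(lengths),
        n_contigs_over_min=len(kept),
        total_bases=total,
        n50=n50,
        n_contigs_in_n50=n_in_n50,
        gc_percent=100.0 * gc / denom if denom else 0.0,
        non_atgc=other,
        mean_length=total / len(kept),
    )


def mean_contig_length(total_bases: int, n_contigs: int) -> float:
    """Mean contig length implied by a (total bases, contig count) pair."""
    if n_contigs <= 0:
        raise ValueError("n_contigs must be positive")
    return total_bases / n_contigs


def _frame_has_orf(codons: list[str], min_aa: int, require_start: bool) -> bool:
    run = 0  # codons since last stop (or frame start), counted only once started
    started = not require_start
    count = 0
    for codon in codons:
        if codon in _STOP_CODONS:
            if count >= min_aa:
                return True
            count = 0
            started = not require_start
            continue
        if not started and codon == "ATG":
            started = True
        if started:
            count += 1
    return False  # ORFs may not span contig ends: an unterminated run does not count


def has_orf(sequence: str, min_orf_aa: int, require_start: bool = True) -> bool:
    """True if the sequence contains an open reading frame of at least
    ``min_orf_aa`` codons (start codon included, stop excluded) in any of
    the six reading frames.  The ORF must be terminated by a stop codon
    within the contig."""
    if min_orf_aa < 1:
        raise ValueError("min_orf_aa must be >= 1")
    seq = sequence.upper()
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            sub = strand_seq[frame:]
            codons = [sub[i : i + 3] for i in range(0, len(sub) - 2, 3)]
            if _frame_has_orf(codons, min_orf_aa, require_start):
                return True
    return False


def filter_contigs(
    contigs: ContigSet,
    min_orf_aa: int = 100,
    exclude_ids: Iterable[str] = (),
    require_start: bool = True,
) -> ContigSet:
    """Retain contigs that contain an ORF of >= ``min_orf_aa`` codons and
    whose id is not in ``exclude_ids``.  Input order is preserved; the
    result may be empty."""
    excluded = set(exclude_ids)
    out = ContigSet()
    for cid, seq in contigs.items():
        if cid in excluded:
            continue
        if has_orf(seq, min_orf_aa, require_start=require_start):
            out.add(cid, seq)
    return out


def write_stats_tsv(stats: TranscriptomeStats, path: str | Path) -> None:
    rows = [
        ("max_contig_length", stats.max_length),
        ("n_contigs_over_min", stats.n_contigs_over_min),
        ("total_bases", stats.total_bases),
        ("n50", stats.n50),
        ("n_contigs_in_n50", stats.n_contigs_in_n50),
        ("gc_percent", f"{stats.gc_percent:.1f}"),
        ("non_atgc", stats.non_atgc),
        ("mean_length", f"{stats.mean_length:.1f}"),
    ]
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in rows:
            fh.write(f"{name}\t{value}\n")
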