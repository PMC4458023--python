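"""Reference-projected consensus sequences and the merged multi-contig alignment.

Samples are represented as consensus sequences obtained by substituting each
sample's variant alleles into the reference contigs (heterozygous sites as
IUPAC ambiguity codes by default).  Contigs that are common to, and polymorphic
in, every sample are concatenated — in reference order — into one positionally
aligned matrix with one row per sample.  No alignment algorithm runs here:
all sequences share the reference coordinate frame, so columns correspond by
construction.

Internal coordinates are 0-based half-open; the 1-based VCF convention is
converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .assembly import ContigSet
from .panel import HET, HOM_ALT, SampleVariantSet, VariantKey

__all__ = [
    "IUPAC_HET",
    "MergedAlignment",
    "build_consensus",
    "build_merged_alignment",
    "select_common_polymorphic_contigs",
]

# Two-base ambiguity codes for heterozygous sites.
IUPAC_HET: dict[frozenset, str] = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
HET_POLICIES = ("iupac", "alt", "ref")


@dataclass
class MergedAlignment:
    """Concatenated per-sample consensus sequences over a shared contig set.

    ``contig_offsets`` maps contig id -> (start, end) in 0-based half-open
    coordinates of the concatenated sequence; offsets partition
    ``[0, total_length)`` in order, without gaps or overlap.
    """

    sample_ids: list[str]
    sequences: list[str]
    contig_offsets: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("one sequence per sample required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def total_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def sequence_of(self, sample_id: str) -> str:
        return self.sequences[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "MergedAlignment":
        seqs = [self.sequence_of(s) for s in sample_ids]
        return MergedAlignment(list(sample_ids), seqs, dict(self.contig_offsets))

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for sid, seq in zip(self.sample_ids, self.sequences):
                fh.write(f">{sid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_offsets_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tstart\tend\n")
            for cid, (start, end) in self.contig_offsets.items():
                fh.write(f"{cid}\t{start}\t{end}\n")

    @classmethod
    def from_fasta(
        cls, fasta_path: str | Path, offsets_path: str | Path | None = None
    ) -> "MergedAlignment":
        sample_ids, seqs = [], []
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            sample_ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        offsets: dict[str, tuple[int, int]] = {}
        if offsets_path is not None:
            with open(offsets_path) as fh:
                next(fh)
                for line in fh:
                    cid, start, end = line.rstrip("\n").split("\t")
                    offsets[cid] = (int(start), int(end))
        else:
            offsets = {"concat": (0, len(seqs[0]))} if seqs else {}
        return cls(sample_ids, seqs, offsets)


def select_common_polymorphic_contigs(
    sets: Sequence[SampleVariantSet],
    reference_order: Sequence[str] | None = None,
) -> list[str]:
    """Contigs on which EVERY sample has at least one variant.

    Returned in ``reference_order`` if given, otherwise sorted — either way
    the result is deterministic.
    """
    if not sets:
        raise ValueError("need at least one sample variant set")
    common: set[str] | None = None
    for svs in sets:
        contigs = svs.contigs_with_variants()
        common = contigs if common is None else common & contigs
    assert common is not None
    if reference_order is not None:
        return [c for c in reference_order if c in common]
    return sorted(common)


def build_consensus(
    reference_seq: str,
    variants: Iterable[tuple[VariantKey, str]],
    het_policy: str = "iupac",
    contig_id: str = "",
) -> str:
    """Substitute one sample's variants into a reference contig sequence.

    Homozygous-alternative sites take the alt base.  Heterozygous sites take
    the two-base IUPAC code (default), or the alt / ref base under policies
    "alt" / "ref".  A ref-allele mismatch against the reference raises.
    """
    if het_policy not in HET_POLICIES:
        raise ValueError(f"het_policy must be one of {HET_POLICIES}")
    seq = list(reference_seq.upper())
    for key, genotype in variants:
        idx = key.pos - 1
        if idx < 0 or idx >= len(seq):
            raise ValueError(
                f"variant position {key.pos} outside contig {contig_id or key.contig!r} "
                f"(length {len(seq)})"
            )
        if seq[idx] != key.ref:
            raise ValueError(
                f"ref allele mismatch at {contig_id or key.contig}:{key.pos}: "
                f"VCF says {key.ref!r}, reference has {seq[idx]!r}"
            )
        if genotype == HOM_ALT:
            seq[idx] = key.alt
        elif genotype == HET:
            if het_policy == "iupac":
                seq[idx] = IUPAC_HET[frozenset((key.ref, key.alt))]
            elif het_policy == "alt":
                seq[idx] = key.alt
            # "ref": leave the reference base
        else:
            raise ValueError(f"unknown genotype {genotype!r}")
    return "".join(seq)


def build_merged_alignment(
    reference: ContigSet,
    sets: Sequence[SampleVariantSet],
    contig_ids: Sequence[str] | None = None,
    het_policy: str = "iupac",
) -> MergedAlignment:
    """Concatenate per-sample consensus sequences over ``contig_ids``.

    If ``contig_ids`` is None, contigs common to and polymorphic in all
    samples are selected automatically (in reference order).
    """
    if contig_ids is None:
        contig_ids = select_common_polymorphic_contigs(sets, reference.ids)
    missing = [c for c in contig_ids if c not in reference]
    if missing:
        raise ValueError(f"contigs not in reference: {missing}")
    by_sample_contig: list[dict[str, list[tuple[VariantKey, str]]]] = []
    for svs in sets:
        per_contig: dict[str, list[tuple[VariantKey, str]]] = {}
        for key, gt in svs.genotypes.items():
            per_contig.setdefault(key.contig, []).append((key, gt))
        by_sample_contig.append(per_contig)

    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for cid in contig_ids:
        end = pos + len(reference[cid])
        offsets[cid] = (pos, end)
        pos = end

    sequences = []
    for svs, per_contig in zip(sets, by_sample_contig):
        parts = [
            build_consensus(
                reference[cid], per_contig.get(cid, ()), het_policy, contig_id=cid
            )
            for cid in contig_ids
        ]
        sequences.append("".join(parts))
    return MergedAlignment([s.sample_id for s in sets], sequences, offsets)
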