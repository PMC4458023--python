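"""Per-sample SNP sets and the cross-species SNP panel.

A "panel" here is the merged collection of biallelic SNPs called per sample
against one reference transcriptome.  The module parses single-sample VCFs,
forms per-species SNP unions, tabulates common/unique SNPs between species
pairs, applies the genotyping-oriented spacing filter (a SNP is kept only if
no other SNP sits within ``min_gap`` bp on either side on the same contig),
and computes mapping-summary percentages from read-count tables.

Two SNPs are the same variant only if contig, position, reference allele AND
alternative allele all match; same-position different-alt calls are counted
as different SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import pysam

from .assembly import ContigSet

__all__ = [
    "VariantKey",
    "SampleVariantSet",
    "SharedUniqueTable",
    "read_sample_vcf",
    "write_sample_vcf",
    "species_union_snps",
    "pairwise_shared_unique",
    "spacing_filter",
    "mapping_percentages",
]

logger = logging.getLogger(__name__)

HET = "het"
HOM_ALT = "hom_alt"
_BASES = frozenset("ACGT")


class VariantKey(NamedTuple):
    """Identity of a biallelic SNP: contig, 1-based position, ref and alt."""

    contig: str
    pos: int
    ref: str
    alt: str


@dataclass
class SampleVariantSet:
    """One sample's SNP calls relative to the reference transcriptome."""

    sample_id: str
    species: str
    genotypes: dict[VariantKey, str] = field(default_factory=dict)
    n_skipped: int = 0

    def add(self, key: VariantKey, genotype: str) -> None:
        if genotype not in (HET, HOM_ALT):
            raise ValueError(f"genotype must be {HET!r} or {HOM_ALT!r}")
        if key.ref == key.alt or key.ref not in _BASES or key.alt not in _BASES:
            raise ValueError(f"invalid SNP alleles in {key}")
        site = (key.contig, key.pos)
        for existing in self.genotypes:
            if (existing.contig, existing.pos) == site:
                raise ValueError(
                    f"duplicate call at {key.contig}:{key.pos} in sample {self.sample_id}"
                )
        self.genotypes[key] = genotype

    @property
    def keys(self) -> set[VariantKey]:
        return set(self.genotypes)

    def contigs_with_variants(self) -> set[str]:
        return {k.contig for k in self.genotypes}

    def __len__(self) -> int:
        return len(self.genotypes)


def _classify_gt(gt: tuple) -> str | None:
    alleles = {a for a in gt if a is not None}
    if alleles == {0, 1}:
        return HET
    if alleles == {1}:
        return HOM_ALT
    return None


def read_sample_vcf(
    path: str | Path,
    sample_id: str | None = None,
    species: str = "",
    reference: ContigSet | None = None,
) -> SampleVariantSet:
    """Parse a single-sample VCF into a :class:`SampleVariantSet`.

    Only biallelic SNP records are kept; indels, multi-allelic rows and
    records without a called non-reference genotype are skipped and counted
    in ``n_skipped``.  Positions stay 1-based.  If ``reference`` is given,
    records on contigs absent from it raise a :class:`ValueError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    with vcf:
        vcf_samples = list(vcf.header.samples)
        if sample_id is None:
            if len(vcf_samples) != 1:
                raise ValueError(
                    f"{path}: expected a single-sample VCF, found {vcf_samples}"
                )
            sample_id = vcf_samples[0]
        elif sample_id not in vcf_samples:
            raise ValueError(f"{path}: sample {sample_id!r} not in VCF {vcf_samples}")
        svs = SampleVariantSet(sample_id=sample_id, species=species)
        for rec in vcf:
            if reference is not None and rec.contig not in reference:
                raise ValueError(f"{path}: unknown contig {rec.contig!r}")
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in _BASES
                or alts[0] not in _BASES
            ):
                svs.n_skipped += 1
                continue
            gt = _classify_gt(rec.samples[sample_id].get("GT", (None,)))
            if gt is None:
                svs.n_skipped += 1
                continue
            svs.add(VariantKey(rec.contig, rec.pos, rec.ref, alts[0]), gt)
    if svs.n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, svs.n_skipped)
    return svs


def write_sample_vcf(
    svs: SampleVariantSet,
    path: str | Path,
    contig_lengths: Mapping[str, int],
    contig_order: Sequence[str] | None = None,
) -> None:
    """Write a SampleVariantSet as a minimal single-sample VCF v4.2 file.

    Records are sorted by reference contig order then position, which makes
    output byte-deterministic for a given variant set.
    """
    order = list(contig_order) if contig_order is not None else list(contig_lengths)
    rank = {cid: i for i, cid in enumerate(order)}
    rows = sorted(svs.genotypes.items(), key=lambda kv: (rank[kv[0].contig], kv[0].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pinepop\n")
        for cid in order:
            fh.write(f"##contig=<ID={cid},length={contig_lengths[cid]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + svs.sample_id
            + "\n"
        )
        for key, gt in rows:
            gt_str = "0/1" if gt == HET else "1/1"
            fh.write(
                f"{key.contig}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t{gt_str}\n"
            )


def species_union_snps(
    sets: Sequence[SampleVariantSet],
    species_map: Mapping[str, str] | None = None,
) -> dict[str, set[VariantKey]]:
    """Union of each species' samples' SNP keys.

    ``species_map`` (sample id -> species) overrides the labels carried on
    the sets; every sample must resolve to a species.
    """
    out: dict[str, set[VariantKey]] = {}
    for svs in sets:
        if species_map is not None:
            if svs.sample_id not in species_map:
                raise ValueError(f"sample {svs.sample_id!r} missing from species map")
            sp = species_map[svs.sample_id]
        else:
            sp = svs.species
        if not sp:
            raise ValueError(f"sample {svs.sample_id!r} has no species assignment")
        out.setdefault(sp, set()).update(svs.keys)
    return out


@dataclass(frozen=True)
class SharedUniqueTable:
    """Common and unique SNP counts in pairwise comparisons between species."""

    species: tuple[str, ...]
    totals: dict[str, int]
    common: dict[tuple[str, str], int]  # unordered pairs, stored both ways
    unique: dict[tuple[str, str], int]  # unique[(a, b)] = SNPs of a absent from b

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.species:
            for b in self.species:
                if a == b:
                    continue
                rows.append(
                    {
                        "species": a,
                        "versus": b,
                        "total": self.totals[a],
                        "common": self.common[(a, b)],
                        "unique": self.unique[(a, b)],
                    }
                )
        return pd.DataFrame(rows)


def pairwise_shared_unique(
    species_sets: Mapping[str, set[VariantKey]],
) -> SharedUniqueTable:
    """Tabulate total, common and unique SNP counts for every species pair.

    Common counts use full variant-key equality (contig, position, ref, alt);
    ``unique[(a, b)] = totals[a] - common[(a, b)]``.
    """
    species = tuple(species_sets)
    if len(species) < 2:
        raise ValueError("need at least two species sets")
    totals = {sp: len(s) for sp, s in species_sets.items()}
    common: dict[tuple[str, str], int] = {}
    unique: dict[tuple[str, str], int] = {}
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            c = len(species_sets[a] & species_sets[b])
            common[(a, b)] = common[(b, a)] = c
            unique[(a, b)] = totals[a] - c
            unique[(b, a)] = totals[b] - c
    return SharedUniqueTable(species=species, totals=totals, common=common, unique=unique)


def spacing_filter(
    variants: Iterable[VariantKey],
    min_gap: int = 50,
) -> set[VariantKey]:
    """Keep only SNPs with a clear flank of more than ``min_gap`` bp.

    A SNP survives iff no other SNP in the input lies within ``min_gap`` bp
    on the same contig (|delta pos| <= min_gap removes BOTH members of a close
    pair — neighbour exclusion, not greedy thinning).  Contigs are independent.
    The result is inclusion-maximal under this rule and does not depend on
    input order.
    """
    by_contig: dict[str, list[VariantKey]] = {}
    for key in variants:
        by_contig.setdefault(key.contig, []).append(key)
    kept: set[VariantKey] = set()
    for keys in by_contig.values():
        keys.sort(key=lambda k: k.pos)
        n = len(keys)
        for i, key in enumerate(keys):
            left_ok = i == 0 or key.pos - keys[i - 1].pos > min_gap
            right_ok = i == n - 1 or keys[i + 1].pos - key.pos > min_gap
            if left_ok and right_ok:
                kept.add(key)
    return kept


def write_panel_tsv(
    panel: Iterable[VariantKey],
    species_sets: Mapping[str, set[VariantKey]],
    path: str | Path,
) -> None:
    """Write a filtered panel as TSV with per-species presence flags."""
    species = list(species_sets)
    keys = sorted(set(panel))
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\talt\t" + "\t".join(species) + "\n")
        for k in keys:
            flags = "\t".join("1" if k in species_sets[sp] else "0" for sp in species)
            fh.write(f"{k.contig}\t{k.pos}\t{k.ref}\t{k.alt}\t{flags}\n")


def write_panel_vcf(
    panel: Iterable[VariantKey],
    path: str | Path,
    contig_lengths: Mapping[str, int],
) -> None:
    """Write a site-only (no genotype columns) VCF of panel positions."""
    keys = sorted(set(panel), key=lambda k: (k.contig, k.pos, k.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=pinepop\n")
        for cid, length in contig_lengths.items():
            fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for k in keys:
            fh.write(f"{k.contig}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\n")


def mapping_percentages(read_counts: pd.DataFrame | Sequence[tuple]) -> pd.DataFrame:
    """Per-sample and merged mapping percentages from raw read counts.

    ``read_counts`` rows are (sample, total_reads, mapped_reads,
    proper_pair_reads, duplicate_reads).  Every percentage is
    ``100 * part / total_reads`` rounded to two decimals; the appended
    ``Merged`` row uses the summed counts.
    """
    cols = ["sample", "total_reads", "mapped_reads", "proper_pair_reads", "duplicate_reads"]
    if isinstance(read_counts, pd.DataFrame):
        df = read_counts[cols].copy()
    else:
        df = pd.DataFrame(list(read_counts), columns=cols)
    if df.empty:
        raise ValueError("empty read-count table")
    if (df["total_reads"] <= 0).any():
        bad = df.loc[df["total_reads"] <= 0, "sample"].tolist()
        raise ValueError(f"non-positive total reads for samples: {bad}")
    merged = {
        "sample": "Merged",
        "total_reads": df["total_reads"].sum(),
        "mapped_reads": df["mapped_reads"].sum(),
        "proper_pair_reads": df["proper_pair_reads"].sum(),
        "duplicate_reads": df["duplicate_reads"].sum(),
    }
    out = pd.concat([df, pd.DataFrame([merged])], ignore_index=True)
    for part, col in [
        ("mapped_reads", "pct_mapped"),
        ("proper_pair_reads", "pct_proper_pairs"),
        ("duplicate_reads", "pct_duplicates"),
    ]:
        out[col] = (100.0 * out[part] / out["total_reads"]).round(2)
    return out
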