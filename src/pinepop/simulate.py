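"""Synthetic multi-taxon species-complex generator with ground truth.

Generates a reference transcriptome, per-sample diploid genotypes, per-sample
VCFs and IUPAC consensus sequences for a configurable complex of closely
related taxa, together with a per-site truth table that downstream tests use
for parameter recovery.

The generative model is deliberately simple (no coalescent genealogies, no
recombination, no indels):

* Within-species polymorphism: segregating sites are placed uniformly on the
  reference (collision-free) with count S ~ Binomial(L, theta * a1), where
  a1 = sum 1/i over the species' 2N-1 chromosome classes — so Watterson's
  estimator S / (L * a1) recovers theta by construction.  Each site's derived
  allele count is drawn from a power-law site-frequency spectrum
  P(i) proportional to 1/i^skew (skew = 1 is the neutral standard; skew > 1
  gives the excess of rare variants that produces negative Tajima's D), and
  derived alleles are assigned to chromosomes at random.
* Shared polymorphism: a configurable fraction of each species' polymorphic
  sites segregates in every species (same alternative allele, independent
  frequencies).
* Divergence: the configured pairwise fixed-difference-rate matrix is fitted
  with a UPGMA tree, and fixed differences are sampled per branch — each such
  site is fixed for the derived allele in every species of that branch's
  clade.  Pairwise rates are reproduced exactly for ultrametric matrices and
  by ultrametric projection otherwise; the ordering of shared-SNP fractions
  always follows the matrix.
* Optional admixed sample: one sample re-drawn with each haplotype's
  species-of-origin sampled per contig between two parent species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .alignment import build_consensus
from .assembly import ContigSet
from .panel import HET, HOM_ALT, SampleVariantSet, VariantKey, write_sample_vcf
from .structure import upgma_tree

__all__ = [
    "AdmixedSample",
    "SimulationConfig",
    "SimulationResult",
    "TruthTable",
    "sample_sfs_count",
    "simulate_complex",
    "write_outputs",
    "study_like_config",
]

_BASES = "ACGT"
_ACRONYMS = {
    "P. sylvestris": "PS",
    "P. mugo": "M",
    "P. uncinata": "UN",
    "P. uliginosa": "UG",
}

SPECIES_POLY = "species_poly"
SHARED_POLY = "shared_poly"
FIXED_DIFF = "fixed_diff"


def species_acronym(name: str, index: int) -> str:
    return _ACRONYMS.get(name, f"S{index + 1}_")


@dataclass(frozen=True)
class AdmixedSample:
    """Marks one sample as an admixed outlier between two parent species."""

    sample_id: str
    parents: tuple[str, str]
    weight: float = 0.5  # probability a haplotype's contig derives from parents[0]


def _default_divergence() -> list[list[float]]:
    # One widespread outgroup-like species vs a cohesive trio: the trio is
    # much closer to each other than any of them is to species 1.
    return [
        [0.0, 0.006, 0.006, 0.006],
        [0.006, 0.0, 0.002, 0.0015],
        [0.006, 0.002, 0.0, 0.002],
        [0.006, 0.0015, 0.002, 0.0],
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic species complex.

    Defaults mirror the study system the package targets: four taxa sampled
    17 times (5+5+4+3), per-site diversity theta = 0.005, a skewed SFS giving
    mildly negative Tajima's D, and a divergence matrix in which the three
    complex members are mutually close but all distant from species 1.
    """

    n_contigs: int = 200
    contig_length_mean: int = 1000
    contig_length_min: int = 300
    species_names: tuple[str, ...] = (
        "P. sylvestris", "P. mugo", "P. uncinata", "P. uliginosa",
    )
    samples_per_species: tuple[int, ...] = (5, 5, 4, 3)
    theta_per_site: float | tuple[float, ...] = 0.005
    divergence_matrix: list[list[float]] = field(default_factory=_default_divergence)
    shared_poly_fraction: float = 0.3
    sfs_skew: float = 1.5
    admixed_sample: AdmixedSample | None = None
    seed: int = 0

    def thetas(self) -> list[float]:
        if isinstance(self.theta_per_site, (int, float)):
            return [float(self.theta_per_site)] * len(self.species_names)
        return [float(t) for t in self.theta_per_site]

    def validate(self) -> None:
        k = len(self.species_names)
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.contig_length_min < 1:
            raise ValueError("contig_length_min must be >= 1")
        if len(self.samples_per_species) != k:
            raise ValueError("samples_per_species must match species_names")
        if any(n < 1 for n in self.samples_per_species):
            raise ValueError("each species needs at least one sample")
        if any(t < 0 for t in self.thetas()) or len(self.thetas()) != k:
            raise ValueError("theta_per_site must be non-negative, one per species")
        dm = np.asarray(self.divergence_matrix, dtype=float)
        if dm.shape != (k, k):
            raise ValueError(f"divergence_matrix must be {k}x{k}")
        if (dm < 0).any() or not np.allclose(dm, dm.T) or np.any(np.diagonal(dm) != 0):
            raise ValueError(
                "divergence_matrix must be symmetric, non-negative, zero-diagonal"
            )
        if not 0.0 <= self.shared_poly_fraction <= 1.0:
            raise ValueError("shared_poly_fraction must be in [0, 1]")
        if self.sfs_skew <= 0:
            raise ValueError("sfs_skew must be positive")
        if self.admixed_sample is not None:
            for p in self.admixed_sample.parents:
                if p not in self.species_names:
                    raise ValueError(f"admixture parent {p!r} is not a species")
            if not 0.0 <= self.admixed_sample.weight <= 1.0:
                raise ValueError("admixture weight must be in [0, 1]")

    def sample_ids(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for idx, (sp, n) in enumerate(zip(self.species_names, self.samples_per_species)):
            acr = species_acronym(sp, idx)
            out[sp] = [f"{acr}{i + 1}" for i in range(n)]
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d["species_names"] = list(self.species_names)
        d["samples_per_species"] = list(self.samples_per_species)
        if isinstance(d["theta_per_site"], tuple):
            d["theta_per_site"] = list(d["theta_per_site"])
        if self.admixed_sample is not None:
            d["admixed_sample"]["parents"] = list(self.admixed_sample.parents)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if d.get("admixed_sample"):
            adm = dict(d["admixed_sample"])
            adm["parents"] = tuple(adm["parents"])
            d["admixed_sample"] = AdmixedSample(**adm)
        for key in ("species_names", "samples_per_species"):
            if key in d:
                d[key] = tuple(d[key])
        if isinstance(d.get("theta_per_site"), list):
            d["theta_per_site"] = tuple(d["theta_per_site"])
        return cls(**d)


def study_like_config(seed: int = 0, admixed: bool = True) -> SimulationConfig:
    """The 17-sample four-taxon configuration with the optional admixed
    outlier (third sample of species 3, mixing evenly with species 1)."""
    adm = AdmixedSample("UN3", ("P. uncinata", "P. sylvestris"), 0.5) if admixed else None
    return SimulationConfig(seed=seed, admixed_sample=adm)


def sample_sfs_count(n_chromosomes: int, sfs_skew: float, rng: np.random.Generator) -> int:
    """Draw a derived-allele count in [1, n-1] from P(i) proportional to
    1/i^skew (skew = 1: the neutral frequency spectrum)."""
    if n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    if sfs_skew <= 0:
        raise ValueError("sfs_skew must be positive")
    i = np.arange(1, n_chromosomes)
    w = i ** (-float(sfs_skew))
    return int(rng.choice(i, p=w / w.sum()))


@dataclass
class TruthTable:
    """Ground truth: one row per simulated variant site, plus per-species
    realized diversity (expected haplotype heterozygosity per site given the
    realized derived-allele counts)."""

    sites: pd.DataFrame
    realized_pi: dict[str, float]

    def write_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)


@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: ContigSet
    variant_sets: list[SampleVariantSet]
    consensus: dict[str, dict[str, str]]  # sample -> contig -> sequence
    truth: TruthTable

    @property
    def species_map(self) -> dict[str, str]:
        return {svs.sample_id: svs.species for svs in self.variant_sets}


@dataclass
class _Site:
    contig: str
    pos: int
    ref: str
    alt: str
    kind: str
    # for polymorphic sites: species -> set of derived chromosome indices
    derived_chroms: dict[str, set[int]] = field(default_factory=dict)
    # for fixed-difference sites: species fixed for the derived allele
    clade: frozenset = frozenset()


def _divergence_branches(
    names: Sequence[str], matrix: np.ndarray
) -> list[tuple[frozenset, float]]:
    """(clade, per-site rate) for every branch of the UPGMA fit of the
    divergence matrix; path lengths between leaves reproduce the matrix when
    it is ultrametric."""
    if len(names) == 1 or not matrix.any():
        return []
    tree = upgma_tree(matrix, list(names))
    branches: list[tuple[frozenset, float]] = []

    def walk(node) -> None:
        for child, bl in node.children:
            if bl > 0:
                branches.append((frozenset(child.leaves()), float(bl)))
            walk(child)

    walk(tree)
    return branches


def simulate_complex(config: SimulationConfig) -> SimulationResult:
    """Run the generator; identical config + seed gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = list(config.species_names)
    thetas = config.thetas()
    ids_by_species = config.sample_ids()
    n_chrom = {sp: 2 * n for sp, n in zip(species, config.samples_per_species)}

    # --- reference contigs -------------------------------------------------
    shape = 4.0  # gamma-distributed lengths: realistic right skew
    raw = rng.gamma(shape, config.contig_length_mean / shape, size=config.n_contigs)
    lengths = np.maximum(np.round(raw).astype(int), config.contig_length_min)
    width = len(str(config.n_contigs))
    contig_ids = [f"contig_{i + 1:0{width}d}" for i in range(config.n_contigs)]
    base_codes = {
        cid: rng.integers(0, 4, size=int(ln)) for cid, ln in zip(contig_ids, lengths)
    }
    reference = ContigSet(
        (cid, "".join(_BASES[b] for b in base_codes[cid])) for cid in contig_ids
    )
    total_len = int(lengths.sum())
    contig_weights = lengths / total_len

    # --- collision-free site placement ------------------------------------
    used: dict[str, set[int]] = {cid: set() for cid in contig_ids}

    def place_sites(n_sites: int) -> list[tuple[str, int]]:
        placed: list[tuple[str, int]] = []
        while len(placed) < n_sites:
            need = n_sites - len(placed)
            picks = rng.choice(config.n_contigs, size=need, p=contig_weights)
            for ci in picks:
                cid = contig_ids[ci]
                pos = int(rng.integers(1, len(reference[cid]) + 1))
                if pos in used[cid]:
                    continue  # collision: resample
                used[cid].add(pos)
                placed.append((cid, pos))
        return placed

    def draw_alt(ref_base: str) -> str:
        others = [b for b in _BASES if b != ref_base]
        return others[int(rng.integers(0, 3))]

    sites: list[_Site] = []

    # --- polymorphic sites -------------------------------------------------
    a1 = {sp: sum(1.0 / i for i in range(1, n_chrom[sp])) if n_chrom[sp] > 1 else 0.0
          for sp in species}
    targets = {
        sp: int(rng.binomial(total_len, min(1.0, thetas[k] * a1[sp])))
        if thetas[k] > 0 and n_chrom[sp] >= 2 else 0
        for k, sp in enumerate(species)
    }
    polymorphic_species = [sp for sp in species if targets[sp] > 0]
    if len(polymorphic_species) > 1 and config.shared_poly_fraction > 0:
        mean_t = float(np.mean([targets[sp] for sp in polymorphic_species]))
        n_shared = min(
            int(round(config.shared_poly_fraction * mean_t)),
            min(targets[sp] for sp in polymorphic_species),
        )
    else:
        n_shared = 0

    for cid, pos in place_sites(n_shared):
        ref_base = reference[cid][pos - 1]
        site = _Site(cid, pos, ref_base, draw_alt(ref_base), SHARED_POLY)
        for sp in polymorphic_species:
            count = sample_sfs_count(n_chrom[sp], config.sfs_skew, rng)
            chroms = rng.choice(n_chrom[sp], size=count, replace=False)
            site.derived_chroms[sp] = set(int(c) for c in chroms)
        sites.append(site)

    for sp in species:
        n_specific = targets[sp] - (n_shared if sp in polymorphic_species else 0)
        for cid, pos in place_sites(n_specific):
            ref_base = reference[cid][pos - 1]
            site = _Site(cid, pos, ref_base, draw_alt(ref_base), SPECIES_POLY)
            count = sample_sfs_count(n_chrom[sp], config.sfs_skew, rng)
            chroms = rng.choice(n_chrom[sp], size=count, replace=False)
            site.derived_chroms[sp] = set(int(c) for c in chroms)
            sites.append(site)

    # --- fixed differences between species ---------------------------------
    dm = np.asarray(config.divergence_matrix, dtype=float)
    for clade, rate in _divergence_branches(species, dm):
        n_fixed = int(rng.binomial(total_len, min(1.0, rate)))
        for cid, pos in place_sites(n_fixed):
            ref_base = reference[cid][pos - 1]
            sites.append(
                _Site(cid, pos, ref_base, draw_alt(ref_base), FIXED_DIFF, clade=clade)
            )

    # --- per-sample genotypes ----------------------------------------------
    # chromosome 2k and 2k+1 of a species belong to its k-th sample
    genotypes: dict[str, dict[VariantKey, str]] = {
        sid: {} for ids in ids_by_species.values() for sid in ids
    }

    def set_genotype(sid: str, site: _Site, dose: int) -> None:
        if dose == 0:
            return
        key = VariantKey(site.contig, site.pos, site.ref, site.alt)
        genotypes[sid][key] = HOM_ALT if dose == 2 else HET

    for site in sites:
        if site.kind == FIXED_DIFF:
            for sp in site.clade:
                for sid in ids_by_species[sp]:
                    set_genotype(sid, site, 2)
        else:
            for sp, chroms in site.derived_chroms.items():
                for k, sid in enumerate(ids_by_species[sp]):
                    dose = (2 * k in chroms) + (2 * k + 1 in chroms)
                    set_genotype(sid, site, int(dose))

    # --- admixed outlier ----------------------------------------------------
    if config.admixed_sample is not None:
        adm = config.admixed_sample
        all_ids = {sid for ids in ids_by_species.values() for sid in ids}
        if adm.sample_id not in all_ids:
            raise ValueError(f"admixed sample {adm.sample_id!r} does not exist")
        sites_by_contig: dict[str, list[_Site]] = {}
        for site in sites:
            sites_by_contig.setdefault(site.contig, []).append(site)
        genotypes[adm.sample_id] = {}
        for cid in contig_ids:
            origins = [
                adm.parents[0] if rng.random() < adm.weight else adm.parents[1]
                for _ in range(2)
            ]
            for site in sites_by_contig.get(cid, ()):
                dose = 0
                for origin in origins:
                    if site.kind == FIXED_DIFF:
                        dose += origin in site.clade
                    elif origin in site.derived_chroms:
                        freq = len(site.derived_chroms[origin]) / n_chrom[origin]
                        dose += rng.random() < freq
                set_genotype(adm.sample_id, site, dose)

    # --- outputs -------------------------------------------------------------
    variant_sets = []
    consensus: dict[str, dict[str, str]] = {}
    for sp in species:
        for sid in ids_by_species[sp]:
            svs = SampleVariantSet(sample_id=sid, species=sp, genotypes=genotypes[sid])
            variant_sets.append(svs)
            per_contig: dict[str, list] = {}
            for key, gt in svs.genotypes.items():
                per_contig.setdefault(key.contig, []).append((key, gt))
            consensus[sid] = {
                cid: build_consensus(
                    reference[cid], per_contig.get(cid, ()), "iupac", contig_id=cid
                )
                for cid in contig_ids
            }

    truth = _build_truth(sites, species, n_chrom, total_len, contig_ids)
    return SimulationResult(config, reference, variant_sets, consensus, truth)


def _build_truth(
    sites: list[_Site],
    species: Sequence[str],
    n_chrom: Mapping[str, int],
    total_len: int,
    contig_order: Sequence[str],
) -> TruthTable:
    rank = {cid: i for i, cid in enumerate(contig_order)}
    rows = []
    het_sum = {sp: 0.0 for sp in species}
    for site in sorted(sites, key=lambda s: (rank[s.contig], s.pos)):
        if site.kind == FIXED_DIFF:
            involved = sorted(site.clade, key=list(species).index)
            counts = {sp: n_chrom[sp] for sp in involved}
        else:
            involved = [sp for sp in species if sp in site.derived_chroms]
            counts = {sp: len(site.derived_chroms[sp]) for sp in involved}
            for sp in involved:
                i, n = counts[sp], n_chrom[sp]
                if n > 1:
                    het_sum[sp] += 2.0 * i * (n - i) / (n * (n - 1))
        rows.append(
            {
                "contig": site.contig,
                "pos": site.pos,
                "ref": site.ref,
                "alt": site.alt,
                "kind": site.kind,
                "species": ";".join(involved),
                "derived_counts": ";".join(f"{sp}={counts[sp]}" for sp in involved),
            }
        )
    columns = ["contig", "pos", "ref", "alt", "kind", "species", "derived_counts"]
    frame = pd.DataFrame(rows, columns=columns)
    realized = {sp: het_sum[sp] / total_len for sp in species}
    return TruthTable(sites=frame, realized_pi=realized)


def write_outputs(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write reference FASTA, per-sample VCFs, truth TSV, the sample->species
    panel and a config echo.  Output bytes depend only on (config, seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ref_path = out / "reference.fasta"
    result.reference.to_fasta(ref_path)
    paths["reference"] = ref_path
    contig_lengths = result.reference.lengths()
    for svs in result.variant_sets:
        p = out / f"{svs.sample_id}_SNPs.vcf"
        write_sample_vcf(svs, p, contig_lengths, result.reference.ids)
        paths[svs.sample_id] = p
    truth_path = out / "truth.tsv"
    result.truth.write_tsv(truth_path)
    paths["truth"] = truth_path
    panel_path = out / "samples.tsv"
    with open(panel_path, "w") as fh:
        fh.write("sample\tspecies\n")
        for svs in result.variant_sets:
            fh.write(f"{svs.sample_id}\t{svs.species}\n")
    paths["samples"] = panel_path
    cfg_path = out / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
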