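"""Config-driven end-to-end orchestration of all analysis stages.

One config (YAML or constructed in Python) drives: input acquisition (either
on-disk reference FASTA + per-sample VCFs + sample panel, or the synthetic
generator), optional contig retention filters, assembly statistics, per-species
SNP unions and the shared/unique table, the spacing-filtered SNP panel, the
merged consensus alignment, diversity statistics, and the relationship /
differentiation analyses (PCoA, UPGMA, pairwise Fst).

Every filtering stage logs its in/out counts.  The run log carries no
timestamps, so identical config + seed produces byte-identical output files.
"""

from __future__ import annotations

import glob as globmod
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import alignment as aln
from . import assembly, diversity, panel, simulate, structure

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("pinepop.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Pipeline inputs and knobs.  Exactly one of (reference_fasta + vcf_glob
    + samples_tsv) or ``simulation`` must be provided."""

    reference_fasta: str | None = None
    vcf_glob: str | None = None
    samples_tsv: str | None = None
    simulation: simulate.SimulationConfig | None = None
    min_gap: int = 50
    het_policy: str = "iupac"
    diversity_ambiguity: str = "expand"
    min_orf_aa: int | None = None
    require_orf_start: bool = True
    exclude_contig_ids: str | None = None  # path to one-id-per-line list
    exclude_samples: list[str] = field(default_factory=list)
    n_permutations: int = 1000
    seed: int = 0
    out_dir: str = "pinepop_out"

    def validate(self) -> None:
        has_paths = self.reference_fasta is not None
        if has_paths == (self.simulation is not None):
            raise ValueError(
                "exactly one of file inputs (reference_fasta/vcf_glob/samples_tsv) "
                "or a simulation block must be given"
            )
        if has_paths:
            for name in ("reference_fasta", "vcf_glob", "samples_tsv"):
                if getattr(self, name) is None:
                    raise ValueError(f"{name} is required with file inputs")
            for p in (self.reference_fasta, self.samples_tsv):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.exclude_contig_ids is not None and not Path(self.exclude_contig_ids).exists():
            raise FileNotFoundError(self.exclude_contig_ids)
        if self.min_gap < 0 or self.n_permutations < 1:
            raise ValueError("min_gap must be >= 0 and n_permutations >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("simulation"):
            raw["simulation"] = simulate.SimulationConfig.from_dict(raw["simulation"])
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed and wrote."""

    config: PipelineConfig
    reference: assembly.ContigSet
    variant_sets: list[panel.SampleVariantSet]
    species_map: dict[str, str]
    species_order: list[str]
    stats: assembly.TranscriptomeStats
    shared_unique: panel.SharedUniqueTable
    filtered_panel: set[panel.VariantKey]
    merged: aln.MergedAlignment
    diversity_table: pd.DataFrame
    pcoa: structure.PCoAResult
    tree: structure.TreeNode
    fst: structure.FstResult
    paths: dict[str, Path]
    truth: simulate.TruthTable | None = None


def _load_inputs(
    config: PipelineConfig, out: Path
) -> tuple[assembly.ContigSet, list[panel.SampleVariantSet], dict[str, str], list[str],
           simulate.TruthTable | None]:
    if config.simulation is not None:
        result = simulate.simulate_complex(config.simulation)
        simulate.write_outputs(result, out / "simulated")
        species_map = result.species_map
        order = list(config.simulation.species_names)
        logger.info(
            "simulated %d contigs, %d samples, %d truth sites",
            len(result.reference), len(result.variant_sets), len(result.truth.sites),
        )
        return result.reference, result.variant_sets, species_map, order, result.truth
    reference = assembly.ContigSet.from_fasta(config.reference_fasta)
    table = pd.read_csv(config.samples_tsv, sep="\t")
    species_map = dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
    order = list(dict.fromkeys(species_map.values()))
    vcf_paths = sorted(globmod.glob(config.vcf_glob))
    if not vcf_paths:
        raise FileNotFoundError(f"no VCFs match {config.vcf_glob!r}")
    sets = []
    for p in vcf_paths:
        svs = panel.read_sample_vcf(p, reference=reference)
        if svs.sample_id not in species_map:
            raise ValueError(f"sample {svs.sample_id!r} missing from {config.samples_tsv}")
        svs.species = species_map[svs.sample_id]
        sets.append(svs)
    logger.info("loaded %d contigs and %d sample VCFs", len(reference), len(sets))
    return reference, sets, species_map, order, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write the full output bundle to config.out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("pinepop")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    paths: dict[str, Path] = {"log": log_path}
    try:
        return _run(config, out, paths)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    return wrap


def _run(config: PipelineConfig, out: Path, paths: dict[str, Path]) -> PipelineResult:
    reference, sets, species_map, species_order, truth = _stage("inputs")(
        _load_inputs, config, out
    )

    # optional contig retention filters (ORF presence, exclusion-id list)
    if config.min_orf_aa is not None or config.exclude_contig_ids is not None:
        exclude_ids: list[str] = []
        if config.exclude_contig_ids is not None:
            exclude_ids = [
                line.strip()
                for line in Path(config.exclude_contig_ids).read_text().splitlines()
                if line.strip()
            ]
        n_before = len(reference)
        reference = _stage("contig_filter")(
            assembly.filter_contigs,
            reference,
            config.min_orf_aa if config.min_orf_aa is not None else 1,
            exclude_ids,
            require_start=config.require_orf_start,
        )
        logger.info("contig filter: %d -> %d contigs", n_before, len(reference))
        kept = set(reference.ids)
        for svs in sets:
            dropped = [k for k in svs.genotypes if k.contig not in kept]
            for k in dropped:
                del svs.genotypes[k]
            if dropped:
                logger.info("%s: dropped %d variants on filtered contigs",
                            svs.sample_id, len(dropped))

    stats = _stage("assembly_stats")(assembly.compute_assembly_stats, reference)
    assembly.write_stats_tsv(stats, out / "assembly_stats.tsv")
    paths["assembly_stats"] = out / "assembly_stats.tsv"

    species_sets = _stage("species_union")(panel.species_union_snps, sets, species_map)
    species_sets = {sp: species_sets[sp] for sp in species_order if sp in species_sets}
    totals_path = out / "species_snp_totals.tsv"
    with open(totals_path, "w") as fh:
        fh.write("species\tn_snps\n")
        for sp in species_sets:
            fh.write(f"{sp}\t{len(species_sets[sp])}\n")
    paths["species_snp_totals"] = totals_path

    shared = _stage("shared_unique")(panel.pairwise_shared_unique, species_sets)
    shared.to_frame().to_csv(out / "shared_unique.tsv", sep="\t", index=False)
    paths["shared_unique"] = out / "shared_unique.tsv"

    merged_panel: set[panel.VariantKey] = set()
    for s in species_sets.values():
        merged_panel |= s
    filtered = _stage("spacing_filter")(panel.spacing_filter, merged_panel, config.min_gap)
    logger.info(
        "spacing filter (min_gap=%d): %d -> %d SNPs",
        config.min_gap, len(merged_panel), len(filtered),
    )
    contig_lengths = reference.lengths()
    panel.write_panel_vcf(filtered, out / "panel_filtered.vcf", contig_lengths)
    panel.write_panel_tsv(filtered, species_sets, out / "panel_filtered.tsv")
    paths["panel_vcf"] = out / "panel_filtered.vcf"
    paths["panel_tsv"] = out / "panel_filtered.tsv"

    contig_ids = _stage("contig_selection")(
        aln.select_common_polymorphic_contigs, sets, reference.ids
    )
    logger.info(
        "selected %d contigs common to and polymorphic in all %d samples",
        len(contig_ids), len(sets),
    )
    if not contig_ids:
        # degenerate but legal (e.g. a zero-variation simulation): keep the
        # pipeline total, align everything
        logger.info("no common polymorphic contigs; aligning all contigs")
        contig_ids = reference.ids
    merged = _stage("merged_alignment")(
        aln.build_merged_alignment, reference, sets, contig_ids, config.het_policy
    )
    merged.to_fasta(out / "merged_alignment.fasta")
    merged.write_offsets_tsv(out / "contig_offsets.tsv")
    paths["merged_alignment"] = out / "merged_alignment.fasta"
    paths["contig_offsets"] = out / "contig_offsets.tsv"
    logger.info("merged alignment: %d samples x %d bp over %d contigs",
                len(merged.sample_ids), merged.total_length, len(contig_ids))

    div = _stage("diversity")(
        diversity.diversity_table, merged, species_map, species_order,
        config.diversity_ambiguity,
    )
    div.to_csv(out / "diversity.tsv", sep="\t", index=False, float_format="%.6g")
    paths["diversity"] = out / "diversity.tsv"

    pdm = _stage("pcoa")(diversity.pairwise_difference_matrix, merged,
                         config.diversity_ambiguity)
    ord_res = _stage("pcoa")(structure.pcoa, pdm.counts, merged.sample_ids)
    ord_res.write_tsv(out / "pcoa.tsv")
    paths["pcoa"] = out / "pcoa.tsv"

    excluded = [s for s in config.exclude_samples if s in merged.sample_ids]
    if excluded:
        logger.info("excluding samples from divergence analyses: %s", excluded)
    group_d = _stage("upgma")(
        structure.mean_group_tn93, merged, species_map, excluded, species_order
    )
    tree = _stage("upgma")(structure.upgma_tree, group_d)
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    paths["tree"] = out / "tree.nwk"

    fst = _stage("fst")(
        structure.pairwise_fst, merged, species_map, excluded,
        config.n_permutations, config.seed, species_order,
    )
    fst.write_tsv(out / "fst.tsv")
    paths["fst"] = out / "fst.tsv"
    logger.info("fst over %d biallelic segregating sites, %d permutations",
                fst.n_sites, config.n_permutations)

    return PipelineResult(
        config=config,
        reference=reference,
        variant_sets=sets,
        species_map=species_map,
        species_order=species_order,
        stats=stats,
        shared_unique=shared,
        filtered_panel=filtered,
        merged=merged,
        diversity_table=div,
        pcoa=ord_res,
        tree=tree,
        fst=fst,
        paths=paths,
        truth=truth,
    )
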