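"""The synthetic species-complex generator and its ground truth."""

import math

import numpy as np
import pytest

from pinepop.alignment import build_consensus, build_merged_alignment
from pinepop.diversity import diversity_stats
from pinepop.panel import VariantKey, pairwise_shared_unique, species_union_snps
from pinepop.simulate import (
    AdmixedSample,
    SimulationConfig,
    sample_sfs_count,
    simulate_complex,
    study_like_config,
    write_outputs,
)


class TestSfsSampler:
    def test_two_chromosomes_only_one_class(self):
        rng = np.random.default_rng(0)
        assert all(sample_sfs_count(2, s, rng) == 1 for s in (0.5, 1.0, 3.0))

    def test_invalid_arguments(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_sfs_count(1, 1.0, rng)
        with pytest.raises(ValueError):
            sample_sfs_count(10, 0.0, rng)

    def test_neutral_singleton_probability(self):
        """For n=10, skew=1, P(count=1) = (1/1)/H_9 with H_9 the 9th harmonic
        number; the empirical rate over 1e5 draws must sit within 3 SE."""
        rng = np.random.default_rng(123)
        n_draws = 100_000
        draws = np.array([sample_sfs_count(10, 1.0, rng) for _ in range(n_draws)])
        assert draws.min() >= 1 and draws.max() <= 9
        h9 = sum(1 / j for j in range(1, 10))
        p_expected = 1 / h9
        se = math.sqrt(p_expected * (1 - p_expected) / n_draws)
        assert abs(np.mean(draws == 1) - p_expected) < 3 * se

    def test_mass_concentrates_with_skew(self):
        rng = np.random.default_rng(5)
        p1 = {}
        for skew in (1.0, 3.0, 8.0):
            draws = [sample_sfs_count(10, skew, rng) for _ in range(20_000)]
            p1[skew] = np.mean(np.array(draws) == 1)
        assert p1[1.0] < p1[3.0] < p1[8.0]
        assert p1[8.0] > 0.99


class TestConfigValidation:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            SimulationConfig(contig_length_min=0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(samples_per_species=(5, 5)).validate()
        with pytest.raises(ValueError):
            SimulationConfig(shared_poly_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(
                admixed_sample=AdmixedSample("PS1", ("P. sylvestris", "nope"))
            ).validate()

    def test_config_dict_round_trip(self):
        cfg = study_like_config(seed=9)
        assert SimulationConfig.from_dict(cfg.to_dict()) == cfg


class TestNullModel:
    def test_zero_rates_produce_no_variants(self):
        cfg = SimulationConfig(
            n_contigs=10, contig_length_mean=300, contig_length_min=100,
            theta_per_site=0.0,
            divergence_matrix=[[0.0] * 4 for _ in range(4)],
            samples_per_species=(2, 2, 2, 2), admixed_sample=None, seed=1,
        )
        res = simulate_complex(cfg)
        assert all(len(s) == 0 for s in res.variant_sets)
        assert len(res.truth.sites) == 0
        for per_contig in res.consensus.values():
            assert all(per_contig[c] == res.reference[c] for c in res.reference.ids)


class TestDeterminism:
    def test_identical_seed_identical_bytes(self, tmp_path):
        cfg = SimulationConfig(
            n_contigs=15, contig_length_mean=400, contig_length_min=150,
            samples_per_species=(2, 2, 2, 2), seed=77,
            admixed_sample=AdmixedSample("M1", ("P. mugo", "P. sylvestris"), 0.5),
        )
        dirs = []
        for name in ("a", "b"):
            out = tmp_path / name
            write_outputs(simulate_complex(cfg), out)
            dirs.append(out)
        files_a = sorted(p.name for p in dirs[0].iterdir())
        files_b = sorted(p.name for p in dirs[1].iterdir())
        assert files_a == files_b
        for name in files_a:
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_different_seed_differs(self):
        base = dict(n_contigs=10, contig_length_mean=300, contig_length_min=100,
                    samples_per_species=(2, 2, 2, 2), admixed_sample=None)
        r1 = simulate_complex(SimulationConfig(seed=1, **base))
        r2 = simulate_complex(SimulationConfig(seed=2, **base))
        assert not r1.truth.sites.equals(r2.truth.sites)


class TestWattersonCalibration:
    def test_segregating_sites_match_theta(self):
        """One species, 10 diploid samples: S/(L*a1) with a1 over 19
        chromosome classes recovers theta within 3 binomial SE."""
        theta = 0.005
        cfg = SimulationConfig(
            n_contigs=50, contig_length_mean=1000, contig_length_min=1000,
            species_names=("sp1",), samples_per_species=(10,),
            theta_per_site=theta, divergence_matrix=[[0.0]],
            shared_poly_fraction=0.0, sfs_skew=1.0, admixed_sample=None, seed=21,
        )
        res = simulate_complex(cfg)
        L = sum(len(res.reference[c]) for c in res.reference.ids)
        a1 = sum(1 / i for i in range(1, 20))
        S = len(res.truth.sites)
        p = theta * a1
        sd = math.sqrt(L * p * (1 - p))
        assert abs(S - L * p) < 3 * sd


class TestTruthAndStructure:
    def test_every_vcf_variant_has_one_truth_row(self, small_result):
        truth_keys = {
            VariantKey(r.contig, r.pos, r.ref, r.alt)
            for r in small_result.truth.sites.itertuples()
        }
        assert len(truth_keys) == len(small_result.truth.sites)  # no duplicates
        for svs in small_result.variant_sets:
            assert set(svs.genotypes) <= truth_keys

    def test_consensus_round_trip_via_build_consensus(self, small_result):
        res = small_result
        for svs in res.variant_sets:
            per_contig = {}
            for key, gt in svs.genotypes.items():
                per_contig.setdefault(key.contig, []).append((key, gt))
            for cid in res.reference.ids:
                rebuilt = build_consensus(
                    res.reference[cid], per_contig.get(cid, ()), "iupac", contig_id=cid
                )
                assert rebuilt == res.consensus[svs.sample_id][cid]

    def test_species_totals_track_truth(self, small_result):
        """Per-species SNP-union totals equal the truth-table site counts for
        that species: every site polymorphic in or fixed for a species is
        carried by at least one of its samples."""
        res = small_result
        unions = species_union_snps(res.variant_sets)
        for sp, keys in unions.items():
            involved = res.truth.sites["species"].str.split(";").apply(lambda s: sp in s)
            assert len(keys) == int(involved.sum())

    def test_complex_cohesion_in_shared_snps(self, study_result):
        """The three complex taxa share more SNPs with each other than any of
        them shares with the reference-side species.  The admixed outlier is
        excluded: its outgroup-derived alleles would otherwise leak into its
        species' union, which is the very behaviour the outlier models."""
        adm = study_result.config.admixed_sample.sample_id
        unions = species_union_snps(
            [s for s in study_result.variant_sets if s.sample_id != adm]
        )
        table = pairwise_shared_unique(unions)
        trio = list(study_result.config.species_names[1:])
        outgroup = study_result.config.species_names[0]
        import itertools

        within = min(table.common[(a, b)] for a, b in itertools.combinations(trio, 2))
        versus = max(table.common[(outgroup, t)] for t in trio)
        assert within > versus

    def test_admixed_sample_shares_more_with_second_parent(self, study_result):
        """The admixed outlier carries more of the outgroup's SNPs than its
        non-admixed conspecifics do."""
        res = study_result
        adm = res.config.admixed_sample
        unions = species_union_snps(res.variant_sets)
        outgroup_keys = unions[adm.parents[1]]
        overlap = {}
        for svs in res.variant_sets:
            if svs.species == adm.parents[0]:
                overlap[svs.sample_id] = len(svs.keys & outgroup_keys)
        others = [v for k, v in overlap.items() if k != adm.sample_id]
        assert overlap[adm.sample_id] > max(others)

    def test_negative_tajimas_d_with_skewed_sfs(self):
        """With sfs_skew > 1 the downstream Tajima's D is negative on average
        over 20 replicate seeds (sign recovery)."""
        ds = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_contigs=20, contig_length_mean=600, contig_length_min=300,
                species_names=("sp1",), samples_per_species=(6,),
                theta_per_site=0.005, divergence_matrix=[[0.0]],
                shared_poly_fraction=0.0, sfs_skew=1.8, admixed_sample=None,
                seed=500 + seed,
            )
            res = simulate_complex(cfg)
            m = build_merged_alignment(res.reference, res.variant_sets,
                                       res.reference.ids)
            ds.append(diversity_stats(m, ambiguity="expand").D)
        assert np.mean(ds) < 0
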