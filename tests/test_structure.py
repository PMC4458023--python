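"""TN93 distances, UPGMA, PCoA and permutation-tested pairwise Fst."""

import io
import itertools
import math

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from pinepop.alignment import MergedAlignment, build_merged_alignment
from pinepop.simulate import SimulationConfig, simulate_complex
from pinepop.structure import (
    pairwise_fst,
    pcoa,
    tn93_distance,
    upgma_tree,
    wc_fst_two_pops,
)


def _oracle_tn93(freqs, P1, P2, Q):
    """Direct, independent evaluation of the TN93 closed form."""
    piA, piC, piG, piT = freqs
    piR, piY = piA + piG, piC + piT
    t1 = -(2 * piA * piG / piR) * math.log(
        1 - piR * P1 / (2 * piA * piG) - Q / (2 * piR)
    )
    t2 = -(2 * piC * piT / piY) * math.log(
        1 - piY * P2 / (2 * piC * piT) - Q / (2 * piY)
    )
    t3 = -2 * (piR * piY - piA * piG * piY / piR - piC * piT * piR / piY) * math.log(
        1 - Q / (2 * piR * piY)
    )
    return t1 + t2 + t3


def _mutated(base, swaps):
    """Apply compensating substitution pairs so pooled frequencies stay equal."""
    a = list(base)
    for pos, new in swaps:
        a[pos] = new
    return "".join(a)


class TestTN93:
    def test_identical_sequences(self):
        comp = tn93_distance("ACGT" * 25, "ACGT" * 25)
        assert comp.defined and comp.d == 0.0
        assert comp.P1 == comp.P2 == comp.Q == 0.0

    def test_constructed_counts_match_oracle(self):
        # L=200, balanced composition; 6 A<->G, 6 C<->T, 8 transversion sites,
        # arranged in compensating pairs so pooled base frequencies stay 1/4
        base = "ACGT" * 50
        a_pos = [4 * i for i in range(12)]       # 'A' positions
        g_pos = [4 * i + 2 for i in range(12)]   # 'G'
        c_pos = [4 * i + 1 for i in range(12)]   # 'C'
        t_pos = [4 * i + 3 for i in range(12)]   # 'T'
        swaps = (
            [(p, "G") for p in a_pos[:3]] + [(p, "A") for p in g_pos[:3]]       # A<->G
            + [(p, "T") for p in c_pos[:3]] + [(p, "C") for p in t_pos[:3]]     # C<->T
            + [(p, "T") for p in a_pos[3:5]] + [(p, "A") for p in t_pos[3:5]]   # transv.
            + [(p, "G") for p in c_pos[3:5]] + [(p, "C") for p in g_pos[3:5]]
        )
        seq_b = _mutated(base, swaps)
        comp = tn93_distance(base, seq_b)
        assert comp.n_sites == 200
        assert (comp.P1, comp.P2, comp.Q) == (6 / 200, 6 / 200, 8 / 200)
        assert comp.freqs == pytest.approx((0.25, 0.25, 0.25, 0.25), abs=1e-12)
        assert comp.d == pytest.approx(_oracle_tn93(comp.freqs, *(6 / 200, 6 / 200, 8 / 200)), abs=1e-12)

    def test_jukes_cantor_reduction(self):
        # equal frequencies and substitutions in JC proportions (P1=P2=p/6,
        # Q=2p/3) must reduce to -(3/4) ln(1 - 4p/3)
        base = "ACGT" * 12  # L=48
        a_pos = [4 * i for i in range(12)]
        c_pos = [4 * i + 1 for i in range(12)]
        g_pos = [4 * i + 2 for i in range(12)]
        t_pos = [4 * i + 3 for i in range(12)]
        swaps = (
            [(a_pos[0], "G"), (g_pos[0], "A")]            # 2 A<->G
            + [(c_pos[0], "T"), (t_pos[0], "C")]          # 2 C<->T
            + [(a_pos[1], "T"), (a_pos[2], "T")]          # 8 transversions
            + [(t_pos[1], "A"), (t_pos[2], "A")]
            + [(c_pos[1], "G"), (c_pos[2], "G")]
            + [(g_pos[1], "C"), (g_pos[2], "C")]
        )
        comp = tn93_distance(base, _mutated(base, swaps))
        p = 12 / 48
        assert comp.d == pytest.approx(-0.75 * math.log(1 - 4 * p / 3), abs=1e-9)

    def test_saturation_is_flagged_not_raised(self):
        # every purine/pyrimidine pairing flipped: Q=1 drives a log argument <= 0
        comp = tn93_distance("AG" * 50, "CT" * 50)
        assert not comp.defined and math.isnan(comp.d)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tn93_distance("ACGT", "ACG")

    def test_ambiguous_sites_are_skipped(self):
        comp = tn93_distance("ACGTN", "ACGTA")
        assert comp.n_sites == 4 and comp.d == 0.0


def _cophenetic_from_tree(tree, labels):
    """2 x merge height for every leaf pair, read off the tree structure."""
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros((n, n))

    def walk(node):
        if node.is_leaf:
            return
        sub = [child.leaves() for child, _ in node.children]
        for la, lb in itertools.combinations(range(len(sub)), 2):
            for x in sub[la]:
                for y in sub[lb]:
                    out[idx[x], idx[y]] = out[idx[y], idx[x]] = 2 * node.height
        for child, _ in node.children:
            walk(child)

    walk(tree)
    return out


class TestUPGMA:
    def test_hand_agglomeration(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma_tree(d, ["A", "B", "C"])
        assert tree.to_newick() == "((A:1,B:1):1,C:2);"

    def test_two_groups_half_distance(self):
        tree = upgma_tree(np.array([[0.0, 3.0], [3.0, 0.0]]), ["x", "y"])
        assert tree.leaf_depths() == {"x": 1.5, "y": 1.5}

    def test_all_equal_distances_tie_invariance(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        for labels in itertools.permutations("WXYZ"):
            tree = upgma_tree(d, list(labels))
            depths = tree.leaf_depths()
            assert set(depths) == set("WXYZ")
            assert all(v == pytest.approx(1.0) for v in depths.values())

    def test_non_symmetric_raises(self):
        with pytest.raises(ValueError):
            upgma_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])

    def test_ultrametric_and_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            pts = rng.normal(size=(n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"g{i}" for i in range(n)]
            tree = upgma_tree(d, labels)
            depths = list(tree.leaf_depths().values())
            assert max(depths) - min(depths) < 1e-9  # ultrametric
            got = _cophenetic_from_tree(tree, labels)
            expected = squareform(cophenet(linkage(squareform(d), "average")))
            assert np.allclose(got, expected, atol=1e-9)

    def test_newick_round_trips(self):
        from Bio import Phylo

        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma_tree(d, ["A", "B", "C"])
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["A", "B", "C"]
        assert parsed.distance("A", "C") == pytest.approx(4.0)


class TestPCoA:
    def test_two_points(self):
        res = pcoa(np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert res.eigenvalues[0] == pytest.approx(2.0)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.0, 1.0])

    def test_three_collinear_points(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(d)
        assert sorted(res.coordinates[:, 0]) == pytest.approx([-1.0, 0.0, 1.0])
        assert res.coordinates.shape[1] == 1  # second axis carries nothing

    def test_euclidean_exactness(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(9, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = pcoa(d)
        rec = res.coordinates
        d2 = np.sqrt(((rec[:, None] - rec[None]) ** 2).sum(-1))
        assert np.allclose(d, d2, atol=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # sorted descending

    def test_matches_skbio_eigenvalues(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(11)
        pts = rng.normal(size=(7, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = pcoa(d)
        theirs = skbio_pcoa(DistanceMatrix(d))
        k = ours.coordinates.shape[1]
        assert np.allclose(
            ours.eigenvalues[:k], np.asarray(theirs.eigvals)[:k], atol=1e-8
        )

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            pcoa(np.zeros((1, 1)))


def _one_site_alignment(spec_a, spec_b, ref="A", alt="C", het="M", pad=20):
    """Alignment with one variant column; spec_* are per-sample genotype codes
    'r' (hom ref), 'h' (het) or 'a' (hom alt)."""
    code = {"r": ref, "h": het, "a": alt}
    ids, seqs, species = [], [], {}
    for sp, spec in (("A", spec_a), ("B", spec_b)):
        for i, g in enumerate(spec):
            sid = f"{sp}{i}"
            ids.append(sid)
            seqs.append(code[g] + "G" * pad)
            species[sid] = sp
    L = pad + 1
    return MergedAlignment(ids, seqs, {"c1": (0, L)}), species


def _oracle_wc_one_site(alt1, n1, alt2, n2):
    """Hand evaluation of the two-population Weir-Cockerham components."""
    p1, p2 = alt1 / n1, alt2 / n2
    n_bar = (n1 + n2) / 2
    n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2))
    p_bar = (alt1 + alt2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
    inner = p_bar * (1 - p_bar) - s2 / 2
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
    b = (n_bar / (n_bar - 1)) * inner
    return a / (a + b)


class TestPairwiseFst:
    def test_identical_composition_no_differentiation(self):
        aln, species = _one_site_alignment("hhrrr", "hhrrr")
        res = pairwise_fst(aln, species, n_permutations=99, seed=0)
        assert res.fst.loc["A", "B"] < 0.05
        assert res.p_values.loc["A", "B"] > 0.5

    def test_fixed_differences_give_one(self):
        aln = MergedAlignment(
            ["a1", "a2", "b1", "b2"],
            ["AAAA" + "G" * 10, "AAAA" + "G" * 10, "TTTT" + "G" * 10, "TTTT" + "G" * 10],
            {"c1": (0, 14)},
        )
        species = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        res = pairwise_fst(aln, species, n_permutations=19, seed=1)
        assert res.fst.loc["A", "B"] == pytest.approx(1.0)

    def test_single_site_matches_hand_oracle(self):
        # species A: 2 alt alleles of 10; species B: 8 alt of 10
        aln, species = _one_site_alignment("hhrrr", "aaaar")
        res = pairwise_fst(aln, species, n_permutations=19, seed=0)
        assert res.fst.loc["A", "B"] == pytest.approx(
            _oracle_wc_one_site(2, 10, 8, 10), abs=1e-12
        )
        assert wc_fst_two_pops([2], [10], [8], [10]) == pytest.approx(
            _oracle_wc_one_site(2, 10, 8, 10), abs=1e-12
        )

    def test_permutation_p_never_zero(self):
        aln, species = _one_site_alignment("aaaar", "rrrrr")
        for seed in range(3):
            res = pairwise_fst(aln, species, n_permutations=200, seed=seed)
            assert res.p_values.loc["A", "B"] >= 1 / 201

    def test_species_with_one_sample_raises(self):
        aln, species = _one_site_alignment("hhrrr", "hhrrr")
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_fst(aln, species, exclude=["B0", "B1", "B2", "B3"])

    def test_fst_ordering_follows_configured_divergence(self):
        """Across 20 seeded replicates, within-trio Fst stays below
        trio-vs-outgroup Fst in at least 95% of runs."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_contigs=30, contig_length_mean=500, contig_length_min=200,
                samples_per_species=(3, 3, 3, 3), admixed_sample=None,
                seed=300 + seed,
            )
            res = simulate_complex(cfg)
            m = build_merged_alignment(res.reference, res.variant_sets,
                                       res.reference.ids)
            fst = pairwise_fst(m, res.species_map, n_permutations=5,
                               seed=seed).fst
            trio = list(cfg.species_names[1:])
            within = max(fst.loc[a, b] for a, b in itertools.combinations(trio, 2))
            versus = min(fst.loc[cfg.species_names[0], t] for t in trio)
            hits += within < versus
        assert hits >= 19
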