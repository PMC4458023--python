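"""Genetic relationships and differentiation between samples and species.

Four analyses on a merged alignment (or matrices derived from it):

* Tamura–Nei (TN93) pairwise distances — substitutions per site allowing
  unequal base frequencies and distinct purine/pyrimidine transition rates;
* UPGMA (average linkage) clustering of a group-level distance matrix into an
  ultrametric tree with newick output;
* principal coordinates analysis (classical metric MDS via the Gower
  double-centering transform) of the sample pairwise-difference matrix;
* pairwise Fst between species (Weir–Cockerham ratio of sums over segregating
  sites, each diploid contributing two alleles) with a permutation test that
  shuffles whole samples between the two species being compared.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import MergedAlignment
from .diversity import _CODE_ALLELES, encode_alignment

__all__ = [
    "TN93Components",
    "TreeNode",
    "PCoAResult",
    "FstResult",
    "tn93_distance",
    "mean_group_tn93",
    "upgma_tree",
    "pcoa",
    "pairwise_fst",
    "wc_fst_two_pops",
]


# ---------------------------------------------------------------------------
# Tamura-Nei distance

@dataclass(frozen=True)
class TN93Components:
    """Observed quantities and the resulting TN93 distance for one pair."""

    freqs: tuple[float, float, float, float]  # piA, piC, piG, piT (pooled)
    P1: float  # proportion of A<->G transition sites
    P2: float  # proportion of C<->T transition sites
    Q: float   # proportion of transversion sites
    n_sites: int
    d: float           # NaN when undefined
    defined: bool

    @property
    def piR(self) -> float:
        return self.freqs[0] + self.freqs[2]

    @property
    def piY(self) -> float:
        return self.freqs[1] + self.freqs[3]


def _tn93_from_counts(
    freqs: tuple[float, float, float, float], P1: float, P2: float, Q: float,
    n_sites: int,
) -> TN93Components:
    piA, piC, piG, piT = freqs
    piR, piY = piA + piG, piC + piT
    undef = TN93Components(freqs, P1, P2, Q, n_sites, math.nan, False)

    def log_term(coeff: float, arg: float, prop: float) -> float | None:
        # coeff * ln(arg); a zero-coefficient term is only meaningful when the
        # corresponding observed proportion is also zero.
        if coeff == 0.0:
            return 0.0 if prop == 0.0 else None
        if arg <= 0.0:
            return None
        return coeff * math.log(arg)

    if piR == 0.0 or piY == 0.0:
        if P1 == P2 == Q == 0.0:
            return TN93Components(freqs, P1, P2, Q, n_sites, 0.0, True)
        return undef
    k1 = 2.0 * piA * piG
    k2 = 2.0 * piC * piT
    t1 = log_term(-k1 / piR, 1.0 - piR * P1 / k1 - Q / (2.0 * piR) if k1 else 1.0, P1)
    t2 = log_term(-k2 / piY, 1.0 - piY * P2 / k2 - Q / (2.0 * piY) if k2 else 1.0, P2)
    coeff3 = -2.0 * (piR * piY - k1 * piY / (2.0 * piR) - k2 * piR / (2.0 * piY))
    t3 = log_term(coeff3, 1.0 - Q / (2.0 * piR * piY), Q)
    if t1 is None or t2 is None or t3 is None:
        return undef
    d = t1 + t2 + t3
    return TN93Components(freqs, P1, P2, Q, n_sites, d, True)


def tn93_distance(seq_a: str, seq_b: str) -> TN93Components:
    """TN93 distance between two equal-length sequences.

    Only sites where both sequences carry an unambiguous A/C/G/T base are
    compared; base frequencies are estimated from the two sequences pooled
    over those sites.  Saturated pairs (any log argument <= 0) are returned
    with ``defined=False`` and ``d=NaN`` rather than raising.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    codes = encode_alignment([seq_a, seq_b])
    a, b = codes[0], codes[1]
    ok = (a <= 3) & (b <= 3)
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        raise ValueError("no comparable sites")
    pooled = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    freqs = tuple((pooled / pooled.sum()).tolist())
    diff = a != b
    purine_a, purine_b = (a == 0) | (a == 2), (b == 0) | (b == 2)
    transition = diff & (purine_a == purine_b)
    p1 = float(np.sum(transition & purine_a)) / n       # A<->G
    p2 = float(np.sum(transition & ~purine_a)) / n      # C<->T
    q = float(np.sum(diff & (purine_a != purine_b))) / n
    return _tn93_from_counts(freqs, p1, p2, q, n)


def mean_group_tn93(
    alignment: MergedAlignment,
    species_map: Mapping[str, str],
    exclude: Sequence[str] = (),
    species_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Group-level distance matrix: mean TN93 over all inter-group sequence
    pairs (excluded samples are dropped first).  Undefined pair distances
    raise, since they cannot be averaged."""
    keep = [s for s in alignment.sample_ids if s not in set(exclude)]
    if species_order is None:
        species_order = list(dict.fromkeys(species_map[s] for s in keep))
    groups = {sp: [s for s in keep if species_map[s] == sp] for sp in species_order}
    mat = np.zeros((len(species_order), len(species_order)))
    for (i, sa), (j, sb) in itertools.combinations(enumerate(species_order), 2):
        ds = []
        for x in groups[sa]:
            for y in groups[sb]:
                comp = tn93_distance(alignment.sequence_of(x), alignment.sequence_of(y))
                if not comp.defined:
                    raise ValueError(f"TN93 undefined between {x} and {y}")
                ds.append(comp.d)
        mat[i, j] = mat[j, i] = float(np.mean(ds))
    return pd.DataFrame(mat, index=list(species_order), columns=list(species_order))


# ---------------------------------------------------------------------------
# UPGMA

@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree; ``height`` is distance to its leaves."""

    label: str | None = None
    height: float = 0.0
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (equal for an ultrametric tree)."""
        depths: dict[str, float] = {}

        def walk(node: "TreeNode", acc: float) -> None:
            if node.is_leaf:
                depths[node.label or ""] = acc
                return
            for child, bl in node.children:
                walk(child, acc + bl)

        walk(self, 0.0)
        return depths

    def to_newick(self, precision: int = 6) -> str:
        def fmt(node: "TreeNode") -> str:
            if node.is_leaf:
                return node.label or ""
            inner = ",".join(
                f"{fmt(child)}:{bl:.{precision}g}" for child, bl in node.children
            )
            return f"({inner})"

        return fmt(self) + ";"


def upgma_tree(
    dist: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
) -> TreeNode:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Merge height is half the inter-cluster distance, so root-to-leaf path
    lengths are equal by construction.  Ties are broken by the smallest
    (row, col) index pair in the current cluster list, making the result
    deterministic.
    """
    if isinstance(dist, pd.DataFrame):
        if labels is None:
            labels = list(dist.index)
        dist = dist.to_numpy(dtype=float)
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diagonal(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if labels is None:
        labels = [f"g{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("one label per matrix row required")
    if n == 1:
        return TreeNode(label=labels[0])

    nodes = [TreeNode(label=lab) for lab in labels]
    sizes = [1] * n
    dm = d.copy()
    active = list(range(n))
    while len(active) > 1:
        best: tuple[int, int] | None = None
        best_d = math.inf
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                dij = dm[active[ii], active[jj]]
                if dij < best_d:
                    best_d = dij
                    best = (ii, jj)
        assert best is not None
        ii, jj = best
        i, j = active[ii], active[jj]
        height = best_d / 2.0
        parent = TreeNode(height=height)
        parent.children = [
            (nodes[i], height - nodes[i].height),
            (nodes[j], height - nodes[j].height),
        ]
        # merged cluster replaces position ii; jj is removed
        new_size = sizes[i] + sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dm[i, k] = dm[k, i] = (sizes[i] * dm[i, k] + sizes[j] * dm[j, k]) / new_size
        nodes[i] = parent
        sizes[i] = new_size
        active.pop(jj)
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# Principal coordinates analysis

@dataclass
class PCoAResult:
    """Embedding of a distance matrix: coordinates for positive eigenvalues."""

    sample_ids: list[str]
    coordinates: np.ndarray       # (n_samples, n_positive_axes)
    eigenvalues: np.ndarray       # all eigenvalues, sorted descending
    percent_variance: np.ndarray  # per positive axis, % of positive eigenvalue sum

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            pct = "\t".join(f"{p:.2f}" for p in self.percent_variance)
            fh.write(f"# percent variance per axis:\t{pct}\n")
            ncols = self.coordinates.shape[1]
            fh.write("sample\t" + "\t".join(f"axis{i+1}" for i in range(ncols)) + "\n")
            for sid, row in zip(self.sample_ids, self.coordinates):
                fh.write(sid + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


def pcoa(
    dist: np.ndarray | pd.DataFrame,
    sample_ids: Sequence[str] | None = None,
) -> PCoAResult:
    """Classical PCoA: Gower-center the squared distances and eigendecompose.

    B = -1/2 * J * D^2 * J with J = I - 11'/n.  Coordinates are eigenvectors
    scaled by sqrt(eigenvalue) for positive eigenvalues; negative eigenvalues
    are reported but yield no coordinates.  Axis signs are fixed so the
    largest-magnitude loading on each axis is positive.
    """
    if isinstance(dist, pd.DataFrame):
        if sample_ids is None:
            sample_ids = list(dist.index)
        dist = dist.to_numpy(dtype=float)
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * abs(evals[0])) if evals.size else 0.0
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        imax = int(np.argmax(np.abs(coords[:, k])))
        if coords[imax, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = evals[pos].sum()
    pct = 100.0 * evals[pos] / pos_sum if pos_sum > 0 else np.zeros(int(pos.sum()))
    return PCoAResult(list(sample_ids), coords, evals, pct)


# ---------------------------------------------------------------------------
# Pairwise Fst with permutation test

def wc_fst_two_pops(
    alt1: np.ndarray, an1: np.ndarray, alt2: np.ndarray, an2: np.ndarray
) -> float:
    """Weir–Cockerham Fst (ratio of sums) for two populations over sites.

    ``alt*`` are per-site alternative-allele counts and ``an*`` the per-site
    called allele totals for each population.  Sites where either population
    has no called alleles are dropped.  Negative values are reported as
    computed.  Returns NaN when no site is informative.
    """
    alt1 = np.asarray(alt1, dtype=float)
    alt2 = np.asarray(alt2, dtype=float)
    an1 = np.asarray(an1, dtype=float)
    an2 = np.asarray(an2, dtype=float)
    ok = (an1 > 0) & (an2 > 0) & (an1 + an2 > 2)
    if not ok.any():
        return math.nan
    n1, n2 = an1[ok], an2[ok]
    p1, p2 = alt1[ok] / n1, alt2[ok] / n2
    r = 2.0
    n_tot = n1 + n2
    n_bar = n_tot / r
    n_c = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1.0)
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    inner = p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r
    a = (n_bar / n_c) * (s2 - inner / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * inner
    denom = float(np.sum(a + b))
    if denom == 0.0:
        return math.nan
    return float(np.sum(a) / denom)


@dataclass
class FstResult:
    """Pairwise Fst matrix over species with permutation p-values."""

    species: list[str]
    fst: pd.DataFrame
    p_values: pd.DataFrame
    n_permutations: int
    excluded: list[str]
    n_sites: int

    def has_negative(self) -> bool:
        mat = self.fst.to_numpy()
        iu = np.triu_indices(mat.shape[0], k=1)
        return bool(np.any(mat[iu] < 0))

    def write_tsv(self, path: str | Path) -> None:
        """Table with Fst below the diagonal and significance stars
        (p < 0.05 '*', p < 0.01 '**')."""
        with open(path, "w") as fh:
            fh.write("species\t" + "\t".join(self.species[:-1]) + "\n")
            for i, sp in enumerate(self.species):
                if i == 0:
                    continue
                cells = []
                for j in range(len(self.species) - 1):
                    if j < i:
                        val = self.fst.iloc[i, j]
                        p = self.p_values.iloc[i, j]
                        stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
                        cells.append(f"{val:.3f}{stars}")
                    else:
                        cells.append("")
                fh.write(sp + "\t" + "\t".join(cells) + "\n")


def _alignment_allele_counts(
    alignment: MergedAlignment, sample_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample alt dosage and called-allele totals at biallelic segregating
    sites, expanding IUPAC heterozygote codes to their two alleles."""
    codes = encode_alignment([alignment.sequence_of(s) for s in sample_ids])
    per_sample = _CODE_ALLELES[codes]          # (n, L, 4) in {0,1,2}
    totals = per_sample.sum(axis=0)            # (L, 4)
    present = totals > 0
    biallelic = present.sum(axis=1) == 2
    if not biallelic.any():
        return np.zeros((len(sample_ids), 0)), np.zeros((len(sample_ids), 0))
    sites = np.nonzero(biallelic)[0]
    # the "alt" allele at each site: the rarer of the two observed alleles
    tot_sites = totals[sites]
    alt_idx = np.zeros(len(sites), dtype=np.int64)
    for k, site_counts in enumerate(tot_sites):
        observed = np.nonzero(site_counts > 0)[0]
        alt_idx[k] = observed[np.argmin(site_counts[observed])]
    sub = per_sample[:, sites, :]
    dosage = sub[:, np.arange(len(sites)), alt_idx].astype(float)
    called = sub.sum(axis=2).astype(float)
    return dosage, called


def pairwise_fst(
    alignment: MergedAlignment,
    species_map: Mapping[str, str],
    exclude: Sequence[str] = (),
    n_permutations: int = 1000,
    seed: int = 0,
    species_order: Sequence[str] | None = None,
) -> FstResult:
    """Pairwise Fst between species with a sample-permutation significance test.

    Fst per pair is the Weir–Cockerham ratio of sums over the pair's
    segregating biallelic sites, each diploid sample contributing two alleles.
    The null distribution shuffles whole samples between the two species only;
    p = (count of permuted Fst >= observed + 1) / (n_permutations + 1), so a
    p-value of zero is impossible by construction.
    """
    excluded = [s for s in alignment.sample_ids if s in set(exclude)]
    keep = [s for s in alignment.sample_ids if s not in set(exclude)]
    if species_order is None:
        species_order = list(dict.fromkeys(species_map[s] for s in keep))
    groups = {sp: [s for s in keep if species_map[s] == sp] for sp in species_order}
    small = [sp for sp, ss in groups.items() if len(ss) < 2]
    if small:
        raise ValueError(f"species with fewer than 2 samples after exclusion: {small}")

    dosage, called = _alignment_allele_counts(alignment, keep)
    idx_of = {s: i for i, s in enumerate(keep)}
    nsp = len(species_order)
    fst = np.full((nsp, nsp), 0.0)
    pvals = np.full((nsp, nsp), 1.0)
    rng = np.random.default_rng(seed)
    for (i, sa), (j, sb) in itertools.combinations(enumerate(species_order), 2):
        rows_a = np.array([idx_of[s] for s in groups[sa]])
        rows_b = np.array([idx_of[s] for s in groups[sb]])
        da, ca = dosage[rows_a], called[rows_a]
        db, cb = dosage[rows_b], called[rows_b]
        obs = wc_fst_two_pops(da.sum(0), ca.sum(0), db.sum(0), cb.sum(0))
        fst[i, j] = fst[j, i] = obs
        if math.isnan(obs):
            continue  # no informative sites: Fst undefined, p stays 1
        pool_d = np.vstack([da, db])
        pool_c = np.vstack([ca, cb])
        na = len(rows_a)
        n_pair = pool_d.shape[0]
        count_ge = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n_pair)
            sel = perm[:na]
            rest = perm[na:]
            f = wc_fst_two_pops(
                pool_d[sel].sum(0), pool_c[sel].sum(0),
                pool_d[rest].sum(0), pool_c[rest].sum(0),
            )
            if not math.isnan(f) and not math.isnan(obs) and f >= obs:
                count_ge += 1
        pvals[i, j] = pvals[j, i] = (count_ge + 1) / (n_permutations + 1)
    species_list = list(species_order)
    return FstResult(
        species=species_list,
        fst=pd.DataFrame(fst, index=species_list, columns=species_list),
        p_values=pd.DataFrame(pvals, index=species_list, columns=species_list),
        n_permutations=n_permutations,
        excluded=excluded,
        n_sites=dosage.shape[1],
    )
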