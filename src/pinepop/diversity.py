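"""Nucleotide diversity statistics on a merged alignment.

Computes, per sample group, the number of segregating sites S, singleton
mutations, nucleotide diversity pi (mean pairwise differences per site, Nei's
estimator), and Tajima's D, plus the sample-by-sample pairwise difference
matrix used for ordination.

Ambiguity handling
------------------
Consensus sequences may carry IUPAC two-base codes at heterozygous sites and
N for missing data.  Two policies are offered:

``missing`` (default)
    Pairwise deletion: any non-A/C/G/T character is ignored — a pair's
    comparison at a site is skipped if either base is ambiguous, and S and
    singletons are counted over unambiguous bases only.  Conservative and
    simple, but blind to polymorphism visible only in heterozygotes.

``expand``
    A two-base IUPAC code contributes both alleles (a "half difference"
    scheme): the difference between two samples at a site is the mean over
    the 2x2 comparisons of their allele pairs, and S/singletons are counted
    on the expanded allele multiset, so a single heterozygote among reference
    homozygotes is a segregating singleton.  With diploid consensus input this
    is the estimator whose expectation matches haplotype diversity; Tajima's
    D then uses 2N chromosomes for its constants.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import MergedAlignment

__all__ = [
    "DiversityStats",
    "TajimaConstants",
    "PairwiseDifferenceMatrix",
    "diversity_stats",
    "tajimas_d",
    "pairwise_difference_matrix",
    "diversity_table",
]

AMBIGUITY_POLICIES = ("missing", "expand")

# Character -> (allele1, allele2) with alleles in 0..3 (ACGT) or None=missing.
_ALLELE_PAIRS: dict[str, tuple[int, int] | None] = {
    "A": (0, 0), "C": (1, 1), "G": (2, 2), "T": (3, 3),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
}
_N_CODES = len(_ALLELE_PAIRS) + 1  # +1 for the missing code
_MISSING = _N_CODES - 1

_CHAR_TO_CODE = np.full(256, _MISSING, dtype=np.uint8)
for _i, _ch in enumerate(_ALLELE_PAIRS):
    _CHAR_TO_CODE[ord(_ch)] = _i
    _CHAR_TO_CODE[ord(_ch.lower())] = _i

# Per-code allele counts (code -> counts over ACGT).
_CODE_ALLELES = np.zeros((_N_CODES, 4), dtype=np.int64)
for _i, _pair in enumerate(_ALLELE_PAIRS.values()):
    _CODE_ALLELES[_i, _pair[0]] += 1
    _CODE_ALLELES[_i, _pair[1]] += 1

# Pairwise difference weight between codes, expansion semantics: mean over
# the 2x2 allele comparisons.  Missing involved -> weight 0 and invalid.
_EXPAND_WEIGHT = np.zeros((_N_CODES, _N_CODES))
_EXPAND_VALID = np.zeros((_N_CODES, _N_CODES), dtype=bool)
_HOM_VALID = np.zeros((_N_CODES, _N_CODES), dtype=bool)
_HOM_DIFF = np.zeros((_N_CODES, _N_CODES))
for _i, _pi in enumerate(_ALLELE_PAIRS.values()):
    for _j, _pj in enumerate(_ALLELE_PAIRS.values()):
        _EXPAND_VALID[_i, _j] = True
        _EXPAND_WEIGHT[_i, _j] = sum(a != b for a in _pi for b in _pj) / 4.0
        if _pi[0] == _pi[1] and _pj[0] == _pj[1]:
            _HOM_VALID[_i, _j] = True
            _HOM_DIFF[_i, _j] = float(_pi[0] != _pj[0])


def encode_alignment(sequences: Sequence[str]) -> np.ndarray:
    """Encode sequences to a (n_samples, L) uint8 code matrix."""
    arrs = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in sequences]
    mat = np.vstack(arrs)
    return _CHAR_TO_CODE[mat]


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 normalizing constants of Tajima's D for n sequences."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("Tajima constants require n >= 2")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(S: int, k_bar: float, n: int) -> float:
    """Tajima's D from S segregating sites and mean pairwise differences k_bar
    among n sequences.  Returns NaN (undefined) when S = 0, when n < 4 (the
    variance is not reliably defined), or when the variance term vanishes."""
    if n < 2:
        raise ValueError("need at least two sequences")
    if S < 0:
        raise ValueError("S must be non-negative")
    if S == 0 or n < 4:
        return math.nan
    c = TajimaConstants.for_n(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (k_bar - S / c.a1) / math.sqrt(var)


@dataclass(frozen=True)
class DiversityStats:
    """Per-group alignment summary: one row of a diversity report."""

    N: int          # number of sequences (samples)
    L: int          # alignment length in bp
    S: int          # segregating sites
    singletons: int
    pi: float       # mean pairwise differences per site
    k_bar: float    # mean pairwise differences per sequence pair (count scale)
    D: float        # Tajima's D; NaN when undefined
    n_chromosomes: int  # chromosomes used for Tajima constants


def _column_allele_counts(codes: np.ndarray, ambiguity: str) -> np.ndarray:
    """(L, 4) allele counts per column.  Under "missing", only unambiguous
    bases count (one allele per sequence); under "expand", every sequence
    contributes its two alleles."""
    counts = np.zeros((codes.shape[1], 4), dtype=np.int64)
    hom = ambiguity == "missing"
    for row in codes:
        contrib = _CODE_ALLELES[row]
        if hom:
            is_hom = row <= 3
            counts[is_hom] += contrib[is_hom] // 2
        else:
            counts += contrib
    return counts


def _segregating_and_singletons(counts: np.ndarray) -> tuple[int, int]:
    present = counts > 0
    n_alleles = present.sum(axis=1)
    seg = n_alleles >= 2
    S = int(seg.sum())
    ones = (counts == 1).sum(axis=1)
    # At a column where every observed allele is unique, one of them is the
    # "type" and the rest are singleton mutations (a 2-sequence difference is
    # one mutation, not two).
    all_unique = seg & (ones == n_alleles)
    singles = np.where(seg, ones - all_unique.astype(np.int64), 0)
    return S, int(singles.sum())


def _pair_stats(
    codes: np.ndarray, ambiguity: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise (differences, compared sites) matrices over all sequence pairs."""
    n = codes.shape[0]
    diffs = np.zeros((n, n))
    compared = np.zeros((n, n), dtype=np.int64)
    weight = _EXPAND_WEIGHT if ambiguity == "expand" else _HOM_DIFF
    valid = _EXPAND_VALID if ambiguity == "expand" else _HOM_VALID
    for i, j in itertools.combinations(range(n), 2):
        v = valid[codes[i], codes[j]]
        d = weight[codes[i], codes[j]][v].sum()
        diffs[i, j] = diffs[j, i] = d
        compared[i, j] = compared[j, i] = int(v.sum())
    return diffs, compared


def diversity_stats(
    alignment: MergedAlignment,
    sample_ids: Sequence[str] | None = None,
    ambiguity: str = "missing",
) -> DiversityStats:
    """Diversity summary for a subset of alignment rows.

    pi uses per-pair compared-site denominators (pairwise deletion), which
    reduces to differences/L on complete data.  Tajima's D is computed from
    S and the count-scale mean pairwise differences; under the "expand"
    policy its constants use 2N chromosomes.
    """
    if ambiguity not in AMBIGUITY_POLICIES:
        raise ValueError(f"ambiguity must be one of {AMBIGUITY_POLICIES}")
    ids = list(sample_ids) if sample_ids is not None else list(alignment.sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    codes = encode_alignment([alignment.sequence_of(s) for s in ids])
    L = codes.shape[1]
    counts = _column_allele_counts(codes, ambiguity)
    S, singletons = _segregating_and_singletons(counts)
    diffs, compared = _pair_stats(codes, ambiguity)
    iu = np.triu_indices(len(ids), k=1)
    if (compared[iu] == 0).any():
        bad = [(ids[i], ids[j]) for i, j in zip(*iu) if compared[i, j] == 0]
        raise ValueError(f"no comparable sites for pairs: {bad}")
    pi = float(np.mean(diffs[iu] / compared[iu]))
    k_bar = float(np.mean(diffs[iu]))
    n_chrom = 2 * len(ids) if ambiguity == "expand" else len(ids)
    D = tajimas_d(S, k_bar, n_chrom)
    return DiversityStats(
        N=len(ids), L=L, S=S, singletons=singletons,
        pi=pi, k_bar=k_bar, D=D, n_chromosomes=n_chrom,
    )


@dataclass
class PairwiseDifferenceMatrix:
    """Sample-by-sample base differences (counts) and per-site rates."""

    sample_ids: list[str]
    counts: np.ndarray
    per_site: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")


def pairwise_difference_matrix(
    alignment: MergedAlignment,
    ambiguity: str = "missing",
) -> PairwiseDifferenceMatrix:
    """Number of base differences per sequence pair, with pairwise deletion.

    ``per_site`` divides each pair's differences by that pair's compared-site
    count; a pair with zero comparable sites is an error.
    """
    if ambiguity not in AMBIGUITY_POLICIES:
        raise ValueError(f"ambiguity must be one of {AMBIGUITY_POLICIES}")
    ids = list(alignment.sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least two sequences")
    codes = encode_alignment(alignment.sequences)
    diffs, compared = _pair_stats(codes, ambiguity)
    n = len(ids)
    per_site = np.zeros_like(diffs)
    for i, j in itertools.combinations(range(n), 2):
        if compared[i, j] == 0:
            raise ValueError(f"no comparable sites between {ids[i]} and {ids[j]}")
        per_site[i, j] = per_site[j, i] = diffs[i, j] / compared[i, j]
    return PairwiseDifferenceMatrix(ids, diffs, per_site)


def diversity_table(
    alignment: MergedAlignment,
    species_map: Mapping[str, str],
    species_order: Sequence[str] | None = None,
    ambiguity: str = "missing",
) -> pd.DataFrame:
    """Per-species diversity rows plus a Total/Average row.

    The total row reports pooled N, L, S and singletons over all samples, the
    across-species average pi, and the average D over species where D is
    defined.
    """
    if species_order is None:
        seen: list[str] = []
        for sid in alignment.sample_ids:
            sp = species_map[sid]
            if sp not in seen:
                seen.append(sp)
        species_order = seen
    rows = []
    for sp in species_order:
        ids = [s for s in alignment.sample_ids if species_map[s] == sp]
        st = diversity_stats(alignment, ids, ambiguity=ambiguity)
        rows.append(
            {"group": sp, "N": st.N, "L": st.L, "S": st.S,
             "singletons": st.singletons, "pi": st.pi, "D": st.D}
        )
    pooled = diversity_stats(alignment, ambiguity=ambiguity)
    pis = [r["pi"] for r in rows]
    ds = [r["D"] for r in rows if not math.isnan(r["D"])]
    rows.append(
        {
            "group": "Total/Aver.",
            "N": pooled.N,
            "L": pooled.L,
            "S": pooled.S,
            "singletons": pooled.singletons,
            "pi": float(np.mean(pis)),
            "D": float(np.mean(ds)) if ds else math.nan,
        }
    )
    return pd.DataFrame(rows)
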