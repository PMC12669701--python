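"""Pairwise kinship estimation, relatedness calling and cohort dedup.

Kinship between two genotyped individuals is estimated with the
within-family robust estimator popularised by the KING toolkit::

    phi_hat = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j))

where counts run over loci non-missing in both individuals, ``N_het,het``
is the number of loci at which both are heterozygous and
``N_opposite_hom`` the number at which they are opposite homozygotes.
Self-kinship is exactly 0.5.  Expected values are ~0.25 for first-degree
and ~0.125 for second-degree relatives; relatedness degrees are called
with the conventional power-of-two midpoint cutoffs (1/2^(5/2) = 0.177,
1/2^(7/2) = 0.0884).

Deduplication builds the union of genetically flagged and self-reported
related pairs, takes connected components of the resulting relatedness
graph, and keeps exactly one uniformly chosen member per component
(seeded, hence reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import UndefinedResultError
from .analytics import rank_sum

__all__ = [
    "Degree",
    "RelatednessCall",
    "DegreeThresholds",
    "king_robust",
    "kinship_matrix",
    "call_degree",
    "flag_related_pairs",
    "dedup_cohort",
    "sharing_vs_kinship",
]

#: Sentinel for a missing genotype in integer genotype vectors.
MISSING = -1


class Degree(str, Enum):
    FIRST = "first"
    SECOND = "second"
    UNRELATED = "unrelated"


@dataclass(frozen=True)
class DegreeThresholds:
    first: float = 0.177    # 1 / 2**(5/2)
    second: float = 0.0884  # 1 / 2**(7/2)


_DEFAULT_THRESHOLDS = DegreeThresholds()


@dataclass(frozen=True)
class RelatednessCall:
    id1: str
    id2: str
    phi: float
    degree: Degree


def king_robust(genotypes_i, genotypes_j) -> float:
    """KING-robust kinship coefficient between two genotype vectors.

    Genotypes are alt-allele dosages in {0, 1, 2}; missing values may be
    encoded as -1 or NaN and are dropped pairwise.  Raises
    :class:`UndefinedResultError` when no usable locus remains (the
    denominator requires at least one heterozygous call).
    """
    gi = np.asarray(genotypes_i, dtype=float)
    gj = np.asarray(genotypes_j, dtype=float)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must share loci")
    ok = ~(np.isnan(gi) | np.isnan(gj)) & (gi != MISSING) & (gj != MISSING)
    gi, gj = gi[ok], gj[ok]
    het_i = gi == 1
    het_j = gj == 1
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        raise UndefinedResultError("no heterozygous loci shared by the pair")
    n_hethet = int((het_i & het_j).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    return (n_hethet - 2 * n_opp) / denom


def kinship_matrix(genotypes: np.ndarray, ids: Sequence[str]) -> "pd.DataFrame":
    """All-pairs KING-robust kinship for an (n individuals x L loci) matrix.

    Returns a long-format DataFrame (id1, id2, phi) over unordered pairs
    i < j.  Pairs with a zero denominator get phi = NaN.  Missing genotypes
    (encoded -1) are not supported by this vectorised path.
    """
    import pandas as pd

    g = np.asarray(genotypes)
    if (g == MISSING).any():
        raise ValueError("vectorised kinship requires complete genotypes")
    het = (g == 1).astype(np.float32)
    hom0 = (g == 0).astype(np.float32)
    hom2 = (g == 2).astype(np.float32)
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_counts = het.sum(axis=1)
    denom = het_counts[:, None] + het_counts[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    iu, ju = np.triu_indices(len(ids), k=1)
    ids = np.asarray(ids)
    return pd.DataFrame(
        {"id1": ids[iu], "id2": ids[ju], "phi": phi[iu, ju].astype(float)}
    )


def call_degree(
    phi: float, thresholds: DegreeThresholds = _DEFAULT_THRESHOLDS
) -> Degree:
    """Relatedness degree from a kinship coefficient."""
    if phi > thresholds.first:
        return Degree.FIRST
    if phi > thresholds.second:
        return Degree.SECOND
    return Degree.UNRELATED


def flag_related_pairs(
    kinship_long, thresholds: DegreeThresholds = _DEFAULT_THRESHOLDS
) -> list[RelatednessCall]:
    """First/second-degree calls from a long-format kinship table."""
    out = []
    for id1, id2, phi in zip(kinship_long["id1"], kinship_long["id2"],
                             kinship_long["phi"]):
        if np.isnan(phi):
            continue
        degree = call_degree(float(phi), thresholds)
        if degree != Degree.UNRELATED:
            out.append(RelatednessCall(str(id1), str(id2), float(phi), degree))
    return out


class _UnionFind:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def dedup_cohort(
    ids: Sequence[str],
    related_pairs: Iterable[RelatednessCall | tuple],
    seed: int,
) -> list[str]:
    """Reduce a cohort to unrelated probands.

    Builds the relatedness graph over the flagged pairs (a pair may be a
    :class:`RelatednessCall` or a bare ``(id1, id2)`` tuple, allowing
    self-reported family links to be merged in), takes connected
    components, and retains exactly one member per component, chosen
    uniformly with the given seed.  Singleton probands are always kept.
    Output preserves the input id order; no flagged pair survives.
    """
    ids = [str(i) for i in ids]
    known = set(ids)
    uf = _UnionFind()
    for pair in related_pairs:
        a, b = (pair.id1, pair.id2) if isinstance(pair, RelatednessCall) else pair[:2]
        a, b = str(a), str(b)
        if a not in known or b not in known:
            raise ValueError(f"related pair ({a}, {b}) references unknown ids")
        uf.union(a, b)
    components: dict[str, list[str]] = {}
    for i in ids:
        if i in uf.parent:
            components.setdefault(uf.find(i), []).append(i)
    rng = np.random.default_rng(seed)
    keep = set(ids) - {m for members in components.values() for m in members}
    for members in components.values():
        keep.add(members[rng.integers(len(members))])
    return [i for i in ids if i in keep]


def sharing_vs_kinship(kinship_long, sharing_pairs: Iterable[tuple[str, str]]):
    """Compare kinship between variant-sharing and non-sharing pairs.

    ``sharing_pairs`` is the set of unordered proband pairs that share at
    least one causal variant.  Returns a dict with the median kinship
    coefficient in each stratum and a two-sided rank-sum p-value.  Raises
    :class:`UndefinedResultError` if either stratum is empty.
    """
    sharing = {frozenset((str(a), str(b))) for a, b in sharing_pairs}
    phi_sharing, phi_other = [], []
    for id1, id2, phi in zip(kinship_long["id1"], kinship_long["id2"],
                             kinship_long["phi"]):
        if np.isnan(phi):
            continue
        bucket = phi_sharing if frozenset((str(id1), str(id2))) in sharing else phi_other
        bucket.append(float(phi))
    if not phi_sharing or not phi_other:
        raise UndefinedResultError("both sharing strata must be non-empty")
    _, p = rank_sum(phi_sharing, phi_other)
    return {
        "median_sharing": float(np.median(phi_sharing)),
        "median_non_sharing": float(np.median(phi_other)),
        "n_sharing": len(phi_sharing),
        "n_non_sharing": len(phi_other),
        "p_value": p,
    }
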