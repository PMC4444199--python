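"""Presence/absence beta-diversity partitioning.

Implements the Sørensen-family partition of compositional dissimilarity into
its turnover (Simpson-based) and nestedness-resultant components, for pairwise
comparisons (temporal: same site at two censuses; spatial: two sites at one
census) and for multiple-site dissimilarity over a whole community matrix.

Notation follows the standard matching-component convention: for two
assemblages, ``a`` is the number of shared species, ``b`` the number unique to
the first and ``c`` the number unique to the second.  Then

    beta_sor = (b + c) / (2a + b + c)          total dissimilarity
    beta_sim = min(b, c) / (a + min(b, c))     turnover (replacement)
    beta_sne = beta_sor - beta_sim             nestedness-resultant

The multiple-site generalisations are built from sums of pairwise
exclusive-species counts, not from averages of pairwise values:

    beta_SIM = S_min / (S_min + (sum_i S_i - S_T))
    beta_SOR = (S_min + S_max) / (2 (sum_i S_i - S_T) + S_min + S_max)
    beta_SNE = beta_SOR - beta_SIM

with ``S_i`` the richness of site i, ``S_T`` the pooled richness, and
``S_min``/``S_max`` the sums over site pairs (i<j) of min/max of the two
exclusive counts b_ij, b_ji.  All counts are kept as integers; division
happens once, at the end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .io_formats import CommunityMatrix

__all__ = [
    "PairCounts",
    "BetaComponents",
    "DissimilarityMatrix",
    "MultiSiteComponents",
    "pair_counts",
    "partition_pair",
    "temporal_partition",
    "spatial_pairwise",
    "multisite_partition",
]


class UndefinedDissimilarityError(ValueError):
    """Raised when both assemblages are empty (all denominators vanish)."""


class PairCounts(NamedTuple):
    """Matching components of two assemblages: shared / unique-to-x / unique-to-y."""

    a: int
    b: int
    c: int


class BetaComponents(NamedTuple):
    """The (total, turnover, nestedness-resultant) dissimilarity triple."""

    sor: float
    sim: float
    sne: float


@dataclass(frozen=True)
class MultiSiteComponents:
    """Multiple-site dissimilarities with their underlying integer sums."""

    SOR: float
    SIM: float
    SNE: float
    n_sites: int
    sum_Si: int          # total of per-site richness
    S_T: int             # pooled (regional) richness
    sum_min: int         # sum over pairs of min(b_ij, b_ji)
    sum_max: int         # sum over pairs of max(b_ij, b_ji)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise site-by-site dissimilarity matrix for one component.

    ``values[i, j]`` is NaN only for a pair of two empty assemblages.
    """

    site_ids: tuple
    values: np.ndarray
    component_label: str  # one of {"sor", "sim", "sne"}

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major (i>j) order."""
        n = self.values.shape[0]
        idx = np.tril_indices(n, k=-1)
        return self.values[idx]


def pair_counts(x: np.ndarray, y: np.ndarray) -> PairCounts:
    """Count species shared by and unique to two presence/absence vectors."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"presence vectors must be 1-D and equal length, got {x.shape} vs {y.shape}"
        )
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    return PairCounts(a, b, c)


def partition_pair(pc: PairCounts) -> BetaComponents:
    """Partition one pairwise comparison into (sor, sim, sne).

    For the degenerate case of exactly one empty assemblage (a = 0 and one of
    b, c zero) the turnover ratio is 0/0; we take the limit of the nested case:
    sim = 0, sor = 1, sne = 1.  Two empty assemblages are undefined and raise.
    """
    a, b, c = pc.a, pc.b, pc.c
    if a < 0 or b < 0 or c < 0:
        raise ValueError(f"counts must be non-negative, got {pc}")
    if a == 0 and b == 0 and c == 0:
        raise UndefinedDissimilarityError(
            "dissimilarity undefined for two empty assemblages"
        )
    sor = (b + c) / (2 * a + b + c)
    m = min(b, c)
    denom = a + m
    sim = m / denom if denom > 0 else 0.0
    return BetaComponents(sor=sor, sim=sim, sne=sor - sim)


def temporal_partition(cm_t1: CommunityMatrix, cm_t2: CommunityMatrix) -> list[BetaComponents]:
    """Per-site temporal dissimilarity between two aligned censuses.

    Expects matrices already aligned and with empty-either sites removed;
    a site empty in both censuses raises ``UndefinedDissimilarityError``.
    """
    if cm_t1.occ.shape != cm_t2.occ.shape:
        raise ValueError("censuses must be aligned to the same sites and species")
    if list(cm_t1.site_ids) != list(cm_t2.site_ids):
        raise ValueError("censuses must share an identical site ordering")
    return [
        partition_pair(pair_counts(cm_t1.occ[i], cm_t2.occ[i]))
        for i in range(cm_t1.occ.shape[0])
    ]


def _pairwise_abc(occ: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared and exclusive species counts for every site pair, vectorised."""
    occ = occ.astype(np.int64)
    a = occ @ occ.T
    richness = occ.sum(axis=1)
    b = richness[:, None] - a  # species at i absent from j
    c = richness[None, :] - a
    return a, b, c


def spatial_pairwise(cm: CommunityMatrix) -> dict[str, DissimilarityMatrix]:
    """All pairwise spatial dissimilarities within one census.

    Returns a dict with keys ``"sor"``, ``"sim"``, ``"sne"``.  Pairs with
    exactly one empty site take the nested-limit convention (sor=1, sim=0,
    sne=1); pairs of two empty sites are NaN.
    """
    occ = cm.occ
    n = occ.shape[0]
    if n == 0:
        raise ValueError("community matrix has no sites")
    a, b, c = _pairwise_abc(occ)
    with np.errstate(invalid="ignore", divide="ignore"):
        sor = (b + c) / (2 * a + b + c)
        m = np.minimum(b, c)
        sim = np.where(a + m > 0, m / np.where(a + m > 0, a + m, 1), 0.0)
    both_empty = (a + b + c) == 0
    sor = np.where(both_empty, np.nan, sor)
    sim = np.where(both_empty, np.nan, sim)
    sne = sor - sim
    out = {}
    for label, vals in (("sor", sor), ("sim", sim), ("sne", sne)):
        v = vals.astype(float)
        np.fill_diagonal(v, 0.0)
        out[label] = DissimilarityMatrix(
            site_ids=tuple(cm.site_ids), values=v, component_label=label
        )
    return out


def multisite_partition(cm: CommunityMatrix) -> MultiSiteComponents:
    """Multiple-site dissimilarity partition over all sites of one census."""
    occ = cm.occ
    n = occ.shape[0]
    if n < 2:
        raise ValueError("multiple-site dissimilarity needs at least 2 sites")
    S_T = int(np.sum(occ.any(axis=0)))
    if S_T == 0:
        raise UndefinedDissimilarityError("all sites empty: dissimilarity undefined")
    richness = occ.sum(axis=1)
    sum_Si = int(richness.sum())
    _, b, _ = _pairwise_abc(occ)
    iu = np.triu_indices(n, k=1)
    b_ij = b[iu]          # exclusive to i w.r.t. j
    b_ji = b.T[iu]        # exclusive to j w.r.t. i
    sum_min = int(np.minimum(b_ij, b_ji).sum())
    sum_max = int(np.maximum(b_ij, b_ji).sum())
    pooled_excess = sum_Si - S_T
    SIM = sum_min / (pooled_excess + sum_min) if (pooled_excess + sum_min) > 0 else 0.0
    denom = 2 * pooled_excess + sum_min + sum_max
    SOR = (sum_min + sum_max) / denom if denom > 0 else 0.0
    return MultiSiteComponents(
        SOR=SOR,
        SIM=SIM,
        SNE=SOR - SIM,
        n_sites=n,
        sum_Si=sum_Si,
        S_T=S_T,
        sum_min=sum_min,
        sum_max=sum_max,
    )
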