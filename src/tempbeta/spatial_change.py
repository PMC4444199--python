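"""Temporal change in spatial beta diversity.

Two complementary questions about the spatial structure of a metacommunity at
two dates:

* Did the overall regional heterogeneity change?  Multiple-site dissimilarity
  is resampled over fixed-size site subsets at each date and the two sampling
  distributions compared empirically ("how often would the opposite ordering
  be observed?").
* Did the pairwise structure change?  A Mantel permutation test correlates
  the two dates' pairwise dissimilarity matrices; a low correlation means
  site pairs that were similar at one date need not be similar at the other,
  even if overall heterogeneity is unchanged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .beta_core import DissimilarityMatrix, multisite_partition
from .io_formats import CommunityMatrix

__all__ = [
    "MultiSiteSampleDistribution",
    "MantelResult",
    "multisite_resample",
    "compare_distributions",
    "mantel",
]


@dataclass(frozen=True)
class MultiSiteSampleDistribution:
    """Resampled multiple-site dissimilarity values for one census."""

    census_label: str
    subset_size: int
    n_samples: int
    SIM_values: np.ndarray
    SNE_values: np.ndarray
    seed: int


@dataclass(frozen=True)
class MantelResult:
    r: float
    r2: float
    p: float
    n_perm: int


def multisite_resample(
    cm: CommunityMatrix, subset_size: int = 50, n_samples: int = 1000, seed: int = 0
) -> MultiSiteSampleDistribution:
    """Multiple-site dissimilarity over repeated uniform site subsets.

    Each sample draws ``subset_size`` sites without replacement and computes
    the multiple-site partition on the sub-matrix.
    """
    if subset_size < 2:
        raise ValueError("subset_size must be at least 2")
    if subset_size > cm.n_sites:
        raise ValueError(f"subset_size {subset_size} exceeds {cm.n_sites} sites")
    rng = np.random.default_rng(seed)
    sim = np.empty(n_samples)
    sne = np.empty(n_samples)
    for k in range(n_samples):
        idx = rng.choice(cm.n_sites, size=subset_size, replace=False)
        sub = CommunityMatrix(
            site_ids=tuple(cm.site_ids[i] for i in idx),
            species_ids=cm.species_ids,
            occ=cm.occ[idx],
            census_label=cm.census_label,
        )
        ms = multisite_partition(sub)
        sim[k] = ms.SIM
        sne[k] = ms.SNE
    return MultiSiteSampleDistribution(
        census_label=cm.census_label,
        subset_size=subset_size,
        n_samples=n_samples,
        SIM_values=sim,
        SNE_values=sne,
        seed=seed,
    )


def _cross_pair_p(v1: np.ndarray, v2: np.ndarray, paired: bool) -> float:
    if paired:
        diffs = v2 - v1
    else:
        diffs = (v2[None, :] - v1[:, None]).ravel()
    return float(((diffs < 0).sum() + 0.5 * (diffs == 0).sum()) / diffs.size)


def compare_distributions(
    d1: MultiSiteSampleDistribution,
    d2: MultiSiteSampleDistribution,
    paired: bool = False,
) -> dict[str, float]:
    """Empirical significance of the difference between two resampled
    multiple-site dissimilarity distributions, per component.

    p is the fraction of cross pairs — one value from each distribution;
    all n_samples² pairs, or replicate-index pairs if ``paired`` — in which
    the second distribution's value falls below the first's, ties counting
    one half: the probability of observing the ordering opposite to a rise
    from the first census to the second.  When the observed mean difference
    is negative, the significance of the observed decline is 1 - p.
    Swapping the distributions maps p to 1 - p.
    """
    if d1.subset_size != d2.subset_size:
        raise ValueError("distributions must use the same subset size")
    return {
        "SIM": _cross_pair_p(d1.SIM_values, d2.SIM_values, paired),
        "SNE": _cross_pair_p(d1.SNE_values, d2.SNE_values, paired),
    }


def mantel(
    m1: DissimilarityMatrix,
    m2: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> MantelResult:
    """Mantel permutation test of two pairwise dissimilarity matrices.

    r is the Pearson correlation over corresponding lower-triangle entries;
    the one-sided ("greater") p permutes the site labels of the second matrix
    (rows and columns jointly): p = (1 + #{r_perm >= r_obs}) / (1 + n_perm).
    With ``exact=True`` all n! site permutations are enumerated instead and
    p = #{r_perm >= r_obs} / n! (the identity included).
    """
    if m1.site_ids != m2.site_ids:
        raise ValueError("matrices must share the same site set and order")
    if not exact and n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    n = m1.values.shape[0]
    iu = np.tril_indices(n, k=-1)
    v1 = m1.values[iu]
    if np.ptp(v1) == 0 or np.ptp(m2.values[iu]) == 0:
        raise ValueError("zero variance in a dissimilarity matrix: r undefined")

    def corr_with(perm) -> float:
        permuted = m2.values[np.ix_(perm, perm)]
        return float(np.corrcoef(v1, permuted[iu])[0, 1])

    r_obs = corr_with(np.arange(n))
    if exact:
        ge = sum(
            corr_with(np.array(p)) >= r_obs - 1e-12
            for p in itertools.permutations(range(n))
        )
        p_val = ge / math.factorial(n)
        n_used = math.factorial(n)
    else:
        rng = np.random.default_rng(seed)
        ge = sum(
            corr_with(rng.permutation(n)) >= r_obs - 1e-12 for _ in range(n_perm)
        )
        p_val = (1 + ge) / (1 + n_perm)
        n_used = n_perm
    return MantelResult(r=r_obs, r2=r_obs**2, p=p_val, n_perm=n_used)
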