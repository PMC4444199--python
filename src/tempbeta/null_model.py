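"""Fixed-frequency (FE) null model for temporal assemblage change.

The null hypothesis is that species populations appear and disappear from
individual sites in a random-like way while each species' regional occupancy
frequency stays fixed: every replicate reassigns each species' presences to a
uniformly random subset of sites of the same size (null model "FE" — species
Frequencies fixed, sites Equiprobable; site richness is free to vary).
Temporal dissimilarity between the reference census and each null assemblage
yields, per site, a null distribution against which the observed temporal
turnover and nestedness-resultant dissimilarities are tested two-sided at the
empirical 2.5/97.5 percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beta_core import pair_counts, partition_pair
from .io_formats import CommunityMatrix

__all__ = [
    "NullEnsemble",
    "SignificanceClassification",
    "fe_reshuffle",
    "null_dissimilarity_ensemble",
    "ks_compare",
    "site_significance",
    "anova_by_class",
]


@dataclass(frozen=True)
class NullEnsemble:
    """Per-site null temporal dissimilarities across replicates.

    ``null_sim``/``null_sne`` have shape (n_reps, n_sites); an entry is NaN
    where that replicate's null assemblage at the site was empty (the
    comparison is undefined, mirroring the removal of empty sites in the
    observed analysis).
    """

    n_reps: int
    site_ids: tuple
    null_sim: np.ndarray
    null_sne: np.ndarray
    seed: int
    reference_census: str = ""


@dataclass(frozen=True)
class SignificanceClassification:
    """Per-site two-sided percentile-test labels, one row per site.

    ``labels`` columns: site, component, observed, q_lo, q_hi, label in
    {"lower", "ns", "higher"}, n_defined, reliable.
    """

    labels: pd.DataFrame
    alpha: float
    percentile_bounds: tuple[float, float]

    def counts(self, component: str) -> dict[str, int]:
        sub = self.labels[self.labels["component"] == component]
        return {k: int((sub["label"] == k).sum()) for k in ("lower", "ns", "higher")}


def fe_reshuffle(cm: CommunityMatrix, rng: np.random.Generator) -> CommunityMatrix:
    """One FE randomisation: per species, presences moved to a uniform random
    subset of sites of identical size; column sums are conserved exactly."""
    occ = _fe_reshuffle_occ(cm.occ, rng)
    return CommunityMatrix(
        site_ids=cm.site_ids,
        species_ids=cm.species_ids,
        occ=occ,
        census_label=f"FE({cm.census_label})",
    )


def _fe_reshuffle_occ(occ: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # Rank i.i.d. uniforms per column: the k smallest ranks form a uniform
    # k-subset, independently across species.
    n_sites, n_species = occ.shape
    keys = rng.random((n_sites, n_species))
    order = np.argsort(keys, axis=0)
    ranks = np.empty_like(order)
    ranks[order, np.arange(n_species)[None, :]] = np.arange(n_sites)[:, None]
    return ranks < occ.sum(axis=0)[None, :]


def _temporal_components(ref: np.ndarray, other: np.ndarray):
    """Vectorised per-site (sim, sne) between two aligned boolean matrices."""
    a = (ref & other).sum(axis=1)
    b = (ref & ~other).sum(axis=1)
    c = (~ref & other).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sor = (b + c) / (2 * a + b + c)
        m = np.minimum(b, c)
        sim = np.where(a + m > 0, m / np.where(a + m > 0, a + m, 1), 0.0)
    undefined = (a + b + c) == 0
    sor = np.where(undefined, np.nan, sor)
    sim = np.where(undefined, np.nan, sim)
    return sim, sor - sim


def null_dissimilarity_ensemble(
    cm_ref: CommunityMatrix,
    cm_shuffle_source: CommunityMatrix,
    n_reps: int = 1000,
    seed: int = 0,
) -> NullEnsemble:
    """Temporal dissimilarities of the reference census against ``n_reps``
    FE reshuffles of ``cm_shuffle_source``'s species frequencies.

    Sites where a null assemblage is empty get NaN for that replicate: the
    dissimilarity with the (non-empty) reference would rest on the degenerate
    one-empty convention rather than the null process, so the draw is excluded
    from the site's null distribution downstream.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if cm_ref.site_ids != cm_shuffle_source.site_ids:
        raise ValueError("matrices must be aligned to the same sites")
    rng = np.random.default_rng(seed)
    ref = cm_ref.occ
    n_sites = ref.shape[0]
    null_sim = np.empty((n_reps, n_sites))
    null_sne = np.empty((n_reps, n_sites))
    for r in range(n_reps):
        null_occ = _fe_reshuffle_occ(cm_shuffle_source.occ, rng)
        empty = ~null_occ.any(axis=1)
        sim, sne = _temporal_components(ref, null_occ)
        sim[empty] = np.nan
        sne[empty] = np.nan
        null_sim[r] = sim
        null_sne[r] = sne
    return NullEnsemble(
        n_reps=n_reps,
        site_ids=cm_ref.site_ids,
        null_sim=null_sim,
        null_sne=null_sne,
        seed=seed,
        reference_census=cm_ref.census_label,
    )


def ks_compare(observed, null_replicate) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of two dissimilarity samples.

    Returns (D, p) with D the supremum ECDF difference and the asymptotic
    two-sided p-value.  NaNs are dropped; an empty sample is an error.
    """
    obs = np.asarray(observed, float)
    nul = np.asarray(null_replicate, float)
    obs = obs[~np.isnan(obs)]
    nul = nul[~np.isnan(nul)]
    if obs.size == 0 or nul.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(obs, nul, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def ks_repeated(observed, ensemble: NullEnsemble, component: str = "sim") -> pd.DataFrame:
    """One KS test per null replicate (observed values vs that replicate's values)."""
    null = ensemble.null_sim if component == "sim" else ensemble.null_sne
    rows = [ks_compare(observed, null[r]) for r in range(ensemble.n_reps)]
    return pd.DataFrame(rows, columns=["D", "p"])


def site_significance(
    observed: dict[str, np.ndarray] | pd.DataFrame,
    ensemble: NullEnsemble,
    alpha: float = 0.05,
    min_defined: int = 100,
) -> SignificanceClassification:
    """Classify each site's observed dissimilarity against its null draws.

    Two-sided: "lower" if the observed value falls strictly below the
    alpha/2 empirical percentile of the site's (defined) null draws, "higher"
    if strictly above the 1-alpha/2 percentile, else "ns".  Percentiles use
    the linear-interpolation order-statistic definition.  Sites with fewer
    than ``min_defined`` defined draws are flagged unreliable.
    """
    lo_pct, hi_pct = 100 * alpha / 2, 100 * (1 - alpha / 2)
    rows = []
    for comp, null in (("sim", ensemble.null_sim), ("sne", ensemble.null_sne)):
        obs = np.asarray(observed[comp], float)
        if obs.shape[0] != len(ensemble.site_ids):
            raise ValueError("observed values must cover the ensemble's sites")
        for i, site in enumerate(ensemble.site_ids):
            draws = null[:, i]
            draws = draws[~np.isnan(draws)]
            q_lo, q_hi = np.percentile(draws, [lo_pct, hi_pct])
            if obs[i] < q_lo:
                label = "lower"
            elif obs[i] > q_hi:
                label = "higher"
            else:
                label = "ns"
            rows.append(
                {
                    "site": site,
                    "component": comp,
                    "observed": obs[i],
                    "q_lo": q_lo,
                    "q_hi": q_hi,
                    "label": label,
                    "n_defined": draws.size,
                    "reliable": draws.size >= min_defined,
                }
            )
    return SignificanceClassification(
        labels=pd.DataFrame(rows), alpha=alpha, percentile_bounds=(lo_pct, hi_pct)
    )


def anova_by_class(
    in_class: np.ndarray, land_change: np.ndarray
) -> tuple[float, tuple[int, int], float, float]:
    """One-way two-group ANOVA of per-site land-cover change by membership in
    one significance class versus all other sites.

    Returns (F, (1, n-2), p, r2) with r2 = SS_between / SS_total.  If the
    within-group sum of squares is zero while the means differ, F is inf.
    """
    in_class = np.asarray(in_class, bool)
    y = np.asarray(land_change, float)
    if in_class.shape != y.shape:
        raise ValueError("grouping and values must have the same length")
    n = y.size
    g1, g0 = y[in_class], y[~in_class]
    if g1.size == 0:
        raise ValueError("significance class group is empty")
    if g0.size == 0:
        raise ValueError("complement group is empty")
    grand = y.mean()
    ss_between = g1.size * (g1.mean() - grand) ** 2 + g0.size * (g0.mean() - grand) ** 2
    ss_total = float(np.sum((y - grand) ** 2))
    ss_within = ss_total - ss_between
    df = (1, n - 2)
    if ss_total == 0:
        return 0.0, df, 1.0, 0.0
    if ss_within <= 0:
        return float("inf"), df, 0.0, 1.0
    F = (ss_between / df[0]) / (ss_within / df[1])
    p = float(stats.f.sf(F, *df))
    return float(F), df, p, ss_between / ss_total
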