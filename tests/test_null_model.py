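"""FE reshuffling null model, KS comparisons, percentile tests, ANOVA."""

import itertools

import numpy as np
import pytest

from tempbeta.beta_core import pair_counts, partition_pair
from tempbeta.io_formats import CommunityMatrix
from tempbeta.null_model import (
    anova_by_class,
    fe_reshuffle,
    ks_compare,
    null_dissimilarity_ensemble,
    site_significance,
)


def _cm(occ, label=""):
    occ = np.asarray(occ, dtype=bool)
    return CommunityMatrix(
        site_ids=tuple(range(occ.shape[0])),
        species_ids=tuple(range(occ.shape[1])),
        occ=occ,
        census_label=label,
    )


class TestFeReshuffle:
    def test_column_sums_always_conserved(self, rng, small_cm):
        for _ in range(50):
            shuffled = fe_reshuffle(small_cm, rng)
            assert np.array_equal(
                shuffled.occ.sum(axis=0), small_cm.occ.sum(axis=0)
            )

    def test_ubiquitous_and_absent_species_unchanged(self, rng):
        occ = np.zeros((6, 3), bool)
        occ[:, 0] = True  # everywhere
        occ[2, 2] = True
        cm = _cm(occ)
        shuffled = fe_reshuffle(cm, rng)
        assert shuffled.occ[:, 0].all()
        assert not shuffled.occ[:, 1].any()

    def test_site_assignment_uniform(self, rng):
        """Each site receives a 2-of-6 species' presence with equal frequency."""
        occ = np.zeros((6, 1), bool)
        occ[:2, 0] = True
        cm = _cm(occ)
        counts = np.zeros(6)
        n = 3000
        for _ in range(n):
            counts += fe_reshuffle(cm, rng).occ[:, 0]
        expected = n * 2 / 6
        # binomial sd ~ sqrt(n p (1-p)) ≈ 25; allow 4 sd
        assert np.all(np.abs(counts - expected) < 4 * np.sqrt(n * (2 / 6) * (4 / 6)))


class TestNullEnsemble:
    def test_full_matrix_source_is_deterministic(self):
        ref = _cm([[1, 0], [0, 1], [1, 1]])
        full = _cm(np.ones((3, 2)))
        ens = null_dissimilarity_ensemble(ref, full, n_reps=5, seed=0)
        expected = [
            partition_pair(pair_counts(ref.occ[i], np.ones(2, bool)))
            for i in range(3)
        ]
        for r in range(5):
            assert ens.null_sim[r] == pytest.approx([e.sim for e in expected])
            assert ens.null_sne[r] == pytest.approx([e.sne for e in expected])

    def test_seed_reproducibility(self, paired_cms):
        cm1, cm2 = paired_cms
        e1 = null_dissimilarity_ensemble(cm1, cm2, n_reps=20, seed=9)
        e2 = null_dissimilarity_ensemble(cm1, cm2, n_reps=20, seed=9)
        assert np.array_equal(e1.null_sim, e2.null_sim, equal_nan=True)
        assert np.array_equal(e1.null_sne, e2.null_sne, equal_nan=True)

    def test_invalid_n_reps(self, paired_cms):
        with pytest.raises(ValueError):
            null_dissimilarity_ensemble(*paired_cms, n_reps=0)

    def test_mean_matches_exhaustive_enumeration(self):
        """Monte-Carlo per-site mean null turnover vs the exact mean over all
        possible reshuffles of a 5-site x 3-species system."""
        ref = _cm([[1, 1, 0], [1, 0, 1], [0, 1, 0], [1, 0, 0], [0, 1, 1]])
        src = _cm([[1, 0, 1], [1, 1, 0], [0, 0, 1], [0, 1, 0], [1, 0, 0]])
        n_sites = 5
        freqs = src.occ.sum(axis=0)
        per_species_subsets = [
            list(itertools.combinations(range(n_sites), int(k))) for k in freqs
        ]
        sums = np.zeros(n_sites)
        counts = np.zeros(n_sites)
        for combo in itertools.product(*per_species_subsets):
            null = np.zeros((n_sites, 3), bool)
            for j, subset in enumerate(combo):
                null[list(subset), j] = True
            for i in range(n_sites):
                if not null[i].any():
                    continue  # NaN draw, excluded
                comp = partition_pair(pair_counts(ref.occ[i], null[i]))
                sums[i] += comp.sim
                counts[i] += 1
        exact_mean = sums / counts

        ens = null_dissimilarity_ensemble(ref, src, n_reps=10_000, seed=3)
        mc_mean = np.nanmean(ens.null_sim, axis=0)
        # MC standard error of a [0,1] mean at n=1e4 is < 0.005; allow 4 se
        assert mc_mean == pytest.approx(exact_mean, abs=0.02)


class TestKsCompare:
    def test_identical_samples_d_zero(self):
        x = [0.1, 0.5, 0.9]
        d, _ = ks_compare(x, x)
        assert d == 0.0

    def test_disjoint_supports_d_one(self):
        d, p = ks_compare([0.1, 0.2], [0.8, 0.9])
        assert d == 1.0 and p < 0.5

    def test_ecdf_example(self):
        d, _ = ks_compare([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        assert d == pytest.approx(1 / 3)

    def test_invariant_to_joint_monotone_relabeling(self, rng):
        x, y = rng.random(40), rng.random(35)
        d1, _ = ks_compare(x, y)
        d2, _ = ks_compare(np.sqrt(x), np.sqrt(y))  # strictly increasing map
        assert d1 == pytest.approx(d2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [0.1])


def _make_ensemble(null_sim, null_sne, site_ids):
    from tempbeta.null_model import NullEnsemble

    return NullEnsemble(
        n_reps=null_sim.shape[0],
        site_ids=site_ids,
        null_sim=null_sim,
        null_sne=null_sne,
        seed=0,
    )


class TestSiteSignificance:
    def test_observed_equal_to_all_draws_is_ns(self):
        null = np.full((1000, 1), 0.4)
        ens = _make_ensemble(null, null, ("S1",))
        cls = site_significance({"sim": [0.4], "sne": [0.4]}, ens)
        assert set(cls.labels["label"]) == {"ns"}

    def test_observed_above_all_draws_is_higher(self, rng):
        null = rng.random((1000, 1)) * 0.5
        ens = _make_ensemble(null, null, ("S1",))
        cls = site_significance({"sim": [0.9], "sne": [0.01]}, ens)
        by_comp = cls.labels.set_index("component")["label"]
        assert by_comp["sim"] == "higher"
        assert by_comp["sne"] == "lower"

    def test_exact_percentile_value_is_ns(self):
        """Strict inequality: sitting exactly on the 2.5th percentile is ns."""
        draws = np.linspace(0, 1, 1000)[:, None]
        ens = _make_ensemble(draws, draws, ("S1",))
        q_lo = np.percentile(draws[:, 0], 2.5)
        cls = site_significance({"sim": [q_lo], "sne": [0.5]}, ens)
        assert cls.labels.set_index("component")["label"]["sim"] == "ns"

    def test_unreliable_flag_for_few_defined_draws(self):
        null = np.full((1000, 1), np.nan)
        null[:50, 0] = 0.3
        ens = _make_ensemble(null, null, ("S1",))
        cls = site_significance({"sim": [0.3], "sne": [0.3]}, ens)
        assert not cls.labels["reliable"].any()
        assert (cls.labels["n_defined"] == 50).all()

    def test_determinism_with_identical_seed(self, paired_cms):
        cm1, cm2 = paired_cms
        from tempbeta.beta_core import temporal_partition

        comps = temporal_partition(cm1, cm2)
        obs = {
            "sim": [c.sim for c in comps],
            "sne": [c.sne for c in comps],
        }
        e1 = null_dissimilarity_ensemble(cm1, cm2, n_reps=200, seed=4)
        e2 = null_dissimilarity_ensemble(cm1, cm2, n_reps=200, seed=4)
        c1 = site_significance(obs, e1)
        c2 = site_significance(obs, e2)
        assert c1.labels["label"].tolist() == c2.labels["label"].tolist()


class TestAnovaByClass:
    def test_identical_group_means_give_f_zero(self):
        f, df, p, r2 = anova_by_class(
            np.array([True, True, False, False]), np.array([1.0, 2.0, 1.0, 2.0])
        )
        assert f == 0.0 and r2 == 0.0 and df == (1, 2)

    def test_degenerate_zero_within_variance(self):
        f, df, p, r2 = anova_by_class(
            np.array([True, True, False, False]), np.array([0.0, 0.0, 1.0, 1.0])
        )
        assert np.isinf(f) and r2 == 1.0

    def test_hand_computed_example(self):
        f, df, p, r2 = anova_by_class(
            np.array([True] * 3 + [False] * 3),
            np.array([1.0, 2.0, 3.0, 2.0, 3.0, 4.0]),
        )
        assert f == pytest.approx(1.5)
        assert df == (1, 4)
        assert r2 == pytest.approx(1.5 / (1.5 + 4))

    def test_empty_group_named_in_error(self):
        with pytest.raises(ValueError, match="class"):
            anova_by_class(np.zeros(4, bool), np.arange(4.0))
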