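"""Pairwise and multiple-site dissimilarity partitioning."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tempbeta.beta_core import (
    BetaComponents,
    PairCounts,
    UndefinedDissimilarityError,
    multisite_partition,
    pair_counts,
    partition_pair,
    spatial_pairwise,
    temporal_partition,
)
from tempbeta.io_formats import CommunityMatrix


def _cm(occ, label=""):
    occ = np.asarray(occ, dtype=bool)
    return CommunityMatrix(
        site_ids=tuple(range(occ.shape[0])),
        species_ids=tuple(range(occ.shape[1])),
        occ=occ,
        census_label=label,
    )


class TestPairCounts:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 1, 0), (1, 0, 1), (1, 1, 1)),
            ((1, 1, 1), (1, 1, 1), (3, 0, 0)),
            ((0, 0), (1, 1), (0, 0, 2)),
        ],
    )
    def test_counting(self, x, y, expected):
        assert pair_counts(np.array(x), np.array(y)) == PairCounts(*expected)

    def test_commutes_by_swapping_exclusives(self, rng):
        x, y = rng.random(30) < 0.4, rng.random(30) < 0.4
        pc, qc = pair_counts(x, y), pair_counts(y, x)
        assert (pc.a, pc.b, pc.c) == (qc.a, qc.c, qc.b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            pair_counts(np.ones(3, bool), np.ones(4, bool))


class TestPartitionPair:
    @pytest.mark.parametrize(
        "pc, expected",
        [
            (PairCounts(1, 1, 1), (0.5, 0.5, 0.0)),
            (PairCounts(2, 3, 0), (3 / 7, 0.0, 3 / 7)),  # pure nestedness
            (PairCounts(0, 2, 3), (1.0, 1.0, 0.0)),      # disjoint assemblages
            (PairCounts(0, 0, 3), (1.0, 0.0, 1.0)),      # one empty: nested limit
        ],
    )
    def test_formula(self, pc, expected):
        comp = partition_pair(pc)
        assert comp == pytest.approx(BetaComponents(*expected))

    def test_two_empty_assemblages_undefined(self):
        with pytest.raises(UndefinedDissimilarityError):
            partition_pair(PairCounts(0, 0, 0))

    @given(
        a=st.integers(0, 50), b=st.integers(0, 50), c=st.integers(0, 50)
    )
    @settings(derandomize=True, max_examples=300)
    def test_additivity_and_bounds(self, a, b, c):
        """sor = sim + sne exactly, with 0 <= sim <= sor <= 1 and sne >= 0."""
        if a == b == c == 0:
            return
        comp = partition_pair(PairCounts(a, b, c))
        assert abs(comp.sor - (comp.sim + comp.sne)) < 1e-12
        assert 0.0 <= comp.sim <= comp.sor <= 1.0
        assert comp.sne >= 0.0

    def test_nestedness_monotone_in_richness_difference(self):
        """For fixed shared count and no replacement, sne grows with the
        size of the nested richness gap."""
        a = 4
        sne = [partition_pair(PairCounts(a, 0, c)).sne for c in range(0, 20)]
        assert all(x < y for x, y in zip(sne, sne[1:]))


class TestTemporalPartition:
    def test_identical_censuses_give_zero(self, small_cm):
        comps = temporal_partition(small_cm, small_cm)
        assert all(c == (0.0, 0.0, 0.0) for c in comps)

    def test_single_site_example(self):
        cm1, cm2 = _cm([[1, 1, 0]]), _cm([[1, 0, 1]])
        (comp,) = temporal_partition(cm1, cm2)
        assert comp == pytest.approx((0.5, 0.5, 0.0))

    def test_matches_per_site_pairwise_oracle(self, paired_cms):
        cm1, cm2 = paired_cms
        comps = temporal_partition(cm1, cm2)
        for i, comp in enumerate(comps):
            expected = partition_pair(pair_counts(cm1.occ[i], cm2.occ[i]))
            assert comp == pytest.approx(expected, abs=1e-15)


class TestSpatialPairwise:
    def test_identical_sites_give_zero_matrices(self):
        cm = _cm([[1, 0, 1]] * 4)
        mats = spatial_pairwise(cm)
        for m in mats.values():
            assert np.allclose(m.values, 0.0)

    def test_two_sites_match_pairwise(self):
        cm = _cm([[1, 1, 0, 0], [0, 1, 1, 1]])
        mats = spatial_pairwise(cm)
        expected = partition_pair(pair_counts(cm.occ[0], cm.occ[1]))
        for label in ("sor", "sim", "sne"):
            assert mats[label].values[0, 1] == pytest.approx(getattr(expected, label))

    def test_matches_brute_force_loops(self, small_cm):
        mats = spatial_pairwise(small_cm)
        n = small_cm.n_sites
        for i, j in itertools.combinations(range(n), 2):
            exp = partition_pair(pair_counts(small_cm.occ[i], small_cm.occ[j]))
            for label in ("sor", "sim", "sne"):
                assert mats[label].values[i, j] == pytest.approx(
                    getattr(exp, label), abs=1e-12
                )
                assert mats[label].values[j, i] == mats[label].values[i, j]

    def test_empty_pair_conventions(self):
        cm = _cm([[0, 0], [0, 0], [1, 1]])
        mats = spatial_pairwise(cm)
        assert np.isnan(mats["sor"].values[0, 1])  # two empty: undefined
        # one empty: nested limit sor=1, sim=0, sne=1
        assert mats["sor"].values[0, 2] == 1.0
        assert mats["sim"].values[0, 2] == 0.0
        assert mats["sne"].values[0, 2] == 1.0


def _multisite_oracle(occ):
    """Direct evaluation of the multiple-site summation formulas."""
    occ = np.asarray(occ, bool)
    n = occ.shape[0]
    sum_Si = sum(int(occ[i].sum()) for i in range(n))
    S_T = int(occ.any(axis=0).sum())
    s_min = s_max = 0
    for i, j in itertools.combinations(range(n), 2):
        b_ij = int((occ[i] & ~occ[j]).sum())
        b_ji = int((occ[j] & ~occ[i]).sum())
        s_min += min(b_ij, b_ji)
        s_max += max(b_ij, b_ji)
    SIM = s_min / ((sum_Si - S_T) + s_min)
    SOR = (s_min + s_max) / (2 * (sum_Si - S_T) + s_min + s_max)
    return SOR, SIM, SOR - SIM


class TestMultisitePartition:
    def test_two_site_reduction_is_exact(self, rng):
        for _ in range(20):
            occ = rng.random((2, 12)) < 0.5
            if not occ.any():
                continue
            ms = multisite_partition(_cm(occ))
            pw = partition_pair(pair_counts(occ[0], occ[1]))
            assert (ms.SOR, ms.SIM, ms.SNE) == pytest.approx(pw, abs=1e-15)

    def test_identical_sites_give_zero(self):
        ms = multisite_partition(_cm([[1, 0, 1]] * 5))
        assert (ms.SOR, ms.SIM, ms.SNE) == (0.0, 0.0, 0.0)

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            occ = rng.random((6, 12)) < 0.4
            if not occ.any():
                continue
            ms = multisite_partition(_cm(occ))
            assert (ms.SOR, ms.SIM, ms.SNE) == pytest.approx(
                _multisite_oracle(occ), abs=1e-12
            )
            assert abs(ms.SOR - (ms.SIM + ms.SNE)) < 1e-12

    def test_invariant_under_row_and_column_permutation(self, rng, small_cm):
        ms = multisite_partition(small_cm)
        perm_occ = small_cm.occ[rng.permutation(10)][:, rng.permutation(8)]
        ms_p = multisite_partition(_cm(perm_occ))
        assert (ms.SOR, ms.SIM, ms.SNE) == pytest.approx((ms_p.SOR, ms_p.SIM, ms_p.SNE))

    def test_all_empty_is_undefined(self):
        with pytest.raises(UndefinedDissimilarityError):
            multisite_partition(_cm(np.zeros((3, 4))))
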