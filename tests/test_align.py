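"""Quantile binning, DP alignment optimality and the dScore calibration."""

import numpy as np
import pytest
from scipy.stats import norm

from eprofiler.align import (AlignConfig, align_profiles, build_binner,
                             dscore, global_align, local_align, pair_score,
                             permutation_mean, x_opt)
from eprofiler.align import _score_matrix
from eprofiler.errors import (DegenerateDistributionError,
                              DegenerateNullError)
from eprofiler.profile import EnergyProfile, ProfileEntry
from eprofiler.synthetic import perturb_profile

from oracles import brute_global, brute_local


def _profile(energies, pid="p"):
    return EnergyProfile(id=pid, entries=[
        ProfileEntry("A", i + 1, "A", float(e)) for i, e in enumerate(energies)
    ])


@pytest.fixture(scope="module")
def std_binner():
    rng = np.random.default_rng(0)
    return build_binner(rng.normal(size=5000), n_bins=20)


class TestBinner:
    def test_two_bins_split_at_fitted_mean(self):
        rng = np.random.default_rng(1)
        sample = rng.normal(3.0, 2.0, size=1000)
        b = build_binner(sample, n_bins=2)
        assert b.boundaries[0] == pytest.approx(sample.mean())

    def test_quartile_boundaries_match_normal_quantiles(self):
        rng = np.random.default_rng(2)
        sample = rng.normal(size=4000)
        b = build_binner(sample, n_bins=4)
        mean, sd = sample.mean(), sample.std(ddof=1)
        np.testing.assert_allclose(
            b.boundaries, norm.ppf([0.25, 0.5, 0.75], mean, sd), atol=1e-12)
        np.testing.assert_allclose(b.boundaries, [-0.6745, 0.0, 0.6745],
                                   atol=0.1)
        assert np.all(np.diff(b.boundaries) > 0)

    def test_location_equivariance(self):
        rng = np.random.default_rng(3)
        sample = rng.normal(size=500)
        b0 = build_binner(sample, n_bins=10)
        b1 = build_binner(sample + 7.5, n_bins=10)
        np.testing.assert_allclose(b1.boundaries, b0.boundaries + 7.5,
                                   atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            build_binner([1.0, 1.0, 1.0])


class TestPairScore:
    def test_identical_energy_attains_delta(self, std_binner):
        assert pair_score(0.3, 0.3, std_binner, s_max=20.0) == 20.0

    def test_adjacent_bins(self, std_binner):
        lo, hi = std_binner.boundaries[4] - 1e-6, std_binner.boundaries[4] + 1e-6
        assert pair_score(lo, hi, std_binner, s_max=20.0) == 19.0

    def test_symmetry_and_edge_clamping(self, std_binner):
        assert pair_score(-50.0, 50.0, std_binner) == \
            pair_score(50.0, -50.0, std_binner)
        # far outside the sample range: extreme bins, distance n_bins-1
        assert pair_score(-50.0, 50.0, std_binner, s_max=20.0) == 1.0


class TestDP:
    def test_self_alignment_attains_x_opt(self, std_binner):
        e = np.random.default_rng(5).normal(size=40)
        res = global_align(e, e, std_binner, s_max=20.0, gap_penalty=10.0)
        assert res.x_r == pytest.approx(20.0 * 40)
        assert res.x_r == pytest.approx(x_opt(40, 40, 20.0))

    def test_length_one_alignment(self, std_binner):
        res = global_align([0.2], [0.2], std_binner, s_max=20.0)
        assert res.pairs == [(0, 0)] and res.x_r == 20.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, std_binner, seed):
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(1, 6, size=2)
        a, b = rng.normal(size=na), rng.normal(size=nb)
        S = _score_matrix(std_binner.bin_of(a), std_binner.bin_of(b), 20.0)
        g = global_align(a, b, std_binner, s_max=20.0, gap_penalty=10.0)
        l = local_align(a, b, std_binner, s_max=20.0, gap_penalty=10.0)
        assert g.x_r == pytest.approx(brute_global(S, 10.0))
        assert l.x_r == pytest.approx(brute_local(S, 10.0))

    def test_local_identical_profiles_full_length(self, std_binner):
        e = np.random.default_rng(6).normal(size=15)
        res = local_align(e, e, std_binner, s_max=20.0, gap_penalty=10.0)
        assert len(res.pairs) == 15
        assert res.x_r == pytest.approx(20.0 * 15)

    def test_local_empty_when_all_pairs_negative(self, std_binner):
        # opposite extreme bins with small s_max: every pair scores < 0
        a = np.full(6, -50.0)
        b = np.full(6, 50.0)
        res = local_align(a, b, std_binner, s_max=10.0, gap_penalty=100.0)
        assert res.pairs == [] and res.x_r == 0.0

    def test_alignment_indices_strictly_increasing(self, std_binner):
        rng = np.random.default_rng(7)
        res = global_align(rng.normal(size=30), rng.normal(size=25),
                           std_binner)
        a_idx = [i for i, _ in res.pairs if i is not None]
        b_idx = [j for _, j in res.pairs if j is not None]
        assert a_idx == sorted(a_idx) == list(range(30))
        assert b_idx == sorted(b_idx) == list(range(25))


class TestPermutationNull:
    def test_length_one_equals_raw_score(self, std_binner):
        m = permutation_mean([0.1], [0.4], std_binner, 20.0, 10.0,
                             n_perm=10, seed=0)
        assert m == global_align([0.1], [0.4], std_binner, 20.0, 10.0).x_r

    def test_deterministic_under_seed(self, std_binner):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=20), rng.normal(size=22)
        m1 = permutation_mean(a, b, std_binner, 20.0, 10.0, n_perm=30, seed=5)
        m2 = permutation_mean(a, b, std_binner, 20.0, 10.0, n_perm=30, seed=5)
        assert m1 == m2

    def test_bounded_by_x_opt(self, std_binner):
        rng = np.random.default_rng(9)
        for _ in range(5):
            na, nb = rng.integers(2, 25, size=2)
            a, b = rng.normal(size=na), rng.normal(size=nb)
            m = permutation_mean(a, b, std_binner, 20.0, 10.0, n_perm=20,
                                 seed=1)
            assert m <= x_opt(na, nb, 20.0) + 1e-9


class TestDScore:
    def test_perfect_alignment_is_zero(self):
        assert dscore(100.0, 100.0, 40.0) == 0.0

    def test_ratio_one_tenth_is_one_ban(self):
        assert dscore(50.0, 140.0, 40.0) == pytest.approx(1.0)

    def test_null_level_hits_cap(self):
        assert dscore(40.0, 140.0, 40.0) == 10.0
        assert dscore(10.0, 140.0, 40.0) == 10.0

    def test_degenerate_null_rejected(self):
        with pytest.raises(DegenerateNullError):
            dscore(50.0, 100.0, 100.0)


class TestAlignProfiles:
    def test_self_alignment_zero_bans_significant(self, helix60_profile):
        res = align_profiles(helix60_profile, helix60_profile,
                             AlignConfig(n_perm=50, seed=42))
        assert res.dscore == 0.0 and res.significant

    def test_reproducible_under_seed(self, helix60_profile):
        noisy = perturb_profile(helix60_profile, 3.0, seed=1)
        cfg = AlignConfig(n_perm=40, seed=13)
        r1 = align_profiles(helix60_profile, noisy, cfg)
        r2 = align_profiles(helix60_profile, noisy, cfg)
        assert (r1.x_r, r1.perm_mean, r1.dscore) == \
            (r2.x_r, r2.perm_mean, r2.dscore)

    def test_symmetry(self, helix60_profile):
        other = perturb_profile(helix60_profile, 5.0, seed=2)
        other = other.with_energies(other.energies, id="other")
        cfg = AlignConfig(n_perm=40, seed=21)
        ab = align_profiles(helix60_profile, other, cfg)
        ba = align_profiles(other, helix60_profile, cfg)
        assert ab.dscore == ba.dscore
        assert ab.perm_mean == ba.perm_mean

    def test_shuffled_copy_not_significant(self, helix60_profile):
        rng = np.random.default_rng(3)
        shuffled = helix60_profile.with_energies(
            rng.permutation(helix60_profile.energies), id="shuffled")
        res = align_profiles(helix60_profile, shuffled,
                             AlignConfig(n_perm=100, seed=17))
        assert res.dscore > 2.5 and not res.significant

    def test_dscore_median_monotone_in_noise(self, helix60_profile):
        medians = []
        for sd in (0.0, 2.0, 8.0, 32.0):
            scores = []
            for rep in range(10):
                noisy = perturb_profile(helix60_profile, sd,
                                        seed=1000 + rep)
                noisy = noisy.with_energies(noisy.energies, id="noisy")
                res = align_profiles(helix60_profile, noisy,
                                     AlignConfig(n_perm=30, seed=rep))
                scores.append(res.dscore)
            medians.append(float(np.median(scores)))
        assert medians[0] == 0.0
        assert all(m2 >= m1 - 1e-9 for m1, m2 in zip(medians, medians[1:]))
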