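"""Distance matrices, UPGMA guide trees, progressive alignment, rendering."""

import numpy as np
import pytest

from eprofiler.align import AlignConfig, build_binner, global_align
from eprofiler.mepal import (DistanceMatrix, consensus_energy, conservation,
                             distance_matrix, mepal, progressive_align,
                             render_mepal, upgma)
from eprofiler.profile import EnergyProfile, ProfileEntry
from eprofiler.synthetic import perturb_profile

from oracles import reference_upgma


def _profile(energies, pid="p"):
    return EnergyProfile(id=pid, entries=[
        ProfileEntry("A", i + 1, "A", float(e)) for i, e in enumerate(energies)
    ])


CFG = AlignConfig(n_perm=30, seed=11)


class TestDistanceMatrix:
    def test_identical_profiles_zero_distance(self, helix60_profile):
        dm = distance_matrix([helix60_profile, helix60_profile], CFG)
        assert dm.matrix[0, 1] == 0.0

    def test_copies_give_all_zero_matrix(self, helix60_profile):
        dm = distance_matrix([helix60_profile] * 3, CFG)
        np.testing.assert_array_equal(dm.matrix, np.zeros((3, 3)))
        assert len(set(dm.labels)) == 3  # disambiguated

    def test_symmetric_with_zero_diagonal(self, helix60_profile):
        others = [perturb_profile(helix60_profile, sd, seed=3)
                  for sd in (2.0, 6.0)]
        dm = distance_matrix([helix60_profile, *others], CFG)
        np.testing.assert_array_equal(dm.matrix, dm.matrix.T)
        np.testing.assert_array_equal(np.diag(dm.matrix), np.zeros(3))
        assert (dm.matrix >= 0).all()


def _canonical_merges(merges):
    return [({frozenset(a), frozenset(b)}, pytest.approx(h, abs=1e-9))
            for a, b, h in merges]


class TestUpgma:
    def test_three_leaf_hand_example(self):
        dm = DistanceMatrix(labels=["A", "B", "C"], matrix=np.array([
            [0.0, 2.0, 8.0],
            [2.0, 0.0, 8.0],
            [8.0, 8.0, 0.0],
        ]))
        tree = upgma(dm)
        merges = tree.merge_order()
        assert sorted(merges[0][0] + merges[0][1]) == ["A", "B"]
        assert merges[0][2] == pytest.approx(1.0)
        assert merges[1][2] == pytest.approx(4.0)
        assert tree.height == pytest.approx(4.0)

    def test_equal_distances_merge_lexicographically(self):
        labels = ["delta", "alpha", "charlie", "bravo"]
        dm = DistanceMatrix(labels=labels, matrix=np.ones((4, 4))
                            - np.eye(4))
        tree = upgma(dm)
        first = tree.merge_order()[0]
        assert sorted(first[0] + first[1]) == ["alpha", "bravo"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_agglomeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        m = rng.uniform(0.1, 10.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = [f"p{k}" for k in range(n)]
        tree = upgma(DistanceMatrix(labels=labels, matrix=m))
        got = tree.merge_order()
        want = reference_upgma(labels, m)
        assert len(got) == len(want)
        for (ga, gb, gh), (wa, wb, wh) in zip(got, want):
            assert {frozenset(ga), frozenset(gb)} == \
                {frozenset(wa), frozenset(wb)}
            assert gh == pytest.approx(wh, abs=1e-9)

    def test_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        rng = np.random.default_rng(42)
        m = rng.uniform(1, 5, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        tree = upgma(DistanceMatrix([f"x{i}" for i in range(6)], m))
        ours = sorted(2 * h for _, _, h in tree.merge_order())
        scipys = sorted(linkage(squareform(m), method="average")[:, 2])
        np.testing.assert_allclose(ours, scipys, atol=1e-9)

    def test_heights_non_decreasing_toward_root(self):
        rng = np.random.default_rng(7)
        m = rng.uniform(0.5, 3.0, size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        tree = upgma(DistanceMatrix([f"y{i}" for i in range(5)], m))
        heights = [h for _, _, h in tree.merge_order()]
        assert heights == sorted(heights)

    def test_nan_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        from eprofiler.errors import EprofilerError
        with pytest.raises(EprofilerError):
            upgma(DistanceMatrix(["a", "b"], m))


class TestProgressive:
    def test_identical_profiles_gap_free(self, helix60_profile):
        result = mepal([helix60_profile] * 3, CFG)
        msa = result.alignment
        assert msa.n_columns == len(helix60_profile)
        for lab in msa.labels:
            assert None not in msa.rows[lab]
        for c in range(msa.n_columns):
            energies = msa.column_energies(c)
            assert len(set(energies)) == 1
            assert msa.consensus[c] == energies[0]
        assert all(v == 1.0 for v in msa.conservation)

    def test_two_profiles_match_pairwise_alignment(self, helix60_profile):
        other = perturb_profile(helix60_profile, 4.0, seed=5)
        other = other.with_energies(other.energies, id="other")
        result = mepal([helix60_profile, other], CFG)
        msa = result.alignment
        sample = np.sort(np.concatenate([helix60_profile.energies,
                                         other.energies]))
        binner = build_binner(sample, n_bins=CFG.n_bins)
        pairwise = global_align(helix60_profile.energies, other.energies,
                                binner, s_max=CFG.effective_s_max,
                                gap_penalty=CFG.effective_gap)
        got = list(zip(msa.rows[msa.labels[0]], msa.rows[msa.labels[1]]))
        assert got == pairwise.pairs

    def test_column_count_bounds(self, helix60_profile):
        short = _profile(helix60_profile.energies[:30], pid="short")
        result = mepal([helix60_profile, short, helix60_profile], CFG)
        assert result.alignment.n_columns >= len(helix60_profile)

    def test_entry_order_preserved_per_profile(self, helix60_profile):
        noisy = [perturb_profile(helix60_profile, sd, seed=i)
                 for i, sd in enumerate((1.0, 3.0, 9.0))]
        result = mepal([helix60_profile, *noisy], CFG)
        for lab, row in result.alignment.rows.items():
            non_gap = [i for i in row if i is not None]
            assert non_gap == sorted(non_gap)
            assert len(non_gap) == len(result.alignment.profiles[lab])


@pytest.fixture(scope="module")
def binner():
    rng = np.random.default_rng(0)
    return build_binner(rng.normal(size=5000), n_bins=20)


class TestConsensusConservation:

    def test_identical_column(self, binner):
        assert consensus_energy([0.4, 0.4, 0.4], binner, 20.0) == 0.4
        assert conservation([0.4, 0.4, 0.4], binner, 20.0) == 1.0

    def test_majority_bin_wins(self, binner):
        # two members in one bin, one member far away: enumerating the
        # candidate sums shows either close member beats the outlier
        close = binner.boundaries[2] + 1e-6
        outlier = binner.boundaries[15] + 1e-6
        col = [close, close, outlier]
        assert consensus_energy(col, binner, 20.0) == close

    def test_tie_breaks_toward_lower_energy(self, binner):
        lo = binner.boundaries[4] - 1e-6
        hi = binner.boundaries[9] + 1e-6
        assert consensus_energy([hi, lo], binner, 20.0) == lo

    def test_single_member(self, binner):
        assert consensus_energy([1.7], binner, 20.0) == 1.7
        assert conservation([1.7], binner, 20.0) == 1.0

    def test_extreme_bins_conservation(self, binner):
        lo, hi = -100.0, 100.0  # bins 0 and 19
        assert conservation([lo, hi], binner, 20.0) == pytest.approx(0.05)

    def test_never_exceeds_one(self, binner):
        rng = np.random.default_rng(4)
        for _ in range(20):
            col = rng.normal(size=rng.integers(2, 6))
            assert 0.0 <= conservation(col, binner, 20.0) <= 1.0


class TestRender:
    def test_identical_profiles_max_conservation_glyph(self, helix60_profile):
        result = mepal([helix60_profile] * 2, CFG)
        text = render_mepal(result.alignment)
        cons_lines = [ln for ln in text.splitlines()
                      if ln.startswith("conservation")]
        glyphs = "".join(ln.split(None, 1)[1] for ln in cons_lines)
        assert set(glyphs) == {"@"}

    def test_gaps_rendered_and_columns_parse_back(self, helix60_profile):
        short = _profile(helix60_profile.energies[:30], pid="short")
        result = mepal([helix60_profile, short], CFG)
        text = render_mepal(result.alignment)
        assert "-" in text
        header_cols = int(text.splitlines()[0].split("columns=")[1])
        label = result.alignment.labels[0]
        seq_rows = [ln for ln in text.splitlines()
                    if ln.startswith(label + " ")]
        reparsed = sum(len(ln.split(None, 1)[1]) for ln in seq_rows)
        assert header_cols == result.alignment.n_columns == reparsed

    def test_newick_contains_all_labels(self, helix60_profile):
        others = [perturb_profile(helix60_profile, sd, seed=9)
                  for sd in (2.0, 5.0)]
        result = mepal([helix60_profile, *others], CFG)
        nwk = result.tree.newick()
        assert nwk.endswith(";")
        for lab in result.distances.labels:
            assert lab in nwk
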