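"""Distances, AMOVA, pairwise Phi, PCoA and Mantel tests."""

import numpy as np
import pandas as pd
import pytest

from conftest import amova_oracle
from selfmeth.core_io import MISSING, GenotypeMatrix
from selfmeth.differentiation import (
    DistanceMatrix,
    amova,
    binary_distance,
    mantel,
    msat_distance,
    pairwise_phi,
    pcoa,
)


def dm_from(arr, ids=None):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"i{k}" for k in range(arr.shape[0])]
    return DistanceMatrix(ids, arr)


class TestBinaryDistance:
    def test_identical_complementary_and_half(self):
        x = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 0, 1]],
            index=list("abcd"), dtype=float,
        )
        d = binary_distance(x).d
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0
        assert d[0, 3] == 0.5

    def test_missing_cells_reduce_denominator(self):
        x = pd.DataFrame([[1, np.nan, 0], [1, 1, 1]], index=["a", "b"])
        assert binary_distance(x).d[0, 1] == pytest.approx(0.5)

    def test_no_joint_columns_raises(self):
        x = pd.DataFrame([[1, np.nan], [np.nan, 1]], index=["a", "b"])
        with pytest.raises(ValueError, match="jointly scored"):
            binary_distance(x)


class TestMsatDistance:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            ([1, 1], [1, 1], 0),  # identical homozygotes
            ([1, 1], [2, 2], 2),  # no shared alleles
            ([1, 2], [1, 3], 1),  # one shared, one mismatched
            ([1, 2], [1, 2], 0),
            ([1, 1], [1, 2], 1),
            ([1, 2], [2, 3], 1),
        ],
    )
    def test_allelic_mismatch_per_locus(self, c1, c2, expected):
        g = GenotypeMatrix(
            ["a", "b"], ["s", "s"], ["L"], np.array([[c1], [c2]])
        )
        assert msat_distance(g).d[0, 1] == expected

    def test_missing_loci_excluded(self):
        calls = np.array(
            [[[1, 1], [3, 4]], [[2, 2], [MISSING, MISSING]]]
        )
        g = GenotypeMatrix(["a", "b"], ["s", "s"], ["L1", "L2"], calls)
        assert msat_distance(g).d[0, 1] == 2.0  # only L1 jointly scored


class TestAmova:
    def test_clonal_groups_phi_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        res = amova(dm_from(d), ["a", "a", "b", "b"], n_perm=99, seed=1)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among + res.pct_within == pytest.approx(100.0)

    def test_all_identical_is_undefined(self):
        res = amova(dm_from(np.zeros((4, 4))), ["a", "a", "b", "b"], n_perm=99, seed=1)
        assert np.isnan(res.phi_st)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_small_n(self, seed):
        """Phi_ST equals the loop-based variance-component oracle to 1e-10
        on random instances with N <= 12 and unequal group sizes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        pts = rng.random((n, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        k = int(rng.integers(2, 4))
        groups = [f"g{i % k}" for i in range(n)]
        res = amova(dm_from(d), groups, n_perm=0)
        assert res.phi_st == pytest.approx(amova_oracle(d, groups), abs=1e-10)

    def test_permutation_p_bounded_and_nonzero(self):
        rng = np.random.default_rng(3)
        pts = rng.random((10, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        res = amova(dm_from(d), ["a"] * 5 + ["b"] * 5, n_perm=199, seed=5)
        assert 1 / 200 <= res.p_value <= 1.0

    def test_strong_divergence_significant(self, study_dataset):
        g, *_ = study_dataset
        sub_idx = np.arange(g.n_individuals)
        dm = msat_distance(g)
        res = amova(dm, list(g.site_labels), n_perm=1000, seed=2)
        assert res.p_value <= 0.001 + 1e-9


class TestPairwisePhi:
    def test_symmetric_and_identical_between_groups(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        out = pairwise_phi(dm_from(d), ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert len(out) == 1
        assert out.iloc[0]["phi_ST"] == pytest.approx(1.0)

    def test_three_groups_give_three_pairs(self):
        rng = np.random.default_rng(0)
        pts = rng.random((9, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        out = pairwise_phi(dm_from(d), ["a", "b", "c"] * 3, n_perm=99, seed=0)
        assert len(out) == 3


class TestPcoa:
    def test_equilateral_triangle_two_equal_axes(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(dm_from(d))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_line_embedding_recovers_spacing(self):
        x = np.array([0.0, 1.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(dm_from(d))
        axis1 = res.coordinates["PCo1"].to_numpy()
        gaps = np.abs(np.diff(axis1))
        np.testing.assert_allclose(gaps, [1.0, 2.0], atol=1e-9)

    def test_duplicate_points_identical_coordinates(self):
        x = np.array([0.0, 0.0, 2.0, 5.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(dm_from(d))
        np.testing.assert_allclose(
            res.coordinates.iloc[0], res.coordinates.iloc[1], atol=1e-9
        )

    def test_matches_skbio(self):
        """Cross-check coordinates against the scikit-bio implementation."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        pts = rng.random((8, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ours = pcoa(dm_from(d))
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            np.sort(ours.eigenvalues[ours.eigenvalues > 1e-8]),
            np.sort(theirs.eigvals.to_numpy()[theirs.eigvals.to_numpy() > 1e-8]),
            rtol=1e-6,
        )


class TestMantel:
    def test_self_correlation_and_affine_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.random((8, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        r, _ = mantel(dm_from(d), dm_from(d), n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        r2, _ = mantel(dm_from(d), dm_from(2.5 * d), n_perm=99, seed=0)
        assert r2 == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="zero-variance"):
            mantel(dm_from(d), dm_from(d), n_perm=99)

    def test_matches_skbio_r(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        p1, p2 = rng.random((7, 2)), rng.random((7, 2))
        d1 = np.sqrt(((p1[:, None] - p1[None, :]) ** 2).sum(-1))
        d2 = np.sqrt(((p2[:, None] - p2[None, :]) ** 2).sum(-1))
        r_ours, _ = mantel(dm_from(d1), dm_from(d2), n_perm=0)
        r_skbio, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1), skbio.DistanceMatrix(d2), permutations=0
        )
        assert r_ours == pytest.approx(r_skbio, abs=1e-10)

    def test_p_never_zero(self):
        rng = np.random.default_rng(10)
        pts = rng.random((10, 2))
        d1 = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        r, p = mantel(dm_from(d1), dm_from(d1), n_perm=199, seed=0)
        assert p >= 1 / 200
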