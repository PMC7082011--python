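import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mitopop import (
    FstMatrix,
    collapse_haplotypes,
    geo_distances,
    haversine_km,
    ibd_regression,
    linearize_fst,
    make_alignment,
    mantel_test,
    mean_significant_fst,
    pairwise_fst,
)
from mitopop.errors import MitopopError
from mitopop.structure import GeoDistanceMatrix


def _two_site_alignment(seqs_a, seqs_b):
    recs = [(f"a{i}", "siteA", s) for i, s in enumerate(seqs_a)]
    recs += [(f"b{i}", "siteB", s) for i, s in enumerate(seqs_b)]
    return make_alignment(recs)


class TestPairwiseFst:
    def test_fixed_difference_gives_one(self):
        aln = _two_site_alignment(["AAAA"] * 5, ["TTTT"] * 5)
        ht = collapse_haplotypes(aln)
        fst = pairwise_fst(ht, n_perm=100, seed=0)
        assert fst.pair("siteA", "siteB")[0] == pytest.approx(1.0)

    def test_identical_pools_near_zero(self):
        rng = np.random.default_rng(2)
        pool = ["AAAA", "AATT", "TTTT", "ATAT"]
        seqs = rng.choice(pool, size=40)
        aln = _two_site_alignment(seqs[:20], seqs[20:])
        ht = collapse_haplotypes(aln)
        fst = pairwise_fst(ht, n_perm=200, seed=3)
        value, p = fst.pair("siteA", "siteB")
        assert abs(value) < 0.15
        assert 0 < p <= 1

    def test_relabeling_invariance(self):
        aln = _two_site_alignment(
            ["AAAA", "AAAA", "AATT"], ["TTTT", "TTTT", "AATT"]
        )
        ht = collapse_haplotypes(aln)
        obs = pairwise_fst(ht, n_perm=100, seed=1).fst
        # permute haplotype rows: identity distances are label-free
        ht2 = collapse_haplotypes(aln)
        order = [2, 0, 1]
        ht2.haplotypes = [ht.haplotypes[i] for i in order]
        ht2.counts = ht.counts[order]
        inv = {o: i for i, o in enumerate(order)}
        ht2.assignments = [inv[a] for a in ht.assignments]
        perm = pairwise_fst(ht2, n_perm=100, seed=1).fst
        assert np.allclose(obs, perm)

    def test_singleton_site_excluded(self):
        recs = [("a1", "siteA", "AAAA"), ("a2", "siteA", "AATT"),
                ("b1", "siteB", "TTTT"), ("b2", "siteB", "TTAA"),
                ("c1", "siteC", "ATAT")]
        ht = collapse_haplotypes(make_alignment(recs))
        with pytest.warns(UserWarning):
            fst = pairwise_fst(ht, n_perm=100, seed=0)
        assert "siteC" not in fst.site_labels

    def test_permutation_p_uniform_under_panmixia(self):
        """Calibration: P ~ Uniform(0,1) when the two sites are one pool.

        Uses the difference-weighted statistic, whose permutation null is
        effectively continuous (the identity flavor ties heavily on small
        discrete samples and is conservative; see the acceptance suite)."""
        from mitopop import pairwise_differences

        rng = np.random.default_rng(8)
        pool = ["".join(rng.choice(list("ACGT"), 25)) for _ in range(12)]
        w = rng.dirichlet(np.ones(12) * 1.5)
        ps = []
        for _ in range(200):
            seqs = rng.choice(pool, size=24, p=w)
            aln = _two_site_alignment(seqs[:12], seqs[12:])
            ht = collapse_haplotypes(aln)
            dm = pairwise_differences(ht)
            fst = pairwise_fst(ht, dm, n_perm=100, seed=int(rng.integers(2**31)))
            ps.append(fst.pair("siteA", "siteB")[1])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestMeanSignificantFst:
    def _matrix(self, vals, ps):
        k = vals.shape[0]
        return FstMatrix([f"s{i}" for i in range(k)], vals, ps, 100, "fst")

    def test_all_significant_equals_plain_mean(self):
        vals = np.array([[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]])
        ps = np.full((3, 3), 0.001)
        assert mean_significant_fst(self._matrix(vals, ps)) == pytest.approx(0.2)

    def test_hand_masked_average(self):
        rng = np.random.default_rng(5)
        k = 5
        vals = np.zeros((k, k))
        ps = np.ones((k, k))
        iu = np.triu_indices(k, 1)
        v = rng.uniform(-0.05, 0.4, len(iu[0]))
        sig = rng.random(len(iu[0])) < 0.6
        vals[iu] = v
        vals = vals + vals.T
        ps[iu] = np.where(sig, 0.01, 0.5)
        ps = np.minimum(ps, ps.T)
        assert mean_significant_fst(self._matrix(vals, ps)) == pytest.approx(
            v[sig].mean()
        )

    def test_no_significant_pairs_is_error(self):
        vals = np.zeros((3, 3))
        ps = np.ones((3, 3))
        with pytest.raises(MitopopError):
            mean_significant_fst(self._matrix(vals, ps))


class TestLinearize:
    @pytest.mark.parametrize(
        "fst,expected", [(0.0, 0.0), (0.5, 1.0), (-0.00739, -0.00739 / 1.00739)]
    )
    def test_closed_form(self, fst, expected):
        assert linearize_fst(fst) == pytest.approx(expected)

    def test_unity_gives_infinity(self):
        assert linearize_fst(1.0) == float("inf")


class TestGeoDistances:
    def test_identical_coordinates_zero(self):
        assert haversine_km(10.0, 20.0, 10.0, 20.0) == pytest.approx(0.0)

    def test_antipodal_half_circumference(self):
        assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(np.pi * 6371.0)

    def test_matches_spherical_law_of_cosines(self):
        lat1, lon1 = 42.33, -8.88
        lat2, lon2 = 28.06, -16.03
        d = haversine_km(lat1, lon1, lat2, lon2)
        p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
        oracle = 6371.0 * np.arccos(
            np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(l2 - l1)
        )
        assert d == pytest.approx(oracle, rel=1e-3)

    def test_frame_interface(self):
        meta = pd.DataFrame(
            {"latitude": [0.0, 0.0], "longitude": [0.0, 1.0], "n": [5, 5]},
            index=pd.Index(["a", "b"], name="site"),
        )
        geo = geo_distances(meta)
        assert geo.km[0, 1] == pytest.approx(111.19, rel=1e-3)


class TestMantel:
    def _random_sym(self, rng, k):
        m = rng.random((k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = self._random_sym(rng, 6)
        Z, r, p = mantel_test(a, a, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_r_affine_invariant_z_not(self):
        rng = np.random.default_rng(1)
        a = self._random_sym(rng, 6)
        b = self._random_sym(rng, 6)
        Z1, r1, _ = mantel_test(a, b, n_perm=99, seed=2)
        Z2, r2, _ = mantel_test(a, 3.0 * b + 1.0, n_perm=99, seed=2)
        assert r1 == pytest.approx(r2)
        assert Z1 != pytest.approx(Z2)

    def test_z_is_upper_triangle_cross_product(self):
        rng = np.random.default_rng(2)
        a = self._random_sym(rng, 5)
        b = self._random_sym(rng, 5)
        Z, _, _ = mantel_test(a, b, n_perm=99, seed=0)
        iu = np.triu_indices(5, 1)
        assert Z == pytest.approx(float(np.sum(a[iu] * b[iu])))

    def test_constant_matrix_rejected(self):
        a = np.zeros((4, 4))
        with pytest.raises(MitopopError):
            mantel_test(a, a, n_perm=99)

    def test_independent_matrices_p_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for i in range(200):
            a = self._random_sym(rng, 7)
            b = self._random_sym(rng, 7)
            _, _, p = mantel_test(a, b, n_perm=100, seed=int(rng.integers(2**31)))
            ps.append(p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestIbdRegression:
    def _fst_from_values(self, labels, values):
        k = len(labels)
        fst = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        fst[iu] = values
        fst = fst + fst.T
        p = np.full((k, k), 0.01)
        return FstMatrix(list(labels), fst, p, 100, "fst")

    def _geo(self, labels, km_vals):
        k = len(labels)
        km = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        km[iu] = km_vals
        return GeoDistanceMatrix(tuple(labels), km + km.T)

    def test_perfectly_collinear_r2_one(self):
        labels = ["a", "b", "c", "d"]
        km = np.array([100.0, 400.0, 900.0, 200.0, 500.0, 300.0])
        slope, icept = 0.05, -0.1
        lin = slope * np.log(km) + icept
        fvals = lin / (1 + lin)  # invert the Slatkin transform
        res = ibd_regression(self._fst_from_values(labels, fvals), self._geo(labels, km),
                             n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(slope)

    def test_matches_normal_equations_oracle(self):
        labels = ["a", "b", "c"]
        km = np.array([150.0, 700.0, 320.0])
        fvals = np.array([0.02, 0.18, 0.07])
        res = ibd_regression(self._fst_from_values(labels, fvals), self._geo(labels, km),
                             n_perm=99, seed=0)
        x = np.log(km)
        y = fvals / (1 - fvals)
        X = np.column_stack([np.ones(3), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0])
        assert res.slope == pytest.approx(beta[1])

    def test_r2_invariant_to_distance_rescaling(self):
        labels = ["a", "b", "c", "d"]
        rng = np.random.default_rng(4)
        km = rng.uniform(100, 2000, 6)
        fvals = rng.uniform(0.0, 0.3, 6)
        m = self._fst_from_values(labels, fvals)
        r1 = ibd_regression(m, self._geo(labels, km), n_perm=99, seed=0)
        r2 = ibd_regression(m, self._geo(labels, 3.7 * km), n_perm=99, seed=0)
        assert r1.r_squared == pytest.approx(r2.r_squared)
        assert r1.slope == pytest.approx(r2.slope)
        assert r1.intercept != pytest.approx(r2.intercept)

    def test_zero_distance_pair_dropped(self):
        labels = ["a", "b", "c"]
        km = np.array([0.0, 700.0, 320.0])
        fvals = np.array([0.02, 0.18, 0.07])
        with pytest.warns(UserWarning):
            with pytest.raises(MitopopError):  # only 2 pairs left
                ibd_regression(self._fst_from_values(labels, fvals),
                               self._geo(labels, km), n_perm=99, seed=0)
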