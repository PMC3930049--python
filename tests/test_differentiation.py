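"""Distance matrices, Mantel machinery, dominant-marker Fst and the neutral
slope envelope."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom as scipy_binom

from mhcpop import simulate
from mhcpop.differentiation import (
    LabeledDistanceMatrix,
    dominant_fst,
    drop_pairs,
    euclidean_presence,
    mantel,
    neutral_slope_envelope,
    partial_mantel,
    standardize01,
)


def ldm_from_condensed(labels, condensed, kind="raw"):
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = condensed
    return LabeledDistanceMatrix(labels, m + m.T, kind)


def random_ldm(rng, n=7):
    labels = [f"P{i}" for i in range(n)]
    return ldm_from_condensed(labels, rng.random(n * (n - 1) // 2))


class TestEuclideanPresence:
    @pytest.mark.parametrize(
        "a,b,expected",
        [((1, 0, 1), (1, 1, 1), 1.0), ((1, 0, 1), (1, 0, 1), 0.0),
         ((1, 0, 0), (0, 1, 0), np.sqrt(2))],
    )
    def test_pairwise_values(self, a, b, expected):
        df = pd.DataFrame([a, b, (0, 0, 0)], index=["x", "y", "z"])
        d = euclidean_presence(df)
        assert d.values[0, 1] == pytest.approx(expected)

    def test_requires_three_populations(self):
        with pytest.raises(ValueError):
            euclidean_presence(pd.DataFrame([[1], [0]], index=["a", "b"]))


class TestStandardize:
    def test_endpoints_and_midpoint(self):
        d = ldm_from_condensed(["a", "b", "c"], [2.0, 5.0, 8.0])
        s = standardize01(d)
        assert sorted(s.condensed()) == pytest.approx([0.0, 0.5, 1.0])
        assert np.all(np.diag(s.values) == 0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        d = random_ldm(rng)
        once = standardize01(d)
        twice = standardize01(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-14)

    def test_range_with_exact_bounds(self):
        rng = np.random.default_rng(4)
        s = standardize01(random_ldm(rng))
        c = s.condensed()
        assert c.min() == 0.0 and c.max() == 1.0
        assert np.all((c >= 0) & (c <= 1))

    def test_degenerate_matrix_rejected(self):
        d = ldm_from_condensed(["a", "b", "c"], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            standardize01(d)


class TestMantel:
    def test_identity_matrices_exact_enumeration(self):
        """Four populations on a line (coords 0,1,3,7): comparing the matrix
        with itself gives R=1 and an exact permutation P of 1/24."""
        coords = np.array([[0, 0], [1, 0], [3, 0], [7, 0]], float)
        g = LabeledDistanceMatrix.from_coords(list("ABCD"), coords)
        b = LabeledDistanceMatrix(list("ABCD"), g.values.copy())
        r = mantel(g, b, exact=True)
        assert r.R == pytest.approx(1.0)
        assert r.P == pytest.approx(1 / 24)

    def test_sampled_p_close_to_exact(self):
        coords = np.array([[0, 0], [1, 0], [3, 0], [7, 0]], float)
        g = LabeledDistanceMatrix.from_coords(list("ABCD"), coords)
        b = LabeledDistanceMatrix(list("ABCD"), g.values.copy())
        exact = mantel(g, b, exact=True).P
        sampled = mantel(g, b, n_perm=10000, seed=11).P
        assert abs(sampled - exact) < 0.01

    def test_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(5)
        a, b = random_ldm(rng), random_ldm(rng)
        ours = mantel(a, b, n_perm=999, seed=1)
        corr, p, _ = sk_mantel(
            DistanceMatrix(a.values, a.labels),
            DistanceMatrix(b.values, b.labels),
            permutations=999,
            alternative="greater",
        )
        assert ours.R == pytest.approx(float(corr), abs=1e-12)
        assert abs(ours.P - float(p)) < 0.05

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(6)
        a = random_ldm(rng)
        b = random_ldm(rng)
        b.labels = [f"Q{i}" for i in range(b.n)]
        with pytest.raises(ValueError):
            mantel(a, b)

    def test_zero_variance_rejected(self):
        a = ldm_from_condensed(["a", "b", "c"], [1.0, 1.0, 1.0])
        b = ldm_from_condensed(["a", "b", "c"], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            mantel(a, b, n_perm=99, seed=0)

    def test_ibd_fit_reported(self):
        rng = np.random.default_rng(7)
        a = random_ldm(rng)
        b = LabeledDistanceMatrix(a.labels, 2.0 * a.values)
        r = mantel(a, b, n_perm=99, seed=0)
        assert r.slope == pytest.approx(2.0)
        assert r.r2 == pytest.approx(1.0)


class TestPartialMantel:
    def test_uncorrelated_control_leaves_r_unchanged(self):
        rng = np.random.default_rng(8)
        base = rng.random(21)
        a = ldm_from_condensed([f"P{i}" for i in range(7)], base)
        b = ldm_from_condensed(a.labels, base + 0.05 * rng.random(21))
        c = random_ldm(rng)
        plain = mantel(a, b, n_perm=99, seed=0).R
        part = partial_mantel(a, b, c, n_perm=99, seed=0).R
        assert abs(part - plain) < 0.05

    def test_control_explaining_a_kills_r(self):
        """When the control matrix carries (almost) all of a's structure the
        partial correlation collapses relative to the plain Mantel R."""
        rng = np.random.default_rng(9)
        a = random_ldm(rng)
        noise1, noise2 = random_ldm(rng), random_ldm(rng)
        b = LabeledDistanceMatrix(a.labels, a.values + 0.3 * noise1.values)
        c = LabeledDistanceMatrix(a.labels, a.values + 0.05 * noise2.values)
        plain = mantel(a, b, n_perm=99, seed=0).R
        part = partial_mantel(a, b, c, n_perm=99, seed=0).R
        assert plain > 0.5
        assert abs(part) < 0.5 * plain

    def test_control_identical_to_predictor_rejected(self):
        rng = np.random.default_rng(21)
        a = random_ldm(rng)
        b = random_ldm(rng)
        c = LabeledDistanceMatrix(b.labels, b.values.copy())
        with pytest.raises(ValueError):
            partial_mantel(a, b, c, n_perm=99, seed=0)

    def test_three_identical_matrices_degenerate(self):
        rng = np.random.default_rng(10)
        a = random_ldm(rng)
        b = LabeledDistanceMatrix(a.labels, a.values.copy())
        c = LabeledDistanceMatrix(a.labels, a.values.copy())
        with pytest.raises(ValueError):
            partial_mantel(a, b, c, n_perm=99, seed=0)


class TestDropPairs:
    def test_nine_populations_three_outlier_pairs(self):
        rng = np.random.default_rng(11)
        labels = ["Br", "Ic", "Il", "Le", "Lo", "Lu", "Or", "Ta", "Va"]
        a = ldm_from_condensed(labels, rng.random(36))
        b = ldm_from_condensed(labels, rng.random(36))
        masked = drop_pairs(a, [("Ic", "Or"), ("Il", "Or"), ("Lu", "Or")])
        r = mantel(masked, b, n_perm=99, seed=0)
        assert r.n_pairs == 33

    def test_empty_list_is_identity(self):
        rng = np.random.default_rng(12)
        a = random_ldm(rng)
        masked = drop_pairs(a, [])
        np.testing.assert_array_equal(masked.effective_mask(), a.effective_mask())

    def test_masking_everything_rejected(self):
        rng = np.random.default_rng(13)
        a = random_ldm(rng, n=3)
        with pytest.raises(ValueError):
            drop_pairs(a, [("P0", "P1"), ("P0", "P2"), ("P1", "P2")])

    def test_unknown_pair_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError):
            drop_pairs(random_ldm(rng), [("P0", "ZZ")])


def geno_frame(bands, pops):
    """bands: list of 0/1 row tuples; pops: population label per row."""
    df = pd.DataFrame(bands, index=[f"i{k}" for k in range(len(bands))])
    df.columns = [f"L{j}" for j in range(df.shape[1])]
    return df, pd.Series(pops, index=df.index)


class TestDominantFst:
    def test_identical_band_frequencies_give_zero(self):
        rows = [(1, 0, 1), (0, 1, 0), (1, 0, 1), (0, 1, 0)]
        geno, pa = geno_frame(rows + rows, ["A"] * 4 + ["B"] * 4)
        d = dominant_fst(geno, pa)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_fixation_gives_one(self):
        geno, pa = geno_frame(
            [(1,), (1,), (1,), (0,), (0,), (0,)], ["A"] * 3 + ["B"] * 3
        )
        d = dominant_fst(geno, pa)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_matches_hand_computed_ratio_of_averages(self):
        """Independent arithmetic oracle: rebuild the debiased estimator from
        scipy's binomial pmf and hand-sum the three loci."""
        bands = [(1, 1, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1), (0, 1, 1)]
        pops = ["A"] * 3 + ["B"] * 3
        geno, pa = geno_frame(bands, pops)
        n = 3
        ks = np.arange(n + 1)
        naive = np.sqrt(1 - ks / n)
        u = np.empty(n + 1)
        for k in ks:
            pmf = scipy_binom.pmf(ks, n, k / n)
            u[k] = 2 * naive[k] - float((pmf * naive).sum())
        kA = np.array([2, 2, 0])
        kB = np.array([1, 2, 3])
        num = den = 0.0
        for locus in range(3):
            q2a, q2b = 1 - kA[locus] / n, 1 - kB[locus] / n
            ua, ub = u[kA[locus]], u[kB[locus]]
            num_l = (q2a + q2b - 2 * ua * ub) / 4
            den_l = (ua + ub) / 2 - (q2a + q2b + 2 * ua * ub) / 4
            if den_l > 1e-12:
                num += num_l
                den += den_l
        expected = max(0.0, num / den)
        d = dominant_fst(geno, pa)
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_bounds_on_simulated_data(self):
        cfg = simulate.SimConfig(seed=2, n_aflp_loci=100)
        geno, pa, _, _ = simulate.simulate_aflp(cfg)
        d = dominant_fst(geno, pa)
        c = d.condensed()
        assert np.all((c >= 0) & (c <= 1))

    def test_all_fixed_bands_rejected(self):
        geno, pa = geno_frame([(1,), (1,), (1,), (1,)], ["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            dominant_fst(geno, pa)


class TestSlopeEnvelope:
    def test_deterministic_for_fixed_seed(self):
        cfg = simulate.SimConfig(seed=4, n_aflp_loci=120)
        geno, pa, _, _ = simulate.simulate_aflp(cfg)
        geo = LabeledDistanceMatrix.from_coords(list(cfg.pop_labels), cfg.coords())
        e1 = neutral_slope_envelope(geno, pa, geo, 50, 10, seed=99)
        e2 = neutral_slope_envelope(geno, pa, geo, 50, 10, seed=99)
        assert e1.slopes == e2.slopes and e1.r2s == e2.r2s

    def test_envelope_brackets_realized_slope(self):
        cfg = simulate.SimConfig(seed=0, ibd_slope_target=0.003)
        geno, pa, _, realized = simulate.simulate_aflp(cfg)
        geo = LabeledDistanceMatrix.from_coords(list(cfg.pop_labels), cfg.coords())
        env = neutral_slope_envelope(geno, pa, geo, 200, 30, seed=0)
        assert env.contains_slope(realized)
        assert env.min_r2 <= env.max_r2

    def test_oversized_subset_rejected(self):
        cfg = simulate.SimConfig(seed=4, n_aflp_loci=50)
        geno, pa, _, _ = simulate.simulate_aflp(cfg)
        geo = LabeledDistanceMatrix.from_coords(list(cfg.pop_labels), cfg.coords())
        with pytest.raises(ValueError):
            neutral_slope_envelope(geno, pa, geo, 60, 10, seed=0)
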