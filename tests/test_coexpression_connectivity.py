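"""Robust correlation, signed TOM and set-pair connectivity."""

import itertools

import numpy as np
import pytest

from xte.coexpression_connectivity import (
    TOMatrix,
    bicor_matrix,
    connectivity_p,
    scale_free_fit,
    set_connectivity,
    signed_tom,
)
from xte.synthetic_data import simulate_coexpression


def _brute_force_tom(corr, beta):
    n = corr.shape[0]
    a = np.power((1 + corr) / 2, beta)
    np.fill_diagonal(a, 0.0)
    tom = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
            den = min(a[i].sum(), a[j].sum()) + 1 - a[i, j]
            tom[i, j] = num / den
    return tom


def _random_corr(rng, n):
    c = rng.uniform(-1, 1, (n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    return c


class TestBicor:
    def test_duplicated_genes_correlate_perfectly(self):
        x = np.random.default_rng(0).normal(0, 1, 40)
        corr = bicor_matrix(np.vstack([x, x]))
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_close_to_pearson_on_clean_gaussian_data(self):
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal([0, 0, 0],
                                    [[1, .6, .2], [.6, 1, .4], [.2, .4, 1]], 500).T
        b = bicor_matrix(X)
        p = np.corrcoef(X)
        assert np.max(np.abs(b - p)) < 0.05

    def test_more_robust_than_pearson_to_one_outlier(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 60)
        y = 0.8 * x + 0.6 * rng.normal(0, 1, 60)
        clean = np.vstack([x, y])
        dirty = clean.copy()
        dirty[1, 0] += 30.0  # one gross outlier
        b_shift = abs(bicor_matrix(dirty)[0, 1] - bicor_matrix(clean)[0, 1])
        p_shift = abs(np.corrcoef(dirty)[0, 1] - np.corrcoef(clean)[0, 1])
        assert b_shift < p_shift

    def test_zero_mad_gene_falls_back_with_warning(self):
        x = np.zeros(20)
        x[:2] = [5.0, -5.0]  # median/MAD both degenerate, variance not
        y = np.random.default_rng(3).normal(0, 1, 20)
        with pytest.warns(RuntimeWarning, match="zero MAD"):
            corr = bicor_matrix(np.vstack([x, y]))
        assert np.isfinite(corr).all()

    def test_constant_gene_gets_zero_correlation(self):
        x = np.full(20, 3.0)
        y = np.random.default_rng(4).normal(0, 1, 20)
        with pytest.warns(RuntimeWarning):
            corr = bicor_matrix(np.vstack([x, y]))
        assert corr[0, 1] == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            bicor_matrix(np.ones((4, 2)))


class TestSignedTom:
    def test_anticorrelated_genes_have_zero_overlap(self):
        corr = -np.ones((3, 3)) + 2 * np.eye(3)
        tom = signed_tom(corr, beta=6)
        off = tom.tom[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-15)

    def test_identical_pair_in_uncorrelated_panel(self):
        # Two perfectly correlated genes in an otherwise independent
        # panel: a_ij = 1, shared-neighbor terms ~ 0, so TOM ~ 1.
        n = 10
        corr = np.eye(n)
        corr[0, 1] = corr[1, 0] = 1.0
        tom = signed_tom(corr, beta=26)
        a_ij = 1.0
        k = ((1 + corr) / 2) ** 26
        np.fill_diagonal(k, 0)
        expected = (k[0] @ k[1] + a_ij) / (min(k[0].sum(), k[1].sum()) + 1 - a_ij)
        assert tom.tom[0, 1] == pytest.approx(expected, rel=1e-12)
        assert tom.tom[0, 1] > 0.99

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            corr = _random_corr(rng, 10)
            beta = float(rng.integers(2, 30))
            tom = signed_tom(corr, beta=beta)
            np.testing.assert_allclose(tom.tom, _brute_force_tom(corr, beta),
                                       atol=1e-12)

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(6)
        tom = signed_tom(_random_corr(rng, 40), beta=12)
        assert np.all(tom.tom >= 0) and np.all(tom.tom <= 1)
        np.testing.assert_allclose(tom.tom, tom.tom.T)

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            signed_tom(np.eye(3), beta=0)

    def test_scale_free_fit_reports_all_betas(self):
        rng = np.random.default_rng(7)
        diag = scale_free_fit(_random_corr(rng, 50), betas=(2, 6, 12))
        assert [d["beta"] for d in diag] == [2.0, 6.0, 12.0]
        assert all(d["mean_connectivity"] >= 0 for d in diag)


class TestSetConnectivity:
    @pytest.fixture
    def tom4(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 0.5, (4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        return TOMatrix(genes=["g0", "g1", "g2", "g3"], tom=m, beta=6)

    def test_shared_members_removed(self, tom4):
        # X = {g0,g1}, Y = {g1,g2}: only the (g0, g2) entry remains.
        assert set_connectivity(tom4, ["g0", "g1"], ["g1", "g2"]) == pytest.approx(
            tom4.tom[0, 2])

    def test_containment_gives_zero(self, tom4):
        assert set_connectivity(tom4, ["g0", "g1", "g2"], ["g1"]) == 0.0

    def test_disjoint_sets_match_double_loop(self, tom4):
        expected = sum(tom4.tom[i, j] for i in (0, 1) for j in (2, 3))
        assert set_connectivity(tom4, ["g0", "g1"], ["g2", "g3"]) == pytest.approx(expected)

    def test_symmetry(self, tom4):
        assert set_connectivity(tom4, ["g0", "g1"], ["g2", "g3"]) == pytest.approx(
            set_connectivity(tom4, ["g2", "g3"], ["g0", "g1"]))

    def test_identical_sets_undefined(self, tom4):
        assert np.isnan(set_connectivity(tom4, ["g0", "g1"], ["g0", "g1"]))

    def test_monotone_in_cross_entries(self, tom4):
        base = set_connectivity(tom4, ["g0"], ["g2"])
        bumped = tom4.tom.copy()
        bumped[0, 2] = bumped[2, 0] = min(1.0, bumped[0, 2] + 0.3)
        tom_b = TOMatrix(genes=tom4.genes, tom=bumped, beta=6)
        assert set_connectivity(tom_b, ["g0"], ["g2"]) > base


class TestConnectivityP:
    def test_identity_tom_gives_p_near_one(self):
        tom = TOMatrix(genes=[f"g{i}" for i in range(20)], tom=np.eye(20), beta=6)
        res = connectivity_p(tom, ["g0", "g1"], ["g2", "g3"], n_draws=500, seed=0)
        assert res.k_xy == 0.0
        assert res.one_sided_p == 1.0

    def test_matches_exhaustive_enumeration_on_toy(self):
        rng = np.random.default_rng(9)
        n = 12
        m = rng.uniform(0, 0.3, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        tom = TOMatrix(genes=[f"g{i}" for i in range(n)], tom=m, beta=6)
        X, Y = ["g0", "g1"], ["g5", "g8"]
        observed = set_connectivity(tom, X, Y)
        # exhaustive truth over all ordered pairs of 2-subsets
        count = total = 0
        for xs in itertools.combinations(range(n), 2):
            for ys in itertools.combinations(range(n), 2):
                xa, ya = np.array(xs), np.array(ys)
                xo = np.setdiff1d(xa, ya)
                yo = np.setdiff1d(ya, xa)
                k = m[np.ix_(xo, yo)].sum() if xo.size and yo.size else 0.0
                count += k >= observed
                total += 1
        p_true = count / total
        n_draws = 1000
        res = connectivity_p(tom, X, Y, n_draws=n_draws, seed=10)
        se = np.sqrt(p_true * (1 - p_true) / n_draws)
        assert abs(res.one_sided_p - p_true) <= 3 * se + 1 / n_draws

    def test_planted_module_pair_detected(self):
        expr, labels, genes = simulate_coexpression(
            60, 40, [(15, 0.9), (15, 0.9)], seed=11)
        corr = bicor_matrix(expr)
        tom = signed_tom(corr, beta=6, genes=genes)
        mod0 = [g for g, l in zip(genes, labels) if l == 0]
        res = connectivity_p(tom, mod0[:7], mod0[7:], n_draws=2000, seed=12)
        assert res.one_sided_p < 0.05

    def test_deterministic_under_seed(self):
        tom = TOMatrix(genes=[f"g{i}" for i in range(15)],
                       tom=np.eye(15), beta=6)
        a = connectivity_p(tom, ["g0"], ["g1"], n_draws=200, seed=13)
        b = connectivity_p(tom, ["g0"], ["g1"], n_draws=200, seed=13)
        assert a.one_sided_p == b.one_sided_p
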