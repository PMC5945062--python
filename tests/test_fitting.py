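"""Power-law MLE, kmin selection, goodness of fit, and model selection."""

import warnings

import numpy as np
import pytest
from scipy import optimize, stats

from grntopo import PowerLawModel, ks_distance, mle_exponent, select_kmin, two_sample_ks
from grntopo.fitting import (
    PowerLawFit,
    fit_alternative,
    gof_pvalue,
    vuong_test,
)


def fixed_kmin_fit(degrees, kmin=1, kmax=None):
    """Fit alpha at a specified kmin (no selection scan)."""
    d = np.asarray(degrees)
    a = mle_exponent(d, kmin=kmin, method="exact")
    m = PowerLawModel(alpha=a, kmin=kmin, kmax=kmax)
    tail = d[d >= kmin]
    return PowerLawFit(alpha=a, kmin=kmin, ks_D=ks_distance(tail, m),
                       n_tail=tail.size, loglik=float(np.sum(m.logpmf(tail))),
                       method="exact", kmax=kmax)


class TestMleExponent:
    def test_all_ones_closed_form(self):
        # 1 + 1/ln 2
        assert mle_exponent([1] * 5, kmin=1) == pytest.approx(2.4427, abs=5e-5)

    def test_small_sample_closed_form(self):
        assert mle_exponent([1, 1, 2, 3, 5], kmin=1) == pytest.approx(1.728, abs=5e-4)

    def test_closed_form_approaches_exact_mle_at_larger_kmin(self):
        m = PowerLawModel(alpha=2.4, kmin=6, kmax=100_000)
        d = m.sample(20_000, 31)
        hill = mle_exponent(d, kmin=6, method="hill")
        exact = mle_exponent(d, kmin=6, method="exact")
        assert abs(hill - exact) < 0.01

    def test_exact_mle_matches_igraph_plfit(self):
        # independent implementation cross-check at fixed kmin
        igraph = pytest.importorskip("igraph")
        d = PowerLawModel(alpha=2.0, kmin=1, kmax=10_000).sample(10_000, 2)
        ours = mle_exponent(d, kmin=1, method="exact")
        theirs = igraph.power_law_fit(list(map(int, d)), xmin=1).alpha
        assert ours == pytest.approx(theirs, abs=1e-5)

    def test_empty_tail_rejected(self):
        with pytest.raises(ValueError, match=">= 2 degrees"):
            mle_exponent([1, 1, 2], kmin=10)

    @pytest.mark.parametrize("alpha", [1.73, 2.0, 3.04, 4.12])
    def test_parameter_recovery_is_unbiased(self, alpha):
        # mean of repeated fits within 2 SE-of-the-mean of truth
        m = PowerLawModel(alpha=alpha, kmin=1, kmax=100_000)
        rng = np.random.default_rng(17)
        n, reps = 5000, 100
        fits = [mle_exponent(m.sample(n, rng), 1, "exact") for _ in range(reps)]
        se_mean = (alpha - 1) / np.sqrt(n) / np.sqrt(reps)
        assert np.mean(fits) == pytest.approx(alpha, abs=4 * se_mean)


class TestKsDistance:
    def test_zero_when_empirical_equals_model(self):
        m = PowerLawModel(alpha=2.0, kmin=1, kmax=4)
        # counts exactly proportional to 1/k^2: lcm(1,4,9,16) = 144
        counts = np.array([144, 36, 16, 9])
        d = np.repeat(np.arange(1, 5), counts)
        assert ks_distance(d, m) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_at_kmin(self):
        m = PowerLawModel(alpha=2.5, kmin=1)
        assert ks_distance([1] * 50, m) == pytest.approx(1 - m.pmf(1), abs=1e-12)

    def test_matches_bruteforce_enumeration(self, rng):
        m = PowerLawModel(alpha=2.3, kmin=2, kmax=500)
        d = m.sample(300, rng)
        tail = d[d >= 2]
        uniq = np.arange(2, 501)
        ecdf = np.searchsorted(np.sort(tail), uniq, side="right") / tail.size
        brute = np.max(np.abs(ecdf - m.cdf(uniq)))
        assert ks_distance(d, m) == pytest.approx(brute, abs=1e-12)

    def test_within_unit_interval(self, rng):
        m = PowerLawModel(alpha=3.0, kmin=1)
        d = rng.integers(1, 50, 200)
        assert 0.0 <= ks_distance(d, m) <= 1.0


class TestSelectKmin:
    def test_recovers_kmin_one_on_pure_powerlaw(self):
        m = PowerLawModel(alpha=2.0, kmin=1, kmax=10_000)
        rng = np.random.default_rng(7)
        hits = sum(select_kmin(m.sample(5000, rng)).kmin == 1 for _ in range(30))
        assert hits >= 27  # >= 90%

    def test_spliced_noise_below_powerlaw_above(self):
        # uniform contamination below the regime must never capture kmin,
        # and alpha of the clean region is recovered
        rng = np.random.default_rng(5)
        m = PowerLawModel(alpha=2.5, kmin=20, kmax=10_000)
        for _ in range(5):
            spl = np.concatenate(
                [rng.integers(1, 15, 2500), m.sample(2500, rng)]
            )
            f = select_kmin(spl)
            assert 20 <= f.kmin <= 60
            assert f.alpha == pytest.approx(2.5, abs=0.2)

    def test_returned_D_is_minimum_over_candidates(self, rng):
        m = PowerLawModel(alpha=2.2, kmin=1, kmax=5000)
        d = m.sample(2000, rng)
        f = select_kmin(d)
        for km in np.unique(d):
            tail = d[d >= km]
            if tail.size < 10 or np.unique(tail).size < 2:
                continue
            a = mle_exponent(tail, kmin=int(km), method="exact")
            alt_d = ks_distance(tail, PowerLawModel(alpha=a, kmin=int(km)))
            assert f.ks_D <= alt_d + 1e-12

    def test_degenerate_input_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="falling back"):
            f = select_kmin([3] * 20)
        assert f.kmin == 3


class TestGofPvalue:
    def test_refuses_coarse_bootstrap(self):
        f = PowerLawFit(alpha=2.0, kmin=1, ks_D=0.1, n_tail=10, loglik=0.0)
        with pytest.raises(ValueError, match="n_boot"):
            gof_pvalue(f, [1, 2, 3] * 10, n_boot=50, seed=0)

    def test_order_invariant(self, rng):
        m = PowerLawModel(alpha=2.5, kmin=1, kmax=10_000)
        d = m.sample(400, rng)
        f = select_kmin(d)
        p1 = gof_pvalue(f, d, n_boot=100, seed=11)
        p2 = gof_pvalue(f, d[::-1].copy(), n_boot=100, seed=11)
        assert p1 == p2

    def test_approximately_uniform_under_null(self):
        # data simulated from the fitted family: p should not concentrate
        rng = np.random.default_rng(42)
        m = PowerLawModel(alpha=2.5, kmin=1, kmax=10_000)
        ps = []
        for _ in range(30):
            d = m.sample(400, rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = select_kmin(d)
                ps.append(gof_pvalue(f, d, n_boot=100, seed=rng))
        assert 0.35 <= np.mean(ps) <= 0.65
        assert np.std(ps) > 0.1  # spread out, not collapsed to one value

    def test_rejects_geometric_tail_at_specified_kmin(self):
        # testing the whole distribution (kmin=1): exponential decay is
        # decisively rejected
        rng = np.random.default_rng(3)
        d = rng.geometric(0.35, 5000)
        f = fixed_kmin_fit(d, kmin=1)
        p = gof_pvalue(f, d, n_boot=100, seed=1, refit="fixed")
        assert p < 0.1


class TestAlternativesAndVuong:
    def test_truncated_poisson_matches_grid_search(self):
        d = np.array([1, 1, 1, 2])
        alt = fit_alternative(d, "poisson", kmin=1)

        def nll(lam):
            # vectorized over the grid
            lp = stats.poisson.logpmf(d[:, None], lam[None, :])
            return -(lp.sum(axis=0) - d.size * np.log(stats.poisson.sf(0, lam)))

        coarse = np.linspace(1e-3, 5.0, 5001)
        lam0 = coarse[np.argmin(nll(coarse))]
        fine = np.linspace(max(lam0 - 2e-3, 1e-6), lam0 + 2e-3, 4001)
        lam_grid = fine[np.argmin(nll(fine))]
        assert alt.params["rate"] == pytest.approx(lam_grid, abs=1e-6)

    def test_exponential_beats_powerlaw_on_geometric_data(self, rng):
        d = rng.geometric(0.3, 5000)
        pl = fixed_kmin_fit(d, kmin=1)
        alt = fit_alternative(d, "exponential", kmin=1)
        assert alt.loglik > pl.loglik

    def test_degenerate_all_equal_boundary(self):
        alt = fit_alternative([4] * 30, "exponential", kmin=4)
        assert np.isfinite(alt.loglik)
        assert alt.loglik == pytest.approx(0.0, abs=1e-12)

    def test_model_compared_with_itself_is_undecided_zero(self, rng):
        d = rng.integers(1, 30, 100)
        pl = fixed_kmin_fit(d, kmin=1)

        class MirrorAlt(type(fit_alternative(d, "poisson", kmin=1))):
            def logpmf(self, k):
                return pl.model.logpmf(k)

        mirror = MirrorAlt(family="poisson", params={"rate": 1.0}, kmin=1,
                           loglik=pl.loglik)
        v = vuong_test(pl, mirror, d)
        assert v.statistic == 0.0 and v.pvalue == 1.0 and v.favored == "undecided"

    def test_mismatched_kmin_rejected(self, rng):
        d = rng.integers(1, 30, 100)
        pl = fixed_kmin_fit(d, kmin=2)
        alt = fit_alternative(d, "poisson", kmin=1)
        with pytest.raises(ValueError, match="different kmin"):
            vuong_test(pl, alt, d)

    def test_favors_power_law_on_powerlaw_data(self):
        m = PowerLawModel(alpha=3.5, kmin=1, kmax=10_000)
        rng = np.random.default_rng(3)
        wins = 0
        reps = 40
        for _ in range(reps):
            d = m.sample(5000, rng)
            pl = fixed_kmin_fit(d, kmin=1)
            alt = fit_alternative(d, "poisson", kmin=1)
            wins += vuong_test(pl, alt, d).favored == "power_law"
        assert wins >= int(0.95 * reps)

    def test_favors_alternative_on_poisson_data(self):
        rng = np.random.default_rng(3)
        wins = 0
        reps = 40
        for _ in range(reps):
            d = rng.poisson(3.0, 8000)
            d = d[d >= 1][:5000]
            pl = fixed_kmin_fit(d, kmin=1)
            alt = fit_alternative(d, "poisson", kmin=1)
            wins += vuong_test(pl, alt, d).favored == "alternative"
        assert wins >= int(0.95 * reps)


class TestTwoSampleKs:
    def test_identical_sequences(self):
        d = np.array([1, 2, 2, 3, 5, 8])
        D, p, ties = two_sample_ks(d, d)
        assert D == 0.0 and p == 1.0 and ties

    def test_disjoint_supports(self):
        D, p, ties = two_sample_ks(np.arange(1, 11), np.arange(100, 111))
        assert D == 1.0 and not ties

    def test_separates_distinct_exponents(self):
        m2 = PowerLawModel(alpha=2.0, kmin=1, kmax=10_000)
        m4 = PowerLawModel(alpha=4.0, kmin=1, kmax=10_000)
        rng = np.random.default_rng(9)
        reps, hits = 40, 0
        for _ in range(reps):
            _, p, _ = two_sample_ks(m2.sample(1000, rng), m4.sample(1000, rng))
            hits += p < 0.01
        assert hits >= int(0.95 * reps)
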