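import numpy as np
import pytest

from conescreen import (
    GeneObservations,
    bootstrap_pvalue,
    fit_restricted,
    fit_unrestricted,
    in_alternative_region,
    lrt_statistic,
)
from conescreen.cone_blrt import test_gene as run_gene_test
from conescreen.cone_blrt import ConeTestError, _bootstrap_statistics

from conftest import make_cone_obs


def grid_restricted_rss(obs: GeneObservations, step: float = 1e-3) -> float:
    """Independent oracle: dense grid search of the pooled RSS over the null
    boundary {b21 = -b11} U {b21 = b11} with b11 <= 0, refined around the
    grid optimum. Uses only the definition of RSS at fixed slopes."""

    def rss_at(b11: np.ndarray, sign: float) -> np.ndarray:
        b21 = sign * b11
        out = np.empty(b11.size)
        for i, (c1, c2) in enumerate(zip(b11, b21)):
            a1 = np.mean(obs.cancer_y - c1 * obs.cancer_x)
            a2 = np.mean(obs.normal_y - c2 * obs.normal_x)
            out[i] = np.sum((obs.cancer_y - a1 - c1 * obs.cancer_x) ** 2) + np.sum(
                (obs.normal_y - a2 - c2 * obs.normal_x) ** 2
            )
        return out

    f1, _, _ = fit_unrestricted(obs)
    lo = min(4 * f1.slope, -1.0)
    best = np.inf
    for sign in (-1.0, +1.0):
        grid = np.arange(lo, 0.0 + step / 2, step)
        vals = rss_at(grid, sign)
        c0 = grid[np.argmin(vals)]
        fine = np.arange(c0 - 2 * step, min(c0 + 2 * step, 0.0) + 5e-7, 1e-6)
        fine = fine[fine <= 0]
        best = min(best, rss_at(fine, sign).min())
    return best


class TestUnrestrictedFit:
    def test_exact_line_and_constant_group(self):
        obs = GeneObservations(
            "g",
            cancer_y=[3.0, 2.0, 1.0],
            cancer_x=[1.0, 2.0, 3.0],
            normal_y=[5.0, 5.0, 5.0],
            normal_x=[1.0, 2.0, 3.0],
        )
        f1, f2, sigma2 = fit_unrestricted(obs)
        assert f1.slope == pytest.approx(-1.0)
        assert f1.rss == pytest.approx(0.0)
        assert f2.slope == pytest.approx(0.0)
        assert sigma2 == pytest.approx(0.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(10)
        obs = make_cone_obs(rng, -0.4, 0.1, n_per_passage=12)
        f1, f2, sigma2 = fit_unrestricted(obs)
        for fit, x, y in (
            (f1, obs.cancer_x, obs.cancer_y),
            (f2, obs.normal_x, obs.normal_y),
        ):
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)
        assert sigma2 == pytest.approx((f1.rss + f2.rss) / (obs.n1 + obs.n2))

    def test_degenerate_covariate_is_error(self):
        with pytest.raises(ConeTestError, match="constant"):
            GeneObservations("g", [1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 2, 3])


@pytest.mark.parametrize(
    "b11, b21, expected",
    [
        (-1.0, 0.0, True),
        (-1.0, 0.99, True),
        (-1.0, -0.99, True),
        (+1.0, 0.0, False),
        (0.0, 0.0, False),
        (-1.0, -2.0, False),
        (-1.0, 1.0, False),   # boundary b21 = -b11
        (-1.0, -1.0, False),  # boundary b21 = b11
    ],
)
def test_alternative_region_membership(b11, b21, expected):
    assert in_alternative_region(b11, b21) is expected


class TestRestrictedFit:
    def test_null_slopes_leave_fit_unchanged(self):
        rng = np.random.default_rng(11)
        obs = make_cone_obs(rng, +0.5, 0.0)
        f1, f2, s2 = fit_unrestricted(obs)
        r1, r2, s2r = fit_restricted(obs)
        assert (r1, r2) == (f1, f2)
        assert s2r == s2

    def test_boundary_data_gives_zero_statistic(self):
        # construct data whose unrestricted slopes satisfy b21 = -b11 exactly
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y1 = 10.0 - 0.5 * x + np.array([0.1, -0.1, 0.0, -0.1, 0.1, 0.0])
        y2 = 10.0 + 0.5 * x + np.array([0.1, -0.1, 0.0, -0.1, 0.1, 0.0])
        obs = GeneObservations("g", y1, x, y2, x)
        f1, f2, s2 = fit_unrestricted(obs)
        assert f2.slope == pytest.approx(-f1.slope)
        assert not in_alternative_region(f1.slope, f2.slope)
        res = run_gene_test(obs, M=10, seed=1)
        assert res.T0 == 0.0
        assert res.p_value == 1.0

    @pytest.mark.parametrize("case", range(20))
    def test_matches_grid_search_oracle(self, case):
        rng = np.random.default_rng(1000 + case)
        b11 = rng.uniform(-0.8, -0.2)
        b21 = rng.uniform(b11 * 0.9, -b11 * 0.9)
        obs = make_cone_obs(rng, b11, b21, sigma=rng.uniform(0.3, 1.5))
        f1, f2, _ = fit_unrestricted(obs)
        if not in_alternative_region(f1.slope, f2.slope):
            pytest.skip("sampled fit left the cone")
        _, _, s2r = fit_restricted(obs)
        rss = s2r * (obs.n1 + obs.n2)
        oracle = grid_restricted_rss(obs)
        assert rss == pytest.approx(oracle, rel=1e-6)

    def test_restricted_never_beats_unrestricted(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            obs = make_cone_obs(
                rng, rng.uniform(-1, 0.5), rng.uniform(-1, 1), n_per_passage=4
            )
            _, _, s2 = fit_unrestricted(obs)
            _, _, s2r = fit_restricted(obs)
            assert s2r >= s2 - 1e-12


class TestLrtStatistic:
    def test_closed_form_values(self):
        assert lrt_statistic(2.0, 2.0, 10) == (0.0, False)
        t, flag = lrt_statistic(2.0, 2.0 * np.e, 10)
        assert t == pytest.approx(10.0)
        assert not flag

    def test_perfect_fit_flags_infinity(self):
        t, flag = lrt_statistic(0.0, 1.0, 10)
        assert t == np.inf and flag
        assert lrt_statistic(0.0, 0.0, 10) == (0.0, False)

    def test_matches_gaussian_likelihood_oracle(self):
        """T0 equals twice the gap between independently maximized Gaussian
        log-likelihoods of the unrestricted and boundary-restricted models."""

        def max_loglik(rss, n):
            s2 = rss / n
            return -n / 2 * np.log(2 * np.pi * s2) - n / 2

        rng = np.random.default_rng(13)
        obs = make_cone_obs(rng, -0.5, 0.05)
        f1, f2, s2 = fit_unrestricted(obs)
        assert in_alternative_region(f1.slope, f2.slope)
        n = obs.n1 + obs.n2
        rss_u = s2 * n
        rss_r = grid_restricted_rss(obs)
        t_expected = 2 * (max_loglik(rss_u, n) - max_loglik(rss_r, n))
        res = run_gene_test(obs, M=10, seed=2)
        assert res.T0 == pytest.approx(t_expected, abs=1e-6)


class TestBootstrap:
    def test_determinism_and_range(self):
        rng = np.random.default_rng(14)
        obs = make_cone_obs(rng, -0.5, 0.0)
        r1 = bootstrap_pvalue(obs, M=299, seed=99)
        r2 = bootstrap_pvalue(obs, M=299, seed=99)
        assert (r1.T0, r1.p_raw, r1.p_addone) == (r2.T0, r2.p_raw, r2.p_addone)
        assert 0 < r1.p_addone <= 1
        r3 = bootstrap_pvalue(obs, M=299, seed=100)
        assert (r3.p_raw != r1.p_raw) or (r3.T0 == r1.T0)

    def test_invalid_m(self):
        rng = np.random.default_rng(15)
        with pytest.raises(ConeTestError, match="M="):
            bootstrap_pvalue(make_cone_obs(rng, -0.5, 0.0), M=0)

    def test_vectorized_matches_scalar_chain(self):
        """The closed-form vectorized bootstrap equals the explicit
        fit_unrestricted -> fit_restricted -> lrt_statistic chain on the
        same resamples."""
        rng = np.random.default_rng(16)
        obs = make_cone_obs(rng, -0.5, 0.1, n_per_passage=4)
        f1, f2, _ = fit_unrestricted(obs)
        r1, r2, _ = fit_restricted(obs)
        pooled = np.concatenate(
            [
                f1.residuals(obs.cancer_x, obs.cancer_y),
                f2.residuals(obs.normal_x, obs.normal_y),
            ]
        )
        M = 50
        t_vec = _bootstrap_statistics(
            obs, (r1, r2), pooled, M, np.random.default_rng(777)
        )
        idx = np.random.default_rng(777).integers(
            0, pooled.size, size=(M, obs.n1 + obs.n2)
        )
        n = obs.n1 + obs.n2
        for b in range(M):
            y1 = r1.fitted(obs.cancer_x) + pooled[idx[b, : obs.n1]]
            y2 = r2.fitted(obs.normal_x) + pooled[idx[b, obs.n1 :]]
            bobs = GeneObservations("g", y1, obs.cancer_x, y2, obs.normal_x)
            bf1, bf2, bs2 = fit_unrestricted(bobs)
            if in_alternative_region(bf1.slope, bf2.slope):
                _, _, bs2r = fit_restricted(bobs)
                t_scalar, _ = lrt_statistic(bs2 * n, bs2r * n, n)
            else:
                t_scalar = 0.0
            assert t_vec[b] == pytest.approx(t_scalar, abs=1e-9)

    def test_scale_equivariance_of_t0(self):
        rng = np.random.default_rng(17)
        obs = make_cone_obs(rng, -0.5, 0.0)
        res = run_gene_test(obs, M=10, seed=3)
        scaled = GeneObservations(
            "g", 7.0 * obs.cancer_y, obs.cancer_x, 7.0 * obs.normal_y, obs.normal_x
        )
        res_scaled = run_gene_test(scaled, M=10, seed=3)
        assert res_scaled.T0 == pytest.approx(res.T0, rel=1e-10)
        assert res_scaled.in_region == res.in_region

    def test_type_i_error_valid_at_cone_vertex(self):
        """At the least-favorable null point (both true slopes 0) the
        bootstrap p-values are stochastically no smaller than uniform:
        the rejection rate never exceeds nominal + 3 Monte-Carlo SEs.
        (The vertex makes the restricted-MLE bootstrap conservative, so
        rates well below nominal are expected here.)"""
        rng = np.random.default_rng(808)
        n = 200
        for alpha in (0.05, 0.10):
            rej = 0
            rng = np.random.default_rng(808)
            for i in range(n):
                obs = make_cone_obs(rng, 0.0, 0.0, gene=f"v{i}")
                rej += bootstrap_pvalue(obs, M=199, seed=808).p_value <= alpha
            bound = alpha + 3 * np.sqrt(alpha * (1 - alpha) / n)
            assert rej / n <= bound

    def test_monotonicity_in_effect_size(self):
        """Median T0 does not decrease as the cancer slope steepens."""
        rng = np.random.default_rng(18)
        medians = []
        for slope in (-0.15, -0.4, -0.8):
            t0s = [
                run_gene_test(make_cone_obs(rng, slope, 0.0), M=1, seed=4).T0
                for _ in range(40)
            ]
            medians.append(np.median(t0s))
        assert medians[0] <= medians[1] <= medians[2]


class TestGeneOrchestration:
    def test_null_region_gene_full_result(self):
        rng = np.random.default_rng(19)
        obs = make_cone_obs(rng, +0.4, 0.0)
        res = run_gene_test(obs, M=50, seed=5)
        assert res.in_region is False
        assert res.T0 == 0.0
        assert res.p_raw == res.p_addone == 1.0
        assert res.sigma2_restricted == res.sigma2_unrestricted

    def test_near_zero_noise_gives_minimum_p(self):
        rng = np.random.default_rng(20)
        obs = make_cone_obs(rng, -0.6, 0.0, sigma=1e-4)
        M = 199
        res = run_gene_test(obs, M=M, seed=6)
        assert res.in_region and res.T0 > 50
        assert res.p_addone == pytest.approx(1 / (M + 1))

    def test_membership_is_not_symmetric(self):
        rng = np.random.default_rng(21)
        obs = make_cone_obs(rng, -0.6, 0.0)
        res = run_gene_test(obs, M=1, seed=7)
        swapped = GeneObservations(
            "g", obs.normal_y, obs.normal_x, obs.cancer_y, obs.cancer_x
        )
        res_sw = run_gene_test(swapped, M=1, seed=7)
        assert res.in_region and not res_sw.in_region
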