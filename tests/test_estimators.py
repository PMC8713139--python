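"""CGI and BAR free-energy estimators, bootstrap errors, overlap diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats
from scipy.special import expit

from dsbredox.constants import beta as beta_of_T
from dsbredox.estimators import (
    EstimationError,
    bar_estimate,
    bar_objective,
    bootstrap_se,
    cgi_estimate,
    fit_gaussian,
    overlap_diagnostics,
)
from dsbredox.synthetic import CftModel, sample_cft_works
from dsbredox.work_io import WorkSet

from conftest import moment_matched


def _ws(values, direction="forward", label="b", T=300.0):
    return WorkSet(label, direction, np.asarray(values, dtype=float), T)


def _pair_from_frames(fwd_frame, rev_frame):
    """Build (forward, backward) WorkSets from forward-frame sample arrays."""
    return _ws(fwd_frame, "forward"), _ws(-np.asarray(rev_frame), "backward")


class TestFitGaussian:
    def test_two_point_closed_form(self):
        fit = fit_gaussian(_ws([1.0, 3.0]))
        assert fit.mean == pytest.approx(2.0)
        assert fit.sd == pytest.approx(np.sqrt(2.0))
        assert not fit.degenerate

    def test_all_equal_flags_degenerate(self):
        fit = fit_gaussian(_ws([5.0, 5.0, 5.0]))
        assert fit.mean == 5.0 and fit.sd == 0.0 and fit.degenerate

    def test_single_sample_rejected(self):
        with pytest.raises(EstimationError):
            fit_gaussian(_ws([1.0]))

    def test_moment_recovery_at_large_n(self):
        rng = np.random.default_rng(77)
        fit = fit_gaussian(_ws(rng.normal(30.0, 4.0, size=10**5)))
        assert fit.mean == pytest.approx(30.0, abs=0.05)
        assert fit.sd == pytest.approx(4.0, abs=0.05)


class TestCgi:
    def test_equal_variance_midpoint(self):
        rng = np.random.default_rng(0)
        f = moment_matched(rng.normal(size=400), 10.0, 2.0)
        r = moment_matched(rng.normal(size=400), 6.0, 2.0)
        fwd, bwd = _pair_from_frames(f, r)
        assert cgi_estimate(fwd, bwd).dG == pytest.approx(8.0, abs=1e-12)

    def test_zero_dissipation_gives_sample_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(20.0, 3.0, size=300)
        fwd, bwd = _pair_from_frames(x, x)
        assert cgi_estimate(fwd, bwd).dG == pytest.approx(x.mean(), abs=1e-10)

    def test_unequal_variance_matches_density_scan_oracle(self):
        rng = np.random.default_rng(2)
        mu_f, sd_f, mu_r, sd_r = 12.0, 2.0, 6.0, 3.0
        f = moment_matched(rng.normal(size=500), mu_f, sd_f)
        r = moment_matched(rng.normal(size=500), mu_r, sd_r)
        fwd, bwd = _pair_from_frames(f, r)
        dg = cgi_estimate(fwd, bwd).dG
        # brute force: sign change of the fitted-pdf difference on [mu_r, mu_f]
        x = np.arange(mu_r, mu_f, 1e-6)
        diff = stats.norm.pdf(x, mu_f, sd_f) - stats.norm.pdf(x, mu_r, sd_r)
        crossings = x[np.nonzero(np.diff(np.sign(diff)))[0]]
        assert crossings.size >= 1
        assert min(abs(crossings - dg)) < 1e-5

    def test_degenerate_sd_rejected(self):
        fwd, bwd = _ws([5.0, 5.0]), _ws([-4.0, -4.5], "backward")
        with pytest.raises(EstimationError, match="degenerate"):
            cgi_estimate(fwd, bwd)

    def test_mismatched_temperatures_rejected(self):
        with pytest.raises(EstimationError, match="temperature"):
            cgi_estimate(_ws([1.0, 2.0], T=300.0), _ws([-1.0, -2.0], "backward", T=310.0))


# frozen fixture: 5 forward works, 5 backward works (kJ/mol, 300 K)
BAR_FIXTURE_FORWARD = [31.42, 35.87, 28.91, 33.05, 30.66]
BAR_FIXTURE_BACKWARD = [-27.11, -25.48, -29.93, -26.02, -28.37]


class TestBar:
    def test_symmetric_configuration_forces_center(self):
        fwd, bwd = _ws([9.0, 7.0]), _ws([-7.0, -9.0], "backward")
        assert bar_estimate(fwd, bwd).dG == pytest.approx(8.0, abs=1e-8)

    def test_repeated_identical_works(self):
        fwd, bwd = _ws([10.0, 10.0]), _ws([-10.0, -10.0], "backward")
        assert bar_estimate(fwd, bwd).dG == pytest.approx(10.0, abs=1e-8)

    def test_fixture_root_matches_grid_scan_oracle(self):
        fwd = _ws(BAR_FIXTURE_FORWARD)
        bwd = _ws(BAR_FIXTURE_BACKWARD, "backward")
        dg = bar_estimate(fwd, bwd, tol=1e-10).dG
        beta = beta_of_T(300.0)
        w_f = np.asarray(BAR_FIXTURE_FORWARD)
        w_rt = -np.asarray(BAR_FIXTURE_BACKWARD)
        # coarse bracket, then exhaustive 1e-6-spaced scan for the sign change
        grid = np.arange(dg - 0.5, dg + 0.5, 1e-6)
        g = bar_objective(grid, w_f, w_rt, beta)
        idx = np.nonzero(np.diff(np.sign(g)))[0]
        assert idx.size == 1
        assert abs(grid[idx[0]] - dg) < 1e-6

    def test_fixture_root_matches_likelihood_maximization(self):
        # independent route: BAR is the unique maximizer of the Bennett
        # log-likelihood; locate the argmax without using the root equation
        fwd = _ws(BAR_FIXTURE_FORWARD)
        bwd = _ws(BAR_FIXTURE_BACKWARD, "backward")
        dg = bar_estimate(fwd, bwd, tol=1e-10).dG
        beta = beta_of_T(300.0)
        w_f = np.asarray(BAR_FIXTURE_FORWARD)
        w_rt = -np.asarray(BAR_FIXTURE_BACKWARD)
        m = np.log(w_f.size / w_rt.size)

        def neg_loglik(x):
            ll_f = np.log(expit(-(m + beta * (w_f - x)))).sum()
            ll_r = np.log(expit(-(-m + beta * (x - w_rt)))).sum()
            return -(ll_f + ll_r)

        res = optimize.minimize_scalar(
            neg_loglik, bounds=(dg - 10, dg + 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert abs(res.x - dg) < 1e-4

    def test_non_overlap_reported(self):
        fwd, bwd = _ws([500.0, 501.0]), _ws([-1.0, -2.0], "backward")
        with pytest.raises(EstimationError, match="overlap"):
            bar_estimate(fwd, bwd)

    def test_objective_strictly_monotone_on_random_inputs(self):
        rng = np.random.default_rng(5)
        beta = beta_of_T(300.0)
        for _ in range(20):
            w_f = rng.normal(rng.uniform(-20, 40), rng.uniform(0.5, 8), size=40)
            w_rt = rng.normal(rng.uniform(-20, 40), rng.uniform(0.5, 8), size=25)
            grid = np.linspace(min(w_f.min(), w_rt.min()) - 20,
                               max(w_f.max(), w_rt.max()) + 20, 400)
            g = bar_objective(grid, w_f, w_rt, beta)
            assert np.all(np.diff(g) > 0), "objective must be strictly monotone"


class TestEquivariance:
    @given(c=st.floats(-30, 30))
    @settings(max_examples=20, deadline=None)
    def test_shift_moves_both_estimates_exactly(self, c):
        model = CftModel(dG_true=25.0, sigma=3.0, n_per_direction=120, seed=9)
        fwd, bwd = sample_cft_works(model)
        shifted_f = _ws(fwd.works + c)
        shifted_b = _ws(bwd.works - c, "backward")
        assert cgi_estimate(shifted_f, shifted_b).dG == pytest.approx(
            cgi_estimate(fwd, bwd).dG + c, abs=1e-8
        )
        assert bar_estimate(shifted_f, shifted_b).dG == pytest.approx(
            bar_estimate(fwd, bwd).dG + c, abs=1e-6
        )


class TestCgiBarAgreement:
    def test_agree_within_combined_se_on_gaussian_data(self, cft_pair):
        model, fwd, bwd = cft_pair
        cgi = cgi_estimate(fwd, bwd).dG
        bar = bar_estimate(fwd, bwd).dG
        se_c = bootstrap_se(fwd, bwd, "cgi", n_boot=300, seed=3)
        se_b = bootstrap_se(fwd, bwd, "bar", n_boot=300, seed=3)
        assert abs(cgi - bar) <= 2.0 * (se_c + se_b)


class TestBootstrap:
    def test_determinism(self, cft_pair):
        _, fwd, bwd = cft_pair
        a = bootstrap_se(fwd, bwd, "cgi", n_boot=150, seed=11)
        b = bootstrap_se(fwd, bwd, "cgi", n_boot=150, seed=11)
        assert a == b

    def test_degenerate_sets_have_zero_se(self):
        fwd = _ws([30.0] * 20)
        bwd = _ws([-30.0] * 20, "backward")
        assert bootstrap_se(fwd, bwd, "bar", n_boot=100, seed=0) == 0.0

    def test_small_n_boot_rejected(self, cft_pair):
        _, fwd, bwd = cft_pair
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_se(fwd, bwd, "cgi", n_boot=50, seed=0)

    def test_bootstrap_se_tracks_repeated_sampling_sd(self):
        # oracle: the sd of CGI estimates over 200 freshly generated
        # datasets; the bootstrap SE from one dataset must land within 30 %
        base = CftModel(dG_true=30.0, sigma=4.0, n_per_direction=500, seed=100)
        fwd, bwd = sample_cft_works(base)
        se_boot = bootstrap_se(fwd, bwd, "cgi", n_boot=1000, seed=1)
        estimates = []
        for k in range(200):
            m = CftModel(dG_true=30.0, sigma=4.0, n_per_direction=500, seed=5000 + k)
            f, b = sample_cft_works(m)
            estimates.append(cgi_estimate(f, b).dG)
        sd_true = np.std(estimates, ddof=1)
        assert se_boot == pytest.approx(sd_true, rel=0.30)


class TestOverlapDiagnostics:
    def test_identical_distributions_have_unit_overlap(self):
        rng = np.random.default_rng(8)
        x = rng.normal(10, 2, size=200)
        fwd, bwd = _pair_from_frames(x, x)
        rep = overlap_diagnostics(fwd, bwd)
        assert rep.bhattacharyya == pytest.approx(1.0, abs=1e-12)
        assert rep.mean_gap == pytest.approx(0.0, abs=1e-10)

    def test_separated_distributions_have_no_overlap(self):
        rng = np.random.default_rng(9)
        f = moment_matched(rng.normal(size=100), 100.0, 1.0)
        r = moment_matched(rng.normal(size=100), 0.0, 1.0)
        fwd, bwd = _pair_from_frames(f, r)
        assert overlap_diagnostics(fwd, bwd).bhattacharyya < 1e-10

    def test_closed_form_matches_quadrature_oracle(self):
        rng = np.random.default_rng(10)
        f = moment_matched(rng.normal(size=100), 2.0, 1.0)
        r = moment_matched(rng.normal(size=100), 0.0, 1.0)
        fwd, bwd = _pair_from_frames(f, r)
        bc = overlap_diagnostics(fwd, bwd).bhattacharyya
        assert bc == pytest.approx(np.exp(-0.5), abs=1e-12)
        x = np.linspace(-12, 14, 400001)
        integrand = np.sqrt(stats.norm.pdf(x, 2, 1) * stats.norm.pdf(x, 0, 1))
        assert bc == pytest.approx(integrate.trapezoid(integrand, x), abs=1e-8)

    def test_ks_pvalues_in_unit_interval(self, cft_pair):
        _, fwd, bwd = cft_pair
        rep = overlap_diagnostics(fwd, bwd)
        assert 0.0 <= rep.ks_p_forward <= 1.0
        assert 0.0 <= rep.ks_p_backward <= 1.0
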