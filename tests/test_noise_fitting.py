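"""Rician noise synthesis, likelihood, ML fitting, ensemble summaries."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from dwires.noise_fitting import (
    DEFAULT_BOUNDS,
    FitBounds,
    FitResult,
    NoiseModel,
    add_rician,
    fit_ensemble,
    fit_tissue,
    rician_loglik,
    simulate_ensemble,
    summarize,
)
from dwires.signal_model import Tissue
from dwires.protocols import PROTOCOLS


class TestNoiseModel:
    def test_sigma_definition(self):
        # SNR defined on the b=0 signal at TE = 100 ms
        nm = NoiseModel(snr=80, T2=125.0)
        assert nm.sigma == pytest.approx(math.exp(-0.8) / 80)

    def test_positive_snr_required(self):
        with pytest.raises(ValueError):
            NoiseModel(snr=0)


class TestAddRician:
    def test_zero_sigma_identity(self, rng):
        s = np.array([0.1, 0.5, 1.0])
        np.testing.assert_array_equal(add_rician(s, 0.0, rng), s)

    def test_rayleigh_mean_at_zero_signal(self, rng):
        """With S = 0 the magnitude is Rayleigh with mean sigma sqrt(pi/2)."""
        sigma = 0.3
        draws = add_rician(np.zeros(200_000), sigma, rng)
        want = sigma * math.sqrt(math.pi / 2)
        assert draws.mean() == pytest.approx(want, rel=0.01)

    def test_empirical_distribution_matches_rician_density(self, rng):
        """Histogram of draws at S/sigma = 5 matches the analytic density."""
        s, sigma = 1.0, 0.2
        draws = add_rician(np.full(100_000, s), sigma, rng)
        hist, edges = np.histogram(draws, bins=40, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        dens = np.exp(rician_loglik(s, sigma, centers))
        # compare where the density is appreciable
        mask = dens > 0.1 * dens.max()
        np.testing.assert_allclose(hist[mask], dens[mask], rtol=0.15)


class TestRicianLoglik:
    def test_density_integrates_to_one(self):
        for nu, sigma in [(0.0, 0.1), (0.5, 0.1), (1.0, 0.02), (0.2, 0.5)]:
            val, err = quad(
                lambda x: math.exp(rician_loglik(nu, sigma, x)) if x > 0 else 0.0,
                1e-12,
                nu + 40 * sigma,
                limit=200,
            )
            assert abs(val - 1.0) < 1e-6

    def test_reduces_to_rayleigh_at_zero_location(self):
        x, sigma = 0.7, 0.3
        got = rician_loglik(0.0, sigma, x)
        want = math.log(x / sigma**2) - x * x / (2 * sigma**2)
        assert got == pytest.approx(want, rel=1e-12)

    def test_large_argument_stable(self):
        # naive I0 would overflow at x*nu/sigma^2 ~ 1e6
        val = rician_loglik(1.0, 1e-3, 1.0)
        assert np.isfinite(val)

    def test_ml_location_consistent(self, rng):
        """The argmax over nu of a large high-SNR sample is close to truth."""
        nu, sigma = 1.0, 0.05
        sample = add_rician(np.full(20_000, nu), sigma, rng)
        grid = np.linspace(0.9, 1.1, 401)
        ll = [np.sum(rician_loglik(g, sigma, sample)) for g in grid]
        assert grid[int(np.argmax(ll))] == pytest.approx(nu, rel=0.01)


class TestSimulateEnsemble:
    def test_noiseless_normalization_cancels_t2(self, baseline, d_opt_80, rng):
        ens = simulate_ensemble(baseline, d_opt_80, NoiseModel(snr=1e12), 3, rng)
        from dwires.noise_fitting import _ProtocolModel

        mu = _ProtocolModel(d_opt_80).normalized_signal(baseline.as_array())
        np.testing.assert_allclose(ens, np.tile(mu, (3, 1)), rtol=1e-9)

    def test_dimensions(self, baseline, d_opt_80, rng):
        ens = simulate_ensemble(baseline, d_opt_80, NoiseModel(snr=80), 1500, rng)
        assert ens.shape == (1500, 4)

    def test_mean_close_to_noiseless_at_snr_80(self, baseline, d_opt_80, rng):
        from dwires.noise_fitting import _ProtocolModel

        ens = simulate_ensemble(baseline, d_opt_80, NoiseModel(snr=80), 20_000, rng)
        mu = _ProtocolModel(d_opt_80).normalized_signal(baseline.as_array())
        np.testing.assert_allclose(ens.mean(axis=0), mu, rtol=0.02)


class TestFitTissue:
    def test_noiseless_recovery_with_truth_start(self, baseline, d_opt_80):
        from dwires.noise_fitting import _ProtocolModel

        mu = _ProtocolModel(d_opt_80).normalized_signal(baseline.as_array())
        # very high SNR: the Rician ML location offset (nu_hat < x by
        # ~sigma^2/(2 x^2)) is then negligible and truth is the optimum
        res = fit_tissue(
            mu,
            d_opt_80,
            NoiseModel(snr=5000),
            fixed_diffusivities=(1.0, 2.0),
            starts=np.array([[baseline.R, baseline.f_i], [5.0, 0.3]]),
        )
        assert res.estimates["R"] == pytest.approx(baseline.R, abs=1e-3)
        assert res.estimates["f_i"] == pytest.approx(baseline.f_i, abs=1e-4)
        assert not res.any_extreme

    def test_free_fit_has_four_parameters(self, baseline, d_opt_80, rng):
        from dwires.noise_fitting import _ProtocolModel

        mu = _ProtocolModel(d_opt_80).normalized_signal(baseline.as_array())
        res = fit_tissue(
            mu, d_opt_80, NoiseModel(snr=80), n_starts=5, rng=rng
        )
        assert not res.fixed_diffusivities
        # all four estimates are free to differ from any fixed value
        assert set(res.estimates) == {"R", "f_i", "D_i", "D_e"}

    def test_extreme_flag_threshold(self):
        bounds = FitBounds()
        # R within 1% of range of the upper bound: 25 - 0.01*24.9 = 24.751
        assert bounds.is_extreme("R", 24.8)
        assert not bounds.is_extreme("R", 24.7)
        assert bounds.is_extreme("f_i", 0.015)  # below 0.01 + 0.0099


class TestSummarize:
    def _mkfit(self, R, f_i, extreme=False):
        return FitResult(
            estimates={"R": R, "f_i": f_i, "D_i": 1.0, "D_e": 2.0},
            objective=0.0,
            extreme={"R": extreme, "f_i": False, "D_i": False, "D_e": False},
            fixed_diffusivities=True,
        )

    def test_identical_fits(self, baseline):
        fits = [self._mkfit(10.0, 0.6)] * 5
        s = summarize(fits, baseline)
        assert s.accuracy["R"] == 0.0
        assert s.precision["R"] == 0.0
        assert s.valid

    def test_hand_built_accuracy_and_sd(self, baseline):
        fits = [self._mkfit(9.0, 0.6), self._mkfit(10.0, 0.6), self._mkfit(11.0, 0.6)]
        s = summarize(fits, baseline)
        assert s.accuracy["R"] == pytest.approx(0.0, abs=1e-12)
        assert s.precision["R"] == pytest.approx(1.0)  # sample SD, n-1

    def test_majority_extreme_marks_invalid(self, baseline):
        fits = [self._mkfit(10.0, 0.6, extreme=True)] * 51 + [
            self._mkfit(10.0, 0.6)
        ] * 49
        s = summarize(fits, baseline)
        assert not s.valid
        assert math.isnan(s.accuracy["R"])

    def test_exclusion_is_order_independent(self, baseline, rng):
        fits = [
            self._mkfit(8.0 + i * 0.1, 0.5, extreme=(i % 3 == 0)) for i in range(30)
        ]
        s1 = summarize(fits, baseline)
        shuffled = list(fits)
        rng.shuffle(shuffled)
        s2 = summarize(shuffled, baseline)
        assert s1.accuracy["R"] == pytest.approx(s2.accuracy["R"], rel=1e-12)
        assert s1.precision["R"] == pytest.approx(s2.precision["R"], rel=1e-12)
        assert s1.valid_fraction == s2.valid_fraction


class TestEnsembleFitting:
    def test_precision_improves_with_snr(self, baseline, d_opt_80):
        """Accuracy and precision both tighten as SNR rises."""
        prec = {}
        acc = {}
        for snr in (30, 500):
            rng = np.random.default_rng(99)
            noise = NoiseModel(snr=snr)
            ens = simulate_ensemble(baseline, d_opt_80, noise, 80, rng)
            fits = fit_ensemble(
                ens, d_opt_80, noise, fixed_diffusivities=(1.0, 2.0),
                n_starts=8, rng=rng,
            )
            s = summarize(fits, baseline)
            prec[snr] = s.precision
            acc[snr] = s.accuracy
        assert prec[500]["R"] < prec[30]["R"]
        assert prec[500]["f_i"] < prec[30]["f_i"]
        assert abs(acc[500]["R"]) < abs(acc[30]["R"])

    def test_se_r_decreases_with_volume_fraction(self, d_opt_80):
        """Radius precision is better in dense tissue (higher f_i), while
        f_i precision is better at low f_i."""
        prec = {}
        for fi in (0.2, 0.6):
            rng = np.random.default_rng(7)
            noise = NoiseModel(snr=50)
            t = Tissue(R=10.0, f_i=fi, D_i=1.0, D_e=2.0)
            ens = simulate_ensemble(t, d_opt_80, noise, 120, rng)
            fits = fit_ensemble(
                ens, d_opt_80, noise, fixed_diffusivities=(1.0, 2.0),
                n_starts=8, rng=rng,
            )
            prec[fi] = summarize(fits, t).precision
        assert prec[0.6]["R"] < prec[0.2]["R"]
        assert prec[0.2]["f_i"] < prec[0.6]["f_i"]

    def test_deterministic_given_seed(self, baseline, d_opt_80):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            noise = NoiseModel(snr=80)
            ens = simulate_ensemble(baseline, d_opt_80, noise, 10, rng)
            fits = fit_ensemble(
                ens, d_opt_80, noise, fixed_diffusivities=(1.0, 2.0),
                n_starts=5, rng=rng,
            )
            out.append([f.estimates["R"] for f in fits])
        assert out[0] == out[1]
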