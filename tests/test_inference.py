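"""Lifetime estimation, bootstrap, Bell fits, force histograms, sigmoids."""

import numpy as np
import pytest

from dimerforce import (
    BellParams,
    BootstrapConfig,
    DwellRecord,
    bell_rate,
    bootstrap_rates,
    fit_bell,
    fit_force_histogram,
    fit_lifetime,
    fit_redimerization,
    frame_to_dwells,
    generate_dwells,
)
from dimerforce.inference import fit_exponential_mixture

KBT = 4.075


def records(dwells, censored=None, force=10.0):
    censored = censored or [False] * len(dwells)
    return [DwellRecord(force=force, dwell=d, censored=c) for d, c in zip(dwells, censored)]


class TestFitLifetime:
    def test_uncensored_mean(self):
        est = fit_lifetime(records([2.0, 2.0, 2.0]))
        assert est.tau == pytest.approx(2.0)
        assert est.k_rupture * est.tau == pytest.approx(1.0)

    def test_censored_closed_form(self):
        # one 5 s rupture plus one 20 s censored hold: tau = 25 s
        est = fit_lifetime(records([5.0, 20.0], censored=[False, True]))
        assert est.tau == pytest.approx(25.0)
        assert est.n_censored == 1

    def test_all_censored_flagged_unbounded(self):
        est = fit_lifetime(records([10.0, 10.0], censored=[True, True]))
        assert est.unbounded
        assert np.isinf(est.tau)

    def test_sampling_consistency(self, rng):
        t = rng.exponential(10.0, 5000)
        est = fit_lifetime(records(list(t)))
        assert est.tau == pytest.approx(10.0, abs=3 * 10.0 / np.sqrt(5000))

    def test_curve_estimator_close_to_mle(self, rng):
        t = list(rng.exponential(5.0, 300))
        mle = fit_lifetime(records(t)).tau
        curve = fit_lifetime(records(t), estimator="curve").tau
        assert curve == pytest.approx(mle, rel=0.1)


class TestBootstrap:
    def test_identical_dwells_zero_sd(self):
        est = bootstrap_rates(records([3.0] * 10), BootstrapConfig(rng_seed=1))
        assert est.tau_sd == pytest.approx(0.0, abs=1e-12)

    def test_bit_identical_under_fixed_seed(self, rng):
        data = records(list(rng.exponential(4.0, 40)))
        a = bootstrap_rates(data, BootstrapConfig(rng_seed=9))
        b = bootstrap_rates(data, BootstrapConfig(rng_seed=9))
        np.testing.assert_array_equal(a.bootstrap_k, b.bootstrap_k)
        assert a.tau == b.tau and a.k_sd == b.k_sd

    def test_sd_scales_like_sampling_error(self, rng):
        # the bootstrap sd estimates the sampling sd of tau-hat ~ tau/sqrt(N)
        data = records(list(rng.exponential(10.0, 200)))
        est = bootstrap_rates(data, BootstrapConfig(rng_seed=2))
        ref = 10.0 / np.sqrt(200)
        assert ref / 2 <= est.tau_sd <= ref * 2

    def test_converges_to_point_mle_for_large_m(self, rng):
        data = records(list(rng.exponential(7.0, 100)))
        mle = fit_lifetime(data).k_rupture
        est = bootstrap_rates(data, BootstrapConfig(n_resamples=500, rng_seed=3))
        assert est.k_rupture == pytest.approx(mle, rel=0.02)

    def test_degenerate_resamples_redrawn(self):
        # heavy censoring: some resamples are all-censored and get redrawn
        data = records([1.0, 8.0, 8.0, 8.0], censored=[False, True, True, True])
        est = bootstrap_rates(data, BootstrapConfig(rng_seed=4))
        assert np.all(np.isfinite(est.bootstrap_k))

    def test_validation(self):
        with pytest.raises(ValueError):
            bootstrap_rates(records([1.0]))
        with pytest.raises(ValueError):
            BootstrapConfig(n_resamples=1)


class TestFitBell:
    def test_noiseless_exact_recovery(self):
        true = BellParams(1e-3, 0.5)
        pts = [(f, bell_rate(true, f), None) for f in (10.0, 20.0, 30.0, 40.0)]
        fit = fit_bell(pts)
        assert fit.params.k0 == pytest.approx(1e-3, rel=1e-9)
        assert fit.params.delta == pytest.approx(0.5, rel=1e-9)

    def test_two_points_determine_line(self):
        true = BellParams(0.01, 1.1)
        pts = [(5.0, bell_rate(true, 5.0), None), (25.0, bell_rate(true, 25.0), None)]
        fit = fit_bell(pts)
        assert fit.params.delta == pytest.approx(1.1, rel=1e-9)

    def test_shift_equivariance(self):
        # shifting forces by c multiplies k0 by exp(-delta c / kBT),
        # leaving delta unchanged
        true = BellParams(1e-3, 0.8)
        c = 7.0
        pts = [(f, bell_rate(true, f), None) for f in (10.0, 20.0, 30.0)]
        shifted = [(f + c, k, None) for f, k, _ in pts]
        a, b = fit_bell(pts), fit_bell(shifted)
        assert b.params.delta == pytest.approx(a.params.delta, rel=1e-9)
        assert b.params.k0 == pytest.approx(
            a.params.k0 * np.exp(-0.8 * c / KBT), rel=1e-6
        )

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_bell([(10.0, 0.0, None), (20.0, 1.0, None)])

    def test_end_to_end_recovery_within_two_se(self):
        true = BellParams(1e-3, 0.8)
        pts = []
        for i, f in enumerate((25.0, 30.0, 35.0, 40.0, 45.0)):
            d = generate_dwells(true, f, 50, rng_seed=300 + i)
            est = bootstrap_rates(frame_to_dwells(d), BootstrapConfig(rng_seed=i))
            pts.append((f, est.k_rupture, est.k_sd))
        fit = fit_bell(pts)
        assert abs(fit.params.delta - 0.8) <= 2 * fit.delta_se


class TestForceHistogram:
    def test_single_gaussian(self, rng):
        forces = rng.normal(50.0, 5.0, 2000)
        (peak,) = fit_force_histogram(forces, 1)
        assert peak.mean == pytest.approx(50.0, abs=0.4)
        assert peak.sd == pytest.approx(5.0, rel=0.1)

    def test_two_separated_modes(self, rng):
        forces = np.concatenate(
            [rng.normal(40.0, 3.0, 1200), rng.normal(65.0, 3.0, 800)]
        )
        lo, hi = fit_force_histogram(forces, 2, rng_seed=0)
        assert lo.mean == pytest.approx(40.0, abs=1.0)
        assert hi.mean == pytest.approx(65.0, abs=1.0)
        assert lo.weight == pytest.approx(0.6, abs=0.05)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_force_histogram([5.0] * 50, 1)
        with pytest.raises(ValueError):
            fit_force_histogram([1.0, 2.0], 1)


class TestRedimerization:
    def test_noiseless_round_trip(self):
        from dimerforce import RedimerCurve

        true = RedimerCurve(Fc=2.7, delta_x=5.0)
        F = np.linspace(1.0, 5.0, 15)
        fit = fit_redimerization(list(zip(F, true.redimerization_probability(F))))
        assert fit.Fc == pytest.approx(2.7, abs=1e-6)
        assert fit.delta_x == pytest.approx(5.0, rel=1e-4)
        assert fit.redimerization_probability(fit.Fc) == pytest.approx(0.5)

    def test_complement_identity(self):
        from dimerforce import RedimerCurve

        curve = RedimerCurve(Fc=3.0, delta_x=4.0)
        F = np.linspace(0, 10, 30)
        total = curve.rupture_probability(F) + curve.redimerization_probability(F)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_noisy_recovery(self, rng):
        from dimerforce import RedimerCurve

        true = RedimerCurve(Fc=2.7, delta_x=5.0)
        F = np.linspace(1.0, 5.0, 25)
        P = np.clip(true.redimerization_probability(F) + rng.normal(0, 0.05, F.size), 0, 1)
        fit = fit_redimerization(list(zip(F, P)))
        assert fit.Fc == pytest.approx(2.7, abs=0.2)

    def test_validation(self):
        with pytest.raises(ValueError):
            fit_redimerization([(1.0, 0.5), (2.0, 0.4)])
        with pytest.raises(ValueError):
            fit_redimerization([(1.0, 1.5), (2.0, 0.4), (3.0, 0.2)])


def test_exponential_mixture_separates_rates(rng):
    t = np.concatenate([rng.exponential(1.0, 600), rng.exponential(100.0, 400)])
    comps = fit_exponential_mixture(t, 2, rng_seed=1)
    (k_fast, w_fast), (k_slow, w_slow) = comps[::-1]
    assert k_fast == pytest.approx(1.0, rel=0.3)
    assert k_slow == pytest.approx(0.01, rel=0.3)
    assert w_fast == pytest.approx(0.6, abs=0.1)
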