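"""MSD estimation, through-origin diffusivity fits, anomalous diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crowddiff as cd
from crowddiff.montecarlo import EnsembleRecord, WalkConfig
from crowddiff.msd import confidence_interval, estimate_msd, fit_de, loglog_diagnostic


def _manual_ensemble(times, sq_disp, seed=0):
    cfg = WalkConfig(
        model="wiener", rho=0.0, n_walks=sq_disp.shape[0],
        n_record=len(times), t_max=float(times[-1]), seed=seed,
    )
    return EnsembleRecord(config=cfg, times=np.asarray(times), sq_disp=np.asarray(sq_disp))


class TestEstimateMSD:
    def test_stationary_walkers(self):
        times = np.linspace(0, 1, 5)
        ens = _manual_ensemble(times, np.zeros((4, 5)))
        curve = estimate_msd(ens)
        assert np.all(curve.msd == 0.0)
        assert np.all(curve.stderr == 0.0)

    def test_two_opposite_walkers(self):
        # displacements d and -d have identical squared displacement d^2
        times = np.linspace(0, 1, 4)
        d2 = 2.25
        ens = _manual_ensemble(times, np.full((2, 4), d2))
        curve = estimate_msd(ens)
        assert np.all(curve.msd == d2)
        assert np.all(curve.stderr == 0.0)  # two identical observations

    def test_single_walk_rejected(self):
        ens = _manual_ensemble(np.linspace(0, 1, 3), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            estimate_msd(ens)

    def test_free_diffusion_msd_over_t_is_six(self):
        cfg = WalkConfig(model="wiener", rho=0.0, n_walks=10_000, seed=41)
        ens = cd.simulate_wiener(cfg)
        curve = estimate_msd(ens)
        ratio = curve.msd[1:] / curve.times[1:]
        assert abs(ratio.mean() - 6.0) < 0.1
        assert np.max(np.abs(ratio - 6.0)) < 0.3


class TestFitDe:
    def test_exact_line(self):
        times = np.linspace(0, 10, 20)
        ens = _manual_ensemble(times, np.tile(6.0 * times, (50, 1)))
        est = confidence_interval(ens)
        assert est.de == pytest.approx(1.0, rel=1e-12)
        assert est.ci_halfwidth == pytest.approx(0.0, abs=1e-12)

    def test_scaled_line(self):
        times = np.linspace(0, 10, 20)
        curve = cd.MSDCurve(times=times, msd=3.0 * times, stderr=np.zeros(20), n_walks=10)
        assert fit_de(curve).de == pytest.approx(0.5, rel=1e-12)

    @given(slope=st.floats(0.1, 50.0))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_through_origin_recovery(self, slope):
        times = np.linspace(0, 4, 17)
        curve = cd.MSDCurve(times=times, msd=slope * times, stderr=np.zeros(17), n_walks=10)
        assert fit_de(curve).slope == pytest.approx(slope, rel=1e-12)

    def test_degenerate_inputs(self):
        times = np.linspace(0, 1, 10)
        curve = cd.MSDCurve(times=times, msd=np.zeros(10), stderr=np.zeros(10), n_walks=10)
        with pytest.raises(ValueError):
            fit_de(curve)
        short = cd.MSDCurve(times=times[:2], msd=times[:2], stderr=np.zeros(2), n_walks=10)
        with pytest.raises(ValueError):
            fit_de(short)

    def test_fit_range_restriction(self):
        times = np.linspace(0, 10, 50)
        # early transient above the asymptote, linear tail of slope 3
        msd = 3.0 * times + 2.0 * (1 - np.exp(-times))
        curve = cd.MSDCurve(times=times, msd=msd, stderr=np.zeros(50), n_walks=10)
        full = fit_de(curve)
        tail = fit_de(curve, fit_range=(5.0, 10.0))
        assert full.slope > 3.0
        assert abs(tail.slope - 3.0) < abs(full.slope - 3.0)


class TestConfidenceInterval:
    def test_identical_walks_zero_width(self):
        times = np.linspace(0, 5, 10)
        ens = _manual_ensemble(times, np.tile(6.0 * times, (100, 1)))
        est = confidence_interval(ens)
        assert est.ci_halfwidth == pytest.approx(0.0, abs=1e-14)

    def test_halfwidth_scales_inverse_sqrt_n(self):
        rng = np.random.default_rng(9)
        times = np.linspace(0, 5, 25)
        slopes = rng.normal(6.0, 0.8, size=10_000)
        sq = slopes[:, None] * times[None, :]
        w_small = confidence_interval(_manual_ensemble(times, sq[:1000])).ci_halfwidth
        w_large = confidence_interval(_manual_ensemble(times, sq)).ci_halfwidth
        assert w_small / w_large == pytest.approx(np.sqrt(10.0), rel=0.15)

    def test_small_ensemble_warns(self):
        times = np.linspace(0, 5, 10)
        rng = np.random.default_rng(10)
        sq = rng.normal(6.0, 0.5, size=(10, 1)) * times[None, :]
        with pytest.warns(UserWarning):
            confidence_interval(_manual_ensemble(times, sq))

    def test_bootstrap_agrees_with_perwalk(self):
        rng = np.random.default_rng(11)
        times = np.linspace(0, 5, 25)
        sq = rng.normal(6.0, 0.8, size=(2000, 1)) * times[None, :]
        ens = _manual_ensemble(times, sq)
        a = confidence_interval(ens, method="perwalk")
        b = confidence_interval(ens, method="bootstrap")
        assert a.ci_halfwidth == pytest.approx(b.ci_halfwidth, rel=0.25)


class TestLoglogDiagnostic:
    def test_pure_diffusion_single_segment(self):
        times = np.linspace(0, 10, 100)
        curve = cd.MSDCurve(times=times, msd=6.0 * times, stderr=np.zeros(100), n_walks=10)
        fit = loglog_diagnostic(curve, n_segments=1)
        assert fit.exponents[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.amplitudes[0] == pytest.approx(6.0, rel=1e-9)

    def test_power_law_recovery(self):
        times = np.logspace(-2, 2, 80)
        curve = cd.MSDCurve(
            times=times, msd=4.0 * times**0.8, stderr=np.zeros(80), n_walks=10
        )
        fit = loglog_diagnostic(curve, n_segments=1)
        assert fit.exponents[0] == pytest.approx(0.8, abs=0.02)
        assert fit.amplitudes[0] == pytest.approx(4.0, rel=0.02)

    def test_two_regime_transition(self):
        # subdiffusive early regime crossing over to normal diffusion,
        # continuous at the knot
        t = np.logspace(-2, 2, 120)
        tc = 1.0
        msd = np.where(t < tc, 6.0 * t**0.7, 6.0 * t)
        curve = cd.MSDCurve(times=t, msd=msd, stderr=np.zeros(120), n_walks=10)
        fit = loglog_diagnostic(curve, n_segments=2, n_candidates=25)
        assert fit.exponents[0] == pytest.approx(0.7, abs=0.05)
        assert fit.exponents[1] == pytest.approx(1.0, abs=0.05)
        assert 0.3 < fit.breakpoints[1] < 3.0

    def test_requires_positive_msd(self):
        times = np.linspace(0, 1, 10)
        curve = cd.MSDCurve(times=times, msd=np.zeros(10), stderr=np.zeros(10), n_walks=10)
        with pytest.raises(ValueError):
            loglog_diagnostic(curve)

    def test_requires_enough_points(self):
        times = np.linspace(0.1, 1, 3)
        curve = cd.MSDCurve(times=times, msd=times, stderr=np.zeros(3), n_walks=10)
        with pytest.raises(ValueError):
            loglog_diagnostic(curve, n_segments=2)


def test_reflected_wiener_plateaus(wiener_06):
    """Obstructed-but-normal diffusion: ln(MSD/t) starts near ln(6 D0) and
    settles at ln(6 De) < ln 6, with early and late local exponents ~1."""
    curve = estimate_msd(wiener_06)
    y = np.log(curve.msd[1:] / curve.times[1:])
    assert y[0] < np.log(6.0) + 0.05  # starts at/below the free plateau
    late = y[-25:]
    de_est = confidence_interval(wiener_06).de
    assert np.mean(late) == pytest.approx(np.log(6.0 * de_est), abs=0.05)
    assert np.mean(late) < np.log(6.0)
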