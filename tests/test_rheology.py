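"""Rheology contracts: GSER conversions, plateau moduli, viscometry, Faxén."""
from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microrheo.core import InvalidArgumentError, MicrorheoError
from microrheo.msd import (MSDCurve, NPAFCurve, compute_npaf, plateau_variance)
from microrheo.rheology import (ComplianceCurve, attach_tau_star,
                                compliance_to_modulus, delta_plateau,
                                directional_viscosity, faxen_prediction,
                                msd_to_compliance, plateau_modulus,
                                relative_viscosity_npaf,
                                trap_stiffness_equipartition)
from microrheo.simulate import (GelModelParams, TrapParams, WallModel,
                                simulate_gel_bead, simulate_near_wall,
                                simulate_trapped_bead)


def _mid_band(omega):
    lw = np.log(omega)
    span = lw[-1] - lw[0]
    return (lw > lw[0] + 0.1 * span) & (lw < lw[-1] - 0.1 * span)


class TestMsdToCompliance:
    def test_direct_evaluation(self, ctx):
        """MSD = 1e-15 m² maps to J = πa·MSD/k_BT ≈ 2.29 Pa⁻¹."""
        curve = MSDCurve(lags=np.geomspace(0.01, 1, 12),
                         values=np.full(12, 1e-15), n_pairs=np.full(12, 100),
                         dimension=2, context=ctx, frame_rate=100.0)
        comp = msd_to_compliance(curve, terminal_slope=0.0)
        assert comp.J[0] == pytest.approx(2.29, rel=0.01)

    def test_zero_msd_zero_compliance(self, ctx):
        curve = MSDCurve(lags=np.geomspace(0.01, 1, 12),
                         values=np.zeros(12), n_pairs=np.full(12, 100),
                         dimension=2, context=ctx, frame_rate=100.0)
        comp = msd_to_compliance(curve, terminal_slope=0.0)
        assert np.all(comp.J == 0.0)

    def test_dimension_corrected_equals_paper_at_d3(self, ctx):
        curve = MSDCurve(lags=np.geomspace(0.01, 1, 12),
                         values=np.geomspace(1e-16, 1e-15, 12),
                         n_pairs=np.full(12, 100), dimension=3, context=ctx,
                         frame_rate=100.0)
        paper = msd_to_compliance(curve, "paper", terminal_slope=0.0)
        corrected = msd_to_compliance(curve, "dimension_corrected",
                                      terminal_slope=0.0)
        assert np.allclose(paper.J, corrected.J, rtol=1e-12)


class TestComplianceToModulus:
    def test_kelvin_voigt_oracle(self, ctx):
        """J(t) = (1/G0)(1 − e^(−tG0/η)) recovers G* = G0 + iωη in mid-band."""
        G0, eta = 5.0, 0.01
        t = np.geomspace(1e-5, 10, 6000)
        J = (1 / G0) * (1 - np.exp(-t * G0 / eta))
        comp = ComplianceCurve(t=t, J=J, terminal_slope=0.0, context=ctx,
                               dimension=2)
        mod = compliance_to_modulus(comp)
        mid = _mid_band(mod.omega)
        assert np.allclose(mod.G_prime[mid], G0, rtol=0.05)
        assert np.allclose(mod.G_doubleprime[mid], eta * mod.omega[mid], rtol=0.05)
        # plateau ordering: G' > G'' at low frequency
        assert mod.G_prime[0] > mod.G_doubleprime[0]

    def test_newtonian_oracle(self, ctx):
        eta = 0.01
        t = np.geomspace(1e-5, 10, 6000)
        comp = ComplianceCurve(t=t, J=t / eta, terminal_slope=1 / eta,
                               context=ctx, dimension=2)
        mod = compliance_to_modulus(comp)
        mid = _mid_band(mod.omega)
        assert np.allclose(mod.G_doubleprime[mid], eta * mod.omega[mid], rtol=0.05)
        assert np.all(np.abs(mod.G_prime[mid]) < 0.05 * eta * mod.omega[mid])

    def test_out_of_band_frequencies_trimmed(self, ctx):
        t = np.geomspace(1e-3, 1, 100)
        comp = ComplianceCurve(t=t, J=t / 0.01, terminal_slope=100.0,
                               context=ctx, dimension=1)
        with pytest.warns(UserWarning, match="trimming"):
            mod = compliance_to_modulus(comp, omega=np.array([1e-6, 10.0, 1e9]))
        assert len(mod.omega) == 1


class TestPlateauModulus:
    def test_direct_evaluation(self, ctx):
        """⟨r²⟩ = 1e-15 m² gives G₀′ = k_BT/(πa·⟨r²⟩) ≈ 0.437 Pa (literal)."""
        res = plateau_modulus(1.0e-15, ctx, convention="paper")
        assert res.G0_prime == pytest.approx(0.437, rel=0.01)

    def test_reciprocal_scaling(self, ctx):
        a = plateau_modulus(1e-15, ctx).G0_prime
        b = plateau_modulus(2e-15, ctx).G0_prime
        assert b == pytest.approx(a / 2, rel=1e-12)

    def test_gel_round_trip_dimension_corrected(self, ctx):
        """simulate (G0 = 5 Pa) → variance → plateau_modulus recovers G0 within 15%."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = simulate_gel_bead(ctx, GelModelParams(5.0, 0.89e-3),
                                     dt=1 / 5000, n_steps=150_000, seed=41)
        var = plateau_variance(traj)  # 2-axis sum
        res = plateau_modulus(var, ctx, convention="dimension_corrected",
                              dimension=2)
        assert res.G0_prime == pytest.approx(5.0, rel=0.15)

    def test_invalid_variance(self, ctx):
        with pytest.raises(InvalidArgumentError):
            plateau_modulus(0.0, ctx)


class TestDeltaPlateau:
    @pytest.mark.parametrize("g_t,g_1,expect",
                             [(2.0, 1.0, 1.0), (0.5, 1.0, -0.5), (3.3, 3.3, 0.0)])
    def test_proportional_change(self, g_t, g_1, expect):
        assert delta_plateau(g_t, g_1) == pytest.approx(expect)


class TestTrapStiffness:
    @pytest.mark.parametrize("axis,kappa,tol", [("x", 3.2e-7, 0.05),
                                                ("z", 6.7e-8, 0.17)])
    def test_equipartition_recovery(self, ou_trajectory, axis, kappa, tol):
        """κ̂ = k_BT/⟨x²⟩ recovers the instrument stiffnesses.

        Single-record tolerances are 3× the estimator's standard error
        (N_eff ≈ T/2τ_c: ~1.7% for x, ~5.5% for the soft z axis); the 5%
        multi-seed recovery check lives in the acceptance suite."""
        assert (trap_stiffness_equipartition(ou_trajectory, axis)
                == pytest.approx(kappa, rel=tol))

    def test_variance_doubling_halves_kappa(self, ou_trajectory):
        doubled = ou_trajectory.with_positions(np.sqrt(2) * ou_trajectory.positions)
        assert (trap_stiffness_equipartition(doubled, "x")
                == pytest.approx(trap_stiffness_equipartition(ou_trajectory, "x") / 2,
                                 rel=1e-9))


class TestNPAFViscometry:
    def test_analytic_exponential_reads_exactly(self):
        """NPAF = exp(−τ*/2) crosses e⁻¹ at τ* = 2 exactly."""
        lags = np.linspace(0.0, 10.0, 2001)
        curve = NPAFCurve(lags=lags, values=np.exp(-lags / 2.0))
        curve.tau_star = lags
        assert relative_viscosity_npaf(curve) == pytest.approx(2.0, rel=1e-6)

    def test_water_reads_unity(self, ou_trajectory, ctx):
        """OU in water: η_r = 1 ± 0.05 from the NPAF intercept."""
        kappa = trap_stiffness_equipartition(ou_trajectory, "x")
        npaf = compute_npaf(ou_trajectory, "x", method="fft", max_lag=2000)
        attach_tau_star(npaf, kappa, ctx)
        assert relative_viscosity_npaf(npaf) == pytest.approx(1.0, abs=0.05)

    def test_double_viscosity_medium(self, ctx, trap):
        traj = simulate_trapped_bead(ctx, trap, 1 / 300, 300_000, seed=43,
                                     medium_viscosity=2 * 0.89e-3)
        kappa = trap_stiffness_equipartition(traj, "x")
        npaf = compute_npaf(traj, "x", method="fft", max_lag=3000)
        attach_tau_star(npaf, kappa, ctx)
        assert relative_viscosity_npaf(npaf) == pytest.approx(2.0, rel=0.10)

    def test_no_crossing_is_error(self):
        lags = np.linspace(0.0, 1.0, 100)
        curve = NPAFCurve(lags=lags, values=np.exp(-lags / 100.0))
        curve.tau_star = lags
        with pytest.raises(MicrorheoError, match="longer"):
            relative_viscosity_npaf(curve)


@pytest.fixture(scope="module")
def fast_trap_traj(ctx, trap):
    """Trapped-bead record at 1 kHz: resolves the early-time Fickian window."""
    return simulate_trapped_bead(ctx, trap, 1 / 1000, 200_000, seed=45)


class TestDirectionalViscosity:
    def test_water_within_10pc(self, fast_trap_traj):
        res = directional_viscosity(fast_trap_traj, np.pi / 3, 0.7)
        assert res.eta_relative == pytest.approx(1.0, rel=0.10)

    def test_x_axis_matches_scalar_msd_pipeline(self, fast_trap_traj, ctx):
        from microrheo.msd import compute_msd
        res = directional_viscosity(fast_trap_traj, np.pi / 2, 0.0)
        n_lags = int(round(res.fit_window[1] * 1000))
        curve = compute_msd(fast_trap_traj, axes=("x",), lag_scheme="all",
                            max_lag_fraction=n_lags / fast_trap_traj.n_samples)
        slope = np.linalg.lstsq(curve.lags[:, None], curve.values, rcond=None)[0][0]
        assert res.D == pytest.approx(slope / 2, rel=1e-9)

    def test_near_wall_anisotropy(self, ctx, trap):
        """Perpendicular apparent viscosity exceeds parallel near a wall."""
        traj = simulate_near_wall(ctx, trap, WallModel(6e-6), 1 / 1000,
                                  150_000, seed=47)
        par = directional_viscosity(traj, np.pi / 2, 0.0).eta_relative
        perp = directional_viscosity(traj, 0.0, 0.0).eta_relative
        assert perp > par > 1.0

    def test_window_too_short_is_error(self, ctx, trap):
        traj = simulate_trapped_bead(ctx, trap, 1 / 300, 20_000, seed=48)
        with pytest.raises(InvalidArgumentError, match="< 5"):
            directional_viscosity(traj, np.pi / 2, 0.0, window_fraction=0.02)


class TestFaxen:
    def test_far_field_limits(self, ctx):
        assert faxen_prediction(ctx, 1.0, "parallel") == pytest.approx(1.0, abs=1e-5)
        assert faxen_prediction(ctx, 1.0, "perpendicular") == pytest.approx(1.0,
                                                                            abs=1e-5)

    def test_half_radius_ratio_parallel(self, ctx):
        """a/h = 0.5 gives the documented truncated-series value ≈ 1.386."""
        assert faxen_prediction(ctx, 6e-6, "parallel") == pytest.approx(1.386,
                                                                        rel=1e-3)

    def test_perpendicular_exceeds_parallel(self, ctx):
        for h in np.geomspace(3.2e-6, 1e-4, 12):
            assert (faxen_prediction(ctx, h, "perpendicular")
                    > faxen_prediction(ctx, h, "parallel"))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(log_h=st.floats(-5.45, -3.0))
    def test_monotone_increase_toward_wall(self, ctx, log_h):
        h = 10 ** log_h
        closer = faxen_prediction(ctx, h, "parallel")
        farther = faxen_prediction(ctx, h * 1.5, "parallel")
        assert closer > farther

    def test_contact_rejected(self, ctx):
        with pytest.raises(InvalidArgumentError):
            faxen_prediction(ctx, 3e-6, "parallel")


class TestPipelineConsistency:
    def test_gel_full_pipeline_matches_plateau_variance(self, ctx):
        """Low-frequency G′ from MSD → J → G* agrees with the variance route
        within 20% on the same simulated gel trajectory."""
        from microrheo.msd import compute_msd, fit_stretched_biexponential
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = simulate_gel_bead(ctx, GelModelParams(5.0, 0.89e-3),
                                     dt=1 / 5000, n_steps=300_000, seed=49)
        curve = compute_msd(traj)
        fit = fit_stretched_biexponential(curve)
        smooth = MSDCurve(lags=curve.lags,
                          values=np.clip(fit(curve.lags), 1e-22, None),
                          n_pairs=curve.n_pairs, dimension=curve.dimension,
                          context=ctx, frame_rate=curve.frame_rate)
        comp = msd_to_compliance(smooth, convention="dimension_corrected",
                                 terminal_slope=0.0)
        mod = compliance_to_modulus(comp)
        g0_pipeline = mod.G_prime[0]
        g0_variance = plateau_modulus(plateau_variance(traj), ctx,
                                      convention="dimension_corrected",
                                      dimension=2).G0_prime
        assert g0_pipeline == pytest.approx(g0_variance, rel=0.20)

    def test_npaf_and_directional_agree_on_newtonian(self, ctx, trap):
        """The two viscometry routes agree within 10% on one trajectory."""
        traj = simulate_trapped_bead(ctx, trap, 1 / 1000, 300_000, seed=50)
        kappa = trap_stiffness_equipartition(traj, "x")
        npaf = compute_npaf(traj, "x", method="fft", max_lag=3000)
        attach_tau_star(npaf, kappa, ctx)
        eta_npaf = relative_viscosity_npaf(npaf)
        eta_dir = directional_viscosity(traj, np.pi / 2, 0.0).eta_relative
        assert eta_npaf == pytest.approx(eta_dir, rel=0.10)
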