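import math

import numpy as np
import pytest

import sludgekit as sk
from sludgekit.errors import (
    BoundaryMinimumWarning,
    DomainError,
    NoLinearZoneError,
    NoOnsetError,
    ValidationError,
)
from sludgekit.settling import (
    branch_crossover,
    compression_velocity,
    compression_velocity_at_time,
    detect_compression_onset,
    extract_hindered_velocity,
    fit_vesilind,
    flux_curve,
    integrated_velocity,
    limiting_flux,
)


class TestBatchSettlingCurve:
    def test_rejects_rising_heights(self):
        with pytest.raises(ValidationError):
            sk.BatchSettlingCurve(
                times=[0, 1, 2, 3], heights=[1.0, 0.8, 0.95, 0.9], X0=3, x0=1
            )

    def test_rejects_heights_above_x0(self):
        with pytest.raises(ValidationError):
            sk.BatchSettlingCurve(times=[0, 1], heights=[1.2, 1.0], X0=3, x0=1)


class TestExtractHinderedVelocity:
    def test_exact_line(self, exact_line_curve):
        # 0.02 m/min * 60 = 1.2 m/h
        assert extract_hindered_velocity(exact_line_curve) == pytest.approx(1.2)

    def test_two_phase_with_noise(self):
        curve, truth = sk.gen_batch_settling_curve(
            v_hindered=0.01, t_star=15.0, b=0.05, x0=1.0, X0=6.6,
            noise_level=0.005, seed=3,
        )
        v = extract_hindered_velocity(curve)
        assert v == pytest.approx(truth["v_hindered_m_per_h"], rel=0.05)

    def test_pure_power_decay_has_no_linear_zone(self):
        t = np.geomspace(1.0, 100.0, 8)
        curve = sk.BatchSettlingCurve(times=t, heights=0.9 / t, X0=3.0, x0=1.0)
        with pytest.raises(NoLinearZoneError):
            extract_hindered_velocity(curve)


class TestFitVesilind:
    # concentrations of the five batch tests (g/L)
    X_TESTS = (2.010, 3.025, 4.100, 5.180, 6.425)

    def test_noiseless_inversion(self):
        v0, n = 11.043, 0.364
        pts = [(x, v0 * math.exp(-n * x)) for x in self.X_TESTS]
        fit = fit_vesilind(pts)
        assert fit.v0 == pytest.approx(v0, rel=1e-6)
        assert fit.n == pytest.approx(n, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_concentration_limit(self, vesilind):
        assert float(vesilind.velocity(0.0)) == pytest.approx(vesilind.v0)

    def test_value_at_blanket_concentration(self, vesilind):
        assert float(vesilind.velocity(6.6)) == pytest.approx(1.000, abs=0.005)

    def test_rejects_non_positive_velocity(self):
        with pytest.raises(ValidationError):
            fit_vesilind([(1.0, 1.0), (2.0, -0.5), (3.0, 0.1)])

    def test_rejects_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_vesilind([(1.0, 1.0), (2.0, 0.5)])


class TestCompressionVelocity:
    def test_unit_base_of_power_law(self, plant5_law):
        # at X = a the power factor is 1: v = b*x0*X0/a (m/min)
        v = compression_velocity(plant5_law, plant5_law.a, enforce_domain=False)
        assert v / 60.0 == pytest.approx(0.04727, abs=1e-5)
        assert v == pytest.approx(2.836, abs=0.001)

    def test_printed_exponent_magnitude(self, plant5_law):
        assert plant5_law.exponent == pytest.approx(22.5, abs=0.01)

    def test_domain_enforced_below_X0(self, plant5_law):
        with pytest.raises(DomainError):
            compression_velocity(plant5_law, 6.0)

    def test_strictly_decreasing(self, plant5_law):
        xs = np.linspace(6.6, 14.0, 60)
        vs = [compression_velocity(plant5_law, x) for x in xs]
        assert np.all(np.diff(vs) < 0)

    def test_matches_numeric_derivative_of_height(self, plant5_law):
        # v_cs = -dx/dt of the mass-balance height, by central difference
        fit = sk.PowerLawFit(
            a=plant5_law.a, b=plant5_law.b, r_squared=1.0, p_value=0.01, n_points=30
        )
        for t in (10.0, 30.0, 90.0):
            h = 1e-5
            dxdt = (
                sk.sludge_height(fit, 1.0, 6.6, t + h)
                - sk.sludge_height(fit, 1.0, 6.6, t - h)
            ) / (2 * h)
            v_model = compression_velocity_at_time(plant5_law, t) / 60.0
            assert v_model == pytest.approx(-dxdt, rel=1e-6)


class TestCompressionVelocityAtTime:
    def test_unit_time(self, plant5_law):
        assert compression_velocity_at_time(plant5_law, 1.0) == pytest.approx(
            plant5_law.prefactor * 60.0, rel=1e-12
        )

    def test_at_90_minutes(self, plant5_law):
        assert compression_velocity_at_time(plant5_law, 90.0) == pytest.approx(
            0.0255, abs=0.001
        )

    def test_algebraic_identity_with_concentration_form(self, plant5_law):
        for t in np.geomspace(1.0, 300.0, 25):
            X = plant5_law.a * t**plant5_law.b
            assert compression_velocity_at_time(plant5_law, t) == pytest.approx(
                compression_velocity(plant5_law, X, enforce_domain=False), rel=1e-12
            )

    def test_identity_over_random_parameter_draws(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            law = sk.CompressionLaw(
                a=rng.uniform(4, 12),
                b=rng.uniform(0.02, 0.3),
                x0=rng.uniform(0.3, 2.0),
                X0=rng.uniform(2, 8),
            )
            t = rng.uniform(1, 200)
            X = law.a * t**law.b
            assert compression_velocity_at_time(law, t) == pytest.approx(
                compression_velocity(law, X, enforce_domain=False), rel=1e-12
            )

    def test_domain_error(self, plant5_law):
        with pytest.raises(DomainError):
            compression_velocity_at_time(plant5_law, 0.5)


class TestDetectCompressionOnset:
    def test_constructed_transition(self):
        curve, truth = sk.gen_batch_settling_curve(
            v_hindered=0.01, t_star=20.0, b=0.0465, x0=1.0, X0=6.6,
            t_max=60.0, n_points=61, noise_level=0.0, seed=0,
        )
        est = detect_compression_onset(curve)
        assert est.t_c == pytest.approx(truth["t_star"], rel=0.15)
        assert est.X_c >= curve.X0 - 1e-9
        assert est.h_c <= curve.x0

    def test_seeded_ensemble_within_tolerance(self):
        n_ok = 0
        for seed in range(22):
            rng = np.random.default_rng(seed)
            t_star = rng.uniform(18.0, 28.0)
            v = rng.uniform(0.008, 0.013)
            curve, _ = sk.gen_batch_settling_curve(
                v_hindered=v, t_star=t_star, b=0.0465, x0=1.0, X0=6.6,
                t_max=60.0, n_points=61, noise_level=0.002, seed=seed + 100,
            )
            est = detect_compression_onset(curve)
            assert est.t_c == pytest.approx(t_star, rel=0.15)
            n_ok += 1
        assert n_ok == 22

    def test_symmetric_v_curve_vertical_bisector(self):
        # identical-magnitude tangent slopes in normalized coordinates:
        # bisector is vertical, intersection at the vertex abscissa
        # vertex at t=14: past the first third of the record (so only the
        # falling limb hosts the hindered window) yet before the log-time
        # tail cut (so the tail fit sees only the rising limb)
        t = np.linspace(0.0, 40.0, 41)
        s = 0.5 / 40.0
        h = np.where(t <= 14.0, 1.0 - s * t, 1.0 - s * 14 + s * (t - 14.0))
        curve = sk.BatchSettlingCurve(
            times=t, heights=h, X0=3.0, x0=1.0, height_tol=1.0
        )
        est = detect_compression_onset(curve)
        assert est.t_c == pytest.approx(14.0, abs=0.5)

    def test_straight_line_no_onset(self):
        t = np.linspace(0.0, 50.0, 20)
        curve = sk.BatchSettlingCurve(times=t, heights=1 - 0.01 * t, X0=3, x0=1)
        with pytest.raises(NoOnsetError):
            detect_compression_onset(curve)

    def test_flat_curve_no_onset(self):
        t = np.linspace(0.0, 90.0, 20)
        curve = sk.BatchSettlingCurve(times=t, heights=np.full(20, 0.8), X0=3, x0=1)
        with pytest.raises(NoOnsetError):
            detect_compression_onset(curve)

    def test_diagnostics_present(self):
        curve, _ = sk.gen_batch_settling_curve(
            v_hindered=0.01, t_star=20.0, b=0.0465, t_max=60.0, n_points=61
        )
        est = detect_compression_onset(curve)
        for key in ("hindered_window", "hindered_slope_m_per_min",
                    "compression_slope_m_per_min", "tangent_angle_rad"):
            assert key in est.diagnostics


class TestIntegratedVelocity:
    def test_hindered_branch(self, integrated_model):
        x = integrated_model.X_c / 2
        expect = integrated_model.vesilind.v0 * math.exp(
            -integrated_model.vesilind.n * x
        )
        assert integrated_velocity(integrated_model, x) == pytest.approx(expect)

    def test_compression_slower_than_hindered_at_onset(self, integrated_model):
        x_above = integrated_model.X_c * 1.001
        v_above = integrated_velocity(integrated_model, x_above)
        v_hindered_at_xc = float(
            integrated_model.vesilind.velocity(integrated_model.X_c)
        )
        assert v_above <= v_hindered_at_xc + 1e-12

    def test_profile_finite_positive_and_branchwise_monotone(self, integrated_model):
        xs = np.linspace(1.0, 14.0, 200)
        vs = np.array([integrated_velocity(integrated_model, x) for x in xs])
        assert np.all(np.isfinite(vs)) and np.all(vs > 0)
        below = xs <= integrated_model.X_c
        assert np.all(np.diff(vs[below]) < 0)
        assert np.all(np.diff(vs[~below]) < 0)

    def test_jump_reported_not_rescaled(self, vesilind, plant5_law):
        # with X_c at the blanket concentration the branches genuinely
        # disagree; the model reports the jump instead of hiding it
        model = sk.IntegratedSettlingModel(
            vesilind=vesilind, compression=plant5_law, X_c=6.6
        )
        assert abs(model.jump_at_onset) > 0.5

    def test_crossover_continuity(self, integrated_model):
        # X_c at the branch crossover makes the law continuous
        assert abs(integrated_model.jump_at_onset) < 1e-9


class TestFlux:
    def test_flux_vanishes_at_low_concentration(self, integrated_model):
        fc = flux_curve(integrated_model, 0.0, [1e-3, 1e-2])
        assert fc.flux_integrated[0] < 0.02
        assert fc.flux_integrated[0] < fc.flux_integrated[1]

    def test_gravity_flux_definition(self, integrated_model):
        xs = np.linspace(1.0, 12.0, 30)
        fc = flux_curve(integrated_model, 0.0, xs)
        expect = [integrated_velocity(integrated_model, x) * x for x in xs]
        assert fc.flux_integrated == pytest.approx(expect)

    def test_hindered_dominates_above_crossover(self, integrated_model):
        xs = np.linspace(integrated_model.X_c + 1e-6, 20.0, 100)
        fc = flux_curve(integrated_model, 0.0, xs)
        assert np.all(fc.flux_integrated <= fc.flux_hindered + 1e-12)

    def test_empty_grid_rejected(self, integrated_model):
        with pytest.raises(ValidationError):
            flux_curve(integrated_model, 0.0, [])

    def test_vesilind_gravity_flux_maximum_at_inverse_n(self, vesilind):
        # calculus identity: d(v0 e^{-nX} X)/dX = 0 at X = 1/n
        xs = np.linspace(0.01, 10.0, 20001)
        flux = vesilind.velocity(xs) * xs
        assert xs[np.argmax(flux)] == pytest.approx(1.0 / vesilind.n, abs=1e-3)

    def test_limiting_flux_ordering(self, integrated_model):
        lim = limiting_flux(integrated_model, u=0.3)
        assert lim.flux_integrated <= lim.flux_hindered + 1e-12
        assert lim.overestimate_fraction >= 0.0

    def test_limiting_flux_requires_positive_underflow(self, integrated_model):
        with pytest.raises(ValidationError):
            limiting_flux(integrated_model, u=0.0)

    def test_boundary_minimum_warns(self, integrated_model):
        with pytest.warns(BoundaryMinimumWarning):
            limiting_flux(integrated_model, u=0.3, X_max=integrated_model.X_c + 0.05)


class TestBranchCrossover:
    def test_velocities_agree_at_crossover(self, vesilind, plant5_law):
        xc = branch_crossover(vesilind, plant5_law)
        vh = float(vesilind.velocity(xc))
        vc = compression_velocity(plant5_law, xc, enforce_domain=False)
        assert vh == pytest.approx(vc, rel=1e-9)

    def test_no_crossover_raises(self, vesilind, plant5_law):
        with pytest.raises(DomainError):
            branch_crossover(vesilind, plant5_law, lo=20.0, hi=30.0)
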